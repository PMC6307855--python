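import numpy as np
import pytest

from glymeta.effects import EffectSize
from glymeta.records import StudyRecord


def mk_effect(d, v, dataset_id="x", n_t=6, n_c=6):
    """Effect size with explicit (d, v); arm sizes only matter for bookkeeping."""
    return EffectSize(dataset_id=dataset_id, d=d, v=v, method="cohen", n_t=n_t, n_c=n_c)


def mk_effects(ds, vs, prefix="s"):
    return [mk_effect(d, v, f"{prefix}{i + 1}") for i, (d, v) in enumerate(zip(ds, vs))]


@pytest.fixture
def fixture_effects():
    """Frozen five-study instance used for cross-checks against independent
    implementations (values also hard-coded in an external reference run)."""
    d = [-1.9, -0.4, -2.6, -1.1, 0.3]
    v = [0.45, 0.30, 0.62, 0.35, 0.28]
    return mk_effects(d, v)


@pytest.fixture
def base_record():
    def make(**overrides):
        defaults = dict(
            dataset_id="rec-1",
            species="mouse",
            ko_line="UIO",
            anesthesia="ketamine_xylazine",
            detection="fluorescence",
            injection_route="cisterna_magna",
            ctrl_mean=10.0, ctrl_disp=2.0, ctrl_disp_type="sd",
            ctrl_n_min=4, ctrl_n_max=4,
            ko_mean=7.0, ko_disp=2.0, ko_disp_type="sd",
            ko_n_min=4, ko_n_max=4,
        )
        defaults.update(overrides)
        return StudyRecord(**defaults)

    return make


@pytest.fixture
def study_csv(tmp_path):
    """Write a minimal well-formed study CSV; rows may override any cell."""
    header = (
        "dataset_id,species,ko_line,anesthesia,detection,injection_route,"
        "age_weeks_min,age_weeks_max,duration_min,"
        "ctrl_mean,ctrl_disp,ctrl_disp_type,ctrl_n,"
        "ko_mean,ko_disp,ko_disp_type,ko_n"
    )

    def write(rows, name="studies.csv"):
        path = tmp_path / name
        path.write_text(header + "\n" + "\n".join(rows) + "\n", encoding="utf-8")
        return path

    return write


def row(
    dataset_id,
    ctrl=(10.0, 2.0, "sd", "4"),
    ko=(7.0, 2.0, "sd", "4"),
    species="mouse",
    ko_line="UIO",
    anesthesia="ketamine_xylazine",
    detection="fluorescence",
    route="cisterna_magna",
    age=("8", "12"),
    duration="30",
):
    return ",".join(
        [
            dataset_id, species, ko_line, anesthesia, detection, route,
            age[0], age[1], duration,
            str(ctrl[0]), str(ctrl[1]), ctrl[2], ctrl[3],
            str(ko[0]), str(ko[1]), ko[2], ko[3],
        ]
    )
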