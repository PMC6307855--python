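"""End-to-end analysis orchestration and forest-plot data.

A single configuration document drives the whole pipeline the way the two
published models (cisterna-magna influx; intracerebral efflux) were run:
ingest -> normalize -> effect sizes -> random-effects pooling (primary,
with fixed-effect alongside for diagnostics) -> exclusion scenarios ->
one-at-a-time moderator screen. The report bundle embeds every active
setting (effect method, tau2 estimator, age rule, reference levels) so any
reproduction discrepancy is attributable, and contains no timestamps:
identical inputs give byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import __version__
from .effects import EffectSize, compute_effects, effects_frame
from .exceptions import ConfigError
from .model import Z_CRIT, MetaAnalysis, MetaAnalysisResults
from .moderators import DEFAULT_COVARIATES, run_moderator_screen
from .records import StudyRecord, load_dataset, normalize_record
from .sensitivity import leave_one_out_table, scenario_table

logger = logging.getLogger("glymeta")


@dataclass
class AnalysisConfig:
    """Configuration document for one full analysis run."""

    input: str
    effect_method: str = "cohen"
    tau2_method: str = "DL"
    age_rule: str = "midpoint"
    scenarios: dict = field(default_factory=dict)  # name -> list of dataset_ids
    moderators: dict = field(default_factory=dict)  # name -> reference level | None
    filter: dict = field(default_factory=dict)  # species / detection allow-lists
    output_dir: str | None = None
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        path = Path(path)
        text = path.read_text(encoding="utf-8")
        if path.suffix in (".yaml", ".yml"):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        if not isinstance(data, dict) or "input" not in data:
            raise ConfigError("analysis config must be a mapping with an 'input' key")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "moderators" in data and isinstance(data["moderators"], list):
            data["moderators"] = {name: None for name in data["moderators"]}
        return cls(**data)


def reduced_model_filter(
    records: Sequence[StudyRecord],
    species_allowed: Sequence[str] | None = None,
    detection_allowed: Sequence[str] | None = None,
) -> list[StudyRecord]:
    """Keep rows whose species and detection method are in the allow-lists.

    Mirrors restricting the efflux model to mouse experiments using
    fluorescence or radioactivity detection. ``None`` means no restriction.
    """
    kept, dropped = [], []
    for rec in records:
        ok = (species_allowed is None or rec.species in species_allowed) and (
            detection_allowed is None or rec.detection in detection_allowed
        )
        (kept if ok else dropped).append(rec)
    if dropped:
        logger.info("filter excluded: %s", ", ".join(r.dataset_id for r in dropped))
    return kept


def forest_data(
    pooled: MetaAnalysisResults, effects: Sequence[EffectSize]
) -> pd.DataFrame:
    """Per-study rows plus the summary (diamond) row, in input order."""
    if not effects:
        raise ConfigError("forest data needs at least one effect")
    rows = []
    for e, w in zip(effects, pooled.weights):
        rows.append(
            {
                "row": "study", "id": e.dataset_id, "est": e.d,
                "ci_low": e.d - Z_CRIT * e.se, "ci_high": e.d + Z_CRIT * e.se,
                "weight_pct": float(w), "model": "", "tau2": "",
                "i2": "", "Q": "", "p_Q": "",
            }
        )
    rows.append(
        {
            "row": "summary", "id": "pooled", "est": pooled.est,
            "ci_low": pooled.ci_low, "ci_high": pooled.ci_high,
            "weight_pct": 100.0, "model": pooled.model,
            "tau2": pooled.tau2, "i2": pooled.het.i2,
            "Q": pooled.het.Q, "p_Q": pooled.het.p_Q,
        }
    )
    return pd.DataFrame(rows)


def forest_to_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def parse_forest_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", keep_default_na=False, float_precision="round_trip"
    )
    for col in ("tau2", "i2", "Q", "p_Q"):
        df[col] = df[col].map(lambda x: float(x) if x != "" else "")
    return df


def plot_forest(df: pd.DataFrame, path: str | Path, title: str = "") -> None:
    """Render the forest table to a vector-graphic file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    studies = df[df["row"] == "study"]
    summary = df[df["row"] == "summary"].iloc[0]
    n = len(studies)
    fig, ax = plt.subplots(figsize=(6, 0.45 * n + 1.6))
    ypos = range(n, 0, -1)
    ax.errorbar(
        studies["est"], list(ypos),
        xerr=[studies["est"] - studies["ci_low"], studies["ci_high"] - studies["est"]],
        fmt="s", color="k", ecolor="k", ms=4, lw=1,
    )
    ax.errorbar(
        [summary["est"]], [0],
        xerr=[[summary["est"] - summary["ci_low"]], [summary["ci_high"] - summary["est"]]],
        fmt="D", color="tab:blue", ms=8, lw=2,
    )
    ax.axvline(0.0, color="gray", lw=0.8, ls="--")
    ax.set_yticks(list(ypos) + [0])
    ax.set_yticklabels(list(studies["id"]) + ["pooled"])
    ax.set_xlabel("standardized mean difference (KO - control)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def run_analysis(config: AnalysisConfig | str | Path) -> dict:
    """Execute the full pipeline for one configuration; return the bundle.

    The bundle is a JSON-serializable mapping with keys ``random``,
    ``fixed``, ``effects``, ``forest``, ``leave_one_out``, ``scenarios``,
    ``moderator_screen``, and ``metadata``. If ``output_dir`` is set the
    bundle and its TSV side-tables are written there.
    """
    if not isinstance(config, AnalysisConfig):
        config = AnalysisConfig.from_file(config)

    records = load_dataset(config.input)
    if config.filter:
        records = reduced_model_filter(
            records,
            species_allowed=config.filter.get("species"),
            detection_allowed=config.filter.get("detection"),
        )
    if not records:
        raise ConfigError("empty analysis set after filtering")
    normalized = [normalize_record(r) for r in records]
    effects = compute_effects(normalized, method=config.effect_method)

    model = MetaAnalysis(effects)
    random_res = model.fit(model="random", tau2_method=config.tau2_method)
    fixed_res = model.fit(model="fixed")

    loo = (
        leave_one_out_table(effects, tau2_method=config.tau2_method)
        if len(effects) >= 2
        else pd.DataFrame()
    )
    scen = (
        scenario_table(effects, config.scenarios, tau2_method=config.tau2_method)
        if config.scenarios
        else pd.DataFrame()
    )
    covariates = tuple(config.moderators) if config.moderators else DEFAULT_COVARIATES
    screen = run_moderator_screen(
        normalized, effects,
        covariate_names=covariates,
        age_rule=config.age_rule,
        reference_levels={
            k: v for k, v in (config.moderators or {}).items() if v is not None
        },
        tau2_method=config.tau2_method,
    )
    forest = forest_data(random_res, effects)

    bundle = {
        "metadata": {
            "package": "glymeta",
            "version": __version__,
            "settings": {
                "input": str(config.input),
                "effect_method": config.effect_method,
                "tau2_method": config.tau2_method,
                "age_rule": config.age_rule,
                "filter": config.filter,
                "scenarios": config.scenarios,
                "moderators": {k: v for k, v in (config.moderators or {}).items()},
                "seed": config.seed,
            },
            "k": len(effects),
            "dataset_ids": [e.dataset_id for e in effects],
        },
        "random": random_res.to_dict(),
        "fixed": fixed_res.to_dict(),
        "effects": effects_frame(effects).to_dict("records"),
        "forest": forest.to_dict("records"),
        "leave_one_out": loo.to_dict("records"),
        "scenarios": scen.to_dict("records"),
        "moderator_screen": screen.table.where(screen.table.notna(), None).to_dict(
            "records"
        ),
    }

    if config.output_dir:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.json").write_text(
            json.dumps(bundle, indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )
        forest_to_tsv(forest, outdir / "forest.tsv")
        if len(scen):
            scen.to_csv(outdir / "scenarios.tsv", sep="\t", index=False)
        if len(loo):
            loo.to_csv(outdir / "leave_one_out.tsv", sep="\t", index=False)
        screen.table.to_csv(outdir / "moderator_screen.tsv", sep="\t", index=False)
        try:
            plot_forest(forest, outdir / "forest.svg")
        except Exception as err:  # plotting is best-effort
            logger.warning("forest plot rendering failed: %s", err)
    return bundle
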