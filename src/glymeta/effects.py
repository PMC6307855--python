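"""Standardized mean differences and their sampling variances.

Sign convention: the KO arm is the "treatment", so ``d = (ko - ctrl) / s``
and reduced tracer transport in AQP4-deficient animals yields a *negative*
SMD. Three standardizers are available:

* ``cohen``  — pooled SD of both arms (default, no small-sample correction);
* ``hedges`` — Cohen's d shrunk by the small-sample factor
  ``J = 1 - 3 / (4(n_t + n_c - 2) - 1)``;
* ``glass``  — control-arm SD only (Glass's delta).

The sampling variance is the standard large-sample approximation
``v = (n_t + n_c)/(n_t n_c) + d^2 / (2(n_t + n_c))`` (for Glass's delta the
second term uses ``2(n_c - 1)``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import DegenerateInputError
from .records import StudyRecord

METHODS = ("cohen", "hedges", "glass")


@dataclass(frozen=True)
class EffectSize:
    dataset_id: str
    d: float
    v: float
    method: str
    n_t: int
    n_c: int
    j_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.v <= 0:
            raise DegenerateInputError(
                f"{self.dataset_id}: sampling variance must be positive"
            )
        if not 0 < self.j_factor <= 1:
            raise DegenerateInputError(
                f"{self.dataset_id}: small-sample factor J must lie in (0, 1]"
            )

    @property
    def se(self) -> float:
        return math.sqrt(self.v)


def smd_variance(d: float, n_t: int, n_c: int) -> float:
    """Large-sample variance of an SMD standardized by the pooled SD."""
    if n_t < 2 or n_c < 2:
        raise DegenerateInputError("both arms need n >= 2")
    return (n_t + n_c) / (n_t * n_c) + d * d / (2 * (n_t + n_c))


def _pooled_sd(s_t: float, n_t: int, s_c: float, n_c: int) -> float:
    sp2 = ((n_t - 1) * s_t**2 + (n_c - 1) * s_c**2) / (n_t + n_c - 2)
    if sp2 <= 0:
        raise DegenerateInputError("pooled SD is zero; SMD undefined")
    return math.sqrt(sp2)


def cohens_d(
    m_t: float, s_t: float, n_t: int, m_c: float, s_c: float, n_c: int,
    dataset_id: str = "",
) -> EffectSize:
    """Cohen's d from two-arm summary statistics (treatment minus control)."""
    if n_t < 2 or n_c < 2:
        raise DegenerateInputError("both arms need n >= 2")
    d = (m_t - m_c) / _pooled_sd(s_t, n_t, s_c, n_c)
    return EffectSize(dataset_id, d, smd_variance(d, n_t, n_c), "cohen", n_t, n_c)


def hedges_g(
    m_t: float, s_t: float, n_t: int, m_c: float, s_c: float, n_c: int,
    dataset_id: str = "",
) -> EffectSize:
    """Small-sample-corrected SMD (Hedges' g)."""
    base = cohens_d(m_t, s_t, n_t, m_c, s_c, n_c, dataset_id)
    j = 1.0 - 3.0 / (4 * (n_t + n_c - 2) - 1)
    return EffectSize(
        dataset_id, j * base.d, j * j * base.v, "hedges", n_t, n_c, j_factor=j
    )


def glass_delta(
    m_t: float, n_t: int, m_c: float, s_c: float, n_c: int,
    dataset_id: str = "",
) -> EffectSize:
    """Glass's delta: mean difference standardized by the control-arm SD."""
    if s_c <= 0:
        raise DegenerateInputError("control SD must be positive")
    if n_t < 2 or n_c < 2:
        raise DegenerateInputError("both arms need n >= 2")
    delta = (m_t - m_c) / s_c
    v = (n_t + n_c) / (n_t * n_c) + delta * delta / (2 * (n_c - 1))
    return EffectSize(dataset_id, delta, v, "glass", n_t, n_c)


def compute_effect(rec: StudyRecord, method: str = "cohen") -> EffectSize:
    """Effect size for one normalized study record (KO minus control)."""
    if not rec.is_normalized:
        raise DegenerateInputError(
            f"{rec.dataset_id}: record must be normalized (SD-based, single n) "
            "before computing effect sizes"
        )
    args = (rec.ko_mean, rec.ko_disp, rec.ko_n, rec.ctrl_mean, rec.ctrl_disp, rec.ctrl_n)
    if method == "cohen":
        return cohens_d(*args, dataset_id=rec.dataset_id)
    if method == "hedges":
        return hedges_g(*args, dataset_id=rec.dataset_id)
    if method == "glass":
        return glass_delta(
            rec.ko_mean, rec.ko_n, rec.ctrl_mean, rec.ctrl_disp, rec.ctrl_n,
            dataset_id=rec.dataset_id,
        )
    raise ValueError(f"unknown effect-size method {method!r}")


def compute_effects(
    records: Sequence[StudyRecord], method: str = "cohen"
) -> list[EffectSize]:
    return [compute_effect(rec, method) for rec in records]


def effects_frame(effects: Iterable[EffectSize]) -> pd.DataFrame:
    """Tabular view: dataset_id, d, se, v, method, n_t, n_c."""
    rows = [
        (e.dataset_id, e.d, e.se, e.v, e.method, e.n_t, e.n_c) for e in effects
    ]
    return pd.DataFrame(
        rows, columns=["dataset_id", "d", "se", "v", "method", "n_t", "n_c"]
    )


def effects_to_tsv(effects: Iterable[EffectSize], path) -> None:
    effects_frame(effects).to_csv(path, sep="\t", index=False)


def as_arrays(effects: Sequence[EffectSize]) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Split effects into (d, v, ids) arrays for the numerical core."""
    d = np.array([e.d for e in effects], dtype=float)
    v = np.array([e.v for e in effects], dtype=float)
    ids = [e.dataset_id for e in effects]
    return d, v, ids
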