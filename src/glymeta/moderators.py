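"""Moderator encoding and the one-at-a-time covariate screen.

Study-level covariates (KO line, anesthesia, age, injection rate, ...) are
encoded one at a time into a meta-regression design: categorical covariates
get treatment (dummy) coding against a reference level, numeric covariates
enter as a single centered column. With as few as 9-13 datasets, models with
more than one covariate rarely converge, so the screen fits one
single-moderator model per covariate and reports failures (constant
moderator, rank deficiency, non-convergence) explicitly rather than
dropping them.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .effects import EffectSize
from .exceptions import (
    ConstantModeratorError,
    ConvergenceError,
    DegenerateInputError,
)
from .model import MetaRegression, MetaRegressionResults
from .records import StudyRecord, resolve_covariates

logger = logging.getLogger("glymeta")

#: covariates available from resolve_covariates, in screen order
DEFAULT_COVARIATES = (
    "ko_line",
    "age_weeks",
    "anesthesia",
    "injection_rate",
    "duration",
    "detection",
    "tracer_kda",
    "injection_volume_ul",
    "species",
)


@dataclass
class EncodedModerator:
    """Design matrix (intercept first) plus bookkeeping for one covariate."""

    name: str
    design: np.ndarray
    term_labels: list[str]
    used_mask: np.ndarray  # rows of the input that enter the model
    reference_level: str | None
    notices: list[str] = field(default_factory=list)


def _is_missing(value) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and np.isnan(value):
        return True
    return False


def _try_numeric(values: list) -> list[float] | None:
    out = []
    for value in values:
        if isinstance(value, (int, float)) and not isinstance(value, bool):
            out.append(float(value))
            continue
        try:
            out.append(float(str(value)))
        except ValueError:
            return None
    return out


def encode_moderator(
    covariates: Sequence[Mapping[str, object]] | pd.DataFrame,
    name: str,
    reference_level: str | None = None,
) -> EncodedModerator:
    """Build a single-moderator design from per-record covariate mappings.

    Numeric covariates become one centered column; rows missing the value
    are excluded from the model (mask False) with a logged warning.
    Categorical covariates are dummy-coded against ``reference_level``
    (default: most frequent level, ties broken alphabetically); the explicit
    level ``"unreported"`` participates like any other. A covariate mixing
    numeric and non-numeric tokens (e.g. volumetric rates plus a pulsed
    protocol code) is coerced to categorical with a notice.
    """
    if isinstance(covariates, pd.DataFrame):
        rows = covariates.to_dict("records")
    else:
        rows = [dict(r) for r in covariates]
    if not rows or name not in rows[0]:
        raise KeyError(f"covariate {name!r} not present in records")
    raw = [r[name] for r in rows]
    notices: list[str] = []

    present = [x for x in raw if not _is_missing(x)]
    if not present:
        raise ConstantModeratorError(f"{name}: all values missing")

    numeric = _try_numeric(present)
    some_numeric = any(_try_numeric([x]) is not None for x in present)
    if numeric is not None:
        # fully numeric -> single centered column over non-missing rows
        mask = np.array([not _is_missing(x) for x in raw])
        if not mask.all():
            dropped = [i for i, m in enumerate(mask) if not m]
            msg = f"{name}: {len(dropped)} record(s) missing numeric value, excluded"
            logger.warning(msg)
            notices.append(msg)
        values = np.array(_try_numeric([raw[i] for i in np.flatnonzero(mask)]))
        if np.ptp(values) == 0:
            raise ConstantModeratorError(f"constant moderator: {name}")
        centered = values - values.mean()
        design = np.column_stack([np.ones(len(values)), centered])
        return EncodedModerator(name, design, ["intercept", name], mask, None, notices)

    # categorical path: missing -> "unreported" level, everything stringified
    if some_numeric:
        msg = f"{name}: mixed numeric/categorical tokens, coerced to categorical"
        logger.info(msg)
        notices.append(msg)
    levels = ["unreported" if _is_missing(x) else str(x) for x in raw]
    counts = Counter(levels)
    if len(counts) < 2:
        raise ConstantModeratorError(f"constant moderator: {name}")
    if reference_level is None:
        reference_level = sorted(counts, key=lambda lv: (-counts[lv], lv))[0]
    elif reference_level not in counts:
        raise KeyError(f"{name}: reference level {reference_level!r} absent")
    dummy_levels = sorted(lv for lv in counts if lv != reference_level)
    mask = np.ones(len(levels), dtype=bool)
    design = np.column_stack(
        [np.ones(len(levels))]
        + [[1.0 if lv == dl else 0.0 for lv in levels] for dl in dummy_levels]
    )
    return EncodedModerator(
        name, design, ["intercept"] + dummy_levels, mask, reference_level, notices
    )


def fit_moderator(
    effects: Sequence[EffectSize],
    covariates: Sequence[Mapping[str, object]],
    name: str,
    reference_level: str | None = None,
    tau2_method: str = "DL",
    tol: float = 1e-10,
    max_iter: int = 100,
) -> MetaRegressionResults:
    """Encode one covariate and fit the single-moderator mixed-effects model."""
    enc = encode_moderator(covariates, name, reference_level)
    used = [e for e, m in zip(effects, enc.used_mask) if m]
    reg = MetaRegression(
        used, enc.design, enc.term_labels,
        moderator=name, reference_level=enc.reference_level,
    )
    return reg.fit(tau2_method=tau2_method, tol=tol, max_iter=max_iter)


@dataclass
class ScreenEntry:
    covariate: str
    result: MetaRegressionResults | None = None
    failure_reason: str | None = None

    @property
    def ok(self) -> bool:
        return self.result is not None


@dataclass
class ScreenResult:
    entries: list[ScreenEntry]

    def __getitem__(self, covariate: str) -> ScreenEntry:
        for entry in self.entries:
            if entry.covariate == covariate:
                return entry
        raise KeyError(covariate)

    @property
    def table(self) -> pd.DataFrame:
        """Summary sorted by p_QM; failed covariates sink to the bottom."""
        rows = []
        for entry in self.entries:
            if entry.ok:
                r = entry.result
                rows.append(
                    {
                        "covariate": entry.covariate,
                        "k_used": r.k_used,
                        "QM": r.QM,
                        "df": r.QM_df,
                        "p_QM": r.p_QM,
                        "tau2_resid": r.tau2_resid,
                        "r2_percent": r.r2_percent,
                        "converged": r.converged,
                        "failure_reason": "",
                    }
                )
            else:
                rows.append(
                    {
                        "covariate": entry.covariate,
                        "k_used": np.nan, "QM": np.nan, "df": np.nan,
                        "p_QM": np.nan, "tau2_resid": np.nan,
                        "r2_percent": np.nan, "converged": False,
                        "failure_reason": entry.failure_reason,
                    }
                )
        df = pd.DataFrame(rows)
        return df.sort_values(
            "p_QM", kind="stable", na_position="last"
        ).reset_index(drop=True)


def run_moderator_screen(
    records: Sequence[StudyRecord],
    effects: Sequence[EffectSize],
    covariate_names: Sequence[str] = DEFAULT_COVARIATES,
    age_rule: str = "midpoint",
    reference_levels: Mapping[str, str] | None = None,
    tau2_method: str = "DL",
) -> ScreenResult:
    """Fit one single-moderator model per covariate; capture failures."""
    if len(records) != len(effects):
        raise DegenerateInputError("records and effects must align")
    covs = [resolve_covariates(r, age_rule=age_rule) for r in records]
    refs = dict(reference_levels or {})
    entries: list[ScreenEntry] = []
    for name in covariate_names:
        try:
            res = fit_moderator(
                effects, covs, name,
                reference_level=refs.get(name), tau2_method=tau2_method,
            )
            entries.append(ScreenEntry(name, result=res))
        except ConstantModeratorError:
            entries.append(ScreenEntry(name, failure_reason="constant moderator"))
        except ConvergenceError as err:
            entries.append(ScreenEntry(name, failure_reason=f"non-convergence: {err}"))
        except (DegenerateInputError, KeyError) as err:
            entries.append(ScreenEntry(name, failure_reason=str(err)))
    return ScreenResult(entries)
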