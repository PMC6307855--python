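"""Leave-one-out and named-subset exclusion re-analysis.

Used to localize heterogeneity: when a handful of datasets (e.g. the three
possibly non-independent ones from a single publication) drive Cochran's Q,
re-pooling every exclusion scenario shows how much of I² they carry.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import pandas as pd

from .effects import EffectSize
from .exceptions import DegenerateInputError
from .model import MetaAnalysis, MetaAnalysisResults


def _pool(effects: Sequence[EffectSize], model: str, tau2_method: str) -> MetaAnalysisResults:
    return MetaAnalysis(effects).fit(model=model, tau2_method=tau2_method)


def leave_one_out(
    effects: Sequence[EffectSize],
    model: str = "random",
    tau2_method: str = "DL",
) -> list[tuple[str, MetaAnalysisResults]]:
    """Re-pool after excluding each dataset in turn, in input order."""
    if len(effects) < 2:
        raise DegenerateInputError("leave-one-out needs at least two studies")
    out = []
    for i, excluded in enumerate(effects):
        rest = [e for j, e in enumerate(effects) if j != i]
        out.append((excluded.dataset_id, _pool(rest, model, tau2_method)))
    return out


def exclude_subset(
    effects: Sequence[EffectSize],
    excluded_ids: Iterable[str],
    model: str = "random",
    tau2_method: str = "DL",
) -> MetaAnalysisResults:
    """Pool the complement of ``excluded_ids`` (order-insensitive)."""
    excluded = set(excluded_ids)
    known = {e.dataset_id for e in effects}
    unknown = excluded - known
    if unknown:
        raise KeyError(f"unknown dataset ids: {sorted(unknown)}")
    rest = [e for e in effects if e.dataset_id not in excluded]
    if not rest:
        raise DegenerateInputError("exclusion leaves no studies to pool")
    return _pool(rest, model, tau2_method)


def scenario_table(
    effects: Sequence[EffectSize],
    scenarios: Mapping[str, Sequence[str]],
    model: str = "random",
    tau2_method: str = "DL",
) -> pd.DataFrame:
    """Named exclusion scenarios, one pooled result per row."""
    rows = []
    for name, ids in scenarios.items():
        res = exclude_subset(effects, ids, model=model, tau2_method=tau2_method)
        rows.append(
            {
                "scenario": name,
                "excluded": ",".join(ids),
                "k": res.k,
                "est": res.est,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
                "p": res.p,
                "tau2": res.tau2,
                "i2": res.het.i2,
                "Q": res.het.Q,
                "p_Q": res.het.p_Q,
            }
        )
    return pd.DataFrame(rows)


def leave_one_out_table(
    effects: Sequence[EffectSize],
    model: str = "random",
    tau2_method: str = "DL",
) -> pd.DataFrame:
    """Leave-one-out results as a scenario-style table."""
    scenarios = {f"loo:{e.dataset_id}": [e.dataset_id] for e in effects}
    return scenario_table(effects, scenarios, model=model, tau2_method=tau2_method)
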