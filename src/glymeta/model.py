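"""Inverse-variance pooling and mixed-effects meta-regression.

The estimation model is the standard two-level normal-normal hierarchy:
each dataset contributes an observed SMD ``d_i`` with known sampling
variance ``v_i`` around a true study effect ``theta_i``, and the true
effects scatter around the population mean with between-study variance
``tau^2`` (optionally shifted by moderators ``x_i beta``):

    d_i | theta_i ~ N(theta_i, v_i),    theta_i ~ N(mu + x_i beta, tau^2)

``tau^2`` is estimated by the DerSimonian-Laird moment estimator (``DL``,
the default) or by restricted maximum likelihood (``REML``, Fisher scoring).
Both generalize to a design matrix, so the intercept-only meta-regression
is numerically identical to the plain random-effects pool.

The public surface follows the model/results idiom: build a
:class:`MetaAnalysis` (or :class:`MetaRegression`) from effect sizes, call
``fit()``, and read estimates, heterogeneity and weights off the returned
results object. Thin functional wrappers (:func:`fixed_effect`,
:func:`random_effects`, :func:`cochran_q`, :func:`tau2_dl`,
:func:`tau2_reml`) are provided for scripting.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .effects import EffectSize, as_arrays
from .exceptions import ConvergenceError, DegenerateInputError

logger = logging.getLogger("glymeta")

#: two-sided 95% normal quantile used for every Wald interval
Z_CRIT = float(stats.norm.ppf(0.975))

TAU2_METHODS = ("DL", "REML")


@dataclass(frozen=True)
class HeterogeneityStats:
    """Cochran's Q decomposition of between-study variability."""

    Q: float
    df: int
    p_Q: float
    tau2: float
    i2: float  # percent
    C: float   # DL scaling constant sum(w) - sum(w^2)/sum(w)

    def __post_init__(self) -> None:
        assert self.Q >= 0 and self.tau2 >= 0 and 0 <= self.i2 < 100


def _q_statistic(d: np.ndarray, v: np.ndarray) -> tuple[float, int, float, float]:
    """Return (Q, df, p_Q, C) using fixed-effect weights."""
    w = 1.0 / v
    est = float(np.sum(w * d) / np.sum(w))
    Q = float(np.sum(w * (d - est) ** 2))
    df = len(d) - 1
    p_Q = float(stats.chi2.sf(Q, df)) if df > 0 else 1.0
    C = float(np.sum(w) - np.sum(w**2) / np.sum(w))
    return Q, df, p_Q, C


def _i2_from_q(Q: float, df: int) -> float:
    if Q <= 0:
        return 0.0
    return max(0.0, (Q - df) / Q) * 100.0


def _tau2_dl_arrays(d: np.ndarray, v: np.ndarray) -> float:
    Q, df, _, C = _q_statistic(d, v)
    if C <= 0:
        raise DegenerateInputError("DL scaling constant C is zero; tau2 undefined")
    return max(0.0, (Q - df) / C)


def _reml_projection(
    d: np.ndarray, v: np.ndarray, X: np.ndarray, tau2: float
) -> np.ndarray:
    """P = W - W X (X' W X)^-1 X' W with W = diag(1/(v + tau2))."""
    w = 1.0 / (v + tau2)
    W = np.diag(w)
    WX = w[:, None] * X
    xtwx_inv = np.linalg.inv(X.T @ WX)
    return W - WX @ xtwx_inv @ WX.T


def _tau2_reml_arrays(
    d: np.ndarray,
    v: np.ndarray,
    X: np.ndarray | None = None,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> float:
    """REML tau^2 via Fisher scoring, floored at zero.

    The update is ``tau2 <- tau2 + (d' P P d - tr P) / tr(P P)`` with the
    REML projection matrix ``P``; at the zero boundary a non-positive score
    means the restricted likelihood is maximized at ``tau2 = 0``.
    """
    k = len(d)
    if X is None:
        X = np.ones((k, 1))
    if k <= X.shape[1]:
        return 0.0
    tau2 = max(_tau2_dl_with_design(d, v, X), 1e-4)  # moment start
    for _ in range(max_iter):
        P = _reml_projection(d, v, X, tau2)
        Pd = P @ d
        score = float(d @ (P @ Pd) - np.trace(P))
        info = float(np.trace(P @ P))
        step = score / info
        new = tau2 + step
        if new < 0.0:
            new = 0.0
        if abs(new - tau2) < tol:
            return new
        if new == 0.0 and tau2 == 0.0:
            return 0.0
        tau2 = new
    raise ConvergenceError(
        f"REML tau2 estimation did not converge in {max_iter} iterations",
        last_iterate=tau2,
    )


def _tau2_dl_with_design(d: np.ndarray, v: np.ndarray, X: np.ndarray) -> float:
    """Method-of-moments tau^2 for a meta-regression design (DL extension).

    ``tau2 = max(0, (QE - (k - p)) / tr(P))`` where ``QE`` is the residual
    heterogeneity statistic under fixed-effect weights and ``P`` the
    corresponding projection. Reduces to plain DL for an intercept-only X.
    """
    k, p = X.shape
    if k <= p:
        return 0.0
    P = _reml_projection(d, v, X, 0.0)
    QE = float(d @ P @ d)
    trP = float(np.trace(P))
    if trP <= 0:
        raise DegenerateInputError("moment scaling constant is zero; tau2 undefined")
    return max(0.0, (QE - (k - p)) / trP)


def _estimate_tau2(
    d: np.ndarray,
    v: np.ndarray,
    X: np.ndarray,
    method: str,
    tol: float,
    max_iter: int,
) -> float:
    if method == "DL":
        return _tau2_dl_with_design(d, v, X)
    if method == "REML":
        return _tau2_reml_arrays(d, v, X, tol=tol, max_iter=max_iter)
    raise ValueError(f"unknown tau2 method {method!r}; expected one of {TAU2_METHODS}")


# ---------------------------------------------------------------------------
# Results containers


class MetaAnalysisResults:
    """Pooled estimate, Wald inference, heterogeneity, and study weights."""

    def __init__(
        self,
        *,
        ids: Sequence[str],
        d: np.ndarray,
        v: np.ndarray,
        model: str,
        tau2_method: str | None,
        tau2: float,
        het: HeterogeneityStats,
    ):
        self.dataset_ids = list(ids)
        self.d = d
        self.v = v
        self.k = len(d)
        self.model = model
        self.tau2_method = tau2_method
        self.tau2 = tau2
        self.het = het
        w = 1.0 / (v + tau2)
        self.est = float(np.sum(w * d) / np.sum(w))
        self.se = float(math.sqrt(1.0 / np.sum(w)))
        self.ci_low = self.est - Z_CRIT * self.se
        self.ci_high = self.est + Z_CRIT * self.se
        self.z = self.est / self.se
        self.p = float(2.0 * stats.norm.sf(abs(self.z)))
        self.weights = w / np.sum(w) * 100.0  # percent, sums to 100

    def __repr__(self) -> str:
        return (
            f"<MetaAnalysisResults k={self.k} model={self.model} "
            f"est={self.est:.3f} [{self.ci_low:.3f}, {self.ci_high:.3f}]>"
        )

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "model": self.model,
            "tau2_method": self.tau2_method,
            "est": self.est,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "z": self.z,
            "p": self.p,
            "tau2": self.tau2,
            "Q": self.het.Q,
            "df": self.het.df,
            "p_Q": self.het.p_Q,
            "i2": self.het.i2,
            "weights": {
                i: float(w) for i, w in zip(self.dataset_ids, self.weights)
            },
        }

    def summary(self) -> str:
        h = self.het
        lines = [
            f"Meta-analysis ({self.model} effects"
            + (f", tau2 via {self.tau2_method}" if self.model == "random" else "")
            + f"), k = {self.k}",
            f"  SMD = {self.est:.4f}  95% CI [{self.ci_low:.4f}, {self.ci_high:.4f}]"
            f"  z = {self.z:.3f}  p = {self.p:.4g}",
            f"  Heterogeneity: Q = {h.Q:.4f} (df = {h.df}, p = {h.p_Q:.4g}), "
            f"tau2 = {self.tau2:.4f}, I2 = {h.i2:.1f}%",
            "  Study weights (%):",
        ]
        for i, w in zip(self.dataset_ids, self.weights):
            lines.append(f"    {i:<24s} {w:6.2f}")
        return "\n".join(lines)


class MetaAnalysis:
    """Inverse-variance pooling model over per-study effect sizes."""

    def __init__(self, effects: Sequence[EffectSize]):
        if len(effects) == 0:
            raise DegenerateInputError("at least one effect size is required")
        self.effects = list(effects)
        self._d, self._v, self._ids = as_arrays(self.effects)

    @classmethod
    def from_records(cls, records, method: str = "cohen", normalize: bool = True):
        """Build the model from study records (optionally normalizing first)."""
        from .effects import compute_effects
        from .records import normalize_record

        if normalize:
            records = [normalize_record(r) for r in records]
        return cls(compute_effects(records, method=method))

    def heterogeneity(self, tau2: float = 0.0) -> HeterogeneityStats:
        d, v = self._d, self._v
        if len(d) == 1:
            logger.info("k = 1: heterogeneity statistics degenerate (Q = 0, I2 = 0)")
            return HeterogeneityStats(0.0, 0, 1.0, tau2, 0.0, 0.0)
        Q, df, p_Q, C = _q_statistic(d, v)
        return HeterogeneityStats(Q, df, p_Q, tau2, _i2_from_q(Q, df), C)

    def fit(
        self,
        model: str = "random",
        tau2_method: str = "DL",
        tol: float = 1e-10,
        max_iter: int = 100,
    ) -> MetaAnalysisResults:
        d, v = self._d, self._v
        if model == "fixed":
            tau2, method = 0.0, None
        elif model == "random":
            method = tau2_method
            if len(d) == 1:
                logger.info("k = 1: tau2 fixed at 0, pooled result is the single study")
                tau2 = 0.0
            else:
                X = np.ones((len(d), 1))
                tau2 = _estimate_tau2(d, v, X, tau2_method, tol, max_iter)
        else:
            raise ValueError(f"unknown model {model!r}; expected 'fixed' or 'random'")
        return MetaAnalysisResults(
            ids=self._ids, d=d, v=v, model=model, tau2_method=method,
            tau2=tau2, het=self.heterogeneity(tau2),
        )


@dataclass
class CoefficientTable:
    labels: list[str]
    beta: np.ndarray
    se: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    z: np.ndarray
    p: np.ndarray

    def rows(self) -> list[dict]:
        return [
            {
                "term": lab, "beta": float(b), "se": float(s),
                "ci_low": float(lo), "ci_high": float(hi),
                "z": float(zz), "p": float(pp),
            }
            for lab, b, s, lo, hi, zz, pp in zip(
                self.labels, self.beta, self.se, self.ci_low,
                self.ci_high, self.z, self.p,
            )
        ]


class MetaRegressionResults:
    """Moderator coefficients, the QM test, and heterogeneity accounting."""

    def __init__(
        self,
        *,
        moderator: str,
        coefficients: CoefficientTable,
        QM: float,
        QM_df: int,
        p_QM: float,
        tau2_resid: float,
        tau2_total: float,
        reference_level: str | None,
        k_used: int,
        tau2_method: str,
        converged: bool = True,
    ):
        self.moderator = moderator
        self.coefficients = coefficients
        self.QM = QM
        self.QM_df = QM_df
        self.p_QM = p_QM
        self.tau2_resid = tau2_resid
        self.tau2_total = tau2_total
        self.r2_percent = r2_explained(tau2_total, tau2_resid)
        self.reference_level = reference_level
        self.k_used = k_used
        self.tau2_method = tau2_method
        self.converged = converged

    def __repr__(self) -> str:
        return (
            f"<MetaRegressionResults moderator={self.moderator!r} k={self.k_used} "
            f"QM={self.QM:.3f} p={self.p_QM:.4g} R2={self.r2_percent:.1f}%>"
        )

    def to_dict(self) -> dict:
        return {
            "moderator": self.moderator,
            "coefficients": self.coefficients.rows(),
            "QM": self.QM,
            "QM_df": self.QM_df,
            "p_QM": self.p_QM,
            "tau2_resid": self.tau2_resid,
            "tau2_total": self.tau2_total,
            "r2_percent": self.r2_percent,
            "reference_level": self.reference_level,
            "k_used": self.k_used,
            "tau2_method": self.tau2_method,
            "converged": self.converged,
        }

    def summary(self) -> str:
        lines = [
            f"Mixed-effects meta-regression on '{self.moderator}' "
            f"(k = {self.k_used}, tau2 via {self.tau2_method})",
            f"  QM({self.QM_df}) = {self.QM:.4f}, p = {self.p_QM:.4g}",
            f"  tau2 residual = {self.tau2_resid:.4f}  "
            f"(intercept-only {self.tau2_total:.4f}; "
            f"{self.r2_percent:.2f}% heterogeneity explained)",
        ]
        if self.reference_level is not None:
            lines.append(f"  reference level: {self.reference_level}")
        lines.append(f"  {'term':<24s} {'beta':>9s} {'se':>8s} {'z':>8s} {'p':>10s}")
        for row in self.coefficients.rows():
            lines.append(
                f"  {row['term']:<24s} {row['beta']:9.4f} {row['se']:8.4f} "
                f"{row['z']:8.3f} {row['p']:10.4g}"
            )
        return "\n".join(lines)


class MetaRegression:
    """Single-moderator (or custom-design) mixed-effects meta-regression.

    ``design`` must include the intercept as its first column; term labels
    follow the design's columns. Rows are aligned with ``effects``.
    """

    def __init__(
        self,
        effects: Sequence[EffectSize],
        design: np.ndarray,
        term_labels: Sequence[str],
        moderator: str = "",
        reference_level: str | None = None,
    ):
        self.effects = list(effects)
        X = np.asarray(design, dtype=float)
        if X.ndim != 2 or X.shape[0] != len(self.effects):
            raise DegenerateInputError("design rows must align with effects")
        if X.shape[1] + 1 > X.shape[0]:
            raise DegenerateInputError(
                f"design with {X.shape[1]} columns needs at least "
                f"{X.shape[1] + 1} studies, got {X.shape[0]}"
            )
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise DegenerateInputError("rank-deficient design matrix")
        if len(term_labels) != X.shape[1]:
            raise DegenerateInputError("one label per design column required")
        self.design = X
        self.term_labels = list(term_labels)
        self.moderator = moderator
        self.reference_level = reference_level
        self._d, self._v, self._ids = as_arrays(self.effects)

    def fit(
        self,
        tau2_method: str = "DL",
        tol: float = 1e-10,
        max_iter: int = 100,
    ) -> MetaRegressionResults:
        d, v, X = self._d, self._v, self.design
        k, p = X.shape
        try:
            tau2_resid = _estimate_tau2(d, v, X, tau2_method, tol, max_iter)
        except ConvergenceError:
            raise
        # intercept-only tau2 on exactly the same records, same estimator,
        # so the heterogeneity-explained ratio nests correctly
        tau2_total = _estimate_tau2(
            d, v, np.ones((k, 1)), tau2_method, tol, max_iter
        )
        w = 1.0 / (v + tau2_resid)
        WX = w[:, None] * X
        cov = np.linalg.inv(X.T @ WX)
        beta = cov @ (WX.T @ d)
        se = np.sqrt(np.diag(cov))
        z = beta / se
        pvals = 2.0 * stats.norm.sf(np.abs(z))
        coeffs = CoefficientTable(
            labels=self.term_labels,
            beta=beta, se=se,
            ci_low=beta - Z_CRIT * se, ci_high=beta + Z_CRIT * se,
            z=z, p=pvals,
        )
        if p > 1:
            bm = beta[1:]
            QM = float(bm @ np.linalg.solve(cov[1:, 1:], bm))
            QM_df = p - 1
            p_QM = float(stats.chi2.sf(QM, QM_df))
        else:
            QM, QM_df, p_QM = 0.0, 0, 1.0
        return MetaRegressionResults(
            moderator=self.moderator,
            coefficients=coeffs,
            QM=QM, QM_df=QM_df, p_QM=p_QM,
            tau2_resid=tau2_resid, tau2_total=tau2_total,
            reference_level=self.reference_level,
            k_used=k, tau2_method=tau2_method,
        )


def r2_explained(tau2_total: float, tau2_resid: float) -> float:
    """Percent of between-study variance removed by the moderators."""
    if tau2_total < 0:
        raise ValueError("tau2_total must be nonnegative")
    if tau2_total == 0.0:
        return 0.0
    return max(0.0, (tau2_total - tau2_resid) / tau2_total) * 100.0


# ---------------------------------------------------------------------------
# Functional wrappers


def fixed_effect(effects: Sequence[EffectSize]) -> MetaAnalysisResults:
    return MetaAnalysis(effects).fit(model="fixed")


def random_effects(
    effects: Sequence[EffectSize],
    tau2_method: str = "DL",
    tol: float = 1e-10,
    max_iter: int = 100,
) -> MetaAnalysisResults:
    return MetaAnalysis(effects).fit(
        model="random", tau2_method=tau2_method, tol=tol, max_iter=max_iter
    )


def cochran_q(effects: Sequence[EffectSize]) -> HeterogeneityStats:
    return MetaAnalysis(effects).heterogeneity()


def tau2_dl(effects: Sequence[EffectSize]) -> float:
    d, v, _ = as_arrays(list(effects))
    if len(d) < 2:
        raise DegenerateInputError("tau2 estimation needs k >= 2")
    return _tau2_dl_arrays(d, v)


def tau2_reml(
    effects: Sequence[EffectSize], tol: float = 1e-10, max_iter: int = 100
) -> float:
    d, v, _ = as_arrays(list(effects))
    if len(d) < 2:
        raise DegenerateInputError("tau2 estimation needs k >= 2")
    return _tau2_reml_arrays(d, v, tol=tol, max_iter=max_iter)
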