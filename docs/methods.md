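# Methods

## Estimation model

The package pools study-level standardized mean differences (SMDs) under
the usual two-level normal hierarchy: observed effect `d_i ~ N(θ_i, v_i)`
with known sampling variance `v_i`, true effects `θ_i ~ N(μ + x_i β, τ²)`.
The sign convention is KO minus control in pooled-SD units, so impaired
transport in AQP4-deficient animals produces negative SMDs.

**Effect sizes.** Cohen's d (pooled SD, no small-sample correction) is the
default, matching how the source corpus was analyzed; Hedges' g
(`J = 1 − 3/(4(n_t+n_c−2) − 1)`, `g = J d`, `v_g = J² v`) and Glass's Δ
(control-arm SD; variance `(n_t+n_c)/(n_t n_c) + Δ²/(2(n_c−1))`) are
selectable to reproduce sensitivity variants. The SMD variance is the
standard large-sample approximation
`v = (n_t+n_c)/(n_t n_c) + d²/(2(n_t+n_c))`; the choice is pinned in run
metadata because several near-equivalent variants exist in the literature
and they matter at the corpus's small arm sizes (often 3–8 animals).

**Between-study variance.** Two estimators:

- *DerSimonian–Laird* (default): `τ² = max(0, (Q − df)/C)` with
  `C = Σw − Σw²/Σw`, fixed-effect weights `w = 1/v`. With moderators this
  generalizes to the method-of-moments form
  `τ² = max(0, (Q_E − (k − p))/tr(P))`, `P = W − WX(XᵀWX)⁻¹XᵀW`, which
  reduces exactly to DL for an intercept-only design — so the intercept-only
  meta-regression and the plain random-effects pool are numerically
  identical (tested to 1e-10).
- *REML*: Fisher scoring on the restricted likelihood,
  `τ² ← τ² + (dᵀP²d − tr P)/tr(P²)`, started at the moment estimate,
  floored at zero, converged when successive iterates differ by less than
  `tol` (default 1e-10, max 100 iterations; non-convergence raises and
  carries the last iterate). The same update serves intercept-only and
  moderated designs. It matches brute-force maximization of the restricted
  likelihood to <1e-8 and R metafor to metafor's own convergence tolerance.

**Inference.** Wald intervals with the normal 0.975 quantile throughout
(no Knapp–Hartung adjustment — the corpus this mirrors reported plain 95%
CIs and z-style p-values). `I² = max(0, (Q − df)/Q)·100`, defined as 0 when
Q = 0. For a single study: Q = 0, df = 0, I² reported as 0 with a logged
caveat rather than NA so singleton subsets never crash a pipeline.

**Meta-regression.** One covariate per model is the default and the
screen's only mode: with 9–13 datasets, two-covariate models typically fail
to converge, and the screen is designed to report such failures (constant
moderator, rank deficiency, non-convergence) as explicit entries rather
than dropping covariates silently. Categorical moderators use treatment
coding against a configurable reference level (default: most frequent
level, ties broken alphabetically; the published efflux analysis used the
0.017 µl/min injection rate as its reference, which can be set via config).
Numeric moderators enter as one centered column. A covariate mixing numeric
and protocol-code tokens (e.g. volumetric rates plus a pulsed-pressure
label) is coerced to categorical with a notice. QM is the Wald chi-square
on all non-intercept coefficients; it is invariant under change of
reference level. `R² = max(0, (τ²_total − τ²_resid)/τ²_total)·100` uses the
intercept-only τ² computed *on exactly the records entering the moderated
fit* (records missing a numeric covariate are excluded from that
moderator's model only), keeping the nesting exact.

## Data extraction conventions

Ingest normalization mirrors how study tables are transcribed from the
literature: SEM-reported dispersions become `SD = SEM·√n` using the
resolved sample size of that arm; sample sizes reported as ranges (either
dash dialect) resolve to the range minimum; originals are kept in
provenance columns and normalization is idempotent. Missing categorical
covariates become the explicit level `"unreported"` — an unreported
circulation time is itself an analyzable (and, in the efflux corpus,
informative) level — while missing numeric covariates exclude the record
from that moderator's model only, with a warning. Age ranges convert to a
numeric moderator by the midpoint rule by default (min/max selectable);
the numeric coding used in the original analysis is not documented, so the
choice is exposed in configuration rather than hard-coded. Possibly
non-independent datasets from a single publication are loaded as ordinary
rows; their influence is assessed downstream through exclusion scenarios
rather than by dropping data at ingest.

## Synthetic data

The generator emulates the cisterna-magna influx corpus: per study it draws
moderator values, a true effect `θ_i = μ + x_i β + u_i` with
`u_i ~ N(0, τ²)`, then animal-level outcomes — controls
`N(baseline_mean, baseline_sd)`, KO `N(baseline_mean + θ_i·baseline_sd,
baseline_sd)` — and writes the empirical summaries. Injecting the effect in
SD units makes `θ_i` exactly the generative SMD, so recovery of μ is a
direct check of the whole pipeline. Defaults (chosen once as the realistic
operating point and not tuned): k = 13 datasets, μ = −1.7, residual
τ² = 0.3, 4–8 animals per arm, baseline 100 ± 20 (arbitrary units), an
anesthesia moderator at the corpus's level frequencies
(ketamine/xylazine 0.69, avertin 0.24, chloral hydrate 0.07) with
β_avertin = +1.7 — the null-study pattern — 25% of rows SEM-coded and 15%
range-coded (range = true n + 2, so the minimum-n rule recovers the size
actually used). Reproducibility: one root seed; replicate r uses
`SeedSequence(seed, spawn_key=(r,))`, so any replicate reruns in isolation.

What the generator does **not** emulate: non-normal outcomes (thresholded
areas and % injected radiation are bounded), correlated arms, publication
bias, digitization error from figure extraction, and dependence between the
moderators (in the real corpus anesthesia, KO line, and injection rate are
confounded). Passing recovery tests therefore show the estimators behave
correctly under the model's own assumptions, not that the published corpus
satisfies them.

## Numerical choices and limitations

- Problem sizes: the Monte-Carlo recovery checks use 2000 replicates at
  k = 20, 10 animals/arm (coverage, bias) and 500 replicates at k = 50,
  50/arm (null-τ² behavior) — large enough that binomial noise on coverage
  is ~0.5 percentage points.
- The large-sample SMD variance understates the exact sampling variance of
  Cohen's d at very small arms (factor ≈ m/(m−2) with m = n_t+n_c−2, ~12%
  at 10/arm); the generator-consistency check of
  `var(d) ≈ mean(v) + τ²` is therefore run at 50/arm, where the formula
  error is well inside Monte Carlo noise. DL coverage at small k sits
  slightly below nominal (~93% at k = 20), a known property of the
  estimator, not a defect of the implementation.
- Ties and degenerate inputs: zero pooled SD raises a degenerate-input
  error; I² uses the 0/0 → 0 convention; τ² estimates are floored at 0;
  all pooled statistics are invariant to study order (tested).
- Forest tables serialize to TSV with round-trip-exact float parsing, and
  the full report bundle embeds every active setting (effect method, τ²
  estimator, age rule, reference levels, filters) with no timestamps, so
  identical inputs give byte-identical outputs.
- Reproduction of the published pooled numbers requires the deposited
  per-study supplementary tables; the acceptance tests encode the full
  check (including trying DL then REML, since the original software's τ²
  estimator is not stated) and run it whenever transcriptions are placed in
  `data/`.
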