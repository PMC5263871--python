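# Methods

This note documents the models and procedures the package implements, the
choices made where the design was genuinely open, and what the synthetic
generator does and does not emulate. It states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## The debt of a single outcome measure

One record is a triple `(X_s, X_e, X_r)` plus a recovery time `T > 0`:
the value of an ecosystem attribute at recovery onset, after `T` years, and
in a reference system. The unknown trajectory between the two observations
is interpolated exponentially, `f(t) = X_s e^{rt}` with
`r = ln(X_e/X_s)/T`, reflecting the typically nonlinear shape of recovery;
a linear interpolation is provided as a sensitivity alternative. The
per-annum debt is

    RDt = X_r − (X_e − X_s) / ln(X_e / X_s)

(the reference minus the logarithmic mean of the endpoints), with the
analytic limit `RDt = X_r − X_s` when `X_e = X_s`. Declining trajectories
need no special casing: they simply give `r < 0`, and the same closed form
applies. The linear analogue replaces the logarithmic mean by the
arithmetic mean `(X_s + X_e)/2`. For increasing recovery below the
reference the exponential chord lies under the linear one, so the
exponential debt is systematically the larger of the two; the tests assert
this ordering and the suite's oracle checks both closed forms against
Simpson quadrature of the interpolated trajectory.

### Geometry of the triple

Five cases arise. `a`: recovering from below (`X_s ≤ X_e ≤ X_r`).
`b`: the end value exceeds the reference — this covers both the
both-above case and upward crossings, which receive the same treatment
(only values above the reference are reflected). `c`: declining below the
reference. `d`: crossing the reference downward (`X_s > X_r ≥ X_e`).
`e`: zero reference. Upward crossings are flagged in the output so
sensitivity runs can filter them.

Values above the reference are interpreted as equivalent deficits and
reflected below it with `Z = X_r²/X` — a multiplicative reflection with
fixed point at the reference. This form (rather than, say, `2X_r − X`) is
bounded: it cannot produce negative working values, and it caps every debt
ratio at 100% of reference. The same principle handles the rare case
`RDt > |X_r|`: the ratio becomes `100·|X_r|/RDt`, continuous at the
boundary (both branches give 100 there), at the cost of non-monotonicity
beyond it — a documented limitation, not an error. A negative `RDt`
(trajectory above reference after all transforms; possible only through
zero-constant adjustment) clamps to 0 and is flagged.

### Zero values

Zero endpoints or a zero reference break the logarithmic rate. Nine
candidate repair strategies are implemented: the fixed additive constants
0.01, 0.05, 0.1, 0.5, 1, and four record-specific amounts derived from the
decade `[10^k, 10^(k+1))` of `m = max(|X_s|, |X_e|)` (falling back to
`|X_r|`): the start of that decade, its median `5·10^k`, and the start and
median of the next decade up (for `m = 0.81`: 0.1, 0.5, 1, 5). A zero
reference is handled by adding the constant to all three values and
reclassifying; a zero endpoint by adding it to both endpoints after any
reflections. Records with all three values zero are unusable and are
excluded with a flag.

The strategy is selected from the data: for each candidate, the debt ratios
of zero-affected records are compared with those of the unaffected
remainder by a two-sided Mann–Whitney rank-sum test (exact enumeration when
both samples are ≤ 20 and untied, otherwise the tie-corrected normal
approximation); the selected strategy is the one not distinguishable from
the rest of the database (`p > 0.05`, ties broken by largest `p`), with a
flag when none passes.

## The three-level meta-analysis

Debt ratios are clustered within primary studies, so effect `i` in study
`j` is modelled as

    y_ij = x_ij' β + u_j + w_ij + e_ij,
    u_j ~ N(0, τ²_study),  w_ij ~ N(0, τ²_effect),  e_ij ~ N(0, v_ij known)

The two heterogeneity components are estimated by REML; `β` by GLS at the
estimates, with Wald 95% intervals (no Knapp–Hartung-type adjustment, and no
multiple-testing correction across categories). The marginal covariance is
block-diagonal by study and each block is a diagonal plus a rank-one
matrix, so the restricted likelihood is evaluated in O(n) via the Woodbury
identity — this is what keeps the 200-replicate coverage study and the
500-replicate Q_M study inside a few minutes on one CPU.

Numerical choices: the components are optimized on the natural scale under
box constraints `[0, ub]` with L-BFGS-B from five deterministic starting
points spread around a moment estimate of total heterogeneity, followed by
a Nelder–Mead polish (finite-difference gradients limit quasi-Newton
accuracy near the optimum). Boundary estimates of exactly 0 are expected
(categories with few studies) and reachable under this parameterization;
estimates below 1e-10 are truncated to 0. A saturated design (`n ≤ p`) pins
both components at 0. The reported restricted log-likelihood includes the
`+½ ln|X'X|` constant so values are directly comparable with standard
mixed-model software; one test cross-checks `μ`, `se`, both components and
the log-likelihood against an independent R implementation on a small
dataset, and the suite verifies that the optimizer dominates a dense zoomed
grid search of the REML surface.

Moderators are categorical. The reference-coded fit (with intercept)
provides the omnibus `Q_M` Wald chi-square on the non-intercept
coefficients with `df = categories − 1`; whether the omnibus test should
include the intercept is a convention, and this package adopts the
non-intercept-coefficients reading. The cell-means fit (no intercept)
provides per-category estimates and intervals. Categories with fewer than
two effects are set aside by the pipeline with a logged note rather than
entering a singular fit. Fixing `τ²_study = 0` with one effect per study
reduces the model to the standard two-level random-effects meta-analysis
(verified against a grid-plus-golden-section oracle).

Missing sampling variances — the majority case in ecological databases —
are imputed as the arithmetic mean of the observed variances within the
same recovery metric, with the `imputed` flag retained. This is defensible
exactly when heterogeneity dominates sampling error, which is why I² (the
Q-based form, computed on the variance-reporting subset, per metric) is
reported alongside every run: when I² is high, random-effects weights are
nearly uniform and the imputation is immaterial to the point estimates.
Subcategory contrasts (richness vs diversity indexes; pools vs fluxes) use
per-side pooled fits plus a Mann–Whitney test on the raw ratios, because
heavily skewed subcategory sizes make Wald contrasts unreliable.

The homogeneity test Q_E is deliberately not exposed: a random-effects
model is adopted here for conceptual reasons, with heterogeneity expected
a priori and quantified by I² instead.

## The synthetic generator

The generator emulates the conditions the estimators are designed for, with
every record constructed so that recomputing its debt ratio recovers the
realized truth exactly:

- 348 studies contributing 3–19 outcome measures each (~3,800 records);
  150-study databases are used for the replicated coverage studies.
- Per-record true ratio `ρ = clip(μ_metric + u_j + w_ij + ε_ij, 1, 99)`
  with defaults `τ²_study = 120`, `τ²_effect = 30`, sampling variances
  log-normal with median 4 — free parameters chosen so that heterogeneity
  dominates sampling error (I² > 90% on generated data, matching the
  regime the imputation strategy assumes). The clip keeps the constructive
  inversion well-posed; the clamping rate is recorded in the truth sidecar
  and a warning is raised if it exceeds 10%.
- True per-metric means 48.5 / 30 / 37 / 36% (abundance, diversity,
  carbon, nitrogen); moderator labels carry no true effect by default.
- Scenario mixture proportional to 1993 : 424 : 446 : 953 : 236 (a–e);
  zero endpoints on 628/3816 of records; 79% of variances masked,
  independently of effect size; recovery times log-normal with median 9
  years (ln-scale sd 0.857, giving mean ≈ 13).

Construction inverts the debt formula: for a target ratio, a feasible start
value is drawn and the end value solved by bisection on the logarithmic
mean (monotone in the end value). Scenario `b`/`d` records are built by
reflecting a below-reference pair above the reference (the reflection is an
involution, so the truth is preserved exactly); scenario `e` records by
translating a below-reference pair so the reference is exactly 0 while the
shifted endpoints' decade median equals the translation constant — hence
truth recovery for zero-affected records presumes the median-of-same-decade
strategy, which is also why the selection procedure, run on generated
databases, must and does pick it. Very low ratios (≲ 10%) cannot satisfy
the decade constraint; such draws fall back to regular scenario-`a`
records, slightly depressing the realized `e` share (the mixture test
allows for this).

The generator does not mimic real covariate distributions (climate class,
plot counts, areas), reporting biases, rounding, or correlations between
moderators and true effects. Passing recovery tests on synthetic data
therefore demonstrates estimator correctness under the stated model, not
robustness to model violations in real databases.

## Operating characteristics and problem sizes

`scripts/acceptance.py` and the acceptance tests compute: CI coverage of
the true pooled abundance debt over 200 replicated 150-study databases
(checked against the 93–97% band); Q_M type-I error at α = 0.05 over 500
null simulations of 100-study effect tables — 100 studies reflects the
scale of databases the model targets; at materially smaller study counts
the Wald Q_M is known to be anticonservative; REML-vs-grid agreement on 50
small datasets; quadrature agreement on 10³ triples; the [0, 100] ratio
bound on 10⁴ random records; and inversion roundtrips on 10³ draws. These
sizes are the package's own validation design and keep the full suite in
single-digit minutes on one CPU.

## Known limitations

- The debt ratio is non-monotone in `RDt` beyond `RDt = |X_r|` (the
  reflection branch), and upward crossings reflect only the exceeding
  value; both cases are flagged for sensitivity filtering.
- Exactly two time points per record: chronosequences must be collapsed to
  their first and last observations before ingestion; no multi-point
  trajectory fitting.
- Negative references are processed without reflection (flagged); ratios
  then use `|X_r|`.
- The Wald Q_M shows mild type-I inflation for small numbers of studies.
- Alternative likelihoods (log-normal, Gamma) and meta-regression on
  continuous covariates are out of scope; the normal-likelihood mixed
  model is the only pooling model implemented.
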