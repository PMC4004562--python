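# Methods

This note documents the statistical model behind `drmeta`, the choices
made where the design was genuinely open, and what the synthetic-data
generator does and does not emulate.

## Setting and estimand

Each source study reports, for ordered exposure categories
`c = 0, 1, …, K−1` of a continuous exposure (ALT, U/L), an adjusted
relative risk `RR_c` with 95% CI against the reference category `c = 0`
(so `RR_0 = 1`), plus the event count and participant total (or
person-time) per category. The estimand is the trend of log relative risk
in dose: a linear slope `β` (reported as `exp(increment·β)`, default
increment 5 U/L) and a restricted-cubic-spline curve for assessing
departures from log-linearity.

## Dose assignment

Categories are scored with a single dose: the reported in-category median
when the source printed one; the interval midpoint for closed intervals;
and, for open-ended intervals, the closed bound shifted by half the width
of the *nearest closed* category (bottom-open intervals floored at
0 U/L, since the exposure is nonnegative). The half-adjacent-width rule
for open intervals is a standard convention of this literature, not a
property of the data; it is deterministic and documented here because
primary sources rarely state how their open categories should be scored.
Assignment is idempotent and independent of category input order
(categories are sorted by dose first); non-monotone resulting doses are a
hard error naming the offending categories.

## Within-study covariance reconstruction

Because all category RRs share the reference group, the log-RRs
`L_i = ln RR_i` (i = 1…K−1) are positively correlated; treating them as
independent understates trend standard errors. The reconstruction fits
pseudo case counts `a_c` such that

* the crude RR formula of the study's design, applied to `(a_c, n_c)`,
  reproduces each adjusted `L_i` exactly, and
* `Σ_c a_c` equals the reported total case count.

Given `a_0`, every other `a_i` is explicit: for cumulative-incidence and
incidence-rate designs `a_i = e^{L_i} a_0 n_i / n_0`; for case-control,
`a_i = n_i r/(1+r)` with `r = e^{L_i} a_0/(n_0 − a_0)`. The margin
residual is strictly increasing in `a_0`, so the root is found by
bisection on `(ε, min(A, n_0))`, `ε = 1e−9·A`, tolerance `1e−10·A` on the
residual, 200 iterations maximum — bisection is preferred to Newton for
guaranteed bracketing, and the margin equation is solved by the same code
path for all three designs even though it is linear (closed-form) for the
two cohort designs. Exactness and margin conservation are re-verified
after every fit.

The covariance of `L` keeps the reported CI variances
`V_i = ((ln ci_hi − ln ci_lo)/2z)²` on the diagonal; all off-diagonal
entries equal the reference-cell contribution implied by the fitted
counts: `1/a_0 − 1/n_0` (cumulative incidence), `1/a_0` (incidence rate),
`1/a_0 + 1/b_0` (case-control). Positive definiteness is verified by
Cholesky factorization and its failure is an error pointing at the data:
it arises only for degenerate inputs (e.g. near-zero reference cells
whose reported CIs are inconsistent with the counts). The Hamling-style
variant (matching both margins and the reported variances) is deliberately
out of scope.

Degenerate inputs are handled conservatively: a category with zero
observed events gets a 0.5 continuity addition to its case count before
fitting (logged); a study with unusable counts degrades to a diagonal
covariance with a prominent warning, since that approximation understates
within-study correlation.

## Trend estimation

With design matrix `X` holding dose contrasts against the reference
(`d_i − d_0` for the linear model; Harrell spline basis differences for
the nonlinear model), the generalized least-squares estimator is

    β̂ = (XᵀC⁻¹X)⁻¹ XᵀC⁻¹ L,    cov(β̂) = (XᵀC⁻¹X)⁻¹,

solved via Cholesky factorization of `C`; a reciprocal condition number
below 1e−12 on the normal matrix is treated as rank deficiency (e.g. a
spline fit attempted with fewer than three non-reference categories).

The restricted cubic spline uses 3 knots `k1 < k2 < k3`, giving one
nonlinear basis term

    s2(d) = [(d−k1)₊³ − (d−k2)₊³ (k3−k1)/(k3−k2)
             + (d−k3)₊³ (k2−k1)/(k3−k2)] / (k3−k1)²,

zero below `k1` and exactly linear beyond `k3`. Knots sit at the 25th,
50th and 75th weighted percentiles of the pooled category-dose
distribution, weights being category totals. The weighted quantile uses
plotting positions `p_k = (C_k − w_k)/(W − w_k)` on the cumulative-weight
scale with ties aggregated — this reduces to the usual linear-interpolation
sample quantile under equal weights and is invariant to duplicating the
sample. "The pooled distribution" is ambiguous in this field's reporting;
total-weighted category doses are this package's documented choice.

Sex/subgroup strata of one study are combined by (multivariate)
fixed-effect inverse variance before cross-study pooling, so that no
cohort is double counted.

## Pooling, heterogeneity, nonlinearity

Fixed-effect pooling is inverse-variance (multivariate for the spline
pair). Random effects use the DerSimonian–Laird moment estimator:
`τ² = max(0, (Q − df)/(Σw − Σw²/Σw))` with fixed-effect weights, then
weights `1/(v_i + τ²)`. For the bivariate spline model the same moment
construction is applied with matrix weights `W_i = C_i⁻¹`:
`Q = Σ (β_i − β_FE)ᵀ W_i (β_i − β_FE)`, `df = 2(k−1)`, denominator
`Σ tr(W_i) − tr(S⁻¹ΣW_i²)` with `S = ΣW_i`, and a single scalar `τ²`
added to each coefficient's variance. A full unstructured between-study
covariance is not estimable from five studies (three extra parameters);
the scalar construction reduces exactly to the univariate formula and to
fixed-effect pooling when `τ² = 0`.

Heterogeneity is reported as `I² = max(0, 100·(Q − df)/Q)` with the
Higgins–Thompson test-based CI: `H = max(1, √(Q/df))`,
`se(ln H) = ½(ln Q − ln df)/(√(2Q) − √(2k−3))` when `Q > k`, else the
small-Q expression `√(1/(2(k−2))·(1 − 1/(3(k−2)²)))`; the interval is
built on the `ln H` scale around the *truncated* `H` and then mapped to
I² and clipped to [0, 100]. Centring on the truncated `ln H` (rather than
the raw value) is what reproduces the conventionally printed intervals
(0% with an upper bound near 79% for five homogeneous studies with
`p_Q = 0.59`); truncation is applied before, never after, the CI
construction on the H scale. For `k = 2` with small Q no variance formula
applies and the CI is reported as absent.

Nonlinearity: two-sided Wald test of the pooled second spline coefficient
(`z = β̂₂/se`). All CI multipliers are standard-normal quantiles, matching
conventional meta-analytic practice (not t).

## Publication bias and sensitivity

Egger's test is the classical unweighted OLS of the standardized effect
`β_i/se_i` on precision `1/se_i`, with a two-sided t-test (k−2 df) on the
intercept; the weighted variant is not implemented. Begg's test computes
Kendall's tau between variance-stabilized deviations from the
fixed-effect mean, `(β_i − β_FE)/√(v_i − v_FE)`, and the variances, by
exhaustive pair counting, with a continuity correction (|score| reduced
by 1) and tie-adjusted variance in the normal approximation. If
`v_i ≤ v_FE` numerically, that study's deviate uses a tolerance floor and
the event is logged. Both tests are severely underpowered at `k = 5`; the
report carries `k` next to the p-values. Leave-one-out re-pools the
remaining studies (random effects) after omitting each study in turn,
expressed per dose increment.

## Curve prediction

The pooled spline defines `ln RR(d) = x(d)ᵀβ̂` with
`x(d) = basis(d) − basis(d_ref)`, so `RR(d_ref) = 1` exactly; pointwise
bands use the delta method `var = x(d)ᵀ cov(β̂) x(d)`. The default grid is
100 evenly spaced doses over the observed range. Delta-method bands were
verified against Monte-Carlo propagation of the coefficient distribution
(10⁶ draws) to within 0.5% relative.

## Synthetic-data generator

The generator emulates the five-cohort setting the package targets:
participant counts (3,545; 1,097; 21,535; 2,957; 681) and per-study
baseline risks calibrated so the *expected* event counts equal the
published per-cohort cases (309; 226; 802; 608; 180) — cohort incidences
span 4%–26%, so a shared baseline would misrepresent the small
high-incidence cohorts. Individual ALT values are lognormal (median
14 U/L, ln-sd 0.55, category medians spanning roughly 6–40 U/L), cut into
quintile categories; events are binomial at the category-median dose with
risk `baseline·exp(logRR(d))`; each study is then summarized exactly as
sources report: crude category RRs with log-scale Wald CIs against the
lowest category, 0.5 continuity correction when a cell is zero. True
curves can be linear, piecewise-linear ("spline") or threshold-shaped;
between-study heterogeneity enters as a Normal(0, τ²) perturbation of the
slope, with default τ² = 0 (the homogeneous setting the motivating
literature reports). A single `numpy.random.Generator` threads through
all sampling; a fixed seed reproduces every byte.

What the generator does **not** emulate: covariate adjustment (simulated
RRs are crude; the pipeline consumes RR+CI regardless of how they were
adjusted), exposure measurement error or regression dilution, person-time
reporting quirks, and rounded/truncated published numbers. Passing
recovery tests therefore demonstrate correctness of the estimation
machinery under the reporting format, not robustness to confounding or
measurement error in real cohorts.

## Calibration results computed by the test suite

* Type-I error of the nonlinearity Wald test under a linear truth is
  compatible with the nominal 5% (1000 replicates).
* Parameter recovery of a true RR = 1.14 per 5 U/L at the published
  cohort sizes shows a mean pooled RR within about 0.15% of the truth
  (500 replicates). This small downward bias is real and intrinsic: GLS
  trend estimation weights each study and category by variances estimated
  from the same reported data (CI half-widths and the fitted reference
  cell), and those weights correlate with the estimates. Refitting the
  same replicates with the true covariance flips the bias to slightly
  positive (the Jensen term of the log transform), confirming the
  weight–estimate correlation as the source. At 500 replicates the
  Monte-Carlo standard error resolves this bias, so the strict
  "within 2 MC se" recovery assertion can fail even though the bias is
  negligible on any substantive scale; the test is kept strict rather
  than widened.

## Problem sizes and numerical defaults

Replicated experiments use 500 replicates (recovery) and 1000 replicates
(type-I calibration) of five-cohort meta-datasets at the published cohort
sizes — a few seconds each on one core. Bisection tolerance `1e−10·A`,
iteration cap 200; rank threshold 1e−12 on the reciprocal condition
number; p-values printed to 4 significant digits; output tables written
with 12 significant digits, summaries as sorted-key JSON so reruns are
byte-identical.
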