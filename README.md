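# drmeta — dose-response meta-analysis of category-level cohort results

`drmeta` estimates a pooled dose-response relationship between a continuous
exposure and a binary outcome from *published, category-level* study
results — the situation of a typical epidemiological meta-analysis, where
each cohort reports adjusted relative risks (RR) with 95% CIs for 3–5
exposure categories against a shared reference category, plus the event
count and participant total per category. The motivating application is
circulating alanine aminotransferase (ALT, U/L) as the exposure and
incident metabolic syndrome as the outcome, pooled over five prospective
cohorts, but the machinery is generic.

## What it computes

For each study with log relative risks `L = (ln RR_1, …, ln RR_m)` for the
non-reference categories:

1. **Covariance reconstruction (pseudo-counts).** Category RRs share a
   reference group, so the `L_i` are correlated. `drmeta` fits pseudo
   case counts `a_i` that reproduce each adjusted `L_i` exactly through
   the design's crude-RR formula while conserving the study's total case
   margin (one-dimensional root finding on the reference cell `a_0`).
   The off-diagonal covariance is `1/a_0 − 1/n_0` (cumulative incidence),
   `1/a_0` (incidence rate) or `1/a_0 + 1/b_0` (case-control); reported
   CI variances stay on the diagonal.
2. **Generalized least-squares trend.** With dose contrasts
   `x_i = d_i − d_ref` (linear) or a 3-knot restricted-cubic-spline basis,
   `β̂ = (XᵀC⁻¹X)⁻¹ XᵀC⁻¹L`, `cov(β̂) = (XᵀC⁻¹X)⁻¹`. Sex/subgroup strata
   are combined within study by fixed-effect inverse variance.
3. **Pooling.** Fixed-effect and DerSimonian–Laird random-effects
   combination across studies (multivariate for the two spline
   coefficients), with Cochran Q, I² and its Higgins–Thompson test-based
   95% CI. Nonlinearity is judged by a Wald test that the pooled second
   spline coefficient is zero.
4. **Diagnostics.** Egger regression and Begg rank-correlation tests for
   funnel-plot asymmetry, a funnel table for plotting, and leave-one-out
   re-pooling.
5. **Reporting.** The linear trend is expressed as an RR per dose
   increment (default 5 U/L), `RR = exp(5·β̂)`, and the spline curve as
   RR versus dose anchored at RR = 1 at a reference dose (default the
   lowest assigned dose), with delta-method confidence bands.

Open-ended exposure categories get a scalar dose by the standard
half-adjacent-width convention; reported category medians always win.

A synthetic-data module generates five-cohort meta-datasets with a known
true curve, matching the published cohorts' participant and event margins,
so the whole chain is testable end to end without access to primary data.

## Worked example

Simulate a five-cohort study table with a true RR of 1.14 per 5 U/L and
analyse it:

```bash
drmeta simulate --out studies.csv --seed 11
drmeta run --input studies.csv --out results/
```

`results/summary.json` from this exact run contains (abridged):

```
RR per 5 U/L: 1.127 (1.090-1.166)
I2 = 38.9%, 95% CI (0%, 77%), p_Q = 0.16
P nonlinearity (random effects): 0.7789
Egger p: 0.2729   Begg p: 0.8065
Leave-one-out RR range: 1.117 - 1.141
knots: [10.5, 14.0, 18.7]
```

Read: the pooled linear trend estimates a 13% higher metabolic-syndrome
risk per 5 U/L of ALT (the generating truth was 14%, within the CI);
heterogeneity is compatible with chance; the spline term gives no evidence
of departure from log-linearity (as it should — the truth was linear);
neither asymmetry test suggests small-study effects; and no single cohort
drives the result. `results/` also holds `curve.tsv` (the RR-versus-dose
curve with its band), `per_study.tsv`, `funnel.tsv` and `manifest.json`.

`drmeta validate --input studies.csv` checks a table against the data
contract (exit 0 = clean) and prints one finding per violated rule.

## Input format

Long-format CSV, one row per exposure category:

```
study_id, stratum_id, design, label, dose_low, dose_high, dose_assigned,
rr, ci_low, ci_high, cases, total, is_reference, followup_years
```

`design` ∈ {cumulative_incidence, incidence_rate, case_control}; empty
string means absent (open interval bound, unreported median); the
reference category is flagged explicitly, carries `rr = 1`, and `total`
is person-time for incidence-rate designs. See `docs/methods.md` for the
statistical details and design choices.
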