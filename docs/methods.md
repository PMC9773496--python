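# Methods

`metaepi` implements a two-step meta-epidemiological analysis comparing
intervention effect estimates between randomised trials recruiting in
primary care (PC) and in secondary or tertiary care (ST), across a
collection of meta-analyses (MAs) of binary outcomes.

## Model

**Trial effects.** Each trial contributes an odds ratio on the natural-log
scale. With cells a (events, experimental), b (non-events, experimental),
c, d (control):

    log OR = ln(ad/bc),    Var(log OR) = 1/a + 1/b + 1/c + 1/d   (Woolf)

Events are re-coded per MA so that OR < 1 always means benefit of the
experimental intervention: for MAs whose outcome event is desirable
(e.g. smoking cessation), events and non-events are swapped in both arms,
which replaces the OR by its reciprocal. Trials with no event in both arms
carry no information about the OR and are excluded; trials in which every
patient had the event are treated symmetrically. When exactly one cell
pattern is zero, 0.5 is added to all four cells (Haldane–Anscombe); this
correction is configurable off, in which case single-zero trials are
excluded too.

**Step 1 — per-MA meta-regression.** Within MA *k*, trial log-ORs are
modelled as

    y_i = β0 + β1 x_i + u_i + ε_i,   x_i = 1 for PC trials,
    u_i ~ N(0, τ²_k),   ε_i ~ N(0, v_i)  with v_i known,

fitted by weighted least squares with weights 1/(v_i + τ̂²_k). β1 is the
log ratio of odds ratios: ROR = exp(β1) = OR(PC) / OR(ST), with ROR < 1
meaning smaller apparent benefit in primary-care trials. Estimation
requires at least 3 analysable trials with both settings represented (the
eligibility filters enforce the same floor at selection time).

**Step 2 — pooling across MAs.** The per-MA log-RORs, with sampling
variances se², are combined by a univariate random-effects meta-analysis
with between-MA variance τ². Heterogeneity is summarised by Cochran's Q
(computed at fixed-effect weights), I² = max(0, (Q − df)/Q)·100 with its
95% CI, and τ̂².

**Subgroups and adjustment.** Planned subgroup analyses split MAs by
intervention type (pharmacological vs non-pharmacological), control group
(active vs inactive, where inactive = placebo, no added intervention to
usual care, or sham; "other" comparators are excluded from this
dichotomy and counted), and outcome objectivity (objective = all-cause
mortality or objectively assessed; subjective = clinician/patient-influenced
or subjectively assessed; "unclear" excluded and counted). Each subgroup
is pooled with its own τ² — re-using a common τ² across subgroups is the
main alternative; per-subgroup estimation is the more conservative choice
when subgroup heterogeneity differs. Differences between subgroups are
tested with the fixed-effect Q statistic across the random-effects
subgroup estimates, Q = Σ_g w_g (θ̂_g − θ̂̄)², w_g = 1/se²_g, referred to a
χ² distribution with (groups − 1) df — the standard two-stage subgroup
interaction test. Sensitivity analyses re-fit step 1 with one
dichotomised Cochrane risk-of-bias domain (high/unclear/missing vs low)
as an extra moderator; when the covariate is constant within an MA the
pipeline falls back to the unadjusted estimate for that MA and logs the
fallback, and collinear designs are reported as degenerate.

## Variance estimators and intervals

τ² is estimated by REML (default) or DerSimonian–Laird moments; both are
exposed because either is defensible for this design and published
analyses rarely say which was used.

* **DL (moments).** With fixed-effect weights W = diag(1/v) and hat-free
  projector P = W − WX(X′WX)⁻¹X′W, τ̂² = max(0, (Q_E − (n−p)) / tr P),
  the moment estimator generalised to models with moderators. Negative
  moment solutions are truncated at zero.
* **REML.** The estimate solves the restricted score equation
  y′PPy = tr P. A non-positive score at τ² = 0 puts the maximiser on the
  boundary. Otherwise Fisher scoring (update (y′PPy − tr P)/tr PP),
  started from the DL value, runs until |Δτ²| < 1e-8 (max 100
  iterations); because plain scoring is only linearly convergent and can
  oscillate near flat maxima, the first iterate that crosses the root
  closes a bracket that is finished by Brent root-finding (xtol 1e-12).
  Non-convergence is flagged on the result, reported by the pipeline and
  excluded from pooling, never silently dropped.

Coefficient intervals are Wald-normal by default; the Knapp–Hartung
adjustment (covariance scaled by the weighted residual mean square,
t reference with n − p df) is available by flag and is advisable when
many MAs have only 3–4 trials. The I² interval uses the test-based
log-H method: H = √(Q/df), se(ln H) = ½(ln Q − ln df)/(√(2Q) − √(2k−3))
for Q > k and the small-Q variance formula otherwise, limits mapped
through I² = 100(H²−1)/H² and truncated to [0, 100]. With df = 1 and
Q ≤ 2 the small-Q formula is undefined and the maximally wide interval
(0, 100) is returned. The Q-profile method was considered as an
alternative; the test-based method was chosen as the more widely
implemented default.

## Selection rules

Applied in a fixed order, each stage emitting a reconciliated report:
(1) one MA per review — the primary-efficacy-outcome MA when flagged,
else the MA with most trials; (2) within-MA duplicates keep the row with
the largest randomised sample size; (3) trials appearing in several MAs
stay in the most recent review's MA; (4) eligibility: ≥ 3 trials, ≥ 1 PC
and ≥ 1 ST. Ties at (2) and (3) are undetermined by the rules; they are
broken deterministically (first-listed row; lexicographically smallest
review id) and always logged. The 3-trial floor is evaluated on listed
trials by default — selection precedes analysis — with a switch to count
only analysable (non-double-zero) trials instead.

## Synthetic cohorts

The generator draws, per MA: a true control-vs-experimental log-OR
δ_k ~ N(μ_δ, σ²_δ), a true setting effect b_k ~ N(μ_b, τ²_between), and a
within-MA variance τ²_k ~ Gamma. Per trial: a control risk from a Beta
distribution, a trial-level deviation e_i ~ N(0, τ²_k), true
log-OR = δ_k + b_k x_i + e_i, experimental risk via the odds transform,
and Binomial event counts per arm.

Defaults are anchored to the cohort the pipeline targets: 76 MAs; trial
counts 1 + Poisson with means 1.2 (PC) and 2.5 (ST), giving medians of
2 PC and 3 ST trials per MA; log-normal sample sizes with medians 276
(PC, log-sd 1.0) and 139 (ST, log-sd 1.08, floor 20), matching the
reported medians and approximating the reported interquartile ranges;
control risks Beta(2, 5) (median ≈ 0.26 — typical binary-outcome trial
risks; no cohort summary exists for this quantity); μ_δ = −0.3 with
σ²_δ = 0.25 (modest true benefits varying across topics); μ_b = ln 0.97
and τ²_between = 0.07, the cohort-scale values; τ²_k ~ Gamma(1.5, 0.04)
(mean 0.06, mild within-MA heterogeneity). About 30% of MAs are coded
with a beneficial outcome event, in which case the stored counts are on
the beneficial coding and the pipeline's re-coding recovers the
harm-coded truth. Categorical metadata (medical field, control type,
outcome class, risk-of-bias levels) follow the cohort's category
frequencies. Sparse cells and zero-event arms arise naturally from small
trials at low risk; `force_zero_arm_frac` additionally zeroes control
arms to exercise the continuity-correction path.

One integer seed drives everything; per-MA substreams are spawned from a
`SeedSequence`, so datasets are bit-identical under the same seed.

What the generator does **not** emulate: correlation between trial size
and effect (small-study effects), non-normal between-trial effect
distributions, correlated risk-of-bias domains, outcome misclassification,
or the literature-screening process. Passing recovery tests therefore
show that the estimator chain is consistent and calibrated under its own
assumptions — not that those assumptions hold in any real cohort.

## Problem sizes and numerical checks

The Monte-Carlo experiments run at the cohort scale of 76 MAs: 500–1000
replicates for bias and interval coverage of the combined log-ROR
(empirical Monte-Carlo standard errors ≈ 0.003 on the log scale), and
2000 replicates for the interaction test's type-I error under a null
split, simulated at the second-step level (true log-RORs plus sampling
noise with standard errors uniform on 0.15–0.6, the precision range of
typical step-1 estimates). REML estimates are verified against a
grid-plus-refinement maximisation of an independently coded restricted
likelihood (agreement to 1e-6) and against R's `metafor`; DL against its
closed-form moment expression and against `statsmodels`' pooled DL.

## Known limitations

* The Woolf variance and the 0.5 correction are large-sample devices; with
  very rare events, per-trial estimates are biased toward the null and no
  continuity rule is fully satisfactory. Whether the original two-step
  analyses corrected, and how, is generally unreported; both behaviours
  are available.
* Step 2 treats step-1 standard errors as known, the usual two-step
  simplification; it understates uncertainty when MAs have very few
  trials (the Knapp–Hartung flag mitigates this at both steps).
* Trials are matched across reviews by identifier only; no fuzzy
  author/year matching is attempted.
* Quartiles in descriptive tables use linear interpolation between closest
  ranks; published tables using another convention will differ slightly.
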