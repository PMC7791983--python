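# Methods

This note documents the statistical content of the package: the
responsiveness statistics, the threshold family, the Box-Cox regression
stage, the synthetic cohort generator and its calibration, the numerical
choices, and what the tests do and do not establish.

## Setting

One record per patient: a pre-operative and a 6-month post-operative
score on one instrument (OHS/OKS, integer 0–48, or the EQ-5D-3L index,
−0.59 to 1 at 0.001 resolution), a five-level transition anchor
(*much better* … *much worse*), age, gender, 12 binary comorbidity
flags, and a collection-period label (2009–2011 / 2012–2015). All scales
ascend, so the change score `d = post − pre` is positive for
improvement. The analysis is complete-case throughout: invalid or
missing rows are rejected at ingest with row-numbered diagnostics, never
imputed — the cohorts this mirrors were themselves restricted to
patients completing both questionnaires.

## Univariate responsiveness

For a cohort (or a transition stratum) with mean change `m`, change SD
`s`, and pre/post Spearman correlation `r`:

* naive ratio `m/s`;
* **paired-data SRM** `= (m/s) / (√2·√(1−r))`. The denominator converts
  the paired ratio to the scale of an independent-groups contrast; it
  exceeds the naive ratio when `r > 0.5` and equals it at `r = 0.5`.
  `r` is the Spearman coefficient, not Pearson: the rank correlation is
  the one robust to the scores' ceilings, and the one the summary tables
  this package reproduces report. Undefined at `r = 1`.
* **SES** `= |mean(pre, all) − mean(post, improved)| / sd(pre, improved)`
  where "improved" pools the *much better* and *a little better* anchor
  levels. The denominator is deliberately the pooled improved-subjects
  pre-operative SD (the convention of the worked example this reproduces)
  rather than a per-stratum SD; `ses_denominator="stratum"` switches to
  each stratum's own pre-SD for stratum rows.
* **RI** `= (mean d, a little better − mean d, about the same) /
  sd(d, about the same)`. Computed for cohort totals only, since it
  consumes two strata by construction.
* Effect labels use Cohen's practical thresholds: |x| < 0.5 small,
  0.5–0.8 moderate (boundaries inclusive), > 0.8 large.

**Confidence intervals.** No analytic distribution is attempted for
these composites; `summarize` attaches nonparametric patient-level
bootstrap percentile intervals (default 1000 replicates, seeded).
Stratum-level resampling is within-stratum with the cohort-level
anchor quantities held fixed. Spearman's own CI uses the Fisher-z
normal approximation with SE `1/√(n−3)`.

## Improvement thresholds

* **Paired MCID** `= SRM_paired · √2 · √(1−r) · s`, evaluated through
  the identity so it stays consistent with whichever SRM produced the
  summary; algebraically it equals the cohort mean change. For Oxford
  scores the reported threshold rounds *up* to the 1-point resolution
  (a patient must clear the full capacity of benefit; this turns the
  calibrated mean changes 21.1 / 15.8 into thresholds 22 / 16); the
  EQ-5D threshold is left unrounded at 0.001 resolution. Both behaviours
  are configurable.
* **Independent MCID** `= d · √2 · √(1−r) · s` for Cohen's d ∈ {0.5, 0.8}
  by default.
* **MDC95** `= 1.96 · √2 · sd(pre) · √(1−ICC)` with the improved-subjects
  pre-operative SD as baseline dispersion and ICC 0.9 by default. This is
  the standard construction for the smallest change beyond test-retest
  measurement error; no other formula is in scope.
* A patient is **improved** iff `d ≥ threshold` (boundary inclusive, so
  the capacity-of-benefit score itself qualifies).
* An anchor-based "short-distance" MCID has no standard computable
  definition; `McidSet` can carry such a value as user-supplied metadata
  only, clearly labelled as not computed.

## Box-Cox regression stage

The post-operative score, shifted strictly positive (+1 for Oxford
scales, +0.60 for the EQ-5D index), is transformed by
`T(y; θ) = (y^θ − 1)/θ` (log at θ = 0) and regressed on a polynomial in
the pre-score — cubic for Oxford scores, quadratic for EQ-5D — plus
untransformed covariates (age in years, a female indicator, comorbidity
flags). Modelling the post score rather than the change avoids
transforming a variable that is negative for deteriorating patients;
change is derived at prediction time.

θ is chosen by profile maximum likelihood on a grid over [−2, 2] with
step 0.01, refined by bounded scalar optimization to 1e-4, with the
Jacobian term `(θ−1)·Σ log y` included so likelihoods are comparable
across θ. One QR factorization of the (θ-free) design is reused across
the entire profile. Rank-deficient designs and constant responses are
rejected, and the refinement is guarded never to return less than the
grid maximum.

**Prediction.** The default prediction inverts the transform at the
fitted linear predictor — the conditional *median* of the post score,
matching a percentile-style presentation; a conditional-mean option
integrates the inverse transform over the Gaussian residual with 21-node
Gauss-Hermite quadrature. Linear predictors outside the transform's
invertible domain (`θη + 1 ≤ 0`) yield undefined predictions, which are
counted, logged and excluded from percentages rather than silently
dropped — the analogue of the absent predicted cells that ceiling
effects produce in lower transition strata. Predicted change is
predicted post minus *observed* pre; predicted improvement applies the
same threshold rule as observed improvement.

**Covariate screening.** Each candidate (age, gender, 12 comorbidities)
is added alone to the pre-score-only model at that model's fitted θ; it
is selected only if both its Wald chi-squared statistic and its absolute
coefficient exceed thresholds. The reference analysis used absolute
cutoffs (chi-squared 2000, |coefficient| 200) at a cohort of ~181k and
its own transformed-response scale; since both statistics scale with
sample size and response units, the defaults here rescale them — the
chi-squared cutoff proportionally to `n`, the coefficient cutoff as 0.4
of the transformed response's SD (the fraction the absolute cutoff
corresponds to at the source scale). Both are overridable; the
adaptation is a design choice of this package, not a published rule.

## Synthetic cohort generator

The generator's job is to produce cohorts with the joint structure the
analysis assumes, calibrated to published summary tables, so that the
full pipeline is testable without licensed data.

Per transition stratum: `(pre, change)` are drawn from a Gaussian copula
with normal margins (or, for EQ-5D multimodal mode, a 3-component normal
mixture margin for change, sampled through the copula by numerical CDF
inversion so the rank dependence is preserved). Then `post = pre +
change`, both scores are clipped to the instrument range and rounded to
its resolution, and the stored change is re-derived as `post − pre`.
Comorbidity effects enter as mean-centred additive shifts
(`effect · (flag − prevalence)`) on the latent change, so subgroup
contrasts exist without moving the population mean. Ages are truncated
normal on [13, 102]; gender, comorbidity flags and period are Bernoulli
draws at the scenario prevalences. Everything is driven by one seed
through a spawned seed tree: identical spec ⇒ byte-identical CSV.

**Calibration.** Clipping and rounding perturb moments — the Oxford
ceiling at 48 is genuinely engaged (the hip preset leaves ~15% of raw
draws above a bound, EQ-5D ~28%, matching the well-known ceiling effect
of these instruments; the fraction is reported in cohort metadata, not
hidden). The latent change mean/SD and the copula correlation are
therefore calibrated per stratum by a damped fixed-point search under
common random numbers (default: 8 iterations on a 50k panel, seconds per
cohort): simulate, measure the observed change mean/SD and
Spearman(pre, post), shift/rescale/nudge, repeat. Observed moments then
land within combined Monte-Carlo error of the targets.

**Presets.** Four presets (`hip-ohs`, `hip-eq5d`, `knee-oks`,
`knee-eq5d`) encode published per-stratum change means/SDs, pre-means,
Spearman targets, transition proportions (renormalized over transition
respondents, which is what makes the stratum means mix back to the
published totals), and baseline covariate prevalences. Where a needed
value is not published, the presets use the value implied by the
published statistics: one pre-SD per instrument (hip Oxford 7.9 from the
improved-subjects SD; knee Oxford 7.1, implied by the published SES with
its printed means; EQ-5D 0.267, implied by the published MDC at ICC
0.9), and EQ-5D much-better change means/SDs refined within their
1-decimal printing precision so the mixture reproduces the 3-decimal
published totals (0.428 and 0.309). Default comorbidity effect sizes are
small negative shifts on the covariates the screening stage is meant to
find (circulation/depression for hip, plus diabetes for knee) and are
free parameters for recovery tests.

**EQ-5D multimodality.** Observed EQ-5D-3L change histograms are
multimodal because the index lives on a coarse, irregular grid of
attainable tariff values with full health isolated at 1.0. Multimodal
mode emulates this with two devices: the mixture margin for change, and
snapping of pre/post scores to a *synthetic* evenly spaced lattice of
attainable index values with an isolated ceiling (no real value set is
computed — the package consumes indices as given, and the lattice is
labelled synthetic). Under the calibrated moments the mixture alone is
smeared unimodal by the ceiling; with lattice snapping the change
histogram shows a clear comb (≥ 5 modes at n = 50k) while the calibrated
moments and Spearman are preserved to the third decimal.

**What the generator does not emulate** — hence what passing tests do
not show about real data: item-level Oxford response patterns and EQ-5D
dimension profiles (scores are generated at summary level); real tariff
values; informative missingness (the generator emits complete cases
only); non-Gaussian within-stratum dependence beyond the copula; and any
real-data percentages — the observed/predicted improvement percentages
of the licensed cohorts are not reproducible from synthetic data, and
the test suite instead checks structural invariants (stratum ordering,
exact aggregation, internal consistency of predicted vs observed
percentages on the same cohort).

## Evaluation and reporting

Observed improvement percentages are exact counts at the threshold,
total and per stratum; the weighted stratum average equals the total
identically. AUC is the pairwise concordance probability (ties credited
0.5), with either a Hanley–McNeil normal interval (default) or a
Clopper–Pearson interval treating the concordant share of the
`n₊·n₋` pairs as binomial successes — the latter is one conservative
reading of an "exact binomial" interval for a concordance probability,
and both are labelled in output. The AUC predictor is the model's
predicted change scored against observed improvement, within stratum for
per-level cells; single-class cells are reported absent. The two-period
sensitivity check reruns the total summary on each period subset and
reports differences with within-period bootstrap CIs, leaving the
judgment of materiality to the reader. The assembled report serializes
deterministically (sorted keys, 6-decimal rounding) with the config hash
embedded.

## Numerical choices and problem sizes

* Bootstrap: percentile intervals, default 1000 replicates; the pipeline
  default is 200 for routine runs.
* θ search: grid [−2, 2] step 0.01, bounded refinement to 1e-4; fits at
  the grid boundary (the Oxford presets profile to θ = 2) are reported
  as-is.
* Improvement boundary: `d ≥ threshold`, with a 1e-9 float-fuzz guard;
  ceil-rounding likewise guards against `22.0000001 → 23`.
* Test and calibration sizes were chosen so sampling error is small
  relative to the tolerances checked: n = 50,000 cohorts for preset
  recovery (Monte-Carlo SE of the total SRM ≈ 0.006), n = 20,000 ×
  20 replicates for θ recovery, 50k calibration panels.

## Known limitations

* The calibrated presets reproduce first/second moments, rank
  correlations and proportions — not the full joint distribution of the
  real cohorts; statistics sensitive to higher moments (e.g. the exact
  improvement percentages) will differ from any real extract.
* Stratum-level SES uses the pooled improved-subjects pre-SD by default;
  the per-stratum alternative changes stratum SES values materially when
  stratum pre-dispersions differ.
* The Box-Cox stage fits a single model per cohort and stratifies at
  prediction; no per-stratum transform parameters are estimated.
* The MDC's baseline SD convention (improved-subjects pre-SD) is one of
  several defensible choices; the MDC is sensitive to it.
* Screening thresholds are a rescaled adaptation of absolute published
  cutoffs; at very small n the chi-squared cutoff becomes permissive and
  the coefficient cutoff dominates.
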