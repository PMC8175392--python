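# Methods

## The analysis problem

Overweight/obese postmenopausal women differ widely in how they accumulate
sitting time: some sit in short, frequently interrupted bouts, others in long
uninterrupted ones. The pipeline asks whether this *pattern* — summarized by
mean sitting-bout duration — is associated with the microRNA cargo of
endothelial-cell-derived extracellular vesicles, using a two-stage design:
a pooled-RNA screening of an 84-assay CVD miR panel, then individual-sample
validation of five candidates in ethnicity-augmented groups. Because the
exposure is observational, comparisons are adjusted by inverse-probability
weighting with a covariate-balancing propensity score.

## Behavioral metrics

Minute epochs carry activity counts and a posture label (`sit`, `stand`,
`move`, `walk`). Non-wear is detected by a zero-run scan: a minute is
non-wear iff it lies in a run of ≥ `window` (default 90) zero-count minutes,
where up to `spike_tolerance` (2) consecutive nonzero minutes are absorbed
when flanked by ≥ `flank` (30) zeros on both sides. The named algorithm's
parameters are not fixed by convention everywhere, so all three are exposed.
An adherent day has ≥ 600 wear minutes; participants need ≥ 4 adherent days.
Sitting bouts are maximal runs of sit-labelled wear minutes with no minimum
duration and no tolerance; bouts never bridge non-wear gaps or midnight.
The participant's mean sitting-bout duration pools bout durations across
adherent days before averaging (the mean-of-daily-means variant is available
via `bout_mean_per_day=True`; with heterogeneous day lengths the two differ).
MVPA is the count of wear minutes at ≥ 1952 counts/min (inclusive).

## Phenotyping and pooling

Quartiles are computed cohort-wide over all adherent participants with linear
interpolation between order statistics; ties at a cut go to the lower
quartile (so a constant vector is all Q1). IS = bout Q1 ∧ MVPA Q1;
SS = bout Q4 ∧ MVPA Q1. Augmentation adds Hispanic participants from MVPA Q2
at bout Q1 (→ IS+) or Q4 (→ SS+). Pools hold 3 members (one pool of 2 when
the group size is 2 mod 3; one pool of 4 when it is 1 mod 3, chosen over two
pools of 2 to minimize pool-count distortion; configurable). A greedy
assignment draws each pool's members from distinct parent studies whenever
the remaining inventory allows, with seeded random tie-breaking.

## Expression

Pooling equal RNA masses averages molecule abundance linearly, so pooled
Ct = −log2(mean of 2^−Ct) over detected members. Relative expression is
2^−ΔCt with ΔCt = Ct(target) − mean Ct(stage controls): the array control
panel at screening, SNORD61 + the cel-miR-39 spike-in at validation.
Not-detected reactions are missing, never imputed to a ceiling cycle; the
scale of relative expression is arbitrary but consistent within a stage.

## Weighting

The treatment indicator is T = 1 for the SS side. The propensity is logistic
in seven covariates (physical functioning, MVPA, wear days, wear time, waist,
BMI, age), with coefficients solving the just-identified ATE balance moments
(1/n) Σ [T/π − (1−T)/(1−π)] x = 0 (x includes an intercept). At a root,
inverse-probability-weighted first moments of every covariate are *exactly*
equal across arms — the property the tests assert at 1e−6. Numerically:
covariates are standardized internally; the solver is damped Newton with
analytic Jacobian from the logistic MLE start (tolerance 1e−8 on the moment
norm, ≤200 iterations with step halving), backed by a trust-region root
finder.

An exact root need not exist. With few units in one arm relative to the
covariate dimension — e.g. five IS pools against seven covariates — the
control units' convex hull may not intersect the treated hull, and then *no*
positive weights balance first moments (verifiable by linear programming).
This is intrinsic to pooled-stage weighting, which is why such analyses
report residual imbalance rather than exact balance. `cbps_fit` raises by
default; with `on_infeasible="best"` it returns the minimum-moment-norm
(GMM) fit flagged `converged=False`, which the pipeline uses at both stages
so that bootstrap resamples do not abort. Balance diagnostics (standardized
average differences of covariates, squares, and pairwise interactions using
the pooled unweighted SD, plus weighted Kolmogorov–Smirnov statistics) report
what the weighting actually achieved.

Weights are stabilized by the marginal treated fraction
(w = p̄/π̂ or (1−p̄)/(1−π̂)) and then normalized to mean 1 within each arm
(Hajek form). The normalization is exact by construction and leaves every
ratio-of-means estimator unchanged; the intercept moment alone only equates
the two arm-wise weight sums, not their level.

Missing covariates (waist, physical functioning) are completed by a single
chained-equations imputation with predictive mean matching: OLS on the other
covariates, donor = observed value of one of the k = 5 nearest predicted
means (seeded draw), 10 cycles. Imputed values always lie in the observed
support.

## Effect estimation and selection

ATE(miR) = weighted mean expression (T=1) − weighted mean (T=0). Uncertainty
comes from a stratified bootstrap (arm sizes preserved, B = 1000 by default)
that re-fits the CBPS and re-derives weights inside every resample, so
propensity-model variability propagates; resamples whose fit fails are
redrawn, and more than 10% failures is an error. The 95% CI is the normal
approximation ATE ± 1.96·SD_boot (this reconstructs the reported validation
bounds for three of five candidates at printed precision; a percentile CI is
available by flag — the remaining row is consistent with neither at printed
precision, so no special casing is done). Standardized ATE = ATE / SD_boot;
significance = CI strictly excluding zero (lower > 0 or upper < 0, so a
bound exactly at zero is not significant). Screening ranks by |standardized
ATE| (ties: |ATE|, then name) and keeps the 5 of the top 10 with the largest
unweighted SD — a guard against assays whose small variance inflates the
standardized effect. All resamples are shared across the 84 assays within a
run, which is what "refit per resample" implies when the weights do not
depend on the outcome. No multiplicity correction is applied; the selection
is rank-based.

## Enrichment

Per pathway P, query Q (union of the candidates' target genes), universe U:
one-sided Fisher's exact p on (|P∩Q|, |P∖Q|, |Q∖P|, |U∖(P∪Q)|), ranked
ascending. Pathways, target maps, and the universe are always user-supplied
files; no database content is bundled, because predicted-target resources
are versioned external services.

## The synthetic cohort generator

One latent sitting propensity s ~ N(0,1) per participant drives everything
behavioral: mean bout duration 39·exp(0.45·s) min (median 39, ±1 SD spans
≈ 25–61 min, matching the short-bout/long-bout group contrast), total
sitting 603 + 110·s min/day of a 14–16 h wear window, MVPA
3.5·exp(−0.15·s + 0.45·ε) min/day (weak negative coupling calibrated to a
~1.4× MVPA ratio between the bout extremes), walking similar. Days are
alternating lognormal sit/break renewals filled with posture-conditional
counts (sit/stand 0–99, daily movement 100–759, walking 760–1951, MVPA
1952–5000 cpm); worn days vary uniformly between `min_days` (4) and `n_days`
per participant. Covariates: age truncated-normal (mean 65.9, SD 6.6, min
55), BMI lower-truncated at 25, waist correlated with BMI, physical
functioning in [0,100] loading negatively on s, Hispanic fraction 0.34,
parent studies 30/59/11%. A shared factor z feeds both s and (for designated
miRs) expression with one path coefficient, `confounding_strength`, so
weighting demonstrably removes bias. Ct values are
control-baseline − log2(expression) with log2 expression =
baseline_j + effect_j·s + confounding path + N(0, σ); control assays sit at
the baseline with SD 0.1 cycles. Missingness is MCAR on waist and physical
functioning only — real missingness mechanisms may not be, and passing
imputation tests here says nothing about MNAR data. Other idealizations:
posture labels are error-free, assay noise is lognormal with no
amplification-efficiency or batch structure, and pooling is exactly
equal-mass; real data violate all three, so passing tests demonstrate
correctness of the statistical machinery, not field performance.

`generate_confounded_trial` is the parameter-recovery harness: covariates
from the cohort generator, treatment logistic in a standardized linear
covariate score (correctly specified propensity), outcome
effect·T + confounding·score + N(0,1), so the true ATE is exactly the
configured effect. The full pipeline's group ATE has no closed form (it
depends on realized quartile cells), which is why coverage is checked on
this trial design.

## Problem sizes in the test suite

Chosen to make the checks statistically decisive: bias/coverage over 200
replicate trials (n = 120, B = 200; the [0.90, 0.985] coverage band is ±3
binomial SDs around 0.95); planted-signal recovery over 50 replicate cohorts
(n = 400, ≤5 worn days, effects 1.5 log2 units/unit s, B = 100) requiring
≥90% exact recovery of the planted five; null calibration over 24 replicates
with a per-miR selection-count bound of 8 (≈4.9σ under uniform 5/84
selection); Fisher oracle equivalence on every 2×2 table with total count
≤ 30. All randomness is seeded; there is no wall-clock seeding anywhere.

## Known limitations

- Pool-level weighting with seven covariates and few pools is fragile by
  construction; the best-balance fallback reports, rather than hides, the
  residual imbalance.
- Pool covariates are arithmetic means of member covariates (median
  available); how pooled samples should inherit covariates is a modeling
  choice with no ground truth.
- The normal-approximation CI can disagree with percentile intervals for
  skewed bootstrap distributions at small B.
- Quartile thresholds are always recomputed from the supplied cohort, so
  group definitions shift with cohort composition — intended, but it means
  labels are not transferable across cohorts.
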