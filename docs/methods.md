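# Methods

## Setting and purpose

`iecv` implements a clustered-validation framework for clinical prediction
models, built around the model that predicts favorable functional outcome
(dichotomized GOS/eGOS/mRS) after aneurysmal subarachnoid hemorrhage from
six predictors: age, WFNS grade (I–III vs IV–V), premorbid hypertension,
CT Fisher grade (1–4), aneurysm size (< vs ≥ 13 mm) and aneurysm location
(six sites).  The framework answers two questions a single external
validation cannot: how variable is model performance across plausible
validation cohorts, and how much of an observed performance drop is
explained by case-mix homogeneity versus genuine miscalibration.

## Model and metrics

The prediction model is an unpenalized maximum-likelihood logistic
regression (statsmodels IRLS; convergence tolerance 1e-10, 200
iterations).  Reference levels are Fisher grade 1 and location ACA — the
lowest level of each factor; they are recorded in serialized models.  Age
enters linearly; no splines are fitted, since the framework's subject is
the validation machinery, not maximal model fidelity.

Discrimination and calibration are measured per validation cohort:

* **Harrell's c** — computed by the midrank identity
  c = (Σ event midranks − n₁(n₁+1)/2) / (n₁n₀), which equals exhaustive
  pair enumeration with ties counted ½ exactly (tested against the O(n²)
  enumeration).  The default SE is the DeLong rank-statistic variance; a
  percentile bootstrap (B = 2000) is available.  The choice of SE method
  is a package decision, not something inherited from prior work.
* **Model-based c** — the expected concordance were outcomes truly
  Bernoulli(p): pairwise numerator p_max(1−p_min), denominator
  p_i(1−p_j) + p_j(1−p_i); a tied pair contributes exactly ½.  Exact over
  all pairs up to n = 2000; beyond that a seeded sample of 10⁶ random
  ordered pairs is used and the estimate is flagged approximate.  Its
  defining property — equality with E[Harrell c(p, Y)] over Y ~
  Bernoulli(p) — is verified by Monte Carlo in the test suite.
* **Calibration intercept** — intercept of a logistic fit of y with the
  linear predictor as fixed offset (0 = agreement on average).
* **Calibration slope** — slope of the logistic recalibration
  y ~ a + b·lp (1 = ideal).
* **Calibration curves** — ten equal-count quantile bins (collapsed when
  predictions are degenerate) plus a lowess smooth of y on logit(p) with
  p clipped to [0.001, 0.999]; the original plotting tool is not
  reproduced bit-for-bit.

Degenerate outcomes raise dedicated errors; complete separation
(all fitted probabilities at the boundary) raises a separation error,
while quasi-separation from an empty covariate-by-outcome cell — routine
when a small cluster lacks a factor level — only warns, because the
remaining coefficients and the ranking of predictions stay usable.

## Validation designs

**Leave-one-cluster-out cross-validation.**  Each cluster (study) is held
out once; the model is refitted on the rest and all metrics are evaluated
on the held-out cluster.  The split is deliberately non-random.  Results
are invariant to cluster iteration order (each evaluation depends only on
its own train/test partition).

**Optimism-corrected benchmark.**  Harrell's bootstrap with B = 200:
refit on each patient-resample, optimism = mean(c on resample − c of the
resample model on the original data), corrected = apparent − optimism.
One-class resamples are redrawn (capped at 20 attempts); resamples whose
refit is completely separated are redrawn under the same cap, since in
small overfit settings a few percent of resamples are separable and would
otherwise abort the whole correction.

**Single-study view.**  One cluster's results are reframed as a
stand-alone external validation, with the decomposition
Δ = Harrell c − model-based c.  |Δ| > 0.02 is labeled a case-mix
contribution; |slope − 1| > 0.2 or |intercept| > 0.2 is labeled
miscalibration-consistent.  Both thresholds are reporting conventions of
this package, not estimates.

**Random-effects pooling.**  Per-cluster estimates θ_k are modeled as
N(μ, τ² + se_k²).  τ² by REML (default; bounded scalar optimization) or
DerSimonian–Laird; pooled mean by inverse-variance weights 1/(se_k²+τ²);
Wald 95% CI (Hartung–Knapp optional); Cochran's Q with fixed-effect
weights and I² = max(0, (Q−df)/Q)·100.  c-statistics are pooled on the
logit scale with delta-method SEs (se_logit = se_c / (c(1−c))), the
convention of standard meta-analysis tooling for concordance indices;
intercepts and slopes on the identity scale.  When SEs are reconstructed
from printed CIs, se = (upper − lower)/3.92 on the analysis scale, so
back-transformed intervals are asymmetric by design.  REML is the
default because, on the published per-cluster rows, it reproduces the
printed pooled intercept and its CI more closely than DL; both estimators
are exposed and agree to within the documented tolerance on
well-conditioned inputs.

**Membership models.**  Relatedness of a development/validation pair is
the apparent c of a logistic regression of the membership indicator on
all six predictors plus the outcome — in-sample by design, matching how
the readout is used in practice; the membership model is itself never
cross-validated.  Bands: c < 0.70 related, 0.70–0.80 moderately distinct,
≥ 0.80 distinct; joint labels combine the band with whether validation
c ≥ 0.70.  Complete separation between the samples is reported as c = 1
with a flag (the "perfectly distinct" extreme), not as an error.

## Multiple imputation

Chained equations over the pooled repository (not per cluster) with the
outcome in every conditional model; this follows the original analysis
and implies some dilution of between-cluster heterogeneity when whole
columns are imputed for a cluster — a known limitation, restated here,
and the reason imputation is done once before splitting rather than
inside each training fold.  Per-variable conditionals: Bayesian linear
regression for age (PMM optional), logistic with an approximate posterior
draw for binaries, ridge-stabilized multinomial for Fisher grade and
location.  Defaults m = 5 and 10 cycles (the original report states
neither; these are the conventional defaults of chained-equation
software).  Rubin's rules combine per-imputation performance estimates:
pooled = mean, T = W̄ + (1 + 1/m)B, with c combined on the logit scale.

## Synthetic repository

The generator draws covariates per cluster (truncated-normal age on
[18, 95] — only mean/SD are published, so a bounded plausible shape was
chosen; Bernoulli and categorical draws for the rest) and outcomes from
logit⁻¹(α + shift_k + m_k·x'β), where shift_k and m_k carry between-study
heterogeneity.  Heterogeneity is parameterized as an intercept shift plus
a scalar multiplier on the whole linear predictor, matching what the
calibration intercept and slope detect; optional N(0, τ²) perturbations
of both are available for recovery studies.  Raw GOS/eGOS/mRS scores are
drawn conditionally on y by a monotone mechanism (the better extreme of
the scale is likelier the higher p), so the dichotomization layer is
exercised end to end; per-cluster outcome scales in the preset are an
emulation choice (mRS for two clusters, eGOS for two, GOS otherwise).

The `sahit-like` preset fixes 14 clusters with the published sizes
(total n = 11,931), age moments, WFNS IV–V prevalence (0 to 0.78),
Fisher/size/location marginals, favorable-outcome targets (0.60–0.92) and
the published block-missingness pattern (e.g. hypertension never recorded
in four clusters; where a cluster's marginal was not reported, the
full-cohort marginal is used and the column is blanked).  The generating
coefficients are plausible aSAH effect sizes chosen once for this package
(they are not the original model's coefficients, which are not public);
per-cluster intercept shifts are calibrated by a deterministic root solve
so each cluster hits its favorable-outcome target in expectation.  Slope
multipliers are 1 in the preset: the preset emulates case-mix and
prevalence heterogeneity, not effect heterogeneity, so synthetic slope
spread is narrower than the published range.  Item-level MAR missingness
is a separate mechanism: a logistic model in standardized age whose
intercept is solved to match the requested marginal rate.

What passing tests on this generator do **not** show: real repositories
have correlated predictors (the generator draws them independently within
cluster), informative missingness beyond age-dependent MAR, outcome-scale
conversion error, and effect heterogeneity between studies.

## Reproducibility and problem sizes

Every random stage takes an explicit seed; derived stage seeds are small
offsets of the pipeline seed.  Dataset generation, imputation, and
bootstrap are reproducible bit-for-bit given the seed.  The test suite
uses reduced problem sizes chosen to keep each statistical assertion's
error bands honest: parameter recovery at n = 40,000–50,000, calibration
recovery at n = 10⁵, heterogeneity recovery with 14 clusters × 500
patients × 100 replicates, optimism direction over 50 replicates of an
n = 100 overfit setting, and end-to-end pipeline tests on down-scaled
presets.  The acceptance script runs the full-size preset (n = 11,931).

## Known limitations

* The original model's coefficients and exact functional forms are not
  public; all synthetic results characterize the framework, not the
  original fitted model.
* The eGOS is treated as an 8-level scale (1–8), consistent with its
  dichotomization at 4–8 vs 1–3; no ninth level exists in the
  implementation.  Scale priority when several scores coexist is
  GOS > mRS > eGOS; the ordering of mRS vs eGOS is a package decision
  recorded in pipeline provenance.
* Binary and categorical imputation draws approximate the parameter
  posterior (scaled noise on the linear predictor; none for multinomial);
  with the repository-scale fractions of missingness this understates
  between-imputation variance only mildly.
* I² is floored at zero, so under true homogeneity its average over
  replicates is biased upward (the floor clips only negative values);
  tests therefore assert smallness, not literal zero.
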