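# Methods

`icgsig` implements a prognostic pipeline for glioma expression cohorts built
around an 18-gene ion-channel signature: genes whose expression tracks WHO
tumor grade are discovered in a grade-annotated cohort, combined into a
direction-weighted standardized risk score, and validated against survival in
independent high-grade cohorts, with a resampling test guarding against the
fact that many random gene sets are weakly prognostic.

## Signature discovery

Each retained feature (probe set) is tested for monotone association with
ordinal WHO grade (I–IV) by Spearman rank correlation with average ranks for
ties. P-values use the t approximation on ranks, `t = ρ√((n−2)/(1−ρ²))` with
`n−2` degrees of freedom; for n ≤ 9 untied inputs the scalar routine switches
to the exact permutation distribution. All tested features are corrected
jointly by the Benjamini–Hochberg step-up rule, and a gene from the
restriction set (the ion-channel list) enters the signature when at least one
of its features reaches adjusted p below `alpha` (default 0.05); its weight
is the sign of the correlation, +1 rising with grade, −1 falling. If two
qualifying features of one gene disagree in sign the gene is excluded and
logged rather than arbitrated.

Pre-filters mirror standard microarray practice: features must carry a
"present" detection call in at least two thirds of samples (marginal calls
count as absent), features on chromosomes X/Y are removed (features with
*missing* chromosome annotation are retained with a warning — we fail open on
metadata and closed on data), and multi-probe genes are collapsed by the
geometric mean on the linear scale, i.e. the arithmetic mean of log2 values.

Two cohort-level descriptive tests accompany discovery: a one-tailed
hypergeometric (Fisher) enrichment of ion-channel features among
down-regulated significant features, and a Welch t-test comparing the ρ
distribution of ion-channel features against all others. Welch is used
because the two groups differ in size by roughly two orders of magnitude.

## Risk score

For sample *j* and signature genes *i = 1..n* with weights `W_i ∈ {+1, −1}`:

    S_j = Σ_i W_i · (e_ij − μ_i) / τ_i

where `μ_i`, `τ_i` are the mean and sample (n−1) standard deviation of gene
*i* across all samples of the same cohort. Standardization is always
within-cohort: the score is a relative ranking, which sidesteps platform
differences between discovery and validation arrays. The sum is not divided
by n; the dichotomization cutoff at zero is scale-free, so any positive
rescaling leaves the classes unchanged. Samples with `S > 0` are classed
iCG+ (elevated predicted death risk); an exact zero is iCG−. Genes absent
from a cohort's platform, or constant across it (τ = 0), are dropped with a
logged list and the score uses the intersection.

## Survival models

Kaplan–Meier curves and the two-group log-rank test are delegated to
lifelines. Cox proportional-hazards regression is implemented natively:
Newton–Raphson on the partial likelihood with the Efron correction for tied
event times, step-halving on any iteration that decreases the likelihood,
convergence at relative log-likelihood change below 1e-9 (max 100
iterations). Confidence intervals are Wald-type, `exp(β ± 1.96·se)`, and the
Wald statistic `Z = β/se` is the effect-size summary used throughout. The
engine exists in-house because the resampling test needs tens of thousands
of univariate fits per run; a vectorized no-ties fast path makes one fit
~0.3 ms. Correctness is pinned in the test suite against lifelines (tied and
untied data), against a brute-force grid search of the partial likelihood,
and against a finite-difference Hessian.

A fit whose coefficient exceeds 20 in absolute value, or whose standard
error exceeds 10, is rejected as a monotone-likelihood / complete-separation
case: the likelihood flattens toward an asymptote and Newton convergence at
such a point does not correspond to a finite maximum. Stratified analysis
(e.g. by IDH1 mutation status) refits the model independently within each
stratum; strata without events are skipped with a warning.

## Resampling significance

The observed signature's Wald Z (univariate Cox on the dichotomized class)
is compared with B random signatures of the same size drawn uniformly
without replacement from a gene pool (default: all genes measured in the
validation cohort; optionally a restricted "disease-associated" pool). The
right-tailed empirical p is `#{Z_b ≥ Z_obs}/B`, displayed as `< 1/B` when no
draw exceeds the observed value. Random draws carry weight +1 by default;
when a per-gene direction table from the discovery cohort is supplied, each
sampled gene instead takes the sign of its grade correlation — the natural
analogue of how the tested signature was weighted, which widens the null Z
dispersion and is therefore the conservative default in the pipeline. Draws
whose Cox fit fails (all patients in one class, separation) contribute Z = 0
— conservative toward the observed signature — and are counted in the
result's metadata.

## Synthetic cohorts

The generator emulates the structure of the real cohorts without any
download: a discovery cohort with grades drawn from (0.075, 0.075, 0.15,
0.70) — the grade-IV-skewed mix of surgical series — and a validation cohort
of grade III/IV samples only. All genes are iid Normal on the log2 scale
with baseline 8 and noise SD 1.0; each planted signature gene's mean shifts
by `W_g · 0.5` log2 units per grade step, so +1 genes rise and −1 genes fall
with grade.

Validation survival follows a proportional-hazards model that is exact by
construction: event time ~ Exponential with hazard
`0.06 · exp(0.71 · z_true)` events/month, where `z_true` is the
cohort-standardized true risk score of the planted signature; censoring is
Uniform(0, 60 months), independent of the event process. The baseline
0.06/month corresponds to a ~12-month median survival for an average
patient, matching the dismal prognosis of high-grade glioma; the 60-month
window yields roughly 70–80% observed events. A Weibull shape knob is
exposed (hazard `h0·k·t^(k−1)`) but defaults to 1 (exponential), the
simplest generator for which the Cox model is exactly specified. The
coefficient 0.71 per SD was fixed once by a large-n (400k) simulation so
that the marginal Cox hazard ratio of the dichotomized true classes is ≈
2.8, the effect size of the largest validation cohort the method targets.

What the generator does **not** emulate: inter-gene correlation (background
genes are independent — the pipeline makes no use of covariance structure),
batch effects, probe saturation, or realistic detection-call patterns (calls
are all-present unless a flat absent rate is requested). Passing tests on
these cohorts therefore demonstrate the statistical machinery under a
correctly specified model, not robustness to real microarray artifacts.

## Numerical and design choices

- Exact-zero risk scores are iCG− (strict inequality defines the high-risk
  class).
- BH adjustment is applied over all retained features jointly, before
  restricting to the ion-channel set.
- Empirical p uses the plain `r/B` convention with a `< 1/B` display at
  zero exceedances, not `(r+1)/(B+1)`.
- The presence filter uses a 1e-12 tolerance at the ≥ two-thirds boundary so
  an exact 2-of-3 pattern is retained.
- Listwise deletion for Cox fits with missing covariates; the count of
  dropped rows is logged.
- Every run is driven by a single integer seed; outputs embed the config
  hash and seed, and re-running a configuration reproduces byte-identical
  summaries.
- Plots are not produced; Kaplan–Meier step curves and the null-Z vector are
  written as TSV, ready for any plotting frontend.

## Known limitations

- Discovery power at the default effect size (0.5 log2/grade against SD 1.0)
  is moderate: the grade distribution is 70% grade IV, and tie-averaged
  ranks attenuate the achievable Spearman ρ of planted genes to ≈ 0.35,
  close to the BH-effective detection threshold (|ρ| ≈ 0.30 at n = 120 with
  ~1,000 features). Typical replicates recover 14–16 of 18 planted genes
  with no direction flips; full recovery of 16+ occurs in roughly half of
  replicates.
- The resampling test's problem sizes in the shipped checks (150–300
  patients, B = 200–1,000, pools of a few hundred genes) were chosen so the
  whole suite runs on a laptop-scale budget; the machinery itself is
  size-agnostic.
- The score assumes within-cohort standardization is meaningful, i.e. the
  cohort is reasonably homogeneous; mixing platforms or tissue types within
  one "cohort" violates that premise.
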