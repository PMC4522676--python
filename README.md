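# icgsig

Ion-channel gene-signature analysis for glioma expression cohorts: discover
genes whose expression tracks WHO tumor grade, combine them into a
direction-weighted risk score, validate the score against patient survival,
and test whether the signature actually beats random gene sets of the same
size.

The package is aimed at computational biologists working with bulk
expression cohorts (microarray or summarized RNA-seq) that carry ordinal
tumor-grade annotation and/or survival outcomes. It ships the published
18-gene ion-channel signature (2 genes up-regulated in high-grade glioma,
CLIC1 and CLIC4; 16 down-regulated, including KCNMA1, GRIA2, and SCN1A) and
every stage needed to rebuild such a signature from scratch on a new cohort.

## The method

**Discovery.** For each feature, Spearman's rank correlation ρ against WHO
grade (I–IV); Benjamini–Hochberg correction over all retained features;
genes from a restriction list (ion channels) with adjusted p < 0.05 enter
the signature with weight W = sign(ρ). Standard microarray pre-filters
apply: present-call fraction ≥ 2/3, removal of chrX/chrY features,
geometric-mean collapse of multi-probe genes.

**Risk score.** For a patient with log2 expression e_i of signature gene i,

    S = Σ_i W_i · (e_i − μ_i) / τ_i

with μ_i, τ_i the within-cohort mean and standard deviation of gene i.
Patients with S > 0 are classed iCG+ (high predicted death risk), the rest
iCG−.

**Survival.** Kaplan–Meier curves and log-rank test by risk class;
univariate, multivariate, and stratified Cox proportional-hazards
regression reporting hazard ratios, Wald 95% CIs, and the Wald statistic
Z = β/se (Efron tie handling).

**Resampling test.** The signature's Z is compared against B random
signatures of identical size drawn from a gene pool; the right-tailed
empirical p is the fraction of random signatures scoring at least as well.
This guards against the known pitfall that many random gene sets are
prognostic in cancer cohorts.

A seeded synthetic-cohort generator (grade-skewed discovery cohorts with a
planted signature; high-grade validation cohorts with exponential
proportional-hazards survival) makes the whole pipeline testable offline.

## Worked example

Run the full pipeline on a synthetic discovery + validation bundle:

```sh
icgsig run-all --synthetic --seed 7 --b 1000 --out-dir demo/
```

prints

```
signature size: 17 (2 up, 15 down)
resampling: z_observed=4.683, empirical P < 0.001
summary written to demo/summary.json
```

Reading `demo/summary.json`: discovery on a 120-patient grade-annotated
cohort recovered 17 of the 18 planted ion-channel genes with the correct
directions (both up-regulated genes among them). On the 120-patient
validation cohort the score split patients into iCG+/iCG− classes whose
survival differs sharply — log-rank p = 1.0 × 10⁻⁶, univariate Cox hazard
ratio 3.24 (95% CI 1.98–5.29), i.e. iCG+ patients die at roughly three times
the rate of iCG− patients. None of 1,000 random 18-gene signatures drawn
from the same cohort matched the observed Wald Z of 4.68 (empirical
P < 0.001), so the planted signature's prognostic power is not a
random-gene-set artifact.

Each stage is also available on its own files — `icgsig discover`, `score`,
`survival`, `resample`, `simulate` — and as plain library calls
(`icgsig.discovery`, `icgsig.scoring`, `icgsig.survival`,
`icgsig.resampling`, `icgsig.synthetic`).

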