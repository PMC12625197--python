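# Methods

This note documents the models, numerical choices and known limitations of
`nulisapipe`. It covers what each stage assumes, which tunable parameters
matter, what the synthetic generator does and does not emulate, and where
the design was genuinely open.

## Data model and normalization

The central carrier is a samples × analytes grid of abundances with missing
values as NaN, tagged with its scale. Panel data arrive on a log2 "NPQ"
scale (assay-normalized protein quantification, log2-transformed upstream so
the noise is approximately Gaussian). Analyses run on a fixed chain

    log2_npq  →  linear_npq (2^x)  →  log10  →  z-score per analyte

applied in that order and only in that order; requesting a backward or
skipped transition raises. Z-scores use the sample SD (ddof = 1) over all
retained samples of an analyte, computed once on the full QC'd matrix before
any per-analysis subsetting, so every contrast sees the same scale. The
per-analyte mean/SD of the log10 values are retained, which makes cutoffs
derived on the z scale invertible to linear NPQ units
(`linear = 10^(z·sd + mean)`).

## Quality control

* **Outlier fences.** Per analyte, Q1 and Q3 are computed with the
  linear-interpolation quantile convention (the common default in
  statistical software; recorded in the QC report), and values strictly
  outside `(Q1 − 1.5·IQR, Q3 + 1.5·IQR)` are set to missing. Values exactly
  at a fence are retained. Analytes with fewer than four observed values get
  no fences and are flagged instead. Masking precedes call-rate computation.
* **Call-rate filter.** Rates are the fraction of non-missing cells per
  analyte / per sample. The two-step filter removes analytes and samples
  below 65%, recomputes rates on the reduced matrix, then applies 85%.
  Within a step both axes are judged on the rates at step entry (analytes
  dropped first); recomputation happens only between the steps. The staged
  design deliberately retains borderline analytes/samples whose rates
  recover once genuinely bad rows/columns are gone; the unit suite contains
  a hand-traced fixture exercising exactly that rescue.
* **LOD/CV.** LOD is `mean + 3·SD` of designated negative-control samples —
  an explicit assumption, since the upstream definition is not standardized
  — and CV is `100·SD/mean` within replicate groups on the linear scale.
  Both are report-only; they never filter.

## Differential abundance

Each analyte is modeled by OLS on the z-scored abundance with a single
predictor (disease-vs-control indicator, or a continuous phenotype), age at
draw, sex, and two surrogate variables; two-sided t-tests give per-protein
p-values and Benjamini–Hochberg adjusts across the panel within one
contrast (that is the FDR family; different contrasts are separate
families). Complete-case analysis per analyte; analytes with too few
complete cases or a rank-deficient design are skipped with a recorded
reason. Phenotype models regress protein on phenotype (protein as outcome),
a direction choice recorded in the results object.

**Surrogate variables.** Missing cells are imputed by resampling observed
values of the same analyte (seeded); the primary design is regressed out;
the SVs start as the leading left singular vectors of the residual matrix
and are refined by one reweighting pass: analytes are weighted by the
fraction of their residual variance the initial SVs explain, and the SVs are
re-extracted from the *weighted, column-centered data* (not the residuals).
The second point matters: re-extracting from residuals can never recover the
part of a batch factor that is aligned with the primary design, and it is
precisely that part that inflates the null. The regression suite contains a
confounded-batch fixture demonstrating inflation without SVs and restored
calibration with them. The returned SVs are orthonormal with a
deterministic sign convention. `n_sv = 2` by default.

## Cross-disease comparison

Effect sizes from independent contrasts are compared per protein with
`z = (β₁ − β₂)/√(SE₁² + SE₂²)` (two-sided normal p, BH across the panel per
pair); discordance categories are FDR-significant / nominal / ns. Effect
vectors are compared by Pearson correlation. Hierarchical clustering uses
Euclidean distance with complete linkage; rows are sorted lexicographically
by label before linkage so the tree (and its Newick export) is invariant
under input permutation. The scorecard gives each protein, per disease, +2
for a positive FDR-significant association, +1 for positive and nominally
significant only, the mirrored negatives for β < 0, and 0 otherwise
(two-sided p-values with the sign read from β); totals and absolute totals
rank proteins by cross-disease consistency. Missing cells score 0 and set a
completeness flag.

## Biomarker cutoffs

* **Two-component GMM.** Univariate EM with a deterministic median-split
  initialization (no multi-start, hence bit-reproducible), tolerance 1e-8 on
  the log-likelihood, at most 1000 iterations, components relabeled so
  μ₁ < μ₂. A variance floor of `1e-4 · var(x)` averts collapse; a fit that
  ends on the floor raises unless explicitly allowed. By default the model
  is selected by BIC between a shared-variance and a free-variance
  parameterization, mirroring the model-selection default of standard
  mixture software. This is not cosmetic: the equal-likelihood crossing of
  a free-variance fit is hypersensitive to noise in the two variance
  estimates (sampling SD ≈ 0.04 at n = 5000 even for well-separated unit-
  variance components — verified against an independent mixture
  implementation), while the shared-variance crossing is markedly stabler
  (SD ≈ 0.024). On genuinely equal-spread components BIC picks the shared
  model and the crossing is recovered within ±0.05 in ≥95% of replicates at
  n = 5000; on heavily overlapping unequal-spread mixtures (like the
  generator's default biomarker) the crossing has an intrinsic sampling SD
  of ≈ 0.07 at that n for *any* maximum-likelihood fit, which no
  implementation choice can shrink.
* **Crossing cutoff.** `π₁N(x;μ₁,σ₁) = π₂N(x;μ₂,σ₂)` is solved analytically
  (quadratic in x after logs) and the root between the means is returned;
  the posterior probability of each component there is 0.5 by construction.
  Extreme weight imbalance can leave no root between the means; that is an
  error with diagnostics, not a silent extrapolation.
* **Youden / dual cutoffs.** Candidate thresholds are midpoints of adjacent
  sorted unique values plus sentinels beyond the range; a value above the
  threshold is called positive. Youden maximizes J with ties resolved
  toward the smallest cutoff (equivalent to an exhaustive scan, which the
  tests verify). The dual scheme takes the largest threshold retaining 95%
  sensitivity (lower) and the smallest retaining 95% specificity (upper);
  on well-separated classes the two may cross, which is flagged as an empty
  intermediate zone rather than an error. Tri-class labeling is
  `< lower → low`, `> upper → high`, else intermediate; missing values are
  excluded and counted separately.
* A caveat the tests make explicit: the population Youden optimum solves
  `f₁ = f₂` while the GMM crossing solves `π₁f₁ = π₂f₂`, so the two agree
  exactly only for equal component weights; and the empirical Youden
  maximizer converges at a slow (cube-root) rate, so single-replicate
  agreement bands are unreliable — the suite asserts agreement of the
  replicate mean.

## Evaluation metrics

Confusion summaries expose counts plus concordance (%), sensitivity,
specificity, PPV and NPV, with non-binary entries (missing, intermediate)
excluded into `n_excluded`. All reported percentages are rounded to two
decimals with ties away from zero — the convention that reproduces every
printed ratio the acceptance script recomputes (e.g. 15.625% → 15.63). AUC
is the Mann–Whitney statistic with ties counted ½; its CI comes from the
DeLong placement-value variance, clipped to [0, 1]. Logistic predictors are
ML fits that refuse to return silently diverged coefficients under
separation (downstream horizon-AUCs fall back to ranking by the raw marker,
which is AUC-equivalent). Kruskal–Wallis uses the tie-corrected H; Dunn's
post-hoc z compares mean ranks with the tie-corrected variance, Bonferroni-
adjusted over the requested comparisons only. The APOE-ε4 concordance takes
binary proteoform calls against six diploid genotypes (ε4-containing =
positive), reporting overall, per-genotype and allele-stratum accuracies.
Over-representation is the upper-tail hypergeometric with fold enrichment
`(k/n)/(K/N)` and BH across pathways; annotation maps are user-supplied
(no ontology download or ID translation).

## Progression

Survival records carry time in years from blood draw to onset (events) or
last follow-up (censored). Per-protein Cox PH models adjust for age and sex;
hazard ratios are per SD of the z-scored marker; BH across the panel.
Tie handling is the Efron approximation of the underlying survival library;
simulated event times are continuous so ties are absent almost surely, and
on tie-free data Efron and Breslow coincide — the oracle tests exploit this
by checking against an independent Newton solver on the (tie-free) Breslow
partial likelihood to 1e-6. Monotone likelihoods (infinite HR) are flagged
and skipped, never reported as estimates. Kaplan–Meier curves use the
product-limit estimator with a log-rank comparison between cutoff-defined
groups; plain KM by group is reported rather than covariate-adjusted
survival curves. Fixed-horizon discrimination labels progressors as events
within the horizon and non-progressors as records followed at least that
long without an event; censored records shorter than the horizon are
ambiguous and excluded.

## Synthetic cohort generator

The generator emulates, with full ground truth and seed-determinism:
heteroscedastic per-analyte Gaussian noise on the log2 scale (per-analyte
SDs log-uniform on [0.2, 1.0]); five diagnosis groups with per-protein
effects in within-group SD units and demographics (age means/SDs, sex
fractions, APOE genotype frequencies) patterned on a memory-clinic cohort;
optional per-analyte age/sex slopes; rank-`n_latent` batch structure
(default 2 factors, loading SD 0.3 in analyte-SD units); MCAR missingness
(default 2%) and ±(3–6)·IQR outliers (default 0.5%) so the QC fence
provably catches them; a two-component bimodal biomarker on the z scale
(default weights 0.54/0.46, means −0.8/0.9, SDs 0.6/0.7 — a roughly
half-and-half split like a biomarker-positivity distribution) coupled to a
latent Centiloid-like amyloid variable at correlation 0.8 with positivity
at > 20; an APOE-ε4 proteoform shifted 2.5 noise-SDs per ε4 allele
(deliberate overlap, so concordance < 100% is reproducible by design); and
exponential-baseline proportional-hazards progression among controls
(default 0.02 events/year) with independent exponential censoring
parameterized by the intended censoring fraction (default 0.6).

What it does **not** emulate: assay chemistry or sequencing reads, real
imaging (the amyloid variable is a scalar analog), non-Gaussian heavy tails,
informative missingness (an MCAR default; intensity-dependent missingness is
out of the box only as a stress-test hook), longitudinal within-person
trajectories, or population structure. Tests passing on these cohorts
demonstrate that the estimators recover what they are pointed at under the
stated noise model — not that the model captures every pathology of real
plasma panels.

## Problem sizes and reproducibility

The test suite and the acceptance script run on deliberately modest sizes —
cohorts of 40–400 per group, 12–40 analytes, 25–100 simulation replicates,
mixtures of n = 5000 — chosen so the full chain re-runs from scratch in a
few minutes on one CPU while leaving the Monte-Carlo bands comfortably
informative. All randomness flows through explicit seeds
(`numpy.random.default_rng`); identical configurations are bit-identical,
which the pipeline manifest verifies by hashing every output.

## Known limitations

* One sample per participant is assumed for cross-sectional analyses; no
  mixed-effects modeling of repeated draws.
* CDR-like ordinal phenotypes are treated as continuous predictors.
* The SV estimator fixes the dimension (default 2) rather than estimating it.
* No >2-component mixtures and no Bayesian mixture fitting.
* Cox models: no time-varying covariates, no competing risks.
* The ε4-proteoform caller here thresholds a single analyte (by default via
  the GMM crossing); the real assay's caller is proprietary, so only the
  concordance *structure* — not its published values — is reproduced on
  synthetic data.
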