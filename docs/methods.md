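# Methods

This note documents the models, the synthetic-data generator, and the
numerical choices behind each pipeline stage, in the order the pipeline
runs them.

## Data model and scales

All matrices are CpG-by-sample delimited text with probe ids in the first
column. Beta values are methylation proportions in [0, 1]; the M-value is
M = log2((β + offset)/(1 − β + offset)). The primary analyses run on the
beta scale (effects are then directly interpretable as percent-methylation
differences); the M-scale is available as a sensitivity scale and is used
internally where exact linearity matters (see the surrogate-variable
recovery tests below). With offset 0 a boundary beta is rejected rather
than silently mapped to ±∞.

Annotation follows the 450k manifest conventions: 1-based coordinates,
semicolon-separated gene symbols (deduplicated per probe, matched
case-sensitively after trimming), island relations N/S_Shore → shore and
N/S_Shelf → shelf, an absent relation → open sea. The enhancer flag is an
overlapping (non-exclusive) annotation, as in the manifest; the four
island-relation classes are exhaustive and disjoint.

## Synthetic-data generator

Every downstream stage is tested against data with known ground truth.
The generative model is

    β_ij = logistic( logit(Σ_k w_ik r_kj) + Σ_l f_il λ_lj
                     + male_i s_j + dx_i d_j + ε_ij ),   ε ~ N(0, σ²)

with cell-type mixing weights w (Dirichlet around realistic cord-blood
means: granulocytes ≈ 43%, CD4+ T ≈ 19%, CD8+ T ≈ 13%, B ≈ 11%, nRBC ≈ 10%,
monocytes ≈ 8%, NK ≈ 0.5%), cell profiles r built from a bimodal baseline
with per-type logit deviations plus planted one-vs-rest marker probes,
latent factor scores f ~ N(0,1) with sparse logit-scale loadings, sex
effects carried by dedicated chrX (2%) and chrY (0.5%) probe blocks, and a
diagnosis effect d_j spiked only into CpGs annotated to a designated
risk-gene set. Because every effect acts on the logit scale and is mapped
back through the logistic, generated betas always lie strictly inside
(0, 1).

Choices worth noting:

- **Effect calibration.** `delta` is the intended *beta-scale* group
  difference. The logit-scale coefficient is calibrated per CpG,
  d_j = logit(m_j + δ/2) − logit(m_j − δ/2) at that CpG's baseline mean
  m_j (clipped to keep m_j ± δ/2 inside [0.02, 0.98]), so the realized
  beta-scale difference is ≈ δ at every spiked CpG, not only at β = 0.5.
- **Direction imbalance.** Spiked effects are hypermethylated with
  probability 0.69 by default, mirroring the direction imbalance reported
  for cord blood.
- **Sex encoding.** chrY probes are near-unmethylated-looking in females
  (logit shift −3) and mid-range in males (+3); chrX probes run ≈0.8 logit
  units higher in females. The QC sex check thresholds the per-sample
  difference of chrY and chrX medians at the midpoint of the two 1-D
  cluster means.
- **Probe-count bias.** Genes receive probes with Zipf-like weights
  (≈ n_cpgs/10 genes, 25% intergenic probes, 5% dual-gene probes), so the
  ontology stage's probe-number bias is a real feature of the synthetic
  universe. Region classes are drawn at 31% island / 23% shore / 10% shelf
  / 36% open sea; 22% of probes carry the enhancer flag.
- **Defaults.** 10,000 CpGs × 120 samples (runs in seconds); outcome
  prevalence 22% ASD / 43% non-TD / 35% TD; logit noise sd 0.25; ~0.1% of
  detection p-values planted above 0.01; per-sample mean log2 intensity
  ~N(12, 0.3).

What the generator does **not** emulate: Infinium I/II chemistry
differences, raw intensities (the intensity summary is drawn directly),
spatial/batch plate structure beyond generic latent factors, correlated
neighbouring CpGs, and genotype-driven meQTL structure. Passing tests
therefore demonstrate correct recovery under the stated generative model,
not robustness to every artefact of real arrays.

## Quality control

Probes are removed when detection p > 0.01 in strictly more than 10% of
samples (both inequalities strict), then when listed as cross-reactive.
Samples are removed for mean log2 intensity < 10.5, failed-detection
fraction > 20%, or predicted/recorded sex discordance. The intensity
summary is an input column rather than derived from raw intensities — the
10.5 threshold presumes minfi-style medians, and raw intensity processing
is out of scope. Batch diagnostics: one-way ANOVA p-values of the top
principal components (right-singular vectors of the probe-centred matrix)
against each categorical covariate, plus a slope test for continuous ones.

## Cell-type deconvolution

Constrained projection per sample: minimise ‖y − Rᵀw‖² subject to w ≥ 0 and
Σw ≤ 1. The solver augments the active-set NNLS system with a slack
variable and a heavily weighted row enforcing Σw + slack = 1
(weight 1000 ≫ data scale), which is deterministic and recovers noiseless
mixtures to machine precision. The inequality (not equality) lets
unmodelled cell types absorb residual mass; estimates are reported raw,
without renormalisation to sum to one, so the residual mass stays visible.
Discriminating probes are the per-type largest and smallest one-vs-rest
mean contrasts, ties broken by probe id.

## Surrogate variables

The estimator residualises the data on the primary (diagnosis) design,
takes the top right-singular vectors as initial candidates, then iterates
(5 rounds): compute per-probe posterior probabilities of association with
the candidate SVs (given the primary) and with the primary (marginal),
weight each probe by P(SV-associated) × (1 − P(outcome-associated)), and
recompute the SVD on the weighted, row-centred **data** matrix. Two
numerical points matter:

- The final SVD must be on the weighted data, not the residuals: residual
  right-singular vectors are exactly orthogonal to the outcome design, and
  adjusting for such directions only deflates residual variance (inflating
  every test statistic).
- The protection weight uses the *marginal* outcome association. A
  conditional test loses all power once an outcome-collinear SV enters the
  model, so outcome-aligned directions would never be penalised. With the
  marginal weight, a planted factor equal to the outcome itself is kept out
  of SV1 (|corr| < 0.1 in simulations). The flip side is intended
  behaviour: genuinely outcome-confounded latent structure is partially
  absorbed into the protected effect rather than removed.

The posterior probabilities come from a histogram-based local-fdr (20
bins, monotone density, π₀ = min(1, 2·mean(p > 0.5))).

**Choosing k.** For k = 0..K_max the genome-wide inflation factor
λ(k) = median(χ²₁-quantile of 1 − p)/0.4549 is computed from the
association p-values adjusted for the first k SVs. Models whose |λ − 1|
comes within 0.05 of the best are treated as equally calibrated — the
median-based λ estimate itself carries sampling noise of roughly that
order at 10⁴ probes — and the smallest such k is selected (k = 0 is
admissible). K_max defaults to 10. A permutation (parallel-analysis)
estimator of the latent dimension is also provided: factors are counted
while their singular values exceed the 95th percentile of row-permuted
residual matrices.

The planted-factor recovery scenario used in tests runs on the M-value
scale with a single cell type: there the generator's model is exactly
linear, so the true latent dimension equals the planted one. On the beta
scale the logistic nonlinearity turns factor harmonics into genuine extra
latent components, and "the right k" is larger than the number of planted
factors — a property of the scale, not a failure of the estimator.

## Site-wise association

Vectorised OLS with a common design across probes; the excluded diagnosis
group is dropped, not dummy-coded, and missing covariate values are handled
complete-case per model. Moderation fits (d₀, s₀²) by matching the mean and
variance of log s² (Newton inversion of the trigamma function); the
homogeneous edge case (all s² identical) pools exactly at that value with
d₀ = ∞, and `prior_df=0` disables shrinkage (recovering the ordinary
per-probe t). The implementation agrees with Bioconductor limma's
`squeezeVar` to 6+ digits on shared inputs (cross-checked in the test
suite via Rscript). Two-sided p-values with d₀ + d degrees of freedom;
BH step-up q-values; sex-chromosome probes are retained site-wise (only
the global analysis is autosome-restricted).

## Global methylation

Per-sample unweighted means (×100) over autosomal probes, overall and per
stratum; the overall mean identically equals the CpG-count-weighted average
of the four region means. Group tests: stratum mean ~ group + SVs,
optionally sex-stratified (cells with < 3 samples per group are skipped).
The distributional test evaluates each sample's empirical CDF on a fixed
grid of 101 equally spaced beta values and uses the mean absolute
difference between group-mean CDFs (an integrated L1 distance) with
group-label permutation; p = (1 + #{perm ≥ obs})/(1 + n_perm), bounded
below by 1/(n_perm + 1). The exact statistic of the original
distributional test was unspecified, so this integrated-absolute-difference
form is the package's own, clearly named choice.

## Enrichment and ontology

Gene-level 2×2 chi-square without continuity correction at each threshold
of the grid (0.0001 … 0.99); strict p < t selection; expected overlap =
margins product / universe. Permutation controls default to 10 random gene
sets of the risk-set size drawn uniformly without replacement (a
probe-count-matched stratified draw is available behind a flag, since
uniform vs matched sampling for the controls was not specified).
Restricting to a probe list (e.g. meQTL targets) subsets the results and
rebuilds the universe; restriction to all probes reproduces the
unrestricted curve exactly. Risk-gene lists are flat sets; scores or
categories within them are ignored.

Ontology testing estimates each gene's selection probability as a moving
average (window = max(5, n/20)) of the selection indicator over genes
sorted by probe count, averaging within tied counts so the estimate is
order-invariant; category odds are the odds-ratio of mean member vs
non-member probabilities, and the p-value comes from the Wallenius
noncentral hypergeometric upper tail (scipy's implementation; with odds 1
it reduces exactly to the central hypergeometric). Note the upper-tail p
is nondecreasing in the odds — higher category odds make a large overlap
less surprising — approaching 1 as odds → ∞ and 0 as odds → 0. Categories
need ≥ 5 universe genes. Cross-tissue aggregation sums average-tie ranks
of category p-values across tissues; categories missing in a tissue are
flagged rather than imputed.

## Problem sizes and determinism

Test and acceptance runs use 10,000 CpGs × 120 samples for genome-scale
properties (null calibration, enrichment power, SV recovery over seeds
1–10) and smaller matrices for unit-level oracles; these sizes make every
property estimable with comfortable Monte-Carlo margins while each suite
runs in well under five minutes. All randomness flows through explicit
integer seeds (numpy `default_rng`); the pipeline writes the seed, package
versions, and per-stage filter counts to its run log, and identical
(inputs, config, seed) produce byte-identical output tables.

## Known limitations

- Reference-free deconvolution, DMR calling, and robust/trended variants
  of variance moderation are not implemented.
- The λ-guided k selection is a heuristic on a noisy statistic; with
  several adequately calibrated models it prefers the smallest, and in
  simulation it recovers the planted dimension in ~9/10 seeds, not always.
- The Wallenius odds uses a single mean-odds parameter per category
  (category vs rest), not per-gene odds.
- The cohort-summary trend test covers binary/ordinal and continuous
  covariates; multi-level nominal covariates inside the trend framework
  (e.g. race/ethnicity) are summarised but their printed p-values are not
  reproduced by a plain chi-square and are not targeted.
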