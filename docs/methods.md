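# Methods

## The problem

A genomic prediction model — a regression of a quantitative phenotype on
genome-wide SNP allele counts — is usually validated by cross-validation
with random splits, which implicitly assumes the individuals to be predicted
come from the same population as the training sample. In breeding programs
and cross-population applications that assumption fails: the targets are
future generations or other populations, genetically distant from the
training set, and random-split accuracy overstates what the model will
deliver. `gpdecay` estimates a *decay curve*: the predictive correlation
rho (Pearson correlation between predicted and observed phenotypes) as a
function of the genetic distance between training and target samples,
measured by F_ST.

## Models and estimators

**Prediction model.** The additive linear model y = mu + X beta + eps with X
the standardized allele counts, fitted with the elastic net. Tuning
maximizes the mean out-of-fold Pearson correlation over a grid of mixing
parameters (0.1 … 1.0 by 0.1 by default) crossed with a log-spaced penalty
path (100 values from the data-derived maximum down to 0.001 of it),
assessed by repeated k-fold cross-validation (5 runs of 10 folds by
default). Correlations are averaged across runs *before* selection; ties go
to the larger penalty, i.e. the sparser model. The whole framework is
model-agnostic: any fit/predict pair that yields predictive correlations can
replace the elastic net. Prediction error variance is derived from the
correlation, PEV = (1 − rho²)·Var(y), which holds for any model.

**Kinship.** The allelic-correlation genomic relationship
k_ij = (1/m) Σ_k X̃_ik X̃_jk. Standardization always uses the denominator-n
standard deviation computed on the *full* sample before any split, so
training and target subsamples live in one coordinate system. The squared
Euclidean distance between standardized profiles satisfies
d²_ij = m (k_ii + k_jj − 2 k_ij); the package implements and tests this
self-consistent form (a commonly printed variant with a factor 2n is
dimensionally inconsistent with the 1/m in the kinship definition). This
identity is why k-means on standardized genotypes produces minimally
related — maximally differentiated — subsets.

**F_ST.** A Beta-Binomial maximum-likelihood estimator under the
Balding–Nichols model: training allele frequencies pi_k are plugged in as
ancestral; the target's pooled allele count c_k out of n_k chromosomes is
Beta-Binomial with alpha = pi(1−F)/F, beta = (1−pi)(1−F)/F. The
log-likelihood (binomial coefficient omitted, constant in F) is maximized
by bounded Brent search on [1e-6, 0.99], tolerance 1e-6. Markers
monomorphic in training are excluded; at least 10 usable markers are
required. Markers are treated as independent (a composite likelihood under
linkage — the point estimate is unaffected in expectation, no correction is
attempted).

*Plug-in bias.* Because the training frequencies are estimates from 2·n_TR
chromosomes, the estimator carries an upward bias of roughly 1/(2 n_TR):
random splits of one homogeneous sample measure ≈ 0.005 at n_TR = 100, not
zero. This is why the swap-series stopping threshold of 0.005 is attainable
only with training subsamples of roughly a hundred individuals or more, and
why random-split cross-validation pairs sit at F_ST ≲ 0.01 rather than 0.

## The decay-curve procedure

1. Split the sample into a training and a target subsample with k-means
   (k = 2, best of 25 seeded restarts by within-cluster sum of squares) on
   the standardized genotypes; the larger cluster trains the model (tie:
   the cluster containing the lowest sample index). Optionally rebalance by
   greedily moving target individuals into training, each step keeping the
   estimated F_ST as large as possible.
2. Estimate F_ST(0) and rho_D(0) for that pair.
3. For m = step, 2·step, …: create `reps_per_m` (default 40) new pairs by
   swapping m random individuals between the sides; per pair, re-fit the
   model on the new training subsample and record (F_ST(m), rho_D(m)).
   Stop after the first m whose mean F_ST ≤ 0.005. The step is the smallest
   value in [2, 20] that yields at most 30 schedule points, overridable.
   The schedule is capped at m = min(n_TR, n_TA)/2: swapping m and n − m
   individuals produce mirror-image mixtures, so mixing is maximal at half
   and the mean F_ST rises again beyond it.
4. Smooth the points by degree-1 LOESS (tricube weights, span 0.75 by
   default) evaluated on a 100-point grid over the observed F_ST range.
   The 95% band is fit ± 1.96·SE from the local-fit equivalent kernel, with
   residual variance RSS/(n − tr L); a percentile bootstrap band (resampling
   points) is available since no canonical CI construction exists for LOESS.
5. Fit the straight line rho ~ F_ST by OLS (rho_L). It extrapolates beyond
   the observed range and may go negative where the true curve flattens
   toward zero; values are returned untruncated. A companion regression of
   rho² on F_ST² reports both R² values for scale comparison.

Queries at a given F_ST return both the LOESS value and the mean of raw
points within |F_ST(m) − F_ST| ≤ 0.01 (the comparison statistic used in the
validation experiments); queries beyond the observed range raise an error
directing the caller to the linear fit.

## Simulations

**Synthetic populations.** The default generator is Balding–Nichols:
ancestral frequencies uniform on (0.05, 0.95), population frequencies
Beta-distributed at the chosen divergence F, genotypes Binomial(2, p).
This matches the F_ST estimator's model exactly, making
generation→estimation a closed loop for calibration tests. Optional LD is
injected by a Gaussian-copula AR(1) haplotype chain that preserves marginal
frequencies.

**Breeding program.** 200 founders; a trait with n_causal random causal
variants among markers with founder MAF > 0.05, mean-zero normal additive
effects rescaled so Var(Xb)/(Var(Xb)+1) = h² = 0.55 exactly in the founders
(noise sd fixed at 1); a model fitted on all founders; then replicated
rounds of: 200 progeny by random mating without selfing (Poisson crossovers
on a 21-chromosome map of 1 Morgan each, uniform breakpoints, no
interference; unphased founders phased by one random coin flip per
heterozygote per replicate), phenotypes from the same trait, F_ST of progeny
vs founders, predictive correlation of the founder-fitted model, truncation
selection of the top 20 phenotypes as next parents. Per-round means of F_ST
and rho are the reference points the decay curve should anticipate.
Early-round progeny can be folded back into an augmented training set and
the model refitted.

**Cross-population prediction.** One labelled population trains the model;
every other label is a target, reported with its F_ST, rho_P and a Fisher-z
95% CI (flagged wide below 10 individuals). Effect sizes are shared across
populations.

## What the generator does and does not emulate

Independent Balding–Nichols draws reproduce allele-frequency divergence but
*not* shared-haplotype structure: each population's frequencies drift
independently per marker, and any copula LD is re-drawn per population.
Measured consequence: with causal variants genotyped and effects shared,
cross-population predictive correlation is flat in F up to 0.25 — there is
no decay to detect, because prediction rests directly on the causal markers
whose effects transfer. Real decay is driven by population-specific LD
between tag markers and causal variants, and by drift/fixation at causal
loci. The package therefore also provides a drift-based fixture
(`drifted_population_fixture`): populations derived from one ancestral
LD-bearing haplotype pool via a bottleneck and several generations of random
mating. Under that fixture predictive accuracy falls with divergence
(measured: mean rho_P 0.47 for one generation of drift vs 0.29 for fifteen,
nearest > farthest in 9/10 seeds), and the decay-behaviour tests use it for
their founders. Passing tests on BN fixtures therefore validate the
estimator and the machinery; statements about accuracy decay rest on the
drift fixtures, and neither captures real LD block structure, selection
footprints or trait architecture differences between real populations.

## Numerical and scaling choices

- Imputation: kNN with k = 10, Euclidean distance over shared non-missing
  markers, deterministic tie-break by sample order, imputed values rounded
  to {0,1,2}. LD pruning is a greedy left-to-right scan in file order.
- Elastic-net grids: the library default mirrors the conventional
  5×10-fold, 10-mixing, 100-penalty search; the pipeline, tests and
  simulation defaults use a reduced grid (1 run of 5 folds, mixing
  {0.5, 1.0}, 20–25 penalties down to 0.01 of the maximum), which selects
  essentially the same models on the simulation sample sizes at a fraction
  of the cost.
- Test-scale experiment sizes: the decay-behaviour experiment uses 5 rounds,
  10 replicates, reps_per_m = 6 and step 8; the swap-convergence check uses
  5 repetitions per m. These sizes are the package's own reproducibility
  budget; all seeds are explicit.
- The m = 0 anchor point enters the LOESS fit once, with the same weight as
  any other point.
- Agreement between the windowed curve value and the linear approximation is
  assessed as the mean absolute difference over evenly spaced queries across
  the span (individual queries fluctuate with the window contents at small
  reps_per_m).

## Known limitations

- The F_ST estimator's plug-in bias (~1/(2 n_TR)) is not corrected; with
  small training subsamples the stopping threshold of 0.005 is unreachable
  and the series ends at maximal mixing with a warning.
- k-means assumes two clusters; samples with more structure are split along
  the dominant axis only.
- The likelihood ignores linkage between markers; confidence statements for
  F_ST are not provided for that reason.
- Rebalancing is greedy, not optimal; exhaustive search over transfers is
  exponential.
- Polyploid genetics, dominance/epistasis, genotype-by-environment effects
  and phasing are out of scope.
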