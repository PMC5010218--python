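# gpdecay

Decay curves of genomic-prediction accuracy over genetic distance.

Genomic prediction regresses a quantitative phenotype on genome-wide SNP
allele counts and is the workhorse of genomic selection in plant and animal
breeding, and increasingly of risk prediction in human genetics. Its
accuracy is usually quoted from random-split cross-validation, which
silently assumes the individuals to be predicted come from the population
the model was trained on. Breeders and geneticists routinely violate that
assumption: the real targets are future generations of a selection program,
other countries' varieties, other families, other ancestry groups.
`gpdecay` estimates how fast accuracy is lost as the target drifts away —
the decay of the predictive correlation rho (Pearson correlation between
predicted and observed phenotypes) as a function of the fixation index
F_ST between training and target samples.

The core procedure manufactures training/target pairs at a range of genetic
distances out of a *single* genotyped, phenotyped sample:

1. **Split** the sample into two minimally related subsamples with k-means
   (k = 2) on standardized allele counts (Euclidean distance between
   standardized marker profiles is monotone in kinship,
   d²_ij = m(k_ii + k_jj − 2k_ij), so the clusters are maximally
   differentiated). The larger cluster trains the model.
2. **Estimate distance and accuracy** for the pair: F_ST by maximizing a
   Beta-Binomial likelihood of the target's allele counts with the training
   frequencies plugged in as ancestral, and rho from an elastic net tuned to
   maximize out-of-fold predictive correlation.
3. **Swap-resample**: exchange m random individuals between the sides,
   refit, re-estimate — many replicates per m, m stepped up until the two
   sides are fully mixed (mean F_ST ≤ 0.005).
4. **Smooth** the (F_ST(m), rho_D(m)) cloud with degree-1 LOESS (95%
   pointwise band) and fit the straight-line approximation rho_L by OLS,
   which extrapolates beyond the largest observed F_ST.

Validation machinery is included: a forward breeding-program simulation
(random mating with Poisson recombination on a 21-chromosome map, additive
traits at h² = 0.55, truncation selection) whose per-generation
(F_ST, rho) means the curve should anticipate; a cross-population
prediction experiment with Fisher-z confidence intervals; and synthetic
Balding–Nichols and drift-derived population generators so everything runs
offline with known ground truth.

## Worked example

```python
import numpy as np
from gpdecay import (
    apply_qc, assign_trait, phenotype, standardize,
    split_minimally_related, fst_beta_binomial, generate_swap_series,
    fit_decay_curve, fit_linear, query_curve,
)
from gpdecay.pipeline import decay_points_from_series
from gpdecay.synthetic_data import drifted_population_fixture

# two populations drifted apart from one ancestral haplotype pool
g = apply_qc(drifted_population_fixture(sizes=(100, 100), n_markers=2000, seed=1))
trait = assign_trait(g, n_causal=200, h2=0.55, seed=2)
y = phenotype(g, trait, seed=3)

x = standardize(g)
pair = split_minimally_related(x, seed=4)
est = fst_beta_binomial(g, pair.train_idx, pair.target_idx)
print(f"split: n_TR={pair.n_train} n_TA={pair.n_target} F_ST(0)={est.value:.3f}")

series = generate_swap_series(x, g, pair, step=8, reps_per_m=6, seed=5)
points = decay_points_from_series(
    x, y, series, seed=6,
    cv_runs=1, folds=5, l1_ratios=(0.5, 1.0), n_alphas=20, alpha_min_ratio=0.01,
)
curve = fit_decay_curve(points)
linear = fit_linear(points)
print(f"linear approximation: rho_L = {linear.intercept:.2f} "
      f"{linear.slope:+.2f} * F_ST  (R^2 = {linear.r_squared:.2f})")
q = query_curve(curve, 0.05)
print(f"at F_ST = 0.05: curve rho_D = {q.loess:.2f}, "
      f"window mean = {q.window_mean:.2f}, 95% CI = ({q.ci[0]:.2f}, {q.ci[1]:.2f})")
```

prints

```
split: n_TR=100 n_TA=100 F_ST(0)=0.131
linear approximation: rho_L = 0.22 -2.27 * F_ST  (R^2 = 0.41)
at F_ST = 0.05: curve rho_D = 0.09, window mean = 0.15, 95% CI = (0.04, 0.14)
```

The clustering split sits at F_ST(0) = 0.131 — far more differentiated than
any random split of the same sample, which would measure ≈ 0.005 (the
estimator's plug-in floor at this training size). Accuracy decays from
rho ≈ 0.22 at F_ST ≈ 0 at roughly 2.3 correlation units per unit of F_ST;
at F_ST = 0.05 the smoothed curve expects rho ≈ 0.09–0.15. The window mean
averages the raw points with |F_ST(m) − 0.05| ≤ 0.01 and is the statistic
compared against realized accuracies in the validation experiments.

## Command line

A thin CLI wraps the same pipeline:

```sh
gpdecay fixtures --seed 3 --out fixtures/          # synthetic test data
gpdecay qc genotypes.csv --out clean.csv           # MAF/missingness/LD QC
gpdecay split clean.csv --out pair.csv             # k-means split + F_ST
gpdecay fst clean.csv --train a.txt --target b.txt # Beta-Binomial F_ST
gpdecay decay --config run.yaml                    # full decay pipeline
gpdecay simulate-breeding --config sim.yaml        # selection program overlay
gpdecay simulate-crosspop --config xp.yaml         # cross-population targets
```

Configs are YAML; every random operation takes an explicit seed and reruns
are bit-identical. Exit codes: 0 success, 1 validation error, 2 runtime
error.

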