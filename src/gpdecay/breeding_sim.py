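"""Forward genomic-selection simulation and cross-population prediction.

The breeding program starts from a founder population on which a genomic
prediction model is fitted, then iterates rounds of: random mating without
selfing (Poisson crossovers on a genetic map, no interference), additive
phenotype generation, F_ST of the progeny against the founders, predictive
correlation of the founder-fitted model on the progeny, and truncation
selection of the highest phenotypes as next-round parents.  Selection plus
drift push the progeny away from the founders, so per-round mean F_ST rises
while the mean predictive correlation rho-bar falls -- the trajectory the
decay curve is meant to anticipate.

Founder genotypes are unphased allele counts; heterozygotes are phased by a
random coin flip once per replicate, an approximation that preserves allele
frequencies and is neutral for an additive trait.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .exceptions import UndefinedCorrelationError, ValidationError
from .fst import allele_frequencies, fst_beta_binomial, fst_mle
from .genotype_io import GenotypeMatrix, Phenotype, StandardizedMatrix
from .prediction import FittedModel, fit_elastic_net, predict_phenotypes, predictive_correlation


@dataclass
class GeneticMap:
    """Marker positions in Morgans on numbered chromosomes."""

    chrom_of: np.ndarray  # per-marker chromosome index, 0-based
    pos_morgans: np.ndarray
    chrom_lengths: np.ndarray  # Morgans per chromosome

    def __post_init__(self):
        self.chrom_of = np.asarray(self.chrom_of, dtype=int)
        self.pos_morgans = np.asarray(self.pos_morgans, dtype=float)
        self.chrom_lengths = np.asarray(self.chrom_lengths, dtype=float)
        for c in range(self.chrom_lengths.size):
            pos = self.pos_morgans[self.chrom_of == c]
            if pos.size and (np.diff(pos) < 0).any():
                raise ValidationError(f"positions on chromosome {c} not sorted")

    @property
    def n_markers(self) -> int:
        return self.chrom_of.size


def uniform_map(
    n_markers: int, n_chrom: int = 21, chrom_length: float = 1.0
) -> GeneticMap:
    """Markers allocated uniformly across ``n_chrom`` chromosomes of equal
    genetic length (1 Morgan each by default)."""
    base = n_markers // n_chrom
    extra = n_markers % n_chrom
    counts = np.array([base + (1 if c < extra else 0) for c in range(n_chrom)])
    chrom_of = np.repeat(np.arange(n_chrom), counts)
    pos = np.concatenate(
        [(np.arange(c) + 0.5) * chrom_length / max(c, 1) for c in counts]
    )
    return GeneticMap(chrom_of=chrom_of, pos_morgans=pos,
                      chrom_lengths=np.full(n_chrom, chrom_length))


@dataclass
class TraitModel:
    """Additive genetic architecture: causal markers, effects, noise scale."""

    causal_idx: np.ndarray
    effects: np.ndarray
    noise_sd: float
    h2_target: float
    h2_realized: float

    def genetic_values(self, counts: np.ndarray) -> np.ndarray:
        return counts[:, self.causal_idx] @ self.effects


@dataclass
class SelectionTrajectory:
    """Per-replicate, per-round F_ST and predictive correlation."""

    fst: np.ndarray  # (replicates, rounds)
    rho: np.ndarray  # (replicates, rounds)
    retained_progeny: list = field(default_factory=list)

    @property
    def rounds(self) -> int:
        return self.fst.shape[1]

    @property
    def mean_fst(self) -> np.ndarray:
        return np.nanmean(self.fst, axis=0)

    @property
    def mean_rho(self) -> np.ndarray:
        return np.nanmean(self.rho, axis=0)


@dataclass
class PopPrediction:
    """Cross-population prediction record for one target population."""

    label: str
    fst: float
    rho: float
    ci_low: float
    ci_high: float
    n_target: int
    wide: bool


def phase_genotypes(g_counts: np.ndarray, rng: np.random.Generator):
    """Split unphased counts into two haplotypes; heterozygote alleles are
    assigned to a haplotype at random."""
    counts = np.asarray(g_counts)
    hom = (counts // 2).astype(np.int8)  # 1 where count==2
    het = counts == 1
    flip = rng.integers(0, 2, size=counts.shape).astype(np.int8)
    h1 = hom + np.where(het, flip, 0).astype(np.int8)
    h2 = hom + np.where(het, 1 - flip, 0).astype(np.int8)
    return h1, h2


def _chrom_index(gmap: GeneticMap):
    return [
        (np.flatnonzero(gmap.chrom_of == c), gmap.pos_morgans[gmap.chrom_of == c])
        for c in range(gmap.chrom_lengths.size)
    ]


def _gamete(h1: np.ndarray, h2: np.ndarray, chrom_idx, chrom_lengths,
            rng: np.random.Generator) -> np.ndarray:
    """One recombinant gamete: Poisson(L) crossovers per chromosome, uniform
    breakpoints, no interference, random starting haplotype."""
    out = np.empty(h1.shape, dtype=np.int8)
    for c, (idx, pos) in enumerate(chrom_idx):
        if idx.size == 0:
            continue
        length = chrom_lengths[c]
        n_cross = rng.poisson(length)
        start = rng.integers(0, 2)
        if n_cross == 0:
            phase = np.full(idx.size, start)
        else:
            bp = np.sort(rng.uniform(0.0, length, n_cross))
            phase = (start + np.searchsorted(bp, pos)) % 2
        out[idx] = np.where(phase == 0, h1[idx], h2[idx])
    return out


def _mate_haplotypes(h1, h2, chrom_idx, chrom_lengths, n_progeny, rng):
    """Random mating without selfing on phased parents; returns progeny
    haplotypes and the parent index pairs."""
    n_parents = h1.shape[0]
    p1 = np.empty((n_progeny, h1.shape[1]), dtype=np.int8)
    p2 = np.empty_like(p1)
    pairs = np.empty((n_progeny, 2), dtype=int)
    for i in range(n_progeny):
        a, b = rng.choice(n_parents, size=2, replace=False)
        pairs[i] = (a, b)
        p1[i] = _gamete(h1[a], h2[a], chrom_idx, chrom_lengths, rng)
        p2[i] = _gamete(h1[b], h2[b], chrom_idx, chrom_lengths, rng)
    return p1, p2, pairs


def random_mating(
    parents: GenotypeMatrix,
    gmap: GeneticMap,
    n_progeny: int,
    seed: int,
    id_prefix: str = "prog",
) -> GenotypeMatrix:
    """Generate progeny allele counts via random mating without selfing.

    Each progeny draws two distinct parents uniformly; each parent
    contributes one recombinant gamete.  The chosen parent pairs are exposed
    on the returned matrix as ``parent_pairs``.
    """
    if parents.n_samples < 2:
        raise ValidationError("random mating needs >= 2 parents (no selfing)")
    if gmap.n_markers != parents.n_markers:
        raise ValidationError("genetic map does not cover all markers")
    if parents.has_missing():
        raise ValidationError("parents must have complete genotypes")
    rng = np.random.default_rng(seed)
    h1, h2 = phase_genotypes(parents.counts, rng)
    chrom_idx = _chrom_index(gmap)
    p1, p2, pairs = _mate_haplotypes(h1, h2, chrom_idx, gmap.chrom_lengths,
                                     n_progeny, rng)
    out = GenotypeMatrix(
        sample_ids=[f"{id_prefix}_{i:04d}" for i in range(n_progeny)],
        marker_ids=list(parents.marker_ids),
        counts=(p1 + p2).astype(float),
        chrom=parents.chrom,
        pos=parents.pos,
    )
    out.parent_pairs = pairs
    return out


def assign_trait(
    founders: GenotypeMatrix,
    n_causal: int,
    h2: float = 0.55,
    maf_min: float = 0.05,
    seed: int = 0,
    noise_sd: float = 1.0,
) -> TraitModel:
    """Random causal variants (founder MAF > ``maf_min``) with mean-zero
    normal additive effects rescaled to hit the target heritability.

    Effects are drawn N(0, 1) and multiplied by the constant that makes
    Var(X beta) / (Var(X beta) + noise_sd^2) equal ``h2`` in the founder
    sample, so the realized founder heritability matches the target up to
    floating point.
    """
    if founders.has_missing():
        raise ValidationError("founders must have complete genotypes")
    if not (0.0 <= h2 < 1.0):
        raise ValidationError("h2 must lie in [0, 1)")
    p = founders.counts.mean(axis=0) / 2.0
    maf = np.minimum(p, 1.0 - p)
    eligible = np.flatnonzero(maf > maf_min)
    if eligible.size < n_causal:
        raise ValidationError(
            f"only {eligible.size} markers pass MAF > {maf_min}; "
            f"cannot place {n_causal} causal variants"
        )
    rng = np.random.default_rng(seed)
    causal = np.sort(rng.choice(eligible, size=n_causal, replace=False))
    if h2 == 0.0:
        effects = np.zeros(n_causal)
        return TraitModel(causal, effects, noise_sd, 0.0, 0.0)
    effects = rng.standard_normal(n_causal)
    gv = founders.counts[:, causal] @ effects
    var_g = float(np.var(gv))
    if var_g == 0:
        raise ValidationError("causal variants carry no genetic variance")
    target_var = h2 / (1.0 - h2) * noise_sd**2
    effects *= np.sqrt(target_var / var_g)
    var_g = float(np.var(founders.counts[:, causal] @ effects))
    h2_real = var_g / (var_g + noise_sd**2)
    return TraitModel(causal, effects, noise_sd, h2, h2_real)


def phenotype(g: GenotypeMatrix, trait: TraitModel, seed: int) -> Phenotype:
    """y = X_causal beta + eps with eps ~ N(0, noise_sd^2)."""
    if g.has_missing():
        raise ValidationError("phenotype generation requires complete genotypes")
    rng = np.random.default_rng(seed)
    y = trait.genetic_values(g.counts)
    if trait.noise_sd > 0:
        y = y + rng.normal(0.0, trait.noise_sd, size=g.n_samples)
    return Phenotype(sample_ids=list(g.sample_ids), y=y)


def run_selection_program(
    founders: GenotypeMatrix,
    trait: TraitModel,
    model: FittedModel,
    rounds: int = 10,
    n_progeny: int = 200,
    n_selected: int = 20,
    replicates: int = 100,
    seed: int = 0,
    gmap: GeneticMap | None = None,
    scaler: StandardizedMatrix | None = None,
    keep_rounds: int = 0,
) -> SelectionTrajectory:
    """Replicated multi-round truncation-selection program.

    Per replicate and round: progeny by random mating, phenotypes from the
    trait model, Beta-Binomial F_ST with the founders as ancestral
    population, predictive correlation of the founder-fitted ``model``
    (genotypes standardized through ``scaler`` if given), then the
    ``n_selected`` highest phenotypes become the next parents.  Progeny of
    the first ``keep_rounds`` rounds of the first replicate are retained for
    training-set augmentation.
    """
    if n_selected < 2:
        raise ValidationError("need n_selected >= 2 to mate without selfing")
    if gmap is None:
        gmap = uniform_map(founders.n_markers)
    if gmap.n_markers != founders.n_markers:
        raise ValidationError("genetic map does not cover all markers")
    pi = allele_frequencies(founders, np.arange(founders.n_samples))
    chrom_idx = _chrom_index(gmap)
    fst = np.full((replicates, rounds), np.nan)
    rho = np.full((replicates, rounds), np.nan)
    retained = []
    ss = np.random.SeedSequence(seed)
    for rep, child in enumerate(ss.spawn(replicates)):
        rng = np.random.default_rng(child)
        h1, h2 = phase_genotypes(founders.counts, rng)
        for rnd in range(rounds):
            p1, p2, _ = _mate_haplotypes(h1, h2, chrom_idx, gmap.chrom_lengths,
                                         n_progeny, rng)
            counts = (p1 + p2).astype(float)
            y = trait.genetic_values(counts)
            if trait.noise_sd > 0:
                y = y + rng.normal(0.0, trait.noise_sd, size=n_progeny)
            est = fst_mle(pi, counts.sum(axis=0), 2.0 * n_progeny)
            fst[rep, rnd] = est.value
            x_new = scaler.apply(counts) if scaler is not None else counts
            preds = predict_phenotypes(model, x_new)
            try:
                rho[rep, rnd] = predictive_correlation(preds, y)
            except UndefinedCorrelationError:
                rho[rep, rnd] = np.nan
            if rep == 0 and rnd < keep_rounds:
                retained.append(
                    GenotypeMatrix(
                        sample_ids=[f"r{rnd + 1}_prog_{i:04d}" for i in range(n_progeny)],
                        marker_ids=list(founders.marker_ids),
                        counts=counts.copy(),
                    )
                )
            top = np.argsort(y)[::-1][:n_selected]
            h1, h2 = p1[top], p2[top]
    return SelectionTrajectory(fst=fst, rho=rho, retained_progeny=retained)


@dataclass
class AugmentResult:
    genotypes: GenotypeMatrix
    model: FittedModel
    scaler: StandardizedMatrix
    phenotype: Phenotype


def _safe_standardize(counts: np.ndarray, sample_ids, marker_ids) -> StandardizedMatrix:
    """Standardization tolerant of monomorphic columns (scale forced to 1, so
    the column becomes identically zero and is ignored by the model)."""
    center = counts.mean(axis=0)
    scale = counts.std(axis=0)
    scale = np.where(scale == 0, 1.0, scale)
    return StandardizedMatrix(
        values=(counts - center) / scale,
        center=center,
        scale=scale,
        sample_ids=list(sample_ids),
        marker_ids=list(marker_ids),
    )


def augment_and_refit(
    founders: GenotypeMatrix,
    retained_progeny,
    trait: TraitModel,
    seed: int = 0,
    **fit_kwargs,
) -> AugmentResult:
    """Refit the prediction model on founders plus early-round progeny.

    ``retained_progeny`` is the list kept by :func:`run_selection_program`
    (typically the first two rounds).  Duplicate sample ids are dropped,
    phenotypes are regenerated from the same trait model, and the elastic
    net is refitted on the augmented, restandardized training set.
    """
    counts = [founders.counts]
    ids = list(founders.sample_ids)
    for g in retained_progeny:
        counts.append(g.counts)
        ids += list(g.sample_ids)
    counts = np.vstack(counts)
    seen, keep = set(), []
    for i, sid in enumerate(ids):
        if sid not in seen:
            seen.add(sid)
            keep.append(i)
    counts = counts[keep]
    ids = [ids[i] for i in keep]
    aug = GenotypeMatrix(sample_ids=ids, marker_ids=list(founders.marker_ids),
                         counts=counts)
    pheno = phenotype(aug, trait, seed=seed)
    scaler = _safe_standardize(aug.counts, aug.sample_ids, aug.marker_ids)
    model = fit_elastic_net(scaler.values, pheno.y, seed=seed, **fit_kwargs)
    return AugmentResult(genotypes=aug, model=model, scaler=scaler, phenotype=pheno)


def cross_population_experiment(
    g: GenotypeMatrix,
    train_pop: str,
    trait: TraitModel,
    seed: int = 0,
    **fit_kwargs,
) -> list:
    """Fit on one labelled population, predict each of the others.

    The same causal effects generate phenotypes in every population.  Per
    target population the Beta-Binomial F_ST (training as ancestral), the
    predictive correlation rho_P, and its 95% Fisher-z confidence interval
    are reported; targets below 10 individuals are flagged ``wide``.
    """
    if g.pop_labels is None:
        raise ValidationError("genotypes carry no population labels")
    labels = np.asarray(g.pop_labels)
    if train_pop not in labels:
        raise ValidationError(f"no samples labelled {train_pop!r}")
    others = [l for l in dict.fromkeys(labels) if l != train_pop]
    if not others:
        raise ValidationError("need >= 2 population labels")
    pheno = phenotype(g, trait, seed=seed)
    train_idx = np.flatnonzero(labels == train_pop)
    scaler = _safe_standardize(g.counts[train_idx],
                               [g.sample_ids[i] for i in train_idx],
                               g.marker_ids)
    model = fit_elastic_net(scaler.values, pheno.y[train_idx], seed=seed,
                            **fit_kwargs)
    out = []
    for label in others:
        idx = np.flatnonzero(labels == label)
        est = fst_beta_binomial(g, train_idx, idx)
        preds = predict_phenotypes(model, scaler.apply(g.counts[idx]))
        r = predictive_correlation(preds, pheno.y[idx])
        n = idx.size
        if n > 3:
            z = np.arctanh(np.clip(r, -0.999999, 0.999999))
            half = 1.96 / np.sqrt(n - 3)
            lo, hi = float(np.tanh(z - half)), float(np.tanh(z + half))
        else:
            lo, hi = -1.0, 1.0
        out.append(
            PopPrediction(label=str(label), fst=est.value, rho=r,
                          ci_low=lo, ci_high=hi, n_target=int(n),
                          wide=bool(n < 10))
        )
    return out
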