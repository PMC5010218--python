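"""Synthetic structured populations under the Balding-Nichols model.

Each population j diverges from a shared ancestral population with its own
divergence F_j: ancestral allele frequencies pi_k are drawn from a chosen
law, population frequencies from Beta(pi_k (1-F_j)/F_j, (1-pi_k)(1-F_j)/F_j),
and genotypes are Binomial(2, p_jk) per marker.  This matches the model the
Beta-Binomial F_ST estimator assumes, so the generator doubles as its
round-trip oracle.  Optional linkage disequilibrium is injected through a
Gaussian-copula AR(1) haplotype chain that preserves the per-marker
marginal frequencies exactly while correlating adjacent markers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.stats import norm

from .exceptions import ValidationError
from .genotype_io import GenotypeMatrix, Phenotype, write_genotypes


@dataclass
class PopulationSpec:
    """Parameters of a multi-population Balding-Nichols simulation.

    ``anc_freq_law`` is ``("uniform", lo, hi)`` or ``("beta", a, b)``;
    ``ld_rho`` is the latent AR(1) correlation between adjacent markers on a
    haplotype (0 = linkage equilibrium).
    """

    n_pops: int
    sizes: list
    fst_true: list
    n_markers: int
    anc_freq_law: tuple = ("uniform", 0.05, 0.95)
    ld_rho: float = 0.0

    def __post_init__(self):
        if len(self.sizes) != self.n_pops or len(self.fst_true) != self.n_pops:
            raise ValidationError("sizes and fst_true must have length n_pops")
        if any(s < 2 for s in self.sizes):
            raise ValidationError("each population needs >= 2 individuals")
        if any(not (0.0 < f < 1.0) for f in self.fst_true):
            raise ValidationError("fst_true values must lie in (0, 1)")
        if not (0.0 <= self.ld_rho < 1.0):
            raise ValidationError("ld_rho must lie in [0, 1)")


def _draw_ancestral(spec: PopulationSpec, rng: np.random.Generator) -> np.ndarray:
    law = spec.anc_freq_law
    if law[0] == "uniform":
        return rng.uniform(law[1], law[2], size=spec.n_markers)
    if law[0] == "beta":
        return np.clip(rng.beta(law[1], law[2], size=spec.n_markers), 1e-4, 1 - 1e-4)
    raise ValidationError(f"unknown ancestral frequency law {law!r}")


def _haplotypes_ld(
    p: np.ndarray, n_hap: int, rho: float, rng: np.random.Generator
) -> np.ndarray:
    """AR(1) Gaussian-copula haplotypes with marginal allele frequencies p."""
    m = p.size
    z = np.empty((n_hap, m))
    z[:, 0] = rng.standard_normal(n_hap)
    innov = rng.standard_normal((n_hap, m - 1)) if m > 1 else None
    s = np.sqrt(1.0 - rho * rho)
    for k in range(1, m):
        z[:, k] = rho * z[:, k - 1] + s * innov[:, k - 1]
    return (norm.cdf(z) < p).astype(np.int8)


def simulate_structured_population(
    spec: PopulationSpec, seed: int
) -> GenotypeMatrix:
    """Generate genotypes for all populations; pop_labels record membership."""
    rng = np.random.default_rng(seed)
    pi = _draw_ancestral(spec, rng)
    blocks = []
    labels = []
    sample_ids = []
    for j in range(spec.n_pops):
        fj = spec.fst_true[j]
        lam = (1.0 - fj) / fj
        p_j = rng.beta(pi * lam, (1.0 - pi) * lam)
        p_j = np.clip(p_j, 0.0, 1.0)
        nj = spec.sizes[j]
        if spec.ld_rho == 0.0:
            counts = rng.binomial(2, p_j, size=(nj, spec.n_markers)).astype(float)
        else:
            h1 = _haplotypes_ld(p_j, nj, spec.ld_rho, rng)
            h2 = _haplotypes_ld(p_j, nj, spec.ld_rho, rng)
            counts = (h1 + h2).astype(float)
        blocks.append(counts)
        labels += [f"pop{j}"] * nj
        sample_ids += [f"pop{j}_s{i:04d}" for i in range(nj)]
    return GenotypeMatrix(
        sample_ids=sample_ids,
        marker_ids=[f"M{k:05d}" for k in range(spec.n_markers)],
        counts=np.vstack(blocks),
        pop_labels=labels,
    )


def two_population_fixture(
    f: float,
    sizes=(100, 100),
    n_markers: int = 2000,
    seed: int = 0,
    ld_rho: float = 0.0,
) -> GenotypeMatrix:
    """Convenience wrapper: two populations at equal divergence ``f``."""
    spec = PopulationSpec(
        n_pops=2,
        sizes=list(sizes),
        fst_true=[f, f],
        n_markers=n_markers,
        ld_rho=ld_rho,
    )
    return simulate_structured_population(spec, seed)


def drifted_population_fixture(
    generations=(4, 4),
    sizes=(100, 100),
    bottleneck: int = 25,
    n_markers: int = 2000,
    ancestral_n: int = 150,
    ld_rho: float = 0.9,
    seed: int = 0,
) -> GenotypeMatrix:
    """Populations derived from one ancestral haplotype pool by drift.

    An ancestral sample with copula LD is generated, then each population is
    a bottleneck of ``bottleneck`` individuals random-mated for its entry in
    ``generations``.  Unlike independent Balding-Nichols draws, this gives
    populations that share haplotypes but have drifted apart in allele
    frequencies *and* local LD -- the structure under which genomic
    prediction genuinely loses accuracy across populations.
    """
    from .breeding_sim import random_mating, uniform_map

    rng = np.random.default_rng(seed)
    spec = PopulationSpec(
        n_pops=1, sizes=[ancestral_n], fst_true=[1e-6], n_markers=n_markers,
        ld_rho=ld_rho,
    )
    anc = simulate_structured_population(spec, int(rng.integers(2**31 - 1)))
    gmap = uniform_map(n_markers)
    blocks, labels, ids = [], [], []
    for j, (gens, n_out) in enumerate(zip(generations, sizes)):
        take = rng.choice(ancestral_n, bottleneck, replace=False)
        cur = anc.take_samples(take)
        for t in range(gens):
            n = n_out if t == gens - 1 else bottleneck
            cur = random_mating(cur, gmap, n, seed=int(rng.integers(2**31 - 1)))
        blocks.append(cur.counts)
        labels += [f"pop{j}"] * n_out
        ids += [f"pop{j}_s{i:04d}" for i in range(n_out)]
    return GenotypeMatrix(
        sample_ids=ids,
        marker_ids=list(anc.marker_ids),
        counts=np.vstack(blocks),
        pop_labels=labels,
    )


def make_fixture_suite(seed: int, outdir) -> dict:
    """Write a deterministic suite of small named fixtures plus a manifest.

    Fixtures: a two-population split fixture, a homogeneous fixture, a
    missing-data fixture, an LD fixture, and a trait fixture (genotypes plus
    a phenotype file).  Returns the manifest dict.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    manifest = {"seed": int(seed), "fixtures": {}}

    def _register(name, path, **params):
        manifest["fixtures"][name] = {"file": path.name, **params}

    # two-population fixture at a recoverable divergence
    s_two = int(rng.integers(2**31 - 1))
    g_two = two_population_fixture(0.05, sizes=(40, 40), n_markers=400, seed=s_two)
    p = outdir / "two_pop.csv"
    write_genotypes(g_two, p, format="csv")
    _register("two_pop", p, fst_true=0.05, sizes=[40, 40], n_markers=400, seed=s_two)

    # effectively homogeneous population (divergence at the model's floor)
    s_hom = int(rng.integers(2**31 - 1))
    g_hom = two_population_fixture(1e-4, sizes=(40, 40), n_markers=400, seed=s_hom)
    p = outdir / "homogeneous.csv"
    write_genotypes(g_hom, p, format="csv")
    _register("homogeneous", p, fst_true=1e-4, sizes=[40, 40], n_markers=400, seed=s_hom)

    # missing-data fixture: mask 5% of calls at random
    s_mis = int(rng.integers(2**31 - 1))
    g_mis = two_population_fixture(0.05, sizes=(20, 20), n_markers=100, seed=s_mis)
    mask = rng.random(g_mis.counts.shape) < 0.05
    counts = g_mis.counts.copy()
    counts[mask] = np.nan
    g_mis = GenotypeMatrix(
        sample_ids=g_mis.sample_ids,
        marker_ids=g_mis.marker_ids,
        counts=counts,
        pop_labels=g_mis.pop_labels,
    )
    p = outdir / "missing.csv"
    write_genotypes(g_mis, p, format="csv")
    _register("missing", p, fst_true=0.05, missing_frac=0.05, seed=s_mis)

    # LD fixture
    s_ld = int(rng.integers(2**31 - 1))
    g_ld = two_population_fixture(
        0.05, sizes=(30, 30), n_markers=200, seed=s_ld, ld_rho=0.8
    )
    p = outdir / "ld.csv"
    write_genotypes(g_ld, p, format="csv")
    _register("ld", p, fst_true=0.05, ld_rho=0.8, seed=s_ld)

    # trait fixture: genotypes plus an additive phenotype
    from .breeding_sim import assign_trait, phenotype as sim_phenotype

    s_tr = int(rng.integers(2**31 - 1))
    g_tr = two_population_fixture(0.02, sizes=(50, 50), n_markers=300, seed=s_tr)
    trait = assign_trait(g_tr, n_causal=30, h2=0.55, seed=s_tr)
    pheno = sim_phenotype(g_tr, trait, seed=s_tr + 1)
    p = outdir / "trait_genotypes.csv"
    write_genotypes(g_tr, p, format="csv")
    with open(outdir / "trait_phenotypes.csv", "w") as fh:
        for sid, y in zip(pheno.sample_ids, pheno.y):
            fh.write(f"{sid},{y:.10f}\n")
    _register(
        "trait",
        p,
        phenotype_file="trait_phenotypes.csv",
        n_causal=30,
        h2_target=0.55,
        h2_realized=round(trait.h2_realized, 6),
        seed=s_tr,
    )

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
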