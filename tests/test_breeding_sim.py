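import numpy as np
import pytest

from gpdecay import (
    GenotypeMatrix,
    assign_trait,
    augment_and_refit,
    cross_population_experiment,
    fit_elastic_net,
    phenotype,
    random_mating,
    run_selection_program,
    standardize,
    two_population_fixture,
    uniform_map,
)
from gpdecay.breeding_sim import phase_genotypes
from gpdecay.exceptions import ValidationError

from conftest import FAST_ENET, ancestral_target_fixture, qc_standardize


@pytest.fixture(scope="module")
def founders():
    g = two_population_fixture(0.03, sizes=(50, 50), n_markers=600, seed=31)
    from gpdecay import apply_qc

    return apply_qc(g, maf_min=0.01)


@pytest.fixture(scope="module")
def trait(founders):
    return assign_trait(founders, n_causal=80, h2=0.55, seed=32)


class TestGeneticMap:
    def test_uniform_map_covers_all_markers(self):
        gm = uniform_map(100, n_chrom=21)
        assert gm.n_markers == 100
        assert len(np.unique(gm.chrom_of)) == 21
        for c in range(21):
            pos = gm.pos_morgans[gm.chrom_of == c]
            assert (np.diff(pos) > 0).all()
            assert pos.max() < 1.0

    def test_unsorted_positions_rejected(self):
        from gpdecay import GeneticMap

        with pytest.raises(ValidationError):
            GeneticMap(chrom_of=[0, 0], pos_morgans=[0.5, 0.1],
                       chrom_lengths=[1.0])


class TestRandomMating:
    def test_homozygous_parents_breed_true(self):
        g = GenotypeMatrix(
            ["p1", "p2", "p3"], [f"m{j}" for j in range(30)],
            np.zeros((3, 30)),
        )
        prog = random_mating(g, uniform_map(30), n_progeny=10, seed=0)
        assert (prog.counts == 0).all()

    def test_phasing_preserves_counts(self, founders):
        rng = np.random.default_rng(0)
        h1, h2 = phase_genotypes(founders.counts, rng)
        np.testing.assert_array_equal(h1 + h2, founders.counts.astype(np.int8))

    def test_allele_frequencies_conserved_without_selection(self, founders):
        """Progeny frequencies stay within binomial sampling error of the
        parental frequencies (|dp| < 4 sd), checked across seeds."""
        p_parent = founders.counts.mean(axis=0) / 2
        n_prog = 200
        sd = np.sqrt(p_parent * (1 - p_parent) / (2 * n_prog))
        worst_frac_outside = 0.0
        for seed in range(20):
            prog = random_mating(founders, uniform_map(founders.n_markers),
                                 n_progeny=n_prog, seed=seed)
            p_child = prog.counts.mean(axis=0) / 2
            outside = np.abs(p_child - p_parent) >= 4 * sd
            worst_frac_outside = max(worst_frac_outside, outside.mean())
        # 4-sigma exceedances should be very rare
        assert worst_frac_outside < 0.01

    def test_no_selfing(self, founders):
        prog = random_mating(founders, uniform_map(founders.n_markers),
                             n_progeny=50, seed=3)
        assert (prog.parent_pairs[:, 0] != prog.parent_pairs[:, 1]).all()

    def test_single_parent_rejected(self):
        g = GenotypeMatrix(["p1"], ["m0", "m1"], np.array([[1.0, 2.0]]))
        with pytest.raises(ValidationError, match="selfing"):
            random_mating(g, uniform_map(2), n_progeny=5, seed=0)


class TestTraitModel:
    def test_realized_heritability_matches_target(self, founders):
        t = assign_trait(founders, n_causal=80, h2=0.55, seed=1)
        assert t.h2_realized == pytest.approx(0.55, abs=1e-6)
        gv = t.genetic_values(founders.counts)
        assert np.var(gv) / (np.var(gv) + 1.0) == pytest.approx(0.55, abs=1e-6)

    def test_zero_heritability_gives_zero_effects(self, founders):
        t = assign_trait(founders, n_causal=10, h2=0.0, seed=2)
        assert (t.effects == 0).all()

    def test_single_causal_variant(self, founders):
        t = assign_trait(founders, n_causal=1, h2=0.3, seed=3)
        assert t.causal_idx.size == 1
        assert t.effects.size == 1 and t.effects[0] != 0

    def test_causal_variants_respect_maf_filter(self, founders, trait):
        p = founders.counts.mean(axis=0) / 2
        maf = np.minimum(p, 1 - p)
        assert (maf[trait.causal_idx] > 0.05).all()

    def test_too_many_causal_rejected(self, founders):
        with pytest.raises(ValidationError):
            assign_trait(founders, n_causal=founders.n_markers + 1, seed=0)


class TestPhenotype:
    def test_zero_noise_returns_genetic_values(self, founders, trait):
        import dataclasses

        t0 = dataclasses.replace(trait, noise_sd=0.0)
        y = phenotype(founders, t0, seed=4)
        np.testing.assert_allclose(y.y, trait.genetic_values(founders.counts))

    def test_regression_on_genetic_value_has_unit_slope(self, founders, trait):
        slopes = []
        for seed in range(20):
            y = phenotype(founders, trait, seed=seed).y
            gv = trait.genetic_values(founders.counts)
            slopes.append(np.polyfit(gv, y, 1)[0])
        assert np.mean(slopes) == pytest.approx(1.0, abs=0.15)

    def test_same_seed_same_phenotypes(self, founders, trait):
        a = phenotype(founders, trait, seed=5)
        b = phenotype(founders, trait, seed=5)
        np.testing.assert_array_equal(a.y, b.y)


class TestSelectionProgram:
    @pytest.fixture(scope="class")
    def program(self, founders, trait):
        pheno = phenotype(founders, trait, seed=40)
        x = standardize(founders)
        model = fit_elastic_net(x.values, pheno.y, seed=41, **FAST_ENET)
        traj = run_selection_program(
            founders, trait, model, rounds=5, n_progeny=100, n_selected=20,
            replicates=5, seed=42, scaler=x, keep_rounds=2,
        )
        return traj

    def test_fst_increases_over_rounds(self, program):
        from scipy.stats import spearmanr

        rho = spearmanr(np.arange(5), program.mean_fst).statistic
        assert rho > 0.9

    def test_accuracy_declines_within_noise(self, program):
        assert program.mean_rho[0] >= program.mean_rho[-1]

    def test_trajectory_shape_and_retention(self, program):
        assert program.fst.shape == (5, 5)
        assert len(program.retained_progeny) == 2
        assert program.retained_progeny[0].n_samples == 100

    def test_zero_heritability_gives_no_predictive_signal(self, founders):
        t0 = assign_trait(founders, n_causal=20, h2=0.0, seed=50)
        y0 = phenotype(founders, t0, seed=51)
        # a model trained on pure noise
        x = standardize(founders)
        rng = np.random.default_rng(52)
        from gpdecay import FittedModel

        model = FittedModel(intercept=0.0,
                            coefficients=rng.standard_normal(founders.n_markers) * 0.01,
                            mixing=1.0, penalty=0.1, n_nonzero=0, cv_correlation=0.0)
        traj = run_selection_program(
            founders, t0, model, rounds=3, n_progeny=80, n_selected=20,
            replicates=5, seed=53, scaler=x,
        )
        assert abs(np.nanmean(traj.rho)) <= 0.1


class TestAugmentation:
    def test_augmented_size_and_ids(self, founders, trait):
        pheno = phenotype(founders, trait, seed=60)
        x = standardize(founders)
        model = fit_elastic_net(x.values, pheno.y, seed=61, **FAST_ENET)
        traj = run_selection_program(
            founders, trait, model, rounds=2, n_progeny=50, n_selected=20,
            replicates=1, seed=62, scaler=x, keep_rounds=2,
        )
        res = augment_and_refit(founders, traj.retained_progeny, trait, seed=63,
                                **FAST_ENET)
        assert res.genotypes.n_samples == founders.n_samples + 100
        assert len(set(res.genotypes.sample_ids)) == res.genotypes.n_samples

    def test_refit_on_more_data_fits_training_at_least_as_well(self, founders, trait):
        pheno = phenotype(founders, trait, seed=70)
        x = standardize(founders)
        model = fit_elastic_net(x.values, pheno.y, seed=71, **FAST_ENET)
        traj = run_selection_program(
            founders, trait, model, rounds=2, n_progeny=100, n_selected=20,
            replicates=1, seed=72, scaler=x, keep_rounds=2,
        )
        res = augment_and_refit(founders, traj.retained_progeny, trait, seed=73,
                                **FAST_ENET)
        from gpdecay import predict_phenotypes, predictive_correlation

        rho_aug = predictive_correlation(
            predict_phenotypes(res.model, res.scaler.values), res.phenotype.y
        )
        assert rho_aug > 0.3  # refit retains genuine signal on its training set


def _drift_population(anc, generations, bottleneck, n_out, seed, gmap):
    """Derive a diverged population by bottlenecking the ancestral sample and
    random-mating for several generations: drift on shared haplotypes, the
    mechanism that degrades cross-population prediction."""
    rng = np.random.default_rng(seed)
    cur = anc.take_samples(rng.choice(anc.n_samples, bottleneck, replace=False))
    for t in range(generations):
        n = n_out if t == generations - 1 else bottleneck
        cur = random_mating(cur, gmap, n, seed=int(rng.integers(2**31 - 1)))
    return cur


class TestCrossPopulation:
    def test_accuracy_decreases_with_divergence(self):
        """Targets derived from the training population by increasing
        amounts of drift show rising F_ST and falling predictive
        correlation between the nearest and the farthest population."""
        near_rho, far_rho, wins = [], [], 0
        for seed in range(10):
            anc = two_population_fixture(
                1e-6, sizes=(150, 10), n_markers=600, seed=300 + seed,
                ld_rho=0.9,
            ).take_samples(np.arange(150))
            gmap = uniform_map(anc.n_markers)
            trait = assign_trait(anc, n_causal=100, h2=0.55, seed=seed)
            pops = [
                _drift_population(anc, gens, 20, 60, seed * 10 + k, gmap)
                for k, gens in enumerate((1, 15))
            ]
            counts = np.vstack([anc.counts] + [p.counts for p in pops])
            ids = list(anc.sample_ids)
            labels = ["train"] * anc.n_samples
            for name, p in zip(("near", "far"), pops):
                ids += [f"{name}_{s}" for s in p.sample_ids]
                labels += [name] * p.n_samples
            g = GenotypeMatrix(ids, anc.marker_ids, counts, pop_labels=labels)
            recs = cross_population_experiment(g, "train", trait, seed=seed,
                                               **FAST_ENET)
            by = {r.label: r for r in recs}
            assert by["near"].fst < by["far"].fst
            near_rho.append(by["near"].rho)
            far_rho.append(by["far"].rho)
            wins += by["near"].rho > by["far"].rho
        assert np.mean(near_rho) > np.mean(far_rho)
        assert wins >= 7

    def test_ci_widens_as_target_shrinks(self, founders, trait):
        labels = ["big"] * 60 + ["mid"] * 25 + ["small"] * 15
        g = GenotypeMatrix(founders.sample_ids, founders.marker_ids,
                           founders.counts, pop_labels=labels)
        recs = cross_population_experiment(g, "big", trait, seed=7, **FAST_ENET)
        width = {r.label: r.ci_high - r.ci_low for r in recs}
        assert width["small"] > width["mid"]

    def test_missing_labels_rejected(self, founders, trait):
        with pytest.raises(ValidationError):
            cross_population_experiment(founders, "popX", trait, seed=0)
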