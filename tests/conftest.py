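import numpy as np
import pytest

from gpdecay import (
    GenotypeMatrix,
    PopulationSpec,
    apply_qc,
    simulate_structured_population,
    standardize,
    two_population_fixture,
)


def qc_standardize(g):
    """Drop monomorphic/rare markers, then standardize; returns (g, x)."""
    g = apply_qc(g, maf_min=0.01)
    return g, standardize(g)

# small elastic-net grid used throughout the tests to keep fits fast; the
# tuning criterion (out-of-fold correlation) is unchanged
FAST_ENET = dict(cv_runs=1, folds=5, l1_ratios=(0.5, 1.0), n_alphas=20,
                 alpha_min_ratio=1e-2)


def ancestral_target_fixture(f, sizes=(100, 100), n_markers=2000, seed=0):
    """Two populations where the first sits at the ancestral frequencies
    (divergence at the model floor) and the second has diverged by f, so the
    training-as-ancestral F_ST estimator should recover f."""
    spec = PopulationSpec(
        n_pops=2, sizes=list(sizes), fst_true=[1e-6, f], n_markers=n_markers
    )
    return simulate_structured_population(spec, seed=seed)


@pytest.fixture(scope="session")
def two_pop():
    """Two clearly diverged populations, 40+40 samples, 800 markers."""
    return two_population_fixture(0.05, sizes=(40, 40), n_markers=800, seed=11)


@pytest.fixture(scope="session")
def two_pop_std(two_pop):
    return standardize(two_pop)


@pytest.fixture()
def tiny_genotypes():
    """Hand-written 3x4 matrix used for parser round-trips."""
    return GenotypeMatrix(
        sample_ids=["s1", "s2", "s3"],
        marker_ids=["m1", "m2", "m3", "m4"],
        counts=np.array(
            [[0.0, 1.0, 2.0, 1.0], [1.0, 1.0, 0.0, 2.0], [2.0, 0.0, 1.0, 0.0]]
        ),
    )
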