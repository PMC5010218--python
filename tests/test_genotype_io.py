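import numpy as np
import pytest

from gpdecay import (
    GenotypeMatrix,
    apply_qc,
    impute_missing,
    prune_correlated,
    read_genotypes,
    standardize,
    write_genotypes,
)
from gpdecay.exceptions import (
    MonomorphicMarkerError,
    ParseError,
    ValidationError,
)


def _gm(counts, **kw):
    counts = np.asarray(counts, dtype=float)
    n, m = counts.shape
    return GenotypeMatrix(
        sample_ids=[f"s{i}" for i in range(n)],
        marker_ids=[f"m{j}" for j in range(m)],
        counts=counts,
        **kw,
    )


class TestParsing:
    @pytest.mark.parametrize("fmt", ["csv", "plink_raw"])
    def test_round_trip_preserves_matrix_and_ids(self, tiny_genotypes, tmp_path, fmt):
        path = tmp_path / f"g.{fmt}"
        write_genotypes(tiny_genotypes, path, format=fmt)
        back = read_genotypes(path, format=fmt)
        assert back.sample_ids == tiny_genotypes.sample_ids
        assert back.marker_ids == tiny_genotypes.marker_ids
        np.testing.assert_array_equal(back.counts, tiny_genotypes.counts)
        # a second round trip is bit-identical
        path2 = tmp_path / f"g2.{fmt}"
        write_genotypes(back, path2, format=fmt)
        assert path.read_text() == path2.read_text()

    @pytest.mark.parametrize("fmt,missing_token", [("csv", ""), ("plink_raw", "NA")])
    def test_missing_cells_flagged(self, tmp_path, fmt, missing_token):
        g = _gm([[0, 1], [2, np.nan]])
        path = tmp_path / "g.txt"
        write_genotypes(g, path, format=fmt)
        row = path.read_text().splitlines()[2]
        assert missing_token in row.replace(",", " ").split(" ")
        back = read_genotypes(path, format=fmt)
        assert np.isnan(back.counts[1, 1])
        assert not np.isnan(back.counts[0, 0])

    def test_duplicated_sample_id_rejected(self, tmp_path):
        path = tmp_path / "dup.csv"
        path.write_text("id,m1,m2\na,0,1\na,1,2\n")
        with pytest.raises(ValidationError, match="duplicat"):
            read_genotypes(path, format="csv")

    def test_illegal_allele_count_names_line(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("id,m1\na,0\nb,3\n")
        with pytest.raises(ParseError, match="line 3"):
            read_genotypes(path, format="csv")


class TestQc:
    def test_monomorphic_marker_removed(self):
        g = _gm([[0, 1], [0, 2], [0, 1]])
        out = apply_qc(g, maf_min=0.01)
        assert out.marker_ids == ["m1"]

    def test_boundary_missingness_kept_but_excess_removed(self):
        # marker m0: 25% missing -> removed at threshold 0.20; m1: 0% missing
        counts = np.array(
            [[np.nan, 1], [0, 1], [1, 2], [2, 0]], dtype=float
        )
        out = apply_qc(_gm(counts), maf_min=0.01, missing_max=0.20)
        assert out.marker_ids == ["m1"]

    def test_retained_set_matches_hand_computed_mafs(self):
        # 5 samples x 10 markers; per-marker allele counts chosen so the MAFs
        # are 0, .1, .2, .3, .4, .5, .6(=>.4), .05, .01-ish, and one missing-heavy
        cols = [
            [0, 0, 0, 0, 0],      # maf 0.0  -> drop
            [1, 0, 0, 0, 0],      # maf 0.1
            [2, 0, 0, 0, 0],      # maf 0.2
            [2, 1, 0, 0, 0],      # maf 0.3
            [2, 2, 0, 0, 0],      # maf 0.4
            [2, 2, 1, 0, 0],      # maf 0.5
            [2, 2, 2, 0, 0],      # p=.6 -> maf .4
            [2, 2, 2, 2, 2],      # maf 0 -> drop
            [1, 1, 1, 1, 1],      # maf .5
            [np.nan, np.nan, 1, 0, 0],  # 40% missing -> drop
        ]
        g = _gm(np.array(cols, dtype=float).T)
        out = apply_qc(g, maf_min=0.05, missing_max=0.20)
        assert out.marker_ids == ["m1", "m2", "m3", "m4", "m5", "m6", "m8"]

    def test_all_markers_removed_is_an_error(self):
        g = _gm([[0, 0], [0, 0]])
        with pytest.raises(ValidationError):
            apply_qc(g)


class TestImpute:
    def test_complete_matrix_returned_unchanged(self, tiny_genotypes):
        out = impute_missing(tiny_genotypes)
        assert out is tiny_genotypes

    def test_identical_samples_share_their_value(self):
        counts = np.array(
            [[0, 1, 2], [0, 1, 2], [0, np.nan, 2], [0, 1, 2]], dtype=float
        )
        out = impute_missing(_gm(counts), k_neighbours=3)
        assert out.counts[2, 1] == 1.0
        # non-missing entries untouched
        assert (out.counts[:, 0] == 0).all()

    def test_matches_brute_force_knn(self):
        rng = np.random.default_rng(42)
        counts = rng.integers(0, 3, size=(5, 5)).astype(float)
        counts[1, 2] = np.nan
        counts[4, 0] = np.nan
        g = _gm(counts)
        out = impute_missing(g, k_neighbours=2)

        def brute(i, j, k=2):
            cands = []
            for s in range(5):
                if s == i or np.isnan(counts[s, j]):
                    continue
                shared = ~np.isnan(counts[i]) & ~np.isnan(counts[s])
                d = np.sqrt(np.nansum((counts[i][shared] - counts[s][shared]) ** 2))
                cands.append((d, s))
            cands.sort()
            cands = cands[:k]
            w = np.array([1 / (d + 1e-12) for d, _ in cands])
            v = np.array([counts[s, j] for _, s in cands])
            return float(np.clip(np.rint(np.dot(w, v) / w.sum()), 0, 2))

        assert out.counts[1, 2] == brute(1, 2)
        assert out.counts[4, 0] == brute(4, 0)
        assert not out.has_missing()

    def test_fully_missing_sample_is_an_error(self):
        counts = np.array([[np.nan, np.nan], [0, 1], [1, 2]], dtype=float)
        with pytest.raises(ValidationError, match="every marker"):
            impute_missing(_gm(counts))


class TestPrune:
    def test_duplicated_column_removed(self):
        base = np.array([0, 1, 2, 1, 0, 2], dtype=float)
        other = np.array([2, 0, 1, 1, 2, 0], dtype=float)
        g = _gm(np.column_stack([base, base, other]))
        out = prune_correlated(g)
        assert out.marker_ids == ["m0", "m2"]

    def test_three_identical_columns_keep_first(self):
        col = np.array([0, 2, 1, 1, 0], dtype=float)
        g = _gm(np.column_stack([col, col, col]))
        out = prune_correlated(g)
        assert out.marker_ids == ["m0"]

    def test_independent_markers_untouched(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 3, size=(200, 30)).astype(float)
        g = _gm(counts)
        out = prune_correlated(g, r_max=0.95)
        assert out.n_markers == 30
        # verify the fixture really is below the threshold
        r = np.corrcoef(counts.T)
        np.fill_diagonal(r, 0)
        assert np.abs(r).max() <= 0.95

    def test_zero_variance_column_dropped_with_warning(self):
        g = _gm(np.column_stack([[1, 1, 1, 1], [0, 1, 2, 0]]).astype(float))
        with pytest.warns(UserWarning, match="zero-variance"):
            out = prune_correlated(g)
        assert out.marker_ids == ["m1"]


class TestStandardize:
    def test_hand_computed_column(self):
        g = _gm(np.array([[0.0], [1.0], [2.0]]))
        x = standardize(g)
        expected = np.array([-np.sqrt(1.5), 0.0, np.sqrt(1.5)])
        np.testing.assert_allclose(x.values[:, 0], expected, atol=1e-12)

    def test_columns_have_zero_mean_unit_variance(self, two_pop):
        x = standardize(two_pop)
        np.testing.assert_allclose(x.values.mean(axis=0), 0, atol=1e-10)
        np.testing.assert_allclose(x.values.var(axis=0), 1, atol=1e-8)

    def test_restandardization_is_stable(self, two_pop):
        x = standardize(two_pop)
        again = (x.values - x.values.mean(axis=0)) / x.values.std(axis=0)
        np.testing.assert_allclose(again, x.values, atol=1e-10)

    def test_monomorphic_marker_is_an_error(self):
        g = _gm([[0, 1], [0, 2], [0, 0]])
        with pytest.raises(MonomorphicMarkerError, match="apply_qc"):
            standardize(g)

    def test_apply_projects_new_samples_into_same_coordinates(self, two_pop):
        x = standardize(two_pop)
        np.testing.assert_allclose(
            x.apply(two_pop.counts[:5]), x.values[:5], atol=1e-12
        )


def test_qc_impute_prune_pipeline_order(two_pop):
    """Fixed-order preprocessing returns a complete, polymorphic matrix."""
    rng = np.random.default_rng(5)
    counts = two_pop.counts.copy()
    counts[rng.random(counts.shape) < 0.05] = np.nan
    g = GenotypeMatrix(two_pop.sample_ids, two_pop.marker_ids, counts)
    g = apply_qc(g)
    g = impute_missing(g)
    assert not g.has_missing()
    g = prune_correlated(g)
    x = standardize(g)  # must not raise: QC removed monomorphic markers
    assert x.n_markers == g.n_markers
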