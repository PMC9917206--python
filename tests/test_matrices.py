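import numpy as np
import pandas as pd
import pytest

from genospec.matrices import (
    CountMatrix,
    consolidate_features,
    filter_low_expression,
    log_transform,
    read_counts_tsv,
    rpkm,
    screen_outliers,
    write_matrix_tsv,
    write_metadata_tsv,
)
from tests.conftest import make_counts


class TestConsolidate:
    def test_transcript_counts_sum_into_genes(self):
        cm = make_counts([[3] * 4, [4] * 4], features=["t1", "t2"])
        out = consolidate_features(cm, {"t1": "G", "t2": "G"})
        assert list(out.feature_ids) == ["G"]
        assert (out.counts.loc["G"] == 7).all()

    def test_one_to_one_map_renames_rows(self):
        cm = make_counts([[1, 2, 3, 4], [5, 6, 7, 8]], features=["t1", "t2"])
        out = consolidate_features(cm, {"t1": "g1", "t2": "g2"})
        assert sorted(out.feature_ids) == ["g1", "g2"]
        np.testing.assert_array_equal(
            out.counts.sort_index().to_numpy(), cm.counts.to_numpy()
        )

    def test_column_sums_conserved_under_random_map(self):
        rng = np.random.default_rng(0)
        vals = rng.integers(0, 1000, size=(500, 8))
        cm = make_counts(vals, features=[f"t{i}" for i in range(500)])
        fmap = {f"t{i}": f"g{rng.integers(0, 60)}" for i in range(500)}
        # brute-force per-gene sums
        expected = {}
        for i in range(500):
            g = fmap[f"t{i}"]
            expected[g] = expected.get(g, 0) + vals[i]
        out = consolidate_features(cm, fmap)
        np.testing.assert_array_equal(out.counts.sum(axis=0), cm.counts.sum(axis=0))
        for g, row in expected.items():
            np.testing.assert_array_equal(out.counts.loc[g].to_numpy(), row)

    def test_unmapped_feature_raises_with_names(self):
        cm = make_counts([[1] * 4, [1] * 4], features=["t1", "weird"])
        with pytest.raises(KeyError, match="weird"):
            consolidate_features(cm, {"t1": "g1"})


class TestLowExpressionFilter:
    def test_threshold_is_strict(self):
        cm = make_counts(
            [
                [101, 101, 101, 0],  # kept: > 100 in 3 samples
                [100, 100, 100, 100],  # removed: never strictly above 100
                [0, 0, 0, 0],  # removed
            ]
        )
        out = filter_low_expression(cm, min_count=100, min_samples=3)
        assert list(out.feature_ids) == ["f0"]

    def test_outlier_samples_excluded_from_tally(self):
        cm = make_counts([[101, 101, 101, 0]])
        cm.outlier["s0"] = True
        out = filter_low_expression(cm, 100, 3)
        assert out.counts.shape[0] == 0

    def test_subset_and_idempotent(self):
        rng = np.random.default_rng(1)
        cm = make_counts(rng.integers(0, 300, size=(50, 8)))
        once = filter_low_expression(cm, 100, 3)
        twice = filter_low_expression(once, 100, 3)
        assert set(once.feature_ids) <= set(cm.feature_ids)
        assert list(once.feature_ids) == list(twice.feature_ids)

    def test_min_samples_exceeding_sample_count_errors(self):
        cm = make_counts([[1, 1, 1, 1]])
        with pytest.raises(ValueError):
            filter_low_expression(cm, 100, 5)


class TestRpkm:
    def test_unit_case(self):
        cm = make_counts([[10, 10, 10, 10]])
        lengths = pd.Series({"f0": 1000})
        libs = pd.Series(1_000_000, index=cm.sample_ids)
        em = rpkm(cm, lengths, libs)
        assert em.unit == "rpkm"
        assert (em.values == 10.0).all().all()

    def test_zero_count_gives_zero(self):
        cm = make_counts([[0, 0, 0, 0], [5, 5, 5, 5]])
        em = rpkm(cm, pd.Series({"f0": 500, "f1": 2000}))
        assert (em.values.loc["f0"] == 0.0).all()

    def test_matches_two_step_normalisation(self):
        rng = np.random.default_rng(2)
        vals = rng.integers(1, 5000, size=(100, 8))
        cm = make_counts(vals)
        lengths = pd.Series(rng.integers(200, 9000, size=100), index=cm.feature_ids)
        em = rpkm(cm, lengths)
        # independent oracle: per-kb first, then per-million of library
        per_kb = vals / (lengths.to_numpy()[:, None] / 1000.0)
        expected = per_kb / (vals.sum(axis=0)[None, :] / 1e6)
        np.testing.assert_allclose(em.values.to_numpy(), expected, rtol=1e-12)

    def test_roundtrip_recovers_counts(self):
        rng = np.random.default_rng(3)
        vals = rng.integers(0, 2000, size=(40, 8))
        cm = make_counts(vals)
        lengths = pd.Series(rng.integers(300, 4000, size=40), index=cm.feature_ids)
        libs = cm.library_sizes()
        em = rpkm(cm, lengths, libs)
        back = (
            em.values.mul(lengths / 1000.0, axis=0).mul(libs / 1e6, axis=1)
        )
        np.testing.assert_allclose(back.to_numpy(), vals, rtol=1e-9)

    def test_zero_library_size_errors(self):
        cm = make_counts([[0, 1, 1, 1]])
        with pytest.raises(ValueError):
            rpkm(cm, pd.Series({"f0": 1000}))


class TestLogTransform:
    @pytest.mark.parametrize("value,expected", [(1.0, 1.0), (0.0, 0.0), (7.0, 3.0)])
    def test_known_values(self, value, expected):
        cm = make_counts([[1, 1, 1, 1]])
        em = rpkm(cm, pd.Series({"f0": 1000}), pd.Series(1e6, index=cm.sample_ids))
        em.values.iloc[0, :] = value
        out = log_transform(em)
        assert out.unit == "log2rpkm"
        assert np.allclose(out.values.iloc[0], expected)

    def test_rejects_double_log_and_negative_pseudocount(self):
        cm = make_counts([[1, 1, 1, 1]])
        em = rpkm(cm, pd.Series({"f0": 1000}))
        logged = log_transform(em)
        with pytest.raises(ValueError):
            log_transform(logged)
        with pytest.raises(ValueError):
            log_transform(em, pseudocount=-0.5)


class TestOutlierScreen:
    def _uniform(self, n_per_group=4, value=50):
        genos = [g for g in ("Z+", "Z-", "A+", "A-") for _ in range(n_per_group)]
        vals = np.full((30, len(genos)), value)
        return make_counts(vals, genotypes=genos)

    def test_identical_samples_unflagged(self):
        cm = self._uniform()
        out, report = screen_outliers(cm)
        assert not out.outlier.any()
        assert not report["flagged"].any()

    def test_depleted_library_flagged(self):
        rng = np.random.default_rng(4)
        genos = [g for g in ("Z+", "Z-", "A+", "A-") for _ in range(6)]
        vals = rng.poisson(200, size=(200, 24))
        vals[:, 0] = rng.binomial(vals[:, 0], 0.1)  # one aberrant Z+ fish
        cm = make_counts(vals, genotypes=genos)
        out, report = screen_outliers(cm, k=3.0)
        assert out.outlier["s0"]
        assert out.outlier.sum() == 1

    def test_infinite_k_flags_nothing(self):
        cm = self._uniform()
        cm.counts.iloc[:, 0] = 1  # wildly different library
        out, _ = screen_outliers(cm, k=np.inf)
        assert not out.outlier.any()

    def test_error_when_group_would_collapse(self):
        genos = [g for g in ("Z+", "Z-", "A+", "A-") for _ in range(3)]
        vals = np.full((20, 12), 100)
        vals[:, 0] = 1
        vals[:, 1] = 10000
        cm = make_counts(vals, genotypes=genos)
        with pytest.raises(ValueError, match="Z\\+"):
            screen_outliers(cm, k=0.5)


def test_counts_tsv_roundtrip(tmp_path):
    cm = make_counts([[1, 2, 3, 4], [5, 6, 7, 8]])
    write_matrix_tsv(cm.counts, tmp_path / "m.tsv")
    write_metadata_tsv(cm, tmp_path / "meta.tsv")
    back = read_counts_tsv(tmp_path / "m.tsv", tmp_path / "meta.tsv")
    pd.testing.assert_frame_equal(back.counts, cm.counts)
    pd.testing.assert_series_equal(back.genotypes, cm.genotypes, check_names=False)
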