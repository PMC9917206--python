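import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from genospec.differential import (
    SUMMED_CONTRASTS,
    bh_adjust,
    call_degs,
    run_contrasts,
    student_t,
)
from genospec.matrices import ExpressionMatrix
from genospec.simulate import SimulationConfig, generate_counts


def brute_force_bh(p):
    """Step-up oracle: q_i = min over j with p_j >= p_i of p_(j) * m / rank(j)."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running_min = np.inf
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running_min = min(running_min, p[i] * m / rank_from_top)
        q[i] = min(running_min, 1.0)
    return q


def log_expr(values, genotypes):
    samples = [f"s{i}" for i in range(values.shape[1])]
    return ExpressionMatrix(
        values=pd.DataFrame(values, columns=samples),
        unit="log2rpkm",
        genotypes=pd.Series(list(genotypes), index=samples),
    )


class TestStudentT:
    def test_identical_groups(self):
        t, p = student_t([1, 2, 3], [1, 2, 3])
        assert t == 0 and p == 1

    def test_antisymmetry(self):
        t1, p1 = student_t([1, 2, 3], [4, 5, 7])
        t2, p2 = student_t([4, 5, 7], [1, 2, 3])
        assert t1 == -t2 and p1 == p2

    def test_closed_form_example(self):
        # pooled var = 1, se = sqrt(2/3), t = -3/se, df = 4
        t, p = student_t([1, 2, 3], [4, 5, 6])
        assert t == pytest.approx(-3 / np.sqrt(2 / 3), rel=1e-12)
        assert p == pytest.approx(0.0214, abs=5e-4)

    def test_agrees_with_scipy_on_random_vectors(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            a, b = rng.normal(size=6), rng.normal(size=5)
            t, p = student_t(a, b)
            ref = stats.ttest_ind(a, b, equal_var=True)
            assert t == pytest.approx(ref.statistic, rel=1e-12)
            assert p == pytest.approx(ref.pvalue, rel=1e-12)

    def test_zero_variance_conventions(self):
        t, p = student_t([2, 2], [2, 2])
        assert (t, p) == (0.0, 1.0)
        t, p = student_t([3, 3], [1, 1])
        assert t == np.inf and p == 0.0


class TestBHAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.05])[0] == pytest.approx(0.05)

    def test_hand_worked_step_up(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_all_ones(self):
        assert (bh_adjust([1.0, 1.0, 1.0]) == 1.0).all()

    def test_nan_propagates(self):
        q = bh_adjust([0.01, np.nan, 0.03])
        assert np.isnan(q[1]) and not np.isnan(q[0])
        # remaining values adjusted as if NaN absent
        np.testing.assert_allclose(q[[0, 2]], brute_force_bh([0.01, 0.03]))

    def test_matches_oracle_on_enumerated_grid(self):
        grid = [0.001, 0.02, 0.2, 0.7, 1.0]
        for n in (1, 2, 3, 4):
            for combo in itertools.product(grid, repeat=n):
                np.testing.assert_allclose(
                    bh_adjust(list(combo)), brute_force_bh(combo), atol=1e-12
                )

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30))
    def test_order_preserving_and_dominates_p(self, p):
        q = bh_adjust(p)
        assert (q >= np.asarray(p) - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()


class TestRunContrasts:
    def geno24(self):
        return [g for g in ("Z+", "Z-", "A+", "A-") for _ in range(6)]

    def test_constant_feature_is_null_in_all_contrasts(self):
        rng = np.random.default_rng(6)
        vals = rng.normal(5, 1, size=(20, 24))
        vals[0, :] = 3.14
        ct = run_contrasts(log_expr(vals, self.geno24()))
        for c in list(SUMMED_CONTRASTS) + ["Z-_vs_A-"]:
            assert ct.loc[0, f"t_{c}"] == 0
            assert ct.loc[0, f"p_{c}"] == 1

    def test_specificity_contrast_equals_direct_two_group_test(self):
        rng = np.random.default_rng(7)
        genos = self.geno24()
        vals = rng.normal(size=(30, 24))
        ct = run_contrasts(log_expr(vals, genos))
        zminus = [i for i, g in enumerate(genos) if g == "Z-"]
        aminus = [i for i, g in enumerate(genos) if g == "A-"]
        ref = stats.ttest_ind(vals[:, zminus], vals[:, aminus], axis=1, equal_var=True)
        np.testing.assert_allclose(ct["t_Z-_vs_A-"], ref.statistic, rtol=1e-10)
        np.testing.assert_allclose(ct["p_Z-_vs_A-"], ref.pvalue, rtol=1e-10)

    def test_planted_zplus_gene_hits_contrasts_1_to_3_not_4(self):
        """Power: a 4-fold Z+-only drop at n=6 is significant in the three Z+
        contrasts and null in Z- vs A- for the large majority of replicates."""
        rng = np.random.default_rng(8)
        genos = self.geno24()
        hits = np.zeros(4)
        n_rep = 60
        for _ in range(n_rep):
            vals = rng.normal(8, 0.4, size=(1, 24))
            zplus = [i for i, g in enumerate(genos) if g == "Z+"]
            vals[0, zplus] -= 2.0  # fold 4 on log2 scale
            ct = run_contrasts(log_expr(np.vstack([vals, rng.normal(8, 0.4, (9, 24))]), genos))
            for j, c in enumerate(list(SUMMED_CONTRASTS) + ["Z-_vs_A-"]):
                hits[j] += ct.loc[0, f"p_{c}"] < 0.05
        assert (hits[:3] >= 0.9 * n_rep).all()
        assert hits[3] <= 0.2 * n_rep

    def test_missing_genotype_errors(self):
        vals = np.zeros((3, 18))
        genos = [g for g in ("Z+", "Z-", "A+") for _ in range(6)]
        with pytest.raises(ValueError, match="A-"):
            run_contrasts(log_expr(vals, genos))


def contrast_row(q1, q2, q3, q4, lfcs=(-1, -1, -1, 0.1)):
    cols = {}
    for (c, q, lfc) in zip(list(SUMMED_CONTRASTS) + ["Z-_vs_A-"], (q1, q2, q3, q4), lfcs):
        cols[f"t_{c}"] = [0.0]
        cols[f"p_{c}"] = [q]
        cols[f"q_{c}"] = [q]
        cols[f"lfc_{c}"] = [lfc]
    return pd.DataFrame(cols, index=["gene"])


class TestCallDegs:
    def test_clear_down_call(self):
        calls = call_degs(contrast_row(0.001, 0.001, 0.001, 0.9), 0.15, 0.05)
        row = calls.loc["gene"]
        assert row["is_deg"] and row["direction"] == "down"

    def test_specificity_veto(self):
        """A gene also moving between Z- and A- is not Z+-specific."""
        calls = call_degs(contrast_row(0.001, 0.001, 0.001, 0.001), 0.15, 0.05)
        assert not calls.loc["gene", "is_deg"]

    def test_direction_inconsistency_blocks_call(self):
        calls = call_degs(
            contrast_row(0.001, 0.001, 0.001, 0.9, lfcs=(-1, 1, -1, 0)), 0.15, 0.05
        )
        assert not calls.loc["gene", "is_deg"]

    def test_monotone_in_thresholq_components(self):
        """Lowering any summed-contrast q never removes a call; raising q4 never does."""
        rng = np.random.default_rng(9)
        for _ in range(200):
            qs = rng.uniform(0, 0.2, 3)
            q4 = rng.uniform(0, 1)
            base = call_degs(contrast_row(*qs, q4), 0.15, 0.05).loc["gene", "is_deg"]
            if base:
                lower = call_degs(contrast_row(*(qs * 0.5), min(1, q4 * 2)), 0.15, 0.05)
                assert lower.loc["gene", "is_deg"]

    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            call_degs(contrast_row(0.1, 0.1, 0.1, 0.9), summed_q_threshold=0)
        with pytest.raises(ValueError):
            call_degs(contrast_row(0.1, 0.1, 0.1, 0.9), specificity_alpha=1.5)
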