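"""CSR curves, AUC, F50, Shannon entropy and the scaffold summary."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import spearmanr

from cdplib.scaffold_metrics import (auc, count_ratios, csr_curve, f50,
                                     scaled_shannon_entropy, shannon_entropy,
                                     sse_profile, summarize_scaffolds)

from conftest import table

count_lists = st.lists(st.integers(min_value=1, max_value=50), min_size=1, max_size=40)


def riemann_auc(curve, n_grid=200_000):
    """Independent oracle: fine Riemann sum over the piecewise-linear curve."""
    xs = np.linspace(0, 1, n_grid + 1)
    ys = np.interp(xs, curve.x, curve.y)
    return float(np.trapezoid(ys, xs))


class TestCSRCurve:
    def test_hand_computed_points(self):
        c = csr_curve(table([4, 3, 2, 1]))
        assert c.x.tolist() == [0.0, 0.25, 0.5, 0.75, 1.0]
        assert c.y.tolist() == [0.0, 0.4, 0.7, 0.9, 1.0]

    def test_all_singletons_lie_on_the_diagonal(self):
        c = csr_curve(table([1] * 17))
        assert np.allclose(c.y, c.x)

    def test_single_chemotype_is_two_points(self):
        c = csr_curve(table([9]))
        assert c.points == [(0.0, 0.0), (1.0, 1.0)]

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(count_lists)
    def test_curve_shape_invariants(self, counts):
        c = csr_curve(table(counts))
        assert np.all(np.diff(c.x) > 0)
        assert np.all(np.diff(c.y) >= -1e-15)
        # sorted-descending counts make the curve concave
        assert np.all(np.diff(np.diff(c.y)) <= 1e-12)


class TestAUC:
    def test_all_singleton_diagonal_is_exactly_half(self):
        assert auc(csr_curve(table([1] * 137))) == 0.5

    def test_hand_computed_trapezoid(self):
        assert auc(csr_curve(table([4, 3, 2, 1]))) == pytest.approx(0.625, abs=1e-15)

    def test_extreme_concentration_approaches_one(self):
        counts = [999001] + [1] * 999
        assert auc(csr_curve(table(counts))) > 0.99

    def test_staircase_convention(self):
        # counts [3,1]: y_right = 0.75, 1.0; each weighted 1/2
        assert auc(csr_curve(table([3, 1]), convention="staircase")) == \
            pytest.approx(0.875)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(count_lists)
    def test_agrees_with_riemann_oracle(self, counts):
        c = csr_curve(table(counts))
        assert auc(c) == pytest.approx(riemann_auc(c), abs=5e-6)
        assert 0.5 - 1e-12 <= auc(c) <= 1.0 + 1e-12

    def test_moving_a_compound_up_never_decreases_auc(self):
        # enumeration over small tables: shift one compound from a
        # less-populated to a more-populated chemotype
        for counts in ([5, 4, 3, 2], [4, 2, 2, 1], [3, 3, 3], [6, 1, 1]):
            base = auc(csr_curve(table(counts)))
            for i in range(len(counts)):
                for j in range(i + 1, len(counts)):
                    if counts[j] <= 1:
                        continue
                    moved = list(counts)
                    moved[i] += 1
                    moved[j] -= 1
                    assert auc(csr_curve(table(moved))) >= base - 1e-12


class TestF50:
    def test_dominant_chemotype(self):
        assert f50(table([5, 3, 1, 1])) == 0.25

    def test_all_singletons_even_m(self):
        assert f50(table([1] * 20)) == 0.5

    def test_single_chemotype(self):
        assert f50(table([7])) == 1.0

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(count_lists)
    def test_bounds(self, counts):
        v = f50(table(counts))
        assert 1 / len(counts) <= v <= 1.0

    def test_f50_and_auc_rank_libraries_oppositely(self):
        rng = np.random.default_rng(7)
        aucs, f50s = [], []
        for _ in range(60):
            counts = rng.integers(1, 30, size=rng.integers(3, 25)).tolist()
            t = table(counts)
            aucs.append(auc(csr_curve(t)))
            f50s.append(f50(t))
        rho = spearmanr(aucs, f50s).statistic
        assert rho <= 0


class TestShannonEntropy:
    def test_single_chemotype_is_zero(self):
        assert shannon_entropy([8]).se == 0.0

    def test_uniform_reaches_log2_n(self):
        assert shannon_entropy([2, 2, 2, 2]).se == 2.0

    def test_hand_computed_skewed_pair(self):
        assert shannon_entropy([3, 1]).se == pytest.approx(0.8113, abs=5e-5)

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(count_lists)
    def test_permutation_invariance_and_uniform_maximum(self, counts):
        res = shannon_entropy(counts)
        assert res.se == pytest.approx(shannon_entropy(counts[::-1]).se, abs=1e-12)
        assert -1e-12 <= res.se <= math.log2(len(counts)) + 1e-12
        if len(set(counts)) > 1:
            assert res.se < math.log2(len(counts))

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(count_lists)
    def test_agrees_with_direct_sum_oracle(self, counts):
        p_total = sum(counts)
        expected = -sum((c / p_total) * math.log2(c / p_total) for c in counts)
        assert shannon_entropy(counts).se == pytest.approx(expected, abs=1e-12)

    def test_empty_counts_raise(self):
        with pytest.raises(ValueError):
            shannon_entropy([])


class TestScaledShannonEntropy:
    def test_uniform_top_n_is_exactly_one(self):
        assert scaled_shannon_entropy(table([10] * 8), n_top=8).sse == 1.0

    def test_single_selected_chemotype_is_zero(self):
        assert scaled_shannon_entropy(table([5, 1, 1]), n_top=1).sse == 0.0

    def test_n_top_clamps_to_table_size(self):
        res = scaled_shannon_entropy(table([4, 3, 2]), n_top=70)
        assert res.n_selected == 3
        assert res.sse == pytest.approx(res.se / math.log2(3))

    def test_selection_renormalizes_population(self):
        # top-2 of [6, 2, 1]: P=8, p=(0.75, 0.25)
        res = scaled_shannon_entropy(table([6, 2, 1]), n_top=2)
        assert res.se == pytest.approx(shannon_entropy([6, 2]).se, abs=1e-14)

    def test_profile_grid_and_skewed_tables(self):
        uniform = table([5] * 30)
        assert all(r.sse == 1.0 for r in sse_profile(uniform, [5, 10, 20]))
        skewed = table([100, 1, 1, 1, 1, 1])
        assert all(r.sse < 1.0 for r in sse_profile(skewed, [2, 4, 6]))

    def test_default_grid_runs_5_to_70(self):
        results = sse_profile(table([3] * 80))
        assert [r.n_top for r in results] == list(range(5, 75, 5))


class TestSummaries:
    def test_printed_count_ratios_reproduce_from_integers(self):
        # ratios recomputable from printed integer counts, 3-decimal rounding
        anticancer = count_ratios(70, 76, 65)
        assert anticancer["N_over_M"] == 0.921
        assert anticancer["Nsing_over_N"] == 0.929
        assert anticancer["Nsing_over_M"] == 0.855
        gras = count_ratios(238, 2249, 150)
        assert gras["N_over_M"] == 0.106
        assert gras["Nsing_over_N"] == 0.630
        assert count_ratios(935, 2500, 642)["N_over_M"] == 0.374

    def test_summary_on_all_singleton_table(self):
        s = summarize_scaffolds(table([1] * 12))
        assert s.N_over_M == 1.0 and s.Nsing_over_M == 1.0
        assert s.auc == 0.5 and s.f50 == 0.5

    def test_summary_fields_consistent(self):
        s = summarize_scaffolds(table([4, 3, 2, 1]))
        assert (s.N, s.M, s.N_sing) == (4, 10, 1)
        assert s.N_over_M == pytest.approx(0.4)
        assert s.auc == pytest.approx(0.625)
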