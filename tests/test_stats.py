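"""Bin-wise comparison, KS normality, Kruskal–Wallis + Dunn."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import stats as sps

from gaitdf import binwise_compare, binwise_compare_arrays, kruskal_dunn, ks_normality
from conftest import make_curve
from oracles import kruskal_H, ks_sup_distance


class TestBinwiseCompare:
    def test_identical_constant_groups_no_change(self):
        a = np.ones((5, 100))
        comp = binwise_compare_arrays(a, a.copy(), tail="two_sided")
        assert comp.percent_changed == 0
        assert np.all(comp.p == 1.0)
        assert np.all(comp.t_stat == 0.0)

    def test_identical_samples_t_zero(self):
        # per bin a = b = {1,2,3}: t = 0, one-sided p = 0.5, two-sided p = 1
        a = np.tile([[1.0], [2.0], [3.0]], (1, 100))
        one = binwise_compare_arrays(a, a.copy(), tail="one_sided_auto")
        two = binwise_compare_arrays(a, a.copy(), tail="two_sided")
        assert np.all(one.t_stat == 0.0)
        assert np.all(one.p == 0.5)
        assert np.all(two.p == 1.0)

    def test_matches_scipy_pooled_t(self, rng):
        a = rng.normal(size=(8, 100))
        b = rng.normal(0.3, 1.0, size=(12, 100))
        comp = binwise_compare_arrays(a, b, tail="two_sided")
        t_ref, p_ref = sps.ttest_ind(a, b, axis=0, equal_var=True)
        np.testing.assert_allclose(comp.t_stat, t_ref, atol=1e-12)
        np.testing.assert_allclose(comp.p, p_ref, atol=1e-12)

    def test_swap_symmetry(self, rng):
        a = rng.normal(size=(10, 100))
        b = rng.normal(0.5, 1.0, size=(10, 100))
        ab = binwise_compare_arrays(a, b, tail="two_sided")
        ba = binwise_compare_arrays(b, a, tail="two_sided")
        np.testing.assert_allclose(ab.t_stat, -ba.t_stat, atol=1e-12)
        np.testing.assert_allclose(ab.p, ba.p, atol=1e-12)
        assert ab.percent_changed == ba.percent_changed

    def test_one_sided_auto_halves_p(self, rng):
        a = rng.normal(size=(10, 100))
        b = rng.normal(size=(10, 100))
        one = binwise_compare_arrays(a, b, tail="one_sided_auto")
        two = binwise_compare_arrays(a, b, tail="two_sided")
        np.testing.assert_allclose(one.p, two.p / 2.0, atol=1e-12)

    def test_sem_uses_curve_count(self, rng):
        a = rng.normal(size=(9, 100))
        b = rng.normal(size=(4, 100))
        comp = binwise_compare_arrays(a, b, tail="two_sided")
        np.testing.assert_allclose(
            comp.sem_a, a.std(axis=0, ddof=1) / 3.0, atol=1e-12
        )
        np.testing.assert_allclose(
            comp.sem_b, b.std(axis=0, ddof=1) / 2.0, atol=1e-12
        )

    def test_span_recovery_with_bh(self):
        # 10 sigma shift on bins 20..54 (35 bins), 30 curves per group
        rng = np.random.default_rng(123)
        sigma = 0.3
        template = np.cos(np.linspace(0, np.pi, 100))
        shift = np.zeros(100)
        shift[19:54] = 10 * sigma
        a = template + rng.normal(0, sigma, size=(30, 100))
        b = template + shift + rng.normal(0, sigma, size=(30, 100))
        comp = binwise_compare_arrays(a, b, tail="two_sided", correction="bh")
        assert abs(comp.percent_changed - 35) <= 3

    def test_group_metadata_from_curves(self, rng):
        curves_a = [
            make_curve(rng.normal(size=100), rng.normal(size=100),
                       curve_id=f"a{k}", animal_id=f"a{k}")
            for k in range(3)
        ]
        curves_b = [
            make_curve(rng.normal(size=100), rng.normal(size=100),
                       curve_id=f"b{k}", animal_id=f"b{k}", condition="lesioned")
            for k in range(3)
        ]
        comp = binwise_compare(curves_a, curves_b, tail="two_sided")
        assert (comp.group_a, comp.group_b) == ("CMR", "LMR")
        assert comp.joint == "metatarsus" and comp.axis == "y"
        table = comp.to_frame()
        assert list(table["bin"]) == list(range(1, 101))

    def test_animal_means_mode_reduces_units(self, rng):
        curves_a = [
            make_curve(rng.normal(size=100), rng.normal(size=100),
                       curve_id=f"a{k}", animal_id=f"an{k % 2}")
            for k in range(6)
        ]
        curves_b = [
            make_curve(rng.normal(size=100), rng.normal(size=100),
                       curve_id=f"b{k}", animal_id=f"bn{k % 2}")
            for k in range(6)
        ]
        comp = binwise_compare(curves_a, curves_b, animal_means=True)
        assert comp.n_a == 2 and comp.n_b == 2

    def test_validation(self, rng):
        a = rng.normal(size=(2, 100))
        with pytest.raises(ValueError):
            binwise_compare_arrays(a, rng.normal(size=(1, 100)))
        with pytest.raises(ValueError):
            binwise_compare_arrays(a, a, alpha=1.5)
        with pytest.raises(ValueError):
            binwise_compare_arrays(a, a, tail="left")


class TestKSNormality:
    def test_statistic_matches_ecdf_loop_oracle(self, rng):
        for n in (20, 57, 200):
            x = rng.normal(2.0, 3.0, size=n)
            stat, _ = ks_normality(x)
            assert stat == pytest.approx(ks_sup_distance(x), abs=1e-10)

    def test_normal_sample_not_rejected(self):
        for seed in (1, 2, 3):
            x = np.random.default_rng(seed).normal(size=10_000)
            _, p = ks_normality(x)
            assert p > 0.05

    def test_uniform_sample_rejected(self):
        x = np.random.default_rng(4).uniform(size=10_000)
        _, p = ks_normality(x)
        assert p < 0.001

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError, match="at least 5"):
            ks_normality([1.0, 2.0])
        with pytest.raises(ValueError, match="identical"):
            ks_normality([3.0] * 10)


class TestKruskalDunn:
    def test_closed_form_two_groups(self):
        # ranks 1..6: H = 12/(6*7) * (6^2/3 + 15^2/3) - 3*7 = 27/7
        result = kruskal_dunn({"a": [1, 2, 3], "b": [4, 5, 6]})
        assert result.kw_H == pytest.approx(27.0 / 7.0, abs=1e-3)
        assert result.kw_H == pytest.approx(3.857, abs=1e-3)

    def test_matches_independent_rank_implementation(self, rng):
        for _ in range(100):
            k = rng.integers(2, 5)
            groups = {
                f"g{j}": rng.integers(0, 8, size=rng.integers(2, 9)).astype(float)
                for j in range(k)
            }
            if np.ptp(np.concatenate(list(groups.values()))) == 0:
                continue
            result = kruskal_dunn(groups)
            assert result.kw_H == pytest.approx(
                kruskal_H(list(groups.values())), abs=1e-10
            )

    def test_identical_groups_degenerate(self):
        result = kruskal_dunn({"a": [2.0, 2.0, 2.0], "b": [2.0, 2.0]})
        assert result.kw_H == 0.0
        assert result.kw_p == 1.0
        assert (result.dunn.values == 1.0).all()

    def test_dunn_flags_large_location_shift(self):
        rng = np.random.default_rng(8)
        spread = 1.0
        groups = {
            "a": rng.normal(0.0, spread, 30),
            "b": rng.normal(0.0, spread, 30),
            "c": rng.normal(10.0 * spread, spread, 30),
        }
        result = kruskal_dunn(groups)
        assert result.dunn.loc["a", "c"] < 0.05
        assert result.dunn.loc["b", "c"] < 0.05
        assert result.dunn.loc["a", "b"] > 0.05
        assert ("a", "c") in result.significant_pairs()

    def test_dunn_matrix_symmetric(self, rng):
        groups = {f"g{j}": rng.normal(j, 1.0, 12) for j in range(4)}
        result = kruskal_dunn(groups)
        np.testing.assert_allclose(result.dunn.values, result.dunn.values.T)

    def test_bonferroni_never_below_unadjusted(self, rng):
        groups = {f"g{j}": rng.normal(j * 0.5, 1.0, 15) for j in range(3)}
        adj = kruskal_dunn(groups, p_adjust="bonferroni").dunn
        raw = kruskal_dunn(groups, p_adjust=None).dunn
        assert (adj.values >= raw.values - 1e-15).all()

    def test_validation(self):
        with pytest.raises(ValueError, match="2 groups"):
            kruskal_dunn({"a": [1.0, 2.0]})
        with pytest.raises(ValueError, match="fewer than 2"):
            kruskal_dunn({"a": [1.0, 2.0], "b": [1.0]})
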