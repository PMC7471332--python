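"""Welch tests, repeated-measures ANOVA, smoothing, voxel-wise statistics."""

import numpy as np
import pytest

import glymph_t1 as g
from glymph_t1.group_stats import fwhm_to_sigma_mm
from glymph_t1.volume import ImageVolume


def welch_oracle(a, b):
    """Direct evaluation of the Welch formulas (summary-statistic route)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    v1, v2 = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
    t = (a.mean() - b.mean()) / np.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (a.size - 1) + v2**2 / (b.size - 1))
    return t, df


def rm_anova_oracle(x):
    """Textbook sums-of-squares decomposition, written independently."""
    x = np.asarray(x, float)
    n, k = x.shape
    grand = x.mean()
    ss_cond = sum(n * (x[:, j].mean() - grand) ** 2 for j in range(k))
    ss_subj = sum(k * (x[i].mean() - grand) ** 2 for i in range(n))
    ss_tot = ((x - grand) ** 2).sum()
    ss_err = ss_tot - ss_cond - ss_subj
    return (ss_cond / (k - 1)) / (ss_err / ((k - 1) * (n - 1)))


class TestWelch:
    def test_identical_samples(self):
        res = g.welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_summary_on_printed_node_stats(self):
        # dcLN: Gd group (1093, 127, n=6) vs saline (1895, 281, n=9)
        res = g.welch_t_summary(1093.0, 127.0, 6, 1895.0, 281.0, 9)
        assert abs(res.statistic) == pytest.approx(7.49, abs=0.01)
        assert res.df == pytest.approx(11.87, abs=0.01)
        assert res.p < 1e-4

    def test_equal_variance_equal_n_df_is_pooled(self):
        res = g.welch_t_summary(10.0, 2.0, 8, 12.0, 2.0, 8)
        assert res.df == pytest.approx(14.0)

    def test_raw_matches_summary_formulas(self, rng):
        a = rng.normal(5, 2, 9)
        b = rng.normal(6, 3, 7)
        res = g.welch_t(a, b)
        t, df = welch_oracle(a, b)
        assert res.statistic == pytest.approx(t, rel=1e-12)
        assert res.df == pytest.approx(df, rel=1e-12)
        rs = g.welch_t_summary(a.mean(), a.std(ddof=1), a.size, b.mean(), b.std(ddof=1), b.size)
        assert rs.p == pytest.approx(res.p, rel=1e-10)

    def test_degenerate_zero_variance(self):
        eq = g.welch_t([3.0, 3.0], [3.0, 3.0])
        assert eq.p == 1.0 and eq.degenerate
        ne = g.welch_t([3.0, 3.0], [4.0, 4.0])
        assert ne.p == 0.0 and ne.degenerate

    def test_sample_size_guard(self):
        with pytest.raises(ValueError):
            g.welch_t([1.0], [2.0, 3.0])


class TestRmAnovaOneway:
    def test_seven_regions_give_df6(self, rng):
        x = rng.normal(2000, 100, size=(7, 7))
        res = g.rm_anova_oneway(x)
        assert res.df_num == 6
        assert res.df_den == 36

    def test_identical_columns_give_zero_f(self):
        x = np.tile(np.arange(5, dtype=float).reshape(-1, 1), (1, 4))
        res = g.rm_anova_oneway(x)
        assert res.F == pytest.approx(0.0)

    def test_matches_brute_force_oracle(self):
        x = np.array([[3.0, 5.0, 9.0], [2.0, 4.0, 8.0], [4.0, 7.0, 9.0]])
        res = g.rm_anova_oneway(x)
        assert res.F == pytest.approx(rm_anova_oracle(x), rel=1e-12)

    def test_matches_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        x = rng.normal(0, 1, size=(8, 5))
        df = pd.DataFrame({
            "y": x.ravel(),
            "subject": np.repeat(np.arange(8), 5),
            "cond": np.tile(np.arange(5), 8),
        })
        tab = pg.rm_anova(data=df, dv="y", within="cond", subject="subject", correction=False)
        res = g.rm_anova_oneway(x)
        assert res.F == pytest.approx(float(tab["F"].iloc[0]), rel=1e-9)
        assert res.p == pytest.approx(float(tab["p_unc"].iloc[0]), rel=1e-6)

    def test_missing_cells_rejected(self):
        x = np.ones((3, 3))
        x[0, 0] = np.nan
        with pytest.raises(ValueError):
            g.rm_anova_oneway(x)


class TestMixedAnova:
    def test_identical_groups_zero_group_f(self, rng):
        block = rng.normal(0, 1, size=(4, 3))
        x = np.vstack([block, block])
        res = {r.effect: r for r in g.mixed_anova(x, ["a"] * 4 + ["b"] * 4)}
        assert res["group"].F == pytest.approx(0.0)

    def test_matches_pingouin_balanced(self, rng):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        x = rng.normal(0, 1, size=(10, 3)) + np.array([0.0, 0.5, 1.0])
        x[5:] += 1.5
        labels = ["kx"] * 5 + ["iso"] * 5
        df = pd.DataFrame({
            "y": x.ravel(),
            "subject": np.repeat(np.arange(10), 3),
            "time": np.tile(np.arange(3), 10),
            "group": np.repeat(labels, 3),
        })
        tab = pg.mixed_anova(data=df, dv="y", within="time", subject="subject", between="group")
        res = {r.effect: r for r in g.mixed_anova(x, labels)}
        by_src = {row["Source"].lower(): row for _, row in tab.iterrows()}
        assert res["group"].F == pytest.approx(float(by_src["group"]["F"]), rel=1e-9)
        assert res["time"].F == pytest.approx(float(by_src["time"]["F"]), rel=1e-9)
        assert res["interaction"].F == pytest.approx(float(by_src["interaction"]["F"]), rel=1e-9)

    def test_group_f_invariant_to_time_relabeling(self, rng):
        x = rng.normal(0, 1, size=(8, 4))
        labels = ["a"] * 4 + ["b"] * 4
        res1 = {r.effect: r for r in g.mixed_anova(x, labels)}
        perm = rng.permutation(4)
        res2 = {r.effect: r for r in g.mixed_anova(x[:, perm], labels)}
        assert res1["group"].F == pytest.approx(res2["group"].F, rel=1e-12)

    def test_single_timepoint_rejected(self):
        with pytest.raises(ValueError):
            g.mixed_anova(np.ones((4, 1)), ["a", "a", "b", "b"])


class TestSmoothing:
    def test_constant_map_unchanged(self):
        vol = ImageVolume(np.full((10, 10, 10), 42.0), (0.18, 0.18, 0.18))
        out = g.smooth_gaussian(vol, fwhm_mm=0.4)
        np.testing.assert_allclose(out.data, 42.0, rtol=1e-12)

    def test_fwhm_to_sigma_conversion(self):
        assert fwhm_to_sigma_mm(0.4) / 0.18 == pytest.approx(0.9437, abs=1e-3)

    def test_sum_preserved_for_interior_support(self):
        data = np.zeros((20, 20, 20))
        data[8:12, 8:12, 8:12] = 3.0
        vol = ImageVolume(data, (0.18, 0.18, 0.18))
        out = g.smooth_gaussian(vol, fwhm_mm=0.4)
        assert out.data.sum() == pytest.approx(data.sum(), rel=1e-6)

    def test_nan_aware_normalized_convolution(self):
        data = np.full((12, 12, 12), 5.0)
        data[6, 6, 6] = np.nan
        vol = ImageVolume(data, (0.18, 0.18, 0.18))
        out = g.smooth_gaussian(vol, fwhm_mm=0.4)
        # neighbors of the NaN voxel keep the constant value (no zero leakage)
        assert out.data[6, 6, 5] == pytest.approx(5.0, rel=1e-9)


class TestPopulationAverage:
    def test_identical_maps(self):
        m = ImageVolume(np.arange(8.0).reshape(2, 2, 2), (1, 1, 1))
        avg, n = g.population_average([m, m, m])
        np.testing.assert_allclose(avg.data, m.data)
        assert (n == 3).all()

    def test_mean_and_nan_count(self):
        a = ImageVolume(np.full((1, 1, 2), 1000.0), (1, 1, 1))
        b = ImageVolume(np.array([[[3000.0, np.nan]]]), (1, 1, 1))
        avg, n = g.population_average([a, b])
        assert avg.data[0, 0, 0] == pytest.approx(2000.0)
        assert avg.data[0, 0, 1] == pytest.approx(1000.0)
        assert n[0, 0, 1] == 1

    def test_linearity(self, rng):
        ms = [ImageVolume(rng.random((3, 3, 3)), (1, 1, 1)) for _ in range(4)]
        avg, _ = g.population_average(ms)
        scaled, _ = g.population_average(
            [ImageVolume(2 * m.data, (1, 1, 1)) for m in ms])
        np.testing.assert_allclose(scaled.data, 2 * avg.data, rtol=1e-12)


class TestVoxelwiseWelch:
    def _maps(self, rng, n, shape=(8, 8, 8), shift=0.0):
        return [ImageVolume(rng.standard_normal(shape) + shift, (1, 1, 1)) for _ in range(n)]

    def test_t_map_antisymmetric_under_group_swap(self, rng):
        a = self._maps(rng, 4)
        b = self._maps(rng, 5, shift=0.5)
        ab = g.voxelwise_welch(a, b)
        ba = g.voxelwise_welch(b, a)
        np.testing.assert_allclose(ab.t_map.data, -ba.t_map.data, rtol=1e-10)

    def test_planted_effect_recovered(self, rng):
        shape = (12, 12, 12)
        planted = np.zeros(shape, bool)
        planted[3:9, 3:9, 3:9] = True
        a = [ImageVolume(rng.standard_normal(shape) + 6.0 * planted, (1, 1, 1))
             for _ in range(8)]
        b = [ImageVolume(rng.standard_normal(shape), (1, 1, 1)) for _ in range(8)]
        stat = g.voxelwise_welch(a, b, q=0.05)
        inter = (stat.fdr_mask & planted).sum()
        union = (stat.fdr_mask | planted).sum()
        assert inter / union > 0.5

    def test_low_count_voxels_nan(self, rng):
        a = self._maps(rng, 3)
        a[0].data[0, 0, 0] = np.nan
        a[1].data[0, 0, 0] = np.nan
        b = self._maps(rng, 3)
        stat = g.voxelwise_welch(a, b)
        assert np.isnan(stat.p_map.data[0, 0, 0])
        assert not stat.fdr_mask[0, 0, 0]

    def test_group_size_guard(self, rng):
        with pytest.raises(ValueError):
            g.voxelwise_welch(self._maps(rng, 1), self._maps(rng, 3))


class TestBhFdr:
    def test_hand_run_stepup(self):
        # thresholds i*q/m = 0.0125, 0.025, 0.0375, 0.05; p3 = 0.04 > 0.0375
        mask = g.bh_fdr(np.array([0.001, 0.02, 0.04, 0.9]), q=0.05)
        np.testing.assert_array_equal(mask, [True, True, False, False])

    def test_all_ones_empty(self):
        assert not g.bh_fdr(np.ones(10), q=0.05).any()

    def test_all_zeros_full(self):
        assert g.bh_fdr(np.zeros(10), q=0.05).all()

    def test_monotone_in_q(self, rng):
        p = rng.random(200)
        m1 = g.bh_fdr(p, q=0.01)
        m2 = g.bh_fdr(p, q=0.05)
        assert not (m1 & ~m2).any()

    def test_nan_excluded(self):
        p = np.array([0.001, np.nan, 0.002])
        mask = g.bh_fdr(p, q=0.05)
        assert not mask[1] and mask[0] and mask[2]
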