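"""SPGR signal model, linearized fitting, double-angle B1 mapping."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import glymph_t1 as g
from glymph_t1.protocol import RareGrid
from glymph_t1.relaxometry import resample_b1
from glymph_t1.volume import B1Map, ImageVolume, T1Map

ANGLES = (2.0, 5.0, 10.0, 15.0, 20.0, 30.0)
TR = 16.0


def nonlinear_t1_oracle(signals, angles_deg, tr_ms, t1_grid=None):
    """Brute-force grid search minimizing SSE of the raw SPGR model."""
    if t1_grid is None:
        t1_grid = np.arange(100.0, 5000.0, 1.0)
    a = np.deg2rad(np.asarray(angles_deg))
    e1 = np.exp(-tr_ms / t1_grid)[:, None]
    shape_fn = np.sin(a) * (1 - e1) / (1 - e1 * np.cos(a))  # (nT1, nA)
    # optimal M0 for each T1 candidate by linear least squares
    m0 = (shape_fn * signals).sum(axis=1) / (shape_fn**2).sum(axis=1)
    sse = ((m0[:, None] * shape_fn - signals) ** 2).sum(axis=1)
    best = np.argmin(sse)
    return t1_grid[best], m0[best], sse[best]


class TestSpgrSignal:
    def test_zero_flip_angle_gives_zero(self):
        assert g.spgr_signal(1000.0, 2000.0, 0.0, TR) == 0.0

    def test_saturation_free_limit(self):
        # T1 -> 0 (E1 -> 0): S -> M0 sin(alpha)
        assert g.spgr_signal(1.0, 1e-3, 30.0, TR) == pytest.approx(0.5, rel=1e-12)

    def test_closed_form_value(self):
        # independent hand evaluation: E1 = exp(-16/2000)
        e1 = np.exp(-16.0 / 2000.0)
        a = np.deg2rad(10.0)
        expected = 1000.0 * np.sin(a) * (1 - e1) / (1 - e1 * np.cos(a))
        assert expected == pytest.approx(60.06, abs=0.01)
        assert g.spgr_signal(1000.0, 2000.0, 10.0, TR) == pytest.approx(expected, rel=1e-14)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            g.spgr_signal(1000.0, -5.0, 10.0, TR)
        with pytest.raises(ValueError):
            g.spgr_signal(1000.0, 2000.0, 10.0, 0.0)


class TestFitDespot1:
    @pytest.mark.parametrize("t1_true", [1994.0, 2094.0])
    def test_recovers_printed_control_brain_t1(self, t1_true):
        sig = g.spgr_signal(1000.0, t1_true, np.array(ANGLES), TR).reshape(-1, 1, 1, 1)
        fit = g.fit_despot1(sig, ANGLES, TR)
        assert fit.t1.data.ravel()[0] == pytest.approx(t1_true, rel=1e-4)

    @pytest.mark.parametrize("t1_true", [150.0, 500.0, 1200.0, 3000.0, 4900.0])
    def test_two_noiseless_points_are_exact(self, t1_true):
        angles = (5.0, 20.0)
        sig = g.spgr_signal(800.0, t1_true, np.array(angles), TR).reshape(-1, 1, 1, 1)
        fit = g.fit_despot1(sig, angles, TR)
        assert fit.t1.data.ravel()[0] == pytest.approx(t1_true, rel=1e-9)
        assert fit.m0.data.ravel()[0] == pytest.approx(800.0, rel=1e-9)

    @given(
        m0=st.floats(100.0, 5000.0),
        t1=st.floats(200.0, 4500.0),
        kappa=st.floats(0.7, 1.3),
    )
    def test_round_trip_with_b1(self, m0, t1, kappa):
        sig = g.spgr_signal(m0, t1, kappa * np.array(ANGLES), TR).reshape(-1, 1, 1, 1)
        fit = g.fit_despot1(sig, ANGLES, TR, b1map=np.full((1, 1, 1), kappa))
        assert fit.t1.data.ravel()[0] == pytest.approx(t1, rel=1e-3)
        assert fit.m0.data.ravel()[0] == pytest.approx(m0, rel=1e-3)

    def test_linearized_equals_nonlinear_at_zero_noise(self):
        sig = g.spgr_signal(1200.0, 1700.0, np.array(ANGLES), TR)
        fit = g.fit_despot1(sig.reshape(-1, 1, 1, 1), ANGLES, TR)
        t1_nl, m0_nl, sse = nonlinear_t1_oracle(sig, ANGLES, TR,
                                                t1_grid=np.arange(1690, 1710, 0.01))
        assert fit.t1.data.ravel()[0] == pytest.approx(t1_nl, abs=0.02)
        assert sse == pytest.approx(0.0, abs=1e-12)
        assert fit.r_squared.data.ravel()[0] == pytest.approx(1.0, abs=1e-12)

    def test_noisy_fit_matches_gridsearch_oracle(self, rng):
        t1_true, m0_true = 2000.0, 1000.0
        clean = g.spgr_signal(m0_true, t1_true, np.array(ANGLES), TR)
        sigma = 0.02 * clean.max()
        diffs = []
        for _ in range(120):
            noisy = clean + sigma * rng.standard_normal(clean.shape)
            fit = g.fit_despot1(noisy.reshape(-1, 1, 1, 1), ANGLES, TR)
            t1_lin = fit.t1.data.ravel()[0]
            t1_nl, _, _ = nonlinear_t1_oracle(noisy, ANGLES, TR)
            if np.isfinite(t1_lin):
                diffs.append(abs(t1_lin - t1_nl) / t1_nl)
        assert np.median(diffs) < 0.03

    def test_invalid_voxels_are_nan_consistently(self):
        sig = np.zeros((len(ANGLES), 2, 1, 1))
        sig[:, 1, 0, 0] = g.spgr_signal(1000.0, 2000.0, np.array(ANGLES), TR)
        fit = g.fit_despot1(sig, ANGLES, TR)
        assert np.isnan(fit.t1.data[0, 0, 0]) and np.isnan(fit.m0.data[0, 0, 0])
        assert np.array_equal(np.isnan(fit.t1.data), np.isnan(fit.m0.data))
        assert fit.n_valid == 1

    def test_grid_mismatch_raises(self):
        sig = np.ones((6, 2, 2, 2))
        with pytest.raises(ValueError):
            g.fit_despot1(sig, ANGLES, TR, b1map=np.ones((3, 3, 3)))


class TestDamB1Map:
    def test_unity_field_exact(self):
        s1 = np.full((4, 4, 4), 100.0)
        s2 = 2.0 * np.cos(np.deg2rad(70.0)) * s1
        b1 = g.dam_b1_map(s1, s2, 70.0)
        np.testing.assert_allclose(b1.data, 1.0, rtol=1e-12)

    def test_planted_kappa_09(self):
        # S(2a)/S(a) = sin(2*0.9*70)/sin(0.9*70) = 2 cos(63 deg)
        s1 = np.full((2, 2, 2), 50.0) * np.sin(np.deg2rad(63.0))
        s2 = np.full((2, 2, 2), 50.0) * np.sin(np.deg2rad(126.0))
        b1 = g.dam_b1_map(s1, s2, 70.0)
        np.testing.assert_allclose(b1.data, 0.9, rtol=1e-12)

    def test_domain_violations_are_nan(self):
        s1 = np.array([[[1.0, 0.0]]])
        s2 = np.array([[[3.0, 1.0]]])  # ratio > 1; zero denominator
        b1 = g.dam_b1_map(s1, s2, 70.0)
        assert np.isnan(b1.data).all()


class TestResampleB1:
    def test_constant_field_any_target(self):
        grid = RareGrid((6, 6, 5), 0.24, 0.3, 0.2)
        b1 = B1Map(np.full(grid.shape, 1.05), grid.voxel_size)
        out = resample_b1(b1, grid, (10, 10, 10), (0.144, 0.144, 0.125))
        np.testing.assert_allclose(out.data, 1.05, rtol=1e-12)

    def test_identity_on_matching_grids(self):
        # gap 0 and thickness == in-plane makes the RARE grid a plain cube
        grid = RareGrid((8, 8, 8), 0.5, 0.5, 0.0)
        data = 1.0 + 0.1 * np.random.default_rng(0).random(grid.shape)
        b1 = B1Map(data, grid.voxel_size)
        out = resample_b1(b1, grid, (8, 8, 8), (0.5, 0.5, 0.5), presmooth_sigma_vox=0.0)
        np.testing.assert_allclose(out.data, data, rtol=1e-12)

    def test_trilinear_exact_on_affine_field(self):
        grid = RareGrid((10, 10, 8), 0.4, 0.3, 0.2)
        cx, cy, cz = grid.axis_centers_mm()
        field = 1.0 + 0.01 * cx[:, None, None] - 0.02 * cy[None, :, None] + 0.005 * cz[None, None, :]
        b1 = B1Map(field, grid.voxel_size)
        tgt_shape, tgt_vox = (16, 16, 16), (0.2, 0.2, 0.2)
        out = resample_b1(b1, grid, tgt_shape, tgt_vox, presmooth_sigma_vox=0.0)
        tx = (np.arange(16) + 0.5) * 0.2
        expected = 1.0 + 0.01 * tx[:, None, None] - 0.02 * tx[None, :, None] + 0.005 * tx[None, None, :]
        # interior points only (boundary uses nearest extrapolation)
        interior = (
            (tx >= cx[0]) & (tx <= cx[-1]),
            (tx >= cy[0]) & (tx <= cy[-1]),
            (tx >= cz[0]) & (tx <= cz[-1]),
        )
        sel = np.ix_(*[np.where(m)[0] for m in interior])
        np.testing.assert_allclose(out.data[sel], expected[sel], rtol=1e-10)

    def test_all_nan_raises(self):
        grid = RareGrid((4, 4, 4), 0.5, 0.5, 0.0)
        b1 = B1Map(np.full(grid.shape, np.nan), grid.voxel_size)
        with pytest.raises(ValueError):
            resample_b1(b1, grid, (4, 4, 4), (0.5, 0.5, 0.5))


class TestFilterT1:
    def test_strict_upper_bound(self):
        t1 = T1Map(np.array([4999.0, 5000.0, 5001.0]).reshape(1, 1, 3), (1, 1, 1))
        out, n = g.filter_t1(t1)
        np.testing.assert_array_equal(out.data.ravel()[:2], [4999.0, 5000.0])
        assert np.isnan(out.data.ravel()[2]) and n == 1

    def test_negatives_excluded_and_idempotent(self):
        t1 = T1Map(np.array([-3.0, 0.0, 2000.0, 6000.0]).reshape(1, 1, 4), (1, 1, 1))
        out, n = g.filter_t1(t1)
        assert n == 3
        out2, n2 = g.filter_t1(out)
        assert n2 == 0
        np.testing.assert_array_equal(np.isnan(out.data), np.isnan(out2.data))

    def test_all_valid_map_untouched(self):
        t1 = T1Map(np.full((2, 2, 2), 1800.0), (1, 1, 1))
        out, n = g.filter_t1(t1)
        assert n == 0
        np.testing.assert_array_equal(out.data, t1.data)


class TestDerivedImages:
    def test_pdw_is_m0_with_display_fill(self):
        sig = g.spgr_signal(777.0, 2100.0, np.array(ANGLES), TR).reshape(-1, 1, 1, 1)
        sig = np.concatenate([sig, np.zeros_like(sig)], axis=1)  # second voxel invalid
        fit = g.fit_despot1(sig, ANGLES, TR)
        pdw = g.derive_pdw(fit)
        assert pdw.data[0, 0, 0] == pytest.approx(777.0, rel=1e-3)
        assert np.isnan(pdw.data[1, 0, 0])
        disp = g.derive_pdw(fit, for_display=True)
        assert disp.data[1, 0, 0] == 0.0

    def test_spgr_lowfa_is_voxelwise_sum(self):
        a = ImageVolume(np.full((2, 2, 2), 3.0), (1, 1, 1))
        b = ImageVolume(np.full((2, 2, 2), 4.5), (1, 1, 1))
        out = g.derive_spgr_lowfa(a, b)
        np.testing.assert_allclose(out.data, 7.5)
        out2 = g.derive_spgr_lowfa(b, a)
        np.testing.assert_allclose(out.data, out2.data)
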