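"""Cycle integrals (TAWSS/OSI), area fractions, energy loss, 18-parameter summary."""

import numpy as np
import pytest

from aneucloud import (
    FlowState,
    HemoVector,
    compute_energy_loss,
    compute_hoa,
    compute_lsa,
    compute_osi,
    compute_tawss,
    summarize_hemodynamics,
    two_harmonic_waveform,
)
from aneucloud.types import ContractError, FlowWaveform


def _series(waveform, fn):
    """Build a (1, n_steps, 3) WSS series from fn(t) -> 3-vector."""
    return np.array([[fn(t) for t in waveform.times]])


def _fine_oracle(fn, period, n=8000):
    """Quadrature oracle: TAWSS and OSI on a 100x-finer periodic grid."""
    t = np.arange(n) * period / n
    w = np.array([fn(tt) for tt in t])
    closed = np.vstack([w, w[:1]])
    mag = np.linalg.norm(closed, axis=1)
    dt = period / n
    integral_mag = np.trapezoid(mag, dx=dt)
    mean_vec = np.trapezoid(closed, dx=dt, axis=0)
    tawss = integral_mag / period
    osi = 0.5 * (1 - np.linalg.norm(mean_vec) / integral_mag)
    return tawss, osi


class TestTAWSS:
    def test_constant_vector(self, waveform):
        s = _series(waveform, lambda t: (1.0, 0, 0))
        assert compute_tawss(s, waveform)[0] == pytest.approx(1.0)

    def test_sign_flip_keeps_magnitude(self, waveform):
        s = _series(waveform, lambda t: (1.0, 0, 0) if t < 0.4 else (-1.0, 0, 0))
        assert compute_tawss(s, waveform)[0] == pytest.approx(1.0)

    def test_piecewise_magnitudes(self, waveform):
        s = _series(waveform, lambda t: (1.0, 0, 0) if t < 0.4 else (0, 2.0, 0))
        assert compute_tawss(s, waveform)[0] == pytest.approx(1.5, abs=1e-9)

    def test_single_step_rejected(self, waveform):
        with pytest.raises(ContractError):
            compute_tawss(np.zeros((1, 1, 3)), waveform)

    def test_smooth_series_matches_quadrature_oracle(self, waveform):
        fn = lambda t: (1 + 0.5 * np.sin(2 * np.pi * t / 0.8),
                        0.3 * np.cos(2 * np.pi * t / 0.8), 0.1)
        s = _series(waveform, fn)
        tawss_o, osi_o = _fine_oracle(fn, waveform.period)
        assert compute_tawss(s, waveform)[0] == pytest.approx(tawss_o, rel=1e-3)
        assert compute_osi(s, waveform)[0] == pytest.approx(osi_o, rel=1e-3, abs=1e-6)


class TestOSI:
    def test_constant_direction_is_zero(self, waveform):
        s = _series(waveform, lambda t: (0.5 + 0.1 * np.sin(t), 0, 0))
        assert compute_osi(s, waveform)[0] == pytest.approx(0.0, abs=1e-12)

    def test_full_reversal_is_half(self, waveform):
        s = _series(waveform, lambda t: (1.0, 0, 0) if t < 0.4 else (-1.0, 0, 0))
        assert compute_osi(s, waveform)[0] == pytest.approx(0.5)

    def test_orthogonal_half_cycles(self, waveform):
        s = _series(waveform, lambda t: (1.0, 0, 0) if t < 0.4 else (0, 1.0, 0))
        assert compute_osi(s, waveform)[0] == pytest.approx(
            0.5 * (1 - np.sqrt(2) / 2), abs=1e-9)

    def test_zero_field_convention(self, waveform):
        s = np.zeros((3, waveform.n_steps, 3))
        assert np.all(compute_osi(s, waveform) == 0.0)

    def test_pointwise_bounds_on_cohort(self, tiny_cohort):
        for cloud in tiny_cohort:
            assert np.all(cloud.osi >= 0) and np.all(cloud.osi <= 0.5)
            peak = np.linalg.norm(cloud.wss_series, axis=2).max(axis=1)
            assert np.all(cloud.tawss <= peak + 1e-9)


class TestAreaFractions:
    def _cloud_with_tawss(self, small_cloud, values):
        import copy

        c = copy.copy(small_cloud)
        c.tawss = np.asarray(values, dtype=float)
        c.osi = np.clip(np.asarray(values, dtype=float), 0, 0.5)
        return c

    def test_lsa_extremes(self, small_cloud):
        n = small_cloud.geometry.n_points
        high = self._cloud_with_tawss(small_cloud, np.full(n, 10.0))
        low = self._cloud_with_tawss(small_cloud, np.full(n, 0.01))
        assert compute_lsa(high, parent_mean_wss=5.0) == 0.0
        assert compute_lsa(low, parent_mean_wss=5.0) == 1.0

    def test_lsa_half_area_two_level_field(self, small_cloud):
        areas = small_cloud.geometry.point_areas
        half = np.cumsum(areas) / areas.sum() <= 0.5
        values = np.where(half, 0.01, 10.0)
        c = self._cloud_with_tawss(small_cloud, values)
        frac = compute_lsa(c, parent_mean_wss=5.0)
        assert frac == pytest.approx(0.5, abs=2 * areas.max() / areas.sum())

    def test_hoa_extremes(self, small_cloud):
        n = small_cloud.geometry.n_points
        c = self._cloud_with_tawss(small_cloud, np.full(n, 0.4))
        assert compute_hoa(c, osi_threshold=0.2) == 1.0
        c = self._cloud_with_tawss(small_cloud, np.full(n, 0.1))
        assert compute_hoa(c, osi_threshold=0.2) == 0.0

    def test_nonpositive_reference_rejected(self, small_cloud):
        with pytest.raises(ContractError):
            compute_lsa(small_cloud, parent_mean_wss=0.0)


class TestEnergyLoss:
    def test_lossless(self):
        s = FlowState(pressure=150.0, velocity=0.4, flow_rate=4e-6)
        assert compute_energy_loss(s, [s]) == pytest.approx(0.0)

    def test_hand_computed_drop(self):
        inlet = FlowState(200.0, 0.5, 5e-6)
        outlet = FlowState(100.0, 0.5, 5e-6)
        assert compute_energy_loss(inlet, [outlet]) == pytest.approx(5.0e-4)

    def test_two_equal_outlets_match_single(self):
        inlet = FlowState(200.0, 0.5, 5e-6)
        single = [FlowState(120.0, 0.4, 5e-6)]
        split = [FlowState(120.0, 0.4, 2.5e-6), FlowState(120.0, 0.4, 2.5e-6)]
        assert compute_energy_loss(inlet, split) == pytest.approx(
            compute_energy_loss(inlet, single))

    def test_flow_imbalance_rejected(self):
        inlet = FlowState(200.0, 0.5, 5e-6)
        with pytest.raises(ContractError):
            compute_energy_loss(inlet, [FlowState(100.0, 0.5, 4e-6)])


class TestSummary:
    def test_exactly_eighteen_parameters(self, small_cloud):
        hv = summarize_hemodynamics(small_cloud)
        assert len(HemoVector.FIELDS) == 18
        assert hv.as_array().shape == (18,)
        for q in ("wss", "tawss", "osi", "pressure", "velocity"):
            lo = getattr(hv, f"{q}_min")
            mid = getattr(hv, f"{q}_avg")
            hi = getattr(hv, f"{q}_max")
            assert lo <= mid <= hi
        assert 0 <= hv.hoa <= 1 and 0 <= hv.lsa <= 1
        assert hv.osi_max <= 0.5

    def test_uniform_field_collapses(self, hemisphere, waveform):
        import copy

        from aneucloud import simulate_hemo_fields

        cloud = simulate_hemo_fields(hemisphere, waveform, seed=1)
        c = copy.copy(cloud)
        n = hemisphere.n_points
        c.wss_series = np.tile(np.array([1.0, 0, 0]), (n, waveform.n_steps, 1))
        c.pressure = np.full(n, 120.0)
        c.velocity = np.full(n, 0.3)
        c.tawss = c.osi = c.wss_sys = None
        hv = summarize_hemodynamics(c)
        assert hv.wss_avg == pytest.approx(hv.wss_max, rel=1e-12)
        assert hv.wss_min == pytest.approx(hv.wss_max, rel=1e-12)
        assert hv.pressure_avg == pytest.approx(hv.pressure_max, rel=1e-12)
        assert hv.pressure_min == pytest.approx(hv.pressure_max, rel=1e-12)

    def test_single_hot_point_moves_only_max(self, small_cloud):
        import copy

        base = summarize_hemodynamics(small_cloud)
        c = copy.copy(small_cloud)
        vel = small_cloud.velocity.copy()
        vel[5] = vel.max() * 10
        c.velocity = vel
        hot = summarize_hemodynamics(c)
        assert hot.velocity_max > base.velocity_max
        assert hot.velocity_min == base.velocity_min
        assert hot.velocity_avg == pytest.approx(base.velocity_avg, rel=0.05)

    def test_area_weighted_average_two_level(self, small_cloud):
        # value 4 on a quarter of the area, 0 elsewhere -> avg = 1
        import copy

        areas = small_cloud.geometry.point_areas
        frac = np.cumsum(areas) / areas.sum()
        values = np.where(frac <= 0.25, 4.0, 0.0)
        c = copy.copy(small_cloud)
        c.velocity = values
        hv = summarize_hemodynamics(c)
        assert hv.velocity_avg == pytest.approx(1.0, abs=4 * areas.max() / areas.sum())

    def test_point_reordering_invariance(self, small_cloud):
        import copy

        from aneucloud.types import SacGeometry

        perm = np.random.default_rng(3).permutation(small_cloud.geometry.n_points)
        inv = np.empty_like(perm)
        inv[perm] = np.arange(perm.size)
        g = small_cloud.geometry
        geom = SacGeometry(g.surface_points[perm], g.point_areas[perm],
                           g.point_normals[perm], inv[g.neck_ring],
                           int(inv[g.dome_tip]), g.parent_diameter,
                           g.shape_flag, g.location_flag)
        c = copy.copy(small_cloud)
        c.geometry = geom
        c.wss_series = small_cloud.wss_series[perm]
        c.pressure = small_cloud.pressure[perm]
        c.velocity = small_cloud.velocity[perm]
        c.tawss = c.osi = c.wss_sys = None
        a = summarize_hemodynamics(small_cloud).as_array()
        b = summarize_hemodynamics(c).as_array()
        np.testing.assert_allclose(a, b, rtol=1e-10)
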