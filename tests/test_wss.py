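"""WSS extraction, cycle averaging and the metric suite."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hemoshear import units
from hemoshear.meshing import Region, build_channel_mesh
from hemoshear.solver import FlowConditions, simulate_steady
from hemoshear.wss import (
    HemodynamicMetrics,
    TaggingError,
    UndefinedRatioError,
    WallShearSeries,
    compute_metrics,
    time_average_wss,
    wall_shear_series,
)


def make_series(avg, weights=None, regions=None, times=None, wss=None):
    """Hand-built series for metric tests (single snapshot by default)."""
    avg = np.asarray(avg, dtype=float)
    n = len(avg)
    s = WallShearSeries(
        times=np.array([0.0]) if times is None else times,
        period=1.0,
        wss=avg[None, :] if wss is None else wss,
        weights=np.ones(n) if weights is None else np.asarray(weights, float),
        regions=np.asarray(regions) if regions is not None else np.zeros(n, int),
    )
    s.time_averaged = avg
    return s


class TestWallShearExtraction:
    def test_poiseuille_channel_wss(self):
        mesh = build_channel_mesh(8 * 3.2, 3.2, 0.2)
        flow = FlowConditions(mean_flow=20.0, max_flow=20.0, reference_diameter=3.2)
        f = simulate_steady(mesh, flow)
        s = wall_shear_series(f, mesh, flow.viscosity)
        h = units.mm_to_m(3.2)
        q = flow.mean_velocity() * h
        x = (mesh.wall_cell[:, 0] + 0.5) * mesh.cell_size
        developed = (x > 0.5 * 8 * 3.2) & (x < 0.95 * 8 * 3.2)
        assert s.wss[0, developed] == pytest.approx(6 * flow.viscosity * q / h**2, rel=0.05)

    def test_zero_field_gives_zero_series(self):
        mesh = build_channel_mesh(10.0, 2.0, 0.25)
        flow = FlowConditions(mean_flow=0.0, max_flow=0.0, reference_diameter=2.0)
        f = simulate_steady(mesh, flow)
        s = wall_shear_series(f, mesh, flow.viscosity)
        assert not np.any(s.wss)

    def test_wss_linear_in_viscosity(self):
        mesh = build_channel_mesh(10.0, 2.0, 0.25)
        flow = FlowConditions(mean_flow=5.0, max_flow=5.0, reference_diameter=2.0)
        f = simulate_steady(mesh, flow)
        s1 = wall_shear_series(f, mesh, flow.viscosity)
        s2 = wall_shear_series(f, mesh, 2 * flow.viscosity)
        assert np.allclose(s2.wss, 2 * s1.wss)


class TestTimeAverage:
    def test_rectified_sine_mean(self):
        t = np.linspace(0.0, 1.0, 1001)
        a = math.pi / 2
        w = a * np.abs(np.sin(2 * math.pi * t))
        s = WallShearSeries(
            times=t, period=1.0, wss=w[:, None],
            weights=np.ones(1), regions=np.zeros(1, int),
        )
        s = time_average_wss(s)
        # mean of A|sin| is 2A/pi = 1 for A = pi/2
        assert s.time_averaged[0] == pytest.approx(1.0, rel=1e-3)

    def test_constant_series_averages_exactly(self):
        t = np.linspace(0.0, 0.9375, 33)
        s = WallShearSeries(
            times=t, period=0.9375, wss=np.full((33, 4), 2.7),
            weights=np.ones(4), regions=np.zeros(4, int),
        )
        assert time_average_wss(s).time_averaged == pytest.approx(2.7)

    def test_matches_oversampled_riemann_oracle(self):
        rng = np.random.default_rng(7)
        t = np.linspace(0.0, 1.0, 201)
        coef = rng.normal(size=(3, 2))
        def signal(tt):
            out = np.full_like(tt, 1.5)
            for k, (a, b) in enumerate(coef, start=1):
                out = out + a * np.sin(2 * math.pi * k * tt) + b * np.cos(2 * math.pi * k * tt)
            return np.abs(out)
        s = WallShearSeries(
            times=t, period=1.0, wss=signal(t)[:, None],
            weights=np.ones(1), regions=np.zeros(1, int),
        )
        avg = time_average_wss(s).time_averaged[0]
        tt = np.linspace(0.0, 1.0, 2001)  # 10x oversampled Riemann sum
        oracle = signal(tt)[:-1].sum() * (tt[1] - tt[0])
        assert avg == pytest.approx(oracle, rel=5e-3)

    def test_non_monotone_times_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            WallShearSeries(
                times=np.array([0.0, 0.2, 0.1]), period=1.0,
                wss=np.zeros((3, 1)), weights=np.ones(1), regions=np.zeros(1, int),
            )


class TestMetrics:
    def test_uniform_field(self):
        s = make_series([3.0] * 6, regions=[1, 1, 1, 2, 2, 0])
        m = compute_metrics(s)
        assert (m.mwss, m.hwss, m.pwss) == (3.0, 3.0, 3.0)
        assert m.mp_ratio == m.hp_ratio == 1.0
        assert m.lsar == 0.0

    def test_half_low_half_high_gives_lsar_half(self):
        # sac: half the arc at 0.05*PWSS, half at 2*PWSS
        s = make_series(
            [0.05 * 4.0, 2 * 4.0, 4.0, 4.0],
            regions=[1, 1, 2, 2],
        )
        m = compute_metrics(s)
        assert m.pwss == 4.0
        assert m.lsar == 0.5

    def test_all_below_threshold_gives_lsar_one(self):
        s = make_series([0.01, 0.02, 5.0, 5.0], regions=[1, 1, 2, 2])
        assert compute_metrics(s).lsar == 1.0

    def test_threshold_is_strict(self):
        # elements exactly at 0.1*PWSS are NOT low-shear
        s = make_series([0.5, 0.5, 5.0], regions=[1, 1, 2])
        assert compute_metrics(s).lsar == 0.0

    def test_weighted_mean_uses_arc_lengths(self):
        s = make_series([1.0, 3.0, 2.0], weights=[3.0, 1.0, 1.0], regions=[1, 1, 2])
        m = compute_metrics(s)
        assert m.mwss == pytest.approx((3 * 1.0 + 1 * 3.0) / 4)

    def test_peak_hwss_mode(self):
        wss = np.array([[1.0, 2.0, 9.0], [4.0, 1.0, 9.0]])
        t = np.array([0.0, 1.0])
        s = WallShearSeries(
            times=t, period=1.0, wss=wss,
            weights=np.ones(3), regions=np.array([1, 1, 2]),
        )
        m_avg = compute_metrics(s, hwss_mode="time-averaged")
        m_peak = compute_metrics(s, hwss_mode="peak")
        assert m_avg.hwss == pytest.approx(2.5)
        assert m_peak.hwss == pytest.approx(4.0)

    def test_zero_pwss_raises(self):
        s = make_series([1.0, 1.0, 0.0], regions=[1, 1, 2])
        with pytest.raises(UndefinedRatioError):
            compute_metrics(s)

    def test_empty_region_raises(self):
        s = make_series([1.0, 1.0], regions=[1, 1])
        with pytest.raises(TaggingError):
            compute_metrics(s)

    @given(c=st.floats(1e-3, 1e3))
    @settings(max_examples=30, deadline=None)
    def test_scale_equivariance(self, c):
        base = np.array([0.2, 1.5, 0.04, 2.0, 1.0, 1.2])
        regions = [1, 1, 1, 1, 2, 2]
        m1 = compute_metrics(make_series(base, regions=regions))
        m2 = compute_metrics(make_series(c * base, regions=regions))
        assert m2.mwss == pytest.approx(c * m1.mwss, rel=1e-9)
        assert m2.hwss == pytest.approx(c * m1.hwss, rel=1e-9)
        assert m2.pwss == pytest.approx(c * m1.pwss, rel=1e-9)
        assert m2.lsar == m1.lsar
        assert m2.mp_ratio == pytest.approx(m1.mp_ratio, rel=1e-9)
        assert m2.hp_ratio == pytest.approx(m1.hp_ratio, rel=1e-9)

    def test_lsar_monotone_in_threshold(self):
        rng = np.random.default_rng(3)
        avg = rng.lognormal(0, 1.2, size=40)
        regions = np.array([1] * 30 + [2] * 10)
        s = make_series(avg, regions=regions)
        fracs = np.linspace(0.1, 0.0, 11)
        lsars = [compute_metrics(s, threshold_fraction=f).lsar for f in fracs]
        assert all(a >= b - 1e-12 for a, b in zip(lsars, lsars[1:]))

    def test_hwss_at_least_mwss_and_permutation_invariance(self):
        rng = np.random.default_rng(5)
        avg = rng.lognormal(0, 1, size=25)
        regions = np.array([1] * 20 + [2] * 5)
        w = rng.uniform(0.5, 2.0, size=25)
        m = compute_metrics(make_series(avg, weights=w, regions=regions))
        assert m.hwss >= m.mwss
        assert m.hp_ratio >= m.mp_ratio
        perm = rng.permutation(25)
        mp = compute_metrics(make_series(avg[perm], weights=w[perm], regions=regions[perm]))
        assert mp.mwss == pytest.approx(m.mwss)
        assert mp.hwss == m.hwss
        assert mp.lsar == pytest.approx(m.lsar)
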