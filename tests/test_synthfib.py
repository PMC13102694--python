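"""Forward simulator: growth kinetics, record composition, geometry,
rendering, and the encoding-fidelity invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tapetrace.errors import (
    ConfigurationError,
    InfeasibleGeometryError,
    InvalidModelError,
    OutOfBoundsError,
)
from tapetrace.skeleton import _menger_curvature
from tapetrace.synthfib import (
    DyeSchedule,
    GrowthModel,
    PromoterWaveform,
    RenderConfig,
    compose_fiber_record,
    generate_centerline_curve,
    render_volume,
    simulate_growth,
)


class TestGrowth:
    @pytest.mark.parametrize(
        "a,b,t0,t,expected",
        [(2.0, 1.0, 1.0, 3.0, 4.0), (4.0, 0.5, 0.0, 4.0, 8.0)],
    )
    def test_closed_form_half_length(self, a, b, t0, t, expected):
        m = GrowthModel(t0=t0, a=a, b=b, duration=10)
        assert m.length_at(t) == pytest.approx(expected)

    def test_round_trip_invertibility(self):
        m = GrowthModel(t0=0.5, a=1.7, b=0.7, duration=9)
        traj = simulate_growth(m, 100)
        t = np.random.default_rng(0).uniform(0.6, 9.4, 100)
        assert np.abs(traj.time_at(traj.length_at(t)) - t).max() < 1e-9
        assert np.all(np.diff(traj.t) > 0) and np.all(np.diff(traj.s) > 0)

    @pytest.mark.parametrize(
        "kwargs",
        [dict(a=-1.0), dict(a=1.0, b=0.0), dict(a=1.0, b=1.5), dict(a=1.0, duration=-2)],
    )
    def test_invalid_models_rejected(self, kwargs):
        with pytest.raises(InvalidModelError):
            GrowthModel(t0=0, b=kwargs.pop("b", 1.0), duration=kwargs.pop("duration", 5.0), **kwargs)

    @given(
        a=st.floats(0.2, 5), b=st.floats(0.3, 1), t0=st.floats(0, 2),
        dur=st.floats(1, 20),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_growth_strictly_increasing_property(self, a, b, t0, dur):
        m = GrowthModel(t0=t0, a=a, b=b, duration=dur)
        traj = simulate_growth(m, 64)
        assert traj.s[0] == 0.0
        assert np.all(np.diff(traj.s) > 0)


class TestRecord:
    def _traj(self, a=5.0, b=1.0, t0=0.0, dur=4.0):
        return simulate_growth(GrowthModel(t0=t0, a=a, b=b, duration=dur))

    def test_constant_structural_level(self):
        rec = compose_fiber_record(self._traj(), {}, None, structural_level=3.25)
        assert np.allclose(rec.channels["structural"], 3.25)

    def test_dye_switch_at_half_fraction(self):
        sch = DyeSchedule(events=((0.0, "d1"), (2.0, "d2")), fixation_time=4.0)
        rec = compose_fiber_record(self._traj(), {}, sch, 1.0, dye_smoothing_um=0.0)
        d2 = rec.channels["d2"]
        onset = rec.arclength[np.argmax(d2 > d2.max() / 2)]
        assert onset / rec.half_length == pytest.approx(0.5, abs=0.01)
        # encoding fidelity: ground-truth switch position is exact
        assert rec.model.length_at(2.0) / rec.half_length == pytest.approx(0.5)

    def test_signal_pulse_peaks_at_deposition_arclength(self):
        wf = PromoterWaveform(baseline=1, amplitude=5, stim_time=1.2, delay=0.1,
                              tau_rise=0.05, tau_decay=0.4)
        rec = compose_fiber_record(self._traj(), {"sig": wf}, None, 1.0)
        s_peak = rec.arclength[np.argmax(rec.channels["sig"])]
        assert abs(s_peak - rec.model.length_at(wf.peak_time)) <= 2 * (
            rec.arclength[1] - rec.arclength[0]
        )

    def test_mirror_symmetry_of_full_profile(self):
        sch = DyeSchedule(events=((0.0, "d1"), (2.0, "d2")), fixation_time=4.0)
        wf = PromoterWaveform(baseline=1, amplitude=5, stim_time=1.5, delay=0)
        rec = compose_fiber_record(self._traj(), {"sig": wf}, sch, 2.0)
        _, ch = rec.full_profile()
        n = len(rec.arclength)
        for v in ch.values():
            left, right = v[:n][::-1], v[n - 1 :]
            r = np.corrcoef(left, right)[0, 1] if np.std(v) > 0 else 1.0
            assert r == pytest.approx(1.0)

    def test_waveform_dye_channel_collision_rejected(self):
        sch = DyeSchedule(events=((0.0, "d1"),), fixation_time=4.0)
        wf = PromoterWaveform(baseline=1, amplitude=1, stim_time=1)
        with pytest.raises(ConfigurationError):
            compose_fiber_record(self._traj(), {"d1": wf}, sch, 1.0)


class TestCenterlineCurve:
    def test_zero_curvature_is_straight(self):
        pts = generate_centerline_curve(20.0, 0.0, soma_radius=30.0, seed=0)
        assert np.linalg.norm(pts[-1] - pts[0]) == pytest.approx(20.0, rel=0.01)

    def test_deterministic_given_seed(self):
        a = generate_centerline_curve(15.0, 0.2, 9.0, seed=5)
        b = generate_centerline_curve(15.0, 0.2, 9.0, seed=5)
        assert np.array_equal(a, b)

    @pytest.mark.parametrize("seed", range(5))
    def test_curvature_bound_and_confinement(self, seed):
        pts = generate_centerline_curve(18.0, 0.2, 9.0, seed=seed)
        assert _menger_curvature(pts).max() <= 0.2 * 1.05
        assert np.linalg.norm(pts, axis=1).max() <= 9.0
        arc = np.linalg.norm(np.diff(pts, axis=0), axis=1).sum()
        assert arc == pytest.approx(18.0, rel=0.01)

    def test_infeasible_geometry_rejected(self):
        with pytest.raises(InfeasibleGeometryError):
            generate_centerline_curve(40.0, 0.05, soma_radius=5.0, seed=0)


class TestRender:
    def _cfg(self, **kw):
        base = dict(
            shape=(32, 48, 48), voxel_spacing=(0.4, 0.25, 0.25),
            psf_sigma=(0.5, 0.2, 0.2), background=10.0, read_noise_sd=1.0,
            photon_scale=1.0, soma_radius=4.0, seed=7,
        )
        base.update(kw)
        return RenderConfig(**base)

    def _fiber(self, length_days=4.0, center=(6.0, 6.0, 6.0)):
        traj = simulate_growth(GrowthModel(t0=0, a=1.0, b=1, duration=length_days))
        rec = compose_fiber_record(traj, {}, None, structural_level=100.0)
        poly = generate_centerline_curve(rec.total_length, 0.0, 30.0, seed=1, center=center)
        return rec, poly

    def test_zero_fibers_zero_noise_is_background(self):
        cfg = self._cfg(read_noise_sd=0.0, photon_scale=0.0)
        res = render_volume([], [], cfg)
        assert np.allclose(res.volume.data, 10.0)

    def test_same_seed_bit_identical(self):
        cfg = self._cfg()
        f = self._fiber()
        a = render_volume([f], [], cfg).volume.data
        b = render_volume([f], [], cfg).volume.data
        assert np.array_equal(a, b)

    def test_doubling_length_doubles_integrated_intensity(self):
        cfg = self._cfg(shape=(24, 32, 200))
        sums = {}
        for days in (10.0, 20.0):
            traj = simulate_growth(GrowthModel(t0=0, a=1.0, b=1, duration=days))
            rec = compose_fiber_record(traj, {}, None, structural_level=100.0)
            x0 = (200 - 1) * 0.25 / 2
            n = 200
            pts = np.column_stack(
                [np.full(n, 4.6), np.full(n, 4.0),
                 np.linspace(x0 - days, x0 + days, n)]
            )
            res = render_volume([(rec, pts)], [], cfg, noise=False)
            sums[days] = float((res.noise_free.channel("structural") - 10.0).sum())
        assert sums[20.0] / sums[10.0] == pytest.approx(2.0, rel=0.02)

    def test_out_of_bounds_fiber_named(self):
        cfg = self._cfg()
        rec, poly = self._fiber(center=(0.5, 0.5, 0.5))
        with pytest.raises(OutOfBoundsError, match="fiber 0"):
            render_volume([(rec, poly)], [], cfg)

    def test_ground_truth_switch_fractions_exact(self):
        # encoding fidelity: switch fraction equals s(switch)/s(fixation)
        sch = DyeSchedule(events=((0.0, "d1"), (1.5, "d2")), fixation_time=4.0)
        traj = simulate_growth(GrowthModel(t0=0, a=1.0, b=0.5, duration=4.0))
        rec = compose_fiber_record(traj, {}, sch, 50.0)
        poly = generate_centerline_curve(rec.total_length, 0.0, 30.0, seed=2, center=(6, 6, 6))
        res = render_volume([(rec, poly)], [((6.0, 6.0, 6.0), 4.0)], self._cfg())
        gtf = res.ground_truth.fibers[0]
        model = gtf.record.model
        expected = model.length_at(1.5) / model.length_at(4.0)
        got = gtf.dye_switch_arclengths[0] / gtf.half_length
        assert got == pytest.approx(expected, abs=1e-12)
        assert gtf.cell_label == 1
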