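"""Split search, baseline normalization, timestamp detection, transfer
functions, and time warping."""

import numpy as np
import pytest

from tapetrace.errors import (
    DetectionFailure,
    DivisionUnsafeError,
    InvalidAnchorsError,
    UndefinedCorrelationError,
)
from tapetrace.profiles import FiberProfile
from tapetrace.timeaxis import (
    TimestampSet,
    detect_timestamps,
    find_split,
    fit_transfer,
    normalize_baseline,
    split_halves,
    warp_to_time,
)


def _profile(values: dict, length=20.0):
    n = len(next(iter(values.values())))
    return FiberProfile(np.linspace(0, length, n), {k: np.asarray(v, float) for k, v in values.items()})


def _brute_force_split(ref: np.ndarray, arc: np.ndarray, window_frac: float) -> int:
    """Independent exhaustive oracle over every candidate split."""
    total = arc[-1] - arc[0]
    center = 0.5 * (arc[0] + arc[-1])
    best, best_r = None, -np.inf
    fgrid = np.linspace(0, 1, 500)
    for i in range(2, len(ref) - 2):
        if abs(arc[i] - center) > window_frac / 2 * total:
            continue
        ld = arc[i] - arc[i::-1]
        rd = arc[i:] - arc[i]
        left = np.interp(fgrid, ld / ld[-1], ref[i::-1])
        right = np.interp(fgrid, rd / rd[-1], ref[i:])
        if left.std() == 0 or right.std() == 0:
            continue
        r = np.corrcoef(left, right)[0, 1]
        if r > best_r + 1e-12:
            best, best_r = i, r
    return best


class TestFindSplit:
    def test_mirror_symmetric_profile_splits_at_center(self):
        x = np.linspace(0, 1, 401)
        ref = np.exp(-((x - 0.5) ** 2) / 0.02) + 0.3 * np.sin(8 * np.pi * np.abs(x - 0.5))
        prof = _profile({"ref": ref})
        res = find_split(prof, "ref", 0.2)
        assert res.split_index == 200
        assert res.pearson_r == pytest.approx(1.0, abs=1e-9)

    def test_planted_off_center_split_recovered(self):
        # construct reversed(H) + H with the junction off-center but inside
        # the search window
        rng = np.random.default_rng(7)
        h = np.cumsum(rng.normal(size=230))
        h = h - h.min() + 1
        prof_vals = np.concatenate([h[::-1], h])  # junction at index 229/230
        prof = _profile({"ref": prof_vals})
        res = find_split(prof, "ref", 0.2)
        oracle = _brute_force_split(prof_vals, prof.arclength, 0.2)
        assert res.split_index == oracle
        assert abs(res.split_index - 229.5) <= 1

    def test_constant_reference_rejected(self):
        prof = _profile({"ref": np.ones(100)})
        with pytest.raises(UndefinedCorrelationError):
            find_split(prof, "ref", 0.2)

    def test_in_vivo_window_is_narrower(self):
        x = np.linspace(0, 1, 301)
        ref = np.abs(x - 0.55)  # best mirror point at 0.55, outside 5% radius
        prof = _profile({"ref": ref})
        wide = find_split(prof, "ref", 0.2)
        narrow = find_split(prof, "ref", 0.1)
        assert abs(wide.split_arclength / 20.0 - 0.55) < 0.01
        assert abs(narrow.split_arclength / 20.0 - 0.5) <= 0.05 + 1e-9


class TestNormalizeBaseline:
    def test_constant_channel_becomes_zero(self):
        prof = _profile({"c": np.full(200, 3.0)})
        out = normalize_baseline(prof, 100)
        assert np.allclose(out.channel("c"), 0.0)

    def test_relative_change_arithmetic(self):
        vals = np.full(200, 2.0)
        vals[150] = 3.0
        out = normalize_baseline(_profile({"c": vals}), 100)
        assert out.channel("c")[150] == pytest.approx(0.5)

    def test_zero_baseline_rejected(self):
        vals = np.zeros(200)
        vals[150] = 1.0
        with pytest.raises(DivisionUnsafeError, match="'c'"):
            normalize_baseline(_profile({"c": vals}), 100)


class TestDetectTimestamps:
    def test_sharp_step_located_exactly(self):
        y = np.zeros(1000)
        y[600:] = 1.0
        half = _profile({"d1": np.ones(1000), "d2": y})
        ts = detect_timestamps(half, ["d1", "d2"], [5.0], 10.0)
        assert ts.fractions[0] == pytest.approx(0.600, abs=0.002)
        assert ts.anchors[-1] == (1.0, 10.0, "terminus")

    def test_trapezoid_pulse_onsets_in_dox_mode(self):
        x = np.linspace(0, 1, 1000)
        y = np.interp(x, [0, 0.40, 0.50, 0.70, 1.0], [0, 0, 1, 1, 0])
        half = _profile({"dox": y})
        ts = detect_timestamps(half, ["dox"], [10.0, 12.0], 14.0, mode="dox_pulse")
        assert ts.fractions[0] == pytest.approx(0.40, abs=0.01)
        assert ts.fractions[1] == pytest.approx(0.70, abs=0.01)
        assert ts.times.tolist() == [10.0, 12.0, 14.0]

    def test_flat_channel_fails_detection(self):
        half = _profile({"d1": np.ones(1000), "d2": np.full(1000, 2.0)})
        with pytest.raises(DetectionFailure):
            detect_timestamps(half, ["d1", "d2"], [5.0], 10.0)

    def test_two_switches_detected_in_order(self):
        y2 = np.zeros(1000)
        y2[400:] = 1.0
        y3 = np.zeros(1000)
        y3[750:] = 1.0
        half = _profile({"d1": np.ones(1000), "d2": y2, "d3": y3})
        ts = detect_timestamps(half, ["d1", "d2", "d3"], [3.0, 7.0], 11.0)
        assert ts.fractions[0] == pytest.approx(0.40, abs=0.005)
        assert ts.fractions[1] == pytest.approx(0.75, abs=0.005)


class TestFitTransfer:
    def test_quadratic_through_worked_anchors(self):
        # independent 3x3 linear-solve oracle:
        # [f^2 f 1] coeffs = t  ->  t(f) = (5/3) f^2 + 15.5 f - 37/6
        A = np.array([[0.25, 0.5, 1], [0.49, 0.7, 1], [1.0, 1.0, 1]])
        coeffs = np.linalg.solve(A, [2.0, 5.5, 11.0])
        assert np.allclose(coeffs, [5 / 3, 15.5, -37 / 6])
        anchors = TimestampSet(
            ((0.5, 2.0, "rise_onset"), (0.7, 5.5, "rise_onset"), (1.0, 11.0, "terminus"))
        )
        tf = fit_transfer(anchors, "quadratic")
        assert np.abs(tf(anchors.fractions) - anchors.times).max() < 1e-9
        assert tf(0.85) == pytest.approx(8.2125, abs=1e-9)
        assert np.all(np.diff(tf(np.linspace(0.5, 1, 200))) > 0)

    def test_linear_two_anchors(self):
        anchors = TimestampSet(((0.5, 5.0, "rise_onset"), (1.0, 10.0, "terminus")))
        tf = fit_transfer(anchors, "linear")
        assert tf(0.25) == pytest.approx(2.5)

    @pytest.mark.parametrize("days", [(10.0, 12.0, 14.0), (10.0, 13.0, 18.0)])
    def test_piecewise_linear_passes_through_anchors_exactly(self, days):
        anchors = TimestampSet(
            ((0.45, days[0], "rise_onset"), (0.62, days[1], "decay_onset"),
             (1.0, days[2], "terminus"))
        )
        tf = fit_transfer(anchors, "piecewise_linear")
        assert np.abs(tf(anchors.fractions) - anchors.times).max() < 1e-12

    def test_power_fit_recovers_generating_law(self):
        # anchors generated by t = 4 f^2.5 + 1
        fs = np.array([0.4, 0.7, 1.0])
        ts_ = 4 * fs**2.5 + 1
        anchors = TimestampSet(tuple((f, t, "rise_onset") for f, t in zip(fs[:-1], ts_[:-1])) + ((1.0, float(ts_[-1]), "terminus"),))
        tf = fit_transfer(anchors, "power")
        assert np.abs(tf(fs) - ts_).max() < 1e-9
        assert tf.coefficients["beta"] == pytest.approx(2.5, abs=1e-6)

    def test_monotone_spline_exact_at_anchors(self):
        anchors = TimestampSet(
            ((0.3, 2.0, "rise_onset"), (0.6, 4.0, "rise_onset"),
             (0.8, 7.0, "rise_onset"), (1.0, 11.0, "terminus"))
        )
        tf = fit_transfer(anchors, "monotone_spline")
        assert np.abs(tf(anchors.fractions) - anchors.times).max() < 1e-12

    def test_non_monotone_fit_falls_back_to_piecewise(self):
        # quadratic through these anchors decreases early in [f_min, 1]
        anchors = TimestampSet(
            ((0.1, 0.5, "rise_onset"), (0.8, 1.0, "rise_onset"), (1.0, 6.0, "terminus"))
        )
        tf = fit_transfer(anchors, "quadratic")
        assert tf.model == "piecewise_linear"
        assert any("fallback" in f for f in tf.flags)

    def test_non_increasing_times_rejected(self):
        with pytest.raises(InvalidAnchorsError):
            TimestampSet(((0.5, 5.0, "rise_onset"), (1.0, 4.0, "terminus")))


class TestWarp:
    def test_identity_like_transfer_preserves_values(self):
        n = 500
        prof = _profile({"c": np.sin(np.linspace(0, 6, n))}, length=10.0)
        anchors = TimestampSet(((0.5, 5.0, "rise_onset"), (1.0, 10.0, "terminus")))
        tf = fit_transfer(anchors, "linear")  # t = 10 f
        ts = warp_to_time(prof, tf, dt=0.02)
        assert np.allclose(np.diff(ts.time), 0.02)
        # times span [0, 10]; values preserved under linear map
        assert np.interp(5.0, ts.time, ts.channel("c")) == pytest.approx(
            np.sin(3.0), abs=0.01
        )
        assert ts.extrapolated.sum() > 0  # region before the first anchor

    def test_convex_transfer_stretches_late_fractions(self):
        anchors = TimestampSet(
            ((0.5, 2.0, "rise_onset"), (0.7, 5.5, "rise_onset"), (1.0, 11.0, "terminus"))
        )
        tf = fit_transfer(anchors, "quadratic")
        f = np.linspace(0.5, 1.0, 100)
        gaps = np.diff(tf(f))
        assert np.all(np.diff(gaps) > -1e-12)  # t'' > 0: spacing increases

    def test_bad_dt_rejected(self):
        prof = _profile({"c": np.ones(100)})
        anchors = TimestampSet(((0.5, 5.0, "rise_onset"), (1.0, 10.0, "terminus")))
        tf = fit_transfer(anchors, "linear")
        with pytest.raises(ValueError):
            warp_to_time(prof, tf, dt=0.0)


class TestRoundTrip:
    """Noise-free simulate → render → full pipeline parameter recovery."""

    @pytest.mark.parametrize("b", [0.5, 0.75, 1.0])
    def test_dye_switch_time_recovered(self, b):
        from tapetrace.pipeline import PipelineParams, run_pipeline
        from tapetrace.scenes import SceneConfig, simulate_scene
        from tapetrace.evaluate import match_to_ground_truth
        from tapetrace.synthfib import RenderConfig

        cfg = SceneConfig(
            render=RenderConfig(shape=(128, 128, 128), read_noise_sd=0.0, photon_scale=0.0),
            n_somata=2, b=b, seed=21,
        )
        res = simulate_scene(cfg)
        out = run_pipeline(res.volume, PipelineParams(
            schedule_times=[5.5], fixation_time=cfg.fixation_time,
            transfer_model="linear" if b == 1.0 else "auto",
        ))
        assert out.readouts, "no fiber decoded"
        matched = match_to_ground_truth(out.centerlines, res.ground_truth)
        duration = cfg.fixation_time
        checked = 0
        from tapetrace.evaluate import anchor_true_times

        for lab, ro in out.readouts.items():
            gtf = res.ground_truth.fibers[matched[lab]]
            for _f, t_true in anchor_true_times(ro, out.centerlines[lab], gtf):
                assert abs(t_true - 5.5) <= 0.02 * duration
                checked += 1
        assert checked >= 2

    def test_half_consistency_noise_free(self):
        """The two warped halves of a fiber describe the same history:
        high correlation per channel, median above 0.95 across the cohort."""
        from tapetrace.pipeline import PipelineParams, run_pipeline
        from tapetrace.scenes import SceneConfig, simulate_scene
        from tapetrace.synthfib import PromoterWaveform, RenderConfig

        wf = {
            "signal": PromoterWaveform(
                baseline=40, amplitude=200, stim_time=6.0, delay=0.1,
                tau_rise=0.25, tau_decay=1.2,
            )
        }
        rs = []
        for seed in (21, 33, 104):
            cfg = SceneConfig(
                render=RenderConfig(
                    shape=(128, 128, 128), read_noise_sd=0.0, photon_scale=0.0
                ),
                n_somata=2, seed=seed, waveforms=wf,
            )
            res = simulate_scene(cfg)
            out = run_pipeline(
                res.volume,
                PipelineParams(schedule_times=[5.5], fixation_time=cfg.fixation_time),
            )
            assert out.readouts
            for ro in out.readouts.values():
                if len(ro.halves) < 2:
                    continue
                t0_, t1_ = ro.halves[0].timeseries, ro.halves[1].timeseries
                lo = max(t0_.time[0], t1_.time[0])
                hi = min(t0_.time[-1], t1_.time[-1])
                grid = np.linspace(lo, hi, 300)
                for ch in ("signal", "dye1", "dye2"):
                    a = np.interp(grid, t0_.time, t0_.channel(ch))
                    b_ = np.interp(grid, t1_.time, t1_.channel(ch))
                    r = np.corrcoef(a, b_)[0, 1]
                    rs.append(r)
                    assert r > 0.85
        assert np.median(rs) > 0.95
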