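"""Forward simulator of protein-tape fibers and their confocal imaging.

A tape fiber nucleates at time ``t0`` inside a cell body and elongates
symmetrically from its nucleation point, so each half-fiber is an arclength
record of time: material at arclength ``s`` from the center was deposited at
the unique time ``t`` with ``s(t) = a * (t - t0) ** b``. Channels written
along the fiber:

* a structural channel at constant level (constitutive monomer),
* timestamp dye channels, piecewise by a dye-switch schedule, smoothed along
  arclength by a Gaussian emulating finite labeling kinetics,
* signal channels whose deposition tracks a promoter-activity waveform
  evaluated at deposition time.

Rendering places each fiber record along a 3D polyline inside a voxel grid
as a tube of constant radius, blurs with an anisotropic Gaussian PSF
(confocal stacks are acquired at 0.4 µm per Z-step by default), and applies
Poisson shot noise plus Gaussian read noise. Every volume ships with a
:class:`GroundTruth` carrying the exact arclength↔time maps so each
downstream stage can be tested by parameter recovery.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter, gaussian_filter1d
from scipy.spatial import cKDTree

from .errors import (
    ConfigurationError,
    InfeasibleGeometryError,
    InvalidModelError,
    OutOfBoundsError,
)
from .volume import ImageVolume

__all__ = [
    "GrowthModel",
    "GrowthTrajectory",
    "PromoterWaveform",
    "DoxPulseWaveform",
    "DyeSchedule",
    "RenderConfig",
    "FiberRecord",
    "FiberGroundTruth",
    "GroundTruth",
    "RenderResult",
    "simulate_growth",
    "compose_fiber_record",
    "generate_centerline_curve",
    "render_volume",
    "apply_noise",
    "photon_scale_for_snr",
]


# ---------------------------------------------------------------------------
# growth kinetics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GrowthModel:
    """Power-law elongation of one half-fiber: ``s(t) = a * (t - t0) ** b``.

    Parameters
    ----------
    t0
        Nucleation time (days).
    a
        Elongation-rate coefficient (µm/day**b, per half-fiber).
    b
        Growth exponent; ``b = 1`` is linear elongation, ``b < 1`` the
        decelerating regime that a quadratic/power transfer function models.
    duration
        Recording span (days) from nucleation to fixation.
    """

    t0: float
    a: float
    b: float = 1.0
    duration: float = 10.0

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise InvalidModelError(f"elongation coefficient a={self.a} must be > 0")
        if not 0 < self.b <= 1:
            raise InvalidModelError(f"growth exponent b={self.b} outside (0, 1]")
        if self.duration <= 0:
            raise InvalidModelError(f"duration={self.duration} must be > 0")

    @property
    def fixation_time(self) -> float:
        return self.t0 + self.duration

    def length_at(self, t):
        """Half-fiber arclength (µm) at time ``t`` (vectorized)."""
        dt = np.maximum(np.asarray(t, dtype=float) - self.t0, 0.0)
        return self.a * dt**self.b

    def time_at(self, s):
        """Inverse map: deposition time of material at half-arclength ``s``."""
        s = np.maximum(np.asarray(s, dtype=float), 0.0)
        return self.t0 + (s / self.a) ** (1.0 / self.b)


@dataclass(frozen=True)
class GrowthTrajectory:
    """Sampled growth curve: strictly increasing time and half-length grids."""

    model: GrowthModel
    t: np.ndarray
    s: np.ndarray

    def time_at(self, s):
        return self.model.time_at(s)

    def length_at(self, t):
        return self.model.length_at(t)


def simulate_growth(model: GrowthModel, n_samples: int = 200) -> GrowthTrajectory:
    """Sample the elongation trajectory on ``n_samples`` uniform times.

    Returns a :class:`GrowthTrajectory` whose inverse map satisfies
    ``time_at(length_at(t)) == t`` to floating-point accuracy on
    ``(t0, t0 + duration]``.
    """
    if n_samples < 2:
        raise InvalidModelError(f"n_samples={n_samples} must be >= 2")
    t = np.linspace(model.t0, model.fixation_time, n_samples)
    return GrowthTrajectory(model, t, model.length_at(t))


# ---------------------------------------------------------------------------
# deposition waveforms and dye schedules
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PromoterWaveform:
    """Bi-exponential promoter-activity pulse (peak-normalized).

    ``A(t) = baseline`` before ``stim_time + delay`` and
    ``A(t) = baseline + amplitude * (exp(-u/tau_decay) - exp(-u/tau_rise)) / peak``
    afterwards (``u`` = time since onset), so the excursion above baseline
    peaks exactly at ``amplitude``. All times in days, intensities in a.u.
    """

    baseline: float
    amplitude: float
    stim_time: float
    delay: float = 0.0
    tau_rise: float = 0.1
    tau_decay: float = 0.5

    def __post_init__(self) -> None:
        if self.baseline < 0 or self.amplitude < 0:
            raise InvalidModelError("baseline and amplitude must be >= 0")
        if not 0 < self.tau_rise < self.tau_decay:
            raise InvalidModelError(
                f"need 0 < tau_rise ({self.tau_rise}) < tau_decay ({self.tau_decay})"
            )

    @property
    def onset_time(self) -> float:
        return self.stim_time + self.delay

    @property
    def peak_time(self) -> float:
        """Time at which the pulse attains ``baseline + amplitude``."""
        tr, td = self.tau_rise, self.tau_decay
        return self.onset_time + tr * td / (td - tr) * np.log(td / tr)

    def _peak_value(self) -> float:
        tr, td = self.tau_rise, self.tau_decay
        u = tr * td / (td - tr) * np.log(td / tr)
        return np.exp(-u / td) - np.exp(-u / tr)

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        u = t - self.onset_time
        shape = np.where(
            u > 0,
            np.exp(-np.maximum(u, 0) / self.tau_decay)
            - np.exp(-np.maximum(u, 0) / self.tau_rise),
            0.0,
        )
        return self.baseline + self.amplitude * shape / self._peak_value()

    @property
    def fwhm_days(self) -> float:
        """Full width at half maximum of the pulse, found numerically."""
        t = np.linspace(self.onset_time, self.onset_time + 20 * self.tau_decay, 20001)
        y = self(t) - self.baseline
        half = 0.5 * y.max()
        above = np.where(y >= half)[0]
        return float(t[above[-1]] - t[above[0]])


@dataclass(frozen=True)
class DoxPulseWaveform:
    """Sustained induction pulse (Tet-On style): rise at ``on_time``,
    plateau, exponential decay after ``off_time``.

    Used to emulate the doxycycline-gated timestamp monomer whose rise
    onset, decay onset and the fiber terminus anchor the in vivo time axis.
    """

    baseline: float
    amplitude: float
    on_time: float
    off_time: float
    tau_rise: float = 0.05
    tau_decay: float = 0.3

    def __post_init__(self) -> None:
        if self.off_time <= self.on_time:
            raise InvalidModelError("off_time must be > on_time")
        if self.tau_rise <= 0 or self.tau_decay <= 0:
            raise InvalidModelError("time constants must be > 0")

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        rise = 1.0 - np.exp(-np.maximum(t - self.on_time, 0.0) / self.tau_rise)
        level_off = 1.0 - np.exp(-(self.off_time - self.on_time) / self.tau_rise)
        decay = level_off * np.exp(-np.maximum(t - self.off_time, 0.0) / self.tau_decay)
        y = np.where(t < self.off_time, np.where(t >= self.on_time, rise, 0.0), decay)
        return self.baseline + self.amplitude * y


@dataclass(frozen=True)
class DyeSchedule:
    """Ordered dye-application events; the first event sets the initial dye.

    ``events`` is a list of ``(switch_time_days, channel_id)``; switch times
    must be strictly increasing and precede ``fixation_time``.
    """

    events: tuple[tuple[float, str], ...]
    fixation_time: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "events", tuple((float(t), str(c)) for t, c in self.events))
        times = [t for t, _ in self.events]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise InvalidModelError(f"switch times {times} not strictly increasing")
        if times and times[-1] >= self.fixation_time:
            raise InvalidModelError("last switch time must precede fixation")

    @property
    def channel_ids(self) -> list[str]:
        return [c for _, c in self.events]

    @property
    def switch_times(self) -> list[float]:
        """Times of detectable dye transitions (2nd dye onward)."""
        return [t for t, _ in self.events[1:]]

    def active_channel(self, t: np.ndarray) -> np.ndarray:
        """Index into ``events`` of the dye active at each time (-1 = none)."""
        t = np.asarray(t, dtype=float)
        idx = np.full(t.shape, -1, dtype=int)
        for i, (start, _) in enumerate(self.events):
            idx[t >= start] = i
        return idx


# ---------------------------------------------------------------------------
# fiber record composition
# ---------------------------------------------------------------------------

@dataclass
class FiberRecord:
    """Per-channel deposition intensity along one half-fiber.

    ``arclength`` runs from 0 (nucleation point / fiber center) to the
    half-length at fixation; the full fiber is this record mirrored about 0.
    """

    arclength: np.ndarray
    channels: dict[str, np.ndarray]
    model: GrowthModel
    fixation_time: float
    schedule: DyeSchedule | None = None

    @property
    def half_length(self) -> float:
        return float(self.arclength[-1])

    @property
    def total_length(self) -> float:
        return 2.0 * self.half_length

    def full_profile(self) -> tuple[np.ndarray, dict[str, np.ndarray]]:
        """Mirror the half record into a full-fiber arclength profile.

        Returns ``(arclength from one terminus, channels)``; the fiber
        center (split point) sits at ``half_length``.
        """
        s = self.arclength
        full_s = np.concatenate([self.half_length - s[::-1][:-1], self.half_length + s])
        chans = {
            name: np.concatenate([v[::-1][:-1], v])
            for name, v in self.channels.items()
        }
        return full_s, chans


def compose_fiber_record(
    trajectory: GrowthTrajectory,
    waveforms: dict[str, PromoterWaveform | DoxPulseWaveform] | None = None,
    schedule: DyeSchedule | None = None,
    structural_level: float = 100.0,
    *,
    ds: float = 0.05,
    dye_smoothing_um: float = 0.3,
    dye_level: float = 100.0,
    structural_channel: str = "structural",
) -> FiberRecord:
    """Deposit channel intensities along one half-fiber.

    Each half's deposition at arclength ``s`` equals the channel activity at
    deposition time ``t(s)``; dye channels are piecewise by the schedule with
    a Gaussian incorporation-lag smoothing of ``dye_smoothing_um`` along
    arclength. Mirror the returned half record for the full fiber.
    """
    waveforms = dict(waveforms or {})
    fixation = schedule.fixation_time if schedule is not None else trajectory.model.fixation_time
    if fixation > trajectory.model.fixation_time + 1e-9:
        raise InvalidModelError(
            f"trajectory spans to {trajectory.model.fixation_time} d but the "
            f"schedule fixes at {fixation} d"
        )
    dye_ids = schedule.channel_ids if schedule is not None else []
    clash = set(waveforms) & (set(dye_ids) | {structural_channel})
    if clash:
        raise ConfigurationError(f"waveform channels collide with dye/structural ids: {clash}")

    half_len = float(trajectory.length_at(fixation))
    n = max(int(np.ceil(half_len / ds)) + 1, 2)
    s = np.linspace(0.0, half_len, n)
    t_dep = trajectory.time_at(s)

    channels: dict[str, np.ndarray] = {structural_channel: np.full(n, float(structural_level))}
    for name, wf in waveforms.items():
        channels[name] = np.asarray(wf(t_dep), dtype=float)

    if schedule is not None:
        active = schedule.active_channel(t_dep)
        sigma_samples = dye_smoothing_um / (s[1] - s[0]) if n > 1 else 0.0
        for i, cid in enumerate(dye_ids):
            indicator = (active == i).astype(float) * dye_level
            if sigma_samples > 0:
                indicator = gaussian_filter1d(indicator, sigma_samples, mode="nearest")
            channels[cid] = channels.get(cid, 0.0) + indicator

    return FiberRecord(s, channels, trajectory.model, fixation, schedule)


# ---------------------------------------------------------------------------
# centerline geometry
# ---------------------------------------------------------------------------

def _rotate_towards(d: np.ndarray, target: np.ndarray, angle: float) -> np.ndarray:
    """Rotate unit vector ``d`` towards ``target`` by at most ``angle``."""
    target = target / np.linalg.norm(target)
    cosang = float(np.clip(d @ target, -1.0, 1.0))
    needed = np.arccos(cosang)
    if needed < 1e-12:
        return d
    theta = min(angle, needed)
    perp = target - cosang * d
    nperp = np.linalg.norm(perp)
    if nperp < 1e-12:  # anti-parallel: pick any perpendicular
        perp = np.cross(d, [1.0, 0.0, 0.0])
        if np.linalg.norm(perp) < 1e-6:
            perp = np.cross(d, [0.0, 1.0, 0.0])
        nperp = np.linalg.norm(perp)
    u = perp / nperp
    out = d * np.cos(theta) + u * np.sin(theta)
    return out / np.linalg.norm(out)


def _random_perp(rng: np.random.Generator, d: np.ndarray) -> np.ndarray:
    v = rng.normal(size=3)
    v -= (v @ d) * d
    n = np.linalg.norm(v)
    if n < 1e-12:
        return _random_perp(rng, d)
    return v / n


def _half_walk(
    rng: np.random.Generator,
    n_steps: int,
    ds: float,
    start_dir: np.ndarray,
    max_curvature: float,
    soma_radius: float,
    wobble: float,
) -> np.ndarray:
    max_turn = max_curvature * ds
    p = np.zeros(3)
    d = start_dir.copy()
    pts = np.empty((n_steps, 3))
    # steering starts within one turning diameter of the boundary
    if max_curvature > 0:
        p_steer = max(0.3 * soma_radius, soma_radius - 2.2 / max_curvature)
    else:
        p_steer = np.inf
    for i in range(n_steps):
        p = p + d * ds
        pts[i] = p
        r = np.linalg.norm(p)
        outward = (d @ p) / r if r > 0 else 0.0
        if r > p_steer and outward > 0:
            d = _rotate_towards(d, -p, max_turn)
        elif max_turn > 0 and i >= 3:
            theta = rng.uniform(0, wobble * max_turn)
            u = _random_perp(rng, d)
            d = d * np.cos(theta) + u * np.sin(theta)
            d /= np.linalg.norm(d)
    return pts


def generate_centerline_curve(
    total_length: float,
    max_curvature: float,
    soma_radius: float,
    seed: int,
    *,
    center: tuple[float, float, float] = (0.0, 0.0, 0.0),
    ds: float = 0.1,
    wobble: float = 0.5,
) -> np.ndarray:
    """Random smooth 3D polyline of given arclength, curvature-bounded and
    confined within ``soma_radius`` of ``center``.

    The curve is built as two half-walks from the center point (the
    nucleation site of a bidirectionally growing fiber) in opposite initial
    directions, each taking fixed ``ds`` steps whose turn angle never exceeds
    ``max_curvature * ds``. Near the boundary the walk steers back towards
    the center at full curvature.

    Returns an ``(N, 3)`` array of ``(z, y, x)`` points in µm whose arclength
    midpoint is the center point.
    """
    if total_length <= 0:
        raise InvalidModelError(f"total_length={total_length} must be > 0")
    if max_curvature < 0:
        raise InvalidModelError("max_curvature must be >= 0")
    if total_length / 2 > soma_radius and max_curvature * soma_radius < 2.5:
        raise InfeasibleGeometryError(
            f"a fiber of length {total_length} µm cannot fold inside a "
            f"{soma_radius} µm soma at max curvature {max_curvature} µm^-1"
        )
    rng = np.random.default_rng(seed)
    d0 = rng.normal(size=3)
    d0 /= np.linalg.norm(d0)
    n_half = max(int(round(total_length / 2 / ds)), 1)
    half1 = _half_walk(rng, n_half, ds, d0, max_curvature, soma_radius, wobble)
    half2 = _half_walk(rng, n_half, ds, -d0, max_curvature, soma_radius, wobble)
    pts = np.concatenate([half1[::-1], np.zeros((1, 3)), half2], axis=0)
    return pts + np.asarray(center, dtype=float)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RenderConfig:
    """Confocal forward-model parameters.

    ``voxel_spacing`` is ``(dz, dy, dx)`` in µm with dz = 0.4 µm by default
    (the acquisition Z-step); ``psf_sigma`` the anisotropic Gaussian PSF;
    intensities in arbitrary units. ``photon_scale`` converts intensity to
    expected photon counts for the Poisson shot-noise stage (0 disables it).
    """

    shape: tuple[int, int, int] = (128, 128, 128)
    voxel_spacing: tuple[float, float, float] = (0.4, 0.25, 0.25)
    psf_sigma: tuple[float, float, float] = (0.6, 0.2, 0.2)
    fiber_radius: float = 0.3
    background: float = 20.0
    read_noise_sd: float = 2.0
    photon_scale: float = 1.0
    soma_radius: float = 10.0
    soma_level: float = 80.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.voxel_spacing):
            raise InvalidModelError("voxel spacings must be > 0")


@dataclass
class FiberGroundTruth:
    """Exact per-fiber bookkeeping for parameter-recovery tests."""

    fiber_id: int
    polyline: np.ndarray                    # (N, 3) µm, center at arclength midpoint
    record: FiberRecord
    cell_label: int                         # owning soma (1-based), 0 = none

    @property
    def half_length(self) -> float:
        return self.record.half_length

    @property
    def split_arclength(self) -> float:
        """Arclength of the nucleation point measured from one terminus."""
        return self.record.half_length

    @property
    def dye_switch_arclengths(self) -> list[float]:
        """Half-arclength positions of each dye transition, s(switch)."""
        if self.record.schedule is None:
            return []
        return [float(self.record.model.length_at(t)) for t in self.record.schedule.switch_times]

    def time_at_half_arclength(self, s):
        return self.record.model.time_at(s)


@dataclass
class GroundTruth:
    """Scene-level truth: fibers, somata, schedule."""

    fibers: list[FiberGroundTruth]
    somata: list[tuple[tuple[float, float, float], float]]

    def to_json(self, path: str | Path) -> None:
        out = {
            "somata": [{"center": list(c), "radius": r} for c, r in self.somata],
            "fibers": [
                {
                    "fiber_id": f.fiber_id,
                    "cell_label": f.cell_label,
                    "half_length_um": f.half_length,
                    "growth": {
                        "t0": f.record.model.t0,
                        "a": f.record.model.a,
                        "b": f.record.model.b,
                        "duration": f.record.model.duration,
                    },
                    "fixation_time": f.record.fixation_time,
                    "dye_switch_times": (
                        f.record.schedule.switch_times if f.record.schedule else []
                    ),
                    "dye_switch_arclengths_um": f.dye_switch_arclengths,
                }
                for f in self.fibers
            ],
        }
        Path(path).write_text(json.dumps(out, indent=2))

    def fiber_table(self, fiber_id: int) -> pd.DataFrame:
        """Per-fiber CSV payload: arclength, deposition time, channels."""
        f = self.fibers[fiber_id]
        rec = f.record
        df = pd.DataFrame({"arclength_um": rec.arclength})
        df["time_days"] = rec.model.time_at(rec.arclength)
        for name, vals in rec.channels.items():
            df[name] = vals
        return df


@dataclass
class RenderResult:
    volume: ImageVolume
    noise_free: ImageVolume
    ground_truth: GroundTruth


def _polyline_arclength(pts: np.ndarray) -> np.ndarray:
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def _resample_polyline(pts: np.ndarray, n: int) -> np.ndarray:
    arc = _polyline_arclength(pts)
    grid = np.linspace(0, arc[-1], n)
    return np.column_stack([np.interp(grid, arc, pts[:, k]) for k in range(3)])


def photon_scale_for_snr(
    peak_above_bg: float, background: float, read_noise_sd: float, snr: float
) -> float:
    """Photon scale giving ``peak / noise_sd = snr`` at the fiber peak."""
    var_needed = (peak_above_bg / snr) ** 2 - read_noise_sd**2
    if var_needed <= 0:
        raise InvalidModelError(
            f"target SNR {snr} unreachable: read noise alone exceeds it"
        )
    return (peak_above_bg + background) / var_needed


def apply_noise(
    noise_free: ImageVolume, config: RenderConfig, seed: int | None = None
) -> ImageVolume:
    """Poisson(photon_scale * I) / photon_scale + Gaussian read noise."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    data = noise_free.data.astype(float)
    if config.photon_scale > 0:
        data = rng.poisson(np.maximum(data, 0) * config.photon_scale) / config.photon_scale
    if config.read_noise_sd > 0:
        data = data + rng.normal(0, config.read_noise_sd, size=data.shape)
    return ImageVolume(data.astype(np.float32), noise_free.spacing, list(noise_free.channel_names))


def render_volume(
    fibers: list[tuple[FiberRecord, np.ndarray]],
    somata: list[tuple[tuple[float, float, float], float]],
    config: RenderConfig,
    *,
    noise: bool = True,
    nissl_channel: str = "nissl",
) -> RenderResult:
    """Rasterize fiber records along polylines into a noisy confocal volume.

    Each fiber is a solid tube of radius ``config.fiber_radius`` whose local
    intensity follows the (mirrored) record, blurred by the PSF. The
    noise-free intermediate is a pure function of the inputs; shot/read
    noise is applied with ``config.seed``.
    """
    spacing = np.asarray(config.voxel_spacing)
    shape = tuple(config.shape)
    margin = 3 * np.asarray(config.psf_sigma)
    hi = (np.asarray(shape) - 1) * spacing

    channel_names: list[str] = []
    for rec, _ in fibers:
        for name in rec.channels:
            if name not in channel_names:
                channel_names.append(name)
    channel_names.append(nissl_channel)
    vols = {name: np.zeros(shape, dtype=float) for name in channel_names}

    gt_fibers: list[FiberGroundTruth] = []
    dense_step = float(spacing.min()) / 2.0
    edge = float(spacing.min()) / 2.0

    for fid, (rec, polyline) in enumerate(fibers):
        polyline = np.asarray(polyline, dtype=float)
        if (polyline < margin).any() or (polyline > hi - margin).any():
            raise OutOfBoundsError(
                f"fiber {fid} leaves the volume (needs a 3*psf_sigma margin)"
            )
        full_s, chans = rec.full_profile()
        n_dense = max(int(np.ceil(full_s[-1] / dense_step)) + 1, 2)
        dense = _resample_polyline(polyline, n_dense)
        dense_arc = np.linspace(0, _polyline_arclength(polyline)[-1], n_dense)
        # map record arclength onto the polyline by fractional position
        frac = dense_arc / dense_arc[-1] if dense_arc[-1] > 0 else dense_arc
        rec_arc = frac * full_s[-1]
        dense_vals = {
            name: np.interp(rec_arc, full_s, v) for name, v in chans.items()
        }

        lo_box = np.maximum(dense.min(axis=0) - config.fiber_radius - 3 * np.asarray(config.psf_sigma), 0)
        hi_box = np.minimum(dense.max(axis=0) + config.fiber_radius + 3 * np.asarray(config.psf_sigma), hi)
        lo_idx = np.floor(lo_box / spacing).astype(int)
        hi_idx = np.ceil(hi_box / spacing).astype(int) + 1
        grids = [np.arange(lo_idx[k], min(hi_idx[k], shape[k])) * spacing[k] for k in range(3)]
        zz, yy, xx = np.meshgrid(*grids, indexing="ij")
        coords = np.column_stack([zz.ravel(), yy.ravel(), xx.ravel()])
        tree = cKDTree(dense)
        dist, idx = tree.query(coords, workers=-1)
        occupancy = np.clip((config.fiber_radius - dist) / edge + 0.5, 0.0, 1.0)
        sel = occupancy > 0
        box = tuple(
            slice(lo_idx[k], lo_idx[k] + len(grids[k])) for k in range(3)
        )
        for name, dv in dense_vals.items():
            contrib = np.zeros(len(coords))
            contrib[sel] = dv[idx[sel]] * occupancy[sel]
            vols[name][box] += contrib.reshape(zz.shape)

        mid = polyline[len(polyline) // 2]
        cell = 0
        for si, (c, r) in enumerate(somata):
            if np.linalg.norm(mid - np.asarray(c)) <= r:
                cell = si + 1
                break
        gt_fibers.append(FiberGroundTruth(fid, polyline, rec, cell))

    # soma (Nissl) channel: solid spheres
    for c, r in somata:
        c = np.asarray(c, dtype=float)
        lo_idx = np.maximum(np.floor((c - r - margin) / spacing).astype(int), 0)
        hi_idx = np.minimum(np.ceil((c + r + margin) / spacing).astype(int) + 1, shape)
        grids = [np.arange(lo_idx[k], hi_idx[k]) * spacing[k] for k in range(3)]
        zz, yy, xx = np.meshgrid(*grids, indexing="ij")
        dist = np.sqrt((zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2)
        occ = np.clip((r - dist) / edge + 0.5, 0.0, 1.0)
        box = tuple(slice(lo_idx[k], hi_idx[k]) for k in range(3))
        vols[nissl_channel][box] += config.soma_level * occ

    sigma_vox = np.asarray(config.psf_sigma) / spacing
    data = np.stack(
        [gaussian_filter(vols[name], sigma_vox) + config.background for name in channel_names]
    )
    noise_free = ImageVolume(data.astype(np.float32), tuple(spacing), channel_names)
    noisy = apply_noise(noise_free, config) if noise else noise_free
    gt = GroundTruth(gt_fibers, [(tuple(np.asarray(c, float)), float(r)) for c, r in somata])
    return RenderResult(noisy, noise_free, gt)
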