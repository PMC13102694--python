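"""Per-channel intensity profiles along fiber centerlines.

Two samplers: plain trilinear interpolation at each centerline point (the
high-throughput route), and cylindrical averaging over discs perpendicular
to the local tangent at 0.06 µm intervals (the cultured-cell route, more
robust to centerline jitter for thick fibers).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates

from .errors import OutOfBoundsError
from .volume import ImageVolume

__all__ = [
    "FiberProfile",
    "trilinear_sample",
    "sample_trilinear",
    "sample_cylindrical",
]


@dataclass
class FiberProfile:
    """Intensity vs arclength for every imaging channel of one fiber.

    All channel sequences share the arclength grid. ``step`` is the mean
    grid spacing (µm). Intensities are raw (a.u.) until baseline
    normalization turns them into relative changes.
    """

    arclength: np.ndarray
    channels: dict[str, np.ndarray]
    sampling: str = "trilinear"
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.arclength = np.asarray(self.arclength, dtype=float)
        n = len(self.arclength)
        for name, v in self.channels.items():
            v = np.asarray(v, dtype=float)
            if len(v) != n:
                raise ValueError(
                    f"channel {name!r} has {len(v)} samples, grid has {n}"
                )
            self.channels[name] = v

    @property
    def n_samples(self) -> int:
        return len(self.arclength)

    @property
    def length(self) -> float:
        return float(self.arclength[-1] - self.arclength[0])

    @property
    def step(self) -> float:
        return self.length / (self.n_samples - 1)

    def channel(self, name: str) -> np.ndarray:
        return self.channels[name]


def trilinear_sample(
    arr: np.ndarray,
    spacing,
    points: np.ndarray,
    *,
    oob: str = "clamp",
) -> np.ndarray:
    """Trilinear interpolation of a ``(z, y, x)`` array at physical points.

    ``points`` is ``(n, 3)`` in µm; voxel centers sit at ``index * spacing``.
    Out-of-bounds points are boundary-clamped (``oob='clamp'``) or raise
    (``oob='error'``).
    """
    arr = np.asarray(arr, dtype=float)
    spacing = np.asarray(spacing, dtype=float)
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    idx = pts / spacing
    upper = np.array(arr.shape) - 1
    if oob == "error" and ((idx < 0).any() or (idx > upper).any()):
        raise OutOfBoundsError("sample point outside volume bounds")
    return map_coordinates(arr, idx.T, order=1, mode="nearest")


def _points_out_of_bounds(shape, spacing, points) -> bool:
    idx = np.atleast_2d(points) / np.asarray(spacing, dtype=float)
    return bool((idx < 0).any() or (idx > np.array(shape) - 1).any())


def sample_trilinear(
    volume: ImageVolume,
    cl,
    *,
    oob: str = "clamp",
) -> FiberProfile:
    """Sample every channel at each centerline point by trilinear
    interpolation in physical coordinates."""
    flags = []
    if _points_out_of_bounds(volume.shape, volume.spacing, cl.points):
        if oob == "error":
            raise OutOfBoundsError("centerline leaves the volume")
        flags.append("clamped_out_of_bounds")
    channels = {
        name: trilinear_sample(volume.channel(name), volume.spacing, cl.points)
        for name in volume.channel_names
    }
    return FiberProfile(cl.arclength.copy(), channels, "trilinear", flags)


def _disc_lattice(radius: float, n_rings: int) -> tuple[np.ndarray, np.ndarray]:
    """Sub-sampling lattice over a disc: ``n_rings`` equal-area annuli
    sampled at their mid-area radii with ``6k`` points on ring ``k``.

    Returns (offsets2d (m, 2), weights (m,)); weights sum to 1. Midpoint
    quadrature in r² makes disc means of smooth radial fields accurate to
    well under 1% with the default 3 rings (36 points).
    """
    offs, wts = [], []
    for k in range(1, n_rings + 1):
        r = radius * np.sqrt((2 * k - 1) / (2 * n_rings))
        m = 6 * k
        ang = 2 * np.pi * (np.arange(m) + 0.5 * (k % 2)) / m
        offs.append(np.column_stack([r * np.cos(ang), r * np.sin(ang)]))
        wts.append(np.full(m, 1.0 / (n_rings * m)))
    return np.concatenate(offs), np.concatenate(wts)


def sample_cylindrical(
    volume: ImageVolume,
    cl,
    radius: float,
    *,
    step: float = 0.06,
    n_rings: int = 3,
    oob: str = "clamp",
) -> FiberProfile:
    """Mean intensity over discs perpendicular to the centerline tangent.

    The centerline is resampled at ``step`` (default 0.06 µm) intervals;
    at each position the channels are averaged over a fixed disc lattice of
    the given radius oriented perpendicular to the local direction vector.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    res = cl.resample(max(int(round(cl.length / step)) + 1, 2))
    pts = res.points
    tang = np.gradient(pts, axis=0)
    tang /= np.linalg.norm(tang, axis=1, keepdims=True)
    # deterministic perpendicular frame per point
    ref = np.zeros_like(tang)
    ref[np.arange(len(tang)), np.argmin(np.abs(tang), axis=1)] = 1.0
    u = np.cross(tang, ref)
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    v = np.cross(tang, u)

    offs, wts = _disc_lattice(radius, n_rings)
    # (n_pts, n_lattice, 3)
    lattice = (
        pts[:, None, :]
        + offs[None, :, 0, None] * u[:, None, :]
        + offs[None, :, 1, None] * v[:, None, :]
    )
    flat = lattice.reshape(-1, 3)
    flags = []
    if _points_out_of_bounds(volume.shape, volume.spacing, flat):
        if oob == "error":
            raise OutOfBoundsError("cylindrical sampling region leaves the volume")
        flags.append("clamped_out_of_bounds")
    channels = {}
    for name in volume.channel_names:
        vals = trilinear_sample(volume.channel(name), volume.spacing, flat)
        vals = vals.reshape(len(pts), len(offs))
        channels[name] = vals @ wts
    return FiberProfile(res.arclength.copy(), channels, "cylindrical", flags)
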