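"""Centerline extraction and fiber geometry.

Two extraction routes are offered, mirroring how fiber-like and more
contorted shapes need different treatment:

* ``pca_spline`` — the fiber mask's voxel cloud is projected on its first
  principal axis, trimmed to the central 80% by projection quantile, and a
  smoothing cubic spline is fitted coordinate-wise against the projection
  parameter. Suited to fibers whose PC1 explained variance is high.
* ``morph_skeleton`` — 3D morphological thinning followed by the longest
  geodesic path through the skeleton voxel graph. Fallback for geometries
  the PCA parameterization cannot order (explained variance < 0.8).

Both are resampled to ``n_points`` (default 1,000) equidistant points.
Because the spline route only covers the central 80%, and segmentation
erodes dim fiber tips, centerlines are extrapolated along their end
tangents by up to 20% of the geodesic length until a local minimum of the
structural-monomer channel marks the true terminus.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.interpolate import splev, splprep
from scipy.ndimage import distance_transform_edt
from skimage.morphology import skeletonize

from .errors import UndefinedGeometryError
from .profiles import _disc_lattice, trilinear_sample
from .volume import ImageVolume

__all__ = [
    "Centerline",
    "GeometrySummary",
    "extract_centerline",
    "extrapolate_centerline",
    "recenter_centerline",
    "fiber_geometry",
]


@dataclass
class Centerline:
    """Ordered 3D point sequence (µm) along a fiber.

    ``arclength`` is cumulative from the first point; after resampling,
    consecutive spacing is uniform to within 1%.
    """

    points: np.ndarray
    method: str = "pca_spline"
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.shape[0] < 2 or self.points.shape[1] != 3:
            raise UndefinedGeometryError(
                f"centerline needs >= 2 points of dim 3, got {self.points.shape}"
            )

    @property
    def n_points(self) -> int:
        return len(self.points)

    @property
    def arclength(self) -> np.ndarray:
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(seg)])

    @property
    def length(self) -> float:
        """Geodesic length (µm)."""
        return float(self.arclength[-1])

    @property
    def step(self) -> float:
        """Mean sampling interval (µm)."""
        return self.length / (self.n_points - 1)

    def resample(self, n_points: int = 1000) -> "Centerline":
        """Resample to ``n_points`` equidistant in arclength."""
        arc = self.arclength
        grid = np.linspace(0.0, arc[-1], n_points)
        pts = np.column_stack(
            [np.interp(grid, arc, self.points[:, k]) for k in range(3)]
        )
        return Centerline(pts, self.method, list(self.flags))

    def reversed(self) -> "Centerline":
        return Centerline(self.points[::-1].copy(), self.method, list(self.flags))


@dataclass(frozen=True)
class GeometrySummary:
    """Morphological descriptors of one fiber."""

    geodesic_length: float   # µm
    mean_width: float        # µm
    max_curvature: float     # µm^-1


# ---------------------------------------------------------------------------
# extraction
# ---------------------------------------------------------------------------

def _pca_axes(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    centered = coords - coords.mean(axis=0)
    cov = centered.T @ centered / len(coords)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    return evals[order], evecs[:, order]


def _pca_spline_centerline(
    coords: np.ndarray,
    voxel_diag: float,
    n_points: int,
    trim_frac: float,
    smoothing: float | None,
) -> Centerline:
    _, axes = _pca_axes(coords)
    u_all = (coords - coords.mean(axis=0)) @ axes[:, 0]
    # the spline is *fitted* through the central 80% of points (end voxels
    # bias the fit) but the centerline must still span the whole mask
    u_lo_full, u_hi_full = np.quantile(u_all, [0.002, 0.998])
    lo, hi = np.quantile(u_all, [trim_frac / 2, 1 - trim_frac / 2])
    keep = (u_all >= lo) & (u_all <= hi)
    u, coords = u_all[keep], coords[keep]
    order = np.argsort(u)
    u, coords = u[order], coords[order]

    # collapse voxels sharing a projection bin so the spline gets an
    # ordered, strictly increasing parameterization
    bin_w = max(voxel_diag / 2, (u[-1] - u[0]) / 400)
    bins = np.floor((u - u[0]) / bin_w).astype(int)
    uniq, inv = np.unique(bins, return_inverse=True)
    sums = np.zeros((len(uniq), 3))
    np.add.at(sums, inv, coords)
    counts = np.bincount(inv).astype(float)
    means = sums / counts[:, None]
    u_mean = np.bincount(inv, weights=u) / counts

    if len(uniq) < 4:
        return Centerline(means, "pca_spline").resample(n_points)
    if smoothing is None:
        # target residual about half the voxel diagonal
        smoothing = len(uniq) * (0.5 * voxel_diag) ** 2
    tck, _ = splprep(means.T, u=u_mean, s=smoothing, k=3)
    dense_u = np.linspace(u_mean[0], u_mean[-1], max(4 * n_points, 200))
    dense = np.column_stack(splev(dense_u, tck))
    dense = _extend_linear(dense, u_mean[0] - u_lo_full, u_hi_full - u_mean[-1])
    return Centerline(dense, "pca_spline").resample(n_points)


def _extend_linear(dense: np.ndarray, ext_start: float, ext_end: float) -> np.ndarray:
    """Linearly extend a dense polyline along its end tangents."""
    step = np.linalg.norm(np.diff(dense, axis=0), axis=1).mean()
    out = [dense]
    if ext_end > step:
        tang = dense[-1] - dense[-4]
        tang /= np.linalg.norm(tang)
        n = int(round(ext_end / step))
        out.append(dense[-1] + np.outer(np.linspace(ext_end / n, ext_end, n), tang))
    if ext_start > step:
        tang = dense[0] - dense[3]
        tang /= np.linalg.norm(tang)
        n = int(round(ext_start / step))
        pre = dense[0] + np.outer(np.linspace(ext_start / n, ext_start, n), tang)
        out.insert(0, pre[::-1])
    return np.vstack(out)


def _morph_skeleton_centerline(
    mask: np.ndarray,
    spacing: np.ndarray,
    n_points: int,
) -> Centerline:
    skel = skeletonize(mask)
    vox = np.argwhere(skel)
    if len(vox) < 2:
        vox = np.argwhere(mask)
    index = {tuple(v): i for i, v in enumerate(vox)}
    g = nx.Graph()
    g.add_nodes_from(range(len(vox)))
    offsets = np.array(
        [(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)]
    )
    offsets = offsets[np.any(offsets != 0, axis=1)]
    for i, v in enumerate(vox):
        for off in offsets:
            j = index.get(tuple(v + off))
            if j is not None and j > i:
                g.add_edge(i, j, weight=float(np.linalg.norm(off * spacing)))
    flags = []
    comps = list(nx.connected_components(g))
    comp = max(comps, key=len)
    if len(comps) > 1:
        flags.append("fragmented_skeleton")
    sub = g.subgraph(comp)
    endpoints = [n for n in sub.nodes if sub.degree(n) <= 1]
    if len(endpoints) > 2:
        flags.append("branched")
    # double-sweep longest geodesic path
    start = next(iter(sub.nodes))
    d1 = nx.single_source_dijkstra_path_length(sub, start)
    far1 = max(d1, key=d1.get)
    d2, paths = nx.single_source_dijkstra(sub, far1)
    far2 = max(d2, key=d2.get)
    path = paths[far2]
    pts = vox[path] * spacing
    if len(pts) < 2:
        raise UndefinedGeometryError("skeleton collapsed to a single voxel")
    if len(pts) >= 8:
        # smoothing spline along the chord parameter kills the voxel
        # staircase, which otherwise inflates arclength by ~5-10%
        u = np.concatenate(
            [[0.0], np.cumsum(np.linalg.norm(np.diff(pts, axis=0), axis=1))]
        )
        keep = np.concatenate([[True], np.diff(u) > 1e-9])
        u, pts = u[keep], pts[keep]
        voxel_diag = float(np.linalg.norm(spacing))
        tck, _ = splprep(pts.T, u=u, s=len(pts) * (0.5 * voxel_diag) ** 2, k=3)
        pts = np.column_stack(splev(np.linspace(0, u[-1], max(4 * n_points, 200)), tck))
    return Centerline(pts, "morph_skeleton", flags).resample(n_points)


def extract_centerline(
    mask: np.ndarray,
    spacing: tuple[float, float, float],
    method: str = "pca_spline",
    *,
    n_points: int = 1000,
    trim_frac: float = 0.2,
    smoothing: float | None = None,
) -> Centerline:
    """Extract the centerline of a single-fiber boolean mask.

    Parameters
    ----------
    mask
        Boolean ``(z, y, x)`` array of one fiber (>= 20 voxels).
    spacing
        Voxel spacing ``(dz, dy, dx)`` µm.
    method
        ``pca_spline``, ``morph_skeleton``, or ``auto`` (PCA route when the
        voxel cloud's PC1 explained variance is >= 0.8, thinning otherwise).
    trim_frac
        Total fraction trimmed off the projection ends in the PCA route
        (0.2 keeps the central 80%).
    """
    mask = np.asarray(mask, dtype=bool)
    spacing = np.asarray(spacing, dtype=float)
    coords = np.argwhere(mask) * spacing
    if len(coords) < 20:
        raise UndefinedGeometryError(
            f"fiber mask has {len(coords)} voxels; need >= 20"
        )
    if method == "auto":
        evals, _ = _pca_axes(coords)
        ev1 = evals[0] / evals.sum() if evals.sum() > 0 else 0.0
        method = "pca_spline" if ev1 >= 0.8 else "morph_skeleton"
    voxel_diag = float(np.linalg.norm(spacing))
    if method == "pca_spline":
        return _pca_spline_centerline(coords, voxel_diag, n_points, trim_frac, smoothing)
    if method == "morph_skeleton":
        return _morph_skeleton_centerline(mask, spacing, n_points)
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# extrapolation to fiber termini
# ---------------------------------------------------------------------------

def _moving_average(y: np.ndarray, w: int) -> np.ndarray:
    if w <= 1 or len(y) < 3:
        return y
    w = min(w if w % 2 == 1 else w + 1, len(y) - (1 - len(y) % 2))
    pad = w // 2
    ypad = np.pad(y, pad, mode="edge")
    return np.convolve(ypad, np.ones(w) / w, mode="valid")


def _adjust_one_end(
    end_pts: np.ndarray,
    volume: np.ndarray,
    spacing: np.ndarray,
    cap: float,
    step: float,
    min_window_um: float,
    ref_level: float,
) -> tuple[int, np.ndarray, list[str]]:
    """Locate the true terminus beyond (or before) ``end_pts[-1]``.

    Returns ``(n_retract, extension_points, flags)``: either drop the last
    ``n_retract`` existing points (the mask over-ran into the PSF halo) or
    append the extension points.
    """
    flags: list[str] = []
    tangent = end_pts[-1] - end_pts[max(0, len(end_pts) - 4)]
    norm = np.linalg.norm(tangent)
    if norm < 1e-12:
        return 0, np.empty((0, 3)), ["degenerate_tangent"]
    tangent /= norm
    n_ext = max(int(round(cap / step)), 1)
    dists = np.linspace(cap / n_ext, cap, n_ext)
    cand = end_pts[-1] + dists[:, None] * tangent
    extent = (np.array(volume.shape) - 1) * spacing
    inside = np.all((cand >= 0) & (cand <= extent), axis=1)
    truncated = not inside.all()
    if truncated:
        cand = cand[: int(np.argmin(inside))]
        flags.append("truncated_at_boundary")
    # sample an inner stretch of the centerline plus the extension ray so
    # the terminus can move in either direction
    n_tail = min(max(int(round(cap / step)), 2), len(end_pts) - 2)
    tail = end_pts[-n_tail:]
    prof = trilinear_sample(volume, spacing, np.vstack([tail, cand]))
    w = max(int(round(min_window_um / step)), 1)
    sm = _moving_average(prof, w)
    i_end = n_tail - 1  # index of the current end in the sampled line

    # candidate stops in the outward (extension) region:
    # (1) first strict local minimum of the smoothed profile that is a
    # genuine inter-structure trough: below 60% of the fiber contrast AND
    # followed by a rebound. Noise dips on the monotone edge slope of a
    # terminus decay to background without rebounding and must not stop
    # the search early.
    stop_min = None
    stride = max(w // 2, 1)
    tol = 1e-3 * float(np.ptp(sm)) + 1e-12  # ignore float/interp jitter
    lo_all = float(np.percentile(sm, 5))
    # reference level local to this end: the anisotropic PSF modulates tube
    # brightness with orientation, so the global median would misplace the
    # edge of a dim (axially running) tip. The inner half of the sampled
    # tail shares the tip's orientation and is safely on-fiber.
    hi_local = float(np.percentile(sm[: max(i_end // 2, 2)], 80))
    hi_all = max(hi_local, float(sm[0]))
    if hi_all - lo_all < 0.1 * max(ref_level - lo_all, 1e-12):
        hi_all = ref_level  # end sits in halo/background: fall back
    contrast = hi_all - lo_all
    trough_lvl = lo_all + 0.6 * contrast
    for i in range(max(i_end + 1, stride), len(sm) - stride):
        if (
            sm[i] < sm[i - stride] - tol
            and sm[i] < sm[i + stride] - tol
            and sm[i] < trough_lvl
        ):
            ahead = sm[i : min(i + 8 * stride, len(sm))]
            if ahead.max() >= sm[i] + 0.2 * contrast:
                stop_min = i
                break
    # (2) edge crossing: the structural level falls below 40% of the
    # fiber-interior contrast above the floor — near the mid-edge of a
    # PSF-blurred tube end (kept below 50% so segments dimmed by the
    # anisotropic PSF's orientation dependence are not clipped). Searched
    # from inside the fiber, so an end already below the threshold (halo
    # over-run) retracts.
    stop_cross = None
    stop_rise = None
    lo, hi = lo_all, hi_all
    if hi - lo > 0.1 * max(hi, 1e-12):
        # sustained crossing: the point after which even the best remaining
        # value stays below the edge level — transient noise dips (which
        # recover) cannot trigger it
        suffix_max = np.maximum.accumulate(sm[::-1])[::-1]
        below = np.where(suffix_max < lo + 0.4 * (hi - lo))[0]
        if len(below):
            stop_cross = int(below[0])
        # (3) a rise well above the fiber level: the ray entered another
        # (or a folded-back) structure; stop before absorbing its record
        above = np.where(sm[i_end + 1 :] > hi + 0.5 * (hi - lo))[0]
        if len(above):
            stop_rise = i_end + 1 + int(above[0])
    stops = [s for s in (stop_min, stop_cross, stop_rise) if s is not None]
    if not stops:
        if not truncated:
            flags.append("no_minimum")
        return 0, cand, flags
    stop = min(stops)
    if stop <= i_end:  # retract: halo over-run
        flags.append("retracted")
        return i_end - stop, np.empty((0, 3)), flags
    return 0, cand[: stop - i_end], flags


def extrapolate_centerline(
    cl: Centerline,
    structure_channel: ImageVolume | np.ndarray,
    *,
    spacing: tuple[float, float, float] | None = None,
    structural_name: str = "structural",
    cap_frac: float = 0.2,
    step: float | None = None,
    min_window_um: float = 0.5,
    smooth_window_um: float = 0.8,
) -> Centerline:
    """Extend a centerline along its end tangents to the fiber termini.

    The centerline is first recentered onto the intensity ridge (off-axis
    ends would misdirect the tangent rays). Extension then proceeds in
    steps of the sampling interval, sampling the structural-monomer channel
    by trilinear interpolation, and stops at the first genuine local
    minimum of the 0.5 µm moving-averaged profile, at the sustained
    edge crossing marking a tube end, or at ``cap_frac`` of the geodesic
    length per side, whichever comes first. Ends sitting in the PSF halo
    retract instead.
    """
    if cap_frac <= 0:
        return Centerline(cl.points.copy(), cl.method, list(cl.flags))
    if isinstance(structure_channel, ImageVolume):
        volume = structure_channel.channel(structural_name)
        spc = np.asarray(structure_channel.spacing)
    else:
        if spacing is None:
            raise ValueError("spacing required when passing a bare array")
        volume = np.asarray(structure_channel)
        spc = np.asarray(spacing, dtype=float)

    cl = recenter_centerline(cl, volume, spc)
    # recentering tracks shot noise transversely; fibers are smooth at the
    # sub-µm scale, and the residual wiggle would inflate arclength
    cl = _smooth_polyline(cl, window_um=smooth_window_um)
    cap = cap_frac * cl.length
    h = step if step is not None else cl.step
    n = cl.n_points
    interior = cl.points[n // 5 : -n // 5 or None]
    ref_level = float(np.median(trilinear_sample(volume, spc, interior)))
    pts, f_tail = _fit_terminus(cl.points, volume, spc, cap, h, min_window_um, ref_level)
    pts, f_head = _fit_terminus(pts[::-1], volume, spc, cap, h, min_window_um, ref_level)
    pts = pts[::-1]
    flags = list(dict.fromkeys(cl.flags + f_head + f_tail))
    return Centerline(pts, cl.method, flags).resample(cl.n_points)


def recenter_centerline(
    cl: Centerline,
    volume: np.ndarray,
    spacing,
    *,
    search_radius_um: float = 0.5,
    iterations: int = 2,
    max_shift_um: float = 0.3,
) -> Centerline:
    """Snap centerline points onto the local intensity ridge.

    Each point moves towards the structure-channel intensity centroid of a
    small disc perpendicular to the local tangent; with a symmetric PSF the
    centroid sits on the tube axis. Corrects the off-axis drift that voxel
    skeletons and PCA-spline ends accumulate, which would otherwise
    misplace the terminus search.
    """
    spc = np.asarray(spacing, dtype=float)
    offs, wts = _disc_lattice(search_radius_um, 2)
    offs = np.vstack([[0.0, 0.0], offs])
    wts = np.concatenate([[wts.max()], wts])
    pts = cl.points.copy()
    for _ in range(iterations):
        tang = np.gradient(pts, axis=0)
        tang /= np.linalg.norm(tang, axis=1, keepdims=True)
        ref = np.zeros_like(tang)
        ref[np.arange(len(tang)), np.argmin(np.abs(tang), axis=1)] = 1.0
        u = np.cross(tang, ref)
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        v = np.cross(tang, u)
        lattice = (
            pts[:, None, :]
            + offs[None, :, 0, None] * u[:, None, :]
            + offs[None, :, 1, None] * v[:, None, :]
        )
        vals = trilinear_sample(volume, spc, lattice.reshape(-1, 3)).reshape(
            len(pts), len(offs)
        )
        floor = np.percentile(vals, 10)
        w = np.clip(vals - floor, 0.0, None) * wts[None, :]
        wsum = w.sum(axis=1, keepdims=True)
        ok = wsum[:, 0] > 1e-12
        cx = np.zeros(len(pts))
        cy = np.zeros(len(pts))
        cx[ok] = (w[ok] @ offs[:, 0]) / wsum[ok, 0]
        cy[ok] = (w[ok] @ offs[:, 1]) / wsum[ok, 0]
        shift = cx[:, None] * u + cy[:, None] * v
        norm = np.linalg.norm(shift, axis=1, keepdims=True)
        scale = np.minimum(1.0, max_shift_um / np.maximum(norm, 1e-12))
        pts = pts + shift * scale
    return Centerline(pts, cl.method, list(cl.flags))


def _fit_terminus(
    pts: np.ndarray,
    volume: np.ndarray,
    spacing: np.ndarray,
    cap: float,
    step: float,
    min_window_um: float,
    ref_level: float,
) -> tuple[np.ndarray, list[str]]:
    """Iterate retract/extend on the last point of ``pts`` until the
    terminus settles (a retracted end gets a fresh extension attempt along
    its corrected local tangent)."""
    flags: list[str] = []
    for _ in range(3):
        r, ext, f = _adjust_one_end(
            pts, volume, spacing, cap, step, min_window_um, ref_level
        )
        flags += f
        if r > 0 and r < len(pts) - 8:
            pts = pts[: len(pts) - r]
            continue
        if len(ext):
            pts = np.vstack([pts, ext])
        break
    return pts, list(dict.fromkeys(flags))


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def _smooth_polyline(cl: Centerline, window_um: float) -> Centerline:
    w = max(int(round(window_um / cl.step)), 1)
    if w % 2 == 0:
        w += 1
    if w < 3 or cl.n_points < w + 2:
        return cl
    pad = w // 2
    pts = np.column_stack(
        [
            np.convolve(
                # odd reflection keeps linear end segments linear
                np.pad(cl.points[:, k], pad, mode="reflect", reflect_type="odd"),
                np.ones(w) / w,
                mode="valid",
            )
            for k in range(3)
        ]
    )
    return Centerline(pts, cl.method, list(cl.flags))


def _menger_curvature(pts: np.ndarray) -> np.ndarray:
    """Reciprocal circumradius of each interior consecutive point triplet."""
    a = pts[1:-1] - pts[:-2]
    b = pts[2:] - pts[1:-1]
    c = pts[2:] - pts[:-2]
    cross = np.cross(a, b)
    num = 2.0 * np.linalg.norm(cross, axis=1)
    den = (
        np.linalg.norm(a, axis=1)
        * np.linalg.norm(b, axis=1)
        * np.linalg.norm(c, axis=1)
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        kappa = np.where(den > 1e-300, num / np.maximum(den, 1e-300), 0.0)
    return kappa


def fiber_geometry(
    cl: Centerline,
    mask: np.ndarray | None,
    spacing: tuple[float, float, float],
    *,
    curvature_window_um: float = 1.0,
) -> GeometrySummary:
    """Length, width and curvature of one fiber.

    ``mean_width`` is twice the mean Euclidean distance-transform value of
    the mask sampled at the centerline points (a purely morphological width,
    no intensity fitting); ``max_curvature`` is the maximum three-point
    circumradius reciprocal on a smoothed (default 1 µm window) resampled
    centerline, the smoothing guarding against voxel-noise blow-up.
    """
    spacing = np.asarray(spacing, dtype=float)
    mean_width = 0.0
    if mask is not None:
        edt = distance_transform_edt(np.asarray(mask, dtype=bool), sampling=spacing)
        vals = trilinear_sample(edt, spacing, cl.points)
        mean_width = float(2.0 * np.mean(vals))

    h = max(cl.step, curvature_window_um / 4)
    n_res = max(int(round(cl.length / h)) + 1, 5)
    res = cl.resample(n_res)
    sm = _smooth_polyline(res, curvature_window_um)
    kappa = _menger_curvature(sm.points)
    max_curv = float(kappa.max()) if len(kappa) else 0.0
    return GeometrySummary(cl.length, mean_width, max_curv)
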