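"""Classical instance segmentation of fibers and somata, plus QC filters.

Fibers are thin curvilinear structures segmented by an adaptive (local
Gaussian-mean) threshold with a physical block size, small-object removal
and optional marker-based watershed splitting. Somata are segmented from
the Nissl channel by global thresholding, hole filling, and a
distance-transform watershed that splits touching cells. Distance
transforms are computed with physical voxel spacing throughout, so the
anisotropic Z-step does not distort geometry.

Quality control mirrors the readout platform's three filters: geodesic
length >= 8 µm, skeleton PC1 explained variance >= 0.8, and containment of
the centerline inside a segmented soma.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.segmentation import watershed

from .errors import InconsistencyError, UndefinedGeometryError
from .skeleton import Centerline

__all__ = [
    "LabelVolume",
    "QCReport",
    "FiberQC",
    "segment_fibers",
    "segment_somata",
    "pc1_explained_variance",
    "qc_filter",
]

MIN_FIBER_LENGTH_UM = 8.0
MIN_PC1_EXPLAINED_VARIANCE = 0.8


@dataclass
class LabelVolume:
    """Integer instance labels per voxel (0 = background)."""

    labels: np.ndarray
    spacing: tuple[float, float, float]
    kind: str = "fiber"  # fiber | soma

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError(f"label volume must be 3D, got ndim={self.labels.ndim}")

    @property
    def ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]

    @property
    def n_instances(self) -> int:
        return len(self.ids)

    def mask(self, label_id: int) -> np.ndarray:
        return self.labels == label_id

    def relabel_sequential(self) -> "LabelVolume":
        out = np.zeros_like(self.labels)
        for new, old in enumerate(self.ids, start=1):
            out[self.labels == old] = new
        return LabelVolume(out, self.spacing, self.kind)


# ---------------------------------------------------------------------------
# fiber segmentation
# ---------------------------------------------------------------------------

def _drop_small(mask: np.ndarray, min_voxels: int) -> np.ndarray:
    """Remove connected components with fewer than ``min_voxels`` voxels."""
    lab = cc_label(mask, connectivity=3)
    if lab.max() == 0:
        return mask
    sizes = np.bincount(lab.ravel())
    keep = sizes >= min_voxels
    keep[0] = False
    return keep[lab]

def segment_fibers(
    channel: np.ndarray,
    spacing: tuple[float, float, float],
    *,
    block_size_um: float = 4.0,
    k_sigma: float = 3.0,
    presmooth_um: float = 0.15,
    min_voxels: int = 50,
    use_watershed: bool = False,
    watershed_min_sep_um: float = 0.6,
) -> LabelVolume:
    """Adaptive-threshold instance segmentation of the structural channel.

    The local background is a Gaussian mean with physical block size; a
    voxel is foreground when it exceeds background + ``k_sigma`` robust
    noise SDs (noise estimated by the median absolute deviation of the
    background-subtracted image). Connected components smaller than
    ``min_voxels`` are discarded. With ``use_watershed`` the mask is split
    at Euclidean-distance-transform maxima separated by at least
    ``watershed_min_sep_um``.
    """
    img = np.asarray(channel, dtype=float)
    spacing = tuple(float(s) for s in spacing)
    spc = np.asarray(spacing)
    if presmooth_um > 0:
        img = ndi.gaussian_filter(img, presmooth_um / spc)
    bg = ndi.gaussian_filter(img, block_size_um / spc)
    diff = img - bg
    sigma = 1.4826 * np.median(np.abs(diff - np.median(diff)))
    # contrast floor keeps the threshold meaningful on (near-)noise-free
    # volumes, where the MAD estimate collapses and the PSF halo would pass
    floor = 0.05 * float(np.percentile(diff, 99.9))
    mask = diff > k_sigma * max(sigma, floor, 1e-12)
    mask = ndi.binary_closing(mask, structure=np.ones((3, 3, 3), bool))
    mask = _drop_small(mask, min_voxels)
    if not mask.any():
        return LabelVolume(np.zeros_like(mask, dtype=np.int32), spacing, "fiber")
    if use_watershed:
        labels = _watershed_split(mask, spc, watershed_min_sep_um)
    else:
        labels = cc_label(mask, connectivity=3)
    lv = LabelVolume(labels.astype(np.int32), spacing, "fiber")
    return lv.relabel_sequential()


def _watershed_split(mask: np.ndarray, spc: np.ndarray, min_sep_um: float) -> np.ndarray:
    edt = ndi.distance_transform_edt(mask, sampling=spc)
    min_dist_vox = max(int(round(min_sep_um / float(spc.min()))), 1)
    peaks = peak_local_max(
        edt, min_distance=min_dist_vox, labels=mask, exclude_border=False
    )
    markers = np.zeros_like(mask, dtype=np.int32)
    for i, p in enumerate(peaks, start=1):
        markers[tuple(p)] = i
    if markers.max() == 0:
        return cc_label(mask, connectivity=3)
    return watershed(-edt, markers, mask=mask)


# ---------------------------------------------------------------------------
# soma segmentation
# ---------------------------------------------------------------------------

def segment_somata(
    nissl_channel: np.ndarray,
    spacing: tuple[float, float, float],
    *,
    presmooth_um: float = 0.8,
    threshold: float | None = None,
    min_voxels: int = 500,
    min_sep_um: float = 6.0,
) -> LabelVolume:
    """Threshold + hole-fill + distance-transform watershed on the Nissl
    channel, splitting touching cell bodies."""
    img = np.asarray(nissl_channel, dtype=float)
    spacing = tuple(float(s) for s in spacing)
    spc = np.asarray(spacing)
    sm = ndi.gaussian_filter(img, presmooth_um / spc)
    if threshold is None:
        if np.ptp(sm) <= 0:
            return LabelVolume(np.zeros(img.shape, dtype=np.int32), spacing, "soma")
        threshold = threshold_otsu(sm)
    mask = sm > threshold
    mask = ndi.binary_fill_holes(mask)
    mask = _drop_small(mask, min_voxels)
    if not mask.any():
        return LabelVolume(np.zeros(img.shape, dtype=np.int32), spacing, "soma")
    labels = _watershed_split(mask, spc, min_sep_um)
    return LabelVolume(labels.astype(np.int32), spacing, "soma").relabel_sequential()


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def pc1_explained_variance(points: np.ndarray) -> float:
    """Fraction of coordinate variance on the first principal axis.

    ``lambda_1 / (lambda_1 + lambda_2 + lambda_3)`` of the covariance of the
    point cloud: 1.0 for collinear points, ~1/3 for an isotropic 3D cloud.
    A straightness score used to reject non-fiber-like segments.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if len(pts) < 3:
        raise UndefinedGeometryError(f"need >= 3 points, got {len(pts)}")
    centered = pts - pts.mean(axis=0)
    cov = centered.T @ centered / len(pts)
    evals = np.linalg.eigvalsh(cov)
    total = evals.sum()
    if total <= 0:
        raise UndefinedGeometryError("zero-variance point cloud")
    return float(evals.max() / total)


@dataclass
class FiberQC:
    label: int
    geodesic_length: float
    pc1_explained_variance: float
    inside_soma: bool
    passed: bool
    failure_reasons: list[str] = field(default_factory=list)


@dataclass
class QCReport:
    fibers: list[FiberQC]
    min_length: float
    min_ev: float

    @property
    def survivors(self) -> list[int]:
        return [f.label for f in self.fibers if f.passed]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "label": f.label,
                    "geodesic_length_um": f.geodesic_length,
                    "pc1_explained_variance": f.pc1_explained_variance,
                    "inside_soma": f.inside_soma,
                    "passed": f.passed,
                    "failure_reasons": ";".join(f.failure_reasons),
                }
                for f in self.fibers
            ]
        )


def soma_label_of(cl: Centerline, soma_labels: LabelVolume) -> int:
    """Soma label holding the strict majority of centerline points (0 if
    none does, or if background holds the majority)."""
    spc = np.asarray(soma_labels.spacing)
    idx = np.round(cl.points / spc).astype(int)
    idx = np.clip(idx, 0, np.array(soma_labels.labels.shape) - 1)
    hits = soma_labels.labels[idx[:, 0], idx[:, 1], idx[:, 2]]
    ids, counts = np.unique(hits, return_counts=True)
    best = ids[np.argmax(counts)]
    if best == 0 or counts.max() * 2 <= len(hits):
        return 0
    return int(best)


def qc_filter(
    fiber_labels: LabelVolume,
    skeletons: dict[int, Centerline],
    soma_labels: LabelVolume,
    *,
    min_length: float = MIN_FIBER_LENGTH_UM,
    min_ev: float = MIN_PC1_EXPLAINED_VARIANCE,
) -> QCReport:
    """Apply the three fiber quality filters.

    A fiber passes iff its geodesic length is >= ``min_length`` (8 µm), the
    PC1 explained variance of its skeleton points is >= ``min_ev`` (0.8),
    and the majority of its centerline points fall inside one segmented
    soma.
    """
    report: list[FiberQC] = []
    for lab in fiber_labels.ids:
        lab = int(lab)
        if lab not in skeletons:
            raise InconsistencyError(f"no skeleton for fiber label {lab}")
        cl = skeletons[lab]
        length = cl.length
        ev = pc1_explained_variance(cl.points)
        inside = soma_label_of(cl, soma_labels) > 0
        reasons = []
        if length < min_length:
            reasons.append("geodesic_length")
        if ev < min_ev:
            reasons.append("pc1_explained_variance")
        if not inside:
            reasons.append("outside_soma")
        report.append(FiberQC(lab, length, ev, inside, not reasons, reasons))
    return QCReport(report, min_length, min_ev)
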