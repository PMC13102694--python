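"""Recovery metrics against simulation ground truth."""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from .pipeline import FiberReadout
from .skeleton import Centerline
from .synthfib import FiberGroundTruth, GroundTruth

__all__ = [
    "match_to_ground_truth",
    "true_peak_time",
    "true_peak_times",
    "recovered_peak_time",
]


def match_to_ground_truth(
    centerlines: dict[int, Centerline],
    gt: GroundTruth,
    *,
    max_mean_dist_um: float = 2.0,
) -> dict[int, int]:
    """Map segmented fiber labels to ground-truth fiber ids by mean
    distance between the recovered centerline and the true polyline."""
    trees = [cKDTree(f.polyline) for f in gt.fibers]
    out: dict[int, int] = {}
    for lab, cl in centerlines.items():
        pts = cl.points[:: max(len(cl.points) // 50, 1)]
        dists = [t.query(pts)[0].mean() for t in trees]
        best = int(np.argmin(dists))
        if dists[best] <= max_mean_dist_um:
            out[lab] = gt.fibers[best].fiber_id
    return out


def true_peak_times(gtf: FiberGroundTruth, channel: str) -> list[float]:
    """Deposition times of all local maxima of the true channel record."""
    rec = gtf.record
    y = rec.channels[channel]
    t = rec.model.time_at(rec.arclength)
    peaks = [
        i
        for i in range(1, len(y) - 1)
        if y[i] >= y[i - 1] and y[i] > y[i + 1] and y[i] > y.min() + 0.25 * np.ptp(y)
    ]
    return [float(t[i]) for i in peaks]


def true_peak_time(gtf: FiberGroundTruth, channel: str) -> float:
    rec = gtf.record
    y = rec.channels[channel]
    return float(rec.model.time_at(rec.arclength[int(np.argmax(y))]))


def anchor_true_times(
    readout: FiberReadout, cl: Centerline, gtf: FiberGroundTruth
) -> list[tuple[float, float]]:
    """For every non-terminus anchor of every decoded half, the true
    deposition time of the material at the detected position.

    The anchor's fraction is converted to a 3D point on the measured
    centerline; the nearest point of the true polyline gives the true
    half-arclength, which the growth law converts to a time. Returns
    ``(detected_fraction, true_time)`` pairs.
    """
    arc = cl.arclength
    split_arc = readout.split.split_arclength
    tree = cKDTree(gtf.polyline)
    gt_arc = np.concatenate(
        [[0.0], np.cumsum(np.linalg.norm(np.diff(gtf.polyline, axis=0), axis=1))]
    )
    out = []
    for hr in readout.halves:
        half_len = split_arc if hr.half == 0 else arc[-1] - split_arc
        for f, _t, kind in hr.anchors.anchors:
            if kind == "terminus":
                continue
            s = split_arc - f * half_len if hr.half == 0 else split_arc + f * half_len
            p = np.array([np.interp(s, arc, cl.points[:, k]) for k in range(3)])
            _, i = tree.query(p)
            s_true = abs(gt_arc[i] - gtf.half_length)
            out.append((float(f), float(gtf.record.model.time_at(s_true))))
    return out


def recovered_peak_time(readout: FiberReadout, channel: str) -> float:
    """Recovered time of the channel maximum, averaged over the decoded
    halves of the fiber. A light moving average suppresses single-sample
    noise spikes before the argmax."""
    times = []
    for hr in readout.halves:
        ts = hr.timeseries
        y = np.asarray(ts.channel(channel), dtype=float)
        w = max(len(y) // 100, 1)
        if w > 1:
            y = np.convolve(np.pad(y, w // 2, mode="edge"), np.ones(w) / w, "valid")[
                : len(ts.time)
            ]
        times.append(float(ts.time[int(np.argmax(y))]))
    return float(np.mean(times))
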