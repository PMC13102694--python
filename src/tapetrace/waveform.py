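"""Per-cell analytics on recovered activity time series.

Operates on relative-change waveforms after space-to-time decoding: peak
feature extraction (amplitude, FWHM, onset, time to peak), the line-length
baseline-fluctuation statistic, time-lagged cross-correlation between an
upstream and a downstream signal, two-mode coupled/decoupled
classification, and the fiber-to-cell assignment rules (majority of
centerline points; longest fiber represents the cell).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks
from sklearn.cluster import KMeans

from .segment import LabelVolume, soma_label_of
from .skeleton import Centerline
from .timeaxis import TimeSeries

__all__ = [
    "Peak",
    "PeakFeatures",
    "LagProfile",
    "CouplingLabels",
    "peak_features",
    "line_length",
    "lag_correlation",
    "classify_coupling",
    "assign_fibers_to_cells",
    "post_stim_mean",
]


# ---------------------------------------------------------------------------
# peak features
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Peak:
    amplitude: float       # relative change at the peak
    peak_time: float       # days (absolute)
    time_to_peak: float    # days from the reference time
    fwhm: float            # days
    onset_time: float      # days (absolute)


@dataclass
class PeakFeatures:
    peaks: list[Peak]
    threshold: float

    @property
    def n_peaks(self) -> int:
        return len(self.peaks)


def _cross_time(t: np.ndarray, y: np.ndarray, i_out: int, i_in: int, level: float) -> float:
    """Linear interpolation of the level crossing between two samples."""
    y0, y1 = y[i_out], y[i_in]
    if y1 == y0:
        return float(t[i_in])
    w = (level - y0) / (y1 - y0)
    return float(t[i_out] + w * (t[i_in] - t[i_out]))


def peak_features(
    ts: TimeSeries,
    channel: str,
    reference_time: float,
    *,
    threshold_sd: float = 2.0,
    min_sustain: int = 3,
    min_distance: float | None = None,
    smooth: float | None = None,
) -> PeakFeatures:
    """Detect peaks on a uniform-grid waveform and measure their features.

    A peak is a local maximum exceeding ``threshold_sd`` pre-reference
    standard deviations above zero baseline, sustained for at least
    ``min_sustain`` samples. ``min_distance`` (days) merges local maxima
    closer than that, and ``smooth`` (days) applies a moving average first
    — both guard against noise splitting one peak into several. FWHM is
    measured at half the peak amplitude by linear interpolation of the
    crossings; onset is the last upward threshold crossing before the peak.
    """
    t = ts.time
    y = np.asarray(ts.channel(channel), dtype=float)
    if smooth is not None and smooth > ts.dt:
        w = max(int(round(smooth / ts.dt)), 1)
        y = np.convolve(np.pad(y, w // 2, mode="edge"), np.ones(w) / w, "valid")[
            : len(t)
        ]
    pre = y[t < reference_time]
    if len(pre) < 2:
        raise ValueError("no pre-reference window to estimate baseline SD")
    thr = threshold_sd * float(pre.std())
    dist = max(int(round((min_distance or 0) / ts.dt)), 1)
    idx, _ = find_peaks(
        y,
        height=thr if thr > 0 else None,
        distance=dist,
        prominence=thr / 2 if thr > 0 else None,
    )
    peaks: list[Peak] = []
    above = y > thr
    for i in idx:
        # sustained: min_sustain consecutive supra-threshold samples containing i
        lo = i
        while lo > 0 and above[lo - 1]:
            lo -= 1
        hi = i
        while hi < len(y) - 1 and above[hi + 1]:
            hi += 1
        if hi - lo + 1 < min_sustain:
            continue
        amp = float(y[i])
        half = amp / 2
        # FWHM crossings around the peak
        j = i
        while j > 0 and y[j - 1] >= half:
            j -= 1
        t_left = _cross_time(t, y, max(j - 1, 0), j, half) if j > 0 else float(t[0])
        j = i
        while j < len(y) - 1 and y[j + 1] >= half:
            j += 1
        t_right = _cross_time(t, y, min(j + 1, len(y) - 1), j, half) if j < len(y) - 1 else float(t[-1])
        onset = _cross_time(t, y, max(lo - 1, 0), lo, thr) if lo > 0 else float(t[0])
        peaks.append(
            Peak(
                amplitude=amp,
                peak_time=float(t[i]),
                time_to_peak=float(t[i] - reference_time),
                fwhm=t_right - t_left,
                onset_time=onset,
            )
        )
    return PeakFeatures(peaks, thr)


# ---------------------------------------------------------------------------
# fluctuation and correlation statistics
# ---------------------------------------------------------------------------

def line_length(ts: TimeSeries, channel: str, t_start: float, t_end: float) -> float:
    """Sum of absolute successive differences within a time window — the
    baseline-fluctuation ("line length") statistic."""
    t = ts.time
    sel = (t >= t_start - 1e-12) & (t <= t_end + 1e-12)
    if sel.sum() < 2:
        raise ValueError("line-length window holds fewer than 2 samples")
    y = ts.channel(channel)[sel]
    return float(np.abs(np.diff(y)).sum())


@dataclass
class LagProfile:
    """Pearson correlation of two waveforms as a function of time lag."""

    lags: np.ndarray          # days, symmetric about 0
    correlations: np.ndarray  # r per lag, NaN where undefined
    cell_id: int | None = None

    @property
    def max_r(self) -> float:
        return float(np.nanmax(self.correlations))

    def max_r_near_zero(self, near_zero_frac: float = 0.1) -> float:
        band = np.abs(self.lags) <= near_zero_frac * np.abs(self.lags).max() + 1e-12
        vals = self.correlations[band]
        return float(np.nanmax(vals)) if np.isfinite(vals).any() else np.nan


def lag_correlation(
    ts_a: TimeSeries,
    ts_b: TimeSeries,
    channel_a: str,
    channel_b: str,
    max_lag: float,
    lag_step: float,
    *,
    min_overlap: int = 10,
) -> LagProfile:
    """``r(tau) = Pearson(A(t), B(t + tau))`` on the overlapping window.

    Both series must share the grid spacing; ``lag_step`` must be a
    multiple of it. Positive lag means B follows A. Lags with fewer than
    ``min_overlap`` overlapping samples, or a zero-variance segment, are
    masked as NaN.
    """
    dt = ts_a.dt
    if abs(ts_b.dt - dt) > 1e-9:
        raise ValueError("series must share the grid spacing")
    step = int(round(lag_step / dt))
    if step < 1 or abs(step * dt - lag_step) > 1e-9:
        raise ValueError("lag_step must be a positive multiple of the grid dt")
    a = np.asarray(ts_a.channel(channel_a), dtype=float)
    b = np.asarray(ts_b.channel(channel_b), dtype=float)
    n = min(len(a), len(b))
    a, b = a[:n], b[:n]
    kmax = int(round(max_lag / lag_step))
    lags = np.arange(-kmax, kmax + 1) * lag_step
    rs = np.full(len(lags), np.nan)
    for j, k in enumerate(range(-kmax, kmax + 1)):
        sh = k * step
        if sh >= 0:
            aa, bb = a[: n - sh or None], b[sh:]
        else:
            aa, bb = a[-sh:], b[: n + sh]
        if len(aa) < min_overlap:
            continue
        if aa.std() <= 0 or bb.std() <= 0:
            continue
        rs[j] = np.corrcoef(aa, bb)[0, 1]
    if not np.isfinite(rs).any():
        raise ValueError("correlation undefined at every lag")
    return LagProfile(lags, rs)


# ---------------------------------------------------------------------------
# coupling classification
# ---------------------------------------------------------------------------

@dataclass
class CouplingLabels:
    """Two-mode partition of cells by their lag-correlation profile."""

    labels: list[str]               # type1_decoupled | type2_coupled per cell
    max_r_near_zero: np.ndarray
    degenerate: bool = False


def classify_coupling(
    lag_profiles: list[LagProfile],
    *,
    seed: int = 0,
    near_zero_frac: float = 0.1,
    degenerate_threshold: float = 0.5,
) -> CouplingLabels:
    """2-cluster partition of per-cell lag-correlation vectors.

    Cells whose upstream and downstream signals co-fluctuate show strong
    positive correlation near zero lag ("coupled mode"); the cluster with
    the higher mean correlation inside ``±near_zero_frac * max_lag`` is
    labeled ``type2_coupled``. Initialization is deterministic (the
    farthest pair of profiles seeds the centroids). If all profiles are
    identical the partition is degenerate and a fixed threshold rule
    (near-zero r >= 0.5 -> coupled) applies.
    """
    if len(lag_profiles) < 4:
        raise ValueError("need >= 4 cells to classify")
    lags = lag_profiles[0].lags
    X = np.vstack([np.nan_to_num(p.correlations, nan=0.0) for p in lag_profiles])
    near = np.abs(lags) <= near_zero_frac * np.abs(lags).max() + 1e-12
    r_near = np.array([p.max_r_near_zero(near_zero_frac) for p in lag_profiles])

    if np.allclose(X, X[0]):
        labels = [
            "type2_coupled" if r >= degenerate_threshold else "type1_decoupled"
            for r in r_near
        ]
        return CouplingLabels(labels, r_near, degenerate=True)

    # deterministic farthest-pair initialization
    d2 = ((X[:, None, :] - X[None, :, :]) ** 2).sum(-1)
    i, j = np.unravel_index(np.argmax(d2), d2.shape)
    km = KMeans(
        n_clusters=2, init=X[[i, j]], n_init=1, random_state=seed, max_iter=300
    ).fit(X)
    mean_near = [X[km.labels_ == c][:, near].mean() for c in (0, 1)]
    coupled_cluster = int(np.argmax(mean_near))
    labels = [
        "type2_coupled" if lab == coupled_cluster else "type1_decoupled"
        for lab in km.labels_
    ]
    return CouplingLabels(labels, r_near)


# ---------------------------------------------------------------------------
# fiber -> cell assignment
# ---------------------------------------------------------------------------

def assign_fibers_to_cells(
    centerlines: dict[int, Centerline],
    soma_labels: LabelVolume,
) -> pd.DataFrame:
    """Assign each fiber to the soma holding the majority of its centerline
    points; per cell, mark the longest fiber as the representative.

    Returns a table (fiber_id, cell_label, geodesic_length_um,
    representative); ``cell_label`` 0 means unassigned.
    """
    rows = []
    for fid, cl in centerlines.items():
        rows.append(
            {
                "fiber_id": fid,
                "cell_label": soma_label_of(cl, soma_labels),
                "geodesic_length_um": cl.length,
            }
        )
    df = pd.DataFrame(rows)
    df["representative"] = False
    for cell, grp in df[df.cell_label > 0].groupby("cell_label"):
        df.loc[grp.geodesic_length_um.idxmax(), "representative"] = True
    return df


def post_stim_mean(ts: TimeSeries, channel: str, t_stim: float, window: float) -> float:
    """Mean relative change over ``[t_stim, t_stim + window]``."""
    t = ts.time
    sel = (t >= t_stim - 1e-12) & (t <= t_stim + window + 1e-12)
    if not sel.any():
        raise ValueError("post-stimulation window holds no samples")
    return float(np.mean(ts.channel(channel)[sel]))
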