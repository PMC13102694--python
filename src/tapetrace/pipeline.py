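"""End-to-end readout pipeline: volume in, per-cell time series out.

Stage order follows the readout platforms it reimplements: instance
segmentation (fibers + somata) → skeletonization with terminus
extrapolation → quality control (length / straightness / soma containment)
→ profile extraction → split search → baseline normalization → timestamp
detection → transfer-function fit → time warping → fiber-to-cell
assignment. Every excluded fiber is logged with its reason; the run is a
pure function of (volume, params, seed).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import segment as seg
from .errors import ConfigurationError, DetectionFailure, TapetraceError
from .profiles import FiberProfile, sample_trilinear
from .skeleton import Centerline, extract_centerline, extrapolate_centerline, fiber_geometry
from .timeaxis import (
    SplitResult,
    TimeSeries,
    TimestampSet,
    TransferFunction,
    find_split,
    fit_transfer,
    normalize_baseline,
    split_halves,
    warp_to_time,
    detect_timestamps,
)
from .volume import ImageVolume
from .waveform import assign_fibers_to_cells

logger = logging.getLogger("tapetrace")

__all__ = ["PipelineParams", "HalfReadout", "FiberReadout", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineParams:
    """All knobs of one readout run.

    ``mode`` fixes conventions: cultured cells search the split in a
    20%-of-length window and fit a polynomial transfer; in vivo uses a
    5%-radius window and a piecewise-linear transfer through the induction
    pulse anchors.
    """

    structural_channel: str = "structural"
    dye_channels: list[str] = field(default_factory=lambda: ["dye1", "dye2"])
    signal_channels: list[str] = field(default_factory=lambda: ["signal"])
    nissl_channel: str = "nissl"
    mode: str = "cultured"               # cultured | in_vivo
    schedule_times: list[float] = field(default_factory=lambda: [5.5])
    fixation_time: float = 10.5
    split_ref_channel: str | None = None
    window_frac: float | None = None     # default 0.2 cultured / 0.1 in vivo
    transfer_model: str | None = None    # default auto / piecewise_linear
    dt: float | None = None              # default fixation_time / 500
    baseline_window_frac: float = 0.05
    # segmentation
    block_size_um: float = 4.0
    k_sigma: float = 3.0
    min_voxels: int = 50
    soma_min_sep_um: float = 6.0
    # skeletonization
    n_points: int = 1000
    cap_frac: float = 0.2
    # QC
    min_length_um: float = seg.MIN_FIBER_LENGTH_UM
    min_ev: float = seg.MIN_PC1_EXPLAINED_VARIANCE
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("cultured", "in_vivo"):
            raise ConfigurationError(f"unknown mode {self.mode!r}")
        if self.window_frac is None:
            self.window_frac = 0.2 if self.mode == "cultured" else 0.1
        if self.transfer_model is None:
            self.transfer_model = "auto" if self.mode == "cultured" else "piecewise_linear"
        if self.dt is None:
            self.dt = self.fixation_time / 500
        if self.split_ref_channel is None:
            self.split_ref_channel = (
                self.dye_channels[-1] if self.mode == "cultured" else self.dye_channels[0]
            )

    @property
    def timestamp_mode(self) -> str:
        return "dye_switch" if self.mode == "cultured" else "dox_pulse"

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha1(payload.encode()).hexdigest()[:12]

    def validate_channels(self, volume: ImageVolume) -> None:
        wanted = (
            [self.structural_channel, self.nissl_channel]
            + self.dye_channels
            + self.signal_channels
        )
        missing = [c for c in wanted if c not in volume.channel_names]
        if missing:
            raise ConfigurationError(
                f"channels {missing} not found in volume {volume.channel_names}"
            )


@dataclass
class HalfReadout:
    half: int                       # 0 or 1
    anchors: TimestampSet
    transfer: TransferFunction
    timeseries: TimeSeries


@dataclass
class FiberReadout:
    fiber_id: int
    cell_label: int
    split: SplitResult
    profile: FiberProfile            # raw full profile
    normalized: FiberProfile         # relative change from baseline
    halves: list[HalfReadout]
    flags: list[str] = field(default_factory=list)


@dataclass
class PipelineResult:
    fiber_labels: seg.LabelVolume
    soma_labels: seg.LabelVolume
    centerlines: dict[int, Centerline]
    geometry: dict[int, object]
    qc: seg.QCReport
    assignments: pd.DataFrame
    readouts: dict[int, FiberReadout]
    excluded: dict[int, str]
    config_hash: str

    def timeseries_frame(self) -> pd.DataFrame:
        """Long-format table of all recovered waveforms."""
        rows = []
        for fid, ro in self.readouts.items():
            for hr in ro.halves:
                ts = hr.timeseries
                for name, vals in ts.channels.items():
                    for t, v, ex in zip(ts.time, vals, ts.extrapolated):
                        rows.append(
                            {
                                "cell_id": ro.cell_label,
                                "fiber_id": fid,
                                "half": hr.half,
                                "time_days": t,
                                "channel": name,
                                "rel_change": v,
                                "extrapolated": bool(ex),
                                "config_hash": self.config_hash,
                            }
                        )
        return pd.DataFrame(rows)

    def representative_readouts(self) -> dict[int, FiberReadout]:
        """Cell label -> readout of that cell's representative fiber."""
        reps = {}
        if len(self.assignments) == 0:
            return reps
        sel = self.assignments[self.assignments.representative]
        for _, row in sel.iterrows():
            fid = int(row.fiber_id)
            if fid in self.readouts:
                reps[int(row.cell_label)] = self.readouts[fid]
        return reps


def run_pipeline(volume: ImageVolume, params: PipelineParams) -> PipelineResult:
    """Execute the full readout on one volume. Per-fiber failures are
    logged and excluded; the run continues."""
    params.validate_channels(volume)
    t_start = time.perf_counter()
    spacing = volume.spacing

    fiber_labels = seg.segment_fibers(
        volume.channel(params.structural_channel),
        spacing,
        block_size_um=params.block_size_um,
        k_sigma=params.k_sigma,
        min_voxels=params.min_voxels,
    )
    soma_labels = seg.segment_somata(
        volume.channel(params.nissl_channel), spacing, min_sep_um=params.soma_min_sep_um
    )
    logger.info(
        "segmentation: %d fibers, %d somata (%.1fs)",
        fiber_labels.n_instances,
        soma_labels.n_instances,
        time.perf_counter() - t_start,
    )

    centerlines: dict[int, Centerline] = {}
    geometry: dict[int, object] = {}
    excluded: dict[int, str] = {}
    structural = volume.channel(params.structural_channel)
    for lab in fiber_labels.ids:
        lab = int(lab)
        try:
            mask = fiber_labels.mask(lab)
            cl = extract_centerline(mask, spacing, method="auto", n_points=params.n_points)
            cl = extrapolate_centerline(
                cl, structural, spacing=spacing, cap_frac=params.cap_frac
            )
            centerlines[lab] = cl
            geometry[lab] = fiber_geometry(cl, mask, spacing)
        except TapetraceError as e:
            excluded[lab] = f"skeleton: {e}"
            logger.info("fiber %d excluded at skeletonization: %s", lab, e)

    qc = seg.qc_filter(
        seg.LabelVolume(
            np.where(np.isin(fiber_labels.labels, list(centerlines)), fiber_labels.labels, 0),
            spacing,
            "fiber",
        ),
        centerlines,
        soma_labels,
        min_length=params.min_length_um,
        min_ev=params.min_ev,
    )
    for f in qc.fibers:
        if not f.passed:
            excluded[f.label] = "qc: " + ",".join(f.failure_reasons)

    survivors = {lab: centerlines[lab] for lab in qc.survivors}
    assignments = (
        assign_fibers_to_cells(survivors, soma_labels)
        if survivors
        else pd.DataFrame(columns=["fiber_id", "cell_label", "geodesic_length_um", "representative"])
    )
    cell_of = dict(zip(assignments.get("fiber_id", []), assignments.get("cell_label", [])))

    readouts: dict[int, FiberReadout] = {}
    for lab, cl in survivors.items():
        try:
            readouts[lab] = _decode_fiber(volume, cl, lab, int(cell_of.get(lab, 0)), params)
        except TapetraceError as e:
            excluded[lab] = f"decode: {e}"
            logger.info("fiber %d excluded at decoding: %s", lab, e)

    logger.info(
        "pipeline done: %d/%d fibers decoded (%.1fs)",
        len(readouts),
        fiber_labels.n_instances,
        time.perf_counter() - t_start,
    )
    return PipelineResult(
        fiber_labels,
        soma_labels,
        centerlines,
        geometry,
        qc,
        assignments,
        readouts,
        excluded,
        params.config_hash(),
    )


def _decode_fiber(
    volume: ImageVolume,
    cl: Centerline,
    fiber_id: int,
    cell_label: int,
    params: PipelineParams,
) -> FiberReadout:
    profile = sample_trilinear(volume, cl)
    split = find_split(profile, params.split_ref_channel, params.window_frac)
    normalized = normalize_baseline(
        profile, split.split_index, params.baseline_window_frac
    )
    halves_raw = split_halves(profile, split.split_index)
    halves_norm = split_halves(normalized, split.split_index)
    flags: list[str] = list(profile.flags)
    readout_halves: list[HalfReadout] = []
    for h, (raw, norm) in enumerate(zip(halves_raw, halves_norm)):
        try:
            anchors = detect_timestamps(
                raw,
                params.dye_channels,
                params.schedule_times,
                params.fixation_time,
                mode=params.timestamp_mode,
            )
        except (DetectionFailure, TapetraceError) as e:
            flags.append(f"half{h}_detection_failed")
            logger.debug("fiber %d half %d: %s", fiber_id, h, e)
            continue
        transfer = fit_transfer(anchors, params.transfer_model)
        ts = warp_to_time(norm, transfer, params.dt)
        readout_halves.append(HalfReadout(h, anchors, transfer, ts))
    if not readout_halves:
        raise DetectionFailure("timestamps undetectable on both halves")
    return FiberReadout(
        fiber_id, cell_label, split, profile, normalized, readout_halves, flags
    )
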