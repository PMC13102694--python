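"""Volume, label and table I/O.

Volumes are stored as multi-page TIFF plus a JSON sidecar (``<file>.json``)
holding voxel spacing and channel names; OME-style pixel-size metadata is
honored on read when no sidecar is present. Tables go to CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import ConfigurationError
from .segment import LabelVolume
from .skeleton import Centerline
from .volume import ImageVolume

__all__ = [
    "read_volume",
    "write_volume",
    "read_labels",
    "write_labels",
    "write_centerlines_csv",
    "write_profile_csv",
]


def _sidecar(path: Path) -> Path:
    return Path(str(path) + ".json")


def write_volume(vol: ImageVolume, path: str | Path) -> None:
    path = Path(path)
    tifffile.imwrite(path, np.asarray(vol.data, dtype=np.float32), photometric="minisblack")
    _sidecar(path).write_text(
        json.dumps(
            {
                "axes": "CZYX",
                "spacing_um": list(vol.spacing),
                "channel_names": list(vol.channel_names),
            },
            indent=2,
        )
    )


def read_volume(path: str | Path) -> ImageVolume:
    """Read a multi-channel volume; spacing must come from the sidecar or
    embedded OME metadata, otherwise an explicit error is raised."""
    path = Path(path)
    data = tifffile.imread(path)
    if data.ndim == 2:
        raise ConfigurationError(f"{path} is a 2D image; need a 3D volume")
    meta = None
    if _sidecar(path).exists():
        meta = json.loads(_sidecar(path).read_text())
        spacing = tuple(meta["spacing_um"])
        names = list(meta.get("channel_names", []))
    else:
        spacing = _ome_spacing(path)
        names = []
        if spacing is None:
            raise ConfigurationError(
                f"no voxel spacing for {path}: provide {_sidecar(path).name} "
                "or OME metadata"
            )
    if data.ndim == 3:
        if len(names) > 1:
            raise ConfigurationError(
                f"{path}: {len(names)} channels declared but the stack is 3D; "
                "each channel would be a 2D plane"
            )
        data = data[None]  # single-channel (z, y, x)
    if data.ndim != 4:
        raise ConfigurationError(f"{path}: expected (c, z, y, x), got shape {data.shape}")
    return ImageVolume(data, spacing, names)


def _ome_spacing(path: Path):
    try:
        with tifffile.TiffFile(path) as tf:
            ome = tf.ome_metadata
        if not ome:
            return None
        import re

        m = {
            k: float(re.search(rf'PhysicalSize{k}="([\d.eE+-]+)"', ome).group(1))
            for k in ("Z", "Y", "X")
        }
        return (m["Z"], m["Y"], m["X"])
    except Exception:
        return None


def write_labels(lv: LabelVolume, path: str | Path) -> None:
    path = Path(path)
    tifffile.imwrite(path, lv.labels.astype(np.int32), photometric="minisblack")
    _sidecar(path).write_text(
        json.dumps({"spacing_um": list(lv.spacing), "kind": lv.kind}, indent=2)
    )


def read_labels(path: str | Path) -> LabelVolume:
    path = Path(path)
    meta = json.loads(_sidecar(path).read_text())
    return LabelVolume(tifffile.imread(path), tuple(meta["spacing_um"]), meta["kind"])


def write_centerlines_csv(centerlines: dict[int, Centerline], path: str | Path) -> None:
    rows = []
    for fid, cl in centerlines.items():
        arc = cl.arclength
        for i, (p, a) in enumerate(zip(cl.points, arc)):
            rows.append(
                {
                    "fiber_id": fid,
                    "point_index": i,
                    "z_um": p[0],
                    "y_um": p[1],
                    "x_um": p[2],
                    "arclength_um": a,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_profile_csv(fiber_id: int, profile, path: str | Path) -> None:
    rows = []
    for name, vals in profile.channels.items():
        for a, v in zip(profile.arclength, vals):
            rows.append(
                {
                    "fiber_id": fiber_id,
                    "arclength_um": a,
                    "channel": name,
                    "intensity": v,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)
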