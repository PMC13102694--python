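"""Multi-channel 3D image volume with physical voxel spacing.

Conventions used throughout the package: arrays are indexed ``(c, z, y, x)``
(single channels ``(z, y, x)``), spacing is ``(dz, dy, dx)`` in µm, and the
physical position of voxel ``(i, j, k)`` is ``(i*dz, j*dy, k*dx)`` — i.e.
voxel centers sit on the index lattice scaled by spacing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["ImageVolume"]


@dataclass
class ImageVolume:
    """A ``(c, z, y, x)`` voxel array plus spacing and channel names.

    Parameters
    ----------
    data
        Array of shape ``(n_channels, nz, ny, nx)``.
    spacing
        Physical voxel spacing ``(dz, dy, dx)`` in µm; all entries > 0.
    channel_names
        One name per channel. Auto-filled as ``ch0..chN`` when omitted.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim == 3:  # single channel: promote
            self.data = self.data[None]
        if self.data.ndim != 4:
            raise ValueError(
                f"expected a (c, z, y, x) array, got ndim={self.data.ndim}"
            )
        self.spacing = tuple(float(s) for s in self.spacing)  # type: ignore[assignment]
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive floats, got {self.spacing}")
        if not self.channel_names:
            warnings.warn(
                "no channel names given; auto-naming ch0..chN", stacklevel=2
            )
            self.channel_names = [f"ch{i}" for i in range(self.data.shape[0])]
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.data.shape[0]} channels"
            )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        """Spatial shape ``(nz, ny, nx)``."""
        return self.data.shape[1:]

    @property
    def extent(self) -> np.ndarray:
        """Physical extent (µm) spanned by voxel centers, per axis."""
        return (np.array(self.shape) - 1) * np.array(self.spacing)

    def channel(self, name: str) -> np.ndarray:
        """Return the ``(z, y, x)`` array for a named channel."""
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise KeyError(
                f"channel {name!r} not in {self.channel_names}"
            ) from None
        return self.data[idx]

    def with_channel(self, name: str, arr: np.ndarray) -> "ImageVolume":
        """Return a copy with ``name`` replaced or appended."""
        arr = np.asarray(arr)
        if arr.shape != self.shape:
            raise ValueError(f"shape {arr.shape} != volume shape {self.shape}")
        if name in self.channel_names:
            data = self.data.copy()
            data[self.channel_names.index(name)] = arr
            return ImageVolume(data, self.spacing, list(self.channel_names))
        data = np.concatenate([self.data, arr[None]], axis=0)
        return ImageVolume(data, self.spacing, list(self.channel_names) + [name])
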