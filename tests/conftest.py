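"""Shared fixtures: analytic phantoms and small rendered scenes."""

import numpy as np
import pytest

from tapetrace.scenes import SceneConfig, simulate_scene
from tapetrace.volume import ImageVolume


def make_cylinder_mask(
    shape=(41, 41, 121),
    spacing=(0.2, 0.2, 0.2),
    radius=0.4,
    length=20.0,
    axis="x",
):
    """Boolean mask of a straight cylinder along one axis, centered."""
    spacing = np.asarray(spacing)
    zz, yy, xx = np.meshgrid(
        *[np.arange(s) * d for s, d in zip(shape, spacing)], indexing="ij"
    )
    center = (np.asarray(shape) - 1) * spacing / 2
    coords = {"z": zz, "y": yy, "x": xx}
    along = coords[axis] - center["zyx".index(axis)]
    perp = [coords[a] - center["zyx".index(a)] for a in "zyx" if a != axis]
    r = np.sqrt(perp[0] ** 2 + perp[1] ** 2)
    return (np.abs(along) <= length / 2) & (r <= radius)


def make_arc_points(radius=5.0, arc_angle=2.0, n=400, offset=(10.0, 10.0, 10.0)):
    """Polyline on a circular arc of given radius in the y-x plane."""
    theta = np.linspace(0, arc_angle, n)
    pts = np.column_stack(
        [np.zeros(n), radius * np.sin(theta), radius * (1 - np.cos(theta))]
    )
    return pts + np.asarray(offset)


@pytest.fixture(scope="session")
def rendered_scene():
    """One noisy two-cell scene at SNR 5 with ground truth (session-cached)."""
    cfg = SceneConfig(target_snr=5.0, seed=11)
    return cfg, simulate_scene(cfg)


@pytest.fixture()
def ramp_volume():
    """Single-channel volume with intensity equal to physical x (µm)."""
    shape, spacing = (16, 16, 16), (0.4, 0.25, 0.25)
    zz, yy, xx = np.meshgrid(
        *[np.arange(s) * d for s, d in zip(shape, spacing)], indexing="ij"
    )
    return ImageVolume(xx[None].astype(float), spacing, ["ramp"])
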