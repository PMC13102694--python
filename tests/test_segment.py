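"""Instance segmentation and quality-control filters."""

import numpy as np
import pytest
from scipy.spatial import cKDTree

from tapetrace.errors import InconsistencyError, UndefinedGeometryError
from tapetrace.segment import (
    LabelVolume,
    pc1_explained_variance,
    qc_filter,
    segment_fibers,
    segment_somata,
    soma_label_of,
)
from tapetrace.skeleton import Centerline
from tapetrace.synthfib import (
    GrowthModel,
    RenderConfig,
    apply_noise,
    compose_fiber_record,
    photon_scale_for_snr,
    render_volume,
    simulate_growth,
)

SPACING = (0.4, 0.25, 0.25)


def _render_fibers(polylines, snr=5.0, seed=0, shape=(48, 64, 64)):
    cfg = RenderConfig(shape=shape, voxel_spacing=SPACING, background=15.0,
                       read_noise_sd=1.5, seed=seed)
    fibers = []
    for poly in polylines:
        arc = np.linalg.norm(np.diff(poly, axis=0), axis=1).sum()
        traj = simulate_growth(GrowthModel(t0=0, a=arc / 20, b=1, duration=10))
        fibers.append((compose_fiber_record(traj, {}, None, 100.0), poly))
    nf = render_volume(fibers, [], cfg, noise=False)
    peak = np.percentile(nf.noise_free.channel("structural"), 99.95) - cfg.background
    from dataclasses import replace

    cfg = replace(cfg, photon_scale=photon_scale_for_snr(peak, cfg.background, cfg.read_noise_sd, snr))
    return apply_noise(nf.noise_free, cfg), nf.ground_truth, cfg


def _tube_mask(poly, radius, shape, spacing):
    spacing = np.asarray(spacing)
    grids = [np.arange(s) * d for s, d in zip(shape, spacing)]
    zz, yy, xx = np.meshgrid(*grids, indexing="ij")
    coords = np.column_stack([zz.ravel(), yy.ravel(), xx.ravel()])
    d, _ = cKDTree(poly).query(coords, workers=-1)
    return (d <= radius).reshape(shape)


def _line(p0, p1, n=100):
    return np.linspace(p0, p1, n)


class TestSegmentFibers:
    def test_empty_volume_gives_zero_instances(self):
        lv = segment_fibers(np.zeros((20, 20, 20)), SPACING)
        assert lv.n_instances == 0

    def test_single_fiber_recovered_with_high_overlap(self):
        poly = _line((6.0, 4.0, 3.0), (6.0, 10.0, 12.0))
        vol, gt, cfg = _render_fibers([poly], snr=5.0, seed=1)
        lv = segment_fibers(vol.channel("structural"), SPACING)
        assert lv.n_instances == 1
        tube = _tube_mask(gt.fibers[0].polyline, cfg.fiber_radius, vol.shape, SPACING)
        mask = lv.mask(lv.ids[0])
        assert (mask & tube).sum() / tube.sum() >= 0.9

    def test_two_parallel_fibers_separated(self):
        # separation 4 µm >= 4 * max psf sigma
        p1 = _line((7.0, 5.0, 3.0), (7.0, 5.0, 12.0))
        p2 = _line((7.0, 9.0, 3.0), (7.0, 9.0, 12.0))
        vol, gt, cfg = _render_fibers([p1, p2], snr=6.0, seed=2)
        lv = segment_fibers(vol.channel("structural"), SPACING)
        assert lv.n_instances == 2

    def test_label_conservation(self):
        poly = _line((6.0, 4.0, 3.0), (6.0, 10.0, 12.0))
        vol, _, _ = _render_fibers([poly], seed=3)
        lv = segment_fibers(vol.channel("structural"), SPACING)
        # every nonzero voxel belongs to exactly one positive label
        assert (lv.labels >= 0).all()
        assert set(np.unique(lv.labels)) == set(range(lv.n_instances + 1))


class TestSegmentSomata:
    def _spheres(self, centers, radius=3.0, shape=(40, 48, 48), level=80.0):
        spacing = np.asarray(SPACING)
        grids = [np.arange(s) * d for s, d in zip(shape, spacing)]
        zz, yy, xx = np.meshgrid(*grids, indexing="ij")
        img = np.zeros(shape)
        for c in centers:
            d = np.sqrt((zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2)
            img = np.maximum(img, level * (d <= radius))
        return img

    def test_two_disjoint_spheres(self):
        img = self._spheres([(6, 5, 5), (10, 8, 8)])
        lv = segment_somata(img, SPACING, min_sep_um=2.0)
        assert lv.n_instances == 2

    def test_touching_spheres_split_by_watershed(self):
        # centers 4.8 µm apart at radius 3: overlap of 20% of the radius
        img = self._spheres([(8, 6, 5.0), (8, 6, 9.8)])
        lv = segment_somata(img, SPACING, min_sep_um=2.0)
        assert lv.n_instances == 2

    def test_empty_gives_zero(self):
        lv = segment_somata(np.zeros((20, 20, 20)), SPACING)
        assert lv.n_instances == 0


class TestPC1ExplainedVariance:
    def test_collinear_is_one(self):
        pts = np.outer(np.linspace(0, 1, 50), [1.0, 2.0, -0.5])
        assert pc1_explained_variance(pts) == pytest.approx(1.0)

    def test_isotropic_cloud_is_one_third(self):
        pts = np.random.default_rng(0).normal(size=(100_000, 3))
        assert pc1_explained_variance(pts) == pytest.approx(1 / 3, abs=0.01)

    def test_planar_cloud_is_one_half(self):
        rng = np.random.default_rng(1)
        pts = np.column_stack([rng.normal(size=50_000), rng.normal(size=50_000),
                               np.zeros(50_000)])
        assert pc1_explained_variance(pts) == pytest.approx(0.5, abs=0.01)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(UndefinedGeometryError):
            pc1_explained_variance(np.zeros((2, 3)))
        with pytest.raises(UndefinedGeometryError):
            pc1_explained_variance(np.ones((10, 3)))


def _straight_cl(length, n=200, origin=(2.0, 2.0, 2.0)):
    pts = np.linspace(origin, np.asarray(origin) + [0, 0, length], n)
    return Centerline(pts)


def _wavy_cl(length=10.0, n=400):
    # L-shaped path: low PC1 explained variance by construction
    half = np.linspace((2.0, 2.0, 2.0), (2.0, 2.0, 2.0 + length / 2), n // 2)
    half2 = np.linspace((2.0, 2.0, 2.0 + length / 2),
                        (2.0, 2.0 + length / 2, 2.0 + length / 2), n // 2)
    return Centerline(np.vstack([half, half2]))


def _qc_setup(centerlines, soma_everywhere=True):
    shape = (30, 60, 60)
    fiber_labels = np.zeros(shape, dtype=np.int32)
    for lab in centerlines:
        fiber_labels[lab, 0, 0] = lab  # placeholder voxels; qc uses skeletons
    soma = np.ones(shape, dtype=np.int32) if soma_everywhere else np.zeros(shape, np.int32)
    return (
        LabelVolume(fiber_labels, SPACING, "fiber"),
        LabelVolume(soma, SPACING, "soma"),
    )


class TestQCFilter:
    def test_eight_micron_length_cutoff(self):
        cls = {1: _straight_cl(7.9), 2: _straight_cl(8.1)}
        fl, sl = _qc_setup(cls)
        rep = qc_filter(fl, cls, sl)
        assert rep.survivors == [2]
        failed = next(f for f in rep.fibers if f.label == 1)
        assert failed.failure_reasons == ["geodesic_length"]

    def test_straight_fiber_inside_soma_passes(self):
        cls = {1: _straight_cl(10.0)}
        fl, sl = _qc_setup(cls)
        rep = qc_filter(fl, cls, sl)
        assert rep.fibers[0].pc1_explained_variance == pytest.approx(1.0)
        assert rep.fibers[0].passed

    def test_low_explained_variance_fails(self):
        cl = _wavy_cl()
        assert pc1_explained_variance(cl.points) < 0.8
        fl, sl = _qc_setup({1: cl})
        rep = qc_filter(fl, {1: cl}, sl)
        assert not rep.fibers[0].passed
        assert "pc1_explained_variance" in rep.fibers[0].failure_reasons

    def test_outside_soma_fails(self):
        cls = {1: _straight_cl(10.0)}
        fl, sl = _qc_setup(cls, soma_everywhere=False)
        rep = qc_filter(fl, cls, sl)
        assert rep.fibers[0].failure_reasons == ["outside_soma"]

    def test_missing_skeleton_is_inconsistency(self):
        cls = {1: _straight_cl(10.0)}
        fl, sl = _qc_setup({1: cls[1], 2: _straight_cl(9.0)})
        with pytest.raises(InconsistencyError):
            qc_filter(fl, cls, sl)

    def test_qc_monotone_in_thresholds(self):
        cls = {i: _straight_cl(4 + 2 * i) for i in range(1, 6)}
        fl, sl = _qc_setup(cls)
        prev = None
        for min_len in (4.0, 8.0, 12.0):
            surv = set(qc_filter(fl, cls, sl, min_length=min_len).survivors)
            if prev is not None:
                assert surv <= prev
            prev = surv

    def test_majority_vote_soma_assignment(self):
        shape = (30, 40, 40)
        soma = np.zeros(shape, dtype=np.int32)
        soma[:, :, :24] = 2   # 60% of a straight-x centerline
        soma[:, :, 24:] = 5
        sl = LabelVolume(soma, SPACING, "soma")
        cl = Centerline(np.linspace((2, 2, 0.0), (2, 2, 9.75), 40))
        assert soma_label_of(cl, sl) == 2
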