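# tapetrace

Readout stack for **intracellular protein-tape recorders**: from 3D
multi-channel confocal volumes of self-assembling protein fibers to
per-cell, time-resolved transcriptional-activity waveforms — plus a
ground-truthed forward simulator of tape growth and imaging, so every
stage is testable by parameter recovery without external data.

## The science

A tape fiber nucleates in a cell at time *t₀* and elongates symmetrically
from its center, depositing monomers at its growing tips; position along
the fiber therefore encodes time. Constitutive *structural* monomers form
the backbone, *timestamp* monomers record known-time events (dye switches
in culture, or an induction pulse in vivo), and promoter-driven *signal*
monomers record transcriptional activity at deposition time.

Decoding proceeds per fiber: instance segmentation → centerline
(1,000 equidistant points, extrapolated to the true termini) → per-channel
intensity profiles → optimal mirror split (Pearson-maximizing, searched
around the geometric center) → relative change from the baseline around
the split → timestamp anchors by changepoint detection → a monotone
transfer function *t(f)* from fraction-of-length *f* to days — linear for
one dye switch, quadratic/power for two, piecewise-linear through
induction-pulse anchors in vivo — → waveforms on a real-time axis, with
quality control (length ≥ 8 µm, skeleton PC1 explained variance ≥ 0.8,
soma containment) and majority-vote fiber→cell assignment throughout.

Per-cell analytics include peak amplitude/FWHM/onset/time-to-peak, a
line-length fluctuation statistic, time-lagged cross-correlation between
an upstream and a downstream signal, and a two-mode coupled/decoupled
classification of cells.

See `docs/methods.md` for models, parameters and numerical choices.

## Worked example

Simulate a two-cell volume at SNR 5, run the full readout, and recover
the promoter-pulse peak time:

```python
from tapetrace import PipelineParams, SceneConfig, run_pipeline, simulate_scene
from tapetrace.evaluate import (
    match_to_ground_truth, recovered_peak_time, true_peak_time,
)

cfg = SceneConfig(target_snr=5.0, seed=3)           # 128^3 voxels, 2 cells
res = simulate_scene(cfg)
out = run_pipeline(res.volume, PipelineParams(
    schedule_times=[5.5], fixation_time=cfg.fixation_time))

matched = match_to_ground_truth(out.centerlines, res.ground_truth)
for lab, ro in out.readouts.items():
    gt = res.ground_truth.fibers[matched[lab]]
    print(f"fiber {lab}: split r={ro.split.pearson_r:.3f}  "
          f"peak {recovered_peak_time(ro, 'signal'):.2f} d "
          f"(true {true_peak_time(gt, 'signal'):.2f} d)")
```

prints (seed 3):

```
fiber 1: split r=0.966  peak 7.30 d (true 7.28 d)
fiber 2: split r=0.927  peak 7.63 d (true 7.30 d)
```

Both fibers pass quality control, the mirror split is found near the
geometric center with r ≈ 0.93–0.97, and the day-7 activity pulse is
recovered to a few tenths of a day through a transfer function anchored
at the day-5.5 dye switch and the fixation terminus.

The same flow is scriptable:

```bash
tapetrace simulate --config sim.yaml --seed 3 --out scene/
tapetrace run --in scene/volume.tif --config params.yaml --out out/
```

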