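# microwound

Quantification pipeline for wound-closure assays in engineered 3D
microtissues — sub-millimetre fibroblast–collagen constructs suspended
between flexible PDMS cantilevers, wounded microsurgically and imaged by
time-lapse microscopy (typically every 30 min for 24 h). From calibrated
multi-frame TIFF stacks the package measures:

- **Gap morphometrics** — per-frame brightness-threshold segmentation of
  tissue vs background, extraction of the wound as the largest background
  region fully enclosed by tissue, and shape descriptors: area
  *A = N·p²* (pixel count × pixel size²), centroid, equivalent-ellipse
  semi-axes from the second central moments (*a, b = 2√λ₁, 2√λ₂* of the
  coordinate covariance), circularity *4πA/P²* (Crofton perimeter), and
  tissue width.
- **Closure kinetics** — the gap widens briefly after wounding, then closes
  at a constant rate; the closure rate is −slope of an ordinary
  least-squares line on (t, A) from the widening peak to the last open
  frame, with its standard error, plus closure time, centroid drift and
  relative closure against vehicle controls.
- **Migration directionality** — Laplacian-of-Gaussian nuclei detection,
  greedy shortest-first track linking, and per-track radial migration
  angles (0° = toward the gap centroid, 90° = tangential, folded to
  [0, 180]°) summarized as windrose histograms, with edge vs distal
  (≥ 100 μm from the wound edge) location classes and maximum speeds.
- **Tissue tension** — cantilever-cap bead tracking by iterated
  intensity-weighted centroids; total tension *F(t) = k·(δ₀(t) + δ₁(t))*
  from the per-cantilever deflections δ against post-release rest
  positions and the calibrated spring constant *k* (default
  2.67 μN μm⁻¹), normalized to the pre-wound baseline.

Because raw assay videos are rarely shareable, the package also ships a
**synthetic scene generator** (`microwound.scene`) that renders calibrated
three-channel stacks (tissue band, nuclei, cantilever beads) with exact
ground truth — an elliptical gap with decaying edge roughness following a
prescribed area trajectory, tangential edge / radially inward distal cell
tracks, and beads displaced by a piecewise-linear tension profile — used
throughout the test suite for parameter-recovery validation.

## Worked example

```python
import numpy as np
import microwound as mw

cfg = mw.SceneConfig(seed=1)          # 30,000 μm² gap closing at 1,344 μm²/h
scene = mw.render_scene(cfg)

series = mw.morphometrics_series(scene.tissue)
print(mw.estimate_closure_rate(series).summary())

gt = scene.ground_truth
tracks = mw.track_beads(scene.beads, gt.bead_positions[:, 0], search_radius=8.0,
                        cantilever_ids=gt.bead_cantilever)
ts = mw.total_tension(mw.deflections(tracks, gt.bead_rest),
                      cfg.spring_constant, gt.times)
print(f"baseline {ts.baseline_tension:.2f} μN, "
      f"peak {ts.tension.max():.2f} μN at t = {ts.times[np.argmax(ts.tension)]:.1f} h")
```

prints

```
Closure kinetics
  closure rate       : 1343.8 ± 0.3 μm²/h
  fit window         : 1.00 – 24.00 h (47 frames, r² = 1.0000)
  widening peak      : 36001 μm² at t = 1.00 h
  closure time       : not closed
  centroid drift     : 0.90 μm
baseline 12.54 μN, peak 16.28 μN at t = 11.5 h
```

i.e. the pipeline recovers the generative closure rate (1,344 μm² h⁻¹) to
within its standard error from a noisy rendered movie, the fitted line is
essentially exact after the 1-h widening phase, the wound centroid stays
stationary to sub-pixel precision, and the recovered tension time course
shows the post-wound drop, the ~10 h contraction peak and the sub-baseline
plateau that were generated.

The same steps are available from the shell:

```sh
microwound simulate --out scene/
microwound measure --stack scene/tissue.tif --pixel-size 1.6 --frame-interval 0.5 --out morpho.csv
microwound kinetics --morpho morpho.csv --out kinetics.json
microwound track   --stack scene/nuclei.tif --morpho morpho.csv \
    --pixel-size 1.6 --frame-interval 0.5 --out tracks.csv --windrose rose.csv
microwound tension --stack scene/beads.tif --beads init.csv --baseline rest.csv \
    --k 2.67 --pixel-size 1.6 --frame-interval 0.5 --out tension.csv
```

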