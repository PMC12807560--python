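# nircat-release

Analysis pipeline for electrically evoked dopamine release imaged with
near-infrared catecholamine nanosensors (nIRCats) in acute striatal brain
slices — plus a synthetic-movie simulator so every stage can be exercised
and validated without raw microscope data.

## Who this is for

Labs measuring evoked neurotransmitter release as time-lapse fluorescence
movies (one stack per electrical-stimulation trial) who want the standard
ROI-grid analysis as a tested, scriptable package: hotspot detection,
transient kinetics, per-slice release metrics, and hierarchical group
statistics over a nested design (slices within animals, treatment groups,
striatal regions DMS / DLS / NAc).

## The analysis

1. **ROI grid.** Each field of view (178 × 142 µm by default) is tiled into
   square ROIs, 7 × 7 µm by default — `⌈178/7⌉ × ⌈142/7⌉ = 546` tiles, with
   partial edge tiles retained. 4 µm and 10 µm grids are supported as
   resolution controls.
2. **ΔF/F₀ and active sites.** Per ROI, ΔF/F₀ = (F − F₀)/F₀ with F₀ the
   mean over the pre-stimulation baseline (200 of 600 frames at 9 frames/s
   by default). An ROI is an **active release site** when its peak
   post-stimulation ΔF/F₀ exceeds 3 × the standard deviation of its
   baseline ΔF/F₀ fluctuations (plus a small absolute floor that only
   matters for noiseless synthetic input). **Release site density** is the
   percentage of active ROIs.
3. **Kinetics.** Active-ROI transients are fit with the rise–decay model

   dF/F₀(t) = A · (1 − e^(−t/τ_on)) · e^(−t/τ_off) + B,  t ≥ 0 from stimulation,

   by nonlinear least squares (τ in log space). Fits with τ_off > 10 s are
   excluded from downstream metrics.
4. **Per-slice metrics.** Each slice is stimulated three times (two if the
   electrode loses contact); density, mean peak ΔF/F₀ over active sites,
   and mean non-excluded τ_off are computed per replicate and averaged.
5. **Group statistics.** Linear mixed-effects models (REML, random intercept
   per animal): treatment fixed (t with df = animals − 2) or region fixed
   with single-step (Tukey-style) adjusted pairwise z contrasts. Effect
   sizes: Cohen's f² (marginal R²), partial η², Hedges' g (small-sample
   correction J = 1 − 3/(4ν − 1)). Within-subject metric associations use
   the repeated-measures correlation r_m (uncorrected p).

The simulator plants Gaussian-footprint hotspots (default σ median 1.5 µm;
~98% of 95%-mass diameters ≤ 7 µm) whose time courses follow the same
rise–decay model, multiplicative on a noisy camera baseline, and emits
ground-truth manifests for every planted site.

## Worked example

```python
import numpy as np
from nircat import (AcquisitionProtocol, NoiseModel, manifest_for_density,
                    simulate_movie, build_grid, extract_traces, call_active,
                    site_density, fit_kinetics)

protocol = AcquisitionProtocol()          # 9 fps, 600 frames, stim at 200
noise = NoiseModel()                      # baseline 1000, additive SD 15
manifest = manifest_for_density(40.0, seed=1, protocol=protocol, noise=noise,
                                amplitude=0.05)
stack = simulate_movie(manifest)

grid = build_grid(protocol.fov_width_um, protocol.fov_height_um, 7.0,
                  protocol.um_per_pixel)
traces = extract_traces(stack, grid, protocol.stim_frame)
calls = call_active(traces, protocol.stim_frame)          # k = 3, eps 0.005
active = [c for c in calls if c.is_active]

print(f"grid: {grid.n_tiles} ROIs ({grid.n_tiles_x} x {grid.n_tiles_y})")
print(f"active release sites: {len(active)} "
      f"(density {site_density(calls, grid):.1f}%, planted 40.1%)")
print(f"mean peak dF/F0 over active sites: "
      f"{np.mean([c.peak_dff for c in active]):.4f}")

tr = max(traces, key=lambda t: t.dff[protocol.stim_frame:].max())
fit = fit_kinetics(tr.dff, protocol.stim_frame, protocol.frame_rate)
print(f"brightest ROI fit: tau_on = {fit.tau_on_s:.3f} s, "
      f"tau_off = {fit.tau_off_s:.2f} s, excluded = {fit.excluded}")
```

prints

```
grid: 546 ROIs (26 x 21)
active release sites: 227 (density 41.6%, planted 40.1%)
mean peak dF/F0 over active sites: 0.0134
brightest ROI fit: tau_on = 0.235 s, tau_off = 4.75 s, excluded = False
```

The measured density (41.6%) tracks the planted tile occupancy (40.1%); the
mean *tile-level* peak (0.0134) is lower than the planted per-site amplitude
(0.05) because the ~3 µm-wide footprint is averaged over the 7 µm tile; the
fitted decay constant recovers the planted τ_off = 5 s within noise and
falls under the 10 s exclusion cutoff.

The same stages are available from the shell:

```bash
nircat simulate --n-hotspots 40 --seed 1 --out-tiff movie.tif --out-manifest truth.yaml
nircat detect --stack movie.tif --tile-um 7 --out calls.csv
nircat run --manifest samples.csv --out-dir results/
nircat sweep --manifest samples.csv --out-dir sweep/ --tile-sizes 4,7,10
```

## Layout

| module | role |
| --- | --- |
| `nircat.synthetic` | movie + metrics-table simulators, ground-truth manifests |
| `nircat.stack_io` | TIFF stacks, sample manifests, CSV tables |
| `nircat.roi` | grid construction, ΔF/F₀ traces, active-site calls |
| `nircat.kinetics` | rise–decay fits, analytic peak, exclusion rule |
| `nircat.aggregate` | replicate → slice metrics, analysis table |
| `nircat.stats` | mixed models, Tukey contrasts, effect sizes, rmcorr |
| `nircat.pipeline` / `nircat.cli` | end-to-end runs, grid-size sweep, `nircat` CLI |

See `docs/methods.md` for the modeling assumptions, parameter defaults, and
known limitations.
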