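# Methods

This note documents the models, defaults, and numerical choices behind the
package, and what the synthetic-data validation does and does not establish
about real recordings.

## Acquisition model

A trial is a single-channel movie of `n_frames` frames at `frame_rate`
frames/s; an electrical stimulus is delivered at `stim_frame` (0-based, the
first frame at/after stimulus onset). Defaults mirror the slice protocol:
9 frames/s, 600 frames, stimulation after 200 baseline frames, a
178 × 142 µm field of view. The pixel pitch is not dictated by the
acquisition constants; `um_per_pixel` defaults to 0.5 µm/px and is fully
configurable — every spatial computation goes through it.

## Synthetic movies

The expected intensity at pixel (x, y) and frame t is

```
E[F] = baseline · bleach(t) · (1 + Σ_h A_h · G_h(x, y) · κ_h(t − t_stim))
```

* `G_h` — isotropic 2-D Gaussian footprint, peak-normalized to 1 at the
  hotspot center, so the planted amplitude `A_h` is the expected
  *pixel-level* peak ΔF/F₀ at the center (the tile-level peak is smaller by
  the footprint-over-tile average). Footprint support is truncated at 7σ
  (weight < 2×10⁻¹¹) so rendering cost is local per hotspot.
* `κ_h(t) = (1 − e^(−t/τ_on)) e^(−t/τ_off)` for t ≥ 0, zero before
  stimulation. Peak at `t* = τ_on ln(1 + τ_off/τ_on)`.
* `bleach(t)` — optional monoexponential baseline decay reaching
  `1 − bleach_fraction` at the last frame; off by default, used to probe
  baseline-estimation robustness.
* Noise — additive i.i.d. Gaussian per pixel per frame (`additive_sd`,
  default 15 counts on a baseline of 1000), drawn from one generator seeded
  by the manifest seed after the deterministic expectation is computed, so
  a (manifest, seed) pair reproduces the stack bit-identically. Poisson
  shot noise is deliberately omitted at this signal scale.

Intensities stay continuous in memory; quantization to the 16-bit unsigned
disk grid happens only on TIFF export. This keeps the in-memory movie an
exact realization of the model while disk round trips remain bit-exact for
quantized stacks.

**Footprint size distribution.** Real release sites vary in extent, with
the large majority confined within 7 µm. Footprint σ is drawn lognormal
with median 1.5 µm and 8% log-scale spread. The "95%-mass diameter" of a
footprint is the central 95% interval of its Gaussian profile,
`2 × 1.96 σ` (≈ 5.9 µm at σ = 1.5 µm); under the default distribution ~98%
of diameters fall at or below 7 µm, honoring the observed ≥ 95%
restriction with margin rather than sitting at the boundary.

**Placement.** `random_manifest` places hotspots uniformly in the FOV.
`manifest_for_density` instead samples the requested fraction of grid tiles
and plants one hotspot at each sampled tile's center: tile occupancy — the
ground truth that `planted_density` defines — is then exact, and footprint
spillover into neighboring tiles is negligible. Detection calibration uses
this placement; uniform placement genuinely blurs tile membership for
centers near tile edges and is kept for realism elsewhere.

## Detection

The FOV is tiled by ceiling division on both axes anchored at the origin;
partial edge tiles are kept (178/142 at 7 µm → 26 × 21 = 546). If the
nominal FOV extent is not a whole number of pixels the last nominal tile
can own no pixel; such empty trailing tiles are dropped so the tiles always
partition the pixel frame exactly. Tiles below the pixel pitch are
rejected.

Per ROI: raw trace = unweighted pixel mean per frame; F₀ = mean raw over
frames [0, stim); ΔF/F₀ = (raw − F₀)/F₀; baseline SD = sample (n−1) SD of
the baseline ΔF/F₀ — computed on ΔF/F₀, not raw counts, so the threshold is
unit-free and gain-invariant. An ROI is active when its peak ΔF/F₀ over
[stim, end] strictly exceeds both `k × baseline_sd` (k = 3) and an absolute
floor `eps_abs = 0.005` ΔF/F₀. The floor guards the σ = 0 degeneracy of
noiseless synthetic input and bounds the false-positive rate of the
max-over-frames statistic; at the default noise level it sits at ~4.7
tile-level σ, giving a per-tile false-positive probability well under 2%.
Real acquisitions always carry baseline noise, so the floor is effectively
a synthetic-data guard; it is configurable. Whether the published
threshold was applied to the peak of ΔF/F₀ (our reading) or some other
statistic of "fluorescence change" is not stated in the protocol we
follow; the choice is isolated in `call_active`.

## Kinetics

Nonlinear least squares of the rise–decay model over t ≥ 0 (baseline frames
excluded), with τ_on, τ_off in log space (positivity without bounds) and an
analytic Jacobian. Data-driven starts: B from the last five baseline
frames, A from the trace peak, τ_off from the post-peak 1/e fall time,
τ_on from the half-rise time. Convergence tolerances 1e-10 (relative
change in cost/step), max 500 iterations; non-convergence is reported, not
raised, and an all-zero trace is flagged degenerate. Fits with
τ_off > 10 s are flagged `excluded` after fitting and contribute no τ_off
to any downstream aggregate. τ_on is computed and reported but carries no
validation claims beyond fit recovery; with a 0.2 s rise sampled at 9
frames/s it rests on ~2 frames and is weakly identified in noise.

Fits are computed per active ROI; the field-of-view mean trace can be fit
with the same routine as a diagnostic.

## Aggregation

Metrics are computed per replicate, then averaged over the slice's 2–3
replicates (metric-then-average, matching replicate loss semantics; the
pooled-trace alternative is not the default). A replicate with zero active
ROIs contributes 0 to density and is skipped for the peak/τ_off means;
a slice whose every replicate is empty keeps missing cells, and downstream
models drop missing cells listwise. One replicate is below the protocol's
minimum and is an error (the pipeline logs and skips such slices).

## Group statistics

* **Treatment model** (per region): REML fit of `metric ~ treatment` with a
  random intercept per animal; t = coefficient/SE referred to a t
  distribution with `n_animals − 2` df (the animal-level df of a two-group
  design, matching t(10) reporting at 6+6 animals). Two statsmodels
  boundary cases are handled exactly rather than numerically: zero
  within-group variance returns a flagged degenerate result, and zero
  residual (within-animal) variance collapses analytically to the
  two-sample t on animal means — the exact limit of the mixed model.
  Optimizer fallbacks (default, Powell, Nelder-Mead, L-BFGS) absorb
  boundary-induced failures of the gradient-based REML optimizer.
* **Region model** (per treatment group): REML fit of `metric ~ region`
  (animal random intercept); omnibus Wald F with containment-style
  denominator df `n_obs − n_animals − df1`; all pairwise region contrasts
  with z statistics and single-step adjusted p computed by Monte-Carlo
  integration of the equicoordinate multivariate-normal probability
  (200,000 draws, fixed internal seed). The adjusted p is clipped to be at
  least the unadjusted p — exact in theory, enforced against MC jitter.
* **Effect sizes.** Cohen's f² = R²ₘ/(1 − R²ₘ) with marginal R² = variance
  of the fixed-effects predictor over (fixed + animal + residual); this is
  a declared convention — published mixed-model f² recipes vary and the one
  this emulates is not printed anywhere we can check. Partial
  η² = F·df₁/(F·df₁ + df₂). Hedges' g uses the slice-level pooled SD and
  the small-sample correction J = 1 − 3/(4ν − 1) (the convention under
  which {4,5,6} vs {1,2,3} gives exactly 2.4).
* **rmcorr.** The common within-subject correlation, computed by centering
  both metrics on subject means (identical to the shared-slope ANCOVA
  formulation), df = N_obs − N_subjects − 1, uncorrected p. Subjects with
  fewer than two complete observations are dropped with a log entry.

## Metrics-level design simulator

`simulate_metrics_table` draws per-slice metric values as
`group mean + animal effect + slice residual`, with the animal effect
shared across that animal's rows. Default group means echo the magnitudes
typical of the three striatal regions under sham/GDX (densities ~13–46%,
peaks ~0.02–0.05 ΔF/F₀, τ_off ~4.7–5.9 s); defaults for the
calibration/power suites use 6 animals/group × 2 slices with
animal SD = 13 and slice SD = 10 density points, which puts the group-mean
SEM near 6 points — the scale of the published per-group SEMs. Type-I
calibration runs 1,000 null tables (nominal 5%, accepted band the 99%
binomial interval 3.2–6.8%); power uses 200 tables under a 22-point density
gap and requires > 50% rejection — a consistency check that such a design
can detect an effect of that size, not a reproduction of any group result.

## Validation scales

The test suite exercises the full-size protocol (600-frame, 546-ROI
stacks) for the ΔF/F₀ oracle, kinetic recovery, and detection calibration
(10 planted-density movies), and scaled-down movies (≈ 30 × 24 µm, 80–150
frames) for end-to-end pipeline runs — sizes chosen to keep the suite
quick while covering every code path at least once at full scale.
`scripts/acceptance.py` samples 1,000 footprints for the spatial-extent
fraction.

## What passing tests do and do not show

The simulator validates the *machinery*: grid arithmetic, baseline
normalization, thresholding, fitting, exclusion, aggregation and the
statistical stack, against ground truth and closed-form oracles. It does
not emulate nanosensor photophysics, stimulation artifacts, tissue
autofluorescence, slice drift, shot noise, or spatially correlated
background — so passing tests certify correctness of the analysis given
the stated acquisition model, not performance on any particular
microscope's data. Group-level biological results depend on raw recordings
the package does not ship and are out of scope.

## Known limitations

* Single-pulse transients only; no paired-pulse or overlapping-release
  deconvolution.
* No image registration or motion correction (slice acquisitions are
  assumed stationary).
* τ_on is weakly identified at 9 frames/s and reported without claims.
* The mixed-model df conventions (animals − 2; containment-style region
  df) are declared choices where the emulated reporting is silent.
* Adjusted p values use Monte-Carlo integration; they are reproducible
  (fixed seed) but carry ~10⁻³-scale MC error.
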