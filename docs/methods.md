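# Methods

## The measurement

Many nuclear proteins (PARP1 is the motivating example) are sequestered in
nucleoli and released into the nucleoplasm under genotoxic stress.
`nucleoshuttle` quantifies this relocation from three-channel live-cell
time-lapse movies: a nuclear stain (e.g. SiR-Hoechst) delineates nuclei, a
nucleolar marker (e.g. NPM1-mCherry) delineates nucleoli, and the
protein-of-interest (POI) channel is measured. For every cell and time
point the readout is

    r(t) = mean POI intensity over the nucleolar region
           / mean POI intensity over the nucleoplasmic region  - 1

so r = 0 means no nucleolar enrichment. The nucleoplasm is defined
operationally as the nucleus mask minus the (pooled) nucleolar mask of that
cell. Aggregation is per-cell ratio -> per-image mean over cells ->
per-condition mean +/- SEM over images: the microscopic image is the
replication unit, so the SEM is computed across images, never across cells.

## Pipeline stages

1. **File handling** (`imgio`). One TIFF/OME-TIFF per imaging position;
   well, scene and position are encoded in the file name as
   `<prefix>_w-<well>_s-<scene>_p-<position>.<ext>`. The well -> condition
   mapping comes from the run config. An empty file listing is an error: a
   misconfigured folder can never produce a silent empty run.
2. **Nuclei segmentation** (`segment_nuclei`). Otsu binarization of the
   nuclear-stain channel, hole filling, then either plain 8-connected
   components (`global` backend) or a marker-controlled watershed on the
   smoothed distance transform (`watershed` backend). The global backend is
   retained deliberately: it merges touching nuclei, and that documented
   failure is part of the test suite. Both are followed by a size filter
   (default 200 px at the simulator's scale) and removal of border-touching
   objects. Externally computed masks (e.g. from a neural-network tool) can
   be supplied per frame through `load_external_masks` and pass the same
   filter stage.
3. **Nucleoli segmentation** (`segment_nucleoli`). A random-forest pixel
   classifier on a multi-scale filter bank (raw intensity plus, per scale
   sigma in {1, 2, 4} px: Gaussian, gradient magnitude, Laplacian of
   Gaussian, difference of Gaussians (sigma, 1.6 sigma), structure-tensor
   eigenvalues - 19 features). Trained on sparse brush-stroke labels of the
   classes *nucleolus* and *background*, with equal per-class sample
   weighting. The probability map is binarized with Otsu's threshold
   (per-image, not a fixed 0.5 - it adapts to the map's contrast),
   median-filtered (disk radius 1 px) and instance-labeled. Nucleoli are
   not border-filtered and keep a small minimum area (5 px) so faint
   nucleoli survive. A plain global-threshold path (`threshold_instances`)
   exists only as the comparison baseline: one global cutoff cannot serve
   cells whose marker expression spans a 4-fold range, and the tests assert
   that the classifier's object recall beats it by at least 0.2 on that
   designed scene.
4. **Quantification** (`quantify`). Each nucleolus is assigned to the
   nucleus of maximal pixel overlap (ties to the lower nucleus label;
   orphans are discarded and logged; pixels protruding beyond the assigned
   nucleus are clipped), guaranteeing exact area conservation
   |nucleus| = |nucleolar| + |nucleoplasm| per cell. Cells with an empty
   nucleolar mask or a non-positive nucleoplasmic mean are excluded from
   that frame and counted. Multiple nucleoli are pooled into one
   pixel-area-weighted nucleolar mean per cell (not averaged per
   nucleolus). No camera-offset subtraction is applied by default.
5. **Line profiles** (`profiles`). Bilinear sampling at unit-px spacing
   along a user-defined segment, identical positions in all channels;
   normalization to the channel maximum of a reference frame (own-frame
   maximum by default, t0-referenced or joint-maximum optional);
   trapezoidal AUC, with AUC(t_end)/AUC(t0) as the chromatin-stain change
   metric. This mirrors the manual viewer-based analysis and serves as an
   independent cross-check on the automated series.

## The kinetic model

The simulator and the fitting utility share a single-exponential relaxation

    E(t) = E_inf + (E0 - E_inf) * exp(-t / tau)

where E0 is the baseline nucleolar enrichment (dimensionless, >= 1), E_inf
the post-treatment plateau and tau the time constant in minutes. This is
the simplest law consistent with the observed phenomenology - release
starting immediately at treatment and plateauing after roughly three time
constants (default tau = 30 min puts ~95% of the transition inside 90 min).
`recover_kinetics` fits r(t) = (E_inf - 1) + (E0 - E_inf) exp(-(t-t0)/tau)
by multi-start nonlinear least squares (tau starts {5, 15, 30, 60, 120} min
plus three seeded random starts; parameters bounded non-negative). A series
whose standard deviation is below 1e-3 of its scale is reported as
unidentifiable rather than fitted.

## What the simulator emulates - and what it does not

`simulate.render_movie` draws non-overlapping, randomly oriented elliptical
nuclei (radius 14 +/- 2 px) with a smooth +/-10% intranuclear texture; a
configurable fraction of cells (default 0.3) is placed touching a neighbor
to reproduce cell clustering. Each nucleus holds 1-4 disk nucleoli (radius
4 +/- 0.8 px) kept >= 2 px inside the nuclear envelope. Defaults follow the
acquisition they emulate: 5-min frame interval, 25 frames (0-120 min),
30 cells per image, five images per condition. The marker channel is
constant over time (the marker's localization is assumed stable) with a
per-cell brightness factor drawn from a 4-fold range - uniformly, or
bimodally for the designed mixed-brightness scene. The POI channel is
piecewise constant per cell: nucleoplasmic baseline b ~ U(80, 120) and
nucleolar level b * E(t), which makes the noise-free ratio exactly E(t).
The camera model is Poisson photon noise (default 50 photons per intensity
unit), additive Gaussian read noise (sd 2), clipping and 16-bit
quantization.

Geometry and intensity scales were fixed once at a desk-scale 360 x 360 px
default; they are a coarse stand-in for a 20x/2x-binned field of view.

Not emulated, by design: cell motion, division and focus drift (the
emulated acquisition uses hardware focus stabilization and the analysis is
strictly per-frame); photobleaching and phototoxicity; 3D point-spread
rendering; nucleolar disintegration or marker relocalization. Passing tests
therefore demonstrate correctness of the measurement machinery on
plausible, noisy, clustered scenes with known truth - they do not
demonstrate robustness to drift, bleaching or atypical nucleolar
morphologies in real data.

In **noise-free mode** (`SimConfig.without_noise()`), both noise sources
and the integer quantization are skipped and frames are float64. This mode
exists for exact arithmetic: with truth masks the recovered series equals
E(t) - 1 to float tolerance, which the tests assert. With noise enabled,
quantized integer output is always produced.

## Numerical choices

- Otsu: 256-bin histogram over [min, max]; ties broken toward the lowest
  maximizing threshold; pixels strictly greater than the threshold are
  foreground. A constant image is a degenerate-input error everywhere
  except on probability maps, where it yields an empty labeling.
- Connectivity is 8-connected for all instance labeling.
- Watershed seeding: distance transform smoothed with sigma = 2 px, local
  maxima separated by >= 10 px. Below the typical nucleus diameter
  (~28 px), above the nucleolus scale, so nuclei are not oversplit.
- `filter_labels` relabels survivors 1..K preserving the relative order of
  the original labels, and is idempotent.
- The truncated discrete Laplacian-of-Gaussian kernel has a ~1e-4 relative
  DC response; harmless for classification, acknowledged in the tests.
- Coordinates are 0-based, row-major, origin top-left. The output time
  column is `iteration * frame_interval_min` with 0-based frame indices.
- Seeds: every stochastic component (simulator, forest training, fit
  multi-start) takes an explicit seed; identical config + seed gives
  bit-identical movies, probability maps and output CSVs.

## Problem sizes used in validation

The validation suite and `scripts/acceptance.py` run the full pipeline
(watershed nuclei + trained pixel classifier) on 5 simulated images x
30 cells x 25 frames at default noise for parameter recovery, and
2 images x 30 cells x 25 frames per condition for the three-condition dose
ordering. These sizes match the emulated experiment's per-condition scale
while keeping a complete validation run within a few minutes on one CPU.

## Known limitations

- No tracking: cells are re-segmented per frame, so per-cell trajectories
  across frames are not available (only per-image aggregates are exported
  by default; a per-cell long-format table is an option).
- The watershed backend assumes star-convex nuclei; heavily elongated or
  overlapping (not merely touching) nuclei will be mis-split.
- The classifier is only as good as its brush-stroke labels; the shipped
  training fixture generates them from simulation truth, which is cleaner
  than interactive labels on real data.
- Enrichment estimates inherit a small dilution bias when the nucleolar
  mask includes boundary pixels; with the default geometry this stays well
  inside the tolerances the validation suite asserts.
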