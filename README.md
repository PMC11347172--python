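# nucleoshuttle

Automated quantification of **nucleolar–nucleoplasmic protein shuttling**
in live-cell time-lapse fluorescence microscopy.

Many nuclear proteins — PARP1 is the motivating example — are sequestered
in nucleoli and released into the nucleoplasm under genotoxic stress.
`nucleoshuttle` measures this relocation from three-channel 2D time-lapse
movies (nuclear stain for nuclei, a nucleolar marker such as NPM1-mCherry
for nucleoli, and the protein of interest, POI) acquired one file per
imaging position. For every cell and time point it computes

    r(t) = mean_nucleolar(POI) / mean_nucleoplasmic(POI) − 1

where the nucleoplasm is the nucleus minus that cell's pooled nucleoli,
and aggregates per-cell ratios to a per-condition time series
(mean ± SEM across microscopic images, the replication unit). A built-in
simulator renders ground-truthed synthetic movies — nuclei with 1–4
marker-bright nucleoli, POI enrichment decaying as
E(t) = E∞ + (E0 − E∞)·e^(−t/τ) after treatment, Poisson + Gaussian camera
noise, cell clustering — so every stage is validated against known truth
without any external data.

The pipeline: file listing and position-metadata parsing → stack reading
(TIFF/OME-TIFF, axes normalized to T×C×Y×X) → nuclei instance segmentation
(Otsu + connected components as the merging baseline, marker-controlled
watershed as the default, or externally computed masks) → nucleolus
segmentation by a trainable random-forest pixel classifier on multi-scale
filter-bank features (probability map → Otsu → median filter → instance
labels) → label arithmetic and per-cell feature extraction → ratio series
and exponential-kinetics fitting → CSV + spreadsheet export. A
line-profile module reproduces the manual viewer-based cross-check
(normalized profiles, AUC ratios).

## Worked example

`examples/quantify_shuttling.py` simulates five movies of one condition
(30 cells × 25 frames at 5-min intervals, E0 = 3, E∞ = 1.2, τ = 30 min),
runs the full segmentation pipeline (watershed nuclei + trained pixel
classifier) and fits the kinetic model:

```
condition  time_min  ratio-1   SEM    n_images  n_cells
     H2O2         0    1.951  0.002         5      150
     H2O2        30    0.843  0.001         5      150
     H2O2        60    0.434  0.001         5      150
     H2O2        90    0.284  0.000         5      150
     H2O2       120    0.229  0.000         5      150

fitted kinetics: E0 = 2.951, E_inf = 1.196, tau = 30.1 min (rmse 0.0003)
generating truth: E0 = 3.000, E_inf = 1.200, tau = 30.0 min
```

The series starts near E0 − 1 = 2 (strong nucleolar enrichment) and
plateaus near E∞ − 1 = 0.2 by ~90 min (three time constants); the fit
recovers the generating parameters through the full segmentation path.
The other examples show single capabilities: `simulate_movie.py` (the
ground-truthed simulator), `classifier_vs_threshold.py` (why one global
threshold fails on cells with 4× dimmer marker expression while the pixel
classifier does not), `line_profile_auc.py` (profile normalization and the
AUC(120 min)/AUC(0 min) chromatin-stain metric).

## Command line

A thin CLI wraps the library for batch use:

```bash
nucleoshuttle simulate --out-dir data/ --n-images 5 --seed 1
nucleoshuttle train-classifier --image marker.tif --labels brush.tif --model-out clf.joblib
nucleoshuttle run-all --config run.yaml
nucleoshuttle quantify --config run.yaml --fit-kinetics
nucleoshuttle profile --stack data/sim_w-B2_s-1_p-1.ome.tif --p0 60 10 --p1 60 80 --out prof.csv
```

Runs are driven by a validated YAML config (input folder and name pattern,
channel roles, well→condition table, backend choices, output paths, seed);
outputs are byte-reproducible given the same config, seed and inputs, and
every output file carries the config hash in its header.

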