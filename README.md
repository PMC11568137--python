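# mpoct

Topographic structure/function analysis for microperimetry (MP) and OCT in
intermediate AMD, built entirely around synthetic data with known ground
truth. The package simulates eyes and dual-device microperimetry exams,
co-registers device stimulus grids onto OCT en-face space via vessel
junctions, quantifies biomarkers within a 70 µm radius of each stimulus,
and fits random-intercept mixed-effects structure/function models with
BIC-based model selection.

## Modules

| Module | Role |
| --- | --- |
| `mpoct.synthgen` | Synthetic eyes (EZ/ONL thickness, drusen/SDD height, HRF components), vessel trees, fundus renders, 45-point stimulus grids, 4–2 staircase simulation, direct/psychophysical cohort generation, CSV/PNG/JSON export |
| `mpoct.register` | Vessel segmentation (multi-scale ridge filter), skeleton junction detection, 2-point RANSAC correspondence, closed-form least-squares similarity estimation, en-face→B-scan lookup |
| `mpoct.quantify` | Per-stimulus disc extraction on the anisotropic OCT grid, thickness means and deposit volumes (nl), HRF component filtering at 0.06 nl, MAIA −1→0 adjustment, long-format analysis table |
| `mpoct.stats` | Random-intercept LMMs (ML/REML), marginality-respecting candidate enumeration, BIC selection, marginal R² (fixed-effects variance fraction), eccentricity-dependent slopes with Wald CIs, Spearman, univariate/dichotomized deposit models, descriptive summaries |
| `mpoct.cli` | YAML config, logging, `simulate` / `register` / `quantify` / `analyze` / `run-all` orchestration |

## CLI

```sh
# full pipeline on a 20-patient synthetic cohort
mpoct run-all --seed 1 --n-patients 20 --out runs/demo

# psychophysical (staircase) measurement mode, custom config
mpoct run-all --config my.yaml --mode psychophysical --out runs/stair
```

Outputs in the run directory: cohort exports (`stimuli.csv`, `fundus.png`,
en-face map CSVs), registration JSONs, `analysis_table.csv` (one row per
patient × device × run × point), model coefficient/slope/descriptive
tables, and a `manifest.json` that reproduces the run byte-for-byte.

By default the pipeline quantifies through the hidden ground-truth
transforms (fast, exact). Set `render_fundus: true` and
`use_true_transforms: false` in the YAML config to run the full
image-based registration path.

## Conventions

* En-face frame: origin at the scan corner, x along A-scans, y along
  B-scans, µm units; 97 × 512 grid over 20°×20° at 288 µm/deg by default
  (≈60 µm between B-scans, ≈11.3 µm between A-scans).
* Volumes are nanolitres (1 nl = 10⁶ µm³); disc membership is
  pixel-centre-in-circle with no partial-area weighting.
* Device ranges: MP-3 0–34 dB, MAIA 0–36 dB with raw −1 mapped to 0 at
  quantification time.
* BIC = −2·logLik + k·ln(n) with k = fixed effects + 2 variance
  parameters; ML for selection, REML for the reported final fit.
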