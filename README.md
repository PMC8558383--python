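# thzfb — THz spectroscopy & imaging for insect foreign-body detection

`thzfb` is a desk-scale toolkit for a food-safety problem that X-ray
inspection cannot solve: finding **low-density organic foreign bodies
(insect fragments) in dry food matrices** such as finishing tea.
Terahertz time-domain spectroscopy (THz-TDS) records the electric
field *E(t)* of a sub-picosecond pulse after it interacts with a
sample; insect tissue (fat, protein) absorbs THz radiation more
strongly than dried leaf powder and lengthens the optical path, so its
pulse is **attenuated and delayed**. The package implements the full
analysis chain around that contrast, plus a seeded synthetic generator
that reproduces its statistical structure with exact ground truth — so
every step is testable end-to-end on a laptop.

It is aimed at chemometricians and spectroscopists who want a tested,
reusable reference implementation of the pipeline:

1. **Spectra** — one-sided FFT `Ẽ(ω) = A(ω)e^{−iφ(ω)} = ∫ E(t)e^{−iωt} dt`,
   replicate averaging, analysis-band selection (0.3–1.0 THz by default).
2. **Baseline correction** — three penalized least-squares estimators
   built on one banded Whittaker core
   `z = (W + λDᵀD)⁻¹Wy`:
   * **AsLS** — asymmetric weights, `w_i = p` if `y_i > z_i` else `1 − p`,
     iterated to weight stability;
   * **AirPLS** — adaptive reweighting from the negative residuals,
     `w_i = 0` if `y_i ≥ z_i` else `exp(t(y_i − z_i)/|d|₁)`, stopping at
     `|d|₁ < 0.001·|y|₁`;
   * **BEADS** — sparse decomposition `y = x + f + w` (peaks, baseline,
     noise) by majorization–minimization with a banded zero-phase
     high-pass `H = BA⁻¹`.
3. **Classification** — KNN (Euclidean, majority vote, deterministic
   tie-breaks) and two-class PLS-DA (dummy-coded 0/1 response,
   sequential latent components, 0.5 response cut), both from first
   principles, with detection-table accounting:
   `accuracy = 100·(1 − misclassified/n)`, half-up to 2 decimals, over a
   fixed calibration/prediction split (125/51 for the default 176-sample
   study).
4. **Imaging** — time-of-flight analysis of (x, y, t) reflection cubes:
   per-pixel grayscale and arrival-time maps, grayscale windowing, and
   shape-gated (area/eccentricity/solidity) detection of inclusions.

## Worked example

Each script in `examples/` runs one capability and prints what it
computes. The classification study (`examples/04_classification_study.py`):

```text
model correction  n_miscal_cal  acc_cal_pct  n_miscal_pred  acc_pred_pct
  knn       none             0        100.0              0         100.0
  knn     airpls             0        100.0              0         100.0
  knn       asls             0        100.0              0         100.0
  knn      beads             0        100.0              0         100.0
plsda       none             0        100.0              0         100.0
plsda     airpls             0        100.0              0         100.0
plsda       asls             0        100.0              0         100.0
plsda      beads             0        100.0              0         100.0

config hash: 88695c724c512cd2
PLS-DA components chosen by cross-validation: {'none': 1, 'airpls': 3, 'asls': 2, 'beads': 1}
```

Rows are the 8 cells {KNN, PLS-DA} × {none, AirPLS, AsLS, BEADS}, each
fitted on the 125-sample calibration population and scored on both
populations; under the default synthetic conditions the band
amplitudes separate the classes cleanly, so the cells sit at or near
100 %. The imaging run (`examples/05_imaging_detection.py`) recovers
both implanted inclusions:

```text
delay contrast:       0.796 ps (programmed insect delay: 0.800 ps)
accepted detections:  2
  component at ( 30.0,  32.0) px, area 159 px, eccentricity 0.76, IoU vs truth 0.98
  component at ( 64.1,  62.1) px, area 211 px, eccentricity 0.73, IoU vs truth 0.95
```

A thin CLI mirrors the pipeline stages:

```bash
thzfb simulate spectra --seed 0 --n-tea 88 --n-insect 88 --out data.h5
thzfb classify --model knn --correction airpls --in data.h5 --report report.csv
thzfb study --seed 0 --out results/
thzfb simulate cube --seed 0 --out cube.h5 && thzfb image --cube cube.h5 --out maps/
```

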