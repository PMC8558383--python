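# Methods

This note documents the models behind `thzfb`, the defaults and why
they were chosen, the numerical decisions, and what the synthetic
study does and does not demonstrate.

## The measurement model

A THz-TDS instrument records the electric field `E(t)` of a
sub-picosecond pulse, sampled uniformly in time. The toolkit models
the pulse phenomenologically as a **normalised derivative of a
Gaussian**,

    E(t) = -A · u · exp(1/2 - u²/2),   u = (t - t₀)/σ,

whose leading lobe is positive with peak value `A` at `t₀ - σ`. Two
class models encode the physical contrast between clean matrix and
insect material:

| parameter        | tea  | insect | meaning                          |
|------------------|------|--------|----------------------------------|
| `amplitude_scale`| 1.0  | 0.6    | peak \|E\| (a.u.) — absorption   |
| `center_time`    | 10 ps| 10 ps  | Gaussian centre                  |
| `pulse_width` σ  | 0.5 ps| 0.5 ps| pulse duration                   |
| `delay_shift`    | 0 ps | +0.8 ps| extra flight time (denser medium)|

A 25 %-insect mixture model interpolates linearly between the two.
The time axis is 0–40 ps at 2048 points: ~0.02 ps resolution, a
25.6 THz Nyquist limit far above the 1.2 THz analysis ceiling, and a
0.025 THz frequency grid (≈29 bins in the 0.3–1.0 THz band).

**Drift.** Scattering at medium boundaries adds a slow baseline: a
cubic polynomial in the normalised time coordinate with coefficients
~N(0, drift_sd²) plus one sinusoid with period uniform on [½, 1] of
the record (so the drift spectrum stays below ~0.05 THz). The default
`drift_sd = 0.06` was calibrated once so the mean drift peak-to-peak
is ≈15 % of the tea pulse peak (measured 0.152 over 4000 draws).
Additive white noise defaults to 1 % of the tea peak; imaging adds a
per-pixel multiplicative log-normal speckle (σ = 0.1 on the log scale)
for the randomly oriented leaf bed. All draws flow from one explicit
`numpy` generator per seed.

**What the generator does not model:** Fresnel reflections and
etalon echoes, frequency-dependent absorption line shapes, tablet
thickness/moisture variation, or instrument phase noise. Passing
tests therefore demonstrate the *correctness of the algorithms and
the internal consistency of the pipeline*, not field performance on
real tea measurements — the measured spectra behind the original
study were never deposited, which is exactly why the generator
exists.

## Spectral conventions

One-sided FFT with the **unit-cosine normalisation**: non-DC,
non-Nyquist bins are doubled and divided by the trace length, so a
unit-amplitude on-grid cosine has spectral amplitude 1. Phase is the
negated argument, matching `Ẽ(ω) = A(ω)e^{−iφ(ω)}`. Under this
convention the Parseval identity reads
`Σ E(t)² = n·(A₀² + A_nyq² + Σ_int A_k²/2)` and is verified to 1e-9.
No window is applied by default (a Hann option exists); zero padding
refines the grid without changing the normalisation. A pure delay
multiplies the complex spectrum by a unit-modulus factor and leaves
`A(ω)` untouched — the reason amplitude features ignore the insect
delay while the imaging branch exploits it.

Band selection takes the closed interval; 0.3–1.0 THz is the default
analysis band with 0.3–1.2 THz selectable. Baseline correction in
the classification pipeline is applied to the band-restricted
**frequency-domain amplitude spectra** (the correctors assume
positive-going peaks; a bipolar time pulse violates that — see below).

## Baseline estimators

All three share the banded Whittaker smoother: the exact minimiser of
`Σ wᵢ(yᵢ−zᵢ)² + λ‖Dz‖²` (order-2 differences by default), solved by a
symmetric banded Cholesky factorisation; agreement with a dense
normal-equations solve is verified to 1e-9.

* **AsLS** (defaults λ=1e5, p=0.01, ≤50 iterations): weights p above /
  1−p below the current baseline, iterated until the weight vector is
  exactly stable. p=0.5 collapses to plain Whittaker smoothing with
  uniform weights ½ (equivalently a doubled penalty).
* **AirPLS** (default λ=1e4): weights zero at peak points and
  `exp(t(yᵢ−zᵢ)/|d|₁)` below, i.e. in (0,1], decaying fastest for
  points far below the baseline; stops when the negative-residual mass
  falls below 0.1 % of `|y|₁`. Two degeneracy guards keep short
  records safe: the iteration ends early if the weight vector
  underflows or if so few points carry weight that the penalty null
  space is no longer pinned (the weighted system would be singular).
  Note the stopping rule depends on `|y|₁`, so the *full* algorithm is
  not translation-equivariant even though each smoothing+reweighting
  pass is.
* **BEADS** (defaults: filter degree 2·1, cutoff 0.006, asymmetry
  r=6, λ₀:λ₁:λ₂ = 0.5:5:4 scaled by 0.1·max|y|, δ=1e-6, ≤30
  iterations): majorization–minimization of the asymmetric sparse
  penalty coupled to the banded zero-phase high-pass `H = BA⁻¹`. The
  fixed right-hand side is `d = BᵀBA⁻¹y − λ₀Aᵀ(1−r)/2·1` (the Aᵀ form
  follows from the MM normal equations; A is symmetric banded). The
  non-differentiable |·| is smoothed as `max(|v|, δ)` in both the peak
  and derivative majorizers. The MM cost decreases monotonically but
  sublinearly; the iteration is declared stationary when the update
  falls below `tol·max|y|` with `tol = 2e-3` — far below the 1 % noise
  floor — and logs a warning otherwise. The final baseline is
  `f = (y−x) − H(y−x)` and the noise `w = y−x−f`, making `x+f+w = y`
  exact by construction. Systems up to 512 points are solved densely
  (Cholesky), larger ones sparsely.

**Recovery benchmark.** Baseline recovery is scored on
`baseline_benchmark_signal`: the generator's drift family plus one
positive Gaussian peak (height 1, σ = 0.1 ps — a sharp absorption-like
feature), noise-free. With method defaults the worst recovery RMSE
over ten drift draws is 0.14 % (AsLS) and 1.86 % (AirPLS) of the peak
height. The benchmark uses positive peaks deliberately: AsLS/AirPLS
asymmetry assumes peaks rise above the baseline, and a bipolar THz
pulse's negative lobe drags any asymmetric estimator down (measured
~21 % RMSE) — which is why the pipeline corrects amplitude spectra,
not raw time traces.

## Classification

Features are the baseline-corrected, band-restricted amplitude
spectra; they are mean-centred but **not** variance-scaled, because
the absolute amplitude level is itself the class signal.

* **KNN**: k=3 by default; Euclidean distance; majority vote; ties
  broken by the nearest neighbour among tied classes, then the lowest
  class index. Verified against an independent exhaustive
  re-implementation on 200 random 5-D queries for k ∈ {1, 3, 5}.
* **PLS-DA**: classes dummy-coded 0/1; sequential latent components
  (weight vector = dominant covariance direction, score/loading
  deflation); regression vector `b = W(PᵀW)⁻¹q`; class 1 iff the
  predicted response exceeds 0.5, with the boundary itself assigned to
  class 0. At full rank the coefficients equal the least-squares dummy
  regression (verified to 1e-8), and predictions match an independent
  latent-variable regression implementation. The component count is
  chosen by stratified 5-fold cross-validation on the calibration
  split (seeded fold assignment, capped at 10, smallest count on
  ties).
* **Reporting**: misclassification counts and percent accuracies per
  split, rounded half-up to two decimals via exact decimal arithmetic
  (46/51 → 90.20), plus 2×2 confusion tables.

## The synthetic study

`run_study` simulates one dataset per seed (88 + 88 tablets; a
deterministic stratified split with calibration fraction 125/176
reproduces the 125/51 two-population design), converts it to
band-restricted amplitude spectra and scores all 8 model × correction
cells on the *same* split. For the ~29-bin band the correction
parameters differ from the full-record defaults: AsLS/AirPLS use
λ = 1e7, which pushes the smoothing scale beyond the band width so the
estimators act as asymmetric detrenders — removing each sample's
scattering trend while preserving the spectral curvature that carries
the class contrast — and BEADS uses cutoff 0.04 for the same reason.
All parameters live in `PipelineConfig` and are overridable from YAML;
the report embeds a SHA-256 config hash and identical configs produce
byte-identical CSVs.

Under these conditions the classes are linearly separable in the band
(every insect band-mean below every tea band-mean), so uncorrected
models already score ≈100 % and correction mostly ties rather than
strictly improves — the synthetic study verifies that correction does
not *harm* a clean signal and that the corrected models reach ≥95 %
prediction accuracy, not the harder field claim that correction
rescues a failing model.

## Imaging

The reflection cube is analysed per pixel. The default grayscale
statistic is the peak |E| (inclusions absorb, so they are dark);
peak-to-peak and energy are alternatives. The **delay map** takes the
time of the *signed* maximum of the waveform, refined by three-point
parabolic interpolation (clamped to ±half a sample): the pulse is
antisymmetric, so the two |E| lobes tie exactly and an |E|-based
argmax would pick a lobe by grid alignment or noise; the signed
maximum is unique and marks the arrival of the leading positive lobe.
An all-zero pixel reports the first sample time.

Grayscale **windowing** clamps the map to [lo, hi] and rescales to
[0, 1]; the default window spans the 1 %–50 % quantiles, saturating
the bright background and leaving contrast only in the attenuated
range (the same move as narrowing a 68–1272 instrument range to
80–120). **Detection** thresholds the windowed map (Otsu by default,
candidates below the threshold), applies a 3×3 morphological opening,
labels 8-connected components and gates them on area ≥ 20 px,
eccentricity ≤ 0.97 and solidity ≥ 0.5 — accepting worm-like blobs
and rejecting line artifacts. On the default 96×96×512 cube with two
elliptical inclusions, both are recovered with IoU > 0.9 and the
inside–outside delay contrast matches the programmed 0.8 ps within
one sample.

Coordinates are (row, col), origin top-left, 0-based; physical
position is index × raster step (0.2 mm default). Ellipse centres
must lie on the grid; axes are unrestricted so a single ellipse may
cover the whole field.

## Problem sizes and determinism

Default sizes — 176 traces × 2048 points for the study, 96×96×512 for
imaging, ten seeds for the stochastic comparisons — were chosen so
the whole test suite runs in about a minute on one CPU while keeping
the split sizes and band resolution of the original design. Every
random draw descends from a single integer seed; reports embed the
config hash; re-running any entry point with the same seed reproduces
its output bit for bit.

## Known limitations

* The generator is phenomenological; no optics (Fresnel, etalon,
  deconvolution) and no material-parameter extraction (refractive
  index, absorption coefficient).
* AsLS/AirPLS are inappropriate for bipolar time-domain pulses; use
  them on amplitude spectra or envelope-like signals.
* The AirPLS stopping rule makes the full iteration sensitive to a
  constant signal offset (see above).
* PLS-DA is binary only; no probabilistic calibration of outputs.
* The imaging branch assumes inclusions are darker than background;
  reflective (bright) foreign bodies would need the opposite
  threshold orientation.
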