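"""Seeded synthetic THz measurements with ground truth.

The measured tea/insect spectra behind this toolkit were never
deposited, so every analysis step is exercised on a phenomenological
generator that reproduces their statistical structure:

* a THz pulse modelled as a scaled derivative-of-Gaussian transient;
* insect material attenuates the pulse (smaller amplitude) and delays
  it (longer optical path through denser, fat/protein-rich tissue);
* slow additive baseline drift from scattering at leaf boundaries,
  modelled as a cubic polynomial plus one long-period sinusoid;
* white detector noise, and for imaging a per-pixel multiplicative
  log-normal speckle that mimics the randomly oriented leaf bed.

Every generated object is accompanied by its ground truth (noise-free
baseline, class label, foreign-body mask) so that recovery and
detection accuracy can be scored exactly.  All randomness flows from a
single explicit integer seed through one named generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field as _field, replace

import numpy as np

from .errors import InvalidArgumentError
from .spectra import LabeledSpectralSet, TimeTrace

# Record geometry: 0-40 ps at 2048 points gives ~0.02 ps resolution and
# a 25 THz Nyquist limit, far above the 1.2 THz analysis ceiling.
DEFAULT_T_MAX = 40.0
DEFAULT_N_POINTS = 2048

# Noise floor: 1 % of the tea pulse peak.
DEFAULT_NOISE_SD = 0.01

# Drift scale: chosen so the mean drift peak-to-peak is ~15 % of the
# tea pulse peak under the default drift family (see draw_drift_model).
DEFAULT_DRIFT_SD = 0.06

# Imaging speckle: log-scale sigma of the multiplicative leaf-scatter factor.
DEFAULT_SPECKLE_SIGMA = 0.1

#: calibration fraction mirroring the 125/51 two-population design
CALIBRATION_FRACTION = 125.0 / 176.0


@dataclass(frozen=True)
class PulseModel:
    """Derivative-of-Gaussian THz pulse.

    ``amplitude_scale`` is the peak |E| of the pulse, ``center_time``
    the centre of the underlying Gaussian in ps, ``pulse_width`` its
    sigma in ps and ``delay_shift`` an extra arrival delay in ps for
    denser media (insect tissue).
    """

    amplitude_scale: float
    center_time: float
    pulse_width: float
    delay_shift: float = 0.0

    def __post_init__(self) -> None:
        if self.amplitude_scale < 0:
            raise InvalidArgumentError("amplitude_scale must be >= 0")
        if self.pulse_width <= 0:
            raise InvalidArgumentError("pulse_width must be > 0")

    @property
    def arrival_time(self) -> float:
        return self.center_time + self.delay_shift


@dataclass(frozen=True)
class DriftModel:
    """Smooth additive baseline drift.

    Polynomial coefficients apply to the normalised time coordinate
    u = (t - t_min) / (t_max - t_min) in [0, 1], ascending powers, so
    their magnitude is directly comparable to the signal amplitude.
    The sinusoid has a period of at least half the record so the drift
    stays band-limited far below the pulse's spectral content.
    """

    polynomial_coefficients: tuple = (0.0,)
    sine_amplitude: float = 0.0
    sine_period: float = 1.0
    sine_phase: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "polynomial_coefficients", tuple(float(c) for c in self.polynomial_coefficients)
        )
        if self.sine_period <= 0:
            raise InvalidArgumentError("sine_period must be > 0")

    def evaluate(self, time: np.ndarray) -> np.ndarray:
        time = np.asarray(time, dtype=float)
        span = time[-1] - time[0] if time.size > 1 else 1.0
        u = (time - time[0]) / span if span != 0 else np.zeros_like(time)
        drift = np.polynomial.polynomial.polyval(u, self.polynomial_coefficients)
        if self.sine_amplitude != 0.0:
            drift = drift + self.sine_amplitude * np.sin(
                2.0 * np.pi * time / self.sine_period + self.sine_phase
            )
        return np.asarray(drift, dtype=float)


ZERO_DRIFT = DriftModel(polynomial_coefficients=(0.0,))

# Default class models: insect pulses are attenuated to 60 % of the tea
# amplitude and arrive 0.8 ps later.
TEA_MODEL = PulseModel(amplitude_scale=1.0, center_time=10.0, pulse_width=0.5, delay_shift=0.0)
INSECT_MODEL = PulseModel(amplitude_scale=0.6, center_time=10.0, pulse_width=0.5, delay_shift=0.8)


def mixture_model(
    tea: PulseModel = TEA_MODEL,
    insect: PulseModel = INSECT_MODEL,
    insect_weight: float = 0.25,
) -> PulseModel:
    """Pulse model for a tablet containing a mass fraction of insect material.

    Linear interpolation between the class models; the default 25 %
    insect weight matches the mixture tablets used to illustrate the
    intermediate spectral intensity.
    """
    if not 0.0 <= insect_weight <= 1.0:
        raise InvalidArgumentError("insect_weight must lie in [0, 1]")
    w = float(insect_weight)
    return PulseModel(
        amplitude_scale=(1 - w) * tea.amplitude_scale + w * insect.amplitude_scale,
        center_time=(1 - w) * tea.center_time + w * insect.center_time,
        pulse_width=(1 - w) * tea.pulse_width + w * insect.pulse_width,
        delay_shift=(1 - w) * tea.delay_shift + w * insect.delay_shift,
    )


@dataclass
class GroundTruth:
    """Noise-free components of a synthetic object, for exact scoring."""

    true_baseline: np.ndarray | None = None
    true_label: int | None = None
    true_mask: np.ndarray | None = None
    true_pulse: np.ndarray | None = None
    noise: np.ndarray | None = None


def pulse_waveform(time: np.ndarray, model: PulseModel) -> np.ndarray:
    """Analytic derivative-of-Gaussian pulse, normalised to peak |E| = amplitude_scale.

    E(t) = -A * u * exp(1/2 - u^2 / 2),  u = (t - t0) / sigma,

    with t0 = center_time + delay_shift.  The leading lobe (u = -1) is
    positive with value +A; the trailing lobe is -A.
    """
    u = (np.asarray(time, dtype=float) - model.arrival_time) / model.pulse_width
    return model.amplitude_scale * (-u) * np.exp(0.5 - 0.5 * u * u)


def _rng_of(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def generate_trace(
    model: PulseModel,
    drift: DriftModel = ZERO_DRIFT,
    noise_sd: float = DEFAULT_NOISE_SD,
    n_points: int = DEFAULT_N_POINTS,
    t_max: float = DEFAULT_T_MAX,
    seed: int | np.random.Generator = 0,
) -> tuple[TimeTrace, GroundTruth]:
    """One synthetic time trace: pulse + drift + white noise.

    Returns the trace and a ``GroundTruth`` carrying the noise-free
    drift, the noise-free pulse and the realised noise vector, so that
    ``true_baseline + true_pulse + noise`` reconstructs the field
    exactly.
    """
    if n_points < 64:
        raise InvalidArgumentError("n_points must be >= 64")
    if t_max <= 0:
        raise InvalidArgumentError("t_max must be > 0")
    if noise_sd < 0:
        raise InvalidArgumentError("noise_sd must be >= 0")
    rng = _rng_of(seed)
    time = np.linspace(0.0, float(t_max), int(n_points))
    pulse = pulse_waveform(time, model)
    baseline = drift.evaluate(time)
    noise = (
        rng.normal(0.0, noise_sd, size=n_points) if noise_sd > 0 else np.zeros(n_points)
    )
    trace = TimeTrace(time=time, field=pulse + baseline + noise)
    truth = GroundTruth(true_baseline=baseline, true_pulse=pulse, noise=noise)
    return trace, truth


def draw_drift_model(
    rng: np.random.Generator, drift_sd: float, t_max: float = DEFAULT_T_MAX
) -> DriftModel:
    """Random drift: cubic with N(0, drift_sd^2) coefficients plus one sinusoid.

    The sinusoid period is uniform on [0.5, 1.0] x t_max, keeping the
    drift spectrum below ~0.05 THz for the default record length.
    """
    if drift_sd < 0:
        raise InvalidArgumentError("drift_sd must be >= 0")
    coeffs = rng.normal(0.0, drift_sd, size=4) if drift_sd > 0 else np.zeros(4)
    sine_amp = float(rng.normal(0.0, drift_sd)) if drift_sd > 0 else 0.0
    period = float(rng.uniform(0.5, 1.0) * t_max)
    phase = float(rng.uniform(0.0, 2.0 * np.pi))
    return DriftModel(
        polynomial_coefficients=tuple(coeffs),
        sine_amplitude=sine_amp,
        sine_period=period,
        sine_phase=phase,
    )


def _calibration_split(n_per_class: list[int], fraction: float) -> np.ndarray:
    """Stratified deterministic split flag (True = calibration).

    The total calibration count is round(fraction * n_total), allocated
    to classes by largest remainder so that 88 + 88 samples reproduce
    the 125/51 two-population sizes exactly.  Within a class the first
    samples are calibration.
    """
    n_total = int(sum(n_per_class))
    n_cal_total = int(round(fraction * n_total))
    ideal = [fraction * n for n in n_per_class]
    base = [int(np.floor(x)) for x in ideal]
    remainder = [x - b for x, b in zip(ideal, base)]
    short = n_cal_total - sum(base)
    order = sorted(range(len(n_per_class)), key=lambda i: (-remainder[i], i))
    for i in order[: max(short, 0)]:
        base[i] += 1
    flags = []
    for n, n_cal in zip(n_per_class, base):
        n_cal = min(n_cal, n)
        flags.append(np.concatenate([np.ones(n_cal, bool), np.zeros(n - n_cal, bool)]))
    return np.concatenate(flags)


def generate_dataset(
    n_tea: int,
    n_insect: int,
    tea_model: PulseModel = TEA_MODEL,
    insect_model: PulseModel = INSECT_MODEL,
    drift_sd: float = DEFAULT_DRIFT_SD,
    noise_sd: float = DEFAULT_NOISE_SD,
    n_points: int = DEFAULT_N_POINTS,
    t_max: float = DEFAULT_T_MAX,
    seed: int = 0,
) -> tuple[LabeledSpectralSet, list[GroundTruth]]:
    """A labelled set of tea and insect-contaminated traces.

    Per sample, a fresh drift model and noise vector are drawn; the
    class pulse itself is deterministic, so with ``drift_sd = 0`` and
    ``noise_sd = 0`` all traces of a class are identical.  The returned
    set carries a stratified calibration/prediction flag with the
    calibration fraction 125/176 of the original study design.
    """
    if n_tea < 1 or n_insect < 1:
        raise InvalidArgumentError("need at least one sample per class")
    if not (
        insect_model.amplitude_scale < tea_model.amplitude_scale
        and insect_model.delay_shift > tea_model.delay_shift
    ):
        raise InvalidArgumentError(
            "class contrast must have insect amplitude below tea and "
            "insect delay above tea"
        )
    rng = np.random.default_rng(seed)
    time = np.linspace(0.0, float(t_max), int(n_points))
    features = np.empty((n_tea + n_insect, n_points))
    truths: list[GroundTruth] = []
    labels = np.concatenate([np.zeros(n_tea, int), np.ones(n_insect, int)])
    for row, label in enumerate(labels):
        model = tea_model if label == 0 else insect_model
        drift = draw_drift_model(rng, drift_sd, t_max)
        trace, truth = generate_trace(
            model, drift, noise_sd, n_points=n_points, t_max=t_max, seed=rng
        )
        features[row] = trace.field
        truth.true_label = int(label)
        truths.append(truth)
    split = _calibration_split([n_tea, n_insect], CALIBRATION_FRACTION)
    dataset = LabeledSpectralSet(
        features=features,
        labels=labels,
        variable_axis=time,
        split=split,
        metadata={
            "axis_kind": "time_ps",
            "seed": int(seed),
            "drift_sd": float(drift_sd),
            "noise_sd": float(noise_sd),
        },
    )
    return dataset, truths


def baseline_benchmark_signal(
    seed: int,
    drift_sd: float = DEFAULT_DRIFT_SD,
    peak_height: float = 1.0,
    peak_width: float = 0.1,
    peak_time: float = 20.0,
    noise_sd: float = 0.0,
    n_points: int = DEFAULT_N_POINTS,
    t_max: float = DEFAULT_T_MAX,
) -> tuple[np.ndarray, np.ndarray, GroundTruth]:
    """Baseline-recovery benchmark: drift plus one positive Gaussian peak.

    The penalized least-squares correctors assume positive-going peaks
    on a slow background — the situation of amplitude spectra, where a
    sharp absorption-like feature (sigma 0.1 ps here) rides on the
    scattering trend.  Returns ``(t, y, truth)`` with the drift
    realisation of ``seed`` as the known baseline, so recovery error
    can be scored exactly.
    """
    if peak_width <= 0 or peak_height < 0:
        raise InvalidArgumentError("peak must have positive width and height >= 0")
    rng = np.random.default_rng(seed)
    time = np.linspace(0.0, float(t_max), int(n_points))
    drift = draw_drift_model(rng, drift_sd, t_max).evaluate(time)
    peak = peak_height * np.exp(-0.5 * ((time - peak_time) / peak_width) ** 2)
    noise = rng.normal(0.0, noise_sd, n_points) if noise_sd > 0 else np.zeros(n_points)
    y = drift + peak + noise
    return time, y, GroundTruth(true_baseline=drift, true_pulse=peak, noise=noise)


@dataclass
class THzImageCube:
    """Reflection-mode image cube: one waveform per (x, y) pixel.

    ``cube`` has shape (nx, ny, n_time); ``dx_mm``/``dy_mm`` record the
    raster step of the scanning stage (0.2 mm by default).
    """

    cube: np.ndarray
    time: np.ndarray
    dx_mm: float = 0.2
    dy_mm: float = 0.2
    metadata: dict = _field(default_factory=dict)

    def __post_init__(self) -> None:
        self.cube = np.asarray(self.cube, dtype=float)
        self.time = np.asarray(self.time, dtype=float)
        if self.cube.ndim != 3:
            raise InvalidArgumentError("cube must be a 3-D (nx, ny, n_time) array")
        if self.time.size != self.cube.shape[2]:
            raise InvalidArgumentError("time length must equal the cube's last axis")
        if self.dx_mm <= 0 or self.dy_mm <= 0:
            raise InvalidArgumentError("spatial steps must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.cube.shape)


def ellipse_mask(nx: int, ny: int, center: tuple, axes: tuple) -> np.ndarray:
    """Boolean mask of pixels whose centres fall inside an axis-aligned ellipse."""
    cx, cy = center
    ax, ay = axes
    if ax <= 0 or ay <= 0:
        raise InvalidArgumentError("ellipse axes must be positive")
    rows, cols = np.mgrid[0:nx, 0:ny]
    return ((rows - cx) / ax) ** 2 + ((cols - cy) / ay) ** 2 <= 1.0


def generate_image_cube(
    nx: int,
    ny: int,
    n_time: int,
    insect_ellipses: list,
    tea_model: PulseModel = TEA_MODEL,
    insect_model: PulseModel = INSECT_MODEL,
    noise_sd: float = DEFAULT_NOISE_SD,
    speckle_sigma: float = DEFAULT_SPECKLE_SIGMA,
    t_max: float = DEFAULT_T_MAX,
    seed: int = 0,
) -> tuple[THzImageCube, GroundTruth]:
    """Synthetic reflection cube with elliptical insect inclusions.

    Pixels inside any ellipse carry the attenuated, delayed insect
    pulse; the rest carry the tea pulse.  Each pixel's waveform is
    multiplied by a log-normal speckle factor (sigma on the log scale,
    0 disables it) emulating leaf scattering, then white noise is
    added.  Ellipses are (center, axes) pairs in pixel coordinates;
    centres must lie on the grid.
    """
    if nx < 1 or ny < 1 or n_time < 2:
        raise InvalidArgumentError("cube dimensions too small")
    mask = np.zeros((nx, ny), dtype=bool)
    for center, axes in insect_ellipses:
        cx, cy = center
        if not (0 <= cx <= nx - 1 and 0 <= cy <= ny - 1):
            raise InvalidArgumentError(
                f"ellipse centre {center} lies outside the {nx} x {ny} grid"
            )
        mask |= ellipse_mask(nx, ny, center, axes)
    rng = np.random.default_rng(seed)
    time = np.linspace(0.0, float(t_max), int(n_time))
    tea_wave = pulse_waveform(time, tea_model)
    insect_wave = pulse_waveform(time, insect_model)
    cube = np.where(mask[:, :, None], insect_wave, tea_wave)
    if speckle_sigma > 0:
        speckle = np.exp(rng.normal(0.0, speckle_sigma, size=(nx, ny)))
        cube = cube * speckle[:, :, None]
    if noise_sd > 0:
        cube = cube + rng.normal(0.0, noise_sd, size=cube.shape)
    image = THzImageCube(
        cube=cube,
        time=time,
        metadata={
            "seed": int(seed),
            "noise_sd": float(noise_sd),
            "speckle_sigma": float(speckle_sigma),
            "programmed_delay_ps": float(insect_model.delay_shift - tea_model.delay_shift),
        },
    )
    return image, GroundTruth(true_mask=mask)


#: default two-inclusion layout for a 96 x 96 desk-scale scan
DEFAULT_ELLIPSES = [((30.0, 32.0), (9.0, 6.0)), ((64.0, 62.0), (7.0, 10.0))]
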