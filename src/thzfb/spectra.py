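"""Time-domain THz traces and their frequency-domain representation.

A terahertz time-domain spectrometer records the electric field ``E(t)``
of a sub-picosecond pulse after it has interacted with a sample.  The
frequency-domain picture is the complex spectrum

    E~(omega) = A(omega) * exp(-i * phi(omega)) = FFT[E(t)],

where ``A`` is the amplitude spectrum and ``phi`` the (sign-flipped)
phase.  Dense media attenuate the pulse (smaller ``A``) and delay it
(linear phase ramp); the amplitude spectrum is invariant under a pure
delay, which is why amplitude features are used for classification
while the delay itself is exploited by time-of-flight imaging.

Conventions
-----------
* Time is in picoseconds, so frequencies come out in THz (1/ps).
* One-sided spectra: non-DC, non-Nyquist bins are doubled so that a
  unit-amplitude cosine has unit spectral amplitude.
* No window is applied by default (rectangular); a Hann window is
  available via ``window="hann"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field as _field

import numpy as np

from .errors import AxisMismatchError, EmptySelectionError, InvalidArgumentError

#: relative tolerance for declaring a time axis uniformly sampled
UNIFORM_RTOL = 1e-9


@dataclass
class TimeTrace:
    """A uniformly sampled electric-field pulse E(t).

    Parameters
    ----------
    time : array of float
        Strictly increasing, uniformly spaced sample times in ps.
    field : array of float
        Electric-field amplitude at each sample (arbitrary units).
    metadata : dict
        Free-form annotations (replicate counts, provenance, ...).
    """

    time: np.ndarray
    field: np.ndarray
    metadata: dict = _field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.field = np.asarray(self.field, dtype=float)
        if self.time.ndim != 1 or self.field.ndim != 1:
            raise InvalidArgumentError("time and field must be 1-D arrays")
        if self.time.size != self.field.size:
            raise InvalidArgumentError(
                f"time ({self.time.size}) and field ({self.field.size}) "
                "must have equal length"
            )
        if self.time.size < 2:
            raise InvalidArgumentError("a trace needs at least two samples")
        steps = np.diff(self.time)
        if np.any(steps <= 0):
            raise InvalidArgumentError("time axis must be strictly increasing")
        step = (self.time[-1] - self.time[0]) / (self.time.size - 1)
        if np.max(np.abs(steps - step)) > UNIFORM_RTOL * abs(step):
            raise InvalidArgumentError(
                "time axis is not uniformly sampled within tolerance"
            )

    @property
    def n_points(self) -> int:
        return int(self.time.size)

    @property
    def dt(self) -> float:
        """Sampling interval in ps."""
        return float((self.time[-1] - self.time[0]) / (self.time.size - 1))


@dataclass
class FrequencySpectrum:
    """One-sided complex spectrum E~(omega) = A(omega) exp(-i phi(omega)).

    ``amplitude`` is the modulus of ``complex_amplitude`` and ``phase``
    its negated argument, matching the spectrometer sign convention.
    """

    frequency: np.ndarray
    complex_amplitude: np.ndarray
    amplitude: np.ndarray
    phase: np.ndarray
    metadata: dict = _field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frequency = np.asarray(self.frequency, dtype=float)
        self.complex_amplitude = np.asarray(self.complex_amplitude, dtype=complex)
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        self.phase = np.asarray(self.phase, dtype=float)
        n = self.frequency.size
        if not (self.complex_amplitude.size == self.amplitude.size == self.phase.size == n):
            raise InvalidArgumentError("spectrum arrays must share one length")

    @classmethod
    def from_complex(
        cls, frequency: np.ndarray, complex_amplitude: np.ndarray, metadata: dict | None = None
    ) -> "FrequencySpectrum":
        complex_amplitude = np.asarray(complex_amplitude, dtype=complex)
        return cls(
            frequency=np.asarray(frequency, dtype=float),
            complex_amplitude=complex_amplitude,
            amplitude=np.abs(complex_amplitude),
            phase=-np.angle(complex_amplitude),
            metadata=metadata or {},
        )


@dataclass
class LabeledSpectralSet:
    """A feature matrix of traces or spectra with labels and a fixed split.

    Rows are samples, columns the shared variable axis (time in ps or
    frequency in THz).  ``split`` is a boolean flag per sample, True for
    the calibration population and False for the held-out prediction
    population, mirroring the two-population experimental design.
    """

    features: np.ndarray
    labels: np.ndarray
    variable_axis: np.ndarray
    split: np.ndarray
    label_names: tuple = ("tea", "insect")
    metadata: dict = _field(default_factory=dict)

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels)
        self.variable_axis = np.asarray(self.variable_axis, dtype=float)
        self.split = np.asarray(self.split, dtype=bool)
        if self.features.ndim != 2:
            raise InvalidArgumentError("features must be a 2-D matrix")
        n, p = self.features.shape
        if self.labels.size != n or self.split.size != n:
            raise InvalidArgumentError(
                "labels and split must have one entry per feature row"
            )
        if self.variable_axis.size != p:
            raise InvalidArgumentError(
                "variable_axis length must equal the feature column count"
            )

    @property
    def n_samples(self) -> int:
        return int(self.features.shape[0])

    @property
    def n_variables(self) -> int:
        return int(self.features.shape[1])

    @property
    def calibration_mask(self) -> np.ndarray:
        return self.split

    @property
    def prediction_mask(self) -> np.ndarray:
        return ~self.split

    def subset(self, mask: np.ndarray) -> "LabeledSpectralSet":
        mask = np.asarray(mask, dtype=bool)
        return LabeledSpectralSet(
            features=self.features[mask],
            labels=self.labels[mask],
            variable_axis=self.variable_axis.copy(),
            split=self.split[mask],
            label_names=self.label_names,
            metadata=dict(self.metadata),
        )

    def with_features(
        self, features: np.ndarray, variable_axis: np.ndarray | None = None, **extra_metadata
    ) -> "LabeledSpectralSet":
        """Copy of the set with new features (same samples, new variables)."""
        md = dict(self.metadata)
        md.update(extra_metadata)
        return LabeledSpectralSet(
            features=features,
            labels=self.labels.copy(),
            variable_axis=self.variable_axis.copy() if variable_axis is None else variable_axis,
            split=self.split.copy(),
            label_names=self.label_names,
            metadata=md,
        )


def average_replicates(traces: list[TimeTrace]) -> TimeTrace:
    """Element-wise mean of replicate traces sharing one time axis.

    Replicate averaging suppresses uncorrelated detector noise by
    ``sqrt(n)``; the instrument protocol modelled here records two
    spectra per tablet and averages them.
    """
    if len(traces) == 0:
        raise InvalidArgumentError("need at least one trace to average")
    t0 = traces[0].time
    for trace in traces[1:]:
        if trace.time.size != t0.size or not np.allclose(
            trace.time, t0, rtol=1e-12, atol=0.0
        ):
            raise AxisMismatchError("replicate traces must share one time axis")
    mean = np.mean([trace.field for trace in traces], axis=0)
    return TimeTrace(time=t0.copy(), field=mean, metadata={"n_replicates": len(traces)})


def _one_sided(field: np.ndarray, n_signal: int, zero_pad_to: int | None) -> tuple[np.ndarray, int]:
    """rfft with the unit-cosine amplitude normalisation; returns (scaled X, nfft)."""
    nfft = n_signal if zero_pad_to is None else int(zero_pad_to)
    if nfft < n_signal:
        raise InvalidArgumentError("zero_pad_to must be >= the trace length")
    spectrum = np.fft.rfft(field, n=nfft, axis=-1)
    scale = np.full(spectrum.shape[-1], 2.0 / n_signal)
    scale[..., 0] = 1.0 / n_signal
    if nfft % 2 == 0:  # real Nyquist bin present
        scale[..., -1] = 1.0 / n_signal
    return spectrum * scale, nfft


def _apply_window(field: np.ndarray, window: str | None) -> np.ndarray:
    if window is None or window == "rect":
        return field
    if window == "hann":
        return field * np.hanning(field.shape[-1])
    raise InvalidArgumentError(f"unknown window {window!r}; use None or 'hann'")


def fft_spectrum(
    trace: TimeTrace, zero_pad_to: int | None = None, window: str | None = None
) -> FrequencySpectrum:
    """One-sided FFT of a time trace.

    The frequency grid follows from the ps sampling interval, so it is
    in THz.  Amplitudes use the unit-cosine convention: non-DC,
    non-Nyquist bins are doubled and everything is divided by the
    original trace length, so a cosine of amplitude 1 on the grid shows
    spectral amplitude 1.  Zero padding refines the frequency grid
    without changing that normalisation.
    """
    field = _apply_window(trace.field, window)
    scaled, nfft = _one_sided(field, trace.n_points, zero_pad_to)
    frequency = np.fft.rfftfreq(nfft, d=trace.dt)
    metadata = dict(trace.metadata)
    metadata.update({"n_signal": trace.n_points, "dt_ps": trace.dt, "window": window or "rect"})
    return FrequencySpectrum.from_complex(frequency, scaled, metadata)


def spectral_energy(spectrum: FrequencySpectrum) -> float:
    """Energy of a one-sided spectrum on the time-domain scale.

    With the unit-cosine amplitude convention the discrete Parseval
    identity reads

        sum E(t)^2 = n * (A_0^2 + A_nyq^2 + sum_interior A_k^2 / 2),

    which this helper evaluates so it can be compared against
    ``sum(trace.field ** 2)`` directly.  Only valid without zero
    padding or windowing.
    """
    n = spectrum.metadata.get("n_signal")
    if n is None:
        raise InvalidArgumentError("spectrum lacks n_signal metadata")
    amp2 = spectrum.amplitude**2
    weights = np.full(amp2.size, 0.5)
    weights[0] = 1.0
    if n % 2 == 0:
        weights[-1] = 1.0
    return float(n * np.sum(weights * amp2))


def fft_dataset(
    dataset: LabeledSpectralSet,
    zero_pad_to: int | None = None,
    window: str | None = None,
) -> LabeledSpectralSet:
    """Row-wise FFT of a time-domain set into an amplitude-spectrum set.

    The variable axis switches from ps to THz; labels and the
    calibration/prediction split are carried through unchanged.
    """
    t = dataset.variable_axis
    if t.size < 2:
        raise InvalidArgumentError("time axis too short for an FFT")
    steps = np.diff(t)
    dt = (t[-1] - t[0]) / (t.size - 1)
    if np.any(steps <= 0) or np.max(np.abs(steps - dt)) > UNIFORM_RTOL * abs(dt):
        raise InvalidArgumentError("variable axis must be uniform time in ps")
    fields = _apply_window(dataset.features, window)
    scaled, nfft = _one_sided(fields, t.size, zero_pad_to)
    frequency = np.fft.rfftfreq(nfft, d=dt)
    return dataset.with_features(
        np.abs(scaled), variable_axis=frequency, axis_kind="frequency_thz", window=window or "rect"
    )


def band_select(
    spectrum_set: LabeledSpectralSet, f_min: float, f_max: float
) -> LabeledSpectralSet:
    """Restrict a spectral set to the closed band [f_min, f_max] THz.

    The discriminative tea/insect contrast lives in 0.3-1.0 THz (the
    default analysis band); 0.3-1.2 THz is a supported alternative.
    Selection is idempotent and raises ``EmptySelectionError`` when the
    band misses the grid entirely.
    """
    if not f_min < f_max:
        raise InvalidArgumentError("f_min must be strictly less than f_max")
    axis = spectrum_set.variable_axis
    tol = 1e-9 * max(1.0, abs(f_min), abs(f_max))
    mask = (axis >= f_min - tol) & (axis <= f_max + tol)
    if not np.any(mask):
        raise EmptySelectionError(
            f"band [{f_min}, {f_max}] THz selects no grid points "
            f"on axis [{axis.min()}, {axis.max()}]"
        )
    return spectrum_set.with_features(
        spectrum_set.features[:, mask],
        variable_axis=axis[mask],
        band=(float(f_min), float(f_max)),
    )
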