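"""Whittaker core, AsLS, AirPLS and BEADS behaviour."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thzfb.baselines import (
    AirPLSParams,
    AsLSParams,
    BEADSParams,
    airpls,
    asls,
    beads,
    correct_set,
    whittaker_objective,
    whittaker_smooth,
)
from thzfb.errors import InvalidArgumentError, SingularSystemError
from thzfb.spectra import LabeledSpectralSet
from thzfb.synthetic import baseline_benchmark_signal


class TestWhittaker:
    def test_constant_input_is_fixed_point(self):
        # constants live in the null space of the difference penalty
        z = whittaker_smooth(np.full(100, 3.7), lam=1e4)
        np.testing.assert_allclose(z, 3.7, rtol=1e-10)

    def test_zero_penalty_returns_input(self, rng):
        y = rng.normal(size=80)
        np.testing.assert_allclose(whittaker_smooth(y, lam=0.0), y, atol=1e-8)

    def test_matches_dense_normal_equations(self, rng):
        # independent dense oracle for the banded solver
        n, lam, order = 50, 100.0, 2
        y = rng.normal(size=n)
        w = rng.uniform(0.1, 2.0, size=n)
        d = np.diff(np.eye(n), n=order, axis=0)
        dense = np.linalg.solve(np.diag(w) + lam * d.T @ d, w * y)
        np.testing.assert_allclose(whittaker_smooth(y, w, lam, order), dense, rtol=1e-9, atol=1e-12)

    def test_output_is_the_unique_minimizer(self, rng):
        n, lam = 50, 30.0
        y = rng.normal(size=n)
        w = rng.uniform(0.5, 1.5, size=n)
        z = whittaker_smooth(y, w, lam)
        base = whittaker_objective(y, z, w, lam)
        for _ in range(100):
            perturbation = rng.normal(size=n) * 1e-3
            assert whittaker_objective(y, z + perturbation, w, lam) > base

    def test_all_zero_weights_without_penalty_is_singular(self):
        with pytest.raises(SingularSystemError):
            whittaker_smooth(np.ones(30), np.zeros(30), lam=0.0)

    def test_too_short_input_raises(self):
        with pytest.raises(InvalidArgumentError):
            whittaker_smooth(np.ones(2), lam=1.0, diff_order=2)


class TestAsLS:
    def test_symmetric_p_reduces_to_plain_smoothing(self, rng):
        # p = 1/2 makes both weight branches equal: the iteration is a
        # single Whittaker smooth with uniform weights
        y = rng.normal(size=120)
        fit = asls(y, AsLSParams(lam=1e3, p=0.5))
        np.testing.assert_allclose(
            fit.baseline, whittaker_smooth(y, np.full(y.size, 0.5), 1e3), rtol=1e-10
        )
        assert fit.converged

    def test_recovers_cubic_drift_under_positive_peak(self):
        # spec of the estimator's job: hug the baseline, ignore the peak
        t = np.linspace(0, 40, 2048)
        u = t / 40.0
        drift = 0.3 * (u**3 - 0.5 * u)  # cubic, peak-to-peak ~0.3 scale
        drift = 0.3 * (drift / np.ptp(drift))
        y = drift + np.exp(-0.5 * ((t - 20.0) / 0.1) ** 2)
        fit = asls(y, AsLSParams(lam=1e5, p=0.01))
        rmse = np.sqrt(np.mean((fit.baseline - drift) ** 2))
        assert rmse < 0.02

    def test_pure_drift_is_fully_removed(self):
        # with no peak the whole signal is baseline; lam is set so the
        # smoother can track the drift's curvature tightly
        _, y, truth = baseline_benchmark_signal(4, peak_height=0.0)
        fit = asls(y, AsLSParams(lam=10.0))
        assert np.max(np.abs(fit.corrected)) < 1e-3 * np.max(np.abs(y))

    def test_baseline_plus_corrected_reconstructs_input(self, rng):
        y = rng.normal(size=100)
        fit = asls(y, AsLSParams(lam=10.0))
        np.testing.assert_allclose(fit.baseline + fit.corrected, y, rtol=0, atol=1e-14)
        assert np.all((fit.weights > 0) & (fit.weights < 1))

    @settings(deadline=None, max_examples=15, derandomize=True)
    @given(c=st.floats(-10, 10, allow_nan=False), seed=st.integers(0, 50))
    def test_translation_equivariance(self, c, seed):
        _, y, _ = baseline_benchmark_signal(seed, n_points=256)
        z0 = asls(y, AsLSParams(lam=100.0)).baseline
        z1 = asls(y + c, AsLSParams(lam=100.0)).baseline
        np.testing.assert_allclose(z1, z0 + c, atol=1e-8)


class TestAirPLS:
    def test_zero_input_stops_immediately(self):
        fit = airpls(np.zeros(50), AirPLSParams())
        np.testing.assert_array_equal(fit.baseline, 0.0)
        assert fit.n_iterations == 1
        assert fit.converged

    def test_sinusoidal_drift_only(self):
        # no peaks: the baseline is the whole signal
        t = np.linspace(0, 40, 2048)
        y = 0.2 * np.sin(2 * np.pi * t / 30.0)
        fit = airpls(y, AirPLSParams(lam=1e4))
        rmse = np.sqrt(np.mean((fit.baseline - y) ** 2))
        assert rmse < 0.01 * 0.2

    def test_reweighting_zeroes_peak_points(self):
        _, y, _ = baseline_benchmark_signal(2, noise_sd=0.01)
        fit = airpls(y, AirPLSParams())
        # the peak apex is above every baseline iterate, so any updated
        # weight vector must carry an exact zero there
        assert fit.n_iterations > 1
        assert fit.weights[np.argmax(y)] == 0.0
        assert np.all((fit.weights >= 0) & (fit.weights <= 1.0))

    def test_translation_equivariance_per_iteration(self):
        # the smoothing + reweighting recursion depends on y - z only;
        # the |y|-scaled stopping rule is sidestepped by a signal whose
        # peak keeps |d| above both thresholds for the whole budget
        _, y, _ = baseline_benchmark_signal(1, n_points=512, peak_height=30.0)
        params = AirPLSParams(lam=1e6, max_iter=2)
        fit0 = airpls(y, params)
        fit1 = airpls(y + 4.2, params)
        assert fit0.n_iterations == fit1.n_iterations == 2
        np.testing.assert_allclose(fit1.baseline, fit0.baseline + 4.2, atol=1e-7)


class TestBEADS:
    def test_zero_input_gives_zero_decomposition(self):
        dec = beads(np.zeros(64))
        for part in (dec.sparse_signal, dec.baseline, dec.noise):
            np.testing.assert_array_equal(part, 0.0)

    def test_reconstruction_identity(self, rng):
        y = rng.normal(size=200) + 3.0 * np.sin(np.arange(200) / 30.0)
        dec = beads(y)
        np.testing.assert_allclose(
            dec.sparse_signal + dec.baseline + dec.noise, y,
            atol=1e-10 * np.max(np.abs(y)),
        )

    def test_low_frequency_input_goes_to_baseline(self):
        n = 1000
        y = np.sin(2 * np.pi * np.arange(n) / 500.0)  # far below the cutoff
        dec = beads(y, BEADSParams())
        assert np.max(np.abs(dec.sparse_signal)) < 0.05 * np.max(np.abs(y))
        # the baseline, not the noise, carries the sinusoid
        assert np.sqrt(np.mean((dec.baseline - y) ** 2)) < 0.15

    def test_too_short_input_raises(self):
        with pytest.raises(InvalidArgumentError):
            beads(np.ones(4))

    def test_invalid_params(self):
        with pytest.raises(InvalidArgumentError):
            BEADSParams(cutoff=0.7)
        with pytest.raises(InvalidArgumentError):
            BEADSParams(r=-1.0)


def benchmark_set(n_rows=5, seed0=0, **kwargs):
    rows, baselines_true, peaks = [], [], []
    for s in range(seed0, seed0 + n_rows):
        t, y, truth = baseline_benchmark_signal(s, **kwargs)
        rows.append(y)
        baselines_true.append(truth.true_baseline)
        peaks.append(truth.true_pulse + truth.noise)
    n = len(rows)
    sset = LabeledSpectralSet(
        features=np.array(rows),
        labels=np.zeros(n, int),
        variable_axis=t,
        split=np.ones(n, bool),
    )
    return sset, np.array(baselines_true), np.array(peaks)


class TestCorrectSet:
    def test_none_is_identity(self, small_band_spectra):
        out = correct_set(small_band_spectra, "none")
        np.testing.assert_array_equal(out.features, small_band_spectra.features)
        assert out.metadata["baseline_correction"]["method"] == "none"

    def test_rows_are_corrected_independently(self):
        sset, _, _ = benchmark_set(n_rows=3, n_points=512)
        params = AsLSParams(lam=1e4)
        out = correct_set(sset, "asls", params)
        for i in range(3):
            np.testing.assert_array_equal(
                out.features[i], asls(sset.features[i], params).corrected
            )

    def test_airpls_improves_true_signal_recovery(self):
        # corrected rows should be closer to the drift-free signal than
        # the uncorrected rows are
        sset, _, true_signal = benchmark_set(n_rows=6, noise_sd=0.01)
        corrected = correct_set(sset, "airpls", AirPLSParams())
        rmse_none = np.sqrt(np.mean((sset.features - true_signal) ** 2, axis=1)).mean()
        rmse_corr = np.sqrt(np.mean((corrected.features - true_signal) ** 2, axis=1)).mean()
        assert rmse_corr < rmse_none

    def test_mismatched_params_type_raises(self, small_band_spectra):
        with pytest.raises(InvalidArgumentError):
            correct_set(small_band_spectra, "asls", AirPLSParams())
        with pytest.raises(InvalidArgumentError):
            correct_set(small_band_spectra, "none", AsLSParams())
        with pytest.raises(InvalidArgumentError):
            correct_set(small_band_spectra, "rubber")
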