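"""The synthetic generator: pulses, datasets, cubes, ground truth."""

import numpy as np
import pytest

from thzfb.errors import InvalidArgumentError
from thzfb.spectra import band_select, fft_dataset
from thzfb.synthetic import (
    DEFAULT_DRIFT_SD,
    DriftModel,
    INSECT_MODEL,
    PulseModel,
    TEA_MODEL,
    ZERO_DRIFT,
    baseline_benchmark_signal,
    draw_drift_model,
    generate_dataset,
    generate_image_cube,
    generate_trace,
    mixture_model,
    pulse_waveform,
)


class TestGenerateTrace:
    def test_noise_free_trace_is_the_analytic_pulse(self):
        model = PulseModel(amplitude_scale=1.0, center_time=10.0, pulse_width=0.5)
        trace, truth = generate_trace(model, ZERO_DRIFT, noise_sd=0.0, seed=0)
        u = (trace.time - 10.0) / 0.5
        expected = -u * np.exp(0.5 - 0.5 * u * u)
        np.testing.assert_array_equal(trace.field, expected)
        # normalised so the analytic peak |E| is amplitude_scale; on the
        # grid the sampled maximum sits within one step of it
        assert np.max(np.abs(trace.field)) == pytest.approx(1.0, abs=1e-3)
        np.testing.assert_array_equal(truth.true_baseline, 0.0)

    def test_pulse_absent_leaves_constant_baseline(self):
        model = PulseModel(amplitude_scale=0.0, center_time=10.0, pulse_width=0.5)
        trace, _ = generate_trace(
            model, DriftModel(polynomial_coefficients=(5.0,)), noise_sd=0.0, seed=0
        )
        np.testing.assert_array_equal(trace.field, 5.0)

    def test_same_seed_is_bit_identical(self):
        drift = DriftModel(polynomial_coefficients=(0.1, -0.2), sine_amplitude=0.05, sine_period=25.0)
        a, _ = generate_trace(TEA_MODEL, drift, noise_sd=0.02, seed=7)
        b, _ = generate_trace(TEA_MODEL, drift, noise_sd=0.02, seed=7)
        np.testing.assert_array_equal(a.field, b.field)

    def test_ground_truth_reconstructs_trace_exactly(self):
        drift = DriftModel(polynomial_coefficients=(0.1, 0.3, -0.2))
        trace, truth = generate_trace(INSECT_MODEL, drift, noise_sd=0.05, seed=3)
        np.testing.assert_array_equal(
            trace.field, truth.true_baseline + truth.true_pulse + truth.noise
        )

    @pytest.mark.parametrize("kwargs", [{"n_points": 32}, {"t_max": 0.0}, {"noise_sd": -1.0}])
    def test_invalid_arguments(self, kwargs):
        with pytest.raises(InvalidArgumentError):
            generate_trace(TEA_MODEL, ZERO_DRIFT, **{"noise_sd": 0.0, **kwargs})

    def test_delay_shift_moves_the_pulse(self):
        t = np.linspace(0, 40, 2048)
        tea = pulse_waveform(t, TEA_MODEL)
        insect = pulse_waveform(t, INSECT_MODEL)
        dt = t[1] - t[0]
        delay = (np.argmax(insect) - np.argmax(tea)) * dt
        assert delay == pytest.approx(0.8, abs=dt)


class TestPulseModels:
    def test_invalid_models_rejected(self):
        with pytest.raises(InvalidArgumentError):
            PulseModel(amplitude_scale=1.0, center_time=0.0, pulse_width=0.0)
        with pytest.raises(InvalidArgumentError):
            PulseModel(amplitude_scale=-1.0, center_time=0.0, pulse_width=0.5)

    def test_mixture_interpolates(self):
        mix = mixture_model(insect_weight=0.25)
        assert mix.amplitude_scale == pytest.approx(0.9)
        assert mix.delay_shift == pytest.approx(0.2)


class TestGenerateDataset:
    def test_counts_and_split_sizes(self):
        dataset, truths = generate_dataset(3, 2, seed=0)
        assert dataset.n_samples == 5
        assert int(np.sum(dataset.labels == 1)) == 2
        assert len(truths) == 5
        assert [t.true_label for t in truths] == [0, 0, 0, 1, 1]

    def test_default_study_split_is_125_51(self):
        dataset, _ = generate_dataset(88, 88, seed=0)
        assert int(dataset.calibration_mask.sum()) == 125
        assert int(dataset.prediction_mask.sum()) == 51
        # stratified: both classes present in both populations
        for mask in (dataset.calibration_mask, dataset.prediction_mask):
            assert len(np.unique(dataset.labels[mask])) == 2

    def test_no_randomness_collapses_classes(self):
        dataset, _ = generate_dataset(4, 3, drift_sd=0.0, noise_sd=0.0, seed=0)
        tea = dataset.features[dataset.labels == 0]
        insect = dataset.features[dataset.labels == 1]
        assert np.ptp(tea, axis=0).max() == 0.0
        assert np.ptp(insect, axis=0).max() == 0.0

    def test_contrast_direction_enforced(self):
        bad_insect = PulseModel(amplitude_scale=1.5, center_time=10.0, pulse_width=0.5, delay_shift=0.8)
        with pytest.raises(InvalidArgumentError):
            generate_dataset(2, 2, insect_model=bad_insect, seed=0)

    def test_classes_linearly_separable_in_band_mean(self):
        # brute-force scan: every insect band-mean below every tea band-mean
        dataset, _ = generate_dataset(30, 30, seed=5)
        band = band_select(fft_dataset(dataset), 0.3, 1.0)
        means = band.features.mean(axis=1)
        assert means[dataset.labels == 1].max() < means[dataset.labels == 0].min()

    def test_noise_free_class_contrast(self):
        # peak amplitude and peak time orderings follow the class models
        dataset, truths = generate_dataset(5, 5, drift_sd=0.0, noise_sd=0.0, seed=1)
        t = dataset.variable_axis
        peaks = [np.max(np.abs(tr.true_pulse)) for tr in truths]
        times = [t[np.argmax(tr.true_pulse)] for tr in truths]
        labels = [tr.true_label for tr in truths]
        tea_peak = np.mean([p for p, l in zip(peaks, labels) if l == 0])
        insect_peak = np.mean([p for p, l in zip(peaks, labels) if l == 1])
        tea_time = np.mean([x for x, l in zip(times, labels) if l == 0])
        insect_time = np.mean([x for x, l in zip(times, labels) if l == 1])
        assert tea_peak > insect_peak
        assert insect_time > tea_time

    def test_seed_determinism(self):
        a, _ = generate_dataset(4, 4, seed=11)
        b, _ = generate_dataset(4, 4, seed=11)
        np.testing.assert_array_equal(a.features, b.features)


class TestDriftModel:
    def test_polynomial_is_in_normalised_coordinate(self):
        t = np.linspace(0, 40, 100)
        drift = DriftModel(polynomial_coefficients=(1.0, 2.0)).evaluate(t)
        assert drift[0] == pytest.approx(1.0)
        assert drift[-1] == pytest.approx(3.0)

    def test_drawn_period_at_least_half_record(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            model = draw_drift_model(rng, DEFAULT_DRIFT_SD, t_max=40.0)
            assert model.sine_period >= 20.0


class TestGenerateImageCube:
    def test_homogeneous_without_inclusions(self):
        cube, truth = generate_image_cube(
            8, 8, 128, [], noise_sd=0.0, speckle_sigma=0.0, seed=0
        )
        assert not truth.true_mask.any()
        ref = cube.cube[0, 0]
        np.testing.assert_array_equal(cube.cube, np.broadcast_to(ref, cube.shape))

    def test_covering_ellipse_masks_everything(self):
        cube, truth = generate_image_cube(
            9, 9, 128, [((4.0, 4.0), (100.0, 100.0))], noise_sd=0.0, speckle_sigma=0.0, seed=0
        )
        assert truth.true_mask.all()

    def test_centre_outside_grid_raises(self):
        with pytest.raises(InvalidArgumentError):
            generate_image_cube(8, 8, 128, [((20.0, 4.0), (2.0, 2.0))], seed=0)

    def test_per_pixel_peak_delay_matches_programmed_shift(self):
        cube, truth = generate_image_cube(
            24, 24, 512, [((12.0, 12.0), (5.0, 4.0))],
            noise_sd=0.0, speckle_sigma=0.0, seed=0,
        )
        dt = cube.time[1] - cube.time[0]
        peak_times = cube.time[np.argmax(cube.cube, axis=2)]
        inside = peak_times[truth.true_mask]
        outside = peak_times[~truth.true_mask]
        # exhaustive over pixels: a single shared arrival time per region
        assert np.ptp(inside) == 0.0 and np.ptp(outside) == 0.0
        assert inside[0] - outside[0] == pytest.approx(0.8, abs=dt)

    def test_seed_determinism(self):
        a, _ = generate_image_cube(10, 10, 64, [((5.0, 5.0), (2.0, 3.0))], seed=9)
        b, _ = generate_image_cube(10, 10, 64, [((5.0, 5.0), (2.0, 3.0))], seed=9)
        np.testing.assert_array_equal(a.cube, b.cube)


def test_baseline_benchmark_signal_components():
    t, y, truth = baseline_benchmark_signal(0)
    np.testing.assert_array_equal(y, truth.true_baseline + truth.true_pulse + truth.noise)
    assert truth.true_pulse.max() == pytest.approx(1.0, abs=0.01)
    assert truth.true_pulse.min() >= 0.0
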