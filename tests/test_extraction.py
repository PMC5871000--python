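"""Spectral evaluation: baseline, peaks, assignment, IDF construction."""

import math

import numpy as np
import pytest

from fln_kappa import FLNSpectrum, IDFModel, VibronicMode, default_config, transform_idf
from fln_kappa.core_model import transformed_density
from fln_kappa.extraction import (
    ExtractionError,
    ExtractionParams,
    Peak,
    assign_modes,
    build_idf_samples,
    correct_baseline,
    detect_peaks,
    extract_idf_estimate,
    fit_idf_gaussian,
)
from fln_kappa.simulator import simulate_experiment, simulate_spectrum


GRID = np.arange(16700.0, 17200.0 + 0.25, 0.5)


def _spectrum(intensities, excitation=17950.0, pressure=0.0):
    return FLNSpectrum(
        wavenumbers=GRID,
        intensities=np.asarray(intensities, dtype=float),
        excitation=excitation,
        pressure=pressure,
    )


def _gauss(x, amp, center, sigma):
    return amp * np.exp(-0.5 * ((x - center) / sigma) ** 2)


class TestCorrectBaseline:
    def test_constant_offset_removed(self):
        corrected = correct_baseline(_spectrum(np.full(GRID.size, 37.0)))
        assert np.max(np.abs(corrected.intensities)) < 1e-6 * 37.0

    def test_all_zero_stays_zero(self):
        corrected = correct_baseline(_spectrum(np.zeros(GRID.size)))
        assert np.max(np.abs(corrected.intensities)) < 1e-12

    def test_broad_background_with_narrow_lines(self):
        """Five narrow lines on a broad Gaussian background: line amplitudes
        recovered within 5% and centers essentially unmoved."""
        background = _gauss(GRID, 30.0, 16950.0, 200.0) + 5.0
        centers = [16780.0, 16860.0, 16950.0, 17040.0, 17120.0]
        amps = [100.0, 80.0, 60.0, 90.0, 70.0]
        lines = sum(_gauss(GRID, a, c, 1.0) for a, c in zip(amps, centers))
        corrected = correct_baseline(_spectrum(background + lines))
        for a, c in zip(amps, centers):
            i = np.argmin(np.abs(GRID - c))
            assert corrected.intensities[i] == pytest.approx(a, rel=0.05)

    def test_rejects_too_short_spectrum(self):
        short = FLNSpectrum(
            wavenumbers=np.linspace(16700, 16720, 30),
            intensities=np.zeros(30),
            excitation=17950.0,
            pressure=0.0,
        )
        with pytest.raises(ExtractionError):
            correct_baseline(short)


class TestDetectPeaks:
    def test_single_line_center_and_amplitude(self):
        spec = _spectrum(_gauss(GRID, 100.0, 16950.0, 1.0))
        peaks = detect_peaks(spec)
        assert len(peaks) == 1
        assert peaks[0].center == pytest.approx(16950.0, abs=0.05)
        assert peaks[0].amplitude == pytest.approx(100.0, rel=0.01)

    def test_two_lines_thirty_apart(self):
        y = _gauss(GRID, 100.0, 16940.0, 1.0) + _gauss(GRID, 60.0, 16970.0, 1.0)
        peaks = detect_peaks(_spectrum(y))
        assert len(peaks) == 2

    def test_noise_only_rarely_triggers(self):
        """At the default threshold a pure-noise spectrum yields no peaks in
        at least 95% of seeds."""
        clean = 0
        n_seeds = 100
        for seed in range(n_seeds):
            rng = np.random.default_rng(1000 + seed)
            spec = _spectrum(rng.normal(0.0, 1.0, GRID.size))
            clean += len(detect_peaks(spec)) == 0
        assert clean >= int(0.95 * n_seeds)

    def test_edge_peaks_discarded(self):
        y = _gauss(GRID, 100.0, 16702.0, 1.0) + _gauss(GRID, 100.0, 16950.0, 1.0)
        peaks = detect_peaks(_spectrum(y))
        assert [round(p.center) for p in peaks] == [16950]


class TestAssignModes:
    def test_attested_mode_of_the_strongest_line(self):
        # excitation 17971, emission line at 16998 -> vibrational energy 973
        peak = Peak(center=16998.0, amplitude=50.0, width=1.0, excitation=17971.0, pressure=0.14)
        (assigned,) = assign_modes([peak], [VibronicMode(973.0, 1.0)], tolerance=3.0)
        assert assigned.vib_energy == 973.0

    def test_outside_tolerance_unassigned(self):
        peak = Peak(center=16990.0, amplitude=50.0, width=1.0, excitation=17950.0, pressure=0.0)
        # computed vibrational energy 960, nearest mode 973
        (assigned,) = assign_modes([peak], [973.0], tolerance=3.0)
        assert assigned.vib_energy is None

    def test_tie_breaks_to_lower_energy(self):
        peak = Peak(center=16950.0, amplitude=50.0, width=1.0, excitation=17950.0, pressure=0.0)
        # vibrational energy 1000, equidistant between 999 and 1001
        (assigned,) = assign_modes([peak], [1001.0, 999.0], tolerance=3.0)
        assert assigned.vib_energy == 999.0

    def test_empty_mode_table_rejected(self):
        with pytest.raises(ValueError):
            assign_modes([], [], tolerance=3.0)


def _trace_peaks(mode, positions, amplitudes, pressure=0.0):
    return [
        Peak(
            center=x,
            amplitude=a,
            width=1.0,
            excitation=x + mode,
            pressure=pressure,
            vib_energy=mode,
        )
        for x, a in zip(positions, amplitudes)
    ]


class TestBuildIdfSamples:
    def test_area_weighting_unifies_proportional_traces(self):
        """Two modes whose amplitudes keep a constant 2:1 ratio collapse onto
        one curve after inverse-area weighting."""
        xs = np.linspace(16850.0, 17150.0, 13)
        shape = _gauss(xs, 1.0, 17000.0, 60.0)
        peaks = _trace_peaks(900.0, xs, 2.0 * shape) + _trace_peaks(1000.0, xs, shape)
        samples = build_idf_samples(peaks, ExtractionParams(weighting="area"))
        half = xs.size
        np.testing.assert_allclose(
            samples.pooled_y[::2], samples.pooled_y[1::2], rtol=1e-9
        )
        assert len(samples.traces) == 2 and samples.pooled_x.size == 2 * half

    def test_area_weighted_trace_integrates_to_one(self):
        xs = np.linspace(16800.0, 17200.0, 21)
        peaks = _trace_peaks(973.0, xs, _gauss(xs, 50.0, 17000.0, 60.0))
        samples = build_idf_samples(peaks, ExtractionParams(weighting="area"))
        (weight,) = samples.area_weights.values()
        x, y = samples.traces[973.0]
        assert np.trapezoid(weight * y, x) == pytest.approx(1.0, abs=1e-9)

    def test_all_modes_below_point_minimum_rejected(self):
        peaks = _trace_peaks(973.0, [16900.0, 16950.0], [1.0, 2.0])
        with pytest.raises(ExtractionError):
            build_idf_samples(peaks)

    def test_prefit_pooling_lies_on_generative_density(self, clean_config):
        """Noiseless pooled samples lie on the (pressure-transformed) IDF
        density up to one common scale."""
        p = clean_config.pressures[2]
        spectra = simulate_experiment(clean_config, noise=False)[p]
        est_params = ExtractionParams()
        from fln_kappa.extraction import (
            assign_modes as _assign,
            correct_baseline as _cb,
            detect_peaks as _dp,
            track_amplitudes as _track,
        )

        corrected = [_cb(s, est_params) for s in spectra]
        assigned = []
        for c in corrected:
            assigned.extend(_assign(_dp(c, est_params), list(clean_config.modes)))
        tracked = _track(corrected, assigned, est_params)
        samples = build_idf_samples(tracked, est_params)
        dens = transformed_density(
            clean_config.idf, clean_config.kappa_true, p, samples.pooled_x
        )
        ratio = samples.pooled_y / dens
        assert np.max(np.abs(ratio / np.median(ratio) - 1.0)) < 1e-3


class TestFitIdfGaussian:
    def test_exact_gaussian_recovered_to_six_digits(self):
        xs = np.linspace(16600.0, 17300.0, 25)
        peaks = _trace_peaks(973.0, xs, _gauss(xs, 3.0, 16950.0, 100.0))
        samples = build_idf_samples(peaks)
        est = fit_idf_gaussian(samples)
        assert est.center == pytest.approx(16950.0, abs=1e-3)
        assert est.sigma == pytest.approx(100.0, rel=1e-6)

    def test_too_few_points_rejected(self):
        xs = np.array([16900.0, 16950.0, 17000.0, 17050.0])
        peaks = _trace_peaks(973.0, xs, _gauss(xs, 3.0, 16950.0, 100.0))
        samples = build_idf_samples(peaks)
        with pytest.raises(ExtractionError):
            fit_idf_gaussian(samples, ExtractionParams(min_pooled_points=6))

    def test_noisy_recovery_within_two_se(self):
        """With 5%-of-peak noise the fitted center and width land within
        2 SE of truth in at least 90% of seeds."""
        xs = np.linspace(16750.0, 17150.0, 40)
        hits = 0
        n_seeds = 60
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            y = _gauss(xs, 3.0, 16950.0, 90.0) + rng.normal(0, 0.15, xs.size)
            samples = build_idf_samples(_trace_peaks(973.0, xs, y))
            est = fit_idf_gaussian(samples)
            ok_c = abs(est.center - 16950.0) <= 2 * max(est.center_se, 1e-9)
            ok_s = abs(est.sigma - 90.0) <= 2 * max(est.sigma_se, 1e-9)
            hits += ok_c and ok_s
        assert hits >= int(0.90 * n_seeds) - 2


class TestEndToEnd:
    def test_noiseless_estimates_match_closed_form(self, clean_config):
        """Per-pressure evaluation of noiseless simulations reproduces the
        closed-form IDF transform: centers within 0.2 cm^-1, widths
        within 1%."""
        spectra = simulate_experiment(clean_config, noise=False)
        for p in clean_config.pressures[:5]:
            est = extract_idf_estimate(spectra[p], list(clean_config.modes))
            center_p, sigma_p = transform_idf(
                clean_config.idf, clean_config.kappa_true, p
            )
            assert est.center == pytest.approx(center_p, abs=0.2)
            assert est.sigma == pytest.approx(sigma_p, rel=0.01)

    def test_intensity_scale_invariance(self, clean_config):
        p = clean_config.pressures[1]
        spectra = simulate_experiment(clean_config, noise=False)[p]
        est = extract_idf_estimate(spectra, list(clean_config.modes))
        scaled = [
            FLNSpectrum(
                wavenumbers=s.wavenumbers,
                intensities=137.0 * s.intensities,
                excitation=s.excitation,
                pressure=s.pressure,
            )
            for s in spectra
        ]
        est2 = extract_idf_estimate(scaled, list(clean_config.modes))
        assert est2.center == pytest.approx(est.center, abs=1e-6)
        assert est2.sigma == pytest.approx(est.sigma, rel=1e-6)

    def test_mode_table_robustness(self):
        """Dropping one vibronic mode from the table moves the pooled IDF
        center by less than one standard error (normalization makes the
        modes interchangeable)."""
        cfg = default_config(kappa_true=0.25, seed=11)
        spectra = simulate_experiment(cfg)[cfg.pressures[1]]
        full = extract_idf_estimate(spectra, list(cfg.modes))
        reduced = extract_idf_estimate(spectra, list(cfg.modes)[:-1])
        assert abs(full.center - reduced.center) < max(full.center_se, reduced.center_se)
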