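"""Generative model of the synthetic FLN experiments."""

import json
import math

import numpy as np
import pytest

from fln_kappa import (
    Background,
    IDFModel,
    SimulationConfig,
    VibronicMode,
    default_config,
    generate_experiment,
    line_amplitude,
    simulate_experiment,
    simulate_spectrum,
)
from fln_kappa.core_model import transformed_density
from fln_kappa.simulator import spectrum_rng


def _single_mode_config(**overrides):
    base = dict(
        idf=IDFModel(17000.0, 60.0, 17600.0),
        modes=(VibronicMode(973.0, 1.0),),
        kappa_true=0.25,
        pressures=(0.0, 0.5, 1.0),
        excitations=tuple(np.linspace(17700.0, 18100.0, 9)),
        gain=1.0,
        laser_width=1.0,
        background=Background(0.0, 16950.0, 200.0, 0.0),
        noise_sd=0.0,
    )
    base.update(overrides)
    return SimulationConfig(**base)


class TestLineAmplitude:
    def test_resonant_amplitude_is_idf_density(self):
        # unit gain/strength/laser width, excitation hitting the IDF center
        cfg = _single_mode_config()
        amp = line_amplitude(cfg.idf, cfg.modes[0], 17973.0, cfg, pressure=0.0)
        assert amp == pytest.approx(1.0 / (60.0 * math.sqrt(2 * math.pi)), rel=1e-9)
        assert amp == pytest.approx(6.65e-3, rel=1e-3)

    def test_far_tail_is_negligible(self):
        cfg = _single_mode_config()
        peak = line_amplitude(cfg.idf, cfg.modes[0], 17973.0, cfg)
        tail = line_amplitude(cfg.idf, cfg.modes[0], 17973.0 + 5 * 60.0, cfg)
        assert tail < 1e-5 * peak

    def test_linear_in_mode_strength(self):
        cfg = _single_mode_config()
        weak = VibronicMode(973.0, 0.5)
        strong = VibronicMode(973.0, 1.5)
        a_weak = line_amplitude(cfg.idf, weak, 17950.0, cfg)
        a_strong = line_amplitude(cfg.idf, strong, 17950.0, cfg)
        assert a_strong == pytest.approx(3.0 * a_weak, rel=1e-12)


class TestSimulateSpectrum:
    def test_noiseless_maxima_at_resonant_positions(self):
        cfg = _single_mode_config(
            modes=(VibronicMode(973.0, 1.0), VibronicMode(1130.0, 0.6))
        )
        spec = simulate_spectrum(cfg, 17950.0, 0.0)
        for mode in cfg.modes:
            center = 17950.0 - mode.vib_energy
            i = np.argmin(np.abs(spec.wavenumbers - center))
            window = spec.intensities[i - 8 : i + 9]
            assert np.argmax(window) == 8

    def test_equal_density_modes_have_strength_ratio(self, idf):
        # symmetric positions around the IDF center see equal density, so
        # peak amplitudes scale exactly with B_m
        nu_exc = 17000.0 + 973.0 + 50.0
        modes = (VibronicMode(973.0, 2.0), VibronicMode(1073.0, 1.0))
        cfg = _single_mode_config(modes=modes)
        spec = simulate_spectrum(cfg, nu_exc, 0.0)
        a1 = spec.intensities[np.argmin(np.abs(spec.wavenumbers - (nu_exc - 973.0)))]
        a2 = spec.intensities[np.argmin(np.abs(spec.wavenumbers - (nu_exc - 1073.0)))]
        assert a1 == pytest.approx(2.0 * a2, rel=1e-6)

    def test_unreachable_idf_gives_pure_background(self):
        cfg = _single_mode_config(
            idf=IDFModel(10000.0, 60.0, 10600.0),
            background=Background(3.0, 16950.0, 200.0, 1.0),
        )
        spec = simulate_spectrum(cfg, 17950.0, 0.0)
        expected = cfg.background.evaluate(spec.wavenumbers)
        np.testing.assert_allclose(spec.intensities, expected, rtol=1e-12)

    def test_excitation_must_be_above_window(self):
        cfg = _single_mode_config()
        with pytest.raises(ValueError):
            simulate_spectrum(cfg, 17100.0, 0.0)

    def test_amplitudes_track_transformed_idf(self):
        """Noiseless line amplitudes across excitations lie on the
        pressure-transformed IDF density up to one scale factor."""
        cfg = _single_mode_config(excitations=tuple(np.linspace(17750, 18050, 13)))
        p = 1.0
        positions, amps = [], []
        for exc in cfg.excitations:
            spec = simulate_spectrum(cfg, exc, p)
            pos = exc - 973.0
            i = np.argmin(np.abs(spec.wavenumbers - pos))
            positions.append(spec.wavenumbers[i])
            amps.append(spec.intensities[i])
        dens = transformed_density(cfg.idf, cfg.kappa_true, p, np.array(positions))
        ratio = np.array(amps) / dens
        assert np.max(np.abs(ratio / ratio.mean() - 1.0)) < 1e-6


class TestDeterminism:
    def test_same_seed_same_spectra(self):
        cfg = default_config(kappa_true=0.3, seed=7, n_pressures=3, n_excitations=4)
        a = simulate_experiment(cfg)
        b = simulate_experiment(cfg)
        for p in cfg.pressures:
            for sa, sb in zip(a[p], b[p]):
                np.testing.assert_array_equal(sa.intensities, sb.intensities)

    def test_different_spectra_use_independent_substreams(self):
        r1 = spectrum_rng(7, 0, 0).normal(size=100)
        r2 = spectrum_rng(7, 0, 1).normal(size=100)
        r3 = spectrum_rng(7, 1, 0).normal(size=100)
        assert not np.allclose(r1, r2)
        assert not np.allclose(r1, r3)

    def test_generate_experiment_byte_identical(self, tmp_path):
        cfg = default_config(kappa_true=0.3, seed=3, n_pressures=2, n_excitations=3)
        m1 = generate_experiment(cfg, tmp_path / "a")
        m2 = generate_experiment(cfg, tmp_path / "b")
        for f1 in sorted((tmp_path / "a").iterdir()):
            f2 = tmp_path / "b" / f1.name
            assert f1.read_bytes() == f2.read_bytes()


class TestGenerateExperiment:
    def test_file_count_and_truth_sidecar(self, tmp_path):
        cfg = default_config(kappa_true=0.25, seed=1, n_pressures=3, n_excitations=5)
        manifest_path = generate_experiment(cfg, tmp_path)
        manifest = json.loads(manifest_path.read_text())
        assert len(manifest["spectra"]) == 15
        spectra_files = list(tmp_path.glob("spectrum_*.txt"))
        assert len(spectra_files) == 15
        truth = json.loads((tmp_path / "truth.json").read_text())
        assert truth["kappa_true"] == 0.25
        # ground truth lives only in the sidecar, not the manifest
        assert "kappa_true" not in json.dumps(manifest)

    def test_default_fixture_spans_study_pressure_range(self):
        cfg = default_config()
        assert cfg.pressures[0] == 0.0
        assert cfg.pressures[-1] == pytest.approx(1.2)
        assert len(cfg.pressures) == 8
        assert len(cfg.excitations) == 25


class TestConfigValidation:
    def test_rejects_decreasing_pressures(self):
        with pytest.raises(ValueError):
            _single_mode_config(pressures=(0.5, 0.2))

    def test_rejects_negative_noise(self):
        with pytest.raises(ValueError):
            _single_mode_config(noise_sd=-0.1)

    def test_rejects_unknown_effector(self):
        with pytest.raises(ValueError):
            _single_mode_config(effectors="caffeine")

    def test_roundtrip_via_dict(self):
        cfg = default_config(kappa_true=0.3, seed=5)
        again = SimulationConfig.from_dict(cfg.to_dict())
        assert again == cfg
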