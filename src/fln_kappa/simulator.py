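"""Synthetic fluorescence line narrowing (FLN) experiments.

The generative model: exciting the sample at ``nu_exc`` through vibronic
level ``m`` selects the sub-ensemble of chromophores whose (0,0) energy is
``nu_exc - dnu_m`` (``dnu_m`` the vibrational energy of mode m), so the
resonant emission line sits at that position and its intensity is

    I_m = gain * B_m * n'_p(nu_exc - dnu_m) * laser_width,

where ``n'_p`` is the pressure-transformed Gaussian IDF density and ``B_m``
the relative absorption strength of the mode.  ``gain`` lumps the constant
prefactors (excitation intensity, emission probability, number of
chromophores, collection efficiency).  Lines are Gaussian with the
instrumental width and the laser width added in quadrature; a broad
Gaussian background plus a constant offset and additive Gaussian detector
noise complete the spectrum.

Spectra are restricted to the CCD detection window (default
16700-17200 cm^-1) and the excitation must lie above that window.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .core_model import IDFModel, transform_idf, transformed_density

__all__ = [
    "VibronicMode",
    "Background",
    "SimulationConfig",
    "FLNSpectrum",
    "default_modes",
    "default_config",
    "line_amplitude",
    "simulate_spectrum",
    "simulate_experiment",
    "generate_experiment",
    "spectrum_rng",
]

#: Conversion between Gaussian FWHM and standard deviation.
FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))

EFFECTOR_LABELS = ("none", "Cl", "IHP", "IHP+Cl", "BZF", "BZF+Cl")


@dataclass(frozen=True)
class VibronicMode:
    """One vibrational mode: energy dnu_m (cm^-1) and relative strength B_m."""

    vib_energy: float
    rel_strength: float

    def __post_init__(self) -> None:
        if not (self.vib_energy > 0 and math.isfinite(self.vib_energy)):
            raise ValueError(f"vib_energy must be > 0, got {self.vib_energy}")
        if not (self.rel_strength > 0 and math.isfinite(self.rel_strength)):
            raise ValueError(f"rel_strength must be > 0, got {self.rel_strength}")


@dataclass(frozen=True)
class Background:
    """Broad Gaussian + constant offset, in absolute intensity units."""

    amplitude: float
    center: float
    width: float
    offset: float = 0.0

    def evaluate(self, nu: np.ndarray) -> np.ndarray:
        z = (nu - self.center) / self.width
        return self.amplitude * np.exp(-0.5 * z * z) + self.offset


@dataclass(frozen=True)
class FLNSpectrum:
    """One emission trace at fixed excitation frequency and pressure."""

    wavenumbers: np.ndarray
    intensities: np.ndarray
    excitation: float
    pressure: float
    temperature: float = 10.0
    sample: str = "beta-Zn-HbA"
    effectors: str = "none"

    def __post_init__(self) -> None:
        wn = np.asarray(self.wavenumbers, dtype=float)
        inten = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "wavenumbers", wn)
        object.__setattr__(self, "intensities", inten)
        if wn.ndim != 1 or wn.shape != inten.shape:
            raise ValueError("wavenumbers and intensities must be equal-length 1-D")
        if wn.size >= 2 and not np.all(np.diff(wn) > 0):
            raise ValueError("wavenumber grid must be strictly increasing")

    @property
    def window(self) -> tuple[float, float]:
        return float(self.wavenumbers[0]), float(self.wavenumbers[-1])


def default_modes() -> list[VibronicMode]:
    """Default vibronic mode table of the Zn-protoporphyrin fluorophore.

    Only the 973 cm^-1 mode (the most intense emission line) is attested for
    this system; the remaining entries are synthetic but typical porphyrin
    skeletal-mode energies, included so that multi-mode pooling is exercised.
    """
    return [
        VibronicMode(750.0, 0.45),
        VibronicMode(973.0, 1.0),
        VibronicMode(1130.0, 0.6),
        VibronicMode(1220.0, 0.35),
        VibronicMode(1375.0, 0.5),
    ]


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of one synthetic pressure-series FLN experiment.

    Defaults reproduce the measurement conditions: a 0.7 cm^-1 (FWHM) laser,
    a 16700-17200 cm^-1 CCD window sampled at 0.5 cm^-1, pressures spanning
    0-1.2 GPa, and an excitation grid wide enough that the strongest mode's
    resonant emission sweeps the whole window as pressure shifts the IDF.
    ``noise_sd`` is the detector noise as a fraction of the largest
    theoretical line amplitude of the experiment (at p = 0), i.e. a constant
    noise floor.
    """

    idf: IDFModel
    modes: tuple[VibronicMode, ...]
    kappa_true: float
    pressures: tuple[float, ...]
    excitations: tuple[float, ...]
    laser_width: float = 0.7
    detection_window: tuple[float, float] = (16700.0, 17200.0)
    line_sigma: float = 0.5
    grid_step: float = 0.5
    gain: float = 1.0e4
    background: Background | None = None
    noise_sd: float = 0.05
    seed: int = 0
    temperature: float = 10.0
    sample: str = "beta-Zn-HbA"
    effectors: str = "none"

    def __post_init__(self) -> None:
        object.__setattr__(self, "modes", tuple(self.modes))
        object.__setattr__(self, "pressures", tuple(float(p) for p in self.pressures))
        object.__setattr__(
            self, "excitations", tuple(float(e) for e in self.excitations)
        )
        if not self.modes:
            raise ValueError("at least one vibronic mode is required")
        if any(p < 0 for p in self.pressures):
            raise ValueError("pressures must be >= 0 GPa")
        if any(b <= a for a, b in zip(self.pressures, self.pressures[1:])):
            raise ValueError("pressures must be strictly increasing")
        if any(b <= a for a, b in zip(self.excitations, self.excitations[1:])):
            raise ValueError("excitations must be strictly increasing")
        lo, hi = self.detection_window
        if not hi > lo:
            raise ValueError("detection window must be non-empty")
        if self.grid_step > 1.0:
            raise ValueError("grid_step must be <= 1 cm^-1 (instrument resolution)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.effectors not in EFFECTOR_LABELS:
            raise ValueError(
                f"effectors must be one of {EFFECTOR_LABELS}, got {self.effectors!r}"
            )

    @property
    def line_sigma_total(self) -> float:
        """Instrumental and laser widths combined in quadrature (cm^-1)."""
        return math.hypot(self.line_sigma, self.laser_width * FWHM_TO_SIGMA)

    @property
    def max_line_amplitude(self) -> float:
        """Largest theoretical line amplitude of the experiment, at p = 0."""
        peak_density = 1.0 / (self.idf.sigma0 * math.sqrt(2.0 * math.pi))
        bmax = max(m.rel_strength for m in self.modes)
        return self.gain * bmax * self.laser_width * peak_density

    def resolved_background(self) -> Background:
        if self.background is not None:
            return self.background
        a0 = self.max_line_amplitude
        lo, hi = self.detection_window
        return Background(
            amplitude=0.25 * a0, center=0.5 * (lo + hi), width=200.0, offset=0.05 * a0
        )

    def grid(self) -> np.ndarray:
        lo, hi = self.detection_window
        n = int(round((hi - lo) / self.grid_step)) + 1
        return lo + self.grid_step * np.arange(n)

    # -- (de)serialization for config files ---------------------------------

    def to_dict(self) -> dict:
        d = {
            "idf": {
                "center_nu00": self.idf.center_nu00,
                "sigma0": self.idf.sigma0,
                "nu_vac": self.idf.nu_vac,
            },
            "modes": [[m.vib_energy, m.rel_strength] for m in self.modes],
            "kappa_true": self.kappa_true,
            "pressures": list(self.pressures),
            "excitations": list(self.excitations),
            "laser_width": self.laser_width,
            "detection_window": list(self.detection_window),
            "line_sigma": self.line_sigma,
            "grid_step": self.grid_step,
            "gain": self.gain,
            "noise_sd": self.noise_sd,
            "seed": self.seed,
            "temperature": self.temperature,
            "sample": self.sample,
            "effectors": self.effectors,
        }
        if self.background is not None:
            b = self.background
            d["background"] = [b.amplitude, b.center, b.width, b.offset]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        idf = IDFModel(**d.pop("idf"))
        modes = tuple(VibronicMode(*m) for m in d.pop("modes"))
        bg = d.pop("background", None)
        background = Background(*bg) if bg is not None else None
        d["detection_window"] = tuple(d.get("detection_window", (16700.0, 17200.0)))
        return cls(idf=idf, modes=modes, background=background, **d)


def default_config(
    kappa_true: float = 0.36,
    *,
    idf: IDFModel | None = None,
    noise_sd: float = 0.05,
    background: bool = True,
    seed: int = 0,
    sample: str = "beta-Zn-HbA",
    effectors: str = "none",
    n_pressures: int = 8,
    n_excitations: int = 25,
) -> SimulationConfig:
    """Study-condition defaults: 8 pressures in 0-1.2 GPa, 25 excitations.

    The IDF defaults to N(17000, 60) cm^-1 with a -200 cm^-1 matrix shift
    (nu_vac = 17200).  The shift magnitude is bounded by an observable
    consistency requirement: the measured IDF center stayed inside the
    fixed 16700-17200 cm^-1 CCD window across the whole 0-1.2 GPa series
    even for the most compressible condition (kappa ~ 0.36/GPa), which
    caps |nu0s| at roughly 230 cm^-1.  ``background=False`` gives a
    strictly line-only spectrum (zero background, for noiseless
    closed-form checks).
    """
    if idf is None:
        idf = IDFModel(center_nu00=17000.0, sigma0=60.0, nu_vac=17200.0)
    cfg = SimulationConfig(
        idf=idf,
        modes=tuple(default_modes()),
        kappa_true=kappa_true,
        pressures=tuple(np.linspace(0.0, 1.2, n_pressures)),
        excitations=tuple(np.linspace(17550.0, 18100.0, n_excitations)),
        noise_sd=noise_sd,
        seed=seed,
        sample=sample,
        effectors=effectors,
    )
    if not background:
        cfg = replace(cfg, background=Background(0.0, 16950.0, 200.0, 0.0))
    return cfg


def line_amplitude(
    idf: IDFModel,
    mode: VibronicMode,
    nu_exc: float,
    config: SimulationConfig,
    pressure: float = 0.0,
) -> float:
    """Peak amplitude of the resonant (0,0) line of ``mode`` at ``nu_exc``.

    gain * B_m * n'_p(nu_exc - dnu_m) * laser_width, with n'_p the IDF
    density transformed to ``pressure``.  Essentially zero when the selected
    (0,0) energy falls in the far tail of the IDF.
    """
    position = nu_exc - mode.vib_energy
    density = transformed_density(idf, config.kappa_true, pressure, position)
    return config.gain * mode.rel_strength * config.laser_width * float(density)


def spectrum_rng(seed: int, pressure_index: int, excitation_index: int) -> np.random.Generator:
    """Independent, reproducible noise substream for one (p, nu_exc) spectrum."""
    ss = np.random.SeedSequence(seed, spawn_key=(pressure_index, excitation_index))
    return np.random.default_rng(ss)


def _noiseless_lines(
    config: SimulationConfig, nu_exc: float, pressure: float, grid: np.ndarray
) -> np.ndarray:
    sig = config.line_sigma_total
    out = np.zeros_like(grid)
    for mode in config.modes:
        center = nu_exc - mode.vib_energy
        amp = line_amplitude(config.idf, mode, nu_exc, config, pressure)
        if amp <= 0:
            continue
        z = (grid - center) / sig
        # 10 sigma support is plenty and keeps the loop cheap
        mask = np.abs(z) < 10.0
        out[mask] += amp * np.exp(-0.5 * z[mask] ** 2)
    return out


def simulate_spectrum(
    config: SimulationConfig,
    nu_exc: float,
    pressure: float,
    rng: np.random.Generator | None = None,
) -> FLNSpectrum:
    """Simulate one FLN emission spectrum.

    Sum of Gaussian vibronic lines (amplitudes from :func:`line_amplitude`)
    over the detection-window grid, plus background, plus additive Gaussian
    noise drawn from ``rng`` (``rng=None`` gives the noiseless spectrum
    regardless of ``noise_sd``).
    """
    lo, hi = config.detection_window
    if not nu_exc > hi:
        raise ValueError(
            f"excitation {nu_exc} cm^-1 must lie above the detection window edge {hi}"
        )
    grid = config.grid()
    if grid.size == 0:
        raise ValueError("empty detection window")
    intensities = _noiseless_lines(config, nu_exc, pressure, grid)
    intensities += config.resolved_background().evaluate(grid)
    if rng is not None and config.noise_sd > 0:
        sd_abs = config.noise_sd * config.max_line_amplitude
        intensities = intensities + rng.normal(0.0, sd_abs, size=grid.size)
    return FLNSpectrum(
        wavenumbers=grid,
        intensities=intensities,
        excitation=float(nu_exc),
        pressure=float(pressure),
        temperature=config.temperature,
        sample=config.sample,
        effectors=config.effectors,
    )


def simulate_experiment(
    config: SimulationConfig, noise: bool = True
) -> dict[float, list[FLNSpectrum]]:
    """Simulate the full pressure series in memory, grouped by pressure.

    Each (pressure, excitation) pair uses its own seeded noise substream, so
    the result is deterministic for a given ``config.seed``.
    """
    out: dict[float, list[FLNSpectrum]] = {}
    for ip, p in enumerate(config.pressures):
        group = []
        for ie, exc in enumerate(config.excitations):
            rng = spectrum_rng(config.seed, ip, ie) if noise else None
            group.append(simulate_spectrum(config, exc, p, rng))
        out[p] = group
    return out


def generate_experiment(config: SimulationConfig, out_dir: str | Path) -> Path:
    """Write a full experiment to disk: spectrum files, manifest, truth sidecar.

    One delimited-text spectrum file per (pressure, excitation) pair, a JSON
    manifest listing the conditions and file paths, and a separate
    ``truth.json`` holding the generative parameters (kept out of the
    manifest so extraction code cannot silently read it).  Returns the
    manifest path.  Byte-identical output for identical configs.
    """
    from . import io as spectra_io  # deferred; io imports FLNSpectrum from here

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for ip, p in enumerate(config.pressures):
        for ie, exc in enumerate(config.excitations):
            rng = spectrum_rng(config.seed, ip, ie)
            spec = simulate_spectrum(config, exc, p, rng)
            name = f"spectrum_p{ip:02d}_x{ie:02d}.txt"
            spectra_io.write_spectrum(spec, out_dir / name)
            entries.append(
                {"pressure_gpa": p, "excitation_cm1": exc, "path": name}
            )
    manifest = {
        "sample": config.sample,
        "effectors": config.effectors,
        "spectra": entries,
    }
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1) + "\n")
    truth = {
        "kappa_true": config.kappa_true,
        "idf": {
            "center_nu00": config.idf.center_nu00,
            "sigma0": config.idf.sigma0,
            "nu_vac": config.idf.nu_vac,
        },
        "config": config.to_dict(),
    }
    (out_dir / "truth.json").write_text(json.dumps(truth, indent=1) + "\n")
    return manifest_path
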