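"""End-to-end orchestration: spectra -> IDF series -> compressibility.

These helpers tie the stages together for simulations held in memory (the
recovery studies and the acceptance checks) and for experiments loaded from
disk via :mod:`fln_kappa.io`.  Pressures whose spectra cannot support an
IDF estimate (too few usable lines once noise and the detection window
have taken their toll) are skipped and reported, mirroring how a real
series would be evaluated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .extraction import (
    ExtractionError,
    ExtractionParams,
    IDFEstimate,
    extract_idf_estimate,
)
from .inference import CompressibilityResult, PressureSeries, fit_compressibility
from .simulator import FLNSpectrum, SimulationConfig, VibronicMode, simulate_experiment

__all__ = ["RecoveryOutcome", "extract_idf_series", "recover_kappa"]


@dataclass
class RecoveryOutcome:
    """Everything one pipeline run produced, including skipped pressures."""

    result: CompressibilityResult
    estimates: list[IDFEstimate]
    skipped: list[tuple[float, str]] = field(default_factory=list)

    @property
    def kappa(self) -> float:
        return self.result.kappa_combined

    @property
    def kappa_sd(self) -> float:
        return self.result.kappa_combined_sd


def extract_idf_series(
    spectra_by_pressure: dict[float, list[FLNSpectrum]],
    mode_table: list[VibronicMode] | list[float],
    params: ExtractionParams = ExtractionParams(),
) -> tuple[list[IDFEstimate], list[tuple[float, str]]]:
    """Evaluate every pressure group; return the estimates and the skips."""
    estimates: list[IDFEstimate] = []
    skipped: list[tuple[float, str]] = []
    for pressure in sorted(spectra_by_pressure):
        try:
            estimates.append(
                extract_idf_estimate(spectra_by_pressure[pressure], mode_table, params)
            )
        except ExtractionError as exc:
            skipped.append((pressure, str(exc)))
    return estimates, skipped


def recover_kappa(
    config: SimulationConfig,
    params: ExtractionParams = ExtractionParams(),
    noise: bool = True,
    nu0s: float | None = None,
) -> RecoveryOutcome:
    """Simulate one experiment and run the full evaluation on it."""
    spectra = simulate_experiment(config, noise=noise)
    estimates, skipped = extract_idf_series(spectra, list(config.modes), params)
    if len({e.pressure for e in estimates}) < 3:
        raise ExtractionError(
            f"only {len(estimates)} pressures usable, need >= 3 "
            f"(skipped: {[p for p, _ in skipped]})"
        )
    series = PressureSeries(tuple(estimates))
    result = fit_compressibility(series, nu0s=nu0s)
    return RecoveryOutcome(result=result, estimates=estimates, skipped=skipped)
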