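"""Closed-form physics of pressure-tuned site-selective spectroscopy.

A chromophore embedded in a (frozen) protein matrix has its electronic
(0,0) transition shifted from the vacuum frequency ``nu_vac`` by the
matrix ("solvent") shift ``nu_s = nu_0 - nu_vac``.  Under hydrostatic
pressure ``p`` the line moves linearly,

    nu_p = nu_0 + 2 (nu_0 - nu_vac) kappa p,

where ``kappa`` is the isothermal compressibility of the matrix around the
chromophore (Laird-Skinner linear elastic theory).  Applied to a Gaussian
inhomogeneous distribution function (IDF) of (0,0) energies this gives a
linear shift of the center and a linear broadening of the width:

    nu00(p)  = nu00 + 2 kappa p nu0s,
    sigma(p) = (1 + 2 kappa p) sigma0.

Statistical mechanics links kappa to equilibrium volume fluctuations,
``<(V - <V>)^2> = kappa kB T <V>``, which is why kappa is read as a measure
of conformational flexibility.

Units: wavenumbers in cm^-1, pressure in GPa, kappa in 1/GPa.  SI conversion
happens only inside :func:`volume_fluctuation_variance`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BOLTZMANN_SI",
    "IDFModel",
    "ThermoState",
    "CompressibilityValue",
    "pressure_shift_line",
    "transform_idf",
    "volume_fluctuation_variance",
]

#: Boltzmann constant, J/K (exact, SI definition).
BOLTZMANN_SI = 1.380649e-23

_GPA_TO_PA = 1e9
_A3_TO_M3 = 1e-30
_M6_TO_A6 = 1e60


def _require_finite(**values: float) -> None:
    for name, value in values.items():
        if not math.isfinite(value):
            raise ValueError(f"{name} must be finite, got {value!r}")


@dataclass(frozen=True)
class IDFModel:
    """Gaussian inhomogeneous distribution of (0,0) transition energies.

    Parameters
    ----------
    center_nu00
        Center of the distribution at ambient pressure, cm^-1.
    sigma0
        Standard deviation (width) at ambient pressure, cm^-1; > 0.
    nu_vac
        Vacuum transition frequency of the free chromophore, cm^-1.  It is
        not measurable in the matrix and must be supplied (config or fit);
        there is no physical default.
    """

    center_nu00: float
    sigma0: float
    nu_vac: float

    def __post_init__(self) -> None:
        _require_finite(
            center_nu00=self.center_nu00, sigma0=self.sigma0, nu_vac=self.nu_vac
        )
        if self.sigma0 <= 0:
            raise ValueError(f"sigma0 must be > 0, got {self.sigma0}")

    @property
    def solvent_shift_nu0s(self) -> float:
        """Matrix (solvent) shift of the IDF center, cm^-1 (center - vacuum)."""
        return self.center_nu00 - self.nu_vac

    def density(self, nu: np.ndarray | float) -> np.ndarray | float:
        """Normal probability density of the IDF at ambient pressure."""
        z = (np.asarray(nu, dtype=float) - self.center_nu00) / self.sigma0
        out = np.exp(-0.5 * z * z) / (self.sigma0 * math.sqrt(2.0 * math.pi))
        return out if np.ndim(nu) else float(out)


@dataclass(frozen=True)
class ThermoState:
    """Thermodynamic state of the fluctuating volume element.

    temperature in K, mean volume in A^3; both strictly positive.
    """

    temperature: float
    volume: float

    def __post_init__(self) -> None:
        _require_finite(temperature=self.temperature, volume=self.volume)
        if self.temperature <= 0:
            raise ValueError(f"temperature must be > 0 K, got {self.temperature}")
        if self.volume <= 0:
            raise ValueError(f"volume must be > 0 A^3, got {self.volume}")


@dataclass(frozen=True)
class CompressibilityValue:
    """A compressibility with its standard deviation, both in 1/GPa."""

    kappa: float
    kappa_sd: float = field(default=0.0)

    def __post_init__(self) -> None:
        _require_finite(kappa=self.kappa, kappa_sd=self.kappa_sd)
        if self.kappa_sd < 0:
            raise ValueError(f"kappa_sd must be >= 0, got {self.kappa_sd}")


def pressure_shift_line(
    nu0: float, nu_vac: float, kappa: float, p: float
) -> float:
    """Frequency of one spectral line under hydrostatic pressure.

    nu_p = nu0 + 2 (nu0 - nu_vac) kappa p.  Linear in p; a negative solvent
    shift (nu0 < nu_vac) with kappa > 0 gives a red shift (decreasing
    wavenumber).  No sign of the solvent shift is assumed.

    Parameters are in cm^-1 (frequencies), 1/GPa (kappa) and GPa (p >= 0).
    """
    _require_finite(nu0=nu0, nu_vac=nu_vac, kappa=kappa, p=p)
    if p < 0:
        raise ValueError(f"pressure must be >= 0 GPa, got {p}")
    return nu0 + 2.0 * (nu0 - nu_vac) * kappa * p


def transform_idf(idf: IDFModel, kappa: float, p: float) -> tuple[float, float]:
    """Center and width of the IDF at pressure ``p``.

    Returns ``(center_p, sigma_p)`` with ``center_p = nu00 + 2 kappa p nu0s``
    and ``sigma_p = (1 + 2 kappa p) sigma0``.  Requires ``p >= 0`` and
    ``2 kappa p > -1`` so the width stays positive.
    """
    _require_finite(kappa=kappa, p=p)
    if p < 0:
        raise ValueError(f"pressure must be >= 0 GPa, got {p}")
    scale = 1.0 + 2.0 * kappa * p
    if scale <= 0:
        raise ValueError(
            f"2*kappa*p = {2.0 * kappa * p} must exceed -1 (got width scale {scale})"
        )
    center_p = idf.center_nu00 + 2.0 * kappa * p * idf.solvent_shift_nu0s
    sigma_p = scale * idf.sigma0
    return center_p, sigma_p


def transformed_density(
    idf: IDFModel, kappa: float, p: float, nu: np.ndarray | float
) -> np.ndarray | float:
    """Normal density of the pressure-transformed IDF evaluated at ``nu``."""
    center_p, sigma_p = transform_idf(idf, kappa, p)
    z = (np.asarray(nu, dtype=float) - center_p) / sigma_p
    out = np.exp(-0.5 * z * z) / (sigma_p * math.sqrt(2.0 * math.pi))
    return out if np.ndim(nu) else float(out)


def volume_fluctuation_variance(kappa: float, state: ThermoState) -> float:
    """Equilibrium variance of the volume fluctuations, in A^6.

    ``<(V - <V>)^2> = kappa kB T <V>`` with kappa in 1/GPa and <V> in A^3;
    the SI conversion is internal and the result is returned in A^6.
    """
    _require_finite(kappa=kappa)
    if kappa < 0:
        raise ValueError(f"kappa must be >= 0, got {kappa}")
    kappa_si = kappa / _GPA_TO_PA
    volume_si = state.volume * _A3_TO_M3
    var_si = kappa_si * BOLTZMANN_SI * state.temperature * volume_si
    return var_si * _M6_TO_A6
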