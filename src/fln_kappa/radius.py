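"""Effective interaction radius of the chromophore with its matrix.

The matrix ("solvent") shift of the transition is modeled as a pairwise
power-law interaction nu_s(r) = alpha r^-n (n = 6 for dispersion-type
interactions) integrated over a homogeneous, isotropic shell of solvent
from the effective chromophore radius R0 outward.  The fraction of the
total shift that originates beyond a radius R is then

    P(R) = (R / R0)^-(n-3),

so the radius containing all but an error fraction P of the shift is

    R_(1-P) = R0 * P^(-1/(n-3)),

with R0 = (3 V0 / 4 pi)^(1/3) in the spherical approximation.  n > 3 is
required for the shell integral of r^(2-n) to converge.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "RadiusParams",
    "radius_from_volume",
    "radius_at_error",
    "error_at_radius",
]


def radius_from_volume(volume: float) -> float:
    """Radius of the sphere with the given volume: (3V / 4 pi)^(1/3).

    Volume in A^3, radius in A.  The central part of a heme group is about
    300 A^3, giving R0 of about 4.2 A.
    """
    if not (volume > 0 and math.isfinite(volume)):
        raise ValueError(f"volume must be > 0, got {volume}")
    return (3.0 * volume / (4.0 * math.pi)) ** (1.0 / 3.0)


@dataclass(frozen=True)
class RadiusParams:
    """Chromophore size (volume or radius, exactly one), exponent and error.

    exponent_n > 3 (default 6); error_P is the accepted fraction of the
    shift left outside the reported radius, 0 < P < 1.
    """

    error_P: float
    chromophore_volume: float | None = None
    radius_R0: float | None = None
    exponent_n: float = 6.0

    def __post_init__(self) -> None:
        if (self.chromophore_volume is None) == (self.radius_R0 is None):
            raise ValueError("give exactly one of chromophore_volume or radius_R0")
        if self.radius_R0 is not None and not self.radius_R0 > 0:
            raise ValueError(f"radius_R0 must be > 0, got {self.radius_R0}")
        if self.exponent_n <= 3:
            raise ValueError(
                f"exponent_n must exceed 3 for convergence, got {self.exponent_n}"
            )
        if not 0.0 < self.error_P <= 1.0:
            raise ValueError(f"error_P must be in (0, 1], got {self.error_P}")

    @property
    def r0(self) -> float:
        if self.radius_R0 is not None:
            return self.radius_R0
        return radius_from_volume(self.chromophore_volume)


def radius_at_error(params: RadiusParams) -> float:
    """Radius beyond which only a fraction ``error_P`` of the shift remains.

    R_(1-P) = R0 * P^(-1/(n-3)); P = 1 returns R0 itself.
    """
    return params.r0 * params.error_P ** (-1.0 / (params.exponent_n - 3.0))


def error_at_radius(params: RadiusParams, radius: float) -> float:
    """Fraction of the shift originating outside ``radius``: (R/R0)^-(n-3).

    Exact inverse of :func:`radius_at_error`; requires R >= R0.
    """
    r0 = params.r0
    if radius < r0:
        raise ValueError(f"radius {radius} must be >= R0 = {r0}")
    return (radius / r0) ** (-(params.exponent_n - 3.0))
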