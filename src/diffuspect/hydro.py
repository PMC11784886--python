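"""Stokes-Einstein and Perrin ellipsoid hydrodynamics.

Converts translational diffusion coefficients into hydrodynamic radii and
prolate-ellipsoid shape parameters.  The hydrodynamic radius is the radius
of the sphere with the same translational friction,

    R_h = k_B T / (6 pi eta D).

An elongated molecule is modelled as a prolate ellipsoid of revolution with
semi-axes a > b = c, whose exact translational friction gives

    R_h = a xi / ln((1 + xi) / (b / a)),   xi = sqrt(1 - (b/a)^2),

(the Perrin friction factor).  R_h is strictly increasing in b at fixed a
and tends to a in the sphere limit b -> a, so the semi-minor axis can be
recovered from a measured R_h by bracketed root-finding.

Default solvent conditions are T = 298.15 K and eta = 1.00e-3 Pa s; both
are explicit parameters everywhere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

from scipy.optimize import brentq

__all__ = ["BOLTZMANN", "SolventConditions", "EllipsoidFit", "HydroResult",
           "stokes_einstein_rh", "stokes_einstein_d", "perrin_rh",
           "invert_perrin_semi_minor", "ellipsoid_volume",
           "semi_minor_from_volume", "sas_ratio_rh", "round_half_up"]

#: Boltzmann constant, J K^-1 (exact, 2019 SI).
BOLTZMANN = 1.380649e-23

_NM = 1e-9


@dataclass(frozen=True)
class SolventConditions:
    """Temperature and viscosity context for Stokes-Einstein conversions."""

    temperature: float = 298.15  # K
    viscosity: float = 1.00e-3   # Pa s
    boltzmann: float = BOLTZMANN

    def __post_init__(self):
        if not self.temperature > 0:
            raise ValueError("temperature must be positive")
        if not self.viscosity > 0:
            raise ValueError("viscosity must be positive")


@dataclass(frozen=True)
class EllipsoidFit:
    """Prolate ellipsoid of revolution, semi-axes a >= b = c, in nm."""

    a: float
    b: float

    def __post_init__(self):
        if not 0 < self.b <= self.a:
            raise ValueError("require 0 < b <= a (prolate)")

    @property
    def xi(self) -> float:
        """Eccentricity factor sqrt(1 - (b/a)^2)."""
        return math.sqrt(max(0.0, 1.0 - (self.b / self.a) ** 2))

    @property
    def volume(self) -> float:
        """(4/3) pi a b^2, nm^3."""
        return ellipsoid_volume(self.a, self.b)

    @property
    def rh_perrin(self) -> float:
        return perrin_rh(self.a, self.b)


@dataclass(frozen=True)
class HydroResult:
    """A diffusion coefficient with its hydrodynamic interpretation."""

    D: float
    rh: float
    conditions: SolventConditions
    ellipsoid: EllipsoidFit | None = None

    def __post_init__(self):
        if not self.rh > 0:
            raise ValueError("rh must be positive")
        back = stokes_einstein_rh(self.D, self.conditions)
        if abs(back - self.rh) > 1e-12 * self.rh:
            raise ValueError("rh inconsistent with D under the stored "
                             "conditions")


def stokes_einstein_rh(D: float,
                       conditions: SolventConditions = SolventConditions()
                       ) -> float:
    """Hydrodynamic radius R_h = k_B T / (6 pi eta D), returned in nm.

    No rounding is applied; presentation layers round.
    """
    if not D > 0:
        raise ValueError("D must be positive")
    rh_m = conditions.boltzmann * conditions.temperature / (
        6.0 * math.pi * conditions.viscosity * D)
    return rh_m / _NM


def stokes_einstein_d(rh_nm: float,
                      conditions: SolventConditions = SolventConditions()
                      ) -> float:
    """Diffusion coefficient (m^2 s^-1) of a sphere with radius rh_nm."""
    if not rh_nm > 0:
        raise ValueError("rh must be positive")
    return conditions.boltzmann * conditions.temperature / (
        6.0 * math.pi * conditions.viscosity * rh_nm * _NM)


def perrin_rh(a: float, b: float) -> float:
    """Perrin hydrodynamic radius of a prolate spheroid, same units as a.

    R_h = a xi / ln((1 + xi)/(b/a)) with xi = sqrt(1 - (b/a)^2); continuous
    sphere limit R_h -> a as b -> a.
    """
    if not 0 < b <= a:
        raise ValueError("prolate spheroid requires 0 < b <= a")
    p = b / a
    if p == 1.0:
        return float(a)
    xi = math.sqrt(1.0 - p * p)
    return a * xi / math.log((1.0 + xi) / p)


def invert_perrin_semi_minor(a: float, rh: float) -> float:
    """Semi-minor axis b with perrin_rh(a, b) = rh, by bracketed bisection.

    Monotonicity of the Perrin radius in b guarantees a unique solution in
    (0, a).  Requires 0 < rh < a: the Perrin radius of a genuinely prolate
    spheroid is strictly below its semi-major axis.
    """
    if not a > 0:
        raise ValueError("a must be positive")
    if not 0 < rh < a:
        raise ValueError(
            f"no prolate solution: require 0 < rh < a, got rh={rh}, a={a}")
    lo, hi = 1e-6 * a, a - 1e-9 * a
    f = lambda b: perrin_rh(a, b) - rh
    if f(lo) > 0:
        raise ValueError(f"rh={rh} below the Perrin radius at b={lo:g}")
    return float(brentq(f, lo, hi, xtol=1e-15, rtol=8.9e-16))


def ellipsoid_volume(a: float, b: float) -> float:
    """Volume (4/3) pi a b^2 of an ellipsoid of revolution."""
    if not (a > 0 and b > 0):
        raise ValueError("semi-axes must be positive")
    return 4.0 / 3.0 * math.pi * a * b * b


def semi_minor_from_volume(a: float, volume: float) -> float:
    """b = sqrt(3V / (4 pi a)): semi-minor axis at fixed a and volume."""
    if not (a > 0 and volume > 0):
        raise ValueError("inputs must be positive")
    return math.sqrt(3.0 * volume / (4.0 * math.pi * a))


def sas_ratio_rh(v_sas: float, a_sas: float) -> float:
    """Volume-to-surface radius estimate from solvent-accessible geometry.

    Returns ``v_sas / a_sas``.  Note the semantics: for a sphere of radius
    r this ratio is r/3, not r — it is a compactness length scale, not the
    sphere radius, and is used as a molecular-structure-based lower
    reference for the hydrodynamic radius.
    """
    if not (v_sas > 0 and a_sas > 0):
        raise ValueError("inputs must be positive")
    return v_sas / a_sas


def round_half_up(x: float, decimals: int = 2) -> float:
    """Decimal half-up rounding for report parity (0.125 -> 0.13)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))
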