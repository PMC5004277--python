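"""Substrate and particle property calculations.

A batch adsorption experiment mixes ``m`` grams of ground lignocellulose
particles (treated as uniform spheres of radius ``R``) with ``V_L`` mL of
enzyme solution.  Everything the transport model needs about the solid --
skeletal (solid) density, apparent density, porosity, the fraction of pore
volume wide enough for a cellulase molecule, and the total outer surface
area of the particle population -- follows from the dry-matter composition,
the component densities and the nitrogen-adsorption pore volumes.

Units are fixed package-wide to the cm-min-mg-mL-g system: lengths in cm,
times in min, masses of enzyme in mg, solution volumes in mL, substrate
masses in g, densities in g/cm^3, pore volumes in cm^3/g.  Compositions are
supplied as mass percentages on a dry basis and divided by 100 internally.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .errors import InvalidInputError

__all__ = [
    "SubstrateComposition",
    "ParticleSystem",
    "DerivedProperties",
    "solid_density",
    "apparent_density",
    "porosity",
    "accessible_fraction",
    "outer_surface_area",
    "derive_properties",
]

#: warn when the dry-matter percentages miss 100 by more than this (absolute %)
COMPOSITION_WARN_TOL = 0.5
#: refuse compositions further from 100 % than this
COMPOSITION_ERROR_TOL = 2.0


@dataclass(frozen=True)
class SubstrateComposition:
    """Dry-basis mass percentages and densities of the four solid components.

    Parameters
    ----------
    M_c, M_h, M_l, M_o : float
        Mass percentages (%) of cellulose, hemicellulose, lignin and other
        components (ash etc.); they must sum to ~100.
    rho_c, rho_h, rho_l, rho_o : float
        Component densities (g/cm^3).
    sum_tolerance : float
        Absolute deviation of the percentage sum from 100 that triggers a
        warning; deviations beyond :data:`COMPOSITION_ERROR_TOL` are errors.
    """

    M_c: float
    M_h: float
    M_l: float
    M_o: float
    rho_c: float
    rho_h: float
    rho_l: float
    rho_o: float
    sum_tolerance: float = field(default=COMPOSITION_WARN_TOL, compare=False)

    def __post_init__(self) -> None:
        for name in ("M_c", "M_h", "M_l", "M_o", "rho_c", "rho_h", "rho_l", "rho_o"):
            if getattr(self, name) <= 0:
                raise InvalidInputError(f"{name} must be > 0, got {getattr(self, name)!r}")
        total = self.M_c + self.M_h + self.M_l + self.M_o
        dev = abs(total - 100.0)
        if dev > COMPOSITION_ERROR_TOL:
            raise InvalidInputError(
                f"composition percentages sum to {total:.2f}, deviating from 100 "
                f"by more than {COMPOSITION_ERROR_TOL} %"
            )
        if dev > self.sum_tolerance:
            warnings.warn(
                f"composition percentages sum to {total:.2f} (expected ~100)",
                stacklevel=2,
            )

    @property
    def mass_fractions(self) -> tuple[float, float, float, float]:
        """Mass fractions (dimensionless) of the four components."""
        return (self.M_c / 100.0, self.M_h / 100.0, self.M_l / 100.0, self.M_o / 100.0)

    @property
    def densities(self) -> tuple[float, float, float, float]:
        return (self.rho_c, self.rho_h, self.rho_l, self.rho_o)


@dataclass(frozen=True)
class ParticleSystem:
    """Batch geometry: spherical particles of one size in a stirred bath.

    Parameters
    ----------
    R : float
        Particle radius (cm).
    m : float
        Total particle mass (g).
    V_L : float
        Liquid-phase volume (mL).
    C_0 : float
        Initial bulk enzyme concentration (mg/mL).
    V_p : float
        Total pore volume per substrate mass (cm^3/g).
    V_pa : float
        Pore volume in pores wide enough for the enzyme (cm^3/g).
    composition : SubstrateComposition
    """

    R: float
    m: float
    V_L: float
    C_0: float
    V_p: float
    V_pa: float
    composition: SubstrateComposition

    def __post_init__(self) -> None:
        if self.R <= 0 or self.m <= 0 or self.V_L <= 0:
            raise InvalidInputError("R, m and V_L must all be > 0")
        if self.C_0 < 0:
            raise InvalidInputError("C_0 must be >= 0")
        if self.V_p < 0 or not (0 <= self.V_pa <= self.V_p):
            raise InvalidInputError("pore volumes must satisfy 0 <= V_pa <= V_p")

    def derived(self) -> "DerivedProperties":
        return derive_properties(self)


@dataclass(frozen=True)
class DerivedProperties:
    """Quantities derived from a :class:`ParticleSystem`.

    Attributes
    ----------
    rho_s : float
        Skeletal (solid) density (g/cm^3).
    rho_a : float
        Apparent (envelope) particle density (g/cm^3).
    eps : float
        Particle porosity (dimensionless).
    phi : float
        Enzyme-accessible fraction of the pore volume (dimensionless).
    A : float
        Outer surface area of the whole particle population (cm^2).
    """

    rho_s: float
    rho_a: float
    eps: float
    phi: float
    A: float


def solid_density(comp: SubstrateComposition) -> float:
    """Skeletal density of the solid, ``rho_s = 1 / sum_i(w_i / rho_i)``.

    ``w_i`` are mass fractions; the harmonic mixing rule assumes the
    components pack without excess volume.
    """
    s = sum(w / rho for w, rho in zip(comp.mass_fractions, comp.densities))
    rho_s = 1.0 / s
    if rho_s <= 0:
        raise InvalidInputError("computed solid density is non-positive")
    return rho_s


def apparent_density(rho_s: float, V_p: float) -> float:
    """Apparent (envelope) density, ``rho_a = rho_s / (1 + V_p * rho_s)``."""
    if rho_s <= 0:
        raise InvalidInputError("rho_s must be > 0")
    if V_p < 0:
        raise InvalidInputError("V_p must be >= 0")
    return rho_s / (1.0 + V_p * rho_s)


def porosity(rho_s: float, V_p: float) -> float:
    """Particle porosity, ``eps = V_p / (V_p + 1/rho_s)``; lies in [0, 1)."""
    if rho_s <= 0:
        raise InvalidInputError("rho_s must be > 0")
    if V_p < 0:
        raise InvalidInputError("V_p must be >= 0")
    return V_p / (V_p + 1.0 / rho_s)


def accessible_fraction(V_pa: float, V_p: float) -> float:
    """Fraction ``phi = V_pa / V_p`` of pore volume open to the enzyme."""
    if V_p <= 0:
        raise InvalidInputError("V_p must be > 0")
    if not 0 <= V_pa <= V_p:
        raise InvalidInputError("V_pa must satisfy 0 <= V_pa <= V_p")
    return V_pa / V_p


def outer_surface_area(m: float, rho_a: float, R: float) -> float:
    """Total outer area ``A = 3 m / (rho_a R)`` of ``m`` grams of spheres."""
    if m <= 0 or rho_a <= 0 or R <= 0:
        raise InvalidInputError("m, rho_a and R must all be > 0")
    return 3.0 * m / (rho_a * R)


def derive_properties(sys: ParticleSystem) -> DerivedProperties:
    """Compute all derived particle properties for a batch system."""
    rho_s = solid_density(sys.composition)
    rho_a = apparent_density(rho_s, sys.V_p)
    eps = porosity(rho_s, sys.V_p)
    phi = accessible_fraction(sys.V_pa, sys.V_p) if sys.V_p > 0 else 1.0
    A = outer_surface_area(sys.m, rho_a, sys.R)
    return DerivedProperties(rho_s=rho_s, rho_a=rho_a, eps=eps, phi=phi, A=A)
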