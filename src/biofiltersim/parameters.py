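"""Raw biofilter inputs and the derived model parameters.

The model reduces a packed-bed biofilter to a cascade of ``n`` well-mixed
segments. All compound-, biofilm- and operation-level inputs are collected
here, together with the derived quantities that the analytic solution
actually consumes:

* effective biofilm diffusivity ``De`` from the empirical density
  correlation,
* lumped first-order rate constant ``k1`` from the Monod parameters,
* Thiele-type parameter ``phi = sqrt(k1/De)``,
* per-segment steady attenuation ``gamma1`` and transient rate constant
  ``gamma2``.

Units are SI with time in seconds internally; the maximum specific growth
rate may be supplied in h⁻¹ at the interface (the common literature unit)
and is converted on entry.

Unit conventions for the biofilm density ``Xv``: the diffusivity
correlation consumes it in kg·m⁻³ (its native units), while the
first-order rate constant consumes the biomass concentration in g·m⁻³ so
that it cancels against the half-saturation constant ``K`` (g·m⁻³).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

__all__ = [
    "CompoundParameters",
    "BiofilmParameters",
    "BedOperation",
    "DerivedParameters",
    "effective_diffusivity",
    "first_order_rate",
    "thiele_phi",
    "guarded_tanh",
    "compute_gammas",
]

SECONDS_PER_HOUR = 3600.0

#: Default bed void fraction (gas-accessible volume fraction). It sets the
#: transient time constant gamma2 but cancels out of every steady-state
#: quantity, so steady predictions do not depend on it.
DEFAULT_VOID_FRACTION = 0.35


def _require_positive(name: str, value: float) -> None:
    if not math.isfinite(value) or value <= 0.0:
        raise ValueError(f"{name} must be finite and strictly positive, got {value!r}")


@dataclass(frozen=True)
class CompoundParameters:
    """Physical and kinetic constants of a single pollutant.

    Parameters
    ----------
    henry_dimensionless
        Dimensionless Henry's constant H' = Cg/Cl at gas-biofilm
        equilibrium.
    mu_max
        Maximum specific growth rate µm in s⁻¹. Use
        :meth:`with_mu_max_per_hour` when the literature value is in h⁻¹.
    monod_K
        Monod half-saturation constant K in g·m⁻³.
    yield_Y
        Biomass yield coefficient Y (dimensionless).
    diffusivity_water
        Aqueous diffusivity Dw of the pollutant in m²·s⁻¹.
    """

    henry_dimensionless: float
    mu_max: float
    monod_K: float
    yield_Y: float
    diffusivity_water: float

    def __post_init__(self) -> None:
        _require_positive("henry_dimensionless", self.henry_dimensionless)
        if not math.isfinite(self.mu_max) or self.mu_max < 0.0:
            raise ValueError(f"mu_max must be finite and >= 0, got {self.mu_max!r}")
        _require_positive("monod_K", self.monod_K)
        _require_positive("yield_Y", self.yield_Y)
        _require_positive("diffusivity_water", self.diffusivity_water)

    @classmethod
    def with_mu_max_per_hour(cls, *, mu_max_per_hour: float, **kwargs: float) -> "CompoundParameters":
        """Build with µm given in h⁻¹ (converted exactly to s⁻¹)."""
        return cls(mu_max=mu_max_per_hour / SECONDS_PER_HOUR, **kwargs)


@dataclass(frozen=True)
class BiofilmParameters:
    """Biofilm geometry and density.

    ``density_Xv`` is in kg·m⁻³, ``area_As`` (biofilm area per bed volume)
    in m⁻¹ and ``thickness_delta`` in m.
    """

    density_Xv: float
    area_As: float
    thickness_delta: float

    def __post_init__(self) -> None:
        _require_positive("density_Xv", self.density_Xv)
        _require_positive("area_As", self.area_As)
        _require_positive("thickness_delta", self.thickness_delta)
        # fail early if the density lies outside the diffusivity
        # correlation's positivity range
        _correlation_ratio(self.density_Xv)


@dataclass(frozen=True)
class BedOperation:
    """Bed geometry and gas-flow operating point.

    Exactly one of ``superficial_velocity_ug`` (m·s⁻¹) or ``ebrt``
    (empty bed residence time H/ug, s) must be supplied; the other is
    derived.
    """

    height_H: float
    n_segments: int = 10
    void_fraction_eps: float = DEFAULT_VOID_FRACTION
    superficial_velocity_ug: float | None = None
    ebrt: float | None = None
    inlet_conc_Cg0: float = 0.0

    def __post_init__(self) -> None:
        _require_positive("height_H", self.height_H)
        if int(self.n_segments) != self.n_segments or self.n_segments < 1:
            raise ValueError(f"n_segments must be an integer >= 1, got {self.n_segments!r}")
        if not 0.0 < self.void_fraction_eps < 1.0:
            raise ValueError(f"void_fraction_eps must lie in (0, 1), got {self.void_fraction_eps!r}")
        if self.inlet_conc_Cg0 < 0.0:
            raise ValueError("inlet_conc_Cg0 must be >= 0")
        ug, ebrt = self.superficial_velocity_ug, self.ebrt
        if ug is None and ebrt is None:
            raise ValueError("supply either superficial_velocity_ug or ebrt")
        if ug is not None and ebrt is not None:
            if abs(ebrt * ug - self.height_H) > 1e-12 * self.height_H:
                raise ValueError("ebrt and superficial_velocity_ug are inconsistent: ebrt*ug != H")
        elif ug is None:
            _require_positive("ebrt", ebrt)
            object.__setattr__(self, "superficial_velocity_ug", self.height_H / ebrt)
        else:
            _require_positive("superficial_velocity_ug", ug)
            object.__setattr__(self, "ebrt", self.height_H / ug)
        _require_positive("superficial_velocity_ug", self.superficial_velocity_ug)

    @property
    def segment_length(self) -> float:
        """Segment height Δh = H/n in m."""
        return self.height_H / self.n_segments

    def with_ebrt(self, ebrt: float) -> "BedOperation":
        """Same bed at a different empty bed residence time."""
        return replace(self, ebrt=ebrt, superficial_velocity_ug=None)


@dataclass(frozen=True)
class DerivedParameters:
    """Derived quantities of the segmented analytic model.

    ``flux_coeff`` is the interfacial flux closure De·As·φ·tanh(δφ)
    (m·s⁻¹ per unit bed volume basis); ``gamma1`` is the fraction of
    pollutant surviving one segment at steady state and ``gamma2`` the
    per-segment first-order transient rate constant (s⁻¹).
    """

    De: float
    k1: float
    phi: float
    flux_coeff: float
    gamma1: float
    gamma2: float

    def __post_init__(self) -> None:
        if not 0.0 < self.gamma1 <= 1.0:
            raise ValueError(f"gamma1 must lie in (0, 1], got {self.gamma1!r}")
        _require_positive("gamma2", self.gamma2)
        _require_positive("De", self.De)


#: Turning point of the density correlation. Below this density the
#: predicted De/Dw ratio decreases with density, as physically expected;
#: beyond it the ratio would (unphysically) rise again, so the correlation
#: is treated as invalid there.
CORRELATION_DENSITY_LIMIT = 580.489


def _correlation_ratio(density_kg_m3: float) -> float:
    if density_kg_m3 > CORRELATION_DENSITY_LIMIT:
        raise ValueError(
            f"biofilm density {density_kg_m3} kg·m⁻³ is outside the validity range of "
            f"the effective-diffusivity correlation (monotone below "
            f"{CORRELATION_DENSITY_LIMIT} kg·m⁻³)"
        )
    ratio = 1.0 - 0.43 * density_kg_m3**0.92 / (11.19 + 0.27 * density_kg_m3**0.99)
    if ratio <= 0.0:  # unreachable on the monotone branch; guards the contract
        raise ValueError("effective-diffusivity correlation yielded a non-positive ratio")
    return ratio


def effective_diffusivity(diffusivity_water: float, density_Xv: float) -> float:
    """Effective pollutant diffusivity in the biofilm, m²·s⁻¹.

    Empirical correlation against biofilm density ``Xv`` (kg·m⁻³)::

        De = Dw * [1 - 0.43*Xv^0.92 / (11.19 + 0.27*Xv^0.99)]

    Dense biofilms hinder diffusion, so De <= Dw; the correlation turns
    negative (and a :class:`ValueError` is raised) for densities far
    beyond its calibration range.
    """
    _require_positive("diffusivity_water", diffusivity_water)
    if density_Xv < 0.0:
        raise ValueError("density_Xv must be >= 0")
    if density_Xv == 0.0:
        return diffusivity_water
    return diffusivity_water * _correlation_ratio(density_Xv)


def first_order_rate(mu_max: float, density_Xv: float, yield_Y: float, monod_K: float) -> float:
    """Lumped first-order biodegradation rate constant k1 = µm·X/(Y·K), s⁻¹.

    Linearization of Monod kinetics valid for Cl << K. ``density_Xv`` is
    in kg·m⁻³ and converted to the biomass concentration X in g·m⁻³ so
    the units cancel against ``monod_K`` (g·m⁻³).
    """
    if mu_max < 0.0:
        raise ValueError("mu_max must be >= 0")
    _require_positive("yield_Y", yield_Y)
    _require_positive("monod_K", monod_K)
    if density_Xv < 0.0:
        raise ValueError("density_Xv must be >= 0")
    biomass_g_m3 = 1000.0 * density_Xv
    return mu_max * biomass_g_m3 / (yield_Y * monod_K)


def thiele_phi(k1: float, De: float) -> float:
    """Thiele-type parameter φ = sqrt(k1/De), m⁻¹.

    δφ measures how deeply the pollutant penetrates the biofilm slab
    before being consumed.
    """
    _require_positive("De", De)
    if k1 < 0.0:
        raise ValueError("k1 must be >= 0")
    return math.sqrt(k1 / De)


def guarded_tanh(arg: float) -> float:
    """tanh with explicit saturation to exactly 1.0 for arguments > 20."""
    if arg > 20.0:
        return 1.0
    return math.tanh(arg)


def compute_gammas(
    compound: CompoundParameters,
    biofilm: BiofilmParameters,
    bed: BedOperation,
) -> DerivedParameters:
    """Full derived-parameter chain for a compound/biofilm/bed triple.

    Computes De, k1, φ and the flux closure, then::

        gamma1 = H'·ug / (H'·ug + De·As·φ·tanh(δφ)·Δh)
        gamma2 = [H'·ug + De·As·φ·tanh(δφ)·Δh] / (H'·ε·Δh)

    ``gamma1`` in (0, 1] is the per-segment steady-state survival
    fraction; ``gamma2`` (s⁻¹) the per-segment relaxation rate. The two
    are linked by gamma2 = ug/(gamma1·ε·Δh).
    """
    De = effective_diffusivity(compound.diffusivity_water, biofilm.density_Xv)
    k1 = first_order_rate(compound.mu_max, biofilm.density_Xv, compound.yield_Y, compound.monod_K)
    phi = thiele_phi(k1, De)
    flux_coeff = De * biofilm.area_As * phi * guarded_tanh(biofilm.thickness_delta * phi)

    hp_ug = compound.henry_dimensionless * bed.superficial_velocity_ug
    dh = bed.segment_length
    denom = hp_ug + flux_coeff * dh
    gamma1 = hp_ug / denom
    gamma2 = denom / (compound.henry_dimensionless * bed.void_fraction_eps * dh)
    return DerivedParameters(De=De, k1=k1, phi=phi, flux_coeff=flux_coeff, gamma1=gamma1, gamma2=gamma2)
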