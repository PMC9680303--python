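"""Pollutant concentration inside the biofilm slab.

The biofilm is modelled as a planar slab of thickness δ with Fickian
diffusion and first-order consumption, a Henry-equilibrium boundary at the
gas interface (x = 0) and zero flux at the support (x = δ). The resulting
boundary-value problem has the closed form

    Cl(x) = Cg / [H'(1 + e^(-2δφ))] · [e^(φ(x-2δ)) + e^(-φx)]

which is evaluated here in exactly this grouping: for 0 <= x <= δ every
exponential argument is non-positive, so the expression never overflows
however large δφ gets. Its interfacial derivative,

    dCl/dx |_{x=0} = -(φ·Cg/H')·tanh(φδ),

is the flux closure the gas-phase balance consumes.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np

from .parameters import guarded_tanh

__all__ = [
    "BiofilmProfile",
    "biofilm_concentration",
    "interfacial_gradient",
    "concentration_profile",
    "profile_to_csv",
]


def _check_params(henry: float, phi: float, delta: float) -> None:
    if henry <= 0.0:
        raise ValueError("henry must be > 0")
    if phi < 0.0:
        raise ValueError("phi must be >= 0")
    if delta <= 0.0:
        raise ValueError("delta must be > 0")


def biofilm_concentration(Cg, x, henry: float, phi: float, delta: float):
    """Liquid-phase concentration Cl(x) in the biofilm, g·m⁻³.

    ``x`` may be a scalar or array of positions in [0, δ]; positions
    outside the slab are rejected. At x = 0 this reduces exactly to the
    Henry partition Cg/H'; for φ → 0 the profile is flat (no reaction).
    """
    _check_params(henry, phi, delta)
    if Cg < 0.0:
        raise ValueError("Cg must be >= 0")
    x = np.asarray(x, dtype=float)
    if np.any(x < 0.0) or np.any(x > delta):
        raise ValueError("x must lie within the biofilm slab [0, delta]")
    prefactor = Cg / (henry * (1.0 + np.exp(-2.0 * delta * phi)))
    cl = prefactor * (np.exp(phi * (x - 2.0 * delta)) + np.exp(-phi * x))
    return cl if cl.ndim else float(cl)


def interfacial_gradient(Cg: float, henry: float, phi: float, delta: float) -> float:
    """Concentration gradient dCl/dx at the gas-biofilm interface, g·m⁻⁴.

    Closed form -(φ·Cg/H')·tanh(φδ); always <= 0, i.e. the flux is
    directed into the biofilm. Linear in Cg, so higher gas concentrations
    drive proportionally larger fluxes.
    """
    _check_params(henry, phi, delta)
    if Cg < 0.0:
        raise ValueError("Cg must be >= 0")
    return -(phi * Cg / henry) * guarded_tanh(phi * delta)


@dataclass(frozen=True)
class BiofilmProfile:
    """Sampled concentration profile through the biofilm slab."""

    x_grid: np.ndarray
    cl_values: np.ndarray
    cg_at_interface: float
    henry: float
    phi: float
    delta: float


def concentration_profile(
    Cg: float, henry: float, phi: float, delta: float, n_points: int = 101
) -> BiofilmProfile:
    """Evaluate Cl on ``n_points`` evenly spaced positions across [0, δ]."""
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    x = np.linspace(0.0, delta, n_points)
    cl = biofilm_concentration(Cg, x, henry, phi, delta)
    return BiofilmProfile(x_grid=x, cl_values=cl, cg_at_interface=Cg, henry=henry, phi=phi, delta=delta)


def profile_to_csv(profile: BiofilmProfile) -> str:
    """Render a profile as CSV with a commented metadata header."""
    buf = io.StringIO()
    buf.write(f"# Cg_g_per_m3={profile.cg_at_interface!r}\n")
    buf.write(f"# henry_dimensionless={profile.henry!r}\n")
    buf.write(f"# phi_per_m={profile.phi!r}\n")
    buf.write(f"# delta_m={profile.delta!r}\n")
    buf.write("x_m,Cl_g_per_m3\n")
    for x, cl in zip(profile.x_grid, profile.cl_values):
        buf.write(f"{float(x)!r},{float(cl)!r}\n")
    return buf.getvalue()
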