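"""Electrostatic potential from binned charge density.

Planar branch: the 1-D Poisson equation ε_s ε₀ φ''(z) = −ρ(z) integrated
twice collapses to

    φ(z) = −(1/(ε_s ε₀)) ∫_{z_m}^{z} (z − z′) ρ(z′) dz′,

with φ(z_m) = 0 at the reference plane z_m (the solvent-centre plane by
default). The quadrature is midpoint on the charge-profile bins, which makes
the discrete second difference of φ reproduce the binned ρ exactly.

Radial branch: Gauss's law for the spherically averaged charge,
E(r) = q_enc(r)/(4π ε_s ε₀ r²), with φ(r) = ∫_r^{R_max} E dr so the
potential is zeroed in the far field.

Charge densities are e/Å³; potentials are reported in volts. ε_s defaults
to 1 (explicit solvent charges provide their own screening).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import COULOMB_V_ANG, E_OVER_EPS0_ANG
from .errors import ParameterError
from .profiles import AxialProfile


@dataclass
class PotentialProfile:
    """φ(z) on the same binning as its source charge profile."""

    centers: np.ndarray  # (n_bins,) Å
    phi: np.ndarray  # (n_bins,) V
    z_m: float  # Å, reference plane (φ = 0 there)
    eps_s: float  # relative permittivity used
    rho: np.ndarray | None = None  # source charge density, e/Å³


@dataclass
class RadialFieldProfile:
    """Spherically averaged field and potential; φ(R_max) = 0."""

    radii: np.ndarray  # (n_shells + 1,) Å, shell edges from 0
    field: np.ndarray  # (n_shells + 1,) V/Å at the edges
    phi: np.ndarray  # (n_shells + 1,) V at the edges


def planar_potential(
    rho: AxialProfile, z_m: float | None = None, eps_s: float = 1.0
) -> PotentialProfile:
    """Double-integrate a binned charge density into φ(z) with φ(z_m) = 0.

    z_m defaults to the profile origin (z = 0 on the profile axis) and is
    snapped to the nearest bin centre so the zero-reference invariant holds
    exactly on the grid.
    """
    if eps_s <= 0:
        raise ParameterError(f"relative permittivity must be > 0, got {eps_s}")
    centers = rho.centers
    if z_m is None:
        z_m = 0.0
    if not (rho.edges[0] <= z_m <= rho.edges[-1]):
        raise ParameterError(
            f"z_m = {z_m} Å lies outside the profile range "
            f"[{rho.edges[0]}, {rho.edges[-1]}] Å"
        )
    m = int(np.argmin(np.abs(centers - z_m)))
    dz = rho.dz
    vals = rho.values
    n = len(vals)
    # cumulative charge moments from the reference bin outward (midpoint rule;
    # the reference bin's own charge is excluded — the reference plane belongs
    # in bulk solvent where the binned density vanishes)
    s0 = np.zeros(n)  # ∫ ρ dz'
    s1 = np.zeros(n)  # ∫ z' ρ dz'
    if m + 1 < n:
        s0[m + 1 :] = np.cumsum(vals[m + 1 :]) * dz
        s1[m + 1 :] = np.cumsum(vals[m + 1 :] * centers[m + 1 :]) * dz
    if m > 0:
        s0[m - 1 :: -1] = -np.cumsum(vals[m - 1 :: -1]) * dz
        s1[m - 1 :: -1] = -np.cumsum(vals[m - 1 :: -1] * centers[m - 1 :: -1]) * dz
    integral = centers * s0 - s1  # ∫ (z − z') ρ dz', e/Å
    phi = -(E_OVER_EPS0_ANG / eps_s) * integral
    phi -= phi[m]  # exact zero at the reference bin
    return PotentialProfile(
        centers=centers.copy(),
        phi=phi,
        z_m=float(centers[m]),
        eps_s=eps_s,
        rho=vals.copy(),
    )


def radial_potential(
    shell_edges: np.ndarray, shell_density: np.ndarray, eps_s: float = 1.0
) -> RadialFieldProfile:
    """Gauss-law field and far-field-zeroed potential for spherical shells.

    shell_edges are contiguous radii starting at 0 (n_shells + 1 values);
    shell_density is the charge density per shell in e/Å³. E is evaluated at
    the shell edges (E(0) = 0 handles the origin), and φ(r) integrates E
    inward from R_max by the trapezoid rule.
    """
    if eps_s <= 0:
        raise ParameterError(f"relative permittivity must be > 0, got {eps_s}")
    r = np.asarray(shell_edges, dtype=float)
    rho = np.asarray(shell_density, dtype=float)
    if r.ndim != 1 or len(r) != len(rho) + 1:
        raise ParameterError("need n_shells + 1 edges for n_shells densities")
    if r[0] != 0.0 or np.any(np.diff(r) <= 0):
        raise ParameterError("shell edges must start at 0 and increase")
    shell_vol = 4.0 / 3.0 * np.pi * (r[1:] ** 3 - r[:-1] ** 3)
    q_enc = np.concatenate([[0.0], np.cumsum(rho * shell_vol)])  # e, at edges
    field = np.zeros_like(r)
    nonzero = r > 0
    field[nonzero] = COULOMB_V_ANG * q_enc[nonzero] / (eps_s * r[nonzero] ** 2)
    # φ(r) = ∫_r^{Rmax} E dr (trapezoid), φ(Rmax) = 0
    seg = 0.5 * (field[1:] + field[:-1]) * np.diff(r)
    phi = np.concatenate([np.cumsum(seg[::-1])[::-1], [0.0]])
    return RadialFieldProfile(radii=r, field=field, phi=phi)
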