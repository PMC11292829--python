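"""z-resolved charge and mass density profiles by slab decomposition.

Charge profiles assign each atom's formal charge wholly to the bin holding
its wrapped z-coordinate (point assignment; zero-charge atoms are ignored).
Mass profiles instead apportion each atom's van der Waals sphere among the
slabs it intersects, weighting by intersection volume — the two conventions
deliberately differ.

Bin coordinates are reported relative to the chosen reference origin z0, so
the profile axis spans [−Lz/2, Lz/2). The requested bin width is snapped to
Lz / round(Lz / Δz) so that bins tile the periodic box exactly; this is what
makes the mass/charge conservation identities hold to machine precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import Frame, Selection, Trajectory
from .errors import BinningError, ConfigurationError, ParameterError

ORIGIN_MODES = ("bilayer_midplane", "solvent_center")


def _wrap_rel(z: np.ndarray, z0: float, lz: float) -> np.ndarray:
    """z relative to z0, wrapped into [−Lz/2, Lz/2)."""
    return np.mod(z - z0 + lz / 2.0, lz) - lz / 2.0


@dataclass
class AxialProfile:
    """A binned quantity vs z (bin coordinates relative to the origin z0)."""

    edges: np.ndarray  # (n_bins + 1,) Å, contiguous, uniform
    values: np.ndarray  # (n_bins,)
    quantity: str = ""
    units: str = ""
    origin: str = ""  # human-readable description of z0
    z0: float = 0.0  # absolute z of the origin in frame coordinates (Å)
    frames_averaged: int = 1

    def __post_init__(self):
        self.edges = np.asarray(self.edges, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        widths = np.diff(self.edges)
        if len(widths) == 0 or np.any(widths <= 0):
            raise ParameterError("profile edges must be strictly increasing")
        if not np.allclose(widths, widths[0], rtol=1e-9, atol=0.0):
            raise ParameterError("profile bins must have uniform width")
        if len(self.values) != len(self.edges) - 1:
            raise ParameterError("value count must equal bin count")

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    @property
    def dz(self) -> float:
        return float(self.edges[1] - self.edges[0])

    def symmetrized(self) -> "AxialProfile":
        """Average the profile with its mirror about z = 0."""
        vals = 0.5 * (self.values + self.values[::-1])
        return AxialProfile(
            edges=self.edges.copy(),
            values=vals,
            quantity=self.quantity,
            units=self.units,
            origin=self.origin + " (symmetrized)",
            z0=self.z0,
            frames_averaged=self.frames_averaged,
        )


def locate_reference_origin(frame: Frame, mode: str) -> float:
    """z-coordinate of the profile origin.

    bilayer_midplane: arithmetic mean z of all surfactant head atoms.
    solvent_center: circular mean z of water atoms under z-periodicity,
    so a solvent slab split across the boundary is still centred correctly.
    """
    if mode not in ORIGIN_MODES:
        raise ParameterError(f"origin mode must be one of {ORIGIN_MODES}")
    topo = frame.topology
    if mode == "bilayer_midplane":
        mask = (topo["role"] == "head").to_numpy()
        if not mask.any():
            raise ConfigurationError("bilayer_midplane origin needs head atoms")
        return float(frame.positions[mask, 2].mean())
    mask = (topo["role"] == "water").to_numpy()
    if not mask.any():
        raise ConfigurationError("solvent_center origin needs water atoms")
    lz = frame.box[2]
    theta = frame.positions[mask, 2] * (2.0 * np.pi / lz)
    ang = np.arctan2(np.sin(theta).mean(), np.cos(theta).mean())
    return float(ang * lz / (2.0 * np.pi))


def _bin_grid(lz: float, dz: float) -> tuple[np.ndarray, float, int]:
    """Edges spanning [−Lz/2, Lz/2] with width snapped to divide Lz exactly."""
    if dz <= 0:
        raise ParameterError(f"bin width must be > 0, got {dz}")
    if dz > lz:
        raise BinningError(f"bin width {dz} Å exceeds box length {lz} Å")
    nbins = max(1, int(round(lz / dz)))
    dz_actual = lz / nbins
    edges = -lz / 2.0 + dz_actual * np.arange(nbins + 1)
    edges[-1] = lz / 2.0
    return edges, dz_actual, nbins


def charge_density_profile(
    traj: Trajectory,
    dz: float = 0.5,
    origin_mode: str = "solvent_center",
    symmetrize: bool = False,
    z0: float | None = None,
) -> AxialProfile:
    """Frame-averaged formal-charge density ρ(z) in e/Å³.

    Each atom with nonzero formal charge contributes its whole charge to the
    bin containing its wrapped z relative to the per-frame origin; the bin
    sum is divided by the bin volume Lx·Ly·Δz and averaged over frames.
    """
    box = traj.constant_box()
    edges, dz_actual, nbins = _bin_grid(box[2], dz)
    q = traj.topology["formal_charge"].to_numpy().astype(float)
    charged = np.flatnonzero(q != 0)
    if len(charged) == 0:
        raise ConfigurationError("charge profile needs at least one charged atom")
    accum = np.zeros(nbins)
    z0s = []
    for i in range(traj.n_frames):
        zref = z0 if z0 is not None else locate_reference_origin(
            traj.frame(i), origin_mode
        )
        z0s.append(zref)
        rel = _wrap_rel(traj.positions[i, charged, 2], zref, box[2])
        idx = np.clip(((rel + box[2] / 2.0) / dz_actual).astype(int), 0, nbins - 1)
        accum += np.bincount(idx, weights=q[charged], minlength=nbins)
    values = accum / (traj.n_frames * box[0] * box[1] * dz_actual)
    origin_desc = "fixed" if z0 is not None else origin_mode
    prof = AxialProfile(
        edges=edges,
        values=values,
        quantity="charge_density",
        units="e/A^3",
        origin=f"{origin_desc} (mean z0 = {np.mean(z0s):.6g} A)",
        z0=float(np.mean(z0s)),
        frames_averaged=traj.n_frames,
    )
    return prof.symmetrized() if symmetrize else prof


def sphere_slab_volume(
    radius: float, z_lo: float, z_hi: float, center_z: float = 0.0
) -> float:
    """Exact volume of a sphere's intersection with the infinite slab
    z_lo ≤ z ≤ z_hi, via the spherical-cap difference V_cap(h) = πh²(3r−h)/3."""
    if radius <= 0:
        raise ParameterError(f"radius must be > 0, got {radius}")
    if not z_lo < z_hi:
        raise ParameterError("slab requires z_lo < z_hi")
    return float(
        _volume_below(np.asarray(z_hi), center_z, radius)
        - _volume_below(np.asarray(z_lo), center_z, radius)
    )


def _volume_below(z_plane: np.ndarray, center_z, radius) -> np.ndarray:
    """Volume of the sphere part below the plane z = z_plane (cap formula)."""
    h = np.clip(z_plane - (np.asarray(center_z) - radius), 0.0, 2.0 * radius)
    return np.pi * h * h * (3.0 * radius - h) / 3.0


def mass_density_profile(
    traj: Trajectory,
    selection: Selection,
    dz: float = 0.5,
    origin_mode: str = "bilayer_midplane",
    symmetrize: bool = False,
    z0: float | None = None,
) -> AxialProfile:
    """Frame-averaged vdW-partitioned mass density in amu/Å³.

    For each selected atom and each slab, the fraction of the atom's vdW
    sphere volume intersecting the slab multiplies its mass; slab sums are
    divided by the slab volume and averaged over frames. Spheres crossing
    the periodic z-boundary contribute through their wrapped images.
    """
    if len(selection) == 0:
        raise ConfigurationError("mass density profile needs a non-empty selection")
    box = traj.constant_box()
    lz = box[2]
    edges, dz_actual, nbins = _bin_grid(lz, dz)
    sel = selection.indices
    topo = traj.topology
    mass = topo["mass"].to_numpy()[sel]
    radius = topo["vdw_radius"].to_numpy()[sel]
    if np.any(radius >= lz / 2.0):
        raise BinningError("vdW radius must be smaller than half the box height")
    vsphere = 4.0 / 3.0 * np.pi * radius**3
    weight = mass / vsphere  # amu per Å³ of the atom's own sphere
    accum = np.zeros(nbins)
    for i in range(traj.n_frames):
        zref = z0 if z0 is not None else locate_reference_origin(
            traj.frame(i), origin_mode
        )
        zc = _wrap_rel(traj.positions[i, sel, 2], zref, lz)
        for shift in (0.0, -lz, lz):
            c = zc + shift
            # (n_sel, n_edges) cumulative cap volumes; per-bin = difference
            vb = _volume_below(edges[None, :], c[:, None], radius[:, None])
            accum += (np.diff(vb, axis=1) * weight[:, None]).sum(axis=0)
    values = accum / (traj.n_frames * box[0] * box[1] * dz_actual)
    prof = AxialProfile(
        edges=edges,
        values=values,
        quantity="mass_density",
        units="amu/A^3",
        origin="fixed" if z0 is not None else origin_mode,
        z0=z0 if z0 is not None else 0.0,
        frames_averaged=traj.n_frames,
    )
    return prof.symmetrized() if symmetrize else prof
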