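"""Surfactant tilt (θ) and rotational/azimuthal (φ) angles.

θ is the angle between a surfactant's orientation vector (head-reference
centroid → tail-terminal atom) and the normal of a total-least-squares plane
fitted to the head-reference atoms of the molecule's leaflet, folded to
[0°, 90°]. φ is the angle between the orientation vector's in-plane
projection and the x-axis, folded to [0°, 180°) by default (a full 0–360°
convention is available). Summaries report the time average of the per-frame
molecular means and the standard deviation of that frame-mean time series.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import Trajectory, minimum_image_displacement
from .errors import ConfigurationError, DegenerateFitError, UndefinedAngleError

log = logging.getLogger(__name__)

_DEGENERACY_RTOL = 1e-10


@dataclass(frozen=True)
class SurfacePlane:
    """Total-least-squares plane n·x = offset with unit normal, nz ≥ 0."""

    normal: np.ndarray  # (3,) unit vector
    offset: float  # Å
    residual_rms: float  # Å


@dataclass
class OrientationSeries:
    """Per-frame, per-molecule angles plus Table-style summaries."""

    times: np.ndarray  # (F,)
    molecule_ids: np.ndarray  # (M,)
    theta: np.ndarray  # (F, M) degrees, NaN when undefined
    phi: np.ndarray  # (F, M) degrees, NaN when undefined
    theta_frame_mean: np.ndarray  # (F,)
    phi_frame_mean: np.ndarray  # (F,)
    theta_mean: float
    theta_std: float  # std of the frame-mean time series
    phi_mean: float
    phi_std: float


def fit_plane(points: np.ndarray) -> SurfacePlane:
    """Fit the total-least-squares plane (minimum orthogonal distances).

    Normal is the singular direction of least variance, oriented to have a
    positive z-component (positive x, then y, breaks ties). Collinear or
    duplicate points raise DegenerateFitError.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 3:
        raise DegenerateFitError("plane fit needs at least 3 points of shape (n, 3)")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    # collinear points: only one direction carries variance
    if s[1] <= _DEGENERACY_RTOL * max(s[0], 1.0):
        raise DegenerateFitError("points are collinear or coincident")
    normal = vt[2]
    for comp in (2, 0, 1):
        if abs(normal[comp]) > 1e-12:
            if normal[comp] < 0:
                normal = -normal
            break
    rms = float(s[2] / np.sqrt(pts.shape[0]))
    return SurfacePlane(normal=normal, offset=float(normal @ centroid), residual_rms=rms)


def orientation_vector(
    frame_positions: np.ndarray,
    head_indices: np.ndarray,
    tail_index: int,
    box: np.ndarray,
) -> np.ndarray:
    """Head-reference centroid → tail-terminal vector, minimum-image corrected.

    Works on a single frame (n_atoms, 3) or a stack (F, n_atoms, 3); assumes
    the molecule's true extent is below half the box per axis.
    """
    if len(head_indices) == 0:
        raise ConfigurationError("molecule has no declared head-reference atoms")
    heads = frame_positions[..., head_indices, :]
    anchor = heads[..., 0, :]
    # unwrap head atoms relative to the first one before averaging
    rel = minimum_image_displacement(anchor[..., None, :], heads, box)
    centroid = anchor + rel.mean(axis=-2)
    tail = frame_positions[..., tail_index, :]
    return minimum_image_displacement(centroid, tail, box)


def tilt_angle(v: np.ndarray, plane: SurfacePlane) -> float:
    """θ = arccos(|v̂ · n̂|) in degrees, folded to [0°, 90°]."""
    v = np.asarray(v, dtype=float)
    norm = np.linalg.norm(v)
    if norm == 0:
        raise UndefinedAngleError("tilt of a zero vector is undefined")
    c = abs(float(v @ plane.normal)) / norm
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def _plane_axes(plane: SurfacePlane) -> tuple[np.ndarray, np.ndarray]:
    """In-plane reference frame: the x-axis projected onto the plane, and
    its in-plane perpendicular."""
    n = plane.normal
    e1 = np.array([1.0, 0.0, 0.0]) - n[0] * n
    norm = np.linalg.norm(e1)
    if norm < 1e-12:
        raise UndefinedAngleError(
            "plane normal is parallel to the x-axis; rotational angle undefined"
        )
    e1 /= norm
    return e1, np.cross(n, e1)


def rotational_angle(
    v: np.ndarray, plane: SurfacePlane, full_circle: bool = False
) -> float:
    """φ between the in-plane projection of v and the x-axis.

    Folded to [0°, 180°) by default (orientation as a line); full_circle
    keeps the signed direction on [0°, 360°). A vector parallel to the
    normal has no projection and raises UndefinedAngleError.
    """
    v = np.asarray(v, dtype=float)
    n = plane.normal
    p = v - (v @ n) * n
    if np.linalg.norm(p) <= 1e-10 * max(np.linalg.norm(v), 1e-30):
        raise UndefinedAngleError("vector parallel to plane normal; φ undefined")
    e1, e2 = _plane_axes(plane)
    phi = np.degrees(np.arctan2(p @ e2, p @ e1))
    return float(phi % 360.0) if full_circle else float(phi % 180.0)


def _surfactant_tables(topology):
    """Per-surfactant (molecule_id, head_ref indices, tail-terminal index)."""
    surf = topology.loc[topology["role"].isin(["head", "tail"])]
    out = []
    for mol, sub in surf.groupby("molecule_id"):
        heads = sub.index[sub["head_ref"]].to_numpy()
        tails = sub.index[sub["tail_terminal"]].to_numpy()
        if len(heads) == 0:
            raise ConfigurationError(
                f"surfactant molecule {mol} declares no head-reference atoms"
            )
        if len(tails) != 1:
            raise ConfigurationError(
                f"surfactant molecule {mol} must declare exactly one "
                f"tail-terminal atom, found {len(tails)}"
            )
        out.append((int(mol), heads, int(tails[0])))
    if not out:
        raise ConfigurationError("no surfactant molecules in topology")
    return out


def orientation_summary(
    traj: Trajectory,
    full_circle: bool = False,
    fold_before_mean: bool = True,
) -> OrientationSeries:
    """Tilt/rotational time series and their Table-style summary statistics.

    Per frame: molecules are assigned to leaflets by the sign of their head
    z relative to the bilayer midplane (mean head z); a plane is fitted per
    leaflet from that leaflet's head-reference atoms; each molecule's θ and
    φ are measured against its leaflet's plane; the frame mean runs over the
    molecules of both leaflets. The summary is the time average of frame
    means and the standard deviation of the frame-mean time series.

    fold_before_mean=False averages the raw (unfolded) per-molecule φ within
    a frame before folding the frame mean.
    """
    topo = traj.topology
    mols = _surfactant_tables(topo)
    mol_ids = np.array([m[0] for m in mols])
    n_mol = len(mols)
    F = traj.n_frames
    box = traj.constant_box()

    head_ref_mask = topo["head_ref"].to_numpy()
    head_idx_all = np.flatnonzero(head_ref_mask)
    if len(head_idx_all) < 3:
        raise DegenerateFitError("need at least 3 head-reference atoms in total")

    # per-frame leaflet planes
    planes = np.empty((F, 2), dtype=object)
    head_z = traj.positions[:, head_idx_all, 2]  # (F, H)
    mid = head_z.mean(axis=1)  # (F,)
    for f in range(F):
        lower = head_idx_all[head_z[f] < mid[f]]
        upper = head_idx_all[head_z[f] >= mid[f]]
        for li, idx in enumerate((lower, upper)):
            if len(idx) < 3:
                raise DegenerateFitError(
                    f"frame {f}: leaflet {li} has {len(idx)} head atoms (<3)"
                )
            planes[f, li] = fit_plane(traj.positions[f, idx])

    theta = np.full((F, n_mol), np.nan)
    phi = np.full((F, n_mol), np.nan)
    phi_raw = np.full((F, n_mol), np.nan)
    n_skipped = 0
    for m, (mol, heads, tail) in enumerate(mols):
        vecs = orientation_vector(traj.positions, heads, tail, box)  # (F, 3)
        centroid_z = traj.positions[:, heads, 2].mean(axis=1)
        leaflet = (centroid_z >= mid).astype(int)  # (F,)
        for f in range(F):
            plane = planes[f, leaflet[f]]
            theta[f, m] = tilt_angle(vecs[f], plane)
            try:
                phi_f = rotational_angle(vecs[f], plane, full_circle=True)
            except UndefinedAngleError:
                n_skipped += 1
                continue
            phi_raw[f, m] = phi_f
            fold = 360.0 if full_circle else 180.0
            phi[f, m] = phi_f % fold
    if n_skipped:
        log.info(
            "rotational angle undefined for %d molecule-frames (vector along "
            "the plane normal); skipped",
            n_skipped,
        )

    theta_fm = np.nanmean(theta, axis=1)
    if fold_before_mean:
        phi_fm = _nanmean_or_nan(phi)
    else:
        fold = 360.0 if full_circle else 180.0
        phi_fm = _nanmean_or_nan(phi_raw) % fold
    return OrientationSeries(
        times=traj.times.copy(),
        molecule_ids=mol_ids,
        theta=theta,
        phi=phi,
        theta_frame_mean=theta_fm,
        phi_frame_mean=phi_fm,
        theta_mean=float(np.mean(theta_fm)),
        theta_std=float(np.std(theta_fm)),
        phi_mean=float(np.nanmean(phi_fm)) if not np.all(np.isnan(phi_fm)) else float("nan"),
        phi_std=float(np.nanstd(phi_fm)) if not np.all(np.isnan(phi_fm)) else float("nan"),
    )


def _nanmean_or_nan(arr: np.ndarray) -> np.ndarray:
    """Row-wise nanmean that returns NaN (without warning) for all-NaN rows."""
    out = np.full(arr.shape[0], np.nan)
    counts = (~np.isnan(arr)).sum(axis=1)
    ok = counts > 0
    if ok.any():
        out[ok] = np.nansum(arr[ok], axis=1) / counts[ok]
    return out
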