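"""Domain model: atoms, frames, trajectories, selections, periodic geometry.

Units are Å for length, ps for time, amu for mass and elementary charges (e)
for formal charge throughout the package. Boxes are orthorhombic; only the
three edge lengths (Lx, Ly, Lz) are carried.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import constants as _const

from .errors import (
    ConfigurationError,
    EmptySelectionWarning,
    InvalidBoxError,
    TrajectoryInconsistencyError,
)

#: Valid role tags for atoms.
ROLES = ("head", "tail", "drug", "counterion", "water")

#: Coulomb constant e/(4 pi eps0), in V·Å per elementary charge.
COULOMB_V_ANG = _const.e / (4.0 * np.pi * _const.epsilon_0 * 1e-10)

#: e/(eps0 · 1 Å) in volts — converts (e/Å³)·Å² charge-moment integrals to V.
E_OVER_EPS0_ANG = _const.e / (_const.epsilon_0 * 1e-10)

#: Å²/ps → m²/s.
ANG2_PER_PS_TO_M2_PER_S = 1e-8

#: Columns every topology table carries, with dtypes enforced on construction.
TOPOLOGY_COLUMNS = {
    "atom_id": np.int64,
    "molecule_id": np.int64,
    "species": str,
    "role": str,
    "element": str,
    "mass": np.float64,
    "formal_charge": np.int64,
    "vdw_radius": np.float64,
    "head_ref": bool,
    "tail_terminal": bool,
    "hbond": str,  # "", "donor_h" or "acceptor"
    "bonded_to": np.int64,  # atom_id of the bonded partner, -1 when undeclared
}


@dataclass(frozen=True)
class AtomRecord:
    """One atom: static identity plus a position snapshot."""

    atom_id: int
    molecule_id: int
    element: str
    position: np.ndarray  # (3,) Å
    mass: float  # amu
    formal_charge: int  # e
    vdw_radius: float  # Å
    role: str

    def __post_init__(self):
        if self.mass <= 0:
            raise ValueError(f"mass must be > 0, got {self.mass}")
        if self.vdw_radius <= 0:
            raise ValueError(f"vdw_radius must be > 0, got {self.vdw_radius}")
        if self.role not in ROLES:
            raise ValueError(f"role must be one of {ROLES}, got {self.role!r}")
        if self.formal_charge != int(self.formal_charge):
            raise ValueError("formal_charge must be an integer")


def validate_box(box: np.ndarray | Sequence[float]) -> np.ndarray:
    """Return the box as float array of shape (3,), rejecting invalid cells."""
    box = np.asarray(box, dtype=float)
    if box.shape != (3,):
        raise InvalidBoxError(
            f"expected 3 orthorhombic box lengths, got shape {box.shape}"
        )
    if not np.all(np.isfinite(box)) or np.any(box <= 0):
        raise InvalidBoxError(f"box lengths must be positive and finite, got {box}")
    return box


def validate_topology(df: pd.DataFrame) -> pd.DataFrame:
    """Coerce a topology table to the canonical schema, checking invariants."""
    df = df.copy()
    defaults = {
        "species": "",
        "head_ref": False,
        "tail_terminal": False,
        "hbond": "",
        "bonded_to": -1,
    }
    for col, dtype in TOPOLOGY_COLUMNS.items():
        if col not in df.columns:
            if col in defaults:
                df[col] = defaults[col]
            else:
                raise ConfigurationError(f"topology missing required column {col!r}")
        if col in defaults:
            df[col] = df[col].fillna(defaults[col])
        df[col] = df[col].astype(dtype)
    df = df[list(TOPOLOGY_COLUMNS)]
    if (df["mass"] <= 0).any():
        raise ConfigurationError("all masses must be > 0")
    if (df["vdw_radius"] <= 0).any():
        raise ConfigurationError("all vdW radii must be > 0")
    bad = set(df["role"]) - set(ROLES)
    if bad:
        raise ConfigurationError(f"unknown role tags {sorted(bad)}; valid: {ROLES}")
    if df["atom_id"].duplicated().any():
        raise ConfigurationError("atom_id values must be unique")
    bad_hb = set(df["hbond"]) - {"", "donor_h", "acceptor"}
    if bad_hb:
        raise ConfigurationError(f"unknown hbond tags {sorted(bad_hb)}")
    return df.reset_index(drop=True)


@dataclass
class Frame:
    """One periodic snapshot: positions plus the (frame-invariant) topology."""

    time: float  # ps
    box: np.ndarray  # (3,) Å
    positions: np.ndarray  # (n_atoms, 3) Å
    topology: pd.DataFrame

    def __post_init__(self):
        self.box = validate_box(self.box)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must have shape (n_atoms, 3)")
        if len(self.topology) != len(self.positions):
            raise TrajectoryInconsistencyError(
                f"topology has {len(self.topology)} rows but frame has "
                f"{len(self.positions)} atoms"
            )

    @property
    def n_atoms(self) -> int:
        return self.positions.shape[0]

    def atom(self, index: int) -> AtomRecord:
        row = self.topology.iloc[index]
        return AtomRecord(
            atom_id=int(row.atom_id),
            molecule_id=int(row.molecule_id),
            element=str(row.element),
            position=self.positions[index].copy(),
            mass=float(row.mass),
            formal_charge=int(row.formal_charge),
            vdw_radius=float(row.vdw_radius),
            role=str(row.role),
        )


@dataclass
class Trajectory:
    """Time-ordered frames sharing one topology.

    positions has shape (n_frames, n_atoms, 3); boxes (n_frames, 3);
    times (n_frames,) in ps.
    """

    times: np.ndarray
    boxes: np.ndarray
    positions: np.ndarray
    topology: pd.DataFrame

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.boxes = np.asarray(self.boxes, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise TrajectoryInconsistencyError(
                "positions must have shape (n_frames, n_atoms, 3)"
            )
        nf = self.positions.shape[0]
        if self.boxes.shape != (nf, 3) or self.times.shape != (nf,):
            raise TrajectoryInconsistencyError(
                "times/boxes/positions disagree on frame count"
            )
        for b in self.boxes:
            validate_box(b)
        if len(self.topology) != self.positions.shape[1]:
            raise TrajectoryInconsistencyError(
                f"topology has {len(self.topology)} rows but frames have "
                f"{self.positions.shape[1]} atoms"
            )
        if nf > 1 and np.any(np.diff(self.times) <= 0):
            raise TrajectoryInconsistencyError("frame times must be increasing")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.positions.shape[1]

    def frame(self, i: int) -> Frame:
        return Frame(
            time=float(self.times[i]),
            box=self.boxes[i].copy(),
            positions=self.positions[i].copy(),
            topology=self.topology,
        )

    def constant_box(self, rtol: float = 1e-9) -> np.ndarray:
        """Return the common box, or raise if the box varies between frames."""
        box0 = self.boxes[0]
        if not np.allclose(self.boxes, box0, rtol=rtol, atol=0.0):
            raise TrajectoryInconsistencyError(
                "operation requires a constant box across frames"
            )
        return box0

    @staticmethod
    def from_frames(frames: Sequence[Frame]) -> "Trajectory":
        if not frames:
            raise TrajectoryInconsistencyError("no frames given")
        n = frames[0].n_atoms
        for k, f in enumerate(frames):
            if f.n_atoms != n:
                raise TrajectoryInconsistencyError(
                    f"frame {k} has {f.n_atoms} atoms, expected {n}"
                )
        return Trajectory(
            times=np.array([f.time for f in frames]),
            boxes=np.stack([f.box for f in frames]),
            positions=np.stack([f.positions for f in frames]),
            topology=frames[0].topology,
        )


@dataclass(frozen=True)
class Selection:
    """Resolved, sorted, unique atom indices (positional, 0-based)."""

    indices: np.ndarray
    label: str = ""

    def __post_init__(self):
        idx = np.unique(np.asarray(self.indices, dtype=np.int64))
        object.__setattr__(self, "indices", idx)

    def __len__(self) -> int:
        return len(self.indices)


def minimum_image_displacement(
    a: np.ndarray, b: np.ndarray, box: np.ndarray | Sequence[float]
) -> np.ndarray:
    """Minimum-image displacement b − a in an orthorhombic periodic box.

    Each component of the result lies in [−L/2, L/2). Broadcasts over
    leading axes of a and b.
    """
    box = validate_box(box)
    d = np.asarray(b, dtype=float) - np.asarray(a, dtype=float)
    return np.mod(d + box / 2.0, box) - box / 2.0


def wrap_positions(
    positions: np.ndarray, box: np.ndarray, center: np.ndarray | float = 0.0
) -> np.ndarray:
    """Wrap coordinates into the box centred at `center` (components in
    [center − L/2, center + L/2))."""
    box = validate_box(box)
    p = np.asarray(positions, dtype=float)
    return np.mod(p - center + box / 2.0, box) + np.asarray(center) - box / 2.0


Predicate = Callable[[pd.DataFrame], np.ndarray] | Mapping[str, object]


def resolve_selection(
    source: Trajectory | Frame | pd.DataFrame,
    predicate: Predicate,
    label: str = "",
) -> Selection:
    """Resolve a predicate over the topology into a Selection.

    `predicate` is either a mapping {column: value-or-collection} whose
    clauses are AND-ed, or a callable taking the topology DataFrame and
    returning a boolean mask. Topology is frame-invariant, so the result
    is stable across frames. An empty result warns but is not fatal.
    """
    topo = source if isinstance(source, pd.DataFrame) else source.topology
    if callable(predicate):
        mask = np.asarray(predicate(topo), dtype=bool)
        if mask.shape != (len(topo),):
            raise ConfigurationError("predicate mask has wrong length")
    else:
        mask = np.ones(len(topo), dtype=bool)
        for col, val in predicate.items():
            if col not in topo.columns:
                raise ConfigurationError(
                    f"selection references unknown field {col!r}; "
                    f"known fields: {list(topo.columns)}"
                )
            if isinstance(val, (list, tuple, set, frozenset, np.ndarray)):
                mask &= topo[col].isin(list(val)).to_numpy()
            else:
                mask &= (topo[col] == val).to_numpy()
    idx = np.flatnonzero(mask)
    if len(idx) == 0:
        warnings.warn(
            f"selection {label or predicate!r} matched no atoms",
            EmptySelectionWarning,
            stacklevel=2,
        )
    return Selection(indices=idx, label=label or str(predicate))


def molecule_index_groups(
    topology: pd.DataFrame, indices: np.ndarray | None = None
) -> dict[int, np.ndarray]:
    """Positional indices grouped by molecule_id (sorted by molecule_id)."""
    if indices is None:
        indices = np.arange(len(topology))
    mol = topology["molecule_id"].to_numpy()[indices]
    order = np.argsort(mol, kind="stable")
    indices = np.asarray(indices)[order]
    mol = mol[order]
    bounds = np.flatnonzero(np.diff(mol)) + 1
    groups = np.split(indices, bounds)
    return {int(topology["molecule_id"].iloc[g[0]]): g for g in groups}


def centers_of_mass(
    positions: np.ndarray, topology: pd.DataFrame, groups: Iterable[np.ndarray]
) -> np.ndarray:
    """Mass-weighted centres for index groups; positions may be (n,3) or (F,n,3)."""
    mass = topology["mass"].to_numpy()
    coms = []
    for g in groups:
        m = mass[g]
        coms.append(
            np.tensordot(positions[..., g, :], m, axes=([-2], [0])) / m.sum()
        )
    return np.stack(coms, axis=-2)
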