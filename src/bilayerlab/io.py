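"""File formats: PDB (single/multi-model), XYZ with box comment, the per-atom
topology sidecar, profile TSVs and JSON run summaries.

The sidecar is the authoritative source of masses, formal charges, vdW radii
and role tags: PDB carries none of these reliably, so we never guess them
from a structure file. Structures read without a sidecar get element-based
defaults (standard atomic weight, Bondi radius, zero charge, role "water")
and must have a real sidecar attached before any role-dependent analysis.

PDB support is deliberately narrow: orthorhombic CRYST1, no altloc, no
insertion codes, 1-based serials, Å. XYZ frames carry `Lx Ly Lz [t=<ps>]`
on the comment line. DCD/XTC are out of scope (documented extension point:
implement a reader returning a core.Trajectory).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import Frame, Trajectory, validate_topology
from .errors import (
    InvalidBoxError,
    ParseError,
    SchemaError,
    TrajectoryInconsistencyError,
)
from .profiles import AxialProfile

#: Bondi van der Waals radii (Å), keyed by element symbol.
BONDI_RADII = {
    "H": 1.20, "He": 1.40, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47,
    "Ne": 1.54, "Na": 2.27, "Mg": 1.73, "Si": 2.10, "P": 1.80, "S": 1.80,
    "Cl": 1.75, "Ar": 1.88, "K": 2.75, "Br": 1.85, "I": 1.98, "X": 1.70,
}

#: Standard atomic weights (amu) for structure-only reads.
ATOMIC_MASSES = {
    "H": 1.008, "He": 4.0026, "C": 12.011, "N": 14.007, "O": 15.999,
    "F": 18.998, "Ne": 20.180, "Na": 22.990, "Mg": 24.305, "Si": 28.085,
    "P": 30.974, "S": 32.06, "Cl": 35.45, "Ar": 39.948, "K": 39.098,
    "Br": 79.904, "I": 126.90, "X": 12.011,
}

SIDECAR_REQUIRED = ("atom_id", "molecule_id", "role", "mass", "formal_charge")


def default_topology(
    elements: list[str], atom_ids: np.ndarray, molecule_ids: np.ndarray
) -> pd.DataFrame:
    """Element-keyed placeholder topology for structure-only reads."""
    try:
        mass = [ATOMIC_MASSES[e] for e in elements]
        radius = [BONDI_RADII[e] for e in elements]
    except KeyError as exc:
        raise SchemaError(
            f"no default mass/radius for element {exc.args[0]!r}; provide a sidecar"
        ) from None
    return validate_topology(
        pd.DataFrame(
            {
                "atom_id": atom_ids,
                "molecule_id": molecule_ids,
                "element": elements,
                "mass": mass,
                "formal_charge": 0,
                "vdw_radius": radius,
                "role": "water",
            }
        )
    )


def _infer_format(path: str | Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt.lower()
    suffix = Path(path).suffix.lower().lstrip(".")
    if suffix in ("pdb", "xyz"):
        return suffix
    raise ParseError(f"cannot infer format from {path!r}; pass format='pdb'|'xyz'")


# ---------------------------------------------------------------------------
# PDB
# ---------------------------------------------------------------------------

def _parse_pdb_models(path: Path):
    """Yield (box, atoms) per model; atoms = list of parsed ATOM records."""
    box = None
    models: list[list] = []
    current: list = []
    in_model = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec == "CRYST1":
                try:
                    a, b, c = float(line[6:15]), float(line[15:24]), float(line[24:33])
                    alpha = float(line[33:40])
                    beta = float(line[40:47])
                    gamma = float(line[47:54])
                except ValueError:
                    raise ParseError("malformed CRYST1 record", lineno)
                if not np.allclose([alpha, beta, gamma], 90.0, atol=1e-6):
                    raise InvalidBoxError(
                        f"line {lineno}: triclinic cells are unsupported "
                        f"(angles {alpha}, {beta}, {gamma})"
                    )
                box = np.array([a, b, c])
            elif rec == "MODEL":
                if current:
                    models.append(current)
                current = []
                in_model = True
            elif rec == "ENDMDL":
                models.append(current)
                current = []
                in_model = False
            elif rec in ("ATOM", "HETATM"):
                if len(line.rstrip("\n")) < 54:
                    raise ParseError("ATOM record too short", lineno)
                if line[16] not in (" ", ""):
                    raise ParseError(
                        f"alternate locations unsupported (altloc {line[16]!r})",
                        lineno,
                    )
                if line[26] not in (" ", ""):
                    raise ParseError(
                        f"insertion codes unsupported ({line[26]!r})", lineno
                    )
                try:
                    serial = int(line[6:11])
                    resseq = int(line[22:26])
                    x = float(line[30:38])
                    y = float(line[38:46])
                    z = float(line[46:54])
                except ValueError:
                    raise ParseError("malformed ATOM/HETATM record", lineno)
                element = line[76:78].strip() or line[12:16].strip()[:1]
                current.append((serial, resseq, element, x, y, z))
    if current:
        models.append(current)
    if not models:
        raise ParseError(f"no ATOM records found in {path}")
    if box is None:
        raise InvalidBoxError(f"{path}: no CRYST1 record; box is required")
    return box, models


def _model_to_frame(box, atoms, time: float, topology=None) -> Frame:
    serials = np.array([a[0] for a in atoms], dtype=np.int64)
    resseqs = np.array([a[1] for a in atoms], dtype=np.int64)
    elements = [a[2] for a in atoms]
    pos = np.array([[a[3], a[4], a[5]] for a in atoms])
    if topology is None:
        topology = default_topology(elements, serials, resseqs)
    return Frame(time=time, box=box.copy(), positions=pos, topology=topology)


def read_structure(
    path: str | Path, format: str | None = None, topology: pd.DataFrame | None = None
) -> Frame:
    """Read a single-frame structure (first model of a PDB, first XYZ frame)."""
    traj = read_trajectory(path, format=format, topology=topology)
    return traj.frame(0)


def read_trajectory(
    path: str | Path,
    format: str | None = None,
    topology: pd.DataFrame | None = None,
    dt: float = 1.0,
) -> Trajectory:
    """Read a multi-model PDB or concatenated XYZ file as a Trajectory.

    Frame times come from `t=` markers (XYZ) when present, else 0..(F−1)·dt.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "pdb":
        box, models = _parse_pdb_models(path)
        n0 = len(models[0])
        for k, m in enumerate(models):
            if len(m) != n0:
                raise TrajectoryInconsistencyError(
                    f"model {k + 1} has {len(m)} atoms, expected {n0}"
                )
        frames = [
            _model_to_frame(box, m, time=k * dt, topology=topology)
            for k, m in enumerate(models)
        ]
        return Trajectory.from_frames(frames)
    if fmt == "xyz":
        return _read_xyz(path, topology=topology, dt=dt)
    raise ParseError(f"unsupported format {fmt!r}")


def _read_xyz(path: Path, topology=None, dt: float = 1.0) -> Trajectory:
    frames: list[Frame] = []
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    k = 0
    n0 = None
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError:
            raise ParseError("expected atom count", i + 1)
        if n0 is None:
            n0 = n
        elif n != n0:
            raise TrajectoryInconsistencyError(
                f"frame {k + 1} has {n} atoms, expected {n0}"
            )
        if i + 1 >= len(lines):
            raise ParseError("missing comment line", i + 2)
        comment = lines[i + 1]
        box, time = _parse_xyz_comment(comment, i + 2)
        if time is None:
            time = k * dt
        elements, pos = [], np.empty((n, 3))
        for j in range(n):
            ln = i + 2 + j
            if ln >= len(lines):
                raise ParseError("truncated frame", len(lines))
            parts = lines[ln].split()
            if len(parts) < 4:
                raise ParseError("expected `element x y z`", ln + 1)
            elements.append(parts[0])
            try:
                pos[j] = [float(parts[1]), float(parts[2]), float(parts[3])]
            except ValueError:
                raise ParseError("malformed coordinates", ln + 1)
        topo = topology
        if topo is None:
            topo = default_topology(
                elements,
                np.arange(1, n + 1),
                np.arange(1, n + 1),
            )
        frames.append(Frame(time=time, box=box, positions=pos, topology=topo))
        i += 2 + n
        k += 1
    if not frames:
        raise ParseError(f"no frames found in {path}")
    return Trajectory.from_frames(frames)


def _parse_xyz_comment(comment: str, lineno: int):
    time = None
    tokens = comment.split()
    floats = []
    for tok in tokens:
        if tok.startswith("t="):
            time = float(tok[2:])
            continue
        try:
            floats.append(float(tok))
        except ValueError:
            continue
    if len(floats) < 3:
        raise ParseError(
            "XYZ comment line must carry the box lengths `Lx Ly Lz`", lineno
        )
    return np.array(floats[:3]), time


def write_structure(frame: Frame, path: str | Path, format: str | None = None) -> None:
    write_trajectory(
        Trajectory.from_frames([frame]), path, format=format
    )


def write_trajectory(
    traj: Trajectory, path: str | Path, format: str | None = None
) -> None:
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "pdb":
        _write_pdb(traj, path)
    elif fmt == "xyz":
        _write_xyz(traj, path)
    else:
        raise ParseError(f"unsupported format {fmt!r}")


def _write_pdb(traj: Trajectory, path: Path) -> None:
    box = traj.constant_box()
    topo = traj.topology
    multi = traj.n_frames > 1
    with open(path, "w") as fh:
        fh.write(
            f"CRYST1{box[0]:9.3f}{box[1]:9.3f}{box[2]:9.3f}"
            f"{90.0:7.2f}{90.0:7.2f}{90.0:7.2f} P 1           1\n"
        )
        for f in range(traj.n_frames):
            if multi:
                fh.write(f"MODEL     {f + 1:4d}\n")
            pos = traj.positions[f]
            for i in range(traj.n_atoms):
                row = topo.iloc[i]
                name = str(row.element)[:4]
                fh.write(
                    f"ATOM  {int(row.atom_id) % 100000:5d} {name:<4s} "
                    f"{'MOL':<3s} A{int(row.molecule_id) % 10000:4d}    "
                    f"{pos[i, 0]:8.3f}{pos[i, 1]:8.3f}{pos[i, 2]:8.3f}"
                    f"{1.00:6.2f}{0.00:6.2f}          {str(row.element):>2s}\n"
                )
            if multi:
                fh.write("ENDMDL\n")
        fh.write("END\n")


def _write_xyz(traj: Trajectory, path: Path) -> None:
    topo = traj.topology
    elements = topo["element"].tolist()
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            b = traj.boxes[f]
            fh.write(f"{traj.n_atoms}\n")
            fh.write(
                f"{b[0]:.10g} {b[1]:.10g} {b[2]:.10g} t={traj.times[f]:.10g}\n"
            )
            for i in range(traj.n_atoms):
                p = traj.positions[f, i]
                fh.write(
                    f"{elements[i]} {p[0]:.10f} {p[1]:.10f} {p[2]:.10f}\n"
                )


# ---------------------------------------------------------------------------
# Topology sidecar
# ---------------------------------------------------------------------------

def read_topology_sidecar(path: str | Path) -> pd.DataFrame:
    """Read and validate the per-atom topology table (TSV, '#' comments).

    Required columns: atom_id, molecule_id, role, mass, formal_charge.
    Optional: species, element, vdw_radius (defaults to the Bondi radius of
    the element), head_ref, tail_terminal, hbond, bonded_to. Surfactant
    molecules get defaults: all head-role atoms as head references, and the
    highest-atom_id tail atom as the tail terminus if none is declared.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in SIDECAR_REQUIRED if c not in df.columns]
    if missing:
        raise SchemaError(f"sidecar missing required column(s) {missing}")
    fc = pd.to_numeric(df["formal_charge"], errors="coerce")
    if fc.isna().any():
        raise SchemaError("formal_charge column contains non-numeric values")
    if not np.allclose(fc, np.round(fc), atol=0.0):
        bad = df.loc[fc != np.round(fc), "atom_id"].tolist()
        raise SchemaError(
            f"formal charges must be integers; fractional values on atoms {bad}"
        )
    df["formal_charge"] = fc.astype(np.int64)
    if "element" not in df.columns:
        df["element"] = "X"
    if "vdw_radius" not in df.columns:
        df["vdw_radius"] = np.nan
    # empty strings come back from TSV as NaN; restore the canonical defaults
    for col, default in (("species", ""), ("hbond", ""), ("bonded_to", -1)):
        if col in df.columns:
            df[col] = df[col].fillna(default)
    for col in ("head_ref", "tail_terminal"):
        if col in df.columns:
            df[col] = df[col].fillna(False).astype(bool)
    fill = df["vdw_radius"].isna()
    if fill.any():
        try:
            df.loc[fill, "vdw_radius"] = [
                BONDI_RADII[e] for e in df.loc[fill, "element"]
            ]
        except KeyError as exc:
            raise SchemaError(
                f"no Bondi radius for element {exc.args[0]!r}; "
                "declare vdw_radius explicitly"
            ) from None
    try:
        topo = validate_topology(df)
    except Exception as exc:
        raise SchemaError(str(exc)) from exc
    return apply_surfactant_defaults(topo)


def apply_surfactant_defaults(topo: pd.DataFrame) -> pd.DataFrame:
    """Fill head-reference / tail-terminal declarations for surfactants."""
    topo = topo.copy()
    surf_mols = topo.loc[topo["role"].isin(["head", "tail"]), "molecule_id"].unique()
    for mol in surf_mols:
        sel = topo["molecule_id"] == mol
        sub = topo.loc[sel]
        if not sub["head_ref"].any():
            topo.loc[sel & (topo["role"] == "head"), "head_ref"] = True
        n_term = int(sub["tail_terminal"].sum())
        if n_term > 1:
            raise SchemaError(
                f"molecule {mol} declares {n_term} tail-terminal atoms; exactly 1 allowed"
            )
        if n_term == 0:
            tails = sub.loc[sub["role"] == "tail"]
            if len(tails):
                term_id = tails["atom_id"].idxmax()
                topo.loc[term_id, "tail_terminal"] = True
    return topo


def validate_sidecar_against(topo: pd.DataFrame, n_atoms: int) -> None:
    if len(topo) != n_atoms:
        raise SchemaError(
            f"sidecar has {len(topo)} rows but structure has {n_atoms} atoms"
        )


def write_topology_sidecar(topo: pd.DataFrame, path: str | Path) -> None:
    validate_topology(topo).to_csv(path, sep="\t", index=False)


def attach_topology(traj: Trajectory, topo: pd.DataFrame) -> Trajectory:
    """Return the trajectory with the sidecar topology attached (validated)."""
    topo = validate_topology(topo)
    validate_sidecar_against(topo, traj.n_atoms)
    return Trajectory(
        times=traj.times, boxes=traj.boxes, positions=traj.positions, topology=topo
    )


# ---------------------------------------------------------------------------
# Profile and summary outputs
# ---------------------------------------------------------------------------

def write_profile(profile: AxialProfile, path: str | Path) -> None:
    """Write a two-column (bin center, value) TSV with a '#' header recording
    quantity, units, bin width, origin and frame count. Re-reads bit-exactly."""
    with open(path, "w") as fh:
        fh.write(f"# quantity: {profile.quantity}\n")
        fh.write(f"# units: {profile.units}\n")
        fh.write(f"# bin_width_A: {float(profile.dz)!r}\n")
        fh.write(f"# origin: {profile.origin}\n")
        fh.write(f"# z0_A: {float(profile.z0)!r}\n")
        fh.write(f"# frames_averaged: {profile.frames_averaged}\n")
        fh.write(f"# first_edge_A: {float(profile.edges[0])!r}\n")
        fh.write("bin_center_A\tvalue\n")
        for c, v in zip(profile.centers, profile.values):
            fh.write(f"{float(c)!r}\t{float(v)!r}\n")


def read_profile(path: str | Path) -> AxialProfile:
    meta = {}
    with open(path) as fh:
        lines = fh.readlines()
    data_lines = []
    for ln in lines:
        if ln.startswith("#"):
            key, _, val = ln[1:].partition(":")
            meta[key.strip()] = val.strip()
        elif ln.strip() and not ln.startswith("bin_center"):
            data_lines.append(ln)
    centers = np.array([float(ln.split("\t")[0]) for ln in data_lines])
    values = np.array([float(ln.split("\t")[1]) for ln in data_lines])
    dz = float(meta["bin_width_A"])
    first_edge = float(meta.get("first_edge_A", centers[0] - dz / 2.0))
    edges = first_edge + dz * np.arange(len(centers) + 1)
    return AxialProfile(
        edges=edges,
        values=values,
        quantity=meta.get("quantity", ""),
        units=meta.get("units", ""),
        origin=meta.get("origin", ""),
        z0=float(meta.get("z0_A", 0.0)),
        frames_averaged=int(meta.get("frames_averaged", 1)),
    )


def write_run_summary(summary: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
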