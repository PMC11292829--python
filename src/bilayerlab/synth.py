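"""Synthetic bilayer configurations and trajectories with known ground truth.

This module stands in for the MD engine: it emits two-leaflet ionic
surfactant bilayers in a water slab with counterions and optional drug
molecules, at compositions matching the simulated systems (250 SDS-like
surfactants with 4962 waters; 228 CTAB-like with 2394 waters), plus Brownian
dynamics at user-set diffusion coefficients and analytic charge fixtures.
Every randomly assigned quantity is recorded in a GroundTruthManifest so the
analysis stages can be checked against exact answers.

Surfactants are coarse bead-chains — one charged head bead plus a straight
run of tail beads at the molecule's assigned tilt/azimuth — because the
analyses depend only on positions, charges, radii and role tags, and a
coarse model lets the ground truth be exact. Tail beads carry a small
marker radius by default so the minimum-distance packing criterion
constrains placement without forbidding realistic tilt spreads at the
simulated areal density.

Atomic-overlap avoidance emulates the MD builder's behaviour: no two
non-bonded atoms may be closer than overlap_factor × (sum of vdW radii),
with overlap_factor = 0.6 emulating the builder's packing efficiency factor
(which scales radii rather than distances — behaviourally similar, not
algorithmically identical). Covalently bonded pairs (declared via bonded_to)
are exempt.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.stats import norm

from .core import (
    E_OVER_EPS0_ANG,
    Frame,
    Trajectory,
    validate_topology,
)
from .errors import PackingFailureError, ParameterError

__all__ = [
    "BilayerSpec",
    "DrugBead",
    "GroundTruthManifest",
    "BrownianResult",
    "build_bilayer",
    "build_drug_box",
    "generate_brownian_trajectory",
    "generate_orientation_trajectory",
    "make_charge_fixture",
    "fold_tilt",
    "fold_azimuth",
]


def fold_tilt(x: np.ndarray) -> np.ndarray:
    """Fold angles (degrees) into [0°, 90°] by reflection."""
    y = np.abs(np.asarray(x, dtype=float)) % 180.0
    return np.where(y > 90.0, 180.0 - y, y)


def fold_azimuth(x: np.ndarray) -> np.ndarray:
    """Fold angles (degrees) into [0°, 180°)."""
    return np.asarray(x, dtype=float) % 180.0


@dataclass(frozen=True)
class DrugBead:
    """One bead of a rigid drug template (offsets in Å from the anchor)."""

    offset: tuple[float, float, float]
    element: str
    mass: float
    formal_charge: int = 0
    vdw_radius: float = 1.7
    hbond: str = ""  # "", "donor_h" or "acceptor"
    bond_partner: int = -1  # index of the covalently bonded bead, -1 if none


#: Neutral probe with one hydroxyl donor (O–H) and one acceptor oxygen.
DEFAULT_DRUG_TEMPLATE: tuple[DrugBead, ...] = (
    DrugBead((0.0, 0.0, 0.0), "C", 100.0, 0, 1.70),
    DrugBead((2.6, 0.0, 0.0), "O", 16.0, 0, 1.52, "acceptor", 0),
    DrugBead((-2.6, 0.0, 0.0), "O", 16.0, 0, 1.52, "", 0),
    DrugBead((-3.56, 0.0, 0.0), "H", 1.0, 0, 1.20, "donor_h", 2),
)

#: Zwitterionic probe (ciprofloxacin-like at neutral pH): +1 amine, −1
#: carboxylate, plus a hydroxyl donor.
ZWITTERION_DRUG_TEMPLATE: tuple[DrugBead, ...] = (
    DrugBead((0.0, 0.0, 0.0), "C", 120.0, 0, 1.70),
    DrugBead((2.6, 0.0, 0.0), "N", 30.0, 1, 1.55, "", 0),
    DrugBead((-2.6, 0.0, 0.0), "O", 45.0, -1, 1.52, "acceptor", 0),
    DrugBead((0.0, 2.6, 0.0), "O", 16.0, 0, 1.52, "", 0),
    DrugBead((0.0, 3.56, 0.0), "H", 1.0, 0, 1.20, "donor_h", 3),
)


@dataclass
class BilayerSpec:
    """Recipe for one synthetic bilayer system.

    Defaults reproduce the pure anionic (SDS-like) system: 125 surfactants
    per leaflet (250 total), 4962 single-bead waters, matching counterions,
    a ~52 × 52 Å lateral box of 102 Å height, and per-molecule tilt/azimuth
    drawn from folded normals at the published pure-SDS means and spreads.
    """

    # composition
    n_surfactants_per_leaflet: int = 125
    water_count: int = 4962
    counterion_count: int | None = None  # None → auto-neutralize
    drug_count: int = 0
    drug_template: tuple[DrugBead, ...] = DEFAULT_DRUG_TEMPLATE
    drug_z: float | None = None  # None → random in the water region

    # geometry
    surfactant_length: float = 15.0  # head-to-tail-terminal distance, Å
    tail_beads: int = 4
    head_separation: float = 40.0  # distance between the two head planes, Å
    box_xy: tuple[float, float] = (52.05, 52.16)
    box_z: float = 102.0

    # orientation distributions (degrees)
    tilt_mean: float = 47.416
    tilt_std: float = 6.73
    azimuth_mean: float = 89.114
    azimuth_std: float = 3.56
    azimuth_uniform: bool = False

    # species properties
    head_charge: int = -1
    head_element: str = "S"
    head_mass: float = 97.0
    head_radius: float = 1.8
    head_acceptor: bool = True  # sulfate-like heads accept H-bonds
    tail_element: str = "C"
    tail_mass: float = 42.0
    tail_radius: float = 0.5
    counterion_charge: int = 1
    counterion_element: str = "Na"
    counterion_mass: float = 22.99
    counterion_radius: float = 2.27
    water_element: str = "O"
    water_mass: float = 18.015
    water_radius: float = 1.52
    species: str = "SDS-like"

    # packing
    overlap_factor: float = 0.6
    placement_clearance: float = 2.0  # water/ion stand-off from head planes, Å
    max_retries: int = 500

    seed: int = 0

    def __post_init__(self):
        if min(self.n_surfactants_per_leaflet, self.water_count, self.drug_count) < 0:
            raise ParameterError("counts must be >= 0")
        if self.counterion_count is not None and self.counterion_count < 0:
            raise ParameterError("counterion count must be >= 0")
        if min(self.tilt_std, self.azimuth_std) < 0:
            raise ParameterError("distribution spreads must be >= 0")
        if min(self.surfactant_length, self.head_separation, self.box_z) <= 0:
            raise ParameterError("lengths must be > 0")
        if min(self.box_xy) <= 0:
            raise ParameterError("box lengths must be > 0")
        if self.overlap_factor < 0:
            raise ParameterError("overlap factor must be >= 0")
        if self.tail_beads < 1:
            raise ParameterError("need at least one tail bead")
        if self.head_separation / 2.0 + self.placement_clearance >= self.box_z / 2.0:
            raise ParameterError("head planes leave no water region in the box")

    @property
    def box(self) -> np.ndarray:
        return np.array([self.box_xy[0], self.box_xy[1], self.box_z])

    def auto_counterions(self) -> int:
        total = 2 * self.n_surfactants_per_leaflet * abs(self.head_charge)
        if self.counterion_count is not None:
            return self.counterion_count
        if self.head_charge == 0:
            return 0
        q = abs(self.counterion_charge)
        if q == 0 or total % q:
            raise ParameterError(
                "cannot neutralize surfactant charge with integer counterions"
            )
        return total // q

    # ------------------------------------------------------------------
    # presets at the simulated compositions
    # ------------------------------------------------------------------

    @classmethod
    def sds_like(cls, **overrides) -> "BilayerSpec":
        """Pure anionic bilayer: 250 surfactants, 4962 waters."""
        return cls(**overrides)

    @classmethod
    def ctab_like(cls, **overrides) -> "BilayerSpec":
        """Pure cationic bilayer: 228 surfactants, 2394 waters, Br-like ions."""
        params = dict(
            n_surfactants_per_leaflet=114,
            water_count=2394,
            box_xy=(52.08, 52.17),
            box_z=82.0,
            tilt_mean=40.300,
            tilt_std=3.19,
            azimuth_mean=92.443,
            azimuth_std=3.50,
            head_charge=1,
            head_element="N",
            head_mass=74.0,
            head_acceptor=False,  # no H-bond donors or acceptors
            counterion_charge=-1,
            counterion_element="Br",
            counterion_mass=79.9,
            counterion_radius=1.85,
            species="CTAB-like",
        )
        params.update(overrides)
        return cls(**params)

    @classmethod
    def sds_with_zwitterion(cls, **overrides) -> "BilayerSpec":
        """Anionic bilayer plus 10 zwitterionic (ciprofloxacin-like) drugs."""
        params = dict(
            drug_count=10,
            drug_template=ZWITTERION_DRUG_TEMPLATE,
            box_z=127.15,
            tilt_mean=45.771,
            tilt_std=6.98,
            azimuth_mean=90.463,
            azimuth_std=3.36,
            species="SDS-like+zwitterion",
        )
        params.update(overrides)
        return cls(**params)

    @classmethod
    def sds_with_neutral_drug(cls, **overrides) -> "BilayerSpec":
        """Anionic bilayer plus 5 neutral H-bonding (azithromycin-like) drugs."""
        params = dict(
            drug_count=5,
            drug_template=DEFAULT_DRUG_TEMPLATE,
            box_z=135.14,
            tilt_mean=46.244,
            tilt_std=6.22,
            azimuth_mean=90.353,
            azimuth_std=3.30,
            species="SDS-like+neutral-drug",
        )
        params.update(overrides)
        return cls(**params)


@dataclass
class GroundTruthManifest:
    """Exact record of what the generator emitted (the recovery-test ledger)."""

    seed: int
    spec: dict = field(default_factory=dict)
    molecule_ids: list = field(default_factory=list)
    tilt_deg: list = field(default_factory=list)  # realized per-molecule tilt
    azimuth_deg: list = field(default_factory=list)
    tilt_distribution: dict = field(default_factory=dict)
    azimuth_distribution: dict = field(default_factory=dict)
    charge_layers: dict = field(default_factory=dict)
    diffusion_by_role: dict = field(default_factory=dict)
    dt_ps: float | None = None
    n_frames: int | None = None
    notes: str = ""

    def to_dict(self) -> dict:
        return asdict(self)

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


# ---------------------------------------------------------------------------
# packing helpers
# ---------------------------------------------------------------------------


class _Packer:
    """Sequential placement with the min-distance criterion under full PBC."""

    def __init__(self, box: np.ndarray, factor: float):
        self.box = box
        self.factor = factor
        self._pos: list[np.ndarray] = []
        self._rad: list[float] = []
        self._tree = None
        self._pts = None
        self._dirty = True

    @property
    def n(self) -> int:
        return len(self._rad)

    def _refresh(self):
        if self._dirty and self._pos:
            self._pts = np.mod(np.asarray(self._pos) + self.box / 2.0, self.box)
            self._tree = cKDTree(self._pts, boxsize=self.box)
            self._maxrad = max(self._rad)
            self._dirty = False

    def conflict_mask(self, cand: np.ndarray, crad: np.ndarray) -> np.ndarray:
        """Per-candidate: does it violate the min-distance rule vs accepted atoms?"""
        cand = np.atleast_2d(cand)
        crad = np.broadcast_to(np.atleast_1d(crad).astype(float), (len(cand),))
        out = np.zeros(len(cand), dtype=bool)
        if not self._pos or self.factor == 0:
            return out
        self._refresh()
        cpts = np.mod(cand + self.box / 2.0, self.box)
        rads = np.asarray(self._rad)
        for i, (p, r) in enumerate(zip(cpts, crad)):
            for j in self._tree.query_ball_point(p, self.factor * (r + self._maxrad)):
                d = np.mod(p - self._pts[j] + self.box / 2.0, self.box) - self.box / 2.0
                if np.linalg.norm(d) < self.factor * (r + rads[j]):
                    out[i] = True
                    break
        return out

    def conflicts(self, cand: np.ndarray, crad) -> bool:
        return bool(self.conflict_mask(cand, crad).any())

    def accept(self, cand: np.ndarray, crad) -> None:
        cand = np.atleast_2d(cand)
        crad = np.broadcast_to(np.atleast_1d(crad).astype(float), (len(cand),))
        self._pos.extend(cand)
        self._rad.extend(crad)
        self._dirty = True


def _head_lattice(n: int, box_xy, rng) -> np.ndarray:
    """Jittered square lattice of n xy positions covering the lateral box."""
    nx = int(np.ceil(np.sqrt(n)))
    ny = int(np.ceil(n / nx))
    xs = (np.arange(nx) + 0.5) * box_xy[0] / nx - box_xy[0] / 2.0
    ys = (np.arange(ny) + 0.5) * box_xy[1] / ny - box_xy[1] / 2.0
    grid = np.array([(x, y) for y in ys for x in xs])[:n]
    jitter = rng.uniform(-0.2, 0.2, size=grid.shape)
    return grid + jitter


def _tail_direction(theta_deg: float, phi_deg: float, inward_sign: float):
    th = np.radians(theta_deg)
    ph = np.radians(phi_deg)
    return np.array(
        [np.sin(th) * np.cos(ph), np.sin(th) * np.sin(ph), inward_sign * np.cos(th)]
    )


def _surfactant_beads(head_xy, head_z, direction, spec: BilayerSpec) -> np.ndarray:
    steps = np.arange(1, spec.tail_beads + 1) * (
        spec.surfactant_length / spec.tail_beads
    )
    head = np.array([head_xy[0], head_xy[1], head_z])
    beads = np.vstack([head, head + steps[:, None] * direction])
    beads[:, 0] = np.mod(beads[:, 0] + spec.box_xy[0] / 2, spec.box_xy[0]) - spec.box_xy[0] / 2
    beads[:, 1] = np.mod(beads[:, 1] + spec.box_xy[1] / 2, spec.box_xy[1]) - spec.box_xy[1] / 2
    return beads


def _draw_tilt(rng, spec: BilayerSpec, n: int) -> np.ndarray:
    return fold_tilt(rng.normal(spec.tilt_mean, spec.tilt_std, size=n))


def _draw_azimuth(rng, spec: BilayerSpec, n: int) -> np.ndarray:
    if spec.azimuth_uniform:
        return rng.uniform(0.0, 180.0, size=n)
    return fold_azimuth(rng.normal(spec.azimuth_mean, spec.azimuth_std, size=n))


def _water_region_sampler(spec: BilayerSpec, rng):
    """Uniform positions in the two water slabs outside the head planes."""
    z_lo = spec.head_separation / 2.0 + spec.placement_clearance
    z_hi = spec.box_z / 2.0
    if z_lo >= z_hi:
        raise ParameterError("no water region available")

    def draw(n):
        xy = rng.uniform(-0.5, 0.5, size=(n, 2)) * np.array(spec.box_xy)
        z = rng.uniform(z_lo, z_hi, size=n) * rng.choice([-1.0, 1.0], size=n)
        return np.column_stack([xy, z])

    return draw


def _place_loose(
    packer: _Packer, rng, count: int, radius: float, sampler, max_rounds: int
) -> np.ndarray:
    """Batched random sequential placement of single beads of one radius."""
    placed: list[np.ndarray] = []
    rounds = 0
    while len(placed) < count:
        if rounds >= max_rounds:
            density = packer.n / np.prod(packer.box)
            raise PackingFailureError(
                f"placed {len(placed)}/{count} beads after {rounds} rounds "
                f"(achieved number density {density:.4g} /Å³); loosen the spec"
            )
        rounds += 1
        need = count - len(placed)
        cand = sampler(min(2 * need + 16, 8192))
        ok = ~packer.conflict_mask(cand, radius)
        cand = cand[ok]
        if len(cand) == 0:
            continue
        # thin candidate-candidate conflicts greedily (keep the earlier one)
        cpts = np.mod(cand + packer.box / 2.0, packer.box)
        ctree = cKDTree(cpts, boxsize=packer.box)
        keep = np.ones(len(cand), dtype=bool)
        for i, j in sorted(ctree.query_pairs(2.0 * packer.factor * radius)):
            if keep[i] and keep[j]:
                keep[max(i, j)] = False
        cand = cand[keep][:need]
        if len(cand):
            packer.accept(cand, radius)
            placed.extend(cand)
    return np.array(placed).reshape(count, 3)


# ---------------------------------------------------------------------------
# builders
# ---------------------------------------------------------------------------


def build_bilayer(
    spec: BilayerSpec,
) -> tuple[Frame, pd.DataFrame, GroundTruthManifest]:
    """Build one overlap-free bilayer frame with its sidecar and manifest.

    Leaflets are mirrored about z = 0 with heads exactly on the planes
    z = ±head_separation/2 and tails pointing inward along each molecule's
    assigned (tilt, azimuth). Counterions, drugs and waters fill the water
    slabs. A molecule whose assigned orientation collides with already
    placed atoms is redrawn (bounded retries); the realized angles — not the
    first draws — are what the manifest records, so manifest-based recovery
    is exact even though redraws slightly reshape the tails of the realized
    angle sample. Distribution-level recovery should use
    generate_orientation_trajectory, whose draws are unconstrained.
    """
    rng = np.random.default_rng(spec.seed)
    box = spec.box
    packer = _Packer(box, spec.overlap_factor)

    n_leaf = spec.n_surfactants_per_leaflet
    rows = []
    positions = []
    atom_id = 1
    mol_id = 1
    tilt_real, azim_real, mol_ids = [], [], []

    head_z = spec.head_separation / 2.0
    for leaflet_sign in (1.0, -1.0):  # +1: upper leaflet (tails point down)
        lattice = _head_lattice(n_leaf, spec.box_xy, rng)
        for k in range(n_leaf):
            placed = False
            for _ in range(spec.max_retries):
                theta = float(_draw_tilt(rng, spec, 1)[0])
                phi = float(_draw_azimuth(rng, spec, 1)[0])
                direction = _tail_direction(theta, phi, -leaflet_sign)
                beads = _surfactant_beads(
                    lattice[k], leaflet_sign * head_z, direction, spec
                )
                radii = np.array(
                    [spec.head_radius] + [spec.tail_radius] * spec.tail_beads
                )
                if not packer.conflicts(beads, radii):
                    packer.accept(beads, radii)
                    placed = True
                    break
            if not placed:
                raise PackingFailureError(
                    f"could not place surfactant {mol_id} without overlap after "
                    f"{spec.max_retries} retries"
                )
            tilt_real.append(theta)
            azim_real.append(phi)
            mol_ids.append(mol_id)
            positions.append(beads)
            rows.append(
                dict(
                    atom_id=atom_id,
                    molecule_id=mol_id,
                    species=spec.species,
                    role="head",
                    element=spec.head_element,
                    mass=spec.head_mass,
                    formal_charge=spec.head_charge,
                    vdw_radius=spec.head_radius,
                    head_ref=True,
                    tail_terminal=False,
                    hbond="acceptor" if spec.head_acceptor else "",
                    bonded_to=-1,
                )
            )
            atom_id += 1
            for t in range(spec.tail_beads):
                rows.append(
                    dict(
                        atom_id=atom_id,
                        molecule_id=mol_id,
                        species=spec.species,
                        role="tail",
                        element=spec.tail_element,
                        mass=spec.tail_mass,
                        formal_charge=0,
                        vdw_radius=spec.tail_radius,
                        head_ref=False,
                        tail_terminal=(t == spec.tail_beads - 1),
                        hbond="",
                        bonded_to=atom_id - 1,
                    )
                )
                atom_id += 1
            mol_id += 1

    sampler = _water_region_sampler(spec, rng)

    n_ions = spec.auto_counterions()
    ion_pos = _place_loose(packer, rng, n_ions, spec.counterion_radius, sampler, 200)
    for i in range(n_ions):
        positions.append(ion_pos[i : i + 1])
        rows.append(
            dict(
                atom_id=atom_id,
                molecule_id=mol_id,
                species=spec.counterion_element,
                role="counterion",
                element=spec.counterion_element,
                mass=spec.counterion_mass,
                formal_charge=spec.counterion_charge,
                vdw_radius=spec.counterion_radius,
                head_ref=False,
                tail_terminal=False,
                hbond="",
                bonded_to=-1,
            )
        )
        atom_id += 1
        mol_id += 1

    # drugs: rigid templates, random xy, spec-controlled z
    template = spec.drug_template
    offsets = np.array([b.offset for b in template])
    t_radii = np.array([b.vdw_radius for b in template])
    for _ in range(spec.drug_count):
        placed = False
        for _ in range(spec.max_retries):
            anchor = sampler(1)[0]
            if spec.drug_z is not None:
                anchor[2] = spec.drug_z
            beads = anchor + offsets
            if not packer.conflicts(beads, t_radii):
                packer.accept(beads, t_radii)
                placed = True
                break
        if not placed:
            raise PackingFailureError(
                f"could not place drug molecule {mol_id} without overlap"
            )
        first_atom = atom_id
        positions.append(beads)
        for b in template:
            rows.append(
                dict(
                    atom_id=atom_id,
                    molecule_id=mol_id,
                    species="drug",
                    role="drug",
                    element=b.element,
                    mass=b.mass,
                    formal_charge=b.formal_charge,
                    vdw_radius=b.vdw_radius,
                    head_ref=False,
                    tail_terminal=False,
                    hbond=b.hbond,
                    bonded_to=(first_atom + b.bond_partner) if b.bond_partner >= 0 else -1,
                )
            )
            atom_id += 1
        mol_id += 1

    wat_pos = _place_loose(
        packer, rng, spec.water_count, spec.water_radius, sampler, 200
    )
    for i in range(spec.water_count):
        positions.append(wat_pos[i : i + 1])
        rows.append(
            dict(
                atom_id=atom_id,
                molecule_id=mol_id,
                species="water",
                role="water",
                element=spec.water_element,
                mass=spec.water_mass,
                formal_charge=0,
                vdw_radius=spec.water_radius,
                head_ref=False,
                tail_terminal=False,
                hbond="",
                bonded_to=-1,
            )
        )
        atom_id += 1
        mol_id += 1

    topo = validate_topology(pd.DataFrame(rows))
    frame = Frame(
        time=0.0, box=box, positions=np.vstack(positions), topology=topo
    )
    manifest = GroundTruthManifest(
        seed=spec.seed,
        spec=_spec_dict(spec),
        molecule_ids=mol_ids,
        tilt_deg=tilt_real,
        azimuth_deg=azim_real,
        tilt_distribution=dict(mean=spec.tilt_mean, std=spec.tilt_std, fold="0-90"),
        azimuth_distribution=dict(
            mean=None if spec.azimuth_uniform else spec.azimuth_mean,
            std=None if spec.azimuth_uniform else spec.azimuth_std,
            uniform=spec.azimuth_uniform,
            fold="0-180",
        ),
        charge_layers=dict(
            head_planes_z=[-head_z, head_z],
            head_charge=spec.head_charge,
            counterion_charge=spec.counterion_charge,
            counterion_region=f"|z| in [{head_z + spec.placement_clearance:.2f}, "
            f"{spec.box_z / 2:.2f}] Å",
        ),
        notes="static build; realized per-molecule angles recorded",
    )
    return frame, topo, manifest


def _spec_dict(spec: BilayerSpec) -> dict:
    d = asdict(spec)
    d["drug_template"] = [asdict(b) for b in spec.drug_template]
    return d


def build_drug_box(
    n_drugs: int,
    box: tuple[float, float, float] = (60.0, 60.0, 60.0),
    template: tuple[DrugBead, ...] = DEFAULT_DRUG_TEMPLATE,
    seed: int = 0,
) -> tuple[Frame, pd.DataFrame]:
    """Drug molecules alone on a loose lattice in a periodic box.

    Minimal input for diffusion studies where the bilayer is irrelevant.
    """
    rng = np.random.default_rng(seed)
    box = np.asarray(box, dtype=float)
    n_side = int(np.ceil(n_drugs ** (1.0 / 3.0)))
    grid = []
    for ix in range(n_side):
        for iy in range(n_side):
            for iz in range(n_side):
                grid.append(((ix + 0.5) / n_side, (iy + 0.5) / n_side, (iz + 0.5) / n_side))
    anchors = (np.array(grid[:n_drugs]) - 0.5) * box
    anchors += rng.uniform(-0.5, 0.5, size=anchors.shape)
    offsets = np.array([b.offset for b in template])
    rows, positions = [], []
    atom_id = 1
    for m in range(n_drugs):
        first = atom_id
        positions.append(anchors[m] + offsets)
        for b in template:
            rows.append(
                dict(
                    atom_id=atom_id,
                    molecule_id=m + 1,
                    species="drug",
                    role="drug",
                    element=b.element,
                    mass=b.mass,
                    formal_charge=b.formal_charge,
                    vdw_radius=b.vdw_radius,
                    hbond=b.hbond,
                    bonded_to=(first + b.bond_partner) if b.bond_partner >= 0 else -1,
                )
            )
            atom_id += 1
    topo = validate_topology(pd.DataFrame(rows))
    frame = Frame(time=0.0, box=box, positions=np.vstack(positions), topology=topo)
    return frame, topo


@dataclass
class BrownianResult:
    """A Brownian trajectory plus its continuous (never-wrapped) path."""

    trajectory: Trajectory
    continuous: np.ndarray  # (n_frames, n_atoms, 3), unwrapped ground truth
    manifest: GroundTruthManifest


def generate_brownian_trajectory(
    frame: Frame,
    D_by_role: dict[str, float],
    dt: float = 1.0,
    n_frames: int = 1000,
    seed: int = 0,
) -> BrownianResult:
    """Rigid-molecule Brownian dynamics at known diffusion coefficients.

    Each molecule is displaced per step by independent Gaussian components
    of variance 2·D·dt per axis, with D looked up (in m²/s) by the role of
    the molecule's first atom; roles absent from the map are immobile
    (D = 0). Positions are wrapped into the box; the continuous path is kept
    alongside as ground truth for unwrapping and MSD tests.
    """
    if dt <= 0:
        raise ParameterError("dt must be > 0")
    for role, D in D_by_role.items():
        if D < 0:
            raise ParameterError(f"negative diffusion coefficient for role {role!r}")
    rng = np.random.default_rng(seed)
    topo = frame.topology
    box = frame.box
    mol_of_atom = topo["molecule_id"].to_numpy()
    mol_ids, first_idx = np.unique(mol_of_atom, return_index=True)
    roles = topo["role"].to_numpy()[first_idx]
    # Å²/ps = 1e8 × m²/s
    d_ang = np.array([D_by_role.get(r, 0.0) for r in roles]) * 1e8
    sigma = np.sqrt(2.0 * d_ang * dt)  # per-axis step std, Å

    n_mol = len(mol_ids)
    steps = rng.normal(size=(n_frames - 1, n_mol, 3)) * sigma[None, :, None]
    mol_disp = np.concatenate(
        [np.zeros((1, n_mol, 3)), np.cumsum(steps, axis=0)], axis=0
    )
    col = np.searchsorted(mol_ids, mol_of_atom)
    start = np.mod(frame.positions + box / 2.0, box) - box / 2.0
    continuous = start[None, :, :] + mol_disp[:, col, :]
    wrapped = np.mod(continuous + box / 2.0, box) - box / 2.0
    traj = Trajectory(
        times=np.arange(n_frames) * dt,
        boxes=np.tile(box, (n_frames, 1)),
        positions=wrapped,
        topology=topo,
    )
    manifest = GroundTruthManifest(
        seed=seed,
        diffusion_by_role={r: float(D_by_role.get(r, 0.0)) for r in set(roles)},
        dt_ps=dt,
        n_frames=n_frames,
        notes="rigid-molecule Brownian displacements; variance 2·D·dt per axis",
    )
    return BrownianResult(trajectory=traj, continuous=continuous, manifest=manifest)


def generate_orientation_trajectory(
    spec: BilayerSpec,
    n_frames: int = 200,
    dt: float = 1.0,
    seed: int | None = None,
) -> tuple[Trajectory, GroundTruthManifest]:
    """Trajectory whose surfactant orientations are redrawn every frame.

    Heads, waters, ions and drugs stay fixed; each frame independently
    redraws every surfactant's (tilt, azimuth) from the spec distributions
    and rebuilds the tail beads, emulating the orientational fluctuations a
    thermostatted run shows. Draws are unconstrained by packing, so the
    time-and-molecule-averaged angles are unbiased estimates of the folded
    distribution means.
    """
    if n_frames < 1:
        raise ParameterError("need at least one frame")
    base_frame, topo, manifest = build_bilayer(spec)
    rng = np.random.default_rng(spec.seed if seed is None else seed)

    heads = topo.index[topo["role"] == "head"].to_numpy()
    n_surf = len(heads)
    head_pos = base_frame.positions[heads]  # (n_surf, 3)
    inward = -np.sign(head_pos[:, 2])  # tails point toward z = 0
    steps = np.arange(1, spec.tail_beads + 1) * (
        spec.surfactant_length / spec.tail_beads
    )

    # tail atom indices per surfactant, ordered: shape (n_surf, tail_beads)
    tails = (
        topo.index[topo["role"] == "tail"]
        .to_numpy()
        .reshape(n_surf, spec.tail_beads)
    )

    positions = np.repeat(base_frame.positions[None, :, :], n_frames, axis=0)
    for f in range(n_frames):
        th = np.radians(_draw_tilt(rng, spec, n_surf))
        ph = np.radians(_draw_azimuth(rng, spec, n_surf))
        dirs = np.column_stack(
            [np.sin(th) * np.cos(ph), np.sin(th) * np.sin(ph), inward * np.cos(th)]
        )
        beads = head_pos[:, None, :] + steps[None, :, None] * dirs[:, None, :]
        # keep xy wrapped so molecules stay minimum-image reconstructible
        beads[..., 0] = np.mod(beads[..., 0] + spec.box_xy[0] / 2, spec.box_xy[0]) - spec.box_xy[0] / 2
        beads[..., 1] = np.mod(beads[..., 1] + spec.box_xy[1] / 2, spec.box_xy[1]) - spec.box_xy[1] / 2
        positions[f, tails.ravel()] = beads.reshape(-1, 3)
    traj = Trajectory(
        times=np.arange(n_frames) * dt,
        boxes=np.tile(spec.box, (n_frames, 1)),
        positions=positions,
        topology=topo,
    )
    manifest.n_frames = n_frames
    manifest.dt_ps = dt
    manifest.notes = (
        "per-frame orientation resampling; ground truth is the folded "
        "distribution (tilt and azimuth) in the manifest"
    )
    return traj, manifest


# ---------------------------------------------------------------------------
# analytic charge fixtures
# ---------------------------------------------------------------------------


def make_charge_fixture(
    kind: str,
    box: tuple[float, float, float] = (20.0, 20.0, 80.0),
    sites_per_plane: int = 64,
    sites_negative_plane: int | None = None,
    site_charge: int = 1,
    half_gap: float = 10.0,
    plane_z: float = 0.0,
    layers: list[tuple[float, float, int, int]] | None = None,
    eps_s: float = 1.0,
):
    """Discrete charges realizing an ideal layered ρ(z), plus its closed-form φ.

    kinds:
      capacitor        — +|q| sites on the plane z = −half_gap, −|q| on
                         z = +half_gap (neutral by construction; an unequal
                         request is refused). φ is the textbook capacitor
                         potential: linear between the planes, constant
                         outside, gauge E(far) = 0.
      single_plane     — one charged plane at plane_z; φ is the V-shaped
                         single-sheet potential.
      gaussian_layers  — layers = [(z0, width, n_sites, site_charge), ...];
                         site z-values sit at Gaussian quantiles (stratified,
                         deterministic), and φ is the closed-form potential
                         of the ideal Gaussian sheets.

    Returns (Frame, topology, phi) with phi(z, z_m) in volts, vectorized,
    zeroed at the reference plane z_m.
    """
    box = np.asarray(box, dtype=float)
    area = box[0] * box[1]
    c = E_OVER_EPS0_ANG / eps_s  # V per (e/Å² · Å)

    def _plane_sites(z, n, q):
        nx = int(np.ceil(np.sqrt(n)))
        ny = int(np.ceil(n / nx))
        xs = (np.arange(nx) + 0.5) * box[0] / nx - box[0] / 2
        ys = (np.arange(ny) + 0.5) * box[1] / ny - box[1] / 2
        pts = np.array([(x, yy, z) for yy in ys for x in xs])[:n]
        return pts, np.full(n, q, dtype=int)

    if kind == "capacitor":
        if site_charge == 0:
            raise ParameterError("capacitor needs nonzero site charge")
        if half_gap < 0:
            raise ParameterError("half_gap must be >= 0")
        if sites_negative_plane is not None and sites_negative_plane != sites_per_plane:
            raise ParameterError(
                "non-neutral capacitor refused: the closed form assumes equal "
                "and opposite plane charges"
            )
        p1, q1 = _plane_sites(-half_gap, sites_per_plane, abs(site_charge))
        p2, q2 = _plane_sites(+half_gap, sites_per_plane, -abs(site_charge))
        pos = np.vstack([p1, p2])
        q = np.concatenate([q1, q2])
        sigma = sites_per_plane * abs(site_charge) / area  # e/Å²

        def f(z):
            z = np.asarray(z, dtype=float)
            inner = -c * sigma * (z + half_gap)
            return np.where(
                z < -half_gap, 0.0, np.where(z > half_gap, -2 * c * sigma * half_gap, inner)
            )

    elif kind == "single_plane":
        pos, q = _plane_sites(plane_z, sites_per_plane, site_charge)
        sigma = sites_per_plane * site_charge / area

        def f(z):
            z = np.asarray(z, dtype=float)
            return -c * sigma * np.abs(z - plane_z) / 2.0

    elif kind == "gaussian_layers":
        if not layers:
            raise ParameterError("gaussian_layers needs a layers list")
        pos_list, q_list = [], []
        for z0, width, n_sites, qs in layers:
            if width <= 0 or n_sites < 1:
                raise ParameterError("layer width must be > 0 and n_sites >= 1")
            zq = z0 + width * norm.ppf((np.arange(n_sites) + 0.5) / n_sites)
            p, qq = _plane_sites(0.0, n_sites, qs)
            p = p.copy()
            p[:, 2] = zq
            pos_list.append(p)
            q_list.append(qq)
        pos = np.vstack(pos_list)
        q = np.concatenate(q_list)

        def f(z):
            z = np.asarray(z, dtype=float)
            out = np.zeros_like(z)
            for z0, width, n_sites, qs in layers:
                sigma_l = n_sites * qs / area
                u = (z - z0) / width
                out += -c * sigma_l * width * (u * norm.cdf(u) + norm.pdf(u))
            return out

    else:
        raise ParameterError(f"unknown fixture kind {kind!r}")

    def phi(z, z_m):
        return f(z) - f(np.asarray(z_m, dtype=float))

    n = len(pos)
    topo = validate_topology(
        pd.DataFrame(
            dict(
                atom_id=np.arange(1, n + 1),
                molecule_id=np.arange(1, n + 1),
                species="fixture",
                role="counterion",
                element="Na",
                mass=22.99,
                formal_charge=q,
                vdw_radius=1.0,
            )
        )
    )
    frame = Frame(time=0.0, box=box, positions=pos, topology=topo)
    return frame, topo, phi
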