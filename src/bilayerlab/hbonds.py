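"""Geometric hydrogen-bond detection between two selections.

A bond is a (donor D, hydrogen H, acceptor A) triple with H···A within the
distance cutoff, the D–H···A angle at H above its cutoff, and — when the
acceptor declares a bonded neighbour X — the H···A–X angle at A above its
cutoff. All distances and angles use minimum-image geometry. Donor/acceptor
identity comes from the sidecar's hbond tags (donor hydrogens carry
hbond = "donor_h" with bonded_to pointing at the donor heavy atom;
acceptors carry hbond = "acceptor"), never from element perception.

Defaults follow the Maestro-style convention: H···A ≤ 2.8 Å,
∠D–H···A ≥ 120°, ∠H···A–X ≥ 90°.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .core import Frame, Selection, Trajectory, minimum_image_displacement
from .errors import ConfigurationError, ParameterError


@dataclass(frozen=True)
class HBondCriteria:
    max_ha_distance: float = 2.8  # Å
    min_dha_angle: float = 120.0  # degrees at the hydrogen
    min_hax_angle: float = 90.0  # degrees at the acceptor

    def __post_init__(self):
        if self.max_ha_distance <= 0:
            raise ParameterError("distance cutoff must be > 0")
        for a in (self.min_dha_angle, self.min_hax_angle):
            if not 0.0 < a <= 180.0:
                raise ParameterError("angle cutoffs must lie in (0, 180]")


@dataclass(frozen=True)
class HBondRecord:
    donor_id: int  # atom_id of the donor heavy atom
    hydrogen_id: int
    acceptor_id: int


@dataclass
class HBondSeries:
    times: np.ndarray
    counts: np.ndarray
    records: list[list[HBondRecord]] = field(default_factory=list)

    @property
    def summary(self) -> dict:
        return dict(
            min=int(self.counts.min()),
            max=int(self.counts.max()),
            mean=float(self.counts.mean()),
        )


def _donor_triples(frame: Frame, donors: Selection):
    """(H index, D index) pairs for donor hydrogens inside the selection."""
    topo = frame.topology
    hb = topo["hbond"].to_numpy()
    ids = topo["atom_id"].to_numpy()
    id_to_idx = {int(a): i for i, a in enumerate(ids)}
    h_idx = [i for i in donors.indices if hb[i] == "donor_h"]
    pairs = []
    for h in h_idx:
        parent = int(topo["bonded_to"].iloc[h])
        if parent < 0 or parent not in id_to_idx:
            raise ConfigurationError(
                f"donor hydrogen atom_id={int(ids[h])} has no attached donor atom"
            )
        pairs.append((h, id_to_idx[parent]))
    return pairs, id_to_idx


def detect_hbonds(
    frame: Frame,
    donors: Selection,
    acceptors: Selection,
    criteria: HBondCriteria = HBondCriteria(),
) -> list[HBondRecord]:
    """All (D, H, A) triples satisfying the criteria in one frame."""
    topo = frame.topology
    box = frame.box
    hb = topo["hbond"].to_numpy()
    ids = topo["atom_id"].to_numpy()
    dh_pairs, id_to_idx = _donor_triples(frame, donors)
    a_idx = np.array(
        [i for i in acceptors.indices if hb[i] == "acceptor"], dtype=int
    )
    if not dh_pairs or len(a_idx) == 0:
        return []
    pos = frame.positions
    apos = np.mod(pos[a_idx] + box / 2.0, box)
    tree = cKDTree(apos, boxsize=box)
    records = []
    cos_dha = np.cos(np.radians(criteria.min_dha_angle))
    cos_hax = np.cos(np.radians(criteria.min_hax_angle))
    for h, d in dh_pairs:
        hp = np.mod(pos[h] + box / 2.0, box)
        for k in tree.query_ball_point(hp, criteria.max_ha_distance):
            a = int(a_idx[k])
            if a == h or a == d:
                continue
            v_ha = minimum_image_displacement(pos[h], pos[a], box)
            dist = np.linalg.norm(v_ha)
            if dist > criteria.max_ha_distance or dist == 0:
                continue
            v_hd = minimum_image_displacement(pos[h], pos[d], box)
            nd = np.linalg.norm(v_hd)
            if nd == 0:
                continue
            # angle D–H···A at H; cutoff θ ≥ min ⇔ cos θ ≤ cos(min)
            c = float(v_hd @ v_ha) / (nd * dist)
            if c > cos_dha + 1e-12:
                continue
            x_id = int(topo["bonded_to"].iloc[a])
            if x_id >= 0 and x_id in id_to_idx:
                x = id_to_idx[x_id]
                v_ah = -v_ha
                v_ax = minimum_image_displacement(pos[a], pos[x], box)
                nx = np.linalg.norm(v_ax)
                if nx > 0:
                    cx = float(v_ah @ v_ax) / (dist * nx)
                    if cx > cos_hax + 1e-12:
                        continue
            records.append(
                HBondRecord(
                    donor_id=int(ids[d]),
                    hydrogen_id=int(ids[h]),
                    acceptor_id=int(ids[a]),
                )
            )
    return records


def hbond_series(
    traj: Trajectory,
    donors: Selection,
    acceptors: Selection,
    criteria: HBondCriteria = HBondCriteria(),
) -> HBondSeries:
    """Per-frame bond records and counts between the two selections."""
    records = [
        detect_hbonds(traj.frame(i), donors, acceptors, criteria)
        for i in range(traj.n_frames)
    ]
    return HBondSeries(
        times=traj.times.copy(),
        counts=np.array([len(r) for r in records], dtype=int),
        records=records,
    )
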