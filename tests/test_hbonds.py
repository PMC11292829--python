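"""Geometric H-bond detection: criteria, oracles, selection semantics."""

import numpy as np
import pandas as pd
import pytest

import bilayerlab as bl
from bilayerlab.core import validate_topology
from bilayerlab.errors import ConfigurationError, ParameterError

from conftest import single_frame_trajectory, small_spec


def polar_frame(atoms, box=(30.0, 30.0, 30.0)):
    """atoms: list of (element, pos, role, hbond, bonded_to_atom_id)."""
    rows, pos = [], []
    for i, (el, p, role, hb, bonded) in enumerate(atoms):
        rows.append(dict(atom_id=i + 1, molecule_id=i + 1 if role == "drug" else 100 + i,
                         element=el, mass=16.0 if el == "O" else 1.0,
                         formal_charge=0, vdw_radius=1.52 if el == "O" else 1.2,
                         role=role, hbond=hb, bonded_to=bonded))
        pos.append(p)
    topo = validate_topology(pd.DataFrame(rows))
    return bl.Frame(time=0.0, box=np.array(box), positions=np.array(pos, dtype=float),
                    topology=topo)


def donor_acceptor_frame(ha_distance, dha_angle=180.0, box=(30.0, 30.0, 30.0)):
    """O–H donor aimed at an acceptor O, with configurable geometry."""
    d_pos = np.array([0.0, 0.0, 0.0])
    h_pos = np.array([0.96, 0.0, 0.0])
    a = np.radians(180.0 - dha_angle)
    a_pos = h_pos + ha_distance * np.array([np.cos(a), np.sin(a), 0.0])
    return polar_frame(
        [
            ("O", d_pos, "drug", "", -1),
            ("H", h_pos, "drug", "donor_h", 1),
            ("O", a_pos, "head", "acceptor", -1),
        ],
        box=box,
    )


def selections(frame):
    donors = bl.resolve_selection(frame, {"role": "drug"})
    acceptors = bl.resolve_selection(frame, {"role": ["head", "tail"]})
    return donors, acceptors


class TestDetect:
    def test_collinear_within_cutoff(self):
        frame = donor_acceptor_frame(1.8)
        records = bl.detect_hbonds(frame, *selections(frame))
        assert len(records) == 1
        rec = records[0]
        assert (rec.donor_id, rec.hydrogen_id, rec.acceptor_id) == (1, 2, 3)

    def test_beyond_distance_cutoff(self):
        frame = donor_acceptor_frame(4.0)
        assert bl.detect_hbonds(frame, *selections(frame)) == []

    def test_bent_geometry_rejected(self):
        frame = donor_acceptor_frame(1.8, dha_angle=100.0)  # < 120° default
        assert bl.detect_hbonds(frame, *selections(frame)) == []
        loose = bl.HBondCriteria(min_dha_angle=90.0)
        assert len(bl.detect_hbonds(frame, *selections(frame), loose)) == 1

    def test_acceptor_neighbor_angle(self):
        """H···A–X angle below its cutoff suppresses the bond."""
        frame = donor_acceptor_frame(1.8)
        # add an acceptor neighbour X nearly collinear with H···A (small angle)
        topo = frame.topology.copy()
        x_pos = frame.positions[2] + np.array([-1.4, 0.0, 0.0])  # toward H
        topo.loc[2, "bonded_to"] = 4
        topo = pd.concat(
            [topo, pd.DataFrame([dict(
                atom_id=4, molecule_id=103, element="S", mass=32.0,
                formal_charge=0, vdw_radius=1.8, role="head", hbond="",
                bonded_to=-1, species="", head_ref=False, tail_terminal=False,
            )])],
            ignore_index=True,
        )
        frame2 = bl.Frame(
            time=0.0, box=frame.box,
            positions=np.vstack([frame.positions, x_pos]),
            topology=validate_topology(topo),
        )
        assert bl.detect_hbonds(frame2, *selections(frame2)) == []
        # X on the far side instead: angle ~180°, bond survives
        frame2.positions[3] = frame.positions[2] + np.array([1.4, 0.0, 0.0])
        assert len(bl.detect_hbonds(frame2, *selections(frame2))) == 1

    def test_minimum_image_detection(self):
        """A pair split across the periodic wall is still detected."""
        frame = donor_acceptor_frame(1.8, box=(8.0, 8.0, 8.0))
        frame.positions[2, 0] -= 8.0  # acceptor wrapped one box to the left
        assert len(bl.detect_hbonds(frame, *selections(frame))) == 1

    def test_donor_without_hydrogen_parent_errors(self):
        frame = donor_acceptor_frame(1.8)
        topo = frame.topology.copy()
        topo.loc[1, "bonded_to"] = -1
        frame2 = bl.Frame(time=0.0, box=frame.box, positions=frame.positions,
                          topology=topo)
        with pytest.raises(ConfigurationError):
            bl.detect_hbonds(frame2, *selections(frame2))

    def test_invalid_criteria(self):
        with pytest.raises(ParameterError):
            bl.HBondCriteria(max_ha_distance=0.0)
        with pytest.raises(ParameterError):
            bl.HBondCriteria(min_dha_angle=200.0)


class TestOracle:
    @pytest.mark.parametrize("seed", range(10))
    def test_all_triples_oracle(self, seed):
        """KD-tree detection equals brute-force evaluation of every
        (donor, H, acceptor) triple, on 10 random seeded instances."""
        rng = np.random.default_rng(1000 + seed)
        box = np.array([14.0, 14.0, 14.0])
        atoms = []
        n_donor, n_acc = 12, 10
        for k in range(n_donor):
            d = rng.uniform(0, 14, size=3)
            h = d + rng.normal(scale=0.6, size=3)
            atoms.append(("O", d, "drug", "", -1))
            atoms.append(("H", h, "drug", "donor_h", len(atoms)))
        for k in range(n_acc):
            atoms.append(("O", rng.uniform(0, 14, size=3), "head", "acceptor", -1))
        frame = polar_frame(atoms, box=box)
        donors, acceptors = selections(frame)
        crit = bl.HBondCriteria(max_ha_distance=3.2, min_dha_angle=110.0)
        fast = {
            (r.donor_id, r.hydrogen_id, r.acceptor_id)
            for r in bl.detect_hbonds(frame, donors, acceptors, crit)
        }
        # brute force over every triple
        topo = frame.topology
        pos = frame.positions
        slow = set()
        from bilayerlab import minimum_image_displacement as mic
        for h in np.flatnonzero((topo["hbond"] == "donor_h").to_numpy()):
            d = int(np.flatnonzero(
                (topo["atom_id"] == topo["bonded_to"].iloc[h]).to_numpy()
            )[0])
            for a in np.flatnonzero((topo["hbond"] == "acceptor").to_numpy()):
                v_ha = mic(pos[h], pos[a], frame.box)
                dist = np.linalg.norm(v_ha)
                if dist > crit.max_ha_distance:
                    continue
                v_hd = mic(pos[h], pos[d], frame.box)
                cosang = v_hd @ v_ha / (np.linalg.norm(v_hd) * dist)
                angle = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
                if angle < crit.min_dha_angle:
                    continue
                slow.add((int(topo["atom_id"].iloc[d]),
                          int(topo["atom_id"].iloc[h]),
                          int(topo["atom_id"].iloc[a])))
        assert fast == slow

    def test_monotonic_in_criteria(self):
        rng = np.random.default_rng(77)
        atoms = []
        for k in range(15):
            d = rng.uniform(0, 14, size=3)
            h = d + rng.normal(scale=0.5, size=3)
            atoms.append(("O", d, "drug", "", -1))
            atoms.append(("H", h, "drug", "donor_h", len(atoms)))
        for k in range(15):
            atoms.append(("O", rng.uniform(0, 14, size=3), "head", "acceptor", -1))
        frame = polar_frame(atoms, box=(14, 14, 14))
        donors, acceptors = selections(frame)
        prev = None
        for cut in (4.0, 3.2, 2.8, 2.0, 1.0):
            n = len(bl.detect_hbonds(
                frame, donors, acceptors, bl.HBondCriteria(max_ha_distance=cut)
            ))
            if prev is not None:
                assert n <= prev
            prev = n
        prev = None
        for ang in (60.0, 100.0, 140.0, 175.0):
            n = len(bl.detect_hbonds(
                frame, donors, acceptors,
                bl.HBondCriteria(max_ha_distance=4.0, min_dha_angle=ang),
            ))
            if prev is not None:
                assert n <= prev
            prev = n


class TestSelectionSymmetry:
    def test_swapping_selections_with_swapped_declarations(self):
        """Exchanging the two selections while swapping donor/acceptor
        declarations accordingly finds the same bond."""
        frame = donor_acceptor_frame(1.8)
        base = {(r.donor_id, r.hydrogen_id, r.acceptor_id)
                for r in bl.detect_hbonds(frame, *selections(frame))}
        # relabel: donor group now lives on the "head" side, acceptor on "drug"
        topo = frame.topology.copy()
        topo.loc[[0, 1], "role"] = "head"
        topo.loc[2, "role"] = "drug"
        swapped = bl.Frame(time=0.0, box=frame.box, positions=frame.positions,
                           topology=topo)
        donors = bl.resolve_selection(swapped, {"role": "head"})
        acceptors = bl.resolve_selection(swapped, {"role": "drug"})
        records = bl.detect_hbonds(swapped, donors, acceptors)
        assert {(r.donor_id, r.hydrogen_id, r.acceptor_id)
                for r in records} == base == {(1, 2, 3)}


class TestSeries:
    def test_static_frames_constant_series(self):
        frame = donor_acceptor_frame(1.8)
        traj = bl.Trajectory(
            times=np.arange(10.0),
            boxes=np.tile(frame.box, (10, 1)),
            positions=np.tile(frame.positions, (10, 1, 1)),
            topology=frame.topology,
        )
        series = bl.hbond_series(traj, *selections(frame))
        assert np.array_equal(series.counts, np.ones(10, dtype=int))
        assert series.summary == dict(min=1, max=1, mean=1.0)

    def test_toggled_pair_alternates(self):
        """Displacing the drug beyond the cutoff on alternate frames yields a
        1/0/1/0 count series."""
        frame = donor_acceptor_frame(1.8)
        pos = []
        for k in range(6):
            p = frame.positions.copy()
            if k % 2 == 1:
                p[:2] += np.array([0.0, 0.0, 6.0])  # move the whole donor away
            pos.append(p)
        traj = bl.Trajectory(
            times=np.arange(6.0), boxes=np.tile(frame.box, (6, 1)),
            positions=np.stack(pos), topology=frame.topology,
        )
        series = bl.hbond_series(traj, *selections(frame))
        assert series.counts.tolist() == [1, 0, 1, 0, 1, 0]

    def test_acceptor_free_system_always_zero(self):
        """A cationic-surfactant-like system with no head acceptors yields a
        count of exactly zero in every frame."""
        spec = small_spec(drug_count=2, water_count=40, head_acceptor=False,
                          head_charge=1, counterion_charge=-1,
                          counterion_element="Br", counterion_radius=1.85)
        frame, topo, _ = bl.build_bilayer(spec)
        traj = single_frame_trajectory(frame)
        donors = bl.resolve_selection(traj, {"role": "drug"})
        acceptors = bl.resolve_selection(traj, {"role": ["head", "tail"]})
        series = bl.hbond_series(traj, donors, acceptors)
        assert np.array_equal(series.counts, np.zeros(1, dtype=int))

    def test_pinned_drugs_bond_every_frame(self):
        """Drugs pinned at H-bond distance from an acceptor bond in every
        frame of a static trajectory (constructed geometry)."""
        atoms = []
        for k in range(4):
            base = np.array([4.0 * k + 2.0, 2.0, 2.0])
            atoms.append(("O", base, "drug", "", -1))
            atoms.append(("H", base + [0.96, 0, 0], "drug", "donor_h", len(atoms)))
            atoms.append(("O", base + [2.76, 0, 0], "head", "acceptor", -1))
        frame = polar_frame(atoms, box=(20, 20, 20))
        traj = bl.Trajectory(
            times=np.arange(5.0), boxes=np.tile(frame.box, (5, 1)),
            positions=np.tile(frame.positions, (5, 1, 1)),
            topology=frame.topology,
        )
        series = bl.hbond_series(traj, *selections(frame))
        assert np.array_equal(series.counts, np.full(5, 4))
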