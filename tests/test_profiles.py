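"""Reference origins, charge/mass binning, sphere–slab partitioning."""

import numpy as np
import pandas as pd
import pytest

import bilayerlab as bl
from bilayerlab.core import validate_topology
from bilayerlab.errors import BinningError, ParameterError
from bilayerlab.profiles import locate_reference_origin

from conftest import single_frame_trajectory, small_spec


def ion_frame(z_values, box=(10.0, 10.0, 20.0), charges=None, waters_z=None):
    """Frame of point ions at given z (x = y = 0), optional water beads."""
    z_values = list(z_values)
    charges = charges if charges is not None else [1] * len(z_values)
    waters_z = list(waters_z or [])
    n = len(z_values) + len(waters_z)
    rows = []
    pos = []
    for i, (z, q) in enumerate(zip(z_values, charges)):
        rows.append(dict(atom_id=i + 1, molecule_id=i + 1, element="Na",
                         mass=23.0, formal_charge=q, vdw_radius=1.0,
                         role="counterion"))
        pos.append([0.0, 0.0, z])
    for j, z in enumerate(waters_z):
        rows.append(dict(atom_id=len(z_values) + j + 1,
                         molecule_id=len(z_values) + j + 1, element="O",
                         mass=18.0, formal_charge=0, vdw_radius=1.52,
                         role="water"))
        pos.append([0.0, 0.0, z])
    topo = validate_topology(pd.DataFrame(rows))
    return bl.Frame(time=0.0, box=np.array(box), positions=np.array(pos),
                    topology=topo)


class TestReferenceOrigin:
    def test_symmetric_builder_origins(self, built):
        """Symmetric build: bilayer midplane at 0; the water body's circular
        centre sits half a box away (the two conventions are complementary)."""
        frame, topo, _ = built
        mid = locate_reference_origin(frame, "bilayer_midplane")
        solv = locate_reference_origin(frame, "solvent_center")
        assert mid == pytest.approx(0.0, abs=1e-9)
        lz = frame.box[2]
        assert abs(abs(solv) - lz / 2) < 1.5  # water body centred at ±Lz/2

    def test_translation_covariance(self, built):
        frame, topo, _ = built
        shifted = bl.Frame(
            time=0.0, box=frame.box, positions=frame.positions + [0, 0, 3.0],
            topology=topo,
        )
        lz = frame.box[2]
        for mode in ("bilayer_midplane", "solvent_center"):
            z0 = locate_reference_origin(frame, mode)
            z1 = locate_reference_origin(shifted, mode)
            wrapped = (z1 - z0 - 3.0 + lz / 2) % lz - lz / 2
            assert wrapped == pytest.approx(0.0, abs=1e-6)

    def test_asymmetric_toy_hand_computed(self):
        """All water above the heads: modes differ by the hand-computed offset."""
        frame = ion_frame([], box=(10, 10, 40), waters_z=[8.0, 12.0])
        heads = ion_frame([0.0], box=(10, 10, 40))
        # combine: one head at z=-5 and z=+5, waters at 8 and 12
        rows = pd.concat(
            [
                heads.topology.assign(role="head", atom_id=[100]),
                frame.topology.assign(atom_id=[101, 102]),
            ]
        ).reset_index(drop=True)
        topo = validate_topology(rows)
        pos = np.array([[0, 0, -5.0], [0, 0, 8.0], [0, 0, 12.0]])
        pos2 = np.array([[0, 0, 5.0], [0, 0, 8.0], [0, 0, 12.0]])
        f1 = bl.Frame(time=0, box=(10, 10, 40), positions=pos, topology=topo)
        f2 = bl.Frame(time=0, box=(10, 10, 40), positions=pos2, topology=topo)
        assert locate_reference_origin(f1, "bilayer_midplane") == pytest.approx(-5.0)
        assert locate_reference_origin(f2, "bilayer_midplane") == pytest.approx(5.0)
        # circular mean of two waters far from the wrap: plain midpoint
        assert locate_reference_origin(f1, "solvent_center") == pytest.approx(10.0)


class TestChargeDensity:
    def test_single_ion_bin_value(self):
        frame = ion_frame([2.5], box=(10, 10, 20))
        traj = single_frame_trajectory(frame)
        prof = bl.charge_density_profile(traj, dz=1.0, z0=0.0)
        idx = np.flatnonzero(prof.values)
        assert len(idx) == 1
        assert prof.edges[idx[0]] == pytest.approx(2.0)
        assert prof.values[idx[0]] == pytest.approx(1.0 / (10 * 10 * 1.0))

    def test_neutral_system_integrates_to_zero_exactly(self, built):
        frame, topo, _ = built
        traj = single_frame_trajectory(frame)
        prof = bl.charge_density_profile(traj, dz=0.5, z0=0.0)
        total = (prof.values * prof.dz * frame.box[0] * frame.box[1]).sum()
        assert total == 0.0

    def test_brute_force_binning_oracle(self):
        """500 random charges: per-bin values equal a naive per-atom loop."""
        rng = np.random.default_rng(17)
        z = rng.uniform(-10, 10, size=500)
        q = rng.choice([-2, -1, 1, 2], size=500)
        frame = ion_frame(z, box=(12, 9, 20), charges=q)
        traj = single_frame_trajectory(frame)
        dz = 0.5
        prof = bl.charge_density_profile(traj, dz=dz, z0=0.0)
        expected = np.zeros(len(prof.values))
        for zi, qi in zip(z, q):
            k = int((zi + 10.0) // dz)
            expected[min(k, len(expected) - 1)] += qi
        expected /= 12 * 9 * dz
        assert np.allclose(prof.values, expected, atol=1e-12)

    def test_bad_bin_widths(self):
        frame = ion_frame([0.0])
        traj = single_frame_trajectory(frame)
        with pytest.raises(ParameterError):
            bl.charge_density_profile(traj, dz=0.0, z0=0.0)
        with pytest.raises(BinningError):
            bl.charge_density_profile(traj, dz=100.0, z0=0.0)

    def test_mirror_symmetric_input_gives_mirror_profile(self):
        """A z-mirrored charge arrangement yields a profile equal to its own
        mirror (the symmetry the bilayer systems show on average)."""
        rng = np.random.default_rng(23)
        z = rng.uniform(0.25, 9.75, size=200)
        zs = np.concatenate([z, -z])
        q = np.concatenate([np.ones(200), np.ones(200)]).astype(int)
        frame = ion_frame(zs, box=(10, 10, 20), charges=q)
        prof = bl.charge_density_profile(
            single_frame_trajectory(frame), dz=0.5, z0=0.0
        )
        assert np.allclose(prof.values, prof.values[::-1], atol=1e-12)
        sym = prof.symmetrized()
        assert np.allclose(sym.values, prof.values)


class TestSphereSlab:
    def test_slab_contains_sphere(self):
        v = bl.sphere_slab_volume(2.0, -5.0, 5.0, 0.0)
        assert v == pytest.approx(4.0 / 3.0 * np.pi * 8.0)

    def test_half_space_through_center(self):
        v = bl.sphere_slab_volume(2.0, 0.0, 100.0, 0.0)
        assert v == pytest.approx(2.0 / 3.0 * np.pi * 8.0)

    def test_cap_closed_form(self):
        # cap of height 0.5 on a unit sphere: V = π h²(3r−h)/3 = 5π/24
        full = 4.0 / 3.0 * np.pi
        v = bl.sphere_slab_volume(1.0, -1.0, -0.5, 0.0)
        assert v == pytest.approx(np.pi * 0.25 * 2.5 / 3.0)
        assert full - bl.sphere_slab_volume(1.0, -1.0, 0.5, 0.0) == pytest.approx(
            5 * np.pi / 24
        )

    def test_disjoint_is_zero(self):
        assert bl.sphere_slab_volume(1.0, 5.0, 6.0, 0.0) == 0.0

    def test_invalid_inputs(self):
        with pytest.raises(ParameterError):
            bl.sphere_slab_volume(-1.0, 0.0, 1.0)
        with pytest.raises(ParameterError):
            bl.sphere_slab_volume(1.0, 2.0, 1.0)


def mass_frame(centers_z, radii, masses, box=(10.0, 10.0, 20.0)):
    rows = []
    pos = []
    for i, (z, r, m) in enumerate(zip(centers_z, radii, masses)):
        rows.append(dict(atom_id=i + 1, molecule_id=i + 1, element="C",
                         mass=m, formal_charge=0, vdw_radius=r, role="drug"))
        pos.append([0.0, 0.0, z])
    topo = validate_topology(pd.DataFrame(rows))
    return bl.Frame(time=0.0, box=np.array(box), positions=np.array(pos),
                    topology=topo)


class TestMassDensity:
    def test_atom_fully_inside_one_slab(self):
        frame = mass_frame([2.5], [0.4], [12.0])
        traj = single_frame_trajectory(frame)
        sel = bl.resolve_selection(traj, {"role": "drug"})
        prof = bl.mass_density_profile(traj, sel, dz=1.0, z0=0.0)
        idx = np.flatnonzero(prof.values)
        assert len(idx) == 1
        assert prof.values[idx[0]] == pytest.approx(12.0 / (10 * 10 * 1.0))

    @pytest.mark.parametrize("dz", [0.25, 0.5, 1.0, 2.0])
    def test_mass_conservation_all_widths(self, dz):
        """Σ value·binvolume equals the total selected mass to 1e-6 relative,
        for every bin width, including spheres crossing the z-boundary."""
        rng = np.random.default_rng(31)
        n = 40
        z = rng.uniform(-10, 10, size=n)  # some spheres wrap
        r = rng.uniform(0.3, 2.5, size=n)
        m = rng.uniform(1.0, 100.0, size=n)
        frame = mass_frame(z, r, m)
        traj = single_frame_trajectory(frame)
        sel = bl.resolve_selection(traj, {"role": "drug"})
        prof = bl.mass_density_profile(traj, sel, dz=dz, z0=0.0)
        total = (prof.values * prof.dz * 100.0).sum()
        assert total == pytest.approx(m.sum(), rel=1e-6)

    def test_atom_on_bin_edge_splits_half_half(self):
        frame = mass_frame([2.0], [0.5], [10.0])
        traj = single_frame_trajectory(frame)
        sel = bl.resolve_selection(traj, {"role": "drug"})
        prof = bl.mass_density_profile(traj, sel, dz=1.0, z0=0.0)
        idx = np.flatnonzero(prof.values)
        assert len(idx) == 2
        assert prof.values[idx[0]] == pytest.approx(prof.values[idx[1]])

    def test_refinement_consistency(self):
        """Halving Δz leaves the mass integrated over any fixed aligned
        interval unchanged (vdW partition telescopes exactly)."""
        rng = np.random.default_rng(37)
        z = rng.uniform(-9, 9, size=25)
        r = rng.uniform(0.3, 2.0, size=25)
        m = rng.uniform(1.0, 50.0, size=25)
        frame = mass_frame(z, r, m)
        traj = single_frame_trajectory(frame)
        sel = bl.resolve_selection(traj, {"role": "drug"})
        coarse = bl.mass_density_profile(traj, sel, dz=1.0, z0=0.0)
        fine = bl.mass_density_profile(traj, sel, dz=0.5, z0=0.0)
        agg = fine.values.reshape(-1, 2).mean(axis=1)
        assert np.allclose(agg, coarse.values, rtol=1e-9, atol=1e-12)

    def test_drug_profile_from_builder(self):
        spec = small_spec(drug_count=3, water_count=60)
        frame, topo, _ = bl.build_bilayer(spec)
        traj = single_frame_trajectory(frame)
        sel = bl.resolve_selection(traj, {"role": "drug"})
        prof = bl.mass_density_profile(traj, sel, dz=0.5)
        total = (prof.values * prof.dz * frame.box[0] * frame.box[1]).sum()
        expected = topo.loc[topo["role"] == "drug", "mass"].sum()
        assert total == pytest.approx(expected, rel=1e-6)
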