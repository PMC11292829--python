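"""Shared fixtures: all inputs are generated programmatically at test time."""

import numpy as np
import pandas as pd
import pytest

from bilayerlab import BilayerSpec, Frame, Trajectory, build_bilayer
from bilayerlab.core import validate_topology


def small_spec(**overrides) -> BilayerSpec:
    """Desk-scale bilayer: same architecture as the full system, fewer atoms."""
    params = dict(
        n_surfactants_per_leaflet=9,
        water_count=150,
        box_xy=(32.0, 32.0),
        box_z=64.0,
        head_separation=32.0,
        seed=0,
    )
    params.update(overrides)
    return BilayerSpec(**params)


@pytest.fixture
def spec():
    return small_spec()


@pytest.fixture
def built(spec):
    return build_bilayer(spec)


@pytest.fixture
def toy_topology():
    """Two 2-atom surfactants plus one counterion and one water."""
    return validate_topology(
        pd.DataFrame(
            dict(
                atom_id=[1, 2, 3, 4, 5, 6],
                molecule_id=[1, 1, 2, 2, 3, 4],
                element=["S", "C", "S", "C", "Na", "O"],
                mass=[97.0, 42.0, 97.0, 42.0, 22.99, 18.0],
                formal_charge=[-1, 0, -1, 0, 1, 0],
                vdw_radius=[1.8, 1.7, 1.8, 1.7, 2.27, 1.52],
                role=["head", "tail", "head", "tail", "counterion", "water"],
            )
        )
    )


def single_frame_trajectory(frame: Frame) -> Trajectory:
    return Trajectory(
        times=np.array([frame.time]),
        boxes=frame.box[None, :],
        positions=frame.positions[None, :, :],
        topology=frame.topology,
    )
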