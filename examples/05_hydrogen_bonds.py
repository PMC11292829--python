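"""Hydrogen bonds between drug donors and surfactant head acceptors.

Detection is geometric: H···A within 2.8 Å, donor–H···acceptor angle ≥ 120°,
H···acceptor–neighbour angle ≥ 90° (all configurable), under minimum-image
distances. Donor/acceptor identity comes from sidecar tags, never from
element guessing, so a cationic-surfactant system whose heads carry no
donors or acceptors yields exactly zero bonds — mirroring the published
contrast between the anionic and cationic systems.
"""

import numpy as np
import pandas as pd

import bilayerlab as bl
from bilayerlab.core import validate_topology

# --- constructed pinned geometry: 4 drugs, each aimed at a head oxygen ---
rows, pos = [], []
for k in range(4):
    base = np.array([6.0 * k + 3.0, 3.0, 3.0])
    mol = k + 1
    rows.append(dict(atom_id=len(rows) + 1, molecule_id=mol, element="O",
                     mass=16.0, formal_charge=0, vdw_radius=1.52, role="drug"))
    pos.append(base)
    rows.append(dict(atom_id=len(rows) + 1, molecule_id=mol, element="H",
                     mass=1.0, formal_charge=0, vdw_radius=1.2, role="drug",
                     hbond="donor_h", bonded_to=len(rows)))
    pos.append(base + [0.96, 0.0, 0.0])
    rows.append(dict(atom_id=len(rows) + 1, molecule_id=50 + k, element="O",
                     mass=16.0, formal_charge=-1, vdw_radius=1.52,
                     role="head", hbond="acceptor"))
    pos.append(base + [0.96 + 1.9, 0.0, 0.0])  # H···A = 1.9 Å, collinear
topo = validate_topology(pd.DataFrame(rows))
frame = bl.Frame(time=0.0, box=(30.0, 30.0, 30.0), positions=np.array(pos),
                 topology=topo)
traj = bl.Trajectory(times=np.arange(3.0), boxes=np.tile(frame.box, (3, 1)),
                     positions=np.tile(frame.positions, (3, 1, 1)), topology=topo)
donors = bl.resolve_selection(traj, {"role": "drug"})
acceptors = bl.resolve_selection(traj, {"role": "head"})
series = bl.hbond_series(traj, donors, acceptors)
print("pinned drug–head pairs :", series.summary, "(4 constructed bonds)")
tight = bl.HBondCriteria(max_ha_distance=1.5)
print("with a 1.5 Å cutoff    :",
      bl.hbond_series(traj, donors, acceptors, tight).summary)

# --- builder-based cationic-like system: no acceptors anywhere -----------
spec_cat = bl.BilayerSpec.ctab_like(
    n_surfactants_per_leaflet=20, water_count=200, drug_count=6,
    box_xy=(35.0, 35.0), seed=8,
)
frame_c, topo_c, _ = bl.build_bilayer(spec_cat)
traj_c = bl.Trajectory(
    times=[0.0], boxes=frame_c.box[None], positions=frame_c.positions[None],
    topology=topo_c,
)
donors_c = bl.resolve_selection(traj_c, {"role": "drug"})
acceptors_c = bl.resolve_selection(traj_c, {"role": ["head", "tail"]})
series_c = bl.hbond_series(traj_c, donors_c, acceptors_c)
print("cationic-like system   :", series_c.summary, "(no head acceptors → 0)")
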