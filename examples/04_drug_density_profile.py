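"""vdW-partitioned mass density profile of drug molecules along z.

Each drug atom's van der Waals sphere is apportioned exactly among the slabs
it intersects (spherical-cap volumes), so the profile integrates to the
total drug mass to machine precision regardless of bin width — the check
printed below.
"""

import numpy as np

import bilayerlab as bl

spec = bl.BilayerSpec(
    n_surfactants_per_leaflet=30, water_count=400, drug_count=8,
    box_xy=(40.0, 40.0), seed=6,
)
frame, topo, _ = bl.build_bilayer(spec)
traj = bl.Trajectory(
    times=[0.0], boxes=frame.box[None], positions=frame.positions[None],
    topology=topo,
)
drugs = bl.resolve_selection(traj, {"role": "drug"})
area = frame.box[0] * frame.box[1]
total = topo.loc[drugs.indices, "mass"].sum()

for dz in (0.25, 0.5, 1.0):
    prof = bl.mass_density_profile(traj, drugs, dz=dz, origin_mode="bilayer_midplane")
    integral = (prof.values * prof.dz * area).sum()
    print(f"Δz = {dz:4.2f} Å: ∫ρ dV = {integral:9.3f} amu "
          f"(total drug mass {total:.3f}, rel. err {abs(integral/total-1):.1e})")

prof = bl.mass_density_profile(traj, drugs, dz=1.0)
occupied = prof.centers[prof.values > 0]
print(f"drugs occupy z ∈ [{occupied.min():.1f}, {occupied.max():.1f}] Å "
      "from the bilayer midplane")
# The z-extent of the drug density is how the published profiles distinguish
# interface-localized from delocalized drugs.
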