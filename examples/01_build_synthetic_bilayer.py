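"""Build a synthetic ionic-surfactant bilayer and inspect its ground truth.

The builder stands in for an MD engine: 125 coarse surfactants per leaflet
(anionic heads on mirrored planes, straight tail chains at assigned
tilt/azimuth), auto-matched counterions and a water slab, all packed without
atomic overlap (minimum distance 0.6 × the summed vdW radii, emulating the
packing efficiency factor used to set up the simulated systems).
"""

import numpy as np

import bilayerlab as bl

spec = bl.BilayerSpec.sds_like(seed=1)  # 250 surfactants, 4962 waters
frame, topology, manifest = bl.build_bilayer(spec)

print(f"atoms: {frame.n_atoms}, box: {frame.box} Å")
print(f"net formal charge: {topology['formal_charge'].sum()} e (neutral system)")
counts = topology["role"].value_counts()
print("composition:", {k: int(v) for k, v in counts.items()})
tilts = np.array(manifest.tilt_deg)
print(
    f"assigned tilt: mean {tilts.mean():.2f}°, spread {tilts.std():.2f}° "
    f"(drawn from a folded normal at 47.416° ± 6.73°)"
)
# The manifest records the realized per-molecule angles exactly, so any
# orientation analysis can be checked against known ground truth.
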