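"""Recover surfactant tilt and rotational angles from a synthetic trajectory.

A 50-frame trajectory resamples every surfactant's orientation each frame
(emulating thermal fluctuation about the mean). The analysis fits a plane to
each leaflet's head atoms per frame, measures each molecule's tilt θ (angle
between the head→tail vector and the plane normal, folded to [0°, 90°]) and
rotational angle φ (in-plane projection vs the x-axis, folded to [0°, 180°)),
and reports the time average of frame means with the std of that series —
the same summary convention the published per-system table uses.
"""

import bilayerlab as bl

spec = bl.BilayerSpec(
    n_surfactants_per_leaflet=50, water_count=300, seed=3
)  # tilt 47.416° ± 6.73°, azimuth 89.114° ± 3.56° (pure-anionic defaults)
traj, manifest = bl.generate_orientation_trajectory(spec, n_frames=50, seed=4)
series = bl.orientation_summary(traj)

print(f"frames: {traj.n_frames}, surfactants: {len(series.molecule_ids)}")
print(f"tilt:       {series.theta_mean:6.3f}° (std of frame means {series.theta_std:.3f}°)")
print(f"rotational: {series.phi_mean:6.3f}° (std of frame means {series.phi_std:.3f}°)")
print("generator truth: tilt 47.416°, rotational 89.114°")
# The recovered means approach the generator's folded-normal means as
# n_molecules × n_frames grows; the residual is pure sampling error.
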