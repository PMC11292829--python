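# bilayerlab

Post-processing observables for ionic-surfactant **bilayer trajectories** —
the quantities used to characterize how drug molecules interact with
anionic (SDS-type) and cationic (CTAB-type) surfactant bilayers in water —
together with a **synthetic bilayer/trajectory generator** whose ground
truth is exactly known, so every analysis stage can be validated without
running molecular dynamics.

## Who it is for

Researchers analysing membrane/surfactant MD output (multi-model PDB or XYZ
plus a per-atom topology table) who need reproducible, testable
implementations of the standard bilayer observables; and method developers
who want a controllable stand-in for engine trajectories when validating
analysis code.

## What it computes

- **Orientation angles.** Per leaflet and frame, a total-least-squares plane
  is fitted to the declared head-group atoms. Each surfactant's orientation
  vector **v** runs from its head-reference centroid to its tail-terminal
  atom (minimum-image corrected). The *tilt angle*
  θ = arccos |v̂ · n̂| ∈ [0°, 90°] measures inclination from the leaflet
  normal n̂; the *rotational (azimuthal) angle* φ ∈ [0°, 180°) is the angle
  between v's in-plane projection and the x-axis. Summaries report the time
  average of per-frame molecular means and the standard deviation of that
  frame-mean time series.
- **Charge density ρ(z)** from per-atom *formal charges* (zero-charge atoms
  ignored), point-assigned to uniform slabs relative to a reference origin
  (solvent centre by circular mean, or bilayer midplane), in e/Å³.
- **Electrostatic potential.** Planar geometry:
  φ(z) = −(1/ε_s ε₀) ∫_{z_m}^{z} (z − z′) ρ(z′) dz′ — the collapsed double
  integral of the 1-D Poisson equation, zero at the solvent reference plane
  z_m; radial geometry: Gauss's law E(r) = q_enc(r)/(4π ε_s ε₀ r²) with
  φ(r) = ∫_r^{R_max} E dr (far-field zero). Volts out; ε_s configurable
  (default 1, since explicit charges carry their own screening).
- **Mass density profiles** with exact van-der-Waals partitioning: the
  fraction of each atom's vdW sphere volume intersecting a slab
  (spherical-cap closed form) times its mass, divided by slab volume — so
  profiles integrate to the selected mass to machine precision.
- **Hydrogen bonds** between two selections by geometric criteria
  (H···A ≤ 2.8 Å, ∠D–H···A ≥ 120°, ∠H···A–X ≥ 90° by default), donors and
  acceptors declared in the topology sidecar; per-frame counts and records.
- **Diffusion coefficients** via the Einstein relation: periodic unwrapping,
  sliding-origin MSD of molecular centres of mass (FFT), through-origin fit
  D = slope/(2d) on a 10–50% lag window, in m²/s, with R² diagnostics;
  1-D (z), 2-D (xy) and 3-D modes.
- **Synthetic systems**: two-leaflet bead-chain bilayers at the simulated
  compositions (250 anionic surfactants + 4962 waters, or 228 cationic +
  2394 waters), configurable tilt/azimuth distributions, overlap-free
  placement (min distance = 0.6 × summed vdW radii), counterions, drug
  templates with H-bond donors/acceptors, Brownian dynamics at known D, and
  analytic charge fixtures (capacitor, single plane, Gaussian layers) with
  closed-form potentials.

## Worked example

```python
import bilayerlab as bl

spec = bl.BilayerSpec(n_surfactants_per_leaflet=50, water_count=300, seed=3)
traj, manifest = bl.generate_orientation_trajectory(spec, n_frames=50, seed=4)
series = bl.orientation_summary(traj)
print(f"tilt {series.theta_mean:.3f}° ± {series.theta_std:.3f}°")
print(f"rotational {series.phi_mean:.3f}° ± {series.phi_std:.3f}°")
```

prints

```
tilt 47.499° ± 0.711°
rotational 89.185° ± 0.346°
```

The generator drew every molecule's tilt from a folded normal with mean
47.416° and spread 6.73° and its azimuth from one at 89.114° ± 3.56° (the
pure-anionic defaults), redrawing each frame; the analysis recovers those
means from the coordinates alone to within sampling error (±6.73/√5000 ≈
0.1° here), and the ± values are the standard deviation of the frame-mean
time series. The `examples/` directory has one short script per capability
(building, orientation, charge/potential, drug density, H-bonds, diffusion).

A thin CLI mirrors the library: `bilayerlab build-synthetic`,
`analyze-orientation`, `analyze-density`, `analyze-potential`,
`analyze-hbonds`, `analyze-diffusion`, and `run-all` with a YAML config;
outputs are TSV profiles/series plus JSON summaries and a checksummed run
manifest.

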