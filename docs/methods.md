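# Methods

This note documents the models, conventions and numerical choices behind
bilayerlab, and what its validation does and does not demonstrate.

## Data model and units

Coordinates are Å, times ps, masses amu, charges integer multiples of the
elementary charge e; densities are reported in e/Å³ and amu/Å³ and
potentials in volts (conversion constants from SI CODATA values:
e/(ε₀·Å) = 180.95 V per e/Å, Coulomb constant 14.3996 V·Å/e). Boxes are
orthorhombic only — the simulated systems this package targets use
orthorhombic cells — and triclinic input is rejected explicitly. Topology
(mass, formal charge, vdW radius, role tag, H-bond tags, head/tail
declarations) is frame-invariant and lives in a sidecar table, because PDB
files carry none of it reliably; per-atom vdW radii default to the Bondi
set keyed by element. Analyses that average over frames require a constant
box; constant-pressure box fluctuations are an engine-level concern outside
this package's scope.

## Orientation angles

The surface plane of each leaflet is the total-least-squares (orthogonal
distance) plane through the leaflet's declared head-reference atoms,
computed by SVD; molecules are assigned to leaflets by head z relative to
the mean head z each frame. Two planes per frame (one per leaflet) rather
than one global plane: the leaflets are independent interfaces, and a joint
fit through both head sheets would be degenerate. The orientation vector is
the head-reference centroid → tail-terminal vector under minimum image
(valid while a molecule's true extent is below half the box per axis).

Tilt is folded to [0°, 90°] via the absolute dot product — reported bilayer
tilt means of roughly 40–48° imply an unsigned angle. The rotational angle
is folded to [0°, 180°) (a line convention; a full 0–360° mode exists behind
a flag): head→tail and tail→head describe the same in-plane direction, and
near-uniform azimuths fold to means near 90°, matching the reported values.
Per-frame means can be taken after folding each molecule's angle (default)
or before folding; both orders are implemented. Summary statistics follow
the time-series convention: the mean is the time average of per-frame
molecular means and the quoted spread is the standard deviation of that
frame-mean series (population, ddof = 0), not the pooled per-molecule
spread. Molecules whose vector is parallel to the plane normal have no
defined azimuth; they are skipped and logged, never silently zeroed.

## Density profiles

Profiles bin along z relative to a reference origin recomputed per frame:
`solvent_center` is the circular mean of water-atom z under periodicity
(robust to the solvent slab wrapping across the boundary), and
`bilayer_midplane` is the arithmetic mean of head-atom z. For a bilayer
built at the cell centre the two origins are complementary — the solvent
body's centre sits exactly half a box from the bilayer midplane — and both
are exposed because published figures use both conventions. The requested
bin width is snapped to Lz/round(Lz/Δz) so bins tile the box exactly; this
is what makes the conservation identities exact rather than approximate.

Charge density assigns each nonzero formal charge wholly to the bin holding
its wrapped z (point assignment), then divides by bin volume and averages
over frames. Mass density instead apportions each atom's vdW sphere among
slabs by the exact sphere–slab intersection volume (spherical-cap formula
V_cap(h) = πh²(3r − h)/3), with wrapped images handling spheres crossing the
periodic boundary. The two conventions deliberately differ — formal charges
are point bookkeeping, mass is a volume-filling property — and the vdW
partition telescopes exactly under bin refinement, so integrated slab masses
are invariant to Δz at machine precision.

## Electrostatic potentials

Planar: the 1-D Poisson equation collapses to
φ(z) = −(1/ε_s ε₀)∫_{z_m}^{z}(z − z′)ρ(z′)dz′ with φ(z_m) = 0 *and*
φ′(z_m) = 0 — the gauge appropriate when z_m lies in bulk solvent where the
field vanishes by symmetry. Quadrature is midpoint on the charge-profile
bins via cumulative moment sums; z_m snaps to the nearest bin centre, and
the reference bin's own charge is excluded (exact when ρ(z_m) = 0, i.e.
whenever the reference plane is placed in charge-free bulk, which the gauge
presumes anyway). With that placement, the discrete second difference of φ
reproduces the binned ρ *exactly*, and a discrete parallel-plate fixture
matches its closed form to rounding error. ε_s defaults to 1: with explicit
charged species there is no implicit dielectric; it is exposed because some
workflows apply a solvent permittivity. Note that with formal charges only
(waters carry zero), computed potential magnitudes are much larger than
engine potentials computed from partial charges — shapes, not magnitudes,
are comparable.

Radial: the spherically averaged field follows Gauss's law,
E(r) = q_enc(r)/(4π ε_s ε₀ r²) with E(0) = 0, and φ integrates E inward from
the outermost shell (trapezoid), so φ(R_max) = 0. The printed forms of the
original radial equations are not recoverable from the source text; this is
the standard construction the surrounding prose describes.

## Hydrogen bonds

A bond is a (D, H, A) triple with H···A ≤ 2.8 Å, ∠D–H···A ≥ 120° and, when
the acceptor declares a bonded neighbour X, ∠H···A–X ≥ 90° — the
Maestro-style defaults, fully configurable since no criteria are published
for these systems. Identity comes from sidecar tags (`donor_h` hydrogens
with a `bonded_to` parent; `acceptor` atoms), not element perception: the
coarse synthetic molecules need explicit declarations, and real topologies
are better served by explicit choices than guesses. All geometry is
minimum-image; candidate pairs come from a periodic KD-tree and are verified
exactly. Water-mediated bridges are not counted.

## Diffusion

Coordinates are unwrapped by accumulating nearest-image per-frame
increments (exact while true displacements stay below half the box per
axis; a step beyond 45% of the box triggers an ambiguity warning). The MSD
averages over all sliding time origins (FFT autocorrelation algorithm) and
over molecules, using mass-weighted molecular centres — drugs diffuse as
molecules. Lags are kept to 25% of the trajectory by default: longer lags
average over too few independent origins and only add noise. The Einstein
fit is a through-origin least-squares line on the 10–50% window of the lag
range, D = slope/(2d) converted Å²/ps → m²/s (×10⁻⁸); through-origin
because MSD(0) = 0 identically, and because it makes the R² diagnostic
actually flag ballistic (quadratic) curves, which an intercept fit fits
deceptively well. R² < 0.9 attaches a warning without suppressing the
value. The 1-D (z) mode measures mobility along the bilayer normal; 2-D
(xy) and 3-D modes decompose additively.

## Synthetic systems: what they emulate, and what they do not

Surfactants are coarse bead-chains — one charged head bead on its leaflet
plane plus a straight run of tail beads at the molecule's assigned
(tilt, azimuth) — not atomistic amphiphiles. The analyses consume only
positions, charges, radii and role tags, so coarse geometry loses nothing
while making ground truth exact. Default compositions follow the simulated
systems: 250 anionic surfactants with 4962 waters in a ~52 × 52 × 102 Å
cell (sodium-like counterions), or 228 cationic with 2394 waters and
bromide-like ions; tilt/azimuth defaults are the published per-system means
and spreads (tilt drawn from a normal folded into [0°, 90°], azimuth into
[0°, 180°), or uniform). Waters are single neutral beads; drugs are small
rigid templates with declarable donors/acceptors and optional zwitterionic
(±1) charges.

Placement enforces a minimum distance of overlap_factor × (sum of vdW
radii) between all non-covalently-bonded atoms, with overlap_factor = 0.6
emulating the engine builder's packing efficiency factor behaviourally (the
engine scales radii inside its builder; the emulation constrains distances —
similar effect, not the same algorithm). Tail beads carry a small marker
radius (0.5 Å) by default: they trace the chain axis, and a full carbon
radius would forbid realistic tilt spreads at the simulated areal density
for straight rigid chains. A surfactant whose assigned orientation collides
is redrawn (bounded retries, then a packing error reporting achieved
density); the *realized* angles are what the manifest records, so
manifest-based recovery is exact, while the redraws slightly reshape the
realized angle sample relative to the target distribution. For
distribution-level recovery the orientation-trajectory generator redraws
every molecule's angles each frame *without* packing constraints — emulating
thermal orientational fluctuation, and making the time-and-ensemble average
an unbiased estimator of the folded-distribution mean.

Brownian dynamics displaces molecules rigidly with independent Gaussian
steps of per-axis variance 2·D·dt, D looked up per role (absent roles are
frozen); there is no inertia, no interaction, no internal vibration. This
suffices for MSD estimators and profile averaging, and deliberately nothing
else. Passing tests on these systems demonstrates the *analysis* code is
correct against exact ground truth; it does not validate force fields,
sampling, or any property of real bilayers.

Validation therefore runs at desk scale by design: orientation recovery
uses 228–250 surfactants × 200 frames (standard error ≈ 0.03° on the tilt
mean), diffusion recovery 50 molecules × 10⁴ 1-ps steps (fit scatter a few
percent), and the analytic electrostatics fixtures are exact closed forms.
Published headline numbers from 20 ns engine trajectories are used as
generator parameters for recovery tests, not re-simulated.

## Degenerate inputs and tie-breaks

Collinear or <3 plane points raise a degenerate-fit error; zero orientation
vectors raise an undefined-angle error; plane normals orient to positive z
(then x, then y). Atoms exactly on a bin edge belong to the upper bin for
point charge assignment, and split 50/50 under vdW partitioning by
symmetry of the cap formula. E(0) = 0 at the radial origin. Empty
selections warn rather than fail; an acceptor-free selection legitimately
yields zero H-bonds (the cationic-surfactant case). The duplicated-fixture
non-neutral capacitor is refused because its closed form assumes
neutrality.

## Known limitations

Orthorhombic constant boxes only; no DCD/XTC readers (extension point: any
function returning a `Trajectory`); charge profiles ignore polarization
(formal charges only — potential magnitudes are not comparable to
partial-charge engine output); H-bond lifetimes, order parameters and
finite-size diffusion corrections are out of scope; the builder's straight
rigid chains cannot represent chain melting or gauche defects, and its
packing criterion is a behavioural emulation of the engine builder, not a
reimplementation.
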