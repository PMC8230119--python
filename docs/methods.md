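# Methods

This note documents the models, conventions and numerical choices behind
`yarivmd`, and what the synthetic validation does and does not establish.

## Body-frame free-energy-like maps

The map protocol assumes the reference molecule is rigid enough that a
single rigid-body fit defines a meaningful body frame (for the Yariv
reagent this is justified by its conjugated, planar core). Every frame is
superposed on a reference frame (default: frame 0) by an unweighted
least-squares fit over a selection (default: all non-hydrogen atoms of
molecule 0). Mass weighting is deliberately omitted — the fit is geometric,
and the choice is switchable. The rotation comes from
`scipy.spatial.transform.Rotation.align_vectors`, which always returns a
proper rotation (reflection branches are corrected by the standard
determinant fix and logged). Per-frame RMSD is recomputed from the
transformed coordinates rather than from the solver residual, which is
poorly conditioned near zero; a rigid-rotor trajectory yields RMSD below
1e-9 Å.

Selected-atom positions from all frames are pooled into cubic voxels
(default edge 1 Å, half-open intervals, index = ⌊(x − origin + h/2)/h⌋,
origin at the center of voxel (0,0,0)). Each voxel count `P_i` maps to

    A_i = −kT ln(P_i)          (zero-count voxels masked)

with the global minimum subtracted so min(A) = 0. Two consequences are
worth stating explicitly:

* **Normalisation is irrelevant.** Scaling all counts by any positive
  constant shifts every A_i equally and cancels in the min-subtraction;
  raw counts therefore enter the log directly. This is asserted as a
  property test.
* **Empty voxels are masked, not capped.** −kT ln 0 is undefined; exports
  write the sentinel 999.0 so external viewers exclude those voxels from
  any sensible isolevel.

The temperature for kT defaults to 300 K (kT = 2.494 kJ/mol) and is
recorded in the map metadata; it only scales the map, never its topology.

Low-A regions are connected components (26-connectivity,
`scipy.ndimage.label`) of {A ≤ level}, reported with unweighted
voxel-center centroid, volume, and depth (the minimum A inside the region).
Isolevel volume is a voxel count times h³ — no marching-cubes surface is
computed; rendering is delegated to external viewers via the Gaussian cube
(Bohr units) and OpenDX (Å) writers. Both formats round-trip through the
package's own readers to 1e-5.

`harmonic_fit` recovers a well curvature by ordinary least squares of A on
½r² over unmasked voxels within 2σ of the Boltzmann-weighted centroid
(σ² estimated from the map's own second moment). At 10⁶ samples of a
κ = 1 kJ/mol/Å² well the fit is within a few percent of κ; finite-voxel
averaging biases it slightly low.

## Trajectory handling

Coordinates are angstrom internally; mdtraj backs all format I/O and its
nanometre convention is converted at the boundary. XTC is a compressed
format with 10⁻³ nm precision, so round-trips are exact to 0.01 Å (tested
at that tolerance); PDB coordinates carry three decimals. Bonds come from
CONECT records or residue templates; files with neither get distance-based
perception (d < 1.3 × the sum of covalent radii). The molecule partition is
always the connected components of the bond graph.

`make_whole` unwraps each molecule by walking its bond graph and shifting
every atom to the minimum image relative to its placed neighbour, then
re-images whole molecules relative to molecule 0's centroid. It is
idempotent, commutes with frame reordering (it is strictly per-frame), and
warns with a frame list if any bond still exceeds half the shortest box
edge.

## Interaction classifiers

The geometric thresholds are **not** derived from any simulation; they
follow common structural-chemistry practice and are exposed on a single
`Thresholds` object, and every record carries its raw metrics so users can
re-threshold post hoc:

| interaction | criteria (defaults) |
|---|---|
| π-π parallel | centroid distance ≤ 5.5 Å, interplanar angle ≤ 30°, lateral offset ≤ 2.5 Å |
| π-π T-shaped | distance ≤ 6.0 Å, angle ≥ 60° |
| CH/π | H···centroid ≤ 3.0 Å, C–H···centroid angle ≥ 120°, in-plane offset of H ≤ 1.5 Å |
| H-bond | D···A ≤ 3.5 Å, D–H···A angle ≥ 130° |

Rings are 5/6-cycles of the minimum cycle basis; a six-ring of C/N atoms
with planarity RMS < 0.1 Å counts as aromatic. Roles follow connectivity:
the aromatic ring carrying ≥ 3 exocyclic nitrogens is the Yariv central
hub, other aromatic rings are peripheral, oxygen-containing non-aromatic
rings are saccharides. The ring normal uses the Newell sum over the ordered
loop, so its sign is tied to traversal order; all angle metrics are folded
to [0°, 90°], which makes them orientation-independent.

**Hydrogens are optional.** When absent, C–H positions are reconstructed at
ideal geometry from the heavy-neighbour count (tetrahedral CH, in-plane
aromatic CH, CH₂ pair). Hydroxyl-like donors, whose H direction is a free
rotation, get the best-case rotamer: H in the neighbour–donor–acceptor
plane at the tetrahedral angle, on the acceptor side — so detected H-bonds
are an upper bound for such donors. Implicit-H donation is restricted to
heavy-atom valences that imply a hydrogen (O with ≤ 1 heavy neighbour;
N with ≤ 2 heavy neighbours and no N neighbour), which excludes ethers,
glycosidic oxygens and azo/diazenyl nitrogens.

## Stacking topology and twist

Molecules owning aromatic rings are stack nodes; an edge requires at least
k = 1 parallel-stacked ring pair (a permissive default, matching partially
overlapping, irregular stacks). The stack axis is the principal axis of the
central-ring centroids, the order is the projection rank along it, and a
cyclic stacking graph is reported per path with a warning. The inter-unit
twist is the signed angle between central→peripheral reference vectors
projected perpendicular to the axis, with the axis oriented from unit i to
unit j so positive means a right-handed screw. Because the three arms are
chemically equivalent the twist is only defined modulo 120°; it is folded
to the unique representative in (−60°, 60°]. The handedness statistic (mean
sign of twists) negates exactly under mirror inversion — a parity check
asserted in the tests. Irregularity is quantified per adjacent pair as the
interplanar angle of central-ring normals, the axial rise and the lateral
slip; these are measurable proxies, not reproductions of any reported
number.

## Carbohydrate geometry

Cremer–Pople (Q, θ, φ) puckering coordinates are computed from the standard
mean-plane construction for six-membered rings in the O5-first, C1…C5 atom
order. Under this convention θ near 0° is the ⁴C₁-type pole (verified
against an rdkit-embedded β-D-galactopyranose chair and an independent
scalar-loop implementation of the textbook formulas); reversing the atom
order swaps the poles. Chair bins are θ < 45° and θ > 135°, the
conventional partition of the puckering sphere; the equatorial band is
split into boat (φ within 15° of multiples of 60°) and skew-boat labels.
The chair fraction over frames replaces visual inspection of trajectories
with a statistic.

Chain shape uses residue centroids defined as the mean of the six ring
atoms only, making them insensitive to exocyclic arm motion. The bend at
residue i is the centroid angle (i−1, i, i+1); a hexasaccharide yields four
angles. Triad alignment assigns a sugar triplet to whichever of the three
cyclic peripheral–central–peripheral triads (peripherals ordered by azimuth
about the central normal, both chain directions tried) minimises the summed
centroid-to-centroid distance, with "unbound" beyond a mean distance of
6 Å per pair; occupancy fractions over frames sum to 1 with "unbound"
absorbing the remainder.

## Synthetic generators — what they emulate and what they do not

The generators exist to give every pipeline stage inputs with known
statistical structure:

* `gen_boltzmann_cloud` draws positions directly from the exact stationary
  distribution of a harmonic well (σ² = kT/κ per axis; default κ = 1
  kJ/mol/Å², T = 300 K), optionally over several wells chosen uniformly per
  frame. It tests the *analysis*, not dynamics: there is no kinetics, no
  correlation between frames.
* `gen_rigid_stack` builds schematic planar Yariv mimics (correct ring
  census: one central + three peripheral aromatic rings on N=N linkers,
  optional chair pyranoses; typical bond lengths; exact 3-fold symmetry)
  stacked with a controlled rise (default 3.5 Å, a typical π-stacking
  separation), signed twist and Gaussian orientation/offset jitter. The
  mimic is not chemically parameterised — sufficient for the geometric
  classifier contracts, not for energetics.
* `gen_galactan_chain` places pyranose rings along a 3-D walk with a fixed
  inter-centroid bend (default 120°, spacing 4.6 Å). Turn wobble perturbs
  the bend; dihedral wobble kinks the chain out of plane without changing
  the bend — so the construction bend is exactly the measured mean.
  Optional schematic O2/O4 hydroxyls enable hydrogen-bond analyses.
* `gen_face_migration` alternates a probe between ±z binding sites
  (default z₀ = 4 Å, jitter σ = 0.8 Å) with exponential dwell times,
  recording the latent face state per frame.
* `gen_pucker_mix` draws frames from ideal chair/boat templates at a stated
  mixing fraction with small Cartesian noise.

Defaults were chosen once as representative magnitudes for this chemistry
and are not tuned. Passing tests on these inputs demonstrates that the
analysis recovers known structure under its stated assumptions; it does
not validate force fields, sampling convergence, or the behaviour of real
solvated trajectories (no water, no thermal ring breathing, no anharmonic
wells).

Determinism: each generator consumes a single `numpy` `default_rng(seed)`;
a fixed spec + seed yields byte-identical PDB/XTC/JSON outputs.

## Pipeline and replicas

`run_pipeline` chains the stages and writes a bundle whose files are all
re-readable by the package's own readers; outputs carry no timestamps, so
reruns are byte-identical. Occupancy maps always use every frame;
interaction/stacking classification accepts a frame stride
(`interaction_stride`) because classification, not histogramming, dominates
the cost on long trajectories. `summarize_replicas` refuses bundles whose
analysis parameters differ (reporting the differing keys) and tallies the
modal low-A region count — the "map shape class" (e.g. 3 regions for a
triangular three-well map vs 1 for a single basin) — across replicas.

The quantitative anchors recomputed by `scripts/acceptance.py` run at
desk scale: 2,000 galactotriose conformers for the bend angle (mean
settles well within its ±15° band at that size) and a closed-form box
concentration; the larger map-validation runs in the test suite use
6×10⁴–10⁶ samples, sizes at which the binomial/normal error bands in the
assertions are comfortably resolved.

## Known limitations

* Bond perception by covalent radii can over-connect very distorted
  geometries; CONECT records take precedence when present.
* The best-case-rotamer hydrogen bond criterion overcounts relative to
  explicit-hydrogen trajectories; counts on stripped and unstripped data
  are not directly comparable.
* Triclinic cells are re-imaged by rounding fractional coordinates, which
  is exact for orthorhombic boxes and minimum-image-correct for the
  moderately skewed cells typical of solution MD.
* `minimum_cycle_basis` is quadratic-ish in ring-system size; fine for
  oligomeric assemblies, not intended for polymers with thousands of
  fused rings.
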