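# Methods

## The physical model

Electroporation-based liver treatments (electrochemotherapy, ECT, and
irreversible electroporation, IRE) succeed when the whole tumor is
exposed to an electric field above a treatment-specific target: 400 V/cm
for ECT (8 pulses) and 600 V/cm for IRE (90 pulses). The package solves
the quasi-static continuity equation

    div( sigma(|grad phi|) * grad phi ) = 0

on a labeled voxel grid, one electrode pair at a time, and accumulates
the *field envelope* — the maximum field magnitude each voxel
experiences over the pulse sequence. Tissue conductivity is
field-dependent: below the reversible threshold `E0` it is `sigma0`,
above the irreversible threshold `E1` it saturates at `sigma1`, with a
smooth monotone ramp between. The default ramp is the cubic smoothstep
`3t^2 - 2t^3` on the normalized field, which is C1 at both thresholds
and qualitatively matches the smoothed Heaviside step functions of
commercial FEM codes; a linear ramp is available for sensitivity checks.
Default tissue values (V/cm, S/m):

| tissue      | E0  | E1   | sigma0 | sigma1 |
|-------------|-----|------|--------|--------|
| liver       | 350 | 700  | 0.04   | 0.12   |
| tumor       | 400 | 800  | 0.2    | 0.7    |
| vessel wall | 400 | 800  | 0.26   | 0.78   |
| blood       | 400 | 1100 | 0.7    | 1.05   |

Electroporation does not reseal within a pulse train, so each voxel's
conductivity is evaluated at the largest field it has seen in any
earlier drive; the conductivity state is monotone over the sequence.
Thermal effects, transient waveforms, and pulse-number-dependent
threshold shifts are out of scope; thresholds are fixed per treatment
type.

## Geometry

Simplified study scenes are a spherical tumor (diameters 10/30/50 mm) at
the origin of a liver block, with an optional two-layer cylindrical
vessel — wall thickness 10% of the outer diameter (clamped to one voxel
with a warning when thinner than the grid), around a blood core — either
parallel to the electrodes (axis along z, beside the tumor) or
perpendicular to them (axis along x, *below* the tumor, i.e. in the path
of the advancing tips). Voxel membership is decided by the voxel center;
coordinates are world millimeters; default spacing 0.5 mm isotropic for
production runs.

Electrodes are parallel needles, 1.2 mm diameter with a 40 mm active tip
and an insulated shaft above it. Layouts follow the published study
grid: a square of four electrodes whose axes are 2 mm radially outside
the tumor edge (corner positions on the circle of radius r_tumor + 2), a
hexagon 2 mm outside the edge for 50 mm ECT tumors, a hexagon of radius
7 mm *inside* the tumor for 30 mm IRE, each optionally with a central
electrode. The tumor sits at the middle of the active tips, except for
10 mm tumors with perpendicular vessels of >= 10 mm diameter, where the
tips stop 1 mm (configurable: 1 or 5) past the near tumor edge so that
not every electrode impales the vessel. In the simplified study the
electrodes otherwise keep their nominal positions even when they pierce
the vessel (pierced cells are reported); lateral adjustment — the
smallest 0.5 mm-grid offset that clears the vessel, with unavoidable
cases flagged as breaches and left in place — is applied only in the
patient-style workflows, mirroring how the clinical plans were adapted.

Domain padding defaults to 12 mm of liver beyond the outermost
structure. This is smaller than one tumor diameter for the 30/50 mm
tumors; the no-flux outer boundary is far from the electrode array
relative to the array size, and coverage of the reference case is
unchanged under mesh halving and insensitive to the padding at the 0.1
pp level, which is why the lighter default was kept.

## Discretization and solver

Cell-centered finite volumes with a 7-point stencil; face conductivities
are harmonic means, which reproduces series resistance across tissue
interfaces exactly (verified to machine precision against a 1-D
resistor-chain oracle). The driven pair is a Dirichlet condition at
±V/2 on the active-tip voxels; every other electrode is a floating
perfect conductor, implemented by collapsing its voxels into a single
equipotential unknown (net current through it is conserved identically).
Insulated shafts are zero-conductivity voxels excluded from the system;
the outer boundary is no-flux.

A thin 1.2 mm electrode is badly represented by a voxel staircase at 1 mm
spacing, so faces adjacent to electrode metal carry an embedded-boundary
subcell correction: conductance and field reconstruction use the true
distance from the neighboring voxel center to the analytic capped
cylinder surface (clamped to [0.2 h, h]). With the correction, tumor
coverage of the ECT 10 mm reference case is identical (100.000%) at
0.5, 0.75, 1.0 and 1.5 mm spacing; without it, the 1.0 mm grid is ~2.6
pp low. Per-voxel fields are reconstructed by averaging face potential
differences per axis (one-sided across electrode surfaces) and reported
in V/cm.

The nonlinearity is resolved per drive by damped Picard iteration
(relaxation 0.5, relative conductivity-change tolerance 1e-3, max 50
iterations; typical convergence in 8–10). Linear systems are SPD and
solved by sparse LU below 1000 unknowns, Jacobi-preconditioned CG to
50 000, and CG preconditioned by an in-package smoothed-aggregation
multigrid V(1,1)-cycle above that (typically ~12 CG iterations at rtol
3e-7). Every path is deterministic. Per-drive currents are the net face
flux out of the driven electrode; the discrete imbalance between anode
and cathode currents is reported and stays below the linear-solve
tolerance (<1e-3 relative on study cases, <1e-10 with direct solves).

Two deliberate semantics notes. First, because the conductivity state is
carried across drives, raising one drive's voltage can *lower* the
envelope at voxels whose maximum came from a later drive (more liver is
electroporated, redistributing that drive's current); measured dips are
below ~1.5% of the peak field and tumor coverage is monotone. Second,
drive order matters pointwise near the electrodes for the same reason
(up to ~8% of peak between forward and reversed order) while coverage
changes by <0.5 pp; the default order is outer ring pairs first, then
diagonal (center) pairs. A `carry_conductivity=False` flag resets the
tissue state before each drive for comparison.

## Dosimetry

Coverage is the percentage of tumor voxels whose envelope is at or above
the target field ("at or above": ties count as covered; with floating
point fields ties have measure zero). Success is coverage >= 99.9%.
Collateral exposure is the liver volume at or above the liver IRE
threshold (400 V/cm), as voxel count times voxel volume without
partial-volume weighting. Per-drive currents are checked against the
50 A generator limit (reported, and optionally enforced as an
optimization constraint; not enforced by default since the published
optima exceed 50 A for the IRE 30 mm configuration).

## Voltage optimization

Electrode positions are fixed; only the outer-pair voltage and the
diagonal (center-to-ring, or non-neighbor for the centerless box)
voltage are optimized. The objective is lexicographic: reach the success
threshold, then minimize liver IRE exposure, then prefer higher coverage
and finally lower total voltage (clinically conservative tie-break). The
default search is a deterministic coarse-to-fine grid scan at 100 V
resolution over [100, 3000] V — published optima are all multiples of
100 V in this range — with grids of <= 25 candidates searched
exhaustively, so small-grid results coincide with brute force. A seeded
elitist genetic algorithm over the same snapped grid mirrors the
stochastic optimizers used in the treatment-planning literature and is
available as `method="ga"`; it shares the scoring rule and is
reproducible for a fixed seed.

## Study pipelines

*Vessel neglect*: voltages fixed from the vessel-free optimum (published
values by default), coverage re-evaluated with vessels of diameter
1–15 mm at 0–10 mm distance in both orientations. *Segmentation error*:
the vessel mask is enlarged, shrunk, or shifted in the axial plane by 1
px (average reported error of the automatic vessel segmentation, 0.9 px
rounded) or 3 px (maximum, 2.8 px rounded) at a default 1 mm/px — the
image pixel size is not part of the published record and is
configurable; voltages are optimized on the perturbed geometry
(electrodes nudged off the perturbed vessel) and evaluated on the true
geometry. *Vessel exclusion*: the limiting case with vessels relabeled
as liver during planning. All pipelines emit tidy DataFrames, record
per-cell failures without aborting the sweep, and are bit-reproducible
under a fixed configuration.

## The synthetic patient-like scene

Real patient geometries behind the published second case are not
available, so the segmentation-error workflow runs on a synthetic
stand-in: an ellipsoidal tumor (default extents 15 × 11 × 11 mm,
matching the reported small-tumor case) abutting (<= 2 mm gap) a 15 mm
vessel trunk running parallel to the electrodes, with a 7 mm branch
leaving the trunk a few millimeters below the tumor and crossing
horizontally underneath it — the configuration in which a vessel
actually perturbs the field between the electrode tips. The generator is
deterministic for a fixed seed; the seed jitters only the trunk's
lateral position and the branch geometry. The stand-in reproduces label
topology, scale and vessel-tumor-electrode relations, not patient
anatomy, MRI intensities, or segmentation texture: passing tests on it
demonstrate the workflow's behavior under controlled geometry, not
clinical performance on real images.

## Known limitations and open discrepancies

Two published configurations do not reach the 99.9% success threshold in
this solver at the published voltages: ECT 50 mm / 7 electrodes
(98.8–99.0%) and IRE 30 mm / 7 electrodes (98.1–98.6%). The uncovered
voxels are, respectively, the tumor polar caps that extend beyond the
40 mm active tips (a 50 mm tumor is longer than the tip), and the outer
equatorial shell more than ~8 mm from the interior electrode hexagon. No
voltage pair within the [100, 3000] V bounds closes the gap (even
3000/3000 V gives ~99%), and iterating the pulse sequence to a fully
converged conductivity state changes coverage by less than 0.1 pp, so
this is a genuine model-level disagreement — plausibly a resolution
difference, since the original unstructured meshes used 50 000–70 000
elements for an entire multi-electrode domain and these marginal shells
are ~1% of tumor volume. The corresponding acceptance checks are left
failing rather than relaxed, and the study tables report the computed
values.

Cells in which an electrode penetrates the vessel (the depth-override
cells, and with-center cells whose central electrode impales a small
perpendicular vessel) are anomaly cells: their coverage is sensitive to
how the metal-blood contact rasterizes and does not follow the
monotone diameter/distance/orientation trends; the direction-of-effect
tests exclude them, as the published analysis also treats them as
exceptions.

Coverage percentages at coarse spacing quantize (one voxel of a 10 mm
tumor at 1.5 mm spacing is ~0.6% of its volume); sweeps in the test
suite therefore run at 1.0–1.5 mm while the headline vessel-free cases
are verified at 0.5 mm.
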