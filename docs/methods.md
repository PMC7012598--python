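# Methods

This note documents the models, conventions and numerical choices behind
`ck1switch`, and what the synthetic-data generators do and do not emulate.

## Structures, numbering and selections

Structures are read with gemmi (PDB v3.3 and mmCIF; for mmCIF the
`auth_asym_id` chain naming is used so "chain A/B" matches
crystallographic usage). Author residue numbering is authoritative and
never remapped: CK1δ ΔC spans residues 1–317, and every residue reference
in the package (L152, L173, Y225, segments 168–175, 213–224, 210–230,
anion-site residues R127/K154/K171/R178/K224) is an author number.

Alternate locations are resolved at read time to a single conformer per
atom: highest occupancy wins, ties go to altloc "A" (then alphabetical).
This is deterministic and matches common practice; no deposited-structure
altloc at the probe atoms is known to change a classification, but the
policy is a package decision, not a property of the data. Hydrogens are
kept on read and excluded from every distance, RMSD and occlusion
computation, keeping crystal structures (no hydrogens) and simulation
frames comparable. `strip_nonprotein` retains the 20 standard amino acids
plus selenomethionine and drops everything else (waters, counter-ions,
sulfates, ligands); it is idempotent and reduces ensemble frames
consistently with the topology.

## Loop-switch metric

The conformational state of the activation loop is read from two
distances anchored on the translocating residue L173:

- d_L152 = |L173:CD2 − L152:CD2| — short in "loop up";
- d_Y225 = |L173:CD2 − Y225:OH| — short in "loop down".

Classification compares the two distances directly: up if
d_L152 < d_Y225 − m, down if d_Y225 < d_L152 − m, otherwise
indeterminate, with margin m = 1.0 Å by default. A relative rule was
chosen over absolute thresholds because the two crystallographic clusters
are well separated but no numeric boundary is canonical, and a relative
rule transfers to CK1 homologs surveyed with equivalent probe residues
(the probe mapping is a parameter). The rule is exactly symmetric under
swapping the distances. Chains missing a probe atom (disordered side
chains are common) are never silently dropped: surveys record them in a
skip list and log a warning, because silent omission would bias
conformer counts.

## Superposition and RMSD traces

Rigid superposition is the Kabsch algorithm: SVD of the weighted
cross-covariance with the determinant-sign correction that excludes
reflections. Collinear or coincident point sets (second singular value
numerically zero) raise a degeneracy error rather than returning an
arbitrary rotation. The test suite checks 200 random instances against an
independent quaternion (Horn) closed-form oracle at 1e-8 Å.

Segment traces superpose each frame's fit selection onto the reference,
apply the motion to the whole frame, and measure unweighted RMSD over the
analysis selection. Defaults: heavy backbone N, CA, C, O (the stricter
common reading of "backbone"; a three-atom set is configurable), fit on
the analyzed segment itself — with `fit` = stable core as an explicit
option, since published loop analyses do not always state which
convention was used and the two differ when the segment moves as a rigid
body. No mass weighting anywhere. Replica averaging is the pointwise
arithmetic mean with all replicas retained.

## Pocket volumetrics

The region of interest is a union of inclusion spheres. Defaults place
three spheres of radius 8 Å at (1) the heavy-atom centroid of the Site 1
residues R178/K224, (2) the centroid of the Site 2 residues
R127/K154/K171, and (3) their midpoint for the substrate cleft — a
reproducible, residue-anchored stand-in for sphere placements that are
otherwise defined only pictorially. A regular grid (default 1.0 Å) covers
the union bounding box; points inside ≥1 sphere form the region mask. A
point is closed in a frame iff it lies within the Bondi van der Waals
radius of any protein heavy atom (no probe inflation by default; a
padding parameter exists). Free volume = open points × spacing³; the
ensemble map stores per-point open fractions, and the 0.10 contour keeps
points open in ≥10% of frames. Frame subsampling is expressed in frames,
with a helper converting a time stride ("every 2 ns") when frame times
are present. Frames are assumed superposed to a common reference; a large
centroid drift only warns, because genuine conformational change can also
move the centroid.

Discretization accuracy on an 8 Å sphere: 1.7% volume error at 1.0 Å
spacing, 0.5% at 0.5 Å; a three-sphere union at 0.5 Å agrees with a
10⁶-sample Monte-Carlo estimate to well under 1%. Grids are written as
plain-text OpenDX (values to 6 significant figures, zeros outside the
mask), the format molecular viewers contour natively; the writer is local
because no grid-format library is among the dependencies.

## Essential dynamics

Frames are reduced to heavy backbone atoms, superposed onto one reference
(Kabsch), concatenated across all input systems, and the covariance of
Cartesian fluctuations about the concatenated mean is diagonalized via
SVD of the centered data matrix — numerically equivalent to
diagonalizing the 3N×3N covariance but better conditioned, and efficient
whenever frames ≪ 3N. Eigenvalues use the population normalization
(divide by F): two frames at ±a along one direction give exactly one
nonzero eigenvalue a². No mass weighting: projections are reported in Å.

One shared eigenbasis is fitted on the concatenation of all systems and
each system is then projected separately, so per-system histograms live
in the same PC space and are directly comparable. Projections default to
re-running the fitting superposition; `superpose=False` exists for
coordinates already in the model frame (mode endpoints, the mean), where
an extra fit would be wrong — a subtlety worth noting: a random
collective mode has a small rigid-body component that superposition
absorbs, so planted-mode variances are recovered to a few percent, not
exactly. Histograms use a symmetric range with zero at a bin center.

## Kinetics

Under [S]₀ ≪ Km, substrate depletion is pseudo-first-order with rate
constant (kcat/Km)·[E], so a single endpoint inverts exactly:
kcat/Km = −ln(1 − P/S₀)/([E]·t). This endpoint form matches a triplicate
3-hour single-incubation design (10 µM substrate, 0.2 µM kinase);
replicates are reported as mean ± s.d. (never SEM), and P ≥ S₀ is a
saturation error rather than a number. `initial_rate` provides the
multi-timepoint variant (least-squares slope, restricted to <10%
conversion when S₀ is known). Units: molar and seconds internally for
enzymology, hours for decay — matching how each quantity is reported.

One-phase decay fits Y(t) = (Y₀ − plateau)·e^(−k(t−t₀)) + plateau by
nonlinear least squares (lmfit), with deterministic starts: Y₀ from the
first post-treatment point, plateau from the window minimum, k from a
log-linear fit of Y − plateau. The window runs from the treatment time to
the observed signal minimum. Half-life = ln2/k; the fit is exactly
invariant to rescaling the series. NMR site ratios propagate a single
spectral noise s.d. to the ratio at first order and flag timepoints where
the denominator is below 3× the noise floor as undefined rather than
reporting an unstable number.

The phosphoswitch regression is ordinary least squares of half-life on
the FASP/Degron efficiency ratio (statsmodels), with the slope's 95% CI
from the t distribution and a mean-response confidence band exported on a
uniform grid for plotting. Three points minimum.

## Conservation

Patch identity is reference-anchored: at each author position (mapped
through the gapped reference row), identity = 100 × matching sequences /
total sequences, reference included, gaps counting as mismatches — the
conservative convention for a conservation claim, and the one consistent
with anchoring the patch on specific CK1δ positions rather than on a
column consensus.

## Synthetic generators and their limits

Every generator is a pure function of its parameters and seed and returns
its ground truth. Coordinate noise is isotropic Gaussian; assay noise is
multiplicative Gaussian, except the mutant-panel generator, which adds
Gaussian noise to half-life directly so the panel sits exactly inside the
OLS generative model and confidence-interval coverage can be verified at
its nominal level (with multiplicative noise, nominal coverage would only
hold approximately, and a coverage check would conflate the estimator
with the noise model).

The toy kinase carries a backbone for residues 140–240 and the three
probe atoms with built-in distances (4, 12) Å ("up") and (12, 4) Å
("down") — an 8 Å separation between the two distance profiles. The three
probe atoms are collinear with L173 outside the anchor segment, which
makes the two distance gradients parallel, so isotropic coordinate noise
perturbs both distances coherently and the distance *difference* has the
minimum possible variance (2σ²); classification then recovers 100% of
labels for noise well below a quarter of the separation and degrades
monotonically beyond it. Pocket scenes return closed-form expected
volumes (union volume, a vdW-sphere deficit, or the exact spherical-cap
volume above a slab whose closure plane is aligned to a voxel boundary).

What the generators do not emulate: real force-field dynamics,
anharmonicity or state transitions in trajectories (modes are Gaussian
and stationary), crystallographic disorder beyond missing atoms,
correlated spectral noise, or inter-replicate systematics in assays.
Passing tests therefore certify the estimators and the geometry/linear
algebra, not the biology of any particular trajectory; the two
crystal-structure integration tests are the only checks against real
data, and they require locally supplied copies of the deposited entries.

## Problem sizes

Defaults keep every check desk-scale: PCA recovery uses 2000 frames of a
~400-atom backbone; volumetric grids are ≤ 33³ points at 0.5 Å; the
Monte-Carlo union oracle uses 10⁶ samples; kinetic recovery uses 200
simulated decays and 2000 simulated panels. The full suite runs in under
a minute on one core, and `scripts/acceptance.py` in a few seconds.
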