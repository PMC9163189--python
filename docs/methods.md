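# Methods

## Model

All interactions are two-body and rigid-monomer: the crystal energy is a
sum of atom–atom pair energies between molecules, and monomer geometries
never change.  Three pair-potential forms are supported.

The extended form per atom pair at distance r (Å, energies kJ/mol):

    [1 + a1 r + a2 r^2] exp(alpha - beta r) + A12/r^12
    - f6(delta6, r) C6/r^6 - f8(delta8, r) C8/r^8
    + f1(delta1, r) kC qa qb / r

`f_n` is the Tang–Toennies damping function, evaluated as the
regularized lower incomplete gamma function P(n+1, delta*r), which is
numerically stable at large delta*r where the naive series suffers
cancellation.  The baselines are Buckingham exp-6-1 (stored with the
prefactor A rather than exp(alpha), for conditioning) and Lennard-Jones
12-6-1.  Unit conventions: Å, kJ/mol, elementary charges,
kC = 1389.35458 kJ mol⁻¹ Å e⁻².  Atom types default to element symbols;
charges are per-atom properties of the monomer so one charge set serves
all forms.

## Synthetic reference oracle

The quantum-chemistry stage is replaced by a hidden ground-truth
potential of the extended form.  It returns component-resolved energies
with the component semantics of symmetry-adapted perturbation theory:
electrostatics = the damped charge–charge sum, first-order exchange =
the polynomial-prefactored exponential plus A12/r^12, and the
second-order induction and dispersion channels split the two damped
inverse-power terms (by default r^-8 to induction and r^-6 to
dispersion; the fit only ever uses their sum, so the split is a labeling
choice).  Optional independent Gaussian noise is added per component and
the total re-summed, so component sums are conserved exactly.

Sampling places 70% of configurations uniformly over the interaction
region and 30% log-spaced out to three times the region's outer edge,
with uniform random orientations and rejection of configurations below a
minimum atom–atom contact.  The default region is 0.55–2.2 times the
estimated van-der-Waals contact separation, which covers the repulsive
wall, the well, and the mid-range; the default dataset size is 700
points per dimer.  What the oracle does *not* emulate: basis-set or
method error with geometry-dependent structure, many-body polarization,
and monomer relaxation.  Passing the recovery tests therefore shows the
fitting and search machinery is correct and self-consistent, not that
the functional form suffices for any particular real molecule.

## Fitting protocol

Stages, each freezing its predecessors:

1. **Long range.** Per-atom charges from the electrostatic tail
   (undamped Coulomb model, total charge constrained per monomer,
   handled through the constraint null space with multi-start to escape
   the quadratic model's saddle at zero), and C6/C8 by non-negative
   linear least squares.  Resolving C6 from C8 requires the deep tail
   where residual damping is far below the r^-8/r^-6 contrast, so the
   C-coefficient fit uses separations beyond 1.5x the asymptotic
   threshold; the design matrix is column-normalized so the small ridge
   (1e-8) regularization is scale-free.
2. **Electrostatic damping.** delta1 per pair against the
   electrostatic component over all separations.  The charges are
   refined jointly here: the damped model is exact at every separation
   and the close-range points sharpen the charges far beyond the tail
   alone.  Pairs with vanishing charge products are flagged and get the
   default delta1 = 2/Å.
3. **Dispersion damping.** delta6/delta8 per pair against the
   induction+dispersion sum, with C6/C8 refined jointly (square
   parametrization keeps them non-negative).
4. **Repulsion.** alpha, beta, a1, a2, A12 per pair by weighted
   nonlinear least squares on the total energies, multi-start over
   beta.

Weights: w = 1 for E <= 0 and (E0/(E+E0))^2 for E > 0 with E0 = 20
kJ/mol, emphasizing the attractive well that controls polymorph
ranking.  Charges are fitted per atom rather than per atom type: atoms
sharing a type share pair-table entries, but their charges are resolved
individually (under the per-monomer neutrality constraint).  This keeps
single-pair-type toy systems — one shared type, distinct charges —
fully identifiable, which is what makes machine-precision recovery of a
hidden truth possible.  With several atom types whose atoms sit close
together relative to the sampled separations, per-pair C8 and the
damping exponents become sloppy directions; the joint refinements in
stages 2–3 are what recover them when the data allow it at all.

Charge sign convention: the electrostatic component only determines
charges up to a global sign, so the first charged site is taken
positive.

**Hole control.** The flexible forms can develop "holes": unphysical
minima at short range behind a finite barrier (for example when the
polynomial prefactor goes negative).  `detect_holes` scans the dimer
energy radially inward over random orientations, finds the outermost
(physical) minimum, and reports any deeper inner minimum together with
the barrier between them.  If a fitted field has a hole behind less
than 100 kJ/mol (the default constraint), the repulsive core — A12 for
the extended form, the exponential prefactor for exp-6-1 — is scaled up
by bisection until the constraint holds.  12-6-1 fields with positive
A12 cannot have holes; the fit floors A12 accordingly.

## Crystal model and lattice energies

Lattice matrix rows are the lattice vectors; molecular centers of mass
are fractional, orientations scalar-first quaternions with an improper
flag for inversion images.  Space-group operators come from the
crystallographic tables (gemmi), or from an explicit operator list so
non-standard settings need no transformation.  Symmetry expansion wraps
each image's center of mass into the home cell and raises on special
positions (rigid-body packing assumes general positions).

Lattice energy is per molecule: half the sum of intermolecular pair
energies between the cell and all periodic images.  Repulsion and
dispersion are direct sums within a real-space cutoff (default 15 Å for
final energies; no tail correction — documented convention).  Coulomb
sums use Ewald summation with splitting parameter 4/cutoff (real-space
error ~erfc(4)), reciprocal cutoff set by a 1e-8 accuracy target, and
tinfoil boundary conditions; the extended form's (f1 - 1) short-range
correction is folded into the real-space sum (it is zero beyond 9 Å to
double precision, as are the 1 - f6/f8 corrections, which bounds the
transcendental work).  Intramolecular pairs are excluded by subtracting
their erf-smeared reciprocal contribution.  Cells requiring more than
30000 translation images or 2e6 reciprocal vectors are rejected — such
cells only arise from collapsing or exploding trial structures.

Validation anchor: the Ewald energy of rock salt reproduces the
Madelung constant to ~5e-8 relative, and matches direct neutral-shell
(Evjen) summation on rock salt, zinc blende and fluorite to better than
1e-4 after Richardson extrapolation of the 1/n^2 shell convergence.

## Candidate generation

*Random mode* (the default) follows a two-step scheme per space group:
step 1 samples unrestricted cells (lengths scaled to the molecular
volume, angles within the crystal system's ranges, uniform quaternions)
and keeps "reasonable" packings — packing coefficient 0.35–1.0 and no
atom–atom 12-6-1 pair energy above 2000 kJ/mol — to estimate 5th–95th
percentile cell-length ranges; step 2 samples within those ranges
widened by 20%, applies the same rejection, and gives every survivor a
short, loose 12-6-1 minimization (25 iterations, gradient tolerance
1 kJ/mol per DOF).  Structures that drift apart during the rough
optimization (packing coefficient < 0.3) are discarded.

*Grid mode* packs a deterministic orientation grid: inclusive Euler
angles 0..180° (19 values per angle at the default 10° step) in each of
51 coordination geometries, contracting cell axes by bisection until a
purely repulsive (r0/r)^12 contact energy reaches a threshold, then
keeping the densest 500 per geometry.  The 51 geometries are a
parametrized library of axis-contraction schemes cycling the 27
grid-search space groups with axis-order variants — a stand-in that
preserves the combinatorics (19³ x 51 = 349,809 candidates at full
scale) rather than a reconstruction of any specific legacy catalogue.

## Minimization

Bounded L-BFGS-B with 2-point finite-difference gradients over the
symmetry-reduced vector: free cell parameters of the crystal system
(e.g. a, b, c, beta for monoclinic) plus 7 pose DOF per asymmetric-unit
molecule, quaternions renormalized on evaluation.  DOF are rescaled to
comparable magnitudes (lengths/2 Å, angles/20°, fractional x5,
quaternion x5), which matters greatly for quasi-Newton convergence.
Gradients are numerical; the analytic-gradient consistency check is
therefore not applicable and the optimizer is treated as
derivative-free.

Guard rails: over-packed cells (packing coefficient > 2) are turned
back before an energy evaluation; starts on a violently repulsive wall
are first walked outward by 4% cell inflations until the energy turns
attractive (otherwise the first quasi-Newton step overshoots the
physical minimum into the non-interacting plateau) — this pre-relaxation
can be disabled; collapses (intermolecular contact below 0.7 Å or
energy below -500 kJ/mol per molecule) flag the result and return the
last safe point.  A minimizer pinned at the contact floor is reported
as collapsed, since its true minimum lies inside the excluded region.

The staged protocol minimizes with a 12-6-1 field first and only then
with the extended target, which keeps trajectories out of holes; batch
runs use a search cutoff of 10–12 Å and re-evaluate final energies at
the production cutoff, trading a small consistent energy offset for a
several-fold cost reduction.

## Clustering, ranking, overlap

Duplicates are detected by the transitive closure of three simultaneous
criteria: lattice energy within 0.5 kJ/mol, Niggli-reduced cell
parameters within 1% (lengths) and 1° (angles), and an RMS deviation
below 0.05 Å between fingerprints of the 200 shortest intermolecular
heavy-atom distances.  The representative is the lowest-energy member;
ranking sorts representatives by energy with density and id as
tie-breaks at the 1e-6 kJ/mol level.

The overlap score builds n-molecule clusters (default 20, heavy atoms
only) around a central molecule in each crystal.  The central molecules
are aligned by a proper-rotation Kabsch fit with distance-profile atom
matching, augmented by trial rotations about the reference molecule's
principal axes (the central fit is degenerate for linear molecules and
ambiguous for symmetric ones); remaining molecules are matched by
center of mass with the Hungarian algorithm against a reference pool
carrying extra boundary molecules (shell ties at the cluster surface
otherwise force bad pairings), and a full least-squares superposition
over all matched atoms is iterated to convergence.  The minimum over
symmetry-distinct central choices is reported; 0.8 Å is the match
threshold.  This matching is an approximation that is exact for
near-identical packings, which is the regime in which the score is
used.

## Refinement loop

Starting from a fitted field and a ranked polymorph set, each iteration
mines the symmetry-distinct nearest-neighbor dimers (3 distance shells
by default) of the top 20 polymorphs, queries the oracle at exactly
those geometries, refits the force field on the pooled dataset
(training data plus all mined references, which grows monotonically),
and re-minimizes the top polymorphs.  Convergence is declared when, for
every top polymorph, the energy of a finite 5x5x5 block of unit cells
computed purely from the model agrees within 1 kJ/mol with a hybrid
energy in which each dimer matching a *mined* reference geometry
(distance-multiset agreement within 0.02 Å) receives the substitution
correction "reference energy minus model energy at the reference
geometry".  Evaluating both sides of the correction at the reference
geometry makes the gap a pure measure of model error; and only mined
references enter the substitution, since loose matches against
unrelated training configurations would charge the model with a
geometry mismatch rather than its own error.  Only
the top polymorphs are re-minimized each iteration (a configurable
choice); with a noiseless oracle the loop is a fixed point as soon as
the fitted field reproduces the oracle on the pooled data.

## Problem sizes and study conditions

The synthetic study conditions are: 700 reference points per dimer
(500 in the reduced recovery studies), noiseless by default with
sigma = 0.5 kJ/mol per component as the noisy condition (total noise
sd 1.0 kJ/mol, matching the ~1 kJ/mol fit-residual scale the method
targets), and reduced searches of 2 space groups (P1, P-1) x 20-60
random candidates for the end-to-end experiments.  The planted-truth
experiment generates one candidate pool, minimizes it once with the
hidden truth (defining the "experimental" reference as the truth's
rank-1 crystal) and once with the fitted field, and scores the fitted
ranking against the reference.  Full-scale quotas (349,809 grid
candidates, 500+5000 random structures per group, 13 groups) are
retained as defaults in the generation configuration and exercised
arithmetically; searches at that scale are a matter of CPU hours, not
of different code paths.

## Known limitations

- Two-body, rigid-monomer energetics only; no polarization, no
  higher multipoles, no intramolecular relaxation, no free-energy or
  phonon corrections.
- Z' = 1 generation only (the data model supports more; the samplers do
  not).
- The identifiability of per-pair dispersion parameters degrades with
  many atom types, as discussed above; recovery guarantees apply to the
  toy systems' typing.
- Numerical gradients make minimization O(n_DOF) energy evaluations per
  step; fine for rigid small molecules, the main cost driver at scale.
- The coordination-geometry library and the duplicate-detection
  tolerances are pragmatic substitutes for legacy packing catalogues
  and proprietary similarity tools; both are configurable.
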