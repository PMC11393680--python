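# Methods

This note documents the models, conventions and numerical choices behind
`forcegrad`, in the spirit of a package reference: what is computed, under
which assumptions, and what the tests do and do not demonstrate.

## Coordinate model and conventions

A protein is represented in internal coordinates: per residue, the
backbone torsions (φ, ψ, ω), three backbone bond angles (N-CA-C,
CA-C-N⁺¹, C⁻¹-N-CA) and up to six side-chain torsions χ₁..χ₆, all in
radians in (−π, π], plus padded heavy-atom coordinates in ångström.
Torsions follow the IUPAC sign convention; the implementation was
cross-checked against an independent cheminformatics toolkit on
identical coordinates.  Residue indices are 0-based internally and
1-based in files and messages.  Ideal bond lengths and angles are
Engh–Huber-style stereochemical-dictionary values tabulated per residue;
a text override file (`RES A1 A2 value` for bonds, `RES A1 A2 A3 value`
for angles) can replace backbone values at the idealization step.

Protonation is fixed at pH-7 defaults: histidine is the Nε tautomer,
aspartate/glutamate are deprotonated, lysine/arginine protonated.
Termini are neutral and blunt: no N-terminal amide hydrogen is placed at
residue 1 and no OXT is written; a terminal OXT in an input file is
ignored on read.  Alternate locations, insertion codes, HETATM records,
multiple chains/models and non-standard residues are rejected with
descriptive errors, never silently dropped.

## The differentiable builder

Atoms are placed by natural extension of reference frame: given three
placed atoms a-b-c and a (bond length, bond angle, torsion) triple, the
fourth atom is a closed-form smooth function of all six inputs.  The
first residue is bootstrapped with N at the origin, CA on +x and C in
the xy-plane — an arbitrary convention, since all downstream quantities
are frame-invariant.  The backbone is chained
N→CA→C per residue driven by (ψ, ω, φ); the carbonyl O is placed anti
to the next amide nitrogen (torsion ψ+π, falling back to π at the C
terminus); CB is placed by an improper torsion of +122.8° (N-C-CA-CB),
which fixes the L configuration — the signed volume of (N, C, CB) about
CA is positive for every chiral residue, asserted in the tests.  Side
chains follow per-residue z-matrices; branch atoms (e.g. VAL CG2,
LEU CD2, THR CG2) sit at fixed ±120°-class offsets from the named χ
atom, with offsets chosen to reproduce standard stereochemistry (THR 3R,
ILE 3S) and branch naming such that the common leucine (χ₁=−60°,
χ₂=180°) rotamer is the g−/g− arrangement, not a syn-pentane conflict.

Rings (HIS, PHE, TYR, TRP, PRO) are built from the z-matrix spanning
tree; the ring-closure bond is geometrically dependent and closes only
approximately (worst case ~0.07 Å for the imidazole; exactly for the
ideal benzene ring).  Consequently "bond lengths equal ideal values"
holds exactly for tree bonds and approximately for closure bonds; the
toy force field carries a harmonic term on closure bonds, which
contributes a small constant under torsion-only moves.  Proline's ring
is parameterized by χ₁/χ₂ with the CD-N closure left implicit; the
fixture generator uses (χ₁, χ₂) = (−18°, +6°), which closes CD-N to
within 5·10⁻⁴ Å of its dictionary length under this geometry table.

Hydrogens are placed from heavy-atom positions in consistent,
predetermined conformations — no optimization: amide H in the peptide
plane anti to the carbonyl O; sp³ centres by tetrahedral completion of
their heavy neighbours; methyl (and ammonium) rotors staggered at
torsions 180°/−60°/+60° from the grandparent atom; hydroxyls and thiols
anti to the grandparent; planar NH₂ groups in the sp² plane.  Every
placement is a smooth function of heavy coordinates, so hydrogen
addition is differentiable; it is also idempotent and leaves heavy
coordinates bit-for-bit untouched.

Differentiation is forward-mode: the builder runs on dual numbers (a
value plus a Jacobian row per selected input), so `build_with_jacobian`
and `add_hydrogens_with_jacobian` return exact ∂X/∂θ and
∂X_all/∂X_heavy.  Forward mode is the right trade-off here: the
parameter count (tens of torsions, or 3·n heavy coordinates at desk
scale) is small, and exactness removes any finite-differencing error
from the gradient chain.  Gradient correctness is tested against central
finite differences at relative error below 10⁻⁴ (typically ~10⁻⁷).
Collinear reference frames (cross-product norm < 10⁻⁸ of the segment
product) raise a degenerate-frame error rather than producing garbage.

## Energy backends

The toy force field contains harmonic bonds (k = 2,500 kJ/mol/Å²,
r₀ from the geometry tables), harmonic angles (k = 300 kJ/mol/rad²,
θ₀ from the tables, default 109.47° where untabulated — exact θ₀ only
shifts a constant under torsion-space moves since bond angles are held
fixed), periodic torsions on ω (k = 20 kJ/mol, n = 2, phase π) and on
each χ (k = 2 kJ/mol, n = 3), and nonbonded Lennard-Jones plus Coulomb
terms with per-element LJ parameters, backbone amide partial charges,
1-2/1-3 exclusions and AMBER-style 1-4 scaling (0.5 LJ, 1/1.2 Coulomb).
There are no cutoffs and no periodic boundary: the backend targets
systems of a few hundred atoms where exactness matters more than speed.
Forces are analytic (the dihedral gradient uses the standard
cross-product formulation) and agree with central finite differences to
~10⁻¹⁰ relative; translation and rotation invariance, vanishing net
force and torque, and extensivity are asserted in the tests.  Exactly
coincident atoms produce an explicitly flagged infinite energy — the
flag propagates instead of NaN arithmetic.

The MD-engine adapter exposes the same evaluate-interface backed by
OpenMM (default force field `ff15ipq`, generalized-Born implicit
solvent, the variant exposed as a named option), converting the engine's
kJ/mol/nm forces to kJ/mol/Å exactly (×0.1) and caching the engine
context per topology.  When the engine is not installed the adapter
raises a capability error; every library feature remains exercised
through the toy backend.

## The loss layer

The loss node supplies *U(X_H)* forward and *−F(X_H)* backward at the
all-atom coordinates; gradients with respect to torsions or heavy-atom
coordinates follow by the exact chain rule through the builder Jacobians
(∇_θ U = −Jᵀ F).  The sigmoid transform is an ordinary differentiable
node on top: its derivative *is* applied in the backward pass, which is
the mathematically consistent reading (the alternative — propagating raw
−F regardless of the transform — would make the loss and its gradient
inconsistent).  As printed, the transform's trailing term must read
"− A + 1": only that sign reproduces the three published properties
(supremum 1, infimum −4, sign change near −20,000 kJ/mol; the exact root
is (C·ln 20 − B)/D ≈ −20,256.07 kJ/mol).  The implementation evaluates
the exponential in a saturating form (arguments clipped at ±700) so the
transform is exact over ±10³⁰⁰ and total at ±∞.  Non-finite energies
raise with the raw transform, and saturate to the supremum with zero
reported gradient under the sigmoids (the leak direction is undefined
when the forces behind it are infinite).

The component weight (default 0.01) is multiplied by a linear warm-up
ramp over the first 1,000 steps; warm-up multiplies the configured
weight rather than replacing it.

`toy_finetune_demo` is a desk-scale demonstration, not a surrogate for
fine-tuning a structure predictor: the "model" is a per-fixture torsion
table, the composite loss is a smooth angular error 〈1 − cos Δθ〉 plus
the warm-up-weighted σ* energy loss, and plain gradient descent
(lr = 0.5) is bitwise reproducible for a fixed seed.  On helix fixtures
it reduces both the composite loss and the raw energy within 200 steps.

## Internal-coordinate minimization

`idealize_geometry` resets the three backbone bond angles to table
values and rebuilds coordinates from internal coordinates (which applies
table bond lengths by construction), preserving every torsion exactly.
`minimize_internal` is first-order descent on the free torsions with a
backtracking line search: a step is accepted only if energy strictly
decreases (step halved otherwise, down to a floor of 10⁻⁹ rad), the step
size grows 1.5× after success up to 10⁻² rad per unit gradient, and any
single angle move is capped at 0.2 rad.  A named quasi-Newton optimizer
would converge faster but would not guarantee the monotone-trace
invariant the pipeline and its tests rely on.  Convergence is declared
when an accepted step's energy drop falls below `convergence_tol`
(default 0.01 kJ/mol).  ω is optimized like any torsion from its input
value; no cis/trans flips are attempted.  Because bond lengths and
angles are carried by the builder's tables, torsion-only optimization
preserves covalent geometry to <10⁻⁶ (Å, rad) by construction.

The dataset pipeline (idealize → minimize → filter) rejects entries
whose chains have gaps (a Cα-Cα spacing above 4.5 Å, non-consecutive
author numbering, or a missing residue — the sequential builder needs a
connected chain) and entries that moved more than 5 Å Cα RMSD (Kabsch,
proper rotation) from their starting structure; the atom set is
switchable to all-atom, and chains shorter than three residues fall back
to all heavy atoms for superposition.  The "5 RMSD" filter is read as
5 Å on Cα after optimal superposition — the conventional reading when
units and atom set are unstated.  Per-entry failures are recorded in the
report, never abort the batch, and the report is byte-identical across
reruns.

## Quality metrics

The clash score counts non-bonded pairs whose van der Waals spheres
(H 1.10, C 1.70, N 1.55, O 1.52, S 1.80 Å) overlap by ≥ 0.4 Å,
excluding 1-2 and 1-3 pairs, normalized per 1,000 atoms.  This is a
deliberate approximation of probe-based contact analysis: it has no
hydrogen-bond allowance, so e.g. the O(i)···H(i+4) helix hydrogen bond
is counted, and absolute values are not comparable to crystallographic
suites — only relative comparisons under a fixed criterion are
meaningful, which is how the pipeline uses it.  An exact-threshold tie
counts as a clash (the comparison carries a 10⁻⁹ float guard).

Kabsch RMSD enforces a proper rotation and recomputes the residual
explicitly after superposition (the aligned-residual shortcut loses
half the significant digits to cancellation for near-congruent sets).

lDDT is computed on heavy atoms with correspondence fixed by (residue
index, atom name) — no renaming of symmetric side-chain atoms — over
inter-residue pairs within a 15 Å inclusion radius, averaged over the
0.5/1/2/4 Å thresholds.  Keeping fixed names slightly under-reports
accuracy for symmetric groups; it also removes any dependence on a
renaming heuristic.  The implementation is tested against a naive
pair-enumeration oracle to 10⁻¹² absolute.

## Synthetic fixtures: what they emulate and what they do not

The fixture generator produces ideal α-helices (φ = −57°, ψ = −47°,
ω = 180°), extended chains (φ = ψ = 180°), helices with a central
leucine χ₁ rotated to +60° — a syn-pentane-class conflict whose energy
is ~10⁵ kJ/mol, the clash regime the sigmoid transforms exist for — and
uniform random-torsion chains, all deterministic per seed.  Default
rotamers are the common gauche−/anti values (aromatic rings
perpendicular, χ₂ = 90°).  These fixtures have exactly ideal covalent
geometry, no experimental noise, no missing atoms, single chains and no
ligands; tests passing on them demonstrate the correctness of the
geometric and differential machinery, not performance on experimental
structures, whose B-factor-dependent noise, alternate conformations and
chain breaks this package's readers must handle upstream.

## Problem sizes

The test suite and acceptance script run on fixtures of 2–20 residues
(up to ~350 atoms with hydrogens), minimization budgets of tens of
steps, and a two-torsion grid search at 4–6° globally refined to 0.25°
locally — sizes at which every gradient contract can be verified against
finite differences and every metric against brute-force enumeration.
The library itself has no hard-coded size limits; cost grows as the
square of atom count through the cutoff-free nonbonded sum.

## Known limitations

* The toy force field is an oracle for gradients and plumbing, not a
  calibrated potential; its minimized structures are not AMBER minima.
* Ring closure is approximate (see above); proline's CD-N bond is
  maintained only through its energy term, not as a constraint.
* No support for nucleic acids, ligands, multiple chains, alternate
  protonation states, cis-proline flips, or post-translational
  modifications.
* The OpenMM adapter requires a chargeable-terminus topology the blunt
  builder does not produce; running it on real engines may require a
  capping/terminus pass upstream.
* lDDT without symmetric-atom renaming under-reports accuracy for
  PHE/TYR/ASP/GLU-type symmetric groups, by design.
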