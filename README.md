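# forcegrad

**Molecular-mechanics forces as training gradients for protein structure
models.**

Deep learning structure predictors are trained on geometric losses and
routinely emit physically implausible structures — overlapping atoms,
strained side chains — that a molecular dynamics (MD) force field assigns
astronomical energies.  `forcegrad` implements the machinery needed to use
the physics itself as a training signal:

* a **differentiable all-atom builder**: natural extension of reference
  frame (NeRF) construction of Cartesian coordinates from torsion angles,
  including hydrogen placement at idealized geometry, with exact
  analytic Jacobians through every step;
* an **energy-as-loss layer**: the potential energy *U(X)* of the built
  structure is the loss, and because *F(X) = −∇ₓU(X)*, the backward pass
  at the coordinate node is simply the negative of the physical forces —
  everything upstream (hydrogen addition, NeRF building) is
  differentiated algorithmically and chained on top;
* the **sigmoid energy transforms** that make such a loss trainable.
  Raw protein energies span hundreds of orders of magnitude; the
  modified sigmoid

  σ̃(x) = (1/A + e^(−(D·x+B)/C))⁻¹ − A + 1,  A = 5, B = 10⁶, C = 3·10⁵, D = 5

  compresses them into a bounded range: σ̃ → 1 for large positive
  energies, σ̃ → −4 for large negative energies, with a sign change near
  −20,000 kJ/mol so only genuinely favourable structures yield a
  negative loss.  The leaky variant σ*(x) = 10⁻¹²·x + σ̃(x) keeps a
  nonzero gradient even in the saturated tails.  A loss-component weight
  of 0.01 is ramped linearly from zero over 1,000 warm-up steps;
* an **internal-coordinate minimization pipeline**: covalent geometry is
  idealized to force-field optima, energy is minimized over torsion
  angles only (bond lengths and angles stay exactly ideal), and entries
  are filtered out if the chain has gaps or if minimization moved the
  Cα trace more than 5 Å RMSD from the start — the procedure used to
  build minimized training datasets;
* **structure-quality metrics**: a van der Waals clash score (clashes
  per 1,000 atoms at 0.4 Å overlap), Kabsch RMSD, and a simplified
  all-atom lDDT without symmetric-atom renaming.

Energies and forces come from a self-contained analytic toy force field
(harmonic bonds/angles, periodic torsions, Lennard-Jones + Coulomb with
AMBER-style 1-4 scaling) whose forces are the exact negative gradient,
verified against finite differences; an adapter exposes the same
interface backed by OpenMM (force field `ff15ipq`, generalized-Born
implicit solvent) when that engine is installed.

## Worked example

Generate a synthetic α-helix whose central leucine χ1 has been rotated
into steric conflict, score it, minimize it in torsion space, and score
the result:

```sh
forcegrad fixture --kind clashed-helix --n 8 -o clash.pdb
forcegrad energy clash.pdb
forcegrad minimize clash.pdb --max-steps 60 -o min.pdb --report rep.json
forcegrad score min.pdb --ref clash.pdb --metrics clash,rmsd,lddt
```

The energy report for the clashed input shows the transform at work:

```
"potential_energy_kj_mol": 98332.63445295235,
"transformed_loss": 0.832603158787192
```

a ~10⁵ kJ/mol clash maps to a loss of 0.83 — bounded, finite, and still
informative.  Minimization then repairs the rotamer without disturbing
the fold:

```
minimized clash.pdb: 99943.61 -> 95.45 kJ/mol in 60 steps (accepted)
```

and the scores of the minimized structure against the clashed input:

```
"ca_rmsd_A": 0.3225723063186309,
"clash_count": 10,
"clash_score_per_1000": 113.63636363636364,
"lddt_all_atom": 0.9462732919254658
```

The clash count falls from 39 to 10 (the remainder are helix
hydrogen-bond contacts that a bare vdW criterion counts as overlaps)
while the backbone moves only 0.32 Å — the minimizer acted on side-chain
and backbone torsions, never on covalent geometry.  `forcegrad
demo-train` runs a small end-to-end demonstration of training a
torsion-predicting model against the warm-up-weighted σ* energy loss
combined with an angular-error term.

## Library surface

```python
from forcegrad import (
    generate_fixture, FixtureSpec,        # synthetic test proteins
    build_all_atom, add_hydrogens,        # differentiable construction
    toy_energy, check_forces,             # energy backends + verification
    energy_loss_from_angles, sigma_star,  # the loss machinery
    idealize_geometry, minimize_internal, # the minimization pipeline
    clash_report, kabsch_rmsd, lddt_all_atom,
)
```

`energy_loss_from_angles` / `energy_loss_from_coords` return the
transformed, weighted loss together with its exact gradient with respect
to the input torsions or heavy-atom coordinates — the gradients a
training loop would consume.

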