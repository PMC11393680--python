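"""Structure-quality and accuracy metrics.

* clash report: non-bonded atom pairs whose van der Waals spheres
  overlap by at least a threshold (0.4 A by convention), excluding
  1-2 and 1-3 bonded pairs; the clash score is clashes per 1000 atoms.
  This is a plain vdW-overlap count, not a probe-based contact analysis,
  so absolute values are not comparable to crystallographic suites.
* Kabsch RMSD: least-squares RMSD after optimal proper rotation and
  translation.
* simplified all-atom lDDT: superposition-free preserved-distance
  fraction over inter-residue heavy-atom pairs within a 15 A inclusion
  radius, averaged over the 0.5/1/2/4 A thresholds, with no renaming of
  symmetric side-chain atoms (fixed atom names slightly under-report
  accuracy for symmetric groups).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import DegenerateInputError
from .nerf import AllAtomStructure

__all__ = [
    "DEFAULT_VDW_RADII",
    "ClashReport",
    "clash_report",
    "kabsch_rmsd",
    "lddt_all_atom",
]

#: per-element van der Waals radii (angstrom); override per call if needed
DEFAULT_VDW_RADII = {
    "H": 1.10,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
}

LDDT_THRESHOLDS = (0.5, 1.0, 2.0, 4.0)
LDDT_INCLUSION_RADIUS = 15.0


@dataclass(frozen=True)
class ClashReport:
    clash_pairs: tuple[tuple[int, int, float], ...]   # (i, j, overlap A)
    atom_count: int
    includes_hydrogens: bool

    @property
    def clash_count(self) -> int:
        return len(self.clash_pairs)

    @property
    def clash_score(self) -> float:
        return 1000.0 * self.clash_count / self.atom_count


def _excluded_pairs(structure: AllAtomStructure) -> set[frozenset]:
    bonds = structure.bonds()
    adj: dict[int, list[int]] = {}
    excl: set[frozenset] = set()
    for a, b in bonds:
        excl.add(frozenset((a, b)))
        adj.setdefault(a, []).append(b)
        adj.setdefault(b, []).append(a)
    for j, nbrs in adj.items():
        for x in nbrs:
            for y in nbrs:
                if x < y:
                    excl.add(frozenset((x, y)))
    return excl


def clash_report(
    structure: AllAtomStructure,
    overlap_threshold: float = 0.4,
    radii: dict | None = None,
) -> ClashReport:
    """Count steric clashes: pairs with vdW overlap >= the threshold.

    A pair (i, j) clashes when ``r_vdw(i) + r_vdw(j) - dist(i, j) >=
    overlap_threshold``; covalently bonded (1-2) and geminal (1-3)
    pairs are never counted.
    """
    radii = radii or DEFAULT_VDW_RADII
    x = structure.coords
    m = x.shape[0]
    r = np.array([radii[el] for el in structure.elements])
    excl = _excluded_pairs(structure)
    ii, jj = np.triu_indices(m, k=1)
    d = np.linalg.norm(x[ii] - x[jj], axis=1)
    overlap = r[ii] + r[jj] - d
    # tie-break at the threshold in favour of counting (exact table
    # arithmetic like 1.7 + 1.7 - 3.0 lands epsilon below 0.4 in binary)
    cand = np.where(overlap >= overlap_threshold - 1e-9)[0]
    pairs = tuple(
        (int(ii[k]), int(jj[k]), float(overlap[k]))
        for k in cand
        if frozenset((int(ii[k]), int(jj[k]))) not in excl
    )
    return ClashReport(
        clash_pairs=pairs,
        atom_count=m,
        includes_hydrogens=bool(structure.is_hydrogen.any()),
    )


def kabsch_rmsd(P: np.ndarray, Q: np.ndarray) -> float:
    """RMSD between corresponding point sets after optimal superposition.

    The rotation is constrained to be proper (determinant +1).
    """
    P = np.asarray(P, float)
    Q = np.asarray(Q, float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise DegenerateInputError(
            f"point sets must share shape (n, 3); got {P.shape} vs {Q.shape}"
        )
    if P.shape[0] < 3:
        raise DegenerateInputError("need at least 3 points for superposition")
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)
    rot, _rssd = Rotation.align_vectors(Pc, Qc)
    # recompute the residual explicitly: scipy's reported rssd loses
    # precision to cancellation for near-congruent sets
    resid = rot.apply(Qc) - Pc
    return float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))


def lddt_all_atom(
    predicted: AllAtomStructure,
    reference: AllAtomStructure,
    inclusion_radius: float = LDDT_INCLUSION_RADIUS,
    thresholds: tuple = LDDT_THRESHOLDS,
) -> float:
    """Simplified all-atom lDDT on heavy atoms, no symmetric-atom renaming.

    Over all reference heavy-atom pairs from different residues whose
    reference distance is below ``inclusion_radius``, the score is the
    mean over thresholds of the fraction of pairs whose predicted
    distance deviates by less than the threshold.  Atom correspondence
    is by (residue index, atom name); superposition-free by design.
    """
    if predicted.sequence != reference.sequence:
        raise DegenerateInputError("sequence mismatch between structures")
    ref_keys = [
        (int(reference.res_index[k]), reference.atom_names[k])
        for k in range(reference.n_atoms)
        if not reference.is_hydrogen[k]
    ]
    try:
        pred_idx = np.array(
            [predicted.atom_index(ri, nm) for ri, nm in ref_keys]
        )
    except KeyError as exc:
        raise DegenerateInputError(f"atom correspondence failed: {exc}")
    ref_idx = np.array(
        [reference.atom_index(ri, nm) for ri, nm in ref_keys]
    )
    rx = reference.coords[ref_idx]
    px = predicted.coords[pred_idx]
    res = np.array([ri for ri, _ in ref_keys])

    ii, jj = np.triu_indices(len(ref_keys), k=1)
    different_res = res[ii] != res[jj]
    dr = np.linalg.norm(rx[ii] - rx[jj], axis=1)
    keep = different_res & (dr < inclusion_radius)
    if not keep.any():
        raise DegenerateInputError("no qualifying atom pairs")
    dp = np.linalg.norm(px[ii[keep]] - px[jj[keep]], axis=1)
    dev = np.abs(dp - dr[keep])
    fractions = [np.mean(dev < t) for t in thresholds]
    return float(np.mean(fractions))
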