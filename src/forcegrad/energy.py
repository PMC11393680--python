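"""Potential-energy backends: an analytic toy force field and an MD-engine
adapter.

The toy force field is a self-contained molecular-mechanics potential
(harmonic bonds and angles, periodic torsions, Lennard-Jones and Coulomb
with 1-2/1-3 exclusions and AMBER-style 1-4 scaling) whose forces are
computed analytically as the exact negative gradient of the energy.  It
is small enough to verify against finite differences to machine-level
precision and serves as the desk-scale oracle for every gradient
contract in the package.  The MD-engine adapter exposes the same
interface backed by OpenMM when that engine is installed.

Units: energies in kJ/mol, coordinates in angstrom, forces in kJ/mol/A.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chemistry import residue_topology, ONE_TO_THREE
from .errors import CapabilityError
from .nerf import AllAtomStructure

__all__ = [
    "EnergyResult",
    "ForceFieldSpec",
    "ToyFFParams",
    "ToySystem",
    "toy_energy",
    "md_engine_energy",
    "check_forces",
]

#: Coulomb constant in kJ/mol * angstrom / e^2
COULOMB_K = 1389.35458

# AMBER-style 1-4 scaling
SCALE14_LJ = 0.5
SCALE14_COULOMB = 1.0 / 1.2


@dataclass
class EnergyResult:
    potential_energy: float          # kJ/mol
    forces: np.ndarray               # (m, 3), kJ/mol/A
    backend_id: str
    finite: bool = True

    def __post_init__(self):
        if not np.isfinite(self.potential_energy) or not np.isfinite(
            self.forces
        ).all():
            self.finite = False


@dataclass(frozen=True)
class ForceFieldSpec:
    backend: str = "toy"                     # "toy" | "openmm"
    force_field_name: str = "ff15ipq"
    solvent_model: str = "gbn2"              # generalized-Born variant


@dataclass
class ToyFFParams:
    """Parameters of the toy force field.

    Defaults are chosen so that structures built from the ideal-geometry
    table sit at the minimum of every bonded term; nonbonded parameters
    are coarse per-element values.  There are no cutoffs and no periodic
    boundary: exactness over speed, for systems of a few hundred atoms.
    """

    bond_k: float = 2500.0          # kJ/mol/A^2
    angle_k: float = 300.0          # kJ/mol/rad^2
    omega_k: float = 20.0           # kJ/mol, periodicity 2, phase pi
    chi_k: float = 2.0              # kJ/mol, periodicity 3, phase 0
    lj: dict = field(default_factory=lambda: {
        "C": (3.40, 0.36),
        "N": (3.25, 0.71),
        "O": (2.96, 0.88),
        "S": (3.56, 1.05),
        "H": (2.00, 0.06),
    })
    # backbone amide partial charges (e); all other atoms neutral
    charges: dict = field(default_factory=lambda: {
        "N": -0.4157, "H": 0.2719, "C": 0.5973, "O": -0.5679,
    })
    coulomb_k: float = COULOMB_K
    scale14_lj: float = SCALE14_LJ
    scale14_coulomb: float = SCALE14_COULOMB
    default_angle_deg: float = 109.47


# ---------------------------------------------------------------------------
# the evaluator
# ---------------------------------------------------------------------------
class ToySystem:
    """A fixed topology plus parameter arrays, evaluable at any coordinates.

    Term lists may be supplied explicitly (tiny hand-built test systems)
    or generated from an :class:`AllAtomStructure` via
    :meth:`for_structure`.
    """

    def __init__(
        self,
        n_atoms: int,
        bonds=(),            # (i, j, k, r0)
        angles=(),           # (i, j, k, k_theta, theta0)  [j = centre]
        torsions=(),         # (i, j, k, l, k_phi, n, phase)
        lj_params=None,      # (m, 2): sigma, eps per atom
        charges=None,        # (m,)
        exclusions=None,     # set of frozensets {i, j} fully excluded
        pairs14=None,        # set of frozensets scaled
        scale14_lj: float = SCALE14_LJ,
        scale14_coulomb: float = SCALE14_COULOMB,
        coulomb_k: float = COULOMB_K,
        backend_id: str = "toy",
    ):
        self.n_atoms = n_atoms
        self.backend_id = backend_id
        self.bonds = np.array([b[:2] for b in bonds], dtype=int).reshape(-1, 2)
        self.bond_params = np.array(
            [b[2:] for b in bonds], dtype=float
        ).reshape(-1, 2)
        self.angles = np.array([a[:3] for a in angles], dtype=int).reshape(-1, 3)
        self.angle_params = np.array(
            [a[3:] for a in angles], dtype=float
        ).reshape(-1, 2)
        self.torsions = np.array(
            [t[:4] for t in torsions], dtype=int
        ).reshape(-1, 4)
        self.torsion_params = np.array(
            [t[4:] for t in torsions], dtype=float
        ).reshape(-1, 3)
        self.lj_params = (
            np.zeros((n_atoms, 2)) if lj_params is None
            else np.asarray(lj_params, float)
        )
        self.charges = (
            np.zeros(n_atoms) if charges is None else np.asarray(charges, float)
        )
        self.coulomb_k = coulomb_k

        exclusions = exclusions or set()
        pairs14 = pairs14 or set()
        ii, jj = np.triu_indices(n_atoms, k=1)
        keep, s_lj, s_cc = [], [], []
        for a, b in zip(ii, jj):
            key = frozenset((int(a), int(b)))
            if key in exclusions:
                continue
            keep.append((a, b))
            if key in pairs14:
                s_lj.append(scale14_lj)
                s_cc.append(scale14_coulomb)
            else:
                s_lj.append(1.0)
                s_cc.append(1.0)
        self.nb_pairs = np.array(keep, dtype=int).reshape(-1, 2)
        self.nb_scale_lj = np.array(s_lj)
        self.nb_scale_coulomb = np.array(s_cc)
        # precombine Lorentz-Berthelot parameters per pair
        if self.nb_pairs.size:
            si = self.lj_params[self.nb_pairs[:, 0]]
            sj = self.lj_params[self.nb_pairs[:, 1]]
            self.nb_sigma = 0.5 * (si[:, 0] + sj[:, 0])
            self.nb_eps = np.sqrt(si[:, 1] * sj[:, 1])
            self.nb_qq = (
                self.charges[self.nb_pairs[:, 0]]
                * self.charges[self.nb_pairs[:, 1]]
            )
        else:
            self.nb_sigma = np.zeros(0)
            self.nb_eps = np.zeros(0)
            self.nb_qq = np.zeros(0)

    # -- construction from a protein structure --------------------------
    @classmethod
    def for_structure(
        cls, structure: AllAtomStructure, params: ToyFFParams | None = None
    ) -> "ToySystem":
        params = params or ToyFFParams()
        m = structure.n_atoms
        elements = structure.elements
        names = structure.atom_names
        bonds_global = structure.bonds()

        # adjacency for angle generation and exclusions
        adj = [[] for _ in range(m)]
        for a, b in bonds_global:
            adj[a].append(b)
            adj[b].append(a)

        def topo_of(k):
            return residue_topology(structure.res_codes[k])

        def bond_r0(a, b):
            ra, rb = int(structure.res_index[a]), int(structure.res_index[b])
            na, nb = names[a], names[b]
            if "H" == na[0] or "H" == nb[0]:
                parent, h = (a, b) if nb.startswith("H") else (b, a)
                rule_parent = names[parent]
                topo = topo_of(parent)
                rule = topo.hydrogen_rules.get(rule_parent)
                if rule is not None:
                    return rule.length
                return 1.09
            if ra != rb:      # peptide bond
                return 1.329
            topo = topo_of(a)
            return topo.ideal_bond_lengths.get(frozenset((na, nb)), 1.50)

        inter_backbone_angles = {
            ("CA", "C", "N"): 116.2,
            ("O", "C", "N"): 123.0,
            ("C", "N", "CA"): 121.7,
            ("C", "N", "H"): 119.15,
            ("C", "N", "CD"): 125.0,   # proline
        }

        def angle_theta0(i, j, k):
            ni, nj, nk = names[i], names[j], names[k]
            ri, rj, rk = (int(structure.res_index[x]) for x in (i, j, k))
            if ri == rj == rk:
                topo = topo_of(j)
                for key in ((ni, nj, nk), (nk, nj, ni)):
                    if key in topo.ideal_bond_angles:
                        return topo.ideal_bond_angles[key]
            for key in ((ni, nj, nk), (nk, nj, ni)):
                if key in inter_backbone_angles:
                    return inter_backbone_angles[key]
            return params.default_angle_deg

        bonds = [
            (a, b, params.bond_k, bond_r0(a, b)) for a, b in bonds_global
        ]
        angles = []
        for j in range(m):
            nbrs = sorted(adj[j])
            for x in range(len(nbrs)):
                for y in range(x + 1, len(nbrs)):
                    i, k = nbrs[x], nbrs[y]
                    angles.append(
                        (i, j, k, params.angle_k,
                         np.radians(angle_theta0(i, j, k)))
                    )

        torsions = []
        idx = structure._index
        for r in range(1, structure.n_residues):
            quad = [
                idx.get((r - 1, "CA")), idx.get((r - 1, "C")),
                idx.get((r, "N")), idx.get((r, "CA")),
            ]
            if None not in quad:
                torsions.append((*quad, params.omega_k, 2, np.pi))
        for r in range(structure.n_residues):
            topo = residue_topology(ONE_TO_THREE[structure.sequence[r]])
            for quad_names in topo.chi_definitions:
                quad = [idx.get((r, nm)) for nm in quad_names]
                if None not in quad:
                    torsions.append((*quad, params.chi_k, 3, 0.0))

        # exclusions: 1-2 and 1-3; 1-4 scaled
        excl, p14 = set(), set()
        for a, b in bonds_global:
            excl.add(frozenset((a, b)))
        for j in range(m):
            for x in adj[j]:
                for y in adj[j]:
                    if x < y:
                        excl.add(frozenset((x, y)))
        for a, b in bonds_global:
            for x in adj[a]:
                for y in adj[b]:
                    if x == b or y == a or x == y:
                        continue
                    key = frozenset((x, y))
                    if key not in excl:
                        p14.add(key)

        lj = np.array([params.lj[el] for el in elements])
        charges = np.zeros(m)
        for k in range(m):
            nm = names[k]
            if nm in ("N", "C", "O", "H"):
                charges[k] = params.charges.get(nm, 0.0)

        return cls(
            n_atoms=m,
            bonds=bonds,
            angles=angles,
            torsions=torsions,
            lj_params=lj,
            charges=charges,
            exclusions=excl,
            pairs14=p14,
            scale14_lj=params.scale14_lj,
            scale14_coulomb=params.scale14_coulomb,
            coulomb_k=params.coulomb_k,
        )

    # -- evaluation ------------------------------------------------------
    def evaluate(self, coords: np.ndarray) -> EnergyResult:
        """Energy and analytic forces (exact negative gradient)."""
        x = np.asarray(coords, float).reshape(self.n_atoms, 3)
        U = 0.0
        F = np.zeros_like(x)

        if len(self.bonds):
            i, j = self.bonds[:, 0], self.bonds[:, 1]
            d = x[i] - x[j]
            r = np.linalg.norm(d, axis=1)
            k, r0 = self.bond_params[:, 0], self.bond_params[:, 1]
            U += float(np.sum(0.5 * k * (r - r0) ** 2))
            with np.errstate(divide="ignore", invalid="ignore"):
                f = -(k * (r - r0) / r)[:, None] * d
            f = np.nan_to_num(f, nan=0.0, posinf=np.inf, neginf=-np.inf)
            np.add.at(F, i, f)
            np.add.at(F, j, -f)

        if len(self.angles):
            ii, jj, kk = self.angles.T
            u = x[ii] - x[jj]
            v = x[kk] - x[jj]
            nu = np.linalg.norm(u, axis=1)
            nv = np.linalg.norm(v, axis=1)
            uh = u / nu[:, None]
            vh = v / nv[:, None]
            cos_t = np.clip(np.sum(uh * vh, axis=1), -1.0, 1.0)
            theta = np.arccos(cos_t)
            sin_t = np.sqrt(np.clip(1.0 - cos_t**2, 1e-12, None))
            k, t0 = self.angle_params[:, 0], self.angle_params[:, 1]
            U += float(np.sum(0.5 * k * (theta - t0) ** 2))
            dU = k * (theta - t0)
            dti = (cos_t[:, None] * uh - vh) / (nu * sin_t)[:, None]
            dtk = (cos_t[:, None] * vh - uh) / (nv * sin_t)[:, None]
            np.add.at(F, ii, -dU[:, None] * dti)
            np.add.at(F, kk, -dU[:, None] * dtk)
            np.add.at(F, jj, dU[:, None] * (dti + dtk))

        if len(self.torsions):
            ii, jj, kk, ll = self.torsions.T
            b1 = x[jj] - x[ii]
            b2 = x[kk] - x[jj]
            b3 = x[ll] - x[kk]
            n1 = np.cross(b1, b2)
            n2 = np.cross(b2, b3)
            nb2 = np.linalg.norm(b2, axis=1)
            m1 = np.cross(n1, b2 / nb2[:, None])
            phi = -np.arctan2(
                np.sum(m1 * n2, axis=1), np.sum(n1 * n2, axis=1)
            )
            kp = self.torsion_params[:, 0]
            nper = self.torsion_params[:, 1]
            phase = self.torsion_params[:, 2]
            U += float(np.sum(kp * (1.0 + np.cos(nper * phi - phase))))
            dU = -kp * nper * np.sin(nper * phi - phase)
            sn1 = np.sum(n1 * n1, axis=1)
            sn2 = np.sum(n2 * n2, axis=1)
            dphi_di = -(nb2 / sn1)[:, None] * n1
            dphi_dl = (nb2 / sn2)[:, None] * n2
            p = np.sum(b1 * b2, axis=1) / nb2**2
            q = np.sum(b3 * b2, axis=1) / nb2**2
            dphi_dj = -(1.0 + p)[:, None] * dphi_di + q[:, None] * dphi_dl
            dphi_dk = -(dphi_di + dphi_dj + dphi_dl)
            np.add.at(F, ii, -dU[:, None] * dphi_di)
            np.add.at(F, jj, -dU[:, None] * dphi_dj)
            np.add.at(F, kk, -dU[:, None] * dphi_dk)
            np.add.at(F, ll, -dU[:, None] * dphi_dl)

        if len(self.nb_pairs):
            i, j = self.nb_pairs[:, 0], self.nb_pairs[:, 1]
            d = x[i] - x[j]
            r2 = np.sum(d * d, axis=1)
            coincident = r2 == 0.0
            if coincident.any():
                # exactly overlapping atoms: the repulsive wall dominates;
                # flag via an infinite energy rather than 0*inf artefacts
                r2 = np.where(coincident, 1.0, r2)
                U = np.inf
            with np.errstate(divide="ignore", invalid="ignore"):
                inv_r2 = 1.0 / r2
                inv_r = np.sqrt(inv_r2)
                sr6 = (self.nb_sigma**2 * inv_r2) ** 3
                u_lj = self.nb_scale_lj * 4.0 * self.nb_eps * (sr6**2 - sr6)
                u_cc = (
                    self.nb_scale_coulomb * self.coulomb_k * self.nb_qq * inv_r
                )
                # dU/dr * (1/r); force on i is -dU/dr * d/r
                dudr_r = (
                    self.nb_scale_lj * 4.0 * self.nb_eps
                    * (-12.0 * sr6**2 + 6.0 * sr6) * inv_r2
                    - u_cc * inv_r2
                )
            # coincident atoms: inf - inf above; the repulsive wall wins
            u_lj = np.where(np.isnan(u_lj), np.inf, u_lj)
            U += float(np.sum(u_lj) + np.sum(u_cc))
            f = -dudr_r[:, None] * d
            np.add.at(F, i, f)
            np.add.at(F, j, -f)

        return EnergyResult(U, F, self.backend_id)


def toy_energy(
    structure: AllAtomStructure, params: ToyFFParams | None = None
) -> EnergyResult:
    """Evaluate the toy force field on an all-atom structure."""
    return ToySystem.for_structure(structure, params).evaluate(
        structure.coords
    )


# ---------------------------------------------------------------------------
# MD-engine adapter
# ---------------------------------------------------------------------------
class OpenMMSystem:
    """Adapter evaluating energies/forces with OpenMM (when installed).

    The engine's native kJ/mol/nm forces are converted exactly to
    kJ/mol/A (factor 0.1); the engine context is cached and reused for
    repeated evaluations on the same topology.
    """

    def __init__(self, structure: AllAtomStructure, spec: ForceFieldSpec):
        try:
            import openmm            # noqa: F401
            import openmm.app        # noqa: F401
            import openmm.unit       # noqa: F401
        except ImportError as exc:
            raise CapabilityError(
                "the OpenMM MD engine is not installed; use the toy backend"
            ) from exc
        import io as _io

        from openmm import app, unit, Platform, VerletIntegrator

        from .io import format_pdb

        pdb = app.PDBFile(_io.StringIO(format_pdb(structure)))
        ff = app.ForceField(
            f"{spec.force_field_name}.xml", f"implicit/{spec.solvent_model}.xml"
        )
        system = ff.createSystem(pdb.topology, nonbondedMethod=app.NoCutoff)
        self._unit = unit
        self._context = openmm.Context(
            system, VerletIntegrator(0.001), Platform.getPlatformByName("CPU")
        )
        self.backend_id = f"openmm:{spec.force_field_name}"

    def evaluate(self, coords: np.ndarray) -> EnergyResult:
        unit = self._unit
        self._context.setPositions(coords * 0.1)  # A -> nm
        state = self._context.getState(getEnergy=True, getForces=True)
        u = state.getPotentialEnergy().value_in_unit(unit.kilojoule_per_mole)
        f = state.getForces(asNumpy=True).value_in_unit(
            unit.kilojoule_per_mole / unit.nanometer
        )
        return EnergyResult(float(u), np.asarray(f) * 0.1, self.backend_id)


_OPENMM_CACHE: dict = {}


def md_engine_energy(
    structure: AllAtomStructure, spec: ForceFieldSpec | None = None
) -> EnergyResult:
    """Energy/forces from the MD engine named in ``spec``.

    Raises :class:`~forcegrad.errors.CapabilityError` when the engine is
    not installed; the toy backend covers all library functionality.
    """
    spec = spec or ForceFieldSpec(backend="openmm")
    if spec.backend == "toy":
        return toy_energy(structure)
    key = (structure.sequence, structure.n_atoms, spec)
    system = _OPENMM_CACHE.get(key)
    if system is None:
        system = OpenMMSystem(structure, spec)
        _OPENMM_CACHE[key] = system
    return system.evaluate(structure.coords)


# ---------------------------------------------------------------------------
# force / gradient verification
# ---------------------------------------------------------------------------
def check_forces(backend, coords: np.ndarray, step: float = 1e-4) -> float:
    """Maximum relative deviation between -dU/dx (central differences)
    and the backend's reported forces.

    The deviation is normalised by the largest finite-difference force
    magnitude, so a backend whose forces are off by a factor of two
    reports a deviation of about 1.
    """
    coords = np.asarray(coords, float)
    base = backend.evaluate(coords)
    if not base.finite:
        raise ValueError("non-finite energy at the evaluation point")
    m = coords.shape[0]
    f_fd = np.zeros_like(coords)
    skipped = 0
    for a in range(m):
        for d in range(3):
            xp = coords.copy()
            xm = coords.copy()
            xp[a, d] += step
            xm[a, d] -= step
            up = backend.evaluate(xp).potential_energy
            um = backend.evaluate(xm).potential_energy
            if not (np.isfinite(up) and np.isfinite(um)):
                skipped += 1
                f_fd[a, d] = base.forces[a, d]
                continue
            f_fd[a, d] = -(up - um) / (2.0 * step)
    scale = max(float(np.abs(f_fd).max()), 1e-8)
    return float(np.abs(base.forces - f_fd).max() / scale)
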