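"""Differentiable all-atom construction via natural extension of reference
frame (NeRF).

The builder turns a :class:`~forcegrad.chemistry.ProteinSample` (torsions +
bond angles) into Cartesian coordinates, optionally with hydrogens, using
only smooth elementary operations.  The same code path, run on
:class:`~forcegrad.vecmath.Dual` inputs, yields the exact Jacobian of every
coordinate with respect to any chosen subset of input angles (or, for
hydrogen addition, with respect to the heavy-atom coordinates) — this is
what lets an energy evaluated on the built structure be chained back to
the inputs analytically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import vecmath as vm
from .chemistry import (
    ANGLE_INDEX,
    BACKBONE_ANGLES,
    BACKBONE_LENGTHS,
    CB_IMPROPER_DEG,
    MAX_HEAVY_ATOMS,
    ONE_TO_THREE,
    ProteinSample,
    ResidueTopology,
    element_of,
    residue_topology,
)
from .errors import (
    BuildError,
    DegenerateFrameError,
    MeasurementError,
    PlacementError,
)

__all__ = [
    "AllAtomStructure",
    "place_atom",
    "build_all_atom",
    "build_with_jacobian",
    "add_hydrogens",
    "add_hydrogens_with_jacobian",
    "strip_hydrogens",
    "measure_internal",
]

_COLLINEAR_TOL = 1e-8
_HALF_HCH = math.radians(109.47) / 2.0


# ---------------------------------------------------------------------------
# structure container
# ---------------------------------------------------------------------------
@dataclass
class AllAtomStructure:
    """Cartesian structure with per-atom metadata.

    Atoms are ordered residue by residue: heavy atoms in topology order,
    then that residue's hydrogens (when present).
    """

    coords: np.ndarray                 # (m, 3) angstrom
    atom_names: tuple[str, ...]
    res_index: np.ndarray              # (m,) 0-based residue index
    res_codes: tuple[str, ...]         # (m,) 3-letter codes
    is_hydrogen: np.ndarray            # (m,) bool
    sequence: str
    residue_numbers: np.ndarray        # (n,) author numbering
    provenance: str = "built-from-angles"
    _index: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        if not self._index:
            self._index = {
                (int(self.res_index[k]), self.atom_names[k]): k
                for k in range(len(self.atom_names))
            }

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    @property
    def n_residues(self) -> int:
        return len(self.sequence)

    @property
    def has_hydrogens(self) -> bool:
        return bool(self.is_hydrogen.any())

    @property
    def elements(self) -> tuple[str, ...]:
        return tuple(element_of(n) for n in self.atom_names)

    def atom_index(self, res_i: int, name: str) -> int:
        try:
            return self._index[(res_i, name)]
        except KeyError:
            raise KeyError(f"no atom {name!r} in residue {res_i}") from None

    def xyz(self, res_i: int, name: str) -> np.ndarray:
        return self.coords[self.atom_index(res_i, name)]

    def bonds(self) -> list[tuple[int, int]]:
        """Global covalent bond list (heavy-heavy, peptide, and X-H)."""
        out: list[tuple[int, int]] = []
        for i in range(self.n_residues):
            topo = residue_topology(ONE_TO_THREE[self.sequence[i]])
            for a, b in topo.bonds:
                ka = self._index.get((i, a))
                kb = self._index.get((i, b))
                if ka is not None and kb is not None:
                    out.append((ka, kb))
            if i > 0:
                kc = self._index.get((i - 1, "C"))
                kn = self._index.get((i, "N"))
                if kc is not None and kn is not None:
                    out.append((kc, kn))
            for parent, rule in topo.hydrogen_rules.items():
                kp = self._index.get((i, parent))
                if kp is None:
                    continue
                for hname in rule.names:
                    kh = self._index.get((i, hname))
                    if kh is not None:
                        out.append((kp, kh))
        return out

    def replace_coords(self, coords: np.ndarray) -> "AllAtomStructure":
        return AllAtomStructure(
            coords=np.asarray(coords, float),
            atom_names=self.atom_names,
            res_index=self.res_index,
            res_codes=self.res_codes,
            is_hydrogen=self.is_hydrogen,
            sequence=self.sequence,
            residue_numbers=self.residue_numbers,
            provenance=self.provenance,
        )


def strip_hydrogens(structure: AllAtomStructure) -> AllAtomStructure:
    keep = ~structure.is_hydrogen
    idx = np.where(keep)[0]
    return AllAtomStructure(
        coords=structure.coords[idx],
        atom_names=tuple(structure.atom_names[k] for k in idx),
        res_index=structure.res_index[idx],
        res_codes=tuple(structure.res_codes[k] for k in idx),
        is_hydrogen=np.zeros(idx.size, dtype=bool),
        sequence=structure.sequence,
        residue_numbers=structure.residue_numbers,
        provenance=structure.provenance,
    )


# ---------------------------------------------------------------------------
# the NeRF primitive
# ---------------------------------------------------------------------------
def place_atom(a, b, c, bond_length, bond_angle, torsion):
    """Place atom ``d`` bonded to ``c`` given the frame ``a-b-c``.

    The result satisfies |d-c| = bond_length, angle(b, c, d) = bond_angle
    and dihedral(a, b, c, d) = torsion.  All inputs may be Dual-valued;
    the construction is composed of smooth elementary operations only, so
    exact partial derivatives flow through.
    """
    cb = c - b
    ba = b - a
    u_cb = vm.unit(cb)
    u_ba = vm.unit(ba)
    n_raw = vm.cross(u_ba, u_cb)
    n_norm = vm.value_of(vm.norm(n_raw))
    if n_norm < _COLLINEAR_TOL:
        raise DegenerateFrameError(
            "reference atoms a, b, c are (near-)collinear; torsion undefined"
        )
    n = n_raw / vm.norm(n_raw)
    m = vm.cross(n, u_cb)
    ct, st = vm.cos(bond_angle), vm.sin(bond_angle)
    cp, sp = vm.cos(torsion), vm.sin(torsion)
    return c + bond_length * ((-1.0 * ct) * u_cb + st * (cp * m + sp * n))


# ---------------------------------------------------------------------------
# building from internal coordinates
# ---------------------------------------------------------------------------
def _angle_getter(sample: ProteinSample, free: dict | None):
    """Return a lookup (res_i, name) -> float | Dual.

    ``free`` maps (res_i, name) -> Dual seed; everything else comes from
    the sample's angle table as a plain float.
    """

    def get(i: int, name: str, required: bool = True):
        key = (i, name)
        if free is not None and key in free:
            return free[key]
        j = ANGLE_INDEX[name]
        if required and not sample.angle_mask[i, j]:
            raise BuildError(
                f"residue {i}: required angle {name!r} is absent"
            )
        return float(sample.angles[i, j])

    return get


def _resolve_torsion(spec, get, i: int):
    kind = spec[0]
    if kind == "chi":
        return get(i, f"chi{spec[1]}")
    if kind == "chi+":
        return get(i, f"chi{spec[1]}") + math.radians(spec[2])
    if kind == "fixed":
        return math.radians(spec[1])
    raise BuildError(f"unknown torsion spec {spec!r}")


def _heavy_neighbors(topo: ResidueTopology, atom: str) -> list[str]:
    """Heavy neighbours of ``atom`` within the residue, in topology order."""
    nbrs = []
    for a, b in topo.bonds:
        other = b if a == atom else (a if b == atom else None)
        if other is not None and not other.startswith("H"):
            nbrs.append(other)
    order = {name: k for k, name in enumerate(topo.heavy_atoms)}
    return sorted(set(nbrs), key=lambda x: order[x])


def _place_hydrogens(pos, i, topo, get_prev_atoms):
    """Yield (name, position) for every hydrogen of residue ``i``.

    ``pos`` maps (res_i, atom_name) -> position (array or Dual);
    ``get_prev_atoms`` gives access to the previous residue for the
    backbone amide hydrogen.  Positions are smooth functions of heavy
    coordinates; discrete choices (neighbour ordering) are fixed by
    topology, never by coordinates.
    """
    for parent, rule in topo.hydrogen_rules.items():
        p = pos.get((i, parent))
        if p is None:
            raise PlacementError(
                f"residue {i}: missing heavy parent atom {parent!r}"
            )
        geom = rule.geometry
        ang = math.radians(rule.angle_deg)
        if geom == "amide":
            prev = get_prev_atoms(i)
            if prev is None:
                continue  # no amide H at the first residue
            c_prev, o_prev = prev
            yield rule.names[0], place_atom(
                o_prev, c_prev, p, rule.length, ang, math.pi
            )
            continue

        nbr_names = _heavy_neighbors(topo, parent)
        nbrs = []
        for nm in nbr_names:
            q = pos.get((i, nm))
            if q is None:
                raise PlacementError(
                    f"residue {i}: hydrogen parent {parent!r} is missing "
                    f"neighbour {nm!r}"
                )
            nbrs.append(q)

        if geom in ("sp3_1", "sp2_1"):
            units = [vm.unit(q - p) for q in nbrs]
            s = units[0]
            for u in units[1:]:
                s = s + u
            direction = -1.0 * vm.unit(s)
            yield rule.names[0], p + rule.length * direction
        elif geom == "sp3_2":
            if len(nbrs) != 2:
                raise PlacementError(
                    f"residue {i}: {parent} expects 2 heavy neighbours, "
                    f"found {len(nbrs)}"
                )
            u1, u2 = (vm.unit(q - p) for q in nbrs)
            bis = -1.0 * vm.unit(u1 + u2)
            perp = vm.unit(vm.cross(u1, u2))
            ch, sh = math.cos(_HALF_HCH), math.sin(_HALF_HCH)
            yield rule.names[0], p + rule.length * (ch * bis + sh * perp)
            yield rule.names[1], p + rule.length * (ch * bis - sh * perp)
        elif geom in ("methyl", "sp2_2", "torsion_fixed"):
            b_name = nbr_names[0]
            b = nbrs[0]
            grand_names = [
                nm for nm in _heavy_neighbors(topo, b_name) if nm != parent
            ]
            grand = None
            for nm in grand_names:
                grand = pos.get((i, nm))
                if grand is not None:
                    break
            if grand is None and b_name == "CA":
                grand = pos.get((i, "N"))
            if grand is None:
                raise PlacementError(
                    f"residue {i}: no reference grandparent for {parent}"
                )
            if geom == "methyl":
                torsions = (math.pi, -math.pi / 3.0, math.pi / 3.0)
                for hname, tau in zip(rule.names, torsions):
                    yield hname, place_atom(grand, b, p, rule.length, ang, tau)
            elif geom == "sp2_2":
                for hname, tau in zip(rule.names, (math.pi, 0.0)):
                    yield hname, place_atom(
                        grand, b, p, rule.length, math.radians(120.0), tau
                    )
            else:  # torsion_fixed: anti to the grandparent
                yield rule.names[0], place_atom(
                    grand, b, p, rule.length, ang, math.pi
                )
        else:  # pragma: no cover - table integrity
            raise PlacementError(f"unknown hydrogen geometry {geom!r}")


def _build_positions(sample: ProteinSample, include_hydrogens: bool, free=None):
    """Core z-matrix walk.  Returns (pos dict, ordered atom keys)."""
    n = sample.n_residues
    get = _angle_getter(sample, free)
    L = BACKBONE_LENGTHS
    pos: dict[tuple[int, str], object] = {}
    order: list[tuple[int, str, bool]] = []  # (res, name, is_hydrogen)

    for i in range(n):
        topo = sample.topology(i)
        if i == 0:
            ncac = get(0, "ncac")
            pos[(0, "N")] = np.zeros(3)
            pos[(0, "CA")] = np.array([L[("N", "CA")], 0.0, 0.0])
            # C in the xy-plane, completing the N-CA-C angle
            comp = math.pi - ncac
            pos[(0, "C")] = pos[(0, "CA")] + L[("CA", "C")] * (
                vm.vec3(vm.cos(comp), vm.sin(comp), 0.0)
                if vm.is_dual(ncac)
                else np.array(
                    [math.cos(vm.value_of(comp)), math.sin(vm.value_of(comp)), 0.0]
                )
            )
        else:
            pos[(i, "N")] = place_atom(
                pos[(i - 1, "N")], pos[(i - 1, "CA")], pos[(i - 1, "C")],
                L[("C", "N")], get(i - 1, "cacn"), get(i - 1, "psi"),
            )
            pos[(i, "CA")] = place_atom(
                pos[(i - 1, "CA")], pos[(i - 1, "C")], pos[(i, "N")],
                L[("N", "CA")], get(i, "cnca"), get(i, "omega"),
            )
            pos[(i, "C")] = place_atom(
                pos[(i - 1, "C")], pos[(i, "N")], pos[(i, "CA")],
                L[("CA", "C")], get(i, "ncac"), get(i, "phi"),
            )
        # carbonyl oxygen: anti to the next amide nitrogen (psi + pi)
        if sample.angle_mask[i, ANGLE_INDEX["psi"]] or (
            free is not None and (i, "psi") in free
        ):
            tor_o = get(i, "psi") + math.pi
        else:
            tor_o = math.pi
        pos[(i, "O")] = place_atom(
            pos[(i, "N")], pos[(i, "CA")], pos[(i, "C")],
            L[("C", "O")], math.radians(BACKBONE_ANGLES[("CA", "C", "O")]),
            tor_o,
        )
        order += [(i, "N", False), (i, "CA", False), (i, "C", False), (i, "O", False)]

        if "CB" in topo.heavy_atoms:
            pos[(i, "CB")] = place_atom(
                pos[(i, "N")], pos[(i, "C")], pos[(i, "CA")],
                L[("CA", "CB")],
                math.radians(BACKBONE_ANGLES[("C", "CA", "CB")]),
                math.radians(CB_IMPROPER_DEG),
            )
            order.append((i, "CB", False))
        for p in topo.sidechain:
            tor = _resolve_torsion(p.torsion, get, i)
            pos[(i, p.atom)] = place_atom(
                pos[(i, p.refs[0])], pos[(i, p.refs[1])], pos[(i, p.refs[2])],
                p.length, math.radians(p.angle_deg), tor,
            )
            order.append((i, p.atom, False))

    if include_hydrogens:
        def prev_atoms(i):
            if i == 0:
                return None
            return pos[(i - 1, "C")], pos[(i - 1, "O")]

        for i in range(n):
            topo = sample.topology(i)
            for name, p in _place_hydrogens(pos, i, topo, prev_atoms):
                pos[(i, name)] = p
                order.append((i, name, True))
        # keep atom ordering residue-contiguous: heavy then H per residue
        order.sort(key=lambda t: (t[0], t[2]))
    return pos, order


def _assemble(sample, pos, order, provenance) -> AllAtomStructure:
    coords = np.array([vm.value_of(pos[(i, nm)]) for i, nm, _ in order])
    return AllAtomStructure(
        coords=coords,
        atom_names=tuple(nm for _, nm, _ in order),
        res_index=np.array([i for i, _, _ in order], dtype=int),
        res_codes=tuple(ONE_TO_THREE[sample.sequence[i]] for i, _, _ in order),
        is_hydrogen=np.array([h for _, _, h in order], dtype=bool),
        sequence=sample.sequence,
        residue_numbers=sample.residue_numbers.copy(),
        provenance=provenance,
    )


def build_all_atom(
    sample: ProteinSample, include_hydrogens: bool = True
) -> AllAtomStructure:
    """Build Cartesian coordinates from the sample's internal coordinates.

    Backbone atoms are chained N -> CA -> C with (phi, psi, omega) and the
    per-residue backbone bond angles; bond lengths come from the ideal
    geometry table; side chains follow the per-residue z-matrix driven by
    chi angles; hydrogens are appended per the hydrogen rules.
    """
    pos, order = _build_positions(sample, include_hydrogens)
    return _assemble(
        sample, pos, order,
        "built-from-angles",
    )


def build_with_jacobian(
    sample: ProteinSample,
    free_angles: list[tuple[int, str]],
    include_hydrogens: bool = True,
):
    """Build and differentiate: returns (structure, J).

    ``J`` has shape (n_atoms, 3, P) with P = len(free_angles); it is the
    exact Jacobian of every atomic coordinate with respect to the listed
    angle slots, computed by forward-mode differentiation through the
    entire construction (including hydrogen placement).
    """
    values = [sample.angles[i, ANGLE_INDEX[name]] for i, name in free_angles]
    seeds = vm.seed_params(values)
    free = {key: s for key, s in zip(free_angles, seeds)}
    pos, order = _build_positions(sample, include_hydrogens, free=free)
    structure = _assemble(sample, pos, order, "built-from-angles")
    P = len(free_angles)
    J = np.zeros((len(order), 3, P))
    for k, (i, nm, _) in enumerate(order):
        p = pos[(i, nm)]
        if vm.is_dual(p):
            J[k] = p.jac
    return structure, J


# ---------------------------------------------------------------------------
# hydrogen addition to existing heavy-atom coordinates
# ---------------------------------------------------------------------------
def _hydrogen_pass(structure: AllAtomStructure, pos):
    """Run hydrogen placement over ``pos`` (which may hold Duals)."""
    n = structure.n_residues
    order = []
    def prev_atoms(i):
        if i == 0:
            return None
        return pos[(i - 1, "C")], pos[(i - 1, "O")]

    for i in range(n):
        topo = residue_topology(ONE_TO_THREE[structure.sequence[i]])
        for name, p in _place_hydrogens(pos, i, topo, prev_atoms):
            pos[(i, name)] = p
            order.append((i, name))
    return order


def add_hydrogens(heavy: AllAtomStructure) -> AllAtomStructure:
    """Append hydrogens at idealized geometry to a heavy-atom structure.

    Hydrogen positions are deterministic, smooth functions of the heavy
    coordinates ("consistent, predetermined conformations"); heavy-atom
    coordinates pass through bit-for-bit unchanged.  Idempotent: a
    structure that already carries hydrogens is returned as-is.
    """
    if heavy.has_hydrogens:
        return heavy
    pos = {
        (int(heavy.res_index[k]), heavy.atom_names[k]): heavy.coords[k]
        for k in range(heavy.n_atoms)
    }
    h_order = _hydrogen_pass(heavy, pos)

    order = []
    for i in range(heavy.n_residues):
        order += [
            (int(heavy.res_index[k]), heavy.atom_names[k], False)
            for k in range(heavy.n_atoms)
            if heavy.res_index[k] == i
        ]
        order += [(ri, nm, True) for ri, nm in h_order if ri == i]
    coords = np.array([vm.value_of(pos[(i, nm)]) for i, nm, _ in order])
    return AllAtomStructure(
        coords=coords,
        atom_names=tuple(nm for _, nm, _ in order),
        res_index=np.array([i for i, _, _ in order], dtype=int),
        res_codes=tuple(
            ONE_TO_THREE[heavy.sequence[i]] for i, _, _ in order
        ),
        is_hydrogen=np.array([h for _, _, h in order], dtype=bool),
        sequence=heavy.sequence,
        residue_numbers=heavy.residue_numbers.copy(),
        provenance="hydrogens-added-to-heavy",
    )


def add_hydrogens_with_jacobian(heavy: AllAtomStructure):
    """Like :func:`add_hydrogens` but also return dX_all/dX_heavy.

    Returns (structure, J) where J has shape (n_all, 3, 3 * n_heavy): the
    Jacobian of all coordinates (hydrogens included) with respect to the
    flattened heavy-atom coordinates.  Heavy rows are the identity.
    """
    if heavy.has_hydrogens:
        raise PlacementError("input already contains hydrogens")
    n_heavy = heavy.n_atoms
    seeds = vm.seed_params(heavy.coords.reshape(-1))
    pos = {}
    for k in range(n_heavy):
        key = (int(heavy.res_index[k]), heavy.atom_names[k])
        comps = seeds[3 * k: 3 * k + 3]
        pos[key] = vm.vec3(*comps)
    h_order = _hydrogen_pass(heavy, pos)

    order = []
    for i in range(heavy.n_residues):
        order += [
            (int(heavy.res_index[k]), heavy.atom_names[k], False)
            for k in range(n_heavy)
            if heavy.res_index[k] == i
        ]
        order += [(ri, nm, True) for ri, nm in h_order if ri == i]
    coords = np.array([vm.value_of(pos[(i, nm)]) for i, nm, _ in order])
    J = np.array([pos[(i, nm)].jac for i, nm, _ in order])
    structure = AllAtomStructure(
        coords=coords,
        atom_names=tuple(nm for _, nm, _ in order),
        res_index=np.array([i for i, _, _ in order], dtype=int),
        res_codes=tuple(ONE_TO_THREE[heavy.sequence[i]] for i, _, _ in order),
        is_hydrogen=np.array([h for _, _, h in order], dtype=bool),
        sequence=heavy.sequence,
        residue_numbers=heavy.residue_numbers.copy(),
        provenance="hydrogens-added-to-heavy",
    )
    return structure, J


# ---------------------------------------------------------------------------
# inverse: measure internal coordinates from Cartesian coordinates
# ---------------------------------------------------------------------------
def measure_internal(structure: AllAtomStructure) -> ProteinSample:
    """Measure (phi, psi, omega), backbone bond angles and chi angles.

    First/last residues carry absent flags for the torsions that lack a
    fourth reference atom.  Heavy-atom coordinates are copied into the
    returned sample's padded arrays.
    """
    n = structure.n_residues
    sample = ProteinSample.empty(structure.sequence, id="measured")
    sample.residue_numbers = structure.residue_numbers.copy()

    def xyz(i, name):
        return structure.xyz(i, name)

    for i in range(n):
        topo = residue_topology(ONE_TO_THREE[structure.sequence[i]])
        try:
            N, CA, C = xyz(i, "N"), xyz(i, "CA"), xyz(i, "C")
        except KeyError as exc:
            raise MeasurementError(str(exc)) from None
        if (
            np.linalg.norm(np.cross(CA - N, C - CA))
            < _COLLINEAR_TOL * np.linalg.norm(CA - N) * np.linalg.norm(C - CA)
        ):
            raise MeasurementError(f"residue {i}: collinear backbone N-CA-C")
        sample.set_angle(i, "ncac", vm.bond_angle(N, CA, C))
        if i > 0:
            Cp = xyz(i - 1, "C")
            CAp = xyz(i - 1, "CA")
            sample.set_angle(i, "phi", vm.dihedral(Cp, N, CA, C))
            sample.set_angle(i, "omega", vm.dihedral(CAp, Cp, N, CA))
            sample.set_angle(i, "cnca", vm.bond_angle(Cp, N, CA))
        if i < n - 1:
            Nn = xyz(i + 1, "N")
            sample.set_angle(i, "psi", vm.dihedral(N, CA, C, Nn))
            sample.set_angle(i, "cacn", vm.bond_angle(CA, C, Nn))
        for k, quad in enumerate(topo.chi_definitions):
            try:
                pts = [xyz(i, nm) for nm in quad]
            except KeyError as exc:
                raise MeasurementError(str(exc)) from None
            sample.set_angle(i, f"chi{k + 1}", vm.dihedral(*pts))
        for j, name in enumerate(topo.heavy_atoms):
            sample.heavy_coords[i, j] = xyz(i, name)
            sample.heavy_mask[i, j] = True
    return sample
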