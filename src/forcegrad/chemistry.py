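"""Residue chemistry tables and the internal-coordinate protein data model.

A protein is carried through the package as a :class:`ProteinSample`: a
sequence, a per-residue table of torsion and bond angles (radians), and
padded per-residue heavy-atom coordinates.  Side-chain and backbone
geometry (ideal bond lengths/angles, torsion definitions, hydrogen
placement rules) is tabulated here once, per residue type, and consumed
by the builder, the energy backends and the minimizer.

Conventions
-----------
* Coordinates in angstroms; angles stored in radians, reported in
  degrees at the CLI.
* Residue indexing is 0-based internally, 1-based in files and messages.
* Atom ordering within a residue is the documented order of
  ``ResidueTopology.heavy_atoms`` (backbone N, CA, C, O first, then side
  chain in build order).
* Histidine is the N-epsilon tautomer; ASP/GLU carry no acidic proton,
  LYS and ARG are protonated (pH-7 defaults).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateInputError, UnsupportedResidueError

__all__ = [
    "ANGLE_NAMES",
    "N_ANGLE_SLOTS",
    "MAX_HEAVY_ATOMS",
    "THREE_TO_ONE",
    "ONE_TO_THREE",
    "STANDARD_RESIDUES",
    "HydrogenRule",
    "SidechainPlacement",
    "ResidueTopology",
    "ProteinSample",
    "GapReport",
    "residue_topology",
    "detect_gaps",
    "validate_sample",
    "element_of",
    "BACKBONE_LENGTHS",
    "BACKBONE_ANGLES",
    "CB_IMPROPER_DEG",
]

# ---------------------------------------------------------------------------
# angle-slot layout of a ProteinSample (one row per residue)
# ---------------------------------------------------------------------------
#: torsions phi/psi/omega, the three backbone bond angles
#: (N-CA-C, CA-C-N(+1), C(-1)-N-CA), then side-chain torsions chi1..chi6
ANGLE_NAMES = (
    "phi", "psi", "omega",
    "ncac", "cacn", "cnca",
    "chi1", "chi2", "chi3", "chi4", "chi5", "chi6",
)
N_ANGLE_SLOTS = len(ANGLE_NAMES)
ANGLE_INDEX = {name: i for i, name in enumerate(ANGLE_NAMES)}

MAX_HEAVY_ATOMS = 14  # tryptophan

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}
STANDARD_RESIDUES = tuple(sorted(THREE_TO_ONE))


def element_of(atom_name: str) -> str:
    """Element symbol from a (package-convention) PDB atom name."""
    ch = atom_name.strip()[0]
    if ch in "0123456789":  # e.g. rare 1HB-style names; we never emit these
        ch = atom_name.strip()[1]
    return ch


# ---------------------------------------------------------------------------
# backbone ideal geometry (Engh & Huber style values, angstrom / degrees)
# ---------------------------------------------------------------------------
BACKBONE_LENGTHS = {
    ("N", "CA"): 1.458,
    ("CA", "C"): 1.525,
    ("C", "N"): 1.329,   # peptide bond to next residue
    ("C", "O"): 1.231,
    ("CA", "CB"): 1.530,
}
BACKBONE_ANGLES = {
    ("N", "CA", "C"): 111.2,
    ("CA", "C", "N"): 116.2,   # to next residue
    ("C", "N", "CA"): 121.7,   # from previous residue
    ("CA", "C", "O"): 120.8,
    ("C", "CA", "CB"): 110.1,
    ("N", "CA", "CB"): 110.5,
}

#: improper torsion dihedral(N, C, CA, CB) fixing the L configuration at CA.
#: Magnitude follows from the three tetrahedral angles above; the sign is
#: the one that reproduces the conventional L-amino-acid frame.
CB_IMPROPER_DEG = 122.8


# ---------------------------------------------------------------------------
# table record types
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class HydrogenRule:
    """Hydrogens attached to one heavy atom.

    ``geometry`` is the placement class used by the builder:

    ``amide``
        backbone N-H, planar, anti to the preceding carbonyl oxygen;
    ``sp3_1`` / ``sp3_2``
        completion of a tetrahedral centre with 3 / 2 known heavy
        neighbours;
    ``methyl``
        three-fold rotor staggered against the preceding heavy-atom
        torsion (also used for the LYS ammonium group);
    ``sp2_1`` / ``sp2_2``
        planar centre with 2 / 1 known heavy neighbours;
    ``torsion_fixed``
        single rotatable proton (hydroxyl, thiol) placed anti to the
        grandparent heavy atom.
    """

    names: tuple[str, ...]
    length: float           # X-H bond length, angstrom
    geometry: str
    angle_deg: float = 109.5


@dataclass(frozen=True)
class SidechainPlacement:
    """One z-matrix row: ``atom`` is bonded to ``refs[2]`` and placed from
    the frame (refs[0], refs[1], refs[2]) with the given ideal bond length
    (angstrom), bond angle (degrees) and torsion specifier.

    torsion specifiers: ``("chi", k)`` uses chi_k; ``("chi+", k, off)``
    uses chi_k plus a fixed offset in degrees (branch atoms);
    ``("fixed", deg)`` is a rigid (ring/planar-group) torsion.
    """

    atom: str
    refs: tuple[str, str, str]
    length: float
    angle_deg: float
    torsion: tuple


@dataclass(frozen=True)
class ResidueTopology:
    residue_code: str
    heavy_atoms: tuple[str, ...]
    bonds: tuple[tuple[str, str], ...]
    ideal_bond_lengths: dict
    ideal_bond_angles: dict
    chi_definitions: tuple[tuple[str, str, str, str], ...]
    hydrogen_rules: dict          # parent heavy atom -> HydrogenRule
    sidechain: tuple[SidechainPlacement, ...]
    ring_closures: tuple[tuple[str, str], ...] = ()

    @property
    def n_chi(self) -> int:
        return len(self.chi_definitions)

    @property
    def hydrogen_count(self) -> int:
        return sum(len(r.names) for r in self.hydrogen_rules.values())


def _sc(atom, refs, length, angle, torsion):
    return SidechainPlacement(atom, refs, length, angle, torsion)


# Side-chain z-matrices.  refs are atom names within the residue; the
# placed atom is covalently bonded to refs[2].  Values are standard
# stereochemical-dictionary numbers (rounded); they can be overridden by a
# force-field geometry file at the io layer.
_SIDE = {
    "ALA": [],
    "GLY": [],
    "SER": [_sc("OG", ("N", "CA", "CB"), 1.417, 110.8, ("chi", 1))],
    "CYS": [_sc("SG", ("N", "CA", "CB"), 1.808, 114.2, ("chi", 1))],
    "THR": [
        _sc("OG1", ("N", "CA", "CB"), 1.433, 109.6, ("chi", 1)),
        _sc("CG2", ("N", "CA", "CB"), 1.521, 111.5, ("chi+", 1, -120.0)),
    ],
    "VAL": [
        _sc("CG1", ("N", "CA", "CB"), 1.521, 110.5, ("chi", 1)),
        _sc("CG2", ("N", "CA", "CB"), 1.521, 110.5, ("chi+", 1, 122.3)),
    ],
    "ILE": [
        _sc("CG1", ("N", "CA", "CB"), 1.530, 110.4, ("chi", 1)),
        _sc("CG2", ("N", "CA", "CB"), 1.521, 110.5, ("chi+", 1, 122.3)),
        _sc("CD1", ("CA", "CB", "CG1"), 1.513, 113.8, ("chi", 2)),
    ],
    "LEU": [
        _sc("CG", ("N", "CA", "CB"), 1.530, 116.3, ("chi", 1)),
        _sc("CD1", ("CA", "CB", "CG"), 1.521, 110.7, ("chi", 2)),
        _sc("CD2", ("CA", "CB", "CG"), 1.521, 110.7, ("chi+", 2, 122.0)),
    ],
    "ASP": [
        _sc("CG", ("N", "CA", "CB"), 1.516, 112.6, ("chi", 1)),
        _sc("OD1", ("CA", "CB", "CG"), 1.249, 118.4, ("chi", 2)),
        _sc("OD2", ("CA", "CB", "CG"), 1.249, 118.4, ("chi+", 2, 180.0)),
    ],
    "ASN": [
        _sc("CG", ("N", "CA", "CB"), 1.516, 112.6, ("chi", 1)),
        _sc("OD1", ("CA", "CB", "CG"), 1.231, 120.8, ("chi", 2)),
        _sc("ND2", ("CA", "CB", "CG"), 1.328, 116.4, ("chi+", 2, 180.0)),
    ],
    "GLU": [
        _sc("CG", ("N", "CA", "CB"), 1.530, 114.1, ("chi", 1)),
        _sc("CD", ("CA", "CB", "CG"), 1.516, 112.6, ("chi", 2)),
        _sc("OE1", ("CB", "CG", "CD"), 1.249, 118.4, ("chi", 3)),
        _sc("OE2", ("CB", "CG", "CD"), 1.249, 118.4, ("chi+", 3, 180.0)),
    ],
    "GLN": [
        _sc("CG", ("N", "CA", "CB"), 1.530, 114.1, ("chi", 1)),
        _sc("CD", ("CA", "CB", "CG"), 1.516, 112.6, ("chi", 2)),
        _sc("OE1", ("CB", "CG", "CD"), 1.231, 120.8, ("chi", 3)),
        _sc("NE2", ("CB", "CG", "CD"), 1.328, 116.4, ("chi+", 3, 180.0)),
    ],
    "MET": [
        _sc("CG", ("N", "CA", "CB"), 1.530, 114.1, ("chi", 1)),
        _sc("SD", ("CA", "CB", "CG"), 1.803, 112.7, ("chi", 2)),
        _sc("CE", ("CB", "CG", "SD"), 1.791, 100.9, ("chi", 3)),
    ],
    "LYS": [
        _sc("CG", ("N", "CA", "CB"), 1.530, 114.1, ("chi", 1)),
        _sc("CD", ("CA", "CB", "CG"), 1.530, 111.3, ("chi", 2)),
        _sc("CE", ("CB", "CG", "CD"), 1.530, 111.3, ("chi", 3)),
        _sc("NZ", ("CG", "CD", "CE"), 1.489, 112.0, ("chi", 4)),
    ],
    "ARG": [
        _sc("CG", ("N", "CA", "CB"), 1.530, 114.1, ("chi", 1)),
        _sc("CD", ("CA", "CB", "CG"), 1.530, 111.3, ("chi", 2)),
        _sc("NE", ("CB", "CG", "CD"), 1.461, 112.0, ("chi", 3)),
        _sc("CZ", ("CG", "CD", "NE"), 1.329, 124.2, ("chi", 4)),
        _sc("NH1", ("CD", "NE", "CZ"), 1.326, 120.0, ("fixed", 0.0)),
        _sc("NH2", ("CD", "NE", "CZ"), 1.326, 120.0, ("fixed", 180.0)),
    ],
    "PHE": [
        _sc("CG", ("N", "CA", "CB"), 1.502, 113.8, ("chi", 1)),
        _sc("CD1", ("CA", "CB", "CG"), 1.390, 120.7, ("chi", 2)),
        _sc("CD2", ("CA", "CB", "CG"), 1.390, 120.7, ("chi+", 2, 180.0)),
        _sc("CE1", ("CB", "CG", "CD1"), 1.390, 120.7, ("fixed", 180.0)),
        _sc("CE2", ("CB", "CG", "CD2"), 1.390, 120.7, ("fixed", 180.0)),
        _sc("CZ", ("CG", "CD1", "CE1"), 1.390, 120.0, ("fixed", 0.0)),
    ],
    "TYR": [
        _sc("CG", ("N", "CA", "CB"), 1.502, 113.8, ("chi", 1)),
        _sc("CD1", ("CA", "CB", "CG"), 1.390, 120.7, ("chi", 2)),
        _sc("CD2", ("CA", "CB", "CG"), 1.390, 120.7, ("chi+", 2, 180.0)),
        _sc("CE1", ("CB", "CG", "CD1"), 1.390, 120.7, ("fixed", 180.0)),
        _sc("CE2", ("CB", "CG", "CD2"), 1.390, 120.7, ("fixed", 180.0)),
        _sc("CZ", ("CG", "CD1", "CE1"), 1.390, 120.0, ("fixed", 0.0)),
        _sc("OH", ("CD1", "CE1", "CZ"), 1.376, 119.9, ("fixed", 180.0)),
    ],
    "HIS": [
        _sc("CG", ("N", "CA", "CB"), 1.497, 113.8, ("chi", 1)),
        _sc("ND1", ("CA", "CB", "CG"), 1.371, 122.7, ("chi", 2)),
        _sc("CD2", ("CA", "CB", "CG"), 1.356, 131.1, ("chi+", 2, 180.0)),
        _sc("CE1", ("CB", "CG", "ND1"), 1.321, 109.3, ("fixed", 180.0)),
        _sc("NE2", ("CG", "ND1", "CE1"), 1.324, 111.7, ("fixed", 0.0)),
    ],
    "TRP": [
        _sc("CG", ("N", "CA", "CB"), 1.498, 113.6, ("chi", 1)),
        _sc("CD1", ("CA", "CB", "CG"), 1.365, 126.9, ("chi", 2)),
        _sc("CD2", ("CA", "CB", "CG"), 1.433, 126.7, ("chi+", 2, 180.0)),
        _sc("NE1", ("CB", "CG", "CD1"), 1.374, 110.2, ("fixed", 180.0)),
        _sc("CE2", ("CB", "CG", "CD2"), 1.409, 107.2, ("fixed", 180.0)),
        _sc("CE3", ("CB", "CG", "CD2"), 1.398, 133.9, ("fixed", 0.0)),
        _sc("CZ2", ("CG", "CD2", "CE2"), 1.394, 122.4, ("fixed", 180.0)),
        _sc("CZ3", ("CG", "CD2", "CE3"), 1.382, 118.6, ("fixed", 180.0)),
        _sc("CH2", ("CD2", "CE2", "CZ2"), 1.368, 117.5, ("fixed", 0.0)),
    ],
    "PRO": [
        _sc("CG", ("N", "CA", "CB"), 1.492, 104.5, ("chi", 1)),
        _sc("CD", ("CA", "CB", "CG"), 1.503, 106.1, ("chi", 2)),
    ],
}

# bonds that close rings (not independently placeable by the z-matrix),
# with their dictionary ideal lengths
_RING_CLOSURES = {
    "HIS": ((("NE2", "CD2"), 1.374),),
    "PHE": ((("CE2", "CZ"), 1.390),),
    "TYR": ((("CE2", "CZ"), 1.390),),
    "TRP": ((("NE1", "CE2"), 1.370), (("CZ3", "CH2"), 1.400)),
    "PRO": ((("CD", "N"), 1.473),),
}

_AROMATIC_CH = 1.080
_NH = 1.010
_OH = 0.960
_SH = 1.340
_CH = 1.090

# hydrogen rules beyond the shared backbone N-H / CA-H entries
_SIDE_H = {
    "ALA": {"CB": ("HB1 HB2 HB3", _CH, "methyl")},
    "ARG": {
        "CB": ("HB2 HB3", _CH, "sp3_2"),
        "CG": ("HG2 HG3", _CH, "sp3_2"),
        "CD": ("HD2 HD3", _CH, "sp3_2"),
        "NE": ("HE", _NH, "sp2_1"),
        "NH1": ("HH11 HH12", _NH, "sp2_2"),
        "NH2": ("HH21 HH22", _NH, "sp2_2"),
    },
    "ASN": {"CB": ("HB2 HB3", _CH, "sp3_2"), "ND2": ("HD21 HD22", _NH, "sp2_2")},
    "ASP": {"CB": ("HB2 HB3", _CH, "sp3_2")},
    "CYS": {"CB": ("HB2 HB3", _CH, "sp3_2"), "SG": ("HG", _SH, "torsion_fixed", 96.0)},
    "GLN": {
        "CB": ("HB2 HB3", _CH, "sp3_2"),
        "CG": ("HG2 HG3", _CH, "sp3_2"),
        "NE2": ("HE21 HE22", _NH, "sp2_2"),
    },
    "GLU": {"CB": ("HB2 HB3", _CH, "sp3_2"), "CG": ("HG2 HG3", _CH, "sp3_2")},
    "GLY": {},
    "HIS": {
        "CB": ("HB2 HB3", _CH, "sp3_2"),
        "CD2": ("HD2", _AROMATIC_CH, "sp2_1"),
        "CE1": ("HE1", _AROMATIC_CH, "sp2_1"),
        "NE2": ("HE2", _NH, "sp2_1"),       # N-epsilon tautomer
    },
    "ILE": {
        "CB": ("HB", _CH, "sp3_1"),
        "CG1": ("HG12 HG13", _CH, "sp3_2"),
        "CG2": ("HG21 HG22 HG23", _CH, "methyl"),
        "CD1": ("HD11 HD12 HD13", _CH, "methyl"),
    },
    "LEU": {
        "CB": ("HB2 HB3", _CH, "sp3_2"),
        "CG": ("HG", _CH, "sp3_1"),
        "CD1": ("HD11 HD12 HD13", _CH, "methyl"),
        "CD2": ("HD21 HD22 HD23", _CH, "methyl"),
    },
    "LYS": {
        "CB": ("HB2 HB3", _CH, "sp3_2"),
        "CG": ("HG2 HG3", _CH, "sp3_2"),
        "CD": ("HD2 HD3", _CH, "sp3_2"),
        "CE": ("HE2 HE3", _CH, "sp3_2"),
        "NZ": ("HZ1 HZ2 HZ3", _NH, "methyl"),   # protonated ammonium
    },
    "MET": {
        "CB": ("HB2 HB3", _CH, "sp3_2"),
        "CG": ("HG2 HG3", _CH, "sp3_2"),
        "CE": ("HE1 HE2 HE3", _CH, "methyl"),
    },
    "PHE": {
        "CB": ("HB2 HB3", _CH, "sp3_2"),
        "CD1": ("HD1", _AROMATIC_CH, "sp2_1"),
        "CD2": ("HD2", _AROMATIC_CH, "sp2_1"),
        "CE1": ("HE1", _AROMATIC_CH, "sp2_1"),
        "CE2": ("HE2", _AROMATIC_CH, "sp2_1"),
        "CZ": ("HZ", _AROMATIC_CH, "sp2_1"),
    },
    "PRO": {
        "CB": ("HB2 HB3", _CH, "sp3_2"),
        "CG": ("HG2 HG3", _CH, "sp3_2"),
        "CD": ("HD2 HD3", _CH, "sp3_2"),
    },
    "SER": {"CB": ("HB2 HB3", _CH, "sp3_2"), "OG": ("HG", _OH, "torsion_fixed", 108.5)},
    "THR": {
        "CB": ("HB", _CH, "sp3_1"),
        "OG1": ("HG1", _OH, "torsion_fixed", 108.5),
        "CG2": ("HG21 HG22 HG23", _CH, "methyl"),
    },
    "TRP": {
        "CB": ("HB2 HB3", _CH, "sp3_2"),
        "CD1": ("HD1", _AROMATIC_CH, "sp2_1"),
        "NE1": ("HE1", _NH, "sp2_1"),
        "CE3": ("HE3", _AROMATIC_CH, "sp2_1"),
        "CZ2": ("HZ2", _AROMATIC_CH, "sp2_1"),
        "CZ3": ("HZ3", _AROMATIC_CH, "sp2_1"),
        "CH2": ("HH2", _AROMATIC_CH, "sp2_1"),
    },
    "TYR": {
        "CB": ("HB2 HB3", _CH, "sp3_2"),
        "CD1": ("HD1", _AROMATIC_CH, "sp2_1"),
        "CD2": ("HD2", _AROMATIC_CH, "sp2_1"),
        "CE1": ("HE1", _AROMATIC_CH, "sp2_1"),
        "CE2": ("HE2", _AROMATIC_CH, "sp2_1"),
        "OH": ("HH", _OH, "torsion_fixed", 108.5),
    },
    "VAL": {
        "CB": ("HB", _CH, "sp3_1"),
        "CG1": ("HG11 HG12 HG13", _CH, "methyl"),
        "CG2": ("HG21 HG22 HG23", _CH, "methyl"),
    },
}


def _build_topology(code: str) -> ResidueTopology:
    side = _SIDE[code]
    heavy = ["N", "CA", "C", "O"]
    if code != "GLY":
        heavy.append("CB")
    heavy.extend(p.atom for p in side)

    bonds = [("N", "CA"), ("CA", "C"), ("C", "O")]
    lengths = {
        frozenset(k): v for k, v in BACKBONE_LENGTHS.items() if k != ("C", "N")
    }
    angles = {k: v for k, v in BACKBONE_ANGLES.items()}
    if code != "GLY":
        bonds.append(("CA", "CB"))
    for p in side:
        bonds.append((p.refs[2], p.atom))
        lengths[frozenset((p.refs[2], p.atom))] = p.length
        angles[(p.refs[1], p.refs[2], p.atom)] = p.angle_deg
    closures = tuple(pair for pair, _len in _RING_CLOSURES.get(code, ()))
    for pair, ideal in _RING_CLOSURES.get(code, ()):
        bonds.append(pair)
        lengths[frozenset(pair)] = ideal

    chi = []
    for p in side:
        if p.torsion[0] == "chi":
            k = p.torsion[1]
            assert k == len(chi) + 1, f"{code}: chi order broken"
            chi.append((p.refs[0], p.refs[1], p.refs[2], p.atom))

    hrules = {}
    if code != "PRO":  # proline nitrogen is tertiary: no amide hydrogen
        hrules["N"] = HydrogenRule(("H",), _NH, "amide", 119.15)
    if code == "GLY":
        hrules["CA"] = HydrogenRule(("HA2", "HA3"), _CH, "sp3_2")
    else:
        hrules["CA"] = HydrogenRule(("HA",), _CH, "sp3_1")
    for parent, spec in _SIDE_H[code].items():
        names = tuple(spec[0].split())
        angle = spec[3] if len(spec) > 3 else 109.5
        hrules[parent] = HydrogenRule(names, spec[1], spec[2], angle)

    return ResidueTopology(
        residue_code=code,
        heavy_atoms=tuple(heavy),
        bonds=tuple(bonds),
        ideal_bond_lengths=lengths,
        ideal_bond_angles=angles,
        chi_definitions=tuple(chi),
        hydrogen_rules=hrules,
        sidechain=tuple(side),
        ring_closures=closures,
    )


_TOPOLOGIES = {code: _build_topology(code) for code in STANDARD_RESIDUES}


def residue_topology(code: str) -> ResidueTopology:
    """Immutable chemistry table entry for a 3-letter residue code."""
    code = code.upper()
    if code not in _TOPOLOGIES:
        raise UnsupportedResidueError(
            f"unsupported residue {code!r}: only the 20 standard amino acids"
        )
    return _TOPOLOGIES[code]


# ---------------------------------------------------------------------------
# protein sample container
# ---------------------------------------------------------------------------
@dataclass
class ProteinSample:
    """A single-chain protein in internal-coordinate + heavy-atom form.

    ``angles``/``angle_mask`` have shape ``(n, 12)`` laid out per
    :data:`ANGLE_NAMES`; ``heavy_coords``/``heavy_mask`` are padded to
    :data:`MAX_HEAVY_ATOMS` per residue in topology atom order.
    """

    sequence: str
    angles: np.ndarray
    angle_mask: np.ndarray
    heavy_coords: np.ndarray
    heavy_mask: np.ndarray
    residue_numbers: np.ndarray
    id: str = ""

    @property
    def n_residues(self) -> int:
        return len(self.sequence)

    def topology(self, i: int) -> ResidueTopology:
        return residue_topology(ONE_TO_THREE[self.sequence[i]])

    def angle(self, i: int, name: str) -> float:
        return float(self.angles[i, ANGLE_INDEX[name]])

    def set_angle(self, i: int, name: str, value: float, present: bool = True):
        j = ANGLE_INDEX[name]
        self.angles[i, j] = value
        self.angle_mask[i, j] = present

    def copy(self) -> "ProteinSample":
        return ProteinSample(
            sequence=self.sequence,
            angles=self.angles.copy(),
            angle_mask=self.angle_mask.copy(),
            heavy_coords=self.heavy_coords.copy(),
            heavy_mask=self.heavy_mask.copy(),
            residue_numbers=self.residue_numbers.copy(),
            id=self.id,
        )

    @classmethod
    def empty(cls, sequence: str, id: str = "") -> "ProteinSample":
        n = len(sequence)
        for aa in sequence:
            if aa not in ONE_TO_THREE:
                raise UnsupportedResidueError(f"unknown 1-letter code {aa!r}")
        return cls(
            sequence=sequence,
            angles=np.zeros((n, N_ANGLE_SLOTS)),
            angle_mask=np.zeros((n, N_ANGLE_SLOTS), dtype=bool),
            heavy_coords=np.full((n, MAX_HEAVY_ATOMS, 3), np.nan),
            heavy_mask=np.zeros((n, MAX_HEAVY_ATOMS), dtype=bool),
            residue_numbers=np.arange(1, n + 1),
            id=id,
        )


@dataclass(frozen=True)
class GapReport:
    gap_positions: tuple[tuple[int, int], ...]

    @property
    def has_gaps(self) -> bool:
        return len(self.gap_positions) > 0


def detect_gaps(sample: ProteinSample, ca_break_cutoff: float = 4.5) -> GapReport:
    """Report chain breaks between consecutive residues.

    A gap is flagged when either residue lacks a CA, the author numbering
    is non-consecutive, or the CA-CA distance exceeds ``ca_break_cutoff``
    (default 4.5 A; trans peptide spacing is ~3.8 A, cis ~2.9 A).
    """
    n = sample.n_residues
    if n < 2:
        raise DegenerateInputError("need at least 2 residues to detect gaps")
    gaps = []
    for i in range(n - 1):
        ca_i_ok = bool(sample.heavy_mask[i, 1])
        ca_j_ok = bool(sample.heavy_mask[i + 1, 1])
        if not (ca_i_ok and ca_j_ok):
            gaps.append((i, i + 1))
            continue
        if sample.residue_numbers[i + 1] != sample.residue_numbers[i] + 1:
            gaps.append((i, i + 1))
            continue
        d = np.linalg.norm(
            sample.heavy_coords[i + 1, 1] - sample.heavy_coords[i, 1]
        )
        if d > ca_break_cutoff:
            gaps.append((i, i + 1))
    return GapReport(tuple(gaps))


def validate_sample(sample: ProteinSample) -> list[str]:
    """Return human-readable invariant violations (empty list = valid)."""
    out: list[str] = []
    n = sample.n_residues
    if n < 2:
        out.append("sample: fewer than 2 residues")
    for i, aa in enumerate(sample.sequence):
        if aa not in ONE_TO_THREE:
            out.append(f"residue {i}: unknown code {aa!r}")
            continue
        topo = sample.topology(i)
        mask = sample.angle_mask[i]
        vals = sample.angles[i]
        for j, name in enumerate(ANGLE_NAMES):
            if mask[j] and not (-math.pi < vals[j] <= math.pi + 1e-12):
                out.append(f"residue {i}: angle {name} out of range (-pi, pi]")
        for k in range(topo.n_chi, 6):
            if mask[ANGLE_INDEX[f"chi{k + 1}"]]:
                out.append(
                    f"residue {i}: chi{k + 1} flagged present but "
                    f"{topo.residue_code} has only {topo.n_chi} chi angles"
                )
        hm = sample.heavy_mask[i]
        hc = sample.heavy_coords[i]
        if hm[len(topo.heavy_atoms):].any():
            out.append(f"residue {i}: heavy-atom mask set beyond topology")
        present = np.where(hm)[0]
        if present.size and not np.isfinite(hc[present]).all():
            out.append(f"residue {i}: non-finite coordinate under set mask")
    return out
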