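"""PDB input/output, synthetic fixture generation and configuration.

PDB is the sole structure format (single model, single chain, standard
residues).  Reading rejects — rather than silently drops — HETATM
records, alternate locations, insertion codes and non-standard residues;
the terminal OXT oxygen is the one exception and is ignored, matching
the package's neutral-terminus convention.  Residues are numbered
1-based in files and messages, 0-based internally.
"""

from __future__ import annotations

import io as _io
import math
from dataclasses import dataclass

import numpy as np
import yaml

from .chemistry import (
    ANGLE_INDEX,
    ONE_TO_THREE,
    ProteinSample,
    THREE_TO_ONE,
    element_of,
    residue_topology,
)
from .errors import PDBFormatError, UnsupportedResidueError
from .nerf import AllAtomStructure, build_all_atom, measure_internal

__all__ = [
    "FixtureSpec",
    "generate_fixture",
    "read_pdb",
    "write_pdb",
    "format_pdb",
    "structure_from_sample",
    "load_geometry_overrides",
    "load_config",
]


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for a synthetic test protein.

    kinds: ``helix`` (phi = -57, psi = -47, omega = 180), ``extended``
    (phi = psi = 180), ``clashed-helix`` (helix with one central chi1
    rotated into steric conflict), ``random-torsions`` (all torsions
    uniform).  ``perturbation_deg`` adds seeded Gaussian noise to every
    torsion.  Default sequence is poly-alanine, except ``clashed-helix``
    which puts a leucine at the centre so there is a chi1 to rotate.
    """

    kind: str = "helix"
    n_residues: int = 8
    sequence: str | None = None
    perturbation_deg: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_residues < 2:
            raise ValueError("n_residues must be >= 2")
        if self.perturbation_deg < 0:
            raise ValueError("perturbation_deg must be >= 0")
        if self.kind not in (
            "helix", "extended", "clashed-helix", "random-torsions"
        ):
            raise ValueError(f"unknown fixture kind {self.kind!r}")


# default side-chain rotamers used by the generator (degrees)
_CHI_DEFAULTS = {
    "generic": (-60.0, 180.0, 180.0, 180.0, 180.0, 180.0),
    # perpendicular ring and proline pucker values
    "PHE": (-60.0, 90.0), "TYR": (-60.0, 90.0), "TRP": (-60.0, 90.0),
    "HIS": (-60.0, 90.0),
    "PRO": (-18.0, 6.0),
}
# a gauche+ chi1 on a central residue of an alpha helix collides with the
# preceding turn; frozen after inspection of the built geometry
_CLASH_CHI1_DEG = 60.0


def generate_fixture(spec: FixtureSpec) -> ProteinSample:
    """Deterministically generate a synthetic ProteinSample."""
    n = spec.n_residues
    if spec.sequence is not None:
        seq = spec.sequence.upper()
        if len(seq) != n:
            raise ValueError("sequence length must equal n_residues")
    elif spec.kind == "clashed-helix":
        seq = "A" * (n // 2) + "L" + "A" * (n - n // 2 - 1)
    else:
        seq = "A" * n

    rng = np.random.default_rng(spec.seed)
    sample = ProteinSample.empty(seq, id=f"{spec.kind}-{n}-{spec.seed}")
    if spec.kind == "extended":
        phi, psi = math.pi, math.pi
    else:
        phi, psi = math.radians(-57.0), math.radians(-47.0)

    for i in range(n):
        topo = sample.topology(i)
        if i > 0:
            sample.set_angle(i, "phi", phi)
            sample.set_angle(i, "omega", math.pi)
            sample.set_angle(i, "cnca", math.radians(121.7))
        if i < n - 1:
            sample.set_angle(i, "psi", psi)
            sample.set_angle(i, "cacn", math.radians(116.2))
        sample.set_angle(i, "ncac", math.radians(111.2))
        code = ONE_TO_THREE[seq[i]]
        chis = _CHI_DEFAULTS.get(code, _CHI_DEFAULTS["generic"])
        for k in range(topo.n_chi):
            sample.set_angle(i, f"chi{k + 1}", math.radians(chis[k]))

    if spec.kind == "random-torsions":
        for i in range(n):
            topo = sample.topology(i)
            names = ["phi", "psi", "omega"] + [
                f"chi{k + 1}" for k in range(topo.n_chi)
            ]
            for nm in names:
                if sample.angle_mask[i, ANGLE_INDEX[nm]]:
                    sample.set_angle(
                        i, nm, float(rng.uniform(-math.pi, math.pi))
                    )
    elif spec.kind == "clashed-helix":
        centre = n // 2
        sample.set_angle(centre, "chi1", math.radians(_CLASH_CHI1_DEG))

    if spec.perturbation_deg > 0:
        for i in range(n):
            topo = sample.topology(i)
            names = ["phi", "psi", "omega"] + [
                f"chi{k + 1}" for k in range(topo.n_chi)
            ]
            for nm in names:
                j = ANGLE_INDEX[nm]
                if sample.angle_mask[i, j]:
                    noise = rng.normal(0.0, math.radians(spec.perturbation_deg))
                    v = (sample.angles[i, j] + noise + math.pi) % (
                        2 * math.pi
                    ) - math.pi
                    sample.angles[i, j] = v

    built = build_all_atom(sample, include_hydrogens=False)
    for i in range(n):
        topo = sample.topology(i)
        for j, name in enumerate(topo.heavy_atoms):
            sample.heavy_coords[i, j] = built.xyz(i, name)
            sample.heavy_mask[i, j] = True
    return sample


def structure_from_sample(
    sample: ProteinSample, include_hydrogens: bool = False
) -> AllAtomStructure:
    """Convenience: build the Cartesian structure for a sample."""
    return build_all_atom(sample, include_hydrogens=include_hydrogens)


# ---------------------------------------------------------------------------
# PDB writing
# ---------------------------------------------------------------------------
def format_pdb(structure: AllAtomStructure) -> str:
    """Serialize to PDB text (ATOM/TER/END, 3-decimal coordinates)."""
    if np.abs(structure.coords).max() >= 1e4:
        raise PDBFormatError(
            "coordinate magnitude >= 10^4 A cannot be represented in PDB"
        )
    lines = []
    serial = 0
    for k in range(structure.n_atoms):
        serial += 1
        name = structure.atom_names[k]
        fullname = f" {name:<3s}" if len(name) < 4 else name
        res_i = int(structure.res_index[k])
        lines.append(
            f"ATOM  {serial:5d} {fullname}{'':1s}{structure.res_codes[k]:>3s} "
            f"A{int(structure.residue_numbers[res_i]):4d}    "
            f"{structure.coords[k, 0]:8.3f}{structure.coords[k, 1]:8.3f}"
            f"{structure.coords[k, 2]:8.3f}{1.00:6.2f}{0.00:6.2f}"
            f"          {element_of(name):>2s}  "
        )
    last_res = int(structure.res_index[-1])
    serial += 1
    lines.append(
        f"TER   {serial:5d}      {structure.res_codes[-1]:>3s} "
        f"A{int(structure.residue_numbers[last_res]):4d}"
        + " " * 53
    )
    lines.append("END" + " " * 77)
    return "\n".join(lines) + "\n"


def write_pdb(structure: AllAtomStructure, path) -> None:
    with open(path, "w") as fh:
        fh.write(format_pdb(structure))


# ---------------------------------------------------------------------------
# PDB reading
# ---------------------------------------------------------------------------
def read_pdb(path) -> ProteinSample:
    """Read a single-chain heavy-atom PDB into a ProteinSample.

    Heavy atoms are mapped through the residue topology; internal
    coordinates are measured from the coordinates.  HETATM records,
    alternate locations, insertion codes, multiple chains/models and
    non-standard residues raise descriptive errors.  Hydrogens and a
    terminal OXT are ignored.
    """
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    with open(path) as fh:
        text = fh.read()
    for ln in text.splitlines():
        if ln.startswith("HETATM"):
            raise PDBFormatError(
                f"HETATM record not supported: {ln[:27]!r}"
            )
    structure = parser.get_structure("pdb", _io.StringIO(text))
    models = list(structure)
    if len(models) != 1:
        raise PDBFormatError(f"expected 1 model, found {len(models)}")
    chains = list(models[0])
    if len(chains) != 1:
        raise PDBFormatError(f"expected 1 chain, found {len(chains)}")

    residues = []
    for res in chains[0]:
        het, resseq, icode = res.id
        if het.strip():
            raise PDBFormatError(f"non-standard record for residue {resseq}")
        if icode.strip():
            raise PDBFormatError(f"insertion code at residue {resseq}")
        if res.resname not in THREE_TO_ONE:
            raise UnsupportedResidueError(
                f"residue {resseq}: unsupported residue {res.resname!r}"
            )
        residues.append(res)
    if len(residues) < 2:
        raise PDBFormatError("need at least 2 residues")

    seq = "".join(THREE_TO_ONE[r.resname] for r in residues)
    atom_rows = []
    numbers = []
    for i, res in enumerate(residues):
        numbers.append(res.id[1])
        topo = residue_topology(res.resname)
        present = {}
        for atom in res:
            if atom.is_disordered() or (
                getattr(atom, "get_altloc", lambda: " ")() or " "
            ).strip():
                raise PDBFormatError(
                    f"alternate location for atom {atom.get_name()!r} in "
                    f"residue {res.id[1]}"
                )
            name = atom.get_name()
            if name.startswith("H") or name in ("OXT",):
                continue
            if name not in topo.heavy_atoms:
                raise PDBFormatError(
                    f"residue {res.id[1]} ({res.resname}): unexpected atom "
                    f"{name!r}"
                )
            present[name] = np.asarray(atom.get_coord(), float)
        for name in topo.heavy_atoms:
            if name not in present:
                raise PDBFormatError(
                    f"residue {res.id[1]} ({res.resname}): missing atom "
                    f"{name!r}"
                )
            atom_rows.append((i, name, present[name]))

    coords = np.array([row[2] for row in atom_rows])
    all_atom = AllAtomStructure(
        coords=coords,
        atom_names=tuple(row[1] for row in atom_rows),
        res_index=np.array([row[0] for row in atom_rows], dtype=int),
        res_codes=tuple(
            ONE_TO_THREE[seq[row[0]]] for row in atom_rows
        ),
        is_hydrogen=np.zeros(len(atom_rows), dtype=bool),
        sequence=seq,
        residue_numbers=np.array(numbers, dtype=int),
        provenance="hydrogens-added-to-heavy",
    )
    sample = measure_internal(all_atom)
    sample.residue_numbers = np.array(numbers, dtype=int)
    sample.id = str(path)
    return sample


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------
def load_geometry_overrides(path) -> dict:
    """Parse an ideal-geometry override file.

    One record per line: ``RES A1 A2 value`` (bond length, angstrom) or
    ``RES A1 A2 A3 value`` (bond angle, degrees); ``*`` as RES applies
    to every residue.  Blank lines and ``#`` comments are ignored.
    """
    bonds: dict = {}
    angles: dict = {}
    with open(path) as fh:
        for ln_no, raw in enumerate(fh, 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) == 4:
                res, a1, a2, val = parts
                bonds[(res, frozenset((a1, a2)))] = float(val)
            elif len(parts) == 5:
                res, a1, a2, a3, val = parts
                angles[(res, (a1, a2, a3))] = float(val)
            else:
                raise PDBFormatError(
                    f"{path}:{ln_no}: expected 4 or 5 fields, got {len(parts)}"
                )
    return {"bonds": bonds, "angles": angles}


def load_config(path) -> dict:
    """Load a YAML configuration file into a flat dict."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise PDBFormatError(f"config {path} must be a mapping")
    return data
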