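"""Internal-coordinate energy minimization and dataset construction.

The pipeline mirrors how a minimized training set is produced from
experimental structures: covalent geometry (bond lengths and bond
angles) is first idealized to the force field's optimal values, then the
potential energy is minimized over torsion angles only — bond lengths
and angles stay exactly ideal throughout, so a model that predicts
torsions can in principle reproduce a minimized structure perfectly.
Entries are filtered out when the chain has gaps (the sequential builder
requires a connected chain) or when minimization moved the structure
more than a cutoff RMSD (default 5 A, C-alpha, after optimal
superposition) away from where it started.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .chemistry import (
    ANGLE_INDEX,
    BACKBONE_ANGLES,
    ProteinSample,
    detect_gaps,
)
from .energy import ToyFFParams, ToySystem
from .loss import free_torsion_slots
from .nerf import build_all_atom, build_with_jacobian
from .quality import kabsch_rmsd

__all__ = [
    "MinimizationConfig",
    "MinimizationResult",
    "idealize_geometry",
    "minimize_internal",
    "filter_entry",
    "build_minimized_dataset",
]


@dataclass(frozen=True)
class MinimizationConfig:
    max_steps: int = 150
    convergence_tol: float = 0.01      # kJ/mol per accepted step
    initial_step: float = 1e-4         # rad per unit gradient
    rmsd_reject_cutoff: float = 5.0    # angstrom, C-alpha
    rmsd_atoms: str = "ca"             # "ca" | "all"
    free_backbone_angles: bool = False
    seed: int = 0
    step_floor: float = 1e-9
    max_rotation: float = 0.2          # rad, per-step cap on any angle move


@dataclass
class MinimizationResult:
    minimized: ProteinSample
    energy_trace: list[float]
    initial_energy: float
    final_energy: float
    rmsd_from_start: float
    verdict: str                        # "accepted" | "rejected(<reason>)"
    n_steps: int = 0

    @property
    def accepted(self) -> bool:
        return self.verdict == "accepted"


def _wrap(a):
    return (a + np.pi) % (2.0 * np.pi) - np.pi


def idealize_geometry(
    sample: ProteinSample, table: dict | None = None
) -> ProteinSample:
    """Fix bond lengths and bond angles to their ideal (force-field
    optimal) values, preserving every torsion exactly, and rebuild
    the Cartesian coordinates from the resulting internal coordinates.

    ``table`` optionally overrides the built-in backbone bond-angle
    values, keyed like :data:`~forcegrad.chemistry.BACKBONE_ANGLES`.
    """
    angles = dict(BACKBONE_ANGLES)
    if table:
        angles.update(table)
    out = sample.copy()
    n = out.n_residues
    for i in range(n):
        out.set_angle(i, "ncac", math.radians(angles[("N", "CA", "C")]))
        if i < n - 1:
            out.set_angle(i, "cacn", math.radians(angles[("CA", "C", "N")]))
        if i > 0:
            out.set_angle(i, "cnca", math.radians(angles[("C", "N", "CA")]))
    # bond lengths live in the builder's table: rebuilding applies them
    rebuilt = build_all_atom(out, include_hydrogens=False)
    for i in range(n):
        topo = out.topology(i)
        for j, name in enumerate(topo.heavy_atoms):
            out.heavy_coords[i, j] = rebuilt.xyz(i, name)
            out.heavy_mask[i, j] = True
    out.id = sample.id
    return out


def _free_slots(sample: ProteinSample, config: MinimizationConfig):
    free = free_torsion_slots(sample)
    if config.free_backbone_angles:
        for i in range(sample.n_residues):
            for nm in ("ncac", "cacn", "cnca"):
                if sample.angle_mask[i, ANGLE_INDEX[nm]]:
                    free.append((i, nm))
    return free


def _ca_coords(sample: ProteinSample) -> np.ndarray:
    return sample.heavy_coords[:, 1, :].copy()


def minimize_internal(
    sample: ProteinSample,
    config: MinimizationConfig | None = None,
    params: ToyFFParams | None = None,
    free: list[tuple[int, str]] | None = None,
) -> MinimizationResult:
    """Gradient descent on torsion angles with backtracking line search.

    A step is accepted only if the energy decreases, so the energy trace
    is strictly decreasing over accepted steps; the run stops when the
    per-step decrease falls below ``convergence_tol``, the step size
    hits its floor, or ``max_steps`` is reached.  Bond lengths and
    angles are carried by the builder's ideal table and are therefore
    untouched by construction.
    """
    config = config or MinimizationConfig()
    work = sample.copy()
    if free is None:
        free = _free_slots(work, config)
    slots = [(i, ANGLE_INDEX[nm]) for i, nm in free]

    # system topology is fixed; build once
    structure, J = build_with_jacobian(work, free, include_hydrogens=True)
    system = ToySystem.for_structure(structure, params)
    res = system.evaluate(structure.coords)
    if not res.finite:
        return MinimizationResult(
            minimized=work, energy_trace=[], initial_energy=float("inf"),
            final_energy=float("inf"), rmsd_from_start=0.0,
            verdict="rejected(non-finite)",
        )

    def theta_vec():
        return np.array([work.angles[i, j] for i, j in slots])

    def set_theta(theta):
        for (i, j), v in zip(slots, _wrap(theta)):
            work.angles[i, j] = v

    def energy_only(theta):
        set_theta(theta)
        st = build_all_atom(work, include_hydrogens=True)
        return system.evaluate(st.coords), st

    U = res.potential_energy
    trace = [U]
    alpha = config.initial_step
    theta = theta_vec()
    n_accept = 0

    for _ in range(config.max_steps):
        structure, J = build_with_jacobian(work, free, include_hydrogens=True)
        res = system.evaluate(structure.coords)
        grad = np.einsum("ad,adp->p", -res.forces, J)
        gmax = np.abs(grad).max() if grad.size else 0.0
        if gmax == 0.0:
            break
        accepted = False
        while alpha >= config.step_floor:
            step = alpha * grad
            cap = np.abs(step).max()
            if cap > config.max_rotation:
                step = step * (config.max_rotation / cap)
            trial = theta - step
            res_t, _st = energy_only(trial)
            if res_t.finite and res_t.potential_energy < U:
                accepted = True
                break
            alpha *= 0.5
        if not accepted:
            set_theta(theta)  # restore best point
            break
        drop = U - res_t.potential_energy
        theta = _wrap(trial)
        set_theta(theta)
        U = res_t.potential_energy
        trace.append(U)
        n_accept += 1
        alpha = min(alpha * 1.5, 1e-2)
        if drop < config.convergence_tol:
            break

    # finalize coordinates
    final_structure = build_all_atom(work, include_hydrogens=False)
    for i in range(work.n_residues):
        topo = work.topology(i)
        for j, name in enumerate(topo.heavy_atoms):
            work.heavy_coords[i, j] = final_structure.xyz(i, name)
            work.heavy_mask[i, j] = True

    if config.rmsd_atoms == "all" or sample.n_residues < 3:
        # Kabsch needs >= 3 points; short chains use all heavy atoms
        start = build_all_atom(sample, include_hydrogens=False).coords
        end = final_structure.coords
        rmsd = kabsch_rmsd(start, end)
    else:
        rmsd = kabsch_rmsd(_ca_coords(sample), _ca_coords(work))
    verdict = "accepted"
    if rmsd > config.rmsd_reject_cutoff:
        verdict = "rejected(rmsd)"
    return MinimizationResult(
        minimized=work,
        energy_trace=trace,
        initial_energy=trace[0],
        final_energy=trace[-1],
        rmsd_from_start=float(rmsd),
        verdict=verdict,
        n_steps=n_accept,
    )


def filter_entry(
    original: ProteinSample,
    result: MinimizationResult,
    config: MinimizationConfig | None = None,
) -> str:
    """Dataset admission rule: gaps first, then the RMSD cutoff."""
    config = config or MinimizationConfig()
    if detect_gaps(original).has_gaps:
        return "rejected(gap)"
    if result.verdict == "rejected(non-finite)":
        return result.verdict
    if result.rmsd_from_start > config.rmsd_reject_cutoff:
        return "rejected(rmsd)"
    return "accepted"


def build_minimized_dataset(
    samples: list[ProteinSample],
    config: MinimizationConfig | None = None,
    params: ToyFFParams | None = None,
) -> dict:
    """Run idealize -> minimize -> filter over a batch.

    Returns a report dict with per-entry verdicts and energy deltas plus
    the accepted minimized samples (``minimized``) and their unminimized
    originals (``originals``).  Per-entry failures are recorded and never
    abort the batch; the run is deterministic for a fixed config.
    """
    config = config or MinimizationConfig()
    entries = []
    minimized: list[ProteinSample] = []
    originals: list[ProteinSample] = []
    for sample in samples:
        entry = {"id": sample.id}
        try:
            if detect_gaps(sample).has_gaps:
                entry["verdict"] = "rejected(gap)"
                entries.append(entry)
                continue
            ideal = idealize_geometry(sample)
            result = minimize_internal(ideal, config, params)
            verdict = filter_entry(sample, result, config)
            entry.update({
                "verdict": verdict,
                "initial_energy": result.initial_energy,
                "final_energy": result.final_energy,
                "energy_delta": result.final_energy - result.initial_energy,
                "rmsd_from_start": result.rmsd_from_start,
                "n_steps": result.n_steps,
            })
            if verdict == "accepted":
                result.minimized.id = sample.id
                minimized.append(result.minimized)
                originals.append(sample)
        except Exception as exc:  # record, never abort the batch
            entry["verdict"] = f"failed({type(exc).__name__}: {exc})"
        entries.append(entry)
    report = {
        "n_input": len(samples),
        "n_accepted": len(minimized),
        "config": {
            "max_steps": config.max_steps,
            "convergence_tol": config.convergence_tol,
            "rmsd_reject_cutoff": config.rmsd_reject_cutoff,
            "rmsd_atoms": config.rmsd_atoms,
            "seed": config.seed,
        },
        "entries": entries,
    }
    return {"report": report, "minimized": minimized, "originals": originals}
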