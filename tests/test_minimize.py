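"""Idealization, torsion-space minimization, filtering, batch pipeline."""

import json
import math

import numpy as np
import pytest

from forcegrad.chemistry import ANGLE_INDEX, detect_gaps
from forcegrad.energy import ToySystem
from forcegrad.io import FixtureSpec, generate_fixture
from forcegrad.minimize import (
    MinimizationConfig,
    MinimizationResult,
    build_minimized_dataset,
    filter_entry,
    idealize_geometry,
    minimize_internal,
)
from forcegrad.nerf import build_all_atom
from forcegrad.quality import clash_report
from forcegrad.vecmath import bond_angle


def _tree_bond_deviation(sample) -> float:
    """Largest deviation of builder-placed (z-matrix tree) bond lengths
    from the ideal table; ring-closure bonds are geometrically dependent
    and excluded."""
    st = build_all_atom(sample, include_hydrogens=False)
    worst = 0.0
    for i in range(sample.n_residues):
        topo = sample.topology(i)
        closures = set(map(frozenset, topo.ring_closures))
        for a, b in topo.bonds:
            if frozenset((a, b)) in closures:
                continue
            d = np.linalg.norm(st.xyz(i, a) - st.xyz(i, b))
            ideal = topo.ideal_bond_lengths[frozenset((a, b))]
            worst = max(worst, abs(d - ideal))
    return worst


class TestIdealize:
    def test_backbone_angles_restored(self):
        sample = generate_fixture(FixtureSpec(kind="helix", n_residues=4))
        sample.set_angle(2, "ncac", math.radians(100.0))  # distorted
        ideal = idealize_geometry(sample)
        st = build_all_atom(ideal, include_hydrogens=False)
        ang = bond_angle(st.xyz(2, "N"), st.xyz(2, "CA"), st.xyz(2, "C"))
        assert abs(ang - math.radians(111.2)) < 1e-6

    def test_bond_lengths_from_table_even_for_distorted_input(self):
        sample = generate_fixture(FixtureSpec(kind="helix", n_residues=4))
        sample.heavy_coords *= 1.10  # stretch every stored bond by 10%
        ideal = idealize_geometry(sample)
        ca = ideal.heavy_coords[0, 1] - ideal.heavy_coords[0, 0]
        assert abs(np.linalg.norm(ca) - 1.458) < 1e-6

    def test_torsions_preserved_exactly(self):
        sample = generate_fixture(FixtureSpec(
            kind="helix", n_residues=5, sequence="ALSVA",
            perturbation_deg=20.0, seed=8,
        ))
        ideal = idealize_geometry(sample)
        for i in range(5):
            for nm in ("phi", "psi", "omega", "chi1", "chi2"):
                j = ANGLE_INDEX[nm]
                if sample.angle_mask[i, j]:
                    assert abs(
                        ideal.angles[i, j] - sample.angles[i, j]
                    ) < 1e-9

    def test_idempotent(self):
        sample = generate_fixture(FixtureSpec(kind="helix", n_residues=4))
        once = idealize_geometry(sample)
        twice = idealize_geometry(once)
        np.testing.assert_allclose(
            twice.heavy_coords[twice.heavy_mask],
            once.heavy_coords[once.heavy_mask], atol=1e-6,
        )


@pytest.fixture(scope="module")
def clash_run():
    sample = idealize_geometry(generate_fixture(FixtureSpec(
        kind="clashed-helix", n_residues=8,
    )))
    config = MinimizationConfig(max_steps=60)
    return sample, config, minimize_internal(sample, config)


class TestMinimizeInternal:
    @pytest.fixture
    def run(self, clash_run):
        return clash_run

    def test_energy_trace_strictly_decreasing(self, run):
        _, _, result = run
        trace = result.energy_trace
        assert all(b < a for a, b in zip(trace, trace[1:]))
        assert result.final_energy == trace[-1]
        assert result.final_energy < result.initial_energy

    def test_clash_count_reduced(self, run):
        sample, _, result = run
        before = clash_report(
            build_all_atom(sample, include_hydrogens=True)
        ).clash_count
        after = clash_report(
            build_all_atom(result.minimized, include_hydrogens=True)
        ).clash_count
        assert after < before

    def test_covalent_geometry_preserved(self, run):
        _, _, result = run
        assert _tree_bond_deviation(result.minimized) < 1e-6
        st = build_all_atom(result.minimized, include_hydrogens=False)
        for i in range(result.minimized.n_residues):
            ang = bond_angle(st.xyz(i, "N"), st.xyz(i, "CA"), st.xyz(i, "C"))
            assert abs(ang - math.radians(111.2)) < 1e-6

    def test_stationary_point_barely_moves(self):
        tight = MinimizationConfig(max_steps=400, convergence_tol=1e-6)
        sample = idealize_geometry(generate_fixture(FixtureSpec(
            kind="helix", n_residues=4, sequence="AASA",
        )))
        converged = minimize_internal(sample, tight).minimized
        again = minimize_internal(converged, tight)
        assert again.n_steps <= 1
        assert again.rmsd_from_start < 0.1

    def test_two_torsion_system_reaches_grid_search_optimum(self):
        """Brute-force oracle: exhaustive grid over the two free torsions
        of an idealized dipeptide (4-degree global sweep refined to 0.25
        degrees around the optimum).  The minimizer, started inside the
        optimal basin, must land within tolerance of the grid optimum."""
        free = [(0, "psi"), (1, "phi")]
        sample = idealize_geometry(generate_fixture(FixtureSpec(
            kind="extended", n_residues=2,
        )))
        base = build_all_atom(sample, include_hydrogens=True)
        system = ToySystem.for_structure(base)

        def energy(psi, phi):
            s = sample.copy()
            s.angles[0, ANGLE_INDEX["psi"]] = psi
            s.angles[1, ANGLE_INDEX["phi"]] = phi
            st = build_all_atom(s, include_hydrogens=True)
            return system.evaluate(st.coords).potential_energy

        coarse = np.radians(np.arange(-180.0, 180.0, 4.0))
        best = (np.inf, 0.0, 0.0)
        for a in coarse:
            for b in coarse:
                u = energy(a, b)
                if u < best[0]:
                    best = (u, a, b)
        window = np.radians(np.arange(-4.0, 4.0, 0.25))
        fine = best
        for da in window:
            for db in window:
                u = energy(best[1] + da, best[2] + db)
                if u < fine[0]:
                    fine = (u, best[1] + da, best[2] + db)

        start = sample.copy()
        start.angles[0, ANGLE_INDEX["psi"]] = best[1]
        start.angles[1, ANGLE_INDEX["phi"]] = best[2]
        result = minimize_internal(
            start,
            MinimizationConfig(max_steps=300, convergence_tol=1e-6),
            free=free,
        )
        # continuous descent may dip slightly below the finite grid
        assert result.final_energy <= fine[0] + 1e-6
        assert fine[0] - result.final_energy < 0.05


class TestFilterEntry:
    def _result(self, rmsd):
        sample = generate_fixture(FixtureSpec(kind="helix", n_residues=3))
        return MinimizationResult(
            minimized=sample, energy_trace=[1.0, 0.5],
            initial_energy=1.0, final_energy=0.5,
            rmsd_from_start=rmsd, verdict="accepted",
        )

    def test_rmsd_above_cutoff_rejected(self):
        sample = generate_fixture(FixtureSpec(kind="helix", n_residues=3))
        verdict = filter_entry(sample, self._result(6.0),
                               MinimizationConfig(rmsd_reject_cutoff=5.0))
        assert verdict == "rejected(rmsd)"

    def test_small_motion_accepted(self):
        sample = generate_fixture(FixtureSpec(kind="helix", n_residues=3))
        assert filter_entry(sample, self._result(2.0)) == "accepted"

    def test_gap_rejected_regardless_of_rmsd(self):
        sample = generate_fixture(FixtureSpec(kind="helix", n_residues=3))
        sample.residue_numbers = np.array([1, 2, 9])
        assert filter_entry(sample, self._result(0.1)) == "rejected(gap)"


class TestDatasetPipeline:
    def _batch(self):
        batch = [
            generate_fixture(FixtureSpec(kind="helix", n_residues=4, seed=k))
            for k in range(3)
        ]
        batch.append(generate_fixture(FixtureSpec(
            kind="extended", n_residues=4, seed=5,
        )))
        gappy = generate_fixture(FixtureSpec(kind="helix", n_residues=4,
                                             seed=9))
        gappy.residue_numbers = np.array([1, 2, 3, 8])
        gappy.id = "gappy"
        batch.append(gappy)
        return batch

    def test_gap_entry_rejected_others_accepted(self):
        out = build_minimized_dataset(
            self._batch(), MinimizationConfig(max_steps=20),
        )
        verdicts = [e["verdict"] for e in out["report"]["entries"]]
        assert verdicts.count("accepted") == 4
        assert verdicts.count("rejected(gap)") == 1
        assert out["report"]["n_accepted"] == 4

    def test_accepted_entries_lowered_energy(self):
        out = build_minimized_dataset(
            self._batch(), MinimizationConfig(max_steps=20),
        )
        for entry in out["report"]["entries"]:
            if entry["verdict"] == "accepted":
                assert entry["final_energy"] <= entry["initial_energy"]

    def test_rerun_is_byte_identical(self):
        cfg = MinimizationConfig(max_steps=15)
        r1 = build_minimized_dataset(self._batch(), cfg)["report"]
        r2 = build_minimized_dataset(self._batch(), cfg)["report"]
        assert json.dumps(r1, sort_keys=True) == json.dumps(r2, sort_keys=True)

    def test_chain_with_gap_never_enters_minimization(self):
        gappy = generate_fixture(FixtureSpec(kind="helix", n_residues=4))
        gappy.residue_numbers = np.array([1, 2, 3, 8])
        assert detect_gaps(gappy).has_gaps
        out = build_minimized_dataset([gappy])
        assert out["report"]["entries"][0]["verdict"] == "rejected(gap)"
        assert "final_energy" not in out["report"]["entries"][0]
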