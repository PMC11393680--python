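"""NeRF atom placement, all-atom building, hydrogens and measurement."""

import math

import numpy as np
import pytest

from forcegrad.chemistry import STANDARD_RESIDUES, THREE_TO_ONE
from forcegrad.errors import BuildError, DegenerateFrameError
from forcegrad.io import FixtureSpec, generate_fixture
from forcegrad.nerf import (
    add_hydrogens,
    build_all_atom,
    build_with_jacobian,
    measure_internal,
    place_atom,
    strip_hydrogens,
)
from forcegrad.quality import kabsch_rmsd
from forcegrad.vecmath import bond_angle, dihedral


class TestPlaceAtom:
    A = np.zeros(3)
    B = np.array([1.0, 0.0, 0.0])
    C = np.array([1.0, 1.0, 0.0])

    def test_worked_examples(self):
        d = place_atom(self.A, self.B, self.C, 1.0, math.pi / 2, math.pi)
        np.testing.assert_allclose(d, [2.0, 1.0, 0.0], atol=1e-12)
        d0 = place_atom(self.A, self.B, self.C, 1.0, math.pi / 2, 0.0)
        np.testing.assert_allclose(d0, [0.0, 1.0, 0.0], atol=1e-12)

    def test_constraints_reproduced_on_random_frames(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            a, b, c = rng.normal(scale=3.0, size=(3, 3))
            if np.linalg.norm(np.cross(b - a, c - b)) < 1e-3:
                continue
            length = rng.uniform(0.9, 1.9)
            angle = rng.uniform(0.2, math.pi - 0.2)
            torsion = rng.uniform(-math.pi, math.pi)
            d = place_atom(a, b, c, length, angle, torsion)
            assert abs(np.linalg.norm(d - c) - length) < 1e-6
            assert abs(bond_angle(b, c, d) - angle) < 1e-6
            assert (
                abs((dihedral(a, b, c, d) - torsion + math.pi)
                    % (2 * math.pi) - math.pi) < 1e-6
            )

    def test_collinear_frame_raises(self):
        with pytest.raises(DegenerateFrameError):
            place_atom(
                np.zeros(3), np.array([1.0, 0, 0]), np.array([2.0, 0, 0]),
                1.0, 1.0, 1.0,
            )


class TestBuildAllAtom:
    def test_backbone_bond_lengths_from_table(self):
        sample = generate_fixture(FixtureSpec(kind="helix", n_residues=5))
        st = build_all_atom(sample, include_hydrogens=False)
        for i in range(5):
            n_ca = np.linalg.norm(st.xyz(i, "CA") - st.xyz(i, "N"))
            assert abs(n_ca - 1.458) < 1e-6
            ca_c = np.linalg.norm(st.xyz(i, "C") - st.xyz(i, "CA"))
            assert abs(ca_c - 1.525) < 1e-6

    def test_internal_alanine_hydrogen_count(self):
        sample = generate_fixture(FixtureSpec(kind="helix", n_residues=5))
        st = build_all_atom(sample, include_hydrogens=True)
        for i in range(1, 5):
            n_h = int(np.sum(st.is_hydrogen[st.res_index == i]))
            assert n_h == 5

    def test_round_trip_build_measure_rebuild(self):
        sample = generate_fixture(FixtureSpec(
            kind="helix", n_residues=6, sequence="AVLSTG",
            perturbation_deg=10.0, seed=4,
        ))
        st1 = build_all_atom(sample, include_hydrogens=False)
        measured = measure_internal(st1)
        st2 = build_all_atom(measured, include_hydrogens=False)
        assert kabsch_rmsd(st1.coords, st2.coords) < 1e-4

    def test_frame_invariance(self, helix8):
        from conftest import random_rigid_transform

        st = build_all_atom(helix8, include_hydrogens=True)
        rng = np.random.default_rng(2)
        rot, shift = random_rigid_transform(rng)
        moved = st.coords @ rot.T + shift
        assert kabsch_rmsd(st.coords, moved) < 1e-9

    @pytest.mark.parametrize(
        "code", [c for c in STANDARD_RESIDUES if c != "GLY"]  # GLY is achiral
    )
    def test_l_chirality(self, code):
        seq = "A" + THREE_TO_ONE[code] + "A"
        sample = generate_fixture(FixtureSpec(
            kind="helix", n_residues=3, sequence=seq,
        ))
        st = build_all_atom(sample, include_hydrogens=False)
        n, ca, c, cb = (st.xyz(1, nm) for nm in ("N", "CA", "C", "CB"))
        signed_volume = np.linalg.det(np.stack([n - ca, c - ca, cb - ca]))
        assert signed_volume > 0  # L configuration

    def test_missing_angle_raises_with_location(self, helix8):
        broken = helix8.copy()
        broken.angle_mask[3, 0] = False  # drop phi of residue 3
        with pytest.raises(BuildError, match="residue 3.*phi"):
            build_all_atom(broken)

    def test_gradient_matches_finite_differences(self):
        """A scalar of built coordinates, differentiated through the
        builder's Jacobian, agrees with central differences."""
        sample = generate_fixture(FixtureSpec(kind="helix", n_residues=4))
        free = [(1, "phi"), (1, "psi"), (2, "chi1")]
        st, J = build_with_jacobian(sample, free, include_hydrogens=True)
        i = st.atom_index(0, "N")
        j = st.atom_index(3, "CB")

        def distance(s):
            stx = build_all_atom(s, include_hydrogens=True)
            return float(np.linalg.norm(
                stx.coords[j] - stx.coords[i]
            ))

        d0 = np.linalg.norm(st.coords[j] - st.coords[i])
        u = (st.coords[j] - st.coords[i]) / d0
        grad_analytic = np.einsum("d,dp->p", u, J[j] - J[i])
        h = 1e-5
        from forcegrad.chemistry import ANGLE_INDEX

        for p, (ri, nm) in enumerate(free):
            sp = sample.copy()
            sp.angles[ri, ANGLE_INDEX[nm]] += h
            sm = sample.copy()
            sm.angles[ri, ANGLE_INDEX[nm]] -= h
            fd = (distance(sp) - distance(sm)) / (2 * h)
            assert abs(grad_analytic[p] - fd) / max(abs(fd), 1e-8) < 1e-4


class TestAddHydrogens:
    @pytest.fixture
    def heavy(self):
        sample = generate_fixture(FixtureSpec(
            kind="helix", n_residues=4, sequence="ASTA",
        ))
        return build_all_atom(sample, include_hydrogens=False)

    def test_amide_hydrogen_geometry(self, heavy):
        st = add_hydrogens(heavy)
        h = st.xyz(1, "H")
        n = st.xyz(1, "N")
        assert abs(np.linalg.norm(h - n) - 1.01) < 1e-6
        # in the C(prev)-N-CA plane
        c_prev = st.xyz(0, "C")
        ca = st.xyz(1, "CA")
        normal = np.cross(c_prev - n, ca - n)
        normal /= np.linalg.norm(normal)
        assert abs(np.dot(h - n, normal)) < 1e-6

    def test_methyl_geometry(self, heavy):
        st = add_hydrogens(heavy)
        cb = st.xyz(0, "CB")
        ca = st.xyz(0, "CA")
        hs = [st.xyz(0, f"HB{k}") for k in (1, 2, 3)]
        for h in hs:
            assert abs(
                math.degrees(bond_angle(h, cb, ca)) - 109.5
            ) < 1e-6
        # three-fold symmetry: equal H-H separations
        seps = [
            np.linalg.norm(hs[0] - hs[1]),
            np.linalg.norm(hs[1] - hs[2]),
            np.linalg.norm(hs[0] - hs[2]),
        ]
        assert max(seps) - min(seps) < 1e-9

    def test_heavy_coordinates_unchanged_bit_for_bit(self, heavy):
        st = add_hydrogens(heavy)
        for k in range(heavy.n_atoms):
            ri = int(heavy.res_index[k])
            nm = heavy.atom_names[k]
            assert np.array_equal(heavy.coords[k], st.xyz(ri, nm))

    def test_idempotent(self, heavy):
        once = add_hydrogens(heavy)
        assert add_hydrogens(once) is once

    def test_strip_then_add_is_stable(self, heavy):
        once = add_hydrogens(heavy)
        again = add_hydrogens(strip_hydrogens(once))
        np.testing.assert_allclose(again.coords, once.coords, atol=1e-12)


class TestMeasureInternal:
    def test_recovers_input_torsions(self):
        sample = generate_fixture(FixtureSpec(kind="helix", n_residues=4))
        st = build_all_atom(sample, include_hydrogens=False)
        measured = measure_internal(st)
        assert abs(measured.angle(1, "phi") - math.radians(-57)) < 1e-6
        assert abs(measured.angle(1, "psi") - math.radians(-47)) < 1e-6
        assert abs(abs(measured.angle(1, "omega")) - math.pi) < 1e-6

    def test_terminal_flags(self):
        sample = generate_fixture(FixtureSpec(kind="helix", n_residues=3))
        measured = measure_internal(build_all_atom(sample, False))
        from forcegrad.chemistry import ANGLE_INDEX

        assert not measured.angle_mask[0, ANGLE_INDEX["phi"]]
        assert not measured.angle_mask[0, ANGLE_INDEX["omega"]]
        assert not measured.angle_mask[2, ANGLE_INDEX["psi"]]

    def test_glycine_has_no_chi(self):
        sample = generate_fixture(FixtureSpec(
            kind="helix", n_residues=3, sequence="AGA",
        ))
        measured = measure_internal(build_all_atom(sample, False))
        from forcegrad.chemistry import ANGLE_INDEX

        assert not measured.angle_mask[1, ANGLE_INDEX["chi1"]]
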