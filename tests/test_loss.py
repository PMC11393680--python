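"""Sigmoid transforms, warm-up schedule, gradient chain, training demo."""

import numpy as np
import pytest
from scipy.optimize import brentq

from forcegrad.chemistry import ANGLE_INDEX
from forcegrad.energy import ToySystem
from forcegrad.io import FixtureSpec, generate_fixture
from forcegrad.loss import (
    LossConfig,
    NonFiniteEnergyError,
    SigmoidParams,
    energy_loss_from_angles,
    energy_loss_from_coords,
    free_torsion_slots,
    sigma_star,
    sigma_star_derivative,
    sigma_tilde,
    toy_finetune_demo,
    warmup_weight,
)
from forcegrad.nerf import build_all_atom, strip_hydrogens


class TestSigmaTilde:
    def test_supremum_is_one(self):
        assert sigma_tilde(1e9) == pytest.approx(1.0, abs=1e-9)
        assert sigma_tilde(float("inf")) == 1.0

    def test_infimum_is_minus_four(self):
        assert sigma_tilde(-1e9) == pytest.approx(-4.0, abs=1e-9)
        assert sigma_tilde(float("-inf")) == -4.0

    def test_value_at_zero(self):
        # closed form with the default constants: (1/5 + e^(-10/3))^-1 - 4
        assert sigma_tilde(0.0) == pytest.approx(0.24315, abs=1e-4)

    def test_root_location(self):
        """Sign change at (C ln 20 - B)/D ~ -20256.07 kJ/mol, i.e. about
        -20,000 at the nearest thousand."""
        root = brentq(sigma_tilde, -1e6, 0.0, xtol=1e-6)
        assert root == pytest.approx(-20256.07, abs=0.01)
        assert round(root, -3) == -20000.0

    def test_monotone_and_bounded(self):
        xs = np.concatenate([
            -np.logspace(9, -3, 300), [0.0], np.logspace(-3, 9, 300),
        ])
        vals = np.asarray(sigma_tilde(xs))
        assert np.all(np.diff(vals) >= 0)
        assert np.all(vals >= -4.0) and np.all(vals <= 1.0)
        # strictly monotone and strictly inside the bounds away from
        # float saturation
        xs_mid = np.linspace(-1e6, 1e6, 500)
        vals_mid = np.asarray(sigma_tilde(xs_mid))
        assert np.all(np.diff(vals_mid) > 0)
        assert np.all(vals_mid > -4.0) and np.all(vals_mid < 1.0)

    def test_overflow_safe_at_extremes(self):
        assert sigma_tilde(-1e300) == -4.0
        assert sigma_tilde(1e300) == 1.0


class TestSigmaStar:
    def test_equals_tilde_plus_leak(self):
        xs = np.array([-1e8, -2e4, -1.0, 0.0, 1.0, 3e5, 1e9])
        p = SigmoidParams()
        diff = np.asarray(sigma_star(xs, p)) - np.asarray(sigma_tilde(xs, p))
        # leak * x recovered up to float cancellation against sigma_tilde
        np.testing.assert_allclose(
            diff, p.leak_fraction * xs, rtol=1e-4, atol=1e-18,
        )

    def test_value_at_zero(self):
        assert sigma_star(0.0) == pytest.approx(0.24315, abs=1e-4)

    def test_huge_positive_energy(self):
        assert sigma_star(1e12) == pytest.approx(2.0, abs=1e-6)

    def test_leak_slope_in_flat_region(self):
        x, h = -1e9, 1e3
        slope = (sigma_star(x + h) - sigma_star(x)) / h
        assert slope == pytest.approx(1e-12, rel=0.1)

    def test_derivative_at_least_leak_everywhere(self):
        xs = np.concatenate([-np.logspace(9, 0, 50), np.logspace(0, 9, 50)])
        d = np.asarray(sigma_star_derivative(xs))
        assert np.all(d >= 1e-12)


class TestWarmup:
    @pytest.mark.parametrize("step,expected", [
        (0, 0.0), (500, 0.005), (1000, 0.01), (5000, 0.01),
    ])
    def test_linear_ramp_to_component_weight(self, step, expected):
        assert warmup_weight(step) == pytest.approx(expected, abs=1e-15)

    def test_zero_warmup_gives_full_weight(self):
        cfg = LossConfig(warmup_steps=0)
        assert warmup_weight(0, cfg) == cfg.component_weight


class TestEnergyLossChain:
    @pytest.fixture
    def sample(self):
        return generate_fixture(FixtureSpec(
            kind="helix", n_residues=3, sequence="ALS",
        ))

    def test_raw_loss_equals_backend_energy(self, sample):
        cfg = LossConfig(transform="raw", component_weight=1.0,
                         warmup_steps=0)
        lv = energy_loss_from_angles(sample, config=cfg)
        st = build_all_atom(sample, include_hydrogens=True)
        u = ToySystem.for_structure(st).evaluate(st.coords).potential_energy
        assert abs(lv.loss - u) / abs(u) < 1e-10

    def test_angle_gradients_match_finite_differences(self, sample):
        cfg = LossConfig(transform="sigma_star", component_weight=1.0,
                         warmup_steps=0)
        lv = energy_loss_from_angles(sample, config=cfg)
        h = 1e-5
        for i, nm in free_torsion_slots(sample):
            j = ANGLE_INDEX[nm]
            sp = sample.copy()
            sp.angles[i, j] += h
            sm = sample.copy()
            sm.angles[i, j] -= h
            fd = (
                energy_loss_from_angles(sp, config=cfg).loss
                - energy_loss_from_angles(sm, config=cfg).loss
            ) / (2 * h)
            rel = abs(lv.grad_angles[i, j] - fd) / max(abs(fd), 1e-10)
            assert rel < 1e-3

    def test_coordinate_gradients_match_finite_differences(self, sample):
        cfg = LossConfig(transform="sigma_star", component_weight=1.0,
                         warmup_steps=0)
        heavy = strip_hydrogens(build_all_atom(sample, True))
        lv = energy_loss_from_coords(heavy, config=cfg)
        h = 1e-5
        rng = np.random.default_rng(0)
        atoms = rng.choice(heavy.n_atoms, size=6, replace=False)
        for a in atoms:
            for d in range(3):
                cp = heavy.coords.copy()
                cp[a, d] += h
                cm = heavy.coords.copy()
                cm[a, d] -= h
                fd = (
                    energy_loss_from_coords(
                        heavy.replace_coords(cp), config=cfg).loss
                    - energy_loss_from_coords(
                        heavy.replace_coords(cm), config=cfg).loss
                ) / (2 * h)
                rel = abs(lv.grad_coords[a, d] - fd) / max(abs(fd), 1e-8)
                assert rel < 1e-4

    def test_warmup_scales_the_loss(self, sample):
        cfg = LossConfig(transform="sigma_star", component_weight=0.01,
                         warmup_steps=1000)
        half = energy_loss_from_angles(sample, config=cfg, step=500)
        full = energy_loss_from_angles(sample, config=cfg, step=1000)
        assert half.loss == pytest.approx(0.5 * full.loss, rel=1e-12)

    def test_nonfinite_energy_handling(self, sample):
        # two exactly coincident atoms -> infinite Lennard-Jones energy
        heavy = strip_hydrogens(build_all_atom(sample, True))
        bad = heavy.coords.copy()
        bad[heavy.atom_index(2, "CB")] = bad[heavy.atom_index(0, "N")]
        broken = heavy.replace_coords(bad)
        with pytest.raises(NonFiniteEnergyError):
            energy_loss_from_coords(
                broken, config=LossConfig(transform="raw"),
            )
        for transform in ("sigma_tilde", "sigma_star"):
            lv = energy_loss_from_coords(
                broken,
                config=LossConfig(transform=transform, component_weight=1.0,
                                  warmup_steps=0),
            )
            assert not lv.finite
            assert lv.loss == pytest.approx(1.0)   # saturated supremum
            assert np.all(lv.grad_coords == 0.0)


class TestFinetuneDemo:
    def _fixtures(self):
        return [
            generate_fixture(FixtureSpec(kind="helix", n_residues=4, seed=k))
            for k in range(2)
        ]

    def test_descent_and_energy_reduction(self):
        report = toy_finetune_demo(self._fixtures(), seed=0, steps=60)
        assert not report["diverged"]
        trace = report["trace"]
        assert trace[-1]["total"] < trace[0]["total"]
        assert trace[-1]["energy_kj_mol"] < trace[0]["energy_kj_mol"]

    def test_identical_seeds_identical_reports(self):
        r1 = toy_finetune_demo(self._fixtures(), seed=3, steps=25)
        r2 = toy_finetune_demo(self._fixtures(), seed=3, steps=25)
        assert r1 == r2

    def test_different_seeds_differ(self):
        r1 = toy_finetune_demo(self._fixtures(), seed=1, steps=5)
        r2 = toy_finetune_demo(self._fixtures(), seed=2, steps=5)
        assert r1["trace"] != r2["trace"]
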