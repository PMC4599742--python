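"""Gaussian RBF collocation: interpolation, operators, time stepping."""

import numpy as np
import pytest

from rbfcme import (
    LatticeBox,
    LatticeDistribution,
    assemble_generator,
    build_birth_death,
    evolve,
)
from rbfcme.rbf import (
    ConditioningError,
    approx_mult,
    approx_shift,
    collocation_step,
    discretize_generator,
    evaluate,
    interpolate,
    make_basis,
)


def grid_centres(m, step=1.0, d=2):
    axes = [np.arange(m) * step for _ in range(d)]
    mesh = np.meshgrid(*axes, indexing="ij")
    return np.stack([g.ravel() for g in mesh], axis=1)


class TestMakeBasis:
    def test_single_centre(self):
        b = make_basis(np.array([[3.0, 4.0]]))
        np.testing.assert_array_equal(b.A, [[1.0]])
        assert b.condition_estimate == 1.0

    def test_distant_centres_give_identity(self):
        b = make_basis(np.array([[0.0], [1e4]]), sigma=1.0)
        np.testing.assert_allclose(b.A, np.eye(2), atol=1e-300)

    def test_factorization_round_trip(self, rng):
        b = make_basis(grid_centres(10), shape_c=1.0)
        R = b.solve(b.A)
        assert np.abs(R - np.eye(100)).max() <= 1e-8

    def test_condition_monotone_in_sigma(self):
        centres = grid_centres(8)
        conds = [make_basis(centres, sigma=s).condition_estimate for s in (0.3, 0.8, 1.6)]
        assert conds[0] <= conds[1] <= conds[2]

    def test_conditioning_error_raised(self):
        # hugely overlapping Gaussians: near-singular interpolation matrix
        with pytest.raises(ConditioningError):
            make_basis(grid_centres(6), sigma=1e4)

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            make_basis(np.array([[0.0]]), sigma=-1.0)


class TestInterpolateEvaluate:
    def test_basis_function_values_give_unit_vector(self):
        b = make_basis(grid_centres(5), shape_c=1.0)
        c = interpolate(b, b.A[:, 7])
        expected = np.zeros(25)
        expected[7] = 1.0
        np.testing.assert_allclose(c.alpha, expected, atol=1e-10)

    def test_zero_values_zero_coefficients(self):
        b = make_basis(grid_centres(4), shape_c=1.0)
        assert np.all(interpolate(b, np.zeros(16)).alpha == 0.0)

    def test_round_trip_random_values(self, rng):
        b = make_basis(grid_centres(7), shape_c=1.0)
        v = rng.random(49)
        c = interpolate(b, v)
        np.testing.assert_allclose(evaluate(b, c, b.centres), v, atol=1e-8)

    def test_evaluate_matches_naive_sum(self, rng):
        b = make_basis(grid_centres(4), shape_c=0.9)
        alpha = rng.standard_normal(16)
        pts = rng.random((10, 2)) * 3
        got = evaluate(b, alpha, pts)
        naive = np.zeros(10)
        for j in range(16):
            term = np.ones(10)
            for k in range(2):
                term *= np.exp(-((pts[:, k] - b.centres[j, k]) ** 2) / b.sigma[j, k])
            naive += alpha[j] * term
        np.testing.assert_allclose(got, naive, atol=1e-12)

    def test_far_from_centres_vanishes(self):
        b = make_basis(grid_centres(3), shape_c=1.0)
        val = evaluate(b, np.ones(9), np.array([[500.0, 500.0]]))
        assert abs(val[0]) < 1e-200

    def test_dimension_mismatch(self):
        b = make_basis(grid_centres(3))
        with pytest.raises(ValueError):
            interpolate(b, np.ones(5))


class TestShiftAndMult:
    def test_shift_zero_is_identity(self):
        b = make_basis(grid_centres(5), shape_c=1.0)
        np.testing.assert_array_equal(approx_shift(b, 1, 0), np.eye(25))

    def test_shifted_nodal_values_are_exact(self, rng):
        """Nodal values of the shifted interpolant equal the interpolant
        evaluated at the displaced nodes (exact by construction)."""
        b = make_basis(grid_centres(6), shape_c=1.1)
        alpha = rng.standard_normal(36)
        for k, n in [(1, 1), (2, 1), (1, -1)]:
            shifted = approx_shift(b, k, n) @ alpha
            nodal = b.A @ shifted
            pts = b.centres.copy()
            pts[:, k - 1] -= n
            np.testing.assert_allclose(nodal, evaluate(b, alpha, pts), atol=1e-9)

    def test_on_grid_gaussian_shift_is_permutation(self):
        """A basis function whose shifted centre is also a centre maps to the
        corresponding unit coefficient vector under the unit shift."""
        b = make_basis(grid_centres(6, step=1.0), shape_c=1.0)
        src = np.zeros(36)
        src[b.centres.shape[0] // 2] = 1.0  # centre (3, 0) in C-order: index 18
        i = 18
        target = list(b.centres[i])
        target[0] += 1.0
        j = next(
            idx for idx, c in enumerate(b.centres) if tuple(c) == tuple(target)
        )
        shifted = approx_shift(b, 1, 1) @ src
        expected = np.zeros(36)
        expected[j] = 1.0
        np.testing.assert_allclose(shifted, expected, atol=1e-8)

    def test_mult_identity_and_scalar(self):
        b = make_basis(grid_centres(4), shape_c=1.0)
        np.testing.assert_allclose(approx_mult(b, lambda x, y: np.ones_like(x)), np.eye(16), atol=1e-10)
        np.testing.assert_allclose(approx_mult(b, 3.5 * np.ones(16)), 3.5 * np.eye(16), atol=1e-9)

    def test_mult_nodal_identity(self, rng):
        b = make_basis(grid_centres(5), shape_c=1.0)
        a_vals = rng.random(25)
        alpha = rng.standard_normal(25)
        W = approx_mult(b, a_vals)
        nodal = b.A @ (W @ alpha)
        np.testing.assert_allclose(nodal, a_vals * (b.A @ alpha), atol=1e-9)

    def test_mult_rejects_nonfinite(self):
        b = make_basis(grid_centres(3))
        with pytest.raises(ValueError):
            approx_mult(b, np.array([1.0, np.inf] + [0.0] * 7))


class TestDiscretizedGenerator:
    def test_zero_propensities_zero_matrix(self):
        net = build_birth_death(1.0, 1.0)
        from rbfcme.models import ReactionChannel, ReactionNetwork

        zero_net = ReactionNetwork(
            1, (ReactionChannel((1,), lambda x: np.zeros_like(np.asarray(x, float))),)
        )
        b = make_basis(np.arange(8.0)[:, None], shape_c=0.8)
        L = discretize_generator(b, zero_net).matrix
        np.testing.assert_allclose(L, 0.0, atol=1e-12)

    def test_single_channel_equals_term(self):
        net = build_birth_death(2.0, 1.0)
        from rbfcme.models import ReactionNetwork

        b = make_basis(np.arange(10.0)[:, None], shape_c=0.8)
        birth_only = ReactionNetwork(1, (net.channels[0],))
        L1 = discretize_generator(b, birth_only).matrix
        T = approx_shift(b, 1, 1)
        W = approx_mult(b, net.channels[0])
        np.testing.assert_allclose(L1, (T - np.eye(10)) @ W, atol=1e-12)

    def test_interpolatory_limit_matches_exact_generator(self):
        """With a basis centred on every state and sharp Gaussians the nodal
        action of the collocation generator converges to the exact one."""
        net = build_birth_death(5.0, 1.0)
        box = LatticeBox((0,), (25,))
        gen = assemble_generator(net, box)
        centres = box.states().astype(float)
        v = np.exp(-((np.arange(26) - 5.0) ** 2) / 8.0)
        errs = []
        for c in (0.6, 0.4, 0.25):
            b = make_basis(centres, shape_c=c)
            Lt = discretize_generator(b, net).matrix
            nodal = b.A @ (Lt @ interpolate(b, v).alpha)
            errs.append(np.abs(nodal - gen.matrix @ v).max())
        assert errs[2] < 1e-6
        assert errs[2] <= errs[1] <= errs[0]


class TestCollocationStep:
    def setup_method(self):
        self.net = build_birth_death(5.0, 1.0)
        self.box = LatticeBox((0,), (25,))
        self.centres = self.box.states().astype(float)
        self.basis = make_basis(self.centres, shape_c=0.25)
        self.gen = discretize_generator(self.basis, self.net)
        u0 = np.zeros(26)
        u0[0] = 1.0
        self.u0 = u0
        self.alpha0 = interpolate(self.basis, u0)

    def test_dt_zero_is_identity(self):
        out = collocation_step(self.gen, self.alpha0, 0.0)
        np.testing.assert_array_equal(out.alpha, self.alpha0.alpha)

    def test_semigroup(self):
        one = collocation_step(self.gen, self.alpha0, 3.0)
        two = collocation_step(self.gen, collocation_step(self.gen, self.alpha0, 1.3), 1.7)
        np.testing.assert_allclose(one.alpha, two.alpha, atol=1e-8)

    def test_matches_exact_evolve(self):
        exact = evolve(
            assemble_generator(self.net, self.box),
            LatticeDistribution(self.box, self.u0),
            2.0,
        )
        stepped = collocation_step(self.gen, self.alpha0, 2.0)
        np.testing.assert_allclose(stepped.nodal_values(), exact.values, atol=1e-6)

    def test_negative_dt_rejected(self):
        with pytest.raises(ValueError):
            collocation_step(self.gen, self.alpha0, -0.1)
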