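"""Free energy, prediction errors, inference dynamics and Hebbian
learning."""

import numpy as np
import pytest

from temporalpc.core import (
    TPCConfig,
    TPCModel,
    filter_sequence,
    free_energy,
    infer,
    inference_step,
    prediction_errors,
    single_step_update,
    sparse_free_energy,
    sparse_inference_step,
    sparse_weight_update,
    update_weights,
)
from temporalpc.kalman import tpc_equilibrium
from temporalpc.state_space import (
    StateSpaceModel,
    make_control_sequence,
    make_tracking_model,
    simulate,
)
from conftest import random_tpc


def scalar_model(A=1.0, B=0.0, C=1.0, x_prev=0.0, f="linear"):
    return TPCModel(
        A=[[A]], B=[[B]], C=[[C]], f=f, x_prev=np.array([x_prev])
    )


class TestFreeEnergy:
    def test_perfect_prediction_is_zero(self, rng):
        m = random_tpc(rng)
        u = rng.standard_normal(1)
        x = m.A @ m.x_prev + m.B @ u
        y = m.C @ x
        assert free_energy(m, x, u, y) == pytest.approx(0.0, abs=1e-12)

    def test_scalar_hand_arithmetic(self):
        # 1/2 (2-1)^2 + 1/2 (1-0)^2 = 1
        m = scalar_model()
        assert free_energy(m, [1.0], [0.0], [2.0]) == pytest.approx(1.0)

    def test_matches_quadratic_form_oracle(self, rng):
        """Independently coded quadratic-form evaluation agrees."""
        m = random_tpc(rng, diag_precisions=True)
        x = rng.standard_normal(3)
        u = rng.standard_normal(1)
        y = rng.standard_normal(3)
        ry = y - m.C @ x
        rx = x - m.A @ m.x_prev - m.B @ u
        expected = 0.5 * np.einsum("i,ij,j->", ry, m.Pi_y, ry) + 0.5 * np.einsum(
            "i,ij,j->", rx, m.Pi_x, rx
        )
        assert free_energy(m, x, u, y) == pytest.approx(expected, rel=1e-12)

    def test_nonnegative(self, rng):
        for _ in range(20):
            m = random_tpc(rng, f="tanh", diag_precisions=True)
            assert (
                free_energy(
                    m,
                    rng.standard_normal(3),
                    rng.standard_normal(1),
                    rng.standard_normal(3),
                )
                >= 0.0
            )


class TestPredictionErrors:
    def test_perfect_prediction(self, rng):
        m = random_tpc(rng)
        u = rng.standard_normal(1)
        x = m.A @ m.x_prev + m.B @ u
        ex, ey = prediction_errors(m, x, u, m.C @ x)
        assert np.allclose(ex, 0) and np.allclose(ey, 0)

    def test_scalar_case(self):
        m = scalar_model()
        ex, ey = prediction_errors(m, [1.0], [0.0], [2.0])
        assert ex == pytest.approx([1.0]) and ey == pytest.approx([1.0])

    def test_precision_weighting_matches_solve_oracle(self, rng):
        """eps = Sigma^{-1} residual computed via linalg.solve."""
        Sx = np.array([[2.0, 0.3, 0.0], [0.3, 1.0, 0.1], [0.0, 0.1, 0.5]])
        m = random_tpc(rng)
        m.Pi_x = np.linalg.inv(Sx)
        x = rng.standard_normal(3)
        u = rng.standard_normal(1)
        ex, _ = prediction_errors(m, x, u, rng.standard_normal(3))
        resid = x - m.A @ m.x_prev - m.B @ u
        assert np.allclose(ex, np.linalg.solve(Sx, resid))


class TestInferenceStep:
    def test_scalar_hand_arithmetic(self):
        # x=0: 0 + 0.5 * (-0 + 1*(1-0)) = 0.5
        m = scalar_model()
        out = inference_step(m, np.array([0.0]), [0.0], [1.0], 0.5)
        assert out == pytest.approx([0.5])

    def test_equilibrium_is_fixed_point(self, rng):
        ss = StateSpaceModel(
            A=rng.standard_normal((3, 3)) * 0.5,
            B=rng.standard_normal((3, 1)),
            C=rng.standard_normal((3, 3)),
            Sigma_x=np.eye(3),
            Sigma_y=np.eye(3),
        )
        m = TPCModel.from_state_space(ss)
        m.x_prev = rng.standard_normal(3)
        u = rng.standard_normal(1)
        y = rng.standard_normal(3)
        x_star = tpc_equilibrium(ss, m.x_prev, u, y)
        assert np.allclose(inference_step(m, x_star, u, y, 0.1), x_star, atol=1e-10)

    @pytest.mark.parametrize("f", ["linear", "tanh"])
    def test_matches_negative_gradient(self, rng, f):
        """Update direction equals -dF/dx by central differences."""
        for _ in range(20):
            dx = int(rng.integers(1, 6))
            dy = int(rng.integers(1, 6))
            m = TPCModel(
                A=rng.standard_normal((dx, dx)),
                B=rng.standard_normal((dx, 1)),
                C=rng.standard_normal((dy, dx)),
                Pi_x=np.diag(rng.uniform(0.5, 2, dx)),
                Pi_y=np.diag(rng.uniform(0.5, 2, dy)),
                f=f,
                x_prev=rng.standard_normal(dx),
            )
            x = rng.standard_normal(dx)
            u = rng.standard_normal(1)
            y = rng.standard_normal(dy)
            h = 1e-4
            direction = (inference_step(m, x, u, y, h) - x) / h
            grad = np.zeros(dx)
            eps = 1e-5
            for j in range(dx):
                e = np.zeros(dx)
                e[j] = eps
                grad[j] = (
                    free_energy(m, x + e, u, y) - free_energy(m, x - e, u, y)
                ) / (2 * eps)
            scale = max(1.0, np.abs(grad).max())
            assert np.abs(direction + grad).max() / scale < 1e-5


class TestInfer:
    def test_converges_to_closed_form(self, rng):
        ss = StateSpaceModel(
            A=rng.standard_normal((3, 3)) * 0.5,
            B=rng.standard_normal((3, 1)),
            C=rng.standard_normal((3, 3)),
            Sigma_x=np.eye(3),
            Sigma_y=np.eye(3),
        )
        m = TPCModel.from_state_space(ss)
        m.x_prev = rng.standard_normal(3)
        u, y = rng.standard_normal(1), rng.standard_normal(3)
        x_hat = infer(m, u, y, TPCConfig(inference_steps=500, step_size=0.2))
        assert np.allclose(x_hat, tpc_equilibrium(ss, m.x_prev, u, y), atol=1e-6)

    def test_start_independence_linear(self, rng):
        """Convex objective: two different starts agree after enough
        iterations."""
        m = random_tpc(rng)
        u, y = rng.standard_normal(1), rng.standard_normal(3)
        cfg = TPCConfig(inference_steps=1000, step_size=0.1)
        a = infer(m, u, y, cfg)
        m2 = TPCModel(
            A=m.A, B=m.B, C=m.C, f=m.f, x_prev=m.x_prev + rng.standard_normal(3) * 5
        )
        # same previous estimate inside F, different iteration start
        m2.x_prev = m.x_prev
        b = infer(m2, u, y, cfg)
        assert np.allclose(a, b, atol=1e-6)

    def test_does_not_mutate_memory(self, rng):
        m = random_tpc(rng)
        before = m.x_prev.copy()
        infer(m, rng.standard_normal(1), rng.standard_normal(3), TPCConfig())
        assert np.array_equal(m.x_prev, before)

    def test_convergence_tolerance_stops_early(self, rng):
        m = random_tpc(rng)
        cfg = TPCConfig(inference_steps=10_000, step_size=0.1, convergence_tol=1e-12)
        x = infer(m, rng.standard_normal(1), rng.standard_normal(3), cfg)
        assert np.all(np.isfinite(x))


class TestSingleStep:
    def test_pure_prediction_without_sensory_weight(self, rng):
        """C = 0 and a full step: the update lands on A x_prev + B u."""
        m = random_tpc(rng)
        m.C = np.zeros_like(m.C)
        u = rng.standard_normal(1)
        out = single_step_update(m, u, np.zeros(3), 1.0)
        assert np.allclose(out, m.A @ m.x_prev + m.B @ u)

    def test_scalar_hand_arithmetic(self):
        # 0 + 0.5*(-0 + 0 + 0 + (2-0)) = 1
        m = scalar_model()
        assert single_step_update(m, [0.0], [2.0], 0.5) == pytest.approx([1.0])

    def test_equals_one_identity_precision_inference_step(self, rng):
        m = random_tpc(rng)  # identity precisions by default
        u, y = rng.standard_normal(1), rng.standard_normal(3)
        a = single_step_update(m, u, y, 0.2)
        b = inference_step(m, m.x_prev.copy(), u, y, 0.2)
        assert np.allclose(a, b)


class TestWeightUpdates:
    def test_zero_errors_zero_deltas(self, rng):
        m = random_tpc(rng)
        u = rng.standard_normal(1)
        x = m.A @ m.x_prev + m.B @ u
        dA, dB, dC = update_weights(m, x, u, m.C @ x, eta=0.1, apply=False, advance=False)
        assert np.allclose(dA, 0) and np.allclose(dB, 0) and np.allclose(dC, 0)

    def test_outer_product_by_hand(self):
        """dA = eta * eps_x f(x_prev)^T for a constructed 2-d case."""
        m = TPCModel(
            A=np.zeros((2, 2)),
            B=np.zeros((2, 1)),
            C=np.zeros((2, 2)),
            x_prev=np.array([2.0, 3.0]),
            learn_A=True,
        )
        # eps_x = x_hat - A x_prev - B u = x_hat = [1, 0]
        dA, _, _ = update_weights(
            m, np.array([1.0, 0.0]), [0.0], np.zeros(2), eta=0.1, apply=False,
            advance=False,
        )
        assert np.allclose(dA, [[0.2, 0.3], [0.0, 0.0]])

    def test_flags_gate_application_and_memory_advances(self, rng):
        m = random_tpc(rng)
        m.learn_A, m.learn_B, m.learn_C = True, False, False
        A0, B0, C0 = m.A.copy(), m.B.copy(), m.C.copy()
        x_hat = rng.standard_normal(3)
        update_weights(m, x_hat, rng.standard_normal(1), rng.standard_normal(3), 0.01)
        assert not np.array_equal(m.A, A0)
        assert np.array_equal(m.B, B0) and np.array_equal(m.C, C0)
        assert np.array_equal(m.x_prev, x_hat)

    def test_small_eta_does_not_increase_free_energy(self, rng):
        """A single Hebbian step on a fixed (x, u, y) triple is descent."""
        for _ in range(10):
            m = random_tpc(rng)
            m.learn_A = m.learn_B = m.learn_C = True
            u, y = rng.standard_normal(1), rng.standard_normal(3)
            x_hat = infer(m, u, y, TPCConfig(inference_steps=200, step_size=0.1))
            before = free_energy(m, x_hat, u, y)
            update_weights(m, x_hat, u, y, eta=1e-4, advance=False)
            assert free_energy(m, x_hat, u, y) <= before + 1e-12

    def test_hebbian_locality(self, rng):
        """dA depends only on (eps_x, f(x_prev)); dC only on
        (eps_y, f(x_hat)): perturbing C leaves dA unchanged when eps_x is
        held fixed, and vice versa."""
        m = random_tpc(rng)
        x_hat = rng.standard_normal(3)
        u, y = rng.standard_normal(1), rng.standard_normal(3)
        dA1, _, _ = update_weights(m, x_hat, u, y, 0.1, apply=False, advance=False)
        m.C = m.C + rng.standard_normal(m.C.shape)  # eps_x unaffected by C
        dA2, _, dC2 = update_weights(m, x_hat, u, y, 0.1, apply=False, advance=False)
        assert np.allclose(dA1, dA2)
        m.A = m.A + rng.standard_normal(m.A.shape)  # eps_y unaffected by A
        _, _, dC3 = update_weights(m, x_hat, u, y, 0.1, apply=False, advance=False)
        assert np.allclose(dC2, dC3)


class TestFilterSequence:
    def test_empty_input(self, rng):
        m = random_tpc(rng)
        traj = simulate(
            make_tracking_model(0.001, seed=0), np.zeros((0, 1)), 0, seed=0
        )
        res = filter_sequence(m, traj, TPCConfig())
        assert len(res.estimates) == 0
        assert np.isnan(res.mse_state) and np.isnan(res.mse_observation)

    def test_noise_free_exact_inversion_limit(self):
        """With true weights, invertible C and no noise, converged
        inference recovers the state almost exactly."""
        rng = np.random.default_rng(0)
        C = rng.standard_normal((3, 3)) + 3 * np.eye(3)
        ss = StateSpaceModel(
            A=np.eye(3) * 0.9,
            B=np.zeros((3, 1)),
            C=C,
            Sigma_x=np.zeros((3, 3)),
            Sigma_y=np.zeros((3, 3)),
            noise_free=True,
        )
        traj = simulate(ss, np.zeros((30, 1)), 30, seed=1, x0=np.ones(3))
        m = TPCModel(A=ss.A, B=ss.B, C=ss.C, f="linear", x_prev=np.ones(3))
        res = filter_sequence(
            m, traj, TPCConfig(inference_steps=3000, step_size=0.2)
        )
        assert res.mse_state < 1e-6

    def test_result_lengths_and_trace(self, rng):
        ss = make_tracking_model(0.001, seed=1)
        traj = simulate(ss, make_control_sequence(20), 20, seed=2)
        res = filter_sequence(TPCModel.from_state_space(ss), traj, TPCConfig())
        assert res.estimates.shape == (20, 3)
        assert res.predicted_observations.shape == (20, 3)
        assert res.free_energy_trace.shape == (20,)
        assert np.all(res.free_energy_trace >= 0)

    def test_csv_and_json_export(self, rng, tmp_path):
        ss = make_tracking_model(0.001, seed=1)
        traj = simulate(ss, make_control_sequence(5), 5, seed=2)
        cfg = TPCConfig()
        res = filter_sequence(TPCModel.from_state_space(ss), traj, cfg)
        res.to_csv(tmp_path / "r.csv")
        res.to_json(tmp_path / "r.json", config=cfg)
        import json

        payload = json.loads((tmp_path / "r.json").read_text())
        assert payload["n_steps"] == 5
        assert payload["config"]["inference_steps"] == cfg.inference_steps


class TestSparseVariant:
    def test_reduction_to_twice_free_energy(self, rng):
        m = random_tpc(rng)  # identity precisions
        x, y = rng.standard_normal(3), rng.standard_normal(3)
        dense = free_energy(m, x, np.zeros(1), y)
        m.B = np.zeros_like(m.B)
        assert sparse_free_energy(m, x, y, 0.0, 0.0) == pytest.approx(
            2 * dense, rel=1e-10
        )

    def test_scalar_hand_arithmetic(self):
        # 1 + 1 + 0.5 + 0.1 = 2.6
        m = TPCModel(A=[[0.0]], B=[[0.0]], C=[[1.0]], x_prev=np.array([0.0]))
        val = sparse_free_energy(m, np.array([1.0]), np.array([0.0]), 0.5, 0.1)
        assert val == pytest.approx(2.6)

    def test_lambda_zero_matches_plain_inference(self, rng):
        m = random_tpc(rng)
        m.B = np.zeros_like(m.B)
        x, y = rng.standard_normal(3), rng.standard_normal(3)
        a = sparse_inference_step(m, x, y, 0.05, lambda_x=0.0)
        b = inference_step(m, x, np.zeros(1), y, 0.05)
        assert np.allclose(a, b)

    def test_large_lambda_shrinks_activity(self, rng):
        m = random_tpc(rng)
        x = np.array([1.0, -2.0, 3.0])
        y = np.zeros(3)
        out = sparse_inference_step(m, x, y, 1e-3, lambda_x=1e3)
        assert np.all(np.abs(out) < np.abs(x))

    def test_sparse_objective_descends(self, rng):
        """Inference iterates and a small weight step both decrease the
        sparse objective."""
        for _ in range(10):
            m = random_tpc(rng)
            m.B = np.zeros_like(m.B)
            m.learn_A = m.learn_C = True
            y = rng.standard_normal(3)
            x = m.x_prev.copy()
            lam_x, lam_C = 0.3, 0.2
            start = prev = sparse_free_energy(m, x, y, lam_x, lam_C)
            for _ in range(50):
                x = sparse_inference_step(m, x, y, 0.02, lam_x)
                cur = sparse_free_energy(m, x, y, lam_x, lam_C)
                # small per-step slack for iterates crossing an L1 kink
                assert cur <= prev + lam_x * 0.02
                prev = cur
            assert prev < start
            sparse_weight_update(m, x, y, eta=1e-4, lambda_C=lam_C, advance=False)
            assert sparse_free_energy(m, x, y, lam_x, lam_C) <= prev + 1e-9

    def test_subgradient_matches_finite_difference_off_kinks(self, rng):
        """Away from zeros, the L1 term's contribution equals
        lambda*sign(x) (checked through the descent direction)."""
        m = random_tpc(rng)
        m.B = np.zeros_like(m.B)
        x = np.array([0.7, -1.3, 2.1])
        y = rng.standard_normal(3)
        h = 1e-3
        lam = 0.4
        with_l1 = sparse_inference_step(m, x, y, h, lam)
        without = sparse_inference_step(m, x, y, h, 0.0)
        assert np.allclose((without - with_l1) / h, 0.5 * lam * np.sign(x))
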