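"""Reference Kalman filter, the tPC analytic equilibrium, and a
brute-force Bayesian-conditioning oracle.

Both the Kalman filter and temporal predictive coding solve the recursive
Bayesian filtering problem p(x_k | y_{1:k}) for a linear-Gaussian state
space.  The Kalman filter propagates a full Gaussian posterior
N(x̂_k, Sigma_k) through the projection / correction recursion; the tPC
equilibrium is the same recursion with the previous posterior collapsed
to a point mass (Sigma_{k-1} = 0), so its gain uses the process noise
alone:

    K_tpc = Sigma_x C' (C Sigma_x C' + Sigma_y)^{-1}.

The brute-force oracle stacks the whole linear-Gaussian system over k
steps into one joint Gaussian and conditions on all observations; it is
exact and serves as the independent ground truth in tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import FilterResult, TPCModel
from .state_space import StateSpaceModel, Trajectory

__all__ = [
    "KalmanState",
    "kalman_project",
    "kalman_correct",
    "kalman_filter",
    "tpc_equilibrium",
    "equilibrium_filter",
    "brute_force_posterior",
]


@dataclass
class KalmanState:
    """Posterior mean, covariance and the last Kalman gain."""

    x_hat: np.ndarray
    Sigma_k: np.ndarray
    K: np.ndarray | None = None


def _require_linear(model: StateSpaceModel) -> None:
    if model.f != "linear":
        raise ValueError("Kalman recursion requires a linear model")


def kalman_project(
    state: KalmanState, model: StateSpaceModel, u: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Projection (time update): propagate mean and covariance through
    the dynamics.

        x⁻ = A x̂_{k-1} + B u_k
        Σ⁻ = A Σ_{k-1} A' + Σ_x
    """
    _require_linear(model)
    u = np.atleast_1d(np.asarray(u, dtype=float))
    x_minus = model.A @ state.x_hat + model.B @ u
    Sigma_minus = model.A @ state.Sigma_k @ model.A.T + model.Sigma_x
    return x_minus, Sigma_minus


def kalman_correct(
    x_minus: np.ndarray,
    Sigma_minus: np.ndarray,
    model: StateSpaceModel,
    y: np.ndarray,
    joseph: bool = False,
) -> KalmanState:
    """Correction (measurement update) with gain
    K = Σ⁻C'(CΣ⁻C' + Σ_y)^{-1}.

    The covariance update uses the simple form (I - KC)Σ⁻ symmetrized
    after computation; ``joseph`` switches to the Joseph stabilized form
    for very long runs.
    """
    _require_linear(model)
    C = model.C
    S = C @ Sigma_minus @ C.T + model.Sigma_y
    K = np.linalg.solve(S.T, (Sigma_minus @ C.T).T).T
    x_hat = x_minus + K @ (np.asarray(y, float) - C @ x_minus)
    I = np.eye(len(x_minus))
    if joseph:
        Sigma = (I - K @ C) @ Sigma_minus @ (I - K @ C).T + K @ model.Sigma_y @ K.T
    else:
        Sigma = (I - K @ C) @ Sigma_minus
    Sigma = 0.5 * (Sigma + Sigma.T)
    return KalmanState(x_hat=x_hat, Sigma_k=Sigma, K=K)


def kalman_filter(
    model: StateSpaceModel,
    traj: Trajectory,
    x0: np.ndarray | None = None,
    Sigma0: np.ndarray | None = None,
    joseph: bool = False,
) -> tuple[list[KalmanState], FilterResult]:
    """Run the full projection/correction recursion over a trajectory.

    ``x0`` defaults to zero and ``Sigma0`` to the identity.  Returns the
    per-step posterior states and a FilterResult with the same schema as
    the tPC filter for side-by-side comparison (ŷ_k = C x⁻_k, the
    one-step-ahead observation prediction; the free-energy slot carries
    the innovation squared norm).
    """
    _require_linear(model)
    dx, dy = model.dx, model.dy
    x0 = np.zeros(dx) if x0 is None else np.asarray(x0, dtype=float)
    Sigma0 = np.eye(dx) if Sigma0 is None else np.asarray(Sigma0, dtype=float)
    state = KalmanState(x_hat=x0, Sigma_k=Sigma0)
    N = traj.N
    states: list[KalmanState] = []
    estimates = np.empty((N, dx))
    predicted = np.empty((N, dy))
    innov = np.empty(N)
    for k in range(N):
        x_minus, Sigma_minus = kalman_project(state, model, traj.controls[k])
        predicted[k] = model.C @ x_minus
        state = kalman_correct(
            x_minus, Sigma_minus, model, traj.observations[k], joseph=joseph
        )
        states.append(state)
        estimates[k] = state.x_hat
        innov[k] = float(np.sum((traj.observations[k] - predicted[k]) ** 2))
    if N == 0:
        mse_state = mse_obs = float("nan")
    else:
        mse_state = float(np.mean((estimates - traj.states) ** 2))
        mse_obs = float(np.mean((predicted - traj.observations) ** 2))
    result = FilterResult(
        estimates=estimates,
        predicted_observations=predicted,
        free_energy_trace=innov,
        mse_state=mse_state,
        mse_observation=mse_obs,
    )
    return states, result


def tpc_equilibrium(
    model: StateSpaceModel, x_prev: np.ndarray, u: np.ndarray, y: np.ndarray
) -> np.ndarray:
    """Closed-form equilibrium of linear tPC inference.

    Identical to one Kalman projection/correction step with the previous
    posterior covariance forced to zero, so the gain is fixed at
    K = Σ_x C'(C Σ_x C' + Σ_y)^{-1}.
    """
    _require_linear(model)
    u = np.atleast_1d(np.asarray(u, dtype=float))
    x_minus = model.A @ np.asarray(x_prev, float) + model.B @ u
    C = model.C
    S = C @ model.Sigma_x @ C.T + model.Sigma_y
    K = np.linalg.solve(S.T, (model.Sigma_x @ C.T).T).T
    return x_minus + K @ (np.asarray(y, float) - C @ x_minus)


def equilibrium_filter(model: StateSpaceModel, traj: Trajectory) -> FilterResult:
    """Filter a trajectory with the analytic tPC equilibrium at every
    step (the fully converged inference limit), starting from x̂_0 = 0."""
    _require_linear(model)
    N = traj.N
    dx, dy = model.dx, model.dy
    estimates = np.empty((N, dx))
    predicted = np.empty((N, dy))
    x_prev = np.zeros(dx)
    for k in range(N):
        u = traj.controls[k]
        predicted[k] = model.C @ (model.A @ x_prev + model.B @ u)
        x_prev = tpc_equilibrium(model, x_prev, u, traj.observations[k])
        estimates[k] = x_prev
    if N == 0:
        mse_state = mse_obs = float("nan")
    else:
        mse_state = float(np.mean((estimates - traj.states) ** 2))
        mse_obs = float(np.mean((predicted - traj.observations) ** 2))
    return FilterResult(
        estimates=estimates,
        predicted_observations=predicted,
        free_energy_trace=np.zeros(N),
        mse_state=mse_state,
        mse_observation=mse_obs,
    )


def brute_force_posterior(
    model: StateSpaceModel,
    observations: np.ndarray,
    controls: np.ndarray,
    k: int,
    x0: np.ndarray | None = None,
    Sigma0: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Exact posterior p(x_k | y_{1:k}) by joint-Gaussian conditioning.

    Stacks (x_0, x_1, ..., x_k, y_1, ..., y_k) into a single Gaussian —
    every variable is a linear map of (x_0, process noises, observation
    noises) — and conditions on the observed block.  Exponential in
    nothing but cubic in k·dx, intended for small k (≤ 30); used only as
    a test oracle.
    """
    _require_linear(model)
    if k < 1:
        raise ValueError("k must be >= 1")
    dx, dy = model.dx, model.dy
    observations = np.atleast_2d(np.asarray(observations, dtype=float))
    controls = np.atleast_2d(np.asarray(controls, dtype=float))
    if observations.shape[0] < k or controls.shape[0] < k:
        raise ValueError("need at least k observations and controls")
    x0 = np.zeros(dx) if x0 is None else np.asarray(x0, dtype=float)
    Sigma0 = np.eye(dx) if Sigma0 is None else np.asarray(Sigma0, dtype=float)

    # Latent stack z = (x_1..x_k); mean and covariance by linear recursion.
    # x_j = A x_{j-1} + B u_j + w_j, so x_j = A^j x_0 + sum of mapped noises.
    mean_x = np.empty((k, dx))
    # cov[(i, j)] blocks of the latent stack
    cov_x = np.zeros((k * dx, k * dx))
    # P[j] = Cov(x_j, x_0-chain): track via recursion on full covariance.
    # Build jointly: Cov(x_i, x_j) = A Cov(x_{i-1}, x_j) for i > j.
    prev_mean = x0
    var = [None] * (k + 1)
    var[0] = Sigma0
    means = [x0]
    for j in range(1, k + 1):
        prev_mean = model.A @ prev_mean + model.B @ controls[j - 1]
        means.append(prev_mean)
        var[j] = model.A @ var[j - 1] @ model.A.T + model.Sigma_x
    for j in range(1, k + 1):
        mean_x[j - 1] = means[j]
        block = var[j]
        cov_x[(j - 1) * dx : j * dx, (j - 1) * dx : j * dx] = block
        cross = block
        for i in range(j + 1, k + 1):
            cross = model.A @ cross
            cov_x[(i - 1) * dx : i * dx, (j - 1) * dx : j * dx] = cross
            cov_x[(j - 1) * dx : j * dx, (i - 1) * dx : i * dx] = cross.T

    # Observation stack: y_j = C x_j + v_j
    H = np.kron(np.eye(k), model.C)
    mean_y = (H @ mean_x.reshape(-1)).reshape(k, dy)
    cov_yy = H @ cov_x @ H.T + np.kron(np.eye(k), model.Sigma_y)
    cov_xy = cov_x @ H.T

    y_flat = observations[:k].reshape(-1)
    resid = y_flat - mean_y.reshape(-1)
    gain = np.linalg.solve(cov_yy.T, cov_xy.T).T
    mean_post = mean_x.reshape(-1) + gain @ resid
    cov_post = cov_x - gain @ cov_xy.T

    sl = slice((k - 1) * dx, k * dx)
    mean_k = mean_post[sl]
    cov_k = cov_post[sl, sl]
    return mean_k, 0.5 * (cov_k + cov_k.T)
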