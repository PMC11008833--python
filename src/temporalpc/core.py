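"""The temporal predictive coding (tPC) engine.

A tPC network maintains an estimate x̂ of the hidden state of a dynamical
world.  At each discrete observation step k it minimises the variational
free energy

    F_k = 1/2 (y_k - C f(x_k))' Pi_y (y_k - C f(x_k))
        + 1/2 (x_k - A f(x̂_{k-1}) - B u_k)' Pi_x (x_k - A f(x̂_{k-1}) - B u_k)

by gradient descent on x_k (neural dynamics) and, optionally, on the
weight matrices A, B, C (Hebbian plasticity).  Pi_x and Pi_y are the
precisions (inverse noise covariances); the prediction errors

    eps_y = Pi_y (y_k - C f(x_k))
    eps_x = Pi_x (x_k - A f(x̂_{k-1}) - B u_k)

are the quantities carried by error neurons in the circuit-level reading
of the model.  Inference is an Euler discretisation of
tau dx/dt = -dF/dx with step size dt/tau; the fully online variant takes
a single such step per observation.  A sparse variant adds L1 penalties
on the latent activity and on C for the movie-trained models.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .state_space import StateSpaceModel, Trajectory, get_nonlinearity

__all__ = [
    "TPCModel",
    "TPCConfig",
    "FilterResult",
    "free_energy",
    "prediction_errors",
    "inference_step",
    "infer",
    "single_step_update",
    "update_weights",
    "filter_sequence",
    "sparse_free_energy",
    "sparse_inference_step",
    "sparse_weight_update",
]


@dataclass
class TPCModel:
    """Learnable tPC network state: weights, precisions and the carried
    previous estimate x̂_{k-1}.

    The weights are the network's *estimates* of the generative matrices,
    not necessarily the ground truth.  ``x_prev`` plays the role of the
    memory neurons holding the previous inference; it is reloaded after
    each observation step.
    """

    A: np.ndarray
    B: np.ndarray
    C: np.ndarray
    Pi_x: np.ndarray | None = None
    Pi_y: np.ndarray | None = None
    f: str = "linear"
    x_prev: np.ndarray | None = None
    learn_A: bool = False
    learn_B: bool = False
    learn_C: bool = False

    def __post_init__(self) -> None:
        self.A = np.atleast_2d(np.asarray(self.A, dtype=float))
        self.B = np.atleast_2d(np.asarray(self.B, dtype=float))
        self.C = np.atleast_2d(np.asarray(self.C, dtype=float))
        dx = self.A.shape[0]
        dy = self.C.shape[0]
        if self.Pi_x is None:
            self.Pi_x = np.eye(dx)
        if self.Pi_y is None:
            self.Pi_y = np.eye(dy)
        self.Pi_x = np.atleast_2d(np.asarray(self.Pi_x, dtype=float))
        self.Pi_y = np.atleast_2d(np.asarray(self.Pi_y, dtype=float))
        if self.x_prev is None:
            self.x_prev = np.zeros(dx)
        self.x_prev = np.asarray(self.x_prev, dtype=float)
        if not np.all(np.isfinite(self.x_prev)):
            raise ValueError("x_prev must be finite")
        get_nonlinearity(self.f)

    @property
    def dx(self) -> int:
        return self.A.shape[0]

    @property
    def dy(self) -> int:
        return self.C.shape[0]

    @classmethod
    def from_state_space(
        cls, model: StateSpaceModel, use_precisions: bool = True, **kwargs
    ) -> "TPCModel":
        """Build a tPC network with the true generative weights.

        With ``use_precisions`` the noise covariances are inverted into
        the network's precisions; otherwise identity precisions are used
        (the learned configurations let A and C absorb the covariance
        structure instead).
        """
        Pi_x = np.linalg.inv(model.Sigma_x) if use_precisions else None
        Pi_y = np.linalg.inv(model.Sigma_y) if use_precisions else None
        return cls(
            A=model.A.copy(),
            B=model.B.copy(),
            C=model.C.copy(),
            Pi_x=Pi_x,
            Pi_y=Pi_y,
            f=model.f,
            **kwargs,
        )

    @classmethod
    def for_learning(
        cls, dx: int, du: int, dy: int, f: str = "linear", **kwargs
    ) -> "TPCModel":
        """Initial network for online system identification: A = 0 and C
        the identity (zero-padded when rectangular), with learning on."""
        C = np.zeros((dy, dx))
        np.fill_diagonal(C, 1.0)
        return cls(
            A=np.zeros((dx, dx)),
            B=np.zeros((dx, du)),
            C=C,
            f=f,
            learn_A=True,
            learn_C=True,
            **kwargs,
        )


@dataclass
class TPCConfig:
    """Inference/learning hyperparameters.

    ``step_size`` is the Euler ratio dt/tau; ``inference_steps`` the
    number of gradient iterations per observation (1 gives the fully
    online single-step variant); ``eta`` the Hebbian learning rate;
    ``lambda_x``/``lambda_C`` the L1 weights of the sparse variant.
    """

    inference_steps: int = 20
    step_size: float = 0.2
    eta: float = 0.0
    lambda_x: float = 0.0
    lambda_C: float = 0.0
    seed: int | None = None
    convergence_tol: float | None = None

    def __post_init__(self) -> None:
        if self.step_size <= 0:
            raise ValueError("step_size must be positive")
        if self.inference_steps < 1:
            raise ValueError("inference_steps must be >= 1")
        if self.eta < 0 or self.lambda_x < 0 or self.lambda_C < 0:
            raise ValueError("eta and sparsity weights must be non-negative")


@dataclass
class FilterResult:
    """Per-step filtering output plus MSE summaries.

    ``mse_state`` and ``mse_observation`` are squared errors averaged
    over time steps and dimensions; NaN for empty input.
    """

    estimates: np.ndarray
    predicted_observations: np.ndarray
    free_energy_trace: np.ndarray
    mse_state: float
    mse_observation: float

    def to_csv(self, path: str | Path) -> None:
        n = len(self.estimates)
        cols: dict[str, np.ndarray] = {"k": np.arange(1, n + 1)}
        for i in range(self.estimates.shape[1] if n else 0):
            cols[f"xhat_{i + 1}"] = self.estimates[:, i]
        for i in range(self.predicted_observations.shape[1] if n else 0):
            cols[f"yhat_{i + 1}"] = self.predicted_observations[:, i]
        cols["free_energy"] = self.free_energy_trace
        pd.DataFrame(cols).to_csv(path, index=False)

    def summary(self) -> dict:
        return {
            "mse_state": self.mse_state,
            "mse_observation": self.mse_observation,
            "n_steps": int(len(self.estimates)),
        }

    def to_json(self, path: str | Path, config: TPCConfig | None = None) -> None:
        payload = self.summary()
        if config is not None:
            payload["config"] = {
                "inference_steps": config.inference_steps,
                "step_size": config.step_size,
                "eta": config.eta,
                "lambda_x": config.lambda_x,
                "lambda_C": config.lambda_C,
                "seed": config.seed,
                "convergence_tol": config.convergence_tol,
            }
        Path(path).write_text(json.dumps(payload, indent=2))


def _check_finite(name: str, *arrays) -> None:
    for a in arrays:
        if not np.all(np.isfinite(a)):
            raise FloatingPointError(f"non-finite values in {name}")


def free_energy(m: TPCModel, x: np.ndarray, u: np.ndarray, y: np.ndarray) -> float:
    """Variational free energy F_k at latent value ``x`` (non-negative)."""
    fn, _ = get_nonlinearity(m.f)
    x = np.asarray(x, dtype=float)
    _check_finite("free_energy inputs", x, u, y)
    r_y = np.asarray(y, float) - m.C @ fn(x)
    r_x = x - m.A @ fn(m.x_prev) - m.B @ np.atleast_1d(np.asarray(u, float))
    return float(0.5 * r_y @ m.Pi_y @ r_y + 0.5 * r_x @ m.Pi_x @ r_x)


def prediction_errors(
    m: TPCModel, x: np.ndarray, u: np.ndarray, y: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Precision-weighted temporal and sensory prediction errors
    (eps_x, eps_y)."""
    fn, _ = get_nonlinearity(m.f)
    x = np.asarray(x, dtype=float)
    _check_finite("prediction_errors inputs", x, u, y)
    eps_y = m.Pi_y @ (np.asarray(y, float) - m.C @ fn(x))
    eps_x = m.Pi_x @ (x - m.A @ fn(m.x_prev) - m.B @ np.atleast_1d(np.asarray(u, float)))
    return eps_x, eps_y


def inference_step(
    m: TPCModel, x: np.ndarray, u: np.ndarray, y: np.ndarray, step_size: float
) -> np.ndarray:
    """One Euler step of the neural dynamics tau dx/dt = -dF/dx:

        x <- x + h (-eps_x + f'(x) ⊙ C' eps_y)
    """
    if step_size <= 0:
        raise ValueError("step_size must be positive")
    _, fprime = get_nonlinearity(m.f)
    x = np.asarray(x, dtype=float)
    eps_x, eps_y = prediction_errors(m, x, u, y)
    x_new = x + step_size * (-eps_x + fprime(x) * (m.C.T @ eps_y))
    if not np.all(np.isfinite(x_new)):
        raise FloatingPointError(
            "non-finite inference update: "
            f"max|eps_x|={np.max(np.abs(eps_x)):.3g}, "
            f"max|eps_y|={np.max(np.abs(eps_y)):.3g}"
        )
    return x_new


def stable_step_size(m: TPCModel, step_size: float, margin: float = 1.8) -> float:
    """Cap the Euler step at ``margin``/λmax(Pi_x + C' Pi_y C).

    For linear f the free energy is an exact quadratic with Hessian
    H = Pi_x + C' Pi_y C, and Euler integration of the gradient flow is
    stable only for step < 2/λmax(H); the same bound is conservative for
    tanh (|f'| <= 1).  Without the cap, a badly conditioned emission
    matrix makes the iterative dynamics diverge geometrically.
    """
    H = m.Pi_x + m.C.T @ m.Pi_y @ m.C
    lam = float(np.linalg.eigvalsh(H)[-1])
    if lam <= 0:
        return step_size
    return min(step_size, margin / lam)


def infer(m: TPCModel, u: np.ndarray, y: np.ndarray, cfg: TPCConfig) -> np.ndarray:
    """Iterative inference of x̂_k for one observation.

    Starts from the carried previous estimate x̂_{k-1} and applies
    ``cfg.inference_steps`` Euler steps with the step size capped at the
    quadratic stability limit (see ``stable_step_size``), stopping early
    when the ∞-norm of the update falls below ``cfg.convergence_tol``,
    if set.  Does not mutate ``m.x_prev``.
    """
    x = m.x_prev.copy()
    h = stable_step_size(m, cfg.step_size)
    for _ in range(cfg.inference_steps):
        x_new = inference_step(m, x, u, y, h)
        if cfg.convergence_tol is not None and np.max(
            np.abs(x_new - x)
        ) < cfg.convergence_tol:
            return x_new
        x = x_new
    return x


def single_step_update(
    m: TPCModel, u: np.ndarray, y: np.ndarray, step_size: float
) -> np.ndarray:
    """Fully online variant: one inference step per observation with the
    dendritic (precision-free temporal term) dynamics

        x̂_k = x + h (-x + A f(x̂_{k-1}) + B u + f'(x) ⊙ C' eps_y),  x = x̂_{k-1}.

    The state precision is omitted here; in the learned configurations it
    is absorbed into A.
    """
    if step_size <= 0:
        raise ValueError("step_size must be positive")
    fn, fprime = get_nonlinearity(m.f)
    x = m.x_prev.copy()
    eps_y = m.Pi_y @ (np.asarray(y, float) - m.C @ fn(x))
    pred = m.A @ fn(m.x_prev) + m.B @ np.atleast_1d(np.asarray(u, float))
    x_new = x + step_size * (-x + pred + fprime(x) * (m.C.T @ eps_y))
    if not np.all(np.isfinite(x_new)):
        raise FloatingPointError("non-finite single-step update")
    return x_new


def update_weights(
    m: TPCModel,
    x_hat: np.ndarray,
    u: np.ndarray,
    y: np.ndarray,
    eta: float,
    apply: bool = True,
    advance: bool = True,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Hebbian weight deltas evaluated at the converged estimate x̂_k:

        dA = eta eps_x f(x̂_{k-1})',  dB = eta eps_x u',  dC = eta eps_y f(x̂_k)'

    Deltas are applied in place only where the corresponding ``learn_*``
    flag is set; with ``advance`` the memory x̂_{k-1} is reloaded with x̂_k
    afterwards.  Returns (dA, dB, dC) regardless of the flags.
    """
    if eta < 0:
        raise ValueError("eta must be non-negative")
    fn, _ = get_nonlinearity(m.f)
    x_hat = np.asarray(x_hat, dtype=float)
    u = np.atleast_1d(np.asarray(u, dtype=float))
    eps_x, eps_y = prediction_errors(m, x_hat, u, y)
    dA = eta * np.outer(eps_x, fn(m.x_prev))
    dB = eta * np.outer(eps_x, u)
    dC = eta * np.outer(eps_y, fn(x_hat))
    if apply:
        if m.learn_A:
            m.A = m.A + dA
        if m.learn_B:
            m.B = m.B + dB
        if m.learn_C:
            m.C = m.C + dC
    if advance:
        m.x_prev = x_hat.copy()
    return dA, dB, dC


def predict_observation(m: TPCModel, u: np.ndarray) -> np.ndarray:
    """One-step-ahead observation prediction ŷ_k = C f(A f(x̂_{k-1}) + B u_k)
    (reduces to C(A x̂_{k-1} + B u_k) for linear f)."""
    fn, _ = get_nonlinearity(m.f)
    return m.C @ fn(m.A @ fn(m.x_prev) + m.B @ np.atleast_1d(np.asarray(u, float)))


def filter_sequence(
    m: TPCModel, traj: Trajectory, cfg: TPCConfig, learn: bool = False
) -> FilterResult:
    """Run one epoch of the tPC filtering loop over a trajectory.

    For each step k the observation prediction ŷ_k is recorded with the
    weights *before* any update at step k, so prediction quality is
    honestly one-step-ahead; then x̂_k is inferred (the single-step
    variant when ``cfg.inference_steps == 1``), the weights optionally
    updated, and the memory advanced.
    """
    N = traj.N
    dx, dy = m.dx, m.dy
    if N == 0:
        return FilterResult(
            estimates=np.zeros((0, dx)),
            predicted_observations=np.zeros((0, dy)),
            free_energy_trace=np.zeros(0),
            mse_state=float("nan"),
            mse_observation=float("nan"),
        )
    if traj.observations.shape[1] != dy:
        raise ValueError("observation dimension mismatch with model")
    estimates = np.empty((N, dx))
    predicted = np.empty((N, dy))
    fe = np.empty(N)
    for k in range(N):
        u_k = traj.controls[k]
        y_k = traj.observations[k]
        predicted[k] = predict_observation(m, u_k)
        if cfg.inference_steps == 1:
            x_hat = single_step_update(m, u_k, y_k, cfg.step_size)
        else:
            x_hat = infer(m, u_k, y_k, cfg)
        fe[k] = free_energy(m, x_hat, u_k, y_k)
        if learn:
            update_weights(m, x_hat, u_k, y_k, cfg.eta, apply=True, advance=True)
        else:
            m.x_prev = x_hat.copy()
        estimates[k] = x_hat
    mse_state = float(np.mean((estimates - traj.states) ** 2))
    mse_obs = float(np.mean((predicted - traj.observations) ** 2))
    return FilterResult(
        estimates=estimates,
        predicted_observations=predicted,
        free_energy_trace=fe,
        mse_state=mse_state,
        mse_observation=mse_obs,
    )


# --------------------------------------------------------------------------
# Sparse variant (movie-trained models).  The objective drops the 1/2
# factors and precision weighting of F_k and adds L1 penalties:
#     ||y - C f(x)||^2 + ||x - A f(x_prev)||^2 + lx |x|_1 + lC sum|C_ij|
# so with lx = lC = 0 it equals 2 * free_energy at identity precisions.
# --------------------------------------------------------------------------


def sparse_free_energy(
    m: TPCModel, x: np.ndarray, y: np.ndarray, lambda_x: float, lambda_C: float
) -> float:
    """Sparse objective (unweighted squared norms plus L1 terms); no
    control input (B treated as zero)."""
    fn, _ = get_nonlinearity(m.f)
    x = np.asarray(x, dtype=float)
    r_y = np.asarray(y, float) - m.C @ fn(x)
    r_x = x - m.A @ fn(m.x_prev)
    return float(
        r_y @ r_y
        + r_x @ r_x
        + lambda_x * np.sum(np.abs(x))
        + lambda_C * np.sum(np.abs(m.C))
    )


def sparse_inference_step(
    m: TPCModel,
    x: np.ndarray,
    y: np.ndarray,
    step_size: float,
    lambda_x: float,
) -> np.ndarray:
    """Subgradient descent step on the sparse objective in x.

    Uses sign(0) = 0 for the L1 subgradient; the quadratic terms give the
    same direction as ``inference_step`` with identity precisions (up to
    the absent factor 1/2, absorbed into the step size convention here).
    """
    if step_size <= 0:
        raise ValueError("step_size must be positive")
    fn, fprime = get_nonlinearity(m.f)
    x = np.asarray(x, dtype=float)
    eps_y = np.asarray(y, float) - m.C @ fn(x)
    eps_x = x - m.A @ fn(m.x_prev)
    grad = 2.0 * (-eps_x + fprime(x) * (m.C.T @ eps_y)) - lambda_x * np.sign(x)
    x_new = x + step_size * 0.5 * grad
    if not np.all(np.isfinite(x_new)):
        raise FloatingPointError("non-finite sparse inference update")
    return x_new


def sparse_weight_update(
    m: TPCModel,
    x_hat: np.ndarray,
    y: np.ndarray,
    eta: float,
    lambda_C: float,
    apply: bool = True,
    advance: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Hebbian updates for the sparse objective: the usual error-activity
    outer products plus L1 shrinkage on C.  The deltas are the exact
    (sub)gradient of half the sparse objective, so a small eta never
    increases it.  Returns (dA, dC)."""
    fn, _ = get_nonlinearity(m.f)
    x_hat = np.asarray(x_hat, dtype=float)
    eps_y = np.asarray(y, float) - m.C @ fn(x_hat)
    eps_x = x_hat - m.A @ fn(m.x_prev)
    dA = eta * np.outer(eps_x, fn(m.x_prev))
    dC = eta * (np.outer(eps_y, fn(x_hat)) - 0.5 * lambda_C * np.sign(m.C))
    if apply:
        if m.learn_A:
            m.A = m.A + dA
        if m.learn_C:
            m.C = m.C + dC
    if advance:
        m.x_prev = x_hat.copy()
    return dA, dC
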