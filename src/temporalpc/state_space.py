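"""Linear/nonlinear Gaussian state-space models and trajectory simulation.

The generative process is a hidden Markov model with Gaussian noise,

    x_k = A f(x_{k-1}) + B u_k + w_x,   w_x ~ N(0, Sigma_x)
    y_k = C f(x_k)     + w_y,           w_y ~ N(0, Sigma_y)

where ``f`` is either the identity or ``tanh`` applied elementwise.  This
module defines the model container, the simulator, and the benchmark
systems used throughout the package: a Newtonian tracking model
(position / velocity / acceleration with an exponentially decaying control
input) and a set of noise-covariance cases used to probe whether learnt
weights can absorb non-identity noise structure.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "StateSpaceModel",
    "Trajectory",
    "simulate",
    "make_tracking_model",
    "make_control_sequence",
    "make_covariance_case",
    "COVARIANCE_CASES",
]


def _as_2d(name: str, m) -> np.ndarray:
    arr = np.atleast_2d(np.asarray(m, dtype=float))
    if arr.ndim != 2:
        raise ValueError(f"{name} must be a 2-D matrix, got ndim={arr.ndim}")
    return arr


def _check_spd(name: str, m: np.ndarray, allow_zero: bool = False) -> None:
    if not np.allclose(m, m.T):
        raise ValueError(f"{name} must be symmetric")
    if allow_zero and np.allclose(m, 0.0):
        return
    try:
        np.linalg.cholesky(m)
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"{name} must be positive definite (Cholesky failed)") from exc


def get_nonlinearity(f: str) -> tuple[Callable, Callable]:
    """Return ``(f, f')`` for a nonlinearity tag.

    ``f'`` is evaluated elementwise; for the identity it is the ones vector.
    """
    if f == "linear":
        return (lambda x: x, lambda x: np.ones_like(x))
    if f == "tanh":
        return (np.tanh, lambda x: 1.0 - np.tanh(x) ** 2)
    raise ValueError(f"unknown nonlinearity {f!r}; expected 'linear' or 'tanh'")


@dataclass
class StateSpaceModel:
    """The generative quadruple (A, B, C, f) with noise covariances.

    Parameters
    ----------
    A : (dx, dx) state-transition matrix.
    B : (dx, du) control-gain matrix.
    C : (dy, dx) emission matrix.
    Sigma_x : (dx, dx) process-noise covariance, symmetric positive definite.
    Sigma_y : (dy, dy) observation-noise covariance, symmetric positive definite.
    f : nonlinearity tag, ``"linear"`` or ``"tanh"``.
    noise_free : if True, permits Sigma_x = Sigma_y = 0 (deterministic
        simulation for diagnostics; the public default enforces PD).
    """

    A: np.ndarray
    B: np.ndarray
    C: np.ndarray
    Sigma_x: np.ndarray
    Sigma_y: np.ndarray
    f: str = "linear"
    noise_free: bool = False

    def __post_init__(self) -> None:
        self.A = _as_2d("A", self.A)
        self.B = _as_2d("B", self.B)
        self.C = _as_2d("C", self.C)
        self.Sigma_x = _as_2d("Sigma_x", self.Sigma_x)
        self.Sigma_y = _as_2d("Sigma_y", self.Sigma_y)
        dx, du, dy = self.dx, self.du, self.dy
        if self.A.shape != (dx, dx):
            raise ValueError(f"A must be square, got {self.A.shape}")
        if self.B.shape[0] != dx:
            raise ValueError(f"B has {self.B.shape[0]} rows, expected {dx}")
        if self.C.shape != (dy, dx):
            raise ValueError(
                f"C shape {self.C.shape} inconsistent with dx={dx}, dy={dy}"
            )
        if self.Sigma_x.shape != (dx, dx):
            raise ValueError("Sigma_x shape inconsistent with dx")
        if self.Sigma_y.shape != (dy, dy):
            raise ValueError("Sigma_y shape inconsistent with dy")
        _check_spd("Sigma_x", self.Sigma_x, allow_zero=self.noise_free)
        _check_spd("Sigma_y", self.Sigma_y, allow_zero=self.noise_free)
        get_nonlinearity(self.f)  # validates the tag

    @property
    def dx(self) -> int:
        return self.A.shape[0]

    @property
    def du(self) -> int:
        return self.B.shape[1]

    @property
    def dy(self) -> int:
        return self.C.shape[0]

    def nonlinearity(self) -> tuple[Callable, Callable]:
        return get_nonlinearity(self.f)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "A": self.A.tolist(),
            "B": self.B.tolist(),
            "C": self.C.tolist(),
            "Sigma_x": self.Sigma_x.tolist(),
            "Sigma_y": self.Sigma_y.tolist(),
            "f": self.f,
            "noise_free": self.noise_free,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "StateSpaceModel":
        payload = json.loads(Path(path).read_text())
        return cls(**{k: v for k, v in payload.items()})


@dataclass
class Trajectory:
    """Aligned sequences of hidden states, observations and controls.

    ``states[k-1]`` stores the mathematical x_k for k = 1..N; the k = 0
    initial condition is not part of the stored sequence.
    """

    states: np.ndarray  # (N, dx)
    observations: np.ndarray  # (N, dy)
    controls: np.ndarray  # (N, du)
    seed: int | None = None

    def __post_init__(self) -> None:
        self.states = np.atleast_2d(np.asarray(self.states, dtype=float))
        self.observations = np.atleast_2d(np.asarray(self.observations, dtype=float))
        self.controls = np.atleast_2d(np.asarray(self.controls, dtype=float))
        if not (
            len(self.states) == len(self.observations) == len(self.controls)
        ):
            raise ValueError("states, observations and controls must share length")

    @property
    def N(self) -> int:
        return self.states.shape[0]

    def __len__(self) -> int:
        return self.N

    def to_csv(self, path: str | Path) -> None:
        cols: dict[str, np.ndarray] = {"k": np.arange(1, self.N + 1)}
        for i in range(self.states.shape[1]):
            cols[f"x_{i + 1}"] = self.states[:, i]
        for i in range(self.observations.shape[1]):
            cols[f"y_{i + 1}"] = self.observations[:, i]
        for i in range(self.controls.shape[1]):
            cols[f"u_{i + 1}"] = self.controls[:, i]
        pd.DataFrame(cols).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "Trajectory":
        df = pd.read_csv(path)
        x = df[[c for c in df.columns if c.startswith("x_")]].to_numpy()
        y = df[[c for c in df.columns if c.startswith("y_")]].to_numpy()
        u = df[[c for c in df.columns if c.startswith("u_")]].to_numpy()
        return cls(states=x, observations=y, controls=u)


def simulate(
    model: StateSpaceModel,
    controls: Sequence | np.ndarray,
    N: int,
    seed: int | None = None,
    x0: np.ndarray | None = None,
) -> Trajectory:
    """Simulate ``N`` steps of the generative process.

    ``controls`` must provide at least ``N`` rows of u_k (k = 1..N);
    ``x0`` is the k = 0 initial state and defaults to the zero vector.
    Noise draws are reproducible from ``seed``.
    """
    if N < 0:
        raise ValueError("N must be non-negative")
    dx, du, dy = model.dx, model.du, model.dy
    u = np.asarray(controls, dtype=float)
    if u.size == 0:
        u = np.zeros((len(controls), du))
    else:
        u = np.atleast_2d(u.reshape(len(u), -1))
    if u.shape[0] < N:
        raise ValueError(f"need at least {N} controls, got {u.shape[0]}")
    if u.shape[1] != du:
        raise ValueError(f"control dimension {u.shape[1]} != du={du}")
    x0 = np.zeros(dx) if x0 is None else np.asarray(x0, dtype=float)
    if x0.shape != (dx,):
        raise ValueError(f"x0 must have shape ({dx},)")

    rng = np.random.default_rng(seed)
    fn, _ = model.nonlinearity()
    states = np.empty((N, dx))
    observations = np.empty((N, dy))
    if model.noise_free and np.allclose(model.Sigma_x, 0):
        wx = np.zeros((N, dx))
    else:
        wx = rng.multivariate_normal(np.zeros(dx), model.Sigma_x, size=N)
    if model.noise_free and np.allclose(model.Sigma_y, 0):
        wy = np.zeros((N, dy))
    else:
        wy = rng.multivariate_normal(np.zeros(dy), model.Sigma_y, size=N)

    x = x0
    for k in range(N):
        x = model.A @ fn(x) + model.B @ u[k] + wx[k]
        states[k] = x
        observations[k] = model.C @ fn(x) + wy[k]
    return Trajectory(
        states=states, observations=observations, controls=u[:N], seed=seed
    )


def make_tracking_model(dk: float, seed: int | None = None) -> StateSpaceModel:
    """Newtonian tracking benchmark: position, velocity, acceleration.

    The transition matrix is the Taylor integrator for constant
    acceleration over an interval ``dk``; the scalar control drives the
    acceleration.  The emission matrix is 3x3 with i.i.d. standard-normal
    entries drawn from ``seed`` (the observations are deliberately
    scrambled), and both noise covariances are identity.
    """
    if dk <= 0:
        raise ValueError("dk must be positive")
    A = np.array(
        [[1.0, dk, dk**2 / 2.0], [0.0, 1.0, dk], [0.0, 0.0, 1.0]]
    )
    B = np.array([[0.0], [0.0], [1.0]])
    C = np.random.default_rng(seed).standard_normal((3, 3))
    return StateSpaceModel(
        A=A, B=B, C=C, Sigma_x=np.eye(3), Sigma_y=np.eye(3), f="linear"
    )


def make_control_sequence(N: int, k_origin: int = 1) -> np.ndarray:
    """Exponentially decaying scalar control u_k = exp(-0.01 k), k = 1..N.

    ``k_origin`` shifts the index origin (0 makes u_1 = 1).
    """
    if N < 0:
        raise ValueError("N must be non-negative")
    k = np.arange(k_origin, k_origin + N, dtype=float)
    return np.exp(-0.01 * k).reshape(-1, 1)


# Noise-covariance cases for the covariance-learning experiment.  The
# non-identity diagonal case has one deliberately large variance (10) so
# that learnt recurrent weights can be checked for absorbing it; the
# positive-definite case is a fixed symmetric matrix with unit diagonal.
COVARIANCE_CASES = ("identity", "nonidentity_diagonal", "positive_definite")

_NONIDENTITY_DIAGONAL = np.diag([10.0, 1.0, 1.0])
_POSITIVE_DEFINITE = np.array(
    [
        [1.0, 0.2, 0.5],
        [0.2, 1.0, 0.4],
        [0.5, 0.4, 1.0],
    ]
)


def make_covariance_case(case: str) -> tuple[np.ndarray, np.ndarray]:
    """Return (Sigma_x, Sigma_y) for a named noise-covariance case.

    Both covariances are set to the same matrix in every case.
    """
    if case == "identity":
        m = np.eye(3)
    elif case == "nonidentity_diagonal":
        m = _NONIDENTITY_DIAGONAL
    elif case == "positive_definite":
        m = _POSITIVE_DEFINITE
    else:
        raise ValueError(
            f"unknown covariance case {case!r}; expected one of {COVARIANCE_CASES}"
        )
    _check_spd("covariance case", m)
    return m.copy(), m.copy()
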