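"""Movie-like stimuli, centre-surround filtering, sparse movie training
and reverse-correlation receptive fields.

The training stimuli are synthetic drifting oriented gratings/bars —
motion-rich stand-ins for natural-movie patches (they share the moving
oriented structure but not the 1/f statistics of natural scenes, so the
Gabor-shaped filters that emerge from natural movies are not expected
here).  Frames are bandpass filtered with a retina-like
difference-of-Gaussians kernel, z-scored, and fed to a sparse linear tPC
model.  After training, each hidden neuron's spatio-temporal receptive
field (STRF) is estimated by white-noise reverse correlation: the
activity-weighted average of the 5 stimulus frames preceding and
including each time step,

    STRF_i = 1/(T-5) * sum_{k=5}^{T} x_{i,k} y_{k-4:k}.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import (
    TPCConfig,
    TPCModel,
    sparse_inference_step,
    sparse_weight_update,
)

__all__ = [
    "MovieDataset",
    "STRF",
    "generate_synthetic_movies",
    "centre_surround_filter",
    "preprocess_dataset",
    "train_movie_model",
    "infer_activities",
    "reverse_correlation",
    "compute_strf",
]


@dataclass
class MovieDataset:
    """A stack of grayscale movies with identical shape.

    ``movies`` has shape (n_movies, n_frames, H, W).
    """

    movies: np.ndarray
    seed: int | None = None

    def __post_init__(self) -> None:
        self.movies = np.asarray(self.movies, dtype=float)
        if self.movies.ndim != 4:
            raise ValueError("movies must have shape (n_movies, n_frames, H, W)")
        if not np.all(np.isfinite(self.movies)):
            raise ValueError("movie pixel values must be finite")

    @property
    def n_movies(self) -> int:
        return self.movies.shape[0]

    @property
    def n_frames(self) -> int:
        return self.movies.shape[1]

    @property
    def patch_size(self) -> int:
        return self.movies.shape[2]


@dataclass
class STRF:
    """Per-neuron spatio-temporal kernel over 5 frame lags.

    ``kernel[lag]`` is the spatial map at lag 4-lag frames in the past
    (kernel[4] is the current frame, lag 0).
    """

    neuron_index: int
    kernel: np.ndarray  # (5, H, W)
    n_samples: int

    def __post_init__(self) -> None:
        self.kernel = np.asarray(self.kernel, dtype=float)
        if self.kernel.ndim != 3 or self.kernel.shape[0] != 5:
            raise ValueError("kernel must have shape (5, H, W)")
        if not np.all(np.isfinite(self.kernel)):
            raise ValueError("kernel must be finite")


def generate_synthetic_movies(
    n_movies: int = 1000,
    patch_size: int = 16,
    n_frames: int = 50,
    speeds: tuple[float, float] = (0.5, 2.0),
    orientations: tuple[float, float] = (0.0, np.pi),
    seed: int | None = None,
    spatial_freq: tuple[float, float] = (0.5, 1.5),
) -> MovieDataset:
    """Drifting oriented gratings with random orientation, speed, phase
    and spatial frequency per movie.

    The dataset is augmented with a left-right mirrored copy of every
    movie so both motion directions along each orientation are
    represented; the returned dataset therefore holds 2*n_movies movies.
    """
    if n_movies < 1:
        raise ValueError("n_movies must be >= 1")
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:patch_size, 0:patch_size].astype(float)
    movies = np.empty((n_movies, n_frames, patch_size, patch_size))
    for m in range(n_movies):
        theta = rng.uniform(*orientations)
        speed = rng.uniform(*speeds)
        phase = rng.uniform(0, 2 * np.pi)
        freq = rng.uniform(*spatial_freq) * 2 * np.pi / patch_size
        axis = np.cos(theta) * xx + np.sin(theta) * yy
        for k in range(n_frames):
            movies[m, k] = np.sin(freq * axis - speed * freq * k * 1.0 - phase)
    mirrored = movies[:, :, :, ::-1]
    return MovieDataset(movies=np.concatenate([movies, mirrored], axis=0), seed=seed)


def _dog_kernel(sigma_center: float, sigma_surround: float, radius: int) -> np.ndarray:
    ax = np.arange(-radius, radius + 1, dtype=float)
    xx, yy = np.meshgrid(ax, ax)
    r2 = xx**2 + yy**2

    def g(s):
        k = np.exp(-r2 / (2 * s**2))
        return k / k.sum()

    return g(sigma_center) - g(sigma_surround)


def centre_surround_filter(
    movie: np.ndarray, sigma_center: float = 1.0, sigma_surround: float = 2.0
) -> np.ndarray:
    """Retina-like spatial bandpass: per-frame convolution with a
    zero-sum difference-of-Gaussians kernel.  Constant frames map to
    (numerically) zero."""
    if not (sigma_surround > sigma_center > 0):
        raise ValueError("need sigma_surround > sigma_center > 0")
    movie = np.asarray(movie, dtype=float)
    radius = int(np.ceil(4 * sigma_surround))
    kernel = _dog_kernel(sigma_center, sigma_surround, radius)
    out = np.empty_like(movie)
    frames = movie if movie.ndim == 3 else movie[None]
    dst = out if movie.ndim == 3 else out.reshape((1,) + movie.shape)
    for i, frame in enumerate(frames):
        dst[i] = ndimage.convolve(frame, kernel, mode="nearest")
    return out


def preprocess_dataset(
    dataset: MovieDataset, sigma_center: float = 1.0, sigma_surround: float = 2.0
) -> MovieDataset:
    """Centre-surround filter every movie, then z-score per movie."""
    out = np.empty_like(dataset.movies)
    for m in range(dataset.n_movies):
        filtered = centre_surround_filter(
            dataset.movies[m], sigma_center, sigma_surround
        )
        sd = filtered.std()
        out[m] = (filtered - filtered.mean()) / (sd if sd > 1e-12 else 1.0)
    return MovieDataset(movies=out, seed=dataset.seed)


def train_movie_model(
    dataset: MovieDataset,
    hidden_size: int = 320,
    tpc_cfg: TPCConfig | None = None,
    n_epochs: int = 1,
) -> TPCModel:
    """Train a sparse linear tPC model on flattened movie frames.

    Frames become dy = patch_size² observation vectors; B = 0 and the
    carried estimate resets to zero at every movie boundary so temporal
    structure never leaks across movies.  Weights start at A = 0 and
    small random C (i.i.d. N(0, 0.01)).
    """
    if tpc_cfg is None:
        tpc_cfg = TPCConfig(
            inference_steps=50, step_size=0.01, eta=0.01, lambda_x=0.1, lambda_C=0.1
        )
    dy = dataset.patch_size**2
    rng = np.random.default_rng(tpc_cfg.seed)
    model = TPCModel(
        A=np.zeros((hidden_size, hidden_size)),
        B=np.zeros((hidden_size, 1)),
        C=rng.normal(0.0, 0.1, size=(dy, hidden_size)),
        f="linear",
        learn_A=True,
        learn_C=True,
    )
    for epoch in range(n_epochs):
        for m in range(dataset.n_movies):
            model.x_prev = np.zeros(hidden_size)
            for k in range(dataset.n_frames):
                y = dataset.movies[m, k].ravel()
                x = model.x_prev.copy()
                for _ in range(tpc_cfg.inference_steps):
                    x = sparse_inference_step(
                        model, x, y, tpc_cfg.step_size, tpc_cfg.lambda_x
                    )
                sparse_weight_update(
                    model, x, y, tpc_cfg.eta, tpc_cfg.lambda_C
                )
                if not np.all(np.isfinite(model.C)):
                    raise FloatingPointError(
                        f"training diverged at epoch {epoch}, movie {m}"
                    )
    return model


def infer_activities(
    model: TPCModel,
    frames: np.ndarray,
    inference_steps: int = 50,
    step_size: float = 0.01,
    lambda_x: float = 0.0,
    reset: bool = False,
) -> np.ndarray:
    """Run the model's inference over a frame sequence and return the
    hidden activities (T, dx).  The carried estimate flows from frame to
    frame unless ``reset``."""
    frames = np.asarray(frames, dtype=float)
    T = frames.shape[0]
    acts = np.empty((T, model.dx))
    model.x_prev = np.zeros(model.dx)
    for k in range(T):
        y = frames[k].ravel()
        x = np.zeros(model.dx) if reset else model.x_prev.copy()
        for _ in range(inference_steps):
            x = sparse_inference_step(model, x, y, step_size, lambda_x)
        acts[k] = x
        model.x_prev = x.copy()
    return acts


def reverse_correlation(
    activities: np.ndarray, frames: np.ndarray, neuron_index: int
) -> STRF:
    """Activity-weighted average of the 5-frame stimulus history:
    STRF_i = 1/(T-5) Σ_{k=5..T} x_{i,k} y_{k-4:k} (index convention and
    the T-5 divisor kept as stated, so T-4 terms are averaged with
    divisor T-5)."""
    frames = np.asarray(frames, dtype=float)
    activities = np.atleast_2d(np.asarray(activities, dtype=float))
    T = frames.shape[0]
    if T < 5:
        raise ValueError("need at least 5 frames")
    if activities.shape[0] != T:
        raise ValueError("activities and frames must share length")
    x_i = activities[:, neuron_index]
    kernel = np.zeros((5,) + frames.shape[1:])
    # math index k runs 5..T (1-based); array index j = k-1 runs 4..T-1
    for j in range(4, T):
        kernel += x_i[j] * frames[j - 4 : j + 1]
    kernel /= T - 5
    return STRF(neuron_index=neuron_index, kernel=kernel, n_samples=T)


def compute_strf(
    model: TPCModel,
    noise_frames: np.ndarray,
    neuron_index: int,
    inference_steps: int = 50,
    step_size: float = 0.01,
    lambda_x: float = 0.0,
) -> STRF:
    """Estimate a neuron's STRF by probing the model with white noise.

    ``noise_frames`` is a (T, H, W) movie of i.i.d. pixel noise; the
    model relaxes on each frame and the resulting activities weight the
    reverse correlation."""
    acts = infer_activities(
        model, noise_frames, inference_steps, step_size, lambda_x
    )
    return reverse_correlation(acts, noise_frames, neuron_index)
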