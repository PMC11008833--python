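# Methods

This note documents the models implemented in `temporalpc`, the
numerical and design choices behind them, what the synthetic benchmarks
do and do not establish, and the package's known limitations.

## Generative model and inference

The world model is a Gaussian hidden Markov chain
`x_k = A f(x_{k-1}) + B u_k + ω_x`, `y_k = C f(x_k) + ω_y` with
`ω_x ~ N(0, Σx)`, `ω_y ~ N(0, Σy)` and `f ∈ {identity, tanh}` applied
elementwise.  States are indexed from k = 1; the k = 0 initial condition
is an argument to the simulator (zero by default) and is not part of the
stored trajectory.

The tPC network estimates `x_k` by gradient descent on the variational
free energy `F_k`, a precision-weighted sum of squared sensory and
temporal prediction errors.  Three inference regimes are provided:

* **Iterative** (`infer`): Euler integration of `τ dx/dt = -∂F/∂x`
  starting from the carried estimate `x̂_{k-1}`, for a fixed iteration
  budget with an optional ∞-norm early-stopping tolerance.  A fixed
  budget rather than a convergence loop is the default because accuracy
  as a function of the budget is itself an object of study (the tracking
  sweep).
* **Single-step** (`single_step_update`): one update per observation,
  using the dendritic form `x̂_k = x + h(-x + A f(x̂_{k-1}) + B u +
  f'(x) ⊙ Cᵀ εy)` with `x = x̂_{k-1}`.  The state precision is omitted
  from this form; in learned configurations it is absorbed into `A`.
  This is the fully online circuit: the memory of the previous estimate
  lives only in the one-step recurrent delay.
* **Closed form** (`tpc_equilibrium`, linear `f` only): the exact
  minimiser, `x̂ = x⁻ + ΣxCᵀ(CΣxCᵀ+Σy)⁻¹(y − Cx⁻)` with
  `x⁻ = A x̂_{k-1} + B u` — algebraically one Kalman step whose carried
  posterior covariance is forced to zero.

**Stability cap.**  For linear `f` the free energy is an exact quadratic
with Hessian `H = Πx + CᵀΠyC`, and Euler integration of the gradient
flow diverges geometrically when `step · λmax(H) > 2`.  `infer` therefore
caps the effective step at `1.8 / λmax(H)` (conservative for `tanh`,
where `|f'| ≤ 1`).  Random scrambling matrices routinely produce
`λmax > 10`, so without the cap a nominal step of 0.2 diverges.  The cap
applies only to the iterative path: `inference_step` itself is the raw
Euler step (and is what the gradient-oracle tests check), and the
single-step variant is deliberately left uncapped because it *is* the
circuit under study — its instability for badly conditioned emission
matrices is reported, not hidden.

**Learning.**  After inference converges, weights receive one Hebbian
update `ΔA = η εx f(x̂_{k-1})ᵀ`, `ΔB = η εx uᵀ`, `ΔC = η εy f(x̂_k)ᵀ`
(evaluated at the converged `x̂_k`), and the memory is reloaded with
`x̂_k`.  One-step observation predictions `ŷ_k = C f(A f(x̂_{k-1}) + B u_k)`
are always recorded with the weights *before* the step-k update, so
prediction quality is honestly one-step-ahead.  For linear `f` this
reduces to `C(A x̂_{k-1} + B u_k)`.

**Sparse variant.**  The movie-trained models minimise
`‖y − Cf(x)‖² + ‖x − Af(x̂_{k-1})‖² + λx|x|₁ + λC Σ|C_ij|` (no ½ factors,
identity precisions, B = 0).  Updates use the exact subgradient of half
this objective with `sign(0) = 0`, so the λ-shrinkage enters the
inference step as `-h·(λx/2)·sign(x)` and the C update as
`-η·(λC/2)·sign(C)`; a scalar multiple of the full subgradient was
chosen over the plain L1 coefficient so small steps are guaranteed not
to increase the objective.  With λ = 0 the operations reduce exactly to
the non-sparse ones.

## Reference Kalman filter and oracle

The Kalman filter uses the textbook projection/correction recursion.
The covariance update is the simple form `(I−KC)Σ⁻`, symmetrised after
computation; the Joseph stabilised form is available behind a flag for
long runs.  `Σ0` defaults to the identity and `x̂0` to zero (the
benchmarks' true initial state); both are arguments.

`brute_force_posterior` is the package's independent ground truth: it
stacks the linear-Gaussian system over k steps into one joint Gaussian
over `(x_1..x_k, y_1..y_k)` and conditions on all observations.  It is
exact, `O((k·dx)³)`, and used only in tests (k ≤ ~30).

## Benchmarks

**Tracking.**  Newtonian position/velocity/acceleration with the
constant-acceleration Taylor transition over `Δk = 0.001`, control
`u_k = e^{-0.01k}` on the acceleration, `Σx = Σy = I`, and a fixed 3×3
emission matrix with i.i.d. N(0,1) entries (deliberately scrambled
observations).  N = 1000 steps per trial, 10 trials by default.
Two empirical findings are worth stating plainly, because they deviate
from the idealised expectation that converged tPC sits within a few
percent of the Kalman filter:

1. The converged (equilibrium) tPC state MSE is roughly 1.5–3× the
   Kalman filter's on this system.  The tPC gain fixes the prior
   covariance at `Σx`, whereas the Kalman steady-state prior is
   `AΣ_{k-1}Aᵀ + Σx`; in weakly observed directions of a random
   scrambling `C` the difference is large.  In a well-conditioned scalar
   benchmark (`A = C = Σx = Σy = 1`) the same comparison gives 0.667 vs
   0.618 — an 8% gap — so the size of the gap is a property of the
   observation geometry, not of the implementation.
2. Partially converged inference (20 capped iterations) can score
   slightly *better* on state MSE than the exact equilibrium (~3% here):
   under-optimising the free energy smooths the estimate and acts as a
   regulariser against observation noise.

**Online learning.**  The learnt model starts from `A = 0`,
`C = I` with identity precisions, knows `B`, and adapts `A` and `C`
online with `η = 2·10⁻⁵` over 8 epochs of the trajectory (the carried
estimate resets at epoch boundaries, weights persist).  The learning
rate is small because the Hebbian outer products scale with the latent
magnitude, which grows to order 10–100 on this nonstationary system.
The reproduced pattern: learnt-weight observation predictions fall
within 2× of the Kalman filter's observation MSE, while the latent
representation remains unidentifiable (state MSE hundreds of times the
true-weight model's) and random weights are catastrophically worse at
the observation level.

**Covariance encoding.**  Same system with
`Σx = Σy = diag(10,1,1)` or a fixed symmetric positive-definite matrix
with unit diagonal (`[[1,.2,.5],[.2,1,.4],[.5,.4,1]]`).  The learner
still assumes identity precisions, so any covariance structure must be
absorbed by `A` and `C`.  In this implementation the alignment of the
largest learnt `|A_ii|` with the high-variance dimension is a
*transient* of early learning: it is strongest after a single epoch
(7/10 seeded runs) and is destroyed by prolonged training, because the
Hebbian fixed point is the lag-one regression of the inferred latents,
in which the noisiest dimension is shrunk rather than amplified.  The
covariance experiment therefore defaults to one epoch and reports the
learnt matrices so the structure can be inspected directly.

**Pendulum.**  Frictionless pendulum (`g = 9.81 m/s²`, `L = 3 m`)
released at 1.8 rad with 2.2 rad/s — a large-amplitude, strongly
nonlinear orbit — integrated with classic RK4 at a fixed internal step
of `dk/10` (deterministic; energy drift < 10⁻⁶ % over 250 s; small-angle
period within 0.1% of `2π√(L/g)`).  Observations are the states plus
N(0, 0.1²) noise at `dk = 0.1 s`.  Runs default to 250 s (2500 steps) and
20 paired simulations to keep the experiment fast; the angle is not
wrapped during integration, only for phase-portrait export.  Linear and
`tanh` networks (`A = 0`, `C = I` init, both learnable, `B = 0`) train
online with `η = 0.1`, 20 inference iterations at step 0.2, and are
scored on one-step observation predictions over the final 80 s against
the clean states (scores against the noisy observations are reported
alongside).  The nonlinear advantage is robust across `η ∈ [0.1, 0.5]`:
`tanh` bounds the activities so the Hebbian updates stay tame at a
learning rate fast enough to track the orbit, where the linear model's
updates grow with the ~3 rad state magnitude.  At much smaller learning
rates neither model is in this online-tracking regime and the ordering
is not reproduced; η = 0.1 was fixed from the plateau.

**Movies and STRFs.**  Training stimuli are drifting sinusoidal
gratings with random orientation, speed, phase and spatial frequency,
augmented with left-right mirrored copies — synthetic stand-ins that
share the moving-oriented structure of natural-movie patches but *not*
their 1/f statistics, so Gabor-shaped filters are not expected and not
asserted; what the tests establish is the machinery: sparsification of
`C` under the L1 penalty, descent of the objective, and correctness of
reverse correlation.  Frames are bandpass filtered with a zero-sum
difference-of-Gaussians kernel (σ_center = 1 px, σ_surround = 2 px by
default; truncated at 4σ_surround), then z-scored per movie; the carried
estimate resets at movie boundaries.  The STRF of neuron i is the
activity-weighted mean of the 5-frame stimulus history,
`STRF_i = 1/(T−5) Σ_{k=5..T} x_{i,k} y_{k−4:k}` — the index convention
and `T−5` divisor are kept verbatim from the defining formula (T−4 terms
averaged with divisor T−5), and probing noise is i.i.d. standard normal
per pixel.  The recovery test plants a known spatial filter as a
neuron's emission row; the network's converged activity is then
proportional to the filter's projection of the frame, so white-noise
reverse correlation must return the filter at lag 0 (cosine > 0.99
measured at T = 20 000) and noise elsewhere.

## Degenerate inputs and conventions

Zero-length trajectories yield empty results with NaN MSEs.  Zero noise
covariances are permitted only behind an explicit `noise_free` flag;
the public surface otherwise requires symmetric positive-definite
covariances (checked by Cholesky).  All randomness flows through
`numpy.random.default_rng` seeds carried in the configuration objects;
every experiment is bit-reproducible from (config, seed).  MSEs are
squared errors averaged over time steps and dimensions.

## Limitations

* tPC carries no posterior covariance; there is no uncertainty output.
* The Kalman reference requires linear `f`; no extended/unscented
  variants are provided.
* The single-step variant can diverge for emission matrices with
  `λmax(I + CᵀC)` beyond the Euler stability limit; this is a property
  of the circuit and is surfaced rather than patched.
* Noise is Gaussian and the system matrices time-invariant; there is no
  continuous-time SDE simulation and no multi-layer hierarchy.
* Movie training hyperparameters (λx, λC, η) are exposed as
  configuration with sensible defaults; no claim is made that they
  reproduce any particular published receptive-field figure.
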