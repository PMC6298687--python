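"""Outer parameter-adjustment loop: GP-based Bayesian optimization.

The outer loop treats the mean beta power reported by the inner stimulator
as a black-box objective f(theta) over the stimulation parameters
theta = (phase trigger, power threshold, amplitude) and minimizes it with
as few 20-second evaluations as possible.

Surrogate: a Gaussian process f ~ GP(m, k) whose prior mean is learned as
the mean of the training data and whose covariance is a Matern-5/2 kernel
over inputs scaled to the unit box, modified to be periodic in the phase
dimension by measuring phase distance along the chord of the unit circle
(2 sin(dtheta/2), rescaled so the small-angle slope matches the linear
dimensions).  The chordal construction is an isometric embedding, so the
kernel stays positive definite.  Kernel hyperparameters (per-dimension
length scales, signal variance, noise variance) are learned by MAP:
marginal likelihood times weakly-informative log-normal priors, optimized
in log-space with analytic gradients.

Posterior at a query point x*, given n observations with kernel matrix K
and cross-covariances k:

    mu_n(x*)      = m + k^T (K + sigma_n^2 I)^{-1} (y - m)
    sigma_n^2(x*) = k(x*, x*) - k^T (K + sigma_n^2 I)^{-1} k

Acquisition: the lower confidence bound u = mu - kappa_n * sigma with the
schedule kappa_n = nu * sqrt(tau_n), tau_n = 2 log(n^{d/2+2} pi^2 / (3 delta)),
which is the no-regret schedule at nu = 1; the default nu = 0.25 deliberately
favours exploitation.  The acquisition surface is minimized by 32 local
searches started from a Latin hypercube, run in lockstep as a batched
projected gradient descent (periodic dimensions wrap), with a final
quasi-Newton polish of the best candidate.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.linalg import cho_solve, cholesky, solve_triangular
from scipy.optimize import minimize
from scipy.stats import qmc

__all__ = [
    "ObservationSet",
    "Hyperparams",
    "GPModel",
    "AcquisitionConfig",
    "AdcRunResult",
    "IllConditionedKernelError",
    "kernel_matrix",
    "fit_hyperparameters",
    "posterior",
    "kappa_schedule",
    "lcb",
    "suggest_next",
    "evaluate_params",
    "run_adc",
    "StimObjective",
    "derive_seed",
]

JITTER_FRAC = 1e-8
VAR_CLIP_TOL = 1e-9


class IllConditionedKernelError(RuntimeError):
    """Cholesky factorization failed; consider increasing jitter."""


def derive_seed(*parts: int) -> int:
    """Deterministic child seed below 2**31 from integer components."""
    return int(np.random.SeedSequence(list(parts)).generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# data containers


@dataclass
class ObservationSet:
    """Parameter-outcome pairs over the active dimensions.

    ``x`` holds physical coordinates (n, d); ``bounds`` is (d, 2);
    ``periodic`` flags dimensions whose physical extent is one period.
    """

    bounds: np.ndarray
    periodic: np.ndarray
    names: tuple[str, ...]
    x: np.ndarray = None
    y: np.ndarray = None

    def __post_init__(self) -> None:
        self.bounds = np.atleast_2d(np.asarray(self.bounds, dtype=float))
        self.periodic = np.asarray(self.periodic, dtype=bool)
        if self.x is None:
            self.x = np.empty((0, self.dim))
        if self.y is None:
            self.y = np.empty(0)
        self.x = np.atleast_2d(np.asarray(self.x, dtype=float))
        self.y = np.asarray(self.y, dtype=float)
        if len(self.y) and not np.all(np.isfinite(self.y)):
            raise ValueError("observations must be finite")

    @property
    def dim(self) -> int:
        return len(self.bounds)

    @property
    def n(self) -> int:
        return len(self.y)

    def to_unit(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        lo, hi = self.bounds[:, 0], self.bounds[:, 1]
        return (x - lo) / (hi - lo)

    def from_unit(self, u: np.ndarray) -> np.ndarray:
        lo, hi = self.bounds[:, 0], self.bounds[:, 1]
        return lo + np.asarray(u) * (hi - lo)

    def add(self, x: np.ndarray, y: float) -> None:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if not np.isfinite(y):
            raise ValueError("observation must be finite")
        self.x = np.vstack([self.x, x])
        self.y = np.append(self.y, y)


@dataclass(frozen=True)
class Hyperparams:
    """Kernel hyperparameters in unit-box coordinates."""

    length_scales: np.ndarray
    signal_var: float
    noise_var: float

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.length_scales) <= 0):
            raise ValueError("length scales must be positive")
        if self.signal_var <= 0 or self.noise_var < 0:
            raise ValueError("variances must be positive")


# ---------------------------------------------------------------------------
# kernel


def _dim_distances(u1: np.ndarray, u2: np.ndarray, periodic: np.ndarray) -> np.ndarray:
    """Per-dimension distances, shape (n1, n2, d), in unit-box units.

    Periodic dimensions use the chordal metric sin(pi*du)/pi, whose
    small-separation slope equals the linear metric's.
    """
    du = u1[:, None, :] - u2[None, :, :]
    s = np.abs(du)
    if periodic.any():
        per = np.abs(np.sin(np.pi * du)) / np.pi
        s = np.where(periodic[None, None, :], per, s)
    return s


def _matern52(r: np.ndarray) -> np.ndarray:
    sq5r = math.sqrt(5.0) * r
    return (1.0 + sq5r + 5.0 * r * r / 3.0) * np.exp(-sq5r)


def kernel_matrix(
    u1: np.ndarray,
    u2: np.ndarray,
    hyper: Hyperparams,
    periodic: np.ndarray,
) -> np.ndarray:
    """Matern-5/2 kernel with per-dimension length scales (unit-box inputs)."""
    ls = np.asarray(hyper.length_scales, dtype=float)
    if np.any(ls <= 0):
        raise ValueError("length scales must be positive")
    s = _dim_distances(np.atleast_2d(u1), np.atleast_2d(u2), periodic)
    r = np.sqrt(np.sum((s / ls) ** 2, axis=-1))
    return hyper.signal_var * _matern52(r)


# ---------------------------------------------------------------------------
# GP model


@dataclass
class GPModel:
    obs: ObservationSet
    hyper: Hyperparams
    mean: float = 0.0
    _chol: np.ndarray | None = None
    _alpha: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.obs.n > 0:
            self.mean = float(np.mean(self.obs.y))
            u = self.obs.to_unit(self.obs.x)
            k = kernel_matrix(u, u, self.hyper, self.obs.periodic)
            k[np.diag_indices_from(k)] += (
                self.hyper.noise_var + JITTER_FRAC * self.hyper.signal_var
            )
            try:
                self._chol = cholesky(k, lower=True)
            except np.linalg.LinAlgError as exc:
                raise IllConditionedKernelError(
                    "kernel matrix not positive definite; increase jitter or "
                    "noise variance"
                ) from exc
            self._alpha = cho_solve((self._chol, True), self.obs.y - self.mean)


def posterior(gp: GPModel, x_query: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Posterior mean and variance at query points (physical coordinates).

    With no observations this is the prior (training-mean default 0 and the
    prior variance).  Variance is clipped at zero with a small tolerance.
    """
    obs = gp.obs
    xq = np.atleast_2d(np.asarray(x_query, dtype=float))
    uq = obs.to_unit(xq)
    prior_var = gp.hyper.signal_var * np.ones(len(uq))
    if obs.n == 0:
        return np.full(len(uq), gp.mean), prior_var
    u = obs.to_unit(obs.x)
    kvec = kernel_matrix(uq, u, gp.hyper, obs.periodic)
    mu = gp.mean + kvec @ gp._alpha
    v = solve_triangular(gp._chol, kvec.T, lower=True)
    var = prior_var - np.sum(v * v, axis=0)
    var = np.where(var > -VAR_CLIP_TOL, np.maximum(var, 0.0), var)
    if np.any(var < 0):
        var = np.maximum(var, 0.0)
    return mu, var


# ---------------------------------------------------------------------------
# MAP hyperparameter fit


def _nll_and_grad(
    log_params: np.ndarray,
    u: np.ndarray,
    y: np.ndarray,
    periodic: np.ndarray,
    prior_mu: np.ndarray,
    prior_sd: np.ndarray,
) -> tuple[float, np.ndarray]:
    """Negative log (marginal likelihood * prior) and gradient in log-space."""
    d = u.shape[1]
    ls = np.exp(log_params[:d])
    sf2 = math.exp(log_params[d])
    sn2 = math.exp(log_params[d + 1])
    n = len(y)

    s = _dim_distances(u, u, periodic)
    sq = (s / ls) ** 2
    r = np.sqrt(np.sum(sq, axis=-1))
    sq5r = math.sqrt(5.0) * r
    e = np.exp(-sq5r)
    k0 = (1.0 + sq5r + 5.0 * r * r / 3.0) * e  # correlation matrix
    kmat = sf2 * k0
    kmat[np.diag_indices_from(kmat)] += sn2 + JITTER_FRAC * sf2
    try:
        low = cholesky(kmat, lower=True)
    except np.linalg.LinAlgError:
        return 1e25, np.zeros_like(log_params)
    yc = y - y.mean()
    alpha = cho_solve((low, True), yc)
    nll = (
        0.5 * yc @ alpha
        + np.sum(np.log(np.diag(low)))
        + 0.5 * n * math.log(2.0 * math.pi)
    )
    # prior: independent normals on the log-parameters
    z = (log_params - prior_mu) / prior_sd
    nll += 0.5 * float(z @ z)

    kinv = cho_solve((low, True), np.eye(n))
    w = np.outer(alpha, alpha) - kinv  # d(logML)/dK = 0.5 * W

    grad = np.empty_like(log_params)
    # d k0 / d r = -(5/3) r (1 + sqrt5 r) e^{-sqrt5 r}; with
    # dr/dlog ls_i = -sq_i / r this gives dK/dlog ls_i = sf2*(5/3)(1+sqrt5 r)e * sq_i
    base = sf2 * (5.0 / 3.0) * (1.0 + sq5r) * e
    for i in range(d):
        dk = base * sq[..., i]
        grad[i] = -0.5 * np.sum(w * dk)
    grad[d] = -0.5 * np.sum(w * (sf2 * k0))  # dK/dlog sf2 = sf2*k0 (jitter term negligible)
    grad[d + 1] = -0.5 * np.trace(w) * sn2
    grad += z / prior_sd
    return float(nll), grad


def _prior_spec(dim: int, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Log-normal priors: length scales centered on 1/4 box width, noise on
    var(y)/10, signal on var(y); widths one decade (sd of log10 = 0.5)."""
    vy = float(np.var(y)) if len(y) > 1 and np.var(y) > 0 else 1.0
    mu = np.concatenate(
        [np.full(dim, math.log(0.25)), [math.log(vy)], [math.log(vy / 10.0)]]
    )
    sd = np.full(dim + 2, 0.5 * math.log(10.0))
    return mu, sd


def fit_hyperparameters(
    obs: ObservationSet,
    seed: int = 0,
    warm_start: Hyperparams | None = None,
    n_restarts: int = 1,
    maxiter: int = 40,
) -> Hyperparams:
    """MAP estimate of the kernel hyperparameters.

    Deterministic given the seed.  With fewer than two observations the
    prior medians are returned with a warning.  Multi-start: the prior
    median, the warm start (if provided), plus ``n_restarts`` jittered
    starts; the best final value wins.
    """
    dim = obs.dim
    prior_mu, prior_sd = _prior_spec(dim, obs.y)
    if obs.n < 2:
        warnings.warn("fewer than 2 observations: using prior-median hyperparameters")
        return Hyperparams(
            length_scales=np.exp(prior_mu[:dim]),
            signal_var=math.exp(prior_mu[dim]),
            noise_var=math.exp(prior_mu[dim + 1]),
        )
    u = obs.to_unit(obs.x)
    vy = max(float(np.var(obs.y)), 1e-12)
    lb = np.concatenate([np.full(dim, math.log(1e-3)), [math.log(vy * 1e-4)],
                         [math.log(vy * 1e-6)]])
    ub = np.concatenate([np.full(dim, math.log(30.0)), [math.log(vy * 1e4)],
                         [math.log(vy * 1e3)]])

    if warm_start is not None:
        # warm-started refits converge in a handful of iterations; the
        # periodic cold restarts of the caller guard against local optima
        starts = [
            np.concatenate(
                [
                    np.log(warm_start.length_scales),
                    [math.log(warm_start.signal_var)],
                    [math.log(warm_start.noise_var)],
                ]
            )
        ]
    else:
        starts = [prior_mu.copy()]
        rs = np.random.RandomState(derive_seed(seed, obs.n))
        for _ in range(n_restarts):
            starts.append(prior_mu + 0.5 * rs.standard_normal(dim + 2))

    best = None
    for x0 in starts:
        res = minimize(
            _nll_and_grad,
            np.clip(x0, lb, ub),
            args=(u, obs.y, obs.periodic, prior_mu, prior_sd),
            jac=True,
            method="L-BFGS-B",
            bounds=list(zip(lb, ub)),
            options={"maxiter": maxiter},
        )
        if best is None or res.fun < best.fun:
            best = res
    p = best.x
    return Hyperparams(
        length_scales=np.exp(p[:dim]),
        signal_var=math.exp(p[dim]),
        noise_var=math.exp(p[dim + 1]),
    )


# ---------------------------------------------------------------------------
# acquisition


@dataclass(frozen=True)
class AcquisitionConfig:
    """GP-LCB settings.  ``nu`` scales exploration; ``delta`` is the
    schedule's confidence parameter; ``dim`` the active dimensionality."""

    nu: float = 0.25
    delta: float = 0.1
    dim: int = 1
    scheduled: bool = True
    kappa_fixed: float | None = None

    def __post_init__(self) -> None:
        if self.nu < 0:
            raise ValueError("nu must be non-negative")
        if not (0.0 < self.delta < 1.0):
            raise ValueError("delta must lie in (0, 1)")
        if self.dim not in (1, 2, 3):
            raise ValueError("dim must be 1, 2 or 3")


def kappa_schedule(n: int, config: AcquisitionConfig) -> float:
    """kappa_n = nu * sqrt(tau_n), tau_n = 2 log(n^{d/2+2} pi^2 / (3 delta))."""
    if not config.scheduled and config.kappa_fixed is not None:
        return config.kappa_fixed
    n = max(int(n), 1)
    tau_n = 2.0 * math.log(
        n ** (config.dim / 2.0 + 2.0) * math.pi**2 / (3.0 * config.delta)
    )
    return config.nu * math.sqrt(max(tau_n, 0.0))


def lcb(
    mu: np.ndarray, sigma: np.ndarray, n: int, config: AcquisitionConfig
) -> np.ndarray:
    """Lower confidence bound mu - kappa_n * sigma."""
    return mu - kappa_schedule(n, config) * sigma


def _acq_values(gp: GPModel, u: np.ndarray, kap: float) -> np.ndarray:
    x = gp.obs.from_unit(u)
    mu, var = posterior(gp, x)
    return mu - kap * np.sqrt(var)


def suggest_next(
    gp: GPModel,
    config: AcquisitionConfig,
    seed: int = 0,
    n_starts: int = 32,
    n_iter: int = 35,
) -> np.ndarray:
    """Global minimization of the LCB over the box (phase treated periodically).

    32 Latin-hypercube starts advance in lockstep by projected finite-
    difference gradient descent; the best candidate receives an L-BFGS-B
    polish.  The returned point's utility is no worse than at any start.
    Ties break toward the lowest utility, then the earliest start index.
    """
    obs = gp.obs
    d = obs.dim
    kap = kappa_schedule(max(obs.n, 1), config)
    sampler = qmc.LatinHypercube(d=d, seed=derive_seed(seed, obs.n, 17))
    u = sampler.random(n_starts)
    u0 = u.copy()
    per = obs.periodic

    def project(v: np.ndarray) -> np.ndarray:
        v = np.where(per[None, :], np.mod(v, 1.0), np.clip(v, 0.0, 1.0))
        return v

    h = 1e-4
    lr = 0.08
    m = np.zeros_like(u)
    v2 = np.zeros_like(u)
    eye = np.eye(d)
    for t in range(1, n_iter + 1):
        # central differences for all starts and dimensions in one batch
        probe = np.concatenate(
            [u[:, None, :] + h * eye[None, :, :], u[:, None, :] - h * eye[None, :, :]],
            axis=1,
        ).reshape(-1, d)
        fv = _acq_values(gp, project(probe), kap).reshape(n_starts, 2 * d)
        grad = (fv[:, :d] - fv[:, d:]) / (2 * h)
        m = 0.9 * m + 0.1 * grad
        v2 = 0.99 * v2 + 0.01 * grad**2
        step = lr * (m / 0.9) / (np.sqrt(v2 / 0.99) + 1e-9)
        u = project(u - step)
    f_final = _acq_values(gp, u, kap)
    f_start = _acq_values(gp, u0, kap)
    best = int(np.argmin(f_final))

    res = minimize(
        lambda z: float(_acq_values(gp, project(np.atleast_2d(z)), kap)[0]),
        u[best],
        method="L-BFGS-B",
        bounds=[(0.0, 1.0)] * d,
        options={"maxiter": 15},
    )
    cand_u = project(np.atleast_2d(res.x))[0] if res.fun < f_final[best] else u[best]
    cand_f = min(float(res.fun), float(f_final[best]))
    # guarantee: no worse than any start
    if cand_f > f_start.min():
        cand_u = u0[int(np.argmin(f_start))]
    return obs.from_unit(cand_u)


# ---------------------------------------------------------------------------
# objective & ADC loop


DIM_SPECS = {
    "phase": dict(periodic=True),
    "threshold": dict(periodic=False),
    "amplitude": dict(periodic=False),
}


@dataclass
class StimObjective:
    """Beta-power objective over a subset of the stimulation parameters.

    Maps an active-dimension vector to a full parameter set (inactive
    dimensions pinned at ``fixed``), runs the closed loop for
    ``settle + window`` seconds, and returns
    ``10*log10(mean linear alpha-SWIFT power over the window)`` plus
    optional Gaussian measurement noise of standard deviation
    ``noise_sigma`` dB.  Each evaluation uses a fresh simulation seed
    derived from ``base_seed`` and the evaluation counter, so repeated
    evaluations scatter like repeated measurements on a live system.
    """

    sim_params: object
    active: tuple[str, ...] = ("phase",)
    fixed: object = None
    mode: object = None
    settle: float = 2.0
    window: float = 3.0
    noise_sigma: float = 0.0
    base_seed: int = 0
    count: int = field(default=0)

    def __post_init__(self) -> None:
        from .neuromass import load_defaults
        from .policy import PolicyMode, StimParams

        if self.mode is None:
            self.mode = PolicyMode.PHASE_POWER
        cfg = load_defaults()
        if self.fixed is None:
            pol = cfg["policy"]
            self.fixed = StimParams(
                theta=float(pol["theta_star"]),
                p_th_db=float(pol["p_th_star"]),
                amplitude_ma=float(pol["amp_star"]),
            )
        b = cfg["bounds"]
        table = {"phase": b["phase"], "threshold": b["threshold"],
                 "amplitude": b["amplitude"]}
        self.bounds = np.array([table[a] for a in self.active], dtype=float)
        self.periodic = np.array(
            [DIM_SPECS[a]["periodic"] for a in self.active], dtype=bool
        )
        self._noise_rs = np.random.RandomState(derive_seed(self.base_seed, 424243))

    def make_params(self, x: np.ndarray):
        from .policy import StimParams

        kw = {
            "theta": self.fixed.theta,
            "p_th_db": self.fixed.p_th_db,
            "amplitude_ma": self.fixed.amplitude_ma,
        }
        keymap = {"phase": "theta", "threshold": "p_th_db", "amplitude": "amplitude_ma"}
        for name, val in zip(self.active, np.atleast_1d(x)):
            kw[keymap[name]] = float(val)
        return StimParams(**kw)

    def __call__(self, x: np.ndarray, seed: int | None = None) -> float:
        self.count += 1
        sim_seed = seed if seed is not None else derive_seed(self.base_seed, self.count)
        f = evaluate_params(
            self.make_params(x),
            self.sim_params,
            self.mode,
            settle=self.settle,
            window=self.window,
            noise_sigma=0.0,
            seed=sim_seed,
        )
        if self.noise_sigma > 0:
            f += self.noise_sigma * self._noise_rs.standard_normal()
        return f

    def clean(self, x: np.ndarray, window: float = 8.0, seed: int = 0) -> float:
        """Low-variance evaluation for response surfaces (no injected noise)."""
        return evaluate_params(
            self.make_params(x),
            self.sim_params,
            self.mode,
            settle=self.settle,
            window=window,
            noise_sigma=0.0,
            seed=seed,
        )


def evaluate_params(
    stim_params,
    sim_params,
    mode,
    settle: float = 2.0,
    window: float = 3.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
    noise_rng: np.random.RandomState | None = None,
) -> float:
    """One outer-loop objective evaluation.

    Runs the policy for ``settle + window`` seconds, averages the linear
    alpha-SWIFT power over the final ``window`` seconds, and returns it in
    dB, optionally plus Gaussian measurement noise eps ~ N(0, noise_sigma^2)
    (used by the noise-tolerance experiments).
    """
    from .policy import run_closed_loop

    if settle <= 0 or window <= 0:
        raise ValueError("settle and window must be positive")
    _, _, mean_pow = run_closed_loop(
        sim_params,
        stim_params,
        mode,
        duration=settle + window,
        seed=seed,
        burn_in=min(1.0, settle / 2.0),
        window_start=settle,
    )
    f = 10.0 * math.log10(max(mean_pow, 1e-300))
    if noise_sigma > 0:
        rs = noise_rng if noise_rng is not None else np.random.RandomState(seed)
        f += noise_sigma * rs.standard_normal()
    return f


@dataclass
class AdcRunResult:
    """Full log of one adaptive-dual-control run."""

    x: np.ndarray  # (budget, d) visited points
    f: np.ndarray  # (budget,) observed outcomes
    mu: np.ndarray  # (budget,) posterior mean at the point when proposed
    sigma: np.ndarray  # (budget,) posterior sd at proposal time
    kappa: np.ndarray  # (budget,) LCB weight used
    best_so_far: np.ndarray
    recommended_x: np.ndarray  # argmin of the final posterior mean
    seed: int
    config: AcquisitionConfig

    def to_frame(self):
        import pandas as pd

        d = self.x.shape[1]
        data = {f"x{i}": self.x[:, i] for i in range(d)}
        data.update(
            f=self.f, mu=self.mu, sigma=self.sigma, kappa=self.kappa,
            best=self.best_so_far,
        )
        return pd.DataFrame(data, index=np.arange(1, len(self.f) + 1))

    def to_text(self, path) -> None:
        frame = self.to_frame()
        with open(path, "w") as fh:
            fh.write(f"# seed={self.seed} nu={self.config.nu} "
                     f"delta={self.config.delta} dim={self.config.dim}\n")
            frame.to_csv(fh, sep="\t", index_label="iteration",
                         float_format="%.6g")


def run_adc(
    objective: Callable[[np.ndarray], float],
    bounds: np.ndarray,
    periodic: np.ndarray,
    budget: int,
    n_init: int = 3,
    seed: int = 0,
    config: AcquisitionConfig | None = None,
    names: tuple[str, ...] | None = None,
) -> AdcRunResult:
    """Full outer loop: evaluate, refit the GP, minimize the acquisition.

    Starts from ``n_init`` uniform-random points, then iterates until
    ``budget`` evaluations have been spent.  Hyperparameters are refit
    (warm-started) after every new observation.  The recommendation is the
    minimizer of the final posterior mean (kappa = 0 search), which is the
    setting a clinician would deploy after the run.
    """
    bounds = np.atleast_2d(np.asarray(bounds, dtype=float))
    periodic = np.asarray(periodic, dtype=bool)
    d = len(bounds)
    if budget < n_init or n_init < 1:
        raise ValueError("need budget >= n_init >= 1")
    if config is None:
        config = AcquisitionConfig(dim=d)
    obs = ObservationSet(
        bounds=bounds,
        periodic=periodic,
        names=names or tuple(f"x{i}" for i in range(d)),
    )
    rs = np.random.RandomState(derive_seed(seed, 1))
    xs, fs, mus, sigmas, kaps = [], [], [], [], []
    hyper = None
    gp = None
    for it in range(budget):
        if it < n_init:
            x = bounds[:, 0] + rs.uniform(size=d) * (bounds[:, 1] - bounds[:, 0])
            mu_p, sd_p, kap = np.nan, np.nan, np.nan
        else:
            warm = None if (it - n_init) % 15 == 0 else hyper
            hyper = fit_hyperparameters(obs, seed=derive_seed(seed, 2, it),
                                        warm_start=warm)
            gp = GPModel(obs, hyper)
            x = suggest_next(gp, config, seed=derive_seed(seed, 3, it))
            m, v = posterior(gp, x)
            mu_p, sd_p = float(m[0]), float(math.sqrt(max(v[0], 0.0)))
            kap = kappa_schedule(obs.n, config)
        y = float(objective(np.atleast_1d(x)))
        obs.add(x, y)
        xs.append(np.atleast_1d(x))
        fs.append(y)
        mus.append(mu_p)
        sigmas.append(sd_p)
        kaps.append(kap)
    hyper = fit_hyperparameters(obs, seed=derive_seed(seed, 2, budget),
                                warm_start=hyper)
    gp = GPModel(obs, hyper)
    recommended = suggest_next(
        gp,
        AcquisitionConfig(nu=0.0, delta=config.delta, dim=config.dim),
        seed=derive_seed(seed, 4),
    )
    fs = np.asarray(fs)
    return AdcRunResult(
        x=np.vstack(xs),
        f=fs,
        mu=np.asarray(mus),
        sigma=np.asarray(sigmas),
        kappa=np.asarray(kaps),
        best_so_far=np.minimum.accumulate(fs),
        recommended_x=np.atleast_1d(recommended),
        seed=seed,
        config=config,
    )
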