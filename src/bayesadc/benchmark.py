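"""Benchmarking of the outer-loop optimizer against derivative-free baselines.

Reproduces the evaluation methodology around the adaptive dual controller:

* response-surface sweeps over the active stimulation parameters,
* baseline optimizers (Nelder-Mead simplex and DIRECT, both bounded, with
  every evaluation intercepted and logged),
* regret analytics: instantaneous regret r_t = f(theta_t) - f(theta*),
  cumulative R_T and average R_T/T, and an exponential-decay fit
  R_T/T = alpha + T0 * exp(-T/tau) whose asymptote alpha summarizes how
  well an algorithm finds *and exploits* the optimum,
* the noise-tolerance experiment: Gaussian noise of growing standard
  deviation added to the power measurement, with the fitted alpha tracked
  against the resulting signal-to-noise ratio (amplitude convention,
  SNR = 20 log10(sigma_signal / sigma_noise)).

Regret is always computed from the noise-free response surface at the
visited points (nearest grid node); the noisy measurement only drives the
optimizer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .bayesopt import (
    AcquisitionConfig,
    StimObjective,
    derive_seed,
    run_adc,
)

__all__ = [
    "ResponseSurface",
    "Trajectory",
    "RegretCurve",
    "RegretFit",
    "SnrResult",
    "sweep",
    "run_baseline",
    "regret",
    "fit_regret_asymptote",
    "compare_algorithms",
    "snr_experiment",
    "summary_table",
]

ALGORITHMS = ("bayesopt", "nelder_mead", "direct")


@dataclass
class ResponseSurface:
    """Noise-free objective tabulated on a rectangular grid."""

    axes: list[np.ndarray]  # per-dimension grids (physical units)
    values: np.ndarray  # shape = tuple(len(g) for g in axes)
    names: tuple[str, ...]
    bounds: np.ndarray
    periodic: np.ndarray

    @property
    def f_min(self) -> float:
        return float(np.min(self.values))

    @property
    def x_min(self) -> np.ndarray:
        idx = np.unravel_index(int(np.argmin(self.values)), self.values.shape)
        return np.array([g[i] for g, i in zip(self.axes, idx)])

    def lookup(self, x: np.ndarray) -> float:
        """Value at the nearest grid node; raises if outside the bounds."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        idx = []
        for xi, grid, (lo, hi), per in zip(x, self.axes, self.bounds, self.periodic):
            tol = 1e-9 * max(1.0, abs(hi - lo))
            if per:
                span = hi - lo
                xi = lo + ((xi - lo) % span)
            elif not (lo - tol <= xi <= hi + tol):
                raise ValueError(f"point {xi} outside bounds [{lo}, {hi}]")
            idx.append(int(np.argmin(np.abs(grid - xi))))
        return float(self.values[tuple(idx)])

    def lookup_many(self, xs: np.ndarray) -> np.ndarray:
        return np.array([self.lookup(x) for x in np.atleast_2d(xs)])


def sweep(
    objective: StimObjective,
    resolution: int = 16,
    seed: int = 0,
    window: float = 8.0,
) -> ResponseSurface:
    """Tabulate the noise-free objective on a ``resolution``-per-dimension grid.

    Every node is evaluated with the same simulation seed and a long
    averaging window, so the surface is smooth up to a small common Monte
    Carlo error and the empirical minimizer attains zero regret by
    construction.
    """
    if resolution < 8:
        raise ValueError("resolution of at least 8 per dimension required")
    axes = [np.linspace(lo, hi, resolution) for lo, hi in objective.bounds]
    mesh = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([m.ravel() for m in mesh], axis=-1)
    vals = np.empty(len(pts))
    node_seed = derive_seed(seed, 55)
    for i, p in enumerate(pts):
        vals[i] = objective.clean(p, window=window, seed=node_seed)
    return ResponseSurface(
        axes=axes,
        values=vals.reshape([resolution] * len(axes)),
        names=objective.active,
        bounds=np.asarray(objective.bounds, dtype=float),
        periodic=np.asarray(objective.periodic, dtype=bool),
    )


@dataclass
class Trajectory:
    """Ordered list of evaluated points and observed values."""

    x: np.ndarray  # (m, d)
    f: np.ndarray  # (m,)
    algorithm: str
    seed: int


def run_baseline(
    algorithm: str,
    objective: Callable[[np.ndarray], float],
    bounds: np.ndarray,
    budget: int,
    seed: int = 0,
) -> Trajectory:
    """Run a bounded baseline optimizer, logging every evaluation.

    ``nelder_mead``: the simplex method with out-of-bounds proposals clipped
    coordinate-wise, started from a uniform-random point.  ``direct``: the
    deterministic DIRECT algorithm (first evaluation at the box center).
    If the optimizer terminates before the budget is exhausted the log is
    padded by repeating its final point (the algorithm "stays" at its
    answer and keeps incurring that regret).
    """
    if budget < 10:
        raise ValueError("budget of at least 10 evaluations required")
    bounds = np.atleast_2d(np.asarray(bounds, dtype=float))
    lo, hi = bounds[:, 0], bounds[:, 1]
    log_x: list[np.ndarray] = []
    log_f: list[float] = []

    def wrapped(x: np.ndarray) -> float:
        xc = np.clip(np.atleast_1d(x), lo, hi)
        if len(log_f) >= budget:
            return log_f[-1]
        y = float(objective(xc))
        log_x.append(xc.copy())
        log_f.append(y)
        return y

    if algorithm == "nelder_mead":
        from scipy.optimize import minimize

        rs = np.random.RandomState(seed)
        x0 = lo + rs.uniform(size=len(lo)) * (hi - lo)
        # initial simplex spanning 15 % of each box width (reflected at the
        # upper bound); scipy's default 5 %-of-x0 perturbation degenerates
        # for coordinates near zero and is not meaningful on a bounded box
        d = len(lo)
        simplex = np.tile(x0, (d + 1, 1))
        for i in range(d):
            step = 0.15 * (hi[i] - lo[i])
            simplex[i + 1, i] += step if x0[i] + step <= hi[i] else -step
        minimize(
            wrapped,
            x0,
            method="Nelder-Mead",
            options={
                "maxfev": budget,
                "xatol": 1e-12,
                "fatol": 1e-12,
                "adaptive": False,
                "initial_simplex": simplex,
            },
        )
    elif algorithm == "direct":
        from scipy.optimize import direct

        direct(
            wrapped,
            list(map(tuple, bounds)),
            maxfun=budget,
            maxiter=20_000,
            locally_biased=False,
            vol_tol=0.0,
            len_tol=0.0,
        )
    else:
        raise ValueError(f"unknown algorithm {algorithm!r}")

    while len(log_f) < budget:
        log_x.append(log_x[-1])
        log_f.append(log_f[-1])
    return Trajectory(
        x=np.vstack(log_x)[:budget],
        f=np.asarray(log_f)[:budget],
        algorithm=algorithm,
        seed=seed,
    )


@dataclass
class RegretCurve:
    r: np.ndarray  # instantaneous regret per iteration
    cumulative: np.ndarray
    average: np.ndarray


def regret(trajectory: Trajectory | np.ndarray, surface: ResponseSurface) -> RegretCurve:
    """Regret of a trajectory against the noise-free surface.

    r_t = f(theta_t) - f(theta*) with f taken from the surface (nearest
    node), so r_t >= 0 and R_T is non-decreasing.
    """
    xs = trajectory.x if isinstance(trajectory, Trajectory) else np.atleast_2d(trajectory)
    f = surface.lookup_many(xs)
    r = f - surface.f_min
    cum = np.cumsum(r)
    avg = cum / np.arange(1, len(r) + 1)
    return RegretCurve(r=r, cumulative=cum, average=avg)


@dataclass
class RegretFit:
    alpha: float
    t0: float
    tau: float
    stderr: tuple[float, float, float]
    converged: bool
    residual_rms: float


def fit_regret_asymptote(average_regret: np.ndarray) -> RegretFit:
    """Nonlinear least-squares fit of R_T/T = alpha + T0 exp(-T/tau).

    ``alpha`` is the asymptote, ``tau`` the decay time constant (in
    iterations).  A non-converged fit is returned flagged, with residual
    diagnostics, rather than raised.
    """
    from scipy.optimize import curve_fit

    y = np.asarray(average_regret, dtype=float)
    if len(y) < 20:
        raise ValueError("series of at least 20 iterations required")
    t = np.arange(1, len(y) + 1, dtype=float)

    if np.ptp(y) < 1e-12:  # constant series: alpha = c, T0 ~ 0
        return RegretFit(
            alpha=float(y.mean()), t0=0.0, tau=1.0,
            stderr=(0.0, 0.0, 0.0), converged=True, residual_rms=0.0,
        )

    def model(tt, alpha, t0, tau):
        return alpha + t0 * np.exp(-tt / tau)

    p0 = (float(y[-1]), float(y[0] - y[-1]), max(len(y) / 3.0, 1.0))
    try:
        popt, pcov = curve_fit(
            model, t, y, p0=p0,
            bounds=([-np.inf, -np.inf, 1e-6], [np.inf, np.inf, 1e6]),
            maxfev=20_000,
        )
        err = np.sqrt(np.diag(pcov))
        resid = y - model(t, *popt)
        return RegretFit(
            alpha=float(popt[0]), t0=float(popt[1]), tau=float(popt[2]),
            stderr=tuple(float(e) for e in err), converged=True,
            residual_rms=float(np.sqrt(np.mean(resid**2))),
        )
    except RuntimeError:
        resid = y - model(t, *p0)
        return RegretFit(
            alpha=float(p0[0]), t0=float(p0[1]), tau=float(p0[2]),
            stderr=(math.inf, math.inf, math.inf), converged=False,
            residual_rms=float(np.sqrt(np.mean(resid**2))),
        )


@dataclass
class AlgorithmSummary:
    algorithm: str
    best_so_far: np.ndarray  # (trials, budget)
    mean_best: np.ndarray
    sd_best: np.ndarray
    mean_average_regret: np.ndarray
    fit: RegretFit
    visited: np.ndarray  # (trials, budget, d) for sampling histograms


def _run_trial(
    algorithm: str,
    objective_factory: Callable[[int], StimObjective],
    surface: ResponseSurface,
    budget: int,
    trial_seed: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    obj = objective_factory(trial_seed)
    if algorithm == "bayesopt":
        res = run_adc(
            obj,
            bounds=obj.bounds,
            periodic=obj.periodic,
            budget=budget,
            n_init=3,
            seed=trial_seed,
            config=AcquisitionConfig(dim=len(obj.bounds)),
        )
        xs, fs = res.x, res.f
    else:
        traj = run_baseline(algorithm, obj, obj.bounds, budget, seed=trial_seed)
        xs, fs = traj.x, traj.f
    rc = regret(Trajectory(x=xs, f=fs, algorithm=algorithm, seed=trial_seed), surface)
    return xs, np.minimum.accumulate(fs), rc.average


def compare_algorithms(
    objective_factory: Callable[[int], StimObjective],
    surface: ResponseSurface,
    trials: int = 50,
    budget: int = 100,
    seed: int = 0,
    algorithms: Sequence[str] = ALGORITHMS,
) -> dict[str, AlgorithmSummary]:
    """Head-to-head comparison on a common response surface.

    For each algorithm: ``trials`` independent runs of ``budget``
    evaluations on the stochastic objective; summaries are the mean +/- sd
    best-so-far curve, the mean average-regret curve, its exponential-
    asymptote fit, and the visited points (for sampling histograms).
    """
    if trials < 20:
        raise ValueError("at least 20 trials required for stable summaries")
    out: dict[str, AlgorithmSummary] = {}
    for alg in algorithms:
        bests = np.empty((trials, budget))
        avgs = np.empty((trials, budget))
        visited = np.empty((trials, budget, len(surface.axes)))
        alg_id = list(ALGORITHMS).index(alg) if alg in ALGORITHMS else 99
        for t in range(trials):
            ts = derive_seed(seed, alg_id, t)
            xs, best, avg = _run_trial(alg, objective_factory, surface, budget, ts)
            visited[t] = xs
            bests[t] = best
            avgs[t] = avg
        mean_avg = avgs.mean(axis=0)
        out[alg] = AlgorithmSummary(
            algorithm=alg,
            best_so_far=bests,
            mean_best=bests.mean(axis=0),
            sd_best=bests.std(axis=0),
            mean_average_regret=mean_avg,
            fit=fit_regret_asymptote(mean_avg),
            visited=visited,
        )
    return out


def summary_table(results: dict[str, AlgorithmSummary]):
    """Asymptote/time-constant summary, one row per algorithm."""
    import pandas as pd

    rows = []
    for alg, s in results.items():
        rows.append(
            dict(
                algorithm=alg,
                alpha=s.fit.alpha,
                alpha_se=s.fit.stderr[0],
                tau=s.fit.tau,
                tau_se=s.fit.stderr[2],
                converged=s.fit.converged,
            )
        )
    return pd.DataFrame(rows).set_index("algorithm")


def snr_db(sigma_signal: float, sigma_noise: float) -> float:
    """Amplitude-convention signal-to-noise ratio in dB."""
    return 20.0 * math.log10(sigma_signal / sigma_noise)


@dataclass
class SnrResult:
    sigmas: np.ndarray
    snr_db: np.ndarray
    alphas: dict[str, np.ndarray]  # algorithm -> alpha per sigma
    sigma_signal: float
    sigma_rep: float


def measurement_noise_sd(
    objective_factory: Callable[[int], StimObjective],
    surface: ResponseSurface,
    n_rep: int = 12,
    seed: int = 0,
) -> float:
    """Baseline noise amplitude: sd of repeated measures at the optimum."""
    obj = objective_factory(derive_seed(seed, 7))
    vals = [obj(surface.x_min) for _ in range(n_rep)]
    return float(np.std(vals))


def snr_experiment(
    objective_factory: Callable[[float, int], StimObjective],
    surface: ResponseSurface,
    sigma_grid: Sequence[float],
    trials: int = 20,
    budget: int = 100,
    seed: int = 0,
    algorithms: Sequence[str] = ALGORITHMS,
    sigma_rep: float | None = None,
) -> SnrResult:
    """Asymptotic regret under increasingly noisy power measurements.

    ``objective_factory(sigma, trial_seed)`` must return an objective with
    Gaussian noise of standard deviation ``sigma`` dB injected into each
    measurement.  The signal amplitude is the sd of the beta power across
    the search space (from the sweep); the noise amplitude combines the
    repeated-measurement sd with the injected sigma in quadrature.
    """
    sigma_grid = np.asarray(list(sigma_grid), dtype=float)
    if 0.0 not in sigma_grid:
        raise ValueError("sigma grid must include 0")
    sigma_signal = float(np.std(surface.values))
    if sigma_rep is None:
        sigma_rep = measurement_noise_sd(
            lambda ts: objective_factory(0.0, ts), surface, seed=derive_seed(seed, 11)
        )
    alphas: dict[str, list[float]] = {alg: [] for alg in algorithms}
    for sigma in sigma_grid:
        res = compare_algorithms(
            lambda ts, s=sigma: objective_factory(s, ts),
            surface,
            trials=trials,
            budget=budget,
            seed=derive_seed(seed, 13, int(sigma * 1000)),
            algorithms=algorithms,
        )
        for alg in algorithms:
            alphas[alg].append(res[alg].fit.alpha)
    noise_tot = np.sqrt(sigma_rep**2 + sigma_grid**2)
    snr = np.array([snr_db(sigma_signal, nt) for nt in noise_tot])
    return SnrResult(
        sigmas=sigma_grid,
        snr_db=snr,
        alphas={k: np.asarray(v) for k, v in alphas.items()},
        sigma_signal=sigma_signal,
        sigma_rep=float(sigma_rep),
    )
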