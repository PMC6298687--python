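"""Synthetic signal and objective generators with documented ground truth.

Everything here is generated programmatically from a seed; the files the
CLI writes are runtime outputs, not shipped data.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np

from .bayesopt import Hyperparams, ObservationSet, kernel_matrix
from .neuromass import simulate, tune_defaults

__all__ = ["make_tone", "make_chirp", "make_dd_trace", "make_gp_objective",
           "make_fixtures", "sha256_of_array"]


def sha256_of_array(x: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(x).tobytes()).hexdigest()


def make_tone(
    seed: int = 0, f0: float = 29.0, fs: float = 1000.0, duration: float = 60.0,
    noise: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Unit-amplitude sinusoid (plus optional white noise); returns (t, x)."""
    t = np.arange(int(duration * fs)) / fs
    x = np.sin(2 * np.pi * f0 * t)
    if noise > 0:
        x = x + noise * np.random.RandomState(seed).standard_normal(len(t))
    return t, x


def make_chirp(
    seed: int = 0, f_start: float = 20.0, f_stop: float = 40.0,
    fs: float = 1000.0, duration: float = 60.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Linear chirp spanning the beta band; returns (t, x)."""
    from scipy.signal import chirp

    t = np.arange(int(duration * fs)) / fs
    return t, chirp(t, f_start, duration, f_stop)


def make_dd_trace(seed: int = 0, duration: float = 30.0):
    """Unstimulated dopamine-depleted trace at the calibrated defaults."""
    return simulate(tune_defaults("DD"), duration, seed=seed)


def make_gp_objective(
    seed: int = 0, length_scale: float = 0.2, n: int = 200, noise_sd: float = 0.05,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Draw a 1D function from a Matern-5/2 GP with known hyperparameters.

    Returns (x, y, truth) with x on a regular grid in [0, 1]; ``truth``
    records the generating length scale, signal variance and noise sd for
    recovery tests.
    """
    rs = np.random.RandomState(seed)
    x = np.linspace(0.0, 1.0, n)
    hyper = Hyperparams(
        length_scales=np.array([length_scale]), signal_var=1.0, noise_var=0.0
    )
    k = kernel_matrix(x[:, None], x[:, None], hyper, np.array([False]))
    k[np.diag_indices_from(k)] += 1e-10
    f = np.linalg.cholesky(k) @ rs.standard_normal(n)
    y = f + noise_sd * rs.standard_normal(n)
    truth = dict(length_scale=length_scale, signal_var=1.0, noise_sd=noise_sd)
    return x, y, truth


def make_fixtures(kind: str, seed: int, outdir) -> Path:
    """Write one fixture kind to ``outdir``; returns the file path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if kind == "tone":
        t, x = make_tone(seed)
        path = outdir / f"tone_seed{seed}.txt"
        np.savetxt(path, np.column_stack([t, x]), header="time_s x")
    elif kind == "chirp":
        t, x = make_chirp(seed)
        path = outdir / f"chirp_seed{seed}.txt"
        np.savetxt(path, np.column_stack([t, x]), header="time_s x")
    elif kind == "dd_trace":
        trace = make_dd_trace(seed)
        path = outdir / f"dd_trace_seed{seed}.txt"
        trace.to_text(path)
        (outdir / f"dd_trace_seed{seed}.sha256").write_text(
            sha256_of_array(trace.samples) + "\n"
        )
    elif kind == "gp_objective":
        x, y, truth = make_gp_objective(seed)
        path = outdir / f"gp_objective_seed{seed}.txt"
        hdr = " ".join(f"{k}={v}" for k, v in truth.items())
        np.savetxt(path, np.column_stack([x, y]), header=f"x y | {hdr}")
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    return path
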