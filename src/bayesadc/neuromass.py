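"""Surrogate basal-ganglia beta-oscillation simulator.

Two reciprocally coupled neural-mass populations stand in for the
subthalamic nucleus (STN, excitatory) and globus pallidus (GP, inhibitory):
each population's mean voltage V obeys a second-order synapto-dendritic
filter driven by the sigmoidal firing rate of the other population, with a
one-step conduction delay,

    V_e'' + 2*gamma*V_e' + gamma^2*V_e = gamma^2 * (drive - g_ie*S(V_i(t-d)) + xi_e)
    V_i'' + 2*gamma*V_i' + gamma^2*V_i = gamma^2 * (        g_ei*S(V_e(t-d)) + xi_i)

with S a logistic rate function centered on its inflection.  Above a
critical loop gain the delayed negative feedback undergoes a supercritical
Hopf bifurcation and the pair oscillates in the beta band; the
dopamine-depleted (DD) parameter set sits above that threshold (noisy limit
cycle), the naive set below it (noise-sustained resonance).  A slow
Ornstein-Uhlenbeck modulation of gamma wanders the oscillation's center
frequency by a fraction of a hertz over seconds, which broadens the
long-run spectral peak the way real parkinsonian beta wanders, while
leaving the rhythm predictable over the few cycles a real-time phase
estimator needs.

DBS pulses are converted to voltage steps (charge / membrane capacitance)
and added directly to the excitatory population's voltage; the recorded
LFP is the inhibitory (pallidal) population's voltage.

Integration is explicit Euler at dt = 1 ms so stimulus pulses align with
samples.  All randomness flows from a single seed through the legacy
MT19937 generator, which the numba fast path reproduces bit-exactly.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
import yaml

__all__ = [
    "SimParams",
    "PopulationState",
    "LFPTrace",
    "Spectrum",
    "NumericalBlowupError",
    "InsufficientDataError",
    "dbs_pulse_delta_v",
    "step",
    "simulate",
    "psd",
    "band_power_db",
    "tune_defaults",
    "load_defaults",
]

BETA_BAND = (12.0, 35.0)


class NumericalBlowupError(RuntimeError):
    """State became non-finite during integration."""

    def __init__(self, step_index: int):
        self.step_index = step_index
        super().__init__(f"non-finite state at step {step_index}")


class InsufficientDataError(ValueError):
    pass


@dataclass(frozen=True)
class SimParams:
    """Parameters of the two-population surrogate.

    ``g_exc_to_inh`` / ``g_inh_to_exc`` are the dimensionless coupling
    gains; their product (times the sigmoid slopes at the operating point)
    is the loop gain that controls the Hopf bifurcation.  ``drive`` is a
    constant excitatory input that offsets the operating point slightly
    above the sigmoid inflection.  ``wander_frac``/``wander_tau`` specify
    the OU modulation of ``gamma`` (fractional amplitude, correlation time).
    """

    dt: float = 0.001
    delay: float = 0.001
    g_exc_to_inh: float = 1.6
    g_inh_to_exc: float = 1.6
    qmax: float = 1.0
    threshold: float = 0.0
    slope: float = 0.25
    gamma: float = 235.0
    noise: float = 0.2
    drive: float = 0.1
    wander_frac: float = 0.024
    wander_tau: float = 3.0
    c_m: float = 1.0e-6
    state: str = "DD"

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.delay < self.dt:
            raise ValueError("delay must be at least one time step")
        if self.c_m <= 0:
            raise ValueError("capacitance must be positive")
        if self.slope <= 0 or self.qmax <= 0:
            raise ValueError("sigmoid parameters must be positive")

    @property
    def delay_steps(self) -> int:
        return int(round(self.delay / self.dt))

    @property
    def fs(self) -> float:
        return 1.0 / self.dt

    def rate(self, v: float) -> float:
        """Centered sigmoid firing rate, S(threshold) = 0; saturates cleanly."""
        try:
            return (
                self.qmax / (1.0 + math.exp(-(v - self.threshold) / self.slope))
                - self.qmax / 2.0
            )
        except OverflowError:
            return -self.qmax / 2.0 if v < self.threshold else self.qmax / 2.0

    def fixed_point(self) -> tuple[float, float]:
        """Deterministic equilibrium (v_e0, v_i0) by damped iteration."""
        ve0 = vi0 = 0.0
        for _ in range(800):
            vi0 += 0.1 * (self.g_exc_to_inh * self.rate(ve0) - vi0)
            ve0 += 0.1 * ((self.drive - self.g_inh_to_exc * self.rate(vi0)) - ve0)
        return ve0, vi0


@dataclass
class PopulationState:
    """Instantaneous state: voltages, voltage rates, delay buffers, OU term."""

    v_e: float
    v_i: float
    dv_e: float
    dv_i: float
    buf_e: np.ndarray  # past v_e, oldest first
    buf_i: np.ndarray
    eta: float = 0.0  # OU modulation of gamma
    v_e0: float = 0.0
    v_i0: float = 0.0

    @classmethod
    def initial(cls, params: SimParams) -> "PopulationState":
        ve0, vi0 = params.fixed_point()
        d = params.delay_steps
        return cls(
            v_e=ve0,
            v_i=vi0,
            dv_e=0.0,
            dv_i=0.0,
            buf_e=np.full(d, ve0),
            buf_i=np.full(d, vi0),
            v_e0=ve0,
            v_i0=vi0,
        )

    def check_finite(self, step_index: int) -> None:
        if not (
            math.isfinite(self.v_e)
            and math.isfinite(self.v_i)
            and math.isfinite(self.dv_e)
            and math.isfinite(self.dv_i)
        ):
            raise NumericalBlowupError(step_index)


@dataclass
class LFPTrace:
    """Simulated field potential plus its stimulation-event log."""

    samples: np.ndarray  # LFP relative to the fixed point, at params.fs
    fs: float
    stim_times: np.ndarray  # seconds, strictly increasing
    stim_delta_v: np.ndarray  # voltage step of each event
    params: SimParams
    seed: int

    def __post_init__(self) -> None:
        if len(self.stim_times) > 1 and not np.all(np.diff(self.stim_times) > 0):
            raise ValueError("stimulation event times must be strictly increasing")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.fs

    def to_text(self, path) -> None:
        """Columnar export: time_s, lfp, stim_deltaV (zero off-pulse)."""
        n = len(self.samples)
        dv = np.zeros(n)
        idx = np.round(np.asarray(self.stim_times) * self.fs).astype(int)
        dv[idx[idx < n]] = self.stim_delta_v[idx < n]
        t = np.arange(n) / self.fs
        np.savetxt(
            path,
            np.column_stack([t, self.samples, dv]),
            header="time_s lfp stim_deltaV",
            fmt="%.6f %.9e %.9e",
        )

    @classmethod
    def from_text(cls, path, params: SimParams | None = None, seed: int = -1) -> "LFPTrace":
        data = np.loadtxt(path)
        t, lfp, dv = data.T
        fs = 1.0 / (t[1] - t[0])
        mask = dv != 0.0
        return cls(
            samples=lfp,
            fs=fs,
            stim_times=t[mask],
            stim_delta_v=dv[mask],
            params=params if params is not None else SimParams(),
            seed=seed,
        )

    def to_hdf5(self, path) -> None:
        """Binary container for long runs."""
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("lfp", data=self.samples, compression="gzip")
            f.create_dataset("stim_times", data=self.stim_times)
            f.create_dataset("stim_delta_v", data=self.stim_delta_v)
            f.attrs["fs"] = self.fs
            f.attrs["seed"] = self.seed
            for k, v in vars(self.params).items():
                f.attrs[f"param_{k}"] = v


@dataclass(frozen=True)
class Spectrum:
    freqs: np.ndarray  # Hz, monotone increasing
    power_db: np.ndarray  # 10*log10 of the Welch density
    peak_freq: float  # argmax frequency in the 10-45 Hz search band
    halfwidth_6db: float  # interpolated half-amplitude half-width, Hz


def dbs_pulse_delta_v(amplitude_ma: float, pulse_width_s: float, c_m: float) -> float:
    """Voltage step of one DBS pulse: injected charge over capacitance.

    The pulse is much shorter than the 1 ms integration step, so it is
    integrated to a total charge Q = I * t_pw and applied as a step
    dV = Q / C_m.  Exactly linear in amplitude and width.
    """
    if pulse_width_s <= 0:
        raise ValueError("pulse width must be positive")
    if c_m <= 0:
        raise ValueError("capacitance must be positive")
    if amplitude_ma < 0:
        raise ValueError("amplitude must be non-negative")
    return amplitude_ma * 1e-3 * pulse_width_s / c_m


def step(
    state: PopulationState,
    params: SimParams,
    pulse: float | None = None,
    noise: tuple[float, float, float] = (0.0, 0.0, 0.0),
    step_index: int = -1,
) -> PopulationState:
    """Advance the model by one explicit-Euler step (pure reference path).

    ``noise`` supplies the three standard-normal draws of the step in the
    order (OU wander, excitatory drive, inhibitory drive); passing zeros
    gives the deterministic skeleton.  ``pulse`` (a voltage step) is added
    to the excitatory population before integration.  The returned state is
    new; the input is not mutated.
    """
    z_eta, z_e, z_i = noise
    dt = params.dt
    a_ou = math.exp(-dt / params.wander_tau)
    s_ou = params.wander_frac * math.sqrt(1.0 - a_ou * a_ou)
    eta = a_ou * state.eta + s_ou * z_eta
    gam = params.gamma * (1.0 + eta)
    g2 = gam * gam

    v_e = state.v_e
    if pulse:
        v_e = v_e + pulse

    s_e = params.rate(state.buf_e[0])
    s_i = params.rate(state.buf_i[0])
    n_e = params.noise * z_e
    n_i = params.noise * z_i
    acc_e = -2.0 * gam * state.dv_e - g2 * v_e + g2 * (
        params.drive - params.g_inh_to_exc * s_i + n_e
    )
    acc_i = -2.0 * gam * state.dv_i - g2 * state.v_i + g2 * (
        params.g_exc_to_inh * s_e + n_i
    )

    buf_e = np.roll(state.buf_e, -1)
    buf_i = np.roll(state.buf_i, -1)
    buf_e[-1] = v_e
    buf_i[-1] = state.v_i

    new = PopulationState(
        v_e=v_e + dt * state.dv_e,
        v_i=state.v_i + dt * state.dv_i,
        dv_e=state.dv_e + dt * acc_e,
        dv_i=state.dv_i + dt * acc_i,
        buf_e=buf_e,
        buf_i=buf_i,
        eta=eta,
        v_e0=state.v_e0,
        v_i0=state.v_i0,
    )
    new.check_finite(step_index)
    return new


Controller = Callable[[int, float], Optional[float]]


def simulate(
    params: SimParams,
    duration: float,
    controller: Controller | None = None,
    seed: int = 0,
) -> LFPTrace:
    """Run the surrogate for ``duration`` seconds (reference Python path).

    ``controller(k, lfp_sample)`` is called once per step with the sample
    index and the most recent LFP sample (0.0 at k = 0) and may return a
    voltage step to deliver before integrating that step; ``None`` with no
    stimulation.  The LFP is the inhibitory-population voltage relative to
    its fixed point.  Identical (params, seed, controller) give bit-identical
    traces.
    """
    if duration < params.dt:
        raise ValueError("duration shorter than one step")
    n = int(round(duration / params.dt))
    rs = np.random.RandomState(seed)
    st = PopulationState.initial(params)
    lfp = np.empty(n)
    times: list[float] = []
    dvs: list[float] = []
    prev = 0.0
    for k in range(n):
        pulse = controller(k, prev) if controller is not None else None
        if pulse:
            times.append(k * params.dt)
            dvs.append(pulse)
        noise = (
            float(rs.standard_normal()),
            float(rs.standard_normal()),
            float(rs.standard_normal()),
        )
        st = step(st, params, pulse=pulse, noise=noise, step_index=k)
        lfp[k] = st.v_i - st.v_i0
        prev = lfp[k]
    return LFPTrace(
        samples=lfp,
        fs=params.fs,
        stim_times=np.asarray(times),
        stim_delta_v=np.asarray(dvs),
        params=params,
        seed=seed,
    )


def _interp_halfwidth(freqs: np.ndarray, p_db: np.ndarray, i_peak: int) -> float:
    """Interpolated distance from the peak to the -6 dB crossings (mean of sides)."""
    target = p_db[i_peak] - 6.0
    sides = []
    for direction in (1, -1):
        j = i_peak
        while 0 < j < len(p_db) - 1:
            j += direction
            if p_db[j] < target:
                f1, f0 = freqs[j], freqs[j - direction]
                p1, p0 = p_db[j], p_db[j - direction]
                frac = (target - p0) / (p1 - p0)
                sides.append(abs(f0 + frac * (f1 - f0) - freqs[i_peak]))
                break
    if not sides:
        return float("nan")
    return float(np.mean(sides))


def psd(
    trace: LFPTrace | np.ndarray,
    fs: float | None = None,
    nperseg: int = 8192,
    overlap: float = 0.5,
    search_band: tuple[float, float] = (10.0, 45.0),
) -> Spectrum:
    """Welch-averaged power spectral density with beta-peak summary.

    Peak frequency is the argmax of the density inside ``search_band``;
    the half-width is the interpolated offset at which the density has
    fallen 6 dB (half amplitude) below the peak.
    """
    from scipy.signal import welch

    if isinstance(trace, LFPTrace):
        x, fs = trace.samples, trace.fs
    else:
        x = np.asarray(trace)
        if fs is None:
            raise ValueError("fs required for raw arrays")
    if len(x) < nperseg:
        raise InsufficientDataError(
            f"trace of {len(x)} samples shorter than one segment ({nperseg})"
        )
    freqs, pxx = welch(x, fs=fs, nperseg=nperseg, noverlap=int(nperseg * overlap))
    with np.errstate(divide="ignore"):
        p_db = 10.0 * np.log10(pxx)
    band = (freqs >= search_band[0]) & (freqs <= search_band[1])
    i_local = int(np.argmax(pxx[band]))
    i_peak = int(np.nonzero(band)[0][i_local])
    return Spectrum(
        freqs=freqs,
        power_db=p_db,
        peak_freq=float(freqs[i_peak]),
        halfwidth_6db=_interp_halfwidth(freqs, p_db, i_peak),
    )


def band_power_db(
    trace: LFPTrace | np.ndarray,
    fs: float | None = None,
    band: tuple[float, float] = BETA_BAND,
    nperseg: int = 8192,
) -> float:
    """Integrated band power in dB (trapezoidal over the Welch density)."""
    from scipy.signal import welch

    if isinstance(trace, LFPTrace):
        x, fs = trace.samples, trace.fs
    else:
        x = np.asarray(trace)
    if len(x) < nperseg:
        raise InsufficientDataError("trace shorter than one segment")
    freqs, pxx = welch(x, fs=fs, nperseg=nperseg, noverlap=nperseg // 2)
    m = (freqs >= band[0]) & (freqs <= band[1])
    return float(10.0 * np.log10(np.trapezoid(pxx[m], freqs[m])))


def load_defaults() -> dict:
    """Parsed contents of the versioned calibration file."""
    ref = importlib.resources.files("bayesadc").joinpath("data/defaults.yaml")
    with ref.open("r") as f:
        return yaml.safe_load(f)


def tune_defaults(state: str = "DD") -> SimParams:
    """Calibrated parameter set for the requested model state.

    ``state`` is ``"DD"`` (dopamine-depleted: loop gain above the Hopf
    threshold, pronounced ~29 Hz peak) or ``"naive"`` (below threshold,
    noise-sustained resonance with much weaker beta power).
    """
    cfg = load_defaults()["sim"]
    key = state.lower().replace("ï", "i")
    if key not in ("dd", "naive"):
        raise ValueError(f"unknown state {state!r}; expected 'DD' or 'naive'")
    kw = dict(cfg["shared"])
    kw.update(cfg[key])
    return SimParams(state="DD" if key == "dd" else "naive", **kw)
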