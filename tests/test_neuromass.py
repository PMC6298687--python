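"""Unit tests of the neural-mass surrogate: pulses, stepping, IO."""

import math
from dataclasses import replace

import numpy as np
import pytest

from bayesadc.neuromass import (
    InsufficientDataError,
    LFPTrace,
    NumericalBlowupError,
    PopulationState,
    SimParams,
    Spectrum,
    dbs_pulse_delta_v,
    psd,
    simulate,
    step,
    tune_defaults,
)


class TestPulseChargeRule:
    def test_zero_amplitude(self):
        assert dbs_pulse_delta_v(0.0, 90e-6, 1e-6) == 0.0

    def test_hand_arithmetic(self):
        # 2.37 mA for 90 us into 1 uF: Q/C = 2.37e-3 * 9.0e-5 / 1e-6 V
        assert dbs_pulse_delta_v(2.37, 90e-6, 1e-6) == pytest.approx(
            2.37e-3 * 9.0e-5 / 1e-6, rel=1e-15
        )

    def test_exact_linearity(self):
        base = dbs_pulse_delta_v(1.3, 90e-6, 1e-6)
        assert dbs_pulse_delta_v(2.6, 90e-6, 1e-6) == 2.0 * base
        assert dbs_pulse_delta_v(1.3, 180e-6, 1e-6) == 2.0 * base

    @pytest.mark.parametrize(
        "kw", [dict(pulse_width_s=0.0), dict(c_m=0.0), dict(c_m=-1e-6),
               dict(amplitude_ma=-1.0)]
    )
    def test_invalid_parameters(self, kw):
        args = dict(amplitude_ma=1.0, pulse_width_s=90e-6, c_m=1e-6)
        args.update(kw)
        with pytest.raises(ValueError):
            dbs_pulse_delta_v(**args)


def quiescent_params(**kw):
    """Decoupled, noise-free, drive-free parameters: origin is a fixed point."""
    base = dict(
        g_exc_to_inh=0.0, g_inh_to_exc=0.0, drive=0.0, noise=0.0,
        wander_frac=0.0,
    )
    base.update(kw)
    return replace(tune_defaults("DD"), **base)


class TestStep:
    def test_origin_is_fixed_point(self):
        params = quiescent_params()
        st = PopulationState.initial(params)
        for k in range(50):
            st = step(st, params, noise=(0.0, 0.0, 0.0), step_index=k)
        assert st.v_e == 0.0 and st.v_i == 0.0
        assert st.dv_e == 0.0 and st.dv_i == 0.0

    def test_impulse_response_matches_closed_form(self):
        """Decoupled second-order Euler map has the double root 1 - gamma*dt:
        v_n = dV * (1 + n*gamma*dt/lam) * lam^n."""
        params = quiescent_params()
        dt, gam = params.dt, params.gamma
        lam = 1.0 - gam * dt
        dv0 = 0.21
        st = PopulationState.initial(params)
        st = step(st, params, pulse=dv0, noise=(0.0, 0.0, 0.0))
        vs = [st.v_e]
        for _ in range(200):
            st = step(st, params, noise=(0.0, 0.0, 0.0))
            vs.append(st.v_e)
        for n, v in enumerate(vs, start=1):
            expected = dv0 * (1.0 + n * gam * dt / lam) * lam**n
            assert v == pytest.approx(expected, abs=1e-12)
        assert abs(vs[-1]) < 1e-3 * dv0  # decayed toward zero

    def test_blowup_names_step_index(self):
        # gamma*dt > 2 makes explicit Euler unstable
        params = replace(quiescent_params(), gamma=5000.0)
        st = PopulationState.initial(params)
        st = step(st, params, pulse=1.0, noise=(0.0, 0.0, 0.0))
        with pytest.raises(NumericalBlowupError) as err:
            for k in range(10_000):
                st = step(st, params, noise=(0.0, 0.0, 0.0), step_index=k)
        assert err.value.step_index >= 0
        assert str(err.value.step_index) in str(err.value)

    def test_invariants_rejected(self):
        with pytest.raises(ValueError):
            SimParams(dt=-0.001)
        with pytest.raises(ValueError):
            SimParams(delay=0.0001)  # shorter than dt
        with pytest.raises(ValueError):
            SimParams(c_m=0.0)


class TestSimulate:
    def test_determinism_bit_exact(self, dd_params):
        a = simulate(dd_params, 3.0, seed=11)
        b = simulate(dd_params, 3.0, seed=11)
        assert np.array_equal(a.samples, b.samples)

    def test_seeds_differ(self, dd_params):
        a = simulate(dd_params, 3.0, seed=11)
        b = simulate(dd_params, 3.0, seed=12)
        assert not np.array_equal(a.samples, b.samples)

    def test_matches_compiled_kernel(self, dd_params):
        from bayesadc._kernel import closed_loop
        from bayesadc.policy import default_swift_params
        from bayesadc.swift import tone_gain

        sw = default_swift_params(dd_params.fs)
        ref = simulate(dd_params, 2.0, seed=7)
        lfp, _, _, _, err = closed_loop(
            2000, 7, dd_params.dt, dd_params.delay_steps, dd_params.gamma,
            dd_params.g_exc_to_inh, dd_params.g_inh_to_exc, dd_params.qmax,
            dd_params.threshold, dd_params.slope, dd_params.noise,
            dd_params.drive, dd_params.wander_frac, dd_params.wander_tau,
            sw.omega, sw.tau_slow_samples, sw.tau_fast_samples, tone_gain(sw),
            0, 0.0, -90.0, 0.0, 130.0, 10**9, np.zeros(0), 1000,
        )
        assert err == -1
        assert np.array_equal(ref.samples, lfp)

    def test_controller_pulses_are_logged(self, dd_params):
        fire_at = {500, 1500}

        def controller(k, lfp):
            return 0.2 if k in fire_at else None

        trace = simulate(dd_params, 2.0, controller=controller, seed=0)
        assert set(np.round(trace.stim_times / dd_params.dt).astype(int)) == fire_at
        assert np.all(trace.stim_delta_v == 0.2)
        assert np.all(np.diff(trace.stim_times) > 0)

    def test_duration_too_short(self, dd_params):
        with pytest.raises(ValueError):
            simulate(dd_params, 1e-5, seed=0)


class TestTraceIO:
    def test_text_roundtrip(self, dd_params, tmp_path):
        def controller(k, lfp):
            return 0.1 if k == 300 else None

        trace = simulate(dd_params, 1.5, controller=controller, seed=4)
        path = tmp_path / "trace.txt"
        trace.to_text(path)
        back = LFPTrace.from_text(path, params=dd_params, seed=4)
        assert np.allclose(back.samples, trace.samples, atol=1e-8)
        assert len(back.stim_times) == 1
        assert back.stim_delta_v[0] == pytest.approx(0.1, abs=1e-8)

    def test_hdf5_roundtrip(self, dd_params, tmp_path):
        import h5py

        trace = simulate(dd_params, 1.0, seed=4)
        path = tmp_path / "trace.h5"
        trace.to_hdf5(path)
        with h5py.File(path) as f:
            assert np.array_equal(f["lfp"][:], trace.samples)
            assert f.attrs["seed"] == 4


class TestPsd:
    def test_pure_tone_peak(self):
        fs = 1000.0
        t = np.arange(int(30 * fs)) / fs
        rs = np.random.RandomState(0)
        x = np.sin(2 * np.pi * 29.0 * t) + 0.01 * rs.standard_normal(len(t))
        spec = psd(x, fs=fs)
        assert spec.peak_freq == pytest.approx(29.0, abs=0.15)

    def test_white_noise_has_no_prominent_beta_peak(self):
        rs = np.random.RandomState(1)
        x = rs.standard_normal(60_000)
        spec = psd(x, fs=1000.0, nperseg=4096)
        band = (spec.freqs >= 10) & (spec.freqs <= 45)
        # ~1 Hz smoothing removes single-bin estimator fluctuations
        smooth = np.convolve(spec.power_db[band], np.ones(9) / 9, mode="valid")
        assert smooth.max() - np.median(smooth) < 3.0

    def test_insufficient_data(self):
        with pytest.raises(InsufficientDataError):
            psd(np.zeros(1000), fs=1000.0)

    def test_tune_defaults_contract(self):
        dd = tune_defaults("DD")
        nv = tune_defaults("naive")
        assert dd.dt == 0.001
        assert dd.g_exc_to_inh > nv.g_exc_to_inh  # DD gain strictly greater
        with pytest.raises(ValueError):
            tune_defaults("unknown")
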