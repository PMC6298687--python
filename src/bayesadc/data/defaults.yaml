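# Calibrated surrogate parameter sets and controller defaults.
# These constants are the package's versioned calibration: the DD set is tuned
# so that an unstimulated simulation shows a ~29 Hz spectral peak with a
# -6 dB half-width near 1.15 Hz that increases relative to the naive set and
# is suppressed by 130 Hz isochronal stimulation.
sim:
  shared:
    dt: 0.001            # s, integration step
    delay: 0.001         # s, STN<->GP loop delay
    gamma: 235.0         # 1/s, synapto-dendritic rate constant
    qmax: 1.0            # sigmoid maximum rate (model units)
    threshold: 0.0       # sigmoid inflection voltage (model units)
    slope: 0.25          # sigmoid width (model units)
    noise: 0.2           # additive Gaussian drive amplitude (model units)
    drive: 0.1           # constant excitatory input (model units)
    wander_frac: 0.024   # OU fractional modulation of gamma (dimensionless)
    wander_tau: 3.0      # s, OU correlation time
    c_m: 1.0e-6          # F, membrane capacitance
  naive:
    g_exc_to_inh: 1.1
    g_inh_to_exc: 1.1
  dd:
    g_exc_to_inh: 1.6
    g_inh_to_exc: 1.6
swift:
  f0: 29.0               # Hz, beta peak center
  tau_slow: 0.240        # s  (-> 1.15 Hz half-width)
  fast_ratio: 5.0
policy:
  cdbs_rate: 130.0       # Hz
  pulse_width: 9.0e-5    # s
  cdbs_ref_amplitude: 2.37   # mA, reference cDBS condition
  # coordinates of the response-surface minimum region used to pin inactive
  # dimensions in 1D/2D optimization problems (from a 16^3 sweep)
  theta_star: -1.05      # rad
  p_th_star: -60.0       # dB (gate effectively open)
  amp_star: 1.1          # mA
bounds:
  phase: [-3.141592653589793, 3.141592653589793]
  threshold: [-60.0, 0.0]
  amplitude: [0.0, 5.0]
evaluation:
  settle: 2.0            # s, desk-scale settle time before measuring
  window: 3.0            # s, desk-scale measurement window
  settle_full: 10.0      # s, full protocol
  window_full: 10.0      # s, full protocol
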