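# Uniformly 15N-labelled protein: two equivalent His remote nitrogens
# coupled to Cu2+, observed at the echo maximum of the Cu2+ spectrum.
field:
  B0_gauss: 3316
  mw_freq_GHz: 9.7
system:
  g_iso: 2.06
  nuclei:
    - isotope: "15N"
      count: 2
      A_iso_MHz: 2.8
      T_dip_MHz: -0.4
timing_3p:
  tau_ns: 210
  T_start_ns: 12
  dT_ns: 16
  n_points: 602
timing_4p:
  tau_ns: 210
  t_start_ns: 40
  dt_ns: 32
  n1: 256
  n2: 256
processing:
  window: chebyshev
  zerofill_1d: 2048
  zerofill_2d: 1024
  background: exponential
seed: 0
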