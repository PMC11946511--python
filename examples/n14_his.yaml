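# Natural-abundance histidine: one remote 14N near exact cancellation.
# K and eta reproduce the 0.5 / 1.0 / 1.5 MHz quadrupole triplet.
field:
  B0_gauss: 3316
  mw_freq_GHz: 9.7
system:
  g_iso: 2.06
  nuclei:
    - isotope: "14N"
      count: 1
      A_iso_MHz: 1.85
      T_dip_MHz: -0.1
      quadrupole:
        K_MHz: 0.4167
        eta: 0.6
timing_3p:
  tau_ns: 210
  T_start_ns: 12
  dT_ns: 16
  n_points: 602
seed: 0
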