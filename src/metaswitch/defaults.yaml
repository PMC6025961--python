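# Default simulator calibration.  Units package-wide: minutes, µm, mM, AU.
#
# Two-state (telegraph) switching per reporter; exponential single-cell
# elongation; Hill-type acetate induction of the alsS state; multiplicative
# saturating acetate toxicity on growth.  See docs/methods.md for the
# provenance of each value.
switch_params:
  # competence-linked sucC+ state: Poisson entry/exit
  k_on_sucC: 1.6e-3        # 1/min; peak entry rate at full quorum activation
  k_off_sucC: 3.968254e-3  # 1/min; 1/252 -> mean episode 252 min
  # acetate-induced alsS+ state
  k0_alsS: 1.0e-5          # 1/min; basal entry with no acetate
  kmax_alsS: 1.5e-3        # 1/min; maximal acetate-induced entry
  K_alsS: 10.0             # mM; half-activation acetate concentration
  h_alsS: 2.0              # Hill coefficient
  k_off_alsS: 6.666667e-3  # 1/min; 1/150 -> mean episode 150 min
  # growth
  r_base: 9.236708e-3      # 1/min; ln(1.74)/60 -> 74 %/hr unstressed elongation
  penalty_sucC: 0.750256   # ln(1.474)/ln(1.677): 67.7 -> 47.4 %/hr in-state
  penalty_alsS: 0.882153   # ln(1.63)/ln(1.74): 74 -> 63 %/hr in-state
  K_tox: 25.0              # mM acetate halving the growth rate
  growth_cv: 0.08          # lognormal per-cell-cycle growth-rate variability
  # reporters (stable YFP: production minus growth dilution, no degradation)
  beta_on: 80.0            # AU/min production in the on state
  beta_off: 8.0            # AU/min basal production
  meas_cv: 0.03            # lognormal measurement noise on recorded fluorescence
  # division
  L_div: 4.0               # µm division length (sizer)
  div_cv: 0.05             # CV of division-site placement
  # environment coupling (per cell, culture-volume normalised)
  p_A: 7.0e-4              # mM/min acetate secreted per sucC+ cell
  c_A: 1.6e-4              # mM/min acetate taken up per alsS+ cell
  y_acetoin: 0.5           # mol acetoin per mol acetate consumed
  quorum: 1.0              # dimensionless scale on k_on_sucC
  # competence window along the growth curve (batch/pad modes): entry is
  # quorum-activated at moderate density and shut off toward stationary
  K_quorum_od: 0.25        # OD of half-maximal quorum activation
  h_quorum: 2.0
  K_close_od: 0.4          # OD of half-maximal window closure
  h_close: 4.0
  # carbon pool (batch mode)
  K_sec: 1.0               # mM; carbon half-saturation of overflow secretion
  K_carbon: 2.0            # mM; Monod constant of growth on glucose+malate
  yield_carbon: 3.3e-3     # mM carbon consumed per µm of new cell length

scenarios:
  batch:
    mode: batch
    duration: 600.0
    frame_interval: 12.0
    n_founders: 300
    glucose: 22.0          # mM
    malate: 50.0           # mM
    acetate: 0.0
    acetoin: 0.0
  mother_machine:
    mode: mother_machine
    duration: 2880.0
    frame_interval: 12.0
    n_channels: 60
    channel_capacity: 6
  pad:
    mode: pad
    duration: 1320.0       # 22 hr of 12-min frames
    frame_interval: 12.0
    n_founders: 8
    acetate: 20.0          # mM, mid-exponential-like starting level
    glucose: 22.0
    malate: 0.0
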