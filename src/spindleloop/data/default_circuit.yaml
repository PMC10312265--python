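# Shipped default circuit configuration (calibration constants).
#
# The absolute gains and leak rates below are calibration constants, fixed
# once against the reference spindle-tendency conditions (see
# spindleloop.calibrate) and then frozen.  Structural constraints are not
# subject to calibration: L5->CB+ is l5_cb_over_l6_pv (20x) times L6->PV+,
# L5->TRN_M and L5->CB- are l5_trn_fraction times their core counterparts
# (L6->TRN_C, L6->PV-), and matrix projections are four times broader than
# core ones (sigma 8 vs 2).
version: "2026.09-v4"
N: 200
decay_A: 55.0
# Leak rates (1/s): thalamic relay cells are slow integrators, reticular
# cells fast; local interneurons intermediate.  The core/matrix asymmetry
# of relay and reticular leaks is part of the calibration.
decay_overrides:
  "CB+": 45.0
  "PV+": 21.0
  "CB-": 30.0
  "PV-": 30.0
  "TRN_M": 90.0
  "TRN_C": 63.0
  "L1-3a": 70.0
  "L5": 70.0
E_ext: 1.0
E_inh: -1.0
l5_trn_fraction: 0.0
local_inhibition: false
cortical_feedback_tc: false
cortical_feedback_trn: true
mixing_mode: none
mixing_ratio: 0.5
mixing_efficacy: 0.0
l5_cb_over_l6_pv: 20.0
cortical_mix_gain: 40.0
# Conductance scale converting a normalized stimulus waveform into drive
# strong enough to induce the waveform's voltage in the target population.
stimulus_gain: 300.0
eta_minus: 0
eta_plus: 0
rectify: false
projections:
  # thalamoreticular loop (the core pair resonates near 10 Hz; the matrix
  # loop instead rings through its corticoreticular limb, with a weak pair
  # and a strong, broad reticular-to-relay projection)
  "PV+->TRN_C": {gain: 66.0, sigma: 2.0}
  "CB+->TRN_M": {gain: 0.2, sigma: 2.0}
  "TRN_C->PV+": {gain: 58.0, sigma: 2.0}
  "TRN_M->CB+": {gain: 17000.0, sigma: 8.0}
  "TRN_C->TRN_C": {gain: 40.0, sigma: 2.0}
  "TRN_M->TRN_M": {gain: 14.0, sigma: 2.0}
  # thalamocortical and intracortical pathway (core focal, matrix broad)
  "PV+->L3b-4": {gain: 80.0, sigma: 2.0}
  "CB+->L1-3a": {gain: 35.2, sigma: 8.0}
  "L3b-4->L6": {gain: 80.0, sigma: 2.0}
  "L1-3a->L5": {gain: 35.2, sigma: 8.0}
  # corticoreticular feedback
  "L6->TRN_C": {gain: 130.0, sigma: 2.0}
  "L5->TRN_M": {sigma: 2.0}          # gain = l5_trn_fraction x L6->TRN_C
  # corticothalamic feedback
  "L6->PV+": {gain: 60.0, sigma: 2.0}
  "L5->CB+": {sigma: 8.0}            # gain = l5_cb_over_l6_pv x L6->PV+
  # local thalamic inhibition (interneurons receive thalamic, reticular,
  # and cortical drive)
  "PV+->PV-": {gain: 5.0, sigma: 1.0}
  "CB+->CB-": {gain: 5.0, sigma: 1.0}
  "PV-->PV+": {gain: 40.0, sigma: 1.0}
  "CB-->CB+": {gain: 40.0, sigma: 1.0}
  "TRN_C->PV-": {gain: 10.0, sigma: 2.0}
  "TRN_M->CB-": {gain: 10.0, sigma: 2.0}
  "L6->PV-": {gain: 40.0, sigma: 2.0}
  "L5->CB-": {sigma: 8.0}            # gain = l5_trn_fraction x L6->PV-
  # mixing cross-connections (gains derived from the mixing settings)
  "PV+->TRN_M": {sigma: 2.0}
  "CB+->TRN_C": {sigma: 2.0}
  "L6->TRN_M": {sigma: 2.0}
  "L5->TRN_C": {sigma: 2.0}
  "L6->L5": {sigma: 2.0}
  "L5->L6": {sigma: 2.0}
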