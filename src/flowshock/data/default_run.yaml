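# Default run configuration: the 80-min laboratory contamination /
# shock-chlorination experiment in a 500 ml stirred drinking-water reactor.
# All values are also the code defaults; this file exists so users have a
# complete, editable template.
experiment:
  initial_volume: 500.0        # ml
  tap_tcc: 130.6               # cells/ul
  tap_icc: 99.6                # cells/ul
  contaminant_tcc: 14700.0     # cells/ul, 10-fold pre-diluted wastewater
  contaminant_icc_fraction: 0.67
  contaminant_rate: 3.0        # ml/min
  contaminant_duration: 5.0    # min
  chlorine_stock: 72.0         # mg/l free chlorine
  chlorine_rate: 2.5           # ml/min
  chlorine_duration: 5.0       # min
  flowthrough_rate: 100.0      # ml/min
  phase_start_times: [0.0, 15.0, 30.0, 45.0]
  total_duration: 80.0         # min
  time_step: 1.0               # min
  track_volume: true
kinetics:
  icc_kill_rate: 1.5           # 1/min
  icc_resistant_fraction: 0.051
  tcc_decay_rate: 10.6         # cells/ul/min
  tcc_decay_threshold: 0.5     # mg/l
  chlorine_demand_rate: 0.04   # 1/min
  kill_threshold: 0.05         # mg/l (colorimetric detection limit)
instrument:
  cytometer_flow_rate: 14.0    # ul/min
  acquisition_resolution_ms: 100.0
  staining_dilution_factor: 2.0
  staining_delay_min: 10.0
  detection_threshold_fl1: 1000.0
  background_event_rate: 2.0   # events/s
populations:
  tap_pct_lna_tcc: 65.0
  tap_pct_lna_icc: 71.0
  wastewater_pct_hna: 61.3
  chlorine_fl1_drift: 0.0
gates:
  fl1_threshold: 1000.0
  bacteria_gate: [[3.0, 1.0], [5.5, 1.0], [5.5, 5.0], [3.0, 5.0]]
  intact_gate: [[3.0, 1.0], [5.5, 1.0], [5.5, 3.5], [3.0, 3.5]]
  lna_hna_boundary: 6309.57344480193  # 10^3.8
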