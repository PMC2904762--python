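# Default 2x2 experiment emulation: {low, high} process noise x {low, high}
# control cost.  Sigma (process_noise_sd) is the std of the random lateral
# force in N at the 10 ms reference step; the high level is 5x the low level,
# which makes the uncontrolled final positional error 5x larger.  Cost weights
# are in points: error_weight per cm^2 of final error, control_weight per N^2
# of control force per step; the two control-cost levels differ 5-fold, chosen
# so that control cost contributes roughly 10-50% of the total under
# risk-neutral control.  The hand-to-force gain only affects reported hand
# kinematics (force = k * hand displacement), not the control law.
shared:
  mass_kg: 1.0
  dt_s: 0.01
  horizon_s: 1.0
  ball_speed_y_cm_s: 15.0
  target_distance_cm: 15.0
  error_weight: 1.0

conditions:
  low_noise/low_cost:
    process_noise_sd: 1.2
    control_weight: 1.0
    hand_force_gain_N_per_cm: 10.0
  high_noise/low_cost:
    process_noise_sd: 6.0
    control_weight: 1.0
    hand_force_gain_N_per_cm: 50.0
  low_noise/high_cost:
    process_noise_sd: 1.2
    control_weight: 5.0
    hand_force_gain_N_per_cm: 10.0
  high_noise/high_cost:
    process_noise_sd: 6.0
    control_weight: 5.0
    hand_force_gain_N_per_cm: 50.0
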