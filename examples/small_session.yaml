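# A reduced synthetic session for a quick end-to-end demonstration:
# full 10-gesture protocol structure at 3-s motions / 1.5-s rests,
# 4 trials (1 calibration + up to 2 training + at least 1 test).
seed: 5
simulation:
  n_per_gesture: 6
  motion_duration_s: 3.0
  rest_duration_s: 1.5
  n_trials: 4
training:
  epochs: 10
evaluation:
  k_list: [1, 2]
  feature: cwcst_rate
  classifier: cnn
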