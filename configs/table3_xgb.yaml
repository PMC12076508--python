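# XGBoost training parameters, per task, at publication scale.
# Tasks not listed below use the library defaults apart from max_depth.
family: xgb
params:
  max_depth: 20
tasks:
  existence: {}
  zero_vs_one: {}
  n_centers_multiclass: {}
  R_vs_S: {}
  sign_one_center:
    eta: 0.13
  sign_all:
    eta: 0.1
    eval_metric: error
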