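# Random-forest training parameters, per task, at publication scale.
family: rf
params:
  min_samples_leaf: 2
  max_features: sqrt
tasks:
  existence:
    n_estimators: 1800
    max_depth: 100
  zero_vs_one:
    n_estimators: 1200
    max_depth: 420
  n_centers_multiclass:
    n_estimators: 1800
    max_depth: 100
  R_vs_S:
    n_estimators: 1800
    max_depth: 100
  sign_one_center:
    n_estimators: 1200
    max_depth: 100
  sign_all:
    n_estimators: 1200
    max_depth: 420
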