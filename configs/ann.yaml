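# Feed-forward network: 216 -> 500 -> 200 -> softmax, cross-entropy loss,
# Adam, patience-based stopping.  max_iter is the epoch cap; the published
# runs trained for at least 10,000 epochs.
family: ann
params:
  hidden_layer_sizes: [500, 200]
  learning_rate_init: 0.001
  max_iter: 10000
  early_stopping: true
  validation_fraction: 0.1
  n_iter_no_change: 20
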