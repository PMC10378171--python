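# Pinned hyperparameters for the four classifier types. These are the
# library defaults except where noted; pinning them here keeps runs
# reproducible. Values can be overridden per call via make_model(hyper=...).
ann:
  hidden_layer_sizes: [16]      # one hidden layer
  activation: relu
  max_iter: 500
  random_state: 0
dt:
  criterion: gini               # impurity-based splits
  random_state: 0
adaboost:
  n_estimators: 50
  max_depth: 1                  # tree stumps as weak learners
  random_state: 0
svm:
  kernel: rbf
  C: 1.0
  gamma: scale
  random_state: 0
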