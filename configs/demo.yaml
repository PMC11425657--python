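# Desk-scale demo pipeline: 64 px images, 20 training pairs, 100 steps.
seed: 1
image_size: 64
stages: [simulate, train, reconstruct, evaluate]
simulate:
  n_train: 20
  n_test: 4
  n_angles: 120
  kinds: [ellipses, polygons, texture, fractal]
train:
  module1:
    steps: 100
    width: 0.125
    augmentation: []
  module2:
    steps: 100
    width: 0.125
    style_embedding: true
    augmentation: []
reconstruct:
  baselines: [fbp, osem]
evaluate: {}
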