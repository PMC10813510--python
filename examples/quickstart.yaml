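# Quickstart experiment for the command line interface:
#   batscreen run examples/quickstart.yaml --out results/quickstart
generator:
  n: 300
  seed: 1
  mode: threshold
  label_noise: 0.0
classifier: knn
optimizer: [ba, mba]
seed: 1
pop_size: 10
budget: 20
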