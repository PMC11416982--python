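# Desk-scale experiment grid: global saliency mask vs per-site masks vs dense.
arms: [neurosfl, individual_snip, random_global, dense_fedavg]
sparsities: [0.0, 0.5, 0.9]
seeds: [0, 1, 2]
partition_kind: dirichlet
alpha: 0.3
K: 10
rounds: 30
local_epochs: 5
batch_size: 32
lr: 0.01
lr_decay: 0.998
dataset:
  n: 400
  shape: [16, 16, 16]
  n_classes: 2
  effect_size: 5.0
  site_shift_sd: 0.5
  n_sites: 4
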