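# Desk-scale quickstart: 4 heterogeneous clients, 32x32 phantoms, 10 rounds.
clients: 4
rounds: 10
local_epochs: 2
batch_size: 8
lr: 0.003
strategy: paf_fed
r_mode: adaptive
r0: 0.0
r1: 0.5
seed: 0
heterogeneity: 0.8
image_size: 32
n_classes: 4
n_per_client: 40
augment: true
depth: 2
base_width: 8
outdir: runs/quickstart
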