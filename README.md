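# freqfed

Personalized federated learning for multi-site 2D segmentation, with model
aggregation in the frequency domain — a self-contained simulator and library
for studying how partial parameter sharing behaves under statistically
heterogeneous (non-IID) clients, such as hospitals with different scanners
and different organ-class distributions.

## Who this is for

Researchers and students studying personalized federated learning (PFL) for
medical image segmentation who want a small, fully deterministic,
CPU-friendly testbed: every component — U-Net, backprop, Adam, FFT
aggregation, metrics, phantom data — is plain numpy/scipy, seeded end to
end, and covered by tests. No GPU, no real patient data.

## The method

K clients train a shared-architecture U-Net on private data. Parameters are
partitioned into a personalized part W_H (the 1x1 segmentation head and the
BN running statistics (mu, sigma^2), which encode site-specific intensity
regimes) and a shared part W_R (the convolutional trunk and the learned BN
affine (gamma, beta)). Each round, every client trains E local epochs on the
fused loss

    L = CE(G, O) - (2/|C|) * sum_j  sum_i O_ij G_ij / (sum_i O_ij + sum_i G_ij)

and sends W_R to the server. The server aggregates each tensor in the
frequency domain ("FTA"): reshape a cout x cin x kh x kw kernel to a
(cin*kh) x (kw*cout) matrix, take a centered 2D FFT z, split it at a
threshold r into a low band z^l (|u| <= r*H/2, |v| <= r*W/2) and a high
band z^h, then combine the clients' low bands with reciprocal self-attention

    A = softmax_rows( 1 / (Z_l Z_l^T) ),    z_bar^l = mean_i (A Z_l)_i,

which up-weights clients whose components diverge from the group (the slow
convergers). Each client receives z_bar^l fused with its *own* high band,
inverse-transformed: shared coarse structure, personalized detail. The
threshold grows over rounds, r(t) = r0 + (r1 - r0) t / T (defaults 0 -> 0.5).

Setting r = 1 with uniform attention recovers FedAvg exactly; classical
baselines (FedAvg, FedBN, SiloBN, FedRep, local-only) are available as
partition presets on the same machinery.

## Worked example

```sh
freqfed simulate --config src/freqfed/configs/quickstart.yaml \
    --strategy local --strategy paf_fed --outdir runs/demo
freqfed compare runs/demo/local runs/demo/paf_fed
```

The quickstart runs 4 heterogeneous clients (heterogeneity 0.8: strongly
skewed organ prevalences plus client-specific intensity shifts), 40 phantom
images each at 32x32, 10 rounds of 2 local epochs, and prints one JSON
summary line per strategy followed by the comparison table, e.g.:

```
{"strategy": "local", "mean_dsc": 0.5285802884058182, "mean_assd": 0.7823414311805998, "outdir": "runs/demo/local"}
{"strategy": "paf_fed", "mean_dsc": 0.5955675522585111, "mean_assd": 0.917527622499636, "outdir": "runs/demo/paf_fed"}
strategy                run  dsc_c0  assd_c0  dsc_c1  assd_c1  dsc_c2  assd_c2  dsc_c3  assd_c3  dsc_avg  assd_avg
   local   runs/demo/local  0.2970   0.6416  0.7252   0.1139  0.5271   1.5888  0.5651   0.7851   0.5286    0.7823
 paf_fed runs/demo/paf_fed  0.4112   0.8947  0.7172   0.1574  0.5462   1.8022  0.7077   0.8158   0.5956    0.9175
```

`mean_dsc` is the Dice similarity coefficient (overlap, 1 = perfect)
averaged over foreground organ classes and clients on each client's own
held-out test split; `mean_assd` is the average symmetric surface distance
in mm (0 = perfect boundaries). With only 32 training images per client,
purely local models handle their dominant organ but degrade on the organs
they rarely see; the federated run lifts the average DSC by several points
(clients 0 and 3 gain ~0.11 and ~0.14 here) by sharing low-frequency weight
structure learned at the other sites. Each run directory also contains
`history.csv` (per-round losses, validation DSC/ASSD, and the r value),
`metrics.csv`/`.json` (per-client, per-class scores), and `manifest.json`,
from which the run is byte-for-byte reproducible.

As a library:

```python
from freqfed import RoundConfig, make_federation_data, run_federation, evaluate_federation

profiles, datasets = make_federation_data(k=4, heterogeneity=0.8, n_per_client=120,
                                          size=(32, 32), n_classes=4, seed=1)
states, history = run_federation(RoundConfig(n_clients=4, rounds=10, local_epochs=2,
                                             batch_size=8, lr=1e-3, strategy="paf_fed",
                                             base_seed=1), datasets)
print(evaluate_federation(states).client_means())
```

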