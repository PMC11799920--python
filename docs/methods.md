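# Methods

## Problem setting

`freqfed` simulates personalized federated learning (PFL) for 2D multi-organ
segmentation across K sites whose data are statistically heterogeneous in two
ways that dominate real multi-site imaging: the class (organ) ratios differ
strongly between sites, and each site lives in its own intensity regime
(different scanner, sequence, or reconstruction). Clients exchange model
parameters only; raw images never leave a client.

## Model

The base network is a small 2D U-Net: `depth` encoder stages of two 3x3
conv + BN + ReLU units followed by 2x2 max-pooling, a bottleneck of the same
form, decoder stages of nearest-neighbor upsampling + 3x3 conv + BN + ReLU
with concatenated skip connections, and a final 1x1 convolution producing
per-pixel class logits. The 1x1 head plays the role of the "fully connected"
segmentation layers: it is a pixel-wise dense map from features to classes.
The network, its backward pass, and the Adam optimizer are implemented
directly on numpy in double precision; gradients are verified against
central differences in the test suite. The full-scale variant of this
method fine-tunes a pretrained backbone; training here is from scratch,
with He fan-in initialization under an explicit seed, which is the main
reason desk-scale accuracies are far below what the method reaches at full scale.

Batch normalization uses eps = 1e-5 and running-statistic momentum 0.1
(biased batch variance both for normalization and for the running update).
Evaluation always uses a client's *own* running statistics — under the
personalized partitions they are never aggregated.

## Parameter partition

Every tensor has a role (conv weight/bias, BN gamma/beta, BN running
mean/var, head weight/bias). A partition preset maps roles to
personalized (kept local) or shared (communicated):

| preset    | personalized roles                                   |
|-----------|------------------------------------------------------|
| `paf_fed` | head weight+bias, BN running mean+var                |
| `fedavg`  | none                                                 |
| `fedbn`   | all four BN roles                                    |
| `silobn`  | BN running mean+var                                  |
| `fedrep`  | head weight+bias                                     |
| `local`   | everything (no communication)                        |

The `paf_fed` partition keeps the prediction layer and the site-specific
activation statistics local while sharing and aggregating the learned BN
affine parameters (gamma, beta) with the convolutional trunk.

## Frequency-domain attention aggregation

Shared conv tensors W in R^(cout x cin x kh x kw) are permuted to
(cin, kh, kw, cout) and reshaped to a (cin*kh) x (kw*cout) matrix, a
convention recorded per tensor for exact inversion. The matrix's centered
2D FFT is split by a rectangular low-frequency mask
{ |u| <= r*H/2 and |v| <= r*W/2 } in centered integer coordinates; the mask
is axis-wise rather than radial because the matrix axes mix channel and
kernel coordinates and carry no isotropic geometry. The mask is monotone in
r, symmetric under coordinate negation for r < 1 (so real weights map to
Hermitian-symmetric spectra and the inverse transform is real to machine
precision), and always contains the DC coefficient.

Each client's masked low-frequency coefficients are flattened to a real
vector by concatenating real and imaginary parts. With Z_l the K x m matrix
of these vectors, the server computes

    G = Z_l Z_l^T,   A = softmax_rows(1 / G),   z_hat = A Z_l,

guarding |G| < 1e-8 entries by eps with the sign preserved (sign of an exact
zero taken positive). The reciprocal inverts the similarity ordering: a
client whose low-frequency component disagrees with the group receives
*more* weight, damping the dominance of fast-converging clients. No
1/sqrt(d) temperature is applied — the aggregation rule is defined without
it. The final shared low part is the plain mean of the z_hat rows and is
identical for every client; each client's own high-frequency part is
re-inserted before the inverse FFT. Attention is computed independently per
tensor, since the FFT itself is per-tensor. 1D and 0D tensors (BN vectors,
biases) are element-wise averaged — per-channel scalar vectors have no
meaningful 2D frequency structure.

The threshold r either stays fixed or grows linearly over communication
rounds, r(t) = r0 + (r1 - r0) * t / T with defaults r0 = 0, r1 = 0.5 and
0-based t, so training rounds use r in [0, r1). Early rounds share almost
nothing (the models are still near-random); late rounds share a wide
low-frequency band.

Limiting behaviors, all enforced by tests: r = 1 with uniform attention
reduces exactly to FedAvg; K = 1 and identical clients are identities;
client permutation permutes outputs; personalized tensors are bit-identical
across a server round.

## Training loss and metrics

The segmentation loss is pixel-averaged cross-entropy minus a class-averaged
soft-Dice reward,

    L = -(1/n) sum_i sum_j G_ij log O_ij
        - (2/|C|) sum_j (sum_i O_ij G_ij) / (sum_i O_ij + sum_i G_ij),

with probabilities clamped to [1e-7, 1] before the log and 1e-6 added to the
Dice denominator against 0/0 on absent classes. The Dice ratio carries no
internal factor 2 — the factor sits outside as 2/|C| — so the loss attains
-1 exactly at a one-hot-correct prediction with all classes present.
Background is included in the class sum of the loss; evaluation reports
foreground classes only.

Evaluation uses DSC = 2TP/(2TP+FP+FN) and the average symmetric surface
distance (ASSD, mm) between boundaries, where a boundary pixel is a mask
pixel with at least one 4-neighbor outside the mask (the image border counts
as outside, a choice the metric definition leaves open). ASSD is computed
via Euclidean distance transforms with the pixel spacing as sampling, and is
checked against a brute-force pairwise-distance oracle. A class absent from
both maps is *undefined* and excluded from averages (with exclusion counts
surfaced in reports) rather than zero-filled; absent from exactly one map
scores DSC 0.

## Federated loop

All K clients participate every round, executed sequentially in id order
(the aggregate is permutation-invariant, so this matches parallel
execution). Optimizer state is client-local and persists across rounds.
The incoming aggregate is fused with the client's personalized part at the
*start* of its next update; clients are always evaluated in their
post-update state — the E local epochs yield each site's best personalized
parameters for that round. Augmentation is random rotation within ±15
degrees plus horizontal/vertical flips, applied on the fly with the
client's own RNG.

Full-scale defaults are Adam at lr 1e-4, batch 16,
E = 5 local epochs, T = 100 rounds. The desk-scale profile used by the
bundled quickstart and the benchmark script instead uses lr 3e-3 and batch 8.
The full-scale regime fine-tunes a pretrained backbone over T*E = 500 local
epochs — deep into every strategy's plateau; the desk benchmark trains from
scratch for T*E = 20 local epochs, and a step size was chosen at which a
single client's training approaches its plateau inside that budget. Running
the benchmark mid-warmup instead (e.g. at lr 1e-4) measures optimization
speed under parameter averaging, not the data-sharing benefit the
comparison is about.

## Synthetic phantoms

Each image holds up to C-1 elliptical organs on a darker noisy background,
rendered at 32x32 or 64x64 with 1 mm isotropic spacing; labels are exact
rasters; overlaps resolve by z-order (later organ wins), giving adjacent
organ boundaries. Occasional bright corner blobs emulate acquisition
artifacts without touching labels.

Class identity is carried by *shape*, not intensity: the three organ
classes share one intensity band (mean 0.65, sd 0.05, vs background
0.30 ± 0.03) and differ in geometry — large round (semi-axis 6.5-9.5 px,
axis ratio 0.6-1), elongated (6-10 px, ratio 0.2-0.45), and small round
(2.5-4.5 px). This mirrors single-modality abdominal imaging, where organs
overlap heavily in intensity and are told apart by shape and context, and
it makes the inter-client intensity shift a pure site nuisance rather than
a confound of the class-defining feature. (An earlier design with one
intensity band per class made class identity collinear with the site shift,
so cross-client knowledge was contradictory and *every* sharing strategy
scored below local — the opposite of the real phenomenon.)

A single heterogeneity knob h in [0, 1] drives both non-IID axes at once:

* **Label skew.** Each client favors one organ (round-robin). Prevalences
  interpolate *geometrically* (class ratios across real sites differ
  multiplicatively) between the common base 0.65 and the skewed profile
  0.95 favored / 0.30 non-favored: imbalanced but present, as in real
  multi-organ data — sites see all organs, in very different proportions.
  At h = 0.8 a client's non-favored organ appears in ~35% of its images,
  enough to define the task locally but too few examples to master the
  shape from scratch; the federation supplies the missing shape diversity.
  Seeded multiplicative jitter keeps clients distinct even when they favor
  the same organ.
* **Intensity shift.** A client-dependent brightness offset (spread 0.35*h
  across the client range plus seeded jitter) and mildly varying noise sd
  separate the clients' intensity regimes. Strategies that share BN running
  statistics (plain FedAvg) evaluate each site with mismatched
  normalization and degrade; strategies that keep them local are immune —
  the core of the BN-personalization argument.

Splits are 8:1:1 train/val/test (floor for val/test, remainder to train).

What the phantoms do *not* emulate: anatomy (organ shapes, spatial priors,
inter-organ geometry), MRI/CT physics (bias fields, partial volume,
modality-specific contrast), 3D structure, and registration artifacts.
Passing the end-to-end tests therefore shows that the federated mechanisms
behave as designed under controlled non-IID conditions — not that the
method attains any particular accuracy on clinical data.

## Benchmark problem sizes

The end-to-end benchmark (also run by `scripts/acceptance.py`) uses K = 4
clients at heterogeneity 0.8, 120 images per client at 32x32 with C = 4,
T = 10 rounds of E = 2 local epochs, depth-2 width-8 U-Net — small enough
to run on a laptop CPU in minutes while large enough for federated
strategies to separate from purely local training. The quickstart config is
the same setting at 40 images per client. Desk-scale DSC values are not
comparable to full-scale results; only orderings and gaps
computed by the benchmark itself are meaningful. One known scale effect:
with only 10 rounds, the growing threshold r = 0.5 t/10 keeps the
frequency-sharing strategies' communicated band small (at most 20% of
coefficients, ~7% on average), so their advantage over local training is
much smaller at T = 10 than full-tensor sharing's — the low-frequency
mechanism is built for long horizons (T = 100).

## Numerical choices

* All aggregation arithmetic in complex double precision; outputs cast back
  to the model dtype at the end.
* Mask threshold comparisons use a 1e-12 slack so exact integer bounds are
  inclusive.
* Imaginary residue after the inverse FFT above 1e-8 (relative to the real
  part's scale) raises an error instead of being silently discarded.
* Reciprocal guard eps = 1e-8 with sign preservation; softmax is shifted by
  the row max before exponentiation.
* Metric averaging excludes undefined entries; a report row where every
  entry is undefined propagates NaN rather than inventing a value.

## Known limitations

* Sequential client execution only; no partial participation, stragglers,
  or communication failure models.
* No differential privacy or secure aggregation — the privacy contract is
  purely architectural (only named tensors cross the client boundary).
* The FFT aggregation treats each tensor independently; a global
  (cross-layer) attention variant is out of scope.
* 2D only.
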