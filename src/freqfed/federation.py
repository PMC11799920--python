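"""Federated training loop: local updates, server aggregation, evaluation.

Each global round t = 0..T-1:

1. every client trains E local epochs of minibatch Adam on the fused
   Dice + cross-entropy loss, with on-the-fly random rotation (±15°) and
   flips driven by the client's own RNG;
2. the server collects the *shared* tensors (per the strategy's partition
   preset), aggregates them — frequency-domain attention aggregation for the
   FFT strategies, a plain element-wise mean for the classical baselines,
   nothing for ``local`` — and sends each client its aggregate;
3. each client fuses the incoming shared part with its personalized part at
   the start of its next local update; evaluation always sees the client's
   post-update (personalized-best) state.

Only named shared tensors ever cross the client boundary; raw images never
leave a :class:`ClientState`.  Personalized tensors of client k at round
t + 1 therefore depend only on client k's own history.

Strategies (partition preset / aggregator / attention):

================  ==========  ==========  ===========
strategy          partition   aggregator  attention
================  ==========  ==========  ===========
``paf_fed``       paf_fed     FTA         reciprocal
``pf_fed``        paf_fed     FTA         uniform
``fedavg_fft``    fedavg      FTA         uniform
``fedavg``        fedavg      mean        --
``fedbn``         fedbn       mean        --
``silobn``        silobn      mean        --
``fedrep``        fedrep      mean        --
``local``         local       none        --
================  ==========  ==========  ===========

Clients execute sequentially in id order; the server aggregate is invariant
to that order, so this is equivalent to parallel execution.  Optimizer state
is client-local and persists across rounds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage

from .freq_aggregation import aggregate_round, r_schedule
from .losses_metrics import assd, class_average, dsc, fused_loss_and_grad, one_hot
from .model_zoo import UNet, build_unet, classify_parameters
from .synthetic_data import PhantomDataset

STRATEGIES: Dict[str, Tuple[str, Optional[str], Optional[str]]] = {
    # strategy -> (partition preset, aggregator, attention mode)
    "paf_fed": ("paf_fed", "ffta", "reciprocal"),
    "pf_fed": ("paf_fed", "ffta", "uniform"),
    "fedavg_fft": ("fedavg", "ffta", "uniform"),
    "fedavg": ("fedavg", "mean", None),
    "fedbn": ("fedbn", "mean", None),
    "silobn": ("silobn", "mean", None),
    "fedrep": ("fedrep", "mean", None),
    "local": ("local", None, None),
}

AUGMENT_MAX_ROTATION = 15.0  # degrees


@dataclass
class RoundConfig:
    """Hyperparameters of one federated experiment.

    Defaults follow the full-scale training regime (Adam, lr 1e-4, batch 16,
    E=5 local epochs, T=100 rounds); desk-scale experiments override them.
    """

    n_clients: int = 4
    rounds: int = 100
    local_epochs: int = 5
    batch_size: int = 16
    lr: float = 1e-4
    strategy: str = "paf_fed"
    r_mode: str = "adaptive"  # 'fixed' or 'adaptive'
    r_fixed: float = 0.25
    r0: float = 0.0
    r1: float = 0.5
    base_seed: int = 0
    augment: bool = True
    depth: int = 2
    base_width: int = 8
    in_channels: int = 1
    n_classes: int = 4

    def __post_init__(self) -> None:
        if self.n_clients < 1 or self.rounds < 0 or self.local_epochs < 0:
            raise ValueError("require K >= 1, T >= 0, E >= 0")
        if self.batch_size < 1 or self.lr <= 0:
            raise ValueError("require batch_size >= 1 and lr > 0")
        if self.strategy not in STRATEGIES:
            raise ValueError(
                f"unknown strategy {self.strategy!r}; valid: {', '.join(sorted(STRATEGIES))}"
            )


class Adam:
    """Adaptive-moment minibatch gradient descent with per-tensor state."""

    def __init__(self, lr: float, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m: Dict[str, np.ndarray] = {}
        self.v: Dict[str, np.ndarray] = {}

    def step(self, model: UNet, grads: Mapping[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for name, g in grads.items():
            if name not in self.m:
                self.m[name] = np.zeros_like(g)
                self.v[name] = np.zeros_like(g)
            self.m[name] = self.beta1 * self.m[name] + (1.0 - self.beta1) * g
            self.v[name] = self.beta2 * self.v[name] + (1.0 - self.beta2) * g * g
            mhat = self.m[name] / b1t
            vhat = self.v[name] / b2t
            model.params[name].values -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


@dataclass
class ClientState:
    """One client: model, optimizer, private dataset, and its own RNG."""

    client_id: int
    model: UNet
    optimizer: Adam
    dataset: PhantomDataset
    rng: np.random.Generator
    seed: int


@dataclass
class FederationHistory:
    """Per-round training/validation trace (lengths all equal T)."""

    r_values: List[float] = field(default_factory=list)
    train_loss: List[List[float]] = field(default_factory=list)  # [round][client]
    val_dsc: List[List[float]] = field(default_factory=list)
    val_assd: List[List[float]] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        """Wide per-round table: one row per round."""
        rows = []
        for t in range(len(self.r_values)):
            row = {"round": t, "r": self.r_values[t]}
            for k, loss in enumerate(self.train_loss[t]):
                row[f"loss_c{k}"] = loss
            for k, v in enumerate(self.val_dsc[t]):
                row[f"val_dsc_c{k}"] = v
            for k, v in enumerate(self.val_assd[t]):
                row[f"val_assd_c{k}"] = v
            rows.append(row)
        return pd.DataFrame(rows)


def _augment_pair(img: np.ndarray, lab: np.ndarray, rng: np.random.Generator):
    """Random rotation (±15°) and horizontal/vertical flips."""
    angle = rng.uniform(-AUGMENT_MAX_ROTATION, AUGMENT_MAX_ROTATION)
    img = ndimage.rotate(img, angle, reshape=False, order=1, mode="nearest")
    lab = ndimage.rotate(lab, angle, reshape=False, order=0, mode="nearest")
    if rng.random() < 0.5:
        img, lab = img[:, ::-1], lab[:, ::-1]
    if rng.random() < 0.5:
        img, lab = img[::-1, :], lab[::-1, :]
    return np.ascontiguousarray(img), np.ascontiguousarray(lab)


def client_update(state: ClientState, shared: Optional[Mapping[str, np.ndarray]],
                  local_epochs: int, batch_size: int = 16,
                  augment: bool = True) -> Tuple[Dict[str, np.ndarray], float]:
    """Run E local epochs and return (trained shared part, mean epoch loss).

    If ``shared`` is given it is merged with the client's personalized
    tensors before training; with E=0 the merged shared part is returned
    unchanged (loss NaN).  Shared tensor names are remembered from the
    ``shared`` mapping; when None, the caller must have tagged the model via
    ``state.shared_names`` set by :func:`init_clients`.
    """
    model = state.model
    if shared is not None:
        model.load_state(dict(shared), partial=True)
        shared_names = list(shared)
    else:
        shared_names = getattr(state, "shared_names", None)
        if shared_names is None:
            raise ValueError("no shared tensor names available for this client")
    images, labels = state.dataset.subset("train")
    if len(images) == 0:
        raise ValueError(f"client {state.client_id} has an empty training set")
    if local_epochs == 0:
        return {n: model.params[n].values.copy() for n in shared_names}, float("nan")
    n_classes = model.n_classes
    losses = []
    for _ in range(local_epochs):
        order = state.rng.permutation(len(images))
        epoch_losses = []
        for start in range(0, len(order), batch_size):
            idx = order[start : start + batch_size]
            batch_img = images[idx]
            batch_lab = labels[idx]
            if augment:
                pairs = [_augment_pair(im, lb, state.rng) for im, lb in zip(batch_img, batch_lab)]
                batch_img = np.stack([p[0] for p in pairs])
                batch_lab = np.stack([p[1] for p in pairs])
            x = batch_img[:, None]  # (N, 1, H, W)
            g = one_hot(batch_lab, n_classes).transpose(1, 0, 2, 3)  # (N, C, H, W)
            logits = model.forward(x, training=True)
            loss, dlogits = fused_loss_and_grad(logits, g, class_axis=1)
            grads = model.backward(dlogits)
            state.optimizer.step(model, grads)
            epoch_losses.append(loss)
        losses.append(float(np.mean(epoch_losses)))
    return {n: model.params[n].values.copy() for n in shared_names}, float(np.mean(losses))


def init_clients(config: RoundConfig, datasets: Sequence[PhantomDataset]) -> List[ClientState]:
    """Broadcast one seeded initial model W0 to K clients over their datasets."""
    if len(datasets) != config.n_clients:
        raise ValueError(f"{len(datasets)} datasets for {config.n_clients} clients")
    w0 = build_unet(config.in_channels, config.n_classes, config.depth,
                    config.base_width, seed=config.base_seed)
    init_state = w0.state()
    partition = classify_parameters(w0, STRATEGIES[config.strategy][0])
    shared_names = sorted(n for n, side in partition.items() if side == "shared")
    states = []
    for k in range(config.n_clients):
        model = build_unet(config.in_channels, config.n_classes, config.depth,
                           config.base_width, seed=config.base_seed)
        model.load_state(init_state)
        st = ClientState(
            client_id=k,
            model=model,
            optimizer=Adam(config.lr),
            dataset=datasets[k],
            rng=np.random.default_rng(config.base_seed + k),
            seed=config.base_seed + k,
        )
        st.shared_names = shared_names  # type: ignore[attr-defined]
        states.append(st)
    return states


def _client_val_metrics(state: ClientState) -> Tuple[float, float]:
    images, labels = state.dataset.subset("val")
    if len(images) == 0:
        return float("nan"), float("nan")
    report = evaluate_clients([state], subset="val")
    return report.mean_dsc(), report.mean_assd()


def run_federation(config: RoundConfig,
                   datasets: Sequence[PhantomDataset]) -> Tuple[List[ClientState], FederationHistory]:
    """Execute T federated rounds and return final clients plus the history."""
    states = init_clients(config, datasets)
    preset, aggregator, attention = STRATEGIES[config.strategy]
    history = FederationHistory()
    incoming = [None] * config.n_clients  # aggregate from the previous round
    for t in range(config.rounds):
        r = r_schedule(t, config.rounds, config.r_mode, config.r_fixed, config.r0, config.r1)
        shared_parts = []
        round_losses = []
        for state in states:  # deterministic id order; aggregate is order-invariant
            # W_k = [W_H^(k,E), W_R-hat]: fuse the incoming shared part, then train
            wr, loss = client_update(state, incoming[state.client_id],
                                     config.local_epochs, config.batch_size,
                                     config.augment)
            shared_parts.append(wr)
            round_losses.append(loss)
        if aggregator == "ffta" and shared_parts[0]:
            incoming = aggregate_round(shared_parts, r, attention_mode=attention)
        elif aggregator == "mean" and shared_parts[0]:
            names = shared_parts[0]
            mean = {
                n: np.mean(np.stack([wr[n] for wr in shared_parts]), axis=0) for n in names
            }
            incoming = [mean for _ in states]
        else:  # 'local' or empty shared set: no communication
            incoming = [None] * config.n_clients
        history.r_values.append(r)
        history.train_loss.append(round_losses)
        # clients are evaluated in their post-update state: E local epochs
        # yield each site's best personalized parameters for this round
        val = [_client_val_metrics(s) for s in states]
        history.val_dsc.append([v[0] for v in val])
        history.val_assd.append([v[1] for v in val])
    return states, history


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------


@dataclass
class MetricsReport:
    """Per-client, per-foreground-class DSC/ASSD with exclusion counts."""

    table: pd.DataFrame  # columns: client, class_id, dsc, assd, dsc_excluded, assd_excluded

    def client_means(self) -> pd.DataFrame:
        return self.table.groupby("client")[["dsc", "assd"]].mean()

    def class_means(self) -> pd.DataFrame:
        return self.table.groupby("class_id")[["dsc", "assd"]].mean()

    def mean_dsc(self) -> float:
        return float(self.client_means()["dsc"].mean())

    def mean_assd(self) -> float:
        return float(self.client_means()["assd"].mean())

    def to_csv(self, path: str) -> None:
        self.table.to_csv(path, index=False)

    def to_json(self, path: str) -> None:
        payload = {
            "per_client_class": self.table.to_dict(orient="records"),
            "client_means": self.client_means().reset_index().to_dict(orient="records"),
            "mean_dsc": self.mean_dsc(),
            "mean_assd": self.mean_assd(),
        }
        import json

        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def predict_labels(model: UNet, images: np.ndarray, batch_size: int = 32) -> np.ndarray:
    """Argmax class predictions in eval mode (client's own BN statistics)."""
    preds = []
    for start in range(0, len(images), batch_size):
        x = images[start : start + batch_size][:, None]
        logits = model.forward(x, training=False)
        preds.append(np.argmax(logits, axis=1))
    return np.concatenate(preds)


def evaluate_clients(states: Sequence[ClientState], subset: str = "test",
                     test_sets: Optional[Sequence[Tuple[np.ndarray, np.ndarray]]] = None
                     ) -> MetricsReport:
    """Per-client, per-class DSC/ASSD on held-out data.

    Metrics are computed per image and averaged over defined entries; a class
    absent from both prediction and truth in an image is excluded, not
    zero-filled.
    """
    rows = []
    for state in states:
        if test_sets is not None:
            images, labels = test_sets[state.client_id]
        else:
            images, labels = state.dataset.subset(subset)
        if len(images) == 0:
            raise ValueError(f"client {state.client_id} has no '{subset}' images")
        preds = predict_labels(state.model, images)
        spacing = state.dataset.spacing
        for cls in range(1, state.model.n_classes):  # foreground classes only
            dscs = [dsc(p, g, cls) for p, g in zip(preds, labels)]
            assds = [assd(p, g, cls, spacing) for p, g in zip(preds, labels)]
            try:
                d_mean, d_excl = class_average(dscs)
            except ValueError:
                d_mean, d_excl = float("nan"), len(dscs)
            try:
                a_mean, a_excl = class_average(assds)
            except ValueError:
                a_mean, a_excl = float("nan"), len(assds)
            rows.append(
                {
                    "client": state.client_id,
                    "class_id": cls,
                    "dsc": d_mean,
                    "assd": a_mean,
                    "dsc_excluded": d_excl,
                    "assd_excluded": a_excl,
                }
            )
    return MetricsReport(pd.DataFrame(rows))


def evaluate_federation(states: Sequence[ClientState],
                        test_sets: Optional[Sequence[Tuple[np.ndarray, np.ndarray]]] = None
                        ) -> MetricsReport:
    """Evaluate every client on its held-out test split (or explicit sets)."""
    return evaluate_clients(states, subset="test", test_sets=test_sets)
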