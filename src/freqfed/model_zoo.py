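"""Small configurable U-Net and its parameter bookkeeping.

The network is a plain 2D U-Net (encoder / decoder / segmentation head) built
directly on numpy: every tensor is a float64 array, the forward pass records
the caches needed for an explicit hand-written backward pass, and batch
normalization keeps per-channel running statistics exactly as

    BN(x) = gamma * (x - mu) / sqrt(sigma^2 + eps) + beta

with a fixed ``eps`` of 1e-5.  Evaluation always uses the model's *own*
running statistics; they are never replaced by batch statistics.

Every tensor of the model — trainable weights and BN statistics alike — is a
:class:`NamedParameter` with a hierarchical name and a *role*.  Roles drive
the personalized/shared partition used by the federation layer: a
:class:`PartitionSpec` preset maps each role to ``"personalized"`` (kept on
the client) or ``"shared"`` (communicated and aggregated).  The presets mirror
the partial-sharing strategies common in personalized federated learning:

``paf_fed``   segmentation head + BN running statistics personalized
``fedavg``    everything shared
``fedbn``     all four BN roles personalized
``silobn``    only BN running statistics personalized
``fedrep``    only the segmentation head personalized
``local``     everything personalized (no communication)

The "fully-connected layers of segmentation map generation" are realized as
the final 1x1 convolution plus bias: a 1x1 conv is a pixel-wise fully
connected layer, and a U-Net has no dense layers.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Tuple

import numpy as np

BN_EPS = 1e-5
BN_MOMENTUM = 0.1

ROLES = (
    "conv_weight",
    "conv_bias",
    "bn_gamma",
    "bn_beta",
    "bn_running_mean",
    "bn_running_var",
    "head_weight",
    "head_bias",
)

#: roles that are statistics, not optimized by gradient descent
STATISTIC_ROLES = frozenset({"bn_running_mean", "bn_running_var"})

PERSONALIZED = "personalized"
SHARED = "shared"

_PRESET_PERSONALIZED_ROLES: Dict[str, frozenset] = {
    "paf_fed": frozenset({"head_weight", "head_bias", "bn_running_mean", "bn_running_var"}),
    "fedavg": frozenset(),
    "fedbn": frozenset({"bn_gamma", "bn_beta", "bn_running_mean", "bn_running_var"}),
    "silobn": frozenset({"bn_running_mean", "bn_running_var"}),
    "fedrep": frozenset({"head_weight", "head_bias"}),
    "local": frozenset(ROLES),
}

PARTITION_PRESETS = tuple(sorted(_PRESET_PERSONALIZED_ROLES))


class PartitionError(ValueError):
    """A parameter set cannot be split or merged consistently."""


@dataclass
class NamedParameter:
    """One tensor of the model: hierarchical name, role, and values."""

    name: str
    role: str
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown parameter role {self.role!r}")
        self.values = np.asarray(self.values, dtype=np.float64)

    @property
    def shape(self) -> Tuple[int, ...]:
        return tuple(self.values.shape)

    @property
    def trainable(self) -> bool:
        return self.role not in STATISTIC_ROLES


@dataclass(frozen=True)
class PartitionSpec:
    """Total assignment of parameter roles to personalized/shared classes."""

    preset: str
    assignment: Mapping[str, str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.assignment is None:
            if self.preset not in _PRESET_PERSONALIZED_ROLES:
                raise ValueError(
                    f"unknown partition preset {self.preset!r}; "
                    f"valid presets: {', '.join(PARTITION_PRESETS)}"
                )
            pers = _PRESET_PERSONALIZED_ROLES[self.preset]
            object.__setattr__(
                self,
                "assignment",
                {role: (PERSONALIZED if role in pers else SHARED) for role in ROLES},
            )
        missing = set(ROLES) - set(self.assignment)
        if missing:
            raise ValueError(f"partition assignment not total; missing roles {sorted(missing)}")

    def side(self, role: str) -> str:
        return self.assignment[role]


# ---------------------------------------------------------------------------
# numpy nn primitives (forward + explicit backward)
# ---------------------------------------------------------------------------


def _conv2d_fwd(x: np.ndarray, w: np.ndarray, b: np.ndarray):
    """'same'-padded stride-1 convolution via im2col.  w: (Cout, Cin, kh, kw)."""
    n, cin, h, wd = x.shape
    cout, _, kh, kw = w.shape
    ph, pw = kh // 2, kw // 2
    xp = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n, h * wd, cin * kh * kw)
    wm = w.reshape(cout, -1)
    y = cols @ wm.T + b
    y = y.transpose(0, 2, 1).reshape(n, cout, h, wd)
    return y, (cols, x.shape, w)


def _conv2d_bwd(dy: np.ndarray, cache):
    cols, xshape, w = cache
    n, cin, h, wd = xshape
    cout, _, kh, kw = w.shape
    dy2 = dy.reshape(n, cout, h * wd).transpose(0, 2, 1)
    dyf = dy2.reshape(n * h * wd, cout)
    dw = (dyf.T @ cols.reshape(n * h * wd, -1)).reshape(w.shape)
    db = dyf.sum(axis=0)
    dcols = (dy2 @ w.reshape(cout, -1)).reshape(n, h, wd, cin, kh, kw)
    ph, pw = kh // 2, kw // 2
    dxp = np.zeros((n, cin, h + 2 * ph, wd + 2 * pw))
    for i in range(kh):
        for j in range(kw):
            dxp[:, :, i : i + h, j : j + wd] += dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
    dx = dxp[:, :, ph : ph + h, pw : pw + wd]
    return dx, dw, db


def _bn_fwd(x, gamma, beta, rmean, rvar, training):
    if training:
        mu = x.mean(axis=(0, 2, 3))
        var = x.var(axis=(0, 2, 3))
        new_stats = (
            (1.0 - BN_MOMENTUM) * rmean + BN_MOMENTUM * mu,
            (1.0 - BN_MOMENTUM) * rvar + BN_MOMENTUM * var,
        )
    else:
        mu, var = rmean, rvar
        new_stats = None
    inv = 1.0 / np.sqrt(var + BN_EPS)
    xhat = (x - mu[None, :, None, None]) * inv[None, :, None, None]
    y = gamma[None, :, None, None] * xhat + beta[None, :, None, None]
    return y, (xhat, gamma, inv), new_stats


def _bn_bwd(dy, cache):
    xhat, gamma, inv = cache
    m = dy.shape[0] * dy.shape[2] * dy.shape[3]
    dgamma = (dy * xhat).sum(axis=(0, 2, 3))
    dbeta = dy.sum(axis=(0, 2, 3))
    dx = (gamma * inv)[None, :, None, None] * (
        dy - dbeta[None, :, None, None] / m - xhat * dgamma[None, :, None, None] / m
    )
    return dx, dgamma, dbeta


def _relu_fwd(x):
    mask = x > 0
    return x * mask, mask


def _relu_bwd(dy, mask):
    return dy * mask


def _maxpool2_fwd(x):
    n, c, h, w = x.shape
    xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
        n, c, h // 2, w // 2, 4
    )
    idx = xr.argmax(axis=-1)
    y = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
    return y, (idx, x.shape)


def _maxpool2_bwd(dy, cache):
    idx, xshape = cache
    n, c, h, w = xshape
    dxr = np.zeros((n, c, h // 2, w // 2, 4))
    np.put_along_axis(dxr, idx[..., None], dy[..., None], axis=-1)
    return dxr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h, w)


def _upsample2_fwd(x):
    return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)


def _upsample2_bwd(dy):
    n, c, h, w = dy.shape
    return dy.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


# ---------------------------------------------------------------------------
# the U-Net
# ---------------------------------------------------------------------------


class UNet:
    """Encoder/decoder U-Net with BN after each convolution and a 1x1 head.

    Downsampling is 2x2 max-pooling, upsampling is nearest-neighbor followed
    by a 3x3 convolution; skip connections concatenate encoder features onto
    the upsampled decoder features.  ``depth`` counts the number of pooling
    stages; input height/width must be divisible by ``2**depth``.

    Construction is fully deterministic in ``seed`` (He fan-in init).
    """

    def __init__(self, in_channels: int = 1, n_classes: int = 2, depth: int = 2,
                 base_width: int = 8, seed: int = 0):
        if in_channels < 1 or n_classes < 2 or depth < 1 or base_width < 4:
            raise ValueError(
                "invalid U-Net configuration: require in_channels >= 1, "
                "n_classes >= 2, depth >= 1, base_width >= 4"
            )
        self.in_channels = int(in_channels)
        self.n_classes = int(n_classes)
        self.depth = int(depth)
        self.base_width = int(base_width)
        self.seed = int(seed)
        self.params: Dict[str, NamedParameter] = {}
        self._cache = None
        self._build(np.random.default_rng(seed))

    # -- construction ------------------------------------------------------

    def _add_conv(self, rng, name: str, cin: int, cout: int, k: int, head: bool = False):
        std = np.sqrt(2.0 / (cin * k * k))
        w = rng.normal(0.0, std, size=(cout, cin, k, k))
        wrole, brole = ("head_weight", "head_bias") if head else ("conv_weight", "conv_bias")
        self.params[f"{name}.weight"] = NamedParameter(f"{name}.weight", wrole, w)
        self.params[f"{name}.bias"] = NamedParameter(f"{name}.bias", brole, np.zeros(cout))

    def _add_bn(self, name: str, c: int):
        self.params[f"{name}.gamma"] = NamedParameter(f"{name}.gamma", "bn_gamma", np.ones(c))
        self.params[f"{name}.beta"] = NamedParameter(f"{name}.beta", "bn_beta", np.zeros(c))
        self.params[f"{name}.running_mean"] = NamedParameter(
            f"{name}.running_mean", "bn_running_mean", np.zeros(c)
        )
        self.params[f"{name}.running_var"] = NamedParameter(
            f"{name}.running_var", "bn_running_var", np.ones(c)
        )

    def _build(self, rng) -> None:
        w = self.base_width
        cin = self.in_channels
        for i in range(self.depth):
            cout = w * (2 ** i)
            self._add_conv(rng, f"enc{i}.conv1", cin, cout, 3)
            self._add_bn(f"enc{i}.bn1", cout)
            self._add_conv(rng, f"enc{i}.conv2", cout, cout, 3)
            self._add_bn(f"enc{i}.bn2", cout)
            cin = cout
        cb = w * (2 ** self.depth)
        self._add_conv(rng, "bottleneck.conv1", cin, cb, 3)
        self._add_bn("bottleneck.bn1", cb)
        self._add_conv(rng, "bottleneck.conv2", cb, cb, 3)
        self._add_bn("bottleneck.bn2", cb)
        cin = cb
        for i in reversed(range(self.depth)):
            cout = w * (2 ** i)
            self._add_conv(rng, f"dec{i}.up", cin, cout, 3)
            self._add_bn(f"dec{i}.upbn", cout)
            self._add_conv(rng, f"dec{i}.conv1", 2 * cout, cout, 3)
            self._add_bn(f"dec{i}.bn1", cout)
            self._add_conv(rng, f"dec{i}.conv2", cout, cout, 3)
            self._add_bn(f"dec{i}.bn2", cout)
            cin = cout
        self._add_conv(rng, "head", cin, self.n_classes, 1, head=True)

    @property
    def config(self) -> Dict[str, int]:
        return {
            "in_channels": self.in_channels,
            "n_classes": self.n_classes,
            "depth": self.depth,
            "base_width": self.base_width,
            "seed": self.seed,
        }

    # -- parameter access --------------------------------------------------

    def named_parameters(self) -> List[NamedParameter]:
        return list(self.params.values())

    def state(self) -> Dict[str, np.ndarray]:
        """Copy of every tensor (weights and BN statistics) by name."""
        return {n: p.values.copy() for n, p in self.params.items()}

    def load_state(self, tensors: Mapping[str, np.ndarray], partial: bool = False) -> None:
        """Load named tensors; a full load must cover every parameter."""
        unknown = set(tensors) - set(self.params)
        if unknown:
            raise PartitionError(f"unknown parameter names {sorted(unknown)[:3]}...")
        if not partial:
            missing = set(self.params) - set(tensors)
            if missing:
                raise PartitionError(f"missing parameter names {sorted(missing)[:3]}...")
        for name, val in tensors.items():
            p = self.params[name]
            val = np.asarray(val, dtype=np.float64)
            if val.shape != p.values.shape:
                raise PartitionError(
                    f"shape mismatch for {name}: {val.shape} vs {p.values.shape}"
                )
            p.values = val.copy()

    # -- forward / backward ------------------------------------------------

    def _unit_fwd(self, x, conv: str, bn: str, training: bool, caches: dict):
        p = self.params
        y, cc = _conv2d_fwd(x, p[f"{conv}.weight"].values, p[f"{conv}.bias"].values)
        y, bc, new_stats = _bn_fwd(
            y,
            p[f"{bn}.gamma"].values,
            p[f"{bn}.beta"].values,
            p[f"{bn}.running_mean"].values,
            p[f"{bn}.running_var"].values,
            training,
        )
        if new_stats is not None:
            p[f"{bn}.running_mean"].values = new_stats[0]
            p[f"{bn}.running_var"].values = new_stats[1]
        y, rm = _relu_fwd(y)
        caches[conv] = (cc, bc, rm)
        return y

    def _unit_bwd(self, dy, conv: str, bn: str, caches: dict, grads: dict):
        cc, bc, rm = caches[conv]
        dy = _relu_bwd(dy, rm)
        dy, dgamma, dbeta = _bn_bwd(dy, bc)
        grads[f"{bn}.gamma"] = dgamma
        grads[f"{bn}.beta"] = dbeta
        dx, dw, db = _conv2d_bwd(dy, cc)
        grads[f"{conv}.weight"] = dw
        grads[f"{conv}.bias"] = db
        return dx

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """Compute class logits at input resolution.

        Accepts ``(H, W)`` single images (``in_channels`` must be 1, returns
        ``(n_classes, H, W)``) or ``(N, Cin, H, W)`` batches (returns
        ``(N, n_classes, H, W)``).
        """
        x = np.asarray(x, dtype=np.float64)
        squeeze = x.ndim == 2
        if squeeze:
            x = x[None, None]
        if x.ndim != 4 or x.shape[1] != self.in_channels:
            raise ValueError(f"expected (N, {self.in_channels}, H, W) input, got {x.shape}")
        h, w = x.shape[2], x.shape[3]
        if h % (2 ** self.depth) or w % (2 ** self.depth):
            raise ValueError(f"input size {h}x{w} not divisible by 2**depth={2 ** self.depth}")

        caches: dict = {}
        skips = []
        for i in range(self.depth):
            x = self._unit_fwd(x, f"enc{i}.conv1", f"enc{i}.bn1", training, caches)
            x = self._unit_fwd(x, f"enc{i}.conv2", f"enc{i}.bn2", training, caches)
            skips.append(x)
            x, pc = _maxpool2_fwd(x)
            caches[f"pool{i}"] = pc
        x = self._unit_fwd(x, "bottleneck.conv1", "bottleneck.bn1", training, caches)
        x = self._unit_fwd(x, "bottleneck.conv2", "bottleneck.bn2", training, caches)
        for i in reversed(range(self.depth)):
            x = _upsample2_fwd(x)
            x = self._unit_fwd(x, f"dec{i}.up", f"dec{i}.upbn", training, caches)
            x = np.concatenate([skips[i], x], axis=1)
            caches[f"split{i}"] = skips[i].shape[1]
            x = self._unit_fwd(x, f"dec{i}.conv1", f"dec{i}.bn1", training, caches)
            x = self._unit_fwd(x, f"dec{i}.conv2", f"dec{i}.bn2", training, caches)
        p = self.params
        logits, hc = _conv2d_fwd(x, p["head.weight"].values, p["head.bias"].values)
        caches["head"] = hc
        self._cache = caches if training else None
        return logits[0] if squeeze else logits

    def backward(self, dlogits: np.ndarray) -> Dict[str, np.ndarray]:
        """Gradients of the loss w.r.t. every trainable tensor.

        Requires a preceding ``forward(..., training=True)`` on the same batch.
        """
        if self._cache is None:
            raise RuntimeError("backward() requires forward(training=True) first")
        caches = self._cache
        grads: Dict[str, np.ndarray] = {}
        if dlogits.ndim == 3:
            dlogits = dlogits[None]
        dx, dw, db = _conv2d_bwd(dlogits, caches["head"])
        grads["head.weight"] = dw
        grads["head.bias"] = db
        dskips = {}
        for i in range(self.depth):
            dx = self._unit_bwd(dx, f"dec{i}.conv2", f"dec{i}.bn2", caches, grads)
            dx = self._unit_bwd(dx, f"dec{i}.conv1", f"dec{i}.bn1", caches, grads)
            c = caches[f"split{i}"]
            dskips[i] = dx[:, :c]
            dx = dx[:, c:]
            dx = self._unit_bwd(dx, f"dec{i}.up", f"dec{i}.upbn", caches, grads)
            dx = _upsample2_bwd(dx)
        dx = self._unit_bwd(dx, "bottleneck.conv2", "bottleneck.bn2", caches, grads)
        dx = self._unit_bwd(dx, "bottleneck.conv1", "bottleneck.bn1", caches, grads)
        for i in reversed(range(self.depth)):
            dx = _maxpool2_bwd(dx, caches[f"pool{i}"])
            dx = dx + dskips[i]
            dx = self._unit_bwd(dx, f"enc{i}.conv2", f"enc{i}.bn2", caches, grads)
            dx = self._unit_bwd(dx, f"enc{i}.conv1", f"enc{i}.bn1", caches, grads)
        self._cache = None
        return grads


def build_unet(in_channels: int, n_classes: int, depth: int = 2, base_width: int = 8,
               seed: int = 0) -> UNet:
    """Build a seeded U-Net; identical arguments yield identical parameters."""
    return UNet(in_channels, n_classes, depth, base_width, seed)


# ---------------------------------------------------------------------------
# partitioning
# ---------------------------------------------------------------------------


def classify_parameters(model: UNet, preset: str) -> Dict[str, str]:
    """Tag every parameter name personalized/shared under a preset."""
    spec = PartitionSpec(preset)
    return {name: spec.side(p.role) for name, p in model.params.items()}


def split_weights(model: UNet, spec: PartitionSpec | str) -> Tuple[Dict[str, np.ndarray], Dict[str, np.ndarray]]:
    """Split the model's tensors into (W_H personalized, W_R shared) maps."""
    if isinstance(spec, str):
        spec = PartitionSpec(spec)
    w_h: Dict[str, np.ndarray] = {}
    w_r: Dict[str, np.ndarray] = {}
    for name, p in model.params.items():
        side = spec.side(p.role)
        (w_h if side == PERSONALIZED else w_r)[name] = p.values.copy()
    return w_h, w_r


def merge_weights(w_h: Mapping[str, np.ndarray], w_r: Mapping[str, np.ndarray]) -> Dict[str, np.ndarray]:
    """Union of disjoint personalized and shared tensor maps."""
    overlap = set(w_h) & set(w_r)
    if overlap:
        raise PartitionError(f"overlapping parameter names {sorted(overlap)[:3]}")
    merged = {n: np.asarray(v) for n, v in w_h.items()}
    merged.update({n: np.asarray(v) for n, v in w_r.items()})
    return merged


# ---------------------------------------------------------------------------
# checkpoint I/O: named-tensor archive + JSON manifest
# ---------------------------------------------------------------------------


def save_checkpoint(model: UNet, path: str) -> None:
    """Write a checkpoint directory: tensors.npz + manifest.json."""
    os.makedirs(path, exist_ok=True)
    arrays = {n: p.values for n, p in model.params.items()}
    np.savez(os.path.join(path, "tensors.npz"), **arrays)
    manifest = {
        "architecture": model.config,
        "tensors": [
            {"name": n, "role": p.role, "shape": list(p.shape), "dtype": str(p.values.dtype)}
            for n, p in model.params.items()
        ],
    }
    with open(os.path.join(path, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)


def load_checkpoint(path: str) -> UNet:
    with open(os.path.join(path, "manifest.json")) as fh:
        manifest = json.load(fh)
    model = UNet(**manifest["architecture"])
    with np.load(os.path.join(path, "tensors.npz")) as npz:
        model.load_state({n: npz[n] for n in npz.files})
    return model
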