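"""Multi-client 2D abdominal-phantom segmentation datasets.

Each client draws images containing up to C-1 elliptical "organs" on a dark
background.  Heterogeneity across clients emulates the two dominant axes of
real multi-site data:

* **label-distribution skew** — each client favors one organ class (high
  prevalence) and rarely sees the others, so per-client class ratios are
  strongly imbalanced;
* **intensity / domain shift** — clients apply different global brightness
  shifts and noise levels, standing in for different scanners or sequences.

A single ``heterogeneity`` knob in [0, 1] interpolates both axes at once:
0 gives identical client profiles, 1 gives strongly skewed prevalences and
clearly separated intensity regimes.  Everything is deterministic in the
seed.  Occasional bright corner blobs emulate acquisition artifacts without
changing the label map.

Images are float in [0, 1]; label maps are exact integer rasters of the
generating ellipses (later-placed organs win on overlap, mimicking adjacent
organ boundaries).  Each dataset carries an 8:1:1 train/val/test split
(floor for val and test, remainder to train).
"""

from __future__ import annotations

import json
import os
import warnings
from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np

DEFAULT_SPACING = (1.0, 1.0)  # mm

#: per-organ major semi-axis ranges (pixels), sized for 32-64 px images
DEFAULT_SIZE_RANGES: Tuple[Tuple[float, float], ...] = ((6.5, 9.5), (6.0, 10.0), (2.5, 4.0))

#: per-organ minor/major axis-ratio ranges: class identity is carried by
#: shape (large round / elongated / small round), as organ intensities in a
#: single modality overlap too much to discriminate classes
DEFAULT_AXIS_RATIOS: Tuple[Tuple[float, float], ...] = ((0.70, 1.0), (0.22, 0.38), (0.70, 1.0))

#: per-class intensity (mean, sd): organs share one intensity band, well
#: separated from background — class identity is carried by shape alone, so
#: the inter-client brightness shift is a pure site nuisance rather than a
#: confound of the class-defining feature
DEFAULT_INTENSITIES: Tuple[Tuple[float, float], ...] = (
    (0.30, 0.04),
    (0.65, 0.07),
    (0.65, 0.07),
    (0.65, 0.07),
)

_PLACEMENT_RETRIES = 6
_OCCLUSION_LIMIT = 0.6  # fraction of an earlier organ a new one may cover


@dataclass
class ClientProfile:
    """Generative profile of one client's data distribution."""

    prevalence: np.ndarray  # P(organ j appears per image), length C-1
    size_ranges: Sequence[Tuple[float, float]]  # major semi-axis range (px) per organ
    axis_ratios: Sequence[Tuple[float, float]] = DEFAULT_AXIS_RATIOS  # minor/major per organ
    intensity: Sequence[Tuple[float, float]] = DEFAULT_INTENSITIES  # (mean, sd) per class
    brightness: float = 0.0  # global additive shift
    contrast: float = 1.0
    noise_sd: float = 0.03
    artifact_prob: float = 0.0  # bright corner blob probability

    def __post_init__(self) -> None:
        self.prevalence = np.asarray(self.prevalence, dtype=np.float64)
        if np.any(self.prevalence < 0) or np.any(self.prevalence > 1):
            raise ValueError("organ prevalences must lie in [0, 1]")
        if any(lo <= 0 or hi < lo for lo, hi in self.size_ranges):
            raise ValueError("organ size ranges must be positive and ordered")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")


@dataclass
class PhantomDataset:
    """Aligned images and label maps for one client, with split tags."""

    images: np.ndarray  # (n, H, W) float in [0, 1]
    labels: np.ndarray  # (n, H, W) int in 0..C-1
    spacing: Tuple[float, float] = DEFAULT_SPACING
    split: np.ndarray = field(default=None)  # type: ignore[assignment]
    n_classes: int = 0

    def __post_init__(self) -> None:
        if self.images.shape != self.labels.shape:
            raise ValueError("images and labels are not aligned")
        if self.n_classes == 0:
            self.n_classes = int(self.labels.max()) + 1
        if self.split is None:
            self.split = split_tags(len(self.images))

    def __len__(self) -> int:
        return len(self.images)

    def subset(self, tag: str) -> Tuple[np.ndarray, np.ndarray]:
        sel = self.split == tag
        return self.images[sel], self.labels[sel]


def split_tags(n: int) -> np.ndarray:
    """8:1:1 split tags: floor(n/10) val and test, remainder train."""
    n_val = n // 10
    n_test = n // 10
    n_train = n - n_val - n_test
    return np.array(["train"] * n_train + ["val"] * n_val + ["test"] * n_test)


def make_profiles(k: int, heterogeneity: float, seed: int, n_organs: int = 3) -> List[ClientProfile]:
    """K client profiles whose divergence scales with ``heterogeneity``.

    At 0 all profiles are identical; at 1 each client strongly favors one
    organ class (round-robin over organs, plus seeded jitter so that clients
    sharing a favored organ still differ) and sits in its own intensity
    regime.  Deterministic in ``seed``.
    """
    if k < 1:
        raise ValueError("need at least one client")
    if not 0.0 <= heterogeneity <= 1.0:
        raise ValueError(f"heterogeneity must be in [0, 1], got {heterogeneity}")
    rng = np.random.default_rng(seed)
    het = float(heterogeneity)
    base_prev = 0.65
    profiles = []
    for i in range(k):
        favored = i % n_organs
        prev = np.full(n_organs, base_prev)
        for j in range(n_organs):
            # geometric interpolation: class ratios across sites differ
            # multiplicatively; the favored organ dominates while the others
            # stay present but uncommon (imbalanced, not absent)
            target = 0.95 if j == favored else 0.30
            prev[j] = np.exp((1.0 - het) * np.log(base_prev) + het * np.log(target))
        prev = np.clip(prev * np.exp(het * rng.uniform(-0.15, 0.15, n_organs)), 0.02, 0.98)
        spread = (i / (k - 1) - 0.5) if k > 1 else 0.0
        brightness = het * (0.35 * spread + rng.normal(0.0, 0.02))
        noise_sd = 0.03 + het * rng.uniform(0.0, 0.02)
        profiles.append(
            ClientProfile(
                prevalence=prev,
                size_ranges=DEFAULT_SIZE_RANGES[:n_organs],
                axis_ratios=DEFAULT_AXIS_RATIOS[:n_organs],
                intensity=DEFAULT_INTENSITIES[: n_organs + 1],
                brightness=brightness,
                noise_sd=noise_sd,
                artifact_prob=0.25 * het,
            )
        )
    return profiles


def _ellipse_mask(h: int, w: int, cy: float, cx: float, a: float, b: float,
                  theta: float) -> np.ndarray:
    yy, xx = np.mgrid[0:h, 0:w]
    dy = yy - cy
    dx = xx - cx
    ct, st = np.cos(theta), np.sin(theta)
    u = dy * ct + dx * st
    v = -dy * st + dx * ct
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def generate_dataset(profile: ClientProfile, n: int, size: Tuple[int, int], n_classes: int,
                     seed: int) -> PhantomDataset:
    """Render ``n`` phantom images for one client; deterministic in ``seed``.

    Each of the C-1 organ classes appears independently with its profile
    prevalence; organs are ellipses with per-class size priors, resolved on
    overlap by z-order (the later class wins).
    """
    if n < 10:
        raise ValueError("need n >= 10 so the 8:1:1 split is non-empty")
    if n_classes < 2:
        raise ValueError("need at least background + 1 organ class")
    if len(profile.prevalence) != n_classes - 1:
        raise ValueError(
            f"profile has {len(profile.prevalence)} organ prevalences, "
            f"expected {n_classes - 1}"
        )
    h, w = size
    rng = np.random.default_rng(seed)
    means = np.array([m for m, _ in profile.intensity])
    sds = np.array([s for _, s in profile.intensity])
    images = np.empty((n, h, w))
    labels = np.zeros((n, h, w), dtype=np.int64)
    warned = False
    for idx in range(n):
        lab = labels[idx]
        for j in range(1, n_classes):
            if rng.random() >= profile.prevalence[j - 1]:
                continue
            lo, hi = profile.size_ranges[j - 1]
            rlo, rhi = profile.axis_ratios[j - 1]
            # organs must fit inside the frame with a 1 px border
            max_ax = min(h, w) / 2.0 - 1.0
            lo, hi = min(lo, max_ax * 0.8), min(hi, max_ax)
            placed = False
            for _ in range(_PLACEMENT_RETRIES):
                a = rng.uniform(lo, hi)
                b = a * rng.uniform(rlo, rhi)
                margin = max(a, b)
                cy = rng.uniform(margin, h - margin)
                cx = rng.uniform(margin, w - margin)
                mask = _ellipse_mask(h, w, cy, cx, a, b, rng.uniform(0, np.pi))
                occludes = False
                for prev_cls in range(1, j):
                    prev_mask = lab == prev_cls
                    npix = prev_mask.sum()
                    if npix and (mask & prev_mask).sum() > _OCCLUSION_LIMIT * npix:
                        occludes = True
                        break
                if not occludes:
                    placed = True
                    break
            if not placed and not warned:
                warnings.warn("organ placement retry budget exhausted; accepting overlap")
                warned = True
            lab[mask] = j  # z-order: later organ wins
        img = means[lab] + rng.normal(0.0, 1.0, (h, w)) * sds[lab]
        img = profile.contrast * (img - 0.5) + 0.5 + profile.brightness
        img += rng.normal(0.0, profile.noise_sd, (h, w))
        if rng.random() < profile.artifact_prob:
            # bright blob near a random corner, label map untouched
            cy = rng.choice([h * 0.15, h * 0.85])
            cx = rng.choice([w * 0.15, w * 0.85])
            yy, xx = np.mgrid[0:h, 0:w]
            blob = np.exp(-(((yy - cy) ** 2 + (xx - cx) ** 2) / (2.0 * (0.06 * h) ** 2)))
            img += 0.5 * blob
        images[idx] = np.clip(img, 0.0, 1.0)
    return PhantomDataset(images=images, labels=labels, spacing=DEFAULT_SPACING,
                          split=split_tags(n), n_classes=n_classes)


def make_federation_data(k: int, heterogeneity: float, n_per_client: int,
                         size: Tuple[int, int], n_classes: int,
                         seed: int) -> Tuple[List[ClientProfile], List[PhantomDataset]]:
    """Profiles plus one disjoint dataset per client (seeds offset by client id)."""
    profiles = make_profiles(k, heterogeneity, seed, n_organs=n_classes - 1)
    datasets = [
        generate_dataset(p, n_per_client, size, n_classes, seed=seed + 1000 * (i + 1))
        for i, p in enumerate(profiles)
    ]
    return profiles, datasets


# ---------------------------------------------------------------------------
# PNG export / import (optional real-slice ingestion lives in cli_io)
# ---------------------------------------------------------------------------


def export_png(dataset: PhantomDataset, path: str) -> None:
    """Write image/label PNG pairs plus a JSON manifest."""
    import imageio.v3 as iio

    os.makedirs(path, exist_ok=True)
    entries = []
    for i in range(len(dataset)):
        img_name, lab_name = f"img_{i:04d}.png", f"lab_{i:04d}.png"
        iio.imwrite(os.path.join(path, img_name),
                    (dataset.images[i] * 255).round().astype(np.uint8))
        iio.imwrite(os.path.join(path, lab_name), dataset.labels[i].astype(np.uint8))
        entries.append({"image": img_name, "label": lab_name, "split": str(dataset.split[i])})
    manifest = {
        "n_classes": dataset.n_classes,
        "spacing": list(dataset.spacing),
        "items": entries,
    }
    with open(os.path.join(path, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)


def import_nifti_slices(image_paths: Sequence[str], label_paths: Sequence[str],
                        n_classes: int = 0) -> PhantomDataset:
    """Build a dataset from single-slice NIfTI image/label pairs.

    Each file must hold one 2D slice (trailing singleton dimensions are
    squeezed).  Images are min-max scaled to [0, 1] jointly; the pixel
    spacing is taken from the first image's header.
    """
    import nibabel as nib

    if len(image_paths) != len(label_paths):
        raise ValueError("image and label path lists differ in length")
    images, labels = [], []
    spacing = DEFAULT_SPACING
    for i, (ip, lp) in enumerate(zip(image_paths, label_paths)):
        img_nii = nib.load(ip)
        img = np.squeeze(np.asarray(img_nii.dataobj, dtype=np.float64))
        lab = np.squeeze(np.asarray(nib.load(lp).dataobj)).astype(np.int64)
        if img.ndim != 2 or lab.shape != img.shape:
            raise ValueError(f"{ip}: expected aligned single 2D slices")
        if i == 0:
            zooms = img_nii.header.get_zooms()[:2]
            spacing = (float(zooms[0]), float(zooms[1]))
        images.append(img)
        labels.append(lab)
    stack = np.stack(images)
    lo, hi = stack.min(), stack.max()
    if hi > lo:
        stack = (stack - lo) / (hi - lo)
    return PhantomDataset(images=stack, labels=np.stack(labels), spacing=spacing,
                          split=split_tags(len(images)),
                          n_classes=n_classes or int(np.stack(labels).max()) + 1)


def import_png(path: str) -> PhantomDataset:
    """Read a dataset previously written by :func:`export_png`."""
    import imageio.v3 as iio

    with open(os.path.join(path, "manifest.json")) as fh:
        manifest = json.load(fh)
    images, labels, tags = [], [], []
    for item in manifest["items"]:
        images.append(np.asarray(iio.imread(os.path.join(path, item["image"]))) / 255.0)
        labels.append(np.asarray(iio.imread(os.path.join(path, item["label"]))).astype(np.int64))
        tags.append(item["split"])
    return PhantomDataset(
        images=np.stack(images),
        labels=np.stack(labels),
        spacing=tuple(manifest["spacing"]),
        split=np.array(tags),
        n_classes=int(manifest["n_classes"]),
    )
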