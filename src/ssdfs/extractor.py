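"""Attention-aided VGG16-style deep-feature extractor, in pure numpy.

The model mirrors the classification head used for mammogram patches: a frozen
VGG16 convolution stack (13 conv layers of 3x3 filters, 5 max-pools), a 1x1
locally connected attention branch whose sigmoid map weights a global average
pool (weighted GAP, renormalized by the attention mass), dropout(0.5), a dense
128-unit bottleneck, dropout(0.25) and a 1-unit sigmoid head trained with
binary cross-entropy and Adam.  The bottleneck activations are the "deep
features" consumed by the feature selector.

Both forward and backward passes are implemented directly on numpy arrays;
the backbone is frozen, so training touches only the attention and head
parameters and the backbone activations can be cached per image.  Pretrained
ImageNet backbone weights may be loaded from an ``.npz`` if available;
otherwise the backbone uses seeded He-initialized random weights, which is
sufficient for every structural contract the extractor must satisfy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .tabular import LabeledTable

logger = logging.getLogger(__name__)

__all__ = [
    "ExtractorConfig",
    "DeepFeatureBatch",
    "AttentionVGG16",
    "weighted_gap",
    "build_extractor",
    "extract_features",
    "load_images_dir",
]

# VGG16 convolution plan: channels per 3x3 conv layer, 'M' = 2x2 max-pool
_VGG16_PLAN = (64, 64, "M", 128, 128, "M", 256, 256, 256, "M",
               512, 512, 512, "M", 512, 512, 512, "M")


@dataclass(frozen=True)
class ExtractorConfig:
    """Architecture and training settings.

    ``width_multiplier`` scales every conv layer's channel count (1.0 = the
    full VGG16 widths); the bottleneck stays at ``feature_dim`` regardless.
    """

    input_height: int = 299
    input_width: int = 299
    feature_dim: int = 128
    dropout_rates: tuple[float, float] = (0.5, 0.25)
    backbone_frozen: bool = True
    batch_size: int = 64
    initial_learning_rate: float = 1e-2
    optimizer_name: str = "Adam"
    loss_name: str = "binary_crossentropy"
    lr_halving_epoch: int = 3
    width_multiplier: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.feature_dim < 1:
            raise ValueError("feature_dim must be >= 1")
        if not all(0.0 <= r < 1.0 for r in self.dropout_rates):
            raise ValueError("dropout rates must lie in [0, 1)")
        if min(self.input_height, self.input_width) < 32:
            raise ValueError("input must be >= 32 px (five 2x2 pools)")


@dataclass
class DeepFeatureBatch:
    """Extracted features, one row per image, plus optional labels."""

    features: np.ndarray
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.features).all():
            raise ValueError("non-finite feature values")

    def to_table(self) -> LabeledTable:
        if self.labels is None:
            raise ValueError("labels required to build a LabeledTable")
        names = [f"deep_{j}" for j in range(self.features.shape[1])]
        return LabeledTable(self.features, self.labels, names)


def weighted_gap(feature_maps: np.ndarray, attention_map: np.ndarray) -> np.ndarray:
    """Attention-weighted spatial average per channel.

    ``out_c = sum_hw a_hw * f_hwc / sum_hw a_hw``; invariant under positive
    rescaling of the attention map, and equal to plain GAP when the map is
    uniform.  An identically-zero map leaves the average undefined and raises.
    """
    f = np.asarray(feature_maps, dtype=float)
    a = np.asarray(attention_map, dtype=float)
    if a.ndim == 3 and a.shape[-1] == 1:
        a = a[..., 0]
    if a.shape != f.shape[:2]:
        raise ValueError("attention map must match the spatial grid")
    if (a < 0).any():
        raise ValueError("attention weights must be nonnegative")
    mass = a.sum()
    if mass == 0:
        raise ValueError("all-zero attention map: weighted average undefined")
    return np.tensordot(a, f, axes=([0, 1], [0, 1])) / mass


def _sigmoid(x):
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def _relu(x):
    return np.maximum(x, 0.0)


def _conv3x3_relu(x: np.ndarray, W: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Same-padded 3x3 convolution + ReLU.  x: (H, W, Cin); W: (3,3,Cin,Cout)."""
    H, Wd, Cin = x.shape
    xp = np.pad(x, ((1, 1), (1, 1), (0, 0)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(0, 1))
    # win: (H, W, Cin, 3, 3) -> (H*W, 3*3*Cin) matching W.reshape(-1, Cout)
    cols = win.transpose(0, 1, 3, 4, 2).reshape(H * Wd, 9 * Cin)
    out = cols @ W.reshape(9 * Cin, -1) + b
    return _relu(out.reshape(H, Wd, -1))


def _maxpool2(x: np.ndarray) -> np.ndarray:
    H, W, C = x.shape
    H2, W2 = H // 2, W // 2
    return x[: H2 * 2, : W2 * 2].reshape(H2, 2, W2, 2, C).max(axis=(1, 3))


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float):
        self.lr = lr
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray],
             b1=0.9, b2=0.999, eps=1e-8) -> None:
        self.t += 1
        for k, g in grads.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + eps)


class AttentionVGG16:
    """Frozen VGG16-style backbone with an attention-weighted-GAP head."""

    def __init__(self, cfg: ExtractorConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        self._train_rng = np.random.default_rng(
            np.random.SeedSequence(cfg.seed).spawn(1)[0]
        )
        self.backbone: list[tuple[np.ndarray, np.ndarray] | str] = []
        c_in = 3
        for item in _VGG16_PLAN:
            if item == "M":
                self.backbone.append("M")
                continue
            c_out = max(1, int(round(item * cfg.width_multiplier)))
            W = rng.standard_normal((3, 3, c_in, c_out)) * np.sqrt(2.0 / (9 * c_in))
            self.backbone.append((W, np.zeros(c_out)))
            c_in = c_out
        self.backbone_channels = c_in
        gh = cfg.input_height // 32
        gw = cfg.input_width // 32
        self.grid = (gh, gw)
        self.params: dict[str, np.ndarray] = {
            # locally connected 1x1 attention: independent weights per position
            "Wa": rng.standard_normal((gh, gw, c_in)) * np.sqrt(1.0 / c_in),
            "ba": np.zeros((gh, gw)),
            "W1": rng.standard_normal((c_in, cfg.feature_dim)) * np.sqrt(2.0 / c_in),
            "b1": np.zeros(cfg.feature_dim),
            "w2": rng.standard_normal((cfg.feature_dim, 1)) * np.sqrt(2.0 / cfg.feature_dim),
            "b2": np.zeros(1),
        }
        self._adam = _Adam(self.params, cfg.initial_learning_rate)

    # ---------------- preprocessing ----------------

    def _prepare(self, images: np.ndarray) -> np.ndarray:
        x = np.asarray(images, dtype=float)
        if x.ndim == 3:  # grayscale -> replicate to 3 channels
            x = np.repeat(x[..., None], 3, axis=-1)
        if x.ndim != 4 or x.shape[-1] != 3:
            raise ValueError("images must be (n, H, W) or (n, H, W, 3)")
        H, W = self.cfg.input_height, self.cfg.input_width
        if x.shape[1:3] != (H, W):
            from scipy.ndimage import zoom

            logger.info("resampling images %s -> %s", x.shape[1:3], (H, W))
            zh, zw = H / x.shape[1], W / x.shape[2]
            x = np.stack([zoom(im, (zh, zw, 1), order=1) for im in x])
        return x

    def backbone_forward(self, images: np.ndarray) -> np.ndarray:
        """Frozen conv stack; returns feature maps (n, H/32, W/32, C)."""
        x = self._prepare(images)
        outs = []
        for im in x:
            a = im
            for layer in self.backbone:
                a = _maxpool2(a) if layer == "M" else _conv3x3_relu(a, *layer)
            outs.append(a)
        return np.stack(outs)

    # ---------------- head ----------------

    def _head_forward(self, F: np.ndarray, training: bool):
        p = self.params
        s = np.einsum("nhwc,hwc->nhw", F, p["Wa"]) + p["ba"]
        a = _sigmoid(s)
        mass = a.sum(axis=(1, 2), keepdims=True)
        pooled = np.einsum("nhw,nhwc->nc", a, F) / mass[:, :, 0]
        r1, r2 = self.cfg.dropout_rates
        if training:
            d1 = (self._train_rng.random(pooled.shape) >= r1) / (1 - r1)
            pdrop = pooled * d1
        else:
            d1 = None
            pdrop = pooled
        z = pdrop @ p["W1"] + p["b1"]
        feat = _relu(z)
        if training:
            d2 = (self._train_rng.random(feat.shape) >= r2) / (1 - r2)
            rdrop = feat * d2
        else:
            d2 = None
            rdrop = feat
        u = rdrop @ p["w2"] + p["b2"]
        yhat = _sigmoid(u)[:, 0]
        cache = dict(F=F, a=a, mass=mass[:, 0, 0], pooled=pooled, d1=d1,
                     pdrop=pdrop, z=z, feat=feat, d2=d2, rdrop=rdrop, yhat=yhat)
        return cache

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        """Sigmoid head output in (0, 1), inference mode (dropout off)."""
        return self._head_forward(self.backbone_forward(images), training=False)["yhat"]

    def features(self, images: np.ndarray) -> np.ndarray:
        """Bottleneck activations (n, feature_dim), inference mode."""
        return self._head_forward(self.backbone_forward(images), training=False)["feat"]

    # ---------------- training ----------------

    def _head_gradients(self, cache: dict, y: np.ndarray) -> dict[str, np.ndarray]:
        p = self.params
        n = y.size
        du = (cache["yhat"] - y)[:, None] / n  # BCE + sigmoid
        grads = {
            "w2": cache["rdrop"].T @ du,
            "b2": du.sum(axis=0),
        }
        dr = du @ p["w2"].T
        if cache["d2"] is not None:
            dr = dr * cache["d2"]
        dz = dr * (cache["z"] > 0)
        grads["W1"] = cache["pdrop"].T @ dz
        grads["b1"] = dz.sum(axis=0)
        dp = dz @ p["W1"].T
        if cache["d1"] is not None:
            dp = dp * cache["d1"]
        F, a, pooled = cache["F"], cache["a"], cache["pooled"]
        # d pooled_c / d a_hw = (F_hwc - pooled_c) / mass
        da = np.einsum("nc,nhwc->nhw", dp, F - pooled[:, None, None, :])
        da = da / cache["mass"][:, None, None]
        ds = da * a * (1.0 - a)
        grads["Wa"] = np.einsum("nhw,nhwc->hwc", ds, F)
        grads["ba"] = ds.sum(axis=0)
        return grads

    def train_step(self, images: np.ndarray, labels: np.ndarray,
                   feature_maps: np.ndarray | None = None) -> float:
        """One Adam step on the head (backbone untouched); returns the BCE loss."""
        y = np.asarray(labels, dtype=float)
        F = self.backbone_forward(images) if feature_maps is None else feature_maps
        cache = self._head_forward(F, training=True)
        eps = 1e-12
        loss = -np.mean(
            y * np.log(cache["yhat"] + eps) + (1 - y) * np.log(1 - cache["yhat"] + eps)
        )
        self._adam.step(self.params, self._head_gradients(cache, y))
        return float(loss)

    def fit(self, images: np.ndarray, labels: np.ndarray, epochs: int = 2) -> list[float]:
        """Mini-batch training of the head; the learning rate halves after
        ``lr_halving_epoch`` epochs.  Backbone activations are cached once.
        """
        F_all = self.backbone_forward(images)
        y = np.asarray(labels, dtype=float)
        n = y.size
        losses = []
        for epoch in range(epochs):
            if epoch == self.cfg.lr_halving_epoch:
                self._adam.lr /= 2.0
            order = self._train_rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, self.cfg.batch_size):
                idx = order[start:start + self.cfg.batch_size]
                cache = self._head_forward(F_all[idx], training=True)
                eps = 1e-12
                yh = cache["yhat"]
                epoch_loss += -np.sum(
                    y[idx] * np.log(yh + eps) + (1 - y[idx]) * np.log(1 - yh + eps)
                )
                self._adam.step(self.params, self._head_gradients(cache, y[idx]))
            losses.append(epoch_loss / n)
        return losses

    def load_backbone_weights(self, path) -> None:
        """Load conv weights from an ``.npz`` with arrays W0,b0,W1,b1,..."""
        data = np.load(path)
        i = 0
        for li, layer in enumerate(self.backbone):
            if layer == "M":
                continue
            W, b = data[f"W{i}"], data[f"b{i}"]
            if W.shape != layer[0].shape:
                raise ValueError(f"conv layer {i}: shape {W.shape} != {layer[0].shape}")
            self.backbone[li] = (W.astype(float), b.astype(float))
            i += 1


def build_extractor(cfg: ExtractorConfig = ExtractorConfig()) -> AttentionVGG16:
    """Construct the attention-aided extractor (random seeded backbone weights)."""
    return AttentionVGG16(cfg)


def extract_features(
    model: AttentionVGG16, images: np.ndarray, labels=None
) -> DeepFeatureBatch:
    """Deterministic inference-mode feature extraction (dropout disabled)."""
    images = np.asarray(images, dtype=float)
    if images.size == 0:
        raise ValueError("empty image batch")
    feats = model.features(images)
    lab = None if labels is None else np.asarray(labels, dtype=int)
    return DeepFeatureBatch(feats, lab)


def load_images_dir(directory) -> tuple[np.ndarray, np.ndarray | None, list[str]]:
    """Read all PNGs in a directory into a grayscale float batch in [0, 1].

    Labels are parsed from ``_y<digit>`` filename suffixes when every file has
    one; non-image files are skipped with a warning.
    """
    import re
    from pathlib import Path

    from PIL import Image, UnidentifiedImageError

    paths = sorted(Path(directory).iterdir())
    images, names, labels = [], [], []
    for p in paths:
        if not p.is_file():
            continue
        try:
            with Image.open(p) as im:
                arr = np.asarray(im.convert("F"), dtype=float)
        except (UnidentifiedImageError, OSError):
            logger.warning("skipping non-image file %s", p)
            continue
        if arr.max() > 1.0:
            arr = arr / 255.0
        images.append(arr)
        names.append(p.name)
        m = re.search(r"_y(\d)", p.stem)
        labels.append(int(m.group(1)) if m else None)
    if not images:
        raise ValueError(f"no readable images in {directory}")
    batch = np.stack(images)
    lab = np.array(labels, dtype=int) if all(l is not None for l in labels) else None
    return batch, lab, names
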