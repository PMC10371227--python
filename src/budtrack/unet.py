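"""A compact multi-target U-net, implemented directly in NumPy.

The network maps a bright-field Z-stack (1 or 5 sections, presented as
input channels) to the 8-channel semantic probability stack defined in
:mod:`budtrack.targets`.  It is a standard encoder-decoder with skip
connections: ``depth`` resolution levels, two 3x3 conv + ReLU blocks per
level, 2x2 max-pooling down, nearest-neighbour upsampling up, and a final
1x1 convolution with per-channel sigmoids.  Training minimises per-channel
weighted binary cross-entropy with Adam.

The implementation favours clarity and determinism over speed: im2col
convolutions as matrix products, explicit backward passes, and a single
seeded RNG for initialisation and shuffling, so a fixed seed reproduces
training bit-for-bit.  At the default size (depth 4, 8 base filters,
64x64 tiles) it trains on a few hundred images in minutes on one CPU.

``oracle_predict`` provides an idealised stand-in for a trained network:
it emits the ground-truth target stack as probabilities, optionally
softened with a Gaussian halo, so the downstream segmentation and
tracking stages can be exercised and benchmarked independently of
training.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import ndimage
from scipy.special import expit

from .simulate import AnnotatedFrame
from .targets import SizeCategorySpec, build_target_stack


@dataclass
class UNetConfig:
    depth: int = 4  # resolution levels
    base_filters: int = 8
    in_sections: int = 5
    out_channels: int = 8
    channel_weights: Tuple[float, ...] = (1, 1, 1, 1, 1, 1, 1, 2)
    epochs: int = 3
    batch_size: int = 1
    learning_rate: float = 3e-3
    pos_weight: float = 3.0  # up-weight foreground pixels (class imbalance)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth < 2:
            raise ValueError("depth must be >= 2")
        if self.out_channels != 8:
            raise ValueError("the semantic stack has 8 channels")
        if self.in_sections not in (1, 5):
            raise ValueError("in_sections must be 1 or 5")
        if len(self.channel_weights) != self.out_channels:
            raise ValueError("one loss weight per output channel")


# ---------------------------------------------------------------------------
# layers


def _conv_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> tuple:
    """3x3 same-padding convolution.  x: (N,C,H,W); w: (F,C,3,3); b: (F,)."""
    n, c, h, wd = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    cols = sliding_window_view(xp, (3, 3), axis=(2, 3))  # (N,C,H,W,3,3)
    cols = cols.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * wd, c * 9)
    wmat = w.reshape(w.shape[0], -1).T  # (C*9, F)
    out = cols @ wmat + b
    out = out.reshape(n, h, wd, -1).transpose(0, 3, 1, 2)
    return out, (cols, x.shape, w)


def _conv_backward(dout: np.ndarray, cache) -> tuple:
    cols, xshape, w = cache
    n, c, h, wd = xshape
    f = w.shape[0]
    dmat = dout.transpose(0, 2, 3, 1).reshape(n * h * wd, f)
    dw = (cols.T @ dmat).T.reshape(w.shape)
    db = dmat.sum(axis=0)
    # dx: correlate dout with spatially flipped kernels, swapping F<->C
    wflip = w[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)  # (C,F,3,3)
    dp = np.pad(dout, ((0, 0), (0, 0), (1, 1), (1, 1)))
    dcols = sliding_window_view(dp, (3, 3), axis=(2, 3))
    dcols = dcols.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * wd, f * 9)
    dx = dcols @ wflip.reshape(c, -1).T
    dx = dx.reshape(n, h, wd, c).transpose(0, 3, 1, 2)
    return dx, dw, db


def _conv1x1_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> tuple:
    out = np.einsum("nchw,fc->nfhw", x, w) + b[None, :, None, None]
    return out, (x, w)


def _conv1x1_backward(dout: np.ndarray, cache) -> tuple:
    x, w = cache
    dw = np.einsum("nfhw,nchw->fc", dout, x)
    db = dout.sum(axis=(0, 2, 3))
    dx = np.einsum("nfhw,fc->nchw", dout, w)
    return dx, dw, db


def _pool_forward(x: np.ndarray) -> tuple:
    n, c, h, w = x.shape
    xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
    out = xr.max(axis=(3, 5))
    mask = xr == out[:, :, :, None, :, None]
    return out, (mask, x.shape)


def _pool_backward(dout: np.ndarray, cache) -> np.ndarray:
    mask, xshape = cache
    n, c, h, w = xshape
    d = dout[:, :, :, None, :, None] * mask
    return d.reshape(n, c, h, w)


def _upsample_forward(x: np.ndarray) -> np.ndarray:
    return x.repeat(2, axis=2).repeat(2, axis=3)


def _upsample_backward(dout: np.ndarray) -> np.ndarray:
    n, c, h, w = dout.shape
    return dout.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class UNet:
    """Four-level (by default) multi-target U-net; see module docstring."""

    def __init__(self, config: UNetConfig):
        self.config = config
        self.rng = np.random.default_rng(config.seed)
        f = [config.base_filters * 2**i for i in range(config.depth)]
        self.filters = f
        self.params: Dict[str, np.ndarray] = {}
        cin = config.in_sections
        for lvl, nf in enumerate(f):  # encoder double-conv blocks
            self._add_conv(f"enc{lvl}a", cin, nf)
            self._add_conv(f"enc{lvl}b", nf, nf)
            cin = nf
        for lvl in range(config.depth - 2, -1, -1):  # decoder
            self._add_conv(f"up{lvl}", f[lvl + 1], f[lvl])
            self._add_conv(f"dec{lvl}a", 2 * f[lvl], f[lvl])
            self._add_conv(f"dec{lvl}b", f[lvl], f[lvl])
        self.params["head_w"] = self.rng.normal(
            0.0, np.sqrt(2.0 / f[0]), size=(config.out_channels, f[0])
        )
        self.params["head_b"] = np.zeros(config.out_channels)
        self._adam_m = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_v = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_t = 0

    def _add_conv(self, name: str, cin: int, cout: int) -> None:
        scale = np.sqrt(2.0 / (cin * 9))
        self.params[f"{name}_w"] = self.rng.normal(0.0, scale, size=(cout, cin, 3, 3))
        self.params[f"{name}_b"] = np.zeros(cout)

    # -- forward / backward -------------------------------------------------

    def _pad_to_grid(self, x: np.ndarray) -> tuple:
        m = 2 ** (self.config.depth - 1)
        h, w = x.shape[-2:]
        ph, pw = (-h) % m, (-w) % m
        if ph or pw:
            x = np.pad(x, ((0, 0), (0, 0), (0, ph), (0, pw)), mode="reflect")
        return x, (h, w)

    def forward(self, x: np.ndarray, want_cache: bool = False):
        cfg = self.config
        x = np.asarray(x, dtype=np.float64)
        if x.ndim == 3:
            x = x[None]
        x, (h0, w0) = self._pad_to_grid(x)
        cache: Dict[str, object] = {"hw": (h0, w0)}
        skips = []
        a = x
        for lvl in range(cfg.depth):
            for blk in "ab":
                z, cv = _conv_forward(
                    a, self.params[f"enc{lvl}{blk}_w"], self.params[f"enc{lvl}{blk}_b"]
                )
                a = np.maximum(z, 0.0)
                cache[f"enc{lvl}{blk}"] = (cv, z > 0)
            if lvl < cfg.depth - 1:
                skips.append(a)
                a, pc = _pool_forward(a)
                cache[f"pool{lvl}"] = pc
        for lvl in range(cfg.depth - 2, -1, -1):
            a = _upsample_forward(a)
            z, cv = _conv_forward(a, self.params[f"up{lvl}_w"], self.params[f"up{lvl}_b"])
            a = np.maximum(z, 0.0)
            cache[f"up{lvl}"] = (cv, z > 0)
            a = np.concatenate([skips[lvl], a], axis=1)
            for blk in "ab":
                z, cv = _conv_forward(
                    a, self.params[f"dec{lvl}{blk}_w"], self.params[f"dec{lvl}{blk}_b"]
                )
                a = np.maximum(z, 0.0)
                cache[f"dec{lvl}{blk}"] = (cv, z > 0)
        logits, hc = _conv1x1_forward(a, self.params["head_w"], self.params["head_b"])
        cache["head"] = hc
        logits = logits[:, :, :h0, :w0]
        probs = expit(logits)
        if want_cache:
            return probs, logits, cache
        return probs

    def backward(self, dlogits: np.ndarray, cache) -> Dict[str, np.ndarray]:
        """Full backward pass returning parameter gradients."""
        cfg = self.config
        grads: Dict[str, np.ndarray] = {}
        h0, w0 = cache["hw"]
        full_h = cache["head"][0].shape[2]
        full_w = cache["head"][0].shape[3]
        d = np.zeros((dlogits.shape[0], cfg.out_channels, full_h, full_w))
        d[:, :, :h0, :w0] = dlogits
        d, grads["head_w"], grads["head_b"] = _conv1x1_backward(d, cache["head"])
        skip_grads: Dict[int, np.ndarray] = {}
        # decoder: gradient flows from level 0 (output) up to the bottleneck
        for lvl in range(cfg.depth - 1):
            for blk in "ba":
                cv, relu = cache[f"dec{lvl}{blk}"]
                d, grads[f"dec{lvl}{blk}_w"], grads[f"dec{lvl}{blk}_b"] = _conv_backward(
                    d * relu, cv
                )
            nskip = self.filters[lvl]
            skip_grads[lvl] = d[:, :nskip]
            d = d[:, nskip:]
            cv, relu = cache[f"up{lvl}"]
            d, grads[f"up{lvl}_w"], grads[f"up{lvl}_b"] = _conv_backward(d * relu, cv)
            d = _upsample_backward(d)
        # encoder: from the bottleneck back to the input, merging skip grads
        for lvl in range(cfg.depth - 1, -1, -1):
            if lvl < cfg.depth - 1:
                d = _pool_backward(d, cache[f"pool{lvl}"])
                d = d + skip_grads[lvl]
            for blk in "ba":
                cv, relu = cache[f"enc{lvl}{blk}"]
                d, grads[f"enc{lvl}{blk}_w"], grads[f"enc{lvl}{blk}_b"] = _conv_backward(
                    d * relu, cv
                )
        return grads

    def _adam_step(self, grads: Dict[str, np.ndarray]) -> None:
        self._adam_t += 1
        lr, b1, b2, eps = self.config.learning_rate, 0.9, 0.999, 1e-8
        t = self._adam_t
        for k, g in grads.items():
            self._adam_m[k] = b1 * self._adam_m[k] + (1 - b1) * g
            self._adam_v[k] = b2 * self._adam_v[k] + (1 - b2) * g * g
            mhat = self._adam_m[k] / (1 - b1**t)
            vhat = self._adam_v[k] / (1 - b2**t)
            self.params[k] -= lr * mhat / (np.sqrt(vhat) + eps)

    # -- loss ---------------------------------------------------------------

    def loss_and_grad(self, x: np.ndarray, y: np.ndarray):
        """Weighted per-channel BCE and its gradient w.r.t. parameters."""
        probs, logits, cache = self.forward(x, want_cache=True)
        y = np.asarray(y, dtype=np.float64)
        if y.ndim == 3:
            y = y[None]
        w = np.asarray(self.config.channel_weights, dtype=np.float64)[None, :, None, None]
        a = self.config.pos_weight
        eps = 1e-12
        npix = probs.shape[0] * probs.shape[2] * probs.shape[3]
        loss = -np.sum(
            w * (a * y * np.log(probs + eps) + (1 - y) * np.log(1 - probs + eps))
        ) / (npix * w.sum())
        dlogits = w * (probs * (1 + (a - 1) * y) - a * y) / (npix * w.sum())
        grads = self.backward(dlogits, cache)
        return float(loss), grads

    def evaluate_loss(self, images: Sequence[np.ndarray], targets: Sequence[np.ndarray]) -> float:
        losses = []
        for x, y in zip(images, targets):
            probs = self.forward(x)
            y_ = np.asarray(y, dtype=np.float64)[None]
            w = np.asarray(self.config.channel_weights)[None, :, None, None]
            eps = 1e-12
            npix = probs.shape[0] * probs.shape[2] * probs.shape[3]
            a = self.config.pos_weight
            losses.append(
                float(
                    -np.sum(
                        w
                        * (
                            a * y_ * np.log(probs + eps)
                            + (1 - y_) * np.log(1 - probs + eps)
                        )
                    )
                    / (npix * w.sum())
                )
            )
        return float(np.mean(losses))


def build_unet(config: UNetConfig) -> UNet:
    """Construct a seeded, untrained U-net."""
    return UNet(config)


def train_unet(
    model: UNet,
    images: Sequence[np.ndarray],
    targets: Sequence[np.ndarray],
    config: Optional[UNetConfig] = None,
    groups: Optional[Sequence[int]] = None,
    val_fraction: float = 0.2,
) -> Tuple[UNet, Dict[str, List[float]]]:
    """Train in place; returns the model and a loss history.

    ``groups`` (e.g. colony or trap identities) controls the train/val
    split: whole groups are held out, never individual frames, so the
    validation set is independent of the training colonies.
    """
    cfg = config or model.config
    if len(images) == 0:
        raise ValueError("empty training set")
    images = [np.asarray(im, dtype=np.float64) for im in images]
    targets = [np.asarray(tg, dtype=np.float64) for tg in targets]
    n = len(images)
    if groups is None:
        groups = list(range(n))
    uniq = sorted(set(groups))
    rng = np.random.default_rng(cfg.seed + 1)
    val_groups = set(
        rng.choice(uniq, size=max(1, int(round(val_fraction * len(uniq)))), replace=False)
        if len(uniq) > 1
        else []
    )
    tr_idx = [i for i in range(n) if groups[i] not in val_groups]
    va_idx = [i for i in range(n) if groups[i] in val_groups]
    if not tr_idx:
        tr_idx, va_idx = list(range(n)), []

    history: Dict[str, List[float]] = {"train": [], "val": []}
    if va_idx:
        history["val"].append(
            model.evaluate_loss([images[i] for i in va_idx], [targets[i] for i in va_idx])
        )
    for _ in range(cfg.epochs):
        order = rng.permutation(tr_idx)
        losses = []
        for start in range(0, len(order), cfg.batch_size):
            batch = order[start : start + cfg.batch_size]
            x = np.stack([images[i] for i in batch])
            y = np.stack([targets[i] for i in batch])
            loss, grads = model.loss_and_grad(x, y)
            model._adam_step(grads)
            losses.append(loss)
        history["train"].append(float(np.mean(losses)))
        if va_idx:
            history["val"].append(
                model.evaluate_loss([images[i] for i in va_idx], [targets[i] for i in va_idx])
            )
    return model, history


def predict_semantic(model: UNet, zstack: np.ndarray) -> np.ndarray:
    """8-channel probability stack for one Z-stack (n_z, H, W)."""
    zstack = np.asarray(zstack, dtype=np.float64)
    if zstack.ndim == 2:
        zstack = zstack[None]
    if zstack.shape[0] != model.config.in_sections:
        raise ValueError(
            f"expected {model.config.in_sections} sections, got {zstack.shape[0]}"
        )
    return model.forward(zstack)[0]


def oracle_predict(
    frame: AnnotatedFrame,
    spec: SizeCategorySpec,
    sigma: float = 0.0,
    shape: Optional[Tuple[int, int]] = None,
) -> np.ndarray:
    """Idealised semantic prediction straight from the ground truth.

    With ``sigma`` > 0 each binary channel is softened with a Gaussian
    halo while the true support keeps probability >= 0.75, mimicking a
    confident but soft network output (thresholding at 0.5 never loses
    true target pixels for sigma <= 1).
    """
    stack = build_target_stack(frame, spec, shape=shape).astype(np.float64)
    if sigma > 0:
        blurred = np.stack([ndimage.gaussian_filter(c, sigma=sigma) for c in stack])
        stack = np.maximum(blurred, 0.75 * stack)
    return stack


def interior_pixel_f1(
    pred: np.ndarray, truth: np.ndarray, threshold: float = 0.5
) -> float:
    """Pixel F1 of the combined (union over S/M/L) interior channels.

    The three size-category targets are disjoint, so the probability of
    "interior of any size" is the sum of the channel probabilities.
    """
    p = np.minimum(pred[:3].sum(axis=0), 1.0) >= threshold
    t = truth[:3].max(axis=0) >= 0.5
    tp = np.count_nonzero(p & t)
    fp = np.count_nonzero(p & ~t)
    fn = np.count_nonzero(~p & t)
    if tp == 0:
        return 0.0
    prec, rec = tp / (tp + fp), tp / (tp + fn)
    return 2 * prec * rec / (prec + rec)
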