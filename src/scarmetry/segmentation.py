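"""Training and evaluation of the 2D scar/scale segmentation network.

The network (see :mod:`scarmetry.nn.segnet`) outputs two independent sigmoid
channels, one per foreground class (scar, scale), so the joint loss applies
per class exactly in its binary form:

    L_Dice = 1 - (2 sum(p g) + eps) / (sum(p^2) + sum(g^2) + eps)
    L_BCE  = -mean(g log p + (1 - g) log(1 - p))
    L_total = L_Dice + L_BCE

averaged over channels (and samples). Training uses SGD with momentum 0.9,
weight decay 1e-4 and the poly learning-rate schedule
``lr = lr_base * (1 - iter/total_iter)^0.9`` stepped per iteration.
Segmentation quality is reported as Dice similarity coefficient,
sensitivity and specificity from per-class confusion counts.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage

from .nn import SegNet, SGD, poly_lr
from .scene import Label

__all__ = [
    "LossConfig",
    "TrainConfig",
    "SegMetrics",
    "build_segnet",
    "joint_loss",
    "dice_loss",
    "bce_loss",
    "train_segnet",
    "predict_masks",
    "hard_mask",
    "mask_to_onehot",
    "augment_pair",
    "segmentation_metrics",
    "save_checkpoint",
    "load_checkpoint",
]

_CLAMP = 1e-7


@dataclass(frozen=True)
class LossConfig:
    """Smoothing constant for the Dice term and per-channel weights."""

    eps: float = 1.0
    channel_weights: tuple[float, ...] = (1.0, 1.0)

    def __post_init__(self) -> None:
        if self.eps <= 0:
            raise ValueError("eps must be positive")


@dataclass
class TrainConfig:
    input_size: tuple[int, int] = (512, 512)
    epochs: int = 200
    batch_size: int = 2
    lr_base: float = 0.01
    poly_power: float = 0.9
    momentum: float = 0.9
    weight_decay: float = 1e-4
    hflip: bool = True
    vflip: bool = True
    rotation_deg: float = 30.0  # symmetric range [-30, 30]
    pretrained_encoder: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.lr_base, self.momentum, self.weight_decay) < 0 or self.lr_base == 0:
            raise ValueError("rates must be positive")
        if self.rotation_deg < 0:
            raise ValueError("rotation range must be non-negative")
        if self.pretrained_encoder:
            warnings.warn(
                "no pretrained encoder weights are bundled; training from scratch",
                stacklevel=2,
            )


@dataclass
class SegMetrics:
    dsc: float
    sen: float  # NaN when the class is absent from the ground truth
    spe: float  # NaN when the class fills the ground truth
    tp: int
    tn: int
    fp: int
    fn: int


def build_segnet(
    in_channels: int = 3,
    out_channels: int = 2,
    *,
    base_width: int = 64,
    blocks: tuple[int, int, int, int] = (3, 4, 6, 3),
    seed: int = 0,
    pretrained_encoder: bool = False,
) -> SegNet:
    """Construct the encoder-decoder network. ``base_width``/``blocks``
    scale capacity; the defaults match ResNet-34. ``pretrained_encoder`` is
    accepted for interface completeness but no weights are bundled."""
    if pretrained_encoder:
        warnings.warn("no pretrained encoder weights are bundled; using random init", stacklevel=2)
    return SegNet(in_channels, out_channels, base_width=base_width, blocks=blocks, seed=seed)


# ---------------------------------------------------------------------------
# loss


def dice_loss(p: np.ndarray, g: np.ndarray, eps: float = 1.0) -> float:
    """Smoothed Dice loss of one channel (flattened over everything)."""
    p = p.ravel()
    g = g.ravel()
    num = 2.0 * (p * g).sum() + eps
    den = (p * p).sum() + (g * g).sum() + eps
    return float(1.0 - num / den)


def bce_loss(p: np.ndarray, g: np.ndarray) -> float:
    pc = np.clip(p, _CLAMP, 1.0 - _CLAMP)
    return float(-(g * np.log(pc) + (1.0 - g) * np.log(1.0 - pc)).mean())


def joint_loss(
    p: np.ndarray, g: np.ndarray, cfg: LossConfig = LossConfig()
) -> float:
    """Dice + BCE, each averaged over channels with ``cfg.channel_weights``.

    ``p``: soft predictions ``(..., C, H, W)`` (a leading batch axis is
    allowed); ``g``: matching one-hot ground truth.
    """
    loss, _ = joint_loss_and_grad(p, g, cfg, need_grad=False)
    return loss


def joint_loss_and_grad(
    p: np.ndarray, g: np.ndarray, cfg: LossConfig = LossConfig(), need_grad: bool = True
) -> tuple[float, np.ndarray | None]:
    """Joint loss and its gradient w.r.t. ``p``. The Dice term is computed
    per (sample, channel) and averaged; BCE is averaged per channel over all
    pixels, then averaged over channels."""
    p = np.asarray(p, dtype=float)
    g = np.asarray(g, dtype=float)
    if p.shape != g.shape:
        raise ValueError(f"prediction shape {p.shape} != ground truth shape {g.shape}")
    squeeze = p.ndim == 3
    if squeeze:
        p = p[None]
        g = g[None]
    n, c, h, w = p.shape
    wts = np.asarray(cfg.channel_weights, dtype=float)
    if wts.size != c:
        raise ValueError("channel_weights length must equal channel count")
    wts = wts / wts.sum()

    grad = np.zeros_like(p) if need_grad else None
    pc = np.clip(p, _CLAMP, 1.0 - _CLAMP)
    total = 0.0
    npix = h * w
    for ch in range(c):
        dice_ch = 0.0
        for s in range(n):
            ps, gs = p[s, ch], g[s, ch]
            num = 2.0 * (ps * gs).sum() + cfg.eps
            den = (ps * ps).sum() + (gs * gs).sum() + cfg.eps
            dice_ch += 1.0 - num / den
            if need_grad:
                grad[s, ch] += wts[ch] / n * (-(2.0 * gs * den - num * 2.0 * ps) / den**2)
        dice_ch /= n
        pcs, gcs = pc[:, ch], g[:, ch]
        bce_ch = float(-(gcs * np.log(pcs) + (1 - gcs) * np.log(1 - pcs)).mean())
        if need_grad:
            inside = (p[:, ch] > _CLAMP) & (p[:, ch] < 1.0 - _CLAMP)
            grad[:, ch] += (
                wts[ch] * inside * (-(gcs / pcs) + (1 - gcs) / (1 - pcs)) / (n * npix)
            )
        total += wts[ch] * (dice_ch + bce_ch)
    if need_grad and squeeze:
        grad = grad[0]
    return float(total), grad


# ---------------------------------------------------------------------------
# data handling


def mask_to_onehot(mask: np.ndarray) -> np.ndarray:
    """Hard label image (H, W) -> one-hot (2, H, W) for (scar, scale)."""
    mask = np.asarray(mask)
    return np.stack([(mask == Label.SCAR), (mask == Label.SCALE)]).astype(float)


def image_to_input(image: np.ndarray) -> np.ndarray:
    """(H, W, 3) uint8 -> (3, H, W) float in [0, 1]."""
    return np.asarray(image, dtype=float).transpose(2, 0, 1) / 255.0


def augment_pair(
    image: np.ndarray,
    mask: np.ndarray,
    rng: np.random.Generator,
    cfg: TrainConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """Joint geometric augmentation of an image (C, H, W) and its label mask
    (H, W): random horizontal/vertical flips and a rotation drawn uniformly
    from the symmetric range. The image is interpolated bilinearly; the mask
    uses nearest-neighbour so labels stay admissible."""
    if cfg.hflip and rng.random() < 0.5:
        image = image[:, :, ::-1]
        mask = mask[:, ::-1]
    if cfg.vflip and rng.random() < 0.5:
        image = image[:, ::-1, :]
        mask = mask[::-1, :]
    if cfg.rotation_deg > 0:
        angle = rng.uniform(-cfg.rotation_deg, cfg.rotation_deg)
        image = ndimage.rotate(
            image, angle, axes=(1, 2), reshape=False, order=1, mode="nearest"
        )
        mask = ndimage.rotate(mask, angle, reshape=False, order=0, mode="nearest")
    return np.ascontiguousarray(image), np.ascontiguousarray(mask)


# ---------------------------------------------------------------------------
# training / inference


def train_segnet(
    model: SegNet,
    dataset: list[tuple[np.ndarray, np.ndarray]],
    cfg: TrainConfig,
    loss_cfg: LossConfig = LossConfig(),
    *,
    augment: bool = True,
) -> tuple[SegNet, list[float]]:
    """Train in place; returns the model and the per-epoch mean loss history.

    ``dataset`` is a list of ``(image (H,W,3) uint8, mask (H,W) labels)``
    pairs. The poly schedule is stepped per iteration over the whole run.
    Deterministic for a fixed seed under single-threaded execution.
    """
    if not dataset:
        raise ValueError("empty training dataset")
    rng = np.random.default_rng(cfg.seed)
    opt = SGD(model.layers(), momentum=cfg.momentum, weight_decay=cfg.weight_decay)
    n = len(dataset)
    batches_per_epoch = int(np.ceil(n / cfg.batch_size))
    total_iter = cfg.epochs * batches_per_epoch
    history: list[float] = []
    it = 0
    for _epoch in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for b in range(batches_per_epoch):
            idx = order[b * cfg.batch_size : (b + 1) * cfg.batch_size]
            xs, gs = [], []
            for i in idx:
                img, mask = dataset[i]
                x = image_to_input(img)
                m = np.asarray(mask)
                if augment:
                    x, m = augment_pair(x, m, rng, cfg)
                xs.append(x)
                gs.append(mask_to_onehot(m))
            x = np.stack(xs)
            g = np.stack(gs)
            p = model.forward(x, training=True)
            loss, dp = joint_loss_and_grad(p, g, loss_cfg)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"NaN/inf loss at iteration {it}: diverged (lr too high or bad data)"
                )
            opt.zero_grad()
            model.backward(dp)
            opt.step(poly_lr(cfg.lr_base, it, total_iter, cfg.poly_power))
            it += 1
            losses.append(loss)
        history.append(float(np.mean(losses)))
    return model, history


def predict_masks(model: SegNet, images: list[np.ndarray] | np.ndarray) -> np.ndarray:
    """Soft masks ``(N, 2, H, W)`` in [0, 1] for a batch of (H, W, 3) uint8
    images, in input order; inference mode (running BN statistics)."""
    if isinstance(images, np.ndarray) and images.ndim == 3:
        images = [images]
    x = np.stack([image_to_input(im) for im in images])
    return model.forward(x, training=False)


def hard_mask(probs: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Soft (2, H, W) -> hard label image. Pixels above threshold in both
    channels go to the channel with the higher probability."""
    scar, scale = probs[0], probs[1]
    out = np.zeros(scar.shape, dtype=np.int64)
    out[(scar > threshold) & (scar >= scale)] = int(Label.SCAR)
    out[(scale > threshold) & (scale > scar)] = int(Label.SCALE)
    return out


# ---------------------------------------------------------------------------
# metrics


def segmentation_metrics(pred: np.ndarray, gt: np.ndarray, cls: int | str) -> SegMetrics:
    """Per-class DSC / sensitivity / specificity from confusion counts.

    Undefined ratios (empty denominator) are returned as NaN rather than
    silently coerced to 0.
    """
    if isinstance(cls, str):
        cls = int(Label[cls.upper()])
    pred = np.asarray(pred)
    gt = np.asarray(gt)
    if pred.shape != gt.shape:
        raise ValueError("prediction and ground truth shapes differ")
    pp = pred == cls
    gp = gt == cls
    tp = int(np.sum(pp & gp))
    fp = int(np.sum(pp & ~gp))
    fn = int(np.sum(~pp & gp))
    tn = int(np.sum(~pp & ~gp))
    dsc = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else float("nan")
    sen = tp / (tp + fn) if (tp + fn) else float("nan")
    spe = tn / (tn + fp) if (tn + fp) else float("nan")
    return SegMetrics(dsc=dsc, sen=sen, spe=spe, tp=tp, tn=tn, fp=fp, fn=fn)


# ---------------------------------------------------------------------------
# checkpoints


def save_checkpoint(model: SegNet, cfg: TrainConfig | None, path: str | Path) -> None:
    """Write weights as .npz with a JSON sidecar describing the architecture
    and training configuration."""
    path = Path(path)
    with open(path, "wb") as fh:  # file handle keeps the exact filename
        np.savez(fh, **model.state_dict())
    meta = {
        "in_channels": model.in_channels,
        "out_channels": model.out_channels,
        "base_width": model.base_width,
        "blocks": list(model.blocks),
        "seed": model.seed,
        "train_config": asdict(cfg) if cfg is not None else None,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=2))


def load_checkpoint(path: str | Path) -> SegNet:
    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    model = SegNet(
        meta["in_channels"], meta["out_channels"],
        base_width=meta["base_width"], blocks=tuple(meta["blocks"]), seed=meta["seed"],
    )
    with np.load(path) as state:
        model.load_state_dict(dict(state))
    return model
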