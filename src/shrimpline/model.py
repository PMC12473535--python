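"""Learned centerline prediction for one body instance.

The RGB image (scaled to [0, 1]) is concatenated with the instance's binary
mask into a 4-channel tensor and reduced to 3 channels by a learned 1x1
convolution (fusion).  The fused input feeds a small encoder whose deepest
feature map — concatenated with a downsampled copy of the fused input — is
passed through an ASPP block (parallel dilated convolutions at increasing
rates); the ASPP output is upsampled and merged with the encoder skip
connections, each merge followed by convolutional refinement, ending in a
1x1 convolution and sigmoid that yield a per-pixel centerline probability.

Training targets are 3-px-wide bands: the ground-truth polyline rasterized
to a one-pixel 8-connected curve and dilated once with a 3x3 square
element.  The loss is Dice + beta * BCE with a shared stability constant:

    L = 1 - (2*sum(Y*P) + eps) / (sum(Y) + sum(P) + eps)
        + beta * ( -(1/N) * sum( Y*log(P + eps) + (1-Y)*log(1 - P + eps) ) )

optimized with momentum SGD under a multi-step learning-rate schedule.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage.draw import line as draw_line

from .nn import (
    SGD,
    Conv2d,
    Param,
    ReLU,
    avg_pool2,
    avg_pool2_backward,
    sigmoid,
    upsample2,
    upsample2_backward,
)


@dataclasses.dataclass(frozen=True)
class ModelConfig:
    encoder_depth: int = 3
    base_channels: int = 8
    aspp_rates: tuple[int, ...] = (1, 2, 4)
    decoder_channels: tuple[int, ...] = (16, 16, 8)
    inject_downsampled_input: bool = True

    def __post_init__(self) -> None:
        if self.encoder_depth < 2:
            raise ValueError("encoder_depth must be >= 2")
        r = self.aspp_rates
        if r[0] != 1 or any(a >= b for a, b in zip(r, r[1:])):
            raise ValueError("aspp_rates must be strictly increasing, first 1")
        if len(self.decoder_channels) != self.encoder_depth:
            raise ValueError("need one decoder_channels entry per encoder stage")


@dataclasses.dataclass(frozen=True)
class TrainConfig:
    epochs: int = 40
    lr: float = 0.02
    momentum: float = 0.9
    lr_milestones: tuple[int, ...] = (25, 35)
    lr_gamma: float = 0.1
    beta: float = 1.0
    eps: float = 1e-6
    batch_size: int = 4
    clip_grad_norm: float | None = 2.0
    warmup_epochs: int = 4
    augment: bool = True  # random flips / 90-degree rotations per draw
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lr <= 0 or not (0 <= self.momentum < 1):
            raise ValueError("invalid lr/momentum")
        if self.beta < 0 or self.eps <= 0:
            raise ValueError("beta must be >= 0 and eps > 0")


# ---------------------------------------------------------------------------
# Fusion


def fuse_inputs(
    image: np.ndarray, mask: np.ndarray, weights: np.ndarray, bias: np.ndarray
) -> np.ndarray:
    """Per-pixel 1x1 fusion of RGB (scaled to [0,1]) and a binary mask.

    ``weights`` is (3, 4) mapping [R, G, B, mask] -> 3 fused channels,
    ``bias`` is (3,).  Returns an (H, W, 3) float array.
    """
    image = np.asarray(image)
    mask = np.asarray(mask)
    if image.shape[:2] != mask.shape:
        raise ValueError(
            f"image {image.shape[:2]} and mask {mask.shape} disagree"
        )
    img = image.astype(float)
    if img.max() > 1.0:
        img = img / 255.0
    concat = np.concatenate([img, (mask > 0)[..., None].astype(float)], axis=2)
    return concat @ np.asarray(weights, float).T + np.asarray(bias, float)


def concat_input(image: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """4-channel (C, H, W) tensor: RGB scaled to [0, 1] plus binary mask."""
    img = np.asarray(image).astype(float)
    if img.max() > 1.0:
        img = img / 255.0
    m = (np.asarray(mask) > 0).astype(float)
    return np.concatenate([img.transpose(2, 0, 1), m[None]], axis=0)


# ---------------------------------------------------------------------------
# Targets


def make_target(polyline: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """3-px-wide training band: rasterize the polyline, dilate once (3x3).

    The polyline is rasterized segment-by-segment with Bresenham lines,
    giving an 8-connected one-pixel curve, then dilated with a 3x3 square
    element (clipped at the frame).
    """
    polyline = np.asarray(polyline, dtype=float)
    if polyline.ndim != 2 or len(polyline) == 0:
        raise ValueError("polyline must be a non-empty (P, 2) array")
    h, w = shape
    pts = np.round(polyline).astype(int)
    if (pts[:, 0] < 0).any() or (pts[:, 0] >= h).any() or (
        pts[:, 1] < 0
    ).any() or (pts[:, 1] >= w).any():
        raise ValueError("polyline leaves the frame")
    grid = np.zeros(shape, dtype=np.uint8)
    if len(pts) == 1:
        grid[pts[0, 0], pts[0, 1]] = 1
    for (r0, c0), (r1, c1) in zip(pts[:-1], pts[1:]):
        rr, cc = draw_line(r0, c0, r1, c1)
        grid[rr, cc] = 1
    return ndimage.binary_dilation(grid, structure=np.ones((3, 3))).astype(
        np.uint8
    )


# ---------------------------------------------------------------------------
# Loss


def dice_bce_loss(
    pred: np.ndarray,
    target: np.ndarray,
    beta: float = 1.0,
    eps: float = 1e-6,
) -> float:
    """Composite Dice + beta * BCE loss (see module docstring)."""
    p = np.asarray(pred, dtype=float)
    t = np.asarray(target, dtype=float)
    if p.shape != t.shape:
        raise ValueError(f"pred {p.shape} and target {t.shape} disagree")
    inter = float(np.sum(t * p))
    dice = 1.0 - (2.0 * inter + eps) / (float(np.sum(t)) + float(np.sum(p)) + eps)
    n = p.size
    bce = -float(
        np.sum(t * np.log(p + eps) + (1.0 - t) * np.log(1.0 - p + eps))
    ) / n
    return dice + beta * bce


def dice_bce_grad(
    pred: np.ndarray, target: np.ndarray, beta: float, eps: float
) -> np.ndarray:
    """dL/dpred of :func:`dice_bce_loss`."""
    p = np.asarray(pred, dtype=float)
    t = np.asarray(target, dtype=float)
    s = float(np.sum(t)) + float(np.sum(p)) + eps
    inter = float(np.sum(t * p))
    ddice = -(2.0 * t * s - (2.0 * inter + eps)) / (s * s)
    dbce = -(t / (p + eps) - (1.0 - t) / (1.0 - p + eps)) / p.size
    return ddice + beta * dbce


# ---------------------------------------------------------------------------
# Network


class CenterlineNet:
    """Encoder + ASPP + skip-fusion decoder over a fused 3-channel input.

    Holds the fusion 1x1 convolution as its first (jointly trained) layer.
    Layout is fixed by :class:`ModelConfig`; all state is numpy, so results
    are bit-reproducible for a fixed init seed and data order.
    """

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        d = config.encoder_depth
        enc_ch = [config.base_channels * 2**i for i in range(d)]

        self.fuse = Conv2d(4, 3, 1, rng)
        self.enc: list[tuple[Conv2d, ReLU, Conv2d, ReLU]] = []
        prev = 3
        for ch in enc_ch:
            self.enc.append((Conv2d(prev, ch, 3, rng), ReLU(), Conv2d(ch, ch, 3, rng), ReLU()))
            prev = ch

        aspp_in = enc_ch[-1] + (3 if config.inject_downsampled_input else 0)
        aspp_ch = enc_ch[-1]
        self.aspp = [
            (Conv2d(aspp_in, aspp_ch, 3, rng, dilation=rate), ReLU())
            for rate in config.aspp_rates
        ]
        self.aspp_proj = Conv2d(aspp_ch * len(config.aspp_rates), aspp_ch, 1, rng)
        self.aspp_relu = ReLU()

        self.dec: list[tuple[Conv2d, ReLU, Conv2d, ReLU]] = []
        prev = aspp_ch
        for i, ch in enumerate(config.decoder_channels):
            skip_ch = enc_ch[d - 1 - i]
            self.dec.append(
                (Conv2d(prev + skip_ch, ch, 3, rng), ReLU(), Conv2d(ch, ch, 3, rng), ReLU())
            )
            prev = ch
        self.final = Conv2d(prev, 1, 1, rng)

    # -- parameters ---------------------------------------------------------

    def params(self) -> list[Param]:
        out = self.fuse.params()
        for ca, _, cb, _ in self.enc + self.dec:
            out += ca.params() + cb.params()
        for conv, _ in self.aspp:
            out += conv.params()
        out += self.aspp_proj.params() + self.final.params()
        return out

    # -- forward / backward -------------------------------------------------

    def _pad(self, x: np.ndarray) -> tuple[np.ndarray, tuple[int, int]]:
        m = 2**self.config.encoder_depth
        _, h, w = x.shape
        ph = (-h) % m
        pw = (-w) % m
        if ph or pw:
            x = np.pad(x, ((0, 0), (0, ph), (0, pw)), mode="reflect")
        return x, (h, w)

    def forward_fused(self, fused: np.ndarray) -> np.ndarray:
        """Body of the network: fused (3, H, W) -> probability (H, W)."""
        x, (h, w) = self._pad(fused)
        self._orig_hw = (h, w)
        self._padded_fused = x
        skips = []
        for ca, ra, cb, rb in self.enc:
            x = rb.forward(cb.forward(ra.forward(ca.forward(x))))
            skips.append(x)
            x = avg_pool2(x)
        self._skips = skips
        if self.config.inject_downsampled_input:
            down = self._padded_fused
            for _ in range(self.config.encoder_depth):
                down = avg_pool2(down)
            x = np.concatenate([x, down], axis=0)
            self._bottom_split = x.shape[0] - 3
        branches = [r.forward(c.forward(x)) for c, r in self.aspp]
        self._aspp_ch = branches[0].shape[0]
        x = self.aspp_relu.forward(self.aspp_proj.forward(np.concatenate(branches, axis=0)))
        self._dec_splits = []
        for i, (ca, ra, cb, rb) in enumerate(self.dec):
            x = upsample2(x)
            skip = skips[len(skips) - 1 - i]
            self._dec_splits.append(x.shape[0])
            x = np.concatenate([x, skip], axis=0)
            x = rb.forward(cb.forward(ra.forward(ca.forward(x))))
        z = self.final.forward(x)[0]
        self._prob_padded = sigmoid(z)
        return self._prob_padded[:h, :w]

    def forward(self, image: np.ndarray, mask: np.ndarray) -> np.ndarray:
        """Full pass: concat -> learned fusion -> body -> probability map."""
        return self.forward_concat(concat_input(image, mask))

    def forward_concat(self, concat4: np.ndarray) -> np.ndarray:
        fused = self.fuse.forward(concat4)
        return self.forward_fused(fused)

    def fused_input(self, image: np.ndarray, mask: np.ndarray) -> np.ndarray:
        """The model's own (H, W, 3) fused input (Eq-style channel-last)."""
        w = self.fuse.W.value.reshape(3, 4)
        return fuse_inputs(image, mask, w, self.fuse.b.value)

    def backward_from_prob(self, dprob: np.ndarray) -> None:
        """Backpropagate dL/dprob (on the cropped output) to all params."""
        h, w = self._orig_hw
        p = self._prob_padded
        dz = np.zeros_like(p)
        dz[:h, :w] = dprob
        dz = dz * p * (1.0 - p)
        dx = self.final.backward(dz[None])
        dfused_extra = None
        for i in range(len(self.dec) - 1, -1, -1):
            ca, ra, cb, rb = self.dec[i]
            dx = ca.backward(ra.backward(cb.backward(rb.backward(dx))))
            split = self._dec_splits[i]
            dskip = dx[split:]
            dx = upsample2_backward(dx[:split])
            # skip gradient is deferred: store on the skip list
            self._skips[len(self._skips) - 1 - i] = ("grad", dskip)
        dx = self.aspp_proj.backward(self.aspp_relu.backward(dx))
        chunks = np.split(dx, len(self.aspp), axis=0)
        dbottom = None
        for (conv, relu), dc in zip(self.aspp, chunks):
            g = conv.backward(relu.backward(dc))
            dbottom = g if dbottom is None else dbottom + g
        if self.config.inject_downsampled_input:
            split = self._bottom_split
            dfused_extra = dbottom[split:]
            for _ in range(self.config.encoder_depth):
                dfused_extra = avg_pool2_backward(dfused_extra)
            dbottom = dbottom[:split]
        dx = dbottom
        for i in range(len(self.enc) - 1, -1, -1):
            ca, ra, cb, rb = self.enc[i]
            dx = avg_pool2_backward(dx)
            tag = self._skips[i]
            if isinstance(tag, tuple) and tag[0] == "grad":
                dx = dx + tag[1]
            dx = ca.backward(ra.backward(cb.backward(rb.backward(dx))))
        if dfused_extra is not None:
            dx = dx + dfused_extra
        dx = _fold_reflect_pad_grad(dx, self._orig_hw)
        self.fuse.backward(dx)

    # -- persistence --------------------------------------------------------

    def save(self, path: str | Path) -> None:
        arrays = {f"p{i}": p.value for i, p in enumerate(self.params())}
        meta = json.dumps(
            {"schema": 1, "config": dataclasses.asdict(self.config)}
        )
        np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "CenterlineNet":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            cfg_dict = meta["config"]
            cfg_dict["aspp_rates"] = tuple(cfg_dict["aspp_rates"])
            cfg_dict["decoder_channels"] = tuple(cfg_dict["decoder_channels"])
            net = cls(ModelConfig(**cfg_dict))
            for i, p in enumerate(net.params()):
                p.value[...] = data[f"p{i}"]
        return net


def _fold_reflect_pad_grad(dx: np.ndarray, orig_hw: tuple[int, int]) -> np.ndarray:
    """Adjoint of bottom/right ``np.pad(..., mode='reflect')``.

    Reflect padding is separable, so gradients in the padded rows/columns
    fold back onto their mirror sources one axis at a time.
    """
    h, w = orig_hw
    _, hp, wp = dx.shape
    if (hp, wp) == (h, w):
        return dx
    a = dx[:, :h, :].copy()
    for k in range(hp - h):
        a[:, h - 2 - k, :] += dx[:, h + k, :]
    b = a[:, :, :w].copy()
    for j in range(wp - w):
        b[:, :, w - 2 - j] += a[:, :, w + j]
    return b


# ---------------------------------------------------------------------------
# Training


def train(
    dataset: list[tuple[np.ndarray, np.ndarray, np.ndarray]],
    model_cfg: ModelConfig = ModelConfig(),
    train_cfg: TrainConfig = TrainConfig(),
) -> tuple[CenterlineNet, list[float]]:
    """Train a :class:`CenterlineNet` on (image, mask, target) triples.

    One integer seed controls weight initialization and shuffling.  Returns
    the trained net and the per-epoch mean loss history.  A non-finite loss
    aborts with the epoch index.
    """
    if not dataset:
        raise ValueError("empty dataset")
    net = CenterlineNet(model_cfg, seed=train_cfg.seed)
    rng = np.random.default_rng(train_cfg.seed + 1)
    samples = [
        (concat_input(img, mask), np.asarray(t, float)) for img, mask, t in dataset
    ]
    opt = SGD(
        net.params(),
        lr=train_cfg.lr,
        momentum=train_cfg.momentum,
        milestones=train_cfg.lr_milestones,
        gamma=train_cfg.lr_gamma,
        clip_grad_norm=train_cfg.clip_grad_norm,
        warmup_epochs=train_cfg.warmup_epochs,
    )
    history: list[float] = []
    for epoch in range(train_cfg.epochs):
        order = rng.permutation(len(samples))
        losses = []
        for start in range(0, len(order), train_cfg.batch_size):
            batch = order[start : start + train_cfg.batch_size]
            opt.zero_grad()
            for idx in batch:
                x4, target = samples[idx]
                if train_cfg.augment:
                    square = x4.shape[1] == x4.shape[2]
                    k = int(rng.integers(4)) if square else 2 * int(rng.integers(2))
                    if k:
                        x4 = np.rot90(x4, k, axes=(1, 2))
                        target = np.rot90(target, k)
                    if rng.integers(2):
                        x4 = np.flip(x4, axis=2)
                        target = np.flip(target, axis=1)
                    x4 = np.ascontiguousarray(x4)
                    target = np.ascontiguousarray(target)
                prob = net.forward_concat(x4)
                loss = dice_bce_loss(prob, target, train_cfg.beta, train_cfg.eps)
                losses.append(loss)
                dprob = dice_bce_grad(prob, target, train_cfg.beta, train_cfg.eps)
                net.backward_from_prob(dprob / len(batch))
            opt.step(epoch)
        mean_loss = float(np.mean(losses))
        if not np.isfinite(mean_loss):
            raise RuntimeError(f"training diverged at epoch {epoch}")
        history.append(mean_loss)
    return net, history


def make_training_set(
    scenes, crop_size: int = 96
) -> list[tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Per-instance (image, mask, target) crops from ground-truth scenes.

    Each sample is a ``crop_size`` window centered on the instance's
    bounding box, with the 3-px centerline band as target.  Instances whose
    bounding box exceeds the crop are skipped.
    """
    samples = []
    for scene in scenes:
        h, w = scene.image.shape[:2]
        for inst in scene.instances:
            rows = np.flatnonzero(inst.mask.any(axis=1))
            cols = np.flatnonzero(inst.mask.any(axis=0))
            if rows.size == 0:
                continue
            if rows[-1] - rows[0] >= crop_size or cols[-1] - cols[0] >= crop_size:
                continue
            cr = (rows[0] + rows[-1]) // 2
            cc = (cols[0] + cols[-1]) // 2
            r0 = int(np.clip(cr - crop_size // 2, 0, max(h - crop_size, 0)))
            c0 = int(np.clip(cc - crop_size // 2, 0, max(w - crop_size, 0)))
            r1, c1 = min(r0 + crop_size, h), min(c0 + crop_size, w)
            img = scene.image[r0:r1, c0:c1]
            mask = inst.mask[r0:r1, c0:c1]
            poly = inst.centerline_polyline - np.array([r0, c0])
            target = make_target(poly, mask.shape)
            samples.append((img, mask, target))
    return samples


def predict_instance(
    image: np.ndarray,
    mask: np.ndarray,
    net: CenterlineNet,
    threshold: float = 0.5,
) -> np.ndarray:
    """Binary centerline band for one instance: fuse -> forward -> threshold."""
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must be in (0, 1)")
    prob = net.forward(image, mask)
    return (prob >= threshold).astype(np.uint8)
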