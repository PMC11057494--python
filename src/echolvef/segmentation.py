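"""Atrous convolutional network for LV segmentation.

A ResNet-style encoder (strided stem, residual blocks, with dilated
convolutions replacing stride in the deepest stage) feeds an atrous
spatial pyramid pooling head: parallel branches with a 1x1 convolution,
dilated 3x3 convolutions at the configured rates, and a global-pooling
branch, concatenated, projected, reduced to one logit channel and
bilinearly upsampled to the input resolution.  Channel widths scale
with ``width_scale`` so a desk-scale model trains on CPU in minutes;
``width_scale=1`` corresponds to the full 64-channel stem of a standard
ResNet-50-family encoder.

Training is full-batch (or seeded mini-batch) Adam on pixel-wise binary
cross-entropy; evaluation is the Dice similarity coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn

_TOTAL_STRIDE = 4


@dataclass(frozen=True)
class SegConfig:
    input_size: tuple[int, int] = (112, 112)
    width_scale: float = 0.125
    atrous_rates: tuple[int, ...] = (2, 4, 8)
    learning_rate: float = 1e-2
    epochs: int = 200
    batch_size: int = 0  # 0 = full batch
    seed: int = 0
    threshold: float = 0.5

    def __post_init__(self):
        if len(set(self.atrous_rates)) != len(self.atrous_rates) or any(
            r < 1 for r in self.atrous_rates
        ):
            raise ValueError("atrous rates must be distinct and >= 1")
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must lie in (0, 1)")
        if self.input_size[0] % _TOTAL_STRIDE or self.input_size[1] % _TOTAL_STRIDE:
            raise ValueError(
                f"input size must be divisible by the encoder stride {_TOTAL_STRIDE}"
            )

    @property
    def stem_width(self) -> int:
        return max(2, int(round(64 * self.width_scale)))


class _ACNNNet:
    """Encoder + ASPP graph with hand-wired forward/backward."""

    def __init__(self, config: SegConfig):
        rng = np.random.default_rng(config.seed)
        w = config.stem_width
        self.stem = nn.Sequential(nn.Conv2d(1, w, 3, stride=2, rng=rng), nn.ReLU())
        self.block1 = nn.ResidualBlock(w, 2 * w, stride=2, rng=rng)
        # deepest stage: dilation instead of stride keeps the 1/4 grid
        self.block2 = nn.ResidualBlock(2 * w, 2 * w, dilation=2, rng=rng)
        self.aspp_branches = [nn.Sequential(nn.Conv2d(2 * w, w, 1, rng=rng), nn.ReLU())]
        for rate in config.atrous_rates:
            self.aspp_branches.append(
                nn.Sequential(nn.Conv2d(2 * w, w, 3, dilation=rate, rng=rng), nn.ReLU())
            )
        self.aspp_branches.append(
            nn.Sequential(nn.GlobalAvgPool(), nn.Conv2d(2 * w, w, 1, rng=rng), nn.ReLU())
        )
        n_branch = len(self.aspp_branches)
        self.project = nn.Sequential(nn.Conv2d(n_branch * w, w, 1, rng=rng), nn.ReLU())
        self.head = nn.Conv2d(w, 1, 1, rng=rng)
        self.upsample = nn.BilinearUpsample(_TOTAL_STRIDE)
        self._w = w

    def parameters(self):
        params = (
            self.stem.parameters()
            + self.block1.parameters()
            + self.block2.parameters()
            + [p for br in self.aspp_branches for p in br.parameters()]
            + self.project.parameters()
            + self.head.parameters()
        )
        return params

    def forward(self, x):
        feats = self.block2.forward(self.block1.forward(self.stem.forward(x)))
        branch_outs = [br.forward(feats) for br in self.aspp_branches]
        cat = np.concatenate(branch_outs, axis=1)
        logits = self.upsample.forward(self.head.forward(self.project.forward(cat)))
        return logits

    def backward(self, g):
        g = self.project.backward(self.head.backward(self.upsample.backward(g)))
        w = self._w
        g_feats = 0.0
        for i, br in enumerate(self.aspp_branches):
            g_feats = g_feats + br.backward(g[:, i * w : (i + 1) * w])
        self.stem.backward(self.block1.backward(self.block2.backward(g_feats)))


@dataclass
class SegModel:
    """Trained-weight handle plus its config and training history."""

    config: SegConfig
    net: _ACNNNet
    training_history: list[float] = field(default_factory=list)

    def state_arrays(self) -> list[np.ndarray]:
        return [p for p, _ in self.net.parameters()]


def build_acnn(config: SegConfig = SegConfig()) -> SegModel:
    """Untrained network; parameter initialisation is seed-deterministic."""
    return SegModel(config=config, net=_ACNNNet(config))


def _as_batch(frames) -> np.ndarray:
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    return frames[:, None, :, :]  # (N, 1, H, W)


def predict_proba(model: SegModel, frames) -> np.ndarray:
    """Per-pixel foreground probabilities at the input resolution."""
    x = _as_batch(frames)
    h, w = model.config.input_size
    if x.shape[2:] != (h, w):
        raise ValueError(f"expected frames of shape {(h, w)}, got {x.shape[2:]}")
    logits = model.net.forward(x)
    return nn.sigmoid(logits[:, 0])


def predict_mask(model: SegModel, frame) -> np.ndarray:
    """Binarised LV mask for one frame (probability >= threshold)."""
    proba = predict_proba(model, frame)
    mask = proba >= model.config.threshold
    return mask[0] if np.asarray(frame).ndim == 2 else mask


def segment_video(model: SegModel, video) -> np.ndarray:
    """Mask stack for an :class:`~echolvef.io.EchoVideo`."""
    proba = predict_proba(model, video.frames)
    return proba >= model.config.threshold


def train(model: SegModel, frames, masks, config: SegConfig | None = None) -> SegModel:
    """Fit the network with Adam on pixel-wise binary cross-entropy.

    Full-batch by default; a positive ``batch_size`` switches to seeded
    mini-batches.  Returns the same model with per-epoch mean loss
    appended to ``training_history``.
    """
    config = config or model.config
    x = _as_batch(frames)
    y = np.asarray(masks, dtype=float)
    if y.ndim == 2:
        y = y[None]
    if not np.isin(np.unique(y), (0.0, 1.0)).all():
        raise ValueError("training masks must be binary")
    if y.shape != (x.shape[0], x.shape[2], x.shape[3]):
        raise ValueError(f"mask stack shape {y.shape} does not match frames")
    y = y[:, None]
    n = x.shape[0]
    if n < 1:
        raise ValueError("need at least one training pair")
    opt = nn.Adam(model.net.parameters(), lr=config.learning_rate)
    rng = np.random.default_rng(config.seed)
    bs = config.batch_size if 0 < config.batch_size < n else n
    for _ in range(config.epochs):
        order = rng.permutation(n) if bs < n else np.arange(n)
        losses = []
        for start in range(0, n, bs):
            sel = order[start : start + bs]
            logits = model.net.forward(x[sel])
            loss, grad = nn.bce_with_logits(logits, y[sel])
            model.net.backward(grad)
            opt.step()
            losses.append(loss)
        model.training_history.append(float(np.mean(losses)))
    return model


def dice(a, b) -> float:
    """Dice similarity coefficient 2|a&b|/(|a|+|b|); empty vs empty = 1."""
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    if a.shape != b.shape:
        raise ValueError("masks must share a shape")
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(a, b).sum() / denom)


def save_model(model: SegModel, path) -> None:
    """Serialise config + weights to an .npz file."""
    cfg = model.config
    meta = dict(
        input_size=np.array(cfg.input_size),
        width_scale=np.array(cfg.width_scale),
        atrous_rates=np.array(cfg.atrous_rates),
        learning_rate=np.array(cfg.learning_rate),
        epochs=np.array(cfg.epochs),
        batch_size=np.array(cfg.batch_size),
        seed=np.array(cfg.seed),
        threshold=np.array(cfg.threshold),
        history=np.array(model.training_history),
    )
    weights = {f"w{i}": p for i, p in enumerate(model.state_arrays())}
    np.savez(path, **meta, **weights)


def load_model(path) -> SegModel:
    data = np.load(path)
    cfg = SegConfig(
        input_size=tuple(int(v) for v in data["input_size"]),
        width_scale=float(data["width_scale"]),
        atrous_rates=tuple(int(v) for v in data["atrous_rates"]),
        learning_rate=float(data["learning_rate"]),
        epochs=int(data["epochs"]),
        batch_size=int(data["batch_size"]),
        seed=int(data["seed"]),
        threshold=float(data["threshold"]),
    )
    model = build_acnn(cfg)
    for i, p in enumerate(model.state_arrays()):
        p[...] = data[f"w{i}"]
    model.training_history = list(data["history"])
    return model
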