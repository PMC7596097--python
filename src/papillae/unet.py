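"""U-Net-style encoder-decoder segmentation network.

The encoder is a VGG-style stack of 3x3 convolutions (no dense layers) with
2x2 max-pooling between levels; the decoder mirrors it with nearest-
neighbour upsampling, skip-connection concatenation, batch normalisation
and dropout (fraction 0.5) for regularisation; a 1x1 convolution with a
sigmoid yields per-pixel foreground probabilities.  Optimisation uses the
weighted IoU loss from :mod:`papillae.losses` with Adam.

The full-size default configuration mirrors the VGG16 channel progression;
the reduced preset (two levels, 8 base channels, 128x192 patches) trains in
minutes on one CPU and is what the tests and the validation study use.

``use_pretrained_encoder`` exists as an opt-in transfer-learning hook; it
defaults to off and no weights ship with the package.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import nn
from .losses import weighted_iou_loss_grad


@dataclass(frozen=True)
class UNetConfig:
    encoder_widths: tuple[int, ...] = (64, 128, 256, 512)
    convs_per_level: int = 2
    dropout_fraction: float = 0.5
    use_batchnorm: bool = True
    use_pretrained_encoder: bool = False
    patch_height: int = 384
    patch_width: int = 576
    epochs: int = 50
    batch_size: int = 4
    learning_rate: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.dropout_fraction < 1.0):
            raise ValueError("dropout_fraction must be in [0, 1)")
        if len(self.encoder_widths) < 2:
            raise ValueError("need at least two encoder levels")
        d = self.depth
        if self.patch_height % 2**d or self.patch_width % 2**d:
            raise ValueError(
                f"patch size {self.patch_height}x{self.patch_width} not divisible by 2^{d}"
            )
        if self.use_pretrained_encoder:
            raise NotImplementedError(
                "pretrained encoder weights are an opt-in hook; none are bundled"
            )

    @property
    def depth(self) -> int:
        """Number of pooling steps."""
        return len(self.encoder_widths) - 1


def reduced_config(**overrides) -> UNetConfig:
    """Two-level, 8-channel preset for CPU-scale training."""
    params = dict(
        encoder_widths=(8, 16),
        patch_height=128,
        patch_width=192,
        epochs=10,
        batch_size=8,
        learning_rate=2e-3,
    )
    params.update(overrides)
    return UNetConfig(**params)


class UNet:
    """The network graph; built by :func:`build_model`."""

    def __init__(self, config: UNetConfig, in_channels: int = 3):
        self.config = config
        self.in_channels = in_channels
        rng = np.random.default_rng(config.seed)
        self._dropout_rng = np.random.default_rng(config.seed + 1)
        widths = config.encoder_widths
        d = config.depth

        def block(cin: int, cout: int) -> nn.Sequential:
            layers: list[nn.Layer] = []
            c = cin
            for _ in range(config.convs_per_level):
                layers.append(nn.Conv2d(c, cout, 3, rng))
                if config.use_batchnorm:
                    layers.append(nn.BatchNorm2d(cout))
                layers.append(nn.ReLU())
                c = cout
            return nn.Sequential(layers)

        self.enc_blocks = []
        c = in_channels
        for lvl in range(d):
            self.enc_blocks.append(block(c, widths[lvl]))
            c = widths[lvl]
        self.pools = [nn.MaxPool2() for _ in range(d)]
        self.bottleneck = block(c, widths[-1])
        self.ups = [nn.UpsampleNearest2() for _ in range(d)]
        self.dec_blocks = []
        below = widths[-1]
        for lvl in reversed(range(d)):
            self.dec_blocks.insert(0, block(below + widths[lvl], widths[lvl]))
            below = widths[lvl]
        self.dropouts = [
            nn.Dropout(config.dropout_fraction, self._dropout_rng) for _ in range(d)
        ]
        self.head = nn.Conv2d(widths[0], 1, 1, rng)
        self._up_ch: list[int] = [0] * d

    # -- parameter plumbing -------------------------------------------------
    def _modules(self) -> list[nn.Layer]:
        return [*self.enc_blocks, self.bottleneck, *self.dec_blocks, self.head]

    def params(self) -> list[np.ndarray]:
        return [p for m in self._modules() for p in m.params()]

    def grads(self) -> list[np.ndarray]:
        return [g for m in self._modules() for g in m.grads()]

    def state_arrays(self) -> list[np.ndarray]:
        """All persistent arrays: parameters plus batch-norm running stats."""
        out = list(self.params())
        for m in self._modules():
            layers = m.layers if isinstance(m, nn.Sequential) else [m]
            for l in layers:
                if isinstance(l, nn.BatchNorm2d):
                    out.extend([l.running_mean, l.running_var])
        return out

    # -- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """(N, V, H, C) image batch -> (N, V, H) probability maps."""
        d = self.config.depth
        if x.shape[1] % 2**d or x.shape[2] % 2**d:
            raise ValueError(f"input spatial size must be divisible by 2^{d}")
        h = x.astype(np.float32)
        skips = []
        for lvl in range(d):
            h = self.enc_blocks[lvl].forward(h, training)
            skips.append(h)
            h = self.pools[lvl].forward(h, training)
        h = self.bottleneck.forward(h, training)
        for lvl in reversed(range(d)):
            self._up_ch[lvl] = h.shape[-1]
            h = self.ups[lvl].forward(h, training)
            h = np.concatenate([h, skips[lvl]], axis=-1)
            h = self.dec_blocks[lvl].forward(h, training)
            h = self.dropouts[lvl].forward(h, training)
        z = self.head.forward(h, training)[..., 0]
        self._yhat = nn.sigmoid(z)
        return self._yhat

    def backward(self, dyhat: np.ndarray) -> None:
        d = self.config.depth
        dz = (dyhat * self._yhat * (1.0 - self._yhat)).astype(np.float32)
        g = self.head.backward(dz[..., None])
        dskips: list[np.ndarray] = [None] * d  # type: ignore[list-item]
        for lvl in range(d):
            g = self.dropouts[lvl].backward(g)
            g = self.dec_blocks[lvl].backward(g)
            up_ch = self._up_ch[lvl]
            dskips[lvl] = g[..., up_ch:]
            g = self.ups[lvl].backward(g[..., :up_ch])
        g = self.bottleneck.backward(g)
        for lvl in reversed(range(d)):
            g = self.pools[lvl].backward(g)
            g = g + dskips[lvl]
            g = self.enc_blocks[lvl].backward(g)

    def predict(self, image: np.ndarray) -> np.ndarray:
        """Probability map for one (V, H, C) image, padding to fit depth."""
        d = self.config.depth
        v, h = image.shape[:2]
        mult = 2**d
        pv = (-v) % mult
        ph = (-h) % mult
        x = np.pad(image, ((0, pv), (0, ph), (0, 0)), mode="reflect")
        out = self.forward(x[None], training=False)[0]
        return out[:v, :h]


@dataclass
class TrainedModel:
    """A network plus its provenance: config, target and loss history."""

    config: UNetConfig
    target: str  # "papillae" or "tongue"
    net: UNet
    history: dict[str, list[float]] = field(default_factory=lambda: {"train": [], "val": []})

    def predict(self, image: np.ndarray) -> np.ndarray:
        return self.net.predict(image)


def build_model(config: UNetConfig, target: str = "papillae", in_channels: int = 3) -> TrainedModel:
    if target not in ("papillae", "tongue"):
        raise ValueError("target must be 'papillae' or 'tongue'")
    return TrainedModel(config=config, target=target, net=UNet(config, in_channels))


def train(
    model: TrainedModel,
    dataset: list[tuple[np.ndarray, np.ndarray, np.ndarray]],
    split_fraction: float = 0.2,
) -> TrainedModel:
    """Optimise the weighted IoU loss on (image, mask, weight) triples.

    The dataset is shuffled once with the config seed and split train/val
    at ``split_fraction``; per-epoch train and validation losses are
    recorded in ``model.history``.  Deterministic for a fixed seed.
    """
    if not dataset:
        raise ValueError("empty training dataset")
    cfg = model.config
    rng = np.random.default_rng(cfg.seed + 2)
    order = rng.permutation(len(dataset))
    n_val = max(1, int(round(split_fraction * len(dataset)))) if split_fraction > 0 else 0
    val_idx = order[:n_val]
    train_idx = order[n_val:]
    if train_idx.size == 0:
        train_idx, val_idx = order, order[:0]
    opt = nn.Adam(model.net.params(), lr=cfg.learning_rate)

    def batches(idx: np.ndarray):
        for s in range(0, idx.size, cfg.batch_size):
            sel = idx[s : s + cfg.batch_size]
            x = np.stack([dataset[i][0] for i in sel]).astype(np.float32)
            y = np.stack([dataset[i][1] for i in sel]).astype(np.float32)
            w = np.stack([dataset[i][2] for i in sel]).astype(np.float32)
            yield x, y, w

    for epoch in range(cfg.epochs):
        ep_order = train_idx[rng.permutation(train_idx.size)]
        losses = []
        for x, y, w in batches(ep_order):
            yhat = model.net.forward(x, training=True)
            loss, grad = weighted_iou_loss_grad(y, yhat, w)
            if not np.isfinite(loss):
                raise RuntimeError(f"non-finite training loss at epoch {epoch}")
            model.net.backward(grad.astype(np.float32))
            opt.step(model.net.grads())
            losses.append(loss)
        model.history["train"].append(float(np.mean(losses)))
        if val_idx.size:
            vlosses = [
                weighted_iou_loss_grad(y, model.net.forward(x, training=False), w)[0]
                for x, y, w in batches(val_idx)
            ]
            model.history["val"].append(float(np.mean(vlosses)))
    return model


def sliding_window_predict(
    model: TrainedModel,
    image: np.ndarray,
    stride: tuple[int, int] | None = None,
) -> np.ndarray:
    """Whole-image prediction by averaging overlapping window predictions.

    Windows of the configured patch size are slid across the (reflect-
    padded) image at ``stride`` (default: half a patch in each direction);
    each pixel's output is the mean prediction over every window covering
    it, and the result is cropped back to the input size.
    """
    cfg = model.config
    pv, ph = cfg.patch_height, cfg.patch_width
    sv, sh = stride or (pv // 2, ph // 2)
    v, h = image.shape[:2]
    pad_v = (-(v - pv)) % sv if v > pv else pv - v
    pad_h = (-(h - ph)) % sh if h > ph else ph - h
    padded = np.pad(image, ((0, pad_v), (0, pad_h), (0, 0)), mode="reflect")
    acc = np.zeros(padded.shape[:2], dtype=np.float64)
    cnt = np.zeros(padded.shape[:2], dtype=np.float64)
    for r0 in range(0, padded.shape[0] - pv + 1, sv):
        for c0 in range(0, padded.shape[1] - ph + 1, sh):
            win = padded[r0 : r0 + pv, c0 : c0 + ph]
            acc[r0 : r0 + pv, c0 : c0 + ph] += model.net.forward(win[None], training=False)[0]
            cnt[r0 : r0 + pv, c0 : c0 + ph] += 1.0
    return (acc / cnt)[:v, :h].astype(np.float32)


# -- checkpointing ----------------------------------------------------------

def save_model(model: TrainedModel, path: str | Path) -> None:
    """Weights as .npz plus a JSON sidecar (config, target, history)."""
    path = Path(path)
    arrays = {f"p{i}": p for i, p in enumerate(model.net.state_arrays())}
    np.savez(path.with_suffix(".npz"), **arrays)
    sidecar = {
        "config": asdict(model.config),
        "target": model.target,
        "history": model.history,
        "in_channels": model.net.in_channels,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_model(path: str | Path) -> TrainedModel:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    cfg_dict = sidecar["config"]
    cfg_dict["encoder_widths"] = tuple(cfg_dict["encoder_widths"])
    cfg = UNetConfig(**cfg_dict)
    model = build_model(cfg, sidecar["target"], sidecar["in_channels"])
    data = np.load(path.with_suffix(".npz"))
    for i, p in enumerate(model.net.state_arrays()):
        p[...] = data[f"p{i}"]
    model.history = sidecar["history"]
    return model
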