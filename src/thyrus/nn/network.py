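"""Encoder–decoder segmentation network with dense blocks and index unpooling.

The architecture follows the QuickNAT family: four (or three) encoder dense
blocks, a convolutional bottleneck, matching decoders fed by max-pool index
unpooling, skip connections from each encoder to its decoder, and a 1×1
softmax classifier.  Each dense block stacks two 5×5 and one 1×1 convolution,
every convolution preceded by batch normalization and ReLU, with the block's
intermediate feature maps concatenated as inputs to the later layers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from ..rng import split_rng
from .layers import (
    F32,
    Adam,
    BatchNorm2d,
    Conv2d,
    Dropout2d,
    MaxPool2d,
    MaxUnpool2d,
    ReLU,
)

__all__ = ["NetworkConfig", "DenseBlock", "SegmentationNet", "build_network"]


@dataclass
class NetworkConfig:
    n_enc_dec: int = 4
    base_channels: int = 16
    dropout: float = 0.5
    n_classes: int = 2
    kernel_main: int = 5
    kernel_mix: int = 1
    pool: int = 2

    def validate(self) -> None:
        if self.n_enc_dec not in (3, 4):
            raise ValueError("n_enc_dec must be 3 or 4")
        if self.base_channels < 1 or self.n_classes < 2:
            raise ValueError("invalid channel/class counts")
        if self.pool != 2:
            raise ValueError("only 2x2 pooling is supported")


class DenseBlock:
    """BN→ReLU→conv ×3 (5×5, 5×5, 1×1) with intra-block concatenation."""

    def __init__(self, in_ch: int, ch: int, cfg: NetworkConfig, rng: np.random.Generator):
        k, km = cfg.kernel_main, cfg.kernel_mix
        self.bn1, self.relu1 = BatchNorm2d(in_ch), ReLU()
        self.conv1 = Conv2d(in_ch, ch, k, rng)
        self.bn2, self.relu2 = BatchNorm2d(in_ch + ch), ReLU()
        self.conv2 = Conv2d(in_ch + ch, ch, k, rng)
        self.bn3, self.relu3 = BatchNorm2d(2 * ch), ReLU()
        self.conv3 = Conv2d(2 * ch, ch, km, rng)
        self.in_ch, self.ch = in_ch, ch

    def layers(self):
        return [self.bn1, self.conv1, self.bn2, self.conv2, self.bn3, self.conv3]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        a = self.conv1.forward(self.relu1.forward(self.bn1.forward(x, training), training), training)
        xa = np.concatenate([x, a], axis=3)
        b = self.conv2.forward(self.relu2.forward(self.bn2.forward(xa, training), training), training)
        ab = np.concatenate([a, b], axis=3)
        return self.conv3.forward(self.relu3.forward(self.bn3.forward(ab, training), training), training)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        d = self.bn3.backward(self.relu3.backward(self.conv3.backward(dout)))
        da, db = d[..., : self.ch], d[..., self.ch :]
        d = self.bn2.backward(self.relu2.backward(self.conv2.backward(np.ascontiguousarray(db))))
        dx2, da2 = d[..., : self.in_ch], d[..., self.in_ch :]
        da = np.ascontiguousarray(da + da2)
        dx1 = self.bn1.backward(self.relu1.backward(self.conv1.backward(da)))
        return dx1 + dx2


class SegmentationNet:
    def __init__(self, config: NetworkConfig, seed: int = 0):
        config.validate()
        self.config = config
        rng = split_rng(seed, "net-init")
        c = config.base_channels
        n = config.n_enc_dec
        self.encoders = [DenseBlock(1 if i == 0 else c, c, config, rng) for i in range(n)]
        self.pools = [MaxPool2d() for _ in range(n)]
        self.enc_drops = [Dropout2d(config.dropout) for _ in range(n)]
        self.bott_bn, self.bott_relu = BatchNorm2d(c), ReLU()
        self.bott_conv = Conv2d(c, c, config.kernel_main, rng)
        self.bott_drop = Dropout2d(config.dropout)
        self.unpools = [MaxUnpool2d() for _ in range(n)]
        self.decoders = [DenseBlock(2 * c, c, config, rng) for _ in range(n)]
        self.classifier = Conv2d(c, config.n_classes, config.kernel_mix, rng)

    # -- plumbing ---------------------------------------------------------
    def _all_layers(self):
        out = []
        for blk in self.encoders:
            out.extend(blk.layers())
        out += [self.bott_bn, self.bott_conv]
        for blk in self.decoders:
            out.extend(blk.layers())
        out.append(self.classifier)
        return out

    def parameters(self):
        params = []
        for layer in self._all_layers():
            params.extend(layer.parameters())
        return params

    def set_dropout_rng(self, rng: np.random.Generator) -> None:
        for d in self.enc_drops + [self.bott_drop]:
            d.rng = rng

    def _state_arrays(self) -> list[np.ndarray]:
        """Learnable parameters plus batch-norm running statistics."""
        arrays = [p for p, _ in self.parameters()]
        for layer in self._all_layers():
            if isinstance(layer, BatchNorm2d):
                arrays += [layer.running_mean, layer.running_var]
        return arrays

    def state_dict(self) -> list[np.ndarray]:
        return [a.copy() for a in self._state_arrays()]

    def load_state_dict(self, state: list[np.ndarray]) -> None:
        arrays = self._state_arrays()
        if len(arrays) != len(state):
            raise ValueError("state does not match this architecture")
        for a, s in zip(arrays, state):
            a[...] = s

    # -- forward / backward ----------------------------------------------
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """x: (N,H,W,1) float32 -> logits (N,H,W,n_classes)."""
        x = np.ascontiguousarray(x, dtype=F32)
        n_levels = self.config.n_enc_dec
        div = 2 ** n_levels
        if x.shape[1] % div or x.shape[2] % div:
            raise ValueError(f"input H,W must be divisible by {div}")
        skips, indices = [], []
        for blk, pool, drop in zip(self.encoders, self.pools, self.enc_drops):
            x = blk.forward(x, training)
            skips.append(x)
            x, idx = pool.forward(x, training)
            x = drop.forward(x, training)
            indices.append(idx)
        x = self.bott_conv.forward(
            self.bott_relu.forward(self.bott_bn.forward(x, training), training), training
        )
        x = self.bott_drop.forward(x, training)
        for i in range(n_levels - 1, -1, -1):
            x = self.unpools[i].forward(x, indices[i], training)
            x = np.concatenate([x, skips[i]], axis=3)
            x = self.decoders[i].forward(x, training)
        return self.classifier.forward(x, training)

    def backward(self, dlogits: np.ndarray) -> None:
        c = self.config.base_channels
        d = self.classifier.backward(dlogits)
        dskips = [None] * self.config.n_enc_dec
        for i in range(self.config.n_enc_dec):
            d = self.decoders[i].backward(d)
            dup, dskips[i] = np.ascontiguousarray(d[..., :c]), np.ascontiguousarray(d[..., c:])
            d = self.unpools[i].backward(dup)
        d = self.bott_drop.backward(d)
        d = self.bott_bn.backward(self.bott_relu.backward(self.bott_conv.backward(d)))
        for i in range(self.config.n_enc_dec - 1, -1, -1):
            d = self.enc_drops[i].backward(d)
            d = self.pools[i].backward(d)
            d = self.encoders[i].backward(d + dskips[i])

    def predict_probs(self, x: np.ndarray) -> np.ndarray:
        from .losses import softmax

        return softmax(self.forward(x, training=False))


def build_network(config: NetworkConfig | None = None, seed: int = 0) -> SegmentationNet:
    """Construct the segmentation network; identical seed ⇒ identical weights."""
    return SegmentationNet(config or NetworkConfig(), seed=seed)


def save_network(model: SegmentationNet, path, seed: int | None = None) -> None:
    """Checkpoint: parameter arrays + batch-norm running stats + config snapshot."""
    import json

    arrays = {f"state_{i}": a for i, a in enumerate(model.state_dict())}
    meta = {"config": asdict(model.config), "seed": seed}
    np.savez(path, __meta__=json.dumps(meta), **arrays)


def load_network(path) -> SegmentationNet:
    import json

    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["__meta__"]))
        model = SegmentationNet(NetworkConfig(**meta["config"]))
        n = len(model.state_dict())
        model.load_state_dict([data[f"state_{i}"] for i in range(n)])
    return model
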