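"""Model builders: lightweight shuffle/attention extractor and CRNN head.

The extractor stacks depthwise-separable shuffle units, each followed by
efficient channel attention, with 2x2 max-pool downsampling between
stages. The classifier head runs small 3x3 convolution blocks, reads the
resulting feature map as a width-axis sequence, and finishes with an LSTM,
a 64-unit fully connected layer and a softmax over the classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .layers import (
    LSTM,
    Adam,
    BatchNorm2d,
    ChannelShuffle,
    Conv2d,
    Dense,
    DepthwiseConv2d,
    Dropout,
    ECALayer,
    MaxPool2,
    ReLU,
    Sequential,
    ToSequence,
    smoothed_cross_entropy,
    softmax,
)

__all__ = [
    "ExtractorConfig",
    "CRNNConfig",
    "build_extractor",
    "build_crnn",
    "ImageClassifier",
]


@dataclass(frozen=True)
class ExtractorConfig:
    """Shape of the feature extractor.

    ``stage_widths`` are output channels per stage (each must be divisible
    by ``groups``); ``eca_kernel`` is the odd length of the attention's 1-D
    conv; ``input_size`` the (square) image side in pixels.
    """

    stage_widths: tuple[int, ...] = (8, 16)
    groups: int = 2
    eca_kernel: int = 3
    input_size: int = 32
    in_channels: int = 3

    def __post_init__(self) -> None:
        if self.eca_kernel % 2 == 0:
            raise ValueError("eca_kernel must be odd")
        for w in self.stage_widths:
            if w % self.groups != 0:
                raise ValueError(f"stage width {w} not divisible by groups {self.groups}")
        if self.input_size % (2 ** len(self.stage_widths)) != 0:
            raise ValueError("input_size must be divisible by 2^n_stages for pooling")

    @property
    def out_channels(self) -> int:
        return self.stage_widths[-1]

    @property
    def out_size(self) -> int:
        return self.input_size // (2 ** len(self.stage_widths))


@dataclass(frozen=True)
class CRNNConfig:
    """Shape of the convolutional-recurrent classifier head.

    All convolutions are 3x3 with ReLU; each block pools 2x2 with stride 2
    and applies batch normalization and dropout. The final feature map is
    read column by column into the LSTM; a 64-unit fully connected layer
    precedes the softmax over ``n_classes``.
    """

    conv_widths: tuple[int, ...] = (16,)
    dropout: float = 0.1
    lstm_units: int = 32
    fc_units: int = 64
    n_classes: int = 5
    label_smoothing: float = 0.1

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")
        if not 0.0 <= self.label_smoothing < 0.5:
            raise ValueError("label_smoothing must lie in [0, 0.5)")


def build_extractor(config: ExtractorConfig, rng: np.random.Generator) -> Sequential:
    """Assemble the stacked shuffle/attention units.

    Each unit is 1x1 conv -> channel shuffle -> depthwise 3x3 -> 1x1 conv
    -> ECA, with ReLU after each pointwise conv and a 2x2 max pool closing
    every stage.
    """
    layers: list = []
    cin = config.in_channels
    for width in config.stage_widths:
        layers += [
            Conv2d(cin, width, k=1, pad=0, rng=rng),
            ReLU(),
            ChannelShuffle(config.groups),
            DepthwiseConv2d(width, k=3, pad=1, rng=rng),
            Conv2d(width, width, k=1, pad=0, rng=rng),
            ReLU(),
            ECALayer(config.eca_kernel, rng=rng),
            MaxPool2(),
        ]
        cin = width
    return Sequential(*layers)


def build_crnn(
    config: CRNNConfig,
    in_channels: int,
    in_size: int,
    rng: np.random.Generator,
) -> Sequential:
    """Assemble the convolutional-recurrent head for a given input map."""
    layers: list = []
    cin, size = in_channels, in_size
    for width in config.conv_widths:
        if size < 2:
            raise ValueError("input too small for the configured pooling depth")
        layers += [
            Conv2d(cin, width, k=3, pad=1, rng=rng),
            ReLU(),
            MaxPool2(),
            BatchNorm2d(width),
            Dropout(config.dropout, rng=np.random.default_rng(rng.integers(2**31))),
        ]
        cin, size = width, size // 2
    layers += [
        ToSequence(),
        LSTM(cin * size, config.lstm_units, rng=rng),
        Dense(config.lstm_units, config.fc_units, rng=rng),
        ReLU(),
        Dense(config.fc_units, config.n_classes, rng=rng),
    ]
    return Sequential(*layers)


class ImageClassifier:
    """Extractor + CRNN head trained end to end; emits class probabilities."""

    def __init__(self, extractor_cfg: ExtractorConfig, crnn_cfg: CRNNConfig, seed: int = 0):
        self.extractor_cfg = extractor_cfg
        self.crnn_cfg = crnn_cfg
        self.seed = seed
        rng = np.random.default_rng(seed)
        self.extractor = build_extractor(extractor_cfg, rng)
        self.crnn = build_crnn(
            crnn_cfg, extractor_cfg.out_channels, extractor_cfg.out_size, rng
        )
        self.net = Sequential(self.extractor, self.crnn)

    def params(self):
        return self.net.params()

    def logits(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return self.net.forward(x, train=train)

    def predict_proba(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Per-class probability rows (each row sums to 1)."""
        x = _check_images(x, self.extractor_cfg)
        out = [softmax(self.logits(x[i:i + batch_size])) for i in range(0, len(x), batch_size)]
        return np.concatenate(out, axis=0)

    def predict(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        return self.predict_proba(x, batch_size=batch_size).argmax(axis=1)

    def train_step(self, x: np.ndarray, y: np.ndarray, optimizer: Adam) -> float:
        optimizer.zero_grad()
        logits = self.logits(x, train=True)
        loss, dlogits = smoothed_cross_entropy(logits, y, self.crnn_cfg.label_smoothing)
        self.net.backward(dlogits)
        optimizer.step()
        return loss

    def save(self, path) -> None:
        """Checkpoint parameters plus architecture config to an .npz file."""
        import json

        arrays = {f"p{i}": p.value for i, p in enumerate(self.params())}
        meta = json.dumps({
            "extractor": _cfg_dict(self.extractor_cfg),
            "crnn": _cfg_dict(self.crnn_cfg),
            "seed": self.seed,
        })
        np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path) -> "ImageClassifier":
        import json

        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            model = cls(
                ExtractorConfig(**{k: tuple(v) if isinstance(v, list) else v
                                   for k, v in meta["extractor"].items()}),
                CRNNConfig(**{k: tuple(v) if isinstance(v, list) else v
                              for k, v in meta["crnn"].items()}),
                seed=meta["seed"],
            )
            for i, p in enumerate(model.params()):
                p.value[...] = data[f"p{i}"]
        return model


def _cfg_dict(cfg) -> dict:
    from dataclasses import asdict

    return {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(cfg).items()}


def _check_images(x: np.ndarray, cfg: ExtractorConfig) -> np.ndarray:
    x = np.asarray(x, dtype=np.float32)
    if x.ndim == 3:
        x = x[None]
    if x.shape[1] != cfg.in_channels or x.shape[2] != cfg.input_size or x.shape[3] != cfg.input_size:
        raise ValueError(
            f"expected images (N, {cfg.in_channels}, {cfg.input_size}, {cfg.input_size}), got {x.shape}"
        )
    return x
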