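"""The attention-augmented fully convolutional U-Net.

Encoder: five VGG-style stages (two 3×3 conv + BN + ReLU each, same
padding) separated by 2×2/stride-2 max pooling, yielding feature maps at
5 scales (the input resolution and four twofold downsamplings).  When
enabled, a spatial group-wise enhancement block follows each stage.
Decoder: repeated {2×2 stride-2 transposed-convolution upsampling →
concatenation with the same-scale encoder map (U-shaped skip) → conv
stage}, closed by a 1×1 convolution to per-class scores at the full
input resolution.  Disabling the attention blocks gives the plain U-Net
baseline with an otherwise identical layout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import List, Optional, Sequence

import numpy as np

from .layers import (
    BatchNorm2d,
    Conv2d,
    ConvTranspose2d,
    Layer,
    MaxPool2d,
    Param,
    ReLU,
)
from .sge import SGEBlock

__all__ = ["SegModelConfig", "SegUNet", "FeatureMap", "ScoreMap",
           "save_checkpoint", "load_checkpoint"]

#: VGG-16 stage widths, selectable for paper-scale runs
VGG16_WIDTHS = (64, 128, 256, 512, 512)


@dataclass(frozen=True)
class SegModelConfig:
    n_classes: int = 6
    encoder_widths: tuple = (32, 64, 128, 256, 512)
    sge_groups: int = 8
    sge_enabled: bool = True
    same_padding: bool = True  # fixed: full-frame outputs are required
    seed: int = 0

    def __post_init__(self):
        if len(self.encoder_widths) != 5:
            raise ValueError("exactly 5 scales (original + 4 downsamplings) required")
        if not self.same_padding:
            raise ValueError("same_padding is fixed to True")
        if self.sge_enabled:
            for wdt in self.encoder_widths:
                if wdt % self.sge_groups:
                    raise ValueError(
                        f"encoder width {wdt} not divisible by "
                        f"sge_groups={self.sge_groups}")

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "SegModelConfig":
        d = json.loads(text)
        d["encoder_widths"] = tuple(d["encoder_widths"])
        return cls(**d)


@dataclass
class FeatureMap:
    """A 3-D (channels × height × width) activation at one scale."""

    values: np.ndarray
    scale: int  # downsampling exponent: spatial size = input / 2**scale


@dataclass
class ScoreMap:
    """Per-class scores at full resolution; argmax labels break ties low."""

    values: np.ndarray  # (n_classes, H, W)

    @property
    def argmax_labels(self) -> np.ndarray:
        # np.argmax returns the first maximal index → lowest class id wins ties
        return np.argmax(self.values, axis=0)


class _ConvStage:
    """Two (conv → BN → ReLU) units, optionally closed by an SGE block."""

    def __init__(self, c_in: int, c_out: int, cfg: SegModelConfig,
                 rng: np.random.Generator, name: str, with_sge: bool):
        self.layers: List[Layer] = [
            Conv2d(c_in, c_out, 3, rng, f"{name}.conv1"),
            BatchNorm2d(c_out, name=f"{name}.bn1"),
            ReLU(),
            Conv2d(c_out, c_out, 3, rng, f"{name}.conv2"),
            BatchNorm2d(c_out, name=f"{name}.bn2"),
            ReLU(),
        ]
        self.sge: Optional[SGEBlock] = None
        if with_sge:
            self.sge = SGEBlock(c_out, cfg.sge_groups, name=f"{name}.sge")
            self.layers.append(self.sge)

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x, train=True):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


class SegUNet:
    """Maps an RGB section to per-class score maps at full resolution."""

    def __init__(self, config: SegModelConfig = SegModelConfig()):
        self.config = config
        rng = np.random.default_rng(config.seed)
        w = config.encoder_widths
        sge = config.sge_enabled
        self.enc_stages = []
        c_prev = 3
        for s in range(5):
            self.enc_stages.append(
                _ConvStage(c_prev, w[s], config, rng, f"enc{s}", sge))
            c_prev = w[s]
        self.pools = [MaxPool2d() for _ in range(4)]
        self.upconvs = []
        self.dec_stages = []
        for s in range(4, 0, -1):
            self.upconvs.append(
                ConvTranspose2d(w[s], w[s - 1], rng, f"up{s}"))
            self.dec_stages.append(
                _ConvStage(2 * w[s - 1], w[s - 1], config, rng,
                           f"dec{s - 1}", with_sge=False))
        self.head = Conv2d(w[0], config.n_classes, 1, rng, "head")

    # ------------------------------------------------------------------ params

    def params(self) -> List[Param]:
        out = []
        for stage in self.enc_stages:
            out.extend(stage.params())
        for up, stage in zip(self.upconvs, self.dec_stages):
            out.extend(up.params())
            out.extend(stage.params())
        out.extend(self.head.params())
        return out

    def n_parameters(self) -> int:
        return sum(p.size for p in self.params())

    # ----------------------------------------------------------------- encode

    @staticmethod
    def _check_size(x: np.ndarray) -> None:
        h, w = x.shape[-2:]
        if h % 16 or w % 16:
            raise ValueError(
                f"input size {h}×{w} not divisible by 16; pad the image to a "
                "multiple of 16 before encoding")

    def encode(self, x: np.ndarray, train: bool = True) -> List[FeatureMap]:
        """Run the encoder; returns one feature map per scale 0..4.

        ``x`` is (N, 3, H, W) with H and W divisible by 16.
        """
        self._check_size(x)
        feats = []
        for s in range(5):
            x = self.enc_stages[s].forward(x, train)
            feats.append(FeatureMap(values=x, scale=s))
            if s < 4:
                x = self.pools[s].forward(x, train)
        return feats

    # ----------------------------------------------------------------- decode

    def decode(self, feats: Sequence[FeatureMap], train: bool = True) -> np.ndarray:
        """Fuse skip connections and upsample back to full resolution."""
        if len(feats) != 5 or [f.scale for f in feats] != [0, 1, 2, 3, 4]:
            raise ValueError("decode expects 5 feature maps at scales 0..4")
        x = feats[4].values
        self._skip_channels = []
        for i, s in enumerate(range(4, 0, -1)):
            x = self.upconvs[i].forward(x, train)
            skip = feats[s - 1].values
            if skip.shape[-2:] != x.shape[-2:]:
                raise ValueError("skip connection shape mismatch")
            self._skip_channels.append(skip.shape[1])
            x = np.concatenate([skip, x], axis=1)
            x = self.dec_stages[i].forward(x, train)
        return self.head.forward(x, train)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        """Full pass: (N, 3, H, W) → (N, n_classes, H, W) scores."""
        return self.decode(self.encode(x, train), train)

    def backward(self, dscores: np.ndarray) -> None:
        """Back-propagate through decoder and encoder, accumulating grads."""
        dy = self.head.backward(dscores)
        dskips = [None] * 5
        for i in range(3, -1, -1):
            s = 4 - i  # encoder scale the skip came from is s-1... see decode
            dy = self.dec_stages[i].backward(dy)
            c_skip = self._skip_channels[i]
            dskip, dy = dy[:, :c_skip], dy[:, c_skip:]
            dskips[4 - i - 1] = dskip
            dy = self.upconvs[i].backward(dy)
        # dy is now the gradient at the scale-4 encoder output
        for s in range(4, -1, -1):
            if s < 4:
                dy = self.pools[s].backward(dy)
            if dskips[s] is not None:
                dy = dy + dskips[s]
            dy = self.enc_stages[s].backward(dy)

    # ------------------------------------------------------------- prediction

    @staticmethod
    def preprocess(image: np.ndarray) -> np.ndarray:
        """(H, W, 3) uint8 → (3, H, W) float64 in [-0.5, 0.5]."""
        return image.astype(np.float64).transpose(2, 0, 1) / 255.0 - 0.5

    def predict_scores(self, image: np.ndarray) -> ScoreMap:
        x = self.preprocess(image)[None]
        scores = self.forward(x, train=False)
        return ScoreMap(values=scores[0])

    def predict_labels(self, image: np.ndarray) -> np.ndarray:
        """Argmax label map for one (H, W, 3) uint8 image."""
        return self.predict_scores(image).argmax_labels

    # ------------------------------------------------------------ persistence

    def state_arrays(self) -> dict:
        state = {}
        for p in self.params():
            state[p.name] = p.data
        for s, stage in enumerate(self.enc_stages + self.dec_stages):
            prefix = f"stage{s}"
            for j, layer in enumerate(stage.layers):
                if isinstance(layer, BatchNorm2d):
                    state[f"{prefix}.{j}.running_mean"] = layer.running_mean
                    state[f"{prefix}.{j}.running_var"] = layer.running_var
        return state

    def load_state_arrays(self, state: dict) -> None:
        for p in self.params():
            p.data = np.array(state[p.name])
        for s, stage in enumerate(self.enc_stages + self.dec_stages):
            prefix = f"stage{s}"
            for j, layer in enumerate(stage.layers):
                if isinstance(layer, BatchNorm2d):
                    layer.running_mean = np.array(state[f"{prefix}.{j}.running_mean"])
                    layer.running_var = np.array(state[f"{prefix}.{j}.running_var"])


def save_checkpoint(model: SegUNet, path) -> None:
    """Serialize weights + config to an .npz checkpoint."""
    state = {k: np.asarray(v) for k, v in model.state_arrays().items()}
    np.savez(path, __config__=np.frombuffer(
        model.config.to_json().encode(), dtype=np.uint8), **state)


def load_checkpoint(path) -> SegUNet:
    with np.load(path) as data:
        cfg = SegModelConfig.from_json(bytes(data["__config__"]).decode())
        model = SegUNet(cfg)
        model.load_state_arrays({k: data[k] for k in data.files
                                 if k != "__config__"})
    return model
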