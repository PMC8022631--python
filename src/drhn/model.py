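"""The deep recurrent hierarchical network (DRHN) for RGB-D posture sequences.

Architecture, in stage order::

    input [t, H, W, 4]                      (RGB + normalized depth)
    depthwise conv 11x11 / stride 2         -> [t, H/2, W/2, 4]
    pointwise conv -> 64, ReLU              -> [t, H/2, W/2, 64]
    spatial dropout 0.2
    depthwise conv 5x5 / stride 2           -> [t, H/4, W/4, 64]
    pointwise conv -> 128, ReLU             -> [t, H/4, W/4, 128]
    spatial dropout 0.2
    convolutional LSTM, 16 filters, 3x3     -> [H/4, W/4, 16]   (time collapsed)
    spatial dropout 0.3
    MobileNetV2-style inverted-residual backbone (five stride-2 stages)
    pointwise conv -> 1280, ReLU            -> [H/128, W/128, 1280]
    global average pooling                  -> [1280]
    dropout 0.5
    fully connected -> 8, sigmoid           (flattened ontology units)

The two leading depthwise+pointwise stages halve the frame exactly twice
(640x480 -> 160x120 with 128 maps); the ConvLSTM aggregates the 1-4 frame
sequence into a single feature map, which the backbone then classifies.  The
8 sigmoid units are independent — a multi-label head over the flattened
posture tree, not a softmax.

``backbone_width_multiplier`` scales the backbone's channel widths (the
final 1280-wide feature stays fixed, as is conventional for width-scaled
MobileNets), making a CPU-trainable model at reduced resolution without
touching the stage logic.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np
import yaml

from . import nn

__all__ = ["DRHNConfig", "DRHN", "FrameSequence", "build_drhn",
           "count_parameters", "normalize_depth"]


@dataclass
class FrameSequence:
    """A short RGB-D clip: ``frames`` [t, H, W, 4] in [0, 1], t in [1, 4],
    with optional per-frame timestamps in seconds."""

    frames: np.ndarray
    timestamps: list[float] | None = None

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=np.float32)
        if self.frames.ndim != 4 or self.frames.shape[-1] != 4:
            raise ValueError(
                f"expected [t, H, W, 4] frames, got {self.frames.shape}"
            )

    def __len__(self) -> int:
        return len(self.frames)

# MobileNetV2 bottleneck schedule: (expansion, channels, repeats, first stride)
_BACKBONE_SCHEDULE = [
    (1, 16, 1, 1),
    (6, 24, 2, 2),
    (6, 32, 3, 2),
    (6, 64, 4, 2),
    (6, 96, 3, 1),
    (6, 160, 3, 2),
    (6, 320, 1, 1),
]
_BACKBONE_STEM_CHANNELS = 32
_BACKBONE_FINAL_CHANNELS = 1280


def _scale_channels(c: int, multiplier: float) -> int:
    """Width-scaled channel count, rounded to a multiple of 8, floor 8."""
    return max(8, int(round(c * multiplier / 8.0)) * 8)


@dataclass
class DRHNConfig:
    """Hyper-parameters of the posture network.

    Defaults reproduce the full-resolution architecture; for CPU training
    use e.g. ``DRHNConfig(input_height=48, input_width=64,
    backbone_width_multiplier=0.35)``.
    """

    input_height: int = 480
    input_width: int = 640
    input_channels: int = 4
    max_sequence_len: int = 4
    dw1_kernel: int = 11
    dw1_stride: int = 2
    conv1_filters: int = 64
    dw2_kernel: int = 5
    dw2_stride: int = 2
    conv2_filters: int = 128
    lstm_filters: int = 16
    lstm_kernel: int = 3
    dropout_spatial_1: float = 0.2
    dropout_spatial_2: float = 0.2
    dropout_spatial_lstm: float = 0.3
    dropout_head: float = 0.5
    backbone_width_multiplier: float = 1.0
    output_units: int = 8
    depth_max_range_m: float = 4.0
    seed: int = 0

    def validate(self) -> None:
        if self.input_height % 4 or self.input_width % 4:
            raise ValueError(
                f"input dims must be divisible by 4 (two exact stride-2 halvings); "
                f"got {self.input_width}x{self.input_height}"
            )
        for p in (
            self.dropout_spatial_1,
            self.dropout_spatial_2,
            self.dropout_spatial_lstm,
            self.dropout_head,
        ):
            if not 0.0 <= p < 1.0:
                raise ValueError(f"dropout probability {p} outside [0, 1)")
        if self.max_sequence_len < 1:
            raise ValueError("max_sequence_len must be >= 1")


class DRHN:
    """A built posture network: stacked layers plus the config that shaped them."""

    def __init__(self, config: DRHNConfig):
        config.validate()
        self.config = config
        rng = np.random.default_rng(config.seed)
        self._dropout_rng = np.random.default_rng(rng.integers(2**31))
        w = config.backbone_width_multiplier

        frontend = nn.Sequential(
            [
                nn.DepthwiseConv2d(
                    config.input_channels, config.dw1_kernel, config.dw1_stride,
                    rng=rng, name="dw1",
                ),
                nn.Conv2d(
                    config.input_channels, config.conv1_filters, 1,
                    rng=rng, name="conv1",
                ),
                nn.ReLU(),
                nn.SpatialDropout2d(config.dropout_spatial_1, rng=self._dropout_rng),
                nn.DepthwiseConv2d(
                    config.conv1_filters, config.dw2_kernel, config.dw2_stride,
                    rng=rng, name="dw2",
                ),
                nn.Conv2d(
                    config.conv1_filters, config.conv2_filters, 1,
                    rng=rng, name="conv2",
                ),
                nn.ReLU(),
                nn.SpatialDropout2d(config.dropout_spatial_2, rng=self._dropout_rng),
            ]
        )
        self.frontend = nn.TimeDistributed(frontend)
        self.convlstm = nn.ConvLSTM(
            config.conv2_filters, config.lstm_filters, config.lstm_kernel, rng=rng
        )
        self.lstm_dropout = nn.SpatialDropout2d(
            config.dropout_spatial_lstm, rng=self._dropout_rng
        )

        # backbone: stem conv + inverted residual blocks + final pointwise conv.
        # A stride-2 stage falls back to stride 1 once it would shrink a map
        # dimension below 2 px, so tiny training resolutions keep meaningful
        # spatial statistics; at full resolution every stride-2 stage fires
        # (160x120 backbone input ends at 4x5).
        map_h, map_w = config.input_height // 4, config.input_width // 4

        def _stage_stride(requested: int) -> int:
            nonlocal map_h, map_w
            s = requested
            if s == 2 and (map_h < 4 or map_w < 4):
                s = 1
            map_h, map_w = -(-map_h // s), -(-map_w // s)
            return s

        stem_c = _scale_channels(_BACKBONE_STEM_CHANNELS, w)
        layers: list[nn.Layer] = [
            nn.Conv2d(config.lstm_filters, stem_c, 3, _stage_stride(2),
                      bias=False, rng=rng, name="stem"),
            nn.GroupNorm2d(stem_c, name="stem_gn"),
            nn.ReLU6(),
        ]
        cin = stem_c
        for bi, (expand, c, repeats, stride) in enumerate(_BACKBONE_SCHEDULE):
            cout = _scale_channels(c, w)
            for r in range(repeats):
                layers.append(
                    nn.InvertedResidual(
                        cin, cout, _stage_stride(stride if r == 0 else 1), expand,
                        rng=rng, name=f"block{bi}_{r}",
                    )
                )
                cin = cout
        layers += [
            nn.Conv2d(cin, _BACKBONE_FINAL_CHANNELS, 1, bias=False, rng=rng,
                      name="head_conv"),
            nn.GroupNorm2d(_BACKBONE_FINAL_CHANNELS, name="head_gn"),
            nn.ReLU6(),
        ]
        self.backbone = nn.Sequential(layers)
        self.pool = nn.GlobalAvgPool()
        self.head_dropout = nn.Dropout(config.dropout_head, rng=self._dropout_rng)
        self.fc = nn.Dense(_BACKBONE_FINAL_CHANNELS, config.output_units, rng=rng,
                           name="fc")
        self._stages = [
            self.frontend, self.convlstm, self.lstm_dropout,
            self.backbone, self.pool, self.head_dropout, self.fc,
        ]

    # ---- forward / backward -------------------------------------------------

    def _check_input(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        if x.ndim != 5:
            raise ValueError(f"expected [batch, t, H, W, C] input, got shape {x.shape}")
        _, t, h, w, c = x.shape
        cfg = self.config
        if not 1 <= t <= cfg.max_sequence_len:
            raise ValueError(
                f"sequence length {t} outside [1, {cfg.max_sequence_len}]"
            )
        if c != cfg.input_channels:
            raise ValueError(f"expected {cfg.input_channels} channels, got {c}")
        if (h, w) != (cfg.input_height, cfg.input_width):
            raise ValueError(
                f"expected {cfg.input_width}x{cfg.input_height} frames, got {w}x{h}"
            )
        return x

    def forward_logits(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        x = self._check_input(x)
        for stage in self._stages:
            x = stage.forward(x, train=train)
        return x

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Batch of sequences -> batch of 8 sigmoid scores in (0, 1)."""
        return nn.sigmoid(self.forward_logits(x, train=train))

    def backward(self, dlogits: np.ndarray) -> None:
        grad = dlogits.astype(np.float32)
        for stage in reversed(self._stages):
            grad = stage.backward(grad)

    def params(self) -> list[nn.Param]:
        return [p for stage in self._stages for p in stage.params()]

    # ---- introspection ------------------------------------------------------

    def shape_summary(self, t: int | None = None) -> list[tuple[str, tuple]]:
        """Analytic per-stage output shapes (no forward pass executed)."""
        cfg = self.config
        t = cfg.max_sequence_len if t is None else t
        shape = (t, cfg.input_height, cfg.input_width, cfg.input_channels)
        rows = [("input", shape)]
        names = [
            "frontend", "convlstm", "lstm_dropout",
            "backbone", "global_avg_pool", "head_dropout", "fully_connected",
        ]
        for name, stage in zip(names, self._stages):
            shape = stage.out_shape(shape)
            rows.append((name, shape))
        return rows

    def save(self, path) -> None:
        """Checkpoint: weights + running stats, with the config as sidecar YAML."""
        path = Path(path)
        state = {
            "params": {p.name: p.data for p in self.params()},
            "running": {
                f"bn{i}": (l.running_mean, l.running_var)
                for i, l in enumerate(self._batchnorms())
            },
        }
        with open(path, "wb") as fh:
            pickle.dump(state, fh)
        with open(path.with_suffix(path.suffix + ".yaml"), "w") as fh:
            yaml.safe_dump(asdict(self.config), fh)

    @classmethod
    def load(cls, path) -> "DRHN":
        path = Path(path)
        with open(path.with_suffix(path.suffix + ".yaml")) as fh:
            config = DRHNConfig(**yaml.safe_load(fh))
        model = cls(config)
        with open(path, "rb") as fh:
            state = pickle.load(fh)
        for p in model.params():
            p.data[...] = state["params"][p.name]
        for i, l in enumerate(model._batchnorms()):
            l.running_mean, l.running_var = state["running"][f"bn{i}"]
        return model

    def _batchnorms(self):
        def walk(layer):
            if isinstance(layer, nn.BatchNorm2d):
                yield layer
            for attr in ("layers",):
                for sub in getattr(layer, attr, []):
                    yield from walk(sub)
            if isinstance(layer, nn.InvertedResidual):
                yield from walk(layer.body)
            if isinstance(layer, nn.TimeDistributed):
                yield from walk(layer.inner)

        for stage in self._stages:
            yield from walk(stage)


def build_drhn(config: DRHNConfig | None = None) -> DRHN:
    """Build the posture network; see :class:`DRHNConfig` for the knobs."""
    return DRHN(config or DRHNConfig())


def count_parameters(model: DRHN) -> int:
    """Total number of trainable scalar parameters."""
    return sum(p.size for p in model.params())


def normalize_depth(depth_m: np.ndarray, max_range_m: float = 4.0) -> np.ndarray:
    """Clamp metric depth at ``max_range_m`` and scale to [0, 1].

    Invalid (non-positive / NaN) readings map to 0, mimicking the dropouts a
    structured-light sensor produces at edges and reflective surfaces.
    """
    d = np.asarray(depth_m, dtype=np.float32)
    out = np.clip(d / max_range_m, 0.0, 1.0)
    return np.where(np.isfinite(d) & (d > 0), out, 0.0).astype(np.float32)
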