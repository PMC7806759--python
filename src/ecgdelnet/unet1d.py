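"""Configurable 1D U-Net for ECG segmentation.

Encoder/decoder with skip connections, adapted to one-dimensional signals:
all convolutions are 1D and zero-padded so every block preserves input length.
The encoder doubles channel width after each downsampling step (level ``l``
carries ``2^l * N`` channels) and the decoder halves it after each upsampling
step, with encoder features concatenated back in.  A stem convolution sits
right after the input, and a final 1x1 convolution + sigmoid emits the three
wave-probability channels (P, QRS, T).

Three convolutional block families are available — vanilla, residual and
"xception" (depthwise-separable with a residual add) — each composed as two
modules of nonlinearity -> regularizers (spatial dropout, batch norm) ->
convolution, i.e. ``y = C(R(NL(C(R(NL(x))))))`` with an optional additive
skip.  The nonlinearity acts on the raw block input as written; the stem is a
plain convolution so the input polarity is not clipped before any feature has
been extracted.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np

from . import nn
from .ecg_io import ECGRecord
from .mask_codec import SegmentationMask

logger = logging.getLogger("ecgdelnet")

BLOCK_TYPES = ("vanilla", "residual", "xception")


@dataclass(frozen=True)
class ArchitectureConfig:
    """The U-Net hyperparameter bundle."""

    block_type: str = "vanilla"
    levels: int = 4  # L: number of resolution levels (the deepest is the bottleneck)
    blocks_per_level: int = 2  # CB
    base_width: int = 8  # N: channels at the top level
    kernel_size: int = 3
    pool_size: int = 2
    spatial_dropout_p: float = 0.0
    use_batch_norm: bool = True
    in_channels: int = 1
    out_channels: int = 3
    seed: int = 1234

    def __post_init__(self):
        if self.block_type not in BLOCK_TYPES:
            raise ValueError(f"unknown block_type {self.block_type!r}")
        if self.kernel_size % 2 != 1:
            raise ValueError("kernel size must be odd")
        if self.pool_size < 2:
            raise ValueError("pool size must be >= 2")
        if not 0.0 <= self.spatial_dropout_p < 1.0:
            raise ValueError("spatial_dropout_p must be in [0, 1)")
        if not (4 <= self.levels <= 7 and 2 <= self.blocks_per_level <= 6):
            warnings.warn(
                f"L={self.levels}, CB={self.blocks_per_level} is outside the "
                "standard sweep ranges L in [4,7], CB in [2,6]", stacklevel=2)

    @property
    def downsample_factor(self) -> int:
        return self.pool_size ** (self.levels - 1)

    def level_width(self, level: int) -> int:
        return (2 ** level) * self.base_width


class ConvBlock:
    """Two convolutional modules, optionally with an additive skip path.

    Each module is NL -> R -> C (ReLU, then spatial dropout + batch norm, then
    convolution).  Residual and xception blocks add the block input back,
    through a 1x1 projection when channel counts differ; xception uses
    depthwise-separable convolutions in place of full ones.
    """

    def __init__(self, block_type: str, in_channels: int, out_channels: int,
                 cfg: ArchitectureConfig, rng: np.random.Generator,
                 dropout_rng: np.random.Generator):
        if block_type not in BLOCK_TYPES:
            raise ValueError(f"unknown block_type {block_type!r}")
        self.block_type = block_type
        conv = nn.SeparableConv1d if block_type == "xception" else nn.Conv1d
        self.seq: list[nn.Layer] = []
        for cin, cout in ((in_channels, out_channels), (out_channels, out_channels)):
            self.seq.append(nn.ReLU())
            if cfg.spatial_dropout_p > 0:
                self.seq.append(nn.SpatialDropout(cfg.spatial_dropout_p, dropout_rng))
            if cfg.use_batch_norm:
                self.seq.append(nn.BatchNorm1d(cin))
            self.seq.append(conv(cin, cout, cfg.kernel_size, rng))
        self.has_skip = block_type in ("residual", "xception")
        self.proj: nn.Conv1d | None = None
        if self.has_skip and in_channels != out_channels:
            self.proj = nn.Conv1d(in_channels, out_channels, 1, rng, bias=False)

    def params(self) -> list[nn.Param]:
        ps = [p for layer in self.seq for p in layer.params()]
        if self.proj is not None:
            ps += self.proj.params()
        return ps

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        h = x
        for layer in self.seq:
            h = layer.forward(h, training)
        if self.has_skip:
            h = h + (self.proj.forward(x, training) if self.proj is not None else x)
        return h

    def backward(self, dy: np.ndarray) -> np.ndarray:
        d = dy
        for layer in reversed(self.seq):
            d = layer.backward(d)
        if self.has_skip:
            d = d + (self.proj.backward(dy) if self.proj is not None else dy)
        return d


def make_block(block_type: str, in_channels: int, out_channels: int,
               cfg: ArchitectureConfig | None = None,
               rng: np.random.Generator | None = None) -> ConvBlock:
    """Standalone block constructor (used by tests and model surgery)."""
    cfg = cfg or ArchitectureConfig(block_type=block_type)
    rng = rng or np.random.default_rng(cfg.seed)
    return ConvBlock(block_type, in_channels, out_channels, cfg, rng, rng)


def spatial_dropout(x: np.ndarray, p: float, training: bool,
                    seed: int | np.random.Generator = 0) -> np.ndarray:
    """Functional channel dropout on a (batch, channels, length) tensor."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    return nn.SpatialDropout(p, rng).forward(x, training)


class UNet1d:
    """The assembled network; see :func:`build_unet`."""

    def __init__(self, cfg: ArchitectureConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        self.dropout_rng = np.random.default_rng(cfg.seed + 1)
        L, CB = cfg.levels, cfg.blocks_per_level

        self.stem = nn.Conv1d(cfg.in_channels, cfg.base_width, cfg.kernel_size, rng)
        self.enc_blocks: list[list[ConvBlock]] = []
        self.pools = [nn.MaxPool1d(cfg.pool_size) for _ in range(L - 1)]
        prev = cfg.base_width
        for level in range(L):
            width = cfg.level_width(level)
            blocks = []
            for b in range(CB):
                blocks.append(ConvBlock(cfg.block_type, prev if b == 0 else width,
                                        width, cfg, rng, self.dropout_rng))
            self.enc_blocks.append(blocks)
            prev = width

        self.upsamples = [nn.Upsample1d(cfg.pool_size) for _ in range(L - 1)]
        self.upconvs: list[nn.Conv1d] = []
        self.dec_blocks: list[list[ConvBlock]] = []
        for level in range(L - 2, -1, -1):
            width = cfg.level_width(level)
            self.upconvs.append(nn.Conv1d(cfg.level_width(level + 1), width,
                                          cfg.kernel_size, rng))
            blocks = []
            for b in range(CB):
                blocks.append(ConvBlock(cfg.block_type, 2 * width if b == 0 else width,
                                        width, cfg, rng, self.dropout_rng))
            self.dec_blocks.append(blocks)
        # decoder lists are ordered deep -> shallow (levels L-2 .. 0)
        self.out_conv = nn.Conv1d(cfg.base_width, cfg.out_channels, 1, rng)
        self.sigmoid = nn.Sigmoid()
        self._enc_out_channels: list[int] = [cfg.level_width(l) for l in range(L)]

    # ------------------------------------------------------------------
    def params(self) -> list[nn.Param]:
        ps = self.stem.params()
        for blocks in self.enc_blocks:
            for b in blocks:
                ps += b.params()
        for conv in self.upconvs:
            ps += conv.params()
        for blocks in self.dec_blocks:
            for b in blocks:
                ps += b.params()
        ps += self.out_conv.params()
        return ps

    def n_parameters(self) -> int:
        return sum(p.value.size for p in self.params())

    def _check_length(self, T: int) -> None:
        factor = self.cfg.downsample_factor
        if T % factor != 0:
            for level in range(1, self.cfg.levels):
                if T % (self.cfg.pool_size ** level) != 0:
                    raise ValueError(
                        f"input length {T} is not divisible by "
                        f"{self.cfg.pool_size}^{level} at level {level}; "
                        f"pad to a multiple of {factor}")

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """(batch, in_channels, T) -> (batch, 3, T) probabilities in [0, 1]."""
        self._check_length(x.shape[2])
        L = self.cfg.levels
        h = self.stem.forward(x, training)
        enc_out: list[np.ndarray] = []
        for level in range(L):
            if level > 0:
                h = self.pools[level - 1].forward(h, training)
            for block in self.enc_blocks[level]:
                h = block.forward(h, training)
            enc_out.append(h)
        self._enc_out_shapes = [e.shape for e in enc_out]
        h = enc_out[-1]
        for i, level in enumerate(range(L - 2, -1, -1)):
            h = self.upsamples[i].forward(h, training)
            h = self.upconvs[i].forward(h, training)
            h = np.concatenate([enc_out[level], h], axis=1)
            for block in self.dec_blocks[i]:
                h = block.forward(h, training)
        return self.sigmoid.forward(self.out_conv.forward(h, training))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        L = self.cfg.levels
        d = self.out_conv.backward(self.sigmoid.backward(dy))
        dskip: list[np.ndarray | None] = [None] * L
        # reverse the decoder (forward order was level L-2 .. 0)
        for i in range(len(self.dec_blocks) - 1, -1, -1):
            level = L - 2 - i
            for block in reversed(self.dec_blocks[i]):
                d = block.backward(d)
            c_skip = self._enc_out_shapes[level][1]
            dskip[level], d = d[:, :c_skip], d[:, c_skip:]
            d = self.upconvs[i].backward(d)
            d = self.upsamples[i].backward(d)
        for level in range(L - 1, -1, -1):
            for block in reversed(self.enc_blocks[level]):
                d = block.backward(d)
            if level > 0:
                d = self.pools[level - 1].backward(d)
                d = d + dskip[level - 1]
        return self.stem.backward(d)

    # ------------------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {f"param_{i}": p.value for i, p in enumerate(self.params())}
        i = 0
        for bn in self._batch_norms():
            state[f"bn_mean_{i}"] = bn.running_mean
            state[f"bn_var_{i}"] = bn.running_var
            i += 1
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.params()):
            p.value = np.array(state[f"param_{i}"], dtype=np.float64)
            p.grad = np.zeros_like(p.value)
        for i, bn in enumerate(self._batch_norms()):
            bn.running_mean = np.array(state[f"bn_mean_{i}"], dtype=np.float64)
            bn.running_var = np.array(state[f"bn_var_{i}"], dtype=np.float64)

    def _batch_norms(self) -> list[nn.BatchNorm1d]:
        bns = []
        for blocks in self.enc_blocks + self.dec_blocks:
            for block in blocks:
                bns += [l for l in block.seq if isinstance(l, nn.BatchNorm1d)]
        return bns

    def save(self, path: str | Path) -> None:
        """Serialize weights + the full architecture config."""
        path = Path(path)
        np.savez(path, __config__=json.dumps(asdict(self.cfg)), **self.state_dict())

    @classmethod
    def load(cls, path: str | Path) -> "UNet1d":
        with np.load(Path(path), allow_pickle=False) as data:
            cfg = ArchitectureConfig(**json.loads(str(data["__config__"])))
            model = cls(cfg)
            model.load_state_dict({k: data[k] for k in data.files if k != "__config__"})
        return model


def build_unet(config: ArchitectureConfig) -> UNet1d:
    """Instantiate the U-Net family member described by ``config``."""
    return UNet1d(config)


@dataclass
class ModelSummary:
    """Per-level tensor geometry and total parameter count."""

    levels: list[dict] = field(default_factory=list)
    n_parameters: int = 0

    def __str__(self) -> str:
        lines = [f"{'level':>5} {'length':>8} {'channels':>8}"]
        for lv in self.levels:
            lines.append(f"{lv['level']:>5} {lv['length']:>8} {lv['channels']:>8}")
        lines.append(f"parameters: {self.n_parameters}")
        return "\n".join(lines)


def summarize(config: ArchitectureConfig, input_length: int) -> ModelSummary:
    model = build_unet(config)
    levels = []
    length = input_length
    for level in range(config.levels):
        if level > 0:
            length //= config.pool_size
        levels.append({"level": level, "length": length,
                       "channels": config.level_width(level)})
    return ModelSummary(levels=levels, n_parameters=model.n_parameters())


def predict_record(model: UNet1d, record: ECGRecord, strategy: str = "single_lead",
                   window: int = 2048, overlap: float = 0.5) -> list[SegmentationMask]:
    """Tile a record into overlapping windows and stitch probability masks.

    ``single_lead`` feeds one lead at a time and returns one mask per lead;
    ``multi_lead`` stacks all leads as input channels and returns one mask.
    Overlapping window probabilities are averaged; records shorter than the
    window are zero-padded and cropped back (logged).
    """
    if strategy not in ("single_lead", "multi_lead"):
        raise ValueError(f"unknown strategy {strategy!r}")
    if window % model.cfg.downsample_factor != 0:
        raise ValueError(
            f"window {window} not divisible by pool^(L-1) = {model.cfg.downsample_factor}")
    if not 0.0 <= overlap < 1.0:
        raise ValueError("overlap must be in [0, 1)")

    if strategy == "single_lead":
        inputs = [record.signal[:, [lead]].T for lead in range(record.n_leads)]
    else:
        inputs = [record.signal.T]

    masks = []
    for x in inputs:  # x: (channels, T)
        masks.append(SegmentationMask(values=_tiled_forward(model, x, window, overlap).T,
                                      fs=record.fs))
    return masks


def _tiled_forward(model: UNet1d, x: np.ndarray, window: int, overlap: float) -> np.ndarray:
    C, T = x.shape
    if T < window:
        logger.info("record shorter than window (%d < %d): padding", T, window)
        xp = np.zeros((C, window))
        xp[:, :T] = x
        y = model.forward(_normalize(xp)[None], training=False)[0]
        return y[:, :T]
    stride = max(1, int(round(window * (1.0 - overlap))))
    starts = list(range(0, T - window + 1, stride))
    if starts[-1] != T - window:
        starts.append(T - window)
    acc = np.zeros((model.cfg.out_channels, T))
    count = np.zeros(T)
    for s in starts:
        y = model.forward(_normalize(x[:, s:s + window])[None], training=False)[0]
        acc[:, s:s + window] += y
        count[s:s + window] += 1.0
    return acc / count[None, :]


def _normalize(x: np.ndarray) -> np.ndarray:
    """Per-channel z-scoring of one window (training and inference alike)."""
    mean = x.mean(axis=-1, keepdims=True)
    std = x.std(axis=-1, keepdims=True)
    return (x - mean) / np.maximum(std, 1e-8)
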