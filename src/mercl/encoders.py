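"""Spatiotemporal encoding: pluggable spatial encoders + a Residual-TCN.

Each modality stream is first mapped by a *spatial* encoder to a feature
sequence ``s_m`` of shape (T_m, D_m); a registry lets large published
encoders (vision transformers, audio CNNs, attention-free conformers) be
attached through the same callable contract as the small reference encoders
that ship here.  A temporal convolutional network with dilated causal
convolutions, batch normalization, ELU, dropout and residual connections
then produces the spatiotemporal representation ``h_m`` of shape (T_m, D)
with a common feature width D across modalities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._tensor import Tensor, Parameter
from .nn import Module, BatchNorm, Dropout, Linear
from .preprocess import subsample_frames

__all__ = [
    "SpatialFeatures", "TcnConfig", "dilated_conv", "DilatedConv1d",
    "TcnBlock", "ResidualTCN", "receptive_field", "EncoderRegistry",
    "IdentityEncoder", "FrameFeatureEncoder", "LogMelAudioEncoder",
    "BandPowerEegEncoder",
]


@dataclass
class SpatialFeatures:
    """Output of a spatial encoder: (T_m, D_m) feature sequence."""

    features: np.ndarray
    modality: str

    def __post_init__(self):
        self.features = np.atleast_2d(np.asarray(self.features, dtype=np.float64))
        if not np.isfinite(self.features).all():
            raise ValueError(f"non-finite spatial features for {self.modality!r}")


def dilated_conv(x, f, d: int):
    """Dilated causal convolution of a 1-D sequence.

    ``F(t) = sum_{i=0}^{k-1} f(i) * x(t - d*i)`` with ``x(tau) = 0`` for
    ``tau < 0``; the output has the same length as the input.
    """
    x = np.asarray(x, dtype=np.float64).reshape(-1)
    f = np.asarray(f, dtype=np.float64).reshape(-1)
    if x.size == 0 or f.size == 0:
        raise ValueError("dilated_conv requires nonempty input and filter")
    if d < 1:
        raise ValueError(f"dilation must be >= 1, got {d}")
    pad = d * (f.size - 1)
    xp = np.concatenate([np.zeros(pad), x])
    out = np.zeros_like(x)
    for i, fi in enumerate(f):
        out += fi * xp[pad - d * i: pad - d * i + x.size]
    return out


def receptive_field(kernel_size: int, dilations) -> int:
    """Time steps seen by the last output of a stack of dilated convs."""
    return 1 + (kernel_size - 1) * int(sum(dilations))


@dataclass
class TcnConfig:
    kernel_size: int = 3
    dilations: tuple = (1, 2, 4, 8)
    n_blocks: int = 4
    dropout_rate: float = 0.5
    channels: int = 128
    activation: str = "elu"
    convs_per_block: int = 1
    norm_mode: str = "batch"

    def __post_init__(self):
        if len(self.dilations) != self.n_blocks:
            raise ValueError("dilation list length must equal n_blocks")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.kernel_size < 1:
            raise ValueError("kernel_size must be >= 1")


class DilatedConv1d(Module):
    """Causal dilated convolution over (B, T, C_in) -> (B, T, C_out)."""

    def __init__(self, in_ch: int, out_ch: int, kernel_size: int, dilation: int,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        scale = np.sqrt(2.0 / (kernel_size * in_ch + out_ch))
        self.weight = Parameter(rng.normal(0, scale, (kernel_size, in_ch, out_ch)))
        self.bias = Parameter(np.zeros(out_ch))
        self.kernel_size = kernel_size
        self.dilation = dilation

    def forward(self, x: Tensor) -> Tensor:
        x = Tensor.as_tensor(x)
        k, d = self.kernel_size, self.dilation
        t = x.shape[-2]
        pad = d * (k - 1)
        xp = x.pad_time(pad, axis=-2)
        # tap i multiplies x(t - d*i): slice starting at pad - d*i
        out = None
        for i in range(k):
            sl = [slice(None)] * xp.ndim
            sl[-2] = slice(pad - d * i, pad - d * i + t)
            term = xp[tuple(sl)] @ self.weight[i]
            out = term if out is None else out + term
        return out + self.bias


class TcnBlock(Module):
    """dilated conv → batch norm → ELU → dropout → residual add."""

    def __init__(self, in_ch: int, out_ch: int, cfg: TcnConfig, dilation: int,
                 rng: np.random.Generator):
        self.convs = [DilatedConv1d(in_ch if i == 0 else out_ch, out_ch,
                                    cfg.kernel_size, dilation, rng)
                      for i in range(cfg.convs_per_block)]
        self.norms = [BatchNorm(out_ch, mode=cfg.norm_mode)
                      for _ in range(cfg.convs_per_block)]
        self.dropout = Dropout(cfg.dropout_rate, rng=np.random.default_rng(
            rng.integers(2**31)))
        # width-matching linear shortcut when in/out widths differ
        self.shortcut = Linear(in_ch, out_ch, bias=False, rng=rng) \
            if in_ch != out_ch else None
        self.activation = cfg.activation

    def forward(self, x: Tensor) -> Tensor:
        y = x
        for conv, norm in zip(self.convs, self.norms):
            y = conv(y)
            y = norm(y)
            y = y.elu() if self.activation == "elu" else y.relu()
            y = self.dropout(y)
        res = self.shortcut(x) if self.shortcut is not None else x
        return y + res


class ResidualTCN(Module):
    """Stack of TCN blocks with geometrically increasing dilations."""

    def __init__(self, in_width: int, cfg: TcnConfig | None = None,
                 rng: np.random.Generator | None = None):
        cfg = cfg or TcnConfig()
        rng = rng or np.random.default_rng()
        self.cfg = cfg
        widths = [in_width] + [cfg.channels] * cfg.n_blocks
        self.blocks = [TcnBlock(widths[i], widths[i + 1], cfg, d, rng)
                       for i, d in enumerate(cfg.dilations)]

    def forward(self, x) -> Tensor:
        x = Tensor.as_tensor(x)
        if not np.isfinite(x.data).all():
            raise ValueError("non-finite input to ResidualTCN")
        for block in self.blocks:
            x = block(x)
        return x

    def receptive_field(self) -> int:
        return receptive_field(self.cfg.kernel_size,
                               [d * self.cfg.convs_per_block
                                for d in self.cfg.dilations])


# ---------------------------------------------------------------------------
# Spatial encoder registry and reference encoders
# ---------------------------------------------------------------------------

class EncoderRegistry:
    """Maps a modality tag to its spatial encoder.

    An encoder is any callable mapping the modality's preprocessed block
    feature to a ``SpatialFeatures`` (T_m, D_m) array and declaring its
    ``output_width``.  Published pre-trained encoders attach through the
    same contract.
    """

    def __init__(self):
        self._encoders: dict = {}

    def register(self, modality: str, encoder, override: bool = False):
        if not hasattr(encoder, "output_width"):
            raise ValueError("encoder must declare output_width")
        if modality in self._encoders and not override:
            raise ValueError(
                f"encoder already registered for {modality!r}; pass override=True")
        self._encoders[modality] = encoder
        return modality

    def get(self, modality: str):
        try:
            return self._encoders[modality]
        except KeyError:
            raise KeyError(f"no encoder registered for modality {modality!r}") from None

    def __contains__(self, modality):
        return modality in self._encoders


class IdentityEncoder:
    """Passes precomputed (T, D) features through unchanged."""

    def __init__(self, output_width: int, modality: str = "video"):
        self.output_width = output_width
        self.modality = modality

    def __call__(self, features) -> SpatialFeatures:
        feats = np.atleast_2d(np.asarray(features, dtype=np.float64))
        if feats.shape[1] != self.output_width:
            raise ValueError(
                f"expected width {self.output_width}, got {feats.shape[1]}")
        return SpatialFeatures(feats, self.modality)


class _FixedRandomMap:
    """Seeded, non-trained linear map standing in for a pre-trained backbone."""

    def __init__(self, in_width, out_width, seed):
        rng = np.random.default_rng(seed)
        self.w = rng.normal(0, 1.0 / np.sqrt(in_width), (in_width, out_width))
        self.b = rng.normal(0, 0.05, out_width)

    def __call__(self, x):
        return np.tanh(x @ self.w + self.b)


class FrameFeatureEncoder:
    """Reference video encoder: subsample frames, fixed nonlinear projection.

    Stands in for a large pre-trained vision backbone: it is deterministic,
    untrained and frozen; only its output shape contract matters downstream.
    """

    def __init__(self, in_width: int, output_width: int = 32,
                 frames_per_block: int = 16, seed: int = 11):
        self.output_width = output_width
        self.frames_per_block = frames_per_block
        self._map = _FixedRandomMap(in_width, output_width, seed)

    def __call__(self, video_block) -> SpatialFeatures:
        frames = np.asarray(video_block, dtype=np.float64)
        if frames.ndim > 2:                       # raw frames → flatten pixels
            frames = frames.reshape(frames.shape[0], -1)
        frames = subsample_frames(frames, self.frames_per_block)
        return SpatialFeatures(self._map(frames), "video")


class LogMelAudioEncoder:
    """Reference audio encoder over a (frames, n_mels) log-Mel spectrogram.

    Averages spectrogram frames into ``t_out`` temporal chunks and applies a
    fixed nonlinear projection per chunk.
    """

    def __init__(self, n_mels: int = 20, output_width: int = 32,
                 t_out: int = 16, seed: int = 12):
        self.output_width = output_width
        self.t_out = t_out
        self._map = _FixedRandomMap(n_mels, output_width, seed)

    def __call__(self, lms) -> SpatialFeatures:
        lms = np.atleast_2d(np.asarray(lms, dtype=np.float64))
        edges = np.linspace(0, lms.shape[0], self.t_out + 1).round().astype(int)
        chunks = np.stack([lms[edges[i]:max(edges[i + 1], edges[i] + 1)].mean(axis=0)
                           for i in range(self.t_out)])
        return SpatialFeatures(self._map(chunks), "audio")


class BandPowerEegEncoder:
    """Reference EEG encoder over per-block (channels, bands) power.

    A small fixed dense stack over the flattened channel x band grid — an
    attention-free convolutional design in spirit — repeated to ``t_out``
    time steps so the temporal encoder sees a sequence.  Band powers are
    log-compressed first since raw powers span decades.
    """

    def __init__(self, n_channels: int, n_bands: int = 5, output_width: int = 32,
                 t_out: int = 4, seed: int = 13):
        self.output_width = output_width
        self.t_out = t_out
        self._map = _FixedRandomMap(n_channels * n_bands, output_width, seed)

    def __call__(self, psd) -> SpatialFeatures:
        flat = np.log(np.asarray(psd, dtype=np.float64).reshape(-1) + 1e-12)
        row = self._map(flat[None, :])
        return SpatialFeatures(np.repeat(row, self.t_out, axis=0), "eeg")
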