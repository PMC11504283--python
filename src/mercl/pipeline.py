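"""End-to-end model assembly: features → encoders → embeddings → fusion.

``build_features`` turns raw trials into per-block spatial feature arrays
(one row of blocks across the whole dataset), and ``MerclModel`` bundles the
trainable components: the shared Residual-TCN temporal encoder, the three
projection heads, the six cross-modal attention blocks and the classifier.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from ._tensor import Tensor
from .encoders import (BandPowerEegEncoder, EncoderRegistry, FrameFeatureEncoder,
                       LogMelAudioEncoder, ResidualTCN, TcnConfig)
from .fusion import MlpClassifier, PairwiseCMA
from .losses import MODALITIES, MerclWeights, ProjectionHead
from .preprocess import (PreprocessConfig, audio_energy_select, eeg_band_psd,
                         log_mel_spectrogram, segment_trial)

__all__ = ["FeatureSet", "ModelConfig", "MerclModel", "build_features",
           "default_registry"]


@dataclass
class FeatureSet:
    """Per-block spatial features for every modality, plus block metadata."""

    video: np.ndarray                  # (N, T_v, D_in)
    audio: np.ndarray                  # (N, T_a, D_in)
    eeg: np.ndarray                    # (N, T_e, D_in)
    labels: np.ndarray                 # (N,)
    trial_ids: np.ndarray              # (N,) str
    energy_flags: list                 # AudioEnergyFlag per block

    def __len__(self):
        return self.labels.size

    def subset(self, idx) -> "FeatureSet":
        idx = np.asarray(idx)
        return FeatureSet(self.video[idx], self.audio[idx], self.eeg[idx],
                          self.labels[idx], self.trial_ids[idx],
                          [self.energy_flags[i] for i in idx])

    def as_dict(self) -> dict:
        return {"video": self.video, "audio": self.audio, "eeg": self.eeg}


def default_registry(video_in_width: int, eeg_channels: int,
                     spatial_width: int = 32, frames_per_block: int = 16,
                     audio_t_out: int = 16, eeg_t_out: int = 4) -> EncoderRegistry:
    """Registry with the three reference spatial encoders."""
    reg = EncoderRegistry()
    reg.register("video", FrameFeatureEncoder(video_in_width, spatial_width,
                                              frames_per_block))
    reg.register("audio", LogMelAudioEncoder(20, spatial_width, audio_t_out))
    reg.register("eeg", BandPowerEegEncoder(eeg_channels, 5, spatial_width,
                                            eeg_t_out))
    return reg


def build_features(trials, pre_cfg: PreprocessConfig | None = None,
                   registry: EncoderRegistry | None = None) -> FeatureSet:
    """Segment trials into blocks and spatially encode every modality.

    Audio energy flags are computed once over all blocks of the dataset so
    percentile/relative thresholds see the full batch of energies.
    """
    pre_cfg = pre_cfg or PreprocessConfig()
    if registry is None:
        first = trials[0]
        v_width = int(np.prod(first.video.shape[1:]))
        registry = default_registry(v_width, first.eeg.shape[0],
                                    frames_per_block=pre_cfg.video_frames_per_block)
    v_rows, a_rows, e_rows, labels, tids, audio_blocks = [], [], [], [], [], []
    for trial in trials:
        bs = segment_trial(trial, pre_cfg.block_len_s, pre_cfg.overlap_frac,
                           pre_cfg.lag_s)
        for video_b, audio_b, eeg_b in bs.blocks:
            lms = log_mel_spectrogram(audio_b, trial.audio_fs, pre_cfg.window_ms,
                                      pre_cfg.hop_ms, pre_cfg.n_mels)
            psd = eeg_band_psd(eeg_b, trial.eeg_fs, pre_cfg.band_edges_hz)
            v_rows.append(registry.get("video")(video_b).features)
            a_rows.append(registry.get("audio")(lms.lms).features)
            e_rows.append(registry.get("eeg")(psd.psd).features)
            audio_blocks.append(audio_b)
            labels.append(bs.label)
            tids.append(bs.trial_id)
    flags = audio_energy_select(audio_blocks, pre_cfg.energy_threshold_mode,
                                pre_cfg.energy_threshold_value)
    return FeatureSet(np.stack(v_rows), np.stack(a_rows), np.stack(e_rows),
                      np.array(labels), np.array(tids), flags)


@dataclass
class ModelConfig:
    n_classes: int = 4
    width: int = 128                   # common representation width D
    proj_width: int = 64               # shared embedding width P
    n_heads: int = 4
    hidden: int = 256
    classifier_dropout: float = 0.1
    pooling: str = "mean"              # temporal pooling before projection
    fusion_pooling: str = "mean"
    normalized: bool = True
    raw_scores: bool = False
    tcn: dict = field(default_factory=dict)
    seed: int = 0


class MerclModel:
    """Shared TCN + projection heads + pairwise CMA + MLP classifier."""

    def __init__(self, in_width: int, cfg: ModelConfig | None = None):
        self.cfg = cfg or ModelConfig()
        self.in_width = in_width
        rng = np.random.default_rng(self.cfg.seed)
        tcn_cfg = TcnConfig(channels=self.cfg.width, **self.cfg.tcn)
        self.tcn = ResidualTCN(in_width, tcn_cfg, rng)
        self.projections = {m: ProjectionHead(self.cfg.width, self.cfg.proj_width,
                                              self.cfg.pooling,
                                              self.cfg.normalized, rng)
                            for m in MODALITIES}
        self.cma = PairwiseCMA(self.cfg.width, self.cfg.n_heads,
                               self.cfg.fusion_pooling, self.cfg.raw_scores,
                               rng=rng)
        self.classifier = MlpClassifier(6 * self.cfg.width, self.cfg.n_classes,
                                        self.cfg.hidden,
                                        self.cfg.classifier_dropout, rng)

    # -- parameter groups ----------------------------------------------
    def encoder_parameters(self):
        params = self.tcn.parameters()
        for p in self.projections.values():
            params.extend(p.parameters())
        return params

    def head_parameters(self):
        return self.cma.parameters() + self.classifier.parameters()

    def encoder_modules(self):
        return [self.tcn] + list(self.projections.values())

    def encoder_checksum(self) -> float:
        return float(sum(np.sum(p.data * (i + 1))
                         for i, p in enumerate(self.encoder_parameters())))

    def train(self):
        for m in self.encoder_modules() + [self.cma, self.classifier]:
            m.train()
        return self

    def eval(self):
        for m in self.encoder_modules() + [self.cma, self.classifier]:
            m.eval()
        return self

    # -- forward pieces --------------------------------------------------
    def encode(self, features: dict) -> dict:
        """Spatial features (N, T, D_in) → spatiotemporal h_m (N, T, D)."""
        return {m: self.tcn(Tensor.as_tensor(features[m])) for m in MODALITIES}

    def embed(self, h: dict) -> dict:
        """h_m → shared-space embeddings z_m (N, P)."""
        return {m: self.projections[m](h[m]) for m in MODALITIES}

    def fuse_and_classify(self, h: dict):
        fused = self.cma(h)
        return self.classifier(fused.concatenated), fused

    # -- persistence ------------------------------------------------------
    def _all_parameters(self):
        return self.encoder_parameters() + self.head_parameters()

    def save(self, path):
        path = Path(path)
        arrays = {f"param_{i}": p.data for i, p in enumerate(self._all_parameters())}
        for j, m in enumerate(self.encoder_modules()):
            for k, mod in enumerate(m.modules()):
                if hasattr(mod, "running_mean"):
                    arrays[f"bn_{j}_{k}_mean"] = mod.running_mean
                    arrays[f"bn_{j}_{k}_var"] = mod.running_var
        np.savez(path, config=json.dumps({"in_width": self.in_width,
                                          "cfg": asdict(self.cfg)}), **arrays)

    @classmethod
    def load(cls, path):
        data = np.load(Path(path).with_suffix(".npz") if not str(path).endswith(".npz")
                       else path, allow_pickle=False)
        meta = json.loads(str(data["config"]))
        model = cls(meta["in_width"], ModelConfig(**meta["cfg"]))
        for i, p in enumerate(model._all_parameters()):
            p.data = data[f"param_{i}"].copy()
        for j, m in enumerate(model.encoder_modules()):
            for k, mod in enumerate(m.modules()):
                if hasattr(mod, "running_mean") and f"bn_{j}_{k}_mean" in data:
                    mod.running_mean = data[f"bn_{j}_{k}_mean"].copy()
                    mod.running_var = data[f"bn_{j}_{k}_var"].copy()
        return model
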