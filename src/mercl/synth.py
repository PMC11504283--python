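"""Synthetic three-modality trial generator.

Emulates the statistical structure the pipeline assumes: every trial has a
class-conditional latent vector, and each modality observes a different
linear view of that latent — so the three streams share class structure
without being copies of each other:

* a **video** frame-feature sequence (per-frame noisy copies of the
  modality view, standing in for backbone features of rendered frames),
* an **audio** waveform of amplitude-modulated tones whose per-band
  loudness encodes the latent coordinates, so a log-Mel spectrogram
  recovers class-informative features,
* a multi-channel **EEG** signal whose per-band oscillation amplitudes
  encode the latent coordinates, so band power recovers them.

A controllable ``modality_gap`` adds a fixed per-modality offset direction
to each view (larger gap → lower same-sample cross-modal similarity), and
``silent_audio_frac`` replaces that fraction of trials' audio with
near-zero noise (1e-4 amplitude) to exercise energy-based exclusion.

What this generator does **not** emulate: real EEG physiology (evoked
potentials, artifacts, 1/f background), natural video statistics, or
perceptually plausible audio.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .preprocess import TrialRecord

__all__ = ["SynthSpec", "SynthDataset", "generate", "export", "load"]

_BAND_CENTER_HZ = (2.0, 6.0, 10.5, 21.5, 37.5)


@dataclass
class SynthSpec:
    n_classes: int = 4                 # mirrors the HVHA/LVHA/LVLA/HVLA scheme
    n_trials_per_class: int = 10
    latent_width: int = 8
    class_separation: float = 2.0
    latent_noise_sd: float = 0.25
    noise_sd: dict = field(default_factory=lambda: {
        "video": 0.10, "audio": 0.005, "eeg": 0.10})
    modality_gap: float = 0.5
    silent_audio_frac: float = 0.0
    trial_len_s: float = 8.0
    video_fps: float = 16.0
    video_feature_width: int = 16
    audio_fs: float = 16000.0
    eeg_fs: float = 128.0
    eeg_channels: int = 8
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.silent_audio_frac <= 1.0:
            raise ValueError("silent_audio_frac must be in [0, 1]")
        if any(v < 0 for v in self.noise_sd.values()) or self.latent_noise_sd < 0:
            raise ValueError("noise standard deviations must be nonnegative")
        if self.n_classes < 2 or self.n_trials_per_class < 1:
            raise ValueError("need >= 2 classes and >= 1 trial per class")
        if self.latent_width < max(self.n_classes, 3):
            raise ValueError("latent_width must be >= max(n_classes, 3)")


@dataclass
class SynthDataset:
    trials: list                       # TrialRecord
    latents: np.ndarray                # (n_trials, L) true latent vectors
    modality_views: dict               # modality -> (n_trials, L) linear views
    silent_trial_ids: list
    spec: SynthSpec

    def labels(self) -> np.ndarray:
        return np.array([t.label for t in self.trials])

    def manifest(self) -> dict:
        return {"spec": asdict(self.spec), "n_trials": len(self.trials),
                "silent_trial_ids": list(self.silent_trial_ids)}


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _orthonormal(rng, rows, cols):
    q, _ = np.linalg.qr(rng.normal(size=(max(rows, cols), cols)))
    return q[:rows] if rows <= q.shape[0] else q


def generate(spec: SynthSpec) -> SynthDataset:
    """Draw a dataset from the spec; same spec (incl. seed) → same dataset."""
    rng = np.random.default_rng(spec.seed)
    L = spec.latent_width
    n = spec.n_classes * spec.n_trials_per_class

    # equidistant-ish centroids: orthonormal directions scaled by separation
    centroids = _orthonormal(rng, spec.n_classes, L) * spec.class_separation
    # per-modality linear views: each mixing map is the nearest orthogonal
    # matrix to a shared map plus a modality-specific perturbation, so the
    # three views are linked (high same-sample similarity at zero gap) but
    # not identical; gap offsets are mutually orthogonal directions
    shared = np.linalg.qr(rng.normal(size=(L, L)))[0]
    mix = {}
    for m in ("video", "audio", "eeg"):
        u, _, vt = np.linalg.svd(shared + 0.4 * rng.normal(size=(L, L)) / np.sqrt(L))
        mix[m] = u @ vt
    gap_dirs = np.linalg.qr(rng.normal(size=(L, 3)))[0].T   # 3 orthonormal rows
    gap = {m: gap_dirs[i] for i, m in enumerate(("video", "audio", "eeg"))}

    labels = np.repeat(np.arange(spec.n_classes), spec.n_trials_per_class)
    latents = centroids[labels] + spec.latent_noise_sd * rng.normal(size=(n, L))
    views = {m: latents @ mix[m].T + spec.modality_gap * gap[m]
             for m in ("video", "audio", "eeg")}

    n_silent = int(round(spec.silent_audio_frac * n))
    silent_ids = sorted(rng.choice(n, size=n_silent, replace=False).tolist())
    silent_set = set(silent_ids)

    # fixed observation maps from the modality view to each raw stream
    frame_map = rng.normal(0, 1.0 / np.sqrt(L), (L, spec.video_feature_width))
    eeg_map = rng.normal(0, 1.0 / np.sqrt(L),
                         (L, spec.eeg_channels * len(_BAND_CENTER_HZ)))
    tone_freqs = np.geomspace(200.0, 4000.0, L)

    n_frames = int(round(spec.trial_len_s * spec.video_fps))
    t_audio = np.arange(int(round(spec.trial_len_s * spec.audio_fs))) / spec.audio_fs
    t_eeg = np.arange(int(round(spec.trial_len_s * spec.eeg_fs))) / spec.eeg_fs

    trials = []
    for i in range(n):
        # video: per-frame noisy copies of the projected view
        base = views["video"][i] @ frame_map
        video = base[None, :] + spec.noise_sd["video"] * rng.normal(
            size=(n_frames, spec.video_feature_width))

        # audio: amplitude-modulated tone stack
        if i in silent_set:
            audio = 1e-4 * rng.normal(size=t_audio.size)
        else:
            amps = 0.05 * (1.0 + _sigmoid(views["audio"][i]))
            phases = rng.uniform(0, 2 * np.pi, L)
            audio = np.sum(amps[:, None] * np.sin(
                2 * np.pi * tone_freqs[:, None] * t_audio[None, :]
                + phases[:, None]), axis=0)
            audio += spec.noise_sd["audio"] * rng.normal(size=t_audio.size)

        # EEG: per-channel per-band oscillation amplitudes
        amp_grid = 0.5 * (1.0 + _sigmoid(views["eeg"][i] @ eeg_map)).reshape(
            spec.eeg_channels, len(_BAND_CENTER_HZ))
        phases = rng.uniform(0, 2 * np.pi,
                             (spec.eeg_channels, len(_BAND_CENTER_HZ)))
        eeg = np.zeros((spec.eeg_channels, t_eeg.size))
        for b, f in enumerate(_BAND_CENTER_HZ):
            eeg += amp_grid[:, b:b + 1] * np.sin(
                2 * np.pi * f * t_eeg[None, :] + phases[:, b:b + 1])
        eeg += spec.noise_sd["eeg"] * rng.normal(size=eeg.shape)

        trials.append(TrialRecord(
            trial_id=f"trial_{i:04d}", label=int(labels[i]), video=video,
            video_fps=spec.video_fps, audio=audio, audio_fs=spec.audio_fs,
            eeg=eeg, eeg_fs=spec.eeg_fs))

    return SynthDataset(trials=trials, latents=latents, modality_views=views,
                        silent_trial_ids=silent_ids, spec=spec)


def export(dataset: SynthDataset, path) -> Path:
    """Write the HDF5 + WAV container layout (plus a JSON manifest)."""
    import h5py
    from scipy.io import wavfile

    path = Path(path)
    try:
        path.mkdir(parents=True, exist_ok=True)
        wav_dir = path / "wav"
        wav_dir.mkdir(exist_ok=True)
        with h5py.File(path / "trials.h5", "w") as f:
            for t in dataset.trials:
                g = f.create_group(t.trial_id)
                g.create_dataset("video", data=t.video)
                g["video"].attrs["fps"] = t.video_fps
                g.create_dataset("eeg", data=t.eeg)
                g["eeg"].attrs["fs_hz"] = t.eeg_fs
                g.attrs["label"] = t.label
                g.attrs["audio_fs"] = t.audio_fs
                # 64-bit float WAV: bit-exact round trip
                wavfile.write(wav_dir / f"{t.trial_id}.wav", int(t.audio_fs),
                              t.audio)
            f.create_dataset("latents", data=dataset.latents)
            for m, v in dataset.modality_views.items():
                f.create_dataset(f"views/{m}", data=v)
        (path / "manifest.json").write_text(
            json.dumps(dataset.manifest(), indent=2))
    except OSError as err:
        raise OSError(f"failed to export dataset to {path}: {err}") from err
    return path


def load(path) -> SynthDataset:
    """Round-trip loader for the exported container layout."""
    import h5py
    from scipy.io import wavfile

    path = Path(path)
    manifest = json.loads((path / "manifest.json").read_text())
    spec = SynthSpec(**manifest["spec"])
    trials = []
    with h5py.File(path / "trials.h5", "r") as f:
        trial_ids = sorted(k for k in f.keys() if k.startswith("trial_"))
        for tid in trial_ids:
            g = f[tid]
            fs, audio = wavfile.read(path / "wav" / f"{tid}.wav")
            if np.issubdtype(audio.dtype, np.integer):   # PCM → float in [-1, 1]
                audio = audio / float(np.iinfo(audio.dtype).max)
            trials.append(TrialRecord(
                trial_id=tid, label=int(g.attrs["label"]),
                video=g["video"][...], video_fps=float(g["video"].attrs["fps"]),
                audio=np.asarray(audio, dtype=np.float64), audio_fs=float(fs),
                eeg=g["eeg"][...], eeg_fs=float(g["eeg"].attrs["fs_hz"])))
        latents = f["latents"][...]
        views = {m: f[f"views/{m}"][...] for m in ("video", "audio", "eeg")}
    return SynthDataset(trials=trials, latents=latents, modality_views=views,
                        silent_trial_ids=manifest["silent_trial_ids"], spec=spec)
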