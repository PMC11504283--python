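"""Trial preprocessing: segmentation, EEG band power, log-Mel spectrograms.

A trial is one stimulus/response recording carrying three temporally aligned
streams — a video frame(-feature) sequence, an audio waveform and a
multi-channel EEG array — plus an integer emotion label.  Preprocessing cuts
every trial into fixed-length windows (4 s with 50 % overlap by default),
after an optional fixed per-modality lag correction, and turns each window
into modality features:

* EEG: band power in the five classical bands delta (0.4–4 Hz), theta
  (4–8 Hz), alpha (8–13 Hz), beta (13–30 Hz) and gamma (30–45 Hz), obtained
  by zero-phase band-limited filtering followed by average power.
* audio: a log-Mel spectrogram (50 ms Hamming window, 10 ms hop, 20 Mel
  filter banks).
* audio presence: the energy of each window, thresholded so that silent or
  near-silent audio can be excluded from the sample-wise alignment loss.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

__all__ = [
    "TrialRecord", "BlockSet", "EegBandPsd", "LogMelSpectrogram",
    "AudioEnergyFlag", "PreprocessConfig", "TrialTooShortError",
    "NyquistError", "DEFAULT_BAND_EDGES_HZ", "segment_trial", "eeg_band_psd",
    "log_mel_spectrogram", "audio_energy_select", "subsample_frames",
]

#: (low, high) edges in Hz of the five EEG bands, in canonical order
#: delta, theta, alpha, beta, gamma.
DEFAULT_BAND_EDGES_HZ: tuple = (
    (0.4, 4.0), (4.0, 8.0), (8.0, 13.0), (13.0, 30.0), (30.0, 45.0))


class TrialTooShortError(ValueError):
    """Raised when a trial cannot supply even a single block."""


class NyquistError(ValueError):
    """Raised when the sampling rate cannot resolve the requested bands."""


@dataclass
class TrialRecord:
    """One trial: three synchronized streams and a label.

    ``video`` may be raw frames (T, H, W, C) or a precomputed frame-feature
    sequence (T, D_v); both are treated as a sequence sampled at
    ``video_fps``.  EEG is (channels, samples) in microvolts.
    """

    trial_id: str
    label: int
    video: np.ndarray
    video_fps: float
    audio: np.ndarray
    audio_fs: float
    eeg: np.ndarray
    eeg_fs: float

    def __post_init__(self):
        self.video = np.asarray(self.video, dtype=np.float64)
        self.audio = np.asarray(self.audio, dtype=np.float64).reshape(-1)
        self.eeg = np.asarray(self.eeg, dtype=np.float64)
        for name, fs in (("video_fps", self.video_fps),
                         ("audio_fs", self.audio_fs), ("eeg_fs", self.eeg_fs)):
            if fs <= 0:
                raise ValueError(f"{name} must be positive, got {fs}")
        if self.eeg.ndim != 2:
            raise ValueError("eeg must be (channels, samples)")

    def durations_s(self) -> dict:
        return {
            "video": self.video.shape[0] / self.video_fps,
            "audio": self.audio.shape[0] / self.audio_fs,
            "eeg": self.eeg.shape[1] / self.eeg_fs,
        }


@dataclass
class BlockSet:
    """Aligned fixed-length windows cut from one trial."""

    blocks: list                       # (video_block, audio_block, eeg_block)
    start_times_s: np.ndarray
    block_len_s: float
    overlap_frac: float
    lag_s: dict
    label: int
    trial_id: str

    def __len__(self):
        return len(self.blocks)


@dataclass
class EegBandPsd:
    psd: np.ndarray                    # (channels, n_bands), power units
    band_edges_hz: tuple


@dataclass
class LogMelSpectrogram:
    lms: np.ndarray                    # (frames, n_mels), natural-log power
    window_ms: float
    hop_ms: float
    n_mels: int
    log_floor: float


@dataclass
class AudioEnergyFlag:
    energy: float
    is_present: bool
    threshold: float


@dataclass
class PreprocessConfig:
    block_len_s: float = 4.0
    overlap_frac: float = 0.5
    band_edges_hz: tuple = DEFAULT_BAND_EDGES_HZ
    n_mels: int = 20
    window_ms: float = 50.0
    hop_ms: float = 10.0
    energy_threshold_mode: str = "relative"
    energy_threshold_value: float = 0.05
    lag_s: dict = field(default_factory=dict)
    video_frames_per_block: int = 16


def _stream_slice(arr, fs, t0, t1, time_axis=0):
    i0 = int(round(t0 * fs))
    n = int(round((t1 - t0) * fs))
    sl = [slice(None)] * arr.ndim
    sl[time_axis] = slice(i0, i0 + n)
    return arr[tuple(sl)]


def segment_trial(trial: TrialRecord, block_len_s: float = 4.0,
                  overlap_frac: float = 0.5, lag_s: dict | None = None) -> BlockSet:
    """Cut a trial into aligned overlapping blocks.

    Block starts step by ``block_len_s * (1 - overlap_frac)``; the number of
    blocks is ``floor((duration - block_len) / hop) + 1``.  ``lag_s`` applies
    a fixed synchronization lag per modality (the named modality's stream is
    advanced by dropping its first ``lag`` seconds) before windowing.
    """
    if not 0.0 <= overlap_frac < 1.0:
        raise ValueError(f"overlap_frac must be in [0, 1), got {overlap_frac}")
    if block_len_s <= 0:
        raise ValueError("block_len_s must be positive")
    lag_s = dict(lag_s or {})
    for m in lag_s:
        if m not in ("video", "audio", "eeg"):
            raise ValueError(f"unknown modality in lag_s: {m!r}")

    streams = {
        "video": (trial.video, trial.video_fps, 0),
        "audio": (trial.audio, trial.audio_fs, 0),
        "eeg": (trial.eeg, trial.eeg_fs, 1),
    }
    trimmed = {}
    for m, (arr, fs, axis) in streams.items():
        lag = lag_s.get(m, 0.0)
        if lag:
            arr = _stream_slice(arr, fs, lag, arr.shape[axis] / fs, time_axis=axis)
        trimmed[m] = (arr, fs, axis)

    duration = min(arr.shape[axis] / fs for arr, fs, axis in trimmed.values())
    hop = block_len_s * (1.0 - overlap_frac)
    if duration < block_len_s - 1e-9:
        raise TrialTooShortError(
            f"trial {trial.trial_id!r} too short: {duration:.3f} s of aligned "
            f"signal, need at least one {block_len_s} s block")
    n_blocks = int(np.floor((duration - block_len_s) / hop + 1e-9)) + 1
    starts = np.arange(n_blocks) * hop

    blocks = []
    for t0 in starts:
        t1 = t0 + block_len_s
        v, vfs, _ = trimmed["video"]
        a, afs, _ = trimmed["audio"]
        e, efs, _ = trimmed["eeg"]
        blocks.append((_stream_slice(v, vfs, t0, t1),
                       _stream_slice(a, afs, t0, t1),
                       _stream_slice(e, efs, t0, t1, time_axis=1)))
    return BlockSet(blocks=blocks, start_times_s=starts, block_len_s=block_len_s,
                    overlap_frac=overlap_frac, lag_s=lag_s, label=trial.label,
                    trial_id=trial.trial_id)


def subsample_frames(video_block: np.ndarray, n_frames: int) -> np.ndarray:
    """Uniformly subsample a frame sequence to ``n_frames`` frames."""
    t = video_block.shape[0]
    if t == 0:
        raise ValueError("empty video block")
    idx = np.linspace(0, t - 1, n_frames).round().astype(int)
    return video_block[idx]


def eeg_band_psd(eeg_block: np.ndarray, fs: float,
                 band_edges: tuple = DEFAULT_BAND_EDGES_HZ,
                 filter_order: int = 4) -> EegBandPsd:
    """Per-channel band power via zero-phase Butterworth bandpass filtering.

    Each band is isolated with a ``filter_order``-order IIR bandpass applied
    forward-backward (zero phase); the band power is the mean squared
    amplitude of the filtered signal.  Requires ``fs`` above twice the
    highest band edge and a block at least one period of the lowest band
    edge long.
    """
    x = np.atleast_2d(np.asarray(eeg_block, dtype=np.float64))
    if np.isnan(x).any() or not np.isfinite(x).all():
        raise ValueError("EEG block contains NaN or infinite values")
    edges = tuple(tuple(map(float, b)) for b in band_edges)
    fmax = max(hi for _, hi in edges)
    if fs <= 2.0 * fmax:
        raise NyquistError(
            f"sampling rate {fs} Hz cannot resolve bands up to {fmax} Hz "
            f"(need fs > {2 * fmax} Hz)")
    fmin = min(lo for lo, _ in edges)
    if x.shape[1] / fs < 1.0 / fmin:
        raise ValueError(
            f"block of {x.shape[1] / fs:.2f} s is shorter than one period "
            f"of the lowest band edge ({fmin} Hz)")
    psd = np.empty((x.shape[0], len(edges)))
    if not np.any(x):
        psd[:] = 0.0                   # all-zero signal short-circuits filtering
    else:
        for b, (lo, hi) in enumerate(edges):
            sos = sps.butter(filter_order, (lo, hi), btype="bandpass",
                             fs=fs, output="sos")
            filt = sps.sosfiltfilt(sos, x, axis=1)
            psd[:, b] = np.mean(filt**2, axis=1)
    return EegBandPsd(psd=psd, band_edges_hz=edges)


def _mel_hz(m):
    return 700.0 * (10.0 ** (m / 2595.0) - 1.0)


def _hz_mel(f):
    return 2595.0 * np.log10(1.0 + f / 700.0)


def mel_filter_bank(n_mels: int, n_fft: int, fs: float) -> np.ndarray:
    """Triangular Mel filters (HTK scale) on rfft bins: (n_mels, n_fft//2+1)."""
    mel_pts = np.linspace(_hz_mel(0.0), _hz_mel(fs / 2.0), n_mels + 2)
    hz_pts = _mel_hz(mel_pts)
    bins = np.fft.rfftfreq(n_fft, d=1.0 / fs)
    fb = np.zeros((n_mels, bins.size))
    for i in range(n_mels):
        lo, ctr, hi = hz_pts[i], hz_pts[i + 1], hz_pts[i + 2]
        up = (bins - lo) / max(ctr - lo, 1e-12)
        down = (hi - bins) / max(hi - ctr, 1e-12)
        fb[i] = np.clip(np.minimum(up, down), 0.0, None)
    return fb


def log_mel_spectrogram(audio_block: np.ndarray, fs: float,
                        window_ms: float = 50.0, hop_ms: float = 10.0,
                        n_mels: int = 20, log_floor: float = 1e-10) -> LogMelSpectrogram:
    """STFT power → Mel filter bank → natural log (with additive floor).

    The frame count is ``floor((N - window) / hop) + 1`` for a block of N
    samples; scaling the waveform by c > 1 cannot decrease any cell.
    """
    x = np.asarray(audio_block, dtype=np.float64).reshape(-1)
    if x.size == 0:
        raise ValueError("empty audio block")
    win = int(round(fs * window_ms / 1000.0))
    hop = int(round(fs * hop_ms / 1000.0))
    if x.size < win:
        raise ValueError(
            f"audio block of {x.size} samples shorter than one "
            f"{window_ms} ms window ({win} samples)")
    n_frames = (x.size - win) // hop + 1
    window = np.hamming(win)
    idx = np.arange(win)[None, :] + hop * np.arange(n_frames)[:, None]
    frames = x[idx] * window
    spec = np.abs(np.fft.rfft(frames, axis=1)) ** 2
    fb = mel_filter_bank(n_mels, win, fs)
    mel = spec @ fb.T
    return LogMelSpectrogram(lms=np.log(mel + log_floor), window_ms=window_ms,
                             hop_ms=hop_ms, n_mels=n_mels, log_floor=log_floor)


def audio_energy_select(audio_blocks, threshold_mode: str = "relative",
                        threshold_value: float = 0.05):
    """Flag each block as audio-present or silent by total energy Σx².

    Modes: ``absolute`` (threshold is the value itself), ``percentile``
    (threshold is the given percentile of the batch energies) and
    ``relative`` (default; threshold is ``value`` times the median batch
    energy, which separates a silent minority from the speaking majority
    regardless of the silent fraction).
    """
    blocks = list(audio_blocks)
    if not blocks:
        raise ValueError("audio_energy_select needs at least one block")
    energies = np.array([float(np.sum(np.square(np.asarray(b, dtype=np.float64))))
                         for b in blocks])
    if threshold_mode == "absolute":
        thr = float(threshold_value)
    elif threshold_mode == "percentile":
        if not 0.0 <= threshold_value <= 100.0:
            raise ValueError(
                f"percentile must be in [0, 100], got {threshold_value}")
        thr = float(np.percentile(energies, threshold_value))
    elif threshold_mode == "relative":
        if threshold_value < 0:
            raise ValueError("relative threshold factor must be nonnegative")
        thr = float(threshold_value * np.median(energies))
    else:
        raise ValueError(f"unknown threshold_mode {threshold_mode!r}")
    return [AudioEnergyFlag(energy=float(e), is_present=bool(e >= thr), threshold=thr)
            for e in energies]
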