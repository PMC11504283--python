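"""Segmentation, EEG band power, log-Mel spectrogram and energy selection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mercl.preprocess import (DEFAULT_BAND_EDGES_HZ, NyquistError,
                              TrialRecord, TrialTooShortError,
                              audio_energy_select, eeg_band_psd,
                              log_mel_spectrogram, segment_trial)
from oracles import block_starts_bruteforce, periodogram_band_power


def make_trial(duration_s, label=0, video_fps=16.0, audio_fs=1000.0,
               eeg_fs=128.0, n_channels=2):
    n_v = int(round(duration_s * video_fps))
    n_a = int(round(duration_s * audio_fs))
    n_e = int(round(duration_s * eeg_fs))
    rng = np.random.default_rng(0)
    return TrialRecord("t0", label, rng.normal(size=(n_v, 4)), video_fps,
                       rng.normal(size=n_a) * 0.1, audio_fs,
                       rng.normal(size=(n_channels, n_e)), eeg_fs)


class TestSegmentation:
    def test_60s_trial_gives_29_half_overlapping_blocks(self):
        bs = segment_trial(make_trial(60.0), block_len_s=4.0, overlap_frac=0.5)
        assert len(bs) == 29
        assert np.allclose(bs.start_times_s, np.arange(29) * 2.0)

    def test_exactly_one_block_covers_whole_trial(self):
        trial = make_trial(4.0)
        bs = segment_trial(trial)
        assert len(bs) == 1
        _, audio_b, eeg_b = bs.blocks[0]
        assert audio_b.size == trial.audio.size
        assert eeg_b.shape == trial.eeg.shape

    def test_short_trial_raises_not_empty(self):
        with pytest.raises(TrialTooShortError, match="too short"):
            segment_trial(make_trial(3.0))

    @pytest.mark.parametrize("overlap", [-0.1, 1.0, 1.5])
    def test_invalid_overlap_rejected(self, overlap):
        with pytest.raises(ValueError, match="overlap"):
            segment_trial(make_trial(10.0), overlap_frac=overlap)

    @settings(max_examples=120, deadline=None)
    @given(duration=st.floats(4.0, 40.0),
           block_len=st.floats(1.0, 4.0),
           overlap=st.floats(0.0, 0.9))
    def test_block_count_matches_bruteforce_enumeration(self, duration,
                                                        block_len, overlap):
        hop = block_len * (1.0 - overlap)
        trial = make_trial(duration, audio_fs=200.0)
        realized = min(trial.durations_s().values())   # rounded to samples
        expected = block_starts_bruteforce(realized, block_len, hop)
        bs = segment_trial(trial, block_len, overlap)
        assert len(bs) == len(expected)
        assert np.allclose(bs.start_times_s, expected)

    def test_lag_trims_stream_start(self):
        trial = make_trial(10.0)
        bs = segment_trial(trial, lag_s={"eeg": 2.0})
        # eeg stream loses 2 s, so only 8 s of aligned signal remain
        assert len(bs) == 3
        _, _, eeg_b = bs.blocks[0]
        assert np.array_equal(eeg_b, trial.eeg[:, int(2.0 * trial.eeg_fs):
                                               int(6.0 * trial.eeg_fs)])

    def test_all_blocks_share_trial_label(self):
        bs = segment_trial(make_trial(12.0, label=3))
        assert bs.label == 3


class TestEegBandPsd:
    def test_pure_alpha_tone_dominates_alpha_band(self):
        fs = 200.0
        t = np.arange(int(4 * fs)) / fs
        x = np.sin(2 * np.pi * 10.0 * t)          # 10 Hz → alpha (8–13 Hz)
        res = eeg_band_psd(x, fs)
        psd = res.psd[0]
        alpha = psd[2]
        assert all(alpha >= 10 * psd[b] for b in range(5) if b != 2)
        # cross-check magnitude against a direct DFT periodogram
        oracle = periodogram_band_power(x, fs, 8.0, 13.0)
        assert alpha == pytest.approx(oracle, rel=0.05)

    def test_two_tone_signal_power_lands_in_own_bands(self):
        fs = 200.0
        t = np.arange(int(4 * fs)) / fs
        x = np.sin(2 * np.pi * 6.0 * t) + 0.5 * np.sin(2 * np.pi * 21.0 * t)
        psd = eeg_band_psd(x, fs).psd[0]
        theta_oracle = periodogram_band_power(x, fs, 4.0, 8.0)
        beta_oracle = periodogram_band_power(x, fs, 13.0, 30.0)
        assert psd[1] >= 0.9 * theta_oracle
        assert psd[3] >= 0.9 * beta_oracle

    def test_zero_block_gives_zero_power(self):
        psd = eeg_band_psd(np.zeros((3, 512)), 128.0).psd
        assert np.all(psd == 0.0)

    def test_total_band_power_bounded_by_signal_power(self, rng):
        x = rng.normal(size=(2, 1024))
        psd = eeg_band_psd(x, 128.0).psd
        total = np.mean(x**2, axis=1)
        assert np.all(psd.sum(axis=1) <= total * 1.05)
        assert np.all(psd >= 0)

    def test_default_band_edges(self):
        assert DEFAULT_BAND_EDGES_HZ == (
            (0.4, 4.0), (4.0, 8.0), (8.0, 13.0), (13.0, 30.0), (30.0, 45.0))

    def test_nyquist_violation_raises(self):
        with pytest.raises(NyquistError):
            eeg_band_psd(np.ones((1, 400)), fs=80.0)

    def test_nan_rejected(self):
        x = np.ones((1, 1024))
        x[0, 5] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            eeg_band_psd(x, 128.0)


class TestLogMel:
    def test_one_second_at_16khz_gives_96_frames(self):
        lms = log_mel_spectrogram(np.random.default_rng(0).normal(size=16000),
                                  16000.0)
        assert lms.lms.shape == (96, 20)

    def test_silence_hits_log_floor_everywhere(self):
        lms = log_mel_spectrogram(np.zeros(8000), 16000.0, log_floor=1e-10)
        assert np.allclose(lms.lms, np.log(1e-10))

    def test_louder_never_decreases_any_cell(self, rng):
        x = rng.normal(size=8000) * 0.1
        a = log_mel_spectrogram(x, 16000.0).lms
        b = log_mel_spectrogram(3.0 * x, 16000.0).lms
        assert np.all(b >= a - 1e-12)

    def test_n_mels_defaults_to_20(self):
        assert log_mel_spectrogram(np.ones(4000), 16000.0).n_mels == 20

    def test_empty_waveform_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            log_mel_spectrogram(np.array([]), 16000.0)


class TestEnergySelect:
    def test_constant_amplitude_block_energy(self):
        flags = audio_energy_select([np.full(100, 0.5)], "absolute", 1.0)
        assert flags[0].energy == pytest.approx(25.0)

    def test_zero_block_absent_under_any_positive_threshold(self):
        flags = audio_energy_select([np.zeros(64)], "absolute", 1e-9)
        assert not flags[0].is_present

    def test_percentile_mode_excludes_exactly_zero_energy_block(self):
        blocks = [np.zeros(10), np.ones(1), np.ones(1), np.ones(1)]
        flags = audio_energy_select(blocks, "percentile", 10.0)
        assert [f.is_present for f in flags] == [False, True, True, True]
        assert flags[0].threshold == pytest.approx(np.percentile([0, 1, 1, 1], 10))

    def test_percentile_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="percentile"):
            audio_energy_select([np.ones(4)], "percentile", 120.0)

    def test_absolute_mode_is_order_invariant(self, rng):
        blocks = [rng.normal(size=50) for _ in range(6)]
        flags = audio_energy_select(blocks, "absolute", 10.0)
        rev = audio_energy_select(blocks[::-1], "absolute", 10.0)
        assert [f.is_present for f in flags] == [f.is_present for f in rev][::-1]

    def test_percentile_mode_is_permutation_equivariant(self, rng):
        blocks = [rng.normal(size=50) * s for s in (0.01, 0.5, 1.0, 2.0, 3.0)]
        perm = [3, 0, 4, 2, 1]
        flags = audio_energy_select(blocks, "percentile", 25.0)
        permuted = audio_energy_select([blocks[i] for i in perm], "percentile", 25.0)
        assert [flags[i].is_present for i in perm] == [f.is_present for f in permuted]

    def test_relative_default_separates_silent_minority(self, rng):
        loud = [0.3 * rng.normal(size=1000) for _ in range(9)]
        silent = [1e-4 * rng.normal(size=1000) for _ in range(3)]
        flags = audio_energy_select(loud + silent)
        assert [f.is_present for f in flags] == [True] * 9 + [False] * 3
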