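"""Acoustic feature extraction: framing, voicing, F0, jitter, formants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import speechnet as sn
from speechnet.acoustics import (ExtractionConfig, FrameSet, compute_intensity,
                                 compute_jitter, compute_speech_rate,
                                 count_syllables, detect_voiced, estimate_f0,
                                 extract_features, preprocess)

NO_TRIM = ExtractionConfig(trim_threshold_rel=0.0)


def _sine(f0=180.0, sr=22050, dur=2.0, amp=0.5):
    t = np.arange(int(sr * dur)) / sr
    return sn.AudioSignal(amp * np.sin(2 * np.pi * f0 * t), sr)


class TestPreprocess:
    def test_pre_emphasis_closed_form_on_constant(self):
        sig = sn.AudioSignal(np.full(4096, 0.25), 22050)
        frames = preprocess(sig, NO_TRIM)
        # interior pre-emphasized samples are (1 - 0.97) * c
        emph = frames.frames[1] / np.hamming(frames.window_len)
        np.testing.assert_allclose(emph, 0.03 * 0.25, rtol=1e-9)

    def test_frame_count_integer_arithmetic(self):
        frames = preprocess(_sine(dur=1.0), NO_TRIM)
        assert frames.n_frames == 1 + (22050 - 512) // 256 == 85

    def test_all_zero_signal_raises(self):
        with pytest.raises(ValueError):
            preprocess(sn.AudioSignal(np.zeros(22050) + 0.0, 22050),
                       ExtractionConfig())

    def test_short_signal_raises(self):
        with pytest.raises(ValueError, match="shorter"):
            preprocess(sn.AudioSignal(np.ones(100), 22050), NO_TRIM)

    def test_trim_removes_leading_silence(self):
        body = _sine(dur=1.0).samples
        padded = np.concatenate([np.zeros(5000), body, np.zeros(5000)])
        frames = preprocess(sn.AudioSignal(padded, 22050), ExtractionConfig())
        assert 4000 < frames.trim_start <= 5000
        assert frames.trim_stop >= 5000 + body.size - 300


class TestVoicing:
    def test_white_noise_mostly_unvoiced(self, noise_signal):
        mask = detect_voiced(preprocess(noise_signal, NO_TRIM))
        assert mask.mean() <= 0.1

    def test_continuous_vowel_mostly_voiced(self, plain_vowel):
        mask = detect_voiced(preprocess(plain_vowel.signal, ExtractionConfig()))
        assert mask.mean() >= 0.9

    def test_silent_frames_unvoiced(self):
        z = np.zeros((4, 512))
        frames = FrameSet(frames=z, raw_frames=z, window_len=512, hop=256,
                          window="hamming", pre_emphasis=0.97, sample_rate=22050,
                          trimmed_samples=np.zeros(1280))
        assert not detect_voiced(frames).any()


class TestF0:
    def test_pure_tone(self):
        row = extract_features(_sine(180.0), ExtractionConfig())
        assert row.f0_mean == pytest.approx(180.0, abs=1.0)

    def test_out_of_band_tone_flagged_missing(self):
        frames = preprocess(_sine(180.0), NO_TRIM)
        mask = detect_voiced(frames)
        track = estimate_f0(frames, mask, f0_min=300.0, f0_max=400.0)
        assert np.isnan(track.mean_f0)

    def test_invalid_band_raises(self):
        frames = preprocess(_sine(180.0), NO_TRIM)
        with pytest.raises(ValueError):
            estimate_f0(frames, np.ones(frames.n_frames, bool),
                        f0_min=400.0, f0_max=300.0)


class TestJitter:
    def test_equal_periods_zero(self):
        assert compute_jitter(np.full(50, 0.005)) == 0.0

    def test_hand_example(self):
        periods = np.array([10.0, 11.0, 10.0, 11.0]) * 1e-3
        assert compute_jitter(periods, "ratio") == pytest.approx(0.0952381, abs=1e-6)
        assert compute_jitter(periods, "percent") == pytest.approx(9.52381, abs=1e-4)

    def test_too_few_periods_missing(self):
        assert np.isnan(compute_jitter(np.array([0.005])))

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=1e-4, max_value=0.02), min_size=2,
                    max_size=60))
    def test_matches_one_line_oracle(self, periods):
        periods = np.asarray(periods)
        oracle = (np.abs(np.diff(periods)).sum() / (len(periods) - 1)) / periods.mean()
        assert compute_jitter(periods, "ratio") == pytest.approx(oracle, rel=1e-12)


class TestIntensity:
    def test_full_scale_square_wave_is_zero_dbfs(self):
        square = np.where(np.sin(np.arange(22050) / 10.0) >= 0, 1.0, -1.0)
        frames = preprocess(sn.AudioSignal(square, 22050), NO_TRIM)
        assert compute_intensity(frames, calibration_offset_db=0.0) == \
            pytest.approx(0.0, abs=1e-6)

    def test_halving_amplitude_drops_6db(self, plain_vowel):
        loud = preprocess(plain_vowel.signal, NO_TRIM)
        soft = preprocess(sn.AudioSignal(plain_vowel.signal.samples / 2, 22050),
                          NO_TRIM)
        drop = compute_intensity(loud) - compute_intensity(soft)
        assert drop == pytest.approx(20 * np.log10(2), abs=1e-9)

    def test_silent_frames_hit_floor(self):
        z = np.zeros((3, 512))
        frames = FrameSet(frames=z, raw_frames=z, window_len=512, hop=256,
                          window="hamming", pre_emphasis=0.97, sample_rate=22050,
                          trimmed_samples=np.zeros(1024))
        assert compute_intensity(frames, floor_db=-120.0) == -120.0


class TestGainInvariance:
    """+g dB gain shifts intensity exactly; jitter and F1/F2 are unmoved."""

    def test_gain_equivariance_and_invariance(self, plain_vowel, quiet):
        cfg = ExtractionConfig()
        base = extract_features(plain_vowel.signal, cfg, plain_vowel.annotation)
        gained = sn.AudioSignal(plain_vowel.signal.samples * 10 ** (6.0 / 20.0),
                                22050)
        up = extract_features(gained, cfg, plain_vowel.annotation)
        assert up.intensity - base.intensity == pytest.approx(6.0, abs=1e-6)
        assert up.jitter == pytest.approx(base.jitter, abs=1e-9)
        assert up.f1f2 == pytest.approx(base.f1f2, rel=1e-9)


class TestSpeechRate:
    def test_transcript_heuristic_hand_count(self):
        assert count_syllables("hello world") == 3
        assert compute_speech_rate("hello world", 3.0) == pytest.approx(1.0)

    def test_empty_transcript_warns_zero(self):
        with pytest.warns(UserWarning):
            assert compute_speech_rate("", 3.0) == 0.0

    def test_annotation_count_division(self):
        assert compute_speech_rate({"syllable_count": 12}, 9.5) == \
            pytest.approx(1.2631578947)

    def test_vowelless_words_count_one(self):
        assert count_syllables("hmm pfft") == 2


class TestExtractFeatures:
    def test_smoke_all_fields_populated(self, plain_vowel, quiet):
        row = extract_features(plain_vowel.signal, ExtractionConfig(),
                               plain_vowel.annotation)
        for v in row.as_dict().values():
            assert np.isfinite(v)

    def test_near_silence_flags_missing_never_zero(self, quiet):
        sig = sn.AudioSignal(np.full(22050, 1e-9), 22050)
        row = extract_features(sig, ExtractionConfig(), "hello world")
        assert np.isnan(row.jitter) and np.isnan(row.f1f2)
        assert row.warnings

    def test_white_noise_formants_flagged(self, noise_signal, quiet):
        row = extract_features(noise_signal, ExtractionConfig())
        assert np.isnan(row.f1f2)

    def test_jitter_sweep_rank_correlation(self, quiet):
        from scipy import stats as sstats

        planted, recovered = [], []
        for k, jit in enumerate(np.linspace(0.0, 2.0, 10)):
            v = sn.synthesize_vowel(
                sn.VoiceParams(jitter_pct=jit, duration_s=1.5, noise_db=-30.0),
                seed=100 + k)
            row = extract_features(v.signal, ExtractionConfig(), v.annotation)
            planted.append(v.realized_jitter_pct)
            recovered.append(row.jitter)
        rho = sstats.spearmanr(planted, recovered).statistic
        assert rho >= 0.9


class TestAudioIO:
    def test_wav_round_trip_16bit(self, tmp_path):
        sig = _sine(dur=0.2)
        path = tmp_path / "tone.wav"
        sn.write_wav(path, sig)
        back = sn.read_wav(path)
        assert back.sample_rate == sig.sample_rate
        np.testing.assert_allclose(back.samples, sig.samples, atol=1.5 / 2**15)

    def test_stereo_downmix_warns(self, tmp_path):
        from scipy.io import wavfile

        path = tmp_path / "stereo.wav"
        data = (np.ones((1000, 2)) * 1000).astype(np.int16)
        wavfile.write(path, 22050, data)
        with pytest.warns(UserWarning, match="stereo"):
            sig = sn.read_wav(path)
        assert sig.samples.ndim == 1
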