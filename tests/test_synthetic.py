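"""Synthetic generators: planted precision matrices, tables, vowels."""

import json

import numpy as np
import pytest
from scipy import stats

import speechnet as sn
from speechnet import study
from speechnet.network import precision_to_pcor, spearman_matrix
from speechnet.synthetic import (build_precision, formant_filter_response,
                                 write_vowel)


class TestBuildPrecision:
    def test_empty_graph_is_identity(self):
        K = build_precision([], 5)
        np.testing.assert_allclose(K.matrix, np.eye(5))

    def test_two_node_edge_matches_hand_inversion(self):
        # K = [[1, -0.5], [-0.5, 1]]; pcor = -K01/sqrt(K00*K11) = 0.5
        K = build_precision([(0, 1, 0.5)], 2)
        assert K.matrix[0, 1] == pytest.approx(-0.5)
        cov = np.linalg.inv(K.matrix)  # hand: (1/0.75) * [[1, .5], [.5, 1]]
        np.testing.assert_allclose(cov, np.array([[1, 0.5], [0.5, 1]]) / 0.75)
        assert precision_to_pcor(K.matrix)[0, 1] == pytest.approx(0.5, abs=1e-12)

    def test_high_anxiety_topology_round_trip(self):
        labels = study.SPEECH_VARIABLES
        idx = {n: i for i, n in enumerate(labels)}
        edges = [(idx[a], idx[b], w) for a, b, w in study.HIGH_EDGES]
        K = build_precision(edges, 5, labels=labels)
        assert np.linalg.eigvalsh(K.matrix).min() > 0
        P = precision_to_pcor(K.matrix)
        for i, j, w in edges:
            assert P[i, j] == pytest.approx(w, abs=1e-6)

    def test_random_dominant_edge_sets_round_trip(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            p = rng.integers(3, 7)
            pairs = [(i, j) for i in range(p) for j in range(i + 1, p)]
            rng.shuffle(pairs)
            chosen = pairs[: rng.integers(1, p)]
            # row-wise diagonally dominant weights are always feasible
            edges = [(i, j, rng.uniform(-0.9, 0.9) / p) for i, j in chosen]
            P = precision_to_pcor(build_precision(edges, p).matrix)
            for i, j, w in edges:
                assert P[i, j] == pytest.approx(w, abs=1e-6)

    @pytest.mark.parametrize("bad", [(0, 0, 0.5), (0, 1, 1.0), (0, 1, -1.3)])
    def test_invalid_edges_rejected(self, bad):
        with pytest.raises(ValueError):
            build_precision([bad], 3)

    def test_infeasible_set_raises_naming_edges(self):
        # all-positive partials of 0.9 on a triangle are jointly infeasible
        # (no sign flip of the nodes makes I - P positive definite)
        edges = [(0, 1, 0.9), (1, 2, 0.9), (0, 2, 0.9)]
        with pytest.raises(ValueError, match="infeasible|positive-definite"):
            build_precision(edges, 3)


class TestFeatureTable:
    def test_marginals_match_within_3se(self, quiet):
        spec = sn.high_group_spec()
        tab = sn.generate_feature_table(spec, 5)
        for var in study.SPEECH_VARIABLES:
            mean, sd = study.TABLE1[var]["high"]
            se = sd / np.sqrt(spec.n)
            assert abs(tab[var].mean() - mean) < 3 * se

    def test_seed_reproducibility(self, quiet):
        spec = sn.low_group_spec()
        a = sn.generate_feature_table(spec, 9)
        b = sn.generate_feature_table(spec, 9)
        c = sn.generate_feature_table(spec, 10)
        assert a.equals(b)
        assert not a.drop(columns="group").equals(c.drop(columns="group"))

    def test_empty_edges_give_independent_columns(self):
        spec = sn.GroupSpec(label="null", n=400,
                            marginal_means={v: 0.0 for v in study.SPEECH_VARIABLES},
                            marginal_sds={v: 1.0 for v in study.SPEECH_VARIABLES},
                            edges=[])
        tab = sn.generate_feature_table(spec, 3)
        S = spearman_matrix(tab, study.SPEECH_VARIABLES).matrix
        off = S[np.triu_indices(5, 1)]
        # null sampling band for Spearman rho at n = 400 (3 SE)
        assert np.all(np.abs(off) < 3 / np.sqrt(400 - 1))

    def test_large_n_partial_correlations_converge(self, quiet):
        spec = sn.high_group_spec(5000)
        tab = sn.generate_feature_table(spec, 17)
        S = spearman_matrix(tab, study.SPEECH_VARIABLES).matrix
        K = np.linalg.inv(S)
        P = precision_to_pcor(K)
        idx = {n: i for i, n in enumerate(study.SPEECH_VARIABLES)}
        for a, b, w in study.HIGH_EDGES:
            assert abs(P[idx[a], idx[b]] - w) < 0.05

    def test_group_ratings_respect_split(self, quiet):
        low = sn.generate_feature_table(sn.low_group_spec(), 2)
        high = sn.generate_feature_table(sn.high_group_spec(), 2)
        assert set(low["anxiety"]) <= {0, 1}
        assert set(high["anxiety"]) <= {2, 3}

    def test_total_spec_couples_anxiety_to_jitter(self, quiet):
        tab = sn.generate_feature_table(sn.total_group_spec(5000), 21)
        rho = stats.spearmanr(tab["anxiety"], tab["jitter"]).statistic
        assert rho < -0.05  # planted negative coupling survives discretization

    def test_zero_probability_category_warns(self):
        with pytest.warns(UserWarning, match="zero-probability"):
            sn.generate_feature_table(sn.low_group_spec(50), 1)


class TestVowelSynthesis:
    def test_zero_jitter_gives_constant_periods(self):
        v = sn.synthesize_vowel(
            sn.VoiceParams(jitter_pct=0.0, noise_db=-np.inf, duration_s=1.0),
            seed=0)
        assert v.realized_jitter_pct == 0.0
        assert np.ptp(v.periods_s) < 1e-12

    def test_mean_period_matches_f0(self):
        v = sn.synthesize_vowel(sn.VoiceParams(f0_hz=180.0, duration_s=3.0),
                                seed=1)
        assert v.periods_s.mean() == pytest.approx(1 / 180.0, rel=0.005)

    def test_syllable_count_at_study_rate(self):
        v = sn.synthesize_vowel(
            sn.VoiceParams(syllable_rate=1.26, duration_s=10.0), seed=2)
        assert v.syllable_count in (12, 13)
        assert v.annotation["syllable_count"] == v.syllable_count

    def test_formant_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            sn.VoiceParams(formants=((500.0, 80.0), (12000.0, 100.0)),
                           sample_rate=22050)

    def test_rms_calibration_self_consistent(self):
        from speechnet.acoustics import (ExtractionConfig, compute_intensity,
                                         preprocess)
        v = sn.synthesize_vowel(sn.VoiceParams(rms_db=67.5, duration_s=2.0),
                                seed=3)
        frames = preprocess(v.signal, ExtractionConfig())
        assert compute_intensity(frames) == pytest.approx(67.5, abs=0.5)

    def test_filter_response_peaks_at_formants(self):
        from scipy.signal import find_peaks

        # near-isolated resonator: peak at the requested center within a bin
        freqs, mag = formant_filter_response(
            sn.VoiceParams(formants=((500.0, 80.0), (9999.0, 100.0))),
            n_fft=4096)
        bin_hz = freqs[1] - freqs[0]
        low_peaks, _ = find_peaks(mag[: len(freqs) // 2])
        assert np.min(np.abs(freqs[low_peaks] - 500.0)) <= bin_hz

        # cascade: neighbor skirts shift each peak slightly; within 1.5%
        params = sn.VoiceParams(formants=((500.0, 80.0), (1500.0, 100.0),
                                          (2500.0, 140.0)))
        freqs, mag = formant_filter_response(params, n_fft=4096)
        peaks, _ = find_peaks(mag)
        for fc, _bw in params.formants:
            assert np.min(np.abs(freqs[peaks] - fc)) <= 0.015 * fc

    def test_wav_sidecar_round_trip(self, tmp_path):
        v = sn.synthesize_vowel(sn.VoiceParams(duration_s=0.5), seed=4)
        wav = tmp_path / "vowel.wav"
        write_vowel(wav, v)
        back = sn.read_wav(wav)
        assert back.sample_rate == v.signal.sample_rate
        assert len(back) == len(v.signal)
        with open(str(wav) + ".json") as fh:
            truth = json.load(fh)
        assert truth["f0_hz"] == v.params.f0_hz
        assert len(truth["realized_periods_s"]) == len(v.periods_s)
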