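"""Synthetic study data: planted networks, feature tables, and vowels.

Two generators make every downstream stage testable without recordings:

* ``generate_feature_table`` draws per-speaker feature rows from a sparse
  Gaussian graphical model with *known* partial correlations, rescaled to
  requested marginal means/SDs. The ordinal anxiety rating is produced by
  quantile-cutting the latent Gaussian anxiety node, which preserves the
  rank-correlation machinery the network estimator relies on. Default group
  specifications reproduce the reference study's group marginals, sample
  sizes (119 low- / 197 high-anxiety) and published network topologies.

* ``synthesize_vowel`` builds a source-filter vowel: a fractional-delay
  impulse train whose periods carry calibrated Gaussian jitter, cascaded
  two-pole formant resonators, syllable-rate amplitude modulation, additive
  noise, and an intensity calibration that shares its measurement
  definition with the extractor. Ground truth (realized periods, syllable
  count) is returned alongside the signal.

Jitter calibration: with i.i.d. Gaussian period perturbations of standard
deviation sigma (as a fraction of the mean period), the expected local
jitter is E|T_i - T_{i-1}| / E[T] = 2*sigma/sqrt(pi), so sigma is set to
jitter_pct/100 * sqrt(pi)/2.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats

from . import study
from .acoustics import compute_jitter, trim_silence
from .audio import AudioSignal, write_wav
from .network import precision_to_pcor

__all__ = [
    "VoiceParams",
    "GroupSpec",
    "PrecisionMatrix",
    "SynthesizedVowel",
    "build_precision",
    "generate_feature_table",
    "synthesize_vowel",
    "formant_filter_response",
    "low_group_spec",
    "high_group_spec",
    "total_group_spec",
    "generate_study_table",
    "write_vowel",
]

FEATURE_COLUMNS = ["jitter", "f0", "f1f2", "intensity", "speech_rate",
                   "anxiety", "group"]


# ---------------------------------------------------------------------------
# planted Gaussian graphical models


@dataclass(frozen=True)
class PrecisionMatrix:
    """A symmetric positive-definite concentration matrix with node labels."""

    matrix: np.ndarray
    labels: list

    def __post_init__(self):
        M = np.asarray(self.matrix, dtype=float)
        if not np.allclose(M, M.T, atol=1e-10):
            raise ValueError("precision matrix must be symmetric")
        if np.linalg.eigvalsh(M).min() <= 0:
            raise ValueError("precision matrix must be positive definite")
        object.__setattr__(self, "matrix", 0.5 * (M + M.T))

    @property
    def partial_correlations(self) -> np.ndarray:
        return precision_to_pcor(self.matrix)


def build_precision(edges, p: int, labels=None, max_iter: int = 50,
                    tol: float = 1e-6) -> PrecisionMatrix:
    """Precision matrix whose implied partial correlations equal ``edges``.

    With unit diagonal and off-diagonal entries set to minus the target
    partial correlations, the implied partials equal the targets exactly;
    this succeeds whenever the resulting matrix is positive definite (true
    for any diagonally dominant target set). Otherwise the off-diagonal
    block is contracted until PD and the achieved partials are re-checked
    against the targets: an infeasible edge set raises rather than silently
    shrinking.
    """
    if labels is None:
        labels = list(range(p))
    K = np.eye(p)
    for i, j, r in edges:
        i, j = int(i), int(j)
        if i == j:
            raise ValueError(f"self-edge ({i},{j}) is not allowed")
        if not abs(r) < 1:
            raise ValueError(f"edge ({i},{j}): |partial correlation| must be < 1")
        K[i, j] = K[j, i] = -float(r)
    scale = 1.0
    for _ in range(max_iter):
        trial = np.eye(p) + scale * (K - np.eye(p))
        if np.linalg.eigvalsh(trial).min() > 1e-8:
            K = trial
            break
        scale *= 0.9
    else:
        raise ValueError(f"could not reach a positive-definite precision for "
                         f"edge set {list(edges)!r}")
    P = precision_to_pcor(K)
    for i, j, r in edges:
        if abs(P[int(i), int(j)] - r) > tol:
            raise ValueError(
                f"edge set {list(edges)!r} is infeasible: requested partial "
                f"correlation {r} at ({i},{j}), achievable {P[int(i), int(j)]:.6f}")
    return PrecisionMatrix(matrix=K, labels=list(labels))


# ---------------------------------------------------------------------------
# feature tables


@dataclass(frozen=True)
class GroupSpec:
    """Specification of one group's synthetic feature distribution.

    ``edges`` are (node, node, partial correlation) triples over the five
    speech variables plus, optionally, ``anxiety``; ``rating_probs`` is the
    probability vector of the ordinal ratings {0, 1, 2, 3}. When anxiety
    appears in ``edges`` the rating is the quantile-discretized latent
    anxiety node, so the planted anxiety couplings survive rank correlation;
    otherwise ratings are drawn independently.
    """

    label: str
    n: int
    marginal_means: dict
    marginal_sds: dict
    edges: list
    rating_probs: list = field(default_factory=lambda: [0.25, 0.25, 0.25, 0.25])

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if any(sd <= 0 for sd in self.marginal_sds.values()):
            raise ValueError("marginal SDs must be positive")
        probs = np.asarray(self.rating_probs, dtype=float)
        if probs.size != 4 or probs.min() < 0 or abs(probs.sum() - 1) > 1e-9:
            raise ValueError("rating_probs must be 4 non-negative values summing to 1")

    @property
    def nodes(self) -> list:
        names = list(study.SPEECH_VARIABLES)
        if any(study.ANXIETY in (a, b) for a, b, _ in self.edges):
            names.append(study.ANXIETY)
        return names


def generate_feature_table(spec: GroupSpec, seed) -> pd.DataFrame:
    """Draw an n-row feature table from the spec's planted network.

    Continuous columns are multivariate-normal with the planted partial
    correlation structure, affinely rescaled to the marginal means/SDs
    (rank correlations are invariant to this). Deterministic for a fixed
    seed.
    """
    rng = np.random.default_rng(seed)
    nodes = spec.nodes
    index = {name: k for k, name in enumerate(nodes)}
    K = build_precision([(index[a], index[b], r) for a, b, r in spec.edges],
                        len(nodes), labels=nodes)
    cov = np.linalg.inv(K.matrix)
    d = np.sqrt(np.diag(cov))
    corr = cov / np.outer(d, d)
    Z = rng.multivariate_normal(np.zeros(len(nodes)), corr, size=spec.n,
                                method="cholesky")

    probs = np.asarray(spec.rating_probs, dtype=float)
    if np.any(probs == 0):
        warnings.warn(f"group {spec.label!r}: zero-probability rating categories "
                      f"{list(np.flatnonzero(probs == 0))}", stacklevel=2)
    if study.ANXIETY in index:
        cuts = stats.norm.ppf(np.cumsum(probs)[:-1])
        rating = np.searchsorted(cuts, Z[:, index[study.ANXIETY]])
    else:
        rating = rng.choice(4, size=spec.n, p=probs)

    data = {}
    for name in study.SPEECH_VARIABLES:
        col = Z[:, index[name]]
        data[name] = col * spec.marginal_sds[name] + spec.marginal_means[name]
    data["anxiety"] = rating.astype(int)
    data["group"] = spec.label
    return pd.DataFrame(data, columns=FEATURE_COLUMNS)


def _spec_from_study(label: str, n: int, group_key: str, edges,
                     rating_probs) -> GroupSpec:
    means = {v: study.TABLE1[v][group_key][0] for v in study.SPEECH_VARIABLES}
    sds = {v: study.TABLE1[v][group_key][1] for v in study.SPEECH_VARIABLES}
    return GroupSpec(label=label, n=n, marginal_means=means, marginal_sds=sds,
                     edges=list(edges), rating_probs=list(rating_probs))


def low_group_spec(n: int = study.N_LOW) -> GroupSpec:
    """Low-anxiety group: published marginals and the sparser topology
    (no intensity-f1f2 edge)."""
    return _spec_from_study("low", n, "low", study.LOW_EDGES,
                            study.LOW_RATING_PROBS)


def high_group_spec(n: int = study.N_HIGH) -> GroupSpec:
    """High-anxiety group: published marginals, intensity-f1f2 edge present."""
    return _spec_from_study("high", n, "high", study.HIGH_EDGES,
                            study.HIGH_RATING_PROBS)


def total_group_spec(n: int = study.N_TOTAL) -> GroupSpec:
    """Whole-sample spec with anxiety as a sixth latent node coupled
    (negatively) to jitter."""
    return _spec_from_study("total", n, "total", study.TOTAL_EDGES,
                            study.TOTAL_RATING_PROBS)


def generate_study_table(seed, n_low: int = study.N_LOW,
                         n_high: int = study.N_HIGH) -> pd.DataFrame:
    """Two-group table at study sample sizes (group column set per row)."""
    rng = np.random.default_rng(seed)
    with warnings.catch_warnings():
        # the group rating ranges are zero outside the split by construction
        warnings.simplefilter("ignore", UserWarning)
        low = generate_feature_table(low_group_spec(n_low), rng.integers(2**31))
        high = generate_feature_table(high_group_spec(n_high), rng.integers(2**31))
    return pd.concat([low, high], ignore_index=True)


# ---------------------------------------------------------------------------
# vowel synthesis


@dataclass(frozen=True)
class VoiceParams:
    """Ground-truth parameters for a synthetic vowel.

    ``formants`` is an ordered list of (center Hz, bandwidth Hz);
    ``rms_db`` is the target intensity under the extractor's measurement
    definition (dB re full scale + calibration offset); ``syllable_rate``
    is amplitude-modulation events per second (0 = continuous voicing);
    ``noise_db`` is the white-noise floor relative to signal RMS.
    """

    f0_hz: float = 180.0
    jitter_pct: float = 0.5
    formants: tuple = ((500.0, 80.0), (1500.0, 100.0), (2500.0, 140.0))
    rms_db: float = 67.5
    syllable_rate: float = 0.0
    noise_db: float = -40.0
    duration_s: float = 2.0
    sample_rate: int = 22050
    calibration_offset_db: float = 91.0

    def __post_init__(self):
        if self.f0_hz <= 0:
            raise ValueError("f0_hz must be positive")
        if self.jitter_pct < 0:
            raise ValueError("jitter_pct must be non-negative")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if len(self.formants) < 2:
            raise ValueError("at least two formants are required")
        centers = [f for f, _ in self.formants]
        if any(c2 <= c1 for c1, c2 in zip(centers, centers[1:])):
            raise ValueError("formant centers must be strictly increasing")
        if centers[-1] >= self.sample_rate / 2:
            raise ValueError(f"formant center {centers[-1]} Hz is at or above "
                             f"Nyquist ({self.sample_rate / 2} Hz)")


@dataclass(frozen=True)
class SynthesizedVowel:
    """A synthetic vowel plus its ground-truth annotations."""

    signal: AudioSignal
    params: VoiceParams
    epochs_s: np.ndarray
    periods_s: np.ndarray
    syllable_count: int
    syllable_onsets_s: np.ndarray

    @property
    def realized_jitter_pct(self) -> float:
        return compute_jitter(self.periods_s, scale="percent")

    @property
    def annotation(self) -> dict:
        return {"syllable_count": int(self.syllable_count),
                "syllable_onsets_s": [float(t) for t in self.syllable_onsets_s],
                "duration_s": self.params.duration_s}


def _resonator_coeffs(fc: float, bw: float, sr: int):
    r = np.exp(-np.pi * bw / sr)
    theta = 2 * np.pi * fc / sr
    return np.array([1.0, -2 * r * np.cos(theta), r * r])


def formant_filter_response(params: VoiceParams, n_fft: int = 2048):
    """(frequencies, |H|) of the cascaded resonators on an n_fft grid."""
    h = np.ones(n_fft // 2 + 1, dtype=complex)
    for fc, bw in params.formants:
        _, hi = sps.freqz([1.0], _resonator_coeffs(fc, bw, params.sample_rate),
                          worN=n_fft // 2 + 1, fs=params.sample_rate)
        h *= hi
    freqs = np.linspace(0, params.sample_rate / 2, n_fft // 2 + 1)
    return freqs, np.abs(h)


def _syllable_envelope(n: int, sr: int, rate: float, ramp_s: float = 0.02):
    """Raised-cosine gated envelope; returns (envelope, onsets, count)."""
    if rate <= 0:
        return np.ones(n), np.empty(0), 0
    duration = n / sr
    period = 1.0 / rate
    voiced = min(0.7 * period, duration)
    env = np.zeros(n)
    onsets = []
    k = 0
    while k * period < duration:
        onsets.append(k * period)
        i0 = int(round(k * period * sr))
        i1 = min(n, int(round((k * period + voiced) * sr)))
        seg = np.ones(i1 - i0)
        ramp = min(int(ramp_s * sr), max(1, (i1 - i0) // 2))
        up = 0.5 * (1 - np.cos(np.linspace(0, np.pi, ramp)))
        seg[:ramp] = np.minimum(seg[:ramp], up)
        seg[-ramp:] = np.minimum(seg[-ramp:], up[::-1])
        env[i0:i1] = seg
        k += 1
    return env, np.asarray(onsets), len(onsets)


def synthesize_vowel(params: VoiceParams, seed=0) -> SynthesizedVowel:
    """Source-filter synthesis of a vowel-like signal with known truth.

    The glottal source is an impulse train at fractional-sample epoch
    positions (linear interpolation between adjacent samples), with periods
    T_i = (1/f0)(1 + eps_i), eps_i i.i.d. Gaussian calibrated so the
    expected local jitter equals ``jitter_pct``. The realized periods
    (exact, pre-quantization) are returned as ground truth.
    """
    rng = np.random.default_rng(seed)
    sr = params.sample_rate
    n = int(round(params.duration_s * sr))
    T0 = 1.0 / params.f0_hz
    sigma = (params.jitter_pct / 100.0) * np.sqrt(np.pi) / 2.0

    epochs, periods = [], []
    t = T0  # first epoch one period in, avoiding the boundary
    while t < params.duration_s - 1.0 / sr:
        epochs.append(t)
        eps = float(np.clip(rng.normal(0.0, sigma), -0.45, 0.45)) if sigma > 0 else 0.0
        Ti = T0 * (1.0 + eps)
        periods.append(Ti)
        t += Ti
    epochs = np.asarray(epochs)
    periods = np.asarray(periods[:-1])  # last period extends past the end

    # band-limited impulses (windowed sinc) at exact fractional positions,
    # so every glottal pulse has an identical waveform shape
    source = np.zeros(n)
    half_taps = 16
    k = np.arange(-half_taps, half_taps + 1)
    taper = 0.5 + 0.5 * np.cos(np.pi * k / (half_taps + 1))
    for e in epochs:
        pos = e * sr
        base = int(np.round(pos))
        taps = np.sinc(k + base - pos) * taper
        lo, hi = base - half_taps, base + half_taps + 1
        s0, s1 = max(0, lo), min(n, hi)
        source[s0:s1] += taps[s0 - lo : s1 - lo]

    def vocal_tract(sig):
        for fc, bw in params.formants:
            sig = sps.lfilter([1.0], _resonator_coeffs(fc, bw, sr), sig)
        return sig

    x = vocal_tract(source)
    env, onsets, count = _syllable_envelope(n, sr, params.syllable_rate)

    if np.isfinite(params.noise_db):
        # aspiration: white noise through the same vocal tract, gated with
        # the voicing envelope, at noise_db relative to the voiced signal
        aspiration = vocal_tract(rng.normal(0.0, 1.0, size=n))
        sig_rms = np.sqrt(np.mean(x**2))
        asp_rms = np.sqrt(np.mean(aspiration**2))
        if asp_rms > 0:
            aspiration *= sig_rms * 10.0 ** (params.noise_db / 20.0) / asp_rms
        x = x + aspiration
    x = x * env

    # intensity calibration under the extractor's own measurement definition
    start, stop = trim_silence(x, sr, 0.05)
    seg = x[start:stop]
    win, hop = 512, 256
    if seg.size >= win:
        nf = 1 + (seg.size - win) // hop
        fr = seg[np.arange(win)[None, :] + hop * np.arange(nf)[:, None]]
        mean_rms = np.sqrt(np.mean(fr**2, axis=1)).mean()
    else:
        mean_rms = np.sqrt(np.mean(seg**2))
    target = 10.0 ** ((params.rms_db - params.calibration_offset_db) / 20.0)
    x = x * (target / mean_rms)

    return SynthesizedVowel(signal=AudioSignal(x, sr), params=params,
                            epochs_s=epochs, periods_s=periods,
                            syllable_count=count, syllable_onsets_s=onsets)


def write_vowel(path_wav, vowel: SynthesizedVowel, sidecar_json=None) -> None:
    """Write the vowel as 16-bit PCM WAV plus a ground-truth JSON sidecar."""
    write_wav(path_wav, vowel.signal)
    if sidecar_json is None:
        sidecar_json = str(path_wav) + ".json"
    truth = {
        "f0_hz": vowel.params.f0_hz,
        "jitter_pct": vowel.params.jitter_pct,
        "formants": [list(f) for f in vowel.params.formants],
        "rms_db": vowel.params.rms_db,
        "syllable_rate": vowel.params.syllable_rate,
        "noise_db": vowel.params.noise_db,
        "duration_s": vowel.params.duration_s,
        "sample_rate": vowel.params.sample_rate,
        "realized_periods_s": vowel.periods_s.tolist(),
        "realized_jitter_pct": vowel.realized_jitter_pct,
        "epochs_s": vowel.epochs_s.tolist(),
        "syllable_count": vowel.syllable_count,
        "syllable_onsets_s": vowel.syllable_onsets_s.tolist(),
    }
    with open(sidecar_json, "w") as fh:
        json.dump(truth, fh, indent=1)
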