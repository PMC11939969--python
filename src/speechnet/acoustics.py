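"""Extraction of the five acoustic parameters from a mono signal.

The feature set is the classic voice-biomarker panel: local jitter
(cycle-to-cycle period perturbation), mean fundamental frequency (F0),
the first-to-second formant ratio (F1/F2), frame-averaged RMS intensity in
dB, and speech rate in syllables per second.

Processing chain: pre-emphasis and energy-based silence trimming, Hamming
framing (512-sample window, 50% hop by default), a combined
energy/periodicity voicing decision, autocorrelation F0 with parabolic peak
interpolation, epoch-refined period extraction for jitter, 12th-order LPC
(autocorrelation method) root-solving for formants, and an annotation- or
transcript-driven syllable count for speech rate.

Intensity is deliberately computed on the raw (trimmed, non-pre-emphasized)
frame samples: pre-emphasis is a spectral-tilt filter that would attenuate
a low-formant vowel by tens of dB and turn "intensity" into a tilt measure.
The dB reference is full scale plus a calibration offset, since absolute
SPL is unrecoverable from a file; the offset is irrelevant to any
correlation-based analysis downstream.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps
from scipy.linalg import solve_toeplitz

from .audio import AudioSignal

__all__ = [
    "ExtractionConfig",
    "FrameSet",
    "F0Track",
    "FeatureRow",
    "preprocess",
    "detect_voiced",
    "estimate_f0",
    "compute_jitter",
    "estimate_formants",
    "compute_intensity",
    "compute_speech_rate",
    "count_syllables",
    "extract_features",
]


@dataclass(frozen=True)
class ExtractionConfig:
    """Extraction settings; defaults follow common voice-analysis practice.

    ``window_len``/``hop`` are in samples (512/256 ≈ 23 ms / 50% overlap at
    22.05 kHz). ``trim_threshold_rel`` is the short-window RMS threshold for
    leading/trailing silence trimming, relative to the maximum short-window
    RMS (0 disables trimming). ``calibration_offset_db`` places a full-scale
    sine near 91 dB so conversational speech lands near 67 dB.
    """

    window_len: int = 512
    hop: int = 256
    pre_emphasis: float = 0.97
    trim_threshold_rel: float = 0.05
    trim_window_s: float = 0.010
    energy_quantile: float = 0.3
    periodicity_min: float = 0.45
    f0_min: float = 75.0
    f0_max: float = 400.0
    lpc_order: int = 12
    formant_min_hz: float = 90.0
    formant_max_bandwidth_hz: float = 400.0
    formant_analysis_rate_hz: int = 11025
    formant_pre_emphasis: float = 0.0
    jitter_scale: str = "percent"  # or "ratio"
    calibration_offset_db: float = 91.0
    intensity_floor_db: float = -120.0
    rate_denominator: str = "full"  # or "speech": trimmed-duration denominator


@dataclass(frozen=True)
class FrameSet:
    """Framed view of a trimmed signal.

    ``frames`` are pre-emphasized and Hamming-windowed (for spectral and
    periodicity measures); ``raw_frames`` are the un-windowed,
    non-pre-emphasized samples of the same frames (for intensity).
    """

    frames: np.ndarray
    raw_frames: np.ndarray
    window_len: int
    hop: int
    window: str
    pre_emphasis: float
    sample_rate: int
    trimmed_samples: np.ndarray = field(repr=False, default=None)
    trim_start: int = 0
    trim_stop: int = 0

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


@dataclass(frozen=True)
class F0Track:
    """Per-frame F0 estimates plus the epoch-refined period sequence."""

    f0_hz: np.ndarray  # NaN for unvoiced/invalid frames
    voiced: np.ndarray
    periods_s: np.ndarray  # cycle-to-cycle periods from epoch detection

    @property
    def mean_f0(self) -> float:
        valid = self.f0_hz[np.isfinite(self.f0_hz)]
        return float(valid.mean()) if valid.size else float("nan")


@dataclass
class FeatureRow:
    """One speaker's extracted feature vector; missing fields are NaN."""

    jitter: float = float("nan")
    f0_mean: float = float("nan")
    f1: float = float("nan")
    f2: float = float("nan")
    f1f2: float = float("nan")
    intensity: float = float("nan")
    speech_rate: float = float("nan")
    warnings: list = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "jitter": self.jitter,
            "f0": self.f0_mean,
            "f1f2": self.f1f2,
            "intensity": self.intensity,
            "speech_rate": self.speech_rate,
        }


# ---------------------------------------------------------------------------
# framing


def _short_window_rms(x: np.ndarray, win: int) -> np.ndarray:
    n = x.size // win
    if n == 0:
        return np.array([np.sqrt(np.mean(x**2))])
    blocks = x[: n * win].reshape(n, win)
    return np.sqrt(np.mean(blocks**2, axis=1))


def trim_silence(x: np.ndarray, sample_rate: int, threshold_rel: float,
                 window_s: float = 0.010) -> tuple[int, int]:
    """Leading/trailing trim bounds from short-window RMS.

    Returns (start, stop) sample indices; (0, len) when trimming is
    disabled. Raises if every window falls below threshold.
    """
    if threshold_rel <= 0:
        return 0, x.size
    win = max(1, int(round(window_s * sample_rate)))
    rms = _short_window_rms(x, win)
    thresh = threshold_rel * rms.max()
    above = np.flatnonzero(rms >= thresh) if rms.max() > 0 else np.array([])
    if above.size == 0:
        raise ValueError("signal is entirely below the silence threshold")
    start = above[0] * win
    stop = min(x.size, (above[-1] + 1) * win)
    return int(start), int(stop)


def preprocess(signal: AudioSignal, config: ExtractionConfig = ExtractionConfig()) -> FrameSet:
    """Pre-emphasize, trim silence, and frame a signal.

    Pre-emphasis is ``y[t] = x[t] - a*x[t-1]`` (first sample passed
    through); framing keeps only full windows: ``1 + (N - window)//hop``.
    """
    x = signal.samples
    win, hop = config.window_len, config.hop
    if x.size < win:
        raise ValueError(f"signal ({x.size} samples) shorter than one window ({win})")
    start, stop = trim_silence(x, signal.sample_rate, config.trim_threshold_rel,
                               config.trim_window_s)
    x = x[start:stop]
    if x.size < win:
        raise ValueError("trimmed signal shorter than one analysis window")
    emph = np.empty_like(x)
    emph[0] = x[0]
    emph[1:] = x[1:] - config.pre_emphasis * x[:-1]

    n_frames = 1 + (x.size - win) // hop
    idx = np.arange(win)[None, :] + hop * np.arange(n_frames)[:, None]
    raw_frames = x[idx]
    frames = emph[idx] * np.hamming(win)[None, :]
    return FrameSet(frames=frames, raw_frames=raw_frames, window_len=win, hop=hop,
                    window="hamming", pre_emphasis=config.pre_emphasis,
                    sample_rate=signal.sample_rate, trimmed_samples=x,
                    trim_start=start, trim_stop=stop)


# ---------------------------------------------------------------------------
# voicing and F0


def _autocorr_peaks(frames: np.ndarray, lag_min: int, lag_max: int,
                    window: np.ndarray = None):
    """Normalized autocorrelation over a lag band, vectorized via FFT.

    When the taper ``window`` is given, the frame autocorrelation is divided
    by the window's own autocorrelation (Boersma's correction), removing the
    lag-proportional attenuation that otherwise favors harmonic sub-lags
    when the window spans only a few pitch periods.

    Returns (best lag per frame, normalized peak value per frame, and the
    full normalized autocorrelation array for parabolic refinement).
    """
    n = frames.shape[1]
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    spec = np.fft.rfft(frames, nfft, axis=1)
    ac = np.fft.irfft(spec * np.conj(spec), nfft, axis=1)[:, : lag_max + 2]
    r0 = ac[:, 0].copy()
    r0[r0 <= 0] = np.inf  # silent frame -> zero periodicity
    acn = ac / r0[:, None]
    if window is not None:
        wspec = np.fft.rfft(window, nfft)
        wac = np.fft.irfft(wspec * np.conj(wspec), nfft)[: lag_max + 2]
        acn = acn / np.maximum(wac / wac[0], 0.1)
    band = acn[:, lag_min : lag_max + 1]
    best = band.argmax(axis=1) + lag_min
    peak = acn[np.arange(frames.shape[0]), best]
    return best, peak, acn


def detect_voiced(frames: FrameSet, energy_quantile: float = 0.3,
                  periodicity_min: float = 0.45,
                  f0_min: float = 75.0, f0_max: float = 400.0) -> np.ndarray:
    """Voicing mask: frame RMS clearing an energy gate AND a normalized
    autocorrelation peak in the F0 band at or above ``periodicity_min``.

    The energy gate is half the ``energy_quantile`` quantile of frame RMS:
    a silence gate that keeps every frame of a uniformly voiced signal
    (periodicity then decides voicing) while rejecting pause frames, which
    sit far below the quantile in bimodal recordings.
    """
    rms = np.sqrt(np.mean(frames.raw_frames**2, axis=1))
    energy_ok = rms >= 0.5 * np.quantile(rms, energy_quantile)
    sr = frames.sample_rate
    lag_min = max(2, int(np.floor(sr / f0_max)))
    lag_max = min(frames.window_len - 2, int(np.ceil(sr / f0_min)))
    _, peak, _ = _autocorr_peaks(frames.frames, lag_min, lag_max,
                                 np.hamming(frames.window_len))
    return energy_ok & (peak >= periodicity_min)


def _parabolic(y_m1: float, y_0: float, y_p1: float) -> float:
    denom = y_m1 - 2 * y_0 + y_p1
    if denom == 0:
        return 0.0
    return float(np.clip(0.5 * (y_m1 - y_p1) / denom, -1, 1))


def _pick_lag(corrected: np.ndarray, raw: np.ndarray, lag_min: int,
              lag_max: int, octave_cost: float = 0.02,
              raw_floor: float = 0.15):
    """Choose the pitch lag among local autocorrelation maxima.

    Candidates are in-band local maxima of the window-corrected
    autocorrelation whose uncorrected value clears ``raw_floor`` (a guard
    against noise amplified by the window correction at long lags). Each is
    scored value - octave_cost * log2(lag/lag_min), the small short-lag
    preference that breaks the exact tie between the true period and its
    integer multiples in a perfectly periodic frame, while leaving genuine
    harmonic sub-lags (whose correlation is visibly lower) unselected.
    """
    seg = corrected[lag_min : lag_max + 1]
    interior = (seg[1:-1] >= seg[:-2]) & (seg[1:-1] >= seg[2:])
    cand = np.flatnonzero(interior) + 1 + lag_min
    cand = cand[raw[cand] >= raw_floor]
    if cand.size == 0:
        return None
    score = corrected[cand] - octave_cost * np.log2(cand / lag_min)
    return int(cand[np.argmax(score)])


def estimate_f0(frames: FrameSet, mask: np.ndarray, f0_min: float = 75.0,
                f0_max: float = 400.0, periodicity_min: float = 0.45,
                lpc_order: int = 12) -> F0Track:
    """Frame-level F0 by interpolated autocorrelation peaks, plus an
    epoch-refined cycle-to-cycle period sequence for jitter.

    Frames whose in-band autocorrelation peak stays below
    ``periodicity_min`` are treated as having no valid F0.
    """
    if not (0 < f0_min < f0_max < frames.sample_rate / 2):
        raise ValueError("require 0 < f0_min < f0_max < Nyquist")
    sr = frames.sample_rate
    lag_min = max(2, int(np.floor(sr / f0_max)))
    lag_max = min(frames.window_len - 2, int(np.ceil(sr / f0_min)))
    best, peak, acn = _autocorr_peaks(frames.frames, lag_min, lag_max,
                                      np.hamming(frames.window_len))
    _, _, raw_acn = _autocorr_peaks(frames.frames, lag_min, lag_max)

    f0 = np.full(frames.n_frames, np.nan)
    rows = np.flatnonzero(mask & (peak >= periodicity_min))
    for i in rows:
        lag = _pick_lag(acn[i], raw_acn[i], lag_min, lag_max)
        if lag is None:
            continue
        delta = _parabolic(acn[i, lag - 1], acn[i, lag], acn[i, lag + 1])
        f0_i = sr / (lag + delta)
        if f0_min <= f0_i <= f0_max:
            f0[i] = f0_i
    # suppress octave/subharmonic glitches before averaging
    valid_idx = np.flatnonzero(np.isfinite(f0))
    if valid_idx.size:
        med = np.median(f0[valid_idx])
        off = (f0[valid_idx] <= 0.8 * med) | (f0[valid_idx] >= 1.25 * med)
        f0[valid_idx[off]] = np.nan
    valid = f0[np.isfinite(f0)]
    if valid.size:
        periods = _epoch_periods(frames.trimmed_samples, sr, float(valid.mean()),
                                 lpc_order)
    else:
        periods = np.empty(0)
    return F0Track(f0_hz=f0, voiced=mask.copy(), periods_s=periods)


def _track_epochs(mag: np.ndarray, T: float, search: float = 0.25,
                  min_rel_height: float = 0.05) -> np.ndarray:
    """Sequential epoch marks on a residual-magnitude envelope.

    Starting at the strongest sample, epochs are marched forward and
    backward one expected period at a time, taking the local maximum within
    ±``search``*T of the prediction. Sequential tracking cannot alternate
    between a primary and a secondary excitation peak the way greedy global
    peak picking can. Marks in near-silent regions (below
    ``min_rel_height`` of the global maximum) end the march across that
    gap, and tracking restarts beyond it.
    """
    n = mag.size
    w = max(1, int(search * T))
    floor = min_rel_height * mag.max()
    visited = np.zeros(n, dtype=bool)
    all_marks = []
    while True:
        cand = np.where(visited, -1.0, mag)
        start = int(np.argmax(cand))
        if cand[start] < floor:
            break
        marks = [start]
        for direction in (1, -1):
            pos = start
            while True:
                pred = pos + direction * int(round(T))
                lo, hi = pred - w, pred + w + 1
                if lo < 0 or hi > n:
                    break
                local = int(np.argmax(mag[lo:hi])) + lo
                if mag[local] < floor or visited[local]:
                    break
                marks.append(local)
                pos = local
        marks = np.sort(np.asarray(marks))
        lo = max(0, marks[0] - w)
        hi = min(n, marks[-1] + w + 1)
        visited[lo:hi] = True
        all_marks.extend(marks.tolist())
        if visited.all():
            break
    return np.sort(np.asarray(all_marks, dtype=int))


def _epoch_periods(x: np.ndarray, sr: int, f0_mean: float, lpc_order: int,
                   max_shift: int = 3) -> np.ndarray:
    """Cycle-to-cycle periods: LPC-residual epoch marks refined by
    waveform cross-correlation between consecutive cycles.

    A whole-signal LPC inverse filter flattens the formant structure so the
    residual peaks mark excitation instants; integer marks are then refined
    to sub-sample period estimates by maximizing the normalized
    cross-correlation of adjacent cycle-length windows (parabolic
    interpolation over the lag). Gaps outside (0.7, 1.3)x the mean period
    (octave errors, syllable pauses) are discarded.
    """
    a = _lpc(x, lpc_order)
    if a is None:
        return np.empty(0)
    resid = sps.lfilter(np.concatenate(([1.0], a)), [1.0], x)
    mag = np.abs(resid)
    # light smoothing merges the multi-sample excitation burst into one lobe
    mag = np.convolve(mag, np.ones(3) / 3.0, mode="same")
    T = sr / f0_mean
    peaks = _track_epochs(mag, T)
    if peaks.size < 3:
        return np.empty(0)
    x = resid  # correlate whitened pulses: no resonator ringing bias
    half = max(4, int(0.45 * T))
    shift = max(max_shift, int(0.3 * T))
    lags = np.arange(-shift, shift + 1)
    periods = []
    for p0, p1 in zip(peaks[:-1], peaks[1:]):
        gap = p1 - p0
        # generous gate on the raw marks; the corrected period is re-gated
        if not (0.5 * T < gap < 1.5 * T):
            continue
        if p0 - half < 0 or p1 + half + shift >= x.size or p1 - half - shift < 0:
            continue
        s0 = x[p0 - half : p0 + half]
        e0 = np.sqrt(np.sum(s0**2))
        if e0 == 0:
            continue
        corr = np.empty(lags.size)
        for li, lag in enumerate(lags):
            s1 = x[p1 - half + lag : p1 + half + lag]
            e1 = np.sqrt(np.sum(s1**2))
            corr[li] = np.dot(s0, s1) / (e0 * e1) if e1 > 0 else -1.0
        li = int(np.argmax(corr))
        delta = 0.0
        if 0 < li < lags.size - 1:
            delta = _parabolic(corr[li - 1], corr[li], corr[li + 1])
        period = (gap + lags[li] + delta) / sr
        if 0.75 / f0_mean < period < 1.25 / f0_mean:
            periods.append(period)
    return np.asarray(periods)


# ---------------------------------------------------------------------------
# jitter


def compute_jitter(periods_s: np.ndarray, scale: str = "percent") -> float:
    """Local jitter: mean absolute consecutive period difference divided by
    the mean period; ``scale='percent'`` multiplies by 100.

    Returns NaN (flagged missing) with fewer than two periods.
    """
    periods = np.asarray(periods_s, dtype=float)
    if periods.size < 2:
        return float("nan")
    if np.any(periods <= 0):
        raise ValueError("periods must be positive")
    local = np.mean(np.abs(np.diff(periods))) / np.mean(periods)
    return float(local * 100.0) if scale == "percent" else float(local)


# ---------------------------------------------------------------------------
# formants


def _lpc(x: np.ndarray, order: int):
    """LPC coefficients a_1..a_order by the autocorrelation (Levinson) method.

    Solves the Toeplitz normal equations R a = -r via Levinson recursion
    (scipy's solve_toeplitz); returns None for degenerate frames.
    """
    x = np.asarray(x, dtype=float)
    if x.size <= order:
        return None
    r = np.correlate(x, x, mode="full")[x.size - 1 : x.size + order]
    if r[0] <= 0:
        return None
    r = r.copy()
    r[0] *= 1.0 + 1e-9  # white-noise ridge for numerical stability
    try:
        return solve_toeplitz((r[:order], r[:order]), -r[1 : order + 1])
    except np.linalg.LinAlgError:
        return None


def _frame_formants(frame: np.ndarray, sr: int, order: int, fmin: float,
                    max_bw: float):
    """Per-frame formant candidates: ((freqs...), (bandwidths...)) or None."""
    a = _lpc(frame, order)
    if a is None:
        return None
    roots = np.roots(np.concatenate(([1.0], a)))
    roots = roots[np.imag(roots) > 0]
    freqs = np.angle(roots) * sr / (2 * np.pi)
    bws = -np.log(np.maximum(np.abs(roots), 1e-12)) * sr / np.pi
    keep = (freqs >= fmin) & (freqs <= sr / 2 - 50) & (bws <= max_bw)
    if keep.sum() < 2:
        return None
    order_idx = np.argsort(freqs[keep])
    return freqs[keep][order_idx], bws[keep][order_idx]


def _resonator_logmag(f, fc: float, bw: float, sr: int):
    """Log magnitude of a two-pole digital resonator at frequencies ``f``."""
    r = np.exp(-np.pi * bw / sr)
    z = np.exp(-2j * np.pi * np.asarray(f, dtype=float) / sr)
    den = 1.0 - 2.0 * r * np.cos(2 * np.pi * fc / sr) * z + (r * r) * z * z
    return -np.log(np.maximum(np.abs(den), 1e-12))


def _harmonic_envelope(x: np.ndarray, sr: int, f0: float, n_fft: int = 8192):
    """Harmonic frequencies and log amplitudes from an averaged spectrum.

    Uses ~3-period Hann windows so individual harmonics are resolved; each
    harmonic's amplitude is the spectral peak within ±f0/3 of its nominal
    position (tolerant of jitter-induced drift).
    """
    win = int(3 * sr / f0)
    if x.size < win or win < 8:
        return None
    hop = win // 2
    nf = 1 + (x.size - win) // hop
    idx = np.arange(win)[None, :] + hop * np.arange(nf)[:, None]
    P = np.mean(np.abs(np.fft.rfft(x[idx] * np.hanning(win), n_fft, axis=1)) ** 2,
                axis=0)
    freqs = np.fft.rfftfreq(n_fft, 1.0 / sr)
    ks = np.arange(1, int((sr / 2 - f0 / 2) / f0) + 1)
    hf = np.empty(ks.size)
    amp = np.empty(ks.size)
    for i, k in enumerate(ks):
        sel = (freqs > k * f0 - f0 / 3) & (freqs < k * f0 + f0 / 3)
        j = int(np.argmax(P[sel]))
        hf[i] = freqs[sel][j]
        amp[i] = 0.5 * np.log(max(P[sel][j], 1e-30))
    return hf, amp


def _fit_resonance(hf, resid, f_init: float, f0: float, sr: int,
                   span: float = 1.7, bw_grid=None):
    """Least-squares single-resonance fit to residual harmonic amplitudes.

    Grid search over center frequency (±0.8 f0 around the initial value)
    and bandwidth, gain profiled out in closed form; weights proportional
    to harmonic amplitude so far-shoulder harmonics barely count. Returns
    the refined center or None when under-determined.
    """
    near = (hf > f_init - span * f0) & (hf < f_init + span * f0)
    if near.sum() < 3:
        return None
    X, Y = hf[near], resid[near]
    w = np.exp(Y - Y.max())
    if (w > 0.05).sum() < 3:
        return None
    if bw_grid is None:
        bw_grid = np.geomspace(30.0, 350.0, 12)
    fc_grid = np.linspace(max(f_init - 0.8 * f0, 60.0), f_init + 0.8 * f0, 81)
    best = (np.inf, None)
    wsum = w.sum()
    for bw in bw_grid:
        for fc in fc_grid:
            model = _resonator_logmag(X, fc, bw, sr)
            gain = np.sum(w * (Y - model)) / wsum
            sse = np.sum(w * (Y - model - gain) ** 2)
            if sse < best[0]:
                best = (sse, fc)
    return best[1]


def estimate_formants(frames: FrameSet, mask: np.ndarray, order: int = 12,
                      formant_min_hz: float = 90.0,
                      max_bandwidth_hz: float = 400.0,
                      analysis_rate_hz: int = 11025,
                      pre_emphasis: float = 0.0,
                      f0_hint: float = None):
    """Mean F1, F2 and their ratio from per-frame LPC root candidates.

    Per voiced frame, LPC (autocorrelation method) polynomial roots with
    positive imaginary part give candidate resonances (frequency from the
    root angle, bandwidth from its radius); broad-bandwidth and sub-90-Hz
    roots are rejected and the two lowest surviving frequencies taken as
    F1/F2. Frames with fewer than two candidates are ignored; returns
    (nan, nan, nan) if no frame qualifies.

    A 12th-order all-pole fit resolves ~6 resonances, the right density for
    an ~11 kHz analysis band; signals sampled faster are decimated to
    ``analysis_rate_hz`` for this step (None disables). This path applies
    its own ``pre_emphasis`` (default none: appropriate for a
    flat-spectrum excitation; raise toward 0.97 for natural glottal
    sources, whose -12 dB/oct tilt otherwise drags poles downward).
    """
    if order >= frames.window_len:
        raise ValueError("LPC order must be below the window length")
    sr = frames.sample_rate
    x = frames.trimmed_samples
    fsr = sr
    if analysis_rate_hz and sr > analysis_rate_hz:
        import math

        g = math.gcd(sr, int(analysis_rate_hz))
        x = sps.resample_poly(x, analysis_rate_hz // g, sr // g)
        fsr = int(analysis_rate_hz)
    win = max(order + 2, int(round(frames.window_len * fsr / sr)))
    hop = max(1, int(round(frames.hop * fsr / sr)))
    if x.size < win:
        return float("nan"), float("nan"), float("nan")
    if pre_emphasis:
        y = np.empty_like(x)
        y[0] = x[0]
        y[1:] = x[1:] - pre_emphasis * x[:-1]
    else:
        y = x
    nf = 1 + (y.size - win) // hop
    idx = np.arange(win)[None, :] + hop * np.arange(nf)[:, None]
    ana = y[idx] * np.hamming(win)[None, :]
    # map analysis-frame centers onto the original voicing mask
    centers = (hop * np.arange(nf) + win / 2) / fsr
    orig = np.clip(np.round((centers * sr - frames.window_len / 2)
                            / frames.hop).astype(int), 0, frames.n_frames - 1)
    use = np.flatnonzero(mask[orig])
    picks = [
        f for i in use
        if (f := _frame_formants(ana[i], fsr, order, formant_min_hz,
                                 max_bandwidth_hz)) is not None
    ]
    if not picks:
        return float("nan"), float("nan"), float("nan")
    f1 = float(np.mean([p[0][0] for p in picks]))
    f2 = float(np.mean([p[0][1] for p in picks]))
    b1 = float(np.mean([p[1][0] for p in picks]))
    b2 = float(np.mean([p[1][1] for p in picks]))
    est = [[f1, b1], [f2, b2]]
    three = [p for p in picks if p[0].size >= 3]
    if len(three) > len(picks) / 2:
        est.append([float(np.mean([p[0][2] for p in three])),
                    float(np.mean([p[1][2] for p in three]))])

    # analysis-by-synthesis refinement of F1/F2 against the harmonic
    # envelope (LPC roots are biased toward strong harmonics when the
    # window resolves them); needs a pitch estimate to locate harmonics
    if f0_hint is not None and np.isfinite(f0_hint) and f0_hint > 0:
        env = _harmonic_envelope(y, fsr, float(f0_hint))
        if env is not None:
            hf, amp = env
            for _ in range(2):
                for i in range(2):
                    resid = amp.copy()
                    for j, (fj, bj) in enumerate(est):
                        if j != i:
                            resid -= _resonator_logmag(hf, fj, bj, fsr)
                    fc = _fit_resonance(hf, resid, est[i][0], float(f0_hint),
                                        fsr)
                    if fc is not None:
                        est[i][0] = fc
            if est[1][0] > est[0][0] > 0:
                f1, f2 = est[0][0], est[1][0]
    return f1, f2, f1 / f2


# ---------------------------------------------------------------------------
# intensity and speech rate


def compute_intensity(frames: FrameSet, calibration_offset_db: float = 91.0,
                      floor_db: float = -120.0) -> float:
    """Mean frame RMS in dB re full scale, plus a calibration offset.

    The mean is over RMS values of the un-windowed, non-pre-emphasized frame
    samples; all-silent input is clamped to ``floor_db``.
    """
    rms = np.sqrt(np.mean(frames.raw_frames**2, axis=1))
    mean_rms = rms.mean()
    if mean_rms <= 0:
        return float(floor_db)
    return float(20.0 * np.log10(mean_rms) + calibration_offset_db)


_VOWEL_RUN = re.compile(r"[aeiouy]+", re.IGNORECASE)


def count_syllables(transcript: str) -> int:
    """Orthographic syllable count: maximal vowel runs per word, at least
    one per word containing any letter."""
    total = 0
    for word in re.findall(r"[a-zA-Z']+", transcript):
        total += max(1, len(_VOWEL_RUN.findall(word)))
    return total


def compute_speech_rate(annotation, duration_s: float) -> float:
    """Syllables per second from a transcript, an annotation dict with a
    ``syllable_count`` entry, or a bare count.

    Empty annotations give rate 0 with a warning.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if annotation is None or (isinstance(annotation, str) and not annotation.strip()):
        warnings.warn("empty annotation: speech rate set to 0", stacklevel=2)
        return 0.0
    if isinstance(annotation, str):
        count = count_syllables(annotation)
    elif isinstance(annotation, dict):
        count = int(annotation["syllable_count"])
    else:
        count = int(annotation)
    return count / duration_s


# ---------------------------------------------------------------------------
# composition


def extract_features(signal: AudioSignal, config: ExtractionConfig = ExtractionConfig(),
                     annotation=None) -> FeatureRow:
    """Run the full extraction chain on one signal.

    Missing sub-features propagate as NaN (never silent zeros), with a note
    in ``row.warnings``; speech rate uses the full, untrimmed duration by
    default (``config.rate_denominator='speech'`` switches to the trimmed
    one).
    """
    row = FeatureRow()
    try:
        frames = preprocess(signal, config)
    except ValueError as exc:
        row.warnings.append(f"preprocess: {exc}")
        if annotation is not None:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                row.speech_rate = compute_speech_rate(annotation, signal.duration_s)
        else:
            row.speech_rate = 0.0
        return row

    mask = detect_voiced(frames, config.energy_quantile, config.periodicity_min,
                         config.f0_min, config.f0_max)
    track = estimate_f0(frames, mask, config.f0_min, config.f0_max,
                        config.periodicity_min, config.lpc_order)
    row.f0_mean = track.mean_f0
    if not np.isfinite(row.f0_mean):
        row.warnings.append("f0: no voiced frames with a valid in-band peak")

    row.jitter = compute_jitter(track.periods_s, config.jitter_scale)
    if not np.isfinite(row.jitter):
        row.warnings.append("jitter: fewer than two usable periods")

    row.f1, row.f2, row.f1f2 = estimate_formants(
        frames, mask, config.lpc_order, config.formant_min_hz,
        config.formant_max_bandwidth_hz, config.formant_analysis_rate_hz,
        config.formant_pre_emphasis, f0_hint=row.f0_mean)
    if not np.isfinite(row.f1f2):
        row.warnings.append("formants: no frame produced two candidates")

    row.intensity = compute_intensity(frames, config.calibration_offset_db,
                                      config.intensity_floor_db)

    if config.rate_denominator == "speech":
        duration = (frames.trim_stop - frames.trim_start) / signal.sample_rate
    else:
        duration = signal.duration_s
    if annotation is not None:
        row.speech_rate = compute_speech_rate(annotation, duration)
    else:
        row.warnings.append("speech_rate: no annotation supplied")
    return row


def config_with(config: ExtractionConfig, **kwargs) -> ExtractionConfig:
    """Return a copy of ``config`` with fields replaced."""
    return replace(config, **kwargs)
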