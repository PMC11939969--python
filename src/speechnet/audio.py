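"""Audio container and WAV I/O.

Signals are held as float64 arrays on a full-scale ±1 grid, whatever the
on-disk bit depth. Only mono analysis is supported; stereo input is
downmixed with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.io import wavfile

__all__ = ["AudioSignal", "read_wav", "write_wav"]

_PCM_SCALE = {np.dtype("int16"): 2.0**15, np.dtype("int32"): 2.0**31}


@dataclass(frozen=True)
class AudioSignal:
    """A sampled mono waveform.

    Parameters
    ----------
    samples : ndarray
        Amplitudes, dimensionless, nominally within ±1 full scale.
    sample_rate : int
        Sampling rate in Hz.
    """

    samples: np.ndarray
    sample_rate: int

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1 or samples.size == 0:
            raise ValueError("AudioSignal requires a non-empty 1-D sample array")
        if not np.all(np.isfinite(samples)):
            raise ValueError("AudioSignal samples must be finite")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        object.__setattr__(self, "samples", samples)

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sample_rate

    def __len__(self) -> int:
        return self.samples.size


def read_wav(path) -> AudioSignal:
    """Read a PCM or float WAV file as a mono :class:`AudioSignal`.

    16/24/32-bit integer PCM is rescaled to ±1; stereo files are downmixed
    to mono by channel averaging (with a warning).
    """
    rate, data = wavfile.read(path)
    if data.ndim == 2:
        warnings.warn(f"{path}: stereo input downmixed to mono", stacklevel=2)
        data = data.mean(axis=1)
    if data.dtype in _PCM_SCALE:
        samples = data.astype(np.float64) / _PCM_SCALE[data.dtype]
    elif data.dtype == np.uint8:  # 8-bit WAV is unsigned
        samples = (data.astype(np.float64) - 128.0) / 128.0
    else:
        samples = data.astype(np.float64)
    return AudioSignal(samples, int(rate))


def write_wav(path, signal: AudioSignal) -> None:
    """Write a signal as 16-bit PCM WAV, clipping at full scale."""
    clipped = np.clip(signal.samples, -1.0, 1.0 - 1.0 / 2**15)
    wavfile.write(path, signal.sample_rate, (clipped * 2**15).astype(np.int16))
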