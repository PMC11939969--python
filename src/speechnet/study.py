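"""Reference study conditions: published group marginals and planted topologies.

These constants describe the cross-sectional speech-under-stress study the
package emulates: 316 speakers performing an oral task, self-rating state
anxiety on a 4-point scale (0-3), split into a low-anxiety group (ratings
0-1, n = 119) and a high-anxiety group (ratings 2-3, n = 197), with five
acoustic parameters per speaker. The partial-correlation topologies are the
published network estimates; they serve as planted ground truth for the
synthetic generator and as recovery targets in tests.
"""

from __future__ import annotations

SPEECH_VARIABLES = ["jitter", "f0", "f1f2", "intensity", "speech_rate"]
ANXIETY = "anxiety"

N_LOW = 119
N_HIGH = 197
N_TOTAL = N_LOW + N_HIGH

# Published per-group descriptives: variable -> group -> (mean, SD).
# Jitter is on the percent scale (local jitter ~0.5%); intensity in dB;
# speech rate in syllables/s over the full task duration.
TABLE1 = {
    "anxiety": {"total": (1.83, 1.01), "low": (0.70, 0.46), "high": (2.51, 0.50)},
    "jitter": {"total": (0.50, 0.07), "low": (0.51, 0.06), "high": (0.49, 0.08)},
    "f0": {"total": (181.88, 18.53), "low": (179.20, 18.70), "high": (183.49, 18.29)},
    "f1f2": {"total": (0.25, 0.05), "low": (0.25, 0.06), "high": (0.25, 0.05)},
    "intensity": {"total": (67.54, 5.64), "low": (67.78, 5.41), "high": (67.40, 5.78)},
    "speech_rate": {"total": (1.26, 0.57), "low": (1.26, 0.61), "high": (1.26, 0.55)},
}

# Published Cohen's d (low minus high, pooled SD). The f1f2 and jitter rows
# are ill-conditioned to recompute from 2-decimal marginals; the other four
# reproduce to ~3 decimals.
TABLE1_COHENS_D = {
    "anxiety": -3.731,
    "jitter": 0.229,
    "f0": -0.232,
    "f1f2": 0.145,
    "intensity": 0.068,
    "speech_rate": 0.000,
}

# Planted partial-correlation edge sets (node, node, partial correlation).
# Total network: anxiety enters as a latent node coupled only to jitter.
TOTAL_EDGES = [
    ("anxiety", "jitter", -0.17),
    ("jitter", "f0", -0.39),
    ("speech_rate", "intensity", 0.28),
    ("intensity", "f1f2", 0.26),
    ("f1f2", "f0", 0.24),
]

HIGH_EDGES = [
    ("speech_rate", "intensity", 0.28),
    ("intensity", "f1f2", 0.33),
    ("f1f2", "f0", 0.20),
    ("jitter", "f0", -0.39),
]

# The published low-anxiety panel omits the intensity-f1f2 edge; the f1f2-f0
# weight is fixed by the published expected-influence arithmetic (global EI
# 0.19 = 0.28 + w - 0.39 and f1f2 EI 0.30 = w, hence w = 0.30).
LOW_EDGES = [
    ("speech_rate", "intensity", 0.28),
    ("f1f2", "f0", 0.30),
    ("jitter", "f0", -0.39),
]

# Rating distributions consistent with the published group anxiety marginals
# (low: mean 0.70 of {0,1}; high: mean 2.51 of {2,3}) and the 119/197 split.
LOW_RATING_PROBS = [0.30, 0.70, 0.0, 0.0]
HIGH_RATING_PROBS = [0.0, 0.0, 0.49, 0.51]
_P_LOW = N_LOW / N_TOTAL
TOTAL_RATING_PROBS = [
    _P_LOW * LOW_RATING_PROBS[0],
    _P_LOW * LOW_RATING_PROBS[1],
    (1 - _P_LOW) * HIGH_RATING_PROBS[2],
    (1 - _P_LOW) * HIGH_RATING_PROBS[3],
]
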