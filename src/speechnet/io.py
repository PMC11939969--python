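"""Feature-table and network serialization (CSV/JSON round trips)."""

from __future__ import annotations

import json
import warnings

import numpy as np
import pandas as pd

from .study import ANXIETY, SPEECH_VARIABLES

__all__ = ["read_feature_csv", "write_feature_csv", "write_network_json",
           "read_network_json"]

REQUIRED_COLUMNS = SPEECH_VARIABLES + [ANXIETY]


def read_feature_csv(path) -> pd.DataFrame:
    """Read a feature table, validating header and value ranges.

    Required columns: jitter, f0, f1f2, intensity, speech_rate, anxiety
    (plus optional group). Unknown columns are dropped with a warning;
    empty cells round-trip as NaN; anxiety ratings outside {0,1,2,3} fail
    with the offending row named.
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    extra = [c for c in df.columns if c not in REQUIRED_COLUMNS + ["group"]]
    if extra:
        warnings.warn(f"{path}: ignoring unknown columns {extra}", stacklevel=2)
        df = df.drop(columns=extra)
    for col in REQUIRED_COLUMNS:
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}: non-numeric value in column {col!r}: {exc}")
    ratings = df[ANXIETY].dropna()
    bad = ~ratings.isin([0, 1, 2, 3])
    if bad.any():
        row = int(ratings.index[np.flatnonzero(bad.to_numpy())[0]])
        raise ValueError(f"{path}: row {row}: anxiety rating "
                         f"{ratings.loc[row]!r} outside the 0-3 scale")
    return df


def write_feature_csv(table: pd.DataFrame, path) -> None:
    cols = [c for c in REQUIRED_COLUMNS + ["group"] if c in table.columns]
    table[cols].to_csv(path, index=False, float_format="%.12g")


def write_network_json(results, path) -> None:
    """Serialize a fit (SpeechNetworkResults or NetworkModel-backed dict)."""
    payload = results.to_dict() if hasattr(results, "to_dict") else results
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)


def read_network_json(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
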