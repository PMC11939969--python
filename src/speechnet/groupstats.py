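"""Group descriptives: two-group split, pooled t-tests, Cohen's d.

The anxiety rating (ordinal 0-3) splits speakers into a low group (ratings
0-1) and a high group (2-3). Group contrasts are Student (pooled-variance)
t-tests with two-sided p-values and pooled-SD Cohen's d, oriented
low-minus-high. Welch's unequal-variance test is available behind a flag.
No multiple-comparison correction is applied.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .study import ANXIETY, SPEECH_VARIABLES

__all__ = [
    "split_groups",
    "cohens_d_pooled",
    "cohens_d_from_samples",
    "independent_t",
    "independent_t_from_stats",
    "table_one",
]


def split_groups(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split on the anxiety rating: <=1 -> low, >=2 -> high.

    Raises on ratings outside {0, 1, 2, 3}, naming the offending row.
    """
    if ANXIETY not in table.columns:
        raise ValueError("table has no 'anxiety' column")
    ratings = table[ANXIETY]
    bad = ~ratings.isin([0, 1, 2, 3])
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(f"row {row}: anxiety rating {ratings.iloc[row]!r} "
                         "outside the 0-3 scale")
    low = table[ratings <= 1].reset_index(drop=True)
    high = table[ratings >= 2].reset_index(drop=True)
    return low, high


def cohens_d_pooled(m1: float, s1: float, n1: int, m2: float, s2: float,
                    n2: int) -> float:
    """Pooled-SD Cohen's d = (m1 - m2) / sp with
    sp^2 = ((n1-1)s1^2 + (n2-1)s2^2) / (n1 + n2 - 2)."""
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 observations")
    sp2 = ((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2)
    if sp2 == 0:
        if m1 == m2:
            return 0.0
        return float("nan")  # undefined: unequal means, zero pooled spread
    return (m1 - m2) / np.sqrt(sp2)


def cohens_d_from_samples(x1, x2) -> float:
    x1, x2 = np.asarray(x1, float), np.asarray(x2, float)
    return cohens_d_pooled(x1.mean(), x1.std(ddof=1), x1.size,
                           x2.mean(), x2.std(ddof=1), x2.size)


def independent_t(x1, x2, welch: bool = False) -> tuple[float, float, float]:
    """Two-sided independent-samples t-test; pooled (Student) by default.

    Returns (t, df, p).
    """
    x1, x2 = np.asarray(x1, float), np.asarray(x2, float)
    if x1.size < 2 or x2.size < 2:
        raise ValueError("each sample needs at least 2 values")
    res = stats.ttest_ind(x1, x2, equal_var=not welch)
    df = float(res.df)
    return float(res.statistic), df, float(res.pvalue)


def independent_t_from_stats(m1, s1, n1, m2, s2, n2,
                             welch: bool = False) -> tuple[float, float, float]:
    """Summary-statistic variant of :func:`independent_t`."""
    res = stats.ttest_ind_from_stats(m1, s1, n1, m2, s2, n2,
                                     equal_var=not welch)
    if welch:
        v1, v2 = s1**2 / n1, s2**2 / n2
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    else:
        df = n1 + n2 - 2
    return float(res.statistic), float(df), float(res.pvalue)


def table_one(table: pd.DataFrame, variables=None,
              welch: bool = False) -> pd.DataFrame:
    """Descriptive table: per-group mean/SD, pooled t, p, and Cohen's d
    (low minus high) for each variable, anxiety rating included."""
    if variables is None:
        variables = [ANXIETY] + [v for v in SPEECH_VARIABLES if v in table.columns]
    low, high = split_groups(table)
    if len(low) < 2 or len(high) < 2:
        raise ValueError(f"two-group statistics need >=2 rows per group "
                         f"(low n={len(low)}, high n={len(high)})")
    rows = []
    for var in variables:
        x_lo = low[var].dropna().to_numpy(float)
        x_hi = high[var].dropna().to_numpy(float)
        x_all = table[var].dropna().to_numpy(float)
        t, df, p = independent_t(x_lo, x_hi, welch=welch)
        rows.append({
            "variable": var,
            "total_mean": x_all.mean(), "total_sd": x_all.std(ddof=1),
            "low_mean": x_lo.mean(), "low_sd": x_lo.std(ddof=1),
            "high_mean": x_hi.mean(), "high_sd": x_hi.std(ddof=1),
            "n_low": x_lo.size, "n_high": x_hi.size,
            "t": t, "df": df, "p_value": p,
            "cohens_d": cohens_d_from_samples(x_lo, x_hi),
        })
    return pd.DataFrame(rows).set_index("variable")
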