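"""Permutation-based comparison of two groups' networks.

Both groups' networks are estimated (Spearman -> glasso -> EBIC), and three
families of statistics are referred to their permutation distributions
under random reassignment of rows to groups (group sizes preserved, full
re-estimation per permutation):

* global expected influence: S = |sum of edge weights(A) - sum(B)| over
  unique edges (so the node-EI total is twice each group's sum);
* edge weights: the maximum absolute difference M plus uncorrected
  per-edge tests;
* node centrality: per-node absolute expected-influence differences.

p-values use the add-one Monte-Carlo estimator (1 + #{perm >= obs})/(1 + P),
so they lie in [1/(P+1), 1] and are never zero. No multiplicity correction
is applied.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network import _estimate_weights, expected_influence
from .study import SPEECH_VARIABLES

__all__ = ["ComparisonResult", "nct", "NetworkComparisonTest"]


@dataclass(frozen=True)
class ComparisonResult:
    """Observed statistics and permutation p-values of a two-group test."""

    labels: list
    weights_a: np.ndarray
    weights_b: np.ndarray
    global_strength_a: float  # signed sum of unique edge weights
    global_strength_b: float
    global_statistic: float  # S = |sum_A - sum_B|
    global_p: float
    max_edge_statistic: float  # M = max_ij |w_A - w_B|
    max_edge_p: float
    edge_diff: np.ndarray  # signed w_A - w_B, (p, p)
    edge_p: np.ndarray  # per-edge permutation p, (p, p)
    ei_diff: np.ndarray  # signed EI_A - EI_B, per node
    ei_p: np.ndarray
    n_permutations: int
    n_failed: int
    seed: int
    group_sizes: tuple = (0, 0)

    def edge_frame(self) -> pd.DataFrame:
        rows = []
        p = len(self.labels)
        for i in range(p):
            for j in range(i + 1, p):
                rows.append({"node_i": self.labels[i], "node_j": self.labels[j],
                             "weight_a": self.weights_a[i, j],
                             "weight_b": self.weights_b[i, j],
                             "difference": self.edge_diff[i, j],
                             "p_value": self.edge_p[i, j]})
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            "Network comparison test (permutation)",
            "=" * 48,
            f"groups: n = {self.group_sizes[0]} vs {self.group_sizes[1]}   "
            f"permutations: {self.n_permutations}",
            f"global expected influence: A = {self.global_strength_a:.2f}; "
            f"B = {self.global_strength_b:.2f}; "
            f"S = {self.global_statistic:.2f}, p = {self.global_p:.2f}",
            f"maximum edge difference:   M = {self.max_edge_statistic:.2f}, "
            f"p = {self.max_edge_p:.2f}",
            "",
            "Per-edge tests (uncorrected):",
        ]
        for _, r in self.edge_frame().iterrows():
            lines.append(f"  {r.node_i:>12s} -- {r.node_j:<12s} "
                         f"dA-B = {r.difference:+.3f}  p = {r.p_value:.3f}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "labels": list(self.labels),
            "weights_a": self.weights_a.tolist(),
            "weights_b": self.weights_b.tolist(),
            "global": {"a": self.global_strength_a, "b": self.global_strength_b,
                       "S": self.global_statistic, "p": self.global_p},
            "max_edge": {"M": self.max_edge_statistic, "p": self.max_edge_p},
            "edge_diff": self.edge_diff.tolist(),
            "edge_p": self.edge_p.tolist(),
            "ei_diff": self.ei_diff.tolist(),
            "ei_p": self.ei_p.tolist(),
            "n_permutations": self.n_permutations,
            "n_failed": self.n_failed,
            "seed": self.seed,
            "group_sizes": list(self.group_sizes),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)


def _stats_from_weights(W: np.ndarray):
    iu = np.triu_indices(W.shape[0], 1)
    return W[iu].sum(), expected_influence(W)


def nct(table_a: pd.DataFrame, table_b: pd.DataFrame, columns=None,
        n_permutations: int = 1000, seed: int = 0, gamma: float = 0.5,
        n_lambdas: int = 100, lambda_min_ratio: float = 0.01,
        max_failure_rate: float = 0.05) -> ComparisonResult:
    """Two-group permutation network comparison test.

    ``columns`` defaults to the five speech parameters (the anxiety rating,
    which defines the groups, is excluded from the compared networks).
    """
    if columns is None:
        columns = [c for c in SPEECH_VARIABLES if c in table_a.columns]
    columns = list(columns)
    if any(c not in table_b.columns for c in columns):
        raise ValueError("both tables must share the node columns")
    Xa = table_a[columns].dropna().to_numpy(float)
    Xb = table_b[columns].dropna().to_numpy(float)
    p = len(columns)
    if len(Xa) < 3 * p or len(Xb) < 3 * p:
        raise ValueError(f"each group needs at least {3 * p} complete rows")
    rng = np.random.default_rng(seed)

    def estimate(X):
        return _estimate_weights(X, len(X), gamma, n_lambdas, lambda_min_ratio)

    Wa, Wb = estimate(Xa), estimate(Xb)
    sum_a, ei_a = _stats_from_weights(Wa)
    sum_b, ei_b = _stats_from_weights(Wb)
    obs_global = abs(sum_a - sum_b)
    diff = Wa - Wb
    obs_edge = np.abs(diff)
    obs_max = obs_edge.max()
    obs_ei = np.abs(ei_a - ei_b)

    pooled = np.vstack([Xa, Xb])
    na, n = len(Xa), len(pooled)
    ge_global = 0
    ge_max = 0
    ge_edge = np.zeros((p, p), dtype=int)
    ge_ei = np.zeros(p, dtype=int)
    failed = 0
    done = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        try:
            Wpa = estimate(pooled[perm[:na]])
            Wpb = estimate(pooled[perm[na:]])
        except (ValueError, np.linalg.LinAlgError):
            failed += 1
            continue
        sa, eia = _stats_from_weights(Wpa)
        sb, eib = _stats_from_weights(Wpb)
        d = np.abs(Wpa - Wpb)
        ge_global += abs(sa - sb) >= obs_global
        ge_max += d.max() >= obs_max
        ge_edge += d >= obs_edge
        ge_ei += np.abs(eia - eib) >= obs_ei
        done += 1
    if failed > max_failure_rate * n_permutations:
        raise RuntimeError(f"{failed}/{n_permutations} permutations failed")

    def pval(count):
        return (1.0 + count) / (1.0 + done)

    edge_p = pval(ge_edge.astype(float))
    np.fill_diagonal(edge_p, 1.0)
    return ComparisonResult(
        labels=columns, weights_a=Wa, weights_b=Wb,
        global_strength_a=float(sum_a), global_strength_b=float(sum_b),
        global_statistic=float(obs_global), global_p=float(pval(ge_global)),
        max_edge_statistic=float(obs_max), max_edge_p=float(pval(ge_max)),
        edge_diff=diff, edge_p=edge_p,
        ei_diff=ei_a - ei_b, ei_p=pval(ge_ei.astype(float)),
        n_permutations=done, n_failed=failed, seed=seed,
        group_sizes=(len(Xa), len(Xb)))


class NetworkComparisonTest:
    """Model-style wrapper around :func:`nct`.

    >>> result = NetworkComparisonTest(low_table, high_table).fit(seed=1)
    >>> print(result.summary())
    """

    def __init__(self, table_a: pd.DataFrame, table_b: pd.DataFrame,
                 columns=None):
        self.table_a = table_a
        self.table_b = table_b
        self.columns = columns

    def fit(self, n_permutations: int = 1000, seed: int = 0,
            **kwargs) -> ComparisonResult:
        return nct(self.table_a, self.table_b, columns=self.columns,
                   n_permutations=n_permutations, seed=seed, **kwargs)
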