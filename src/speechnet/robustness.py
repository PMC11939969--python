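"""Bootstrap accuracy and stability of network estimates.

Three procedures, all with full model re-estimation per resample and fully
seed-deterministic:

* nonparametric (row-resampling) bootstrap 95% percentile CIs per edge;
* bootstrapped difference tests for edge pairs and expected-influence
  pairs (a difference is "significant" when its bootstrap CI excludes 0;
  deliberately uncorrected for multiplicity);
* the case-dropping correlation-stability (CS) coefficient: the largest
  proportion of rows that can be dropped such that, with 95% certainty,
  subsample expected influence still correlates >= 0.7 with the
  full-sample values. CS below 0.25 is conventionally considered
  unstable, above 0.5 stable; the report carries that flag.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network import _estimate_weights, expected_influence

__all__ = ["StabilityReport", "CSReport", "bootstrap_edges", "cs_coefficient"]

CS_GRID = np.round(np.arange(0.05, 0.80, 0.05), 2)


@dataclass(frozen=True)
class StabilityReport:
    """Edge-accuracy bootstrap output."""

    labels: list
    edge_index: list  # (i, j) label pairs, upper triangle order
    point_estimates: np.ndarray  # per-edge sample weights
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    boot_mean: np.ndarray
    edge_diff_significant: np.ndarray  # (n_edges, n_edges) bool
    ei_point: np.ndarray
    ei_diff_significant: np.ndarray  # (p, p) bool
    n_boot: int
    n_failed: int
    seed: int

    def edge_ci_frame(self) -> pd.DataFrame:
        names = [f"{a}--{b}" for a, b in self.edge_index]
        return pd.DataFrame({
            "edge": names, "estimate": self.point_estimates,
            "boot_mean": self.boot_mean,
            "ci_lower": self.ci_lower, "ci_upper": self.ci_upper,
        })

    def to_dict(self) -> dict:
        return {
            "labels": list(self.labels),
            "edges": [list(e) for e in self.edge_index],
            "estimate": self.point_estimates.tolist(),
            "ci_lower": self.ci_lower.tolist(),
            "ci_upper": self.ci_upper.tolist(),
            "boot_mean": self.boot_mean.tolist(),
            "edge_diff_significant": self.edge_diff_significant.tolist(),
            "expected_influence": self.ei_point.tolist(),
            "ei_diff_significant": self.ei_diff_significant.tolist(),
            "n_boot": self.n_boot, "n_failed": self.n_failed, "seed": self.seed,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)


def _upper(W: np.ndarray) -> np.ndarray:
    p = W.shape[0]
    iu = np.triu_indices(p, 1)
    return W[iu]


def bootstrap_edges(table: pd.DataFrame, columns=None, n_boot: int = 1000,
                    seed: int = 0, gamma: float = 0.5, n_lambdas: int = 100,
                    lambda_min_ratio: float = 0.01,
                    max_failure_rate: float = 0.05) -> StabilityReport:
    """Row-resampling bootstrap of the full estimation chain.

    Per replicate, rows are resampled with replacement and the whole
    Spearman -> glasso -> EBIC chain re-run. Replicates whose estimation
    fails (e.g. a constant resampled column) are dropped and counted;
    more than ``max_failure_rate`` failures aborts.
    """
    if n_boot < 100:
        warnings.warn(f"n_boot = {n_boot} < 100: bootstrap CIs will be coarse",
                      stacklevel=2)
    if columns is None:
        columns = [c for c in table.columns if c != "group"]
    X = table[list(columns)].dropna().to_numpy(float)
    n, p = X.shape
    rng = np.random.default_rng(seed)

    W_hat = _estimate_weights(X, n, gamma, n_lambdas, lambda_min_ratio)
    ei_hat = expected_influence(W_hat)

    n_edges = p * (p - 1) // 2
    boot_w = np.empty((n_boot, n_edges))
    boot_ei = np.empty((n_boot, p))
    failed = 0
    kept = 0
    for _ in range(n_boot):
        rows = rng.integers(0, n, size=n)
        try:
            W_b = _estimate_weights(X[rows], n, gamma, n_lambdas,
                                    lambda_min_ratio)
        except (ValueError, np.linalg.LinAlgError):
            failed += 1
            continue
        boot_w[kept] = _upper(W_b)
        boot_ei[kept] = expected_influence(W_b)
        kept += 1
    if failed > max_failure_rate * n_boot:
        raise RuntimeError(f"{failed}/{n_boot} bootstrap replicates failed")
    boot_w, boot_ei = boot_w[:kept], boot_ei[:kept]

    lo, hi = np.percentile(boot_w, [2.5, 97.5], axis=0)
    # difference tests: bootstrap CI of each pairwise difference vs 0
    dw = boot_w[:, :, None] - boot_w[:, None, :]
    dlo, dhi = np.percentile(dw, [2.5, 97.5], axis=0)
    edge_sig = (dlo > 0) | (dhi < 0)
    np.fill_diagonal(edge_sig, False)
    de = boot_ei[:, :, None] - boot_ei[:, None, :]
    elo, ehi = np.percentile(de, [2.5, 97.5], axis=0)
    ei_sig = (elo > 0) | (ehi < 0)
    np.fill_diagonal(ei_sig, False)

    labels = list(columns)
    iu = np.triu_indices(p, 1)
    edge_index = [(labels[i], labels[j]) for i, j in zip(*iu)]
    return StabilityReport(labels=labels, edge_index=edge_index,
                           point_estimates=_upper(W_hat), ci_lower=lo,
                           ci_upper=hi, boot_mean=boot_w.mean(axis=0),
                           edge_diff_significant=edge_sig, ei_point=ei_hat,
                           ei_diff_significant=ei_sig, n_boot=n_boot,
                           n_failed=failed, seed=seed)


@dataclass(frozen=True)
class CSReport:
    """Case-dropping stability curve and CS coefficient."""

    cs_coefficient: float
    curve: pd.DataFrame = field(repr=False)  # drop, q05, median, q95, n_kept
    threshold: float
    certainty: float
    n_boot: int
    seed: int

    @property
    def quality(self) -> str:
        if self.cs_coefficient > 0.5:
            return "stable"
        if self.cs_coefficient >= 0.25:
            return "moderate"
        return "unstable"

    def to_dict(self) -> dict:
        return {"cs_coefficient": self.cs_coefficient, "quality": self.quality,
                "threshold": self.threshold, "certainty": self.certainty,
                "n_boot": self.n_boot, "seed": self.seed,
                "curve": self.curve.to_dict(orient="list")}


def cs_coefficient(table: pd.DataFrame, columns=None, n_boot: int = 1000,
                   seed: int = 0, drops=None, threshold: float = 0.7,
                   certainty: float = 0.95, gamma: float = 0.5,
                   n_lambdas: int = 100, lambda_min_ratio: float = 0.01) -> CSReport:
    """Case-dropping bootstrap of expected-influence stability.

    For each drop proportion, ``n_boot`` subsamples (without replacement)
    are re-estimated and their expected influence correlated (Pearson, over
    nodes) with the full-sample values; the CS coefficient is the largest
    drop whose ``1 - certainty`` quantile correlation still reaches
    ``threshold``. Degenerate subsample correlations (zero variance or
    failed fits) count as below threshold.
    """
    if columns is None:
        columns = [c for c in table.columns if c != "group"]
    X = table[list(columns)].dropna().to_numpy(float)
    n, p = X.shape
    drops = CS_GRID if drops is None else np.asarray(drops, float)
    usable = drops[np.floor(n * (1 - drops)).astype(int) >= 3 * p]
    if usable.size < drops.size:
        warnings.warn("largest drop proportions leave fewer than 3p rows; "
                      "grid truncated", stacklevel=2)
    rng = np.random.default_rng(seed)

    W_full = _estimate_weights(X, n, gamma, n_lambdas, lambda_min_ratio)
    ei_full = expected_influence(W_full)

    rows_out = []
    cs = 0.0
    for drop in usable:
        keep = int(np.floor(n * (1 - drop)))
        corrs = np.empty(n_boot)
        for b in range(n_boot):
            rows = rng.choice(n, size=keep, replace=False)
            try:
                W_s = _estimate_weights(X[rows], keep, gamma, n_lambdas,
                                        lambda_min_ratio)
                ei_s = expected_influence(W_s)
                if ei_s.std() == 0 or ei_full.std() == 0:
                    corrs[b] = -2.0  # undefined: counted below any threshold
                else:
                    corrs[b] = np.corrcoef(ei_s, ei_full)[0, 1]
            except (ValueError, np.linalg.LinAlgError):
                corrs[b] = -2.0
        q05 = np.quantile(corrs, 1 - certainty)
        rows_out.append({"drop": float(drop), "q05": float(q05),
                         "median": float(np.median(corrs)),
                         "q95": float(np.quantile(corrs, certainty)),
                         "n_kept": keep})
        if q05 >= threshold:
            cs = float(drop)
    curve = pd.DataFrame(rows_out)
    return CSReport(cs_coefficient=cs, curve=curve, threshold=threshold,
                    certainty=certainty, n_boot=n_boot, seed=seed)
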