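"""Regularized partial-correlation network estimation.

The model: node variables are assumed monotonically related to a latent
Gaussian vector; edges are the partial correlations implied by a sparse
inverse of the Spearman correlation matrix, estimated by graphical lasso
with the penalty chosen by the Extended Bayesian Information Criterion
(EBIC, gamma = 0.5 by default, which prefers sparse graphs). Centrality is
expected influence (the signed sum of a node's edge weights), the
appropriate index when negative edges are present.

`SpeechNetwork` is the model object (statsmodels-style): build it from a
feature DataFrame, call :meth:`SpeechNetwork.fit`, and work with the
returned :class:`SpeechNetworkResults` (weights, EBIC path, centrality,
bootstrap stability, layout, summary table). The module-level functions
(:func:`spearman_matrix`, :func:`glasso_fit`, :func:`ebic_select`, ...) are
the underlying primitives.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .glasso import glasso_fit, glasso_path
from .study import ANXIETY, SPEECH_VARIABLES

__all__ = [
    "CorrelationMatrix",
    "NetworkModel",
    "RedundancyReport",
    "spearman_matrix",
    "goldbricker",
    "glasso_fit",
    "ebic_select",
    "precision_to_pcor",
    "expected_influence",
    "fr_layout",
    "SpeechNetwork",
    "SpeechNetworkResults",
]


# ---------------------------------------------------------------------------
# correlation


@dataclass(frozen=True)
class CorrelationMatrix:
    matrix: np.ndarray
    labels: list
    n: int
    repaired: bool = False


def _rank_columns(X: np.ndarray) -> np.ndarray:
    return stats.rankdata(X, axis=0, method="average")


def _spearman(X: np.ndarray) -> np.ndarray:
    """Spearman rho via Pearson correlation of average ranks."""
    R = _rank_columns(X)
    sd = R.std(axis=0)
    if np.any(sd == 0):
        raise ValueError(f"constant column at index {int(np.flatnonzero(sd == 0)[0])}: "
                         "Spearman correlation undefined")
    return np.corrcoef(R, rowvar=False)


def _pd_repair(S: np.ndarray, floor: float = 1e-6) -> tuple[np.ndarray, bool]:
    w, V = np.linalg.eigh(S)
    if w.min() > floor:
        return S, False
    w = np.clip(w, floor, None)
    S2 = (V * w) @ V.T
    d = np.sqrt(np.diag(S2))
    S2 = S2 / np.outer(d, d)
    np.fill_diagonal(S2, 1.0)
    return 0.5 * (S2 + S2.T), True


def spearman_matrix(table: pd.DataFrame, columns=None) -> CorrelationMatrix:
    """Pairwise Spearman correlations (average-rank ties) after listwise
    deletion, with eigenvalue-clipping PD repair when needed (flagged)."""
    if columns is None:
        columns = [c for c in table.columns if c != "group"]
    sub = table[list(columns)].dropna()
    if len(sub) < 3:
        raise ValueError("need at least 3 complete rows for a correlation matrix")
    for c in columns:
        if sub[c].nunique() <= 1:
            raise ValueError(f"constant column {c!r}: Spearman correlation undefined")
    S = _spearman(sub.to_numpy(dtype=float))
    S, repaired = _pd_repair(S)
    if repaired:
        warnings.warn("Spearman matrix was not positive definite; eigenvalues clipped",
                      stacklevel=2)
    return CorrelationMatrix(matrix=S, labels=list(columns), n=len(sub),
                             repaired=repaired)


# ---------------------------------------------------------------------------
# redundancy screening


@dataclass(frozen=True)
class RedundancyReport:
    """Node pairs flagged as statistically redundant.

    A pair is flagged when its zero-order |rho| is at least ``r_min`` and
    fewer than ``prop_max`` of the remaining nodes discriminate the two
    correlation profiles (dependent-correlation z test).
    """

    flagged: list
    details: pd.DataFrame
    r_min: float
    prop_max: float
    alpha: float
    untestable: bool = False


def _dependent_corr_z(r_jk: float, r_hk: float, r_jh: float, n: int,
                      method: str = "steiger1980") -> float:
    """z statistic for H0: rho_jk = rho_hk with shared variable k.

    ``steiger1980`` uses the mean-correlation plug-in; ``hittner2003`` the
    back-transformed mean Fisher z (both as documented for the cocor/psych
    implementations).
    """
    clip = 0.999999
    r_jk, r_hk, r_jh = (float(np.clip(v, -clip, clip)) for v in (r_jk, r_hk, r_jh))
    z_jk, z_hk = np.arctanh(r_jk), np.arctanh(r_hk)
    if z_jk == z_hk:
        return 0.0
    if method == "hittner2003":
        rm = np.tanh((z_jk + z_hk) / 2.0)
        rm2 = rm * rm
    else:
        rm2 = (r_jk**2 + r_hk**2) / 2.0
    f = min((1.0 - r_jh) / (2.0 * (1.0 - rm2)), 1.0)
    h = (1.0 - f * rm2) / (1.0 - rm2)
    return float((z_jk - z_hk) * np.sqrt((n - 3) / (2.0 * (1.0 - r_jh) * h)))


def goldbricker(table: pd.DataFrame, columns=None, r_min: float = 0.50,
                prop_max: float = 0.25, alpha: float = 0.05,
                method: str = "steiger1980") -> RedundancyReport:
    """Redundant-node screen on a feature table.

    For every pair correlating at |rho| >= ``r_min``, each third variable's
    correlations with the two candidates are compared by a dependent-
    correlation z test; if the proportion of significantly different
    profiles is below ``prop_max`` the pair carries no distinct information
    and is flagged.
    """
    corr = spearman_matrix(table, columns)
    S, labels, n = corr.matrix, corr.labels, corr.n
    p = len(labels)
    if p < 4:
        raise ValueError("redundancy screening needs at least 4 nodes")
    if n < 10:
        return RedundancyReport([], pd.DataFrame(), r_min, prop_max, alpha,
                                untestable=True)
    rows, flagged = [], []
    for j in range(p):
        for h in range(j + 1, p):
            r0 = S[j, h]
            if abs(r0) < r_min:
                continue
            others = [k for k in range(p) if k not in (j, h)]
            n_sig = sum(
                2 * stats.norm.sf(abs(_dependent_corr_z(S[j, k], S[h, k], r0, n,
                                                        method))) < alpha
                for k in others)
            prop = n_sig / len(others)
            rows.append({"node_a": labels[j], "node_b": labels[h],
                         "zero_order_r": r0, "prop_significant": prop})
            if prop < prop_max:
                flagged.append((labels[j], labels[h]))
    return RedundancyReport(flagged, pd.DataFrame(rows), r_min, prop_max, alpha)


# ---------------------------------------------------------------------------
# estimation


def precision_to_pcor(K: np.ndarray) -> np.ndarray:
    """Partial correlations from a PD precision matrix:
    w_ij = -K_ij / sqrt(K_ii K_jj), zero diagonal."""
    K = np.asarray(K, dtype=float)
    if np.linalg.eigvalsh(0.5 * (K + K.T)).min() <= 0:
        raise ValueError("precision matrix is not positive definite")
    d = np.sqrt(np.diag(K))
    W = -K / np.outer(d, d)
    np.fill_diagonal(W, 0.0)
    return 0.5 * (W + W.T)


def _lambda_grid(S: np.ndarray, n_lambdas: int, lambda_min_ratio: float) -> np.ndarray:
    off = np.abs(S - np.diag(np.diag(S)))
    lam_max = max(off.max(), 1e-4)
    return np.exp(np.linspace(np.log(lam_max), np.log(lam_max * lambda_min_ratio),
                              n_lambdas))


@dataclass(frozen=True)
class NetworkModel:
    """A selected partial-correlation network."""

    labels: list
    weights: np.ndarray
    lambda_selected: float
    gamma: float
    ebic_path: pd.DataFrame = field(repr=False)
    n: int
    precision: np.ndarray = field(repr=False, default=None)

    @property
    def edge_count(self) -> int:
        return int(np.count_nonzero(np.triu(self.weights, 1)))

    def edges(self) -> list:
        out = []
        for i in range(len(self.labels)):
            for j in range(i + 1, len(self.labels)):
                if self.weights[i, j] != 0:
                    out.append((self.labels[i], self.labels[j],
                                float(self.weights[i, j])))
        return out


def ebic_select(S, n: int = None, gamma: float = 0.5, n_lambdas: int = 100,
                lambda_min_ratio: float = 0.01, labels=None) -> NetworkModel:
    """Graphical lasso over a log-spaced lambda path with EBIC selection.

    The path runs from the smallest lambda giving an empty graph (the
    largest absolute off-diagonal correlation) down to ``lambda_min_ratio``
    times that; ties in EBIC resolve to the sparser (larger-lambda) fit.
    """
    if isinstance(S, CorrelationMatrix):
        labels = S.labels if labels is None else labels
        n = S.n if n is None else n
        S = S.matrix
    S = np.asarray(S, dtype=float)
    p = S.shape[0]
    if n is None:
        raise ValueError("sample size n is required")
    if labels is None:
        labels = list(range(p))
    if n < p + 1:
        warnings.warn(f"n = {n} < p + 1 = {p + 1}: EBIC selection is unreliable",
                      stacklevel=2)
    lambdas = _lambda_grid(S, n_lambdas, lambda_min_ratio)
    Zs, ebics, edges, lls = glasso_path(S, n, gamma, lambdas)
    sel = int(np.argmin(ebics))  # argmin takes the first (sparsest) on ties
    path = pd.DataFrame({"lambda": lambdas, "edge_count": edges,
                         "ebic": ebics, "loglik": lls})
    return NetworkModel(labels=list(labels), weights=precision_to_pcor(Zs[sel]),
                        lambda_selected=float(lambdas[sel]), gamma=gamma,
                        ebic_path=path, n=int(n), precision=Zs[sel])


def _estimate_weights(X: np.ndarray, n: int, gamma: float = 0.5,
                      n_lambdas: int = 100, lambda_min_ratio: float = 0.01) -> np.ndarray:
    """Fast path used by resampling procedures: ranks -> glasso -> weights."""
    S, _ = _pd_repair(_spearman(X))
    lambdas = _lambda_grid(S, n_lambdas, lambda_min_ratio)
    Zs, ebics, _, _ = glasso_path(S, n, gamma, lambdas)
    return precision_to_pcor(Zs[int(np.argmin(ebics))])


# ---------------------------------------------------------------------------
# centrality and layout


def expected_influence(W: np.ndarray) -> np.ndarray:
    """One-step expected influence: the signed row sum of edge weights."""
    W = np.asarray(W, dtype=float)
    if not np.allclose(W, W.T, atol=1e-10):
        raise ValueError("weight matrix must be symmetric")
    return W.sum(axis=1) - np.diag(W)


def fr_layout(W: np.ndarray, labels=None, seed: int = 0,
              iterations: int = 50) -> pd.DataFrame:
    """Fruchterman-Reingold coordinates with |weight| as attraction."""
    import networkx as nx

    W = np.asarray(W, dtype=float)
    p = W.shape[0]
    if labels is None:
        labels = list(range(p))
    if p == 1:
        return pd.DataFrame([[0.0, 0.0]], index=list(labels), columns=["x", "y"])
    G = nx.Graph()
    G.add_nodes_from(range(p))
    for i in range(p):
        for j in range(i + 1, p):
            if W[i, j] != 0:
                G.add_edge(i, j, weight=abs(W[i, j]))
    pos = nx.spring_layout(G, seed=seed, iterations=iterations, weight="weight")
    coords = np.array([pos[i] for i in range(p)])
    return pd.DataFrame(coords, index=list(labels), columns=["x", "y"])


# ---------------------------------------------------------------------------
# model / results objects


class SpeechNetwork:
    """Partial-correlation network model for a feature table.

    Parameters
    ----------
    data : DataFrame
        One row per speaker. Non-numeric and ``group`` columns are ignored
        unless ``columns`` is given. Rows with missing values in the
        selected columns are dropped (listwise).
    columns : sequence of str, optional
        Node variables, in order. Defaults to the five speech parameters
        plus ``anxiety`` when present.
    """

    def __init__(self, data: pd.DataFrame, columns=None):
        if columns is None:
            columns = [c for c in SPEECH_VARIABLES + [ANXIETY] if c in data.columns]
            if not columns:
                columns = [c for c in data.columns
                           if c != "group" and pd.api.types.is_numeric_dtype(data[c])]
        self.columns = list(columns)
        self.data = data[self.columns].dropna().reset_index(drop=True)
        self.n_dropped = len(data) - len(self.data)

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, columns=None) -> "SpeechNetwork":
        return cls(data, columns=columns)

    @property
    def nobs(self) -> int:
        return len(self.data)

    def correlations(self) -> CorrelationMatrix:
        return spearman_matrix(self.data, self.columns)

    def screen_redundancy(self, **kwargs) -> RedundancyReport:
        return goldbricker(self.data, self.columns, **kwargs)

    def fit(self, gamma: float = 0.5, n_lambdas: int = 100,
            lambda_min_ratio: float = 0.01) -> "SpeechNetworkResults":
        corr = self.correlations()
        model = ebic_select(corr, gamma=gamma, n_lambdas=n_lambdas,
                            lambda_min_ratio=lambda_min_ratio)
        return SpeechNetworkResults(self, model, corr)


class SpeechNetworkResults:
    """Fit results: edge weights, selection path, centrality, stability."""

    def __init__(self, model: SpeechNetwork, network: NetworkModel,
                 corr: CorrelationMatrix):
        self.model = model
        self.network = network
        self.corr = corr

    # -- estimates ----------------------------------------------------------
    @property
    def labels(self) -> list:
        return self.network.labels

    @property
    def weights(self) -> pd.DataFrame:
        return pd.DataFrame(self.network.weights, index=self.labels,
                            columns=self.labels)

    @property
    def lambda_(self) -> float:
        return self.network.lambda_selected

    @property
    def ebic_path(self) -> pd.DataFrame:
        return self.network.ebic_path

    def expected_influence(self) -> pd.Series:
        return pd.Series(expected_influence(self.network.weights),
                         index=self.labels, name="expected_influence")

    def edges(self) -> list:
        return self.network.edges()

    def layout(self, seed: int = 0, iterations: int = 50) -> pd.DataFrame:
        return fr_layout(self.network.weights, self.labels, seed, iterations)

    # -- stability ----------------------------------------------------------
    def bootstrap(self, n_boot: int = 1000, seed: int = 0, **kwargs):
        from .robustness import bootstrap_edges

        return bootstrap_edges(self.model.data, self.model.columns,
                               n_boot=n_boot, seed=seed,
                               gamma=self.network.gamma, **kwargs)

    def cs_coefficient(self, n_boot: int = 1000, seed: int = 0, **kwargs):
        from .robustness import cs_coefficient

        return cs_coefficient(self.model.data, self.model.columns,
                              n_boot=n_boot, seed=seed,
                              gamma=self.network.gamma, **kwargs)

    # -- reporting ----------------------------------------------------------
    def summary(self) -> str:
        net = self.network
        ei = self.expected_influence()
        lines = [
            "Partial-correlation network (graphical lasso + EBIC)",
            "=" * 56,
            f"nodes: {len(self.labels)}   n = {net.n}   "
            f"edges: {net.edge_count}",
            f"gamma = {net.gamma:g}   selected lambda = {net.lambda_selected:.4f}",
            "",
            "Edges (partial correlation):",
        ]
        for a, b, w in sorted(self.edges(), key=lambda e: -abs(e[2])):
            lines.append(f"  {a:>12s} -- {b:<12s} {w:+.3f}")
        if net.edge_count == 0:
            lines.append("  (empty graph)")
        lines.append("")
        lines.append("Expected influence:")
        for name, v in ei.items():
            lines.append(f"  {name:>12s} {v:+.3f}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        net = self.network
        return {
            "labels": list(self.labels),
            "weights": net.weights.tolist(),
            "lambda": net.lambda_selected,
            "gamma": net.gamma,
            "n": net.n,
            "edge_count": net.edge_count,
            "expected_influence": self.expected_influence().tolist(),
            "ebic_path": {
                "lambda": net.ebic_path["lambda"].tolist(),
                "edge_count": net.ebic_path["edge_count"].tolist(),
                "ebic": net.ebic_path["ebic"].tolist(),
            },
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)

    def edge_list(self) -> pd.DataFrame:
        return pd.DataFrame(self.edges(), columns=["node_i", "node_j", "weight"])
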