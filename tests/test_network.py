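"""Network estimation: Spearman, glasso, EBIC selection, centrality."""

import numpy as np
import pandas as pd
import pytest

import speechnet as sn
from speechnet import study
from speechnet.network import (SpeechNetwork, ebic_select, expected_influence,
                               fr_layout, glasso_fit, goldbricker,
                               precision_to_pcor, spearman_matrix)


def _objective(K, S, lam):
    sign, logdet = np.linalg.slogdet(K)
    if sign <= 0:
        return np.inf
    off = K - np.diag(np.diag(K))
    return -logdet + np.trace(S @ K) + lam * np.abs(off).sum()


def _cyclic_oracle(S, lam, sweeps=400):
    """Independent minimizer: cyclic 1-D golden-section over each entry."""
    from scipy.optimize import minimize_scalar

    p = S.shape[0]
    K = np.linalg.inv(S)
    for _ in range(sweeps):
        for i in range(p):
            for j in range(i, p):
                def f(v, i=i, j=j):
                    Kt = K.copy()
                    Kt[i, j] = Kt[j, i] = v
                    return _objective(Kt, S, lam)

                res = minimize_scalar(f, bracket=(K[i, j] - 0.3, K[i, j] + 0.3))
                if np.isfinite(res.fun):
                    K[i, j] = K[j, i] = res.x
        # lasso solutions sit at exact zeros; snap and keep if better
        for i in range(p):
            for j in range(i + 1, p):
                Kt = K.copy()
                Kt[i, j] = Kt[j, i] = 0.0
                if _objective(Kt, S, lam) <= _objective(K, S, lam):
                    K = Kt
    return K


class TestSpearman:
    def test_monotone_transform_gives_unit_rho(self):
        x = np.linspace(0, 1, 40)
        tab = pd.DataFrame({"a": x, "b": np.exp(3 * x), "c": -x**3})
        S = spearman_matrix(tab, ["a", "b", "c"]).matrix
        assert S[0, 1] == pytest.approx(1.0)
        assert S[0, 2] == pytest.approx(-1.0)

    def test_hand_rank_example(self):
        tab = pd.DataFrame({"x": [1, 2, 3], "y": [3, 1, 2], "z": [1, 2, 3]})
        S = spearman_matrix(tab, ["x", "y", "z"]).matrix
        assert S[0, 1] == pytest.approx(-0.5)

    def test_constant_column_names_offender(self):
        tab = pd.DataFrame({"x": [1, 2, 3, 4], "y": [1, 1, 1, 1]})
        with pytest.raises(ValueError, match="'y'"):
            spearman_matrix(tab, ["x", "y"])

    def test_listwise_deletion_counts_n(self, study_table):
        tab = study_table.copy()
        tab.loc[:9, "jitter"] = np.nan
        corr = spearman_matrix(tab, study.SPEECH_VARIABLES)
        assert corr.n == len(study_table) - 10


class TestGlasso:
    def test_full_shrinkage_gives_diagonal(self):
        S = np.array([[1.0, 0.5], [0.5, 1.0]])
        K = glasso_fit(S, lam=0.6)
        assert K[0, 1] == 0.0

    def test_unpenalized_limit_inverts(self):
        rng = np.random.default_rng(0)
        A = rng.normal(size=(4, 4))
        S = A @ A.T / 4 + np.eye(4)
        np.testing.assert_allclose(glasso_fit(S, 0.0), np.linalg.inv(S),
                                   atol=1e-5)

    def test_p2_closed_form_soft_threshold(self):
        S = np.array([[1.0, 0.5], [0.5, 1.0]])
        K = glasso_fit(S, lam=0.2)
        assert precision_to_pcor(K)[0, 1] == pytest.approx(0.3, abs=1e-6)

    def test_kkt_conditions_hold(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            A = rng.normal(size=(5, 8))
            S = np.corrcoef(A)
            lam = rng.uniform(0.05, 0.4)
            K = glasso_fit(S, lam)
            W = np.linalg.inv(K)
            # stationarity of -logdet K + tr(SK) + lam|K|_offdiag:
            # W - S = lam * sign(K) on the support, |W - S| <= lam off it
            for i in range(5):
                for j in range(i + 1, 5):
                    grad = W[i, j] - S[i, j]
                    if K[i, j] == 0:
                        assert abs(grad) <= lam + 1e-4
                    else:
                        assert grad == pytest.approx(lam * np.sign(K[i, j]),
                                                     abs=1e-4)

    def test_matches_cyclic_descent_oracle_p3(self):
        rng = np.random.default_rng(3)
        for _ in range(3):
            A = rng.normal(size=(3, 30))
            S = np.corrcoef(A)
            lam = 0.15
            K = glasso_fit(S, lam)
            K_oracle = _cyclic_oracle(S, lam, sweeps=60)
            assert _objective(K, S, lam) == pytest.approx(
                _objective(K_oracle, S, lam), abs=1e-3)

    def test_matches_sklearn_reference(self):
        sklearn = pytest.importorskip("sklearn.covariance")
        rng = np.random.default_rng(9)
        A = rng.normal(size=(5, 60))
        S = np.corrcoef(A)
        _, K_ref = sklearn.graphical_lasso(S, alpha=0.1, tol=1e-10)
        K = glasso_fit(S, 0.1)
        np.testing.assert_allclose(K, K_ref, atol=2e-4)

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValueError):
            glasso_fit(np.eye(2), -0.1)


class TestPrecisionToPcor:
    def test_diagonal_gives_empty(self):
        assert np.all(precision_to_pcor(np.diag([2.0, 3.0, 1.0])) == 0)

    def test_hand_formula(self):
        K = np.array([[2.0, -1.0], [-1.0, 2.0]])
        assert precision_to_pcor(K)[0, 1] == pytest.approx(0.5)

    def test_non_pd_raises(self):
        with pytest.raises(ValueError):
            precision_to_pcor(np.array([[1.0, 2.0], [2.0, 1.0]]))


class TestEbicSelect:
    def test_independent_data_selects_empty_graph(self, independent_table):
        corr = spearman_matrix(independent_table, study.SPEECH_VARIABLES)
        model = ebic_select(corr)
        assert model.edge_count == 0

    def test_edge_counts_monotone_along_path(self, study_table):
        fit = SpeechNetwork(study_table).fit()
        counts = fit.ebic_path["edge_count"].to_numpy()
        lams = fit.ebic_path["lambda"].to_numpy()
        assert np.all(np.diff(lams) < 0)
        assert np.all(np.diff(counts) >= 0)  # E non-increasing in lambda

    def test_node_permutation_consistency(self, study_table):
        cols = study.SPEECH_VARIABLES
        fit = SpeechNetwork(study_table, columns=cols).fit()
        perm = [cols[i] for i in (3, 0, 4, 1, 2)]
        fit_p = SpeechNetwork(study_table, columns=perm).fit()
        assert set(map(frozenset, [(a, b) for a, b, _ in fit.edges()])) == \
            set(map(frozenset, [(a, b) for a, b, _ in fit_p.edges()]))

    def test_weights_bounded_and_symmetric(self, study_table):
        fit = SpeechNetwork(study_table).fit()
        W = fit.weights.to_numpy()
        assert np.all(np.abs(W) < 1)
        np.testing.assert_allclose(W, W.T)
        assert np.all(np.diag(W) == 0)

    def test_small_n_warns(self):
        rng = np.random.default_rng(2)
        tab = pd.DataFrame(rng.normal(size=(5, 5)),
                           columns=study.SPEECH_VARIABLES)
        with pytest.warns(UserWarning, match="unreliable"):
            SpeechNetwork(tab, columns=study.SPEECH_VARIABLES).fit()


class TestExpectedInfluence:
    def test_empty_network_zero(self):
        assert np.all(expected_influence(np.zeros((4, 4))) == 0)

    def test_signed_row_sum(self):
        W = np.zeros((4, 4))
        W[0, 1] = W[1, 0] = 0.28
        W[0, 2] = W[2, 0] = 0.33
        assert expected_influence(W)[0] == pytest.approx(0.61)

    def test_total_is_twice_edge_sum(self, study_table):
        fit = SpeechNetwork(study_table).fit()
        W = fit.weights.to_numpy()
        ei = expected_influence(W)
        assert ei.sum() == pytest.approx(2 * np.triu(W, 1).sum())


class TestGoldbricker:
    def test_duplicate_column_flagged(self, study_table):
        tab = study_table.copy()
        tab["jitter_copy"] = tab["jitter"]
        rep = goldbricker(tab, study.SPEECH_VARIABLES + ["jitter_copy"])
        assert ("jitter", "jitter_copy") in rep.flagged

    def test_independent_columns_unflagged(self, independent_table):
        rep = goldbricker(independent_table, study.SPEECH_VARIABLES)
        assert rep.flagged == []

    def test_study_topology_not_redundant(self, study_table):
        rep = goldbricker(study_table,
                          study.SPEECH_VARIABLES + [study.ANXIETY])
        assert rep.flagged == []

    def test_tiny_sample_untestable(self):
        rng = np.random.default_rng(0)
        tab = pd.DataFrame(rng.normal(size=(6, 5)),
                           columns=study.SPEECH_VARIABLES)
        assert goldbricker(tab, study.SPEECH_VARIABLES).untestable


class TestLayout:
    def test_single_node_origin(self):
        pos = fr_layout(np.zeros((1, 1)), ["solo"])
        np.testing.assert_allclose(pos.loc["solo"], [0.0, 0.0])

    def test_seed_reproducibility(self, study_table):
        fit = SpeechNetwork(study_table).fit()
        a = fit.layout(seed=4)
        b = fit.layout(seed=4)
        pd.testing.assert_frame_equal(a, b)

    def test_stronger_edge_pulls_closer(self):
        # layouts are rescaled to a unit box, so compare distances within
        # one graph: a strong pair should sit closer than a weak pair
        W = np.zeros((4, 4))
        W[0, 1] = W[1, 0] = 0.9
        W[2, 3] = W[3, 2] = 0.1
        W[1, 2] = W[2, 1] = 0.2  # connect the components
        pos = fr_layout(W, seed=0, iterations=200).to_numpy()
        strong = np.linalg.norm(pos[0] - pos[1])
        weak = np.linalg.norm(pos[2] - pos[3])
        assert strong < weak


class TestResultsSurface:
    def test_summary_and_export(self, study_table, tmp_path):
        fit = SpeechNetwork(study_table).fit()
        text = fit.summary()
        assert "Expected influence" in text and "lambda" in text
        fit.to_json(tmp_path / "net.json")
        from speechnet.io import read_network_json

        payload = read_network_json(tmp_path / "net.json")
        assert payload["labels"] == fit.labels
        assert len(payload["weights"]) == len(fit.labels)
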