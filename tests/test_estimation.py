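"""Node-wise LASSO estimation: solver contracts, lambda selection, network
assembly."""

import numpy as np
import pytest

from clpnet import (
    cv_candidate_lambdas,
    drop_autoregressive,
    ebic,
    estimate_transition,
    fit_node_regression,
    lasso_fit,
    standardize_wave,
)
from clpnet.estimation import EstimationError
from clpnet.nodes import node_index


def _orthonormal_design(rng, n, p):
    A = rng.standard_normal((n, p))
    A = A - A.mean(0)
    return np.linalg.qr(A)[0] * np.sqrt(n)  # centered, X'X/n = I


# -- standardization ---------------------------------------------------------

def test_standardize_unit_example():
    z = standardize_wave(np.array([[-1.0], [0.0], [1.0]]), "T1", ("Q1",))
    assert np.allclose(z.z[:, 0], [-1.0, 0.0, 1.0])


def test_standardize_moments_and_back_transform():
    rng = np.random.default_rng(0)
    m = rng.normal(30, 12, size=(50, 15))
    z = standardize_wave(m, "T1")
    assert np.allclose(z.z.mean(0), 0.0, atol=1e-10)
    assert np.allclose(z.z.std(0, ddof=1), 1.0, atol=1e-10)
    assert np.allclose(z.z * z.sd + z.mean, m)


def test_standardize_constant_column_names_node():
    m = np.random.default_rng(1).normal(size=(20, 15))
    m[:, node_index("Q9")] = 3.0
    with pytest.raises(EstimationError, match="Q9"):
        standardize_wave(m, "T2")


# -- LASSO solver ------------------------------------------------------------

def test_lambda_max_zeroes_everything():
    rng = np.random.default_rng(2)
    X = rng.standard_normal((60, 5))
    y = rng.standard_normal(60)
    lam_max = np.max(np.abs((X - X.mean(0)).T @ (y - y.mean()))) / 60
    beta, _ = lasso_fit(X, y, lam_max * 1.0001)
    assert np.all(beta == 0.0)


def test_zero_lambda_equals_ols():
    rng = np.random.default_rng(3)
    X = rng.standard_normal((40, 4))
    y = X @ [1.0, -2.0, 0.5, 0.0] + rng.standard_normal(40)
    beta, b0 = lasso_fit(X, y, 0.0)
    Xi = np.column_stack([np.ones(40), X])
    ref = np.linalg.lstsq(Xi, y, rcond=None)[0]
    assert np.allclose(beta, ref[1:], atol=1e-6)
    assert b0 == pytest.approx(ref[0], abs=1e-6)


def test_soft_threshold_closed_form_on_orthonormal_designs():
    rng = np.random.default_rng(4)
    for _ in range(10):
        n, p = int(rng.integers(20, 51)), int(rng.integers(1, 6))
        X = _orthonormal_design(rng, n, p)
        y = rng.standard_normal(n)
        lam = float(rng.uniform(0.01, 0.5))
        beta, _ = lasso_fit(X, y, lam)
        b = X.T @ (y - y.mean()) / n
        assert np.allclose(beta, np.sign(b) * np.maximum(np.abs(b) - lam, 0),
                           atol=1e-6)


def test_negative_lambda_rejected():
    with pytest.raises(ValueError):
        lasso_fit(np.eye(3), np.ones(3), -0.1)


# -- EBIC --------------------------------------------------------------------

def test_ebic_identities():
    rng = np.random.default_rng(5)
    X = rng.standard_normal((337, 15))
    y = X[:, 0] * 0.5 + rng.standard_normal(337)
    beta = np.zeros(15)
    beta[[0, 3, 7]] = [0.5, 0.1, -0.2]  # k = 3
    b0 = 0.0
    bic = ebic(X, y, beta, b0, gamma=0.0)
    resid = y - X @ beta
    assert bic == pytest.approx(337 * np.log(resid @ resid / 337) + 3 * np.log(337))
    # the gamma penalty increment is exactly 2*gamma*k*log(p)
    assert ebic(X, y, beta, b0, gamma=0.5) - bic == pytest.approx(
        2 * 0.5 * 3 * np.log(15)
    )
    # empty model: n log(variance around the intercept), no k penalty
    empty = ebic(X, y, np.zeros(15), y.mean(), gamma=0.5)
    assert empty == pytest.approx(337 * np.log(np.sum((y - y.mean()) ** 2) / 337))


def test_ebic_perfect_fit_is_an_error():
    X = np.random.default_rng(6).standard_normal((20, 2))
    y = X @ [1.0, 2.0]
    with pytest.raises(EstimationError):
        ebic(X, y, np.array([1.0, 2.0]), 0.0)


# -- lambda selection --------------------------------------------------------

def test_cv_grid_deterministic_decreasing_positive():
    rng = np.random.default_rng(7)
    X = rng.standard_normal((100, 15))
    y = X[:, 2] * 0.5 + rng.standard_normal(100)
    a = cv_candidate_lambdas(X, y, seed=3)
    b = cv_candidate_lambdas(X, y, seed=3)
    assert np.array_equal(a, b)
    assert np.all(a > 0) and np.all(np.diff(a) < 0 if a.size > 1 else [True])


def test_cv_prefers_heavy_penalty_under_the_null():
    rng = np.random.default_rng(8)
    X = rng.standard_normal((100, 15))
    y = rng.standard_normal(100)
    cand = cv_candidate_lambdas(X, y, seed=0)
    lam_max = np.max(np.abs((X - X.mean(0)).T @ (y - y.mean()))) / 100
    assert cand[0] >= 0.5 * lam_max  # candidate set concentrates near lambda_max


def test_cv_requires_enough_subjects():
    with pytest.raises(EstimationError):
        cv_candidate_lambdas(np.random.default_rng(0).standard_normal((8, 3)),
                             np.zeros(8), folds=10)


def test_node_regression_recovers_single_strong_predictor():
    rng = np.random.default_rng(9)
    hits = within = 0
    reps = 200
    for r in range(reps):
        X = rng.standard_normal((337, 15))
        y = 0.6 * X[:, 4] + 0.8 * rng.standard_normal(337)
        Xz = (X - X.mean(0)) / X.std(0, ddof=1)
        yz = (y - y.mean()) / y.std(ddof=1)
        beta, _, _ = fit_node_regression(Xz, yz, seed=r)
        if beta[4] != 0:
            hits += 1
            # truth on the z scale: 0.6 / sd(y) = 0.6 / 1.0 (sd(y) = 1 here)
            if 0.4 <= beta[4] <= 0.7:
                within += 1
    assert hits == reps
    assert within / reps >= 0.95


def test_node_regression_null_gives_empty_support():
    rng = np.random.default_rng(10)
    empty = 0
    reps = 100
    for r in range(reps):
        X = rng.standard_normal((337, 15))
        y = rng.standard_normal(337)
        Xz = (X - X.mean(0)) / X.std(0, ddof=1)
        yz = (y - y.mean()) / y.std(ddof=1)
        beta, _, _ = fit_node_regression(Xz, yz, seed=r)
        empty += np.all(beta == 0)
    assert empty / reps >= 0.90


def test_node_regression_deterministic():
    rng = np.random.default_rng(11)
    X = rng.standard_normal((100, 15))
    y = 0.5 * X[:, 1] + rng.standard_normal(100)
    b1, i1, s1 = fit_node_regression(X, y, seed=5)
    b2, i2, s2 = fit_node_regression(X, y, seed=5)
    assert np.array_equal(b1, b2) and i1 == i2 and s1.chosen == s2.chosen


# -- network assembly --------------------------------------------------------

def test_estimated_network_shape_and_determinism(paper_panel_noclip):
    net = estimate_transition(paper_panel_noclip, "T1->T2", seed=1)
    assert net.B_hat.shape == (15, 15)
    assert np.all(np.isfinite(net.B_hat))
    assert net.ar_retained
    net2 = estimate_transition(paper_panel_noclip, "T1->T2", seed=1)
    assert np.array_equal(net.B_hat, net2.B_hat)


def test_drop_autoregressive_is_an_idempotent_diagonal_mask(paper_panel_noclip):
    net = estimate_transition(paper_panel_noclip, "T2->T3", seed=1)
    v1 = drop_autoregressive(net)
    v2 = drop_autoregressive(v1)
    assert not v1.ar_retained
    assert np.all(np.diag(v1.B_hat) == 0.0)
    assert np.array_equal(v1.B_hat, v2.B_hat)
    off = ~np.eye(15, dtype=bool)
    assert np.array_equal(v1.B_hat[off], net.B_hat[off])


def test_scale_equivariance_of_estimated_network(paper_panel_noclip):
    import dataclasses

    data = paper_panel_noclip
    scaled_scores = {w: m.copy() for w, m in data.scores.items()}
    for w in scaled_scores:
        scaled_scores[w][:, 3] *= 7.5  # rescale one raw node everywhere
    scaled = dataclasses.replace(data, scores=scaled_scores)
    a = estimate_transition(data, "T1->T2", seed=2).B_hat
    b = estimate_transition(scaled, "T1->T2", seed=2).B_hat
    assert np.allclose(a, b, atol=1e-8)


def test_constant_node_aborts_with_node_named(small_panel):
    import dataclasses

    scores = {w: m.copy() for w, m in small_panel.scores.items()}
    scores["T1"][:, node_index("Q13")] = 50.0
    broken = dataclasses.replace(small_panel, scores=scores)
    with pytest.raises(EstimationError, match="Q13"):
        estimate_transition(broken, "T1->T2", seed=0)


def test_edge_list_and_manifest_roundtrip(paper_panel_noclip):
    net = estimate_transition(paper_panel_noclip, "T1->T2", seed=1)
    edges = net.to_edge_list()
    assert set(edges.columns) == {"from_node", "to_node", "weight", "transition", "ar_flag"}
    assert len(edges) == net.edge_count(include_ar=True)
    man = net.manifest()
    assert man["gamma"] == 0.5 and man["cv_folds"] == 10
    assert man["edge_count_excl_ar"] <= man["edge_count_incl_ar"]
    g = net.to_graph()
    assert g.number_of_nodes() == 15
    assert g.number_of_edges() == len(edges)
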