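"""Bootstrap machinery: CS coefficient contracts and edge-weight CIs.

The expensive full-pipeline stability checks live in the acceptance suite;
here the resampling logic is exercised with cheap injected estimators plus
one realistically sized run of the edge CI bootstrap.
"""

import numpy as np
import pytest

from clpnet.estimation import EstimationError
from clpnet.nodes import NODE_CODES
from clpnet.stability import (
    EdgeCIResult,
    cs_coefficient,
    edge_ci_bootstrap,
    edge_ci_overlap,
)

from conftest import random_panel

DROPS = (0.1, 0.3, 0.5, 0.7)


def test_data_independent_estimator_has_maximal_cs(small_panel):
    fixed = np.arange(15, dtype=float)  # distinct values, ignores the data
    res = cs_coefficient(
        small_panel, "T1->T2", drops=DROPS, n_boot=40, seed=0,
        centrality_fn=lambda ds: fixed,
    )
    assert res.cs == max(DROPS)
    assert all(np.allclose(r, 1.0) for r in res.correlations.values())


def test_pure_noise_estimator_has_zero_cs(small_panel):
    rng = np.random.default_rng(1)
    res = cs_coefficient(
        small_panel, "T1->T2", drops=DROPS, n_boot=40, seed=0,
        centrality_fn=lambda ds: rng.standard_normal(15),
    )
    assert res.cs == 0.0


def test_cs_curve_reports_quantiles(small_panel):
    res = cs_coefficient(
        small_panel, "T1->T2", drops=DROPS, n_boot=20, seed=3,
        centrality_fn=lambda ds: np.arange(15, dtype=float),
    )
    curve = res.curve()
    assert list(curve["drop"]) == list(DROPS)
    assert {"q05", "q50", "q95"} <= set(curve.columns)


def test_cs_rejects_bad_inputs(small_panel):
    with pytest.raises(ValueError):
        cs_coefficient(small_panel, "T1->T2", metric="pagerank")
    with pytest.raises(ValueError):
        cs_coefficient(small_panel, "T1->T2", drops=(0.5, 0.99))


def test_infeasible_proportions_are_excluded(small_panel):
    def fragile(ds):
        if ds.n_subjects < 50:
            raise EstimationError("too small")
        return np.arange(15, dtype=float)

    res = cs_coefficient(
        small_panel, "T1->T2", drops=(0.1, 0.6), n_boot=10, seed=0,
        centrality_fn=fragile,
    )  # n = 80: dropping 60% leaves 32 subjects
    assert 0.6 in res.infeasible
    assert res.cs == 0.1


def _mean_outer_network(ds):
    mu = ds.wave_matrix("T1").mean(axis=0) / 100.0
    return np.outer(mu, mu)


def test_degenerate_resampling_gives_zero_width_cis(small_panel):
    idx = np.zeros(small_panel.n_subjects, dtype=int)  # n copies of one row
    clones = small_panel.subset(idx)
    res = edge_ci_bootstrap(clones, "T1->T2", n_boot=30, seed=0,
                            network_fn=_mean_outer_network)
    assert np.allclose(res.upper - res.lower, 0.0)


def test_edge_ci_bootstrap_deterministic(small_panel):
    a = edge_ci_bootstrap(small_panel, "T1->T2", n_boot=25, seed=9,
                          network_fn=_mean_outer_network)
    b = edge_ci_bootstrap(small_panel, "T1->T2", n_boot=25, seed=9,
                          network_fn=_mean_outer_network)
    assert np.array_equal(a.lower, b.lower) and np.array_equal(a.upper, b.upper)


def test_edge_ci_failure_rate_aborts(small_panel):
    calls = {"n": 0}

    def broken(ds):
        calls["n"] += 1
        if calls["n"] > 1:  # full-sample fit succeeds, every replicate fails
            raise EstimationError("boom")
        return np.zeros((15, 15))

    with pytest.raises(EstimationError, match="aborted"):
        edge_ci_bootstrap(small_panel, "T1->T2", n_boot=20, seed=0,
                          network_fn=broken)


def test_strong_edge_ci_excludes_zero():
    """A true cross-lagged effect of 0.5 with low noise is detected: the
    bootstrap percentile interval stays away from zero."""
    import dataclasses

    from clpnet.simulate import generate_panel, make_paper_like_config

    cfg = make_paper_like_config(seed=21, clip_mode="none", with_stage_meta=False)
    B1 = np.zeros((15, 15))
    B1[4, 6] = 0.5
    noise = cfg.noise_sd.copy()
    noise[0] = 0.5
    cfg = dataclasses.replace(cfg, B1=B1, noise_sd=noise)
    data = generate_panel(cfg)
    res = edge_ci_bootstrap(data, "T1->T2", n_boot=60, seed=2, cv_seed=2)
    point, lo, hi = res.interval(NODE_CODES[4], NODE_CODES[6])
    assert lo > 0.0
    assert lo <= hi


def test_ci_width_shrinks_with_sample_size():
    """Percentile intervals from the case bootstrap narrow as n grows (an
    OLS-based network keeps the check fast)."""

    def ols_network(ds):
        X = ds.wave_matrix("T1")
        Y = ds.wave_matrix("T2")
        Xz = (X - X.mean(0)) / X.std(0, ddof=1)
        Yz = (Y - Y.mean(0)) / Y.std(0, ddof=1)
        return np.linalg.lstsq(Xz, Yz, rcond=None)[0]

    widths = {}
    for n in (200, 1000):
        data = random_panel(n, seed=31)
        res = edge_ci_bootstrap(data, "T1->T2", n_boot=60, seed=4,
                                network_fn=ols_network)
        off = ~np.eye(15, dtype=bool)
        widths[n] = np.median((res.upper - res.lower)[off])
    assert widths[1000] < widths[200]


def _fake_ci(intervals):
    p = len(NODE_CODES)
    point = np.zeros((p, p))
    lo = np.zeros((p, p))
    hi = np.zeros((p, p))
    for (src, dst), (a, b) in intervals.items():
        i, j = NODE_CODES.index(src), NODE_CODES.index(dst)
        point[i, j] = (a + b) / 2
        lo[i, j], hi[i, j] = a, b
    return EdgeCIResult("T1->T2", tuple(NODE_CODES), point, lo, hi, 100, 0, 0)


def test_edge_ci_overlap_interval_arithmetic():
    res = _fake_ci({
        ("Q1", "Q2"): (0.1, 0.2),
        ("Q3", "Q4"): (0.3, 0.4),
        ("Q5", "Q6"): (0.1, 0.3),
        ("Q7", "Q8"): (0.2, 0.4),
    })
    rep = edge_ci_overlap(
        res, [("Q1", "Q2"), ("Q3", "Q4"), ("Q5", "Q6"), ("Q7", "Q8")]
    )
    row = rep[(rep.edge_a == "Q1->Q2") & (rep.edge_b == "Q3->Q4")].iloc[0]
    assert not row.overlaps and row.gap == pytest.approx(0.1)
    row = rep[(rep.edge_a == "Q5->Q6") & (rep.edge_b == "Q7->Q8")].iloc[0]
    assert row.overlaps and row.overlap_length == pytest.approx(0.1)
    # an edge compared with itself overlaps fully
    self_rep = edge_ci_overlap(res, [("Q1", "Q2"), ("Q1", "Q2")])
    assert self_rep.iloc[0].overlaps
    assert self_rep.iloc[0].overlap_length == pytest.approx(0.1)
    with pytest.raises(ValueError):
        edge_ci_overlap(res, [("Q1", "Q2")])
    with pytest.raises(KeyError):
        edge_ci_overlap(res, [("Q1", "Q2"), ("QX", "Q2")])
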