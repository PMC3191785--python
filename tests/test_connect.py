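"""Connectivity graphs, summary ratios and condition comparisons."""

import numpy as np
import pandas as pd
import pytest

from spikeglm import (
    ConnectivityGraph,
    Edge,
    ValidationError,
    compare_conditions,
    connectivity_anova,
    ei_balance,
    group_fractions,
    mean_ei_ratio,
    significant_edges,
    summarize,
)
from spikeglm.fit import EnsembleFit, GLMFit
from spikeglm import WindowScheme


def _fake_efit(coefs, ses, scheme, n_cells):
    """EnsembleFit with prescribed coefficients/SEs for every target."""
    fits = []
    K = scheme.K
    for c in range(n_cells):
        p = 1 + n_cells * K
        alpha = np.zeros(p)
        Sigma = np.zeros((p, p))
        for (i, k), v in coefs.get(c, {}).items():
            alpha[1 + i * K + k] = v
        for (i, k), s in ses.get(c, {}).items():
            Sigma[1 + i * K + k, 1 + i * K + k] = s**2
        fits.append(
            GLMFit(
                alpha_hat=alpha,
                rho=0.0,
                Q_kind="identity",
                loglik=0.0,
                penalized_loglik=0.0,
                Sigma=Sigma,
                bic=0.0,
                n_samples=1,
                converged=True,
                n_iter=1,
                trace=[],
                target_cell=c,
                scheme=scheme,
                n_cells=n_cells,
                delta_s=0.001,
            )
        )
    return EnsembleFit(fits=fits, scheme=scheme, n_cells=n_cells, delta_s=0.001)


@pytest.fixture
def k2():
    return WindowScheme.from_list([[1, 3], [4, 6]])


def test_no_significant_coefficients_gives_empty_graph(k2):
    efit = _fake_efit(
        {0: {(1, 0): 0.1}, 1: {}},
        {0: {(1, 0): 0.2}, 1: {}},
        k2,
        2,
    )
    g = significant_edges(efit)
    assert g.edges == []
    assert mean_ei_ratio(g) == 0.0


def test_wald_interval_formula(k2):
    efit = _fake_efit({1: {(0, 0): 0.5}}, {1: {(0, 0): 0.1}}, k2, 2)
    g = significant_edges(efit)
    (e,) = g.edges
    assert (e.source, e.target, e.sign) == (0, 1, 1)
    assert e.ci_low == pytest.approx(0.304, abs=1e-3)
    assert e.ci_high == pytest.approx(0.696, abs=1e-3)


def _full_graph(n_cells, K, sign=1):
    edges = [
        Edge(i, c, k, sign, 0.5 * sign, 0.1 * sign, 0.9 * sign)
        for i in range(n_cells)
        for c in range(n_cells)
        if i != c
        for k in range(K)
    ]
    return ConnectivityGraph(n_cells=n_cells, K=K, edges=edges)


def test_mean_ei_ratio_normalization_bound():
    g = _full_graph(4, 3)
    assert mean_ei_ratio(g) == 1.0
    with pytest.raises(ValidationError):
        mean_ei_ratio(ConnectivityGraph(n_cells=1, K=3, edges=[]))


def test_mean_ei_ratio_invariant_to_relabeling():
    rng = np.random.default_rng(71)
    edges = [
        Edge(i, c, k, 1, 0.5, 0.1, 0.9)
        for (i, c, k) in {
            (rng.integers(4), rng.integers(4), rng.integers(3)) for _ in range(15)
        }
        if i != c
    ]
    g = ConnectivityGraph(n_cells=4, K=3, edges=edges)
    perm = rng.permutation(4)
    g_perm = ConnectivityGraph(
        n_cells=4,
        K=3,
        edges=[
            Edge(perm[e.source], perm[e.target], e.window, e.sign, e.coefficient,
                 e.ci_low, e.ci_high)
            for e in edges
        ],
    )
    assert mean_ei_ratio(g) == mean_ei_ratio(g_perm)


def test_ei_balance_examples():
    edges = [Edge(0, 1, k, 1, 0.5, 0.1, 0.9) for k in range(10)]
    edges += [Edge(1, 0, k, -1, -0.5, -0.9, -0.1) for k in range(9)]
    g = ConnectivityGraph(n_cells=2, K=10, edges=edges)
    bal, inf_flag = ei_balance(g)
    assert bal == pytest.approx(10 / 9, abs=1e-9)
    assert bal == pytest.approx(1.11, abs=0.005)
    assert not inf_flag
    g_equal = ConnectivityGraph(n_cells=2, K=10, edges=edges[:9] + edges[10:])
    assert ei_balance(g_equal)[0] == 1.0
    g_exc = ConnectivityGraph(n_cells=2, K=10, edges=edges[:3])
    with pytest.warns(UserWarning):
        bal, inf_flag = ei_balance(g_exc)
    assert np.isinf(bal) and inf_flag


def test_group_fraction_denominators():
    g = ConnectivityGraph(n_cells=13, K=9, edges=[])
    fracs, counts, denom = group_fractions(g, ["RS"] * 8 + ["FS"] * 5)
    assert denom == {"RS-RS": 64, "RS-FS": 80, "FS-FS": 25}
    assert all(v == 0.0 for v in fracs.values())
    g8 = ConnectivityGraph(n_cells=12, K=9, edges=[])
    _, _, denom8 = group_fractions(g8, ["RS"] * 6 + ["FS"] * 6)
    assert denom8 == {"RS-RS": 36, "RS-FS": 72, "FS-FS": 36}


def test_group_counts_sum_to_pairs_and_denominators_to_c_squared():
    rng = np.random.default_rng(72)
    n = 6
    edges = []
    for i in range(n):
        for c in range(n):
            if rng.random() < 0.4:
                for k in range(2):
                    edges.append(Edge(i, c, k, 1, 0.5, 0.1, 0.9))
    g = ConnectivityGraph(n_cells=n, K=2, edges=edges)
    types = ["RS"] * 4 + ["FS"] * 2
    fracs, counts, denom = group_fractions(g, types)
    assert sum(counts.values()) == len(g.significant_pairs(include_self=True))
    assert sum(denom.values()) == n * n


def test_group_fractions_requires_types():
    g = ConnectivityGraph(n_cells=2, K=2, edges=[])
    with pytest.raises(ValidationError):
        group_fractions(g, ["RS", "unknown"])


def test_compare_identical_paired_does_not_reject():
    v = [0.3, 0.4, 0.5, 0.35, 0.45]
    res = compare_conditions(v, v, paired=True)
    assert res["pvalue"] > 0.05


def test_compare_detects_denser_condition():
    rng = np.random.default_rng(73)
    a = 0.3 + rng.normal(0, 0.05, 20)
    b = 0.5 + rng.normal(0, 0.05, 20)
    res = compare_conditions(a, b, paired=True)
    assert res["pvalue"] < 0.05
    with pytest.raises(ValidationError):
        compare_conditions(a, b[:-1], paired=True)


def test_anova_finds_period_not_outcome_effect():
    rng = np.random.default_rng(74)
    rows = []
    group_mu = {"RS-RS": 0.2, "RS-FS": 0.3, "FS-FS": 0.7}
    for dataset in range(8):
        for group, mu in group_mu.items():
            for outcome in ("successful", "unsuccessful"):
                for period in ("background", "reaching"):
                    val = mu + (0.25 if period == "reaching" else 0.0)
                    rows.append(
                        {
                            "cell_group": group,
                            "outcome": outcome,
                            "period": period,
                            "fraction": val + rng.normal(0, 0.08),
                        }
                    )
    table = connectivity_anova(pd.DataFrame(rows))
    assert table.loc["C(period)", "PR(>F)"] < 0.05
    assert table.loc["C(outcome)", "PR(>F)"] > 0.05
    assert table.loc["C(cell_group)", "PR(>F)"] < 0.05


def test_edge_recovery_precision_recall(scheme3):
    # strong planted couplings, Bonferroni across lags: precision/recall >= 0.9
    from spikeglm import make_ground_truth, simulate_ensemble
    from spikeglm.fit import fit_ensemble
    from spikeglm.spikeio import bin_spikes

    from conftest import full_trial_spec

    precs, recs = [], []
    for s in range(5):
        gt = make_ground_truth(
            2, 2, scheme3, density=0.25, coupling_scale=0.6, seed=700 + s
        )
        ens = simulate_ensemble(gt, full_trial_spec(80))
        efit = fit_ensemble(bin_spikes(ens, "all"), scheme3)
        g = significant_edges(efit, bonferroni_lags=True)
        truth = {
            (i, c, k)
            for (c, i, k), v in gt.coupling.items()
            if v != 0.0 and i != c
        }
        found = {(e.source, e.target, e.window) for e in g.offdiag_edges()}
        tp = len(found & truth)
        if truth:
            recs.append(tp / len(truth))
        if found:
            precs.append(tp / len(found))
    assert np.mean(precs) >= 0.9
    assert np.mean(recs) >= 0.9


def test_summarize_consistency(k2):
    efit = _fake_efit(
        {1: {(0, 0): 0.5, (0, 1): -0.4}},
        {1: {(0, 0): 0.1, (0, 1): 0.1}},
        k2,
        2,
    )
    g = significant_edges(efit)
    g.condition = "reaching-successful"
    s = summarize(g, ["RS", "FS"])
    assert s.n_excitatory == 1 and s.n_inhibitory == 1
    assert s.ei_balance == 1.0
    assert s.group_counts["RS-FS"] == 1
    assert s.mean_ei_ratio == pytest.approx(2 / (2 * 2), abs=1e-12)
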