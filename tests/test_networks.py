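import numpy as np
import pandas as pd
import pytest
from scipy import stats

from metawas.datatypes import DataError
from metawas.networks import (LocalFdr, ShrinkagePartialCorrelation,
                              build_network, compare_networks, local_fdr,
                              network_edges, shrinkage_partial_correlation,
                              spearman_matrix)


def _gaussian_means(n_compounds, n_accessions, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(rng.normal(size=(n_compounds, n_accessions)),
                        index=[f"c{i}" for i in range(n_compounds)],
                        columns=[f"a{i}" for i in range(n_accessions)])


# --- Spearman layer --------------------------------------------------------

def test_spearman_monotone_and_reversed_pairs():
    means = pd.DataFrame(
        [[1, 2, 3, 4, 5], [1, 4, 9, 16, 25], [5, 4, 3, 2, 1]],
        index=["up", "up2", "down"], columns=list("abcde"), dtype=float)
    rho, p = spearman_matrix(means)
    assert rho.loc["up", "up2"] == pytest.approx(1.0)
    assert rho.loc["up", "down"] == pytest.approx(-1.0)
    assert p.loc["up", "up2"] == pytest.approx(0.0)


def test_spearman_null_pvalues_are_uniform():
    means = _gaussian_means(20, 96, seed=1)
    _, p = spearman_matrix(means)
    vals = p.to_numpy()[np.triu_indices(20, 1)]
    assert stats.kstest(vals, "uniform").pvalue > 0.01


def test_spearman_insufficient_overlap_is_na():
    means = _gaussian_means(3, 6, seed=2)
    means.iloc[0, :3] = np.nan
    means.iloc[1, 3:] = np.nan
    rho, p = spearman_matrix(means)
    assert np.isnan(rho.iloc[0, 1]) and np.isnan(p.iloc[0, 1])


# --- shrinkage partial correlation ----------------------------------------

def test_zero_shrinkage_matches_inverse_correlation_oracle():
    X = pd.DataFrame(np.random.default_rng(5).normal(size=(1000, 5)))
    est = ShrinkagePartialCorrelation(shrinkage=0.0).fit(X)
    R = np.corrcoef(X.to_numpy().T)
    omega = np.linalg.inv(R)
    d = np.sqrt(np.diag(omega))
    expected = -omega / np.outer(d, d)
    np.fill_diagonal(expected, 1.0)
    np.testing.assert_allclose(est.pcor_.to_numpy(), expected, atol=1e-10)


def test_chain_conditioning_removes_indirect_correlation():
    rng = np.random.default_rng(6)
    x = rng.normal(size=500)
    y = x + rng.normal(size=500)
    z = y + rng.normal(size=500)
    est = ShrinkagePartialCorrelation().fit(pd.DataFrame({"x": x, "y": y, "z": z}))
    assert abs(np.corrcoef(x, z)[0, 1]) > 0.4
    assert abs(est.pcor_.loc["x", "z"]) < 0.1


def test_null_partial_correlations_concentrated_near_zero():
    means = _gaussian_means(20, 96, seed=7)
    pcor, lam = shrinkage_partial_correlation(means)
    off = np.abs(pcor.to_numpy()[np.triu_indices(20, 1)])
    assert np.quantile(off, 0.95) < 0.3
    assert 0.0 <= lam <= 1.0


def test_pcor_matrix_symmetric_unit_diagonal_positive_definite():
    means = _gaussian_means(15, 40, seed=8)
    est = ShrinkagePartialCorrelation().fit(means.T)
    P = est.pcor_.to_numpy()
    assert np.allclose(P, P.T)
    assert np.allclose(np.diag(P), 1.0)
    R_sh = (1 - est.shrinkage_) * est.corr_.to_numpy() \
        + est.shrinkage_ * np.eye(15)
    assert np.linalg.eigvalsh(R_sh).min() > 0


def test_constant_compound_excluded_with_warning():
    means = _gaussian_means(5, 30, seed=9)
    means.iloc[2] = 7.0
    with pytest.warns(UserWarning, match="constant or low-coverage"):
        est = ShrinkagePartialCorrelation().fit(means.T)
    assert "c2" in est.dropped_
    assert est.pcor_.shape == (4, 4)


def test_first_order_mode_bounded_by_marginal():
    rng = np.random.default_rng(10)
    X = pd.DataFrame(rng.normal(size=(200, 4)))
    X[1] = X[0] + rng.normal(size=200) * 0.5
    full = ShrinkagePartialCorrelation(order="first").fit(X)
    assert np.all(np.abs(full.pcor_.to_numpy()) <= 1.0 + 1e-12)


# --- local FDR -------------------------------------------------------------

def test_degenerate_statistics_give_fdr_one():
    with pytest.warns(UserWarning, match="degenerate"):
        fdr, eta0 = local_fdr(np.zeros(100))
    assert np.all(fdr == 1.0)
    assert eta0 == 1.0


def test_local_fdr_monotone_and_argmin_at_largest_statistic():
    rng = np.random.default_rng(11)
    null = rng.normal(0, 0.1, size=900)
    alt = np.concatenate([rng.normal(0.6, 0.05, 50),
                          rng.normal(-0.6, 0.05, 50)])
    x = np.clip(np.concatenate([null, alt]), -0.99, 0.99)
    fdr, eta0 = local_fdr(x)
    order = np.argsort(np.abs(x))
    assert np.all(np.diff(fdr[order]) <= 1e-12)
    assert fdr[np.abs(x).argmax()] == fdr.min()


def test_eta0_recovery_in_mixture():
    rng = np.random.default_rng(12)
    n = 96
    null = np.tanh(rng.normal(0, 1 / np.sqrt(n - 3), size=900))
    alt = np.clip(rng.normal(0.6, 0.05, 100) * rng.choice([-1, 1], 100),
                  -0.99, 0.99)
    fdr, eta0 = local_fdr(np.concatenate([null, alt]))
    assert 0.8 <= eta0 <= 1.0
    assert fdr[900:].mean() < fdr[:900].mean()


# --- network summaries -----------------------------------------------------

def _edges(pairs, fdrs, signs=None):
    signs = signs or ["+"] * len(pairs)
    return pd.DataFrame({
        "compound_i": [p[0] for p in pairs],
        "compound_j": [p[1] for p in pairs],
        "rho": 0.5, "pcor": 0.5,
        "sign": signs, "local_fdr": fdrs,
    })


def test_triangle_and_star_summaries():
    triangle = _edges([("a", "b"), ("b", "c"), ("a", "c")], [0.01] * 3)
    summary, kept = build_network(triangle, 0.05)
    assert summary.n_nodes == 3 and summary.n_edges == 3
    assert summary.average_degree == pytest.approx(2.0)
    assert summary.clustering_by_degree == {2: 1.0}
    star = _edges([("h", "x"), ("h", "y"), ("h", "z"), ("h", "w")], [0.01] * 4)
    s2, _ = build_network(star, 0.05)
    assert s2.clustering_by_degree[4] == 0.0
    assert s2.degree_distribution == {1: 4, 4: 1}


def test_empty_network_allowed():
    summary, kept = build_network(_edges([("a", "b")], [0.5]), 0.05)
    assert summary.n_nodes == 0 and summary.n_edges == 0


def test_identical_networks_compare_as_equal():
    e = _edges([("a", "b"), ("b", "c"), ("c", "d")], [0.01] * 3)
    res = compare_networks(e, e.copy(), fdr_cutoff=0.05, n_perm=200, seed=0)
    assert len(res["shared_edges"]) == 3
    assert res["p_average_degree"] > 0.5
    assert res["p_degree_distribution"] > 0.5
    assert res["sign_table"]["agree"].all()


def test_sign_disagreement_reported():
    ea = _edges([("a", "b")], [0.01], signs=["+"])
    eb = _edges([("a", "b")], [0.01], signs=["-"])
    res = compare_networks(ea, eb, fdr_cutoff=0.05, n_perm=50, seed=1)
    assert res["shared_edges"] == [("a", "b")]
    assert not res["sign_table"]["agree"].iloc[0]


def test_disjoint_compound_spaces_error():
    ea = _edges([("a", "b")], [0.01])
    eb = _edges([("x", "y")], [0.01])
    with pytest.raises(DataError):
        compare_networks(ea, eb)


def test_spearman_network_at_least_as_dense_as_partial(small_simulation):
    _, _, panel, _ = small_simulation
    means = np.log2(panel.values).groupby(panel.meta["accession"]).mean().T
    edges_p = network_edges(means, fdr_on="pcor")
    edges_r = network_edges(means, fdr_on="rho")
    for cutoff in (0.05, 0.2):
        n_p = (edges_p["local_fdr"] < cutoff).sum()
        n_r = (edges_r["local_fdr"] < cutoff).sum()
        assert n_r >= n_p
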