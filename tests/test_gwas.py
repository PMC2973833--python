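import numpy as np
import pandas as pd
import pytest
from scipy import stats

from metawas.datatypes import DataError, GenotypeSet
from metawas.gwas import (MixedModelScan, emma_scan, genomic_inflation,
                          kinship, maf_filter, qvalues, scan_all)
from metawas.synthetic import SimulationConfig, simulate_genotypes


def test_maf_filter_boundary_and_brute_force():
    rng = np.random.default_rng(0)
    counts = [4, 48, 5, 10, 90, 95, 1, 50, 30, 6]   # minor counts of 96
    cols = {}
    for j, c in enumerate(counts):
        v = np.zeros(96)
        v[rng.choice(96, c, replace=False)] = 1
        cols[f"1:{100 + j}"] = v
    matrix = pd.DataFrame(cols, index=[f"a{i}" for i in range(96)])
    snps = pd.DataFrame({"chrom": 1, "pos": range(100, 110)},
                        index=matrix.columns)
    gset = GenotypeSet(matrix=matrix, snps=snps)
    kept = maf_filter(gset, 0.05)
    expected = [f"1:{100 + j}" for j, c in enumerate(counts)
                if min(c, 96 - c) / 96 > 0.05]
    assert list(kept.snp_ids) == expected
    assert "1:100" not in kept.snp_ids        # 4/96 = 0.0417 below cutoff
    assert "1:101" in kept.snp_ids            # 48/96 retained


def test_kinship_hand_counts(toy_genotypes):
    K = kinship(toy_genotypes)
    # a1 vs a2 share alleles at SNPs 1 and 3 -> 2/4
    assert K.loc["a1", "a2"] == pytest.approx(0.5)
    # a1 vs a3: matches at none -> 0/4... check by hand: (0,1),(0,1),(1,0),(1,0)
    assert K.loc["a1", "a3"] == pytest.approx(0.0)
    assert np.allclose(np.diag(K), 1.0)


def test_kinship_identical_and_complementary():
    matrix = pd.DataFrame([[0, 1, 0, 1], [0, 1, 0, 1], [1, 0, 1, 0]],
                          index=list("xyz"),
                          columns=["1:1", "1:2", "1:3", "1:4"], dtype=float)
    snps = pd.DataFrame({"chrom": 1, "pos": [1, 2, 3, 4]},
                        index=matrix.columns)
    K = kinship(GenotypeSet(matrix=matrix, snps=snps))
    assert K.loc["x", "y"] == 1.0
    assert K.loc["x", "z"] == 0.0


def test_identity_kinship_reduces_to_ols():
    rng = np.random.default_rng(1)
    n, m = 60, 40
    matrix = pd.DataFrame((rng.random((n, m)) < 0.4).astype(float),
                          index=[f"a{i}" for i in range(n)],
                          columns=[f"1:{j}" for j in range(m)])
    snps = pd.DataFrame({"chrom": 1, "pos": range(m)}, index=matrix.columns)
    gset = GenotypeSet(matrix=matrix, snps=snps)
    y = pd.Series(rng.normal(size=n), index=matrix.index)
    K = pd.DataFrame(np.eye(n), index=matrix.index, columns=matrix.index)
    p_mm = emma_scan(y, gset, K)
    # OLS F-test oracle per SNP
    for snp in list(matrix.columns)[:10]:
        x = matrix[snp].to_numpy()
        X = np.column_stack([np.ones(n), x])
        beta, rss1, *_ = np.linalg.lstsq(X, y.to_numpy(), rcond=None)
        rss1 = float(((y.to_numpy() - X @ beta) ** 2).sum())
        rss0 = float(((y - y.mean()) ** 2).sum())
        F = (rss0 - rss1) / (rss1 / (n - 2))
        p_ols = stats.f.sf(F, 1, n - 2)
        assert p_mm[snp] == pytest.approx(p_ols, abs=1e-8)


def test_monomorphic_snp_gets_p_one():
    n = 30
    matrix = pd.DataFrame({"1:1": np.zeros(n), "1:2": np.arange(n) % 2},
                          index=[f"a{i}" for i in range(n)], dtype=float)
    snps = pd.DataFrame({"chrom": 1, "pos": [1, 2]}, index=matrix.columns)
    gset = GenotypeSet(matrix=matrix, snps=snps)
    y = pd.Series(np.random.default_rng(2).normal(size=n), index=matrix.index)
    K = pd.DataFrame(np.eye(n), index=matrix.index, columns=matrix.index)
    p = emma_scan(y, gset, K)
    assert p["1:1"] == 1.0
    assert p["1:2"] < 1.0


def test_scan_invariant_under_accession_permutation():
    cfg = SimulationConfig(n_accessions=40, n_snps=200, n_chromosomes=2,
                           seed=3)
    g = simulate_genotypes(cfg)
    K = kinship(g)
    rng = np.random.default_rng(4)
    y = pd.Series(rng.normal(size=40), index=g.accessions)
    p1 = emma_scan(y, g, K)
    perm = rng.permutation(40)
    order = list(np.asarray(g.accessions)[perm])
    g2 = GenotypeSet(matrix=g.matrix.loc[order], snps=g.snps, genes=g.genes)
    p2 = emma_scan(y.loc[order], g2, K.loc[order, order])
    np.testing.assert_allclose(p1.to_numpy(), p2.to_numpy(), atol=1e-8)


def test_mixed_model_beats_ols_under_structure():
    # genomic-control calibration on a structured null (scaled-down sizes)
    from metawas.evaluation import mixed_model_calibration
    res = mixed_model_calibration(seed=5, n_traits=10, n_snps=1000)
    assert res["mixed_inflation"] <= 1.15
    assert res["ols_inflation"] > res["mixed_inflation"]


def test_planted_causal_snp_ranks_highly():
    cfg = SimulationConfig(n_accessions=96, n_snps=1000, seed=6)
    g = simulate_genotypes(cfg)
    K = kinship(g)
    G = g.matrix.to_numpy()
    Gz = (G - G.mean(0)) / G.std(0)
    rng = np.random.default_rng(7)
    hits = 0
    n_sims = 20
    for _ in range(n_sims):
        j = rng.integers(G.shape[1])
        u = Gz @ rng.normal(size=G.shape[1]) / np.sqrt(G.shape[1])
        signal = Gz[:, j]
        y = signal + u + rng.normal(size=96) * np.sqrt(1.5)  # h2 ~ 0.4 direct
        p = emma_scan(pd.Series(y, index=g.accessions), g, K)
        rank = int((p < p.iloc[j]).sum())
        hits += rank < 10
    assert hits >= 0.8 * n_sims


def test_null_pvalues_uniform():
    cfg = SimulationConfig(n_accessions=96, n_snps=500, n_structure_groups=1,
                           ld_block_length=1, seed=8)
    g = simulate_genotypes(cfg)
    K = kinship(g)
    rng = np.random.default_rng(9)
    pooled = []
    for _ in range(10):
        y = pd.Series(rng.normal(size=96), index=g.accessions)
        pooled.append(emma_scan(y, g, K).to_numpy())
    pooled = np.concatenate(pooled)
    assert stats.kstest(pooled, "uniform").pvalue > 0.01


def test_delta_refinement_beats_grid(small_simulation):
    _, g, panel, _ = small_simulation
    K = kinship(g)
    means = np.log2(panel.values).groupby(panel.meta["accession"]).mean().T
    scan = MixedModelScan(grid_points=20).fit(g, means.iloc[0], K)
    # the internal assertion already enforces grid dominance; spot-check the
    # fitted attributes are consistent
    assert scan.sigma_g2_ > 0
    assert scan.sigma_e2_ == pytest.approx(scan.delta_ * scan.sigma_g2_)


def test_requires_complete_trait_and_psd_kinship(toy_genotypes):
    y = pd.Series([1.0, np.nan, 2.0], index=toy_genotypes.accessions)
    K = kinship(toy_genotypes)
    with pytest.raises(DataError, match="complete"):
        emma_scan(y, toy_genotypes, K)
    bad = K.copy()
    bad.iloc[0, 1] = bad.iloc[1, 0] = 2.0   # breaks PSD
    with pytest.raises(DataError, match="positive semidefinite"):
        emma_scan(pd.Series([1.0, 2.0, 3.0], index=toy_genotypes.accessions),
                  toy_genotypes, bad)


def test_qvalues_bh_limit_hand_computation():
    p = np.array([0.001] * 10 + [0.5] * 90)
    q, pi0 = qvalues(p, pi0=1.0)
    np.testing.assert_allclose(q[:10], 0.01)
    assert pi0 == 1.0


def test_qvalues_all_one():
    q, pi0 = qvalues(np.ones(100))
    assert np.allclose(q, pi0)


def test_qvalues_pi0_near_one_under_null():
    p = np.random.default_rng(10).uniform(size=10_000)
    p = np.clip(p, 1e-12, 1.0)
    q, pi0 = qvalues(p)
    assert 0.9 <= pi0 <= 1.1


def test_qvalues_monotone_in_p():
    rng = np.random.default_rng(11)
    p = np.clip(rng.beta(0.5, 3, size=500), 1e-12, 1.0)
    q, _ = qvalues(p)
    order = np.argsort(p)
    assert np.all(np.diff(q[order]) >= -1e-12)


def test_qvalues_small_m_falls_back_to_bh():
    with pytest.warns(UserWarning, match="Benjamini"):
        q, pi0 = qvalues(np.array([0.01, 0.2, 0.9]))
    assert pi0 == 1.0


def test_genomic_inflation_is_one_for_uniform():
    p = (np.arange(10_000) + 0.5) / 10_000
    assert genomic_inflation(p) == pytest.approx(1.0, abs=0.02)


def test_scan_all_output_contract(small_simulation):
    _, g, panel, _ = small_simulation
    K = kinship(g)
    means = np.log2(panel.values).groupby(panel.meta["accession"]).mean().T
    assoc = scan_all(means.iloc[:3], g, K, grid_points=30)
    assert set(assoc.columns) == {"compound_id", "snp_id", "chrom", "pos",
                                  "beta", "p", "q"}
    assert assoc["compound_id"].nunique() == 3
    assert ((assoc["p"] > 0) & (assoc["p"] <= 1)).all()
    assert ((assoc["q"] >= 0) & (assoc["q"] <= 1)).all()
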