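"""Benchmark routines exercising the whole pipeline on simulated data.

Each function regenerates its inputs from a seed, runs the relevant stages,
and returns summary statistics; they back both the heavier end of the test
suite and ``scripts/acceptance.py``.  Problem sizes (96 accessions x 2,000
SNPs, 50 null traits, 25 hotspot runs of 30 metabolites, 100-metabolite
heritability panels) mirror the study design at a desk-computable scale.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import genes_hotspots as gh
from . import gwas, ld, networks, preprocess, quantgen
from .synthetic import SimulationConfig, simulate_genotypes, simulate_metabolome

__all__ = [
    "accession_means_from_panel",
    "mixed_model_calibration",
    "hotspot_benchmark",
    "heritability_recovery",
    "network_oracles",
    "ld_oracles",
    "study_condition_summary",
]


def _child_seed(seed: int, k: int) -> int:
    return int((seed * 1_000_003 + k) % (2**31 - 1))


def accession_means_from_panel(panel) -> pd.DataFrame:
    """Quick compound x accession means (log2) for benchmark scans."""
    return np.log2(panel.values).groupby(panel.meta["accession"]).mean().T


def mixed_model_calibration(seed: int = 0, n_traits: int = 50,
                            n_snps: int = 2000, fst: float = 0.2,
                            h2_background: float = 0.5) -> dict:
    """Genomic inflation of the mixed-model scan vs naive OLS on a
    structured null.

    Traits carry a polygenic background u ~ MVN(0, K) scaled to the target
    background heritability plus white noise; no SNP has a direct effect.
    Returns median genomic inflation factors over the traits.
    """
    from scipy import stats

    cfg = SimulationConfig(n_accessions=96, n_snps=n_snps, fst=fst,
                           seed=_child_seed(seed, 1))
    g = simulate_genotypes(cfg)
    K = gwas.kinship(g)
    Kn = K.to_numpy()
    S, U = np.linalg.eigh(Kn)
    L = U * np.sqrt(np.clip(S, 0, None))
    G = g.matrix.to_numpy()
    Gz = (G - G.mean(0)) / G.std(0)
    n = G.shape[0]
    rng = np.random.default_rng(_child_seed(seed, 2))
    infl_mm, infl_ols = [], []
    for _ in range(n_traits):
        u = L @ rng.normal(size=n)
        u = (u - u.mean()) / u.std() * np.sqrt(h2_background)
        y = u + rng.normal(size=n) * np.sqrt(1 - h2_background)
        p_mm = gwas.emma_scan(pd.Series(y, index=g.accessions), g, K)
        infl_mm.append(gwas.genomic_inflation(p_mm))
        yv = y - y.mean()
        r = (Gz * yv[:, None]).sum(0) / np.sqrt(
            (Gz**2).sum(0) * (yv**2).sum())
        t = r * np.sqrt((n - 2) / (1 - r**2))
        infl_ols.append(gwas.genomic_inflation(
            2 * stats.t.sf(np.abs(t), n - 2)))
    return {
        "mixed_inflation": float(np.median(infl_mm)),
        "ols_inflation": float(np.median(infl_ols)),
        "n_traits": n_traits,
        "n_snps": int(G.shape[1]),
    }


def hotspot_benchmark(seed: int = 0, n_runs: int = 25,
                      n_metabolites: int = 30, hotspot_metabolites: int = 12,
                      window_genes: int = 5, q_cutoff: float = 0.2,
                      n_perm: int = 2) -> dict:
    """Planted-hotspot recovery and null calibration over scaled runs.

    Each run simulates 96 accessions x 2,000 SNPs with a pleiotropic gene
    driving 12 of 30 metabolites, scans all metabolites, calls candidates,
    sets the hotspot threshold from within-compound permutations, and
    checks whether the planted gene lands in a reported hotspot.  The same
    machinery applied to within-compound-shuffled means gives the null
    hotspot count.
    """
    recovered = 0
    null_counts = []
    for run in range(n_runs):
        cfg = SimulationConfig(
            n_accessions=96, n_snps=2000, n_metabolites=n_metabolites,
            hotspot_metabolites=hotspot_metabolites,
            seed=_child_seed(seed, 10 + run))
        g = simulate_genotypes(cfg)
        panel, truth = simulate_metabolome(g, cfg)
        means = accession_means_from_panel(panel)
        gf = gwas.maf_filter(g)
        K = gwas.kinship(gf)
        assoc = gwas.scan_all(means, gf, K, grid_points=50)
        snp_gene = gh.assign_snps_to_genes(gf.snps, g.genes)
        cands = gh.call_candidate_genes(assoc, snp_gene, q_cutoff, 2)
        null = gh.permutation_null(
            means, gf, K, n_perm=n_perm, q_cutoff=q_cutoff, min_snps=2,
            window_genes=window_genes, snp_gene_map=snp_gene,
            seed=_child_seed(seed, 500 + run), grid_points=50)
        spots = gh.sliding_hotspots(cands, g.genes,
                                    window_genes=window_genes,
                                    null_max=null["null_max"])
        if any(truth.hotspot_gene in h.gene_ids for h in spots):
            recovered += 1

        rng = np.random.default_rng(_child_seed(seed, 900 + run))
        arr = means.to_numpy().copy()
        for i in range(arr.shape[0]):
            arr[i] = arr[i, rng.permutation(arr.shape[1])]
        shuffled = pd.DataFrame(arr, index=means.index, columns=means.columns)
        assoc0 = gwas.scan_all(shuffled, gf, K, grid_points=50)
        cands0 = gh.call_candidate_genes(assoc0, snp_gene, q_cutoff, 2)
        spots0 = gh.sliding_hotspots(cands0, g.genes,
                                     window_genes=window_genes,
                                     null_max=null["null_max"])
        null_counts.append(len(spots0))
    return {
        "recovery_rate": recovered / n_runs,
        "null_hotspots_per_run": float(np.mean(null_counts)),
        "n_runs": n_runs,
    }


def heritability_recovery(seed: int = 0, targets=(0.2, 0.45, 0.8),
                          n_metabolites: int = 100) -> dict:
    """Mean estimated H2 per simulated target heritability."""
    out = {}
    for k, h2 in enumerate(targets):
        cfg = SimulationConfig(n_accessions=96, n_metabolites=n_metabolites,
                               n_snps=600, target_h2=h2,
                               seed=_child_seed(seed, 20 + k))
        g = simulate_genotypes(cfg)
        panel, truth = simulate_metabolome(g, cfg)
        norm = preprocess.preprocess_panel(panel)["A"]
        model = quantgen.HeritabilityModel(truth.group_assignment).fit(norm)
        out[h2] = float(model.h2_.mean())
    return out


def network_oracles(seed: int = 0, n_reps: int = 25) -> dict:
    """Partial-correlation oracle checks and GGM edge-recovery comparison.

    * zero-shrinkage limit vs direct inverse-correlation partial
      correlations (max abs difference on a well-conditioned p=5, n=1000
      Gaussian sample);
    * chain conditioning: X -> Y -> Z gives corr(X,Z) >> 0 but
      pcor(X,Z) ~ 0 at n=500;
    * mean precision-recall AUC of edge ranking by local fdr vs by |rho| on
      20-compound / 10-edge / |pcor|=0.5 / n=96 simulations.
    """
    from sklearn.metrics import average_precision_score

    rng = np.random.default_rng(_child_seed(seed, 30))
    X = pd.DataFrame(rng.normal(size=(1000, 5)))
    est = networks.ShrinkagePartialCorrelation(shrinkage=0.0).fit(X)
    R = np.corrcoef(X.to_numpy().T)
    omega = np.linalg.inv(R)
    d = np.sqrt(np.diag(omega))
    direct = -omega / np.outer(d, d)
    np.fill_diagonal(direct, 1.0)
    lam0_diff = float(np.abs(est.pcor_.to_numpy() - direct).max())

    x = rng.normal(size=500)
    y = x + rng.normal(size=500)
    z = y + rng.normal(size=500)
    chain = networks.ShrinkagePartialCorrelation().fit(
        pd.DataFrame({"x": x, "y": y, "z": z}))
    chain_corr = float(np.corrcoef(x, z)[0, 1])
    chain_pcor = float(abs(chain.pcor_.loc["x", "z"]))

    auc_fdr, auc_rho = [], []
    for rep in range(n_reps):
        cfg = SimulationConfig(
            n_accessions=96, n_metabolites=20, n_snps=200, target_h2=0.99,
            n_causal_per_metabolite=0, network_edges=10, network_pcor=0.5,
            seed=_child_seed(seed, 40 + rep))
        g = simulate_genotypes(cfg)
        panel, truth = simulate_metabolome(g, cfg)
        means = accession_means_from_panel(panel)
        edges = networks.network_edges(means)
        tp = truth.true_partial_corr
        labels = np.array([abs(tp.loc[i, j]) > 0.01 for i, j in
                           zip(edges["compound_i"], edges["compound_j"])])
        auc_fdr.append(average_precision_score(labels, -edges["local_fdr"]))
        auc_rho.append(average_precision_score(labels, edges["rho"].abs()))
    return {
        "lambda0_max_abs_diff": lam0_diff,
        "chain_marginal_corr": chain_corr,
        "chain_abs_pcor": chain_pcor,
        "prauc_local_fdr": float(np.mean(auc_fdr)),
        "prauc_spearman": float(np.mean(auc_rho)),
        "n_reps": n_reps,
    }


def ld_oracles(seed: int = 0) -> dict:
    """Average-maximum SNP-SNP r2 vs brute-force enumeration on a random
    2x3-SNP toy pair, plus the r2 labelling/ordering invariances."""
    rng = np.random.default_rng(_child_seed(seed, 60))
    n = 40
    ga = pd.DataFrame(rng.integers(0, 2, size=(n, 2)).astype(float))
    gb = pd.DataFrame(rng.integers(0, 2, size=(n, 3)).astype(float))
    stat = ld.average_max_r2(ga, gb)
    # brute force over the 6 SNP pairs
    mat = np.array([[ld.r2(ga.iloc[:, i], gb.iloc[:, j]) for j in range(3)]
                    for i in range(2)])
    brute = (np.nanmax(mat, axis=1).mean() + np.nanmax(mat, axis=0).mean()) / 2
    a = rng.integers(0, 2, size=n).astype(float)
    b = rng.integers(0, 2, size=n).astype(float)
    base = ld.r2(a, b)
    flip = ld.r2(1 - a, b)
    perm = rng.permutation(n)
    reorder = ld.r2(a[perm], b[perm])
    return {
        "avg_max_r2_abs_diff": float(abs(stat - brute)),
        "r2_flip_abs_diff": float(abs(base - flip)),
        "r2_reorder_abs_diff": float(abs(base - reorder)),
    }


def study_condition_summary(seed: int = 0, n_metabolites: int = 100) -> dict:
    """One full study-condition run: simulate, preprocess, heritability,
    genetic CV, and partial-correlation network edge counts at local FDR
    5% and 20%."""
    cfg = SimulationConfig(n_accessions=96, n_metabolites=n_metabolites,
                           n_snps=1000, network_edges=15,
                           seed=_child_seed(seed, 70))
    g = simulate_genotypes(cfg)
    panel, truth = simulate_metabolome(g, cfg)
    norm = preprocess.preprocess_panel(panel)["A"]
    model = quantgen.HeritabilityModel(truth.group_assignment).fit(norm)
    means = quantgen.estimate_accession_means(norm)
    cv = quantgen.genetic_cv(means)
    edges = networks.network_edges(means)
    strict, _ = networks.build_network(edges, 0.05)
    lenient, _ = networks.build_network(edges, 0.20)
    return {
        "mean_h2": float(model.h2_.mean()),
        "sd_h2": float(model.h2_.std()),
        "mean_genetic_cv_pct": float(cv.mean() * 100),
        "edges_fdr05": strict.n_edges,
        "nodes_fdr05": strict.n_nodes,
        "edges_fdr20": lenient.n_edges,
        "nodes_fdr20": lenient.n_nodes,
        "eta0": float(edges.attrs["eta0"]),
        "n_metabolites": n_metabolites,
    }
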