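"""Gene-level candidate links and permutation-calibrated hotspots.

A gene-metabolite link is a candidate when at least ``min_snps`` (default 2)
distinct SNPs within 1 kb of the gene are significantly associated with the
metabolite.  Hotspots are found by (1) counting significantly associated
metabolites per gene, (2) sliding averages of those counts over 100-gene
windows (confined within chromosomes), (3) keeping genes whose covering
window average exceeds the permutation-derived null maximum, (4) dropping
genes with no passing immediate neighbour, and (5) retaining the resulting
maximal runs only if they average more than two compounds per gene, or
contain at least eight genes averaging more than one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import GenotypeSet

__all__ = [
    "assign_snps_to_genes",
    "call_candidate_genes",
    "per_gene_compound_counts",
    "sliding_window_means",
    "sliding_hotspots",
    "permutation_null",
    "HotspotInterval",
    "CandidateLink",
]


@dataclass
class CandidateLink:
    gene_id: str
    compound_id: str
    n_significant_snps: int
    min_q: float


@dataclass
class HotspotInterval:
    chrom: object
    gene_ids: list
    start: int
    end: int
    mean_compounds: float


def assign_snps_to_genes(snps: pd.DataFrame, genes: pd.DataFrame,
                         window: int = 1000) -> dict:
    """SNP -> list of gene ids with pos in [start - window, end + window]
    (1-based inclusive on both ends); a SNP may map to several genes.

    ``snps`` is indexed by SNP id with columns chrom, pos; ``genes`` has
    gene_id, chrom, start, end.
    """
    out: dict[str, list] = {}
    gene_chroms = set(genes["chrom"])
    for chrom, sub in snps.groupby("chrom"):
        if chrom not in gene_chroms:
            warnings.warn(f"no gene models on chromosome {chrom!r}; "
                          "its SNPs are unassigned")
            continue
        pos = sub["pos"].to_numpy()
        order = np.argsort(pos, kind="stable")
        pos_sorted = pos[order]
        ids = sub.index.to_numpy()[order]
        for _, g in genes[genes["chrom"] == chrom].iterrows():
            lo = np.searchsorted(pos_sorted, g["start"] - window, side="left")
            hi = np.searchsorted(pos_sorted, g["end"] + window, side="right")
            for snp_id in ids[lo:hi]:
                out.setdefault(snp_id, []).append(g["gene_id"])
    return out


def call_candidate_genes(assoc: pd.DataFrame, snp_gene_map: dict,
                         q_cutoff: float, min_snps: int = 2) -> pd.DataFrame:
    """Candidate (gene, compound) links from a per-SNP association table.

    ``assoc`` needs columns compound_id, snp_id, q.  Returns a DataFrame
    with gene_id, compound_id, n_significant_snps, min_q.
    """
    sig = assoc[assoc["q"] < q_cutoff]
    rows = []
    if len(sig):
        expanded = []
        for snp_id, compound, q in zip(sig["snp_id"], sig["compound_id"], sig["q"]):
            for gene in snp_gene_map.get(snp_id, ()):
                expanded.append((gene, compound, snp_id, q))
        if expanded:
            df = pd.DataFrame(expanded,
                              columns=["gene_id", "compound_id", "snp_id", "q"])
            grouped = df.groupby(["gene_id", "compound_id"]).agg(
                n_significant_snps=("snp_id", "nunique"), min_q=("q", "min"))
            grouped = grouped[grouped["n_significant_snps"] >= min_snps]
            rows = grouped.reset_index()
    if not isinstance(rows, pd.DataFrame):
        rows = pd.DataFrame(columns=["gene_id", "compound_id",
                                     "n_significant_snps", "min_q"])
    return rows


def per_gene_compound_counts(candidates: pd.DataFrame,
                             genes: pd.DataFrame) -> pd.Series:
    """Number of distinct associated compounds per gene, zero-filled over
    the full gene annotation."""
    counts = pd.Series(0, index=genes["gene_id"], dtype=int)
    if len(candidates):
        c = candidates.groupby("gene_id")["compound_id"].nunique()
        counts.loc[c.index] = c
    return counts


def _ordered_genes(genes: pd.DataFrame) -> pd.DataFrame:
    return genes.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


def sliding_window_means(counts: pd.Series, genes: pd.DataFrame,
                         window_genes: int = 100) -> pd.Series:
    """Per-gene maximum covering-window average of compound counts.

    Windows of ``window_genes`` consecutive genes slide with step 1 within
    each chromosome; the window average is assigned to every gene in the
    window and a gene's value is the maximum over its covering windows.
    Chromosomes shorter than the window use the chromosome length (with a
    warning).
    """
    genes = _ordered_genes(genes)
    out = pd.Series(np.nan, index=genes["gene_id"])
    for chrom, sub in genes.groupby("chrom", sort=False):
        ids = sub["gene_id"].to_numpy()
        x = counts.reindex(ids).fillna(0).to_numpy(dtype=float)
        n = len(x)
        w = window_genes
        if n < w:
            warnings.warn(f"chromosome {chrom!r} has {n} genes < window "
                          f"{w}; window truncated")
            w = n
        csum = np.concatenate([[0.0], np.cumsum(x)])
        wm = (csum[w:] - csum[:-w]) / w      # window means, len n - w + 1
        vals = np.empty(n)
        for i in range(n):
            lo = max(0, i - w + 1)
            hi = min(i, n - w)
            vals[i] = wm[lo:hi + 1].max()
        out.loc[ids] = vals
    return out


def sliding_hotspots(candidates: pd.DataFrame, genes: pd.DataFrame,
                     window_genes: int = 100,
                     null_max: float = 0.0) -> list:
    """Hotspot intervals from candidate links (see module docstring).

    All retention thresholds are strict ">" comparisons.
    """
    genes = _ordered_genes(genes)
    counts = per_gene_compound_counts(candidates, genes)
    win = sliding_window_means(counts, genes, window_genes)
    passing = win > null_max

    hotspots: list[HotspotInterval] = []
    for chrom, sub in genes.groupby("chrom", sort=False):
        ids = list(sub["gene_id"])
        ok = passing.reindex(ids).to_numpy()
        # step 4: drop genes with no passing immediate neighbour
        surv = ok.copy()
        for i in range(len(ids)):
            if not ok[i]:
                continue
            left = ok[i - 1] if i > 0 else False
            right = ok[i + 1] if i < len(ids) - 1 else False
            surv[i] = left or right
        # maximal runs of surviving genes
        i = 0
        while i < len(ids):
            if not surv[i]:
                i += 1
                continue
            j = i
            while j < len(ids) and surv[j]:
                j += 1
            run = ids[i:j]
            mean_c = float(counts.reindex(run).mean())
            if mean_c > 2.0 or (len(run) >= 8 and mean_c > 1.0):
                rows = sub[sub["gene_id"].isin(run)]
                hotspots.append(HotspotInterval(
                    chrom=chrom, gene_ids=run,
                    start=int(rows["start"].min()),
                    end=int(rows["end"].max()),
                    mean_compounds=mean_c))
            i = j
    return hotspots


def permutation_null(means: pd.DataFrame, genotypes: GenotypeSet,
                     K: pd.DataFrame, n_perm: int, q_cutoff: float,
                     min_snps: int = 2, window_genes: int = 100,
                     snp_gene_map: dict | None = None, seed: int = 0,
                     grid_points: int = 50) -> dict:
    """Null summaries from within-compound accession shuffling.

    Per permutation, each compound's accession means are re-sampled without
    replacement (independently per compound), the full scan, candidate
    calling and sliding averages are recomputed, and the maximum sliding
    average is recorded.  Returns the per-permutation maxima (``null_max``
    is their overall maximum: the 'maximum average number of false
    compounds per gene'), the per-permutation genes-per-metabolite counts,
    and their mean (expected false genes per metabolite).
    """
    from .gwas import scan_all

    if snp_gene_map is None:
        snp_gene_map = assign_snps_to_genes(genotypes.snps, genotypes.genes)
    rng = np.random.default_rng(seed)
    max_averages = []
    genes_per_metabolite = []
    for _ in range(max(n_perm, 1)):
        arr = means.to_numpy(dtype=float).copy()
        for i in range(arr.shape[0]):
            arr[i, :] = arr[i, rng.permutation(arr.shape[1])]
        shuffled = pd.DataFrame(arr, index=means.index, columns=means.columns)
        assoc = scan_all(shuffled, genotypes, K, grid_points=grid_points)
        cands = call_candidate_genes(assoc, snp_gene_map, q_cutoff, min_snps)
        counts = per_gene_compound_counts(cands, genotypes.genes)
        win = sliding_window_means(counts, genotypes.genes, window_genes)
        max_averages.append(float(win.max()))
        per_met = (cands.groupby("compound_id")["gene_id"].nunique()
                   .reindex(means.index, fill_value=0)
                   if len(cands) else pd.Series(0, index=means.index))
        genes_per_metabolite.append(per_met.to_numpy())
    per_met_all = np.concatenate(genes_per_metabolite)
    return {
        "max_sliding_averages": max_averages,
        "null_max": float(max(max_averages)),
        "genes_per_metabolite": genes_per_metabolite,
        "expected_false_genes_per_metabolite": float(per_met_all.mean()),
    }
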