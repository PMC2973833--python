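"""Gene-level linkage disequilibrium on homozygous accession panels.

Genes are collapsed to biallelic loci: the empirically most frequent
haplotype over the gene's SNPs becomes the major allele (0) and all other
haplotypes the minor allele (1); ties go to the lexicographically smallest
haplotype string for determinism.  r^2 is the squared Pearson correlation
of the binary allele vectors.  Two screens are provided:

* non-syntenic (trans) LD among genes co-associated with the same compound
  but on different chromosomes, with the 99th percentile and maximum of all
  non-syntenic r^2 reported alongside;
* a hotspot-versus-genome profile using the average maximum SNP-SNP r^2:
  per gene pair, all SNP-pair r^2 are computed, each SNP's maximum is taken
  from its own gene's side, and the two side-wise means of those maxima are
  averaged.  The significance cutoff is the mean of this statistic over all
  different-chromosome gene pairs in the data (recomputed, never
  hard-coded).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .datatypes import DataError, GenotypeSet

__all__ = [
    "CollapsedLocus",
    "collapse_gene",
    "r2",
    "nonsyntenic_ld_screen",
    "average_max_r2",
    "hotspot_genome_ld_profile",
]


@dataclass
class CollapsedLocus:
    gene_id: str
    alleles: pd.Series            # per accession: 0 = major haplotype, 1 = other
    major_haplotype: str
    major_frequency: float


def collapse_gene(genotypes: GenotypeSet, gene_snps: list,
                  gene_id: str = "") -> CollapsedLocus:
    """Collapse a gene's SNPs into one biallelic locus.

    Accessions with any missing SNP in the gene are dropped (no haplotype is
    fabricated).  The most frequent haplotype string is the major allele;
    frequency ties break to the lexicographically smallest string.
    """
    if not gene_snps:
        raise DataError(f"gene {gene_id!r} has no mapped SNPs")
    sub = genotypes.matrix.loc[:, gene_snps]
    complete = sub.notna().all(axis=1)
    if not complete.any():
        raise DataError(f"all accessions missing for gene {gene_id!r}")
    sub = sub.loc[complete].astype(int)
    haplotypes = sub.apply(lambda row: "".join(map(str, row)), axis=1)
    freq = haplotypes.value_counts()
    top = freq.max()
    major = min(freq.index[freq == top])   # lexicographic tie-break
    alleles = (haplotypes != major).astype(int)
    return CollapsedLocus(gene_id=gene_id, alleles=alleles,
                          major_haplotype=major,
                          major_frequency=float(top / len(haplotypes)))


def r2(a, b) -> float:
    """Squared correlation LD between two binary allele vectors.

    Computed over positions non-missing in both; equals
    (p_ab - p_a p_b)^2 / (p_a(1-p_a) p_b(1-p_b)).  Monomorphic input -> NaN.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise DataError("allele vectors differ in length")
    ok = ~(np.isnan(a) | np.isnan(b))
    a, b = a[ok], b[ok]
    if len(a) < 2 or a.std() == 0 or b.std() == 0:
        return np.nan
    pa, pb, pab = a.mean(), b.mean(), (a * b).mean()
    return float((pab - pa * pb) ** 2 / (pa * (1 - pa) * pb * (1 - pb)))


def _collapse_many(genotypes: GenotypeSet, gene_snps_map: dict) -> dict:
    out = {}
    for gene_id, snps in gene_snps_map.items():
        try:
            out[gene_id] = collapse_gene(genotypes, snps, gene_id)
        except DataError:
            continue
    return out


def nonsyntenic_ld_screen(candidates: pd.DataFrame, collapsed: dict,
                          genes: pd.DataFrame,
                          r2_threshold: float = 0.4) -> dict:
    """Trans-LD among co-associated genes on different chromosomes.

    ``candidates`` carries gene_id/compound_id; ``collapsed`` maps gene id
    to :class:`CollapsedLocus`.  Returns the gene pairs above threshold, the
    full non-syntenic r^2 list, its 99th percentile and maximum.
    """
    chrom_of = dict(zip(genes["gene_id"], genes["chrom"]))
    pairs = set()
    for _, grp in candidates.groupby("compound_id"):
        gs = sorted(set(grp["gene_id"]))
        for g1, g2 in combinations(gs, 2):
            if (g1 in collapsed and g2 in collapsed
                    and chrom_of.get(g1) != chrom_of.get(g2)):
                pairs.add((g1, g2))
    records, values = [], []
    for g1, g2 in sorted(pairs):
        a = collapsed[g1].alleles
        b = collapsed[g2].alleles
        shared = a.index.intersection(b.index)
        val = r2(a.loc[shared], b.loc[shared])
        if np.isnan(val):
            continue
        values.append(val)
        if val > r2_threshold:
            records.append({"gene_1": g1, "gene_2": g2, "r2": val})
    values = np.asarray(values)
    return {
        "pairs_above_threshold": pd.DataFrame(
            records, columns=["gene_1", "gene_2", "r2"]),
        "all_nonsyntenic_r2": values,
        "percentile_99": float(np.percentile(values, 99)) if len(values) else np.nan,
        "max": float(values.max()) if len(values) else np.nan,
    }


def average_max_r2(geno_a: pd.DataFrame, geno_b: pd.DataFrame) -> float:
    """Average maximum SNP-SNP r^2 between two genes' SNP sets.

    Steps: (1) r^2 for every SNP pair across the two genes; (2) per-SNP
    maximum taken separately from each gene's side; (3) the two side-wise
    means of those maxima averaged.
    """
    mat = np.empty((geno_a.shape[1], geno_b.shape[1]))
    for i in range(geno_a.shape[1]):
        for j in range(geno_b.shape[1]):
            mat[i, j] = r2(geno_a.iloc[:, i], geno_b.iloc[:, j])
    if np.isnan(mat).all():
        return np.nan
    side_a = np.nanmax(mat, axis=1).mean()
    side_b = np.nanmax(mat, axis=0).mean()
    return float((side_a + side_b) / 2.0)


def hotspot_genome_ld_profile(hotspot_genes: list, all_genes: list,
                              genotypes: GenotypeSet,
                              gene_snps_map: dict) -> dict:
    """Average-maximum SNP-SNP r^2 between hotspot genes and a gene list.

    Returns the profile matrix (hotspot genes x genes), the significance
    cutoff (mean statistic over all different-chromosome gene pairs in the
    profile), and the boolean significance calls.  Genes without mapped
    SNPs yield NA rows/columns.
    """
    chrom_of = dict(zip(genotypes.genes["gene_id"], genotypes.genes["chrom"]))
    mat = pd.DataFrame(np.nan, index=list(hotspot_genes), columns=list(all_genes))
    for g1 in hotspot_genes:
        snps1 = gene_snps_map.get(g1, [])
        if not snps1:
            continue
        sub1 = genotypes.matrix.loc[:, snps1]
        for g2 in all_genes:
            snps2 = gene_snps_map.get(g2, [])
            if not snps2:
                continue
            mat.loc[g1, g2] = average_max_r2(sub1, genotypes.matrix.loc[:, snps2])
    cross = [mat.loc[g1, g2] for g1 in hotspot_genes for g2 in all_genes
             if chrom_of.get(g1) != chrom_of.get(g2)
             and not pd.isna(mat.loc[g1, g2])]
    cutoff = float(np.mean(cross)) if cross else np.nan
    calls = mat > cutoff if not np.isnan(cutoff) else mat.isna() & False
    return {"profile": mat, "cutoff": cutoff, "significant": calls}
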