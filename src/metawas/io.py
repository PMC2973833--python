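"""Readers and writers for the pipeline's on-disk formats.

Genotypes travel as a TSV matrix (accessions x SNPs, header of ``chrom:pos``
ids) or minimal VCF 4.2 (homozygous diploid calls, read back through
cyvcf2); gene models as BED (0-based half-open) or GFF3 (1-based
inclusive); replicate-level metabolite data as a long-format TSV; accession
means in the wide supplementary-table dialect (rows = compounds keyed by
BinBase id, columns = accessions) so real supplementary files round-trip
through the same reader; network edges as TSV or GraphML.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import DataError, GenotypeSet, MetabolitePanel

__all__ = [
    "write_genotypes_tsv", "read_genotypes_tsv",
    "write_vcf", "read_genotypes_vcf",
    "write_genes_bed", "read_genes_bed",
    "write_genes_gff3", "read_genes_gff3",
    "write_panel_long", "read_panel_long",
    "write_means_wide", "read_means_wide",
    "write_truth", "write_edges_tsv", "write_edges_graphml",
]


# --- genotypes -------------------------------------------------------------

def write_genotypes_tsv(genotypes: GenotypeSet, path) -> None:
    out = genotypes.matrix.copy()
    out.to_csv(path, sep="\t", index_label="accession", na_rep="NA")


def read_genotypes_tsv(path, genes: pd.DataFrame | None = None) -> GenotypeSet:
    matrix = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    matrix.index.name = None
    matrix.columns.name = None
    chrom_pos = [c.split(":") for c in matrix.columns]
    snps = pd.DataFrame({
        "chrom": [int(c) if c.isdigit() else c for c, _ in chrom_pos],
        "pos": [int(p) for _, p in chrom_pos],
    }, index=matrix.columns)
    freq = matrix.mean(axis=0, skipna=True)
    snps["maf"] = np.minimum(freq, 1 - freq)
    if genes is None:
        genes = pd.DataFrame(columns=["gene_id", "chrom", "start", "end"])
    return GenotypeSet(matrix=matrix, snps=snps, genes=genes)


def write_vcf(genotypes: GenotypeSet, path) -> None:
    """Minimal VCF 4.2; inbred accessions written as homozygous diploid
    calls (0/0 or 1/1, ./. when missing)."""
    acc = list(genotypes.accessions)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(genotypes.snps["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(acc) + "\n")
        mat = genotypes.matrix.to_numpy()
        for j, snp_id in enumerate(genotypes.snp_ids):
            row = genotypes.snps.loc[snp_id]
            calls = []
            for v in mat[:, j]:
                if np.isnan(v):
                    calls.append("./.")
                else:
                    a = int(round(v))
                    calls.append(f"{a}/{a}")
            fh.write(f"{row['chrom']}\t{row['pos']}\t{snp_id}\tA\tT\t.\t.\t.\tGT\t"
                     + "\t".join(calls) + "\n")


def read_genotypes_vcf(path, genes: pd.DataFrame | None = None) -> GenotypeSet:
    from cyvcf2 import VCF

    reader = VCF(str(path))
    acc = list(reader.samples)
    cols, chroms, positions, ids = [], [], [], []
    for variant in reader:
        gt = np.asarray(variant.gt_types, dtype=float)
        col = np.where(gt == 0, 0.0,
                       np.where(gt == 3, 1.0, np.nan))
        cols.append(col)
        chrom = variant.CHROM
        chroms.append(int(chrom) if chrom.isdigit() else chrom)
        positions.append(variant.POS)
        ids.append(variant.ID or f"{variant.CHROM}:{variant.POS}")
    reader.close()
    if not cols:
        raise DataError(f"no variants in {path}")
    matrix = pd.DataFrame(np.column_stack(cols), index=acc, columns=ids)
    snps = pd.DataFrame({"chrom": chroms, "pos": positions}, index=ids)
    freq = matrix.mean(axis=0, skipna=True)
    snps["maf"] = np.minimum(freq, 1 - freq)
    if genes is None:
        genes = pd.DataFrame(columns=["gene_id", "chrom", "start", "end"])
    return GenotypeSet(matrix=matrix, snps=snps, genes=genes)


# --- gene models -----------------------------------------------------------

def write_genes_bed(genes: pd.DataFrame, path) -> None:
    bed = pd.DataFrame({
        "chrom": genes["chrom"],
        "start": genes["start"] - 1,   # 1-based inclusive -> 0-based half-open
        "end": genes["end"],
        "name": genes["gene_id"],
    })
    bed.to_csv(path, sep="\t", header=False, index=False)


def read_genes_bed(path) -> pd.DataFrame:
    bed = pd.read_csv(path, sep="\t", header=None,
                      names=["chrom", "start", "end", "name"])
    return pd.DataFrame({
        "gene_id": bed["name"],
        "chrom": bed["chrom"],
        "start": bed["start"] + 1,
        "end": bed["end"],
    })


def write_genes_gff3(genes: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for _, g in genes.iterrows():
            fh.write(f"{g['chrom']}\tmetawas\tgene\t{g['start']}\t{g['end']}"
                     f"\t.\t+\t.\tID={g['gene_id']}\n")


def read_genes_gff3(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9 or parts[2] != "gene":
                continue
            attrs = dict(kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv)
            chrom = parts[0]
            rows.append({
                "gene_id": attrs.get("ID", f"{chrom}:{parts[3]}"),
                "chrom": int(chrom) if chrom.isdigit() else chrom,
                "start": int(parts[3]),
                "end": int(parts[4]),
            })
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end"])


# --- metabolite panels and means -------------------------------------------

def write_panel_long(panel: MetabolitePanel, path) -> None:
    long = panel.values.stack(future_stack=True).rename("ion_count").reset_index()
    long.columns = ["sample_id", "compound_id", "ion_count"]
    long = long.merge(panel.meta, left_on="sample_id", right_index=True)
    cols = ["sample_id", "accession", "experiment", "flat", "replicate",
            "run_date", "compound_id", "ion_count"]
    long[cols].to_csv(path, sep="\t", index=False, na_rep="NA")


def read_panel_long(path) -> MetabolitePanel:
    long = pd.read_csv(path, sep="\t", na_values=["NA"])
    values = long.pivot(index="sample_id", columns="compound_id",
                        values="ion_count")
    meta = (long.drop_duplicates("sample_id")
            .set_index("sample_id")
            [["accession", "experiment", "flat", "replicate", "run_date"]])
    meta = meta.loc[values.index]
    values.columns.name = None
    values.index.name = None
    return MetabolitePanel(values=values, meta=meta)


def write_means_wide(means: pd.DataFrame, path) -> None:
    """Wide supplementary-table dialect: rows = compounds (BinBase id),
    columns = accessions."""
    means.to_csv(path, sep="\t", index_label="ID", na_rep="NA")


def read_means_wide(path) -> pd.DataFrame:
    means = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    means.index = means.index.astype(str)
    means.index.name = None
    return means


# --- truth ledger and edges ------------------------------------------------

def write_truth(truth, path) -> None:
    rows = []
    for compound, entries in truth.causal_map.items():
        for gene, effect in entries:
            rows.append({
                "compound_id": compound, "gene_id": gene, "effect": effect,
                "true_h2": truth.true_h2.get(compound, np.nan),
                "is_hotspot_gene": gene == truth.hotspot_gene,
            })
    pd.DataFrame(rows, columns=["compound_id", "gene_id", "effect",
                                "true_h2", "is_hotspot_gene"]
                 ).to_csv(path, sep="\t", index=False)


def write_edges_tsv(edges: pd.DataFrame, path) -> None:
    cols = ["compound_i", "compound_j", "rho", "pcor", "sign", "local_fdr"]
    edges[[c for c in cols if c in edges.columns]].to_csv(
        path, sep="\t", index=False)


def write_edges_graphml(edges: pd.DataFrame, path,
                        fdr_cutoff: float = 1.0) -> None:
    import networkx as nx

    kept = edges[edges["local_fdr"] < fdr_cutoff]
    g = nx.Graph()
    for _, row in kept.iterrows():
        g.add_edge(row["compound_i"], row["compound_j"],
                   pcor=float(row.get("pcor", np.nan)),
                   rho=float(row.get("rho", np.nan)),
                   sign=str(row.get("sign", "")),
                   local_fdr=float(row["local_fdr"]))
    nx.write_graphml(g, path)
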