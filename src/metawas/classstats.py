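"""Cross-experiment differential abundance and class/pathway enrichment.

Differential abundance uses a two-sample paired t-test per compound shared
between the two experiments, pairing on accession (both experiments measure
the same accessions), Bonferroni correction over the shared compounds, and
a differential flag requiring both adjusted p < alpha and a greater than
two-fold difference.  Fold difference is the ratio of geometric means,
2^(mean log2 difference).  Enrichment of metabolite classes or pathways
among associated compounds uses Pearson's chi-square on 2x2 tables.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import DataError

__all__ = [
    "read_annotation_map",
    "differential_abundance",
    "class_enrichment",
    "shared_gene_analysis",
]


def read_annotation_map(path) -> pd.Series:
    """Two-column TSV (compound_id, label) -> Series compound -> label.
    A compound may appear on several rows (multiple pathways)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["compound_id", "label"],
                     dtype=str, comment="#")
    return pd.Series(df["label"].to_numpy(), index=df["compound_id"].to_numpy())


def differential_abundance(means_a: pd.DataFrame, means_b: pd.DataFrame,
                           alpha: float = 0.05) -> pd.DataFrame:
    """Paired t-tests between two accession-means tables (log2 units).

    Returns per shared compound: t, df, p, p_bonferroni, fold_difference
    (count scale), log2_difference, and the differential flag
    (p_bonferroni < alpha AND |log2 difference| > 1).  Compounds with fewer
    than 3 paired accessions get NA.
    """
    compounds = means_a.index.intersection(means_b.index)
    if len(compounds) == 0:
        raise DataError("no shared compounds between the two tables")
    accessions = means_a.columns.intersection(means_b.columns)
    m = len(compounds)
    rows = []
    for c in compounds:
        a = means_a.loc[c, accessions]
        b = means_b.loc[c, accessions]
        ok = a.notna() & b.notna()
        n = int(ok.sum())
        if n < 3:
            rows.append((c, np.nan, np.nan, np.nan, np.nan, np.nan, False))
            continue
        res = stats.ttest_rel(b[ok], a[ok])
        dlog2 = float((b[ok] - a[ok]).mean())
        p_bonf = min(1.0, float(res.pvalue) * m)
        flag = bool(p_bonf < alpha and abs(dlog2) > 1.0)
        rows.append((c, float(res.statistic), n - 1, float(res.pvalue),
                     p_bonf, dlog2, flag))
    out = pd.DataFrame(rows, columns=["compound_id", "t", "df", "p",
                                      "p_bonferroni", "log2_difference",
                                      "differential"]).set_index("compound_id")
    out["fold_difference"] = np.exp2(out["log2_difference"])
    return out


def class_enrichment(candidates: pd.DataFrame, annotation: pd.Series,
                     universe) -> pd.DataFrame:
    """Per-class Pearson chi-square for over-representation among
    gene-associated compounds.

    The 2x2 table per class crosses in-class membership with association
    with at least one gene; the test has 1 df (no continuity correction).
    Classes with any expected cell below 1 are flagged unreliable but still
    reported.
    """
    universe = pd.Index(universe)
    associated = set(candidates["compound_id"]) & set(universe)
    if not set(candidates["compound_id"]) <= set(universe):
        raise DataError("universe must contain every associated compound")
    ann = annotation.reindex(universe.intersection(annotation.index))
    rows = []
    for cls, members in ann.groupby(ann).groups.items():
        in_class = set(members)
        a = len(in_class & associated)
        b = len(in_class) - a
        c = len(associated) - a
        d = len(universe) - a - b - c
        table = np.array([[a, b], [c, d]], dtype=float)
        expected = stats.contingency.expected_freq(table)
        if table.sum() == 0 or (table.sum(axis=0) == 0).any() \
                or (table.sum(axis=1) == 0).any():
            chi2, p = np.nan, np.nan
        else:
            chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
        rows.append({
            "class": cls, "n_class": len(in_class), "observed": a,
            "expected": float(expected[0, 0]), "chi2": chi2, "p": p,
            "reliable": bool((expected >= 1).all()),
        })
    return pd.DataFrame(rows).set_index("class")


def shared_gene_analysis(candidates: pd.DataFrame, annotation: pd.Series,
                         group: str) -> dict:
    """Gene sharing within one metabolite class or pathway.

    Counts genes associated with >= 2 compounds of the group, and compares
    the group's distribution of per-gene association counts against the
    all-compound distribution with a chi-square test on the binned
    contingency (bins: 1, 2, >= 3 compounds per gene).
    """
    members = set(annotation.index[annotation == group])
    if len(members) < 2:
        raise DataError(f"group {group!r} absent or has fewer than 2 compounds")
    in_group = candidates[candidates["compound_id"].isin(members)]
    per_gene_group = in_group.groupby("gene_id")["compound_id"].nunique()
    per_gene_all = candidates.groupby("gene_id")["compound_id"].nunique()
    shared_genes = sorted(per_gene_group.index[per_gene_group >= 2])

    def binned(counts: pd.Series) -> np.ndarray:
        return np.array([(counts == 1).sum(), (counts == 2).sum(),
                         (counts >= 3).sum()], dtype=float)

    tab = np.vstack([binned(per_gene_group), binned(per_gene_all)])
    keep = tab.sum(axis=0) > 0
    tab = tab[:, keep]
    if tab.shape[1] >= 2 and (tab.sum(axis=1) > 0).all():
        chi2, p, _, _ = stats.chi2_contingency(tab, correction=False)
    else:
        warnings.warn("degenerate sharing table; chi-square not computed")
        chi2, p = np.nan, np.nan
    return {
        "shared_genes": shared_genes,
        "n_shared": len(shared_genes),
        "per_gene_group_counts": per_gene_group,
        "chi2": float(chi2) if chi2 == chi2 else np.nan,
        "p": float(p) if p == p else np.nan,
    }
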