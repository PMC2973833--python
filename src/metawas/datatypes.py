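"""Core in-memory containers shared by all pipeline stages.

The analysis operates on three tables:

* :class:`MetabolitePanel` — replicate-level ion counts (samples x compounds)
  with per-sample metadata (accession, experiment, flat, replicate, run date).
* :class:`GenotypeSet` — homozygous biallelic genotypes (accessions x SNPs,
  coded 0/1, NaN = missing) with SNP and gene-model annotation.
* accession means — a plain :class:`pandas.DataFrame` with compounds as rows
  and accessions as columns (log2 units), the unit of all downstream analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

META_COLUMNS = ("accession", "experiment", "flat", "replicate", "run_date")


class MetawasError(Exception):
    """Base class for errors raised by this package."""


class ConfigError(MetawasError):
    """Invalid configuration (bad parameter values, missing references)."""


class DataError(MetawasError):
    """Malformed or degenerate input data."""


@dataclass
class MetabolitePanel:
    """Replicate-level metabolite ion counts plus sample metadata.

    Parameters
    ----------
    values : DataFrame
        samples x compounds matrix of ion counts; NaN marks a compound not
        detected in that sample.
    meta : DataFrame
        indexed like ``values`` rows, with columns ``accession``,
        ``experiment``, ``flat``, ``replicate``, ``run_date``.
    """

    values: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.meta.index):
            raise DataError("panel values and metadata must share the sample index")
        missing = [c for c in META_COLUMNS if c not in self.meta.columns]
        if missing:
            raise DataError(f"panel metadata lacks columns: {missing}")
        if self.values.columns.has_duplicates:
            raise DataError("compound ids must be unique")
        if self.meta["accession"].isna().any() or self.meta["run_date"].isna().any():
            raise DataError("every sample needs an accession and a run date")

    @property
    def compounds(self) -> pd.Index:
        return self.values.columns

    @property
    def samples(self) -> pd.Index:
        return self.values.index

    def detected(self) -> pd.DataFrame:
        """Boolean detection mask: a compound is present in a sample iff its
        ion count is non-missing and strictly positive."""
        return self.values.notna() & (self.values > 0)

    def subset(self, samples=None, compounds=None) -> "MetabolitePanel":
        values = self.values
        meta = self.meta
        if samples is not None:
            values = values.loc[samples]
            meta = meta.loc[samples]
        if compounds is not None:
            values = values.loc[:, compounds]
        return MetabolitePanel(values=values.copy(), meta=meta.copy())

    def split_experiments(self) -> dict:
        """Panel per experiment label, in first-appearance order."""
        out = {}
        for label in self.meta["experiment"].unique():
            keep = self.meta.index[self.meta["experiment"] == label]
            out[label] = self.subset(samples=keep)
        return out


@dataclass
class GenotypeSet:
    """Accession x SNP binary genotypes with positional annotation.

    ``matrix`` holds 0/1 (major/minor at generation time) with NaN for
    missing calls; accessions are homozygous inbreds so one allele per locus
    suffices.  ``snps`` is indexed by SNP id (``chrom:pos``) with columns
    ``chrom`` and ``pos``; ``genes`` has columns ``gene_id``, ``chrom``,
    ``start``, ``end`` (1-based inclusive).
    """

    matrix: pd.DataFrame
    snps: pd.DataFrame
    genes: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["gene_id", "chrom", "start", "end"]))

    def __post_init__(self) -> None:
        if list(self.matrix.columns) != list(self.snps.index):
            raise DataError("genotype columns must match the SNP annotation index")

    @property
    def accessions(self) -> pd.Index:
        return self.matrix.index

    @property
    def snp_ids(self) -> pd.Index:
        return self.matrix.columns

    def maf(self) -> pd.Series:
        """Minor-allele frequency per SNP over non-missing accessions."""
        freq = self.matrix.mean(axis=0, skipna=True)
        return np.minimum(freq, 1.0 - freq)

    def subset_snps(self, snp_ids) -> "GenotypeSet":
        return GenotypeSet(
            matrix=self.matrix.loc[:, snp_ids].copy(),
            snps=self.snps.loc[snp_ids].copy(),
            genes=self.genes.copy(),
        )
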