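import numpy as np
import pandas as pd
import pytest

from metawas.datatypes import GenotypeSet, MetabolitePanel
from metawas.synthetic import (SimulationConfig, simulate_genotypes,
                               simulate_metabolome)


def make_panel(values: np.ndarray, accessions, compounds=None, flats=None,
               replicates=None, run_dates=None, experiment="A"):
    """Build a panel from a samples x compounds array plus per-sample
    metadata lists."""
    n = values.shape[0]
    compounds = compounds or [f"c{j}" for j in range(values.shape[1])]
    samples = [f"s{i}" for i in range(n)]
    meta = pd.DataFrame({
        "accession": accessions,
        "experiment": [experiment] * n,
        "flat": flats or ["F1"] * n,
        "replicate": replicates or list(range(1, n + 1)),
        "run_date": run_dates or ["d1"] * n,
    }, index=samples)
    return MetabolitePanel(
        values=pd.DataFrame(values, index=samples, columns=compounds),
        meta=meta)


@pytest.fixture
def toy_genotypes():
    """3 accessions x 4 SNPs with hand-checkable allele sharing."""
    matrix = pd.DataFrame(
        [[0, 0, 1, 1],
         [0, 1, 1, 0],
         [1, 1, 0, 0]],
        index=["a1", "a2", "a3"],
        columns=["1:100", "1:200", "2:100", "2:200"], dtype=float)
    snps = pd.DataFrame({"chrom": [1, 1, 2, 2],
                         "pos": [100, 200, 100, 200]},
                        index=matrix.columns)
    genes = pd.DataFrame({
        "gene_id": ["g1", "g2"],
        "chrom": [1, 2],
        "start": [50, 50],
        "end": [250, 150],
    })
    return GenotypeSet(matrix=matrix, snps=snps, genes=genes)


@pytest.fixture(scope="session")
def small_simulation():
    """One small but realistic simulated study shared across tests."""
    cfg = SimulationConfig(n_accessions=48, n_snps=500, n_metabolites=12,
                           n_chromosomes=3, hotspot_metabolites=4,
                           network_edges=4, seed=42)
    genotypes = simulate_genotypes(cfg)
    panel, truth = simulate_metabolome(genotypes, cfg)
    return cfg, genotypes, panel, truth
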