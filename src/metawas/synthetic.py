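"""Synthetic genotype and metabolome generator with a truth ledger.

The generator emulates the statistical structure the downstream analysis
assumes, so every stage can be exercised and parameter recovery tested
without the original study data:

* 96 homozygous inbred accessions in ~8 population-structure groups,
  produced by a two-level Balding-Nichols allele-frequency model with an
  Fst-like divergence parameter;
* LD blocks created by Markov haplotype copying within blocks of
  ``ld_block_length`` SNPs, restarting at block boundaries;
* gene models tiled along each chromosome;
* metabolites on a log-normal ion-count scale whose accession-level values
  combine planted causal-gene effects, an optional planted pleiotropic
  hotspot gene, and a latent Gaussian graphical network drawn from a sparse
  precision matrix; replicate-level noise comes from flat, replicate-in-flat
  and run-batch effects plus Gaussian residuals, all in log2 units.

Accessions are haploid 0/1 vectors: the lines are fully inbred, so one
allele per locus carries the full genotype and no heterozygote state exists.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .datatypes import ConfigError, GenotypeSet, MetabolitePanel
from .genes_hotspots import assign_snps_to_genes

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "simulate_genotypes",
    "simulate_metabolome",
    "build_precision_matrix",
]


@dataclass
class SimulationConfig:
    """All dials of the generator; defaults mirror the study design.

    96 accessions in 8 structure groups, 4 replicate plants per accession
    split over 2 flats, a target broad-sense heritability of 0.45 (the
    regime the study reports), and ion counts centred at 9 log2 units (the
    normalization anchor).
    """

    n_accessions: int = 96
    n_structure_groups: int = 8
    n_snps: int = 2000
    n_chromosomes: int = 5
    ld_block_length: int = 10
    maf_min: float = 0.05
    fst: float = 0.1
    snp_spacing: int = 200          # bp between adjacent SNPs
    gene_length: int = 1500         # bp
    gene_gap: int = 1500            # bp between consecutive genes

    n_metabolites: int = 100
    n_causal_per_metabolite: int = 1
    effect_size: float = 1.0        # per causal SNP, in accession-sd units
    target_h2: float = 0.45
    hotspot_metabolites: int = 0    # m metabolites driven by one shared gene
    network_edges: int = 0          # latent GGM edges among metabolites
    network_pcor: float = 0.5       # |partial correlation| on latent edges

    n_flats: int = 2
    n_replicates: int = 4
    n_run_batches: int = 4
    flat_sd: float = 0.15           # log2 units, per compound
    replicate_sd: float = 0.1       # replicate-in-flat, log2 units
    batch_shift_sd: float = 0.2     # global per-run-date median shift
    residual_sd: float = 0.5        # log2 units
    baseline_log2: float = 9.0
    baseline_sd: float = 0.75
    detection_limit: float = 0.0    # counts below this are recorded missing
    missing_rate: float = 0.0       # extra random dropout
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_accessions": self.n_accessions,
            "n_structure_groups": self.n_structure_groups,
            "n_snps": self.n_snps,
            "n_chromosomes": self.n_chromosomes,
            "ld_block_length": self.ld_block_length,
            "n_metabolites": self.n_metabolites,
            "n_flats": self.n_flats,
            "n_replicates": self.n_replicates,
            "n_run_batches": self.n_run_batches,
        }
        for name, value in counts.items():
            if value < 1:
                raise ConfigError(f"{name} must be >= 1, got {value}")
        if not 0.0 <= self.target_h2 <= 1.0:
            raise ConfigError("target_h2 must lie in [0, 1]")
        if not 0.0 < self.maf_min < 0.5:
            raise ConfigError("maf_min must lie in (0, 0.5)")
        if self.n_snps < self.n_chromosomes:
            raise ConfigError("need at least one SNP per chromosome")
        if self.hotspot_metabolites > self.n_metabolites:
            raise ConfigError("hotspot_metabolites exceeds n_metabolites")


@dataclass
class SimulationTruth:
    """Ledger of the planted structure, for parameter-recovery tests."""

    causal_map: dict                      # compound -> list of (gene_id, effect)
    hotspot_gene: Optional[str]
    true_h2: pd.Series                    # per compound
    true_partial_corr: pd.DataFrame       # compound x compound
    group_assignment: pd.Series           # accession -> structure group
    causal_snps: dict = field(default_factory=dict)  # compound -> snp ids

    def __post_init__(self) -> None:
        m = self.true_partial_corr
        if not np.allclose(m.values, m.values.T):
            raise ConfigError("true_partial_corr must be symmetric")
        if not np.allclose(np.diag(m.values), 1.0):
            raise ConfigError("true_partial_corr must have unit diagonal")


def _group_sizes(n: int, groups: int) -> np.ndarray:
    base = np.full(groups, n // groups)
    base[: n % groups] += 1
    return base


def simulate_genotypes(config: SimulationConfig) -> GenotypeSet:
    """Simulate LD-blocked homozygous genotypes with population structure.

    Ancestral allele frequencies are uniform on (0.1, 0.9); each structure
    group draws its own frequency from a Balding-Nichols Beta distribution
    with divergence ``fst``.  Within a block, each accession copies its
    allele from the previous SNP with high probability (haplotype copying),
    which creates within-block LD; blocks and chromosomes restart the chain.
    SNPs at or below ``maf_min`` after simulation are dropped.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 0])

    n, m = config.n_accessions, config.n_snps
    groups = np.repeat(np.arange(config.n_structure_groups),
                       _group_sizes(n, config.n_structure_groups))
    accessions = [f"acc{i:03d}" for i in range(n)]

    # chromosome / position layout and LD blocks
    per_chrom = _group_sizes(m, config.n_chromosomes)
    chrom = np.repeat(np.arange(1, config.n_chromosomes + 1), per_chrom)
    pos = np.concatenate([
        (np.arange(k) + 1) * config.snp_spacing for k in per_chrom
    ])
    block_id = np.empty(m, dtype=int)
    offset = 0
    next_block = 0
    for c, k in enumerate(per_chrom):
        ids = next_block + np.arange(k) // config.ld_block_length
        block_id[offset:offset + k] = ids
        next_block = ids[-1] + 1
        offset += k

    # Balding-Nichols frequencies drawn per LD block (so the block's SNPs
    # form a haplotype), with small per-SNP jitter to keep loci distinct.
    p_anc_block = rng.uniform(0.1, 0.9, size=next_block)
    if config.fst > 0 and config.n_structure_groups > 1:
        a = p_anc_block * (1 - config.fst) / config.fst
        b = (1 - p_anc_block) * (1 - config.fst) / config.fst
        p_group_block = rng.beta(a, b, size=(config.n_structure_groups,
                                             next_block))
    else:
        p_group_block = np.tile(p_anc_block, (config.n_structure_groups, 1))
    p_group = p_group_block[:, block_id]
    if config.ld_block_length > 1:
        p_group = np.clip(
            p_group + rng.normal(0.0, 0.05, size=p_group.shape), 0.02, 0.98)
    p_acc = p_group[groups, :]                      # n x m

    # Within-block LD via a shared latent uniform per (accession, block):
    # each SNP reuses the block's latent with high probability, otherwise
    # draws a fresh one.  Marginal allele frequencies (hence Fst) are
    # preserved; SNPs sharing the latent are maximally correlated given
    # their frequencies.
    copy_prob = 0.9 if config.ld_block_length > 1 else 0.0
    shared = rng.random((n, next_block))
    fresh = rng.random((n, m))
    use_shared = rng.random((n, m)) < copy_prob
    latent = np.where(use_shared, shared[:, block_id], fresh)
    geno = (latent < p_acc).astype(float)

    if config.missing_rate > 0:
        drop = rng.random((n, m)) < config.missing_rate
        geno[drop] = np.nan

    snp_ids = [f"{c}:{p}" for c, p in zip(chrom, pos)]
    matrix = pd.DataFrame(geno, index=accessions, columns=snp_ids)
    snps = pd.DataFrame({"chrom": chrom, "pos": pos}, index=snp_ids)

    freq = matrix.mean(axis=0, skipna=True)
    maf = np.minimum(freq, 1 - freq)
    keep = maf > config.maf_min
    matrix = matrix.loc[:, keep]
    snps = snps.loc[keep]
    snps["maf"] = maf[keep]

    genes = _tile_genes(per_chrom, config)
    gset = GenotypeSet(matrix=matrix, snps=snps, genes=genes)
    gset.structure_groups = pd.Series(groups, index=accessions, name="group")
    return gset


def _tile_genes(per_chrom: np.ndarray, config: SimulationConfig) -> pd.DataFrame:
    rows = []
    step = config.gene_length + config.gene_gap
    for c, k in enumerate(per_chrom, start=1):
        chrom_len = (k + 1) * config.snp_spacing
        start = 1
        i = 0
        while start + config.gene_length - 1 <= chrom_len:
            rows.append((f"G{c}_{i:04d}", c, start, start + config.gene_length - 1))
            start += step
            i += 1
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end"])


def build_precision_matrix(n: int, n_edges: int, magnitude: float,
                           rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Sparse symmetric precision matrix with controlled partial correlations.

    Edges are sampled with a per-node degree cap that keeps the matrix
    diagonally dominant (hence positive definite) at the requested
    off-diagonal magnitude; each edge gets a random sign.  Returns
    ``(precision, true_pcor)`` where the true partial correlation at an edge
    equals ``magnitude`` up to sign and the diagonal of ``true_pcor`` is 1.
    """
    omega = np.eye(n)
    if n_edges == 0 or magnitude == 0.0:
        return omega, np.eye(n)
    # degree cap 2 allows chains, which create the indirect marginal
    # correlations that distinguish partial from zero-order analysis
    max_degree = 2 if magnitude <= 0.5 else 1
    degree = np.zeros(n, dtype=int)
    placed = 0
    attempts = 0
    adj = np.zeros((n, n), dtype=bool)
    while placed < n_edges and attempts < 100 * n_edges:
        attempts += 1
        i, j = rng.choice(n, size=2, replace=False)
        i, j = min(i, j), max(i, j)
        if adj[i, j] or degree[i] >= max_degree or degree[j] >= max_degree:
            continue
        sign = 1.0 if rng.random() < 0.5 else -1.0
        omega[i, j] = omega[j, i] = -sign * magnitude
        adj[i, j] = True
        degree[[i, j]] += 1
        placed += 1
    if placed < n_edges:
        warnings.warn(
            f"placed only {placed}/{n_edges} network edges under the degree cap")
    # back off the off-diagonal magnitude until comfortably positive definite
    while np.linalg.eigvalsh(omega).min() < 0.05:
        off = ~np.eye(n, dtype=bool)
        omega[off] *= 0.9
    d = np.sqrt(np.diag(omega))
    pcor = -omega / np.outer(d, d)
    np.fill_diagonal(pcor, 1.0)
    return omega, pcor


def simulate_metabolome(
    genotypes: GenotypeSet,
    config: SimulationConfig,
    experiment: str = "A",
) -> tuple[MetabolitePanel, SimulationTruth]:
    """Simulate replicated log-normal ion counts over the given genotypes.

    Accession-level value per metabolite = planted causal-gene effects plus a
    latent Gaussian network component, rescaled so the accession-level
    variance fraction equals ``target_h2``; replicate-level log2 value adds
    per-compound flat and replicate-in-flat effects, a global per-run-batch
    median shift, and Gaussian residual noise, then is exponentiated to the
    count scale.  Counts below ``detection_limit`` are recorded missing.
    """
    config.validate()
    experiment_tag = zlib.crc32(str(experiment).encode()) % (2**31)
    rng = np.random.default_rng([config.seed, 1, experiment_tag])
    n = len(genotypes.accessions)
    p = config.n_metabolites
    compounds = [f"cmp{j:03d}" for j in range(p)]

    snp_gene = assign_snps_to_genes(genotypes.snps, genotypes.genes, window=1000)
    gene_snps: dict[str, list[str]] = {}
    for snp, gs in snp_gene.items():
        for g in gs:
            gene_snps.setdefault(g, []).append(snp)
    mapped_genes = sorted(gene_snps)
    if config.n_causal_per_metabolite > 0 and not mapped_genes:
        raise ConfigError("no gene has a mapped SNP; cannot plant causal effects")

    hotspot_gene = None
    if config.hotspot_metabolites > 0:
        # the mapped gene with the most SNPs, for reliable multi-SNP candidacy
        hotspot_gene = max(mapped_genes, key=lambda g: (len(gene_snps[g]), g))

    G = genotypes.matrix.to_numpy(dtype=float)
    col_mean = np.nanmean(G, axis=0)
    inds = np.where(np.isnan(G))
    G = G.copy()
    G[inds] = np.take(col_mean, inds[1])
    col_sd = G.std(axis=0, ddof=1)
    col_sd[col_sd == 0] = 1.0
    Gz = (G - G.mean(axis=0)) / col_sd
    snp_index = {s: k for k, s in enumerate(genotypes.snp_ids)}

    causal_map: dict[str, list] = {c: [] for c in compounds}
    causal_snps: dict[str, list] = {c: [] for c in compounds}
    genetic = np.zeros((n, p))
    for j, cmp_id in enumerate(compounds):
        genes_j = []
        if hotspot_gene is not None and j < config.hotspot_metabolites:
            genes_j.append(hotspot_gene)
        if config.n_causal_per_metabolite > 0:
            pool = [g for g in mapped_genes if g not in genes_j]
            k = min(config.n_causal_per_metabolite, len(pool))
            genes_j.extend(rng.choice(pool, size=k, replace=False))
        for g in genes_j:
            snp = gene_snps[g][rng.integers(len(gene_snps[g]))]
            effect = config.effect_size * (1.0 if rng.random() < 0.5 else -1.0)
            genetic[:, j] += effect * Gz[:, snp_index[snp]]
            causal_map[cmp_id].append((g, effect))
            causal_snps[cmp_id].append(snp)

    omega, true_pcor = build_precision_matrix(
        p, config.network_edges, config.network_pcor, rng)
    cov = np.linalg.inv(omega)
    d = np.sqrt(np.diag(cov))
    cov = cov / np.outer(d, d)
    latent = rng.multivariate_normal(np.zeros(p), cov, size=n,
                                     method="cholesky")

    accession_value = genetic + latent
    sd = accession_value.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    if config.target_h2 >= 1.0:
        sigma_e = 0.0
        v_g = 1.0
    else:
        sigma_e = config.residual_sd
        v_g = config.target_h2 / (1.0 - config.target_h2) * sigma_e**2
    accession_value = accession_value / sd * np.sqrt(v_g)
    denom = v_g + sigma_e**2
    true_h2 = pd.Series(v_g / denom if denom > 0 else 0.0, index=compounds)

    # replicated design
    baseline = rng.normal(config.baseline_log2, config.baseline_sd, size=p)
    flat_of_rep = np.arange(config.n_replicates) % config.n_flats
    flat_eff = rng.normal(0.0, config.flat_sd, size=(config.n_flats, p))
    rep_eff = rng.normal(0.0, config.replicate_sd,
                         size=(config.n_flats, config.n_replicates, p))

    rows, meta_rows = [], []
    for r in range(config.n_replicates):
        f = flat_of_rep[r]
        for a, acc in enumerate(genotypes.accessions):
            y = (baseline + accession_value[a] + flat_eff[f] + rep_eff[f, r]
                 + rng.normal(0.0, sigma_e, size=p))
            rows.append(y)
            meta_rows.append((f"{experiment}_{acc}_r{r + 1}", acc, experiment,
                              f"F{f + 1}", r + 1))
    log2_values = np.asarray(rows)
    sample_ids = [m[0] for m in meta_rows]

    # run-date batches: samples processed in randomized order, global shift
    order = rng.permutation(len(sample_ids))
    batch_of = np.empty(len(sample_ids), dtype=int)
    for b, chunk in enumerate(np.array_split(order, config.n_run_batches)):
        batch_of[chunk] = b
    shifts = rng.normal(0.0, config.batch_shift_sd, size=config.n_run_batches)
    log2_values = log2_values + shifts[batch_of][:, None]

    counts = np.exp2(log2_values)
    if config.detection_limit > 0:
        counts[counts < config.detection_limit] = np.nan
    if config.missing_rate > 0:
        counts[rng.random(counts.shape) < config.missing_rate] = np.nan

    values = pd.DataFrame(counts, index=sample_ids, columns=compounds)
    meta = pd.DataFrame(
        {
            "accession": [m[1] for m in meta_rows],
            "experiment": [m[2] for m in meta_rows],
            "flat": [m[3] for m in meta_rows],
            "replicate": [m[4] for m in meta_rows],
            "run_date": [f"d{b + 1:02d}" for b in batch_of],
        },
        index=sample_ids,
    )
    panel = MetabolitePanel(values=values, meta=meta)

    known_genes = set(genotypes.genes["gene_id"])
    for cmp_id, entries in causal_map.items():
        for g, _ in entries:
            if g not in known_genes:
                raise ConfigError(f"causal gene {g} absent from the annotation")

    group = getattr(genotypes, "structure_groups", None)
    if group is None:
        group = pd.Series(0, index=genotypes.accessions, name="group")
    truth = SimulationTruth(
        causal_map=causal_map,
        hotspot_gene=hotspot_gene,
        true_h2=true_h2,
        true_partial_corr=pd.DataFrame(true_pcor, index=compounds,
                                       columns=compounds),
        group_assignment=group,
        causal_snps=causal_snps,
    )
    return panel, truth
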