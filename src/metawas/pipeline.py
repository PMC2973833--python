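"""Declarative end-to-end orchestration of the analysis stages.

Each stage reads its upstream outputs from the run directory, writes TSV
outputs plus a JSON manifest (parameters, input hashes, seed), and is
deterministic given config+seed, so deleting a stage's outputs and
re-running reproduces identical downstream files.

Stage order: simulate -> preprocess -> quantgen -> network -> gwas ->
genes -> hotspots -> ld -> enrich -> report.  A run can also start from an
externally supplied accession-means table in the wide supplementary-table
dialect (``network.means_files``), skipping simulate/preprocess/quantgen.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import genes_hotspots, gwas, io, ld, networks, preprocess, quantgen
from .datatypes import ConfigError, DataError
from .synthetic import SimulationConfig, simulate_genotypes, simulate_metabolome

STAGES = ["simulate", "preprocess", "quantgen", "network", "gwas", "genes",
          "hotspots", "ld", "enrich", "report"]

_DEFAULTS: dict = {
    "seed": 0,
    "simulate": {},
    "preprocess": {"within_accession_fraction": 0.5,
                   "predominant_fraction": 0.7, "sample_fraction": 0.5,
                   "target": 9.0},
    "quantgen": {"n_structure_groups": 8},
    "network": {"fdr_cutoff_strict": 0.05, "fdr_cutoff_lenient": 0.20,
                "means_files": None},
    "gwas": {"min_maf": 0.05, "q_cutoff": 0.20},
    "genes": {"min_snps": 2, "window": 1000},
    "hotspots": {"window_genes": 100, "n_perm": 10},
    "ld": {"r2_threshold": 0.4},
    "enrich": {"class_file": None, "alpha": 0.05},
}


def load_config(path) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    cfg = {k: (dict(v) if isinstance(v, dict) else v)
           for k, v in _DEFAULTS.items()}
    for key, value in user.items():
        if isinstance(value, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(value)
        else:
            cfg[key] = value
    for section in ("preprocess",):
        for name in ("within_accession_fraction", "predominant_fraction",
                     "sample_fraction"):
            frac = cfg[section][name]
            if not 0.0 <= frac <= 1.0:
                raise ConfigError(f"{section}.{name} must lie in [0, 1]")
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _require(run_dir: Path, files: list, upstream: str) -> None:
    missing = [f for f in files if not (run_dir / f).exists()]
    if missing:
        raise DataError(
            f"missing upstream outputs {missing}; run the {upstream!r} "
            "stage first")


def _manifest(run_dir: Path, stage: str, params: dict, inputs: list,
              outputs: list, seed: int) -> None:
    record = {
        "stage": stage,
        "seed": seed,
        "params": params,
        "inputs": {f: _sha256(run_dir / f) for f in inputs},
        "outputs": {f: _sha256(run_dir / f) for f in outputs},
    }
    with open(run_dir / f"manifest_{stage}.json", "w") as fh:
        json.dump(record, fh, indent=2, sort_keys=True)


def _experiments(run_dir: Path) -> list:
    return sorted(p.stem.split("panel_norm_")[1]
                  for p in run_dir.glob("panel_norm_*.tsv"))


def run_stage(stage: str, config: dict, run_dir) -> None:
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    if stage not in STAGES:
        raise ConfigError(f"unknown stage {stage!r}; expected one of {STAGES}")
    getattr(_Stages(config, run_dir), stage)()


class _Stages:
    def __init__(self, config: dict, run_dir: Path):
        self.cfg = config
        self.dir = run_dir
        self.seed = int(config.get("seed", 0))

    # -- simulate -----------------------------------------------------------
    def simulate(self) -> None:
        params = dict(self.cfg["simulate"])
        params.setdefault("seed", self.seed)
        sim = SimulationConfig(**params)
        gset = simulate_genotypes(sim)
        panel, truth = simulate_metabolome(gset, sim)
        io.write_genotypes_tsv(gset, self.dir / "genotypes.tsv")
        io.write_vcf(gset, self.dir / "genotypes.vcf")
        io.write_genes_bed(gset.genes, self.dir / "genes.bed")
        io.write_genes_gff3(gset.genes, self.dir / "genes.gff3")
        io.write_panel_long(panel, self.dir / "panel.tsv")
        io.write_truth(truth, self.dir / "truth.tsv")
        truth.group_assignment.rename("group").to_csv(
            self.dir / "structure_groups.tsv", sep="\t", index_label="accession")
        _manifest(self.dir, "simulate", asdict(sim), [],
                  ["genotypes.tsv", "genotypes.vcf", "genes.bed",
                   "genes.gff3", "panel.tsv", "truth.tsv",
                   "structure_groups.tsv"], self.seed)

    # -- preprocess -----------------------------------------------------------
    def preprocess(self) -> None:
        _require(self.dir, ["panel.tsv"], "simulate")
        params = self.cfg["preprocess"]
        panel = io.read_panel_long(self.dir / "panel.tsv")
        normalized = preprocess.preprocess_panel(panel, **params)
        outputs = []
        for label, sub in normalized.items():
            out = f"panel_norm_{label}.tsv"
            io.write_panel_long(sub, self.dir / out)
            outputs.append(out)
        _manifest(self.dir, "preprocess", dict(params), ["panel.tsv"],
                  outputs, self.seed)

    # -- quantgen -------------------------------------------------------------
    def quantgen(self) -> None:
        _require(self.dir, ["genotypes.tsv"], "simulate")
        exps = _experiments(self.dir)
        if not exps:
            raise DataError("missing upstream outputs ['panel_norm_*.tsv']; "
                            "run the 'preprocess' stage first")
        gset = io.read_genotypes_tsv(self.dir / "genotypes.tsv")
        K = gwas.kinship(gset)
        groups_file = self.dir / "structure_groups.tsv"
        if groups_file.exists():
            structure = pd.read_csv(groups_file, sep="\t",
                                    index_col="accession")["group"]
        else:
            structure = quantgen.derive_structure_groups(
                K, self.cfg["quantgen"]["n_structure_groups"])
        outputs = []
        for label in exps:
            panel = io.read_panel_long(self.dir / f"panel_norm_{label}.tsv")
            model = quantgen.HeritabilityModel(structure).fit(panel)
            model.table_.to_csv(self.dir / f"heritability_{label}.tsv", sep="\t")
            means = quantgen.estimate_accession_means(panel)
            io.write_means_wide(means, self.dir / f"means_{label}.tsv")
            cv = quantgen.genetic_cv(means)
            cv.to_csv(self.dir / f"cv_{label}.tsv", sep="\t",
                      index_label="compound_id")
            outputs += [f"heritability_{label}.tsv", f"means_{label}.tsv",
                        f"cv_{label}.tsv"]
        _manifest(self.dir, "quantgen", dict(self.cfg["quantgen"]),
                  ["genotypes.tsv"] + [f"panel_norm_{e}.tsv" for e in exps],
                  outputs, self.seed)

    def _means_tables(self) -> dict:
        files = self.cfg["network"].get("means_files")
        if files:
            return {label: io.read_means_wide(path)
                    for label, path in files.items()}
        tables = {}
        for p in sorted(self.dir.glob("means_*.tsv")):
            label = p.stem.split("means_")[1]
            tables[label] = io.read_means_wide(p)
        if not tables:
            raise DataError("missing upstream outputs ['means_*.tsv']; run "
                            "the 'quantgen' stage first or set "
                            "network.means_files")
        return tables

    # -- network ----------------------------------------------------------
    def network(self) -> None:
        params = self.cfg["network"]
        outputs, summaries = [], []
        for label, means in self._means_tables().items():
            edges = networks.network_edges(means)
            io.write_edges_tsv(edges, self.dir / f"edges_{label}.tsv")
            io.write_edges_graphml(edges, self.dir / f"edges_{label}.graphml",
                                   fdr_cutoff=params["fdr_cutoff_lenient"])
            for name, cutoff in (("strict", params["fdr_cutoff_strict"]),
                                 ("lenient", params["fdr_cutoff_lenient"])):
                summary, _ = networks.build_network(edges, cutoff)
                summaries.append({
                    "experiment": label, "cutoff": cutoff, "name": name,
                    "n_nodes": summary.n_nodes, "n_edges": summary.n_edges,
                    "average_degree": summary.average_degree,
                })
            outputs += [f"edges_{label}.tsv", f"edges_{label}.graphml"]
        pd.DataFrame(summaries).to_csv(self.dir / "network_summary.tsv",
                                       sep="\t", index=False)
        outputs.append("network_summary.tsv")
        _manifest(self.dir, "network",
                  {k: v for k, v in params.items() if k != "means_files"},
                  [], outputs, self.seed)

    # -- gwas -------------------------------------------------------------
    def gwas(self) -> None:
        _require(self.dir, ["genotypes.tsv"], "simulate")
        params = self.cfg["gwas"]
        gset = io.read_genotypes_tsv(self.dir / "genotypes.tsv")
        gset = gwas.maf_filter(gset, params["min_maf"])
        K = gwas.kinship(gset)
        outputs = []
        for label, means in self._means_tables().items():
            assoc = gwas.scan_all(means, gset, K)
            assoc.to_csv(self.dir / f"assoc_{label}.tsv", sep="\t", index=False)
            outputs.append(f"assoc_{label}.tsv")
        _manifest(self.dir, "gwas", dict(params), ["genotypes.tsv"],
                  outputs, self.seed)

    def _gene_models(self) -> pd.DataFrame:
        _require(self.dir, ["genes.bed"], "simulate")
        return io.read_genes_bed(self.dir / "genes.bed")

    # -- genes ------------------------------------------------------------
    def genes(self) -> None:
        params = self.cfg["genes"]
        genes = self._gene_models()
        gset = io.read_genotypes_tsv(self.dir / "genotypes.tsv", genes=genes)
        snp_gene = genes_hotspots.assign_snps_to_genes(
            gset.snps, genes, window=params["window"])
        outputs = []
        for p in sorted(self.dir.glob("assoc_*.tsv")):
            label = p.stem.split("assoc_")[1]
            assoc = pd.read_csv(p, sep="\t")
            cands = genes_hotspots.call_candidate_genes(
                assoc, snp_gene, self.cfg["gwas"]["q_cutoff"],
                params["min_snps"])
            cands.to_csv(self.dir / f"candidates_{label}.tsv", sep="\t",
                         index=False)
            outputs.append(f"candidates_{label}.tsv")
        if not outputs:
            raise DataError("missing upstream outputs ['assoc_*.tsv']; run "
                            "the 'gwas' stage first")
        _manifest(self.dir, "genes", dict(params), ["genes.bed"],
                  outputs, self.seed)

    # -- hotspots -----------------------------------------------------------
    def hotspots(self) -> None:
        params = self.cfg["hotspots"]
        genes = self._gene_models()
        gset = io.read_genotypes_tsv(self.dir / "genotypes.tsv", genes=genes)
        gset = gwas.maf_filter(gset, self.cfg["gwas"]["min_maf"])
        K = gwas.kinship(gset)
        snp_gene = genes_hotspots.assign_snps_to_genes(
            gset.snps, genes, window=self.cfg["genes"]["window"])
        outputs = []
        for label, means in self._means_tables().items():
            cand_file = self.dir / f"candidates_{label}.tsv"
            if not cand_file.exists():
                raise DataError(f"missing upstream outputs "
                                f"['candidates_{label}.tsv']; run the "
                                "'genes' stage first")
            cands = pd.read_csv(cand_file, sep="\t")
            null = genes_hotspots.permutation_null(
                means, gset, K, n_perm=params["n_perm"],
                q_cutoff=self.cfg["gwas"]["q_cutoff"],
                min_snps=self.cfg["genes"]["min_snps"],
                window_genes=params["window_genes"],
                snp_gene_map=snp_gene, seed=self.seed)
            spots = genes_hotspots.sliding_hotspots(
                cands, genes, window_genes=params["window_genes"],
                null_max=null["null_max"])
            rows = [{"chrom": h.chrom, "start": h.start, "end": h.end,
                     "n_genes": len(h.gene_ids),
                     "mean_compounds": h.mean_compounds,
                     "gene_ids": ",".join(map(str, h.gene_ids))}
                    for h in spots]
            df = pd.DataFrame(rows, columns=["chrom", "start", "end",
                                             "n_genes", "mean_compounds",
                                             "gene_ids"])
            df.to_csv(self.dir / f"hotspots_{label}.tsv", sep="\t", index=False)
            with open(self.dir / f"hotspots_{label}.bed", "w") as fh:
                for _, r in df.iterrows():
                    fh.write(f"{r['chrom']}\t{r['start'] - 1}\t{r['end']}\t"
                             f"hotspot\n")
            with open(self.dir / f"hotspot_null_{label}.json", "w") as fh:
                json.dump({k: v for k, v in null.items()
                           if k != "genes_per_metabolite"}, fh, indent=2)
            outputs += [f"hotspots_{label}.tsv", f"hotspots_{label}.bed",
                        f"hotspot_null_{label}.json"]
        _manifest(self.dir, "hotspots", dict(params), ["genes.bed"],
                  outputs, self.seed)

    # -- ld ---------------------------------------------------------------
    def ld(self) -> None:
        params = self.cfg["ld"]
        genes = self._gene_models()
        gset = io.read_genotypes_tsv(self.dir / "genotypes.tsv", genes=genes)
        snp_gene = genes_hotspots.assign_snps_to_genes(
            gset.snps, genes, window=self.cfg["genes"]["window"])
        gene_snps: dict = {}
        for snp, gs in snp_gene.items():
            for g in gs:
                gene_snps.setdefault(g, []).append(snp)
        outputs = []
        for p in sorted(self.dir.glob("candidates_*.tsv")):
            label = p.stem.split("candidates_")[1]
            cands = pd.read_csv(p, sep="\t")
            needed = {g: gene_snps[g] for g in set(cands["gene_id"])
                      if g in gene_snps}
            collapsed = ld._collapse_many(gset, needed)
            screen = ld.nonsyntenic_ld_screen(cands, collapsed, genes,
                                              params["r2_threshold"])
            screen["pairs_above_threshold"].to_csv(
                self.dir / f"nonsyntenic_{label}.tsv", sep="\t", index=False)
            with open(self.dir / f"nonsyntenic_{label}.json", "w") as fh:
                json.dump({"percentile_99": screen["percentile_99"],
                           "max": screen["max"],
                           "n_pairs": int(len(screen["all_nonsyntenic_r2"]))},
                          fh, indent=2)
            outputs += [f"nonsyntenic_{label}.tsv", f"nonsyntenic_{label}.json"]
        if not outputs:
            raise DataError("missing upstream outputs ['candidates_*.tsv']; "
                            "run the 'genes' stage first")
        _manifest(self.dir, "ld", dict(params), ["genes.bed"],
                  outputs, self.seed)

    # -- enrich -------------------------------------------------------------
    def enrich(self) -> None:
        from . import classstats

        params = self.cfg["enrich"]
        outputs = []
        for p in sorted(self.dir.glob("candidates_*.tsv")):
            label = p.stem.split("candidates_")[1]
            cands = pd.read_csv(p, sep="\t")
            means_file = self.dir / f"means_{label}.tsv"
            if means_file.exists():
                universe = list(io.read_means_wide(means_file).index)
            else:
                universe = sorted(set(cands["compound_id"]))
            if params.get("class_file"):
                ann = classstats.read_annotation_map(params["class_file"])
                enr = classstats.class_enrichment(cands, ann, universe)
            else:
                enr = pd.DataFrame(
                    columns=["n_class", "observed", "expected", "chi2", "p",
                             "reliable"])
            enr.to_csv(self.dir / f"enrichment_{label}.tsv", sep="\t")
            outputs.append(f"enrichment_{label}.tsv")
        if not outputs:
            raise DataError("missing upstream outputs ['candidates_*.tsv']; "
                            "run the 'genes' stage first")
        _manifest(self.dir, "enrich",
                  {k: v for k, v in params.items()}, [], outputs, self.seed)

    # -- report -------------------------------------------------------------
    def report(self) -> None:
        lines = ["metawas run report", "=" * 40]
        incomplete = []
        for p in sorted(self.dir.glob("candidates_*.tsv")):
            label = p.stem.split("candidates_")[1]
            cands = pd.read_csv(p, sep="\t")
            lines.append(f"\nExperiment {label}:")
            lines.append(f"  candidate gene-metabolite links: {len(cands)}")
            if len(cands):
                genes_per_met = cands.groupby("compound_id")["gene_id"].nunique()
                mets_per_gene = cands.groupby("gene_id")["compound_id"].nunique()
            else:
                genes_per_met = pd.Series(dtype=int)
                mets_per_gene = pd.Series(dtype=int)
            lines.append("  metabolites by number of associated genes:")
            hist_g = genes_per_met.value_counts().sort_index()
            total_links_g = int((hist_g.index * hist_g).sum()) if len(hist_g) else 0
            for k, v in hist_g.items():
                lines.append(f"    {k} genes: {v} metabolites")
            lines.append("  genes by number of associated metabolites:")
            hist_m = mets_per_gene.value_counts().sort_index()
            for k, v in hist_m.items():
                lines.append(f"    {k} metabolites: {v} genes")
            lines.append(f"  total links (conserved across both views): "
                         f"{total_links_g}")
            hs = self.dir / f"hotspots_{label}.tsv"
            if hs.exists():
                spots = pd.read_csv(hs, sep="\t")
                lines.append(f"  hotspots: {len(spots)}")
                for _, r in spots.iterrows():
                    lines.append(f"    chr{r['chrom']}:{r['start']}-{r['end']}"
                                 f" ({r['n_genes']} genes, "
                                 f"{r['mean_compounds']:.2f} compounds/gene)")
            else:
                incomplete.append(f"hotspots_{label}.tsv")
        ns = self.dir / "network_summary.tsv"
        if ns.exists():
            lines.append("\nNetwork summaries:")
            lines.append(pd.read_csv(ns, sep="\t").to_string(index=False))
        else:
            incomplete.append("network_summary.tsv")
        if incomplete:
            lines.append("\nWARNING: incomplete run; missing: "
                         + ", ".join(incomplete))
        (self.dir / "report.txt").write_text("\n".join(lines) + "\n")
        _manifest(self.dir, "report", {}, [], ["report.txt"], self.seed)
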