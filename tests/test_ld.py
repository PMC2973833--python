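import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from metawas.datatypes import DataError, GenotypeSet
from metawas.ld import (average_max_r2, collapse_gene,
                        hotspot_genome_ld_profile, nonsyntenic_ld_screen, r2)


def _gset(matrix, chrom=None):
    matrix = pd.DataFrame(matrix, dtype=float)
    matrix.index = [f"a{i}" for i in range(matrix.shape[0])]
    matrix.columns = [f"{(chrom or [1]*matrix.shape[1])[j]}:{j + 1}"
                      for j in range(matrix.shape[1])]
    snps = pd.DataFrame({
        "chrom": chrom or [1] * matrix.shape[1],
        "pos": range(1, matrix.shape[1] + 1),
    }, index=matrix.columns)
    return GenotypeSet(matrix=matrix, snps=snps)


# --- collapse --------------------------------------------------------------

def test_single_snp_gene_collapse_is_relabelled_genotype():
    g = _gset([[0], [1], [1], [0]])
    locus = collapse_gene(g, ["1:1"], "g")
    # major haplotype is "0" or "1" by frequency; here tie -> lexicographic "0"
    assert list(locus.alleles) == [0, 1, 1, 0]
    assert locus.major_haplotype == "0"


def test_collapse_hand_tally():
    # haplotypes over 2 SNPs: 00 x4, 01 x3, 11 x1
    rows = [[0, 0]] * 4 + [[0, 1]] * 3 + [[1, 1]]
    locus = collapse_gene(_gset(rows), ["1:1", "1:2"], "g")
    assert locus.major_haplotype == "00"
    assert list(locus.alleles) == [0, 0, 0, 0, 1, 1, 1, 1]
    assert locus.major_frequency == pytest.approx(0.5)


def test_collapse_tie_break_deterministic():
    rows = [[0, 0]] * 3 + [[1, 1]] * 3 + [[0, 1]] * 2
    l1 = collapse_gene(_gset(rows), ["1:1", "1:2"], "g")
    l2 = collapse_gene(_gset(rows), ["1:1", "1:2"], "g")
    assert l1.major_haplotype == "00"            # lexicographically smallest
    assert list(l1.alleles) == list(l2.alleles)


def test_collapse_drops_accessions_with_missing_and_errors_when_all_missing():
    rows = np.array([[0, 0], [1, np.nan], [1, 1]])
    locus = collapse_gene(_gset(rows), ["1:1", "1:2"], "g")
    assert list(locus.alleles.index) == ["a0", "a2"]
    with pytest.raises(DataError, match="missing"):
        collapse_gene(_gset(np.full((3, 1), np.nan)), ["1:1"], "g")


# --- r2 --------------------------------------------------------------------

def test_r2_identical_complement_independent():
    a = np.array([0, 0, 1, 1], dtype=float)
    b = np.array([0, 1, 0, 1], dtype=float)
    assert r2(a, a) == pytest.approx(1.0)
    assert r2(a, 1 - a) == pytest.approx(1.0)     # label swap irrelevant
    assert r2(a, b) == pytest.approx(0.0)         # hand computation
    assert np.isnan(r2(np.zeros(4), a))           # monomorphic


@settings(max_examples=50, deadline=None)
@given(st.integers(0, 2**32 - 1))
def test_r2_invariances_on_random_instances(seed):
    rng = np.random.default_rng(seed)
    n = 30
    a = (rng.random(n) < rng.uniform(0.2, 0.8)).astype(float)
    b = (rng.random(n) < rng.uniform(0.2, 0.8)).astype(float)
    base = r2(a, b)
    if np.isnan(base):
        return
    assert r2(1 - a, b) == pytest.approx(base, abs=1e-12)
    assert r2(a, 1 - b) == pytest.approx(base, abs=1e-12)
    assert r2(b, a) == pytest.approx(base, abs=1e-12)
    perm = rng.permutation(n)
    assert r2(a[perm], b[perm]) == pytest.approx(base, abs=1e-12)
    assert 0.0 <= base <= 1.0 + 1e-12


# --- average maximum SNP-SNP r2 -------------------------------------------

def test_average_max_r2_toy_brute_force():
    rng = np.random.default_rng(3)
    ga = pd.DataFrame((rng.random((40, 2)) < 0.5).astype(float))
    gb = pd.DataFrame((rng.random((40, 3)) < 0.5).astype(float))
    stat = average_max_r2(ga, gb)
    mat = np.array([[r2(ga.iloc[:, i], gb.iloc[:, j]) for j in range(3)]
                    for i in range(2)])
    brute = (np.nanmax(mat, axis=1).mean() + np.nanmax(mat, axis=0).mean()) / 2
    assert stat == pytest.approx(brute, abs=1e-12)


def test_average_max_r2_self_and_single_snp():
    rng = np.random.default_rng(4)
    g1 = pd.DataFrame((rng.random((50, 3)) < 0.5).astype(float))
    assert average_max_r2(g1, g1) == pytest.approx(1.0)
    a = pd.DataFrame((rng.random((50, 1)) < 0.5).astype(float))
    b = pd.DataFrame((rng.random((50, 1)) < 0.5).astype(float))
    assert average_max_r2(a, b) == pytest.approx(
        r2(a.iloc[:, 0], b.iloc[:, 0]))


def test_average_max_dominates_plain_average():
    rng = np.random.default_rng(5)
    for _ in range(10):
        ga = pd.DataFrame((rng.random((40, 3)) < 0.5).astype(float))
        gb = pd.DataFrame((rng.random((40, 4)) < 0.5).astype(float))
        mat = np.array([[r2(ga.iloc[:, i], gb.iloc[:, j]) for j in range(4)]
                        for i in range(3)])
        if np.isnan(mat).any():
            continue
        assert average_max_r2(ga, gb) >= np.nanmean(mat) - 1e-12


def test_average_max_r2_symmetric_and_bounded():
    rng = np.random.default_rng(6)
    ga = pd.DataFrame((rng.random((30, 2)) < 0.5).astype(float))
    gb = pd.DataFrame((rng.random((30, 5)) < 0.5).astype(float))
    ab = average_max_r2(ga, gb)
    ba = average_max_r2(gb, ga)
    assert ab == pytest.approx(ba)
    assert 0.0 <= ab <= 1.0


# --- trans-LD screen -------------------------------------------------------

def test_nonsyntenic_screen_planted_pair_recovered():
    rng = np.random.default_rng(7)
    n = 96
    base = (rng.random(n) < 0.5).astype(float)
    noisy = base.copy()
    flip = rng.random(n) < 0.05
    noisy[flip] = 1 - noisy[flip]                 # planted trans-LD, 5% noise
    other = (rng.random(n) < 0.5).astype(float)
    matrix = np.column_stack([base, noisy, other])
    g = _gset(matrix, chrom=[1, 2, 2])
    genes = pd.DataFrame({
        "gene_id": ["gA", "gB", "gC"], "chrom": [1, 2, 2],
        "start": [1, 1, 10], "end": [5, 5, 15],
    })
    from metawas.ld import _collapse_many
    collapsed = _collapse_many(
        GenotypeSet(matrix=g.matrix, snps=g.snps, genes=genes),
        {"gA": ["1:1"], "gB": ["2:2"], "gC": ["2:3"]})
    cands = pd.DataFrame({
        "gene_id": ["gA", "gB", "gC"],
        "compound_id": ["m1", "m1", "m1"],
        "n_significant_snps": 2, "min_q": 0.01,
    })
    res = nonsyntenic_ld_screen(cands, collapsed, genes, r2_threshold=0.4)
    pairs = set(map(tuple,
                    res["pairs_above_threshold"][["gene_1", "gene_2"]]
                    .to_numpy()))
    assert ("gA", "gB") in pairs
    assert ("gA", "gC") not in pairs
    assert res["max"] >= res["percentile_99"]


def test_nonsyntenic_screen_empty_without_cross_chromosome_pairs():
    genes = pd.DataFrame({"gene_id": ["gA", "gB"], "chrom": [1, 1],
                          "start": [1, 10], "end": [5, 15]})
    cands = pd.DataFrame({"gene_id": ["gA", "gB"],
                          "compound_id": ["m1", "m1"],
                          "n_significant_snps": 2, "min_q": 0.01})
    res = nonsyntenic_ld_screen(cands, {}, genes)
    assert len(res["pairs_above_threshold"]) == 0


def test_hotspot_profile_cutoff_recomputed_from_data():
    rng = np.random.default_rng(8)
    matrix = (rng.random((60, 6)) < 0.5).astype(float)
    g = _gset(matrix, chrom=[1, 1, 1, 2, 2, 2])
    gene_snps = {"h1": ["1:1", "1:2"], "x1": ["1:3"],
                 "x2": ["2:4", "2:5"], "x3": ["2:6"]}
    g.genes = pd.DataFrame({"gene_id": ["h1", "x1", "x2", "x3"],
                            "chrom": [1, 1, 2, 2],
                            "start": [1, 3, 4, 6], "end": [2, 3, 5, 6]})
    res = hotspot_genome_ld_profile(["h1"], ["x1", "x2", "x3"], g, gene_snps)
    cross = [res["profile"].loc["h1", "x2"], res["profile"].loc["h1", "x3"]]
    assert res["cutoff"] == pytest.approx(np.mean(cross))
    assert res["significant"].shape == (1, 3)
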