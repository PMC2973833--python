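# Methods

This note documents the models, the defaults and why they were chosen, the
numerical decisions, what the synthetic-data generator does and does not
emulate, and the known limitations.  It states nothing the test suite or
`scripts/acceptance.py` does not itself compute.

## Study design assumed by the pipeline

The unit of genetic replication is the inbred accession: a panel of N
accessions (defaults emulate N = 96 in ~8 population-structure groups),
each grown with r replicate plants (default 4) split across planting flats
(default 2), profiled by GC-MS in run-date batches.  Accessions are fully
homozygous, so genotypes are haploid 0/1 vectors and a single allele per
locus carries the genotype.  All phenotype modelling happens on the log2
ion-count scale.

## Preprocessing

Detection means a non-missing, strictly positive ion count.  Three steps,
applied independently per experiment and in this fixed order:

1. **Compound presence** — keep a compound iff some accession detects it in
   strictly more than `within_accession_fraction` (default 0.5) of that
   accession's samples.  The boundary is strict: exactly half does not
   qualify.
2. **Sample coverage** — compute the predominant set (compounds detected in
   ≥ 0.7 of all samples; boundary inclusive) and keep samples detecting
   ≥ 0.5 of it.  An empty predominant set keeps all samples with a warning.
   Whether the predominant set should be computed before or after the
   compound filter is genuinely open; the default is after (the compound
   filter removes artefacts that would otherwise dilute the predominant
   set), with `predominant_before_compound_filter` to flip.
3. **Normalization** — value ← log2(count) − median(batch) + 9, where the
   batch median pools all values sharing a run date.  This makes each
   batch's median exactly 9 log2 units and removes any multiplicative
   per-batch sensitivity shift exactly.  Nonpositive counts are an error
   naming the sample and compound, not silently dropped.

Filters are idempotent and the pipeline fixes the order compounds → samples
→ normalization.

## Heritability and accession means

Per compound the fixed-effects model

    y ~ mu + S + F + A(S) + R(F) + eps

is fitted by least squares on orthonormal (SVD) bases, with the type-II sum
of squares of A(S) obtained by comparing the full model against the model
without A(S).  The reported SS table is the sequential (type-I)
decomposition in the order S, F, A(S), R(F), so term SS plus residual SS
equals the corrected total exactly; on balanced designs the type-I and
type-II A(S) terms coincide (unit-tested).

Two heritability statistics are reported:

* `h2` (primary): the expected-mean-squares variance-component estimator,
  σ²_A = max(0, (MS_A − MS_ε)/r̄) with r̄ the mean number of samples per
  accession, H² = σ²_A/(σ²_A + σ²_ε), clipped to [0, 1].
* `h2_ss_ratio`: the type-II SS of A(S) over the corrected total SS.

The ratio form is reported because it is the most literal reading of
"heritability from the A(S) sum of squares", but it is structurally biased
upward at low heritability: with 96 accessions and 4 replicates the ~95
accession degrees of freedom absorb roughly a quarter of pure residual
variation, inflating a true H² of 0.2 to ≈ 0.34.  The variance-component
form removes exactly that bias (recovery within ±0.02 at targets 0.2,
0.45 and 0.8 in the acceptance benchmark) and is therefore primary.
A second, smaller bias affects both forms: genetic variance *between*
structure groups is credited to S, not A(S), so strongly structured causal
architectures deflate H² slightly.

Accession means use the same model without S (structure is deliberately
left in the means because the association scan corrects for it through the
kinship matrix), with full accession dummies and sum-to-zero contrasts on
flat and replicate-in-flat, so the coefficients are directly comparable
adjusted means; on balanced designs they equal raw accession averages.
Genetic CV is the sample standard deviation over the mean of the accession
means, computed on the scale of the input table by default (the log2
scale after normalization); `exponentiate=True` back-transforms to the
count scale first.  CV is scale-dependent — on log2 values anchored at 9
units, typical CVs are a few percent; on back-transformed counts they are
tens of percent — which is why the package never treats a CV level as a
target, only CV comparisons.

Structure groups are an input mapping; when absent, a helper derives them
by average-linkage hierarchical clustering of 1 − kinship.  At divergence
(Fst) 0.2 with ≥ 2,000 SNPs the recovered partition matches the planted
one (> 0.9 purity); at 0.1 the groups are genuinely not separable from 96
accessions and the clustering is only a rough proxy.

## Metabolite networks

Zero-order: Spearman ρ across accessions on pairwise-complete values, with
p-values from t = ρ·√((n−2)/(1−ρ²)) on n−2 df (n the per-pair complete
count; pairs with n < 4 are NA).

Partial: the Schäfer–Strimmer shrinkage estimator.  Columns are
standardized, the correlation matrix R estimated pairwise-complete, and
the shrinkage intensity chosen analytically as λ* = Σ V̂ar(r_ij) / Σ r_ij²
(off-diagonal sums, clipped to [0, 1]); partial correlations are
−Ω_ij/√(Ω_ii Ω_jj) for Ω = (λI + (1−λ)R)⁻¹.  The shrunk matrix is positive
definite for λ > 0, so the inverse always exists.  At λ = 0 on a
well-conditioned problem this equals the classical inverse-correlation
partial correlation to numerical precision (oracle-tested at 1e−10).
Compounds that are constant or observed in fewer than half the accessions
are excluded with a warning.  The estimator conditions on *all* remaining
compounds; a true first-order mode (single conditioning variable, minimum
magnitude over conditioners) is available via `order="first"` for
sensitivity analysis.

Local FDR: the statistic vector (default: the partial correlations) is
modelled as η₀·f₀(x; κ) + (1−η₀)·f_A(x) with f₀ the null density of a
sample correlation with κ effective degrees of freedom,
f₀(r) ∝ (1−r²)^((κ−3)/2).  κ is fit by censored maximum likelihood on the
central 75% of |x| (the censoring quantile is a tunable constant; 0.75
keeps the alternative tail out of the null fit across the regimes
exercised here), η₀ follows as the inside-fraction over the null inside
probability, clipped to [0, 1].  The mixture density of |x| is the
Grenander estimator (slopes of the least concave majorant of the empirical
CDF, computed by pool-adjacent-violators).  fdr(x) = clip(η₀·f₀/f, 0, 1)
is then made monotone non-increasing in |x| by an isotonic least-squares
pass — a smoother correction than a running minimum, which creates large
tie blocks that degrade edge ranking.  Degenerate inputs (all statistics
equal) return fdr ≡ 1 with a warning; below 50 statistics a warning flags
instability.

Network summaries (nodes incident to retained edges, average degree k,
clustering by degree C(k), degree distribution P(k)) are computed with
networkx.  Network comparison reports shared unordered edges and per-edge
sign agreement; connectivity differences (average degree, transitivity)
are tested by pooling the two edge sets and permuting network membership
with per-network edge counts fixed, and degree distributions by a
two-sample KS test.  A node-label permutation was considered and rejected:
relabelling produces an isomorphic graph, leaving every connectivity
statistic unchanged, so it cannot generate a null distribution.

## Association scans

Kinship is identity-by-state allele sharing over non-missing SNPs — for
homozygous panels, the fraction of SNPs with equal alleles; it is PSD by
construction up to missing-data perturbations, and the scan verifies PSD
within tolerance.  SNPs are MAF-filtered (strictly > 0.05 by default);
missing genotypes are mean-imputed per SNP for the scan only.

Per trait, δ = σ²_e/σ²_g is estimated by maximum likelihood (not REML)
under the null model: one eigendecomposition of K, profile likelihood on a
100-point grid over log δ ∈ [−10, 10], refined by bounded scalar
minimization in the bracketing interval; an assertion guarantees the
refined optimum dominates every grid point.  The fitted variance
components are then fixed and every SNP tested by a GLS F-test with
(1, N−2) df on whitened data — the standard population-parameters-
previously-determined approximation, chosen because per-SNP variance
re-estimation at 10⁵–10⁶ (SNP × trait) scale is infeasible and changes
little at these panel sizes (a `per_snp_variance=True` exact mode exists
for small panels).  With K = I the scan reduces exactly to ordinary least
squares (tested at 1e−8).  Monomorphic or collinear SNPs get p = 1.

Q-values are computed per metabolite (each scan is its own multiplicity
family): π₀ from the Storey smoother (cubic fit of π₀(λ) over
λ = 0.05…0.95, evaluated at 0.95, clipped to (0, 1]), then the usual
step-up q = min cumulative π₀·m·p/rank.  Below 20 p-values the estimator
falls back to Benjamini–Hochberg (π₀ = 1) with a warning.  The default
significance threshold for candidate calling is q < 0.20; the stricter
0.05 used in parts of the original analysis is exposed in config.

## Candidate genes and hotspots

SNPs map to genes within a 1 kb window, 1-based inclusive on both ends; a
SNP may map to several genes.  A (gene, metabolite) link needs ≥ 2 distinct
significant SNPs; candidate sets are monotone in both thresholds (tested).

Hotspots: per-gene counts of distinct associated compounds → sliding
window averages (window 100 genes by default, step 1, windows never span
chromosome boundaries — a hotspot is a physical region; short chromosomes
truncate the window with a warning).  The window average is assigned to
every gene in the window and a gene passes if any covering window exceeds
the null maximum.  The null maximum is the largest sliding average
observed when accession labels are shuffled independently within each
compound and the entire scan → candidates → sliding-average chain is
re-run (the permutation and the observed data share one code path; the
identity permutation reproduces the observed statistics exactly).  Passing
genes with no passing immediate neighbour are dropped; maximal runs of the
survivors form intervals, retained iff they average more than two
compounds per gene, or contain at least eight genes averaging more than
one.  All retention comparisons are strict.

The scaled benchmark (96 accessions × 2,000 SNPs, ~135 genes, 30
metabolites of which 12 share one planted gene) uses a 5-gene window —
with ~27 genes per chromosome a 100-gene window would smooth the entire
chromosome into one value — and 2 permutations per run for the threshold.
Under those conditions the planted gene is recovered in ≥ 90% of runs and
shuffled data yield essentially zero hotspots.

## Linkage disequilibrium

Genes collapse to biallelic loci on their empirical SNP haplotypes; the
most frequent haplotype is the major allele, ties break to the
lexicographically smallest string (deterministic), and accessions with any
missing SNP in the gene are dropped rather than imputed into fabricated
haplotypes.  r² is the squared Pearson correlation of binary allele
vectors over shared non-missing accessions, invariant to allele relabeling
and accession reordering (property-tested); monomorphic input is NA.

The trans-LD screen takes gene pairs co-associated with the same compound
on different chromosomes and reports pairs with collapsed-locus r² above
the threshold (default 0.4) together with the 99th percentile and maximum
of all non-syntenic r².  The gene–genome profile uses the
average-maximum statistic: all SNP-pair r² between two genes, the per-SNP
maximum taken from each gene's side, and the two side-wise means averaged;
a gene paired with itself scores exactly 1 and two single-SNP genes reduce
to their plain r².  The significance cutoff is always the mean of the
statistic over all different-chromosome gene pairs in the data at hand —
recomputed, never hard-coded, because it depends on panel structure.  The
statistic is biased upward by the per-SNP maxima; no correction is applied
(none is defined), so its cutoff is interpreted relative to the same
statistic's genome background, not as an absolute LD level.

## Class and pathway statistics

Differential abundance between two experiments: paired t-tests across
accessions (the accession is the pairing unit — the only index shared by
the two experiments), Bonferroni over the shared compounds, and a
differential flag that requires both adjusted p < 0.05 and more than
two-fold difference.  Fold difference is 2^(mean log2 difference) — the
ratio of geometric means, the natural choice on log-normalized data.
Class enrichment is Pearson's χ² (1 df, no continuity correction) on the
2×2 table of class membership × association status; classes with any
expected cell below 1 are flagged unreliable but still reported.  The
gene-sharing analysis counts genes hit by ≥ 2 compounds of a group and
compares the group's per-gene association-count distribution against the
all-compound distribution (χ² over count bins 1, 2, ≥ 3).

## The synthetic-data generator

What it emulates: inbred haploid 0/1 genotypes; population structure from
a two-level Balding–Nichols model with a single Fst-like divergence
parameter (default 0.1; the mixed-model calibration benchmark uses 0.2);
LD blocks via per-block allele frequencies plus a shared latent uniform
per (accession, block) that each SNP reuses with probability 0.9 — this
preserves every SNP's marginal group frequency (hence the realized Fst)
while making block-mates strongly correlated, with a small per-SNP
frequency jitter (sd 0.05) keeping loci distinct; genes tiled along
chromosomes; metabolites whose accession-level values combine planted
causal-SNP effects (genes chosen from those with mapped SNPs; one causal
SNP per gene; signed effects in accession-sd units), an optional
pleiotropic hotspot gene shared by m metabolites, and a latent Gaussian
graphical component drawn from a sparse precision matrix (degree ≤ 2 so
chains exist, eigenvalue-checked, true partial correlations recorded in
the ledger); the accession-level signal rescaled so its variance fraction
equals `target_h2` (default 0.45, the regime the heritability benchmark
targets); replicate-level noise from per-compound flat effects (sd 0.15),
replicate-in-flat effects (sd 0.1), a global per-run-batch shift (sd 0.2,
removed exactly by median normalization), and Gaussian residuals (sd 0.5
log2 units); exponentiation to counts with an optional detection floor
that records low counts as missing.

What it does not emulate: realistic recombination maps or demography,
allele-frequency spectra of real resequencing data, selective sweeps,
epistasis, dominance (meaningless in haploids), correlated missingness,
heteroskedastic measurement error, or retention-time/annotation artefacts
upstream of the ion-count table.  Passing parameter-recovery tests
therefore demonstrates the estimators are correct under the assumed
generative structure — not that real data satisfy that structure.

## Numerical choices and degenerate inputs

* Least-squares bases via SVD (rank-revealing); rank-deficient designs
  (e.g. one replicate per accession) yield NA heritability with a warning.
* Mixed-model eigenvalues clipped at 1e−10; non-PSD kinship beyond −1e−6
  is an error, not a silent fix.
* Monomorphic SNPs: p = 1 in scans, NA in r².
* Haplotype-frequency ties: lexicographic; all retention thresholds
  strict; q-values clipped to [0, 1] and monotone by construction.
* Seeds: every stochastic routine takes an explicit seed; the pipeline
  derives all stage seeds from one config seed, and identical config+seed
  reproduce byte-identical outputs (manifest-hash tested).

## Limitations

* The local-FDR null fit uses a fixed censoring quantile rather than the
  adaptive cutoff search of the reference R implementation; η₀ estimates
  are accurate in the exercised regimes (±0.05) but can drift for very
  dense alternatives.
* The hotspot retention constants (2 compounds/gene; 8 genes at 1) are
  tuned to genome-scale windows; scaled simulations must scale the window,
  as the benchmark does.
* `hotspot_genome_ld_profile` is quadratic in SNPs per gene pair and meant
  for hotspot-gene × genome slices, not all-pairs genome LD.
* Network comparison assumes both edge tables derive from comparable
  compound universes; sign agreement is only evaluated on shared edges.
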