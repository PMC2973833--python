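"""Kinship-corrected single-SNP mixed-model association scans.

Per metabolite, accession means y are modelled as

    y = mu + x_s * beta + u + eps,   u ~ N(0, sigma_g^2 K),  eps ~ N(0, sigma_e^2 I)

with K the identity-by-state kinship matrix.  The variance ratio
delta = sigma_e^2 / sigma_g^2 is estimated once per trait by maximum
likelihood under the null (no-SNP) model — one spectral decomposition of K,
a grid search over log delta in [-10, 10] refined numerically — and reused
for every SNP, whose fixed effect is then tested with a generalized
least-squares F-test on (1, N-2) degrees of freedom.  A per-SNP exact mode
(re-estimating delta under each SNP model) is available for small panels.

Multiplicity is controlled per metabolite with Storey q-values (pi0 from
the smoother over a lambda grid).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .datatypes import DataError, GenotypeSet

__all__ = [
    "maf_filter",
    "kinship",
    "MixedModelScan",
    "emma_scan",
    "qvalues",
    "genomic_inflation",
    "scan_all",
]


def maf_filter(genotypes: GenotypeSet, min_maf: float = 0.05) -> GenotypeSet:
    """Retain SNPs with minor-allele frequency strictly above ``min_maf``."""
    maf = genotypes.maf()
    return genotypes.subset_snps(genotypes.snp_ids[(maf > min_maf).to_numpy()])


def kinship(genotypes: GenotypeSet) -> pd.DataFrame:
    """Identity-by-state allele-sharing fraction per accession pair.

    For homozygous 0/1 genotypes this is the fraction of SNPs (non-missing
    in both accessions) at which the two accessions carry the same allele.
    """
    G = genotypes.matrix.to_numpy(dtype=float)
    if G.shape[0] < 2 or G.shape[1] < 1:
        raise DataError("kinship needs at least 2 accessions and 1 SNP")
    M = (~np.isnan(G)).astype(float)
    A = np.nan_to_num(G)
    B = np.nan_to_num(1.0 - G) * M
    overlap = M @ M.T
    if (overlap == 0).any():
        raise DataError("some accession pair shares no genotyped SNP")
    K = (A @ A.T + B @ B.T) / overlap
    K = (K + K.T) / 2.0
    return pd.DataFrame(K, index=genotypes.accessions,
                        columns=genotypes.accessions)


def _null_ml(y: np.ndarray, S: np.ndarray, Uty: np.ndarray, Utx: np.ndarray,
             grid: np.ndarray) -> tuple[float, float, float]:
    """Profile ML of log delta for the null model; returns
    (delta, sigma_g2, max loglik)."""
    n = len(y)

    def negll(log_delta: float) -> float:
        delta = np.exp(log_delta)
        w = 1.0 / (S + delta)
        xtwx = Utx.T @ (w[:, None] * Utx)
        xtwy = Utx.T @ (w * Uty)
        beta = np.linalg.solve(xtwx, xtwy)
        r = Uty - Utx @ beta
        sigma_g2 = float((w * r * r).sum()) / n
        ll = -0.5 * (n * np.log(2 * np.pi * sigma_g2) + np.log(S + delta).sum() + n)
        return -ll

    vals = np.array([negll(g) for g in grid])
    i = int(vals.argmin())
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    if hi > lo:
        res = optimize.minimize_scalar(negll, bounds=(lo, hi), method="bounded")
        best = res.x if res.fun <= vals[i] else grid[i]
    else:
        best = grid[i]
    # invariant: refined optimum at least as good as every grid point
    assert negll(best) <= vals.min() + 1e-9
    delta = float(np.exp(best))
    w = 1.0 / (S + delta)
    xtwx = Utx.T @ (w[:, None] * Utx)
    beta = np.linalg.solve(xtwx, Utx.T @ (w * Uty))
    r = Uty - Utx @ beta
    sigma_g2 = float((w * r * r).sum()) / n
    return delta, sigma_g2, -negll(best)


class MixedModelScan:
    """Single-trait mixed-model association scan (sklearn-style estimator).

    Parameters
    ----------
    grid_points : size of the log-delta grid on [-10, 10].
    per_snp_variance : re-estimate delta under each SNP model (exact mode,
        for small panels).

    Fitted attributes: ``pvalues_`` (Series per SNP), ``beta_``, ``delta_``,
    ``sigma_g2_``, ``sigma_e2_``, ``loglik_``.
    """

    def __init__(self, grid_points: int = 100, per_snp_variance: bool = False):
        self.grid_points = grid_points
        self.per_snp_variance = per_snp_variance

    def get_params(self, deep: bool = True) -> dict:
        return {"grid_points": self.grid_points,
                "per_snp_variance": self.per_snp_variance}

    def set_params(self, **params):
        for key, value in params.items():
            if key not in self.get_params():
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, value)
        return self

    def fit(self, genotypes: GenotypeSet, y: pd.Series,
            K: pd.DataFrame) -> "MixedModelScan":
        acc = list(genotypes.accessions)
        if list(y.index) != acc:
            y = y.reindex(acc)
        if y.isna().any():
            raise DataError("trait values must be complete accession means")
        Km = K.loc[acc, acc].to_numpy(dtype=float)
        eigvals = np.linalg.eigvalsh(Km)
        if eigvals.min() < -1e-6:
            raise DataError("kinship matrix is not positive semidefinite")
        S, U = np.linalg.eigh(Km)
        S = np.clip(S, 1e-10, None)
        n = len(acc)
        yv = y.to_numpy(dtype=float)
        ones = np.ones((n, 1))
        Uty = U.T @ yv
        Ut1 = U.T @ ones

        grid = np.linspace(-10.0, 10.0, self.grid_points)
        delta, sigma_g2, ll = _null_ml(yv, S, Uty, Ut1, grid)
        self.delta_, self.sigma_g2_ = delta, sigma_g2
        self.sigma_e2_ = delta * sigma_g2
        self.loglik_ = ll

        G = genotypes.matrix.to_numpy(dtype=float)
        col_mean = np.nanmean(G, axis=0)
        miss = np.isnan(G)
        if miss.any():
            G = G.copy()
            G[miss] = np.take(col_mean, np.where(miss)[1])

        if self.per_snp_variance:
            p, beta = self._scan_exact(G, S, U, Uty, Ut1, grid)
        else:
            p, beta = self._scan_fixed(G, S, U, yv, delta)
        self.pvalues_ = pd.Series(p, index=genotypes.snp_ids, name="p")
        self.beta_ = pd.Series(beta, index=genotypes.snp_ids, name="beta")
        return self

    @staticmethod
    def _scan_fixed(G, S, U, yv, delta):
        n = len(yv)
        scale = 1.0 / np.sqrt(S + delta)
        T = scale[:, None] * U.T           # whitening transform
        yt = T @ yv
        ot = T @ np.ones(n)
        Xt = T @ G                         # n x m transformed genotypes

        a11 = float(ot @ ot)
        a12 = Xt.T @ ot
        a22 = (Xt * Xt).sum(axis=0)
        b1 = float(ot @ yt)
        b2 = Xt.T @ yt
        yy = float(yt @ yt)
        det = a11 * a22 - a12**2
        rss0 = yy - b1 * b1 / a11
        with np.errstate(divide="ignore", invalid="ignore"):
            beta = (a11 * b2 - a12 * b1) / det
            alpha = (a22 * b1 - a12 * b2) / det
            rss1 = yy - (alpha * b1 + beta * b2)
            F = (rss0 - rss1) / (rss1 / (n - 2))
        mono = ~(np.nanstd(G, axis=0) > 0) | (det <= 1e-12 * a11 * np.maximum(a22, 1e-30))
        F = np.where(mono, 0.0, np.maximum(F, 0.0))
        p = stats.f.sf(F, 1, n - 2)
        p = np.where(mono, 1.0, p)
        beta = np.where(mono, 0.0, beta)
        return p, beta

    def _scan_exact(self, G, S, U, Uty, Ut1, grid):
        n = G.shape[0]
        yv = U @ Uty
        p = np.ones(G.shape[1])
        beta_out = np.zeros(G.shape[1])
        for j in range(G.shape[1]):
            x = G[:, j]
            if x.std() == 0:
                continue
            X = np.column_stack([np.ones(n), x])
            delta, _, _ = _null_ml(yv, S, U.T @ yv, U.T @ X, grid)
            pj, bj = self._scan_fixed(x[:, None], S, U, yv, delta)
            p[j], beta_out[j] = pj[0], bj[0]
        return p, beta_out


def emma_scan(y: pd.Series, genotypes: GenotypeSet, K: pd.DataFrame,
              **kwargs) -> pd.Series:
    """Per-SNP mixed-model p-values for one trait."""
    return MixedModelScan(**kwargs).fit(genotypes, y, K).pvalues_


def qvalues(p, lambdas: np.ndarray | None = None,
            pi0: float | None = None) -> tuple[np.ndarray, float]:
    """Storey q-values with the pi0 smoother.

    pi0(lambda) = #{p > lambda} / (m (1 - lambda)) over a lambda grid
    (0.05..0.95), smoothed with a cubic fit and evaluated at the largest
    lambda.  With fewer than 20 p-values, falls back to Benjamini-Hochberg
    (pi0 = 1) with a warning.  Returns (q, pi0).
    """
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise DataError("p-values must lie in (0, 1]")
    m = len(p)
    if pi0 is None:
        if m < 20:
            warnings.warn("fewer than 20 p-values; falling back to "
                          "Benjamini-Hochberg (pi0 = 1)")
            pi0 = 1.0
        else:
            if lambdas is None:
                lambdas = np.arange(0.05, 0.96, 0.05)
            pi0_l = np.array([(p > lam).mean() / (1 - lam) for lam in lambdas])
            coef = np.polyfit(lambdas, pi0_l, deg=3)
            pi0 = float(np.clip(np.polyval(coef, lambdas.max()), 1e-8, 1.0))
    order = np.argsort(p)
    ranked = p[order]
    q_sorted = pi0 * m * ranked / (np.arange(m) + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.clip(q_sorted, 0.0, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q, float(pi0)


def genomic_inflation(p) -> float:
    """Genomic-control inflation factor: median association chi-square over
    the null median (0.4549)."""
    p = np.asarray(p, dtype=float)
    chi2 = stats.chi2.isf(np.clip(p, 1e-300, 1.0), df=1)
    return float(np.median(chi2) / stats.chi2.isf(0.5, df=1))


def scan_all(means: pd.DataFrame, genotypes: GenotypeSet, K: pd.DataFrame,
             grid_points: int = 100) -> pd.DataFrame:
    """Scan every compound in a compound x accession means table.

    Returns the association table with columns compound_id, snp_id, chrom,
    pos, beta, p, q; q-values are computed per compound (each scan is its
    own multiplicity family).
    """
    frames = []
    snp_ann = genotypes.snps
    for compound, row in means.iterrows():
        y = row.dropna()
        sub = genotypes
        if len(y) < len(genotypes.accessions):
            sub = GenotypeSet(matrix=genotypes.matrix.loc[y.index],
                              snps=genotypes.snps, genes=genotypes.genes)
        scan = MixedModelScan(grid_points=grid_points).fit(sub, y, K)
        q, pi0 = qvalues(scan.pvalues_.to_numpy())
        frames.append(pd.DataFrame({
            "compound_id": compound,
            "snp_id": scan.pvalues_.index,
            "chrom": snp_ann["chrom"].to_numpy(),
            "pos": snp_ann["pos"].to_numpy(),
            "beta": scan.beta_.to_numpy(),
            "p": scan.pvalues_.to_numpy(),
            "q": q,
        }))
    return pd.concat(frames, ignore_index=True)
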