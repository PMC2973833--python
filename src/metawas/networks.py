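"""Genetic metabolite-metabolite networks across accessions.

Two correlation layers are computed on the accession-means matrix:

* zero-order Spearman rank correlation, with p-values from the Student-t
  approximation t = rho * sqrt((n-2) / (1-rho^2));
* shrinkage partial correlation: the sample correlation matrix is shrunk
  toward the identity with an analytically chosen intensity (the
  Schafer-Strimmer estimator, lambda* = sum Var(r_ij) / sum r_ij^2), and
  partial correlations are read off the negative scaled inverse.

Edges are screened by a density-based local false discovery rate: a
two-component mixture f(x) = eta0*f0(x; kappa) + (1-eta0)*fA(x) whose null
component is the sample-correlation null density with kappa effective
degrees of freedom, fit by censored maximum likelihood on the central part
of the distribution; the mixture density itself is estimated with a
Grenander (monotone decreasing) estimator on |x|.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import special, stats

from .datatypes import DataError

__all__ = [
    "spearman_matrix",
    "ShrinkagePartialCorrelation",
    "shrinkage_partial_correlation",
    "LocalFdr",
    "local_fdr",
    "network_edges",
    "NetworkSummary",
    "build_network",
    "compare_networks",
]


# ---------------------------------------------------------------------------
# zero-order layer

def spearman_matrix(means: pd.DataFrame, min_n: int = 4
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Spearman rho and p-values over accessions.

    ``means`` is compound x accession; correlation runs across accessions on
    pairwise-complete observations.  Pairs with fewer than ``min_n``
    complete accessions are NA.
    """
    X = means.T  # accessions x compounds
    rho = X.corr(method="spearman", min_periods=min_n)
    notna = X.notna().to_numpy(dtype=float)
    n = notna.T @ notna
    r = rho.to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
        p = 2.0 * stats.t.sf(np.abs(t), np.maximum(n - 2, 1))
    p[np.abs(r) >= 1.0] = 0.0
    p[n < min_n] = np.nan
    p[np.isnan(r)] = np.nan
    np.fill_diagonal(p, np.nan)
    return rho, pd.DataFrame(p, index=rho.index, columns=rho.columns)


# ---------------------------------------------------------------------------
# shrinkage partial correlation

class ShrinkagePartialCorrelation:
    """Gaussian graphical model via shrunk-correlation inversion.

    Parameters
    ----------
    shrinkage : float or None
        Fixed shrinkage intensity; None (default) estimates the
        Schafer-Strimmer optimal lambda from the data.
    order : {"full", "first"}
        "full" conditions each pair on all remaining compounds (what the
        shrinkage estimator computes); "first" reports, per pair, the
        single-conditioner partial correlation of minimal magnitude.
    min_coverage : fraction of non-missing accessions a compound needs.

    Fitted attributes: ``pcor_`` (DataFrame), ``shrinkage_``, ``corr_``,
    ``n_eff_``, ``dropped_``.
    """

    def __init__(self, shrinkage: float | None = None, order: str = "full",
                 min_coverage: float = 0.5):
        self.shrinkage = shrinkage
        self.order = order
        self.min_coverage = min_coverage

    def get_params(self, deep: bool = True) -> dict:
        return {"shrinkage": self.shrinkage, "order": self.order,
                "min_coverage": self.min_coverage}

    def set_params(self, **params):
        for key, value in params.items():
            if key not in self.get_params():
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, value)
        return self

    def fit(self, X: pd.DataFrame) -> "ShrinkagePartialCorrelation":
        """X: accessions x compounds matrix (means transposed)."""
        if X.shape[1] < 2:
            raise DataError("need at least two compounds")
        coverage = X.notna().mean(axis=0)
        variance = X.var(axis=0, ddof=1)
        keep = (coverage >= self.min_coverage) & (variance > 0)
        dropped = list(X.columns[~keep.to_numpy()])
        if dropped:
            warnings.warn(f"excluding {len(dropped)} constant or low-coverage "
                          "compounds from network inference")
        self.dropped_ = dropped
        X = X.loc[:, keep.to_numpy()]

        Z = (X - X.mean()) / X.std(ddof=1)
        M = Z.notna().to_numpy(dtype=float)
        Z0 = Z.fillna(0.0).to_numpy()
        n_pair = M.T @ M
        sw = Z0.T @ Z0
        with np.errstate(invalid="ignore", divide="ignore"):
            R = sw / (n_pair - 1)
        R = np.clip(R, -1.0, 1.0)
        np.fill_diagonal(R, 1.0)
        R[np.isnan(R)] = 0.0

        if self.shrinkage is None:
            sw2 = (Z0**2).T @ (Z0**2)
            with np.errstate(invalid="ignore", divide="ignore"):
                var_r = n_pair / (n_pair - 1) ** 3 * (sw2 - sw**2 / n_pair)
            off = ~np.eye(R.shape[0], dtype=bool)
            num = np.nansum(var_r[off])
            den = np.nansum(R[off] ** 2)
            lam = 1.0 if den == 0 else float(np.clip(num / den, 0.0, 1.0))
        else:
            lam = float(self.shrinkage)
        self.shrinkage_ = lam
        self.corr_ = pd.DataFrame(R, index=X.columns, columns=X.columns)
        self.n_eff_ = float(np.median(n_pair))

        R_sh = (1.0 - lam) * R + lam * np.eye(R.shape[0])
        if self.order == "first":
            pcor = _first_order_pcor(R_sh)
        else:
            omega = np.linalg.inv(R_sh)
            d = np.sqrt(np.diag(omega))
            pcor = -omega / np.outer(d, d)
            np.fill_diagonal(pcor, 1.0)
        self.pcor_ = pd.DataFrame(pcor, index=X.columns, columns=X.columns)
        return self


def _first_order_pcor(R: np.ndarray) -> np.ndarray:
    """Per pair, the single-conditioner partial correlation of minimal
    magnitude over all conditioning variables."""
    p = R.shape[0]
    out = R.copy()
    for i in range(p):
        for j in range(i + 1, p):
            best = R[i, j]
            for k in range(p):
                if k in (i, j):
                    continue
                denom = np.sqrt((1 - R[i, k] ** 2) * (1 - R[j, k] ** 2))
                if denom <= 0:
                    continue
                val = (R[i, j] - R[i, k] * R[j, k]) / denom
                if abs(val) < abs(best):
                    best = val
            out[i, j] = out[j, i] = best
    np.fill_diagonal(out, 1.0)
    return out


def shrinkage_partial_correlation(means: pd.DataFrame,
                                  shrinkage: float | None = None,
                                  order: str = "full"
                                  ) -> tuple[pd.DataFrame, float]:
    """Partial-correlation matrix and shrinkage intensity for a
    compound x accession means table."""
    est = ShrinkagePartialCorrelation(shrinkage=shrinkage, order=order)
    est.fit(means.T)
    return est.pcor_, est.shrinkage_


# ---------------------------------------------------------------------------
# local FDR

def _null_logpdf(x: np.ndarray, kappa: float) -> np.ndarray:
    """Log density of a sample correlation under the null with kappa
    effective degrees of freedom: f0(r) = (1-r^2)^((kappa-3)/2) / B(1/2,(kappa-1)/2)."""
    logbeta = special.betaln(0.5, (kappa - 1.0) / 2.0)
    with np.errstate(divide="ignore"):
        return (kappa - 3.0) / 2.0 * np.log1p(-np.clip(x, -1, 1) ** 2) - logbeta


def _null_cdf_abs(x0: float, kappa: float) -> float:
    """P(|r| <= x0) under the null: r^2 ~ Beta(1/2, (kappa-1)/2)."""
    return float(special.betainc(0.5, (kappa - 1.0) / 2.0, min(x0, 1.0) ** 2))


def _fit_null(x: np.ndarray, censor_quantile: float) -> tuple[float, float, float]:
    """Censored ML fit of (kappa, eta0) on the central part of |x|."""
    ax = np.abs(x)
    x0 = float(np.quantile(ax, censor_quantile))
    if x0 <= 0:
        x0 = float(ax[ax > 0].min()) if (ax > 0).any() else 0.01
    inside = ax[ax <= x0]
    frac_inside = len(inside) / len(ax)

    def negll(log_kappa: float) -> float:
        kappa = np.exp(log_kappa) + 3.0
        p_in = _null_cdf_abs(x0, kappa)
        if p_in <= 0:
            return np.inf
        return -(np.sum(_null_logpdf(inside, kappa)) - len(inside) * np.log(p_in))

    from scipy.optimize import minimize_scalar
    res = minimize_scalar(negll, bounds=(np.log(1.0), np.log(1e5)),
                          method="bounded")
    kappa = float(np.exp(res.x) + 3.0)
    eta0 = float(np.clip(frac_inside / max(_null_cdf_abs(x0, kappa), 1e-12),
                         0.0, 1.0))
    return kappa, eta0, x0


def _grenander_density(ax_sorted: np.ndarray) -> np.ndarray:
    """Grenander (monotone non-increasing) density of |x| evaluated at the
    sorted data points: slopes of the least concave majorant of the ECDF,
    obtained by pool-adjacent-violators on the interval slopes."""
    m = len(ax_sorted)
    uniq, counts = np.unique(ax_sorted, return_counts=True)
    F = np.cumsum(counts) / m
    knots = np.concatenate([[0.0], uniq])
    dF = np.diff(np.concatenate([[0.0], F]))
    dx = np.diff(knots)
    if dx[0] == 0.0:  # exact zeros in the data: fold their mass forward
        if len(dx) == 1:
            return np.full(m, np.inf)
        dF[1] += dF[0]
        dx, dF, uniq = dx[1:], dF[1:], uniq  # first interval removed
        first_merged = True
    else:
        first_merged = False
    slopes = list(dF / dx)
    widths = list(dx)
    # PAVA: pool adjacent intervals until slopes are non-increasing
    vals: list[float] = []
    wts: list[float] = []
    lens: list[int] = []
    for s, w in zip(slopes, widths):
        vals.append(s)
        wts.append(w)
        lens.append(1)
        while len(vals) > 1 and vals[-2] < vals[-1]:
            w2 = wts[-1] + wts[-2]
            s2 = (vals[-1] * wts[-1] + vals[-2] * wts[-2]) / w2
            n2 = lens[-1] + lens[-2]
            vals = vals[:-2] + [s2]
            wts = wts[:-2] + [w2]
            lens = lens[:-2] + [n2]
    per_interval = np.repeat(vals, lens)
    if first_merged:
        per_interval = np.concatenate([[per_interval[0]], per_interval])
    # density at each data point = slope of the interval ending at its value
    idx = np.searchsorted(uniq, ax_sorted)
    return per_interval[idx]


class LocalFdr:
    """Density-based local false discovery rate for edge statistics.

    fit(x) estimates the null scale (kappa) and null proportion (eta0) by
    censored ML on the central ``censor_quantile`` of |x|, the mixture
    density by a Grenander estimator on |x|, and sets
    ``fdr_ = clip(eta0 * f0 / f, 0, 1)``, made monotone non-increasing
    in |x|.

    Fitted attributes: ``fdr_``, ``eta0_``, ``kappa_``, ``cutoff_``.
    """

    def __init__(self, censor_quantile: float = 0.75):
        self.censor_quantile = censor_quantile

    def get_params(self, deep: bool = True) -> dict:
        return {"censor_quantile": self.censor_quantile}

    def set_params(self, **params):
        for key, value in params.items():
            if key not in self.get_params():
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, value)
        return self

    def fit(self, x) -> "LocalFdr":
        x = np.asarray(x, dtype=float)
        if len(x) < 2 or np.allclose(x, x[0]):
            warnings.warn("degenerate statistics; local fdr set to 1 everywhere")
            self.fdr_ = np.ones_like(x)
            self.eta0_ = 1.0
            self.kappa_ = np.nan
            self.cutoff_ = np.nan
            return self
        kappa, eta0, x0 = _fit_null(x, self.censor_quantile)
        self.kappa_, self.eta0_, self.cutoff_ = kappa, eta0, x0

        ax = np.abs(x)
        order = np.argsort(ax, kind="stable")
        dens = _grenander_density(ax[order])
        f0 = 2.0 * np.exp(_null_logpdf(ax[order], kappa))  # folded null
        with np.errstate(divide="ignore", invalid="ignore"):
            raw = eta0 * f0 / dens
        raw[~np.isfinite(raw)] = 1.0
        raw = np.clip(raw, 0.0, 1.0)
        # enforce monotone non-increasing in |x| by isotonic (PAVA)
        # least-squares fit over statistics sorted by increasing |x|
        from sklearn.isotonic import IsotonicRegression
        mono = IsotonicRegression(increasing=False).fit_transform(
            np.arange(len(raw)), raw)
        mono = np.clip(mono, 0.0, 1.0)
        fdr = np.empty_like(raw)
        fdr[order] = mono
        self.fdr_ = fdr
        return self


def local_fdr(statistics, censor_quantile: float = 0.75
              ) -> tuple[np.ndarray, float]:
    """Per-statistic local fdr and estimated null proportion eta0."""
    stats_arr = np.asarray(statistics, dtype=float)
    if len(stats_arr) < 50:
        warnings.warn("fewer than 50 statistics; local fdr estimates are "
                      "unstable")
    est = LocalFdr(censor_quantile=censor_quantile).fit(stats_arr)
    return est.fdr_, est.eta0_


# ---------------------------------------------------------------------------
# edge tables and network summaries

def network_edges(means: pd.DataFrame, shrinkage: float | None = None,
                  fdr_on: str = "pcor") -> pd.DataFrame:
    """Full edge table for a compound x accession means matrix.

    Columns: compound_i, compound_j (i < j in column order), rho, pcor,
    sign (of the statistic local fdr is computed on), local_fdr.
    """
    rho, _ = spearman_matrix(means)
    est = ShrinkagePartialCorrelation(shrinkage=shrinkage).fit(means.T)
    pcor = est.pcor_
    compounds = list(pcor.columns)
    iu = np.triu_indices(len(compounds), k=1)
    rho_sub = rho.loc[compounds, compounds].to_numpy()
    edges = pd.DataFrame({
        "compound_i": np.asarray(compounds)[iu[0]],
        "compound_j": np.asarray(compounds)[iu[1]],
        "rho": rho_sub[iu],
        "pcor": pcor.to_numpy()[iu],
    })
    stat = edges["pcor"] if fdr_on == "pcor" else edges["rho"]
    fdr, eta0 = local_fdr(stat.to_numpy())
    edges["sign"] = np.where(stat >= 0, "+", "-")
    edges["local_fdr"] = fdr
    edges.attrs["eta0"] = eta0
    edges.attrs["shrinkage"] = est.shrinkage_
    return edges


@dataclass
class NetworkSummary:
    n_nodes: int
    n_edges: int
    average_degree: float
    clustering_by_degree: dict    # k -> mean C(k)
    degree_distribution: dict     # k -> number of nodes


def _graph_from_edges(edges: pd.DataFrame, fdr_cutoff: float) -> nx.Graph:
    kept = edges[edges["local_fdr"] < fdr_cutoff]
    g = nx.Graph()
    for _, row in kept.iterrows():
        g.add_edge(row["compound_i"], row["compound_j"],
                   pcor=row.get("pcor", np.nan), sign=row.get("sign"))
    return g


def build_network(edges: pd.DataFrame, fdr_cutoff: float
                  ) -> tuple[NetworkSummary, pd.DataFrame]:
    """Retain edges below the local-fdr cutoff and summarize the graph.

    Nodes are the compounds incident to at least one retained edge; average
    degree is 2E/N over those nodes.
    """
    kept = edges[edges["local_fdr"] < fdr_cutoff].copy()
    g = _graph_from_edges(edges, fdr_cutoff)
    n, e = g.number_of_nodes(), g.number_of_edges()
    clustering = nx.clustering(g) if n else {}
    degrees = dict(g.degree())
    by_degree: dict[int, list] = {}
    for node, k in degrees.items():
        by_degree.setdefault(k, []).append(clustering[node])
    summary = NetworkSummary(
        n_nodes=n,
        n_edges=e,
        average_degree=(2.0 * e / n) if n else 0.0,
        clustering_by_degree={k: float(np.mean(v)) for k, v in sorted(by_degree.items())},
        degree_distribution={k: len(v) for k, v in sorted(by_degree.items())},
    )
    return summary, kept


def compare_networks(edges_a: pd.DataFrame, edges_b: pd.DataFrame,
                     fdr_cutoff: float = 0.2, n_perm: int = 1000,
                     seed: int = 0) -> dict:
    """Shared edges, sign agreement, and connectivity-difference tests.

    Connectivity (average degree) and triad closure (transitivity) are
    compared by pooling the retained edges of both networks and randomly
    reassigning network membership (keeping per-network edge counts);
    degree distributions are compared with a two-sample KS test on the
    degree sequences.
    """
    ga = _graph_from_edges(edges_a, fdr_cutoff)
    gb = _graph_from_edges(edges_b, fdr_cutoff)
    universe_a = set(edges_a["compound_i"]) | set(edges_a["compound_j"])
    universe_b = set(edges_b["compound_i"]) | set(edges_b["compound_j"])
    if not universe_a & universe_b:
        raise DataError("compound id spaces do not overlap")

    def key(u, v):
        return (u, v) if u <= v else (v, u)

    set_a = {key(u, v) for u, v in ga.edges()}
    set_b = {key(u, v) for u, v in gb.edges()}
    shared = sorted(set_a & set_b)
    sign_a = {key(r["compound_i"], r["compound_j"]): r["sign"]
              for _, r in edges_a.iterrows()}
    sign_b = {key(r["compound_i"], r["compound_j"]): r["sign"]
              for _, r in edges_b.iterrows()}
    sign_table = pd.DataFrame(
        [{"compound_i": u, "compound_j": v, "sign_a": sign_a.get((u, v)),
          "sign_b": sign_b.get((u, v)),
          "agree": sign_a.get((u, v)) == sign_b.get((u, v))}
         for u, v in shared])

    def stats_of(graph: nx.Graph) -> tuple[float, float, np.ndarray]:
        n = graph.number_of_nodes()
        k = (2.0 * graph.number_of_edges() / n) if n else 0.0
        tri = nx.transitivity(graph) if n else 0.0
        deg = np.array([d for _, d in graph.degree()], dtype=float)
        return k, tri, deg

    ka, ta, da = stats_of(ga)
    kb, tb, db = stats_of(gb)
    obs_k, obs_t = ka - kb, ta - tb

    pooled = list(set_a) + list(set_b)
    na = len(set_a)
    rng = np.random.default_rng(seed)
    exceed_k = exceed_t = 0
    for _ in range(n_perm):
        perm = rng.permutation(len(pooled))
        pa = [pooled[i] for i in perm[:na]]
        pb = [pooled[i] for i in perm[na:]]
        g1, g2 = nx.Graph(pa), nx.Graph(pb)
        k1, t1, _ = stats_of(g1)
        k2, t2, _ = stats_of(g2)
        if abs(k1 - k2) >= abs(obs_k) - 1e-12:
            exceed_k += 1
        if abs(t1 - t2) >= abs(obs_t) - 1e-12:
            exceed_t += 1
    p_degree = (exceed_k + 1) / (n_perm + 1)
    p_transitivity = (exceed_t + 1) / (n_perm + 1)
    if len(da) and len(db):
        p_ks = float(stats.ks_2samp(da, db).pvalue)
    else:
        p_ks = np.nan

    return {
        "shared_edges": shared,
        "sign_table": sign_table,
        "average_degree": (ka, kb),
        "transitivity": (ta, tb),
        "p_average_degree": p_degree,
        "p_transitivity": p_transitivity,
        "p_degree_distribution": p_ks,
    }
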