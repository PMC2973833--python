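"""Broad-sense heritability, adjusted accession means, and genetic CV.

The replicated design is modelled per compound with fixed effects:

    y ~ mu + S + F + A(S) + R(F) + eps,      eps ~ N(0, sigma^2)

where S is the population-structure group, F the planting flat, A the
accession (nested in S) and R the replicate (nested in F).  The type-II
sum of squares of A(S) is computed by comparing the full model against the
model without A(S).  Two heritability statistics are reported: the primary
``h2`` converts the A(S) and residual mean squares to variance components
via their expected values (sigma2_A = (MS_A - MS_E)/r for r replicates per
accession; H2 = sigma2_A / (sigma2_A + sigma2_E)), which is unbiased under
the nested design; ``h2_ss_ratio`` is the raw type-II SS of A(S) over the
corrected total SS, which inflates at low heritability because accession
degrees of freedom absorb residual variation (95 accession df against 384
samples at 4 replicates).  Adjusted accession means come from the same
model without S,
with sum-to-zero contrasts on F and R(F) so the accession coefficients sit
on a common intercept+coefficient scale.  Genetic CV is sd/mean of the
accession means per compound.

Input panels are expected on the log2 scale (the output of
:func:`metawas.preprocess.log2_median_normalize`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform

from .datatypes import DataError, MetabolitePanel

__all__ = [
    "HeritabilityRecord",
    "HeritabilityModel",
    "estimate_heritability",
    "estimate_accession_means",
    "genetic_cv",
    "compare_cv_distributions",
    "derive_structure_groups",
]


@dataclass
class HeritabilityRecord:
    compound: str
    h2: float                # variance-component broad-sense heritability
    h2_ss_ratio: float       # type-II SS of A(S) over corrected total SS
    ss_structure: float
    ss_flat: float
    ss_accession: float      # sequential (type-I) A(S) term of the SS table
    ss_replicate: float
    ss_residual: float
    ss_total: float
    ss_accession_type2: float


def _dummies(labels: pd.Series) -> np.ndarray:
    """Full one-hot coding (no reference level dropped)."""
    return pd.get_dummies(labels.astype("category")).to_numpy(dtype=float)


def _sum_contrasts(labels: pd.Series) -> np.ndarray:
    """Sum-to-zero contrast coding: k levels -> k-1 columns."""
    cats = pd.Categorical(labels)
    levels = list(cats.categories)
    if len(levels) < 2:
        return np.empty((len(labels), 0))
    codes = cats.codes
    out = np.zeros((len(labels), len(levels) - 1))
    for i in range(len(levels) - 1):
        out[codes == i, i] = 1.0
    out[codes == len(levels) - 1, :] = -1.0
    return out


def _nested_sum_contrasts(outer: pd.Series, inner: pd.Series) -> np.ndarray:
    """Sum-to-zero contrasts of ``inner`` separately within each ``outer``."""
    blocks = []
    for level in pd.unique(outer):
        mask = (outer == level).to_numpy()
        sub = _sum_contrasts(inner[mask])
        block = np.zeros((len(outer), sub.shape[1]))
        block[mask, :] = sub
        blocks.append(block)
    return np.hstack(blocks) if blocks else np.empty((len(outer), 0))


def _rss(Q: np.ndarray, y: np.ndarray) -> float:
    """Residual sum of squares given a thin-QR basis of the design."""
    coef = Q.T @ y
    return float(y @ y - coef @ coef)


def _qr_basis(X: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the column space (rank-revealing, via SVD)."""
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    tol = s.max() * max(X.shape) * np.finfo(float).eps if s.size else 0.0
    return U[:, s > tol]


class HeritabilityModel:
    """Estimator computing per-compound heritability records.

    Parameters
    ----------
    structure : mapping accession -> structure group, or None to derive
        groups later (pass them to :meth:`fit`).

    Fitted attributes: ``records_`` (list of :class:`HeritabilityRecord`),
    ``h2_`` (Series indexed by compound), ``table_`` (DataFrame of the SS
    decomposition).
    """

    def __init__(self, structure=None):
        self.structure = structure

    def get_params(self, deep: bool = True) -> dict:
        return {"structure": self.structure}

    def set_params(self, **params):
        for key, value in params.items():
            if key != "structure":
                raise ValueError(f"unknown parameter {key!r}")
            self.structure = value
        return self

    def fit(self, panel: MetabolitePanel, structure=None) -> "HeritabilityModel":
        structure = structure if structure is not None else self.structure
        if structure is None:
            raise DataError("a structure-group mapping is required")
        meta = panel.meta
        group = meta["accession"].map(dict(structure)
                                      if not isinstance(structure, pd.Series)
                                      else structure)
        if group.isna().any():
            raise DataError("some accessions lack a structure-group assignment")

        intercept = np.ones((len(meta), 1))
        S = _dummies(group)
        F = _dummies(meta["flat"])
        A = _dummies(meta["accession"])
        R = _dummies(meta["flat"].astype(str) + "/" + meta["replicate"].astype(str))
        designs = {
            "m0": intercept,
            "mS": np.hstack([intercept, S]),
            "mSF": np.hstack([intercept, S, F]),
            "mSFA": np.hstack([intercept, S, F, A]),
            "full": np.hstack([intercept, S, F, A, R]),
            "noA": np.hstack([intercept, S, F, R]),
        }

        Y = panel.values.to_numpy(dtype=float)
        has_nan = np.isnan(Y).any()
        acc = meta["accession"]
        records = []
        if not has_nan:
            bases = {k: _qr_basis(X) for k, X in designs.items()}
            resid_df = len(meta) - bases["full"].shape[1]
            r_bar = len(meta) / acc.nunique()
            for j, compound in enumerate(panel.compounds):
                records.append(self._one(compound, Y[:, j], bases, resid_df,
                                         r_bar))
        else:
            for j, compound in enumerate(panel.compounds):
                mask = ~np.isnan(Y[:, j])
                if mask.sum() < 3:
                    records.append(self._na_record(compound))
                    continue
                bases = {k: _qr_basis(X[mask]) for k, X in designs.items()}
                resid_df = int(mask.sum()) - bases["full"].shape[1]
                r_bar = mask.sum() / acc[mask].nunique()
                records.append(self._one(compound, Y[mask, j], bases,
                                         resid_df, r_bar))

        self.records_ = records
        self.h2_ = pd.Series({r.compound: r.h2 for r in records})
        self.table_ = pd.DataFrame([vars(r) for r in records]).set_index("compound")
        return self

    @staticmethod
    def _na_record(compound) -> HeritabilityRecord:
        return HeritabilityRecord(compound, np.nan, *([np.nan] * 8))

    def _one(self, compound, y, bases, resid_df, r_bar) -> HeritabilityRecord:
        yc = y - y.mean()
        ss_total = float(yc @ yc)
        if resid_df <= 0 or ss_total == 0.0:
            warnings.warn(f"model rank deficient or constant for {compound}; "
                          "H2 set to NA")
            return self._na_record(compound)
        rss = {k: _rss(Q, y) for k, Q in bases.items()}
        ss_s = rss["m0"] - rss["mS"]
        ss_f = rss["mS"] - rss["mSF"]
        ss_a1 = rss["mSF"] - rss["mSFA"]
        ss_r = rss["mSFA"] - rss["full"]
        ss_a2 = rss["noA"] - rss["full"]
        h2_ss = max(0.0, ss_a2) / ss_total
        df_a = bases["full"].shape[1] - bases["noA"].shape[1]
        ms_a = ss_a2 / df_a if df_a > 0 else np.nan
        ms_e = rss["full"] / resid_df
        sigma2_a = max(0.0, (ms_a - ms_e) / r_bar)
        denom = sigma2_a + ms_e
        h2 = min(1.0, sigma2_a / denom) if denom > 0 else 1.0
        return HeritabilityRecord(compound, h2, h2_ss, ss_s, ss_f, ss_a1,
                                  ss_r, rss["full"], ss_total, ss_a2)


def estimate_heritability(panel: MetabolitePanel, structure) -> list:
    """Per-compound heritability records; see :class:`HeritabilityModel`."""
    return HeritabilityModel(structure).fit(panel).records_


def estimate_accession_means(panel: MetabolitePanel) -> pd.DataFrame:
    """Adjusted genetic means per (compound, accession), log2 units.

    Fits ``y ~ mu + F + A + R(F)`` per compound with full accession dummies
    and sum-to-zero contrasts for flat and replicate-in-flat, so the
    accession coefficients are directly comparable adjusted means.  Returns
    a compound x accession DataFrame; accessions entirely missing for a
    compound are NA.
    """
    meta = panel.meta
    acc_labels = pd.Categorical(meta["accession"])
    accessions = list(acc_labels.categories)
    A = pd.get_dummies(acc_labels).to_numpy(dtype=float)
    Fc = _sum_contrasts(meta["flat"])
    Rc = _nested_sum_contrasts(meta["flat"], meta["replicate"])
    X = np.hstack([A, Fc, Rc])
    n_acc = len(accessions)

    Y = panel.values.to_numpy(dtype=float)
    out = np.full((len(panel.compounds), n_acc), np.nan)
    full_fit = None
    for j in range(Y.shape[1]):
        y = Y[:, j]
        mask = ~np.isnan(y)
        if mask.sum() == 0:
            continue
        if mask.all():
            if full_fit is None:
                full_fit = np.linalg.pinv(X)
            coef = full_fit @ y
            out[j, :] = coef[:n_acc]
        else:
            coef = np.linalg.pinv(X[mask]) @ y[mask]
            out[j, :] = coef[:n_acc]
            present = pd.Index(meta["accession"][mask]).unique()
            absent = [i for i, a in enumerate(accessions) if a not in set(present)]
            out[j, absent] = np.nan
    return pd.DataFrame(out, index=panel.compounds, columns=accessions)


def genetic_cv(means: pd.DataFrame, exponentiate: bool = False) -> pd.Series:
    """Genetic coefficient of variation per compound: sd/mean of accession
    means (sample sd, n-1).  Computed on the scale of the input table;
    ``exponentiate`` back-transforms log2 means to the count scale first.
    Compounds with mean <= 0 get NA with a warning."""
    m = np.exp2(means) if exponentiate else means
    mu = m.mean(axis=1)
    sd = m.std(axis=1, ddof=1)
    cv = sd / mu
    bad = mu <= 0
    if bad.any():
        warnings.warn(f"{int(bad.sum())} compounds with nonpositive mean; CV set NA")
        cv[bad] = np.nan
    cv.name = "genetic_cv"
    return cv


def compare_cv_distributions(cv_a: pd.Series, cv_b: pd.Series) -> dict:
    """Compare two per-compound CV tables on their shared compounds.

    Returns the fraction of compounds with ``cv_b > cv_a``, the fraction of
    ``cv_b`` exceeding ``max(cv_a)``, and the paired per-compound table.
    """
    shared = cv_a.index.intersection(cv_b.index)
    if len(shared) == 0:
        raise DataError("CV tables share no compounds")
    a, b = cv_a.loc[shared], cv_b.loc[shared]
    table = pd.DataFrame({"cv_a": a, "cv_b": b})
    return {
        "fraction_b_greater": float((b > a).mean()),
        "fraction_b_above_max_a": float((b > a.max()).mean()),
        "table": table,
    }


def derive_structure_groups(kinship: pd.DataFrame, n_groups: int = 8) -> pd.Series:
    """Structure groups by average-linkage hierarchical clustering of the
    kinship matrix (distance = 1 - similarity)."""
    d = 1.0 - kinship.to_numpy()
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2
    link = sch.linkage(squareform(d, checks=False), method="average")
    labels = sch.fcluster(link, t=n_groups, criterion="maxclust")
    return pd.Series(labels, index=kinship.index, name="group")
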