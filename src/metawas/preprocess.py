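"""Filtering and normalization of replicate-level ion-count tables.

Three steps, applied independently per experiment and in this order:

1. keep compounds present in strictly more than 50% of the samples of at
   least one accession;
2. keep samples detecting at least 50% of the predominant compounds (those
   detected in at least 70% of all samples);
3. log2-transform and median-normalize within each GC-MS run-date batch,
   standardized to 9 log2 units.

"Detected/present" means a non-missing, strictly positive ion count.
Each step is exposed both as a scikit-learn style transformer operating on
:class:`~metawas.datatypes.MetabolitePanel` objects and as a plain function.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .datatypes import DataError, MetabolitePanel

__all__ = [
    "CompoundPresenceFilter",
    "SampleCoverageFilter",
    "Log2MedianNormalizer",
    "filter_compounds_by_presence",
    "filter_samples_by_coverage",
    "log2_median_normalize",
    "preprocess_panel",
]


class _PanelTransformer:
    """Minimal sklearn-style estimator base for panel transformers."""

    def get_params(self, deep: bool = True) -> dict:
        return {k: v for k, v in vars(self).items() if not k.endswith("_")}

    def set_params(self, **params):
        valid = self.get_params()
        for key, value in params.items():
            if key not in valid:
                raise ValueError(f"unknown parameter {key!r} for "
                                 f"{type(self).__name__}")
            setattr(self, key, value)
        return self

    def fit_transform(self, panel: MetabolitePanel) -> MetabolitePanel:
        return self.fit(panel).transform(panel)


class CompoundPresenceFilter(_PanelTransformer):
    """Retain a compound iff some accession detects it in strictly more than
    ``within_accession_fraction`` of that accession's samples.

    Fitted attributes: ``kept_compounds_`` (Index).
    """

    def __init__(self, within_accession_fraction: float = 0.5):
        self.within_accession_fraction = within_accession_fraction

    def fit(self, panel: MetabolitePanel) -> "CompoundPresenceFilter":
        if panel.values.shape[0] == 0:
            raise DataError("empty panel: no samples")
        det = panel.detected()
        frac = det.groupby(panel.meta["accession"], observed=True).mean()
        keep = (frac > self.within_accession_fraction).any(axis=0)
        self.kept_compounds_ = panel.compounds[keep.to_numpy()]
        return self

    def transform(self, panel: MetabolitePanel) -> MetabolitePanel:
        kept = [c for c in panel.compounds if c in set(self.kept_compounds_)]
        return panel.subset(compounds=kept)


class SampleCoverageFilter(_PanelTransformer):
    """Retain samples detecting >= ``sample_fraction`` of the predominant
    compounds (those detected in >= ``predominant_fraction`` of all samples).

    Fitted attributes: ``predominant_compounds_``, ``kept_samples_``.
    """

    def __init__(self, predominant_fraction: float = 0.7,
                 sample_fraction: float = 0.5):
        self.predominant_fraction = predominant_fraction
        self.sample_fraction = sample_fraction

    def fit(self, panel: MetabolitePanel) -> "SampleCoverageFilter":
        if panel.values.shape[1] == 0:
            raise DataError("empty panel: no compounds")
        det = panel.detected()
        overall = det.mean(axis=0)
        predominant = panel.compounds[(overall >= self.predominant_fraction).to_numpy()]
        self.predominant_compounds_ = predominant
        if len(predominant) == 0:
            warnings.warn("predominant compound set is empty; all samples kept")
            self.kept_samples_ = panel.samples
            return self
        coverage = det.loc[:, predominant].mean(axis=1)
        self.kept_samples_ = panel.samples[(coverage >= self.sample_fraction).to_numpy()]
        return self

    def transform(self, panel: MetabolitePanel) -> MetabolitePanel:
        kept = panel.samples.intersection(self.kept_samples_)
        return panel.subset(samples=kept)


class Log2MedianNormalizer(_PanelTransformer):
    """log2-transform and shift each run-date batch so its median is ``target``.

    The batch median is taken over all non-missing values of the batch (all
    compounds pooled), so multiplying one batch's counts by a constant leaves
    its normalized values unchanged.  Fitted attributes: ``batch_medians_``.
    """

    def __init__(self, target: float = 9.0):
        self.target = target

    def fit(self, panel: MetabolitePanel) -> "Log2MedianNormalizer":
        self._check_positive(panel)
        logs = np.log2(panel.values)
        medians = {}
        for batch, idx in panel.meta.groupby("run_date").groups.items():
            medians[batch] = float(np.nanmedian(logs.loc[idx].to_numpy()))
        self.batch_medians_ = pd.Series(medians)
        return self

    def transform(self, panel: MetabolitePanel) -> MetabolitePanel:
        self._check_positive(panel)
        logs = np.log2(panel.values)
        med = panel.meta["run_date"].map(self.batch_medians_)
        out = logs.sub(med, axis=0) + self.target
        return MetabolitePanel(values=out, meta=panel.meta.copy())

    @staticmethod
    def _check_positive(panel: MetabolitePanel) -> None:
        bad = (panel.values <= 0)
        if bad.any().any():
            stacked = bad.stack()
            sample, compound = stacked.index[stacked.to_numpy().argmax()]
            raise DataError(
                f"nonpositive ion count for sample {sample!r}, "
                f"compound {compound!r}; counts must be > 0 before log2")


def filter_compounds_by_presence(panel: MetabolitePanel,
                                 within_accession_fraction: float = 0.5
                                 ) -> MetabolitePanel:
    return CompoundPresenceFilter(within_accession_fraction).fit_transform(panel)


def filter_samples_by_coverage(panel: MetabolitePanel,
                               predominant_fraction: float = 0.7,
                               sample_fraction: float = 0.5) -> MetabolitePanel:
    return SampleCoverageFilter(predominant_fraction,
                                sample_fraction).fit_transform(panel)


def log2_median_normalize(panel: MetabolitePanel,
                          target: float = 9.0) -> MetabolitePanel:
    return Log2MedianNormalizer(target).fit_transform(panel)


def preprocess_panel(panel: MetabolitePanel,
                     within_accession_fraction: float = 0.5,
                     predominant_fraction: float = 0.7,
                     sample_fraction: float = 0.5,
                     target: float = 9.0,
                     predominant_before_compound_filter: bool = False
                     ) -> dict[str, MetabolitePanel]:
    """Full preprocessing, independently per experiment.

    Returns one normalized panel per experiment label.  The predominant set
    for the sample filter is by default computed after the compound filter;
    ``predominant_before_compound_filter`` flips that (the original order is
    not documented either way).
    """
    out = {}
    for label, sub in panel.split_experiments().items():
        if predominant_before_compound_filter:
            sub = filter_samples_by_coverage(sub, predominant_fraction,
                                             sample_fraction)
            sub = filter_compounds_by_presence(sub, within_accession_fraction)
        else:
            sub = filter_compounds_by_presence(sub, within_accession_fraction)
            sub = filter_samples_by_coverage(sub, predominant_fraction,
                                             sample_fraction)
        out[label] = log2_median_normalize(sub, target)
    return out
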