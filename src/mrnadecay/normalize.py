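"""Quantile normalization, detection filtering and decay-set construction.

Two normalization regimes are used for a chase experiment:

* the "total" regime — all time-0 arrays quantile-normalized together, for
  steady-state differential expression between donor groups;
* the "decay" regime — each donor's chase arrays (0/1/3/5 h) normalized
  against each other only, so that between-donor scale differences cannot
  masquerade as decay.
"""

from __future__ import annotations

import logging
import warnings
from collections.abc import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .io import DecaySet, ExpressionMatrix, ExpressionTableError, SampleSheet

logger = logging.getLogger(__name__)


class QuantileNormalizer(BaseEstimator, TransformerMixin):
    """Force a set of arrays to share one intensity distribution.

    Follows the scikit-learn sample convention: each **row** of ``X`` is one
    array (sample) and each column one probe. ``fit`` computes the reference
    distribution — the across-sample mean of sorted intensity vectors — and
    ``transform`` maps every value to the reference quantile at its rank.
    Tied values receive the mean of the reference quantiles their tie span
    covers, so the transform is deterministic and permutation-equivariant.

    Attributes
    ----------
    reference_quantiles_ : ndarray of shape (n_features,)
        Mean sorted intensity vector of the fitted samples.
    """

    def fit(self, X, y=None):
        X = check_array(X, ensure_min_samples=1, ensure_min_features=1)
        self.reference_quantiles_ = np.sort(X, axis=1).mean(axis=0)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "reference_quantiles_")
        X = check_array(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features, normalizer was fitted on "
                f"{self.n_features_in_}"
            )
        ref = self.reference_quantiles_
        out = np.empty_like(X, dtype=float)
        for i, row in enumerate(X):
            order = np.argsort(row, kind="mergesort")
            sorted_vals = row[order]
            # Average the reference quantiles over each run of tied values.
            _, inverse, counts = np.unique(
                sorted_vals, return_inverse=True, return_counts=True
            )
            tie_means = np.bincount(inverse, weights=ref) / counts
            out[i, order] = tie_means[inverse]
        return out


def quantile_normalize(
    matrix: ExpressionMatrix, sample_subset: Sequence[str] | None = None
) -> ExpressionMatrix:
    """Quantile-normalize a subset of samples within an expression matrix.

    Samples outside the subset are left untouched; the result carries the
    ``normalized`` flag. A single-sample subset is an identity (with a
    warning); an empty subset is rejected.
    """
    subset = list(matrix.sample_ids if sample_subset is None else sample_subset)
    if len(subset) == 0:
        raise ValueError("sample subset must be non-empty")
    unknown = [s for s in subset if s not in matrix.sample_ids]
    if unknown:
        raise ValueError(f"samples not in matrix: {unknown}")
    intensities = matrix.intensities.copy()
    if len(subset) == 1:
        warnings.warn(
            "quantile normalization of a single sample is an identity",
            UserWarning,
            stacklevel=2,
        )
    else:
        X = intensities[subset].to_numpy().T  # samples in rows
        intensities[subset] = QuantileNormalizer().fit_transform(X).T
    return ExpressionMatrix(intensities, matrix.detection_p, normalized=True)


def detection_filter(
    matrix: ExpressionMatrix,
    sheet: SampleSheet,
    alpha: float = 0.05,
    policy: str = "all",
    min_fraction: float = 0.5,
) -> pd.Index:
    """Return probes significantly hybridized above background at time 0.

    A probe counts as detected on an array when its detection p-value is
    below ``alpha``. ``policy`` decides how the per-array calls at time 0
    combine across donors: ``"all"`` (default) requires detection on every
    time-0 array, ``"any"`` on at least one, ``"fraction"`` on at least
    ``min_fraction`` of them.
    """
    if matrix.detection_p is None:
        raise ValueError(
            "matrix has no detection p-values; detection filtering must be "
            "explicitly disabled for such data"
        )
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    t0_samples = sheet.samples_at(0)["sample_id"].tolist()
    if not t0_samples:
        raise ValueError("sample sheet has no time-0 arrays")
    detected = matrix.detection_p[t0_samples].to_numpy() < alpha
    if policy == "all":
        keep = detected.all(axis=1)
    elif policy == "any":
        keep = detected.any(axis=1)
    elif policy == "fraction":
        keep = detected.mean(axis=1) >= min_fraction
    else:
        raise ValueError(f"unknown detection policy {policy!r}")
    return matrix.probe_ids[keep]


def collapse_to_genes(
    matrix: ExpressionMatrix, probe_to_gene: dict[str, str]
) -> ExpressionMatrix:
    """Collapse probes to gene symbols, keeping the max-mean probe per gene.

    Off the default analysis path: hybridization and detection are
    probe-level concepts and the probe→gene mapping is annotation-
    dependent, so the pipeline stays at probe level unless collapsing is
    requested explicitly. Unmapped probes are dropped (logged).
    """
    genes = pd.Series(probe_to_gene).reindex(matrix.probe_ids)
    unmapped = int(genes.isna().sum())
    if unmapped:
        logger.info("collapse_to_genes: dropping %d unmapped probes", unmapped)
    mapped = matrix.probe_ids[genes.notna()]
    means = matrix.intensities.loc[mapped].mean(axis=1)
    best = (
        pd.DataFrame({"gene": genes.loc[mapped], "mean": means})
        .sort_values(["gene", "mean"], kind="mergesort")
        .groupby("gene", sort=True)
        .tail(1)
    )
    keep = best.index
    intensities = matrix.intensities.loc[keep].set_axis(
        pd.Index(best["gene"], name="gene_symbol")
    )
    detection = (
        None
        if matrix.detection_p is None
        else matrix.detection_p.loc[keep].set_axis(intensities.index)
    )
    return ExpressionMatrix(intensities, detection, matrix.normalized)


def build_decay_sets(
    matrix: ExpressionMatrix,
    sheet: SampleSheet,
    detected: Iterable[str] | None = None,
    epsilon: float = 1.0,
    normalize: bool = True,
) -> list[DecaySet]:
    """Build one within-donor-normalized decay set per donor.

    Each donor's chase arrays are quantile-normalized against each other
    only, independently of every other donor, then floored at ``epsilon``
    and natural-log transformed. Donors missing any chase time point are
    excluded with a logged warning rather than raising.

    ``normalize=False`` skips the within-donor quantile normalization and
    logs the raw intensities — useful for isolating the decay estimator
    from normalization effects.
    """
    grid = np.array(sorted(sheet.frame["time_h"].unique()), dtype=float)
    probes = (
        matrix.probe_ids
        if detected is None
        else matrix.probe_ids.intersection(pd.Index(list(detected)), sort=False)
    )
    if len(probes) == 0:
        raise ValueError("no probes survive the detection filter")
    sets: list[DecaySet] = []
    for donor in sheet.donors:
        donor_rows = sheet.donor_samples(donor)
        if sorted(donor_rows["time_h"]) != grid.tolist():
            logger.warning(
                "donor %s lacks the full chase grid %s (has %s); excluded",
                donor,
                grid.tolist(),
                sorted(donor_rows["time_h"].tolist()),
            )
            continue
        sample_ids = donor_rows["sample_id"].tolist()  # time-ordered
        sub = matrix.intensities.loc[probes, sample_ids]
        if normalize:
            norm = QuantileNormalizer().fit_transform(sub.to_numpy().T).T
        else:
            norm = sub.to_numpy()
        n_floored = int((norm < epsilon).sum())
        if n_floored:
            logger.info(
                "donor %s: floored %d cells at epsilon=%g before log", donor, n_floored, epsilon
            )
        log_traj = pd.DataFrame(
            np.log(np.maximum(norm, epsilon)), index=probes, columns=grid
        )
        sets.append(
            DecaySet(
                donor_id=donor,
                group=sheet.group_of(donor),
                times_h=grid,
                log_intensities=log_traj,
            )
        )
    return sets
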