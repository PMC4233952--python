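"""Differential expression and differential transcript-stability testing.

Two comparisons between donor groups are supported:

* steady-state ("total") differential expression at time 0 — one-way ANOVA
  across the three disease groups with a fold-change gate;
* differential mRNA stability — per-gene ratio of group mean half-lives,
  a >2-fold gate, a two-sample t-test on the per-donor half-lives of gated
  genes, and Benjamini–Hochberg FDR adjustment over the tested set.

Also here: categorization of tissue samples into disease groups from joint
status plus modified Mankin histology score, and the 2^−ΔΔCt relative
quantification used for qPCR confirmation.
"""

from __future__ import annotations

import logging
import math
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted
from statsmodels.stats.multitest import multipletests

from .decay import HalfLifeTable
from .io import GROUPS, ExpressionMatrix, SampleSheet

logger = logging.getLogger(__name__)

#: Supported group contrasts for half-life comparison. Each maps to
#: (reference group, alternative group); "pooled_OA" pools every
#: osteoarthritic donor regardless of histologic severity.
SCHEMES = {
    "normal_vs_intact_OA": ("normal", "intact_OA"),
    "normal_vs_fibrillated_OA": ("normal", "fibrillated_OA"),
    "intact_OA_vs_fibrillated_OA": ("intact_OA", "fibrillated_OA"),
    "normal_vs_pooled_OA": ("normal", "pooled_OA"),
}


def categorize_sample(joint_status: str, mankin_score: int) -> str:
    """Assign a disease-group label from joint status and histology score.

    Non-OA joints scoring below 10 on the modified Mankin scale are
    ``normal``; OA joints are ``intact_OA`` below 10 and ``fibrillated_OA``
    at 10 or above. A non-OA joint with a score of 10+ contradicts the
    grading scheme and is rejected rather than silently dropped.
    """
    if joint_status not in ("non-OA", "OA"):
        raise ValueError(f"joint_status must be 'non-OA' or 'OA', got {joint_status!r}")
    score = int(mankin_score)
    if score < 0:
        raise ValueError(f"Mankin score must be non-negative, got {mankin_score}")
    if joint_status == "non-OA":
        if score < 10:
            return "normal"
        raise ValueError(
            f"unclassifiable sample: non-OA joint with Mankin score {score} >= 10"
        )
    return "intact_OA" if score < 10 else "fibrillated_OA"


def one_way_anova(values_by_group) -> tuple[float, float]:
    """Fixed-effects one-way ANOVA F statistic and p-value.

    Degenerate input with zero variance both within and between groups is
    resolved as (F=0, p=1) by convention and logged.
    """
    groups = [np.asarray(g, dtype=float) for g in values_by_group]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >=2 groups with >=2 values each")
    if not all(np.isfinite(g).all() for g in groups):
        raise ValueError("values must be finite")
    allv = np.concatenate(groups)
    if np.ptp(allv) == 0:
        logger.info("one_way_anova: all values identical; returning F=0, p=1")
        return 0.0, 1.0
    f, p = stats.f_oneway(*groups)
    if math.isnan(f):  # zero within-group variance, unequal means
        return math.inf, 0.0
    return float(f), float(p)


def _anova_rows(group_mats: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise one-way ANOVA over matrices of shape (n_genes, n_i).

    Same sums-of-squares decomposition as :func:`one_way_anova`, vectorized
    across genes; degenerate all-constant rows resolve to (F=0, p=1).
    """
    ns = np.array([m.shape[1] for m in group_mats])
    n_tot = int(ns.sum())
    k = len(group_mats)
    allv = np.hstack(group_mats)
    grand = allv.mean(axis=1)
    means = np.column_stack([m.mean(axis=1) for m in group_mats])
    ss_between = (ns * (means - grand[:, None]) ** 2).sum(axis=1)
    ss_within = sum(
        ((m - means[:, [j]]) ** 2).sum(axis=1) for j, m in enumerate(group_mats)
    )
    df_b, df_w = k - 1, n_tot - k
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ss_between / df_b) / (ss_within / df_w)
    degenerate_null = (ss_within == 0) & (ss_between == 0)
    separated = (ss_within == 0) & (ss_between > 0)
    f = np.where(degenerate_null, 0.0, np.where(separated, np.inf, f))
    p = stats.f.sf(f, df_b, df_w)
    p = np.where(degenerate_null, 1.0, np.where(separated, 0.0, p))
    return f, p


def two_sample_t(a, b, equal_variance: bool = True) -> tuple[float, float]:
    """Two-sided two-sample t-test (Student by default, Welch optional)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >=2 values")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("values must be finite")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0 and a.mean() == b.mean():
        return 0.0, 1.0
    with warnings.catch_warnings():
        # near-identical groups trip scipy's catastrophic-cancellation notice;
        # the resulting tiny p-values are exactly what the gate-then-test
        # protocol expects for noiseless separations
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(a, b, equal_var=equal_variance)
    return float(t), float(p)


def benjamini_hochberg(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up FDR adjustment, order-preserving."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def delta_delta_ct(
    ct_target_test: float,
    ct_ref_test: float,
    ct_target_calibrator: float,
    ct_ref_calibrator: float,
) -> float:
    """Relative expression by the 2^−ΔΔCt method.

    ΔΔCt = (Ct_target − Ct_reference) in the test condition minus the same
    difference in the calibrator condition; the fold change is 2^−ΔΔCt.
    """
    cts = (ct_target_test, ct_ref_test, ct_target_calibrator, ct_ref_calibrator)
    if not all(math.isfinite(c) for c in cts):
        raise ValueError("Ct values must be finite")
    ddct = (ct_target_test - ct_ref_test) - (ct_target_calibrator - ct_ref_calibrator)
    return 2.0 ** (-ddct)


def total_expression_differential(
    matrix0: ExpressionMatrix,
    sheet: SampleSheet,
    fc_threshold: float = 2.0,
    p_threshold: float = 0.05,
    epsilon: float = 1.0,
) -> pd.DataFrame:
    """Steady-state differential expression across disease groups at time 0.

    Expects the time-0 arrays quantile-normalized together (the "total"
    regime). Per gene: one-way ANOVA of log2 expression across groups plus
    pairwise log2 group-mean differences; a contrast is significant only if
    both gates pass — |log2 FC| >= log2(fc_threshold) AND ANOVA
    p < p_threshold.
    """
    if not matrix0.normalized:
        raise ValueError("total analysis requires a jointly normalized time-0 matrix")
    if fc_threshold <= 0 or not 0 < p_threshold < 1:
        raise ValueError("thresholds out of range")
    t0 = sheet.samples_at(0)
    present = [g for g in GROUPS if (t0["group"] == g).sum() >= 2]
    skipped = [g for g in GROUPS if g in set(t0["group"]) and g not in present]
    for g in skipped:
        logger.warning("group %s has <2 time-0 donors; its contrasts are skipped", g)
    if len(present) < 2:
        raise ValueError("need >=2 groups with >=2 time-0 donors each")
    log2x = {
        g: np.log2(
            np.maximum(
                matrix0.intensities[t0.loc[t0["group"] == g, "sample_id"]].to_numpy(),
                epsilon,
            )
        )
        for g in present
    }
    fs, ps = _anova_rows([log2x[g] for g in present])
    n_genes = matrix0.shape[0]
    out = pd.DataFrame(index=matrix0.probe_ids)
    for g in present:
        out[f"mean_log2_{g}"] = log2x[g].mean(axis=1)
    lfc_gate = math.log2(fc_threshold)
    any_sig = np.zeros(n_genes, dtype=bool)
    for i, ga in enumerate(present):
        for gb in present[i + 1 :]:
            lfc = out[f"mean_log2_{gb}"] - out[f"mean_log2_{ga}"]
            sig = (np.abs(lfc) >= lfc_gate) & (ps < p_threshold)
            out[f"log2fc_{ga}_vs_{gb}"] = lfc
            out[f"significant_{ga}_vs_{gb}"] = sig
            any_sig |= sig.to_numpy()
    out["F"] = fs
    out["p"] = ps
    out["significant"] = any_sig
    return out


class DifferentialStabilityTest(BaseEstimator):
    """Ratio-gated differential half-life test between two donor groups.

    Mirrors the decay-analysis protocol: per gene, the ratio of group mean
    half-lives is computed; genes changing by more than ``ratio_threshold``-
    fold in either direction are tested with a two-sample t-test on the
    per-donor half-lives; Benjamini–Hochberg FDR adjustment is applied over
    the tested genes only (the gate precedes the test), and a gene is called
    significant when its FDR falls below ``fdr_threshold``.

    Parameters
    ----------
    ratio_threshold : float, default 2.0
        Fold-change gate on the ratio of group mean half-lives (strict:
        ratio > threshold or < 1/threshold).
    fdr_threshold : float, default 0.05
    equal_variance : bool, default True
        Student's pooled-variance t-test; False selects Welch.
    log_scale : bool, default False
        Run the t-test on log half-lives instead of raw hours.
    fdr_universe : {"tested", "all"}, default "tested"
        "all" adjusts over every gene (untested genes enter with p = 1),
        a conservative alternative to gate-then-adjust.

    ``fit(X, y)`` takes ``X`` of shape (n_donors, n_genes) — per-donor
    half-lives in hours — and ``y`` the per-donor group labels (exactly two
    distinct labels; the reference group should sort first or be passed via
    ``reference``).

    Attributes
    ----------
    results_ : DataFrame with per-gene means, ratio, t, p, FDR, direction.
    significant_ : boolean ndarray over genes.
    """

    def __init__(
        self,
        ratio_threshold: float = 2.0,
        fdr_threshold: float = 0.05,
        equal_variance: bool = True,
        log_scale: bool = False,
        fdr_universe: str = "tested",
        reference: str | None = None,
    ):
        self.ratio_threshold = ratio_threshold
        self.fdr_threshold = fdr_threshold
        self.equal_variance = equal_variance
        self.log_scale = log_scale
        self.fdr_universe = fdr_universe
        self.reference = reference

    def fit(self, X, y):
        if self.ratio_threshold <= 1:
            raise ValueError("ratio_threshold must exceed 1")
        if not 0 < self.fdr_threshold < 1:
            raise ValueError("fdr_threshold must lie in (0, 1)")
        if self.fdr_universe not in ("tested", "all"):
            raise ValueError("fdr_universe must be 'tested' or 'all'")
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[0] != len(y):
            raise ValueError("X must be (n_donors, n_genes) with one label per donor")
        labels = sorted(set(y.tolist()))
        if len(labels) != 2:
            raise ValueError(f"need exactly two group labels, got {labels}")
        ref = self.reference if self.reference is not None else labels[0]
        if ref not in labels:
            raise ValueError(f"reference {ref!r} not among labels {labels}")
        alt = next(l for l in labels if l != ref)
        a = X[y == ref]  # reference group, donors × genes
        b = X[y == alt]
        if a.shape[0] < 2 or b.shape[0] < 2:
            raise ValueError("each group needs >=2 donors")
        if np.isnan(X).any():
            raise ValueError("half-life matrix must contain retained rows only")

        mean_a = a.mean(axis=0)
        mean_b = b.mean(axis=0)
        ratio = mean_b / mean_a
        gate = (ratio > self.ratio_threshold) | (ratio < 1.0 / self.ratio_threshold)

        n_genes = X.shape[1]
        tstat = np.full(n_genes, np.nan)
        pval = np.full(n_genes, np.nan)
        ta = np.log(a) if self.log_scale else a
        tb = np.log(b) if self.log_scale else b
        for j in np.nonzero(gate)[0]:
            tstat[j], pval[j] = two_sample_t(
                ta[:, j], tb[:, j], equal_variance=self.equal_variance
            )
        fdr = np.full(n_genes, np.nan)
        if self.fdr_universe == "tested":
            if gate.any():
                fdr[gate] = benjamini_hochberg(pval[gate])
        else:
            fdr = benjamini_hochberg(np.where(gate, pval, 1.0))
        significant = np.zeros(n_genes, dtype=bool)
        significant[gate] = fdr[gate] < self.fdr_threshold

        self.reference_ = ref
        self.alternative_ = alt
        self.results_ = pd.DataFrame(
            {
                f"mean_{ref}": mean_a,
                f"mean_{alt}": mean_b,
                "ratio": ratio,
                "tested": gate,
                "t": tstat,
                "p": pval,
                "fdr": fdr,
                "significant": significant,
                "direction": np.where(mean_b > mean_a, "stabilized", "destabilized"),
            }
        )
        self.significant_ = significant
        return self


def half_life_ratio_test(
    table: HalfLifeTable,
    scheme: str = "normal_vs_pooled_OA",
    ratio_threshold: float = 2.0,
    fdr_threshold: float = 0.05,
    equal_variance: bool = True,
    log_scale: bool = False,
    fdr_universe: str = "tested",
) -> pd.DataFrame:
    """Differential half-life calling for one group contrast.

    Thin wrapper assembling the retained half-life rows for the scheme's
    two donor groups and delegating to :class:`DifferentialStabilityTest`.
    ``direction`` is relative to the reference group: "destabilized" means
    the alternative (OA) group's mean half-life is the smaller one.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; choose from {sorted(SCHEMES)}")
    ref, alt = SCHEMES[scheme]
    donors = table.donors_in(ref) + table.donors_in(alt)
    labels = [ref] * len(table.donors_in(ref)) + [alt] * len(table.donors_in(alt))
    retained = table.retained_half_lives
    if retained.empty:
        raise ValueError("half-life table has no retained rows")
    test = DifferentialStabilityTest(
        ratio_threshold=ratio_threshold,
        fdr_threshold=fdr_threshold,
        equal_variance=equal_variance,
        log_scale=log_scale,
        fdr_universe=fdr_universe,
        reference=ref,
    ).fit(retained[donors].to_numpy().T, np.array(labels))
    results = test.results_
    results.index = retained.index
    return results
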