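"""Log-linear mRNA half-life estimation from chase trajectories.

Under first-order decay, intensity after transcription shutoff follows
I(t) = I0 · e^(−kt), so the natural log of expression is linear in time.
The decay rate k is estimated as the negative OLS slope of ln expression on
hours, and converted to a half-life t½ = ln2 / k. Because a 5 h chase cannot
resolve slow decay, half-lives are capped (24 h by default); transcripts
with a non-negative slope other than exactly zero (apparent accumulation)
get no valid half-life and are excluded row-wise downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_array, check_is_fitted

from .io import DecaySet

LN2 = np.log(2.0)


def fit_log_linear_slope(times_h, ln_intensities) -> tuple[float, float, float]:
    """OLS slope of ln expression on hours for one trajectory.

    Returns ``(slope_per_hour, intercept, r_squared)``. A constant
    trajectory fits exactly with slope 0 and R² defined as 1.
    """
    x = np.asarray(times_h, dtype=float)
    y = np.asarray(ln_intensities, dtype=float)
    if x.ndim != 1 or x.shape != y.shape:
        raise ValueError("times and log-intensities must be 1-D and congruent")
    if len(np.unique(x)) < 2:
        raise ValueError("need at least two distinct time points")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("times and log-intensities must be finite")
    slope, intercept, r2 = _ols(x, y[np.newaxis, :])
    return float(slope[0]), float(intercept[0]), float(r2[0])


def _ols(x: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Row-wise closed-form OLS of Y (n_rows × n_times) on x."""
    xc = x - x.mean()
    sxx = float(xc @ xc)
    ybar = Y.mean(axis=1)
    slope = (Y - ybar[:, None]) @ xc / sxx
    intercept = ybar - slope * x.mean()
    resid = Y - (intercept[:, None] + np.outer(slope, x))
    ss_res = (resid**2).sum(axis=1)
    ss_tot = ((Y - ybar[:, None]) ** 2).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(ss_tot > 0, 1.0 - ss_res / ss_tot, np.where(ss_res == 0, 1.0, 0.0))
    return slope, intercept, r2


def slope_to_half_life(slope, cap_h: float = 24.0):
    """Convert decay slopes (per hour) to capped half-lives (hours).

    Negative slopes give t½ = ln2 / (−slope), truncated at ``cap_h``; a zero
    slope is a non-decaying transcript and maps to the cap; a positive slope
    would imply a non-positive half-life and returns NaN, the invalid
    marker that triggers row-wise exclusion.
    """
    if cap_h <= 0:
        raise ValueError("cap_h must be positive")
    s = np.asarray(slope, dtype=float)
    with np.errstate(divide="ignore"):
        hl = np.where(
            s < 0, np.minimum(LN2 / -s, cap_h), np.where(s == 0, cap_h, np.nan)
        )
    return float(hl) if np.isscalar(slope) else hl


class HalfLifeEstimator(BaseEstimator):
    """Per-transcript log-linear decay fit over a fixed chase grid.

    Parameters
    ----------
    times_h : sequence of float
        Chase time points in hours (at least two distinct values).
    cap_h : float, default 24.0
        Upper truncation for estimated half-lives.

    ``fit`` takes ``X`` of shape (n_transcripts, n_timepoints) holding
    natural-log intensities, one row per transcript trajectory.

    Attributes
    ----------
    slope_ : ndarray — OLS decay slope per hour, one entry per row of X.
    intercept_ : ndarray — fitted ln intensity at t = 0.
    r_squared_ : ndarray — coefficient of determination of each fit.
    half_life_ : ndarray — capped half-life in hours; NaN where invalid.
    valid_ : ndarray of bool — True where the half-life is positive.
    """

    def __init__(self, times_h=(0.0, 1.0, 3.0, 5.0), cap_h: float = 24.0):
        self.times_h = times_h
        self.cap_h = cap_h

    def fit(self, X, y=None):
        x = np.asarray(self.times_h, dtype=float)
        if len(np.unique(x)) < 2:
            raise ValueError("need at least two distinct time points")
        if self.cap_h <= 0:
            raise ValueError("cap_h must be positive")
        X = check_array(X, ensure_min_features=2)
        if X.shape[1] != len(x):
            raise ValueError(
                f"X has {X.shape[1]} columns but {len(x)} time points were given"
            )
        self.slope_, self.intercept_, self.r_squared_ = _ols(x, X)
        self.half_life_ = slope_to_half_life(self.slope_, self.cap_h)
        self.valid_ = ~np.isnan(self.half_life_)
        self.n_features_in_ = X.shape[1]
        return self

    def fit_predict(self, X, y=None) -> np.ndarray:
        """Fit and return the capped half-lives (NaN where invalid)."""
        return self.fit(X).half_life_


@dataclass
class HalfLifeTable:
    """Capped per-donor half-lives with fit diagnostics.

    ``retained`` marks transcripts with a valid (positive) half-life in
    every donor — only those rows enter group means, ratios and the
    short-lived set.
    """

    half_life: pd.DataFrame  # probes × donors, hours (NaN where invalid)
    slope: pd.DataFrame
    r_squared: pd.DataFrame
    retained: pd.Series
    donor_groups: pd.Series  # donor id -> group label
    cap_h: float
    qc_flagged: pd.DataFrame | None = None  # True where R² below the QC floor

    @property
    def retained_half_lives(self) -> pd.DataFrame:
        return self.half_life.loc[self.retained]

    def donors_in(self, group: str) -> list[str]:
        if group == "pooled_OA":
            wanted = {"intact_OA", "fibrillated_OA"}
        else:
            wanted = {group}
        return [d for d, g in self.donor_groups.items() if g in wanted]

    def group_mean(self, group: str) -> pd.Series:
        """Mean retained half-life per transcript across a group's donors.

        ``"pooled_OA"`` pools every osteoarthritic donor into one mean
        rather than averaging the two subgroup means.
        """
        donors = self.donors_in(group)
        if not donors:
            raise ValueError(f"no donors in group {group!r}")
        return self.retained_half_lives[donors].mean(axis=1)

    def write_tsv(self, path) -> None:
        donors = list(self.half_life.columns)
        out = pd.concat(
            {
                "half_life_h": self.half_life,
                "slope_per_h": self.slope,
                "r_squared": self.r_squared,
            },
            axis=1,
        )
        out.columns = [f"{d}.{m}" for m, d in out.columns]
        out = out[[f"{d}.{m}" for d in donors for m in ("half_life_h", "slope_per_h", "r_squared")]]
        out["retained"] = self.retained
        out.index.name = "probe_id"
        out.to_csv(path, sep="\t")


def half_life_table(
    decay_sets: list[DecaySet],
    cap_h: float = 24.0,
    r2_floor: float | None = None,
) -> HalfLifeTable:
    """Fit every donor's trajectories and assemble the half-life table.

    A transcript is retained only if its half-life is a positive value in
    every donor; a single accumulating (positive-slope) fit drops the whole
    row. ``r2_floor``, when given, flags poor fits for review — it never
    drops them.
    """
    if not decay_sets:
        raise ValueError("need at least one decay set")
    probes = decay_sets[0].log_intensities.index
    if len(probes) == 0:
        raise ValueError("empty probe universe")
    for ds in decay_sets[1:]:
        if not ds.log_intensities.index.equals(probes):
            raise ValueError("decay sets must share one probe universe")
    hl, slopes, r2s, groups = {}, {}, {}, {}
    for ds in decay_sets:
        est = HalfLifeEstimator(times_h=ds.times_h, cap_h=cap_h).fit(
            ds.log_intensities.to_numpy()
        )
        hl[ds.donor_id] = est.half_life_
        slopes[ds.donor_id] = est.slope_
        r2s[ds.donor_id] = est.r_squared_
        groups[ds.donor_id] = ds.group
    half_life = pd.DataFrame(hl, index=probes)
    slope = pd.DataFrame(slopes, index=probes)
    r_squared = pd.DataFrame(r2s, index=probes)
    retained = half_life.notna().all(axis=1)
    qc = r_squared < r2_floor if r2_floor is not None else None
    return HalfLifeTable(
        half_life=half_life,
        slope=slope,
        r_squared=r_squared,
        retained=retained,
        donor_groups=pd.Series(groups),
        cap_h=cap_h,
        qc_flagged=qc,
    )


def short_lived_set(
    table: HalfLifeTable, threshold_h: float = 6.0
) -> tuple[pd.Index, float]:
    """Transcripts below ``threshold_h`` in every donor of every group.

    Returns the gene set and its fraction of the retained (evaluated) rows.
    """
    if not 0 < threshold_h < table.cap_h:
        raise ValueError(
            f"threshold must lie in (0, cap={table.cap_h}), got {threshold_h}"
        )
    retained = table.retained_half_lives
    members = retained.index[(retained < threshold_h).all(axis=1)]
    fraction = len(members) / len(retained) if len(retained) else 0.0
    return members, fraction
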