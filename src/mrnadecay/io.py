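"""Data containers and TSV input/output for chase-experiment expression data.

The on-disk formats mirror what a BeadStudio-style export produces: a
tab-separated probe × sample intensity table, optionally with an interleaved
per-sample detection p-value column, plus a separate sample sheet mapping
each array to its donor, disease group and actinomycin-D chase time point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GROUPS = ("normal", "intact_OA", "fibrillated_OA")

#: Suffix conventions of a BeadStudio-style matrix export.
SIGNAL_SUFFIX = ".AVG_Signal"
DETECTION_SUFFIX = ".Detection Pval"


class ExpressionTableError(ValueError):
    """Raised when an expression table or sample sheet violates its contract."""


@dataclass
class ExpressionMatrix:
    """Probe × sample intensity grid with optional parallel detection p-values.

    Parameters
    ----------
    intensities
        DataFrame indexed by probe id with one column per sample id.
    detection_p
        Optional DataFrame of per-hybridization detection p-values, congruent
        in shape and labels with ``intensities``. Small values mean the probe
        signal is distinguishable from background beads.
    normalized
        Whether the intensities have been through quantile normalization.
    """

    intensities: pd.DataFrame
    detection_p: pd.DataFrame | None = None
    normalized: bool = False

    def __post_init__(self) -> None:
        idx = self.intensities.index
        cols = self.intensities.columns
        if idx.has_duplicates:
            dupes = idx[idx.duplicated()].unique().tolist()
            raise ExpressionTableError(f"duplicate probe ids: {dupes}")
        if cols.has_duplicates:
            dupes = cols[cols.duplicated()].unique().tolist()
            raise ExpressionTableError(f"duplicate sample ids: {dupes}")
        vals = self.intensities.to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            raise ExpressionTableError("intensities must be numeric")
        if np.any(vals < 0):
            raise ExpressionTableError("intensities must be non-negative")
        if self.detection_p is not None:
            if not (
                self.detection_p.index.equals(idx)
                and self.detection_p.columns.equals(cols)
            ):
                raise ExpressionTableError(
                    "detection grid must share probe and sample labels with intensities"
                )
            p = self.detection_p.to_numpy()
            if np.any((p < 0) | (p > 1)):
                raise ExpressionTableError("detection p-values must lie in [0, 1]")

    @property
    def probe_ids(self) -> pd.Index:
        return self.intensities.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.intensities.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensities.shape


@dataclass
class SampleSheet:
    """Per-array metadata: donor, disease group and chase time in hours."""

    frame: pd.DataFrame  # columns: sample_id, donor_id, group, time_h

    REQUIRED = ("sample_id", "donor_id", "group", "time_h")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.frame.columns]
        if missing:
            raise ExpressionTableError(f"sample sheet missing columns: {missing}")
        f = self.frame
        if f["sample_id"].duplicated().any():
            raise ExpressionTableError("duplicate sample_id in sample sheet")
        if f.duplicated(subset=["donor_id", "time_h"]).any():
            raise ExpressionTableError("duplicate (donor_id, time_h) pair in sample sheet")
        bad = set(f["group"]) - set(GROUPS)
        if bad:
            raise ExpressionTableError(f"unknown group labels: {sorted(bad)}")
        t0 = set(f.loc[f["time_h"] == 0, "donor_id"])
        no_t0 = sorted(set(f["donor_id"]) - t0)
        if no_t0:
            raise ExpressionTableError(f"donors without a time-0 array: {no_t0}")

    @property
    def donors(self) -> list[str]:
        return sorted(self.frame["donor_id"].unique())

    def group_of(self, donor_id: str) -> str:
        groups = self.frame.loc[self.frame["donor_id"] == donor_id, "group"].unique()
        return str(groups[0])

    def samples_at(self, time_h: float) -> pd.DataFrame:
        return self.frame[self.frame["time_h"] == time_h]

    def donor_samples(self, donor_id: str) -> pd.DataFrame:
        sub = self.frame[self.frame["donor_id"] == donor_id]
        return sub.sort_values("time_h")

    def group_sizes(self) -> dict[str, int]:
        per_donor = self.frame.drop_duplicates("donor_id")
        counts = per_donor["group"].value_counts()
        return {g: int(counts.get(g, 0)) for g in GROUPS}


@dataclass
class DecaySet:
    """One donor's within-donor-normalized chase trajectories.

    ``log_intensities`` holds natural-log intensities, probes × time points,
    columns ordered by ``times_h`` (strictly increasing, starting at 0).
    """

    donor_id: str
    group: str
    times_h: np.ndarray
    log_intensities: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        t = np.asarray(self.times_h, dtype=float)
        if t[0] != 0 or np.any(np.diff(t) <= 0):
            raise ExpressionTableError(
                f"chase times must start at 0 and increase strictly, got {t.tolist()}"
            )
        if not np.isfinite(self.log_intensities.to_numpy()).all():
            raise ExpressionTableError("log-intensity trajectories must be finite")
        self.times_h = t


def read_expression_table(path) -> ExpressionMatrix:
    """Read a TSV expression table, de-interleaving detection p-value columns.

    Two layouts are accepted: plain (probe-id column followed by one intensity
    column per sample) and BeadStudio-style, where every sample contributes a
    ``<sample>.AVG_Signal`` and a ``<sample>.Detection Pval`` column pair.
    """
    try:
        raw = pd.read_csv(path, sep="\t", index_col=0)
    except (pd.errors.ParserError, ValueError) as exc:
        raise ExpressionTableError(f"cannot parse {path}: {exc}") from exc
    if raw.index.has_duplicates:
        dupes = raw.index[raw.index.duplicated()].unique().tolist()
        raise ExpressionTableError(f"duplicate probe ids in {path}: {dupes}")

    det_cols = [c for c in raw.columns if c.endswith(DETECTION_SUFFIX)]
    if det_cols:
        sig_cols = [c for c in raw.columns if c.endswith(SIGNAL_SUFFIX)]
        samples_sig = [c[: -len(SIGNAL_SUFFIX)] for c in sig_cols]
        samples_det = [c[: -len(DETECTION_SUFFIX)] for c in det_cols]
        if sorted(samples_sig) != sorted(samples_det):
            raise ExpressionTableError(
                f"unpaired signal/detection columns in {path}: "
                f"{sorted(set(samples_sig) ^ set(samples_det))}"
            )
        intensities = raw[sig_cols].copy()
        intensities.columns = samples_sig
        detection = raw[[s + DETECTION_SUFFIX for s in samples_sig]].copy()
        detection.columns = samples_sig
    else:
        intensities = raw
        detection = None

    for frame, what in ((intensities, "intensity"), (detection, "detection")):
        if frame is None:
            continue
        for col in frame.columns:
            if not np.issubdtype(frame[col].dtype, np.number):
                bad = frame[col][pd.to_numeric(frame[col], errors="coerce").isna()]
                raise ExpressionTableError(
                    f"non-numeric {what} value in column {col!r}, "
                    f"row {bad.index[0]!r}: {bad.iloc[0]!r}"
                )
        if frame.isna().any().any():
            row, col = next(zip(*np.nonzero(frame.isna().to_numpy())))
            raise ExpressionTableError(
                f"missing {what} value at row {frame.index[row]!r}, "
                f"column {frame.columns[col]!r}"
            )
    return ExpressionMatrix(
        intensities.astype(float),
        None if detection is None else detection.astype(float),
    )


def write_expression_table(matrix: ExpressionMatrix, path) -> None:
    """Write a matrix as TSV; detection p-values interleave BeadStudio-style."""
    if matrix.detection_p is None:
        out = matrix.intensities.copy()
    else:
        pieces = {}
        for s in matrix.sample_ids:
            pieces[s + SIGNAL_SUFFIX] = matrix.intensities[s]
            pieces[s + DETECTION_SUFFIX] = matrix.detection_p[s]
        out = pd.DataFrame(pieces)
    out.index.name = "probe_id"
    out.to_csv(path, sep="\t")


def read_sample_sheet(path) -> SampleSheet:
    """Read a sample sheet (TSV or CSV by extension; TSV default)."""
    sep = "," if str(path).endswith(".csv") else "\t"
    frame = pd.read_csv(path, sep=sep)
    frame["time_h"] = frame["time_h"].astype(float)
    return SampleSheet(frame)


def write_sample_sheet(sheet: SampleSheet, path) -> None:
    sheet.frame.to_csv(path, sep="\t", index=False)
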