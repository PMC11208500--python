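"""Data model and I/O for label-free quantification (LFQ) intensity tables.

The central container is :class:`IntensityTable`, a samples x features grid of
log2 intensities backed by a pandas DataFrame. Missingness is encoded with a
single canonical marker, ``NaN``; the boolean observed mask is always derived
from it, so mask and values can never disagree.

Supported on-disk dialects:

* wide CSV/TSV (one axis samples, one axis features, either orientation),
* long CSV/TSV with (sample, feature, intensity) columns,
* single-run MaxQuant-style tab-separated tables (proteinGroups.txt,
  peptides.txt, evidence.txt), where a zero intensity means "not quantified".

All modelling downstream happens on the log2 scale; raw-scale input is
converted exactly once at ingest via :func:`log2_transform`.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "IntensityTable",
    "read_wide",
    "read_long",
    "read_maxquant_single_run",
    "log2_transform",
    "write_wide",
    "write_long",
]

#: canonical missing marker on the value grid
MISSING = np.nan

LONG_COLUMNS = ("sample_id", "feature_id", "intensity")


def _infer_sep(path: str | Path, sep: str | None) -> str:
    if sep is not None:
        return sep
    return "," if str(path).lower().endswith(".csv") else "\t"


def _duplicates(values) -> list:
    seen: set = set()
    dups: list = []
    for v in values:
        if v in seen and v not in dups:
            dups.append(v)
        seen.add(v)
    return dups


@dataclass
class IntensityTable:
    """Samples x features grid of log2 intensities with NaN as missing marker.

    ``data`` has sample ids on the index and feature ids on the columns.
    Identifiers must be unique on both axes; every non-NaN cell must be finite.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        dup_s = _duplicates(self.data.index)
        if dup_s:
            raise ValueError(f"duplicate sample ids: {dup_s}")
        dup_f = _duplicates(self.data.columns)
        if dup_f:
            raise ValueError(f"duplicate feature ids: {dup_f}")
        values = self.data.to_numpy(dtype=float)
        if np.isinf(values).any():
            rows, cols = np.where(np.isinf(values))
            cell = (self.data.index[rows[0]], self.data.columns[cols[0]])
            raise ValueError(f"non-finite observed value at {cell}")
        self.data = self.data.astype(float)

    # -- basic accessors -------------------------------------------------
    @property
    def sample_ids(self) -> pd.Index:
        return self.data.index

    @property
    def feature_ids(self) -> pd.Index:
        return self.data.columns

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def observed_mask(self) -> np.ndarray:
        """Boolean grid, True where a value was observed."""
        return self.data.notna().to_numpy()

    @property
    def n_observed(self) -> int:
        return int(self.data.notna().to_numpy().sum())

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def copy(self) -> "IntensityTable":
        return IntensityTable(self.data.copy())

    def transpose(self) -> "IntensityTable":
        return IntensityTable(self.data.T)

    # -- long-format conversion ------------------------------------------
    def to_long(self) -> pd.DataFrame:
        """Observed cells as a (sample_id, feature_id, intensity) frame.

        Rows are ordered by sample, then feature, in table order — the
        canonical record order used by the split machinery.
        """
        mask = self.data.notna().to_numpy()
        rows, cols = np.nonzero(mask)
        return pd.DataFrame(
            {
                "sample_id": self.data.index.to_numpy()[rows],
                "feature_id": self.data.columns.to_numpy()[cols],
                "intensity": self.data.to_numpy()[rows, cols],
            }
        )

    @classmethod
    def from_long(
        cls,
        records: pd.DataFrame,
        sample_ids=None,
        feature_ids=None,
    ) -> "IntensityTable":
        """Pivot long records to a wide table.

        ``sample_ids``/``feature_ids`` fix the axes (and their order); pairs
        absent from ``records`` become missing. Duplicate pairs are an error.
        """
        dup = records.duplicated(subset=["sample_id", "feature_id"])
        if dup.any():
            pairs = records.loc[dup, ["sample_id", "feature_id"]].values.tolist()
            raise ValueError(f"duplicate (sample, feature) pairs: {pairs[:5]}")
        wide = records.pivot(index="sample_id", columns="feature_id", values="intensity")
        if sample_ids is not None or feature_ids is not None:
            wide = wide.reindex(index=sample_ids, columns=feature_ids)
        wide.index.name = None
        wide.columns.name = None
        return cls(wide)


def read_wide(
    path: str | Path,
    orientation: str = "samples_rows",
    sep: str | None = None,
    nonpositive_raw_as_missing: bool = False,
) -> IntensityTable:
    """Read a wide CSV/TSV intensity table.

    ``orientation`` declares which axis holds samples (``"samples_rows"`` or
    ``"samples_cols"``). Empty and non-numeric cells map to missing; with
    ``nonpositive_raw_as_missing`` raw-scale zeros/negatives do too.
    The delimiter is inferred from the extension unless ``sep`` is given.
    """
    if orientation not in ("samples_rows", "samples_cols"):
        raise ValueError(f"unknown orientation {orientation!r}")
    sep = _infer_sep(path, sep)
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter=sep)
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: empty file (line 1)") from None
        rows = []
        index = []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(header):
                raise ValueError(
                    f"{path}: line {lineno} has {len(row)} fields, expected {len(header)}"
                )
            index.append(row[0])
            rows.append(row[1:])
    col_ids = header[1:]
    dup = _duplicates(col_ids)
    if dup:
        raise ValueError(f"duplicate column identifiers: {dup}")
    dup = _duplicates(index)
    if dup:
        raise ValueError(f"duplicate row identifiers: {dup}")
    def _parse(cell: str) -> float:
        # exact float parsing (pd.to_numeric trades precision for speed)
        try:
            v = float(cell)
        except ValueError:
            return np.nan
        return v if np.isfinite(v) else np.nan

    frame = pd.DataFrame(rows, index=index, columns=col_ids)
    numeric = frame.map(_parse).astype(float)
    if nonpositive_raw_as_missing:
        numeric = numeric.where(numeric > 0)
    if orientation == "samples_cols":
        numeric = numeric.T
    numeric.index.name = None
    numeric.columns.name = None
    return IntensityTable(numeric)


def read_long(
    path: str | Path,
    sample_col: str = "sample_id",
    feature_col: str = "feature_id",
    value_col: str = "intensity",
    sep: str | None = None,
) -> IntensityTable:
    """Read a long (sample, feature, intensity) CSV/TSV and pivot to wide."""
    sep = _infer_sep(path, sep)
    frame = pd.read_csv(path, sep=sep)
    for col in (sample_col, feature_col, value_col):
        if col not in frame.columns:
            raise ValueError(
                f"column {col!r} not found; available: {list(frame.columns)}"
            )
    records = frame.rename(
        columns={sample_col: "sample_id", feature_col: "feature_id", value_col: "intensity"}
    )[list(LONG_COLUMNS)]
    records["intensity"] = pd.to_numeric(records["intensity"], errors="coerce")
    records = records.dropna(subset=["intensity"])
    return IntensityTable.from_long(records)


def read_maxquant_single_run(
    path: str | Path,
    intensity_column: str = "Intensity",
    feature_column: str = "Protein IDs",
    drop_flag_columns: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Read a single-run MaxQuant-style tab-separated table into long records.

    Returns one record per row with a positive intensity; zero intensities
    mean "not quantified" in LFQ output and are dropped. ``feature_column``
    selects the aggregation level (e.g. "Protein IDs" for proteinGroups.txt,
    "Sequence" for peptides.txt/evidence.txt). Rows carrying a "+" in any of
    ``drop_flag_columns`` (e.g. "Reverse", "Potential contaminant") are
    removed; the filter is off by default.

    Returns a frame with columns (feature_id, intensity); the sample id is
    taken from the file name stem.
    """
    frame = pd.read_csv(path, sep="\t")
    for col in (intensity_column, feature_column):
        if col not in frame.columns:
            raise ValueError(
                f"column {col!r} not found; available: {list(frame.columns)}"
            )
    for flag in drop_flag_columns:
        if flag in frame.columns:
            frame = frame[frame[flag].fillna("") != "+"]
    intens = pd.to_numeric(frame[intensity_column], errors="coerce")
    keep = intens > 0
    records = pd.DataFrame(
        {
            "sample_id": Path(path).stem,
            "feature_id": frame.loc[keep, feature_column].astype(str).to_numpy(),
            "intensity": intens[keep].to_numpy(dtype=float),
        }
    )
    return records.reset_index(drop=True)


def log2_transform(table: IntensityTable) -> IntensityTable:
    """Replace observed raw-scale values by their log2; mask unchanged.

    Not idempotent — the caller tracks which scale a table is on. Any
    observed value <= 0 is an error naming the offending cell.
    """
    values = table.values
    bad = (values <= 0) & np.isfinite(values)
    if bad.any():
        rows, cols = np.where(bad)
        cell = (table.sample_ids[rows[0]], table.feature_ids[cols[0]])
        raise ValueError(f"non-positive observed value at {cell}: {values[rows[0], cols[0]]}")
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.log2(values)
    return IntensityTable(pd.DataFrame(out, index=table.sample_ids, columns=table.feature_ids))


def write_wide(table: IntensityTable, path: str | Path, sep: str = "\t") -> None:
    """Write a wide table (samples on rows) with full float precision."""
    frame = table.data.copy()
    frame.index.name = "sample_id"
    frame.to_csv(path, sep=sep, float_format="%.17g")


def write_long(records: pd.DataFrame, path: str | Path, sep: str = "\t") -> None:
    records.to_csv(path, sep=sep, index=False, float_format="%.17g")
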