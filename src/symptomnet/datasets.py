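"""Ordinal symptom datasets: loading, validation, harmonization, subsetting.

The package works on a participants × symptoms table of ordinal severity
codes.  Two source instruments are supported: an interview rated 0–3
(``PSS_0_3``) and a questionnaire rated 1–5 (``PCL_1_5``).  The questionnaire
scale is harmonized onto the interview scale by shifting each point down one
and collapsing the two most extreme points, so that every dataset downstream
lives on integer codes ``0..3`` (four levels).

Missing cells are carried as NaN internally; the on-disk convention is an
empty CSV cell or the literal string ``NA``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats


class SourceScale(str, Enum):
    """Rating scale of the source instrument."""

    PSS_0_3 = "PSS_0_3"
    PCL_1_5 = "PCL_1_5"


N_LEVELS = 4  # every harmonized dataset uses codes 0..3


class DatasetError(ValueError):
    """Raised for malformed or out-of-contract symptom data."""


@dataclass
class SymptomDataset:
    """A validated participants × symptoms matrix of ordinal codes.

    Parameters
    ----------
    values : ndarray of shape (n, p), float
        Ordinal codes ``0..n_levels-1``; missing cells are NaN.
    node_labels : list of str
        Unique short symptom labels, one per column.
    n_levels : int
        Number of ordinal levels (4 after harmonization).
    source_scale : SourceScale
        Scale the data were recorded on before harmonization.
    """

    values: np.ndarray
    node_labels: list[str]
    n_levels: int = N_LEVELS
    source_scale: SourceScale = SourceScale.PSS_0_3

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DatasetError("values must be a 2-D matrix")
        self.node_labels = [str(x) for x in self.node_labels]
        if len(self.node_labels) != self.values.shape[1]:
            raise DatasetError(
                f"{len(self.node_labels)} labels for {self.values.shape[1]} columns"
            )
        if len(set(self.node_labels)) != len(self.node_labels):
            dupes = sorted({x for x in self.node_labels if self.node_labels.count(x) > 1})
            raise DatasetError(f"duplicate node labels: {dupes}")
        obs = self.values[~np.isnan(self.values)]
        if obs.size and not np.array_equal(obs, np.round(obs)):
            raise DatasetError("non-integer cell value found")
        if obs.size and ((obs < 0).any() or (obs > self.n_levels - 1).any()):
            bad = obs[(obs < 0) | (obs > self.n_levels - 1)]
            raise DatasetError(
                f"cell value(s) {sorted(set(bad.tolist()))} outside [0, {self.n_levels - 1}]"
            )

    # -- basic shape ---------------------------------------------------
    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean (n, p) mask, True where a cell is missing."""
        return np.isnan(self.values)

    @property
    def n_incomplete_rows(self) -> int:
        return int(self.missing_mask.any(axis=1).sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.node_labels)

    def to_csv(self, path: str | Path) -> None:
        df = self.to_frame()
        # keep integer appearance for non-missing cells
        df.to_csv(path, index=False, float_format="%.0f", na_rep="")

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"SymptomDataset(n={self.n}, p={self.p}, n_levels={self.n_levels}, "
            f"incomplete_rows={self.n_incomplete_rows})"
        )


def rescale_pclc(values: np.ndarray) -> np.ndarray:
    """Map 1–5 questionnaire codes onto the 0–3 interview scale.

    1→0, 2→1, 3→2 and both 4 and 5 → 3 (the two most extreme points are
    collapsed onto the single most extreme interview point).  Missing (NaN)
    cells pass through unchanged.
    """
    values = np.asarray(values, dtype=float)
    obs = values[~np.isnan(values)]
    if obs.size and not np.array_equal(obs, np.round(obs)):
        raise DatasetError("non-integer value in 1-5 scale data")
    if obs.size and ((obs < 1).any() or (obs > 5).any()):
        raise DatasetError("value outside the 1-5 questionnaire scale")
    out = values - 1.0
    out[out > 3.0] = 3.0
    return out


def load_dataset(
    path: str | Path, scale: SourceScale | str = SourceScale.PSS_0_3
) -> SymptomDataset:
    """Read a header-rowed CSV of ordinal codes into a harmonized dataset.

    Empty cells and ``NA`` are treated as missing.  Data on the 1–5 scale
    are rescaled to 0–3 on load, so the returned dataset always has four
    levels.
    """
    scale = SourceScale(scale)
    # read the raw header first: pandas silently renames duplicate labels
    import csv as _csv

    with open(path, newline="") as fh:
        for line in fh:
            if line.strip() and not line.startswith("#"):
                raw_labels = next(_csv.reader([line]))
                break
        else:
            raise DatasetError("empty file")
    if len(set(raw_labels)) != len(raw_labels):
        dupes = sorted({x for x in raw_labels if raw_labels.count(x) > 1})
        raise DatasetError(f"duplicate node labels: {dupes}")
    df = pd.read_csv(path, na_values=["NA"], keep_default_na=False, comment="#")
    labels = [str(c) for c in df.columns]
    values = np.full(df.shape, np.nan)
    for j, col in enumerate(df.columns):
        for i, cell in enumerate(df[col]):
            if isinstance(cell, str):
                cell = cell.strip()
                if cell == "":
                    continue
                try:
                    cell = int(cell)
                except ValueError as exc:
                    raise DatasetError(
                        f"non-integer cell {cell!r} at row {i + 1}, column {labels[j]!r}"
                    ) from exc
            if pd.isna(cell):
                continue
            if float(cell) != int(cell):
                raise DatasetError(
                    f"non-integer cell {cell!r} at row {i + 1}, column {labels[j]!r}"
                )
            values[i, j] = int(cell)
    if scale is SourceScale.PCL_1_5:
        values = rescale_pclc(values)
    return SymptomDataset(values, labels, n_levels=N_LEVELS, source_scale=scale)


def listwise_complete(ds: SymptomDataset) -> SymptomDataset:
    """Drop every row containing at least one missing cell (listwise deletion)."""
    keep = ~ds.missing_mask.any(axis=1)
    if not keep.any():
        raise DatasetError("listwise deletion removed every row")
    return SymptomDataset(
        ds.values[keep], ds.node_labels, ds.n_levels, ds.source_scale
    )


@dataclass
class DescriptiveTable:
    """Per-symptom mean, SD (n−1 denominator) and adjusted Fisher–Pearson skewness."""

    table: pd.DataFrame = field(repr=False)

    @property
    def mean(self) -> pd.Series:
        return self.table["mean"]

    @property
    def sd(self) -> pd.Series:
        return self.table["sd"]

    @property
    def skewness(self) -> pd.Series:
        return self.table["skewness"]

    @property
    def degenerate(self) -> list[str]:
        """Labels of constant columns (SD = 0, skewness undefined)."""
        return list(self.table.index[self.table["degenerate"]])

    def to_json(self, path: str | Path) -> None:
        self.table.to_json(path, orient="index", indent=2)


def describe(ds: SymptomDataset) -> DescriptiveTable:
    """Column-wise descriptives over non-missing cells.

    Constant columns are flagged ``degenerate`` (skewness NaN), never
    silently zeroed.
    """
    rows = []
    for j, lab in enumerate(ds.node_labels):
        col = ds.values[:, j]
        col = col[~np.isnan(col)]
        if col.size < 2:
            raise DatasetError(f"column {lab!r} has fewer than 2 observed values")
        sd = float(np.std(col, ddof=1))
        if sd == 0.0:
            skew = np.nan
        else:
            skew = float(stats.skew(col, bias=False))
        rows.append(
            {"mean": float(np.mean(col)), "sd": sd, "skewness": skew,
             "degenerate": sd == 0.0}
        )
    table = pd.DataFrame(rows, index=pd.Index(ds.node_labels, name="symptom"))
    return DescriptiveTable(table)
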