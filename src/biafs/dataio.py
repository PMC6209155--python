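"""Sample-table ingest and bioimpedance feature expansion.

A :class:`SampleTable` holds one frequency band of segmental impedance
measurements (``R1``..``R5``, ohms), anthropometrics (age ``A`` in years,
height ``H`` in cm, weight ``W`` in kg, sex ``G`` coded 0/1) and one or
more continuous body-composition targets (``BFM``, ``TBW``, ... in kg).

:func:`expand_features` builds the derived feature set used throughout the
package: the five primaries are augmented with their reciprocals ``1/Ri``
(segmental conductance terms), all ten pairwise products ``RiRj`` and the
five squares ``Ri^2``.  With the sex indicator included the expanded
matrix has 29 columns in a fixed, documented order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

log = logging.getLogger("biafs")

IMPEDANCE_COLUMNS: tuple[str, ...] = ("R1", "R2", "R3", "R4", "R5")
ANTHROPOMETRIC_COLUMNS: tuple[str, ...] = ("A", "H", "W")
SEX_COLUMN: str = "G"
DEFAULT_TARGETS: tuple[str, ...] = ("BFM", "TBW")

#: pairwise product order: (1,2),(1,3),(1,4),(1,5),(2,3),...,(4,5)
PRODUCT_PAIRS: tuple[tuple[int, int], ...] = (
    (1, 2), (1, 3), (1, 4), (1, 5),
    (2, 3), (2, 4), (2, 5),
    (3, 4), (3, 5),
    (4, 5),
)

_CONST_TOL = 1e-12


def required_columns(target_names: tuple[str, ...]) -> tuple[str, ...]:
    """Columns a sample table must provide (sex included)."""
    return IMPEDANCE_COLUMNS + ANTHROPOMETRIC_COLUMNS + (SEX_COLUMN,) + tuple(target_names)


@dataclass
class SampleTable:
    """Per-subject raw measurements for a single frequency band.

    Parameters
    ----------
    data
        One row per subject.  Must contain ``R1..R5, A, H, W, G`` and the
        named target columns; an optional ``subject_id`` column is carried
        through untouched.
    band
        Frequency-band label (``"1kHz"``, ``"250kHz"``, ``"500kHz"`` or
        free text).  One band per table.
    target_names
        Continuous target columns present in ``data``.
    n_rejected
        Number of rows dropped during ingest (missing or non-positive
        impedance values).
    """

    data: pd.DataFrame
    band: str = "250kHz"
    target_names: tuple[str, ...] = ("BFM",)
    n_rejected: int = 0

    def __post_init__(self) -> None:
        missing = [c for c in required_columns(self.target_names) if c not in self.data.columns]
        if missing:
            raise KeyError(f"sample table is missing required column(s): {missing}")
        # slices (e.g. a held-out partition) may hold a single row; ingest
        # itself requires at least 2 (see read_sample_table)
        if len(self.data) < 1:
            raise ValueError("sample table is empty")
        imp = self.data.loc[:, list(IMPEDANCE_COLUMNS)].to_numpy(dtype=float)
        if not np.all(np.isfinite(imp)) or np.any(imp <= 0):
            raise ValueError("impedance columns must be finite and strictly positive")
        num = self.data.loc[:, [c for c in required_columns(self.target_names)]]
        if num.isna().any().any():
            raise ValueError("sample table contains missing values after ingest")

    @property
    def n_samples(self) -> int:
        return len(self.data)

    def target(self, name: str | None = None) -> np.ndarray:
        """Return a target column as a float vector (first target by default)."""
        name = name or self.target_names[0]
        if name not in self.data.columns:
            raise KeyError(f"unknown target column {name!r}")
        return self.data[name].to_numpy(dtype=float)

    def head(self, n: int) -> "SampleTable":
        return replace(self, data=self.data.iloc[:n].reset_index(drop=True), n_rejected=0)

    def tail(self, n: int) -> "SampleTable":
        return replace(self, data=self.data.iloc[len(self.data) - n:].reset_index(drop=True),
                       n_rejected=0)


def read_sample_table(
    path,
    format: str = "csv",
    column_map: dict[str, str] | None = None,
    band: str = "250kHz",
    target_names: tuple[str, ...] = ("BFM",),
    sheet_name: str | int | None = None,
) -> SampleTable:
    """Read a delimited-text or spreadsheet sample table.

    Rows with missing required fields, non-numeric cells in required
    fields, or non-positive impedances are rejected (counted in
    ``n_rejected`` and logged).  A missing required *column* is fatal.

    Parameters
    ----------
    path
        CSV (comma, header row, UTF-8) or XLSX file.
    format
        ``"csv"`` or ``"xlsx"``.
    column_map
        Optional mapping from file column names to canonical names
        (``{"Age": "A", ...}``).
    sheet_name
        XLSX sheet to read; defaults to the first sheet.
    """
    if format == "csv":
        raw = pd.read_csv(path)
    elif format == "xlsx":
        raw = pd.read_excel(path, sheet_name=sheet_name if sheet_name is not None else 0)
    else:
        raise ValueError(f"unknown format {format!r}; expected 'csv' or 'xlsx'")
    if column_map:
        raw = raw.rename(columns=column_map)

    req = required_columns(target_names)
    missing = [c for c in req if c not in raw.columns]
    if missing:
        raise KeyError(f"input file is missing required column(s): {missing}")

    work = raw.copy()
    for c in req:
        work[c] = pd.to_numeric(work[c], errors="coerce")
    bad_missing = work[list(req)].isna().any(axis=1)
    bad_imp = (work[list(IMPEDANCE_COLUMNS)] <= 0).any(axis=1) & ~bad_missing
    bad = bad_missing | bad_imp
    n_rejected = int(bad.sum())
    if n_rejected:
        log.warning("rejected %d row(s): %d missing/non-numeric, %d non-positive impedance",
                    n_rejected, int(bad_missing.sum()), int(bad_imp.sum()))
    work = work.loc[~bad].reset_index(drop=True)
    if len(work) < 2:
        raise ValueError(f"fewer than 2 valid rows after ingest ({len(work)})")
    return SampleTable(data=work, band=band, target_names=tuple(target_names),
                       n_rejected=n_rejected)


def write_sample_table(table: SampleTable, path) -> None:
    """Write a sample table back to CSV (canonical interchange format)."""
    table.data.to_csv(path, index=False)


@dataclass
class FeatureMatrix:
    """Expanded feature set with per-column metadata.

    ``feature_kinds`` tags each column as ``primary``, ``reciprocal``,
    ``product`` or ``square``.  After :func:`zscore_normalize` the stored
    per-column means/sds allow an exact inverse transform; constant
    columns are flagged (``constant_mask``), their sd left at 0, and they
    are excluded from downstream dependence scoring.
    """

    values: np.ndarray
    feature_names: list[str]
    feature_kinds: list[str]
    normalization: str = "none"           # "none" | "zscore"
    means: np.ndarray | None = None
    sds: np.ndarray | None = None
    constant_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (samples x features)")
        if len(self.feature_names) != self.values.shape[1]:
            raise ValueError("feature_names length does not match column count")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("feature names must be unique")
        if self.constant_mask is None:
            sds = self.values.std(axis=0, ddof=1) if self.n_samples > 1 else np.zeros(self.n_features)
            self.constant_mask = sds <= _CONST_TOL

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def column(self, name: str) -> np.ndarray:
        try:
            j = self.feature_names.index(name)
        except ValueError:
            raise KeyError(f"unknown feature {name!r}") from None
        return self.values[:, j]

    def subset(self, names) -> "FeatureMatrix":
        """Column subset, keeping this matrix's column order and metadata."""
        keep = [j for j, n in enumerate(self.feature_names) if n in set(names)]
        return FeatureMatrix(
            values=self.values[:, keep],
            feature_names=[self.feature_names[j] for j in keep],
            feature_kinds=[self.feature_kinds[j] for j in keep],
            normalization=self.normalization,
            means=None if self.means is None else self.means[keep],
            sds=None if self.sds is None else self.sds[keep],
            constant_mask=self.constant_mask[keep],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.feature_names)


def expand_features(table: SampleTable, include_sex: bool = True) -> FeatureMatrix:
    """Build the expanded bioimpedance feature matrix.

    Column order is fixed: ``R1..R5, A, H, W, [G], 1/R1..1/R5, R1R2, R1R3,
    R1R4, R1R5, R2R3, R2R4, R2R5, R3R4, R3R5, R4R5, R1^2..R5^2`` — 29
    columns with sex included, 28 without.  Deterministic and column-order
    stable across runs.
    """
    df = table.data
    names: list[str] = []
    kinds: list[str] = []
    cols: list[np.ndarray] = []

    for c in IMPEDANCE_COLUMNS + ANTHROPOMETRIC_COLUMNS:
        names.append(c); kinds.append("primary")
        cols.append(df[c].to_numpy(dtype=float))
    if include_sex:
        names.append(SEX_COLUMN); kinds.append("primary")
        cols.append(df[SEX_COLUMN].to_numpy(dtype=float))
    R = {i: df[f"R{i}"].to_numpy(dtype=float) for i in range(1, 6)}
    for i in range(1, 6):
        names.append(f"1/R{i}"); kinds.append("reciprocal")
        cols.append(1.0 / R[i])
    for i, j in PRODUCT_PAIRS:
        names.append(f"R{i}R{j}"); kinds.append("product")
        cols.append(R[i] * R[j])
    for i in range(1, 6):
        names.append(f"R{i}^2"); kinds.append("square")
        cols.append(R[i] ** 2)

    values = np.column_stack(cols)
    if not np.all(np.isfinite(values)):
        raise ValueError("expanded feature matrix contains non-finite values")
    return FeatureMatrix(values=values, feature_names=names, feature_kinds=kinds)


def zscore_normalize(fm: FeatureMatrix) -> FeatureMatrix:
    """Standardize every column to mean 0, sample sd 1 (n−1 denominator).

    Constant columns are flagged and only centered (sd stored as 0);
    stored means/sds make :func:`denormalize` an exact inverse.
    """
    if fm.n_samples < 2:
        raise ValueError("z-scoring needs at least 2 samples")
    means = fm.values.mean(axis=0)
    sds = fm.values.std(axis=0, ddof=1)
    constant = sds <= _CONST_TOL * np.maximum(1.0, np.abs(means))
    if constant.any():
        log.warning("constant feature column(s) flagged: %s",
                    [n for n, c in zip(fm.feature_names, constant) if c])
    safe = np.where(constant, 1.0, sds)
    out = (fm.values - means) / safe
    return FeatureMatrix(
        values=out,
        feature_names=list(fm.feature_names),
        feature_kinds=list(fm.feature_kinds),
        normalization="zscore",
        means=means,
        sds=np.where(constant, 0.0, sds),
        constant_mask=constant,
    )


def denormalize(fm: FeatureMatrix) -> FeatureMatrix:
    """Invert :func:`zscore_normalize` exactly using the stored means/sds."""
    if fm.normalization != "zscore" or fm.means is None or fm.sds is None:
        raise ValueError("matrix is not z-score normalized")
    scale = np.where(fm.sds > 0, fm.sds, 1.0)
    values = fm.values * scale + fm.means
    return FeatureMatrix(values=values, feature_names=list(fm.feature_names),
                         feature_kinds=list(fm.feature_kinds), normalization="none")
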