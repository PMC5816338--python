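"""Reading and writing VVOR velocity recordings and analysis reports.

A recording is a CSV export of a video head-impulse goggle session: one row
per sample with a time stamp (s), head angular velocity (deg/s) and eye
angular velocity (deg/s).  Files may contain several test blocks; by
convention the *last* VVOR test in the file is the one analyzed.

The vendor export schema is not standardized, so the layout is described by a
:class:`CsvDialect` (column names or positions, delimiter, decimal mark, an
optional test-marker column).  A generic default dialect is provided.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd

from .errors import (
    ConfigurationError,
    EmptyRecordingError,
    IncompleteReportError,
    MalformedRecordingError,
)

logger = logging.getLogger(__name__)

ColumnKey = Union[str, int]

#: Gaps longer than this many nominal sample intervals split a block.
GAP_FACTOR = 5.0


@dataclass(frozen=True)
class CsvDialect:
    """Describes the layout of a velocity-recording CSV file.

    Columns may be given as header names (str) or zero-based positions (int).
    ``test_marker`` optionally names a column whose value identifies test
    blocks; the reader returns the last maximal run of rows sharing one
    marker value.  ``decimal_mark`` supports locale exports ("," with ";"
    delimiter).
    """

    column_time: ColumnKey = "Time"
    column_head: ColumnKey = "HeadVelocity"
    column_eye: ColumnKey = "EyeVelocity"
    test_marker: ColumnKey | None = None
    delimiter: str = ","
    decimal_mark: str = "."

    def __post_init__(self) -> None:
        cols = [self.column_time, self.column_head, self.column_eye]
        if len({(type(c).__name__, c) for c in cols}) != 3:
            raise ConfigurationError(f"time/head/eye columns must be distinct, got {cols}")
        if len(self.delimiter) != 1:
            raise ConfigurationError("delimiter must be a single character")
        if self.decimal_mark not in (".", ","):
            raise ConfigurationError("decimal_mark must be '.' or ','")
        if self.delimiter == self.decimal_mark:
            raise ConfigurationError("delimiter and decimal_mark must differ")


DEFAULT_DIALECT = CsvDialect()


@dataclass
class VelocityTrace:
    """Time-aligned head and eye angular-velocity series.

    Parameters
    ----------
    t
        Time stamps in seconds, strictly increasing.
    head_vel, eye_vel
        Head and eye angular velocity in deg/s, same length as ``t``.
    sample_rate
        Nominal sampling rate in Hz; the median inter-sample interval must be
        within 20% of ``1/sample_rate``.
    source
        Free-text provenance (file path, generator parameters, ...).
    """

    t: np.ndarray
    head_vel: np.ndarray
    eye_vel: np.ndarray
    sample_rate: float
    source: str = ""

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.head_vel = np.asarray(self.head_vel, dtype=float)
        self.eye_vel = np.asarray(self.eye_vel, dtype=float)
        n = len(self.t)
        if n < 2 or len(self.head_vel) != n or len(self.eye_vel) != n:
            raise MalformedRecordingError(
                f"t/head_vel/eye_vel must have identical length >= 2, got "
                f"{n}/{len(self.head_vel)}/{len(self.eye_vel)}"
            )
        if not (np.isfinite(self.t).all() and np.isfinite(self.head_vel).all()
                and np.isfinite(self.eye_vel).all()):
            raise MalformedRecordingError("trace contains non-finite values")
        dt = np.diff(self.t)
        if np.any(dt <= 0):
            raise MalformedRecordingError("time stamps must be strictly increasing")
        if self.sample_rate <= 0:
            raise MalformedRecordingError("sample_rate must be positive")
        nominal = 1.0 / self.sample_rate
        med = float(np.median(dt))
        if not (0.8 * nominal <= med <= 1.2 * nominal):
            raise MalformedRecordingError(
                f"median sample interval {med:.6g}s deviates more than 20% "
                f"from nominal {nominal:.6g}s"
            )

    def __len__(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> float:
        """Recorded time span in seconds (last minus first stamp)."""
        return float(self.t[-1] - self.t[0])

    @property
    def median_dt(self) -> float:
        return float(np.median(np.diff(self.t)))

    def replace(self, **changes) -> "VelocityTrace":
        return dataclasses.replace(self, **changes)


def _resolve_column(df: pd.DataFrame, key: ColumnKey, role: str) -> pd.Series:
    if isinstance(key, int):
        if key >= df.shape[1]:
            raise ConfigurationError(
                f"{role} column index {key} out of range (file has {df.shape[1]} columns)")
        return df.iloc[:, key]
    if key not in df.columns:
        raise ConfigurationError(f"{role} column {key!r} not found in file header")
    return df[key]


def _coerce_numeric(s: pd.Series, decimal_mark: str) -> pd.Series:
    if s.dtype == object:
        s = s.astype(str).str.strip()
        if decimal_mark != ".":
            s = s.str.replace(decimal_mark, ".", regex=False)
    return pd.to_numeric(s, errors="coerce")


def _last_marker_run(marker: pd.Series) -> np.ndarray:
    """Boolean mask of the final maximal run of equal marker values."""
    vals = marker.astype(str).to_numpy()
    idx = len(vals) - 1
    last = vals[idx]
    start = idx
    while start > 0 and vals[start - 1] == last:
        start -= 1
    mask = np.zeros(len(vals), dtype=bool)
    mask[start:] = True
    return mask


def read_vvor_csv(path: str | Path, dialect: CsvDialect = DEFAULT_DIALECT) -> VelocityTrace:
    """Read the last VVOR test block of a CSV export as a :class:`VelocityTrace`.

    Rows whose time, head or eye field does not parse as a number are dropped
    (the count is logged).  Gaps longer than ``GAP_FACTOR`` nominal sample
    intervals split the block; only the final segment is kept, with a warning.

    Raises
    ------
    ConfigurationError
        if a configured column is missing.
    EmptyRecordingError
        if no valid rows remain.
    MalformedRecordingError
        if time stamps are not strictly increasing after cleaning.
    """
    path = Path(path)
    has_names = any(isinstance(k, str) for k in
                    (dialect.column_time, dialect.column_head, dialect.column_eye,
                     *( [dialect.test_marker] if dialect.test_marker is not None else [] )))
    df = pd.read_csv(
        path,
        sep=dialect.delimiter,
        decimal=dialect.decimal_mark,
        header=0 if has_names else None,
        skipinitialspace=True,
        dtype=object,
    )
    if dialect.test_marker is not None:
        marker = _resolve_column(df, dialect.test_marker, "test_marker")
        df = df.loc[_last_marker_run(marker)]

    t = _coerce_numeric(_resolve_column(df, dialect.column_time, "time"), dialect.decimal_mark)
    head = _coerce_numeric(_resolve_column(df, dialect.column_head, "head"), dialect.decimal_mark)
    eye = _coerce_numeric(_resolve_column(df, dialect.column_eye, "eye"), dialect.decimal_mark)

    valid = t.notna() & head.notna() & eye.notna()
    n_dropped = int((~valid).sum())
    if n_dropped:
        logger.info("read_vvor_csv: dropped %d unparseable row(s) of %d", n_dropped, len(valid))
    t = t[valid].to_numpy(dtype=float)
    head = head[valid].to_numpy(dtype=float)
    eye = eye[valid].to_numpy(dtype=float)
    if len(t) == 0:
        raise EmptyRecordingError(f"{path}: no valid samples")
    if len(t) < 2:
        raise EmptyRecordingError(f"{path}: only one valid sample")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise MalformedRecordingError(f"{path}: time stamps not strictly increasing")

    nominal = float(np.median(dt))
    gaps = np.flatnonzero(dt > GAP_FACTOR * nominal)
    if gaps.size:
        start = int(gaps[-1]) + 1
        warnings.warn(
            f"{path}: {gaps.size} gap(s) longer than {GAP_FACTOR:g} sample "
            f"intervals; keeping only the final {len(t) - start}-sample segment",
            stacklevel=2,
        )
        t, head, eye = t[start:], head[start:], eye[start:]
        if len(t) < 2:
            raise EmptyRecordingError(f"{path}: final segment after gap split too short")
        nominal = float(np.median(np.diff(t)))

    return VelocityTrace(
        t=t, head_vel=head, eye_vel=eye,
        sample_rate=1.0 / nominal,
        source=str(path),
    )


#: Top-level blocks a complete analysis report must contain.
REQUIRED_REPORT_BLOCKS = ("params", "gain_auc", "gain_scp", "spectral", "saccades", "peaks")


def write_report(results: dict, path: str | Path) -> None:
    """Write an analysis report as deterministic, machine-parseable JSON.

    Keys are sorted and floats use Python's shortest round-trip repr, so the
    same results always produce byte-identical files.

    Raises :class:`IncompleteReportError` if a required block is missing.
    """
    missing = [k for k in REQUIRED_REPORT_BLOCKS if k not in results]
    if missing:
        raise IncompleteReportError(f"report missing required block(s): {missing}")
    text = json.dumps(results, sort_keys=True, indent=2, allow_nan=False) + "\n"
    Path(path).write_text(text, encoding="utf-8")


def read_report(path: str | Path) -> dict:
    """Parse a report written by :func:`write_report`."""
    return json.loads(Path(path).read_text(encoding="utf-8"))
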