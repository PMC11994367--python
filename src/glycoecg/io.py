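"""Reading and writing ECG text records and cohort feature tables.

The ECG dialect is the plain-text export of a two-channel acquisition
board: two columns (time, amplitude), whitespace- or comma-separated,
``#``-prefixed comment lines ignored. The time column may hold seconds or
an integer sample index; the index variant needs an explicit sampling
rate. Amplitudes are carried opaquely in whatever (ADC-scaled) unit the
file uses — every downstream computation is either scale-invariant or
thresholded relative to the signal itself.

Cohort tables are CSV with the header
``subject_id,glucose_mg_dl,hr_bpm,hrv_s,diagnosis`` ('.' decimal
separator, UTF-8); extra columns round-trip untouched.
"""

from __future__ import annotations

import io as _stdio
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (
    DialectError,
    EmptyInputError,
    MalformedRecordError,
    SchemaError,
)

#: Required cohort-table columns, in canonical order.
COHORT_COLUMNS = ("subject_id", "glucose_mg_dl", "hr_bpm", "hrv_s", "diagnosis")

#: Allowed values of the diagnosis column.
DIAGNOSES = ("healthy", "dm", "unknown")

#: Relative jitter in inter-sample spacing tolerated before the record is
#: rejected as irregularly sampled.
MAX_SPACING_JITTER = 0.01


@dataclass
class ECGRecord:
    """A uniformly sampled single-lead voltage trace.

    Attributes
    ----------
    samples:
        Amplitude array (arbitrary, ADC-scaled units).
    fs:
        Sampling rate in Hz.
    t0:
        Time of the first sample in seconds.
    subject_id:
        Optional identifier carried through the pipeline.
    """

    samples: np.ndarray
    fs: float
    t0: float = 0.0
    subject_id: str | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise MalformedRecordError("ECG samples must be one-dimensional")
        if self.samples.size < 2:
            raise MalformedRecordError("an ECG record needs at least 2 samples")
        if not self.fs > 0:
            raise MalformedRecordError(f"sampling rate must be positive, got {self.fs}")

    @property
    def n(self) -> int:
        return int(self.samples.size)

    @property
    def duration(self) -> float:
        """Record duration in seconds (n / fs)."""
        return self.n / self.fs

    @property
    def times(self) -> np.ndarray:
        """Per-sample timestamps implied by (t0, fs)."""
        return self.t0 + np.arange(self.n) / self.fs


def read_ecg_record(
    path: str | Path,
    expected_fs: float | None = None,
    subject_id: str | None = None,
) -> ECGRecord:
    """Read a two-column (time, amplitude) text file into an :class:`ECGRecord`.

    The sampling rate is estimated as the reciprocal of the median
    inter-sample interval. If the time column is an integer sample index
    (unit-spaced), ``expected_fs`` is required and used directly.

    Parameters
    ----------
    path:
        File with >= 2 rows of whitespace- or comma-separated pairs;
        lines starting with ``#`` are ignored.
    expected_fs:
        If given, the estimated rate must agree within 1%.

    Raises
    ------
    EmptyInputError, MalformedRecordError, DialectError
    """
    path = Path(path)
    try:
        frame = pd.read_csv(
            path, sep=r"[,\s]+", comment="#", header=None, engine="python"
        )
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"{path}: no data rows") from None
    if frame.shape[0] < 2:
        raise EmptyInputError(f"{path}: need at least 2 samples, got {frame.shape[0]}")
    if frame.shape[1] < 2:
        raise MalformedRecordError(f"{path}: expected two columns (time, amplitude)")
    try:
        t = frame.iloc[:, 0].to_numpy(dtype=float)
        x = frame.iloc[:, 1].to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise MalformedRecordError(f"{path}: non-numeric data ({exc})") from None

    dt = np.diff(t)
    if np.any(dt <= 0):
        raise MalformedRecordError(f"{path}: time column is not strictly increasing")

    is_index = np.allclose(t, np.round(t)) and np.allclose(dt, 1.0)
    if is_index:
        # Sample-index dialect: the file does not carry physical time.
        if expected_fs is None:
            raise DialectError(
                f"{path}: time column is a sample index; pass expected_fs"
            )
        return ECGRecord(samples=x, fs=float(expected_fs), t0=t[0] / expected_fs,
                         subject_id=subject_id)

    median_dt = float(np.median(dt))
    if np.max(np.abs(dt - median_dt)) > MAX_SPACING_JITTER * median_dt:
        raise DialectError(
            f"{path}: irregular sample spacing beyond "
            f"{MAX_SPACING_JITTER:.0%} of the median interval"
        )
    fs = 1.0 / median_dt
    if expected_fs is not None:
        if abs(fs - expected_fs) > 0.01 * expected_fs:
            raise DialectError(
                f"{path}: estimated rate {fs:.6g} Hz disagrees with "
                f"expected {expected_fs:.6g} Hz by more than 1%"
            )
        fs = float(expected_fs)  # nominal rate is authoritative once validated
    return ECGRecord(samples=x, fs=fs, t0=float(t[0]), subject_id=subject_id)


def write_ecg_record(path: str | Path, record: ECGRecord) -> None:
    """Write a record in the two-column text dialect (seconds, amplitude)."""
    data = np.column_stack([record.times, record.samples])
    header = "time_s amplitude"
    np.savetxt(path, data, fmt="%.9g", header=header)


# ---------------------------------------------------------------------------
# Cohort tables
# ---------------------------------------------------------------------------

def validate_cohort(table: pd.DataFrame, *, for_analysis: bool = False) -> pd.DataFrame:
    """Validate a cohort table against the schema and its invariants.

    Returns the table unchanged on success.

    Parameters
    ----------
    for_analysis:
        Additionally require no missing glucose and strictly positive
        glucose/HR (the precondition of correlation and classification).
    """
    missing = [c for c in COHORT_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"cohort table missing column(s): {', '.join(missing)}")
    for col in ("glucose_mg_dl", "hr_bpm", "hrv_s"):
        if not pd.api.types.is_numeric_dtype(table[col]):
            raise SchemaError(f"cohort column {col!r} is not numeric")
    bad_diag = set(table["diagnosis"].dropna().unique()) - set(DIAGNOSES)
    if bad_diag:
        raise SchemaError(f"unknown diagnosis value(s): {sorted(bad_diag)}")
    if len(table):
        if (table["hrv_s"].dropna() < 0).any():
            raise SchemaError("hrv_s must be non-negative")
        if for_analysis:
            if table["glucose_mg_dl"].isna().any():
                raise SchemaError("missing glucose in rows used for analysis")
            if (table["glucose_mg_dl"] <= 0).any():
                raise SchemaError("glucose must be positive")
            if (table["hr_bpm"].dropna() <= 0).any():
                raise SchemaError("hr_bpm must be positive")
    return table


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    """Read a cohort CSV, enforcing the five-column schema.

    Raises :class:`SchemaError` on a missing column and the pandas parse
    error (a ``ValueError``) on non-numeric numeric fields.
    """
    head = pd.read_csv(path, nrows=0)
    missing = [c for c in COHORT_COLUMNS if c not in head.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s): {', '.join(missing)}")
    table = pd.read_csv(
        path,
        dtype={"subject_id": str, "diagnosis": str},
        converters=None,
    )
    # Force numeric parsing errors to surface with a clear message.
    for col in ("glucose_mg_dl", "hr_bpm", "hrv_s"):
        try:
            table[col] = pd.to_numeric(table[col])
        except (TypeError, ValueError) as exc:
            raise SchemaError(f"{path}: column {col!r} is not numeric ({exc})") from None
    return validate_cohort(table)


def write_cohort_csv(path: str | Path, table: pd.DataFrame) -> None:
    """Write a cohort table as CSV.

    Floats are written with pandas' shortest round-trip representation,
    so ``read_cohort_csv(write_cohort_csv(t)) == t`` value-exactly.
    """
    validate_cohort(table)
    cols = list(COHORT_COLUMNS) + [c for c in table.columns if c not in COHORT_COLUMNS]
    table.loc[:, cols].to_csv(path, index=False)
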