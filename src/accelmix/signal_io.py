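"""Reading and writing traces, interval annotations, and feature tables.

All on-disk formats are plain delimited text:

* trace CSV — columns ``(t, ax, ay, az)`` or ``(ax, ay, az)``, header optional,
  acceleration in G (or m/s^2 with ``input_unit: ms2`` in the config);
* intervals CSV — ``recording_id, label, start_index, end_index, start_s, end_s``
  with 0-based half-open sample-index intervals;
* features CSV — one row per recording with the five mixture features plus
  the conventional overall mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import G_IN_MS2
from .errors import ConsistencyError, InputError, ParseError, SamplingError

#: tolerated relative deviation of inter-sample spacing from its median
_SPACING_TOL = 0.05
#: tolerated relative mismatch between inferred and user-supplied rate
_RATE_TOL = 0.01


@dataclass
class TriaxialTrace:
    """A fixed-rate tri-axial acceleration recording in G."""

    sample_rate_hz: float
    samples: np.ndarray  # shape (n, 3)
    recording_id: str = "trace"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise InputError(
                f"samples must have shape (n, 3), got {self.samples.shape}"
            )
        if len(self.samples) < 1:
            raise InputError("trace must contain at least one sample")
        if not np.isfinite(self.samples).all():
            raise InputError("trace contains non-finite samples")
        if not self.sample_rate_hz > 0:
            raise InputError(f"sample_rate_hz must be > 0, got {self.sample_rate_hz}")

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def duration_s(self) -> float:
        return len(self) / self.sample_rate_hz


def _infer_rate(t: np.ndarray, path: str) -> float:
    dt = np.diff(t)
    if len(dt) == 0:
        raise SamplingError(f"{path}: cannot infer sample rate from a single row")
    med = float(np.median(dt))
    if med <= 0:
        raise SamplingError(f"{path}: non-increasing time column")
    if np.any(np.abs(dt - med) > _SPACING_TOL * med):
        bad = int(np.argmax(np.abs(dt - med))) + 2
        raise SamplingError(
            f"{path}: irregular timestamps (spacing at data row {bad} deviates "
            f"more than {_SPACING_TOL:.0%} from the median {med:.6g} s)"
        )
    return 1.0 / med


def read_trace(
    path: str | Path,
    sample_rate_hz: float | None = None,
    recording_id: str | None = None,
    input_unit: str = "g",
) -> TriaxialTrace:
    """Read a delimited trace file with 3 (ax,ay,az) or 4 (t,ax,ay,az) columns.

    A time column, when present, wins for rate inference (median inter-sample
    spacing); a user-supplied rate that disagrees by more than 1% is an error,
    because the duration-based rest rule would silently break.
    """
    path = Path(path)
    import csv

    try:
        df = pd.read_csv(path, sep=None, engine="python", comment="#", header=None,
                         skip_blank_lines=True)
    except (pd.errors.EmptyDataError, csv.Error):
        raise InputError(f"{path}: empty or unreadable file") from None
    # optional header: first row non-numeric
    first = df.iloc[0]
    if not all(_is_number(v) for v in first):
        df = df.iloc[1:].reset_index(drop=True)
    if df.empty:
        raise InputError(f"{path}: no data rows")
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + 1
            raise ParseError(f"{path}: non-numeric value in data row {line}")
        if coerced.isna().any():
            line = int(coerced.isna().idxmax()) + 1
            raise ParseError(f"{path}: missing value in data row {line}")
        df[col] = coerced
    arr = df.to_numpy(dtype=float)
    if arr.shape[1] == 4:
        rate = _infer_rate(arr[:, 0], str(path))
        if sample_rate_hz is not None and abs(rate - sample_rate_hz) > _RATE_TOL * sample_rate_hz:
            raise SamplingError(
                f"{path}: inferred rate {rate:.4g} Hz disagrees with supplied "
                f"rate {sample_rate_hz:.4g} Hz by more than {_RATE_TOL:.0%}"
            )
        xyz = arr[:, 1:4]
    elif arr.shape[1] == 3:
        if sample_rate_hz is None:
            raise InputError(
                f"{path}: 3-column file has no time column; sample_rate_hz required"
            )
        rate, xyz = sample_rate_hz, arr
    else:
        raise InputError(
            f"{path}: expected 3 (ax,ay,az) or 4 (t,ax,ay,az) columns, got {arr.shape[1]}"
        )
    if input_unit == "ms2":
        xyz = xyz / G_IN_MS2
    return TriaxialTrace(sample_rate_hz=rate, samples=xyz,
                         recording_id=recording_id or path.stem)


def _is_number(v) -> bool:
    try:
        float(v)
        return True
    except (TypeError, ValueError):
        return False


def write_trace(trace: TriaxialTrace, path: str | Path, with_time: bool = True) -> None:
    """Write a trace as CSV; with a time column re-reading recovers the rate."""
    n = len(trace)
    cols = {}
    if with_time:
        cols["t"] = np.arange(n) / trace.sample_rate_hz
    cols.update(ax=trace.samples[:, 0], ay=trace.samples[:, 1], az=trace.samples[:, 2])
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.9g")


# ---------------------------------------------------------------------------
# interval annotations

INTERVAL_COLUMNS = ["recording_id", "label", "start_index", "end_index",
                    "start_s", "end_s"]


def write_intervals(intervals, path: str | Path) -> None:
    """Write an :class:`~accelmix.segmentation.IntervalSet` as CSV."""
    rows = [
        {
            "recording_id": intervals.recording_id,
            "label": lab,
            "start_index": s,
            "end_index": e,
            "start_s": s / intervals.sample_rate_hz,
            "end_s": e / intervals.sample_rate_hz,
        }
        for lab, s, e in intervals.intervals
    ]
    pd.DataFrame(rows, columns=INTERVAL_COLUMNS).to_csv(path, index=False,
                                                        float_format="%.17g")


def read_intervals(path: str | Path):
    """Read an intervals CSV back into an IntervalSet."""
    from .segmentation import IntervalSet  # local import avoids a cycle

    df = pd.read_csv(path)
    missing = set(INTERVAL_COLUMNS) - set(df.columns)
    if missing:
        raise InputError(f"{path}: missing interval column(s) {sorted(missing)}")
    if df.empty:
        return IntervalSet(recording_id="", sample_rate_hz=1.0, intervals=[])
    ids = df["recording_id"].unique()
    if len(ids) != 1:
        raise ConsistencyError(f"{path}: expected one recording_id, got {list(ids)}")
    n = int(df["end_index"].iloc[-1])
    dur = float(df["end_s"].iloc[-1])
    rate = n / dur if dur > 0 else 1.0
    return IntervalSet(
        recording_id=str(ids[0]),
        sample_rate_hz=rate,
        intervals=[(str(r.label), int(r.start_index), int(r.end_index))
                   for r in df.itertuples()],
    )


# ---------------------------------------------------------------------------
# feature tables

GMM_FEATURES = ["mu_low", "sigma_low", "mu_high", "sigma_high", "w_high"]
ALL_FEATURES = GMM_FEATURES + ["mu_total"]
FEATURE_COLUMNS = ["recording_id", "group"] + ALL_FEATURES


@dataclass
class FeatureTable:
    """Per-recording feature vectors with group labels.

    ``column_means``/``column_sds`` are populated by standardization so the
    z-scoring is exactly invertible.
    """

    data: pd.DataFrame
    standardized: bool = False
    column_means: dict = field(default_factory=dict)
    column_sds: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = set(FEATURE_COLUMNS) - set(self.data.columns)
        if missing:
            raise InputError(f"feature table missing column(s) {sorted(missing)}")
        self.data = self.data[FEATURE_COLUMNS].reset_index(drop=True)
        if self.data[ALL_FEATURES].isna().any().any():
            raise InputError("feature table contains missing values")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def groups(self) -> list:
        return sorted(self.data["group"].unique().tolist())


def write_features(table: FeatureTable, path: str | Path) -> None:
    table.data.to_csv(path, index=False, float_format="%.17g")


def read_features(path: str | Path) -> FeatureTable:
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise InputError(f"{path}: empty file") from None
    return FeatureTable(data=df)
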