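"""Rest / in-play segmentation of a match recording.

A sample belongs to a rest interval when the detector signal (5-s centered
moving average of the acceleration index) stays strictly below 0.3 G for at
least 5 s; every other sample is in-play. The minimum duration applies to
rest only — brief low-intensity dips inside a rally (waiting between shots)
merge into the surrounding in-play interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .config import RunConfig
from .errors import ConsistencyError, InputError
from .preprocess import ScalarSeries, moving_average

REST, IN_PLAY = "rest", "in_play"


@dataclass
class IntervalSet:
    """Ordered, non-overlapping labeled intervals tiling ``[0, n)``.

    Intervals are half-open ``[start_index, end_index)`` with labels in
    ``{"rest", "in_play"}``; adjacent intervals carry different labels.
    """

    recording_id: str
    sample_rate_hz: float
    intervals: list = field(default_factory=list)

    def __post_init__(self) -> None:
        prev_end, prev_label = 0, None
        for lab, s, e in self.intervals:
            if lab not in (REST, IN_PLAY):
                raise ConsistencyError(f"unknown interval label {lab!r}")
            if s != prev_end:
                raise ConsistencyError(
                    f"intervals must tile contiguously; gap/overlap at index {s}"
                )
            if e <= s:
                raise ConsistencyError(f"empty interval [{s}, {e})")
            if lab == prev_label:
                raise ConsistencyError(f"adjacent intervals share label {lab!r}")
            prev_end, prev_label = e, lab

    def __len__(self) -> int:
        return len(self.intervals)

    def __eq__(self, other) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return (
            self.recording_id == other.recording_id
            and self.intervals == [tuple(iv) for iv in other.intervals]
            and np.isclose(self.sample_rate_hz, other.sample_rate_hz,
                           rtol=1e-9, atol=0.0)
        )

    @property
    def n_samples(self) -> int:
        return self.intervals[-1][2] if self.intervals else 0

    def labels(self) -> np.ndarray:
        """Per-sample label array ('rest'/'in_play')."""
        out = np.empty(self.n_samples, dtype=object)
        for lab, s, e in self.intervals:
            out[s:e] = lab
        return out

    def duration_s(self, label: str) -> float:
        n = sum(e - s for lab, s, e in self.intervals if lab == label)
        return n / self.sample_rate_hz


def _runs(mask: np.ndarray):
    """Yield (start, end) of maximal True runs in a boolean array."""
    if mask.size == 0:
        return
    edges = np.flatnonzero(np.diff(mask.astype(np.int8)))
    starts = np.concatenate(([0], edges + 1))
    ends = np.concatenate((edges + 1, [mask.size]))
    for s, e in zip(starts, ends):
        if mask[s]:
            yield int(s), int(e)


def detect_intervals(index: ScalarSeries, cfg: RunConfig,
                     recording_id: str = "trace") -> IntervalSet:
    """Segment an acceleration-index series into rest and in-play intervals."""
    if index.kind != "acceleration_index":
        raise InputError(f"expected an acceleration_index series, got {index.kind!r}")
    detector = moving_average(index, cfg.detector_window_s, kind="detector_signal")
    below = detector.values < cfg.rest_threshold_g  # strict: ties are in-play
    min_run = int(round(cfg.rest_min_dur_s * index.sample_rate_hz))
    rest_mask = np.zeros(len(index), dtype=bool)
    for s, e in _runs(below):
        if e - s >= min_run:
            rest_mask[s:e] = True
    intervals = [((REST if is_rest else IN_PLAY), s, e)
                 for (s, e), is_rest in _labeled_runs(rest_mask)]
    return IntervalSet(recording_id=recording_id,
                       sample_rate_hz=index.sample_rate_hz, intervals=intervals)


def _labeled_runs(mask: np.ndarray):
    """Yield ((start, end), value) over maximal constant runs of a bool array."""
    edges = np.flatnonzero(np.diff(mask.astype(np.int8)))
    starts = np.concatenate(([0], edges + 1))
    ends = np.concatenate((edges + 1, [mask.size]))
    for s, e in zip(starts, ends):
        yield (int(s), int(e)), bool(mask[s])


def pool_in_play(index: ScalarSeries, intervals: IntervalSet) -> np.ndarray:
    """Concatenate the acceleration-index values inside in-play intervals."""
    if intervals.n_samples != len(index):
        raise ConsistencyError(
            f"intervals cover {intervals.n_samples} samples but the series "
            f"has {len(index)}"
        )
    parts = [index.values[s:e] for lab, s, e in intervals.intervals if lab == IN_PLAY]
    return np.concatenate(parts) if parts else np.empty(0)


class RestSegmenter(BaseEstimator):
    """Estimator-style wrapper around the rest rule for index arrays.

    ``fit_predict`` labels every sample 1 (in-play) or 0 (rest) and stores
    the interval decomposition in ``intervals_``.
    """

    def __init__(self, sample_rate_hz: float = 200.0,
                 detector_window_s: float = 5.0,
                 rest_threshold_g: float = 0.3, rest_min_dur_s: float = 5.0):
        self.sample_rate_hz = sample_rate_hz
        self.detector_window_s = detector_window_s
        self.rest_threshold_g = rest_threshold_g
        self.rest_min_dur_s = rest_min_dur_s

    def fit_predict(self, X, y=None) -> np.ndarray:
        series = ScalarSeries(sample_rate_hz=self.sample_rate_hz,
                              values=np.asarray(X, dtype=float).ravel(),
                              kind="acceleration_index")
        cfg = RunConfig(detector_window_s=self.detector_window_s,
                        rest_threshold_g=self.rest_threshold_g,
                        rest_min_dur_s=self.rest_min_dur_s)
        self.intervals_ = detect_intervals(series, cfg)
        return (self.intervals_.labels() == IN_PLAY).astype(int)

    def fit(self, X, y=None):
        self.fit_predict(X)
        return self
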