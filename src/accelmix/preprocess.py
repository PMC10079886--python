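"""Raw tri-axial acceleration -> acceleration index.

The acceleration index is the 1-s centered moving average of the vector
norm of the band-pass-filtered (0.5-20 Hz, second-order Butterworth applied
forward-backward) tri-axial signal. Band-passing removes the gravity
component and slow baseline drift as well as high-frequency sensor noise,
so the index is a non-negative envelope of movement intensity in G.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from sklearn.base import BaseEstimator, TransformerMixin

from .config import RunConfig
from .errors import InputError, InputTooShortError
from .signal_io import TriaxialTrace

VALID_KINDS = ("norm", "acceleration_index", "detector_signal")


@dataclass
class ScalarSeries:
    """A single-channel series derived from a trace (norm, index, detector)."""

    sample_rate_hz: float
    values: np.ndarray
    kind: str = "norm"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise InputError("ScalarSeries values must be one-dimensional")
        if self.kind not in VALID_KINDS:
            raise InputError(f"kind must be one of {VALID_KINDS}, got {self.kind!r}")
        if self.kind in ("norm", "acceleration_index") and np.any(self.values < 0):
            raise InputError(f"{self.kind} series must be non-negative")
        if not self.sample_rate_hz > 0:
            raise InputError("sample_rate_hz must be > 0")

    def __len__(self) -> int:
        return len(self.values)


def _design_sos(order: int, low: float, high: float, fs: float) -> np.ndarray:
    return sps.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")


def _min_warmup_samples(band_low_hz: float, fs: float) -> int:
    # three time constants of the slowest (high-pass) corner
    return int(np.ceil(3.0 * fs / (2.0 * np.pi * band_low_hz)))


def bandpass_filter(trace: TriaxialTrace, cfg: RunConfig) -> TriaxialTrace:
    """Zero-phase Butterworth band-pass, each axis independently.

    Forward-backward application cancels phase, so interval boundaries found
    downstream are not shifted; the effective magnitude response is the
    squared single-pass response.
    """
    cfg.validate_for_rate(trace.sample_rate_hz)
    warmup = _min_warmup_samples(cfg.band_low_hz, trace.sample_rate_hz)
    if len(trace) < warmup:
        raise InputTooShortError(
            f"trace of {len(trace)} samples is shorter than the filter warm-up "
            f"({warmup} samples at {trace.sample_rate_hz} Hz)"
        )
    sos = _design_sos(cfg.filter_order, cfg.band_low_hz, cfg.band_high_hz,
                      trace.sample_rate_hz)
    filtered = sps.sosfiltfilt(sos, trace.samples, axis=0)
    return TriaxialTrace(sample_rate_hz=trace.sample_rate_hz, samples=filtered,
                         recording_id=trace.recording_id)


def filter_gain(freq_hz, cfg: RunConfig, sample_rate_hz: float):
    """Analytic magnitude response of the forward-backward filter at ``freq_hz``.

    Used as the oracle for pass/stop-band checks and by the synthetic
    generator's carrier calibration.
    """
    sos = _design_sos(cfg.filter_order, cfg.band_low_hz, cfg.band_high_hz,
                      sample_rate_hz)
    _, h = sps.sosfreqz(sos, worN=np.atleast_1d(freq_hz), fs=sample_rate_hz)
    gain = np.abs(h) ** 2  # forward-backward = squared magnitude
    return gain if np.ndim(freq_hz) else float(gain[0])


def vector_norm(trace: TriaxialTrace) -> ScalarSeries:
    """Euclidean norm sqrt(ax^2 + ay^2 + az^2) per sample."""
    return ScalarSeries(
        sample_rate_hz=trace.sample_rate_hz,
        values=np.linalg.norm(trace.samples, axis=1),
        kind="norm",
    )


def moving_average(series: ScalarSeries, window_s: float,
                   kind: str | None = None) -> ScalarSeries:
    """Centered moving mean; edges average over the available samples only.

    The window is rounded to the nearest sample count and forced odd so the
    window is symmetric about each sample; no padding data is fabricated at
    the recording boundaries.
    """
    if window_s <= 0:
        raise InputError("window_s must be > 0")
    w = int(round(window_s * series.sample_rate_hz))
    if w < 1:
        raise InputError(
            f"window of {window_s} s spans no samples at {series.sample_rate_hz} Hz"
        )
    if w % 2 == 0:
        w += 1
    if w > len(series):
        raise InputTooShortError(
            f"window of {w} samples exceeds series length {len(series)}"
        )
    kernel = np.ones(w)
    sums = np.convolve(series.values, kernel, mode="same")
    counts = np.convolve(np.ones(len(series)), kernel, mode="same")
    return ScalarSeries(sample_rate_hz=series.sample_rate_hz,
                        values=sums / counts, kind=kind or series.kind)


def acceleration_index(trace: TriaxialTrace, cfg: RunConfig) -> ScalarSeries:
    """Band-pass filter -> vector norm -> 1-s moving average, in G."""
    filtered = bandpass_filter(trace, cfg)
    norm = vector_norm(filtered)
    return moving_average(norm, cfg.index_window_s, kind="acceleration_index")


class AccelerationIndexer(BaseEstimator, TransformerMixin):
    """Transformer from raw (n, 3) acceleration arrays to the (n,) index.

    Parameters mirror :class:`~accelmix.config.RunConfig`; ``fit`` is a
    validation no-op so the transformer composes with sklearn pipelines.

    Examples
    --------
    >>> idx = AccelerationIndexer(sample_rate_hz=200.0)
    >>> index = idx.fit_transform(raw_xyz)            # doctest: +SKIP
    """

    def __init__(self, sample_rate_hz: float = 200.0, band_low_hz: float = 0.5,
                 band_high_hz: float = 20.0, filter_order: int = 2,
                 index_window_s: float = 1.0):
        self.sample_rate_hz = sample_rate_hz
        self.band_low_hz = band_low_hz
        self.band_high_hz = band_high_hz
        self.filter_order = filter_order
        self.index_window_s = index_window_s

    def _config(self) -> RunConfig:
        return RunConfig(band_low_hz=self.band_low_hz,
                         band_high_hz=self.band_high_hz,
                         filter_order=self.filter_order,
                         index_window_s=self.index_window_s)

    def fit(self, X, y=None):
        self._config().validate_for_rate(self.sample_rate_hz)
        self.n_features_in_ = 3
        return self

    def transform(self, X) -> np.ndarray:
        trace = TriaxialTrace(sample_rate_hz=self.sample_rate_hz,
                              samples=np.asarray(X, dtype=float))
        return acceleration_index(trace, self._config()).values
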