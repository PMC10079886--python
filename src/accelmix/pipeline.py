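"""End-to-end processing of one recording and cohort assembly helpers."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import RunConfig
from .features import conventional_mean
from .mixture import MixtureFit, fit_gmm_em
from .preprocess import ScalarSeries, acceleration_index
from .segmentation import IntervalSet, detect_intervals, pool_in_play
from .signal_io import TriaxialTrace


@dataclass
class ProcessResult:
    """Artifacts of the full pipeline on one recording."""

    recording_id: str
    index: ScalarSeries
    intervals: IntervalSet
    pool: np.ndarray
    fit: MixtureFit
    mu_total: float

    def feature_row(self, group: str = "") -> dict:
        return {
            "recording_id": self.recording_id,
            "group": group,
            "mu_low": self.fit.mu_low,
            "sigma_low": self.fit.sigma_low,
            "mu_high": self.fit.mu_high,
            "sigma_high": self.fit.sigma_high,
            "w_high": self.fit.w_high,
            "mu_total": self.mu_total,
        }


def process_recording(trace: TriaxialTrace,
                      cfg: RunConfig | None = None) -> ProcessResult:
    """Filter -> norm -> index -> segment -> pool -> mixture fit -> mu_total."""
    cfg = cfg or RunConfig()
    index = acceleration_index(trace, cfg)
    intervals = detect_intervals(index, cfg, recording_id=trace.recording_id)
    pool = pool_in_play(index, intervals)
    fit = fit_gmm_em(pool, cfg)
    mu_total = conventional_mean(trace, intervals,
                                 whole_recording=cfg.mu_total_whole_recording)
    return ProcessResult(recording_id=trace.recording_id, index=index,
                         intervals=intervals, pool=pool, fit=fit,
                         mu_total=mu_total)
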