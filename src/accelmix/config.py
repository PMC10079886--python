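"""Run configuration for the processing pipeline.

All method constants (filter band, smoothing windows, rest rule, EM
settings) live in a single :class:`RunConfig` so every stage of the
pipeline is driven by one reproducible record, serializable to YAML.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

from .errors import ConfigError

#: standard gravity, m/s^2 per G
G_IN_MS2 = 9.80665


@dataclass
class RunConfig:
    """Pipeline constants, in the units the method is defined in (G, s, Hz).

    Parameters
    ----------
    band_low_hz, band_high_hz : float
        Butterworth band-pass corner frequencies. The pass band rejects the
        gravity/baseline component (DC) and high-frequency sensor noise.
    filter_order : int
        Butterworth design order (applied forward-backward, so the
        magnitude response is that of twice the order).
    index_window_s : float
        Moving-average window producing the acceleration index.
    detector_window_s : float
        Second moving-average window producing the rest/in-play detector
        signal from the index.
    rest_threshold_g : float
        Detector level below which a sample is a rest candidate.
    rest_min_dur_s : float
        Minimum duration a sub-threshold run must last to count as rest.
    input_unit : str
        "g" (default) or "ms2"; traces supplied in m/s^2 are divided by
        9.80665 on read.
    em_tol, em_max_iter, em_n_init, em_seed, em_min_samples, em_var_floor
        EM settings for the two-component mixture fit. ``em_tol`` is the
        convergence threshold on the change in mean per-sample
        log-likelihood; ``em_var_floor`` (G^2) guards against singular
        components.
    mu_total_whole_recording : bool
        If True, the conventional mean is taken over the whole recording
        instead of the in-play samples only.
    """

    band_low_hz: float = 0.5
    band_high_hz: float = 20.0
    filter_order: int = 2
    index_window_s: float = 1.0
    detector_window_s: float = 5.0
    rest_threshold_g: float = 0.3
    rest_min_dur_s: float = 5.0
    input_unit: str = "g"
    em_tol: float = 1e-8
    em_max_iter: int = 500
    em_n_init: int = 10
    em_seed: int = 0
    em_min_samples: int = 100
    em_var_floor: float = 1e-6
    hist_bin_width_g: float = 0.02
    mu_total_whole_recording: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.band_low_hz < self.band_high_hz:
            raise ConfigError(
                f"need 0 < band_low_hz < band_high_hz, got "
                f"({self.band_low_hz}, {self.band_high_hz})"
            )
        if self.filter_order < 1:
            raise ConfigError("filter_order must be >= 1")
        for name in ("index_window_s", "detector_window_s", "rest_min_dur_s",
                     "rest_threshold_g", "em_tol", "em_var_floor",
                     "hist_bin_width_g"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        if self.input_unit not in ("g", "ms2"):
            raise ConfigError(f"input_unit must be 'g' or 'ms2', got {self.input_unit!r}")
        if self.em_n_init < 1 or self.em_max_iter < 1:
            raise ConfigError("em_n_init and em_max_iter must be >= 1")

    def validate_for_rate(self, sample_rate_hz: float) -> None:
        """Check the filter band against the Nyquist frequency of a trace."""
        if self.band_high_hz >= sample_rate_hz / 2:
            raise ConfigError(
                f"band_high_hz={self.band_high_hz} must be below the Nyquist "
                f"frequency {sample_rate_hz / 2} Hz"
            )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config field(s): {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if not isinstance(d, dict):
            raise ConfigError(f"config file {path} must contain a mapping")
        return cls.from_dict(d)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
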