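"""Ground-truth-annotated synthetic match data.

Two levels of synthesis:

* :func:`sample_mixture_pool` draws acceleration-index values directly from
  a specified two-component mixture (truncated at 0), for testing the EM
  fit in isolation;
* :func:`simulate_match` builds a full tri-axial raw trace with alternating
  rally/rest bouts. Within a rally a target intensity is re-drawn from the
  truth mixture at exponential dwell times and rendered as amplitude
  modulation of an in-band carrier; the carrier is written in quadrature on
  two axes so the instantaneous norm equals the envelope exactly, making
  the carrier-amplitude-to-index calibration analytic (:func:`carrier_gain`).

The continuous-time match "script" (bout structure, intensity dwells,
carrier) is built independently of the sample rate, so the same underlying
motion can be rendered at 200 Hz and 1,000 Hz for rate-invariance checks.
Sensor noise is parameterized as an amplitude spectral density so its
band-passed statistics are also rate-invariant.

Default bout durations follow the time structure the rest rule itself
induces on racket-sport matches: in-play bouts are multi-point active
periods of tens of seconds (log-normal, median 20 s) — the 5-s rest rule
only splits activity at quiet gaps of at least 5 s, so brief between-shot
walks stay inside a bout — separated by point- and game-break rests
(median 30 s, floored at 12 s, well above the rule's 5-s minimum so ground
truth is recoverable). Each in-play bout opens and closes with
high-intensity play (serve, closing stroke) over ``edge_high_s``, ramps up
and down over ``taper_s``, and never dwells below 0.3 G for more than
``max_low_run_s`` (default 6 s), mirroring the modeling assumption that
low-intensity movement inside active play does not persist long enough to
trip the rest rule.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import signal as sps

from .errors import ConfigError
from .segmentation import IN_PLAY, REST, IntervalSet
from .signal_io import ALL_FEATURES, FeatureTable, TriaxialTrace


@dataclass
class MixtureTruth:
    """True mixture parameters generating in-play intensities (G)."""

    mu_low: float = 0.25
    sigma_low: float = 0.05
    mu_high: float = 0.90
    sigma_high: float = 0.30
    w_high: float = 0.6

    def __post_init__(self) -> None:
        if self.sigma_low <= 0 or self.sigma_high <= 0:
            raise ConfigError("mixture sigmas must be > 0")
        if not 0.0 <= self.w_high <= 1.0:
            raise ConfigError(f"w_high must be in [0, 1], got {self.w_high}")
        if self.mu_low > self.mu_high:
            raise ConfigError("truth requires mu_low <= mu_high")

    @property
    def mean(self) -> float:
        """Mean of the (untruncated) mixture."""
        return (1.0 - self.w_high) * self.mu_low + self.w_high * self.mu_high


def sample_mixture_pool(truth: MixtureTruth, n: int,
                        seed_or_rng=0) -> tuple[np.ndarray, MixtureTruth]:
    """Draw ``n`` index values from ``truth``; negative draws are redrawn."""
    if n < 1:
        raise ConfigError("n must be >= 1")
    rng = _as_rng(seed_or_rng)
    hi = rng.random(n) < truth.w_high
    mu = np.where(hi, truth.mu_high, truth.mu_low)
    sd = np.where(hi, truth.sigma_high, truth.sigma_low)
    x = rng.normal(mu, sd)
    bad = x < 0
    while bad.any():  # truncate at 0 by redrawing within the chosen component
        x[bad] = rng.normal(mu[bad], sd[bad])
        bad = x < 0
    return x, truth


def _as_rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def carrier_gain(freq_hz: float, band_low_hz: float = 0.5,
                 band_high_hz: float = 20.0, order: int = 2) -> float:
    """Forward-backward band-pass gain at the carrier, analog prototype.

    The analog response is rate-free, so a script calibrated with it renders
    to (nearly) the same acceleration index at any sample rate; the digital
    filter's bilinear warping deviates from it by well under 1% inside the
    pass band.
    """
    b, a = sps.butter(order, [2 * np.pi * band_low_hz, 2 * np.pi * band_high_hz],
                      btype="bandpass", analog=True)
    _, h = sps.freqs(b, a, worN=[2 * np.pi * freq_hz])
    return float(np.abs(h[0]) ** 2)


@dataclass
class SynthMatchConfig:
    """Generator settings for one synthetic match recording."""

    sample_rate_hz: float = 200.0
    duration_s: float = 1800.0
    rally_median_s: float = 20.0
    rally_sdlog: float = 0.5
    rally_min_s: float = 6.0
    rest_median_s: float = 30.0
    rest_sdlog: float = 0.30
    rest_min_s: float = 12.0
    truth: MixtureTruth = field(default_factory=MixtureTruth)
    dwell_s: float = 3.5
    taper_s: float = 1.5
    edge_high_s: float = 2.5
    max_low_run_s: float = 6.0
    low_cutoff_g: float = 0.3
    edge_min_g: float = 0.6
    carrier_hz: float = 4.0
    carrier_jitter_hz: float = 1.0
    rest_amplitude_g: float = 0.05
    noise_asd: float = 0.002  # G per sqrt(Hz)
    gravity_g: tuple = (0.0, 0.0, 1.0)
    band_low_hz: float = 0.5
    band_high_hz: float = 20.0
    filter_order: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.truth, dict):
            self.truth = MixtureTruth(**self.truth)
        for name in ("sample_rate_hz", "duration_s", "rally_median_s",
                     "rest_median_s", "dwell_s", "rest_min_s", "rally_min_s"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        if not (self.band_low_hz < self.carrier_hz - self.carrier_jitter_hz
                and self.carrier_hz + self.carrier_jitter_hz < self.band_high_hz):
            raise ConfigError("carrier band must sit inside the filter pass band")
        if self.rest_amplitude_g < 0 or self.noise_asd < 0:
            raise ConfigError("rest_amplitude_g and noise_asd must be >= 0")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["gravity_g"] = list(self.gravity_g)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SynthMatchConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown match-config field(s): {sorted(unknown)}")
        d = dict(d)
        if "gravity_g" in d:
            d["gravity_g"] = tuple(d["gravity_g"])
        return cls(**d)


@dataclass
class MatchScript:
    """Sample-rate-free description of one match's motion."""

    bouts: list  # (label, start_s, end_s)
    segments: list  # (start_s, end_s, intensity_g) covering rally bouts
    carrier_hz: float
    carrier_phase: float
    truth: MixtureTruth
    duration_s: float


def _lognormal(rng, median, sdlog, floor):
    return max(float(rng.lognormal(np.log(median), sdlog)), floor)


def build_match_script(cfg: SynthMatchConfig,
                       rng: np.random.Generator | None = None) -> MatchScript:
    """Draw bout structure and intensity dwells in continuous time."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    if cfg.rest_amplitude_g >= cfg.low_cutoff_g:
        warnings.warn(
            "rest_amplitude_g >= low_cutoff_g: rest bouts are not separable "
            "from in-play and ground truth will be unrecoverable",
            stacklevel=2,
        )
    # alternating rally/rest bouts
    bouts, t = [], 0.0
    label = IN_PLAY
    while t < cfg.duration_s:
        if label == IN_PLAY:
            dur = _lognormal(rng, cfg.rally_median_s, cfg.rally_sdlog, cfg.rally_min_s)
        else:
            dur = _lognormal(rng, cfg.rest_median_s, cfg.rest_sdlog, cfg.rest_min_s)
        end = min(t + dur, cfg.duration_s)
        bouts.append((label, t, end))
        t = end
        label = REST if label == IN_PLAY else IN_PLAY
    # a trimmed trailing bout too short to register (a rest below the floor,
    # or a sliver of play) would be mislabeled by construction; fold it into
    # the preceding bout instead
    while len(bouts) > 1:
        lab, s, e = bouts[-1]
        floor = 8.0 if lab == REST else 5.0  # detectability under the 5-s rule
        if e - s >= floor:
            break
        bouts.pop()
        plab, ps, _ = bouts.pop()
        bouts.append((plab, ps, cfg.duration_s))

    # intensity dwells within each rally
    segments = []
    for lab, s, e in bouts:
        if lab != IN_PLAY:
            continue
        t, low_run = s, 0.0
        weak = cfg.low_cutoff_g + 0.1  # margin: near-threshold play is weak too
        while t < e:
            dwell = min(max(rng.exponential(cfg.dwell_s), 0.3), e - t)
            # serve at the start, closing stroke at the end: rally edges are
            # vigorous, and weak play never outlasts the cap
            edge = t < s + cfg.edge_high_s or t + dwell > e - cfg.edge_high_s
            force = edge or low_run + dwell > cfg.max_low_run_s
            intensity = _draw_intensity(rng, cfg.truth, force, cfg.edge_min_g)
            segments.append((t, t + dwell, intensity))
            # a brief vigorous stroke only partially offsets surrounding weak
            # play in the detector's ~6-s view, so it works the run down
            # instead of resetting it
            if intensity < weak:
                low_run += dwell
            else:
                low_run = max(0.0, low_run - 2.0 * dwell)
            t += dwell

    carrier = cfg.carrier_hz + rng.uniform(-cfg.carrier_jitter_hz,
                                           cfg.carrier_jitter_hz)
    phase = rng.uniform(0, 2 * np.pi)
    return MatchScript(bouts=bouts, segments=segments, carrier_hz=carrier,
                       carrier_phase=phase, truth=cfg.truth,
                       duration_s=cfg.duration_s)


def _draw_intensity(rng, truth: MixtureTruth, force_high: bool,
                    edge_min: float) -> float:
    floor = min(edge_min, truth.mu_high)  # keep feasible for weak truths
    for _ in range(1000):
        hi = force_high or rng.random() < truth.w_high
        x = rng.normal(truth.mu_high if hi else truth.mu_low,
                       truth.sigma_high if hi else truth.sigma_low)
        if x >= 0 and not (force_high and x < floor):
            return float(x)
    return truth.mu_high  # pragma: no cover - unreachable for sane truths


def render_script(script: MatchScript, cfg: SynthMatchConfig,
                  sample_rate_hz: float | None = None,
                  rng: np.random.Generator | None = None,
                  recording_id: str = "synthetic",
                  ) -> tuple[TriaxialTrace, IntervalSet]:
    """Render a script to a raw trace at the given sample rate."""
    rate = sample_rate_hz or cfg.sample_rate_hz
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 1)
    n = int(round(script.duration_s * rate))
    t = np.arange(n) / rate
    gain = carrier_gain(script.carrier_hz, cfg.band_low_hz, cfg.band_high_hz,
                        cfg.filter_order)
    envelope = np.full(n, cfg.rest_amplitude_g)
    for s, e, intensity in script.segments:
        i0, i1 = int(round(s * rate)), int(round(e * rate))
        envelope[i0:i1] = intensity / gain
    # players build up / wind down over ~a second at rally edges
    if cfg.taper_s > 0:
        for lab, s, e in script.bouts:
            if lab != IN_PLAY:
                continue
            half = min(cfg.taper_s, (e - s) / 2.0)
            edges = [(s, 1.0)]
            if e < script.duration_s - 1e-9:  # no wind-down at a cut-off end
                edges.append((e, -1.0))
            for edge, sign in edges:
                i0 = int(round((edge if sign > 0 else edge - half) * rate))
                i1 = int(round((edge + half if sign > 0 else edge) * rate))
                if i1 <= i0:
                    continue
                ramp = (np.arange(i1 - i0) + 0.5) / (i1 - i0)
                if sign < 0:
                    ramp = ramp[::-1]
                seg = envelope[i0:i1]
                envelope[i0:i1] = cfg.rest_amplitude_g + ramp * (
                    seg - cfg.rest_amplitude_g)
    omega = 2 * np.pi * script.carrier_hz
    xyz = np.zeros((n, 3))
    xyz[:, 0] = envelope * np.sin(omega * t + script.carrier_phase)
    xyz[:, 1] = envelope * np.cos(omega * t + script.carrier_phase)
    xyz += np.asarray(cfg.gravity_g)
    # white noise with rate-invariant spectral density
    xyz += rng.normal(0.0, cfg.noise_asd * np.sqrt(rate / 2.0), size=(n, 3))

    intervals = _bouts_to_intervals(script.bouts, rate, n, recording_id)
    trace = TriaxialTrace(sample_rate_hz=rate, samples=xyz,
                          recording_id=recording_id)
    return trace, intervals


def _bouts_to_intervals(bouts, rate, n, recording_id) -> IntervalSet:
    ivs, prev = [], 0
    for k, (lab, s, e) in enumerate(bouts):
        end = n if k == len(bouts) - 1 else int(round(e * rate))
        if end > prev:
            ivs.append((lab, prev, end))
            prev = end
    return IntervalSet(recording_id=recording_id, sample_rate_hz=rate,
                       intervals=ivs)


def simulate_match(cfg: SynthMatchConfig, recording_id: str = "synthetic",
                   ) -> tuple[TriaxialTrace, IntervalSet, MixtureTruth]:
    """Build and render one synthetic match, deterministic under ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    script = build_match_script(cfg, rng)
    trace, intervals = render_script(script, cfg, rng=rng,
                                     recording_id=recording_id)
    return trace, intervals, cfg.truth


# ---------------------------------------------------------------------------
# two-group cohorts


@dataclass
class ParamJitter:
    """Between-recording (player-level) variation of the truth parameters.

    ``amplitude`` is the log-sd of a multiplicative scale on the whole
    intensity profile (sensor placement, garment fit and anthropometrics
    scale measured trunk acceleration player-by-player); the remaining
    fields are additive sds on individual parameters.
    """

    amplitude: float = 0.16
    mu_low: float = 0.02
    sigma_low: float = 0.01
    mu_high: float = 0.05
    sigma_high: float = 0.03
    w_high: float = 0.15


@dataclass
class SynthCohortConfig:
    """Two-group cohort: a match-config template per group plus jitter."""

    groups: dict = field(default_factory=dict)  # name -> SynthMatchConfig
    n_per_group: int = 20
    jitter: ParamJitter = field(default_factory=ParamJitter)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.groups:
            self.groups = default_group_templates()
        self.groups = {
            name: (SynthMatchConfig.from_dict(g) if isinstance(g, dict) else g)
            for name, g in self.groups.items()
        }
        if isinstance(self.jitter, dict):
            self.jitter = ParamJitter(**self.jitter)
        if len(self.groups) != 2:
            raise ConfigError(
                f"exactly two groups required, got {sorted(self.groups)}"
            )
        if self.n_per_group < 2:
            raise ConfigError("n_per_group must be >= 2")

    def to_dict(self) -> dict:
        return {
            "groups": {k: g.to_dict() for k, g in self.groups.items()},
            "n_per_group": self.n_per_group,
            "jitter": dataclasses.asdict(self.jitter),
            "seed": self.seed,
        }

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SynthCohortConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if not isinstance(d, dict):
            raise ConfigError(f"cohort config {path} must be a mapping")
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def default_group_templates(**overrides) -> dict:
    """High-intensity group vs a group shifted down on the high side only.

    The low-side parameters and mixing weight are shared, echoing cohorts
    whose difference is confined to high-intensity play.
    """
    strong = SynthMatchConfig(truth=MixtureTruth(), **overrides)
    weak = SynthMatchConfig(
        truth=MixtureTruth(mu_high=0.78, sigma_high=0.15), **overrides)
    return {"group_hi": strong, "group_lo": weak}


@dataclass
class SynthRecording:
    recording_id: str
    group: str
    trace: TriaxialTrace
    truth_intervals: IntervalSet
    truth: MixtureTruth


def _jitter_truth(truth: MixtureTruth, jit: ParamJitter,
                  rng: np.random.Generator) -> MixtureTruth:
    scale = float(rng.lognormal(0.0, jit.amplitude))
    mu_low = max(scale * truth.mu_low + rng.normal(0, jit.mu_low), 0.05)
    sigma_low = max(scale * truth.sigma_low + rng.normal(0, jit.sigma_low), 0.01)
    mu_high = max(scale * truth.mu_high + rng.normal(0, jit.mu_high),
                  mu_low + 0.2)
    sigma_high = max(scale * truth.sigma_high + rng.normal(0, jit.sigma_high),
                     0.02)
    w_high = float(np.clip(truth.w_high + rng.normal(0, jit.w_high), 0.05, 0.95))
    return MixtureTruth(mu_low=mu_low, sigma_low=sigma_low, mu_high=mu_high,
                        sigma_high=sigma_high, w_high=w_high)


def simulate_cohort(cfg: SynthCohortConfig,
                    ) -> tuple[list[SynthRecording], FeatureTable]:
    """Simulate both groups; returns recordings plus the truth feature table.

    In the truth table the five mixture columns hold each recording's
    (jittered) generating parameters and ``mu_total`` holds the truth
    mixture mean — the intensity summary a conventional overall-mean method
    targets.
    """
    ss = np.random.SeedSequence(cfg.seed)
    children = ss.spawn(2 * cfg.n_per_group)
    recordings, rows = [], []
    k = 0
    for group in sorted(cfg.groups):
        template = cfg.groups[group]
        for i in range(cfg.n_per_group):
            rng = np.random.default_rng(children[k])
            k += 1
            truth = _jitter_truth(template.truth, cfg.jitter, rng)
            match_cfg = dataclasses.replace(template, truth=truth)
            rid = f"{group}_{i:03d}"
            script = build_match_script(match_cfg, rng)
            trace, intervals = render_script(script, match_cfg, rng=rng,
                                             recording_id=rid)
            recordings.append(SynthRecording(rid, group, trace, intervals, truth))
            rows.append({"recording_id": rid, "group": group,
                         "mu_low": truth.mu_low, "sigma_low": truth.sigma_low,
                         "mu_high": truth.mu_high,
                         "sigma_high": truth.sigma_high,
                         "w_high": truth.w_high, "mu_total": truth.mean})
    table = FeatureTable(data=pd.DataFrame(rows, columns=["recording_id",
                                                          "group"] + ALL_FEATURES))
    return recordings, table
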