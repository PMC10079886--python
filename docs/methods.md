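# Methods

## Signal model and processing chain

The pipeline turns a raw tri-axial trace (G, fixed sample rate) into five
mixture features plus one conventional feature per recording:

1. **Band-pass filter.** Second-order Butterworth, 0.5–20 Hz, designed at
   the trace's sample rate and applied forward-backward per axis
   (`scipy.signal.sosfiltfilt`). Forward-backward application cancels phase
   lag — interval boundaries found downstream are not shifted — at the cost
   of squaring the magnitude response (effective order 4). DC (gravity) and
   drift are rejected; a constant 1-G input leaves a residual below 0.01 G.
   Traces shorter than three time constants of the 0.5-Hz corner
   (≈ 1 s) are rejected rather than padded.
2. **Vector norm**, then a **centered moving average** (1-s window for the
   index; a further 5-s pass for the rest detector). Windows are rounded to
   an odd sample count so they are symmetric about each sample; at the
   recording edges the mean is taken over the available samples only — no
   padding data is fabricated. Centered windows keep the smoothed envelope
   aligned with the raw signal's peaks.
3. **Rest rule.** A sample is rest when the detector (5-s average of the
   index, i.e. a second smoothing pass over the 1-s index) stays *strictly*
   below 0.3 G throughout a run of at least 5 s; ties at exactly 0.3 G are
   in-play. The minimum duration applies to rest runs only: sub-5-s dips
   merge into surrounding in-play, on the assumption that genuinely low
   intensity movement during active play does not persist that long.
   Intervals are half-open sample-index ranges `[start, end)` that tile the
   recording; tiling is validated on construction.
4. **Mixture fit.** The pooled in-play index values are fitted with a
   univariate two-component Gaussian mixture by EM, on the raw samples (not
   on binned counts; histograms are produced only for display). The
   likelihood treats samples as independent; in-play index values are in
   fact strongly autocorrelated (smoothing, dwell times), so the fit is a
   quasi-likelihood fit — parameter estimates are consistent for the
   marginal distribution, while the reported log-likelihood should not be
   used for formal model comparison.
5. **Features.** Per-recording vectors (μ_low, σ_low, μ_high, σ_high,
   w_high, μ_total). μ_total is the mean of the *unfiltered* norm,
   restricted by default to in-play samples so both methods see the same
   exposure window (a flag switches to the whole recording). Cohort tables
   are z-scored per column over all rows of both groups pooled, with the
   n−1 standard deviation; means/sds are stored so the transform inverts
   exactly. Group contrasts: Euclidean distance between group-mean vectors
   over feature subsets, and two-class LDA (scikit-learn, equal priors,
   pooled covariance) reporting resubstitution accuracy — a k-fold option
   exists but is not the default, since the contrast of interest is
   in-sample separation of the two feature sets.

## EM details

- Convergence: improvement of the *mean per-sample* log-likelihood below
  `tol` (default 1e−8); scale-free across pool sizes. Cap 500 iterations.
- Initialization: the first run uses a deterministic median split (hard
  responsibilities below/above the sample median); the remaining
  `n_init − 1` (default 10 total) runs draw uniform random per-sample
  responsibilities from the seeded generator. The run with the best final
  log-likelihood wins. The median split almost always finds the global
  optimum on bimodal pools; the random restarts guard against local maxima.
- Degeneracy guards: variance floor 1e−6 G²; a run whose component mass
  falls below 1e−10 samples is discarded; if every run degenerates the fit
  raises instead of returning a singular component.
- Labeling: components are relabeled so μ_low ≤ μ_high, ties broken by
  σ_low ≤ σ_high, making the five features deterministic. The E-step is
  computed in log space (`logaddexp`), so extreme parameter values do not
  underflow.
- The log-likelihood recorded after each M-step is non-decreasing along a
  run (standard EM monotonicity); this is asserted in the tests to 1e−10
  per step, and the whole fit is affine-equivariant: fitting `a·x + b`
  moves means to `a·μ + b`, scales σ by `|a|`, and leaves weights unchanged
  (exactly, up to floating-point error, because both initializations are
  themselves affine-equivariant).

## The synthetic match generator

No public recordings exist for this task, so the generator is the package's
reference instrument. It emulates, in continuous time first (a "script"
independent of sample rate) and then rendered at any rate:

- **Bout structure.** Alternating in-play/rest bouts. In-play bouts are the
  multi-point active periods the 5-s rest rule itself induces — brief
  between-shot pauses stay inside a bout — drawn log-normal with median
  20 s (σ_log 0.5, floor 6 s). Rests (point and game breaks) are log-normal,
  median 30 s (σ_log 0.3, floor 12 s). The floor keeps every true rest well
  above the rule's 5-s minimum, so ground truth is recoverable; a trailing
  bout trimmed below detectability (8 s rest / 5 s play) is folded into its
  neighbor rather than emitted as an impossible sliver.
- **Intensity process.** Within a bout, a target intensity is redrawn from
  the truth mixture at exponential dwell times (mean 3.5 s) and held
  constant over the dwell. Defaults echo the reported peak structure:
  low ≈ 0.25 G (σ 0.05), high ≈ 0.9 G (σ 0.30), w_high 0.6. Draws are
  truncated at 0 (the index is a norm-derived quantity). Three guards make
  the truth segmentation recoverable and physically sensible: each bout
  opens and closes with vigorous play (serve / closing stroke) for 2.5 s at
  ≥ 0.6 G; near-threshold "weak" play (< 0.4 G) never accumulates more
  than 6 s, with brief strong strokes working the accumulated run down
  (2× their duration) rather than resetting it — mirroring what the 5-s
  detector average actually integrates; and the envelope ramps over 1.5 s
  at bout edges (players accelerate and decelerate, and a step envelope
  would be unphysical). A truncated recording end skips the wind-down ramp.
- **Rendering.** The intensity envelope amplitude-modulates an in-band
  carrier (4 ± 1 Hz, seeded) written in quadrature on two axes, so the
  instantaneous motion norm *equals* the envelope; the envelope is
  pre-divided by the analytic forward-backward filter gain at the carrier
  (analog Butterworth prototype, `carrier_gain`), making the
  carrier-amplitude-to-index map the identity by construction and the
  truth-vs-recovered comparison well defined. Rest bouts render a 0.05-G
  envelope. A gravity offset (default 1 G on z) is added, and white sensor
  noise is specified as an amplitude spectral density (default
  0.002 G/√Hz, i.e. a 0.02-G sample sd at 200 Hz): scaling the per-sample
  sd with √(rate/2) keeps the *band-passed* noise statistics identical
  across sample rates, which is what makes the same script render to the
  same features at 200 Hz and 1,000 Hz.
- **Cohorts.** Two group templates that differ only on the high-intensity
  side (μ_high 0.90/σ_high 0.30 vs μ_high 0.78/σ_high 0.15 — a group whose
  hard efforts are both weaker and more uniform), with per-recording
  player-level variation: a multiplicative amplitude factor (log-normal,
  log-sd 0.16) scaling the whole intensity profile, and additive jitter on
  individual parameters (sd: μ_low 0.02, σ_low 0.01, μ_high 0.05,
  σ_high 0.03, w_high 0.15). The amplitude factor models how sensor
  placement, garment fit and anthropometrics scale measured trunk
  acceleration from player to player, and the w_high jitter models
  between-player variation in how much of a match is high-intensity. Both
  are deliberate: they move the overall mean μ_total up and down in *both*
  groups, which is precisely the confound that makes the conventional
  absolute-scale summary a weaker discriminator than the high-side mixture
  features, whose group contrast is largely scale-relative.

### What the generator does and does not emulate

It reproduces the statistical structure the method operates on: alternating
bouts, a bimodal in-play intensity marginal, near-zero rest amplitude,
sensor noise, gravity, selectable sample rate. It does not attempt
biomechanically realistic stroke waveforms, orientation changes of the
sensor, heart-rate channels, or non-stationary fatigue effects. Passing
tests therefore demonstrate that the pipeline recovers known structure of
this kind, not that any particular real cohort separates.

### Known systematic distortions

The pipeline's own smoothing biases the recovered mixture relative to the
generating truth, and the tolerances in the tests account for them:
(1) the 1-s index average blends adjacent dwells, moving mass into the
valley between peaks; (2) bout-edge ramps and boundary placement errors
(≈ ±0.5 s around each rest boundary) leak low values into the pool, pulling
μ_low down by up to ~10–15%; (3) the vigorous bout edges inflate the
recovered w_high (≈ 0.75–0.85 against a nominal 0.6). Peak *locations* are
recovered within 15% per recording at default settings; w_high is reported
but not used as a recovery criterion on rendered traces (pool-level fits
recover it to ±0.03).

## Problem sizes and numerical choices

- Default match: 1800 s at 200 Hz (≈ 400 independent intensity draws
  in-play), the scale at which single-recording mixture estimates are
  stable. Segmentation and closure checks run 20 such matches.
- Cohort benchmark: 20 recordings per group, 600 s at 100 Hz, processed
  with `em_n_init=2, em_tol=1e−7` — the median-split initialization
  dominates on these pools, and the reduced settings keep a 20-replicate
  benchmark inside a coffee break without changing any outcome; replicated
  checks confirmed identical conclusions at the default EM settings.
- Rate-invariance check: one 600-s script rendered at 200 and 1,000 Hz;
  all six features agree within 2% (5% asserted).
- Histogram bin width for display: 0.02 G.
- File formats are plain CSV/YAML/JSON; interval files use 0-based
  half-open sample indices plus start/end seconds, and a time column in a
  trace file always wins for rate inference (a user-supplied rate that
  disagrees by > 1% is an error, because the 0.3 G / 5 s rule is
  duration-based and a silently wrong rate would corrupt it).

## Limitations

- The two-component model is fixed; no model-order selection is provided.
- Resubstitution accuracy overstates out-of-sample performance; with 20
  recordings per group, k-fold estimates (available via the library) are
  noisy but more honest for deployment claims.
- The m/s²-to-G conversion assumes standard gravity; device-specific
  calibration is out of scope.
- Whether a fit should be pooled per player rather than per recording is a
  study-design question; the package fits per recording and leaves
  aggregation to the caller.
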