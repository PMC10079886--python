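# accelmix

External physical load from wearable tri-axial accelerometry, characterized
by a bimodal Gaussian mixture of the *acceleration index*.

## The problem

Trunk-mounted inertial sensors record tri-axial acceleration throughout a
competitive match. The conventional external-load summary — the mean of the
acceleration norm over the session — collapses everything a player did into
one number, so two players with very different intensity *profiles* (one
mixing walking with frequent sprints, the other moving at a steady moderate
pace) can look identical. `accelmix` implements a distribution-based
alternative for racket-sport-style activity with alternating play and rest:

1. **Acceleration index.** Each axis is band-pass filtered (second-order
   Butterworth, 0.5–20 Hz, applied forward-backward), removing gravity and
   baseline drift; the vector norm `sqrt(ax² + ay² + az²)` is smoothed with
   a centered 1-s moving average. The result is a non-negative intensity
   envelope in G.
2. **Rest / in-play segmentation.** A 5-s moving average of the index is the
   detector signal; any maximal period where it stays below 0.3 G for at
   least 5 s is a rest interval, everything else is in-play.
3. **Mixture model.** The in-play index values form a bimodal histogram — a
   low-intensity peak (waiting, walking; ≈ 0.25 G) and a high-intensity
   peak (chasing, strokes; ≈ 0.9 G). Their density is modeled as

       p(x) = (1 − w_high)·N(x | μ_low, σ_low²) + w_high·N(x | μ_high, σ_high²)

   with the five parameters (μ_low, σ_low, μ_high, σ_high, w_high)
   estimated by maximum likelihood via the EM algorithm.
4. **Group comparison.** Per-recording feature vectors (the five mixture
   parameters plus the conventional mean μ_total of the raw norm) are
   z-scored over the cohort; groups are contrasted through Euclidean
   distances between group means over feature subsets and two-class linear
   discriminant analysis (equal priors, pooled covariance).

Because real match recordings of this kind are not publicly deposited, the
package ships a first-class synthetic match generator (`accelmix.synth`)
that renders ground-truth-annotated raw traces — alternating play/rest
bouts, mixture-distributed in-play intensities on an in-band carrier,
sensor noise, gravity offset — so every stage is testable end to end.

## Worked example

```python
import accelmix as am

match = am.SynthMatchConfig(duration_s=600.0, seed=7)
trace, truth_intervals, truth = am.simulate_match(match)
result = am.process_recording(trace)

fit = result.fit
print(f"in-play: {result.intervals.duration_s('in_play'):.1f} s "
      f"({len(result.pool)} index samples)")
print(f"mu_low  = {fit.mu_low:.3f} G   (truth {truth.mu_low:.2f})")
print(f"mu_high = {fit.mu_high:.3f} G   (truth {truth.mu_high:.2f})")
print(f"w_high  = {fit.w_high:.3f}")
print(f"mu_total (conventional) = {result.mu_total:.3f} G")
```

prints

```
in-play: 234.7 s (46940 index samples)
mu_low  = 0.209 G   (truth 0.25)
mu_high = 0.899 G   (truth 0.90)
w_high  = 0.771
mu_total (conventional) = 1.289 G
```

The recovered peak locations sit at the generating truth (the low peak is
pulled down slightly by bout-edge transitions; the mixing weight counts the
vigorous bout edges as high-intensity time — see `docs/methods.md`).
μ_total, computed on the raw unfiltered norm, is dominated by the ~1 G
gravity component, which is exactly why it discriminates intensity profiles
poorly.

The same pipeline is available from the shell:

```bash
accelmix simulate -o sim/                 # two-group synthetic cohort
accelmix process sim/group_hi_*.csv -o out/hi --group group_hi
accelmix compare features.csv -o cmp/     # distances + LDA report
accelmix plot sim/group_hi_000.csv -o fig.png
```

The sklearn-style estimators (`AccelerationIndexer`, `RestSegmenter`,
`IntensityMixture`) compose with scikit-learn pipelines; the module-level
functions (`acceleration_index`, `detect_intervals`, `fit_gmm_em`, ...) are
thin wrappers over them.

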