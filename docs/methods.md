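# Methods

This note records the modelling conventions, parameter choices and
numerical decisions behind `whiskadapt`, in the spirit of a model
description a maintainer can audit.  It states no empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Whisker geometry

A whisker in one 1 kHz video frame is a quadratic 3D Bezier curve defined
by three control points (point 0 closest to the base).  Its unsigned
curvature is the standard space-curve expression
κ₃D(s) = |b′(s) × b″(s)| / |b′(s)|³ (1/mm); for a quadratic curve b″ is
constant, so the formula is evaluated in closed form.  Conventions:

* **Degenerate tangent** (|b′(s)| = 0, coincident control points):
  curvature is reported as 0 with a `DegenerateCurveWarning`.  This occurs
  only for pathological tracking output.
* **Sign of Δκ₃D.**  κ₃D is unsigned; the signed strength is defined as
  κ_contact − κ_rest and is negative when contact straightens the whisker.
  No osculating-plane signed-curvature convention is attempted.
* **Resting curvature κ₃D,0** is estimated per whisker per trial as the
  *median* of κ₃D(0) over all contact-free frames of that trial.  The
  median is robust to tracking noise; a single-frame or mean-based
  estimate would be dominated by outlier frames.
* **Touch strength** is the mean of Δκ₃D(0) over the half-open window
  [onset, onset + 5 ms) — exactly 5 frames at 1 kHz.  Missing frames are a
  hard error listing the absent timestamps.
* **Base kinematics.**  D_b is the Euclidean displacement of control
  point 0 between touch onset and onset + 5 ms; base speed is D_b/Δt
  (mm/ms).
* Units are mm and ms throughout; curvature 1/mm.

## Touch sequences

Touch order within a trial is assigned by ascending onset irrespective of
whisker identity; simultaneous onsets across whiskers are tie-broken by
ascending whisker label and flagged.  Overlapping touches of the same
whisker are treated as a tracking inconsistency (error).  Touch overlap
between whiskers is tested on closed intervals [onset, offset].

"Later touch" thresholds are configuration keys: the first-vs-later
dichotomy uses order ≥ 2 by default, the whisker-specific analysis fits
adapted-state curves on order ≥ 3, and the adapted-asymptote prediction
ratios fit on order > 4.

### Adapting/test selection

A trial enters the whisker-specific analysis when its first two touches
were made by the same (adapting) whisker, a 3rd-or-later touch was made by
the other (test) whisker, and that touch overlaps no touch of another
whisker.  Because the first two touches belong to the adapting whisker,
the *first* qualifying test touch is necessarily the test whisker's first
touch of the trial and therefore probes the unadapted state; we take one
test touch per eligible trial for this reason.  Adapted-state tuning
curves for the test whisker pool that whisker's order ≥ 3 touches from
*all* trials of the session (not only the eligible ones), excluding the
test touches themselves; pooling maximises the fit sample and the
exclusion keeps the prediction out-of-sample.

## Spike metrics

* Responses are spike counts in half-open 30 ms windows starting at touch
  onset; pre-touch activity uses the matching window before onset.
* **Responsiveness screen:** one-sided Wilcoxon signed-rank on
  (post − pre) pairs at α = 0.05, requiring ≥ 10 touches (fewer is
  reported as undetermined).  Counts are non-Gaussian, hence a rank test.
* **Latency** is the first time in the 30 ms after onset at which the
  1 ms-resolution PSTH exceeds the pre-touch baseline mean + 2 SD
  (baseline = 30 ms before onset); undefined if never exceeded.  This
  threshold rule is the least-constrained convention in the package — it
  is a reasonable default, not a canonical definition — and is isolated in
  `latency_from_rates` so alternatives can be swapped in.
* **ROC discriminability** is the normalised Mann–Whitney statistic
  P(s > n) + ½P(s = n), i.e. the AUC traced by sweeping an integer count
  threshold.  Noise counts come from deterministic tilings of touch-free
  periods: for first touches, 30 ms windows tiling the interval between
  pole presentation and first touch onset; for later touches, windows
  tiling inter-touch gaps starting 30 ms after the previous onset.  All
  available non-overlapping windows are used; nothing is sampled randomly.
* **Population response** is the per-touch sum of the simultaneously
  recorded units' 30 ms counts.

## Tuning curves and the α index

* The 5 % of touches with greatest |Δκ₃D| are discarded before fitting
  (ceil(0.05 n) samples; ties broken by removing the later indices).
  Inputs with n < 20 are left unfiltered with a warning.
* Strengths are discretised into 4 equipopulated bins by sorted rank
  (stable over duplicates; bin counts differ by ≤ 1), and an OLS line is
  fitted to the 4 (bin mean strength, bin mean count) points.  Fitting on
  bin means rather than raw samples follows the standard tuning-curve
  recipe; raw-sample OLS can be emulated by setting `n_bins` to the sample
  count.
* The tuning abscissa is |Δκ₃D| for the adaptation analyses; signed Δκ₃D
  remains available for direction-resolved curves.
* **Degenerate fits** (all strengths, or all bin means, identical): the
  slope is undefined (NaN), the intercept is the mean count, and
  predictions are constant — each flagged with a warning.
* **Predictions are floored at 0 counts**: negative firing is unphysical
  and the linear fit can extrapolate below zero.
* **Cross-validation granularity.**  When a queried touch contributed to a
  curve's fit, the curve is refitted without it — one touch at a time,
  including re-filtering and re-binning (`loo_predictions`).  This is used
  for within-fit-set predictions (adapted-asymptote ratios).  For α, first
  touches never enter the later-touch fit, so no exclusion is needed; for
  the whisker-specific analysis, the test touches are excluded from the
  adapted-state fit wholesale.
* FR₁, FR_later and FR₁′ are **medians** of the population response
  (robust to bursty outlier counts); FR_later pools orders ≥ 2 by default
  (configurable).  α is undefined (NaN, flagged) when FR₁ = FR_later.
* The whisker-specific index I uses means over the (few) test touches, is
  antisymmetric in its arguments, and lies in [−1, 1] for non-negative
  rates; it is undefined when FR_test + FR_predicted ≤ 0.

## Session inclusion

A session is analysed when it has ≥ 40 Go trials and ≥ 2 touch-responsive
units.  Excluded sessions still get touch statistics and a summary naming
the failed criteria.

## The synthetic generator

The generator produces trials, touches, per-touch evoked counts, spike
trains and a ground-truth record.  Defaults describe the study-like
condition the pipeline targets: 135 trials per session, 55 % Go, 81 % hit
rate; touches per Go trial negative-binomial with mean ± SD 10.5 ± 5.7 on
hits and 5 ± 7.7 on misses (truncated to ≥ 1 — a Go trial is defined by
whisker-pole contact — which raises the realised miss mean above 5);
log-normal inter-touch intervals (median 45 ms, σ = 0.55, clipped to
≤ 200 ms) and durations (median 30 ms, σ = 0.7, minimum 6 ms so every
strength window lies within contact); log-normal |Δκ₃D| (median
0.02 1/mm, σ = 0.7) with random sign and geometric per-order motor decay
(default ratio 0.85, so strength roughly halves by the fifth touch).
Six units carry linear tuning (slope ≈ 60 counts per 1/mm, intercept
≈ 1.5 counts per 30 ms window) with step adaptation from the second touch
on: intercept ratio 0.32 and slope ratio 0.8.  The distribution families
and the slope ratio are descriptive choices (only histograms and summary
statistics constrain them), made once and labelled non-canonical.

Counts are Poisson with mean max(0, slope·|Δκ| + intercept); evoked
spikes are placed uniformly in [onset + 5, onset + 30) ms on top of
homogeneous 1 Hz background spiking (so spike-train-derived counts include
spontaneous activity, as real windows do).  In noiseless mode
(`noise="none"`) the count table holds the exact linear expectations and
no spike trains are emitted; this mode exists for exact limit-case tests.
When `whisker_specific` is set, the adaptation state tracks each whisker's
own touch count instead of the pooled order.

Randomness: one `numpy` Generator per trial, seeded by
(session seed, trial index), plus a dedicated stream for unit parameters —
partial regeneration is stable and identical seeds give byte-identical
tables.

`implied_alpha` evaluates the α equation on the generator's noiseless
*mean* rates, weighting later orders by the probability that a trial
reaches them.  Exact in the limit cases (0 for motor-only decay, 1 for
sensitivity-only decay); for mixed schedules it differs from the pipeline
estimate, which uses medians of log-normal mixtures, by up to ≈ 0.1.

### What the generator does not emulate

Whisking kinematics beyond a sinusoidal base translation; overlapping
multi-whisker contacts (touches never overlap, so the overlap-exclusion
branch of the trial selection is exercised only by hand-built tables);
touch-strength correlations within a trial beyond the order decay; bursty
or history-dependent spiking (counts are conditionally Poisson); any
coupling of behavioural outcome to simulated activity (hit/miss labels
are drawn independently).  Passing recovery tests therefore show the
estimators are consistent under the assumed generative model, not that
the model captures every property of real recordings.

## Problem sizes and determinism

Limit-case checks run on 60-trial noiseless sessions (≈ 550–600 touches);
the whisker-specific checks on 80-trial sessions; parameter recovery on 10
seeds × 500 trials with Poisson noise, chosen so that the median-based α
estimator's seed-to-seed spread (≈ 0.05–0.15) averages well inside the
±0.1 recovery band.  All analyses are deterministic given the input
tables; pipeline reruns produce byte-identical reports, and report
summaries carry a provenance block (config hash, seed, package version).

## Known limitations

* The latency rule and the rest-curvature median are package conventions,
  not field standards; both are isolated behind small functions.
* α is a ratio of medians and becomes unstable when the first-to-later
  attenuation (its denominator) is small; it is reported as NaN when the
  denominator is exactly zero, but no variance estimate accompanies it.
* Tuning fits assume linearity over the retained strength range; strongly
  sublinear units would bias FR₁′ upward.
* The bending moment M_z is not computed in absolute units (whisker
  stiffness is unknown); Δκ₃D serves as its proxy throughout.
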