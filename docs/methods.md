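# Methods

## Data model and conventions

A trace is a uniformly sampled current series `I[k]` (nA) with sampling rate
`fs` (Hz); sample `k` is at time `k/fs`. Indexing is 0-based and every event
is a half-open sample interval `[start, end)`, so the dwell in samples is
exactly `end − start`. Blockades are treated as *downward* excursions;
traces recorded with the opposite sign convention can be flipped
(`CurrentTrace.flipped()`, or `polarity="up"` in the CBED config).

On disk, traces are delimited text (`time_s,current_nA` or a single current
column) or little-endian float32 with a `key=value` sidecar carrying `fs`.
Delimited output prints 9 significant digits, so a text round trip is
lossless to that precision; event tables round-trip their integer indices
bit-exactly.

## CBED: mixture fit and valley threshold

The empirical current distribution of a stationary trace with blockades is
bimodal: a dominant baseline mode and a smaller blockade mode. CBED models
it as the two-component Gaussian mixture
`p(I) = π₀N(I|μ₀,σ₀²) + π₁N(I|μ₁,σ₁²)` and approximates the fit with
two-means clustering of the scalar samples:

* deterministic initialisation at the 10th/90th percentiles — 1-D two-means
  with ordered centroids has no label-switching ambiguity, and a
  deterministic start makes thresholds reproducible;
* Lloyd iterations until centroid movement < 1e-10 nA (in 1-D each
  iteration is just a midpoint threshold);
* weights, means and variances from the hard assignments (variance ddof=1).
  Responsibility-weighted (EM) estimates would be a refinement, not
  implemented: the hard assignment is the minimal reading of
  centroids-as-means, and on separated modes the difference is negligible.

The baseline component is the one with the larger weight (ties go to the
higher, less blocked, mean). A trace whose clusters cannot carry a variance
(all-equal values, or a cluster of fewer than 2 samples) raises a
degenerate-fit error that points the user to the adaptive detector. On
perfectly two-level traces the within-cluster variance is zero; it is
floored at `(1e-9 · centroid separation)²` so the valley remains solvable
(it lands at essentially the midpoint), preserving exact recovery of
noiseless rectangular events.

Equating the weighted component densities and taking logs gives a quadratic
`Aε² + Bε + C = 0` with

    A = 1/(2σ₁²) − 1/(2σ₀²)
    B = μ₀/σ₀² − μ₁/σ₁²
    C = μ₁²/(2σ₁²) − μ₀²/(2σ₀²) + ln(π₀σ₁/(π₁σ₀))

The root strictly between the means is the histogram valley and becomes the
vertical threshold; with equal variances the equation degenerates to a
linear one, solved directly. If no real root lies between the means (e.g. a
dominant, broad baseline completely covering a rare narrow mode) the
detector raises a threshold-fallback error rather than guessing. When two
roots lie inside the interval (possible with strongly unequal variances)
the one nearer the mean midpoint is taken — the other equality point is the
spurious far-side crossing of the wide component.

The duration (horizontal) threshold converts a minimum event duration
`τmin` into `Nmin = ⌈τmin·fs⌉` samples (ceiling, since a sample count is an
integer and the rule is "at least"). An event is a maximal run of samples
strictly below the vertical threshold of length ≥ `Nmin`; amplitude and
duration conditions are enforced jointly. The strictness matters in one
corner: a single above-threshold noise sample splits a run, so very deep
noise excursions inside an event can break it in two. At a depth/noise
ratio of 20 (the package's high-contrast regime) the probability is
negligible; at ratio 10 it occurs in a few percent of 100-event runs.

## Adaptive CBED

With a drifting open-pore current the global histogram smears and a fixed
threshold fails. The adaptive variant:

1. **Rolling-median baseline** `B[k]`: centered window of
   `N = round(W·fs)` samples, shrinking (never empty) at the edges; for even
   `N` the window is `[k−N/2, k+N/2−1]`. The median steps over blockades
   shorter than half the window, so `W` should be a few times the longest
   expected dwell; default `W = 0.5 s`. Implemented with pandas' rolling
   median (an order-statistics skip list, O(log N) per step), so 10⁷-sample
   traces remain desk-scale.
2. **Residual** `C[k] = I[k] − B[k]`.
3. **Threshold** `T = median(C) − α·SD(C)` over the whole corrected trace
   (ordinary SD, ddof=1), α = 1.5 by default. The residual's own statistics
   make the threshold self-adjust to the noise level.
4. **Calling**: flag `C[k] < T`; join flagged samples whose gaps (samples
   strictly between them) are ≤ `δmax`; each candidate spans first to last
   flagged sample; discard candidates failing the duration rule.

`δmax` defaults to 10% of the minimum event length `⌈fs·Δtmin⌉` (at least 1
sample) — wide enough to bridge single-sample noise recoveries inside an
event, far too narrow to merge distinct events. The duration rule counts
the candidate's full span, joined gaps included (`count_mode="span"`),
because a joined gap is by construction part of one blockade; counting only
flagged samples is available as `count_mode="flagged"`.

## Rough localization

A cheap pre-filter marks candidate regions so the change-point detectors do
not scan the full trace (their pruned/online costs degenerate on long
event-free stretches). The global mode thresholds the drop below the
baseline mean at `n·I_RMS`. Baseline statistics are estimated by iterative
lower-tail sigma-clipping: discard samples more than 2.5 running-SDs below
the running mean, recompute, repeat to a fixed point. On an event-free
trace nothing is clipped and the estimate is the plain sample mean/SD; with
blockades present the estimator stays calibrated for event occupancies well
beyond what a fixed trim fraction tolerates. The local mode maintains
mean/SD over the trailing window (default 50 samples) of *baseline-only*
samples and applies hysteresis: open a candidate when `I[k]` falls below
`mean − nS·SD`, close when it recovers above `mean − nE·SD`. While a
candidate is open the statistics are frozen, so the event cannot inflate
the local SD and close the region early. Regions are padded and merged.

## CUSUM

For a segment starting at `k0`, running mean `m_k` and variance `v_k`
(ddof=1; replaced by `σ²` when a fixed sigma is configured, floored at
`(1e-4·δ)²` otherwise since the first sample of a segment has no variance)
feed the per-sample log-likelihood increments for an up/down shift of
expected magnitude `δ`:

    s_p[k] =  (δ/v_k)(x[k] − m_k − δ/2)
    s_n[k] = −(δ/v_k)(x[k] − m_k + δ/2)

Cumulative sums `S_p, S_n` and clamped decision functions
`g = max(g + s, 0)` confirm a change when `g > h`; the change time is the
index minimising the corresponding cumulative sum since `k0` (earliest
index on ties — deterministic output). The detector then restarts from the
sample after the localized change with all state zeroed, which extends the
single-change scheme to whole traces. Down changes are paired with the next
up change to form events; an unrecovered blockade closes at the region end,
and a second down change while one is open is ignored with a warning.

## PELT

The Gaussian segment cost uses the ML (ddof=0) variance, under which the
quadratic term collapses to the segment length exactly — the standard
likelihood form, and the identity the tests assert. Constant segments are
floored at 1e-12 nA², far below any realistic noise power. Costs are O(1)
from prefix sums of `y` and `y²`.

The dynamic program minimises total cost plus `β` per change point.
Pruning discards a candidate last-change index `τ` once
`F(τ) + c(τ,t) > F(t)`, but — a subtlety with a minimum segment length of
2 — only from time `t + min_segment` on: before that, the dominating index
`t` is itself inadmissible as a last change point and removing `τ`
immediately can lose the optimum. With the delayed removal the result is
exactly the global optimum (verified against a no-pruning O(n²) DP on 200
short traces per acceptance run, and against full recursive enumeration at
n ≤ 12 in the unit tests). `β = "bic"` selects `2·ln n` — two parameters
(mean and variance) per additional segment; the package treats this as its
own standard choice of BIC form.

Segments are mapped to events by comparing each segment mean with the
midpoint of the two extreme segment means in its region: segments below
the midpoint are blockade-level, and consecutive blockade segments merge
into one event (an event with internal substates is still one event).

## Features and clustering

For an event `[start, end)` and a baseline reference (the mixture's μ₀ for
fixed CBED, the rolling median `B(t)` for adaptive CBED, the mean of up to
50 pre-event samples for CUSUM/PELT — each detector's own baseline estimate
is the natural reference), with `drop[k] = baseline − I[k]`:

* `dwell_s = (end − start)/fs`,
* `height_nA = max(drop) ≥ 0`,
* `mean_nA = −mean(drop)` — reported negative so that feature axes read as
  current *changes*; `|mean| ≤ height` always (the average drop cannot
  exceed the maximal drop; the value is clipped to the invariant when a
  pathological reference would violate it).

K-means on the `(mean, height)` plane uses scikit-learn's `KMeans`
(k-means++ initialisation, 10 restarts, seeded — deterministic given the
seed). Axes are raw nA by default; z-scoring is available but off, since
the two features share units and comparable scales.

## Synthetic traces

The generator produces `baseline + drift(t) − Σ depth·1[event] + N(0, σ)`:
rectangular two-level blockades (ground-truth features are then analytically
exact), optional linear or sinusoidal drift, Gaussian noise from a single
integer seed (same seed ⇒ identical trace). Event onsets round to the
nearest sample; dwells to the nearest count, minimum 1.

Default study conditions: baseline 1.0 nA, fs 50–100 kHz, dwell 3–6 ms,
depth 0.4 nA with noise SD 0.02 nA for the high-contrast stable-baseline
regime (depth/noise 20, histogram modes fully separated), and depth 0.3 nA
with a linear drift of 5× the depth across the trace for the drifting
solid-state regime. Detection scoring uses greedy one-to-one interval
matching: a detection matches a truth event when the intersection covers at
least `min_overlap` (0.8 in the headline numbers) of the truth interval.

What the generator does **not** emulate: 1/f and flicker noise, RC-filtered
(non-instantaneous) event edges, intra-event substates, amplifier/bandwidth
effects, event-rate clustering. Passing tests therefore demonstrate
correctness of the algorithms under their stated noise model, not
performance on any particular experimental recording; in particular the
rectangular-edge assumption makes boundary localization easier than for
band-limited real events.

## Problem sizes

The test suite and the acceptance script are sized for a single CPU:
benchmark traces of 1–4 s at 50–100 kHz (up to 2×10⁵ samples), 100-event
recovery runs, 500 random mixtures against a 1e-6-resolution grid oracle,
200 short traces for PELT optimality, 50 step configurations for CUSUM and
100 spike-rejection traces. These sizes give binomial error bars well below
the asserted margins while keeping a full run in seconds.

## Known limitations

* CBED's fixed variant requires a genuinely bimodal histogram; overlapping
  clusters raise explicit degenerate-fit or threshold-fallback errors
  instead of producing arbitrary thresholds (the adaptive variant is the
  intended fallback).
* The CUSUM event-pairing rule (down-then-up) and the PELT
  segment-labelling rule (midpoint of extreme segment means) are this
  package's choices for turning change points into counted events; other
  conventions would change event counts on pathological traces.
* The adaptive duration filter's default gap `δmax` and window `W` are
  package defaults, exposed in the config; appropriate values depend on the
  expected dwell-time scale.
* PELT's pruning loses effectiveness on long homogeneous stretches (cost
  approaches O(n²)); use rough localization for long traces, as the
  pipeline does by default in the CLI.
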