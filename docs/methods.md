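# Methods

## The detection model

`circacp` treats an actigraphy recording as a pseudo-cyclostationary
sequence: activity counts are independent draws whose distribution switches
between a wake regime and a sleep regime roughly once per ~24 h in each
direction. The detector exploits two facts about such data. First, the
*phase* of the alternation is strongly periodic, so a rigid periodic model
can locate each cycle even though it cannot express day-to-day variability
in the switch times. Second, the *distribution* of counts differs sharply
between regimes — wake counts are large and heavy-tailed, sleep counts are
small with a large excess of exact zeros — so within a region known to
contain exactly one switch, the switch is the most significant structural
break in distribution.

### Stage 1: cosinor segmentation

The cosinor model `r(t) = mes + amp·cos((t − φ)·2π/T)` is fitted to the
60 s epoch series with `T` fixed at 1440 min. For fixed `T` the model is
linear in `(mes, amp·cos(ωφ), amp·sin(ωφ))`, so the default solver is
ordinary least squares on the `(1, cos ωt, sin ωt)` basis — the exact
global minimizer of the SSE — followed by the analytic recovery of
`(amp, φ)` and normalization to `amp ≥ 0`, `φ ∈ [0, T)`. An iterative
nonlinear least-squares path is retained for parity and for the optional
Huber loss; because the SSE is non-convex in `φ`, it multi-starts over
`φ ∈ {φ₀, 0, T/4, T/2, 3T/4}` (with `φ₀` from the conventional initializer
`(mes, amp, φ) = (500, 550, 227)`, an opaque seed on the activity-count
scale of adult wrist actigraphy) and keeps the best SSE. The two solvers
agree to ~1e-12 on clean input; tests assert 1e-8.

The fitted curve is dichotomized at `min + 0.18·range`: epochs strictly
below the threshold are nocturnal. The 18% cutoff reflects the roughly
20% sleep proportion in ageing populations; on a pure cosine it implies a
nocturnal fraction of `1 − arccos(2·0.18 − 1)/π ≈ 0.279` of each cycle
(about 400 min), which is used as a closed-form oracle in tests. A flat
fitted curve (relative range ≤ 1e-8) has no day/night split and raises a
degenerate-rhythm error.

### Stage 2: Gamma change-point search

Within a window, counts are `y_k ~ Gamma(θ_k, ξ)` with common shape `ξ` and
a scale that switches once after epoch `k`. The location estimate minimizes
the modified information criterion: the profile −2 log-likelihood of the
two-regime model plus the edge penalty `λ·(2k/n − 1)²·log n`. Profiling the
scales (`θ̂₁ = S₁/(kξ)`, `θ̂₂ = S₂/((n−k)ξ)` with segment sums `S₁, S₂`)
reduces the location-dependent part to

```
2kξ·log S₁ + 2(n−k)ξ·log S₂ − 2kξ·log(kξ) − 2(n−k)ξ·log((n−k)ξ)
    + λ·(2k/n − 1)²·log n,
```

evaluated in O(n) for all `k` via cumulative sums. Equivalence to the
criterion computed from first-principles Gamma log-densities is asserted by
an exhaustive oracle test on hundreds of random windows.

Numerical and design choices:

- **Shape estimation.** `ξ` is the MLE under the homogeneous model,
  Newton-solved from `log ξ − ψ(ξ) = log(mean y) − mean(log y)` with the
  standard closed-form start, falling back to the moment estimator
  `mean²/var` on non-convergence. It is estimated once per window and held
  fixed across H0/H1 and all `k`: the model treats the shape as common and
  non-switching, and joint `(k, ξ)` profiling is deliberately avoided.
- **Zeros.** The Gamma log-likelihood needs positivity; counts are floored
  at `eps = 0.1` (configurable) before likelihood evaluation. `eps` is a
  data-scale quantity: the search is exactly invariant to rescaling all
  counts by `c > 0` when `ξ` is fixed *and* `eps` rescales with the data.
- **Penalty.** `λ = 50` by default. The penalty vanishes identically at
  `k = n/2` and grows toward the edges, where the short-side scale MLE is
  unstable; on homogeneous windows it pulls the (necessarily spurious)
  estimate toward the window centre.
- **Admissible range and ties.** `k ∈ [min_seg, n − min_seg]` with
  `min_seg = 30` epochs guarding degenerate edge MLEs; exact ties go to the
  candidate nearest the window midpoint, then to the smaller `k`.
- **No H0 acceptance.** Each window is constructed to straddle exactly one
  true transition, so a change point is always returned; the gap between
  the H0 BIC and the realized MIC is attached as a diagnostic
  (`h1_advantage`) but never gates detection.

### Windows and the second round

Search windows span midpoint-to-midpoint between adjacent rough cosinor
transitions (series ends for the outermost), guaranteeing exactly one true
transition per window under monophasic sleep; windows shorter than 240
epochs are dropped with a log record. A fixed `±T/4` window is available as
a configurable alternative. After the first pass, windows are rebuilt the
same way from the first-round change points — whose placement no longer
depends on the rigid cosinor phase — and the search re-runs once, with a
fresh shape estimate per window. One pass suffices because the first-round
locations are already within a cycle of the truth; windows too short to
re-search keep their first-round result. The change point `k` indexes the
last epoch of the old regime, so events are stamped at the start of epoch
`k+1`, the first epoch of the new regime.

## Screening

Recordings shorter than 5760 min (four days) are excluded; among the rest,
continuous wearing periods are maximal stretches containing no run of zero
counts longer than 120 min (a run of exactly 120 min does not split — the
rule is read as strictly-greater; the cap is configurable), and a longest
period of at least 5760 min is required. The splitting run is excluded from
both neighbouring periods, and all-zero segments are not wear. Detection
runs on the single longest wearing period. 30 s epochs are aggregated to
60 s by summing pairs — counts are additive intensities — truncating a
trailing odd epoch with a warning.

## Error detection

With two clusters (sleep/wake labels against raw counts), the
Calinski–Harabasz index is `SSB/ΣSSW · (n−2)`. Both the dichotomized
cosinor labels and the labels implied by the detected events (epochs from
SOT to next WOT are sleep; the stretch before the first event takes the
complementary state) are scored on the same counts; a subject is flagged
when the refined segmentation fails to beat the cosinor split by at least
100 CH units. Flagged subjects are excluded from validation summaries but
still written to results carrying the flag. Known false-positive mode:
when a subject's true sleep span happens to match the cosinor's ~400-min
nocturnal band, the cosinor split is already near-optimal and the delta is
small even though detection is accurate.

## Marker validation

Button-press markers are noisy: presses can be missing, duplicated, or far
from any transition, which defeats global sequence alignment — hence plain
proximity matching. For each estimated event, markers within ±180 min
(inclusive, after truncating both to whole minutes) are candidates; an SOT
keeps the latest, a WOT the earliest, and each marker pairs with at most
one event, assigned greedily in time order. Times are reported as minutes
since midnight; SOTs between 00:00 and noon (the configurable changeover)
get +1440 so a single night stays on a continuous axis, and the pair's
`diff` is the signed clock difference so the changeover cannot distort it.
Agreement per kind: Bland–Altman bias and `bias ± 1.96·SD` limits of
agreement, plus the median absolute difference; match rates use the total
estimated events of that kind as denominator.

## The synthetic generator

`synth` emulates exactly the structure the detector assumes — and is
therefore a power calculation, not a realism benchmark. Per 1-min slot the
regime follows a jittered schedule; counts are 0 with the regime's
inflation probability, else Gamma. Defaults, chosen as typical of an older
adult cohort wearing a wrist device:

| parameter | default | meaning |
|---|---|---|
| `mean_sot`, `mean_wot` | 1380, 420 min | sleep 23:00 → 07:00 (~8 h) |
| `day_jitter_sd` | 20 min | independent Gaussian jitter per onset |
| `theta_wake`, `theta_sleep` | 200, 10 | Gamma scales (counts) |
| `theta_winddown` | 45 | ≈ geometric mean of the two regimes |
| `xi` | 0.8 | shared Gamma shape (heavy-tailed counts) |
| `p0_wake`, `p0_sleep`, `p0_winddown` | 0.1, 0.6, 0.3 | zero inflation |
| `winddown_min` | 30 min | sedentary pre-sleep stretch |
| `marker_sd`, `marker_dropout` | 10 min, 0.2 | marker noise / forgetting |
| `n_days` | 7 | recording noon → ≥ noon |

`mean_sot` lives on an extended 0–2880 scale (≥ 1440 = after the following
midnight), which makes shifted schedules plain parameter presets
(`night_shift`: sleep 08:00 → 15:30; `irregular`: jitter 60 min). The
recording starts at noon and spans at least `n_days` full days, so every
simulated day contributes one SOT and one WOT flanked by data, and a 4-day
simulation passes screening. `simulate_cohort` can additionally scatter the
mean onsets between subjects (`between_subject_sd`, default 30 min) for
population-style experiments.

The wind-down regime is on by default because it reproduces a real
phenomenon: activity fades before sleep begins, so detected SOTs are biased
early by up to the wind-down length while WOTs are nearly unbiased — on
simulated cohorts the absolute WOT error distribution is stochastically
smaller than the SOT error distribution. What the generator does *not*
emulate: naps and polyphasic sleep, non-wear gaps, within-regime
autocorrelation and nonstationarity, device saturation, or markers pressed
at random non-transition times. Passing tests therefore demonstrate
correctness of the machinery under the model's own assumptions, not field
accuracy on real cohorts.

## Problem sizes and checks

The test suite and the acceptance script use desk-scale problems chosen so
every stochastic check has small Monte-Carlo error: 200 windows of n=200
for change-point recovery (expected recovery within ±5 epochs ≥ 95% at
scale contrast 2 → 80), consistency across n ∈ {100, 400, 1600} at a mild
2× contrast so the median relative error stays measurable, and a
20-subject × 7-day cohort for end-to-end recovery. Agreement statistics
against the generator's known marker noise are pooled over five replicate
cohorts (~1100 pairs) so the Monte-Carlo error of the SD estimate
(~0.2 min) is negligible next to the expected ±19.6 min limits of
agreement.

## Known limitations

- Monophasic sleep is assumed twice (window construction and the
  one-CP-per-window premise); polyphasic patterns need a different
  segmentation strategy (e.g. Gamma-mixture HMMs).
- The detector reports behavioural rest onset, not physiological sleep:
  long sedentary evenings pull SOT estimates early, a bias the wind-down
  simulation makes visible.
- Counts from true counting processes (step counters, occupancy sensors)
  would be better served by a Poisson change-point variant, which is out of
  scope here.
- The zero floor `eps` injects a small bias into the shape estimate for
  heavily zero-inflated windows; it is logged and configurable.
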