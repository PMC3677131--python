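# Methods

## Model

The agent is an event-based (information-processing) synchronizer: an
internal timekeeper generates the interval to its next event, and two
mechanisms adjust that interval from cycle to cycle.

**Adaptation.** Given the most recent asynchrony
`asyn_n = partner_onset_n − own_onset_n` (index-paired events; missed or
extra events are out of scope), the next onset and timekeeper period are

    t_{n+1} = t_n + T_n + (α + β) · asyn_n
    T_{n+1} = T_n + β · asyn_n

α (phase correction) shifts only the next event; β (period correction)
lastingly retunes the timekeeper. Noise-free consequences, all covered by
tests: `asyn = 0, T = stimulus period` is a fixed point for any gains;
with β = 0 and matched periods asynchronies contract iff 0 < α < 2 and
diverge for α > 2; with β = 0 and a period mismatch S − T the steady-state
asynchrony is (S − T)/α, and only β > 0 drives both the asynchrony to zero
and T to S; over a noise-free run T_final − T_initial = β · Σ asyn_n
exactly.

**Anticipation.** The partner's next interval is extrapolated by ordinary
least squares over the last k observed partner intervals (k ≥ 3 so the
linear system is over-determined; a quadratic trend needs k ≥ 4). The
within-window abscissa is 1..k and the trend is evaluated at k + 1 — any
affine re-indexing gives the same prediction, the convention is fixed only
for reproducibility. The agent schedules its next onset at the predicted
partner onset (coincidence planning). A mimic weight w ∈ [0, 1] moves the
agent from predictor to tracker in two coupled ways: the predicted interval
is the convex blend `(1−w)·extrapolation + w·last interval`, and the
scheduled own interval is `(1−w)·coincidence + w·predicted interval`. The
anchor blend matters: scheduling a copied interval *through* the
partner-anchored coincidence rule would produce own intervals
`2·y_n − y_{n−1}` — still a predictor. Own-anchored copying reproduces the
partner's previous interval exactly, which is what tracking means
operationally (lag-1 cross-correlation above lag-0). Until k partner
intervals exist the agent falls back to its adaptation output.

**Joint layer.** Each cycle the adaptation-planned and
anticipation-predicted intervals are compared. If their absolute
difference is within tolerance — a fixed number of ms, or a Weber fraction
of the current timekeeper period (default mode, 0.02, motivated by
just-noticeable differences for interval timing; fully configurable) — the
planned (adaptation) command executes, flagged `planned`; otherwise the
configured default mechanism's interval executes, flagged `default`. The
output is always exactly one of the two inputs. With default = adaptation
the joint layer only relabels flags, which is tested against the pure
adaptation trajectory.

## Noise arithmetic

Three independent Gaussian sources, each switchable by setting its SD to
zero, all pre-drawn from a per-agent seeded generator so a fixed
configuration is byte-reproducible:

* **perceptual** — added to the asynchrony before it enters the correction
  equations (switchable to veridical);
* **timekeeper** — added to each cycle's realized interval; the stored
  period T_n evolves only through period correction;
* **motor** — an additive per-event delay on produced onsets.

Events are chained on **produced** onsets (`t_n` in the update equation is
the actual previous onset) and agents perceive each other's produced
onsets — observable behaviour on both sides. Two consequences, both
asserted in tests: a fully phase-correcting agent (α = 1) against a
metronome has asynchronies equal to (minus) the current motor delay, so
their SD is σ_motor, and its produced intervals are
`T + m_{n+1} − m_n` with lag-1 autocovariance exactly −σ_motor²— the MA(1)
signature of two-level timing models. Under this arithmetic the dyad
asynchrony of two phase-correcting agents is AR(1) with innovation
variance σ_T² + σ_M², so the partner's asynchrony SD is minimized when the
total phase correction in the dyad is 1. Against a simulated partner with
α = 0.5, timekeeper SD 10 ms and motor SD 5 ms, the measured optimum for a
noise-free agent is therefore α ≈ 0.5 (the bidirectional sweep confirms a
U-shaped SD curve with its minimum there, inside the 0.3–0.5 range
reported for optimally adaptive partners). The classic alternative — a
planned-onset chain in which motor delays are differenced into the
asynchrony — would move that optimum to ≈ 0.33 but contradicts the two
single-agent noise signatures above; the produced-onset chain was chosen
and the alternative is noted here rather than silently assumed.

Period correction is applied on cycles whose executed command came from
the adaptation module (including `planned` and adaptation-default joint
cycles); anticipation-driven cycles leave the timekeeper untouched by
default, switchable via `period_update_on_anticipation`.

A scheduled interval or timekeeper period that becomes non-positive aborts
the run with a `DegenerateTimingError` carrying the cycle index; nothing
is clamped, so instability experiments report divergence explicitly. Gains
outside the documented operating ranges (α in [−1, 1], β in [0, 1]) are
accepted with a warning for exactly such experiments.

## Stimulus generators

Milliseconds throughout, first event at t = 0. Isochronous metronomes;
abrupt (step) tempo changes; sinusoidal tempo modulation
`IOI_i = base + amplitude·sin(2πi/period)` with amplitude < base so every
interval stays positive; and single-interval phase perturbations in which
one interval changes by a shift that permanently displaces all later
onsets (the phase-correction-response paradigm; a local-displacement-only
variant is deliberately not provided). These synthetic sequences emulate
the stimulus side of paced-tapping experiments; the simulated partner in
dyadic runs emulates a noisy human tapper as a phase-correcting agent with
timekeeper and motor noise. What they do not emulate: missed/extra taps,
heavy-tailed or long-range-correlated (fractal) timing noise, and
expressive musical timing — passing tests therefore speak to the model's
mechanics, not to those aspects of real tapping data.

## Estimators

* `estimate_alpha_ar` regresses `asyn_{n+1}` on `asyn_n` and returns
  1 − slope. Valid in the phase-only regime against a fixed metronome;
  attenuated when motor noise is present (errors-in-variables), which is
  documented and the reason the grid search exists.
* `estimate_pcr` averages `(asyn_c − asyn_{c+1}) / shift` over
  perturbation trials, where c is the first displaced stimulus event; for
  a noise-free phase-only agent this equals α exactly.
* `fit_params_gridsearch` re-simulates the observed stimulus at each
  candidate (α, β) with fresh seeds (shared across grid points, i.e.
  common random numbers) and minimizes the summed squared difference of
  five summary statistics: mean asynchrony, SD of asynchrony, lag-1
  asynchrony autocorrelation, SD of response intervals, and lag-1
  autocorrelation of response intervals. The autocorrelations are scaled
  by the corresponding observed SDs so all terms share ms units. Lag-0
  autocorrelations are identically 1 and carry no information. Summary
  statistics rather than per-event trajectories are compared because noise
  realizations differ; the statistic set is fixed. The interval statistics
  are what separates β from α (their sum governs the asynchrony dynamics);
  recovery is exercised against a step-tempo stimulus, which actually
  engages period correction — against a pure metronome (α, β) are only
  identified up to roughly their sum. Ties break toward smaller (α, β)
  lexicographically; a divergent grid point records an infinite loss.
  No bootstrap CIs or multiple-comparison control: estimators return point
  values.

Cross-correlations are Pearson coefficients on the overlapping windows
with per-window means, the standard convention in the tapping literature.
The prediction/tracking ratio is undefined (NaN, flagged) when the lag-1
coefficient is not positive, since the ratio presumes positive
correlations on tempo-changing sequences.

## Numerical and scale choices

* Contraction sweeps classify a gain as convergent when the final
  asynchrony magnitude is strictly below the initial one and divergent
  when it exceeds it (or the run aborts); α = 2.00, where the asynchrony
  alternates sign at constant magnitude, is marginal, and the reported
  boundary is the midpoint of the largest convergent and smallest
  divergent gain. A fixed smallness threshold is deliberately avoided: at
  200 cycles the contraction factor 0.95^199 ≈ 4·10⁻⁵ would misclassify
  gains just below 2 under any absolute cutoff tighter than that.
* Exact statements (fixed points, metronome reduction, cumulative period
  drift, PCR of noise-free agents) are asserted at machine precision or
  1e−9 ms; stochastic statements use seeded runs at sizes where their
  Monte-Carlo error is an order of magnitude below the asserted margin
  (10⁴–10⁵ cycles for noise signatures, 100 runs × 500 cycles per gain for
  the bidirectional sweep, 20 replicates × 500 cycles per grid point for
  recovery).
* The bidirectional loop is event-indexed: both agents produce event n
  before either produces n + 1. A zero-gain partner makes it collapse
  exactly onto the unidirectional loop, which is tested.

## Known limitations

Single decision layer (no hierarchy of internal models across timescales);
no real-time audio or human-in-the-loop operation; Gaussian noise only; no
event dropout/insertion; the AR and perturbation estimates of α need not
agree on real data — they measure partly different mechanisms, and
reconciling them is an open research question rather than an
implementation defect.
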