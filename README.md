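# adamsync

Simulation and analysis of **sensorimotor synchronization** (SMS): how an
agent — a finger tapper, a drummer, or a computer-controlled virtual
partner — keeps its periodic actions in time with a pacing sequence or with
another responsive agent.

The package implements a generative agent model that combines the two
classes of mechanism the tapping literature distinguishes:

* **Adaptation** (reactive error correction). With asynchrony
  `asyn_n = partner onset − own onset` at cycle *n*, an internal timekeeper
  period `T_n`, a phase-correction gain α and a period-correction gain β,

  ```
  t_{n+1} = t_n + T_n + (α + β) · asyn_n
  T_{n+1} = T_n + β · asyn_n
  ```

  Phase correction is a local, one-shot adjustment; period correction is a
  lasting change of the timekeeper. α = β = 0 is an unresponsive metronome,
  α = 1 is perfect one-step phase correction, and gains above 2 are
  unstable.

* **Anticipation** (predictive extrapolation). The partner's next
  inter-onset interval is predicted by an over-determined least-squares
  trend over the last *k* ≥ 3 observed intervals,
  `Int_{n+1} = a + b·(k+1)`, and the agent schedules its own next event to
  coincide with the predicted partner onset. A `mimic_weight` blends this
  predictor behaviour toward copying the partner's previous interval
  (tracking).

* A **joint decision layer** compares the adaptation-planned and
  anticipation-predicted intervals against a tolerance (absolute ms or a
  Weber fraction of the timekeeper period) and executes the planned command
  when they agree, the configured default mechanism otherwise.

Three Gaussian noise sources (perceptual, timekeeper, motor) can corrupt
each cycle. Analysis tools cover asynchrony accuracy/precision, lagged
cross-correlations of interval series, the **prediction/tracking ratio**
(lag-0 over lag-1 cross-correlation; > 1 = predictor, < 1 = tracker), the
AR-regression and perturbation (phase-correction-response) estimators of α,
and simulation-based grid-search fitting of (α, β).

## Worked example

A noise-free anticipatory agent (k = 3, linear fit) synchronizing with a
sinusoidally tempo-modulated sequence (base 500 ms, ±50 ms over 20 events):

```python
import numpy as np
from adamsync import (AdaptParams, AgentSpec, AnticipParams,
                      asynchrony_stats, gen_sinusoidal_tempo,
                      simulate_unidirectional)

stim = gen_sinusoidal_tempo(500, 50, 20, 200)
agent = AgentSpec(adapt=AdaptParams(alpha=1.0),
                  anticip=AnticipParams(k=3, order=1, mimic_weight=0.0),
                  base_period_ms=500.0)
rec = simulate_unidirectional(stim, agent, n_warmup=4)
rep = asynchrony_stats(rec)
print(f"mean asyn {rep.mean_asyn_ms:.3f} ms, sd {rep.sd_asyn_ms:.3f} ms")
print(f"lag-0 cc {rep.cc[0]:.3f}, lag-1 cc {rep.cc[1]:.3f}, "
      f"P/T ratio {rep.pt_ratio:.3f}")
```

prints

```
mean asyn -0.043 ms, sd 5.752 ms
lag-0 cc 0.999, lag-1 cc 0.939, P/T ratio 1.064
```

The agent's intervals match the current stimulus intervals almost
perfectly (lag-0 ≈ 1) and better than the previous ones, so the
prediction/tracking ratio exceeds 1: the agent *predicts* the tempo
changes. Setting `mimic_weight=1.0` makes it copy the partner's previous
interval instead, and the same analysis yields a ratio of 0.953 — a
tracker. The small residual asynchrony SD (5.75 ms) is the linear trend's
local error on a curved tempo profile.

The same runs are available from the shell:

```sh
adamsync generate --kind sinusoidal --base-ioi 500 --amplitude 50 \
    --period-events 20 --n 200 --out stim.csv
adamsync simulate --coupling uni --stimulus stim.csv --mechanism anticipation \
    --alpha 1.0 --k 3 --warmup 4 --out run.csv
adamsync analyze --record run.csv
```

`simulate` writes the per-cycle trace
(`cycle,partner_onset_ms,adam_onset_ms,asynchrony_ms,timekeeper_ms,mechanism`)
plus a metadata sidecar JSON; runs with the same configuration and seed are
byte-identical. Exit codes: 0 success, 2 usage, 3 data/validation,
4 numerical divergence.

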