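"""Packaged desk-scale experiments.

Each function runs one of the model's canonical studies end to end with the
library's own simulators and returns plain numbers, so the same code path
serves scripted reproduction and the test suite:

* a gain sweep locating perfect phase correction (alpha = 1 cancels an
  induced asynchrony on the very next event);
* a gain sweep locating the stability boundary of phase correction
  (contraction below alpha = 2, divergence above);
* the metronome-reduction grid (only zero gains make the output intervals
  invariant to a jittered partner);
* the predictor signature of the anticipation module on a sinusoidally
  tempo-modulated sequence (prediction/tracking ratio above 1);
* the bidirectional sweep for the adaptive-partner gain that minimizes a
  simulated noisy partner's asynchrony variability.
"""

from __future__ import annotations

import warnings
from contextlib import contextmanager

import numpy as np

from .adaptation import AdaptParams, AdaptState, run_adaptation_noise_free
from .analysis import pt_ratio
from .anticipation import AnticipParams
from .errors import DegenerateTimingError
from .simulation import AgentSpec, NoiseParams, simulate_bidirectional, simulate_unidirectional
from .timing import IntervalSeries, OnsetSequence, gen_isochronous, gen_sinusoidal_tempo

__all__ = [
    "perfect_phase_correction_sweep",
    "stability_boundary_sweep",
    "metronome_invariance_grid",
    "predictor_signature",
    "optimal_coupled_gain_sweep",
]

CONVERGENT = "convergent"
DIVERGENT = "divergent"
MARGINAL = "marginal"


@contextmanager
def _allow_extreme_gains():
    """Instability sweeps deliberately exceed the documented gain range."""
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*outside the documented operating range.*")
        yield


def perfect_phase_correction_sweep(
    alphas=None,
    base_ioi: float = 500.0,
    initial_asyn: float = 30.0,
) -> float:
    """Find the phase gain that cancels an induced asynchrony in one step.

    A noise-free phase-only agent synchronizes with a matched isochronous
    metronome, starting with a single imposed asynchrony.  Returns the
    unique alpha in the sweep for which the next event's asynchrony is
    exactly zero.
    """
    if alphas is None:
        alphas = np.round(np.arange(0.1, 1.5001, 0.1), 10)
    stimulus = gen_isochronous(base_ioi, 4)
    hits = []
    with _allow_extreme_gains():
        for alpha in alphas:
            rec = run_adaptation_noise_free(
                stimulus,
                AdaptParams(alpha=float(alpha), beta=0.0),
                AdaptState(timekeeper_ms=base_ioi),
                first_onset=stimulus.onsets[0] - initial_asyn,
            )
            if abs(rec.asynchronies_ms[1]) < 1e-12:
                hits.append(float(alpha))
    if len(hits) != 1:
        raise RuntimeError(f"expected a unique cancelling gain, found {hits}")
    return hits[0]


def stability_boundary_sweep(
    alphas=None,
    n_cycles: int = 200,
    base_ioi: float = 500.0,
    initial_asyn: float = 50.0,
) -> dict:
    """Classify phase-only gains as convergent or divergent and locate the boundary.

    For each gain the noise-free recursion ``asyn_{n+1} = (1 - alpha) *
    asyn_n`` is realized by simulating against a matched metronome with an
    initial asynchrony.  A run whose final asynchrony magnitude shrank
    below the initial one is convergent; one that grew beyond it (or
    aborted on a degenerate interval) is divergent; the knife-edge case
    (alpha = 2, where the asynchrony alternates sign at constant magnitude)
    is marginal.  The reported boundary is the midpoint of the largest
    convergent and smallest divergent gain.
    """
    if alphas is None:
        alphas = np.round(np.arange(0.10, 3.0001, 0.05), 10)
    stimulus = gen_isochronous(base_ioi, n_cycles + 1)
    classes = {}
    for alpha in alphas:
        alpha = float(alpha)
        try:
            with _allow_extreme_gains():
                rec = run_adaptation_noise_free(
                    stimulus,
                    AdaptParams(alpha=alpha, beta=0.0),
                    AdaptState(timekeeper_ms=base_ioi),
                    first_onset=stimulus.onsets[0] - initial_asyn,
                )
        except DegenerateTimingError:
            classes[alpha] = DIVERGENT
            continue
        final = abs(rec.asynchronies_ms[-1])
        if final < abs(initial_asyn):
            classes[alpha] = CONVERGENT
        elif final > abs(initial_asyn):
            classes[alpha] = DIVERGENT
        else:
            classes[alpha] = MARGINAL
    convergent = [a for a, c in classes.items() if c == CONVERGENT]
    divergent = [a for a, c in classes.items() if c == DIVERGENT]
    if not convergent or not divergent:
        raise RuntimeError("sweep did not bracket the stability boundary")
    boundary = (max(convergent) + min(divergent)) / 2.0
    return {"classes": classes, "boundary": boundary}


def metronome_invariance_grid(
    gains=(0.0, 0.25, 0.5), n_events: int = 50, base_period: float = 500.0, seed: int = 0
) -> dict:
    """Find the gain settings that make the output invariant to the partner.

    A noise-free adaptive agent runs against a jittered stimulus for every
    (alpha, beta) pair on the grid; pairs whose output interval SD is
    exactly zero ignore the partner entirely (an unresponsive metronome).
    Returns the invariant pairs and their common gain value.
    """
    rng = np.random.default_rng(seed)
    jitter = rng.normal(0.0, 25.0, n_events - 1)
    stimulus = IntervalSeries(base_period + jitter).to_onsets()
    invariant = []
    for alpha in gains:
        for beta in gains:
            rec = run_adaptation_noise_free(
                stimulus,
                AdaptParams(alpha=alpha, beta=beta),
                AdaptState(timekeeper_ms=base_period),
            )
            if float(np.std(np.diff(rec.adam_onsets_ms))) == 0.0:
                invariant.append((alpha, beta))
    values = {g for pair in invariant for g in pair}
    if len(values) != 1:
        raise RuntimeError(f"expected one common invariant gain, found {invariant}")
    return {"invariant_pairs": invariant, "gain": values.pop()}


def predictor_signature(
    k: int = 3,
    order: int = 1,
    mimic_weight: float = 0.0,
    base_ioi: float = 500.0,
    amplitude: float = 50.0,
    period_events: int = 20,
    n_events: int = 200,
) -> float:
    """Prediction/tracking ratio of a noise-free anticipatory agent.

    The agent schedules each onset at the extrapolated partner time for a
    sinusoidally tempo-modulated stimulus; during the first k+1 events it
    falls back to full phase correction.  Returns the lag-0 over lag-1
    interval cross-correlation ratio, computed after the warm-up.
    """
    stimulus = gen_sinusoidal_tempo(base_ioi, amplitude, period_events, n_events)
    agent = AgentSpec(
        adapt=AdaptParams(alpha=1.0, beta=0.0),
        anticip=AnticipParams(k=k, order=order, mimic_weight=mimic_weight),
        base_period_ms=base_ioi,
    )
    rec = simulate_unidirectional(stimulus, agent, n_warmup=k + 1)
    adam = IntervalSeries(np.diff(rec.adam_onsets_ms[k + 1 :]))
    stim = IntervalSeries(np.diff(rec.partner_onsets_ms[k + 1 :]))
    return pt_ratio(adam, stim)


def optimal_coupled_gain_sweep(
    seed: int,
    alphas=None,
    n_runs: int = 100,
    n_cycles: int = 500,
    partner_alpha: float = 0.5,
    partner_sigma_timekeeper: float = 10.0,
    partner_sigma_motor: float = 5.0,
    base_period: float = 500.0,
) -> dict:
    """Sweep the model's phase gain against a noisy simulated partner.

    A human-like phase-correcting partner (timekeeper and motor noise) is
    coupled bidirectionally with a noise-free phase-only agent; for each
    candidate gain the SD of the dyad's asynchronies is averaged over
    ``n_runs`` seeded runs of ``n_cycles`` cycles.  The same partner noise
    seeds are reused across gains (common random numbers).  Returns the
    per-gain mean SDs and the gain minimizing them.
    """
    if alphas is None:
        alphas = np.round(np.arange(0.0, 1.0001, 0.05), 10)
    run_seeds = (
        np.random.SeedSequence(seed).generate_state(n_runs, dtype=np.uint64) % (2**31)
    ).astype(int)
    mean_sds = []
    for alpha in alphas:
        adam = AgentSpec(adapt=AdaptParams(alpha=float(alpha)), base_period_ms=base_period)
        sds = np.empty(n_runs)
        for j, run_seed in enumerate(run_seeds):
            partner = AgentSpec(
                adapt=AdaptParams(alpha=partner_alpha),
                noise=NoiseParams(
                    sigma_timekeeper=partner_sigma_timekeeper,
                    sigma_motor=partner_sigma_motor,
                    seed=int(run_seed),
                ),
                base_period_ms=base_period,
            )
            rec = simulate_bidirectional(adam, partner, n_cycles)
            sds[j] = np.std(rec.asynchronies_ms, ddof=1)
        mean_sds.append(float(np.mean(sds)))
    mean_sds = np.asarray(mean_sds)
    best = int(np.argmin(mean_sds))
    return {
        "alphas": np.asarray(alphas, dtype=float),
        "mean_sd_asyn_ms": mean_sds,
        "optimal_alpha": float(alphas[best]),
    }
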