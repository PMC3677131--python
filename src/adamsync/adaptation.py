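"""Reactive error correction: one-step phase and period correction.

The adaptive agent follows the two-process linear error-correction model of
the information-processing tradition.  With asynchrony ``asyn_n`` (partner
onset minus own onset at cycle n), phase gain ``alpha`` and period gain
``beta``, the next onset and timekeeper period are

    t_{n+1} = t_n + T_n + (alpha + beta) * asyn_n
    T_{n+1} = T_n + beta * asyn_n

Phase correction is a local adjustment that leaves the timekeeper period
untouched; period correction is a lasting change of the timekeeper that
persists until corrected again.  Empirical gain estimates for human tappers
typically fall between 0.2 and 0.8; the documented operating ranges are
alpha in [-1, 1] and beta in [0, 1], and values outside are accepted with a
warning so instability experiments (e.g. alpha > 2) remain possible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .errors import DegenerateTimingError, ValidationError
from .record import DyadRecord
from .timing import OnsetSequence

__all__ = ["AdaptParams", "AdaptState", "adapt_step", "run_adaptation_noise_free"]


@dataclass(frozen=True)
class AdaptParams:
    """Phase (``alpha``) and period (``beta``) correction gains, dimensionless."""

    alpha: float = 0.0
    beta: float = 0.0

    def __post_init__(self):
        if not (-1.0 <= self.alpha <= 1.0):
            warnings.warn(
                f"alpha={self.alpha} is outside the documented operating range [-1, 1]",
                stacklevel=3,
            )
        if not (0.0 <= self.beta <= 1.0):
            warnings.warn(
                f"beta={self.beta} is outside the documented operating range [0, 1]",
                stacklevel=3,
            )


@dataclass(frozen=True)
class AdaptState:
    """Current and initial timekeeper period (ms, > 0)."""

    timekeeper_ms: float
    base_timekeeper_ms: float | None = None

    def __post_init__(self):
        if not self.timekeeper_ms > 0:
            raise ValidationError(f"timekeeper_ms must be > 0, got {self.timekeeper_ms}")
        if self.base_timekeeper_ms is None:
            object.__setattr__(self, "base_timekeeper_ms", self.timekeeper_ms)


def adapt_step(
    t_n: float, state: AdaptState, asyn_n: float, params: AdaptParams
) -> tuple[float, AdaptState]:
    """One deterministic correction step; no noise is applied here.

    Returns the next onset time and the updated timekeeper state.  Raises
    :class:`DegenerateTimingError` if the implied inter-onset interval or the
    next timekeeper period is non-positive.
    """
    if not np.isfinite(asyn_n):
        raise ValidationError(f"asynchrony must be finite, got {asyn_n}")
    interval = state.timekeeper_ms + (params.alpha + params.beta) * asyn_n
    t_next = t_n + interval
    timekeeper_next = state.timekeeper_ms + params.beta * asyn_n
    if interval <= 0:
        raise DegenerateTimingError(
            f"corrected inter-onset interval {interval:.3f} ms <= 0"
        )
    if timekeeper_next <= 0:
        raise DegenerateTimingError(
            f"timekeeper period driven to {timekeeper_next:.3f} ms <= 0"
        )
    return t_next, replace(state, timekeeper_ms=timekeeper_next)


def run_adaptation_noise_free(
    stimulus: OnsetSequence,
    params: AdaptParams,
    init: AdaptState,
    first_onset: float | None = None,
) -> DyadRecord:
    """Iterate :func:`adapt_step` against a fixed stimulus with zero noise.

    The agent produces one onset per stimulus event (index-paired).  Its
    first onset defaults to the first stimulus onset (zero initial
    asynchrony); pass ``first_onset`` to impose an initial asynchrony.  With
    both gains at 0 the agent is an unresponsive metronome whose intervals
    all equal ``init.timekeeper_ms``.
    """
    s = stimulus.onsets
    n = s.size
    if n < 2:
        raise ValidationError("stimulus must have at least 2 onsets")
    adam = np.empty(n)
    tk = np.empty(n)
    adam[0] = s[0] if first_onset is None else first_onset
    tk[0] = init.timekeeper_ms
    state = init
    for i in range(n - 1):
        asyn = s[i] - adam[i]
        try:
            adam[i + 1], state = adapt_step(adam[i], state, asyn, params)
        except DegenerateTimingError as exc:
            raise DegenerateTimingError(f"{exc} (cycle {i})", cycle=i) from None
        tk[i + 1] = state.timekeeper_ms
    mechanism = ["initial"] + ["adaptation"] * (n - 1)
    return DyadRecord(
        partner_onsets_ms=s.copy(),
        adam_onsets_ms=adam,
        asynchronies_ms=s - adam,
        timekeeper_ms=tk,
        mechanism=mechanism,
        metadata={
            "mode": "adaptation_noise_free",
            "alpha": params.alpha,
            "beta": params.beta,
            "base_timekeeper_ms": init.base_timekeeper_ms,
        },
    )
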