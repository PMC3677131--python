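"""Noise injection, agent composition, and the coupling loops.

An :class:`AgentSpec` bundles the adaptive gains, optional anticipation and
joint-decision settings, the three Gaussian noise sources, and the base
timekeeper period.  Two loops produce :class:`~adamsync.record.DyadRecord`
traces:

* :func:`simulate_unidirectional` — the agent synchronizes with a fixed
  stimulus sequence (the classic paced-tapping arrangement);
* :func:`simulate_bidirectional` — two mutually responsive agents, each
  correcting toward / predicting the other's produced onsets.  Alternation
  is event-indexed: both agents produce event n before either produces n+1.

Noise insertion points (each independently switchable by setting its SD to
zero): timekeeper noise is added to each cycle's realized interval, not to
the stored period, which evolves only through period correction; motor
noise is an additive per-event delay on produced onsets, so consecutive
intervals acquire the differenced MA(1) signature of two-level timing
models; perceptual noise is added to the asynchrony before it enters the
correction equations.  Agents perceive each other's *produced* (noisy)
onsets, i.e. observable behaviour.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._version import __version__
from .adaptation import AdaptParams
from .anticipation import AnticipParams, plan_coincident_interval, predict_next_interval
from .errors import DegenerateTimingError, ValidationError
from .joint import DEFAULT, PLANNED, JointParams, joint_decide
from .record import DyadRecord
from .timing import IntervalSeries, OnsetSequence

__all__ = [
    "NoiseParams",
    "AgentSpec",
    "realize_event",
    "simulate_unidirectional",
    "simulate_bidirectional",
    "run_perturbation_trial",
]


@dataclass(frozen=True)
class NoiseParams:
    """SDs (ms) of the three Gaussian noise sources and the RNG seed.

    A fixed seed makes the resulting DyadRecord byte-identical across runs.
    """

    sigma_timekeeper: float = 0.0
    sigma_motor: float = 0.0
    sigma_perceptual: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for name in ("sigma_timekeeper", "sigma_motor", "sigma_perceptual"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")

    @property
    def silent(self) -> bool:
        return (
            self.sigma_timekeeper == 0
            and self.sigma_motor == 0
            and self.sigma_perceptual == 0
        )


@dataclass(frozen=True)
class AgentSpec:
    """Full configuration of one synchronizing agent.

    Mechanism resolution order: joint > anticipation-only > adaptation-only.
    A joint layer requires the anticipation module to be configured.
    ``use_perceived_asynchrony`` switches whether the correction equations
    receive the perceptually noisy or the veridical asynchrony;
    ``period_update_on_anticipation`` controls whether period correction is
    also applied on cycles whose motor command came from the anticipation
    module (off by default: anticipation-scheduled intervals leave the
    timekeeper untouched).
    """

    adapt: AdaptParams = field(default_factory=AdaptParams)
    anticip: AnticipParams | None = None
    joint: JointParams | None = None
    noise: NoiseParams = field(default_factory=NoiseParams)
    base_period_ms: float = 500.0
    use_perceived_asynchrony: bool = True
    period_update_on_anticipation: bool = False

    def __post_init__(self):
        if self.joint is not None and self.anticip is None:
            raise ValidationError("a joint layer requires an anticipation module")
        if not self.base_period_ms > 0:
            raise ValidationError("base_period_ms must be > 0")

    def to_dict(self) -> dict:
        d = {
            "alpha": self.adapt.alpha,
            "beta": self.adapt.beta,
            "base_period_ms": self.base_period_ms,
            "noise": {
                "sigma_timekeeper": self.noise.sigma_timekeeper,
                "sigma_motor": self.noise.sigma_motor,
                "sigma_perceptual": self.noise.sigma_perceptual,
                "seed": self.noise.seed,
            },
            "use_perceived_asynchrony": self.use_perceived_asynchrony,
            "period_update_on_anticipation": self.period_update_on_anticipation,
        }
        if self.anticip is not None:
            d["anticipation"] = {
                "k": self.anticip.k,
                "order": self.anticip.order,
                "mimic_weight": self.anticip.mimic_weight,
            }
        if self.joint is not None:
            d["joint"] = {
                "tolerance_mode": self.joint.tolerance_mode,
                "tolerance_value": self.joint.tolerance_value,
                "default_mechanism": self.joint.default_mechanism,
            }
        return d


def realize_event(planned_onset: float, noise: NoiseParams, rng: np.random.Generator) -> float:
    """Produce an onset: planned time plus one per-event motor delay draw."""
    if not np.isfinite(planned_onset):
        raise ValidationError("planned onset must be finite")
    if noise.sigma_motor == 0:
        return planned_onset
    return planned_onset + rng.normal(0.0, noise.sigma_motor)


class _AgentRuntime:
    """Per-run mutable state of one agent, with noise pre-drawn for speed."""

    __slots__ = (
        "spec", "alpha", "beta", "anticip", "joint", "k",
        "motor", "tk_noise", "perc_noise", "T", "perceive_noisy",
        "update_T_on_anticip",
    )

    def __init__(self, spec: AgentSpec, n_events: int):
        self.spec = spec
        self.alpha = spec.adapt.alpha
        self.beta = spec.adapt.beta
        self.anticip = spec.anticip
        self.joint = spec.joint
        self.k = spec.anticip.k if spec.anticip is not None else 0
        self.T = spec.base_period_ms
        self.perceive_noisy = spec.use_perceived_asynchrony
        self.update_T_on_anticip = spec.period_update_on_anticipation
        rng = np.random.default_rng(spec.noise.seed)
        ns = spec.noise
        zeros = np.zeros(n_events)
        self.motor = rng.normal(0.0, ns.sigma_motor, n_events) if ns.sigma_motor else zeros
        self.tk_noise = (
            rng.normal(0.0, ns.sigma_timekeeper, n_events) if ns.sigma_timekeeper else zeros
        )
        self.perc_noise = (
            rng.normal(0.0, ns.sigma_perceptual, n_events) if ns.sigma_perceptual else zeros
        )

    def schedule(self, i: int, own: np.ndarray, other: np.ndarray) -> tuple[float, str]:
        """Choose the interval from ``own[i]`` to the agent's next onset.

        ``own``/``other`` hold produced onsets up to and including event i.
        Returns ``(interval, mechanism_flag)`` and updates the timekeeper.
        Raises :class:`DegenerateTimingError` on non-positive intervals or
        timekeeper periods, tagged with the cycle index.
        """
        asyn = other[i] - own[i]
        asyn_p = asyn + self.perc_noise[i] if self.perceive_noisy else asyn
        adapt_interval = self.T + (self.alpha + self.beta) * asyn_p + self.tk_noise[i]
        T_adapted = self.T + self.beta * asyn_p

        chosen = adapt_interval
        flag = "adaptation"
        from_anticipation = False
        if self.anticip is not None and i >= self.k:
            window = IntervalSeries(np.diff(other[i - self.k : i + 1]))
            pred = predict_next_interval(window, self.anticip)
            try:
                coincide = plan_coincident_interval(own[i], other[i] + pred)
            except DegenerateTimingError as exc:
                raise DegenerateTimingError(f"{exc} (cycle {i})", cycle=i) from None
            # predictive scheduling re-anchors on the partner's predicted
            # onset; mimicry copies the predicted (blended) interval from
            # the agent's own last onset, so a pure mimic reproduces the
            # partner's previous interval rather than extrapolating it
            w = self.anticip.mimic_weight
            anticip_interval = (1.0 - w) * coincide + w * pred
            if self.joint is not None:
                if adapt_interval <= 0:
                    raise DegenerateTimingError(
                        f"adaptation interval {adapt_interval:.3f} ms <= 0 (cycle {i})",
                        cycle=i,
                    )
                chosen, flag = joint_decide(
                    adapt_interval, anticip_interval, self.T, self.joint
                )
                from_anticipation = (
                    flag == DEFAULT and self.joint.default_mechanism == "anticipation"
                )
            else:
                chosen, flag = anticip_interval, "anticipation"
                from_anticipation = True

        if chosen <= 0:
            raise DegenerateTimingError(
                f"scheduled inter-onset interval {chosen:.3f} ms <= 0 (cycle {i})",
                cycle=i,
            )
        if from_anticipation and not self.update_T_on_anticip:
            pass  # anticipation-driven cycle: timekeeper untouched
        else:
            if T_adapted <= 0:
                raise DegenerateTimingError(
                    f"timekeeper driven to {T_adapted:.3f} ms <= 0 (cycle {i})",
                    cycle=i,
                )
            self.T = T_adapted
        return chosen, flag


def simulate_unidirectional(
    stimulus: OnsetSequence,
    agent: AgentSpec,
    n_warmup: int = 0,
    first_onset: float | None = None,
    extra_metadata: dict | None = None,
) -> DyadRecord:
    """Synchronize one agent with a fixed (unresponsive) stimulus.

    The agent produces one onset per stimulus event.  Its first onset
    defaults to the first stimulus onset plus a motor-noise draw; pass
    ``first_onset`` to impose an initial asynchrony.  ``n_warmup`` is
    recorded in the metadata for downstream warm-up exclusion.
    """
    s = stimulus.onsets
    n = s.size
    if n < 2:
        raise ValidationError("stimulus must have at least 2 onsets")
    if agent.anticip is not None and n <= agent.anticip.k:
        raise ValidationError(
            f"stimulus too short for anticipation warm-up (k={agent.anticip.k})"
        )
    rt = _AgentRuntime(agent, n)
    adam = np.empty(n)
    tk = np.empty(n)
    planned0 = s[0] if first_onset is None else first_onset
    adam[0] = planned0 + rt.motor[0]
    tk[0] = rt.T
    mechanism = ["initial"]
    for i in range(n - 1):
        interval, flag = rt.schedule(i, adam, s)
        adam[i + 1] = adam[i] + interval + rt.motor[i + 1]
        if adam[i + 1] <= adam[i]:
            raise DegenerateTimingError(
                f"produced onset not increasing at cycle {i + 1}", cycle=i + 1
            )
        tk[i + 1] = rt.T
        mechanism.append(flag)
    metadata = {
        "mode": "unidirectional",
        "agent": agent.to_dict(),
        "seed": agent.noise.seed,
        "n_warmup": n_warmup,
        "version": __version__,
    }
    if extra_metadata:
        metadata.update(extra_metadata)
    return DyadRecord(
        partner_onsets_ms=s.copy(),
        adam_onsets_ms=adam,
        asynchronies_ms=s - adam,
        timekeeper_ms=tk,
        mechanism=mechanism,
        metadata=metadata,
    )


def simulate_bidirectional(
    agent_a: AgentSpec,
    agent_b: AgentSpec,
    n_cycles: int,
    first_onset_a: float = 0.0,
    first_onset_b: float = 0.0,
    extra_metadata: dict | None = None,
) -> DyadRecord:
    """Couple two mutually responsive agents for ``n_cycles`` events each.

    Both agents produce event n before either produces n+1; each corrects
    toward (and, if configured, predicts) the other's produced onsets.  In
    the returned record agent A plays the "adam" role and agent B the
    "partner" role, so the asynchrony column is B minus A and the
    timekeeper/mechanism columns describe agent A.
    """
    ks = [a.anticip.k for a in (agent_a, agent_b) if a.anticip is not None]
    min_cycles = max(2, max(ks) + 2 if ks else 2)
    if n_cycles < min_cycles:
        raise ValidationError(f"n_cycles must be >= {min_cycles} for these agents")
    rt_a = _AgentRuntime(agent_a, n_cycles)
    rt_b = _AgentRuntime(agent_b, n_cycles)
    a = np.empty(n_cycles)
    b = np.empty(n_cycles)
    tk = np.empty(n_cycles)
    a[0] = first_onset_a + rt_a.motor[0]
    b[0] = first_onset_b + rt_b.motor[0]
    tk[0] = rt_a.T
    mechanism = ["initial"]
    for i in range(n_cycles - 1):
        int_a, flag = rt_a.schedule(i, a, b)
        int_b, _ = rt_b.schedule(i, b, a)
        a[i + 1] = a[i] + int_a + rt_a.motor[i + 1]
        b[i + 1] = b[i] + int_b + rt_b.motor[i + 1]
        if a[i + 1] <= a[i] or b[i + 1] <= b[i]:
            raise DegenerateTimingError(
                f"produced onset not increasing at cycle {i + 1}", cycle=i + 1
            )
        tk[i + 1] = rt_a.T
        mechanism.append(flag)
    metadata = {
        "mode": "bidirectional",
        "agent": agent_a.to_dict(),
        "partner": agent_b.to_dict(),
        "seed": [agent_a.noise.seed, agent_b.noise.seed],
        "version": __version__,
    }
    if extra_metadata:
        metadata.update(extra_metadata)
    return DyadRecord(
        partner_onsets_ms=b,
        adam_onsets_ms=a,
        asynchronies_ms=b - a,
        timekeeper_ms=tk,
        mechanism=mechanism,
        metadata=metadata,
    )


def run_perturbation_trial(
    base_ioi: float,
    n_events: int,
    perturbed_index: int,
    shift: float,
    agent: AgentSpec,
    first_onset: float | None = None,
) -> DyadRecord:
    """One phase-correction-response trial against a perturbed metronome.

    The stimulus is isochronous except that interval ``perturbed_index`` is
    lengthened by ``shift``, permanently displacing all later stimulus
    onsets.  The record's metadata marks the first displaced stimulus event
    (``perturbation_cycle = perturbed_index + 1``) and the shift, which the
    PCR estimator requires.
    """
    from .timing import gen_single_perturbation

    stimulus = gen_single_perturbation(base_ioi, n_events, perturbed_index, shift)
    return simulate_unidirectional(
        stimulus,
        agent,
        first_onset=first_onset,
        extra_metadata={
            "perturbation_cycle": perturbed_index + 1,
            "perturbation_shift": shift,
        },
    )
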