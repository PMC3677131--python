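"""Synchronization metrics and timing-parameter estimation.

Metrics: accuracy and precision of asynchronies (mean, SD), interval
variability, lagged Pearson cross-correlations between response and
stimulus interval series, and the prediction/tracking ratio (lag-0 over
lag-1 cross-correlation; > 1 classifies a predictor, < 1 a tracker).

Estimators for the phase-correction gain:

* :func:`estimate_alpha_ar` — the AR-regression approach: against a fixed
  metronome with phase-only correction the asynchronies follow
  ``asyn_{n+1} = (1 - alpha) * asyn_n + noise``, so regressing successive
  asynchronies recovers ``alpha = 1 - slope``.  Biased when motor noise is
  present (the measurement error on asyn_n attenuates the slope); use the
  grid search then.
* :func:`fit_params_gridsearch` — simulation-based fitting: re-simulate the
  observed stimulus at each candidate ``(alpha, beta)`` and minimize the
  squared distance between observed and simulated summary statistics.
* :func:`estimate_pcr` — the perturbation approach: the fraction of a
  single stimulus shift that is compensated on the very next response (the
  phase correction response), which equals alpha for a noise-free
  phase-only agent.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .adaptation import AdaptParams
from .errors import ValidationError
from .record import DyadRecord
from .simulation import AgentSpec, NoiseParams, simulate_unidirectional
from .timing import IntervalSeries, OnsetSequence

__all__ = [
    "MetricsReport",
    "asynchrony_stats",
    "interval_cc",
    "pt_ratio",
    "estimate_alpha_ar",
    "GridFitResult",
    "fit_params_gridsearch",
    "estimate_pcr",
]


@dataclass
class MetricsReport:
    """Summary metrics of one dyadic record."""

    mean_asyn_ms: float
    sd_asyn_ms: float
    sd_adam_ioi_ms: float
    sd_partner_ioi_ms: float
    cc: dict = field(default_factory=dict)  # lag -> coefficient (NaN if undefined)
    pt_ratio: float = math.nan
    pt_ratio_defined: bool = False
    n_cycles: int = 0

    def to_dict(self) -> dict:
        return {
            "mean_asyn_ms": self.mean_asyn_ms,
            "sd_asyn_ms": self.sd_asyn_ms,
            "sd_adam_ioi_ms": self.sd_adam_ioi_ms,
            "sd_partner_ioi_ms": self.sd_partner_ioi_ms,
            "cc": {str(lag): v for lag, v in self.cc.items()},
            "pt_ratio": None if math.isnan(self.pt_ratio) else self.pt_ratio,
            "pt_ratio_defined": self.pt_ratio_defined,
            "n_cycles": self.n_cycles,
        }

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")


def _sd(x: np.ndarray) -> float:
    return float(np.std(x, ddof=1)) if x.size >= 2 else math.nan


def asynchrony_stats(record: DyadRecord, warmup: int | None = None) -> MetricsReport:
    """Accuracy/precision summary plus cross-correlations and P/T ratio.

    ``warmup`` cycles are excluded from every statistic; it defaults to the
    record's own ``n_warmup`` metadata (0 if absent).  Interval
    cross-correlations and the prediction/tracking ratio are computed from
    the two interval series when they are long enough, otherwise left NaN.
    """
    if warmup is None:
        warmup = int(record.metadata.get("n_warmup", 0))
    asyn = record.asynchronies_ms[warmup:]
    if asyn.size < 2:
        raise ValidationError("record too short after warm-up exclusion")
    adam_ioi = np.diff(record.adam_onsets_ms[warmup:])
    partner_ioi = np.diff(record.partner_onsets_ms[warmup:])
    report = MetricsReport(
        mean_asyn_ms=float(np.mean(asyn)),
        sd_asyn_ms=_sd(asyn),
        sd_adam_ioi_ms=_sd(adam_ioi),
        sd_partner_ioi_ms=_sd(partner_ioi),
        n_cycles=int(asyn.size),
    )
    if adam_ioi.size >= 4:
        x = IntervalSeries(adam_ioi)
        y = IntervalSeries(partner_ioi)
        report.cc = interval_cc(x, y, [0, 1])
        ratio = pt_ratio(x, y)
        report.pt_ratio = ratio
        report.pt_ratio_defined = not math.isnan(ratio)
    return report


def interval_cc(x: IntervalSeries, y: IntervalSeries, lags) -> dict:
    """Pearson correlation of ``(x_n, y_{n-lag})`` over the overlapping range.

    ``x`` is the response (tap) series and ``y`` the stimulus series; a
    positive lag correlates the response with *earlier* stimulus intervals.
    Means and SDs are computed per overlapping window.  Zero-variance
    windows yield NaN (undefined) for that lag.
    """
    xv = x.intervals
    yv = y.intervals
    if xv.size != yv.size:
        raise ValidationError("interval series must have equal length")
    out = {}
    for lag in lags:
        lag = int(lag)
        if lag >= 0:
            a, b = xv[lag:], yv[: yv.size - lag] if lag else yv
        else:
            a, b = xv[: xv.size + lag], yv[-lag:]
        if a.size < 3:
            raise ValidationError(f"series too short for lag {lag}")
        if np.std(a) == 0 or np.std(b) == 0:
            out[lag] = math.nan
        else:
            out[lag] = float(np.corrcoef(a, b)[0, 1])
    return out


def pt_ratio(x: IntervalSeries, y: IntervalSeries) -> float:
    """Prediction/tracking ratio: lag-0 over lag-1 cross-correlation.

    Greater than 1 classifies the responder as a predictor of tempo
    changes, less than 1 as a tracker.  Returns NaN when the lag-1
    coefficient is not positive (the ratio presumes positive correlations
    on tempo-changing sequences) or when either coefficient is undefined.
    """
    cc = interval_cc(x, y, [0, 1])
    if math.isnan(cc[0]) or math.isnan(cc[1]) or cc[1] <= 0:
        return math.nan
    return cc[0] / cc[1]


def estimate_alpha_ar(record: DyadRecord, warmup: int | None = None) -> float:
    """AR-regression estimate of the phase-correction gain.

    Fits ``asyn_{n+1} = phi * asyn_n + c`` by least squares and returns
    ``1 - phi``.  Assumes a phase-only regime against a fixed metronome;
    attenuated (biased toward 1) when motor noise is present.
    """
    if warmup is None:
        warmup = int(record.metadata.get("n_warmup", 0))
    asyn = record.asynchronies_ms[warmup:]
    if asyn.size < 10:
        raise ValidationError("need at least 10 cycles for the AR estimate")
    x, y = asyn[:-1], asyn[1:]
    if np.std(x) == 0:
        raise ValidationError("asynchronies have zero variance; gain unidentifiable")
    phi, _ = np.polyfit(x, y, 1)
    return float(1.0 - phi)


@dataclass
class GridFitResult:
    """Best-fitting gains and the full loss table of a grid search."""

    alpha: float
    beta: float
    loss: float
    table: pd.DataFrame  # columns alpha, beta, loss

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(
                {"alpha": self.alpha, "beta": self.beta, "loss": self.loss}, fh, indent=2
            )
            fh.write("\n")

    def table_to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def _ac1(v: np.ndarray) -> float:
    if np.std(v[:-1]) == 0 or np.std(v[1:]) == 0:
        return 0.0
    return float(np.corrcoef(v[:-1], v[1:])[0, 1])


def _summary_stats(asyn: np.ndarray, adam_ioi: np.ndarray) -> np.ndarray:
    """Fixed statistic vector for the grid-search loss.

    Mean asynchrony, SD of asynchrony, lag-1 asynchrony autocorrelation,
    SD of the response intervals, and lag-1 autocorrelation of the response
    intervals.  The lag-0 autocorrelation is identically 1 and carries no
    information, so the serial-dependence statistics are lag-1
    coefficients; the interval statistics separate period from phase
    correction (period correction leaves a lasting, serially dependent
    trace in the produced intervals).
    """
    return np.array(
        [
            np.mean(asyn),
            np.std(asyn, ddof=1),
            _ac1(asyn),
            np.std(adam_ioi, ddof=1),
            _ac1(adam_ioi),
        ]
    )


def fit_params_gridsearch(
    observed: DyadRecord,
    template: AgentSpec,
    alphas,
    betas,
    n_sims: int = 20,
    seed: int = 0,
) -> GridFitResult:
    """Simulation-based grid search for the correction gains.

    For each candidate ``(alpha, beta)`` the observed stimulus (the
    record's partner-onset column) is re-simulated ``n_sims`` times with
    the template's noise settings and fresh seeds, and the loss is the sum
    of squared scaled differences between observed and mean simulated
    summary statistics (see :func:`_summary_stats`; temporal statistics are
    in ms, the autocorrelation is scaled by the observed asynchrony SD to
    share units).  Ties break toward smaller (alpha, beta) lexicographically;
    a simulation failure at a grid point records an infinite loss.
    """
    alphas = list(alphas)
    betas = list(betas)
    if not alphas or not betas:
        raise ValidationError("parameter grid must be non-empty")
    warmup = int(observed.metadata.get("n_warmup", 0))
    obs_asyn = observed.asynchronies_ms[warmup:]
    obs_stats = _summary_stats(obs_asyn, np.diff(observed.adam_onsets_ms[warmup:]))
    # dimensionless autocorrelations are scaled into ms by the observed SDs
    scale = np.array(
        [1.0, 1.0, max(obs_stats[1], 1.0), 1.0, max(obs_stats[3], 1.0)]
    )
    stimulus = OnsetSequence(observed.partner_onsets_ms, label="stimulus")
    first_onset = float(observed.adam_onsets_ms[0])

    rows = []
    ss = np.random.SeedSequence(seed)
    sim_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_sims)]
    for alpha, beta in itertools.product(alphas, betas):
        params = AdaptParams(alpha=alpha, beta=beta)
        stats = []
        try:
            for rep_seed in sim_seeds:
                spec = AgentSpec(
                    adapt=params,
                    noise=NoiseParams(
                        sigma_timekeeper=template.noise.sigma_timekeeper,
                        sigma_motor=template.noise.sigma_motor,
                        sigma_perceptual=template.noise.sigma_perceptual,
                        seed=rep_seed,
                    ),
                    base_period_ms=template.base_period_ms,
                    use_perceived_asynchrony=template.use_perceived_asynchrony,
                )
                rec = simulate_unidirectional(
                    stimulus, spec, n_warmup=warmup, first_onset=first_onset
                )
                stats.append(
                    _summary_stats(
                        rec.asynchronies_ms[warmup:],
                        np.diff(rec.adam_onsets_ms[warmup:]),
                    )
                )
            diff = (np.mean(stats, axis=0) - obs_stats) * scale
            loss = float(diff @ diff)
        except Exception:  # noqa: BLE001 - divergent grid points are non-fatal
            loss = math.inf
        rows.append((alpha, beta, loss))
    table = pd.DataFrame(rows, columns=["alpha", "beta", "loss"])
    # argmin with lexicographic (alpha, beta) tie-break
    best = min(rows, key=lambda r: (r[2], r[0], r[1]))
    return GridFitResult(alpha=best[0], beta=best[1], loss=best[2], table=table)


def estimate_pcr(records) -> float:
    """Phase correction response averaged over perturbation trials.

    Each record must carry ``perturbation_cycle`` (the first stimulus event
    displaced by the shift) and ``perturbation_shift`` in its metadata, as
    written by :func:`adamsync.simulation.run_perturbation_trial`.  Per
    trial the PCR is the fraction of the induced asynchrony jump that is
    compensated on the next response:

        PCR = (asyn_c - asyn_{c+1}) / shift

    which equals alpha exactly for a noise-free phase-only agent.
    """
    records = list(records)
    if not records:
        raise ValidationError("need at least one perturbation record")
    pcrs = []
    for rec in records:
        meta = rec.metadata
        if "perturbation_cycle" not in meta or "perturbation_shift" not in meta:
            raise ValidationError(
                "record lacks perturbation_cycle/perturbation_shift metadata"
            )
        c = int(meta["perturbation_cycle"])
        shift = float(meta["perturbation_shift"])
        if shift == 0:
            raise ValidationError("perturbation shift must be nonzero")
        if not (0 <= c < len(rec) - 1):
            raise ValidationError(f"perturbation cycle {c} outside record")
        asyn = rec.asynchronies_ms
        pcrs.append((asyn[c] - asyn[c + 1]) / shift)
    return float(np.mean(pcrs))
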