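"""Predictive temporal extrapolation: trend fit on recent intervals.

The anticipatory agent predicts the partner's next inter-onset interval by
ordinary least squares on the last ``k`` observed intervals (an
over-determined linear system, ``k >= 3``; quadratic fits need ``k >= 4``).
The fitted trend is evaluated one step past the window:

    Int_{n+1} = a + b * (k + 1)        (linear case)

and the predicted next onset is the partner's last onset plus that interval.
Scheduling one's own next event at the predicted partner onset produces
"predictor" behaviour (lag-0 cross-correlation between own and partner
intervals exceeding lag-1).  Tracking behaviour — mimicking the partner's
previous interval — is available as a convex blend via ``mimic_weight``.

The within-window abscissa is 1..k and extrapolation evaluates at k+1; any
affine re-indexing yields the same prediction, so the choice is cosmetic but
fixed for reproducibility.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateTimingError, ValidationError
from .timing import IntervalSeries

__all__ = [
    "AnticipParams",
    "TrendFit",
    "fit_trend",
    "predict_next_interval",
    "predict_next_onset",
    "plan_coincident_interval",
]


@dataclass(frozen=True)
class AnticipParams:
    """Window size ``k`` (>= 3 intervals), trend order (1 or 2), mimic weight.

    ``mimic_weight`` in [0, 1] blends pure extrapolation (0) with copying
    the last observed interval (1, a pure tracker).
    """

    k: int = 3
    order: int = 1
    mimic_weight: float = 0.0

    def __post_init__(self):
        if self.k < 3:
            raise ValidationError(f"k must be >= 3, got {self.k}")
        if self.order not in (1, 2):
            raise ValidationError(f"order must be 1 or 2, got {self.order}")
        if self.order == 2 and self.k < 4:
            raise ValidationError("order 2 requires k >= 4 (over-determined fit)")
        if not (0.0 <= self.mimic_weight <= 1.0):
            raise ValidationError("mimic_weight must be in [0, 1]")


@dataclass(frozen=True)
class TrendFit:
    """Least-squares trend over a window of intervals.

    ``coeffs`` are ascending polynomial coefficients in the within-window
    index (1..k); ``intercept_a`` and ``slope_b`` expose the linear part,
    ``sse`` the sum of squared residuals in ms^2.
    """

    coeffs: tuple
    order: int
    sse: float

    @property
    def intercept_a(self) -> float:
        return self.coeffs[0]

    @property
    def slope_b(self) -> float:
        return self.coeffs[1]

    def predict(self, index: float) -> float:
        return float(np.polyval(self.coeffs[::-1], index))


def fit_trend(window: IntervalSeries, order: int = 1) -> TrendFit:
    """OLS fit of interval duration against within-window index 1..k.

    The window must be over-determined: at least ``order + 2`` intervals.
    """
    y = window.intervals
    k = y.size
    if k < order + 2:
        raise ValidationError(
            f"window of {k} intervals is under-determined for order {order} "
            f"(need >= {order + 2})"
        )
    x = np.arange(1, k + 1, dtype=float)
    coeffs_desc = np.polyfit(x, y, order)
    residuals = y - np.polyval(coeffs_desc, x)
    return TrendFit(
        coeffs=tuple(coeffs_desc[::-1]),
        order=order,
        sse=float(residuals @ residuals),
    )


def predict_next_interval(window: IntervalSeries, params: AnticipParams) -> float:
    """Extrapolate the fitted trend one step past the window.

    With mimic weight ``w`` returns ``(1-w) * extrapolation + w * last
    interval``.  The window length must equal ``params.k``.
    """
    if len(window) != params.k:
        raise ValidationError(
            f"window length {len(window)} != k = {params.k}"
        )
    w = params.mimic_weight
    last = float(window.intervals[-1])
    if w == 1.0:
        return last
    fit = fit_trend(window, params.order)
    extrap = fit.predict(params.k + 1)
    return (1.0 - w) * extrap + w * last


def predict_next_onset(
    last_partner_onset: float, window: IntervalSeries, params: AnticipParams
) -> float:
    """Predicted time of the partner's next event: last onset + predicted interval."""
    return last_partner_onset + predict_next_interval(window, params)


def plan_coincident_interval(
    adam_last_onset: float, predicted_partner_onset: float
) -> float:
    """Interval that makes the agent's next onset coincide with the prediction."""
    interval = predicted_partner_onset - adam_last_onset
    if interval <= 0:
        raise DegenerateTimingError(
            f"predicted partner onset {predicted_partner_onset:.3f} ms is not "
            f"after the agent's last onset {adam_last_onset:.3f} ms"
        )
    return interval
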