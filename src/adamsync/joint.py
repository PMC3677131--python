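"""Joint decision layer linking adaptation and anticipation.

Each cycle the planned (adaptation) interval and the predicted
(anticipation) interval are compared.  If they agree to within a tolerance
— a fixed number of ms, or a Weber fraction of the current timekeeper
period — the planned motor command from the adaptive module is executed
(flag ``"planned"``).  Otherwise the configured default mechanism supplies
the interval (flag ``"default"``).  The output is always exactly one of the
two inputs; nothing is blended.

The default tolerance is a 2% Weber fraction of the timekeeper period,
motivated by just-noticeable differences for interval timing; it is fully
configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ValidationError

__all__ = ["JointParams", "joint_decide", "PLANNED", "DEFAULT"]

PLANNED = "planned"
DEFAULT = "default"


@dataclass(frozen=True)
class JointParams:
    """Tolerance rule and default mechanism of the joint decision layer."""

    tolerance_mode: str = "weber"  # "absolute" (ms) or "weber" (fraction of T)
    tolerance_value: float = 0.02
    default_mechanism: str = "anticipation"  # or "adaptation"

    def __post_init__(self):
        if self.tolerance_mode not in ("absolute", "weber"):
            raise ValidationError(
                f"tolerance_mode must be 'absolute' or 'weber', got {self.tolerance_mode!r}"
            )
        if self.tolerance_value < 0:
            raise ValidationError("tolerance_value must be >= 0")
        if self.default_mechanism not in ("adaptation", "anticipation"):
            raise ValidationError(
                "default_mechanism must be 'adaptation' or 'anticipation', "
                f"got {self.default_mechanism!r}"
            )

    def effective_tolerance(self, timekeeper_ms: float) -> float:
        if self.tolerance_mode == "absolute":
            return self.tolerance_value
        return self.tolerance_value * timekeeper_ms


def joint_decide(
    adapt_interval: float,
    anticip_interval: float,
    timekeeper_ms: float,
    params: JointParams,
) -> tuple[float, str]:
    """Select the next motor command interval and flag its origin.

    Returns ``(interval, flag)`` with flag ``"planned"`` when the two
    modules agree within tolerance (the adaptation interval is executed) and
    ``"default"`` otherwise (the configured default mechanism's interval is
    executed).
    """
    if adapt_interval <= 0 or anticip_interval <= 0:
        raise ValidationError(
            "joint_decide requires positive intervals, got "
            f"adapt={adapt_interval}, anticip={anticip_interval}"
        )
    discrepancy = abs(adapt_interval - anticip_interval)
    if discrepancy <= params.effective_tolerance(timekeeper_ms):
        return adapt_interval, PLANNED
    if params.default_mechanism == "adaptation":
        return adapt_interval, DEFAULT
    return anticip_interval, DEFAULT
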