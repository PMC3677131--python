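"""Core temporal data types and deterministic pacing-sequence generators.

Event times are real-valued milliseconds with the first event at t = 0 by
convention.  An :class:`OnsetSequence` holds the onset times of one agent or
stimulus; an :class:`IntervalSeries` holds the inter-onset intervals (IOIs)
between consecutive events.  The two round-trip exactly.

The generators produce the pacing sequences used throughout the tapping
literature: isochronous metronomes, abrupt (step) tempo changes, smooth
sinusoidal tempo modulation, and single-interval phase perturbations.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

__all__ = [
    "OnsetSequence",
    "IntervalSeries",
    "intervals_from_onsets",
    "onsets_from_intervals",
    "gen_isochronous",
    "gen_step_tempo",
    "gen_sinusoidal_tempo",
    "gen_single_perturbation",
    "write_onsets_csv",
    "read_onsets_csv",
]


@dataclass(frozen=True)
class OnsetSequence:
    """Strictly increasing event times in ms for one agent or stimulus.

    Parameters
    ----------
    onsets
        Event onset times in milliseconds, strictly increasing.
    label
        Free-text role tag, conventionally ``"stimulus"``, ``"adam"`` or
        ``"partner"``.
    """

    onsets: np.ndarray
    label: str = "stimulus"

    def __post_init__(self):
        arr = np.asarray(self.onsets, dtype=float)
        if arr.ndim != 1 or arr.size == 0:
            raise ValidationError("onsets must be a non-empty 1-D array")
        if not np.all(np.isfinite(arr)):
            raise ValidationError("onsets must be finite")
        if arr.size > 1 and not np.all(np.diff(arr) > 0):
            raise ValidationError("onsets must be strictly increasing")
        object.__setattr__(self, "onsets", arr)

    def __len__(self) -> int:
        return self.onsets.size

    def intervals(self) -> "IntervalSeries":
        return intervals_from_onsets(self)


@dataclass(frozen=True)
class IntervalSeries:
    """Ordered inter-onset intervals in ms, all strictly positive."""

    intervals: np.ndarray

    def __post_init__(self):
        arr = np.asarray(self.intervals, dtype=float)
        if arr.ndim != 1:
            raise ValidationError("intervals must be 1-D")
        if arr.size and not np.all(arr > 0):
            raise ValidationError("all intervals must be > 0")
        object.__setattr__(self, "intervals", arr)

    def __len__(self) -> int:
        return self.intervals.size

    def to_onsets(self, t0: float = 0.0, label: str = "stimulus") -> OnsetSequence:
        return onsets_from_intervals(self, t0, label=label)


def intervals_from_onsets(seq: OnsetSequence) -> IntervalSeries:
    """Consecutive differences of the onset times.

    Requires at least two onsets; the result has length ``len(seq) - 1``.
    """
    if len(seq) < 2:
        raise ValidationError("need at least 2 onsets to form intervals")
    return IntervalSeries(np.diff(seq.onsets))


def onsets_from_intervals(
    intervals: IntervalSeries, t0: float = 0.0, label: str = "stimulus"
) -> OnsetSequence:
    """Cumulative sum of the intervals starting at ``t0``.

    Exact inverse of :func:`intervals_from_onsets`.
    """
    onsets = np.concatenate([[t0], t0 + np.cumsum(intervals.intervals)])
    return OnsetSequence(onsets, label=label)


def _check_positive(name: str, value: float) -> None:
    if not value > 0:
        raise ValidationError(f"{name} must be > 0, got {value}")


def gen_isochronous(base_ioi: float, n_events: int, label: str = "stimulus") -> OnsetSequence:
    """A metronome: ``n_events`` onsets with constant interval ``base_ioi``."""
    _check_positive("base_ioi", base_ioi)
    if n_events < 2:
        raise ValidationError("n_events must be >= 2")
    return OnsetSequence(base_ioi * np.arange(n_events, dtype=float), label=label)


def gen_step_tempo(
    base_ioi: float,
    new_ioi: float,
    change_index: int,
    n_events: int,
    label: str = "stimulus",
) -> OnsetSequence:
    """An abrupt tempo change: intervals switch from ``base_ioi`` to ``new_ioi``.

    Interval indices below ``change_index`` equal ``base_ioi``; from
    ``change_index`` onward they equal ``new_ioi``.
    """
    _check_positive("base_ioi", base_ioi)
    _check_positive("new_ioi", new_ioi)
    if not (0 < change_index < n_events - 1):
        raise ValidationError(
            f"change_index must satisfy 0 < change_index < n_events - 1, got {change_index}"
        )
    intervals = np.full(n_events - 1, base_ioi, dtype=float)
    intervals[change_index:] = new_ioi
    return onsets_from_intervals(IntervalSeries(intervals), 0.0, label=label)


def gen_sinusoidal_tempo(
    base_ioi: float,
    amplitude: float,
    period_events: int,
    n_events: int,
    label: str = "stimulus",
) -> OnsetSequence:
    """Smooth tempo modulation: interval i = base + amplitude * sin(2*pi*i/period).

    ``amplitude`` must be smaller than ``base_ioi`` so every interval stays
    positive.  With amplitude 0 this is identical to :func:`gen_isochronous`.
    """
    _check_positive("base_ioi", base_ioi)
    if amplitude < 0 or amplitude >= base_ioi:
        raise ValidationError("amplitude must satisfy 0 <= amplitude < base_ioi")
    if period_events < 2:
        raise ValidationError("period_events must be >= 2")
    if n_events < 2:
        raise ValidationError("n_events must be >= 2")
    i = np.arange(n_events - 1, dtype=float)
    intervals = base_ioi + amplitude * np.sin(2.0 * np.pi * i / period_events)
    return onsets_from_intervals(IntervalSeries(intervals), 0.0, label=label)


def gen_single_perturbation(
    base_ioi: float,
    n_events: int,
    perturbed_index: int,
    shift: float,
    label: str = "stimulus",
) -> OnsetSequence:
    """Single-interval phase perturbation of an isochronous sequence.

    Exactly one interval (index ``perturbed_index``) differs from ``base_ioi``
    by ``shift``; all subsequent onsets are permanently displaced by ``shift``
    (phase-shift convention, as in the phase-correction-response paradigm).
    """
    _check_positive("base_ioi", base_ioi)
    if n_events < 2:
        raise ValidationError("n_events must be >= 2")
    if not (0 <= perturbed_index < n_events - 1):
        raise ValidationError(
            f"perturbed_index must be a valid interval index, got {perturbed_index}"
        )
    if shift <= -base_ioi:
        raise ValidationError("shift must be > -base_ioi (interval must stay positive)")
    intervals = np.full(n_events - 1, base_ioi, dtype=float)
    intervals[perturbed_index] += shift
    return onsets_from_intervals(IntervalSeries(intervals), 0.0, label=label)


def write_onsets_csv(seq: OnsetSequence, path) -> None:
    """Write a sequence as CSV with header ``cycle,onset_ms`` (one row per event)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["cycle", "onset_ms"])
        for i, t in enumerate(seq.onsets):
            writer.writerow([i, repr(float(t))])


def read_onsets_csv(path, label: str = "stimulus") -> OnsetSequence:
    """Read a ``cycle,onset_ms`` CSV written by :func:`write_onsets_csv`."""
    onsets = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "onset_ms" not in reader.fieldnames:
            raise ValidationError(f"{path}: expected header with an 'onset_ms' column")
        for i, row in enumerate(reader, start=2):
            try:
                onsets.append(float(row["onset_ms"]))
            except (TypeError, ValueError) as exc:
                raise ValidationError(f"{path}: bad onset value at row {i}") from exc
    if not onsets:
        raise ValidationError(f"{path}: no onset rows")
    return OnsetSequence(np.asarray(onsets), label=label)
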