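"""DyadRecord: the per-cycle trace produced by every simulation run.

One row per cycle: the partner (or stimulus) onset, the model's onset, their
signed asynchrony (partner minus model), the model's current timekeeper
period, and a flag naming the mechanism that scheduled the model's onset.
Run metadata (agent specification, seed, software version) travels in a
sidecar dict and is written as JSON next to the CSV.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

CSV_COLUMNS = [
    "cycle",
    "partner_onset_ms",
    "adam_onset_ms",
    "asynchrony_ms",
    "timekeeper_ms",
    "mechanism",
]


@dataclass
class DyadRecord:
    """Paired onset trace of one simulation run.

    Attributes
    ----------
    partner_onsets_ms, adam_onsets_ms
        Strictly increasing onset times of the two agents, index-paired.
    asynchronies_ms
        ``partner_onsets_ms - adam_onsets_ms`` row-wise (exact).
    timekeeper_ms
        The model's timekeeper period at each cycle.
    mechanism
        Per-cycle scheduling flag: ``"initial"`` for event 0, then
        ``"adaptation"`` / ``"anticipation"`` or, in joint mode,
        ``"planned"`` / ``"default"``.
    metadata
        Run provenance: agent spec(s), seed, warm-up length, etc.
    """

    partner_onsets_ms: np.ndarray
    adam_onsets_ms: np.ndarray
    asynchronies_ms: np.ndarray
    timekeeper_ms: np.ndarray
    mechanism: list
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        n = len(self.adam_onsets_ms)
        for name in ("partner_onsets_ms", "asynchronies_ms", "timekeeper_ms"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.size != n:
                raise ValidationError(f"{name} length {arr.size} != {n}")
            setattr(self, name, arr)
        self.adam_onsets_ms = np.asarray(self.adam_onsets_ms, dtype=float)
        if len(self.mechanism) != n:
            raise ValidationError("mechanism length mismatch")
        for name in ("partner_onsets_ms", "adam_onsets_ms"):
            if n > 1 and not np.all(np.diff(getattr(self, name)) > 0):
                raise ValidationError(f"{name} not strictly increasing")

    def __len__(self) -> int:
        return len(self.adam_onsets_ms)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cycle": np.arange(len(self)),
                "partner_onset_ms": self.partner_onsets_ms,
                "adam_onset_ms": self.adam_onsets_ms,
                "asynchrony_ms": self.asynchronies_ms,
                "timekeeper_ms": self.timekeeper_ms,
                "mechanism": self.mechanism,
            }
        )

    def to_csv(self, path) -> None:
        """Write the per-cycle table as UTF-8 CSV (deterministic bytes)."""
        df = self.to_frame()
        # repr-level float formatting keeps seeded runs byte-identical
        with open(path, "w", newline="", encoding="utf-8") as fh:
            fh.write(",".join(CSV_COLUMNS) + "\n")
            for row in df.itertuples(index=False):
                fh.write(
                    f"{row.cycle},{row.partner_onset_ms!r},{row.adam_onset_ms!r},"
                    f"{row.asynchrony_ms!r},{row.timekeeper_ms!r},{row.mechanism}\n"
                )

    def write_metadata(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.metadata, fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_csv(cls, path, metadata_path=None) -> "DyadRecord":
        try:
            df = pd.read_csv(path)
        except Exception as exc:  # noqa: BLE001 - surfaced as a parse error
            raise ValidationError(f"{path}: cannot parse CSV ({exc})") from exc
        missing = [c for c in CSV_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"{path}: missing columns {missing}")
        bad = df[CSV_COLUMNS[:-1]].isna().any(axis=1)
        if bad.any():
            raise ValidationError(
                f"{path}: malformed value at row {int(bad.idxmax()) + 2}"
            )
        metadata = {}
        if metadata_path is not None:
            with open(metadata_path, encoding="utf-8") as fh:
                metadata = json.load(fh)
        return cls(
            partner_onsets_ms=df["partner_onset_ms"].to_numpy(float),
            adam_onsets_ms=df["adam_onset_ms"].to_numpy(float),
            asynchronies_ms=df["asynchrony_ms"].to_numpy(float),
            timekeeper_ms=df["timekeeper_ms"].to_numpy(float),
            mechanism=df["mechanism"].astype(str).tolist(),
            metadata=metadata,
        )
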