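"""Session-level analysis variables built on the detector output:
per-window call counts, per-contact-period emission rates, and the play
asymmetry score."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .detection import Detection

__all__ = [
    "ContactPeriod",
    "RateRecord",
    "UndefinedAsymmetryError",
    "count_in_window",
    "emission_rates",
    "asymmetry_score",
]

PERIOD_TYPES = ("ventral", "dorsal", "none")


@dataclass(frozen=True)
class ContactPeriod:
    period_type: str  # ventral | dorsal | none
    start_s: float
    end_s: float

    def __post_init__(self):
        if self.period_type not in PERIOD_TYPES:
            raise ValueError(f"unknown period_type {self.period_type!r}")
        if not self.end_s > self.start_s:
            raise ValueError("end_s must exceed start_s")


@dataclass(frozen=True)
class RateRecord:
    period_type: str
    total_duration_s: float
    count: int
    rate_per_s: float


class UndefinedAsymmetryError(ValueError):
    """Raised when delivered + received pinnings are both zero."""


def count_in_window(dets: Sequence[Detection], start_s: float, end_s: float) -> int:
    """Detections whose onset lies in the half-open window [start_s, end_s)."""
    return sum(1 for d in dets if start_s <= d.onset_s < end_s)


def emission_rates(
    dets: Sequence[Detection],
    periods: Sequence[ContactPeriod] | pd.DataFrame,
) -> list[RateRecord]:
    """Per-contact-type emission rate: total calls / summed duration.

    Each detection is assigned to the period containing its onset
    (half-open intervals).  A detection starting outside every period is
    counted under ``none`` with a warning.  One record is returned per
    period type present in the schedule (plus ``none`` if needed).
    """
    if isinstance(periods, pd.DataFrame):
        periods = [
            ContactPeriod(r.period_type, float(r.start_s), float(r.end_s))
            for r in periods.itertuples()
        ]
    durations = {t: 0.0 for t in PERIOD_TYPES}
    counts = {t: 0 for t in PERIOD_TYPES}
    for p in periods:
        durations[p.period_type] += p.end_s - p.start_s
    for d in dets:
        for p in periods:
            if p.start_s <= d.onset_s < p.end_s:
                counts[p.period_type] += 1
                break
        else:
            warnings.warn(
                f"unassigned detection at {d.onset_s:.3f}s counted under 'none'",
                stacklevel=2,
            )
            counts["none"] += 1
    out = []
    for t in PERIOD_TYPES:
        if durations[t] == 0.0 and counts[t] == 0:
            continue
        rate = counts[t] / durations[t] if durations[t] > 0 else float("nan")
        out.append(RateRecord(t, durations[t], counts[t], rate))
    return out


def asymmetry_score(delivered: int, received: int) -> float:
    """Play asymmetry: (delivered - received) / (delivered + received).

    Ranges from -1 (only received pinnings) through 0 (equal numbers) to
    +1 (only delivered pinnings); undefined when both counts are zero.
    """
    if delivered < 0 or received < 0:
        raise ValueError("pinning counts must be non-negative")
    total = delivered + received
    if total == 0:
        raise UndefinedAsymmetryError("asymmetry undefined: no pinnings in either direction")
    return (delivered - received) / total
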