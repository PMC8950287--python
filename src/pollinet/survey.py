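"""Phenology and visitation summaries for pollinator field surveys."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["VisitationBout", "DurationSummary", "duration_summary", "peak_window",
           "flowering_duration"]


@dataclass(frozen=True)
class VisitationBout:
    """One legitimate flower visit, timed from entering to escaping."""

    entering: str  # clock time "HH:MM:SS"
    escaping: str
    duration_s: float

    def __post_init__(self):
        if self.duration_s <= 0:
            raise ValueError("visit duration must be positive")


@dataclass(frozen=True)
class DurationSummary:
    mean: float
    sd: float | None  # sample SD (N-1); None when N == 1
    min: float
    max: float
    n: int


def duration_summary(bouts: Sequence) -> DurationSummary:
    """Mean, sample SD (N-1 denominator) and range of visit durations.

    ``bouts`` may be raw durations in seconds or VisitationBout objects.
    """
    durations = np.array(
        [b.duration_s if isinstance(b, VisitationBout) else float(b) for b in bouts]
    )
    n = len(durations)
    if n == 0:
        raise ValueError("no visitation bouts")
    sd = float(durations.std(ddof=1)) if n >= 2 else None
    return DurationSummary(
        mean=float(durations.mean()),
        sd=sd,
        min=float(durations.min()),
        max=float(durations.max()),
        n=n,
    )


def peak_window(hourly: pd.DataFrame) -> tuple[str, int, bool]:
    """Hourly window with the highest visit count pooled across dates.

    ``hourly`` has dates as rows and window labels as columns. Returns
    ``(window_label, pooled_count, tied)``; ties resolve to the earliest
    (left-most) window and set the tie flag.
    """
    if hourly.shape[1] == 0:
        raise ValueError("no hourly windows")
    sums = hourly.sum(axis=0)
    peak = int(np.argmax(sums.to_numpy()))
    tied = int((sums.to_numpy() == sums.iloc[peak]).sum()) > 1
    return str(sums.index[peak]), int(sums.iloc[peak]), tied


def flowering_duration(start_day: int, end_day: int) -> int:
    """Flowering span in days, difference convention (end - start)."""
    if end_day < start_day:
        raise ValueError("flowering end precedes start")
    return int(end_day) - int(start_day)
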