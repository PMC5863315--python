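"""Oscillation-period detection and synchronization classification.

A component's activity series is called periodic with period ``p`` when,
over the trailing analysis window, ``x(t) = x(t + p)`` holds exactly for
every valid ``t``.  Exact equality is well-defined because activity is a
ratio of integer node counts.  The reported period is the smallest such
``p``; it is capped at ``window / 2`` so that at least two full cycles
confirm it — a series whose only recurrence is longer counts as
aperiodic within the window.

A run of the four-graph network driven at period ``P`` is classified as

* ``ETA1``       — all four components lock to the drive: p1 = p2 = p3 = p4 = P;
* ``ETA2``       — the nuclei lock to the drive and both cortices to a
  common subharmonic: p1 = p3 = P and p2 = p4 in {2P, 3P};
* ``NO_SYNC``    — at least one component is aperiodic in the window;
* ``OTHER_SYNC`` — all periodic, but in some other period relationship
  (this includes silent cortices, whose constant-zero series has p = 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np

from .dynamics import ActivityTrace

__all__ = [
    "PeriodEstimate",
    "SyncCategory",
    "SyncClassification",
    "detect_period",
    "detect_periods_batch",
    "classify",
    "classify_trace",
]


@dataclass(frozen=True)
class PeriodEstimate:
    """Detected oscillation period over an analysis window.

    ``period`` is None when no recurrence with p <= window/2 exists
    (aperiodic within the window)."""

    period: int | None
    window: int

    @property
    def is_periodic(self) -> bool:
        return self.period is not None


class SyncCategory(str, Enum):
    ETA1 = "ETA1"
    ETA2 = "ETA2"
    OTHER_SYNC = "OTHER_SYNC"
    NO_SYNC = "NO_SYNC"


@dataclass(frozen=True)
class SyncClassification:
    """Synchronization type of one run.

    ``ratios`` gives the minimal integers r_i with p_i = r_i * g for the
    greatest common base period g, defined only when all four components
    are periodic."""

    category: SyncCategory
    periods: tuple[int | None, int | None, int | None, int | None]
    ratios: tuple[int, int, int, int] | None


def detect_period(series: Sequence[float] | np.ndarray, window: int) -> PeriodEstimate:
    """Smallest p in [1, window // 2] with exact recurrence
    ``x(t) = x(t + p)`` over the trailing ``window`` samples; aperiodic
    (period None) if no such p exists."""
    arr = np.asarray(series)
    if window < 1:
        raise ValueError(f"window must be >= 1, got {window}")
    if arr.ndim != 1:
        raise ValueError("series must be one-dimensional")
    if len(arr) < window:
        raise ValueError(f"series of length {len(arr)} shorter than window {window}")
    tail = arr[-window:]
    for p in range(1, window // 2 + 1):
        if np.array_equal(tail[:-p], tail[p:]):
            return PeriodEstimate(period=p, window=window)
    return PeriodEstimate(period=None, window=window)


def detect_periods_batch(tails: np.ndarray) -> np.ndarray:
    """Vectorized period detection for a stack of windows.

    ``tails`` has shape (batch, window, n_series); returns an int array
    (batch, n_series) with the smallest confirming period per series, or
    0 where aperiodic.  Equivalent to :func:`detect_period` per series.
    """
    if tails.ndim != 3:
        raise ValueError("tails must have shape (batch, window, n_series)")
    batch, window, n_series = tails.shape
    periods = np.zeros((batch, n_series), dtype=np.int32)
    for p in range(1, window // 2 + 1):
        undecided = periods == 0
        if not undecided.any():
            break
        recurs = (tails[:, : window - p, :] == tails[:, p:, :]).all(axis=1)
        periods[undecided & recurs] = p
    return periods


def _as_period(value: PeriodEstimate | int | None) -> int | None:
    if isinstance(value, PeriodEstimate):
        return value.period
    return value


def classify(
    periods: Sequence[PeriodEstimate | int | None], P: int
) -> SyncClassification:
    """Classify a run from the four detected periods (left-LGN, left-VC,
    right-LGN, right-VC order) against the drive period ``P``."""
    if P < 1:
        raise ValueError(f"P must be >= 1, got {P}")
    ps = tuple(_as_period(v) for v in periods)
    if len(ps) != 4:
        raise ValueError(f"expected 4 periods, got {len(ps)}")
    if any(p is None for p in ps):
        return SyncClassification(SyncCategory.NO_SYNC, ps, None)
    base = math.gcd(*ps)  # type: ignore[arg-type]
    ratios = tuple(p // base for p in ps)  # type: ignore[union-attr,misc]
    if all(p == P for p in ps):
        category = SyncCategory.ETA1
    elif ps[0] == ps[2] == P and ps[1] == ps[3] and ps[1] in (2 * P, 3 * P):
        category = SyncCategory.ETA2
    else:
        category = SyncCategory.OTHER_SYNC
    return SyncClassification(category, ps, ratios)  # type: ignore[arg-type]


def classify_trace(trace: ActivityTrace, P: int, window: int) -> SyncClassification:
    """Detect the four component periods over the trailing window of a
    trace and classify the run."""
    estimates = [detect_period(trace.counts[:, c], window) for c in range(4)]
    return classify(estimates, P)
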