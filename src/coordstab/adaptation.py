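"""Sensorimotor-synchronisation scoring for ramped-tempo trials (%Asynchrony).

Each catch is paired with its metronome beep; the absolute timing error is
scaled by the local inter-beep interval (the tempo "at which the error
occurs", which matters because the tempo ramps within a trial) and expressed
as a percentage. The first six catches are treated as task onset and
discarded, so a full 101-catch trial scores 95 catches.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InsufficientDataError, ParameterError
from .synthetic import BeepTrain, EventSeries

__all__ = ["AsynchronyResult", "pair_catches_to_beeps", "percent_asynchrony"]


@dataclass(frozen=True)
class AsynchronyResult:
    """Per-catch asynchrony table plus the trial-level %Asynchrony."""

    catch_times: np.ndarray  # s
    beep_times: np.ndarray  # s
    asynchrony_ms: np.ndarray
    local_interval_ms: np.ndarray
    percent: np.ndarray  # per-catch |error| / local interval * 100
    percent_asynchrony: float  # mean over retained catches
    n_used: int
    n_discarded: int


def pair_catches_to_beeps(
    events: EventSeries,
    beeps: BeepTrain,
    pairing: str = "sequential",
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pair catches (merged hands, time order) with beeps.

    ``sequential`` pairs the k-th catch with the k-th beep up to the shorter
    list (a dropped ball truncates the catch list); ``nearest`` pairs each
    catch with its closest beep instead. Returns (catch_times, beep_times,
    local_interval_ms) where the local interval is the inter-beep interval
    ending at the paired beep (the first beep uses the interval that follows
    it).
    """
    catches = events.merged_catches
    onsets = beeps.onsets
    if catches.size == 0 or onsets.size == 0:
        raise InsufficientDataError("need at least one catch and one beep")
    if pairing == "sequential":
        k = min(catches.size, onsets.size)
        c, b, idx = catches[:k], onsets[:k], np.arange(k)
    elif pairing == "nearest":
        idx = np.clip(np.searchsorted(onsets, catches), 0, onsets.size - 1)
        left = np.clip(idx - 1, 0, onsets.size - 1)
        idx = np.where(
            np.abs(catches - onsets[left]) <= np.abs(catches - onsets[idx]), left, idx
        )
        c, b = catches, onsets[idx]
    else:
        raise ParameterError(f"unknown pairing {pairing!r}")

    intervals = np.diff(onsets) * 1000.0
    if intervals.size == 0:
        raise InsufficientDataError("a single beep defines no interval")
    local = intervals[np.clip(idx - 1, 0, intervals.size - 1)]
    return c, b, local


def percent_asynchrony(
    pairs: tuple[np.ndarray, np.ndarray, np.ndarray],
    discard_first: int = 6,
) -> AsynchronyResult:
    """Trial-level %Asynchrony: mean scaled absolute catch-beep error.

    ``pairs`` is the output of :func:`pair_catches_to_beeps`. The first
    ``discard_first`` pairs are dropped before averaging.
    """
    catches, beep_times, local = (np.asarray(a, float) for a in pairs)
    if discard_first < 0:
        raise ParameterError("discard_first must be >= 0")
    if catches.size < discard_first + 1:
        raise InsufficientDataError(
            f"{catches.size} pairs <= {discard_first} discarded; nothing to score"
        )
    asyn_ms = np.abs(catches - beep_times) * 1000.0
    percent = 100.0 * asyn_ms / local
    keep = slice(discard_first, None)
    return AsynchronyResult(
        catch_times=catches,
        beep_times=beep_times,
        asynchrony_ms=asyn_ms,
        local_interval_ms=local,
        percent=percent,
        percent_asynchrony=float(np.mean(percent[keep])),
        n_used=catches.size - discard_first,
        n_discarded=discard_first,
    )
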