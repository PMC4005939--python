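"""Partial data requests: time windows resolved to array index bounds.

A client asks for a window with ``start_time`` / ``end_time`` / ``duration``
parameters; the window is half-open ``[start, end)`` so that windows tiling
the time axis slice a signal into disjoint, gap-free pieces.  For a
regularly sampled signal the window maps to inclusive 0-based indices of
the samples whose timestamps ``t_start + i / sampling_rate`` fall inside
the window.  Boundary comparisons on canonical seconds use a 1e-9 relative
tolerance so unit conversion round-off cannot shift an index by one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import BadRequest
from .model import Quantity, canonicalize_quantity

#: relative tolerance for boundary comparisons, on canonical seconds
REL_TOL = 1e-9


def _tol(*values: float) -> float:
    return REL_TOL * max(1.0, *(abs(v) for v in values))


@dataclass(frozen=True)
class SliceWindow:
    """Half-open time window [start, end) in canonical seconds."""

    start: float
    end: float

    def contains(self, t: float) -> bool:
        eps = _tol(self.start, self.end, t)
        return t >= self.start - eps and t < self.end - eps


@dataclass(frozen=True)
class IndexBounds:
    """Inclusive 0-based index bounds into a stored array."""

    first_index: int
    last_index: int

    @property
    def count(self) -> int:
        return self.last_index - self.first_index + 1


def _seconds(q: Quantity) -> float:
    return canonicalize_quantity(q, "time").value


def resolve_slice_window(
    params: dict,
    t_start: Quantity,
    t_stop: Quantity,
) -> SliceWindow:
    """Resolve request parameters into a concrete window.

    ``params`` may hold ``start_time``, and at most one of ``end_time`` or
    ``duration``, all as time quantities.  A missing start defaults to the
    signal's ``t_start``; a missing end to the signal's end ``t_stop``.
    """
    unknown = set(params) - {"start_time", "end_time", "duration"}
    if unknown:
        raise BadRequest(f"unknown slicing parameters: {sorted(unknown)}")
    if "end_time" in params and "duration" in params:
        raise BadRequest("give at most one of end_time and duration")

    sig_start = _seconds(t_start)
    sig_end = _seconds(t_stop)
    start = _seconds(params["start_time"]) if "start_time" in params else sig_start
    if "end_time" in params:
        end = _seconds(params["end_time"])
    elif "duration" in params:
        end = start + _seconds(params["duration"])
    else:
        end = sig_end

    eps = _tol(start, end, sig_start, sig_end)
    if end - start <= eps:
        raise BadRequest("requested time window is empty")
    if start >= sig_end - eps or end <= sig_start + eps:
        raise BadRequest("requested window lies outside the signal")
    return SliceWindow(start=start, end=end)


def slice_indices(
    window: SliceWindow,
    t_start: Quantity,
    sampling_rate: Quantity,
    length: int,
) -> IndexBounds:
    """Inclusive index bounds of the samples falling in ``window``.

    Sample ``i`` has timestamp ``t_start + i / sampling_rate``; the result
    covers exactly the samples with ``start <= t_i < end``, clamped to the
    array, or raises :class:`BadRequest` when no sample qualifies.
    """
    if length <= 0:
        raise BadRequest("cannot slice an empty signal")
    t0 = _seconds(t_start)
    rate = canonicalize_quantity(sampling_rate, "frequency").value
    if rate <= 0:
        raise BadRequest("sampling_rate must be positive")

    eps = _tol(window.start, window.end, t0)
    # smallest i with t0 + i/rate >= start  (tolerant ceiling)
    first = math.ceil((window.start - t0 - eps) * rate)
    # largest i with t0 + i/rate < end  (strict, tolerant)
    last = math.ceil((window.end - t0 - eps) * rate) - 1

    first = max(first, 0)
    last = min(last, length - 1)
    if first > last:
        raise BadRequest("no sample falls within the requested window")
    return IndexBounds(first_index=first, last_index=last)


def slice_spiketrain(times, window: SliceWindow) -> np.ndarray:
    """Spike times (canonical seconds, sorted) inside ``window``."""
    arr = np.asarray(times, dtype=float)
    if arr.size == 0:
        return arr
    keep = [t for t in arr if window.contains(t)]
    return np.asarray(keep, dtype=float)


def spiketrain_index_bounds(times, window: SliceWindow) -> Optional[IndexBounds]:
    """Inclusive index bounds of the in-window spikes, or None when empty.

    Because spike times are sorted, the in-window subset is contiguous.
    """
    arr = np.asarray(times, dtype=float)
    inside = [i for i, t in enumerate(arr) if window.contains(t)]
    if not inside:
        return None
    return IndexBounds(first_index=inside[0], last_index=inside[-1])
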