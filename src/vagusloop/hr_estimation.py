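"""Heart-rate estimation from R-event times.

The controller's measured heart rate is the reciprocal of the mean R-R
interval over a rolling 2-second window, converted to beats per minute.
An interval belongs to the window when its *later* R event falls in
``(t - window, t]`` (half-open, so no interval is counted twice as the
window slides).  When fewer than two beats fall inside the window the
estimator holds its last valid value and flags a data gap.
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from collections import deque
from dataclasses import dataclass

import numpy as np

__all__ = ["BeatSeries", "rolling_hr", "RollingHrEstimator", "DataGapWarning"]

logger = logging.getLogger(__name__)

MIN_RR_S = 0.020  # physiological floor on inter-beat intervals
DEFAULT_WINDOW_S = 2.0


class DataGapWarning(UserWarning):
    """Emitted when a rolling window contains fewer than two beats."""


@dataclass(frozen=True)
class BeatSeries:
    """Strictly increasing R-event times in seconds."""

    r_times: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.r_times, dtype=float)
        object.__setattr__(self, "r_times", times)
        if times.ndim != 1:
            raise ValueError("r_times must be a 1-D array")
        if times.size >= 2:
            dts = np.diff(times)
            if np.any(dts <= 0):
                raise ValueError("r_times must be strictly increasing")
            if np.any(dts < MIN_RR_S):
                raise ValueError(
                    f"inter-beat intervals below the {MIN_RR_S*1000:.0f} ms floor"
                )

    def __len__(self) -> int:
        return int(self.r_times.size)


def rolling_hr(
    beats: BeatSeries | np.ndarray,
    t: float,
    window: float = DEFAULT_WINDOW_S,
    last_valid: float | None = None,
) -> float:
    """Mean-R-R heart rate (bpm) at time ``t``.

    Averages the R-R intervals whose later beat lies in ``(t - window, t]``
    and returns ``60 / mean`` (intervals in seconds).  With fewer than two
    beats in the window, returns ``last_valid`` (if given) and logs a
    data-gap warning; with no fallback available a ``ValueError`` is
    raised.
    """
    if window <= 0:
        raise ValueError("window must be > 0")
    times = beats.r_times if isinstance(beats, BeatSeries) else np.asarray(beats, float)
    lo = bisect_right(times, t - window)
    hi = bisect_right(times, t)
    n_in_window = hi - lo
    if n_in_window < 2:
        if last_valid is not None:
            logger.warning(
                "data gap: %d beat(s) in (%.3f, %.3f]; holding last estimate",
                n_in_window,
                t - window,
                t,
            )
            return last_valid
        raise ValueError(
            f"fewer than 2 beats in (t - {window}, t] and no previous estimate to hold"
        )
    # Intervals whose later beat is in the window; the earlier beat of the
    # first interval may precede the window.
    first = max(lo, 1)
    intervals = np.diff(times[first - 1 : hi])
    mean_rr = float(np.mean(intervals))
    return 60.0 / mean_rr


class RollingHrEstimator:
    """Incremental rolling-window estimator for the closed-loop engine.

    Keeps only the beats needed for the current window and holds the last
    valid estimate across data gaps.
    """

    def __init__(self, window: float = DEFAULT_WINDOW_S) -> None:
        if window <= 0:
            raise ValueError("window must be > 0")
        self.window = window
        self._beats: deque[float] = deque()
        self._last: float | None = None
        self._in_gap = False
        self.gap_count = 0

    def add_beat(self, t: float) -> None:
        if self._beats and t <= self._beats[-1]:
            raise ValueError("beat times must be strictly increasing")
        self._beats.append(t)

    def estimate(self, t: float) -> float:
        # Retain one beat before the window so its interval is available.
        while len(self._beats) > 2 and self._beats[1] <= t - self.window:
            self._beats.popleft()
        times = np.fromiter(self._beats, dtype=float)
        in_window = (times > t - self.window) & (times <= t)
        if int(in_window.sum()) < 2:
            self.gap_count += 1
            if self._last is None:
                raise ValueError("no beats yet: cannot estimate heart rate")
            if not self._in_gap:  # warn once per gap run, not per tick
                logger.warning("data gap at t=%.2f s; holding last estimate", t)
                self._in_gap = True
            return self._last
        self._in_gap = False
        hr = rolling_hr(times, t, self.window, last_valid=self._last)
        self._last = hr
        return hr
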