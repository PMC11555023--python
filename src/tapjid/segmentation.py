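"""Behavioural-day segmentation of a continuous tap stream.

A "study day" runs from one morning rise time to the next rather than
midnight to midnight, so that the overnight no-use gap never contributes an
inter-touch interval.  Rise times are detected with a longest-nightly-gap
heuristic: within each noon-to-noon window, the longest event gap of at
least ``min_sleep_gap`` hours whose end falls in the configured clock-time
search window is taken as the night's sleep, and its end as the rise time.

This is a deliberately simple stand-in for dedicated sleep/rise detection:
it reproduces the one property the downstream analysis needs — a stable
partition of events into behavioural days — and is validated against the
synthetic generator's ground-truth wake times.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import EmptyInputError
from .io import DayRecord, TapStream

logger = logging.getLogger(__name__)

_S_PER_DAY = 86_400
_MS_PER_DAY = 86_400_000


@dataclass(frozen=True)
class SegmentationParams:
    """Tunables of the rise-time heuristic.

    min_sleep_gap : hours; event gaps shorter than this never count as sleep.
    search_start_hour, search_end_hour : clock window (possibly wrapping
        midnight) in which the sleep gap must end; default 20:00-12:00.
    min_day_events : days with fewer events are flagged ``low_count`` and,
        by default, excluded from group statistics downstream.
    """

    min_sleep_gap: float = 3.0
    search_start_hour: float = 20.0
    search_end_hour: float = 12.0
    min_day_events: int = 30

    def __post_init__(self) -> None:
        if self.min_sleep_gap <= 0:
            raise ValueError("min_sleep_gap must be > 0")
        if self.min_day_events < 2:
            raise ValueError("min_day_events must be >= 2")


def _clock_in_window(sec_of_day: np.ndarray, start_h: float, end_h: float) -> np.ndarray:
    start, end = start_h * 3600.0, end_h * 3600.0
    if start <= end:
        return (sec_of_day >= start) & (sec_of_day < end)
    return (sec_of_day >= start) | (sec_of_day < end)  # wraps midnight


def detect_rise_times(
    stream: TapStream, params: SegmentationParams | None = None
) -> np.ndarray:
    """Detect one rise time (epoch ms) per behavioural day.

    For every noon-to-noon window spanned by the stream, the end of the
    longest qualifying sleep gap is returned.  Windows without any gap of
    ``min_sleep_gap`` hours ending in the search window produce no rise
    time — that day merges with the next, with a logged warning.
    """
    if params is None:
        params = SegmentationParams()
    ts = stream.timestamps
    if ts.size < 2:
        raise EmptyInputError("stream must span at least one day of events")

    gap_ms = np.diff(ts)
    end_ms = ts[1:]
    sec_of_day = (end_ms // 1000) % _S_PER_DAY
    qualifies = (gap_ms >= params.min_sleep_gap * 3_600_000) & _clock_in_window(
        sec_of_day.astype(float),
        params.search_start_hour,
        params.search_end_hour,
    )
    # assign each qualifying gap end to its noon-to-noon window
    window = (end_ms - _MS_PER_DAY // 2) // _MS_PER_DAY
    rises: list[int] = []
    first_win = int((ts[0] - _MS_PER_DAY // 2) // _MS_PER_DAY)
    last_win = int((ts[-1] - _MS_PER_DAY // 2) // _MS_PER_DAY)
    for w in range(first_win, last_win + 1):
        in_w = qualifies & (window == w)
        if not np.any(in_w):
            # first window has no preceding night, last has no following
            # morning: neither can host a rise, so neither warrants a warning
            has_events = np.any((ts - _MS_PER_DAY // 2) // _MS_PER_DAY == w)
            if has_events and first_win < w < last_win:
                logger.warning(
                    "no sleep gap >= %.1f h found in window %d; day merges with next",
                    params.min_sleep_gap,
                    w,
                )
            continue
        idx = np.flatnonzero(in_w)
        best = idx[np.argmax(gap_ms[idx])]
        rises.append(int(end_ms[best]))
    return np.asarray(sorted(rises), dtype=np.int64)


def split_days(
    stream: TapStream,
    rise_times: np.ndarray,
    params: SegmentationParams | None = None,
) -> list[DayRecord]:
    """Partition events into day records bounded by rise times.

    Day boundaries are half-open ``[rise_i, rise_{i+1})``: an event exactly
    at a rise time starts that day.  Events before the first rise form a
    leading partial day (flagged).  Event count is conserved exactly, and
    ITIs are computed within days only.
    """
    if params is None:
        params = SegmentationParams()
    ts = stream.timestamps
    rise_times = np.asarray(rise_times, dtype=np.int64)
    if rise_times.size == 0:
        records = [DayRecord(day_id=0, timestamps=ts)]
    else:
        # bin index: -1 before the first rise, k in [rise_k, rise_{k+1})
        idx = np.searchsorted(rise_times, ts, side="right") - 1
        records = []
        day_id = 0
        for k in range(-1, rise_times.size):
            day_ts = ts[idx == k]
            if k == -1 and day_ts.size == 0:
                continue  # no leading partial day
            rec = DayRecord(day_id=day_id, timestamps=day_ts)
            if k == -1:
                rec.flags.append("partial_leading")
            records.append(rec)
            day_id += 1
    for rec in records:
        if rec.n_events < params.min_day_events:
            rec.flags.append("low_count")
    return records


def segmentation_report(records: list[DayRecord]) -> "pd.DataFrame":
    """Per-day table: day_id, first event (rise), n_events, flags."""
    import pandas as pd

    return pd.DataFrame(
        {
            "day_id": [r.day_id for r in records],
            "rise_time_ms": [
                int(r.timestamps[0]) if r.n_events else -1 for r in records
            ],
            "n_events": [r.n_events for r in records],
            "flags": [";".join(r.flags) for r in records],
        }
    )
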