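"""Extraction of rehabilitation activity parameters from wheel telemetry.

A revolution counter on an in-cage running wheel yields a per-second
cumulative-distance stream for each subject-day.  Six activity parameters
are derived from it: daily running distance (m/day), running duration
(min/day), number of running bouts per day, mean running-bout duration (s),
running velocity (m/s), and daily rest time (h).

A *running bout* starts at the first second in which the cumulative
distance increases and ends once ``gap_seconds`` (default 6) consecutive
seconds elapse with no change in cumulative distance.  *Rest time* is the
longest daily window, in hours, over which the cumulative distance did not
change; windows are truncated at day boundaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

SECONDS_PER_DAY = 86_400
DEFAULT_GAP_SECONDS = 6

__all__ = [
    "TelemetrySeries",
    "Bout",
    "ActivityFeatures",
    "FEATURE_NAMES",
    "detect_bouts",
    "daily_metrics",
    "weekly_features",
    "features_to_frame",
]

#: Canonical ordering of the six activity parameters.
FEATURE_NAMES = (
    "distance",
    "duration",
    "bouts_per_day",
    "bout_duration",
    "velocity",
    "rest",
)


@dataclass(frozen=True)
class TelemetrySeries:
    """One subject-day of cumulative-distance telemetry.

    Parameters
    ----------
    subject_id:
        Subject label.
    day_index:
        Zero-based day index relative to the start of rehabilitation.
    t:
        Sample times in integer seconds since the start of the day,
        strictly increasing, within ``[0, 86400)``.
    cum_distance:
        Cumulative distance in meters at each sample time; nondecreasing.
    """

    subject_id: str
    day_index: int
    t: np.ndarray
    cum_distance: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.t)
        d = np.asarray(self.cum_distance, dtype=float)
        if t.size != d.size:
            raise ValueError("t and cum_distance must have equal length")
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError("sample times must be strictly increasing")
        if d.size and np.any(np.diff(d) < -1e-9):
            raise ValueError("cumulative distance must be nondecreasing")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "cum_distance", d)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": self.subject_id,
                "day": self.day_index,
                "t_seconds": self.t,
                "cum_distance_m": self.cum_distance,
            }
        )


@dataclass(frozen=True)
class Bout:
    """A maximal run of wheel movement with no idle stretch of
    ``gap_seconds`` or more.

    ``t_start``/``t_end`` are the first and last sample times at which the
    cumulative distance changed; ``distance`` is the cumulative-distance
    increase attributable to the bout.
    """

    t_start: int
    t_end: int
    distance: float

    @property
    def duration(self) -> int:
        """Bout duration in seconds (a single movement sample counts 1 s)."""
        return int(self.t_end - self.t_start + 1)


@dataclass
class ActivityFeatures:
    """The six per-day (or per-week-averaged) rehabilitation parameters.

    ``velocity`` is NaN on idle days (no running duration to divide by);
    downstream averaging skips missing velocities.
    """

    distance: float  # m/day
    duration: float  # min/day
    bouts_per_day: float
    bout_duration: float  # s, mean per bout (NaN on idle days)
    velocity: float  # m/s (NaN on idle days)
    rest: float  # h, longest idle window
    subject_id: str = ""
    day_index: int = -1

    def as_array(self) -> np.ndarray:
        return np.array(
            [getattr(self, name) for name in FEATURE_NAMES], dtype=float
        )

    def is_complete(self) -> bool:
        return bool(np.all(np.isfinite(self.as_array())))


def _movement_times(series: TelemetrySeries) -> tuple[np.ndarray, np.ndarray]:
    """Sample times at which cumulative distance increased, and the
    cumulative distance *before* each movement sample."""
    d = series.cum_distance
    if d.size == 0:
        raise ValueError("empty telemetry series")
    inc = np.diff(d) > 0
    idx = np.nonzero(inc)[0] + 1
    return series.t[idx], idx


def detect_bouts(
    series: TelemetrySeries, gap_seconds: int = DEFAULT_GAP_SECONDS
) -> list[Bout]:
    """Segment a subject-day of telemetry into running bouts.

    A bout is a maximal run of movement samples in which no idle stretch
    reaches ``gap_seconds``.  With 1-s sampling, movement samples at times
    ``a`` and ``b`` (``a < b``) belong to the same bout iff the idle stretch
    between them, ``b - a - 1`` seconds, is shorter than ``gap_seconds``.
    """
    if gap_seconds < 1:
        raise ValueError("gap_seconds must be >= 1")
    move_t, move_idx = _movement_times(series)
    if move_t.size == 0:
        return []
    # Split where the idle stretch between successive movements reaches the
    # gap threshold.
    gaps = np.diff(move_t) - 1
    cut = np.nonzero(gaps >= gap_seconds)[0] + 1
    bouts: list[Bout] = []
    d = series.cum_distance
    for chunk_t, chunk_i in zip(
        np.split(move_t, cut), np.split(move_idx, cut)
    ):
        start, end = int(chunk_t[0]), int(chunk_t[-1])
        dist = float(d[chunk_i[-1]] - d[chunk_i[0] - 1])
        bouts.append(Bout(t_start=start, t_end=end, distance=dist))
    return bouts


def _longest_idle_seconds(
    move_t: np.ndarray, day_seconds: int = SECONDS_PER_DAY
) -> float:
    """Longest contiguous window (s) with no cumulative-distance change,
    truncated at the day boundaries."""
    if move_t.size == 0:
        return float(day_seconds)
    # A movement sample at time t means movement during second (t-1, t];
    # idle seconds before the first movement are [0, t0 - 1].
    leading = float(move_t[0])
    trailing = float(day_seconds - move_t[-1])
    inner = float(np.max(np.diff(move_t) - 1)) if move_t.size > 1 else 0.0
    return max(leading, trailing, inner)


def daily_metrics(
    series: TelemetrySeries, gap_seconds: int = DEFAULT_GAP_SECONDS
) -> ActivityFeatures:
    """Compute the six activity parameters for one subject-day."""
    bouts = detect_bouts(series, gap_seconds=gap_seconds)
    move_t, _ = _movement_times(series)
    rest_h = _longest_idle_seconds(move_t) / 3600.0
    if not bouts:
        return ActivityFeatures(
            distance=0.0,
            duration=0.0,
            bouts_per_day=0.0,
            bout_duration=math.nan,
            velocity=math.nan,
            rest=rest_h,
            subject_id=series.subject_id,
            day_index=series.day_index,
        )
    distance = float(sum(b.distance for b in bouts))
    duration_s = float(sum(b.duration for b in bouts))
    return ActivityFeatures(
        distance=distance,
        duration=duration_s / 60.0,
        bouts_per_day=float(len(bouts)),
        bout_duration=duration_s / len(bouts),
        velocity=distance / duration_s,
        rest=rest_h,
        subject_id=series.subject_id,
        day_index=series.day_index,
    )


def weekly_features(
    days: Sequence[ActivityFeatures],
    weeks: tuple[int, int] = (1, 3),
) -> ActivityFeatures:
    """Average daily activity parameters over the given week range.

    Week ``w`` covers day indices ``7*(w-1) .. 7*w - 1``.  Missing
    (NaN) velocities and bout durations — idle days — are excluded from
    their respective means; all other parameters average over every day in
    range.
    """
    lo, hi = weeks
    first_day, last_day = 7 * (lo - 1), 7 * hi - 1
    in_range = [
        f for f in days if first_day <= f.day_index <= last_day
    ]
    if days and all(f.day_index == -1 for f in days):
        # Features without day annotation: average everything given.
        in_range = list(days)
    if not in_range:
        raise ValueError(f"no days with day_index in weeks {lo}-{hi}")
    arr = np.array([f.as_array() for f in in_range], dtype=float)
    means = []
    for j, name in enumerate(FEATURE_NAMES):
        col = arr[:, j]
        if name in ("velocity", "bout_duration"):
            valid = col[np.isfinite(col)]
            means.append(float(valid.mean()) if valid.size else math.nan)
        else:
            means.append(float(col.mean()))
    return ActivityFeatures(
        *means,
        subject_id=in_range[0].subject_id,
        day_index=-1,
    )


def features_to_frame(features: Iterable[ActivityFeatures]) -> pd.DataFrame:
    """Tabulate feature records (one row per subject-day or subject)."""
    rows = []
    for f in features:
        row = {"subject_id": f.subject_id, "day": f.day_index}
        row.update({name: getattr(f, name) for name in FEATURE_NAMES})
        rows.append(row)
    return pd.DataFrame(rows)
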