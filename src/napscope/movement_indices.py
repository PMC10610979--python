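"""Session movement indices from joint-angle time series.

Each angle's series is reduced to the sleep-movement indices used for the
condition comparison:

* ``n_changes`` — number of repositioning events, i.e. transitions between
  consecutive stable segments whose level shift is at least ``delta_deg``;
* ``max_change_deg`` — the series range (max - min) over present samples;
* ``max_event_change_deg`` — the largest single between-segment level shift;
* ``max_stable_s`` / ``min_stable_s`` — longest and shortest stable-segment
  durations;
* ``duration_s`` — session length.

A *stable segment* is a maximal run of samples that stays within
``tolerance_deg`` of the segment's running median and lasts at least
``min_duration_s``. Isolated single-sample excursions are treated as
impulse noise and dropped; a genuine level change must be confirmed by the
following present sample. Missing runs longer than ``gap_fill_s`` split
the segmentation rather than fabricate stability.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, EmptySeriesError
from .pose_topology import ANGLE_ORDER, Landmark

__all__ = [
    "AngleSeries",
    "StableSegment",
    "IndexParams",
    "MovementIndices",
    "DEFAULT_FPS",
    "fill_gaps",
    "segment_stable_periods",
    "count_changes",
    "max_change",
    "max_event_change",
    "stable_times",
    "series_indices",
    "session_indices",
    "INDEX_COLUMNS",
]

DEFAULT_FPS = 30.0

INDEX_COLUMNS = [
    "angle",
    "n_changes",
    "max_change_deg",
    "max_event_change_deg",
    "max_stable_s",
    "min_stable_s",
    "duration_s",
    "flag",
]


@dataclass
class AngleSeries:
    """One joint angle's time series over a session; NaN marks missing."""

    angle: Landmark
    times_s: np.ndarray
    values_deg: np.ndarray
    fps: float = DEFAULT_FPS

    def __post_init__(self):
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.values_deg = np.asarray(self.values_deg, dtype=float)
        if self.times_s.shape != self.values_deg.shape or self.times_s.ndim != 1:
            raise DomainError("times_s and values_deg must be equal-length 1-D arrays")
        if self.times_s.size and np.any(np.diff(self.times_s) <= 0):
            raise DomainError("times_s must be strictly increasing")
        if self.fps <= 0:
            raise DomainError(f"fps must be positive, got {self.fps}")
        present = self.values_deg[~np.isnan(self.values_deg)]
        if present.size and (present.min() < 0 or present.max() > 180):
            raise DomainError("angle values must lie in [0, 180] degrees")

    @classmethod
    def from_values(
        cls, angle: "Landmark | str", values: Sequence[float], fps: float = DEFAULT_FPS
    ) -> "AngleSeries":
        """Build a series from evenly sampled values (time = index / fps)."""
        key = angle if isinstance(angle, Landmark) else Landmark.parse(angle)
        values = np.asarray(values, dtype=float)
        times = np.arange(values.size) / fps
        return cls(angle=key, times_s=times, values_deg=values, fps=fps)

    @property
    def dt(self) -> float:
        return 1.0 / self.fps

    @property
    def n_present(self) -> int:
        return int(np.sum(~np.isnan(self.values_deg)))

    @property
    def duration_s(self) -> float:
        """Session span covered by the series (sample-and-hold on the last frame)."""
        if self.times_s.size == 0:
            return 0.0
        return float(self.times_s[-1] - self.times_s[0] + self.dt)


@dataclass(frozen=True)
class StableSegment:
    """A maximal interval in which the angle holds one level."""

    start_s: float
    end_s: float
    level_deg: float
    n_samples: int

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass(frozen=True)
class IndexParams:
    """Thresholds operationalizing "stable" and "change".

    tolerance_deg : half-width of the stability band around a segment median
    delta_deg     : minimum between-segment level shift counted as a change
    min_duration_s: minimum stable-segment length
    gap_fill_s    : longest missing run bridged by linear interpolation
    """

    tolerance_deg: float = 5.0
    delta_deg: float = 10.0
    min_duration_s: float = 2.0
    gap_fill_s: float = 1.0

    def __post_init__(self):
        for name in ("tolerance_deg", "delta_deg", "min_duration_s", "gap_fill_s"):
            if getattr(self, name) <= 0:
                raise DomainError(f"IndexParams.{name} must be positive")
        if self.delta_deg < self.tolerance_deg:
            raise DomainError("delta_deg must be >= tolerance_deg")


@dataclass(frozen=True)
class MovementIndices:
    """Per-angle session summary."""

    angle: Landmark
    n_changes: int
    max_change_deg: float
    max_event_change_deg: float
    max_stable_s: float
    min_stable_s: float
    duration_s: float
    flag: str = ""


def fill_gaps(series: AngleSeries, gap_fill_s: float | None = None) -> AngleSeries:
    """Linearly interpolate missing runs no longer than ``gap_fill_s``.

    A run's length is its sample count times the frame period. Longer runs
    (and runs touching the series boundary) are preserved as missing and
    later split the segmentation.
    """
    if gap_fill_s is None:
        gap_fill_s = IndexParams().gap_fill_s
    v = series.values_deg
    isnan = np.isnan(v)
    if not isnan.any():
        return series
    out = v.copy()
    t = series.times_s
    n = v.size
    i = 0
    while i < n:
        if not isnan[i]:
            i += 1
            continue
        j = i
        while j < n and isnan[j]:
            j += 1
        # gap [i, j); bounded iff i > 0 and j < n
        if i > 0 and j < n and (j - i) * series.dt <= gap_fill_s:
            out[i:j] = np.interp(t[i:j], [t[i - 1], t[j]], [v[i - 1], v[j]])
        i = j
    return replace(series, values_deg=out)


def _split_on_long_gaps(series: AngleSeries, gap_fill_s: float) -> list[np.ndarray]:
    """Indices of present samples, split wherever a missing run exceeds gap_fill_s."""
    present = np.flatnonzero(~np.isnan(series.values_deg))
    if present.size == 0:
        return []
    t = series.times_s[present]
    breaks = np.flatnonzero(np.diff(t) > gap_fill_s + series.dt + 1e-12)
    return np.split(present, breaks + 1)


def segment_stable_periods(
    series: AngleSeries, params: IndexParams | None = None
) -> list[StableSegment]:
    """Segment a (gap-filled) series into ordered, non-overlapping stable periods.

    Left-to-right scan: a sample extends the current segment while it lies
    within ``tolerance_deg`` of the segment's running median. An out-of-band
    sample starts a new segment only if the next present sample is also out
    of band (confirmed level change); an isolated excursion is discarded as
    impulse noise. Segments shorter than ``min_duration_s`` are dropped.

    Segment boundaries land on the first sample of the new level, so a
    scheduled repositioning event is localized to within one frame period.
    """
    params = params or IndexParams()
    filled = fill_gaps(series, params.gap_fill_s)
    v = filled.values_deg
    t = filled.times_s
    dt = filled.dt
    segments: list[StableSegment] = []

    for chunk in _split_on_long_gaps(filled, params.gap_fill_s):
        runs: list[list[int]] = []  # runs of sample indices at one level
        cur: list[int] = []
        k = 0
        idx = chunk
        m = idx.size
        while k < m:
            i = int(idx[k])
            if not cur:
                cur.append(i)
                k += 1
                continue
            med = np.median(v[cur])
            if abs(v[i] - med) <= params.tolerance_deg:
                cur.append(i)
                k += 1
                continue
            # out of band: confirm against the next present sample
            if k + 1 < m and abs(v[int(idx[k + 1])] - med) > params.tolerance_deg:
                runs.append(cur)
                cur = [i]
                k += 1
            else:
                # isolated excursion (or trailing outlier): drop the sample
                k += 1
        if cur:
            runs.append(cur)

        for run in runs:
            start = t[run[0]]
            end = t[run[-1]] + dt
            if end - start + 1e-12 >= params.min_duration_s:
                segments.append(
                    StableSegment(
                        start_s=float(start),
                        end_s=float(end),
                        level_deg=float(np.median(v[run])),
                        n_samples=len(run),
                    )
                )
    return segments


def count_changes(segments: Sequence[StableSegment], params: IndexParams | None = None) -> int:
    """Number of consecutive-segment transitions with level shift >= delta_deg."""
    params = params or IndexParams()
    levels = np.array([s.level_deg for s in segments])
    if levels.size < 2:
        return 0
    return int(np.sum(np.abs(np.diff(levels)) >= params.delta_deg - 1e-12))


def max_change(series: AngleSeries) -> float:
    """Series range max - min over present samples (the session's maximum change)."""
    v = series.values_deg
    present = v[~np.isnan(v)]
    if present.size == 0:
        raise EmptySeriesError(f"angle {series.angle.value}: no present samples")
    return float(present.max() - present.min())


def max_event_change(segments: Sequence[StableSegment]) -> float:
    """Largest single between-segment level shift (0 with fewer than 2 segments)."""
    levels = np.array([s.level_deg for s in segments])
    if levels.size < 2:
        return 0.0
    return float(np.max(np.abs(np.diff(levels))))


def stable_times(segments: Sequence[StableSegment]) -> tuple[float, float]:
    """(max, min) stable-segment durations; (0, 0) when no segment qualified."""
    if not segments:
        return (0.0, 0.0)
    durations = [s.duration_s for s in segments]
    return (float(max(durations)), float(min(durations)))


def series_indices(series: AngleSeries, params: IndexParams | None = None) -> MovementIndices:
    """All movement indices for one angle series."""
    params = params or IndexParams()
    flag = ""
    if series.n_present == 0:
        return MovementIndices(
            angle=series.angle,
            n_changes=0,
            max_change_deg=float("nan"),
            max_event_change_deg=float("nan"),
            max_stable_s=0.0,
            min_stable_s=0.0,
            duration_s=series.duration_s,
            flag="all-missing",
        )
    segments = segment_stable_periods(series, params)
    max_st, min_st = stable_times(segments)
    if not segments:
        flag = "no-stable-segment"
    return MovementIndices(
        angle=series.angle,
        n_changes=count_changes(segments, params),
        max_change_deg=max_change(series),
        max_event_change_deg=max_event_change(segments),
        max_stable_s=max_st,
        min_stable_s=min_st,
        duration_s=series.duration_s,
        flag=flag,
    )


def session_indices(
    series_by_angle: "Mapping[Landmark, AngleSeries] | Iterable[AngleSeries]",
    params: IndexParams | None = None,
) -> pd.DataFrame:
    """Movement indices for a whole session: one row per angle.

    Accepts a mapping angle -> series or an iterable of series. All series
    must share the session time base; ``duration_s`` is reported as the
    common session span (identical across rows).
    """
    params = params or IndexParams()
    if isinstance(series_by_angle, Mapping):
        series_list = list(series_by_angle.values())
    else:
        series_list = list(series_by_angle)
    if not series_list:
        raise EmptySeriesError("no angle series supplied")
    order = {a: i for i, a in enumerate(ANGLE_ORDER)}
    series_list.sort(key=lambda s: order[s.angle])
    duration = max(s.duration_s for s in series_list)
    rows = []
    for s in series_list:
        mi = series_indices(s, params)
        rows.append(
            {
                "angle": mi.angle.value,
                "n_changes": mi.n_changes,
                "max_change_deg": mi.max_change_deg,
                "max_event_change_deg": mi.max_event_change_deg,
                "max_stable_s": mi.max_stable_s,
                "min_stable_s": mi.min_stable_s,
                "duration_s": duration,
                "flag": mi.flag,
            }
        )
    return pd.DataFrame(rows, columns=INDEX_COLUMNS)
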