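"""Thermal summation model for insect development.

The model is linear in temperature: a stage completes once the accumulated
degree-hours above its lower developmental threshold ``t`` reach its thermal
constant ``k``,

    D * (T - t) = k        (constant temperature T > t)

so the expected duration at constant ``T`` is ``D = k / (T - t)`` and the
development rate is ``(T - t) / k`` per hour.  At or below the threshold the
rate is zero and the duration infinite — a valid regime, not an error, since
fitted thresholds can exceed the coldest viable rearing temperature.

Units are degree-HOURS for ``k`` and hours for durations throughout.

For variable temperature records the module integrates effective degrees
over a timestamped series (piecewise-constant, left-hold interpolation),
steps a developing individual through its stage sequence, and back-computes
the minimum post-mortem interval (PMImin) consistent with an observed stage:
the shortest time since oviposition such that sequential accumulation —
each stage against its own threshold — reaches that stage by collection.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import (
    ExtrapolationWarning,
    InsufficientRecordError,
    ValidationError,
)

__all__ = [
    "Stage",
    "ThermalSummationParams",
    "TemperatureSeries",
    "StageTimeline",
    "predict_duration",
    "development_rate",
    "accumulate_effective_degrees",
    "stage_progression",
    "estimate_pmi_min",
]

NS_PER_HOUR = 3_600_000_000_000


class Stage(enum.IntEnum):
    """Ordered developmental stages: egg < L1 < L2 < L3 < pupa."""

    egg = 0
    L1 = 1
    L2 = 2
    L3 = 3
    pupa = 4

    def __str__(self) -> str:  # CSV-friendly
        return self.name

    @classmethod
    def parse(cls, value: "Stage | str") -> "Stage":
        if isinstance(value, Stage):
            return value
        try:
            return cls[str(value).strip()]
        except KeyError:
            raise ValidationError(
                f"unknown stage {value!r}; expected one of "
                f"{[s.name for s in cls]}"
            ) from None


LARVAL_INSTARS = (Stage.L1, Stage.L2, Stage.L3)


@dataclass(frozen=True)
class ThermalSummationParams:
    """Per-stage thermal constant ``k`` (degree-hours) and lower
    developmental threshold ``t`` (°C)."""

    stage: Stage
    k: float
    t: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "stage", Stage.parse(self.stage))
        if not (self.k > 0 and math.isfinite(self.k)):
            raise ValidationError(f"thermal constant k must be > 0, got {self.k}")
        if not math.isfinite(self.t):
            raise ValidationError(f"threshold t must be finite, got {self.t}")


class TemperatureSeries:
    """Timestamped temperature record (°C), strictly increasing in time.

    Interpolation is piecewise-constant left-hold: the reading at ``t_i``
    holds over ``[t_i, t_{i+1})``.  Outside the recorded span the nearest
    endpoint reading is held constant; integrations that rely on this emit
    :class:`ExtrapolationWarning`.
    """

    def __init__(self, times: Sequence, temps: Sequence[float]) -> None:
        t = pd.DatetimeIndex(times)
        v = np.asarray(temps, dtype=float)
        if len(t) != len(v):
            raise ValidationError("times and temperatures differ in length")
        if len(t) == 0:
            raise ValidationError("temperature series is empty")
        if len(t) > 1 and not (np.diff(t.asi8) > 0).all():
            raise ValidationError("timestamps must be strictly increasing")
        if not np.isfinite(v).all():
            raise ValidationError("temperatures must be finite")
        self._times = t
        self._temps = v

    def __len__(self) -> int:
        return len(self._times)

    @property
    def times(self) -> pd.DatetimeIndex:
        return self._times

    @property
    def temps(self) -> np.ndarray:
        return self._temps.copy()

    @property
    def start(self) -> pd.Timestamp:
        return self._times[0]

    @property
    def end(self) -> pd.Timestamp:
        return self._times[-1]

    def at(self, when) -> float:
        """Held temperature at an instant (nearest endpoint outside the span)."""
        ts = pd.Timestamp(when)
        i = int(np.searchsorted(self._times.asi8, ts.value, side="right")) - 1
        return float(self._temps[max(i, 0)])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TemperatureSeries":
        missing = {"timestamp", "temp_c"} - set(df.columns)
        if missing:
            raise ValidationError(f"temperature CSV lacks columns: {sorted(missing)}")
        return cls(pd.to_datetime(df["timestamp"]), df["temp_c"].astype(float))

    @classmethod
    def read_csv(cls, path) -> "TemperatureSeries":
        return cls.from_frame(pd.read_csv(path))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"timestamp": self._times.strftime("%Y-%m-%dT%H:%M:%S"),
             "temp_c": self._temps}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class StageTimeline:
    """Stage entry instants produced by :func:`stage_progression`.

    ``entries`` starts with (egg, start); each later pair records the instant
    the individual molted into that stage.  ``completed`` is True when the
    final stage (pupa) finished within the record, at ``completion_time``.
    """

    entries: list[tuple[Stage, pd.Timestamp]] = field(default_factory=list)
    completed: bool = False
    completion_time: pd.Timestamp | None = None

    def entry_time(self, stage: Stage) -> pd.Timestamp | None:
        for s, when in self.entries:
            if s == stage:
                return when
        return None

    @property
    def current_stage(self) -> Stage:
        return self.entries[-1][0]


def predict_duration(params: ThermalSummationParams, temperature: float) -> float:
    """Expected stage duration (hours) at a constant temperature.

    Returns ``inf`` at or below the threshold: no development, not an error.
    """
    if temperature <= params.t:
        return math.inf
    return params.k / (temperature - params.t)


def development_rate(params: ThermalSummationParams, temperature: float) -> float:
    """Development rate (fraction of the stage per hour); zero at or below t."""
    return max(temperature - params.t, 0.0) / params.k


def _interval_breakdown(
    series: TemperatureSeries, start: pd.Timestamp, end: pd.Timestamp
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Segment [start, end] at the series' reading times.

    Returns (segment durations in hours, held temperature per segment,
    whether any part of the interval lies outside the recorded span).
    """
    t = series.times.asi8
    v = series._temps
    lo, hi = start.value, end.value
    inner = t[(t > lo) & (t < hi)]
    edges = np.concatenate(([lo], inner, [hi]))
    dur_h = np.diff(edges) / NS_PER_HOUR
    # held value on each segment = reading at the segment's left edge
    idx = np.searchsorted(t, edges[:-1], side="right") - 1
    held = v[np.clip(idx, 0, len(v) - 1)]
    extrapolated = lo < t[0] or hi > t[-1]
    return dur_h, held, extrapolated


def accumulate_effective_degrees(
    series: TemperatureSeries, t_lower: float, start, end
) -> float:
    """Accumulated degree-hours Σ max(T − t_lower, 0)·Δt over [start, end].

    Piecewise-constant left-hold between readings; non-negative and additive
    over abutting intervals.  Intervals extending beyond the record hold the
    nearest endpoint reading and trigger :class:`ExtrapolationWarning`.
    """
    start, end = pd.Timestamp(start), pd.Timestamp(end)
    if not start < end:
        raise ValidationError("accumulation requires start < end")
    if len(series) < 2:
        raise ValidationError("accumulation requires at least 2 readings")
    dur_h, held, extrapolated = _interval_breakdown(series, start, end)
    if extrapolated:
        warnings.warn(
            "interval extends beyond the temperature record; "
            "nearest reading held constant",
            ExtrapolationWarning,
            stacklevel=2,
        )
    return float(np.sum(np.maximum(held - t_lower, 0.0) * dur_h))


def _ordered_params(
    stage_params: Iterable[ThermalSummationParams],
) -> list[ThermalSummationParams]:
    ordered = sorted(stage_params, key=lambda p: p.stage)
    stages = [p.stage for p in ordered]
    if len(set(stages)) != len(stages):
        raise ValidationError("duplicate stage in parameter list")
    if stages != list(Stage)[: len(stages)]:
        raise ValidationError(
            "stage parameters must form a contiguous run from egg "
            f"(got {[s.name for s in stages]})"
        )
    return ordered


def stage_progression(
    stage_params: Iterable[ThermalSummationParams],
    series: TemperatureSeries,
    start,
) -> StageTimeline:
    """Step an individual through its stages over a temperature record.

    Each stage accumulates effective degrees against its OWN threshold; it
    completes at the first instant its running total reaches its ``k``.
    Within a reading interval the temperature is constant, so completion
    instants are solved exactly — no fixed step size is involved.  The walk
    stops at the end of the record if development is unfinished.
    """
    params = _ordered_params(stage_params)
    start = pd.Timestamp(start)
    if not (series.start <= start <= series.end):
        raise ValidationError("start must lie within the temperature record")

    timeline = StageTimeline(entries=[(params[0].stage, start)])
    edges = series.times.asi8
    i_stage = 0
    remaining = params[0].k  # degree-hours still needed for the current stage
    now_ns = start.value

    seg_idx = int(np.searchsorted(edges, now_ns, side="right"))
    while i_stage < len(params):
        seg_end_ns = edges[seg_idx] if seg_idx < len(edges) else None
        if seg_end_ns is None:
            break  # record exhausted
        temp = series.at(pd.Timestamp(now_ns))
        rate = max(temp - params[i_stage].t, 0.0)  # degree-hours per hour
        seg_h = (seg_end_ns - now_ns) / NS_PER_HOUR
        if rate > 0 and rate * seg_h >= remaining:
            # stage completes within this segment
            now_ns = now_ns + int(round(remaining / rate * NS_PER_HOUR))
            when = pd.Timestamp(now_ns)
            i_stage += 1
            if i_stage < len(params):
                timeline.entries.append((params[i_stage].stage, when))
                remaining = params[i_stage].k
            else:
                timeline.completed = True
                timeline.completion_time = when
        else:
            remaining -= rate * seg_h
            now_ns = seg_end_ns
            seg_idx += 1
    return timeline


def estimate_pmi_min(
    observed_stage: Stage,
    stage_params: Iterable[ThermalSummationParams],
    series: TemperatureSeries,
    collection,
    step_h: float = 1.0,
) -> float:
    """Minimum post-mortem interval (hours) given an observed stage.

    The smallest elapsed time Δ since oviposition such that development
    starting at ``collection − Δ`` reaches ``observed_stage`` by
    ``collection``; found by binary search over Δ (reachedness is monotone
    in Δ because accumulation is non-negative), bracketed to ``step_h``.
    For a constant record this equals Σ_{s < observed} k_s / (T − t_s).

    Raises :class:`InsufficientRecordError` when the record is too short for
    the stage to be reached even starting at the first reading.
    """
    observed_stage = Stage.parse(observed_stage)
    params = _ordered_params(stage_params)
    stages = [p.stage for p in params]
    if observed_stage not in stages:
        raise ValidationError(
            f"observed stage {observed_stage.name} not covered by parameters"
        )
    collection = pd.Timestamp(collection)
    if not (series.start <= collection <= series.end):
        raise ValidationError("collection instant must lie within the record")
    if observed_stage == stages[0]:
        return 0.0  # the first stage may have just been entered

    def reached(delta_h: float) -> bool:
        t0 = collection - pd.Timedelta(hours=delta_h)
        tl = stage_progression(params, series, t0)
        when = tl.entry_time(observed_stage)
        return when is not None and when <= collection

    hi = (collection.value - series.start.value) / NS_PER_HOUR
    if hi <= 0 or not reached(hi):
        raise InsufficientRecordError(
            f"temperature record too short: {observed_stage.name} cannot be "
            f"reached within the {hi:.1f} h covered before collection"
        )
    lo = 0.0
    while hi - lo > step_h:
        mid = 0.5 * (lo + hi)
        if reached(mid):
            hi = mid
        else:
            lo = mid
    return hi
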