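"""Seventeen hydrologic descriptors of a daily paddy water-level series.

The descriptors summarize three aspects of the field water regime that
govern redox state and hence CH4/N2O production:

* **A. Flood periods** — A1 percent of monitored days flooded; A2–A4
  percent of flooded days ponded at 0–5, 5–10, and >10 cm; A5–A8 percent
  of flood events lasting one day, within a week, within a month, and
  more than a month.
* **B. Drainage periods** — B1–B3 percent of drained days with the water
  table at 0→−5, −5→−10, and below −10 cm; B4–B6 mean duration (days) of
  dry events whose deepest level falls in those bands.
* **C. Saturation transitions** — C1 number of flood events; C2 days on
  which the level drops from ≥ +5 cm to ≤ −5 cm within 24 h; C3 days with
  a drop of more than 10 cm within 24 h.

A day is *flooded* iff its level is strictly above the soil surface
(level > 0 cm); level exactly 0 counts as drained in the 0→−5 band.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from datetime import date
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .types import WaterLevelSeries

DESCRIPTOR_NAMES: tuple[str, ...] = (
    "A1", "A2", "A3", "A4", "A5", "A6", "A7", "A8",
    "B1", "B2", "B3", "B4", "B5", "B6",
    "C1", "C2", "C3",
)


class Band(enum.Enum):
    """Daily water-level band (half-open bins; 0 cm itself is drained)."""

    FLOOD_0_5 = "flood_0_5"        # (0, 5]
    FLOOD_5_10 = "flood_5_10"      # (5, 10]
    FLOOD_GT10 = "flood_gt10"      # (10, inf)
    DRAIN_0_5 = "drain_0_5"        # [-5, 0]
    DRAIN_5_10 = "drain_5_10"      # [-10, -5)
    DRAIN_LT10 = "drain_lt10"      # (-inf, -10)

    @property
    def flooded(self) -> bool:
        return self.value.startswith("flood")


class EventKind(enum.Enum):
    FLOOD = "flood"
    DRY = "dry"


class FloodDurationClass(enum.Enum):
    ONE_DAY = "one_day"            # 1 day
    WITHIN_WEEK = "within_week"    # 2-7 days
    WITHIN_MONTH = "within_month"  # 8-30 days
    OVER_MONTH = "over_month"      # >30 days


@dataclass(frozen=True)
class DayState:
    date: date
    band: Band
    level_cm: float


@dataclass(frozen=True)
class HydroEvent:
    """A maximal run of consecutive flooded (or drained) days."""

    kind: EventKind
    start_date: date
    duration_days: int
    extreme_level_cm: float  # max level for floods, min level for dry spells
    duration_class: FloodDurationClass | None = None


@dataclass(frozen=True)
class HydroDescriptors:
    """The 17 descriptors for one field-season (see module docstring)."""

    A1: float
    A2: float
    A3: float
    A4: float
    A5: float
    A6: float
    A7: float
    A8: float
    B1: float
    B2: float
    B3: float
    B4: float
    B5: float
    B6: float
    C1: int
    C2: int
    C3: int

    def as_series(self) -> pd.Series:
        return pd.Series({k: getattr(self, k) for k in DESCRIPTOR_NAMES})


def band_of(level: float) -> Band:
    """Band of a single day's level (flooded iff level > 0)."""
    if level > 10.0:
        return Band.FLOOD_GT10
    if level > 5.0:
        return Band.FLOOD_5_10
    if level > 0.0:
        return Band.FLOOD_0_5
    if level >= -5.0:
        return Band.DRAIN_0_5
    if level >= -10.0:
        return Band.DRAIN_5_10
    return Band.DRAIN_LT10


def classify_days(series: WaterLevelSeries) -> list[DayState]:
    """Assign every day of the series to exactly one level band."""
    return [
        DayState(d.date(), band_of(lv), float(lv))
        for d, lv in zip(series.dates, series.level_cm)
    ]


def _flood_class(duration: int) -> FloodDurationClass:
    if duration <= 1:
        return FloodDurationClass.ONE_DAY
    if duration <= 7:
        return FloodDurationClass.WITHIN_WEEK
    if duration <= 30:
        return FloodDurationClass.WITHIN_MONTH
    return FloodDurationClass.OVER_MONTH


def segment_events(states: Sequence[DayState]) -> list[HydroEvent]:
    """Split the day sequence into maximal flood and dry events.

    Flood and dry events alternate and together cover every day. A flood
    event's class follows its duration (1 / 2–7 / 8–30 / >30 days); a dry
    event is later banded by its deepest (minimum) level.
    """
    events: list[HydroEvent] = []
    if not states:
        return events
    run_start = 0
    flags = [s.band.flooded for s in states]
    for i in range(1, len(states) + 1):
        if i == len(states) or flags[i] != flags[run_start]:
            run = states[run_start:i]
            duration = len(run)
            if flags[run_start]:
                events.append(
                    HydroEvent(
                        kind=EventKind.FLOOD,
                        start_date=run[0].date,
                        duration_days=duration,
                        extreme_level_cm=max(s.level_cm for s in run),
                        duration_class=_flood_class(duration),
                    )
                )
            else:
                events.append(
                    HydroEvent(
                        kind=EventKind.DRY,
                        start_date=run[0].date,
                        duration_days=duration,
                        extreme_level_cm=min(s.level_cm for s in run),
                    )
                )
            run_start = i
    return events


def _pct(count: float, base: float) -> float:
    return 100.0 * count / base if base > 0 else 0.0


def compute_descriptors(series: WaterLevelSeries) -> HydroDescriptors:
    """Compute all 17 descriptors from a daily series.

    Percentage bases: A1 over all monitored days; A2–A4 over flooded days;
    A5–A8 over flood events; B1–B3 over drained days. B4–B6 are mean dry
    event durations per band (0 when the band has no event). C2/C3 scan
    consecutive-day pairs.
    """
    if len(series) < 2:
        raise ValueError("series must span at least 2 days (transitions undefined)")
    states = classify_days(series)
    events = segment_events(states)

    n_days = len(states)
    bands = [s.band for s in states]
    n_flooded = sum(b.flooded for b in bands)
    n_drained = n_days - n_flooded

    a1 = _pct(n_flooded, n_days)
    a2 = _pct(bands.count(Band.FLOOD_0_5), n_flooded)
    a3 = _pct(bands.count(Band.FLOOD_5_10), n_flooded)
    a4 = _pct(bands.count(Band.FLOOD_GT10), n_flooded)

    floods = [e for e in events if e.kind is EventKind.FLOOD]
    n_fe = len(floods)
    cls_counts = {c: sum(e.duration_class is c for e in floods) for c in FloodDurationClass}
    a5 = _pct(cls_counts[FloodDurationClass.ONE_DAY], n_fe)
    a6 = _pct(cls_counts[FloodDurationClass.WITHIN_WEEK], n_fe)
    a7 = _pct(cls_counts[FloodDurationClass.WITHIN_MONTH], n_fe)
    a8 = _pct(cls_counts[FloodDurationClass.OVER_MONTH], n_fe)

    b1 = _pct(bands.count(Band.DRAIN_0_5), n_drained)
    b2 = _pct(bands.count(Band.DRAIN_5_10), n_drained)
    b3 = _pct(bands.count(Band.DRAIN_LT10), n_drained)

    dry = [e for e in events if e.kind is EventKind.DRY]
    mean_dur = {}
    for band in (Band.DRAIN_0_5, Band.DRAIN_5_10, Band.DRAIN_LT10):
        durs = [e.duration_days for e in dry if band_of(e.extreme_level_cm) is band]
        mean_dur[band] = float(np.mean(durs)) if durs else 0.0

    lv = series.level_cm
    c2 = int(np.sum((lv[:-1] >= 5.0) & (lv[1:] <= -5.0)))
    c3 = int(np.sum((lv[:-1] - lv[1:]) > 10.0))

    return HydroDescriptors(
        A1=a1, A2=a2, A3=a3, A4=a4, A5=a5, A6=a6, A7=a7, A8=a8,
        B1=b1, B2=b2, B3=b3,
        B4=mean_dur[Band.DRAIN_0_5],
        B5=mean_dur[Band.DRAIN_5_10],
        B6=mean_dur[Band.DRAIN_LT10],
        C1=n_fe, C2=c2, C3=c3,
    )


def descriptor_table(series_list: Iterable[WaterLevelSeries]) -> pd.DataFrame:
    """Descriptor matrix (one row per field, columns A1..C3, field_id index)."""
    rows = {}
    for s in series_list:
        rows[s.field_id] = compute_descriptors(s).as_series()
    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(DESCRIPTOR_NAMES))
    df.index.name = "field_id"
    return df
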