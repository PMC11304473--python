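"""CSV readers and writers for the pipeline's tabular formats.

All files are UTF-8 comma-delimited with a header row and ISO-8601
dates. The water-level reader places every field on a complete daily
grid: interior gaps up to ``max_gap_days`` are linearly interpolated
(flagged ``observed=False``); longer gaps either reject the field or
drop it, per policy. Readings below the −15 cm tube depth are clamped
to −15 and flagged censored.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .descriptors import DESCRIPTOR_NAMES
from .types import MIN_INGEST_DAYS, TUBE_DEPTH_CM, WaterLevelSeries

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class GapPolicy:
    """How to handle missing days: interpolate short gaps, then raise/drop."""

    max_gap_days: int = 3
    on_long_gap: str = "raise"  # "raise" | "drop"

    def __post_init__(self) -> None:
        if self.max_gap_days < 0:
            raise ValueError("max_gap_days must be >= 0")
        if self.on_long_gap not in ("raise", "drop"):
            raise ValueError("on_long_gap must be 'raise' or 'drop'")


def _gap_runs(missing: np.ndarray) -> list[tuple[int, int]]:
    runs, start = [], None
    for i, m in enumerate(missing):
        if m and start is None:
            start = i
        elif not m and start is not None:
            runs.append((start, i - start))
            start = None
    if start is not None:
        runs.append((start, len(missing) - start))
    return runs


def read_water_series(
    path: str | Path, policy: GapPolicy = GapPolicy()
) -> list[WaterLevelSeries]:
    """Ingest a water_levels.csv into per-field daily series.

    Expects columns ``field_id, date, level_cm`` and optionally
    ``censored``. Duplicate field-dates and non-numeric levels are
    errors; fields spanning fewer than 30 days are dropped with a
    warning.
    """
    df = pd.read_csv(path, dtype={"field_id": str})
    required = {"field_id", "date", "level_cm"}
    if not required.issubset(df.columns):
        raise ValueError(f"water-level CSV must have columns {sorted(required)}")
    bad = pd.to_numeric(df["level_cm"], errors="coerce").isna() & df["level_cm"].notna()
    if bad.any():
        rows = (df.index[bad] + 2).tolist()  # +2: header + 1-based
        raise ValueError(f"non-numeric level_cm at file rows {rows}")
    df["level_cm"] = pd.to_numeric(df["level_cm"])
    df["date"] = pd.to_datetime(df["date"], format="ISO8601")

    out: list[WaterLevelSeries] = []
    for fid, g in df.groupby("field_id", sort=True):
        if g["date"].duplicated().any():
            raise ValueError(f"duplicate field-date rows for field {fid!r}")
        g = g.sort_values("date").set_index("date")
        full = pd.date_range(g.index.min(), g.index.max(), freq="D")
        if len(full) < MIN_INGEST_DAYS:
            warnings.warn(f"field {fid!r} spans {len(full)} days (<{MIN_INGEST_DAYS}); dropped")
            continue
        level = g["level_cm"].reindex(full)
        observed = level.notna().values
        runs = _gap_runs(~observed)
        long_gaps = [r for r in runs if r[1] > policy.max_gap_days]
        if long_gaps:
            msg = (f"field {fid!r} has a gap of {max(r[1] for r in long_gaps)} days "
                   f"(> {policy.max_gap_days})")
            if policy.on_long_gap == "raise":
                raise ValueError(msg)
            warnings.warn(msg + "; field dropped")
            continue
        filled = level.interpolate(method="linear", limit_area="inside").values
        censored = np.zeros(len(full), dtype=bool)
        if "censored" in g.columns:
            censored = (
                g["censored"].reindex(full).fillna(False).astype(bool).values
            )
        below = filled < TUBE_DEPTH_CM
        censored = censored | below
        filled = np.where(below, TUBE_DEPTH_CM, filled)
        # a censored flag on an in-range reading means 'at tube depth'
        filled = np.where(censored, TUBE_DEPTH_CM, filled)
        out.append(
            WaterLevelSeries(
                field_id=str(fid),
                dates=full,
                level_cm=filled,
                censored=censored,
                observed=observed,
            )
        )
        log.info("ingested field %s: %d days, %d gap-filled", fid, len(full),
                 int((~observed).sum()))
    return out


def write_water_series(series: Iterable[WaterLevelSeries], path: str | Path) -> None:
    frames = [s.to_frame() for s in series]
    df = pd.concat(frames, ignore_index=True)
    df["date"] = df["date"].dt.strftime("%Y-%m-%d")
    df.to_csv(path, index=False)


def read_soils(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"field_id": str})
    required = {"field_id", "clay_pct", "silt_pct", "sand_pct", "ph", "oc_pct"}
    if not required.issubset(df.columns):
        raise ValueError(f"soils CSV must have columns {sorted(required)}")
    if "bd_g_cm3" not in df.columns:
        df["bd_g_cm3"] = np.nan
    return df


def read_emissions(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"field_id": str})
    required = {"field_id", "season_year", "ch4_kg_ha", "n2o_g_ha"}
    if not required.issubset(df.columns):
        raise ValueError(f"emissions CSV must have columns {sorted(required)}")
    return df


def read_descriptors(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"field_id": str}).set_index("field_id")
    missing = [c for c in DESCRIPTOR_NAMES if c not in df.columns]
    if missing:
        raise ValueError(f"descriptors CSV missing columns {missing}")
    return df[list(DESCRIPTOR_NAMES)]


def write_descriptors(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=True)
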