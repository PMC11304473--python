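"""Shared domain containers for the rice-field GHG pipeline.

Water levels follow the field convention of a perforated monitoring tube
read daily: the soil surface is 0 cm, positive values are ponded floodwater
height, negative values are the depth of the saturated front below the
surface, and readings are censored at the −15 cm tube depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Optional, Sequence

import numpy as np
import pandas as pd

TUBE_DEPTH_CM = -15.0
#: Minimum monitoring span accepted at ingestion (descriptors on shorter
#: spans are too gap-sensitive to be comparable across fields).
MIN_INGEST_DAYS = 30

PARTICLE_DENSITY_G_CM3 = 2.65


@dataclass
class WaterLevelSeries:
    """One field's daily water-level record on a complete calendar grid.

    Parameters
    ----------
    field_id : str
        Field identifier.
    dates : pandas.DatetimeIndex
        Strictly increasing daily dates with no gaps.
    level_cm : ndarray of float
        Daily water level (cm); positive = ponded depth, negative = depth
        to saturation, floor at −15 (tube depth).
    censored : ndarray of bool
        True where the true level was below the tube depth and was
        recorded as −15.
    observed : ndarray of bool
        False where the value was gap-filled by interpolation.
    """

    field_id: str
    dates: pd.DatetimeIndex
    level_cm: np.ndarray
    censored: np.ndarray = None  # type: ignore[assignment]
    observed: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.dates = pd.DatetimeIndex(self.dates)
        self.level_cm = np.asarray(self.level_cm, dtype=float)
        n = len(self.level_cm)
        if self.censored is None:
            self.censored = np.zeros(n, dtype=bool)
        if self.observed is None:
            self.observed = np.ones(n, dtype=bool)
        self.censored = np.asarray(self.censored, dtype=bool)
        self.observed = np.asarray(self.observed, dtype=bool)
        self.validate()

    def validate(self) -> None:
        n = len(self.level_cm)
        if len(self.dates) != n or len(self.censored) != n or len(self.observed) != n:
            raise ValueError(f"field {self.field_id}: ragged series arrays")
        if n < 2:
            raise ValueError(f"field {self.field_id}: series needs >= 2 days")
        deltas = np.diff(self.dates.values).astype("timedelta64[D]").astype(int)
        if not np.all(deltas == 1):
            raise ValueError(f"field {self.field_id}: dates must be daily with no gaps")
        if np.any(~np.isfinite(self.level_cm)):
            raise ValueError(f"field {self.field_id}: non-finite water level")
        if np.any(self.level_cm < TUBE_DEPTH_CM):
            raise ValueError(f"field {self.field_id}: level below tube depth {TUBE_DEPTH_CM}")
        if np.any(self.censored & (self.level_cm != TUBE_DEPTH_CM)):
            raise ValueError(f"field {self.field_id}: censored day with level != {TUBE_DEPTH_CM}")

    def __len__(self) -> int:
        return len(self.level_cm)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "field_id": self.field_id,
                "date": self.dates,
                "level_cm": self.level_cm,
                "censored": self.censored,
                "observed": self.observed,
            }
        )


@dataclass
class FieldSoil:
    """Measured topsoil properties plus (optionally) PTF-derived hydraulics."""

    field_id: str
    clay_pct: float
    silt_pct: float
    sand_pct: float
    ph: float
    oc_pct: float
    bd_g_cm3: Optional[float] = None
    ksat_mm_h: Optional[float] = None
    wfps_fc_pct: Optional[float] = None
    wfps_wp_pct: Optional[float] = None
    porosity_frac: Optional[float] = None

    def __post_init__(self) -> None:
        total = self.clay_pct + self.silt_pct + self.sand_pct
        if abs(total - 100.0) > 0.5:
            raise ValueError(
                f"field {self.field_id}: texture sums to {total:.2f}, expected 100 +/- 0.5"
            )
        if self.bd_g_cm3 is not None and not (0.0 < self.bd_g_cm3 < PARTICLE_DENSITY_G_CM3):
            raise ValueError(f"field {self.field_id}: bulk density out of (0, 2.65)")
        if self.porosity_frac is not None and not (0.0 < self.porosity_frac < 1.0):
            raise ValueError(f"field {self.field_id}: porosity out of (0, 1)")
        if self.wfps_fc_pct is not None and self.wfps_wp_pct is not None:
            if not (0.0 <= self.wfps_wp_pct <= self.wfps_fc_pct <= 100.0):
                raise ValueError(f"field {self.field_id}: WFPS ordering violated")


@dataclass
class EmissionRecord:
    """Seasonal emissions for one field: CH4 (kg/ha), N2O (g/ha), GWP (mt CO2-eq/ha)."""

    field_id: str
    ch4_kg_ha: float
    n2o_g_ha: float
    gwp_mt_co2eq_ha: float
    season_year: int

    def __post_init__(self) -> None:
        if self.ch4_kg_ha < 0 or self.n2o_g_ha < 0:
            raise ValueError(f"field {self.field_id}: negative seasonal flux")


@dataclass(frozen=True)
class NApplication:
    """One nitrogen fertilizer application."""

    days_after_sowing: int
    kg_n_ha: float
    source: str = "urea"

    def __post_init__(self) -> None:
        if self.kg_n_ha < 0:
            raise ValueError("N dose must be >= 0")


@dataclass
class Management:
    """Standardized agronomic management for one season."""

    sowing_date: date
    harvest_date: date
    n_schedule: Sequence[NApplication] = field(
        default_factory=lambda: DEFAULT_N_SCHEDULE
    )
    residue_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.harvest_date <= self.sowing_date:
            raise ValueError("harvest must follow sowing")
        if not (0.0 <= self.residue_fraction <= 1.0):
            raise ValueError("residue_fraction must be in [0, 1]")
        self.n_schedule = tuple(self.n_schedule)

    @property
    def total_n_kg_ha(self) -> float:
        return float(sum(a.kg_n_ha for a in self.n_schedule))

    def application_dates(self) -> list[date]:
        return [self.sowing_date + timedelta(days=a.days_after_sowing) for a in self.n_schedule]

    def scaled(self, multiplier: float) -> "Management":
        """All split doses scaled proportionally, ratios unchanged."""
        if multiplier < 0:
            raise ValueError("multiplier must be >= 0")
        return Management(
            sowing_date=self.sowing_date,
            harvest_date=self.harvest_date,
            n_schedule=[
                NApplication(a.days_after_sowing, a.kg_n_ha * multiplier, a.source)
                for a in self.n_schedule
            ],
            residue_fraction=self.residue_fraction,
        )


#: Region-standard N fertilization: one basal dose of 25 kg N/ha at planting
#: and two 50 kg N/ha top dressings at 25 and 55 days after sowing
#: (totals the 125 kg N/ha baseline).
DEFAULT_N_SCHEDULE = (
    NApplication(0, 25.0, "DAP"),
    NApplication(25, 50.0, "urea"),
    NApplication(55, 50.0, "urea"),
)
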