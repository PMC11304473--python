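"""Seasonal flux aggregation and AR6 CO2-equivalent accounting.

Seasonal totals of CH4 (kg/ha) and N2O (g/ha) are converted to a
100-year global warming potential by direct mass multiplication with the
AR6 GWP100 factors (27 kg CO2-eq per kg CH4, 273 kg CO2-eq per kg N2O),
reported in metric tons CO2-eq per hectare.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from datetime import date
from typing import Mapping

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class GwpFactors:
    """GWP100 mass-conversion factors (kg CO2-eq per kg gas)."""

    ch4_factor: float = 27.0
    n2o_factor: float = 273.0
    provenance: str = "AR6"


AR6 = GwpFactors()


def seasonal_sum(daily: "pd.Series", sowing: date, harvest: date) -> float:
    """Inclusive sum of a dated daily flux series over [sowing, harvest]."""
    if harvest < sowing:
        raise ValueError("empty season window: harvest precedes sowing")
    idx = pd.DatetimeIndex(daily.index)
    lo, hi = pd.Timestamp(sowing), pd.Timestamp(harvest)
    if lo < idx.min() or hi > idx.max():
        raise ValueError("season window exceeds the flux record")
    mask = (idx >= lo) & (idx <= hi)
    return float(daily.values[mask].sum())


def gwp_co2eq(ch4_kg_ha: float, n2o_g_ha: float, factors: GwpFactors = AR6) -> float:
    """CO2-equivalent of seasonal fluxes, in mt CO2-eq per hectare."""
    if ch4_kg_ha < 0 or n2o_g_ha < 0:
        raise ValueError("fluxes must be nonnegative")
    kg_co2eq = ch4_kg_ha * factors.ch4_factor + (n2o_g_ha / 1000.0) * factors.n2o_factor
    return kg_co2eq / 1000.0


def landscape_summary(
    emissions: pd.DataFrame,
    assignments: Mapping[str, int] | pd.Series | None = None,
    factors: GwpFactors = AR6,
) -> dict:
    """Per-cluster and overall emission statistics.

    Parameters
    ----------
    emissions : DataFrame
        Columns ``field_id, ch4_kg_ha, n2o_g_ha`` (``gwp_mt_co2eq_ha``
        recomputed if absent).
    assignments : mapping field_id -> cluster label, optional
        When given, statistics are additionally reported per cluster.

    Returns
    -------
    dict with ``overall`` (and ``clusters``) blocks of mean/min/max per
    gas and GWP, plus ``ch4_share_pct``: the CH4 fraction of total
    CO2-eq across the landscape.
    """
    df = emissions.copy()
    df["gwp_mt_co2eq_ha"] = [
        gwp_co2eq(c, n, factors) for c, n in zip(df["ch4_kg_ha"], df["n2o_g_ha"])
    ]

    def _block(sub: pd.DataFrame) -> dict:
        ch4_co2 = (sub["ch4_kg_ha"] * factors.ch4_factor).sum()
        total_co2 = (sub["gwp_mt_co2eq_ha"] * 1000.0).sum()
        block = {"n_fields": int(len(sub))}
        for col in ("ch4_kg_ha", "n2o_g_ha", "gwp_mt_co2eq_ha"):
            block[col] = {
                "mean": float(sub[col].mean()),
                "min": float(sub[col].min()),
                "max": float(sub[col].max()),
            }
        block["ch4_share_pct"] = float(100.0 * ch4_co2 / total_co2) if total_co2 > 0 else np.nan
        return block

    out = {"factors": {"ch4": factors.ch4_factor, "n2o": factors.n2o_factor,
                       "provenance": factors.provenance},
           "overall": _block(df)}
    if assignments is not None:
        assignments = pd.Series(dict(assignments)) if not isinstance(assignments, pd.Series) else assignments
        df = df.set_index("field_id") if "field_id" in df.columns else df
        clusters = {}
        for label in sorted(assignments.unique()):
            ids = assignments.index[assignments == label]
            sub = df.loc[df.index.intersection(ids)]
            if sub.empty:
                warnings.warn(f"cluster {label} has no matched emissions; omitted")
                continue
            clusters[int(label)] = _block(sub)
        out["clusters"] = clusters
    return out
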