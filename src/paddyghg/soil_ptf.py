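"""Pedotransfer functions (PTFs) for model-ready soil hydraulic parameters.

From routinely measured topsoil properties (texture, organic carbon, pH,
optionally bulk density) this module derives the parameters a soil
biogeochemistry model needs:

* bulk density from organic carbon (Abdelbaki 2018: BD = 1.449·e^(−0.03·OC));
* total porosity from bulk density and a 2.65 g/cm³ particle density;
* saturated hydraulic conductivity and volumetric water content at field
  capacity (33 kPa) and wilting point (1500 kPa) from the Saxton & Rawls
  (2006) texture/organic-matter equations;
* water-filled pore space (WFPS%) as retention water content over porosity.

Measured bulk density is never overwritten: the PTF estimate is used only
where the measurement is missing, and each output carries a
``measured``/``ptf`` provenance tag.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .types import PARTICLE_DENSITY_G_CM3

#: Van Bemmelen factor converting organic carbon % to organic matter %.
OC_TO_OM = 1.724

_BD_CLAMP = (0.8, 1.8)


@dataclass(frozen=True)
class PtfResult:
    """PTF-derived hydraulic parameters for one field."""

    field_id: str
    bd_g_cm3: float
    porosity_frac: float
    ksat_mm_h: float
    wfps_fc_pct: float
    wfps_wp_pct: float
    bd_provenance: str  # "measured" | "ptf"


def porosity(bd_g_cm3: float) -> float:
    """Total porosity 1 − BD/2.65 (particle density 2.65 g/cm³)."""
    if not (0.0 < bd_g_cm3 < PARTICLE_DENSITY_G_CM3):
        raise ValueError(f"bulk density must be in (0, {PARTICLE_DENSITY_G_CM3}) g/cm3")
    return porosity_expression(bd_g_cm3)


def porosity_expression(bd_g_cm3: float) -> float:
    """The porosity equation without the domain guard (for root-finding)."""
    return 1.0 - bd_g_cm3 / PARTICLE_DENSITY_G_CM3


def bd_from_oc(
    oc_pct: float,
    clay_pct: Optional[float] = None,
    sand_pct: Optional[float] = None,
) -> float:
    """Bulk density (g/cm³) from organic carbon %, after Abdelbaki (2018).

    BD = 1.449·exp(−0.03·OC); the best-performing published form depends
    on OC only, so the texture arguments are accepted for interface
    symmetry but unused. Output clamped to (0.8, 1.8) g/cm³ with a
    warning outside that range. Strictly decreasing in OC.
    """
    if oc_pct <= 0:
        raise ValueError("organic carbon % must be positive")
    bd = 1.449 * math.exp(-0.03 * oc_pct)
    lo, hi = _BD_CLAMP
    if not (lo < bd < hi):
        warnings.warn(f"PTF bulk density {bd:.3f} g/cm3 clamped to ({lo}, {hi})")
        bd = min(max(bd, lo), hi)
    return bd


def ksat_and_retention(sand_pct: float, clay_pct: float, oc_pct: float) -> dict:
    """Saturated conductivity and retention after Saxton & Rawls (2006).

    Parameters are sand and clay in mass % and organic carbon in %
    (converted internally to organic matter via the 1.724 factor).

    Returns
    -------
    dict with ``ksat_mm_h``, ``theta_fc`` (33 kPa), ``theta_wp``
    (1500 kPa), and ``theta_s`` (texture-based saturation), all
    volumetric fractions.
    """
    if sand_pct < 0 or clay_pct < 0 or sand_pct + clay_pct > 100.0:
        raise ValueError("texture outside the simplex")
    S = sand_pct / 100.0
    C = clay_pct / 100.0
    OM = OC_TO_OM * oc_pct

    t1500t = (-0.024 * S + 0.487 * C + 0.006 * OM
              + 0.005 * S * OM - 0.013 * C * OM + 0.068 * S * C + 0.031)
    theta_wp = t1500t + (0.14 * t1500t - 0.02)

    t33t = (-0.251 * S + 0.195 * C + 0.011 * OM
            + 0.006 * S * OM - 0.027 * C * OM + 0.452 * S * C + 0.299)
    theta_fc = t33t + (1.283 * t33t ** 2 - 0.374 * t33t - 0.015)

    ts33t = (0.278 * S + 0.034 * C + 0.022 * OM
             - 0.018 * S * OM - 0.027 * C * OM - 0.584 * S * C + 0.078)
    theta_s33 = ts33t + (0.636 * ts33t - 0.107)

    theta_s = theta_fc + theta_s33 - 0.097 * S + 0.043

    if not (0.0 < theta_wp < theta_fc < theta_s):
        raise ValueError(
            f"retention ordering violated for sand={sand_pct}, clay={clay_pct}, oc={oc_pct}"
        )
    b = (math.log(1500.0) - math.log(33.0)) / (math.log(theta_fc) - math.log(theta_wp))
    lam = 1.0 / b
    ksat = 1930.0 * (theta_s - theta_fc) ** (3.0 - lam)
    return {"ksat_mm_h": ksat, "theta_fc": theta_fc, "theta_wp": theta_wp,
            "theta_s": theta_s}


def wfps(theta: float, porosity_frac: float) -> float:
    """Water-filled pore space %: 100·theta/porosity."""
    if not (0.0 < porosity_frac < 1.0):
        raise ValueError("porosity must be in (0, 1)")
    if theta <= 0:
        raise ValueError("theta must be positive")
    if theta >= porosity_frac:
        raise ValueError("theta must be below porosity")
    return 100.0 * theta / porosity_frac


def parameterize_soils(soils: pd.DataFrame) -> pd.DataFrame:
    """Derive the full PTF parameter set for a soil table.

    Input columns: ``field_id, clay_pct, silt_pct, sand_pct, ph, oc_pct``
    and optionally ``bd_g_cm3`` (NaN where unmeasured). Missing bulk
    densities are PTF-estimated; measured values are kept and tagged.
    Retention water contents that would exceed porosity (heavy soils at
    high bulk density) are capped just below it with a warning so WFPS
    stays below 100 %.
    """
    rows = []
    for rec in soils.to_dict("records"):
        bd = rec.get("bd_g_cm3")
        if bd is None or (isinstance(bd, float) and np.isnan(bd)):
            bd = bd_from_oc(rec["oc_pct"])
            provenance = "ptf"
        else:
            provenance = "measured"
        phi = porosity(bd)
        ret = ksat_and_retention(rec["sand_pct"], rec["clay_pct"], rec["oc_pct"])
        theta_fc, theta_wp = ret["theta_fc"], ret["theta_wp"]
        if theta_fc >= phi:
            warnings.warn(
                f"field {rec['field_id']}: field-capacity water content "
                f"{theta_fc:.3f} exceeds porosity {phi:.3f}; capped"
            )
            scale = 0.99 * phi / theta_fc
            theta_fc *= scale
            theta_wp *= scale
        rows.append(
            PtfResult(
                field_id=str(rec["field_id"]),
                bd_g_cm3=bd,
                porosity_frac=phi,
                ksat_mm_h=ret["ksat_mm_h"],
                wfps_fc_pct=wfps(theta_fc, phi),
                wfps_wp_pct=wfps(theta_wp, phi),
                bd_provenance=provenance,
            )
        )
    return pd.DataFrame([r.__dict__ for r in rows])
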