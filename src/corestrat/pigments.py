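"""Sedimentary photosynthetic-pigment record processing.

Pigment concentrations measured per gram of dry sediment are normalised
to organic carbon (nmol / g OC), converted to influx (deposition per
cm^2 per year), and summarised with the chlorophyll-a preservation index
CPI = Chl a / (Chl a + derivatives) — low values indicate degraded
records in which concentration trends must be read with care.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["PIGMENT_VOCABULARY", "CHL_A_DERIVATIVES", "normalize_to_oc",
           "cpi", "flux", "validate_pigment_names"]

#: Taxonomically diagnostic pigments handled by the pipeline, with their
#: first-order phytoplankton affiliation.
PIGMENT_VOCABULARY: dict[str, str] = {
    "bb_carotene": "all primary producers",
    "chlorophyll_a": "all primary producers",
    "pheophytin_a": "chlorophyll a derivative",
    "pheophorbide_a": "chlorophyll a derivative",
    "alloxanthin": "cryptophytes",
    "diatoxanthin": "diatoms",
    "diadinoxanthin": "diatoms, dinoflagellates, chrysophytes",
    "dinoxanthin": "dinoflagellates & chrysophytes",
    "peridinin": "dinoflagellates",
    "lutein": "chlorophytes",
    "echinenone": "total cyanobacteria",
    "canthaxanthin": "colonial cyanobacteria",
    "myxoxanthophyll": "cyanobacteria",
    "oscillaxanthin": "cyanobacteria (Oscillatoria)",
    "zeaxanthin": "cyanobacteria",
}

#: Chl-a degradation products entering the preservation index.
CHL_A_DERIVATIVES = ("pheophytin_a", "pheophorbide_a")

#: Pigments treated as cyanobacterial for the optional late-stage
#: cyanobacteria-dominance scenario of the synthetic generator.
CYANO_PIGMENTS = ("echinenone", "canthaxanthin", "myxoxanthophyll",
                  "oscillaxanthin", "zeaxanthin")


def validate_pigment_names(names) -> list[str]:
    """Return unknown names (empty list when all validate)."""
    return [n for n in names if n not in PIGMENT_VOCABULARY]


def normalize_to_oc(conc_per_g_dry, tc_percent):
    """Convert nmol per g dry sediment to nmol per g organic carbon.

    ``tc_percent`` is total (organic) carbon in percent of dry mass; the
    conversion divides by the carbon fraction ``tc_percent / 100``.
    """
    conc = np.asarray(conc_per_g_dry, dtype=float)
    tc = np.asarray(tc_percent, dtype=float)
    if np.any(tc <= 0) or np.any(tc > 100):
        raise ValueError("tc_percent must be in (0, 100]")
    out = conc / (tc / 100.0)
    return float(out) if out.ndim == 0 else out


def cpi(chl_a, pheophytin_a, pheophorbide_a):
    """Chlorophyll-a preservation index in [0, 1].

    CPI = Chl a / (Chl a + pheophytin a + pheophorbide a).  All-zero
    input leaves the index undefined (NaN, flagged missing).
    """
    a = np.asarray(chl_a, dtype=float)
    p1 = np.asarray(pheophytin_a, dtype=float)
    p2 = np.asarray(pheophorbide_a, dtype=float)
    if np.any(a < 0) or np.any(p1 < 0) or np.any(p2 < 0):
        raise ValueError("pigment concentrations must be >= 0")
    denom = a + p1 + p2
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom > 0, a / denom, np.nan)
    return float(out) if out.ndim == 0 else out


def flux(conc_per_g_dry, dry_bulk_density_g_cm3, sed_rate_cm_yr):
    """Pigment influx in nmol/cm^2/yr.

    concentration (nmol/g dry) x dry bulk density (g/cm^3) x
    sedimentation rate (cm/yr).
    """
    conc = np.asarray(conc_per_g_dry, dtype=float)
    rho = np.asarray(dry_bulk_density_g_cm3, dtype=float)
    s = np.asarray(sed_rate_cm_yr, dtype=float)
    if np.any(rho <= 0) or np.any(s <= 0):
        raise ValueError("density and sedimentation rate must be positive")
    out = conc * rho * s
    return float(out) if out.ndim == 0 else out


def pigment_table_to_wide(df: pd.DataFrame) -> pd.DataFrame:
    """Pivot a long pigment table (depth_cm, pigment, conc, units) to a
    depth-indexed wide matrix, validating names and unit consistency."""
    unknown = validate_pigment_names(df["pigment"].unique())
    if unknown:
        raise ValueError(f"unknown pigment names: {unknown}")
    if "units" in df and df["units"].nunique() > 1:
        raise ValueError("mixed units in pigment table")
    return df.pivot(index="depth_cm", columns="pigment", values="conc")
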