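"""Cladoceran and Chaoborus subfossil quantification.

Body-part counts from sieved wet-sediment subsamples are converted to a
minimum number of individuals (MNI), then to concentrations (individuals
per cm^3 of wet sediment) using Lycopodium clavatum marker spores to
estimate the fraction of the subsample actually screened, and finally to
influx (individuals per cm^2 per year) using the local sedimentation
rate from an age model.

The MNI follows the most-abundant-body-part rule with a multiplicity
adjustment: paired parts (carapace valves, mandibles) are divided by
their per-individual count before taking the maximum, so e.g. 18
carapace valves represent 9 individuals, not 18.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd

from .geochron import AgeModel

__all__ = ["DEFAULT_PARTS_PER_INDIVIDUAL", "mni", "volume_screened",
           "concentration_and_influx", "process_counts"]

#: Body parts per individual; user-overridable in every entry point.
DEFAULT_PARTS_PER_INDIVIDUAL: dict[str, int] = {
    "headshield": 1,
    "carapace": 2,      # valves
    "postabdomen": 1,
    "mandible": 2,      # Chaoborus
}


def mni(part_counts: dict[str, int],
        parts_per_individual: dict[str, int] | None = None) -> int:
    """Minimum number of individuals from body-part counts.

    Each part count is divided by its per-individual multiplicity and
    rounded up; the MNI is the maximum over parts (the most abundant
    body part after multiplicity adjustment).
    """
    if not part_counts:
        raise ValueError("at least one body part must be recorded")
    mult = dict(DEFAULT_PARTS_PER_INDIVIDUAL)
    if parts_per_individual:
        mult.update(parts_per_individual)
    best = 0
    for part, count in part_counts.items():
        if part not in mult:
            raise KeyError(f"unknown body part {part!r}: no multiplicity")
        if count < 0 or count != int(count):
            raise ValueError("counts must be non-negative integers")
        best = max(best, math.ceil(count / mult[part]))
    return best


def volume_screened(sample_volume_cm3: float, spores_counted: int,
                    spores_added: int) -> float:
    """Wet-sediment volume effectively examined, from the marker-spore
    proportion: volume x spores_counted / spores_added."""
    if spores_added <= 0:
        raise ValueError("spores_added must be positive")
    if spores_counted < 0:
        raise ValueError("spores_counted must be >= 0")
    if sample_volume_cm3 <= 0:
        raise ValueError("sample volume must be positive")
    if spores_counted > spores_added:
        warnings.warn("more spores counted than added; tallies implausible",
                      stacklevel=2)
    if spores_counted == 0:
        warnings.warn("zero spores counted: screened volume 0, "
                      "concentration undefined", stacklevel=2)
    return sample_volume_cm3 * spores_counted / spores_added


def concentration_and_influx(mni_count: int, vol_screened_cm3: float,
                             age_model: AgeModel, depth_cm: float
                             ) -> tuple[float, float]:
    """Concentration (ind/cm^3) and influx (ind/cm^2/yr) at one depth.

    Influx divides the concentration by the local years-per-cm, i.e.
    multiplies by the age model's sedimentation rate at the sample depth.
    """
    if vol_screened_cm3 <= 0:
        return np.nan, np.nan
    conc = mni_count / vol_screened_cm3
    sed = age_model.sed_rate_at(depth_cm)
    if not np.isfinite(sed) or sed <= 0:
        raise ValueError(f"sedimentation rate undefined at {depth_cm} cm")
    return conc, conc * sed


def process_counts(counts: pd.DataFrame, age_model: AgeModel,
                   parts_per_individual: dict[str, int] | None = None
                   ) -> pd.DataFrame:
    """Full subfossil table -> abundance series.

    ``counts`` has columns depth_cm, taxon, body_part, count,
    sample_volume_cm3, spores_counted, spores_added (spore tallies and
    volume constant within a depth).  Returns one row per (depth, taxon)
    with mni, conc_ind_cm3 and influx_ind_cm2_yr.
    """
    rows = []
    for (depth, taxon), grp in counts.groupby(["depth_cm", "taxon"],
                                              sort=True):
        parts = dict(zip(grp["body_part"], grp["count"]))
        n = mni(parts, parts_per_individual)
        vol = volume_screened(float(grp["sample_volume_cm3"].iloc[0]),
                              int(grp["spores_counted"].iloc[0]),
                              int(grp["spores_added"].iloc[0]))
        if vol > 0:
            conc, infl = concentration_and_influx(n, vol, age_model, depth)
        else:
            conc, infl = np.nan, np.nan
        rows.append({"depth_cm": depth, "taxon": taxon, "mni": n,
                     "conc_ind_cm3": conc, "influx_ind_cm2_yr": infl})
    return pd.DataFrame(rows)
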