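"""Bulk organic geochemistry: atomic C:N ratios and Suess-corrected d13C.

The atomic total-carbon to total-nitrogen ratio separates algal organic
matter (roughly 5-8) from vascular-plant input (> 20).  Sedimentary d13C
trends over the industrial era are confounded by the Suess effect — the
progressive 13C depletion of atmospheric CO2 from fossil-fuel burning —
which is removed by subtracting the change in the atmospheric reference
curve relative to a fixed reference year.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

__all__ = ["ATOMIC_MASS_C", "ATOMIC_MASS_N", "SuessCurve", "atomic_cn",
           "suess_correct", "default_suess_curve"]

ATOMIC_MASS_C = 12.011
ATOMIC_MASS_N = 14.007


def atomic_cn(tc_percent, tn_percent):
    """Atomic (molar) TC:TN ratio from weight percents:
    (TC / 12.011) / (TN / 14.007)."""
    tc = np.asarray(tc_percent, dtype=float)
    tn = np.asarray(tn_percent, dtype=float)
    if np.any(tn <= 0):
        raise ValueError("tn_percent must be positive")
    out = (tc / ATOMIC_MASS_C) / (tn / ATOMIC_MASS_N)
    return float(out) if out.ndim == 0 else out


@dataclass
class SuessCurve:
    """Atmospheric CO2 d13C reference curve, tabulated by calendar year
    and evaluated by linear interpolation."""

    year: np.ndarray
    d13c_atm: np.ndarray
    provenance: str = "user"

    def __post_init__(self) -> None:
        self.year = np.asarray(self.year, dtype=float)
        self.d13c_atm = np.asarray(self.d13c_atm, dtype=float)
        if np.any(np.diff(self.year) <= 0):
            raise ValueError("curve years must be strictly increasing")

    def __call__(self, year):
        y = np.asarray(year, dtype=float)
        if np.any(y < self.year[0]) or np.any(y > self.year[-1]):
            raise ValueError("year outside Suess-curve span "
                             f"[{self.year[0]:g}, {self.year[-1]:g}]")
        out = np.interp(y, self.year, self.d13c_atm)
        return float(out) if out.ndim == 0 else out

    @classmethod
    def from_csv(cls, path, provenance: str = "file") -> "SuessCurve":
        df = pd.read_csv(path, comment="#")
        return cls(df["year_ce"], df["d13c_atm_permil"], provenance)


def default_suess_curve() -> SuessCurve:
    """Packaged atmospheric d13C curve.

    This is a SYNTHETIC stand-in table reproducing the accepted shape of
    the industrial-era atmospheric CO2 d13C decline (~ -6.4 permil
    preindustrial falling to ~ -8.6 permil by the late 2010s); it is not
    digitized from any published compilation.  Substitute a measured
    curve via :meth:`SuessCurve.from_csv` for real-data work.
    """
    ref = resources.files("corestrat.data") / "suess_curve_synthetic.csv"
    with resources.as_file(ref) as path:
        return SuessCurve.from_csv(path, provenance="packaged synthetic")


def suess_correct(d13c_measured, year, curve: SuessCurve | None = None,
                  ref_year: float = 1900.0):
    """Remove the atmospheric Suess trend from measured d13C.

    corrected = measured - (d13c_atm(year) - d13c_atm(ref_year)).
    With a declining curve and year > ref_year the correction is
    positive (corrected > measured).
    """
    if curve is None:
        curve = default_suess_curve()
    meas = np.asarray(d13c_measured, dtype=float)
    corr = meas - (np.asarray(curve(year)) - curve(ref_year))
    return float(corr) if corr.ndim == 0 else corr
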