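"""CSV schema registry and validation for the pipeline interchange files.

All stages exchange UTF-8 CSV with a header row and dot decimals; lines
starting with ``#`` are metadata comments (the synthetic generator
records its seed there).  :func:`validate_csv` checks column presence,
numeric types, depth monotonicity and unit tags, and returns a
machine-readable report rather than raising.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["SCHEMAS", "ValidationReport", "validate_csv", "read_csv"]

#: required columns per schema; None marks the depth column whose values
#: must be strictly increasing.
SCHEMAS: dict[str, dict] = {
    "activity": {
        "columns": ["depth_top_cm", "depth_bottom_cm", "dry_mass_cum_g_cm2",
                    "total_pb210_bq_kg", "total_pb210_err"],
        "optional": ["cs137_bq_kg", "cs137_err"],
        "monotone": "depth_top_cm",
    },
    "age_model": {
        "columns": ["depth_cm", "age_ce", "age_lo", "age_hi"],
        "optional": ["sed_rate_cm_yr"],
        "monotone": "depth_cm",
    },
    "spectra": {"wide_depth_first": True},
    "pigments": {
        "columns": ["depth_cm", "pigment", "conc", "units"],
        "units": {"units": {"nmol_g_ds", "nmol_g_oc"}},
    },
    "counts": {
        "columns": ["depth_cm", "taxon", "body_part", "count",
                    "sample_volume_cm3", "spores_counted", "spores_added"],
    },
    "geochem": {
        "columns": ["depth_cm", "tc_pct", "tn_pct", "d13c_permil",
                    "d15n_permil"],
        "monotone": "depth_cm",
    },
    "suess": {
        "columns": ["year_ce", "d13c_atm_permil"],
        "monotone": "year_ce",
    },
    "matrix": {"wide_depth_first": True},
}


@dataclass
class ValidationReport:
    path: str
    schema: str
    failures: list[dict] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.failures

    def add(self, kind: str, message: str, **context) -> None:
        self.failures.append({"kind": kind, "message": message, **context})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.failures)


def read_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def validate_csv(path, schema_name: str) -> ValidationReport:
    """Validate a CSV file against a registered schema."""
    if schema_name not in SCHEMAS:
        raise KeyError(f"unknown schema {schema_name!r}")
    spec = SCHEMAS[schema_name]
    report = ValidationReport(str(path), schema_name)
    if not Path(path).exists():
        report.add("missing_file", f"no such file: {path}")
        return report
    try:
        df = read_csv(path)
    except Exception as err:   # malformed CSV
        report.add("parse_error", str(err))
        return report

    if spec.get("wide_depth_first"):
        if df.shape[1] < 2:
            report.add("columns", "wide table needs a depth column plus "
                                  "at least one value column")
            return report
        for col in df.columns[1:]:
            if schema_name == "spectra":
                try:
                    float(col)
                except ValueError:
                    report.add("column_name",
                               f"wavelength header not numeric: {col!r}",
                               column=col)
            if not np.issubdtype(df[col].dtype, np.number):
                report.add("dtype", f"non-numeric column {col!r}",
                           column=col)
        d = df.iloc[:, 0].to_numpy()
        bad = np.flatnonzero(np.diff(d) <= 0)
        if bad.size:
            report.add("monotone", "depth not strictly increasing",
                       rows=(bad + 1).tolist())
        return report

    for col in spec["columns"]:
        if col not in df.columns:
            report.add("missing_column", f"required column {col!r} absent",
                       column=col)
    if not report.ok:
        return report
    for col in spec["columns"]:
        if col in ("pigment", "taxon", "body_part", "units"):
            continue
        if not np.issubdtype(df[col].dtype, np.number):
            report.add("dtype", f"non-numeric column {col!r}", column=col)
    mono = spec.get("monotone")
    if mono and report.ok:
        d = df[mono].to_numpy()
        bad = np.flatnonzero(np.diff(d) <= 0)
        if bad.size:
            report.add("monotone", f"{mono} not strictly increasing",
                       rows=(bad + 1).tolist())
    for col, allowed in spec.get("units", {}).items():
        wrong = set(df[col].unique()) - allowed
        if wrong:
            report.add("units", f"unknown unit tag(s) {sorted(wrong)} in "
                                f"{col!r}", column=col)
    return report
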