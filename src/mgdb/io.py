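"""Schema-validated CSV readers and writers.

Dialect is fixed: UTF-8, comma separator, header row, ``.`` decimal.
Validation errors name the offending row (1-based data row) and column.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SchemaError

__all__ = [
    "COUNTRY_COLUMNS",
    "CONDITION_COLUMNS",
    "read_country_table",
    "read_condition_table",
    "write_table",
    "read_table",
]

WHO_REGIONS = ("AFR", "AMR", "EMR", "EUR", "SEAR", "WPR")
TOP_GROUPS = ("A", "B", "C", "D")
CONDITION_CLASSES = (
    "malformation", "chromosomal", "single_gene_recessive", "rh_disease", "ntd",
)

_BOOL_MAP = {
    "true": True, "false": False, "1": True, "0": False,
    "yes": True, "no": False,
}


def _as_bool(val, row, col):
    if isinstance(val, (bool, np.bool_)):
        return bool(val)
    key = str(val).strip().lower()
    if key not in _BOOL_MAP:
        raise SchemaError(f"row {row}, column {col!r}: {val!r} is not a boolean")
    return _BOOL_MAP[key]


def _as_float(val, row, col, lo=None, hi=None, allow_nan=False):
    try:
        x = float(val)
    except (TypeError, ValueError):
        raise SchemaError(f"row {row}, column {col!r}: {val!r} is not a number") from None
    if math.isnan(x):
        if allow_nan:
            return x
        raise SchemaError(f"row {row}, column {col!r}: missing value")
    if lo is not None and x < lo or hi is not None and x > hi:
        raise SchemaError(
            f"row {row}, column {col!r}: {x} outside allowed range "
            f"[{lo if lo is not None else '-inf'}, {hi if hi is not None else 'inf'}]"
        )
    return x


def _as_enum(val, row, col, allowed):
    s = str(val).strip()
    if s not in allowed:
        raise SchemaError(f"row {row}, column {col!r}: {val!r} not in {allowed}")
    return s


#: country-year indicator schema, in column order
COUNTRY_COLUMNS = (
    "iso3", "region", "year", "livebirths", "imr", "nmr", "hiv_imr", "alpha",
    "tfr", "anc4", "fortification_mandatory", "fortification_dose_ppm",
    "fortification_reach", "top_group", "universal_screening",
    "antid_standard_practice", "prospective_screening_coverage",
    "observed_top_rate_per_1000",
)

CONDITION_COLUMNS = (
    "condition_id", "condition_class", "baseline_prevalence_per_1000",
    "allele_frequency_q", "eurocat_top_uptake", "restricted_flag", "sb_frac",
    "m_nocare_u5", "m_care_u5",
    "share_cured_care", "share_mm_care", "share_severe_care",
    "share_cured_nocare", "share_mm_nocare", "share_severe_nocare",
    "folate_preventable_flag",
)


def _check_columns(df: pd.DataFrame, expected, what: str) -> None:
    missing = set(expected) - set(df.columns)
    extra = set(df.columns) - set(expected)
    if missing:
        raise SchemaError(f"{what}: missing column(s) {sorted(missing)}")
    if extra:
        raise SchemaError(f"{what}: unexpected column(s) {sorted(extra)}")


def read_country_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a country-year indicator table."""
    df = pd.read_csv(path, encoding="utf-8")
    _check_columns(df, COUNTRY_COLUMNS, f"country table {path}")
    rows = []
    for i, rec in enumerate(df.to_dict("records"), start=1):
        iso3 = str(rec["iso3"]).strip()
        if len(iso3) != 3 or not iso3.isalpha():
            raise SchemaError(f"row {i}, column 'iso3': {rec['iso3']!r} is not a 3-letter code")
        imr = _as_float(rec["imr"], i, "imr", lo=0)
        out = {
            "iso3": iso3.upper(),
            "region": _as_enum(rec["region"], i, "region", WHO_REGIONS),
            "year": int(_as_float(rec["year"], i, "year", lo=1900, hi=2200)),
            "livebirths": _as_float(rec["livebirths"], i, "livebirths", lo=0),
            "imr": imr,
            "nmr": _as_float(rec["nmr"], i, "nmr", lo=0, allow_nan=True),
            "hiv_imr": _as_float(rec["hiv_imr"], i, "hiv_imr", lo=0, hi=imr),
            "alpha": _as_float(rec["alpha"], i, "alpha", lo=0, hi=0.0625),
            "tfr": _as_float(rec["tfr"], i, "tfr", lo=1),
            "anc4": _as_float(rec["anc4"], i, "anc4", lo=0, hi=1),
            "fortification_mandatory": _as_bool(rec["fortification_mandatory"], i, "fortification_mandatory"),
            "fortification_dose_ppm": _as_float(rec["fortification_dose_ppm"], i, "fortification_dose_ppm", lo=0),
            "fortification_reach": _as_float(rec["fortification_reach"], i, "fortification_reach", lo=0, hi=1),
            "top_group": _as_enum(rec["top_group"], i, "top_group", TOP_GROUPS),
            "universal_screening": _as_bool(rec["universal_screening"], i, "universal_screening"),
            "antid_standard_practice": _as_bool(rec["antid_standard_practice"], i, "antid_standard_practice"),
            "prospective_screening_coverage": _as_float(
                rec["prospective_screening_coverage"], i, "prospective_screening_coverage", lo=0, hi=1),
            "observed_top_rate_per_1000": _as_float(
                rec["observed_top_rate_per_1000"], i, "observed_top_rate_per_1000",
                lo=0, allow_nan=True),
        }
        if out["top_group"] == "A" and math.isnan(out["observed_top_rate_per_1000"]):
            raise SchemaError(
                f"row {i}, column 'observed_top_rate_per_1000': required for top_group A"
            )
        rows.append(out)
    return pd.DataFrame(rows, columns=COUNTRY_COLUMNS)


def read_condition_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a condition-parameter table."""
    df = pd.read_csv(path, encoding="utf-8")
    _check_columns(df, CONDITION_COLUMNS, f"condition table {path}")
    rows = []
    for i, rec in enumerate(df.to_dict("records"), start=1):
        cls = _as_enum(rec["condition_class"], i, "condition_class", CONDITION_CLASSES)
        baseline = _as_float(rec["baseline_prevalence_per_1000"], i,
                             "baseline_prevalence_per_1000", lo=0, allow_nan=True)
        q = _as_float(rec["allele_frequency_q"], i, "allele_frequency_q",
                      lo=0, hi=0.5, allow_nan=True)
        if cls == "single_gene_recessive":
            if math.isnan(q) == math.isnan(baseline):
                raise SchemaError(
                    f"row {i}: recessive condition must carry exactly one of "
                    "allele_frequency_q or baseline_prevalence_per_1000"
                )
        elif math.isnan(baseline):
            raise SchemaError(f"row {i}, column 'baseline_prevalence_per_1000': missing value")
        m_nocare = _as_float(rec["m_nocare_u5"], i, "m_nocare_u5", lo=0, hi=1)
        m_care = _as_float(rec["m_care_u5"], i, "m_care_u5", lo=0, hi=m_nocare)
        out = {
            "condition_id": str(rec["condition_id"]).strip(),
            "condition_class": cls,
            "baseline_prevalence_per_1000": baseline,
            "allele_frequency_q": q,
            "eurocat_top_uptake": _as_float(rec["eurocat_top_uptake"], i, "eurocat_top_uptake", lo=0, hi=1),
            "restricted_flag": _as_bool(rec["restricted_flag"], i, "restricted_flag"),
            "sb_frac": _as_float(rec["sb_frac"], i, "sb_frac", lo=0, hi=1),
            "m_nocare_u5": m_nocare,
            "m_care_u5": m_care,
            "folate_preventable_flag": _as_bool(rec["folate_preventable_flag"], i, "folate_preventable_flag"),
        }
        for stratum in ("care", "nocare"):
            shares = [
                _as_float(rec[f"share_{part}_{stratum}"], i, f"share_{part}_{stratum}", lo=0, hi=1)
                for part in ("cured", "mm", "severe")
            ]
            if abs(sum(shares) - 1.0) > 1e-9:
                raise SchemaError(
                    f"row {i}: share_*_{stratum} must sum to 1, got {sum(shares)}"
                )
            out[f"share_cured_{stratum}"], out[f"share_mm_{stratum}"], out[f"share_severe_{stratum}"] = shares
        rows.append(out)
    return pd.DataFrame(rows, columns=CONDITION_COLUMNS)


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a table in the fixed CSV dialect, 12 significant digits."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, encoding="utf-8", float_format="%.12g")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, encoding="utf-8")
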