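"""Deterministic synthetic country and condition tables.

The generator emulates the joint structure of the real indicator data
the model consumes — it is *synthetic* throughout, not a sample of any
real country.  Indicator ranges span the regimes the model
distinguishes: IMR log-uniform on [2, 120] (covering all five access
bands and the steep 10–35 development window), consanguinity zero for
half the countries and uniform on [0.005, 0.04] for the rest (the
Eastern-Mediterranean pattern), total fertility rising with IMR,
antenatal-care coverage falling with it, and HIV-attributable infant
mortality confined to a flagged subset of high-IMR countries.

The condition table ships four synthetic profiles — one per modelled
condition class pathway (neural tube defect, chromosomal, recessive
with allele frequency, Rh disease) — with plausible natural-history
parameters of the right order of magnitude.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import InputError
from .io import CONDITION_COLUMNS, COUNTRY_COLUMNS

__all__ = ["generate_fixtures", "generate_country_table", "generate_condition_table"]


def generate_country_table(n_countries: int, seed: int) -> pd.DataFrame:
    """Deterministic synthetic country-year indicator table."""
    if n_countries < 1:
        raise InputError("n_countries must be >= 1")
    rng = np.random.default_rng(seed)
    regions = np.array(["AFR", "AMR", "EMR", "EUR", "SEAR", "WPR"])

    imr = np.exp(rng.uniform(np.log(2.0), np.log(120.0), n_countries))
    nmr = imr * rng.uniform(0.55, 0.75, n_countries)
    alpha = np.where(
        rng.random(n_countries) < 0.5,
        0.0,
        rng.uniform(0.005, 0.04, n_countries),
    )
    # TFR rises with development stage (proxied by IMR), noisy, clipped to [1.2, 7]
    tfr = np.clip(1.2 + 4.5 * (np.log(imr / 2.0) / np.log(60.0)) + rng.normal(0, 0.4, n_countries), 1.2, 7.0)
    anc4 = np.clip(1.0 - 0.8 * (np.log(imr / 2.0) / np.log(60.0)) + rng.normal(0, 0.05, n_countries), 0.02, 1.0)
    hiv_flag = (rng.random(n_countries) < 0.25) & (imr > 30)
    hiv_imr = np.where(hiv_flag, rng.uniform(0.5, 8.0, n_countries), 0.0)
    hiv_imr = np.minimum(hiv_imr, 0.3 * imr)
    top_group = rng.choice(list("ABCD"), n_countries, p=[0.25, 0.35, 0.1, 0.3])
    mandatory = rng.random(n_countries) < 0.4
    dose = np.where(mandatory, rng.uniform(0.5, 3.0, n_countries), 0.0)
    reach = np.where(mandatory, rng.uniform(0.4, 1.0, n_countries), 0.0)
    observed_top = np.where(top_group == "A", rng.uniform(0.0, 0.5, n_countries), np.nan)

    def code(i: int) -> str:
        # deterministic pronounceable-ish 3-letter codes: SAA, SAB, ...
        return "S" + chr(ord("A") + i // 26) + chr(ord("A") + i % 26)

    df = pd.DataFrame({
        "iso3": [code(i) for i in range(n_countries)],
        "region": regions[rng.integers(0, len(regions), n_countries)],
        "year": 2015,
        "livebirths": np.round(np.exp(rng.uniform(np.log(20e3), np.log(5e6), n_countries))),
        "imr": np.round(imr, 3),
        "nmr": np.round(nmr, 3),
        "hiv_imr": np.round(hiv_imr, 3),
        "alpha": np.round(alpha, 5),
        "tfr": np.round(tfr, 2),
        "anc4": np.round(anc4, 3),
        "fortification_mandatory": mandatory,
        "fortification_dose_ppm": np.round(dose, 2),
        "fortification_reach": np.round(reach, 3),
        "top_group": top_group,
        "universal_screening": rng.random(n_countries) < 0.3,
        "antid_standard_practice": anc4 > 0.6,
        "prospective_screening_coverage": np.where(rng.random(n_countries) < 0.15,
                                                   rng.uniform(0.2, 0.9, n_countries), 0.0).round(3),
        "observed_top_rate_per_1000": np.round(observed_top, 3),
    })
    return df[list(COUNTRY_COLUMNS)]


def generate_condition_table() -> pd.DataFrame:
    """Four synthetic condition profiles, one per modelled pathway."""
    rows = [
        # condition_id, class, baseline, q, eurocat, restricted, sb_frac,
        # m_nocare, m_care, shares care (cured, mm, severe), shares nocare
        ("neural_tube_defects", "ntd", 1.8, np.nan, 0.8, True, 0.15,
         0.90, 0.20, (0.10, 0.50, 0.40), (0.00, 0.10, 0.90), True),
        ("down_syndrome", "chromosomal", 1.6, np.nan, 0.6, True, 0.05,
         0.50, 0.05, (0.00, 0.70, 0.30), (0.00, 0.20, 0.80), False),
        ("severe_recessive_disorder", "single_gene_recessive", np.nan, 0.02, 0.5, False, 0.02,
         0.95, 0.15, (0.20, 0.50, 0.30), (0.00, 0.15, 0.85), False),
        ("rh_disease", "rh_disease", 0.6, np.nan, 0.0, False, 0.20,
         0.60, 0.02, (0.90, 0.08, 0.02), (0.10, 0.30, 0.60), False),
    ]
    recs = []
    for (cid, cls, base, q, eurocat, restricted, sb, m_no, m_ca,
         shares_care, shares_nocare, folate) in rows:
        recs.append({
            "condition_id": cid,
            "condition_class": cls,
            "baseline_prevalence_per_1000": base,
            "allele_frequency_q": q,
            "eurocat_top_uptake": eurocat,
            "restricted_flag": restricted,
            "sb_frac": sb,
            "m_nocare_u5": m_no,
            "m_care_u5": m_ca,
            "share_cured_care": shares_care[0],
            "share_mm_care": shares_care[1],
            "share_severe_care": shares_care[2],
            "share_cured_nocare": shares_nocare[0],
            "share_mm_nocare": shares_nocare[1],
            "share_severe_nocare": shares_nocare[2],
            "folate_preventable_flag": folate,
        })
    return pd.DataFrame(recs, columns=list(CONDITION_COLUMNS))


def generate_fixtures(n_countries: int, seed: int):
    """Return (country table, condition table); deterministic given ``seed``."""
    return generate_country_table(n_countries, seed), generate_condition_table()
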