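"""End-to-end pipeline: country indicators → access → prevention → envelope.

For each country: estimate access to optimal care from the adjusted
IMR.  For each country-condition pair, apply the intervention that
matches the condition class —

* ``ntd``              — folic-acid fortification (mandatory policies only);
* ``single_gene_recessive`` — Hardy–Weinberg baseline (when an allele
  frequency is given) and genetic risk information, with retrospective
  coverage equal to access and the country's prospective screening
  coverage;
* ``rh_disease``       — anti-D prophylaxis;
* ``malformation`` / ``chromosomal`` — no birth-prevalence prevention
  (collateral folate effects apply to orofacial clefts and congenital
  heart disease by condition id);

then prenatal diagnosis/termination under the country's TOP group, and
finally the conserved outcome envelope under binary access.

Counselling is applied without the prenatal-diagnosis variant here:
terminations of diagnosed pregnancies are accounted once, by the TOP
stage, so the envelope never counts an averted birth twice.
"""

from __future__ import annotations

import logging
import math

import pandas as pd

from .access import AccessCurve, MortalityInputs, estimate_access, fit_access_curve
from .config import ModelConfig
from .errors import InputError
from .folate import FortificationPolicy, collateral_reduction, post_fortification_prevalence
from .interventions import (
    AntiDContext,
    TopPolicy,
    TopUptakeTable,
    antid_prevented_per_1000,
    terminations_per_1000,
    top_uptake,
)
from .outcomes import NaturalHistory, aggregate, birth_outcome_envelope, under5_outcomes
from .reproductive import (
    CounsellingContext,
    RecessiveParams,
    counselling_adjusted_prevalence,
    hardy_weinberg_prevalence,
)

logger = logging.getLogger(__name__)

__all__ = ["access_table", "run_pipeline", "regional_summary"]

#: condition ids that receive the collateral folate effect
_COLLATERAL_CLASS = {"orofacial_cleft": "orofacial_cleft", "congenital_heart": "congenital_heart"}


def _country_access(row, curve: AccessCurve, config: ModelConfig):
    inputs = MortalityInputs(
        imr=row["imr"], nmr=row.get("nmr"), hiv_imr=row["hiv_imr"], alpha=row["alpha"]
    )
    return estimate_access(inputs, curve, config.consanguinity)


def access_table(countries: pd.DataFrame, config: ModelConfig | None = None,
                 curve: AccessCurve | None = None) -> pd.DataFrame:
    """Per-country access estimates (percentages rendered to 1 decimal)."""
    config = config or ModelConfig()
    curve = curve or fit_access_curve(config=config.access)
    rows = []
    for _, row in countries.iterrows():
        est = _country_access(row, curve, config)
        rows.append({
            "iso3": row["iso3"],
            "year": row["year"],
            "imr": row["imr"],
            "c_imr": est.consanguinity_imr,
            "hiv_imr": row["hiv_imr"],
            "final_adjusted_imr": est.final_adjusted_imr,
            "access_unadjusted_pct": round(100 * est.access_unadjusted, 1),
            "access_final_pct": round(100 * est.access_final, 1),
        })
    return pd.DataFrame(rows)


def _natural_history(cond) -> NaturalHistory:
    return NaturalHistory(
        m_nocare_u5=cond["m_nocare_u5"],
        m_care_u5=cond["m_care_u5"],
        sb_frac=cond["sb_frac"],
        shares_care=(cond["share_cured_care"], cond["share_mm_care"], cond["share_severe_care"]),
        shares_nocare=(cond["share_cured_nocare"], cond["share_mm_nocare"], cond["share_severe_nocare"]),
    )


def _baseline_prevalence(cond, country, config: ModelConfig) -> float:
    q = cond["allele_frequency_q"]
    if cond["condition_class"] == "single_gene_recessive" and not math.isnan(q):
        params = RecessiveParams(q=q, alpha=country["alpha"],
                                 p_affected_per_birth=config.reproductive.p_affected)
        return 1000.0 * hardy_weinberg_prevalence(params)
    return float(cond["baseline_prevalence_per_1000"])


def _prevented_prevalence(cond, country, baseline: float, access_final: float,
                          config: ModelConfig) -> float:
    """Birth prevalence after pre-pregnancy / periconceptional prevention."""
    cls = cond["condition_class"]
    policy = FortificationPolicy(
        mandatory=bool(country["fortification_mandatory"]),
        dose_ppm=float(country["fortification_dose_ppm"]),
        reach=float(country["fortification_reach"]),
    )
    if cls == "ntd" and bool(cond["folate_preventable_flag"]):
        return post_fortification_prevalence(baseline, policy, config.folate)
    if cls == "single_gene_recessive":
        ctx = CounsellingContext(
            family_size_norm=max(1.0, float(country["tfr"])),
            retro_coverage=access_final,
            pro_coverage=float(country["prospective_screening_coverage"]),
        )
        return counselling_adjusted_prevalence(baseline, ctx)
    if cls == "rh_disease":
        ctx = AntiDContext(
            access=access_final,
            anc4_coverage=float(country["anc4"]),
            standard_practice=bool(country["antid_standard_practice"]),
            efficacy=config.antid.efficacy,
        )
        return baseline - antid_prevented_per_1000(baseline, ctx)
    if cond["condition_id"] in _COLLATERAL_CLASS:
        red = collateral_reduction(_COLLATERAL_CLASS[cond["condition_id"]], policy, config.folate)
        return baseline * (1.0 - red)
    return baseline


def _terminations(cond, country, post: float, access_final: float,
                  config: ModelConfig) -> float:
    group = country["top_group"]
    observed = country["observed_top_rate_per_1000"]
    policy = TopPolicy(
        group=group,
        universal_screening=bool(country["universal_screening"]),
        observed_top_rate_per_1000=float(observed) if group == "A" else None,
    )
    if group == "A":
        return terminations_per_1000(post, 0.0, 0.0, policy)
    table = TopUptakeTable.from_config({cond["condition_id"]: cond["eurocat_top_uptake"]},
                                       config.top)
    if bool(cond["restricted_flag"]):
        table = TopUptakeTable(
            uptake=table.uptake,
            restricted_conditions=frozenset({cond["condition_id"]}),
            restricted_multiplier=config.top.restricted_multiplier,
        )
    u = top_uptake(cond["condition_id"], policy, table)
    return terminations_per_1000(post, access_final, u, policy)


def run_pipeline(countries: pd.DataFrame, conditions: pd.DataFrame,
                 config: ModelConfig | None = None,
                 curve: AccessCurve | None = None) -> pd.DataFrame:
    """Estimate the outcome envelope for every country-condition pair."""
    config = config or ModelConfig()
    curve = curve or fit_access_curve(config=config.access)
    rows = []
    for _, country in countries.iterrows():
        try:
            est = _country_access(country, curve, config)
        except InputError as exc:
            raise InputError(f"country {country['iso3']}: {exc}") from exc
        for _, cond in conditions.iterrows():
            try:
                baseline = _baseline_prevalence(cond, country, config)
                post = _prevented_prevalence(cond, country, baseline, est.access_final, config)
                tops = _terminations(cond, country, post, est.access_final, config)
                nh = _natural_history(cond)
                env = birth_outcome_envelope(post, tops, nh)
                env = under5_outcomes(env, est.access_final, nh)
            except InputError as exc:
                raise InputError(
                    f"country {country['iso3']}, condition {cond['condition_id']}: {exc}"
                ) from exc
            logger.debug("%s/%s: baseline %.3f post %.3f top %.3f",
                         country["iso3"], cond["condition_id"], baseline, post, tops)
            rows.append({
                "iso3": country["iso3"],
                "region": country["region"],
                "year": country["year"],
                "condition_id": cond["condition_id"],
                "livebirths": country["livebirths"],
                "imr": country["imr"],
                "access_unadjusted": est.access_unadjusted,
                "access_final": est.access_final,
                "baseline_per_1000": baseline,
                "affected_post_prevention": env.affected_post_prevention,
                "terminations": env.terminations,
                "stillbirths": env.stillbirths,
                "affected_livebirths": env.livebirths,
                "u5_deaths": env.u5_deaths,
                "cured": env.cured,
                "mild_moderate": env.mild_moderate,
                "severe": env.severe,
                "mean_age_at_death_years": env.mean_age_at_death_years,
            })
    return pd.DataFrame(rows)


#: per-1000 rate / fraction columns of the estimates table
RATE_COLUMNS = [
    "imr", "access_unadjusted", "access_final", "baseline_per_1000",
    "affected_post_prevention", "terminations", "stillbirths",
    "affected_livebirths", "u5_deaths", "cured", "mild_moderate", "severe",
]


def regional_summary(estimates: pd.DataFrame) -> pd.DataFrame:
    """Births-weighted regional aggregation, per condition, plus a world row."""
    parts = []
    for cid, grp in estimates.groupby("condition_id", sort=True):
        reg = aggregate(grp, by="region", weight="livebirths", rate_columns=RATE_COLUMNS)
        reg.insert(0, "condition_id", cid)
        world = aggregate(grp.assign(region="WORLD"), by="region",
                          weight="livebirths", rate_columns=RATE_COLUMNS)
        world.insert(0, "condition_id", cid)
        parts.append(pd.concat([reg, world], ignore_index=True))
    return pd.concat(parts, ignore_index=True)
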