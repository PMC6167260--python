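"""The conserved outcome envelope and regional aggregation.

Baseline birth prevalence is the envelope into which all outcomes must
fit: every affected pregnancy that is not prevented ends in termination,
stillbirth or livebirth, and every affected livebirth ends in under-5
death, survival with disability (severe or mild-to-moderate) or
effective cure.  Both identities are enforced to within 1e-9.

Access to care is binary at the individual level: a fraction ``access``
of the population experiences optimal-care natural history, the rest the
no-care natural history, with no intermediate states.  Survivor
disability shares are therefore mixed with *survivor-mass* weights from
each access stratum — each stratum keeps its own mortality and its own
disability profile — rather than with the raw population access
fraction.

All rates are per 1000 total births (terminations included in the
denominator) so the envelope stays closed under aggregation, which uses
livebirths-weighted means for rates and sums for counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import pandas as pd

from .errors import InputError

__all__ = [
    "NaturalHistory",
    "OutcomeEnvelope",
    "birth_outcome_envelope",
    "under5_outcomes",
    "mean_age_at_death",
    "aggregate",
]

_TOL = 1e-9


@dataclass(frozen=True)
class NaturalHistory:
    """Natural-history parameters of one condition.

    ``m_nocare_u5`` / ``m_care_u5``: fraction of affected livebirths dying
    before age 5 without / with optimal care.  ``shares_nocare`` /
    ``shares_care``: (cured, mild_moderate, severe) fractions over
    survivors at age 5 in each stratum.  ``sb_frac``: stillbirth fraction
    among non-terminated affected pregnancies.  ``death_age_bands``:
    (midpoint age in years, share of under-5 deaths) pairs.
    """

    m_nocare_u5: float
    m_care_u5: float
    sb_frac: float = 0.0
    shares_nocare: tuple = (0.0, 0.2, 0.8)
    shares_care: tuple = (0.5, 0.4, 0.1)
    death_age_bands: tuple = ((0.5, 1.0),)

    def __post_init__(self):
        if not 0 <= self.m_care_u5 <= self.m_nocare_u5 <= 1:
            raise InputError(
                "need 0 <= m_care_u5 <= m_nocare_u5 <= 1, got "
                f"{self.m_care_u5}, {self.m_nocare_u5}"
            )
        if not 0 <= self.sb_frac <= 1:
            raise InputError(f"sb_frac must lie in [0,1], got {self.sb_frac}")
        for name in ("shares_nocare", "shares_care"):
            tr = getattr(self, name)
            if len(tr) != 3 or abs(sum(tr) - 1.0) > _TOL or min(tr) < 0:
                raise InputError(f"{name} must be 3 non-negative fractions summing to 1")
        if self.death_age_bands:
            s = sum(w for _, w in self.death_age_bands)
            if abs(s - 1.0) > _TOL:
                raise InputError(f"death-age-band shares must sum to 1, got {s}")


@dataclass
class OutcomeEnvelope:
    """Per-1000-births allocation of one country-condition's burden."""

    affected_post_prevention: float = 0.0
    terminations: float = 0.0
    stillbirths: float = 0.0
    livebirths: float = 0.0
    u5_deaths: float = 0.0
    cured: float = 0.0
    mild_moderate: float = 0.0
    severe: float = 0.0
    mean_age_at_death_years: float | None = None

    def check(self) -> None:
        """Raise if either conservation identity is violated."""
        vals = [getattr(self, f.name) for f in fields(self)
                if f.name != "mean_age_at_death_years"]
        if min(vals) < -_TOL:
            raise InputError(f"negative envelope field: {self}")
        birth = self.terminations + self.stillbirths + self.livebirths
        if abs(birth - self.affected_post_prevention) > _TOL:
            raise InputError(
                f"birth-outcome identity violated: {birth} != {self.affected_post_prevention}"
            )
        u5 = self.u5_deaths + self.cured + self.mild_moderate + self.severe
        if abs(u5 - self.livebirths) > _TOL:
            raise InputError(f"under-5 identity violated: {u5} != {self.livebirths}")


def birth_outcome_envelope(
    post_prevention_prevalence: float, terminations: float, nh: NaturalHistory
) -> OutcomeEnvelope:
    """Split non-terminated affected pregnancies into stillbirths and livebirths."""
    if terminations > post_prevention_prevalence + _TOL:
        raise InputError(
            f"terminations ({terminations}) exceed prevalence ({post_prevention_prevalence})"
        )
    if post_prevention_prevalence < 0 or terminations < 0:
        raise InputError("rates must be >= 0")
    continuing = post_prevention_prevalence - terminations
    return OutcomeEnvelope(
        affected_post_prevention=post_prevention_prevalence,
        terminations=terminations,
        stillbirths=continuing * nh.sb_frac,
        livebirths=continuing * (1.0 - nh.sb_frac),
    )


def under5_outcomes(env: OutcomeEnvelope, access: float, nh: NaturalHistory) -> OutcomeEnvelope:
    """Allocate affected livebirths to under-5 death, disability or cure.

    Mortality mixes the care/no-care rates by the access fraction;
    survivor shares mix the two strata by their survivor masses, so e.g.
    at access 1 the profile is exactly ``shares_care``.
    """
    if not 0 <= access <= 1:
        raise InputError(f"access must lie in [0,1], got {access}")
    L = env.livebirths
    surv_care = L * access * (1.0 - nh.m_care_u5)
    surv_nocare = L * (1.0 - access) * (1.0 - nh.m_nocare_u5)
    env.u5_deaths = L - surv_care - surv_nocare
    cured_c, mm_c, sev_c = nh.shares_care
    cured_n, mm_n, sev_n = nh.shares_nocare
    env.cured = surv_care * cured_c + surv_nocare * cured_n
    env.mild_moderate = surv_care * mm_c + surv_nocare * mm_n
    env.severe = surv_care * sev_c + surv_nocare * sev_n
    env.mean_age_at_death_years = mean_age_at_death(env.u5_deaths, nh.death_age_bands)
    env.check()
    return env


def mean_age_at_death(u5_deaths: float, bands) -> float | None:
    """Share-weighted mean of death-age-band midpoints; None when no deaths."""
    if u5_deaths <= 0:
        return None
    if not bands:
        raise InputError("non-zero deaths with no death-age bands")
    total = sum(w for _, w in bands)
    if abs(total - 1.0) > _TOL:
        raise InputError(f"band shares must sum to 1, got {total}")
    return sum(age * w for age, w in bands)


#: columns summed during aggregation (absolute counts)
COUNT_COLUMNS = ("livebirths",)


def aggregate(
    table: pd.DataFrame,
    by: str = "region",
    weight: str = "livebirths",
    rate_columns: list | None = None,
) -> pd.DataFrame:
    """Births-weighted aggregation of country rows to regions (or the world).

    Every per-1000 rate or access fraction becomes the ``weight``-weighted
    mean of country values; the weight column itself is summed.
    """
    if (table[weight] < 0).any():
        raise InputError(f"weights in {weight!r} must be >= 0")
    if rate_columns is None:
        rate_columns = [
            c for c in table.columns
            if c not in (by, weight) and pd.api.types.is_numeric_dtype(table[c])
        ]

    def _agg(group: pd.DataFrame) -> pd.Series:
        w = group[weight].to_numpy(dtype=float)
        if w.sum() <= 0:
            raise InputError(f"zero total weight in group {group.name!r}")
        out = {weight: w.sum()}
        for c in rate_columns:
            out[c] = float((group[c].to_numpy(dtype=float) * w).sum() / w.sum())
        return pd.Series(out)

    return table.groupby(by, sort=True).apply(_agg, include_groups=False).reset_index()
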