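"""Folic-acid flour fortification and neural tube defects.

Adequate maternal folate intake prevents a large share — but not all —
of neural tube defects (NTDs: anencephaly, spina bifida,
encephalocoele).  Post-fortification surveillance puts the residual
spina bifida + anencephaly rate at about 0.7 per 1000 births; adding an
11.5% encephalocoele share gives a non-folate-preventable total NTD
floor of 0.77 per 1000, taken to apply to all populations.

For countries with mandatory fortification but no observational data,
the preventable excess above the floor is reduced according to the
fortification dose and the population reach of fortified flour.  The
dose–response is a single exponential ``RR(d) = exp(-k_dose * d)``
(residual fraction of preventable cases at full reach), calibrated so
that a 2 ppm dose brings total NTD prevalence below 1 per 1000
regardless of the pre-fortification baseline; a tabulated dose–response
can be supplied in config to override the exponential.  Voluntary
fortification and supplementation are assumed to have no effect.

Fortification is also given a small collateral proportional reduction
of orofacial clefts and congenital heart disease.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import FolateConfig
from .errors import InputError

__all__ = [
    "FortificationPolicy",
    "residual_ratio",
    "post_fortification_prevalence",
    "split_ntd_subtypes",
    "collateral_reduction",
]

NTD_SUBTYPES = ("anencephaly", "spina_bifida", "encephalocoele")


@dataclass(frozen=True)
class FortificationPolicy:
    """A country's folic-acid fortification policy.

    ``dose_ppm`` is mg folic acid per kg flour; ``reach`` the fraction of
    the population consuming fortified flour.
    """

    mandatory: bool = False
    dose_ppm: float = 0.0
    reach: float = 1.0
    voluntary_or_supplementation_only: bool = False

    def __post_init__(self):
        if self.dose_ppm < 0:
            raise InputError(f"dose_ppm must be >= 0, got {self.dose_ppm}")
        if not 0 <= self.reach <= 1:
            raise InputError(f"reach must lie in [0,1], got {self.reach}")

    @property
    def effective(self) -> bool:
        return self.mandatory and not self.voluntary_or_supplementation_only


def residual_ratio(dose_ppm: float, constants: FolateConfig | None = None) -> float:
    """Fraction of folate-preventable NTD cases remaining at full reach."""
    c = constants or FolateConfig()
    if dose_ppm < 0:
        raise InputError("dose must be >= 0")
    if c.dose_response_table:
        tab = sorted((float(d), float(r)) for d, r in c.dose_response_table)
        doses, ratios = zip(*tab)
        return float(np.interp(dose_ppm, doses, ratios))
    return float(np.exp(-c.k_dose * dose_ppm))


def post_fortification_prevalence(
    baseline_per_1000: float,
    policy: FortificationPolicy,
    constants: FolateConfig | None = None,
    observed_post_per_1000: float | None = None,
) -> float:
    """Total NTD birth prevalence after fortification, per 1000 births.

    Observed post-fortification prevalence, when available, bypasses the
    model entirely.  Otherwise only the excess above the non-preventable
    floor is reduced, scaled by reach; the result never drops below the
    floor nor rises above the baseline.
    """
    c = constants or FolateConfig()
    if baseline_per_1000 < 0:
        raise InputError("baseline must be >= 0")
    if observed_post_per_1000 is not None:
        return observed_post_per_1000
    if not policy.effective:
        return baseline_per_1000
    if baseline_per_1000 <= c.total_floor:
        return baseline_per_1000
    rr = residual_ratio(policy.dose_ppm, c)
    post = baseline_per_1000 - policy.reach * (baseline_per_1000 - c.total_floor) * (1.0 - rr)
    return min(max(post, c.total_floor), baseline_per_1000)


def split_ntd_subtypes(total_per_1000: float, baseline_shares: dict) -> dict:
    """Allocate a total NTD rate to subtypes in proportion to baseline shares.

    Fortification is assumed to act equally on all NTD subtypes, so the
    pre-fortification shares carry over unchanged.
    """
    if set(baseline_shares) != set(NTD_SUBTYPES):
        raise InputError(f"shares must cover exactly {NTD_SUBTYPES}")
    s = sum(baseline_shares.values())
    if abs(s - 1.0) > 1e-9:
        raise InputError(f"subtype shares must sum to 1, got {s}")
    return {k: total_per_1000 * v for k, v in baseline_shares.items()}


def collateral_reduction(
    condition_class: str,
    policy: FortificationPolicy,
    constants: FolateConfig | None = None,
) -> float:
    """Proportional reduction of orofacial clefts / congenital heart disease.

    Zero unless fortification is mandatory; otherwise scales the
    class-specific maximal effect by reach and the dose response.
    """
    c = constants or FolateConfig()
    effects = {
        "orofacial_cleft": c.ofc_max_effect,
        "congenital_heart": c.chd_max_effect,
    }
    if condition_class not in effects:
        raise InputError(f"unknown condition class {condition_class!r}")
    if not policy.effective:
        return 0.0
    return policy.reach * effects[condition_class] * (1.0 - residual_ratio(policy.dose_ppm, c))
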