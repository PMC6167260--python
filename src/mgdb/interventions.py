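"""Anti-D prophylaxis and termination of pregnancy (TOP) assumptions.

Anti-D immunoglobulin given to Rh-negative mothers prevents rhesus
iso-immunisation of subsequent pregnancies.  Its coverage is assumed to
be at least the estimated access to optimal care; where anti-D is
standard obstetric practice, coverage rises to the reach of maternity
services, proxied by four-antenatal-visit (ANC4) coverage.

TOP for fetal impairment depends on prenatal-diagnosis availability and
legal status, encoded in four country groups:

* **A** — legal, high-quality registry data: observed TOP rates are used
  as reported (capped at the affected prevalence).
* **B** — legal, no data: prenatal-diagnosis access follows the
  optimal-care model and uptake among diagnosed pregnancies equals the
  EUROCAT registry average — halved for Down syndrome and spina bifida
  unless the country runs an explicit universal screening policy
  (restricted screening policies reach fewer of these pregnancies).
* **C** — legal status unclear but widespread availability documented:
  treated as group B.
* **D** — illegal / no evidence: no pregnancies are terminated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .config import AntiDConfig, TopConfig
from .errors import InputError, ObservedDataRequired

logger = logging.getLogger(__name__)

__all__ = [
    "TopPolicy",
    "TopUptakeTable",
    "AntiDContext",
    "top_uptake",
    "terminations_per_1000",
    "antid_coverage",
    "antid_prevented_per_1000",
]

TOP_GROUPS = ("A", "B", "C", "D")


@dataclass(frozen=True)
class TopPolicy:
    group: str
    universal_screening: bool = False
    observed_top_rate_per_1000: float | None = None

    def __post_init__(self):
        if self.group not in TOP_GROUPS:
            raise InputError(f"top group must be one of {TOP_GROUPS}, got {self.group!r}")
        if (self.observed_top_rate_per_1000 is not None) != (self.group == "A"):
            raise InputError("observed TOP rate must be present iff group is A")


@dataclass(frozen=True)
class TopUptakeTable:
    """EUROCAT-average TOP uptake per condition, with the 50% restriction."""

    uptake: dict
    restricted_conditions: frozenset = frozenset({"down_syndrome", "spina_bifida"})
    restricted_multiplier: float = 0.5

    def __post_init__(self):
        for cond, u in self.uptake.items():
            if not 0 <= u <= 1:
                raise InputError(f"uptake for {cond!r} must lie in [0,1], got {u}")
        if not 0 <= self.restricted_multiplier <= 1:
            raise InputError("restricted_multiplier must lie in [0,1]")

    @classmethod
    def from_config(cls, uptake: dict, cfg: TopConfig) -> "TopUptakeTable":
        return cls(
            uptake=uptake,
            restricted_conditions=frozenset(cfg.restricted_conditions),
            restricted_multiplier=cfg.restricted_multiplier,
        )


def top_uptake(condition_id: str, policy: TopPolicy, table: TopUptakeTable) -> float:
    """Fraction of prenatally diagnosed pregnancies terminated.

    Group D countries terminate none.  Groups B and C use the EUROCAT
    average, halved for restricted conditions (Down syndrome, spina
    bifida) without a universal screening policy.  Group A countries use
    observed rates directly — requesting a modelled uptake for them
    raises :class:`ObservedDataRequired`.
    """
    if condition_id not in table.uptake:
        raise InputError(f"unknown condition {condition_id!r} in uptake table")
    if policy.group == "A":
        raise ObservedDataRequired("group A uses observed TOP rates, not modelled uptake")
    if policy.group == "D":
        return 0.0
    u = table.uptake[condition_id]
    if condition_id in table.restricted_conditions and not policy.universal_screening:
        u *= table.restricted_multiplier
    return u


def terminations_per_1000(
    affected_prevalence_per_1000: float,
    pnd_access: float,
    uptake: float,
    policy: TopPolicy,
) -> float:
    """Terminated affected pregnancies per 1000 total births.

    Groups B–D: prevalence × prenatal-diagnosis access × uptake.  Group A
    passes the observed rate through, capped at the prevalence.
    """
    if affected_prevalence_per_1000 < 0:
        raise InputError("prevalence must be >= 0")
    if not 0 <= pnd_access <= 1 or not 0 <= uptake <= 1:
        raise InputError("pnd_access and uptake must lie in [0,1]")
    if policy.group == "A":
        if policy.observed_top_rate_per_1000 is None:  # pragma: no cover
            raise InputError("group A requires an observed TOP rate")
        obs = policy.observed_top_rate_per_1000
        if obs > affected_prevalence_per_1000:
            logger.warning(
                "observed TOP rate %.3f exceeds affected prevalence %.3f; capping",
                obs, affected_prevalence_per_1000,
            )
        return min(obs, affected_prevalence_per_1000)
    return affected_prevalence_per_1000 * pnd_access * uptake


@dataclass(frozen=True)
class AntiDContext:
    access: float
    anc4_coverage: float = 0.0
    standard_practice: bool = False
    efficacy: float = 1.0

    def __post_init__(self):
        for name in ("access", "anc4_coverage", "efficacy"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise InputError(f"{name} must lie in [0,1], got {v}")


def antid_coverage(ctx: AntiDContext) -> float:
    """Anti-D coverage: at least access, up to ANC4 reach where standard practice."""
    if ctx.standard_practice:
        return max(ctx.access, ctx.anc4_coverage)
    return ctx.access


def antid_prevented_per_1000(
    baseline_rh_per_1000: float, ctx: AntiDContext, cfg: AntiDConfig | None = None
) -> float:
    """Rh-disease births converted to unaffected, per 1000 births."""
    if baseline_rh_per_1000 < 0:
        raise InputError("baseline must be >= 0")
    efficacy = ctx.efficacy if cfg is None else cfg.efficacy
    return baseline_rh_per_1000 * antid_coverage(ctx) * efficacy
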