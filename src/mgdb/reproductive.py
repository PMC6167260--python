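"""Recessive-disorder prevalence and genetic risk information.

Baseline affected birth prevalence for an autosomal recessive disorder
comes from the Hardy–Weinberg equation, augmented for consanguinity:
``q^2 + alpha * q * (1 - q)`` for allele frequency q and population mean
inbreeding coefficient alpha.

Risk information changes reproductive behaviour of at-risk couples
(both parents carriers; each birth affected with probability 1/4):

* *retrospective* information reaches a couple only through the
  diagnosis of their first affected child.  The maximal-effect rule is
  that counselled couples stop reproducing at that first affected
  birth; against a family-size norm of N births, the expected affected
  births fall from N/4 to 1 - 0.75**N.  With prenatal diagnosis (PND)
  the couple instead continues to the full family size, terminating and
  replacing each subsequent affected pregnancy with probability u (the
  PND/termination uptake).
* *prospective* information (carrier screening before any affected
  birth) lets couples stop once they have two healthy children,
  reducing expected affected births to the negative-binomial mean 2/3;
  there is no effect when the family norm is below 8/3.  With PND every
  affected pregnancy is diagnosable, so the fall equals the uptake u.

Both falls are evaluated directly at real-valued N (the family-size
norm is a population mean, typically the total fertility rate).
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import InputError

__all__ = [
    "RecessiveParams",
    "CounsellingContext",
    "hardy_weinberg_prevalence",
    "retrospective_fall",
    "prospective_fall",
    "counselling_adjusted_prevalence",
]


@dataclass(frozen=True)
class RecessiveParams:
    """Allele frequency and consanguinity for one recessive disorder."""

    q: float
    alpha: float = 0.0
    p_affected_per_birth: float = 0.25

    def __post_init__(self):
        if not 0 <= self.q <= 0.5:
            raise InputError(f"q must lie in [0, 0.5], got {self.q}")
        if not 0 <= self.alpha <= 0.0625:
            raise InputError(f"alpha must lie in [0, 0.0625], got {self.alpha}")
        if not 0 < self.p_affected_per_birth < 1:
            raise InputError("p_affected_per_birth must lie in (0,1)")


@dataclass(frozen=True)
class CounsellingContext:
    """Family-size norm, service coverage and prenatal-diagnosis uptake.

    ``retro_coverage`` (r) — fraction of affected children diagnosed with
    parents counselled, by default the estimated access to services.
    ``pro_coverage`` (p) — fraction of at-risk couples identified before
    any affected birth; zero without a screening programme.
    ``pnd_uptake`` (u) — fraction of diagnosed at-risk pregnancies
    terminated (and replaced).
    """

    family_size_norm: float
    pnd_available: bool = False
    pnd_uptake: float = 0.0
    retro_coverage: float = 0.0
    pro_coverage: float = 0.0

    def __post_init__(self):
        if self.family_size_norm < 1:
            raise InputError("family_size_norm must be >= 1")
        for name in ("pnd_uptake", "retro_coverage", "pro_coverage"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise InputError(f"{name} must lie in [0,1], got {v}")


def hardy_weinberg_prevalence(params: RecessiveParams) -> float:
    """Affected births per birth: q² plus the consanguinity excess αq(1−q)."""
    q = params.q
    return q * q + params.alpha * q * (1.0 - q)


def retrospective_fall(ctx: CounsellingContext) -> float:
    """Proportional fall in affected births among retrospectively counselled couples."""
    n = ctx.family_size_norm
    baseline = n / 4.0
    unavoidable = 1.0 - 0.75 ** n  # expected affected births up to & incl. the first
    if ctx.pnd_available:
        # continue to full family size; post-detection affected pregnancies
        # terminated and replaced with probability u
        return ctx.pnd_uptake * (baseline - unavoidable) / baseline
    return max(0.0, 1.0 - unavoidable / baseline)


def prospective_fall(ctx: CounsellingContext) -> float:
    """Proportional fall when at-risk couples are identified before any affected birth."""
    if ctx.pnd_available:
        return ctx.pnd_uptake
    n = ctx.family_size_norm
    # stop at two healthy children: expected affected births = 2 * (1/4)/(3/4)
    return max(0.0, 1.0 - (2.0 / 3.0) / (n / 4.0))


def counselling_adjusted_prevalence(
    baseline_per_1000: float, ctx: CounsellingContext
) -> float:
    """Birth prevalence after risk information, per 1000 births.

    Couples identified prospectively (coverage p) realise the prospective
    fall; of the rest, the fraction r whose first affected child is
    diagnosed realise the retrospective fall.
    """
    if baseline_per_1000 < 0:
        raise InputError("baseline must be >= 0")
    p, r = ctx.pro_coverage, ctx.retro_coverage
    f_pro = prospective_fall(ctx)
    f_retro = retrospective_fall(ctx)
    factor = p * (1.0 - f_pro) + (1.0 - p) * (1.0 - r * f_retro)
    return baseline_per_1000 * factor
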