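"""Access to optimal care estimated from infant mortality.

Population access to "optimal care" — the standard of diagnosis and
treatment available in equitable high-income settings — is rarely
observed directly.  The model uses the infant mortality rate (IMR,
deaths per 1000 livebirths before age 1) as a proxy: a stepped
expert-derived mapping (the CHERG mortality groups) assigns 100%, 50%,
15%, 5% or 0% access to five IMR bands, and a smooth monotone curve
based on the Beta family of distributions is calibrated to the steps to
remove the discontinuities at band boundaries.

Two adjustments remove components of infant mortality that would
otherwise bias the proxy:

* consanguinity-associated infant deaths (cIMR), which inflate the IMR
  of high-consanguinity populations without reflecting worse services —
  removed by a short fixed-point iteration because cIMR itself depends
  on the access estimate;
* HIV/AIDS-attributable infant deaths (hivIMR), subtracted directly.

Access is a fraction in [0, 1] throughout; output tables render it as a
percentage with one decimal.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.special import betainc

from .config import AccessConfig, ConsanguinityConfig
from .errors import CalibrationError, InputError

logger = logging.getLogger(__name__)

__all__ = [
    "MortalityInputs",
    "SteppedAccessTable",
    "AccessCurve",
    "AccessEstimate",
    "DEFAULT_STEPPED_TABLE",
    "stepped_access",
    "fit_access_curve",
    "consanguinity_imr",
    "adjust_imr_consanguinity",
    "final_adjusted_imr",
    "estimate_access",
]

#: First-cousin-offspring inbreeding coefficient, the reference point for
#: consanguinity-associated excess mortality.
F_REF = 0.0625


@dataclass(frozen=True)
class MortalityInputs:
    """One population's mortality indicators (all rates per 1000 livebirths).

    ``nmr`` is accepted for provenance but unused: IMR is the chosen proxy
    because country series and projections are available for far longer
    periods.  ``alpha`` is the population mean coefficient of consanguinity.
    """

    imr: float
    nmr: float | None = None
    hiv_imr: float = 0.0
    alpha: float = 0.0

    def __post_init__(self):
        if not math.isfinite(self.imr) or self.imr < 0:
            raise InputError(f"imr must be finite and >= 0, got {self.imr}")
        if self.hiv_imr < 0 or self.hiv_imr > self.imr:
            raise InputError(
                f"hiv_imr must lie in [0, imr]: hiv_imr={self.hiv_imr}, imr={self.imr}"
            )
        if not 0 <= self.alpha <= F_REF:
            raise InputError(f"alpha must lie in [0, {F_REF}], got {self.alpha}")


@dataclass(frozen=True)
class SteppedAccessTable:
    """Ordered half-open IMR bands, each mapped to an access fraction.

    ``bands`` is a list of (imr_low, imr_high, access); bands must
    partition [0, inf) and access must be non-increasing, starting at 1
    and ending at 0.
    """

    bands: tuple

    def __post_init__(self):
        b = self.bands
        if not b:
            raise InputError("stepped table needs at least one band")
        if b[0][0] != 0 or not math.isinf(b[-1][1]):
            raise InputError("bands must start at 0 and end at infinity")
        for (lo, hi, acc), (lo2, _, acc2) in zip(b, b[1:]):
            if hi != lo2:
                raise InputError(f"gap/overlap between bands at {hi} vs {lo2}")
            if acc2 > acc:
                raise InputError("access must be non-increasing across bands")
        if b[0][2] != 1.0 or b[-1][2] != 0.0:
            raise InputError("first band access must be 1.0 and last 0.0")

    def lookup(self, imr: float) -> float:
        if not math.isfinite(imr) or imr < 0:
            raise InputError(f"imr must be finite and >= 0, got {imr}")
        for lo, hi, acc in self.bands:
            if lo <= imr < hi:
                return acc
        raise AssertionError("bands do not cover input")  # pragma: no cover


#: The five CHERG mortality groups translated to IMR bands.  Printed
#: integer ranges (≤9, 10–24, 25–54, 55–99, 100+) become half-open real
#: intervals so any non-negative IMR falls in exactly one band.
DEFAULT_STEPPED_TABLE = SteppedAccessTable(
    bands=(
        (0.0, 10.0, 1.00),
        (10.0, 25.0, 0.50),
        (25.0, 55.0, 0.15),
        (55.0, 100.0, 0.05),
        (100.0, math.inf, 0.00),
    )
)


def stepped_access(imr: float, table: SteppedAccessTable = DEFAULT_STEPPED_TABLE) -> float:
    """Access fraction of the stepped band containing ``imr``."""
    return table.lookup(imr)


@dataclass(frozen=True)
class AccessCurve:
    """Smooth monotone IMR→access curve.

    access(m) = 1 for m ≤ m_lo, 0 for m ≥ m_hi, and otherwise
    1 − I((m − m_lo)/(m_hi − m_lo); a, b) with I the regularized
    incomplete beta function.
    """

    m_lo: float
    m_hi: float
    shape_a: float
    shape_b: float
    anchors: tuple = ()

    def __post_init__(self):
        if not self.m_lo < self.m_hi:
            raise InputError("m_lo must be < m_hi")
        if self.shape_a <= 0 or self.shape_b <= 0:
            raise InputError("shape parameters must be positive")

    def __call__(self, imr):
        imr = np.asarray(imr, dtype=float)
        if np.any(~np.isfinite(imr)) or np.any(imr < 0):
            raise InputError("imr must be finite and >= 0")
        x = np.clip((imr - self.m_lo) / (self.m_hi - self.m_lo), 0.0, 1.0)
        out = 1.0 - betainc(self.shape_a, self.shape_b, x)
        return float(out) if out.ndim == 0 else out


def fit_access_curve(
    table: SteppedAccessTable = DEFAULT_STEPPED_TABLE,
    config: AccessConfig | None = None,
) -> AccessCurve:
    """Calibrate the smooth curve to the interior band midpoints.

    The two shape parameters are chosen by least squares over the anchor
    points (band midpoints of the stepped table).  Raises
    :class:`CalibrationError` if any anchor misses by more than the
    configured tolerance.
    """
    cfg = config or AccessConfig()
    anchors = np.asarray(cfg.anchors, dtype=float)

    def residuals(log_ab):
        a, b = np.exp(log_ab)
        x = np.clip((anchors[:, 0] - cfg.m_lo) / (cfg.m_hi - cfg.m_lo), 0, 1)
        return 1.0 - betainc(a, b, x) - anchors[:, 1]

    sol = optimize.least_squares(residuals, x0=[0.0, 0.0])
    a, b = np.exp(sol.x)
    curve = AccessCurve(
        m_lo=cfg.m_lo, m_hi=cfg.m_hi, shape_a=a, shape_b=b,
        anchors=tuple(map(tuple, anchors)),
    )
    errs = np.abs(curve(anchors[:, 0]) - anchors[:, 1])
    if np.any(errs > cfg.anchor_tol):
        raise CalibrationError(
            "access curve missed anchors: "
            + ", ".join(
                f"IMR {m:g}: fitted {curve(m):.4f} vs target {t:g} (|err| {e:.4f})"
                for (m, t), e in zip(anchors, errs)
            )
        )
    return curve


def consanguinity_imr(
    alpha: float, access: float, model: ConsanguinityConfig | None = None
) -> float:
    """Consanguinity-associated infant mortality (per 1000 livebirths).

    Linear in ``alpha``: scaled from the excess mortality ``e_nocare`` at
    the first-cousin reference coefficient, with the care-avertable share
    ``rho`` removed in proportion to access.
    """
    m = model or ConsanguinityConfig()
    if not 0 <= access <= 1:
        raise InputError(f"access must lie in [0,1], got {access}")
    if not 0 <= alpha <= m.f_ref:
        raise InputError(f"alpha must lie in [0, {m.f_ref}], got {alpha}")
    return (alpha / m.f_ref) * m.e_nocare * (1.0 - m.rho * access)


@dataclass
class AccessEstimate:
    """Result of the adjusted access estimation for one population."""

    access_unadjusted: float
    consanguinity_imr: float
    adjusted_imr: float
    final_adjusted_imr: float
    access_final: float
    #: (cIMR, adjusted IMR, access) after each iteration
    iteration_trace: list = field(default_factory=list)
    floor_clamped: bool = False


def adjust_imr_consanguinity(
    inputs: MortalityInputs,
    curve: AccessCurve,
    model: ConsanguinityConfig | None = None,
) -> AccessEstimate:
    """Remove consanguinity-associated deaths from the IMR.

    cIMR depends on access, which depends on the adjusted IMR, so the
    first subtraction (computed at unadjusted access) over-estimates
    cIMR and over-reduces the IMR.  A short fixed-point iteration —
    two rounds by default, after which further rounds change little —
    corrects this: each round recomputes cIMR at the latest access
    estimate and re-subtracts from the *original* IMR.
    """
    m = model or ConsanguinityConfig()
    if m.n_iter < 1:
        raise InputError("n_iter must be >= 1")
    a = curve(inputs.imr)
    est = AccessEstimate(
        access_unadjusted=a,
        consanguinity_imr=0.0,
        adjusted_imr=inputs.imr,
        final_adjusted_imr=inputs.imr,
        access_final=a,
    )
    for _ in range(m.n_iter):
        c = consanguinity_imr(inputs.alpha, a, m)
        adj = inputs.imr - c
        if adj < m.imr_floor:
            adj = m.imr_floor
            est.floor_clamped = True
        a = curve(adj)
        est.iteration_trace.append((c, adj, a))
        est.consanguinity_imr, est.adjusted_imr = c, adj
    return est


def final_adjusted_imr(
    consanguinity_adjusted_imr: float, hiv_imr: float, imr_floor: float = 1.0
) -> float:
    """Subtract HIV-attributable infant mortality, clamped at the floor."""
    if consanguinity_adjusted_imr < 0 or hiv_imr < 0:
        raise InputError("rates must be >= 0")
    out = consanguinity_adjusted_imr - hiv_imr
    if out < imr_floor:
        logger.warning(
            "HIV adjustment drove IMR below floor (%.3f - %.3f < %.3f); clamping",
            consanguinity_adjusted_imr, hiv_imr, imr_floor,
        )
        out = imr_floor
    return out


def estimate_access(
    inputs: MortalityInputs,
    curve: AccessCurve,
    model: ConsanguinityConfig | None = None,
) -> AccessEstimate:
    """Full access estimate: consanguinity iteration, HIV subtraction, curve.

    The adjustments can only lower the IMR, so ``access_final`` is never
    below ``access_unadjusted``.
    """
    m = model or ConsanguinityConfig()
    est = adjust_imr_consanguinity(inputs, curve, m)
    est.final_adjusted_imr = final_adjusted_imr(
        est.adjusted_imr, inputs.hiv_imr, m.imr_floor
    )
    est.access_final = curve(est.final_adjusted_imr)
    return est
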