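"""Two-step MR mediation: product of coefficients, delta-method CIs,
signed proportion mediated."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

from scipy import stats

from .estimators import MRResult
from .sumstats import Z_95

__all__ = ["IndirectEffect", "MediationResult", "indirect_effect", "proportion_mediated",
           "two_step_mediation"]


class IndirectEffect(NamedTuple):
    effect: float
    se: float
    ci_low: float
    ci_high: float


def indirect_effect(a: float, se_a: float, b: float, se_b: float,
                    z: float = Z_95) -> IndirectEffect:
    """Product-of-coefficients indirect effect a*b with a delta-method SE.

    The first-order delta variance is b^2*se_a^2 + a^2*se_b^2 with zero
    covariance: the two coefficients come from non-overlapping two-sample
    fits and are treated as independent.
    """
    if se_a <= 0 or se_b <= 0:
        raise ValueError("standard errors must be > 0")
    eff = a * b
    se = math.sqrt(b * b * se_a * se_a + a * a * se_b * se_b)
    return IndirectEffect(eff, se, eff - z * se, eff + z * se)


def proportion_mediated(indirect: float, total: float, percent: bool = False) -> float:
    """Signed proportion mediated, indirect/total.

    The sign is preserved: opposing indirect and total effects yield a
    negative proportion.  ``percent=True`` scales by 100.
    """
    if abs(total) < 1e-12:
        raise ValueError("undefined proportion: total effect is zero")
    frac = indirect / total
    return 100.0 * frac if percent else frac


@dataclass
class MediationResult:
    """Decomposition of a total effect into direct and mediated components."""

    exposure: str | None
    mediator: str | None
    outcome: str | None
    total_effect: float      # exposure -> outcome, univariable
    total_se: float
    effect_a: float          # exposure -> mediator, univariable
    se_a: float
    effect_b: float          # mediator -> outcome conditional on exposure (MVMR)
    se_b: float
    indirect: float
    indirect_se: float
    ci_low: float
    ci_high: float
    proportion: float        # signed fraction, indirect / total
    direct: float            # total - indirect
    pval: float              # z-test of the indirect effect

    def __post_init__(self) -> None:
        if abs(self.indirect - self.effect_a * self.effect_b) > 1e-12 * max(
            1.0, abs(self.indirect)
        ):
            raise ValueError("indirect effect must equal effect_a * effect_b")

    @property
    def proportion_pct(self) -> float:
        return 100.0 * self.proportion


def two_step_mediation(
    total: MRResult, step_a: MRResult, step_b_mvmr: MRResult
) -> MediationResult:
    """Assemble a mediation decomposition from the three MR fits.

    ``total`` is the univariable exposure->outcome estimate, ``step_a`` the
    univariable exposure->mediator estimate, and ``step_b_mvmr`` the
    mediator's coefficient from the MVMR of outcome on (exposure, mediator).
    """
    for name, r in (("total", total), ("step_a", step_a), ("step_b_mvmr", step_b_mvmr)):
        if r is None:
            raise ValueError(f"missing mediation input: {name}")
    ind = indirect_effect(step_a.beta, step_a.se, step_b_mvmr.beta, step_b_mvmr.se)
    prop = proportion_mediated(ind.effect, total.beta)
    z = ind.effect / ind.se if ind.se > 0 else 0.0
    return MediationResult(
        exposure=total.exposure,
        mediator=step_a.outcome,
        outcome=total.outcome,
        total_effect=total.beta,
        total_se=total.se,
        effect_a=step_a.beta,
        se_a=step_a.se,
        effect_b=step_b_mvmr.beta,
        se_b=step_b_mvmr.se,
        indirect=ind.effect,
        indirect_se=ind.se,
        ci_low=ind.ci_low,
        ci_high=ind.ci_high,
        proportion=prop,
        direct=total.beta - ind.effect,
        pval=float(2 * stats.norm.sf(abs(z))),
    )
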