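"""Univariable two-sample MR estimators on a harmonised instrument set.

All estimators consume a :class:`~mrmediate.sumstats.HarmonisedSet` with a
single exposure.  The inverse-variance-weighted (IVW) estimator is the
primary analysis; MR-Egger and the weighted median are pleiotropy-robust
alternatives under weaker identifying assumptions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .sumstats import HarmonisedSet, Z_95, beta_to_or

__all__ = ["MRResult", "wald_ratio", "ivw", "mr_egger", "weighted_median", "results_table"]


@dataclass
class MRResult:
    """A single causal estimate on the log-effect scale."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_snp: int
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_pval: float | None = None
    exposure: str | None = None
    outcome: str | None = None

    def __post_init__(self) -> None:
        if not self.ci_low <= self.beta <= self.ci_high:
            raise ValueError("CI must bracket the point estimate")
        if self.n_snp < 1:
            raise ValueError("n_snp must be >= 1")

    @property
    def odds_ratio(self) -> float:
        return math.exp(self.beta)


def _require_single_exposure(h: HarmonisedSet) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    if h.n_exposures != 1:
        raise ValueError(f"univariable estimator needs 1 exposure, got {h.n_exposures}")
    return h.bx[:, 0], h.sx[:, 0], h.by, h.sy


def _normal_p(z: float) -> float:
    return float(2.0 * stats.norm.sf(abs(z)))


def wald_ratio(
    bx: float, sx: float, by: float, sy: float, second_order: bool = False,
    exposure: str | None = None, outcome: str | None = None,
) -> MRResult:
    """Single-instrument ratio estimate by/bx.

    The default standard error is the first-order delta approximation
    ``|sy/bx|``, which ignores exposure-side uncertainty; ``second_order``
    adds the ``by^2 * sx^2 / bx^4`` term.
    """
    if bx == 0:
        raise ValueError("null instrument: exposure beta is zero")
    beta = by / bx
    if second_order:
        se = math.sqrt(sy**2 / bx**2 + by**2 * sx**2 / bx**4)
    else:
        se = abs(sy / bx)
    p = _normal_p(beta / se) if se > 0 else (1.0 if beta == 0 else 0.0)
    return MRResult("wald_ratio", beta, se, beta - Z_95 * se, beta + Z_95 * se, p, 1,
                    exposure=exposure, outcome=outcome)


def _ivw_core(bx: np.ndarray, by: np.ndarray, sy: np.ndarray) -> tuple[float, float, float]:
    """Weighted regression of by on bx through the origin; returns (beta, se_fixed, Q)."""
    w = 1.0 / sy**2
    swxx = float(np.sum(w * bx * bx))
    beta = float(np.sum(w * bx * by)) / swxx
    se_fixed = 1.0 / math.sqrt(swxx)
    q = float(np.sum(w * (by - beta * bx) ** 2))
    return beta, se_fixed, q


def ivw(h: HarmonisedSet, mode: str = "random") -> MRResult:
    """Inverse-variance-weighted estimate with outcome-se weights 1/sy^2.

    ``mode="fixed"`` uses the exact weighted-least-squares standard error;
    ``mode="random"`` (default) applies a multiplicative overdispersion factor
    sqrt(max(1, Q/(n-1))), the usual choice when Cochran's Q signals
    heterogeneity.  Reduces to the Wald ratio for a single instrument.
    """
    if mode not in ("fixed", "random"):
        raise ValueError(f"mode must be 'fixed' or 'random', got {mode!r}")
    bx, _, by, sy = _require_single_exposure(h)
    n = h.n_snp
    if n == 0:
        raise ValueError("no instruments")
    beta, se, q = _ivw_core(bx, by, sy)
    if mode == "random" and n > 1:
        se *= math.sqrt(max(1.0, q / (n - 1)))
    p = _normal_p(beta / se)
    return MRResult(f"ivw_{mode}", beta, se, beta - Z_95 * se, beta + Z_95 * se, p, n,
                    exposure=h.exposure_labels[0], outcome=h.outcome_label)


def mr_egger(h: HarmonisedSet) -> MRResult:
    """Weighted regression of by on bx with an intercept (weights 1/sy^2).

    Rows are reoriented internally so every exposure beta is non-negative,
    which the intercept's directional-pleiotropy interpretation requires.
    Coefficient covariance is inflated by max(1, Q_res/(n-2)); p-values and
    CIs use the t distribution with n-2 degrees of freedom.
    """
    if h.n_snp < 3:
        raise ValueError("insufficient instruments for Egger (need >= 3)")
    ho = h.oriented(0)
    bx, _, by, sy = _require_single_exposure(ho)
    n = ho.n_snp
    w = 1.0 / sy**2
    X = np.column_stack([np.ones(n), bx])
    xtwx = X.T @ (w[:, None] * X)
    xtwy = X.T @ (w * by)
    coef = np.linalg.solve(xtwx, xtwy)
    resid = by - X @ coef
    q_res = float(np.sum(w * resid**2))
    sigma2 = max(1.0, q_res / (n - 2))
    cov = sigma2 * np.linalg.inv(xtwx)
    slope, slope_se = float(coef[1]), math.sqrt(cov[1, 1])
    icpt, icpt_se = float(coef[0]), math.sqrt(cov[0, 0])
    tdist = stats.t(df=n - 2)
    tcrit = float(tdist.ppf(0.975))
    return MRResult(
        "mr_egger",
        slope,
        slope_se,
        slope - tcrit * slope_se,
        slope + tcrit * slope_se,
        float(2 * tdist.sf(abs(slope / slope_se))),
        n,
        intercept=icpt,
        intercept_se=icpt_se,
        intercept_pval=float(2 * tdist.sf(abs(icpt / icpt_se))),
        exposure=h.exposure_labels[0],
        outcome=h.outcome_label,
    )


def _weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(ratios)
    r = ratios[order]
    w = weights[order]
    p = (np.cumsum(w) - 0.5 * w) / np.sum(w)
    return float(np.interp(0.5, p, r))


def weighted_median(
    h: HarmonisedSet, n_boot: int = 5000, *, seed: int
) -> MRResult:
    """Weighted median of per-instrument ratios, inverse-variance weighted.

    Consistent when valid instruments carry more than half the total weight.
    The standard error comes from a seeded parametric bootstrap: exposure and
    outcome betas are redrawn from normal(beta, se) ``n_boot`` times and the
    point estimate recomputed on each replicate.
    """
    if h.n_snp < 3:
        raise ValueError("insufficient instruments for weighted median (need >= 3)")
    bx, sx, by, sy = _require_single_exposure(h)
    ratios = by / bx
    weights = bx**2 / sy**2
    beta = _weighted_median_point(ratios, weights)

    rng = np.random.default_rng(seed)
    bxb = rng.normal(bx, sx, size=(n_boot, h.n_snp))
    byb = rng.normal(by, sy, size=(n_boot, h.n_snp))
    rb = byb / bxb
    wb = bxb**2 / sy**2
    order = np.argsort(rb, axis=1)
    rs = np.take_along_axis(rb, order, axis=1)
    ws = np.take_along_axis(wb, order, axis=1)
    pb = (np.cumsum(ws, axis=1) - 0.5 * ws) / np.sum(ws, axis=1, keepdims=True)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        boots[i] = np.interp(0.5, pb[i], rs[i])
    se = float(np.std(boots, ddof=1))
    p = _normal_p(beta / se) if se > 0 else (1.0 if beta == 0 else 0.0)
    return MRResult("weighted_median", beta, se, beta - Z_95 * se, beta + Z_95 * se, p,
                    h.n_snp, exposure=h.exposure_labels[0], outcome=h.outcome_label)


def results_table(results) -> "pd.DataFrame":
    """Tabulate MR results with odds-ratio scale CI columns."""
    import pandas as pd

    rows = []
    for r in results:
        orr = beta_to_or(r.beta, r.se)
        rows.append({
            "exposure": r.exposure,
            "outcome": r.outcome,
            "method": r.method,
            "n_snp": r.n_snp,
            "beta": r.beta,
            "se": r.se,
            "or": orr.odds_ratio,
            "ci_low": orr.ci_low,
            "ci_high": orr.ci_high,
            "pval": r.pval,
            "egger_intercept": r.intercept,
            "egger_intercept_pval": r.intercept_pval,
        })
    return pd.DataFrame(rows)
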