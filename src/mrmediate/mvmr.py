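"""Multivariable MR: joint direct effects of several exposures on one outcome."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import MRResult
from .sumstats import HarmonisedSet

__all__ = ["mvmr_ivw", "mvmr_diagnostics"]

_COND_LIMIT = 1e8


def mvmr_ivw(h: HarmonisedSet) -> list[MRResult]:
    """Weighted multiple regression of by on the exposure beta columns.

    No intercept; weights 1/sy^2.  Coefficient j is exposure j's direct
    effect conditional on the others.  The coefficient covariance is inflated
    by max(1, Q/(n-k)); p-values and CIs use the t distribution with n-k
    degrees of freedom.  With a single exposure this reduces to univariable
    IVW (random mode up to the t/normal reference difference).
    """
    k = h.n_exposures
    n = h.n_snp
    if n <= k:
        raise ValueError(f"need more instruments ({n}) than exposures ({k})")
    w = 1.0 / h.sy**2
    X = h.bx
    if np.linalg.cond(X * np.sqrt(w)[:, None]) > _COND_LIMIT:
        raise ValueError("collinear exposures")
    xtwx = X.T @ (w[:, None] * X)
    coef = np.linalg.solve(xtwx, X.T @ (w * h.by))
    resid = h.by - X @ coef
    q = float(np.sum(w * resid**2))
    sigma2 = max(1.0, q / (n - k))
    cov = sigma2 * np.linalg.inv(xtwx)
    tdist = stats.t(df=n - k)
    tcrit = float(tdist.ppf(0.975))
    out = []
    for j, label in enumerate(h.exposure_labels):
        b = float(coef[j])
        se = math.sqrt(cov[j, j])
        out.append(
            MRResult(
                "mvmr_ivw",
                b,
                se,
                b - tcrit * se,
                b + tcrit * se,
                float(2 * tdist.sf(abs(b / se))),
                n,
                exposure=label,
                outcome=h.outcome_label,
            )
        )
    return out


def _egger_intercept_p(h: HarmonisedSet, exposure_index: int) -> float:
    """Multivariable Egger intercept p after orienting on one exposure."""
    ho = h.oriented(exposure_index)
    n, k = ho.n_snp, ho.n_exposures
    w = 1.0 / ho.sy**2
    X = np.column_stack([np.ones(n), ho.bx])
    xtwx = X.T @ (w[:, None] * X)
    coef = np.linalg.solve(xtwx, X.T @ (w * ho.by))
    resid = ho.by - X @ coef
    sigma2 = max(1.0, float(np.sum(w * resid**2)) / (n - k - 1))
    cov = sigma2 * np.linalg.inv(xtwx)
    t = abs(coef[0]) / math.sqrt(cov[0, 0])
    return float(2 * stats.t.sf(t, df=n - k - 1))


def mvmr_diagnostics(h: HarmonisedSet, results: list[MRResult]) -> pd.DataFrame:
    """Per-exposure heterogeneity and pleiotropy diagnostics.

    For each exposure: the residual-Q heterogeneity p of the no-intercept fit
    (IVW row) and of the intercept fit oriented on that exposure (MR Egger
    row), plus the multivariable Egger intercept p.
    """
    n, k = h.n_snp, h.n_exposures
    w = 1.0 / h.sy**2
    coef = np.array([r.beta for r in results])
    q_ivw = float(np.sum(w * (h.by - h.bx @ coef) ** 2))
    p_q_ivw = float(stats.chi2.sf(q_ivw, n - k))

    rows = []
    for j, label in enumerate(h.exposure_labels):
        ho = h.oriented(j)
        X = np.column_stack([np.ones(n), ho.bx])
        xtwx = X.T @ (w[:, None] * X)
        ce = np.linalg.solve(xtwx, X.T @ (w * ho.by))
        q_egger = float(np.sum(w * (ho.by - X @ ce) ** 2))
        p_q_egger = float(stats.chi2.sf(q_egger, n - k - 1))
        icpt_p = _egger_intercept_p(h, j)
        rows.extend([
            {"exposure": label, "method": "mr_egger", "n_snp": n,
             "p_heterogeneity": p_q_egger, "egger_intercept_p": icpt_p},
            {"exposure": label, "method": "ivw", "n_snp": n,
             "p_heterogeneity": p_q_ivw, "egger_intercept_p": None},
            {"exposure": label, "method": "egger_intercept", "n_snp": None,
             "p_heterogeneity": None, "egger_intercept_p": icpt_p},
        ])
    return pd.DataFrame(rows)
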