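"""Heterogeneity, pleiotropy and influence diagnostics.

Cochran's Q measures instrument heterogeneity around a causal estimate;
leave-one-out refits expose single-variant influence; MR-PRESSO is a
simulation-based global heterogeneity test with per-variant outlier
detection and outlier-corrected re-estimation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import MRResult, ivw, mr_egger, weighted_median
from .sumstats import HarmonisedSet

__all__ = ["CochranQ", "LooTable", "PressoResult", "cochran_q", "leave_one_out", "mr_presso"]


class CochranQ(NamedTuple):
    q: float
    df: int
    pval: float


def cochran_q(h: HarmonisedSet, beta_hat: float, df: int | None = None) -> CochranQ:
    """Cochran's Q = sum((by - beta_hat*bx)^2 / sy^2) with a chi-square tail p.

    ``df`` defaults to n-1 (one slope estimated); pass n-2 for the residual Q
    of an intercept model.
    """
    if h.n_snp < 2:
        raise ValueError("Cochran's Q needs >= 2 instruments")
    bx, by, sy = h.bx[:, 0], h.by, h.sy
    q = float(np.sum((by - beta_hat * bx) ** 2 / sy**2))
    if df is None:
        df = h.n_snp - 1
    return CochranQ(q, df, float(stats.chi2.sf(q, df)))


@dataclass
class LooTable:
    """Leave-one-out refits: one row per omitted instrument."""

    full: MRResult
    rows: list[tuple[str, MRResult]]
    flagged: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        recs = [
            {
                "left_out": vid,
                "beta": r.beta,
                "se": r.se,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "pval": r.pval,
                "n_snp": r.n_snp,
                "influential": vid in self.flagged,
            }
            for vid, r in self.rows
        ]
        return pd.DataFrame(recs)


_ESTIMATORS = {
    "ivw_fixed": lambda h, seed: ivw(h, mode="fixed"),
    "ivw_random": lambda h, seed: ivw(h, mode="random"),
    "mr_egger": lambda h, seed: mr_egger(h),
    "weighted_median": lambda h, seed: weighted_median(h, seed=seed),
}


def leave_one_out(h: HarmonisedSet, method: str = "ivw_random", seed: int = 0) -> LooTable:
    """Refit the chosen estimator once per omitted instrument.

    An omission is flagged as influential when it flips the estimate's sign
    or moves it outside the full-set confidence interval.
    """
    if method not in _ESTIMATORS:
        raise ValueError(f"unknown method {method!r}; choose from {sorted(_ESTIMATORS)}")
    if h.n_snp < 2:
        raise ValueError("leave-one-out needs >= 2 instruments")
    fit = _ESTIMATORS[method]
    full = fit(h, seed)
    rows: list[tuple[str, MRResult]] = []
    flagged: list[str] = []
    for i, vid in enumerate(h.variant_ids):
        mask = np.ones(h.n_snp, dtype=bool)
        mask[i] = False
        sub = fit(h.subset(mask), seed)
        rows.append((vid, sub))
        sign_flip = np.sign(sub.beta) != np.sign(full.beta) and full.beta != 0 and sub.beta != 0
        outside = not (full.ci_low <= sub.beta <= full.ci_high)
        if sign_flip or outside:
            flagged.append(vid)
    return LooTable(full=full, rows=rows, flagged=flagged)


@dataclass
class PressoResult:
    global_rss: float
    global_pval: float
    outlier_ids: list[str]
    per_snp_pvals: dict[str, float]
    corrected: MRResult
    distortion_pval: float | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.global_pval <= 1:
            raise ValueError("global_pval must lie in [0, 1]")


def _loo_betas(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> np.ndarray:
    """IVW slope with each instrument removed, via rank-one downdates."""
    s1 = np.sum(w * bx * by)
    s2 = np.sum(w * bx * bx)
    return (s1 - w * bx * by) / (s2 - w * bx * bx)


def mr_presso(
    h: HarmonisedSet,
    n_sim: int = 1000,
    *,
    seed: int,
    outlier_alpha: float = 0.05,
    distortion_test: bool = False,
) -> PressoResult:
    """Pleiotropy residual-sum-and-outlier test.

    The observed global statistic is the weighted residual sum of squares
    where each instrument's prediction uses the leave-one-out IVW slope.  Its
    null distribution is built from ``n_sim`` parametric draws
    by_i ~ normal(beta_loo_i * bx_i, sy_i); Monte-Carlo p-values use the
    add-one estimator.  Per-instrument outlier p-values are Bonferroni
    compared against ``outlier_alpha``; the corrected estimate is IVW on the
    non-outliers.
    """
    if h.n_snp < 4:
        raise ValueError("MR-PRESSO needs >= 4 instruments")
    if n_sim < 100:
        raise ValueError("n_sim must be >= 100")
    bx, by, sy = h.bx[:, 0], h.by, h.sy
    n = h.n_snp
    w = 1.0 / sy**2

    beta_loo = _loo_betas(bx, by, w)
    obs_res = w * (by - beta_loo * bx) ** 2
    rss_obs = float(np.sum(obs_res))

    rng = np.random.default_rng(seed)
    by_sim = rng.normal(beta_loo * bx, sy, size=(n_sim, n))
    s2 = np.sum(w * bx * bx)
    s1_sim = by_sim @ (w * bx)
    beta_loo_sim = (s1_sim[:, None] - w * bx * by_sim) / (s2 - w * bx * bx)
    res_sim = w * (by_sim - beta_loo_sim * bx) ** 2
    rss_sim = res_sim.sum(axis=1)

    global_pval = (1.0 + np.count_nonzero(rss_sim >= rss_obs)) / (1.0 + n_sim)
    per_p = (1.0 + np.count_nonzero(res_sim >= obs_res, axis=0)) / (1.0 + n_sim)
    outliers = per_p * n < outlier_alpha  # Bonferroni
    outlier_ids = [h.variant_ids[i] for i in np.flatnonzero(outliers)]
    if len(outlier_ids) == n:
        raise RuntimeError("no instruments survive PRESSO outlier removal")

    corrected = ivw(h.subset(~outliers)) if outlier_ids else ivw(h)

    distortion_pval = None
    if distortion_test and outlier_ids:
        full_beta = ivw(h).beta
        d_obs = corrected.beta - full_beta
        k = len(outlier_ids)
        d_null = np.empty(n_sim)
        for s in range(n_sim):
            drop = rng.choice(n, size=k, replace=False)
            mask = np.ones(n, dtype=bool)
            mask[drop] = False
            d_null[s] = ivw(h.subset(mask)).beta - full_beta
        distortion_pval = float(
            (1.0 + np.count_nonzero(np.abs(d_null) >= abs(d_obs))) / (1.0 + n_sim)
        )

    return PressoResult(
        global_rss=rss_obs,
        global_pval=float(global_pval),
        outlier_ids=outlier_ids,
        per_snp_pvals=dict(zip(h.variant_ids, per_p.tolist())),
        corrected=corrected,
        distortion_pval=distortion_pval,
    )
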