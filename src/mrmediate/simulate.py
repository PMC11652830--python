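"""Synthetic three-trait GWAS summary statistics under a linear structural
mediation model exposure -> mediator -> outcome with known truth.

Summary statistics are generated directly (no individual-level genotypes):
true per-allele instrument effects propagate linearly through the structural
coefficients, observed betas add normal noise at the standard per-allele
standard error 1/sqrt(2*maf*(1-maf)*n), and p-values follow from Wald z.
Instrument sets for the exposure and the mediator are disjoint by default so
multivariable analyses exercise their union logic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import stats

from .sumstats import SummaryDataset, VariantAssociation, write_sumstats

__all__ = ["SimulationConfig", "SimulationTruth", "simulate_mediation_gwas",
           "write_fixture_suite"]

# non-palindromic allele pairs only, so harmonisation never drops a variant
_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                 ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]


@dataclass
class SimulationConfig:
    """Generating parameters for one synthetic three-trait dataset."""

    seed: int
    n_instruments_x: int = 50
    n_instruments_m: int = 50
    maf_range: tuple[float, float] = (0.1, 0.4)
    effect_scale: float = 0.05
    n_x: int = 100_000
    n_m: int = 100_000
    n_y: int = 100_000
    a: float = 0.0          # exposure -> mediator
    b: float = 0.0          # mediator -> outcome
    c_prime: float = 0.0    # direct exposure -> outcome
    pleiotropy_mode: str = "none"   # none | balanced | directional
    pleiotropy_sd: float = 0.0
    pleiotropy_mean: float = 0.0
    n_outliers: int = 0
    outlier_multiplier: float = 10.0
    overlap_fraction: float = 0.0   # fraction of M instruments that also hit X
    labels: tuple[str, str, str] = ("exposure", "mediator", "outcome")

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must lie within (0, 0.5], got {self.maf_range}")
        if min(self.n_x, self.n_m, self.n_y) <= 0:
            raise ValueError("sample sizes must be positive")
        if self.pleiotropy_mode not in ("none", "balanced", "directional"):
            raise ValueError(f"unknown pleiotropy_mode {self.pleiotropy_mode!r}")
        if self.n_outliers > self.n_instruments_x:
            raise ValueError("more outliers than exposure instruments")


@dataclass
class SimulationTruth:
    """Generating truth for parameter-recovery assertions."""

    a: float
    b: float
    c_prime: float
    total: float                      # c_prime + a*b, exactly
    outlier_ids: list[str]
    true_effects: dict[str, dict[str, float]]  # trait label -> variant -> true beta
    instrument_ids_x: list[str] = field(default_factory=list)
    instrument_ids_m: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        assert self.total == self.c_prime + self.a * self.b

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "SimulationTruth":
        return cls(**json.loads(Path(path).read_text()))


def _pvals(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    p = 2.0 * stats.norm.sf(np.abs(beta / se))
    return np.clip(p, np.finfo(float).tiny, 1.0)


def simulate_mediation_gwas(
    config: SimulationConfig,
) -> tuple[SummaryDataset, SummaryDataset, SummaryDataset, SimulationTruth]:
    """Generate (exposure, mediator, outcome) summary datasets plus the truth.

    True instrument effects are gamma_i ~ normal(0, effect_scale^2).  An
    exposure instrument affects the mediator with a*gamma_i and the outcome
    with (c_prime + a*b)*gamma_i, plus a pleiotropic term on the outcome per
    ``pleiotropy_mode``; a mediator instrument affects the outcome with
    b*gamma_i.  Planted outliers multiply their outcome effect by
    ``outlier_multiplier``.  Same seed, same bytes.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    nx, nm = cfg.n_instruments_x, cfg.n_instruments_m
    n_var = nx + nm

    ids = [f"rs{1000 + i}" for i in range(n_var)]
    ids_x, ids_m = ids[:nx], ids[nx:]
    chroms = [str(1 + (i % 22)) for i in range(n_var)]
    pos = [1_000_000 + 25_000_000 * (i // 22) for i in range(n_var)]
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=n_var)
    maf = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=n_var)

    gx = rng.normal(0.0, cfg.effect_scale, size=nx)   # effect on X
    gm = rng.normal(0.0, cfg.effect_scale, size=nm)   # effect on M

    total = cfg.c_prime + cfg.a * cfg.b
    true_x = np.concatenate([gx, np.zeros(nm)])
    true_m = np.concatenate([cfg.a * gx, gm])
    true_y = np.concatenate([total * gx, cfg.b * gm])

    if cfg.overlap_fraction > 0:
        k = int(round(cfg.overlap_fraction * nm))
        if k:
            shared = rng.normal(0.0, cfg.effect_scale, size=k)
            true_x[nx:nx + k] += shared
            true_m[nx:nx + k] += cfg.a * shared
            true_y[nx:nx + k] += total * shared

    if cfg.pleiotropy_mode != "none":
        mean = cfg.pleiotropy_mean if cfg.pleiotropy_mode == "directional" else 0.0
        # directional pleiotropy is defined relative to the exposure-raising
        # allele, matching the orientation an intercept model uses
        true_y[:nx] += np.sign(gx) * rng.normal(mean, cfg.pleiotropy_sd, size=nx)

    outlier_ids: list[str] = []
    if cfg.n_outliers:
        which = rng.choice(nx, size=cfg.n_outliers, replace=False)
        true_y[which] = cfg.outlier_multiplier * total * gx[which]
        outlier_ids = [ids[i] for i in sorted(which)]

    se_base = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf))
    datasets = []
    for label, truth_vec, n_trait in (
        (cfg.labels[0], true_x, cfg.n_x),
        (cfg.labels[1], true_m, cfg.n_m),
        (cfg.labels[2], true_y, cfg.n_y),
    ):
        se = se_base / np.sqrt(n_trait)
        beta = truth_vec + rng.normal(0.0, se)
        pval = _pvals(beta, se)
        ds = SummaryDataset(trait_label=label)
        for i in range(n_var):
            ea, oa = _ALLELE_PAIRS[pair_idx[i]]
            ds.add(VariantAssociation(
                variant_id=ids[i], chrom=chroms[i], pos=pos[i],
                effect_allele=ea, other_allele=oa, eaf=float(maf[i]),
                beta=float(beta[i]), se=float(se[i]), pval=float(pval[i]),
                n=n_trait,
            ))
        datasets.append(ds)

    truth = SimulationTruth(
        a=cfg.a, b=cfg.b, c_prime=cfg.c_prime, total=total,
        outlier_ids=outlier_ids,
        true_effects={
            cfg.labels[0]: dict(zip(ids, true_x.tolist())),
            cfg.labels[1]: dict(zip(ids, true_m.tolist())),
            cfg.labels[2]: dict(zip(ids, true_y.tolist())),
        },
        instrument_ids_x=ids_x,
        instrument_ids_m=ids_m,
    )
    return datasets[0], datasets[1], datasets[2], truth


def _exact_pair(ids, bx, by, sx, sy, labels) -> tuple[SummaryDataset, SummaryDataset]:
    """Deterministic exposure/outcome pair with prescribed betas (no noise)."""
    exp = SummaryDataset(trait_label=labels[0])
    out = SummaryDataset(trait_label=labels[1])
    for i, vid in enumerate(ids):
        common = dict(variant_id=vid, chrom=str(1 + i % 22),
                      pos=1_000_000 + 25_000_000 * (i // 22),
                      effect_allele="A", other_allele="G", eaf=0.3)
        zx = abs(bx[i]) / sx[i]
        zy = abs(by[i]) / sy[i]
        exp.add(VariantAssociation(beta=bx[i], se=sx[i],
                                   pval=float(np.clip(2 * stats.norm.sf(zx), 1e-300, 1.0)),
                                   **common))
        out.add(VariantAssociation(beta=by[i], se=sy[i],
                                   pval=float(np.clip(2 * stats.norm.sf(zy), 1e-300, 1.0)),
                                   **common))
    return exp, out


def write_fixture_suite(directory) -> dict[str, dict[str, str]]:
    """Write the canonical named fixtures used by the test suite.

    Emits four fixtures, each as canonical summary-statistics files plus a
    JSON truth sidecar; returns {fixture_name: {role: path}}.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, dict[str, str]] = {}

    def _write(name: str, files: dict[str, SummaryDataset], truth: dict) -> None:
        entry: dict[str, str] = {}
        for role, ds in files.items():
            p = directory / f"{name}.{role}.tsv"
            write_sumstats(ds, p)
            entry[role] = str(p)
        tp = directory / f"{name}.truth.json"
        tp.write_text(json.dumps(truth, indent=1, sort_keys=True))
        entry["truth"] = str(tp)
        manifest[name] = entry

    # every instrument has ratio by/bx exactly 0.3
    ids = [f"rs{i}" for i in range(1, 11)]
    bx = [0.02 * (i + 1) for i in range(10)]
    by = [0.3 * x for x in bx]
    sx = [0.002] * 10
    sy = [0.005] * 10
    exp, out = _exact_pair(ids, bx, by, sx, sy, ("exposure", "outcome"))
    _write("consensus", {"exposure": exp, "outcome": out}, {"ratio": 0.3})

    # points exactly on by = 0.02 + 0.3 * bx
    ids = [f"rs{i}" for i in range(1, 11)]
    bx = [0.05 + 0.03 * i for i in range(10)]
    by = [0.02 + 0.3 * x for x in bx]
    exp, out = _exact_pair(ids, bx, by, [0.002] * 10, [0.005] * 10,
                           ("exposure", "outcome"))
    _write("egger_line", {"exposure": exp, "outcome": out},
           {"intercept": 0.02, "slope": 0.3})

    # simulated consensus with one 10x-ratio outlier
    cfg = SimulationConfig(seed=11, n_instruments_x=31, n_instruments_m=0,
                           a=0.0, b=0.0, c_prime=0.3, n_outliers=1,
                           outlier_multiplier=10.0,
                           n_x=500_000, n_m=500_000, n_y=500_000)
    dx, dm, dy, truth = simulate_mediation_gwas(cfg)
    _write("planted_outlier", {"exposure": dx, "outcome": dy},
           {"ratio": 0.3, "outlier_ids": truth.outlier_ids})

    # full three-trait mediation recovery set
    # strong instruments so the significance filter is rarely binding and
    # selection-induced (winner's curse) bias stays well inside the SEs
    cfg = SimulationConfig(seed=42, n_instruments_x=100, n_instruments_m=100,
                           a=0.4, b=0.5, c_prime=0.1, effect_scale=0.15,
                           n_x=100_000, n_m=100_000, n_y=100_000)
    dx, dm, dy, truth = simulate_mediation_gwas(cfg)
    _write("mediation_recovery",
           {"exposure": dx, "mediator": dm, "outcome": dy},
           {"a": truth.a, "b": truth.b, "c_prime": truth.c_prime,
            "total": truth.total,
            "proportion_mediated": truth.a * truth.b / truth.total})

    (directory / "fixtures.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
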