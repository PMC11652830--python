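"""Pipeline orchestration: bidirectional univariable MR and two-step MR
mediation from a single run configuration, with reproducible seeding and a
machine-readable run manifest."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .estimators import ivw, mr_egger, results_table, weighted_median
from .instruments import (DEFAULT_CLUMP_KB, DEFAULT_CLUMP_R2, DEFAULT_F_MIN,
                          DEFAULT_P_THRESHOLD, LDMatrix, select_instruments)
from .mediation import two_step_mediation
from .mvmr import mvmr_diagnostics, mvmr_ivw
from .sensitivity import cochran_q, leave_one_out, mr_presso
from .sumstats import HarmonisedSet, SummaryDataset, harmonise, read_sumstats

__all__ = ["RunConfig", "StageError", "run_univariable", "run_two_step", "load_config"]

MEDIATION_COLUMNS = ["outcome", "exposure", "mediator", "total", "direct1", "direct2",
                     "indirect", "indirect_se", "ci_low", "ci_high", "proportion_pct"]


class StageError(RuntimeError):
    """An error raised by a pipeline stage, tagged with the stage name."""

    def __init__(self, stage: str, original: Exception):
        super().__init__(f"[{stage}] {original}")
        self.stage = stage
        self.original = original


@dataclass
class RunConfig:
    """Resolved configuration for one pipeline run."""

    seed: int = 0
    p_threshold: float = DEFAULT_P_THRESHOLD
    clump_r2: float = DEFAULT_CLUMP_R2
    clump_kb: float = DEFAULT_CLUMP_KB
    f_min: float = DEFAULT_F_MIN
    palindromic_eaf_window: float = 0.08
    ivw_mode: str = "random"
    n_boot: int = 5000
    presso_sims: int = 1000
    presso_outlier_alpha: float = 0.05
    mediation_alpha: float = 0.05
    bidirectional: bool = False
    datasets: dict[str, str] = field(default_factory=dict)  # role -> path
    ld_matrix: str | None = None
    column_map: dict[str, str] | None = None

    def spawn_seeds(self, n: int) -> list[int]:
        """Derive per-stage integer seeds from the root seed."""
        ss = np.random.SeedSequence(self.seed)
        return [int(s.generate_state(1)[0]) for s in ss.spawn(n)]


def load_config(path) -> RunConfig:
    """Load a YAML/JSON run configuration.

    Recognised blocks: ``datasets`` (role -> path), ``thresholds``,
    ``estimators``, ``sensitivity``, ``mediation``, plus top-level ``seed``
    and ``bidirectional``.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    thresholds = raw.get("thresholds", {})
    est = raw.get("estimators", {})
    sens = raw.get("sensitivity", {})
    med = raw.get("mediation", {})
    return RunConfig(
        seed=int(raw.get("seed", 0)),
        p_threshold=float(thresholds.get("p_threshold", DEFAULT_P_THRESHOLD)),
        clump_r2=float(thresholds.get("clump_r2", DEFAULT_CLUMP_R2)),
        clump_kb=float(thresholds.get("clump_kb", DEFAULT_CLUMP_KB)),
        f_min=float(thresholds.get("f_min", DEFAULT_F_MIN)),
        palindromic_eaf_window=float(thresholds.get("palindromic_eaf_window", 0.08)),
        ivw_mode=str(est.get("ivw_mode", "random")),
        n_boot=int(est.get("n_boot", 5000)),
        presso_sims=int(sens.get("presso_sims", 1000)),
        presso_outlier_alpha=float(sens.get("outlier_alpha", 0.05)),
        mediation_alpha=float(med.get("alpha", 0.05)),
        bidirectional=bool(raw.get("bidirectional", False)),
        datasets={k: str(v) for k, v in raw.get("datasets", {}).items()},
        ld_matrix=raw.get("ld_matrix"),
        column_map=raw.get("column_map"),
    )


def _load_role(cfg: RunConfig, role: str,
               provided: SummaryDataset | None = None) -> SummaryDataset:
    if provided is not None:
        return provided
    try:
        path = cfg.datasets[role]
    except KeyError:
        raise StageError("load", KeyError(f"no dataset configured for role {role!r}"))
    return read_sumstats(path, column_map=cfg.column_map, trait_label=role)


def _stage(name, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001 - tag and rethrow
        raise StageError(name, exc) from exc


def _univariable_once(
    exposure: SummaryDataset,
    outcome: SummaryDataset,
    cfg: RunConfig,
    ld: LDMatrix | None,
    seeds: list[int],
) -> tuple[pd.DataFrame, pd.DataFrame, HarmonisedSet]:
    """One direction of univariable MR with sensitivity analyses."""
    instruments = _stage("select_instruments", select_instruments, exposure, ld,
                         cfg.p_threshold, cfg.clump_r2, cfg.clump_kb, cfg.f_min)
    h = _stage("harmonise", harmonise, exposure, outcome, instruments.variant_ids,
               cfg.palindromic_eaf_window)
    if h.n_snp == 0:
        raise StageError("harmonise", RuntimeError("no instruments survive harmonisation"))

    def _estimate(hset: HarmonisedSet, analysis: str) -> list:
        res = [ivw(hset, mode=cfg.ivw_mode)]
        if hset.n_snp >= 3:
            res.append(_stage("mr_egger", mr_egger, hset))
            res.append(_stage("weighted_median", weighted_median, hset,
                              cfg.n_boot, seed=seeds[0]))
        for r in res:
            r.analysis = analysis  # type: ignore[attr-defined]
        return res

    results = _estimate(h, "primary")

    diag_rows = []
    beta_ivw = results[0].beta
    if h.n_snp >= 2:
        q = _stage("cochran_q", cochran_q, h, beta_ivw)
        diag_rows.append({"exposure": exposure.trait_label, "outcome": outcome.trait_label,
                          "test": "cochran_q_ivw", "statistic": q.q, "df": q.df,
                          "pval": q.pval})
        loo = _stage("leave_one_out", leave_one_out, h,
                     f"ivw_{cfg.ivw_mode}", seeds[1])
        diag_rows.append({"exposure": exposure.trait_label, "outcome": outcome.trait_label,
                          "test": "leave_one_out_influential",
                          "statistic": float(len(loo.flagged)), "df": h.n_snp,
                          "pval": None})
    egger = next((r for r in results if r.method == "mr_egger"), None)
    if egger is not None:
        diag_rows.append({"exposure": exposure.trait_label, "outcome": outcome.trait_label,
                          "test": "egger_intercept", "statistic": egger.intercept,
                          "df": h.n_snp - 2, "pval": egger.intercept_pval})

    if h.n_snp >= 4:
        presso = _stage("mr_presso", mr_presso, h, cfg.presso_sims,
                        seed=seeds[2], outlier_alpha=cfg.presso_outlier_alpha)
        diag_rows.append({"exposure": exposure.trait_label, "outcome": outcome.trait_label,
                          "test": "mr_presso_global", "statistic": presso.global_rss,
                          "df": h.n_snp, "pval": presso.global_pval})
        if presso.outlier_ids:
            keep = [i for i, v in enumerate(h.variant_ids)
                    if v not in set(presso.outlier_ids)]
            results.extend(_estimate(h.subset(keep), "outlier_corrected"))

    table = results_table(results)
    table.insert(0, "analysis", [getattr(r, "analysis", "primary") for r in results])
    return table, pd.DataFrame(diag_rows), h


def run_univariable(
    cfg: RunConfig,
    exposure: SummaryDataset | None = None,
    outcome: SummaryDataset | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Univariable two-sample MR with sensitivity analyses.

    Runs instrument selection, harmonisation, the three estimators (IVW,
    MR-Egger, weighted median), then Cochran's Q, leave-one-out and
    MR-PRESSO; when PRESSO flags outliers the estimators are re-run on the
    pruned set and reported alongside the primary analysis.  With
    ``cfg.bidirectional`` both directions are analysed.
    """
    exposure = _load_role(cfg, "exposure", exposure)
    outcome = _load_role(cfg, "outcome", outcome)
    ld = LDMatrix.from_file(cfg.ld_matrix) if cfg.ld_matrix else None
    seeds = cfg.spawn_seeds(6)

    tables, diags = [], []
    t, d, _ = _univariable_once(exposure, outcome, cfg, ld, seeds[:3])
    tables.append(t)
    diags.append(d)
    if cfg.bidirectional:
        t, d, _ = _univariable_once(outcome, exposure, cfg, ld, seeds[3:])
        tables.append(t)
        diags.append(d)
    return pd.concat(tables, ignore_index=True), pd.concat(diags, ignore_index=True)


def run_two_step(
    cfg: RunConfig,
    exposure: SummaryDataset | None = None,
    mediator: SummaryDataset | None = None,
    outcome: SummaryDataset | None = None,
) -> dict[str, pd.DataFrame]:
    """Two-step MR mediation.

    Step 1: univariable MR for exposure->mediator, mediator->outcome and
    exposure->outcome.  Step 2: MVMR of the outcome on (exposure, mediator)
    over the union of both traits' instruments.  The mediation decomposition
    is assembled only when the mediator's MVMR coefficient is significant at
    ``cfg.mediation_alpha``.
    """
    exposure = _load_role(cfg, "exposure", exposure)
    mediator = _load_role(cfg, "mediator", mediator)
    outcome = _load_role(cfg, "outcome", outcome)
    ld = LDMatrix.from_file(cfg.ld_matrix) if cfg.ld_matrix else None
    seeds = cfg.spawn_seeds(12)

    step1_tables = []
    uni_results = {}
    for i, (exp, out) in enumerate((
        (exposure, mediator), (mediator, outcome), (exposure, outcome),
    )):
        t, d, h = _univariable_once(exp, out, cfg, ld, seeds[3 * i: 3 * i + 3])
        step1_tables.append(t)
        uni_results[(exp.trait_label, out.trait_label)] = ivw(h, mode=cfg.ivw_mode)
    step1 = pd.concat(step1_tables, ignore_index=True)

    # step 2: MVMR over the union of exposure and mediator instruments
    iv_x = select_instruments(exposure, ld, cfg.p_threshold, cfg.clump_r2,
                              cfg.clump_kb, cfg.f_min).variant_ids
    iv_m = select_instruments(mediator, ld, cfg.p_threshold, cfg.clump_r2,
                              cfg.clump_kb, cfg.f_min).variant_ids
    union = list(dict.fromkeys(iv_x + iv_m))
    union = [v for v in union if v in exposure and v in mediator and v in outcome]
    h_mv = _stage("harmonise_mvmr", harmonise, [exposure, mediator], outcome, union,
                  cfg.palindromic_eaf_window)
    mv_results = _stage("mvmr", mvmr_ivw, h_mv)
    mv_table = results_table(mv_results)
    mv_diag = _stage("mvmr_diagnostics", mvmr_diagnostics, h_mv, mv_results)

    total = uni_results[(exposure.trait_label, outcome.trait_label)]
    step_a = uni_results[(exposure.trait_label, mediator.trait_label)]
    step_b = next(r for r in mv_results if r.exposure == mediator.trait_label)

    med_rows = []
    if step_b.pval < cfg.mediation_alpha:
        med = _stage("mediation", two_step_mediation, total, step_a, step_b)
        med_rows.append({
            "outcome": med.outcome, "exposure": med.exposure, "mediator": med.mediator,
            "total": med.total_effect, "direct1": med.effect_a, "direct2": med.effect_b,
            "indirect": med.indirect, "indirect_se": med.indirect_se,
            "ci_low": med.ci_low, "ci_high": med.ci_high,
            "proportion_pct": med.proportion_pct,
        })
    mediation_table = pd.DataFrame(med_rows, columns=MEDIATION_COLUMNS)

    return {
        "step1": step1,
        "mvmr": mv_table,
        "mvmr_diagnostics": mv_diag,
        "mediation": mediation_table,
    }


def _sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(cfg: RunConfig, out_dir, outputs: dict[str, str]) -> str:
    """Write a JSON run manifest recording thresholds, seeds and input hashes."""
    manifest = {
        "package": "mrmediate",
        "version": __version__,
        "seed": cfg.seed,
        "thresholds": {
            "p_threshold": cfg.p_threshold,
            "clump_r2": cfg.clump_r2,
            "clump_kb": cfg.clump_kb,
            "f_min": cfg.f_min,
            "palindromic_eaf_window": cfg.palindromic_eaf_window,
        },
        "estimators": {"ivw_mode": cfg.ivw_mode, "n_boot": cfg.n_boot},
        "sensitivity": {"presso_sims": cfg.presso_sims,
                        "outlier_alpha": cfg.presso_outlier_alpha},
        "mediation_alpha": cfg.mediation_alpha,
        "bidirectional": cfg.bidirectional,
        "inputs": {role: {"path": path, "sha256": _sha256(path)}
                   for role, path in cfg.datasets.items() if Path(path).exists()},
        "outputs": outputs,
    }
    path = Path(out_dir) / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return str(path)
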