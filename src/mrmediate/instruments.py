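"""Instrument selection: significance filtering, greedy LD clumping, F filtering."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .sumstats import SummaryDataset

__all__ = [
    "LDMatrix",
    "InstrumentSet",
    "NoInstrumentsError",
    "genome_wide_filter",
    "ld_clump",
    "f_statistic",
    "select_instruments",
]

DEFAULT_P_THRESHOLD = 5e-8
DEFAULT_CLUMP_R2 = 0.001
DEFAULT_CLUMP_KB = 10_000.0
DEFAULT_F_MIN = 10.0


class NoInstrumentsError(RuntimeError):
    """No variant survives instrument selection; MR cannot proceed."""


@dataclass
class LDMatrix:
    """Pairwise squared-correlation (r^2) matrix over an ordered variant list."""

    variant_ids: list[str]
    r2: np.ndarray

    def __post_init__(self) -> None:
        self.r2 = np.asarray(self.r2, dtype=float)
        n = len(self.variant_ids)
        if self.r2.shape != (n, n):
            raise ValueError(f"r2 matrix shape {self.r2.shape} != ({n}, {n})")
        if not np.allclose(self.r2, self.r2.T, atol=1e-12):
            raise ValueError("r2 matrix must be symmetric")
        if not np.allclose(np.diag(self.r2), 1.0, atol=1e-12):
            raise ValueError("r2 matrix diagonal must be 1")
        if self.r2.size and (self.r2.min() < -1e-12 or self.r2.max() > 1 + 1e-12):
            raise ValueError("r2 values must lie in [0, 1]")
        self._index = {v: i for i, v in enumerate(self.variant_ids)}

    @classmethod
    def identity(cls, variant_ids: Sequence[str]) -> "LDMatrix":
        return cls(list(variant_ids), np.eye(len(variant_ids)))

    def lookup(self, a: str, b: str) -> float:
        """r^2 between two variants; 0 (with a warning) when either is absent."""
        ia = self._index.get(a)
        ib = self._index.get(b)
        if ia is None or ib is None:
            missing = a if ia is None else b
            warnings.warn(f"variant {missing!r} absent from LD matrix; assuming r2=0",
                          stacklevel=2)
            return 0.0
        return float(self.r2[ia, ib])

    @classmethod
    def from_file(cls, path, delimiter: str = "\t") -> "LDMatrix":
        df = pd.read_csv(path, sep=delimiter, index_col=0)
        return cls(list(df.index.astype(str)), df.to_numpy(dtype=float))

    def to_file(self, path, delimiter: str = "\t") -> None:
        pd.DataFrame(self.r2, index=self.variant_ids, columns=self.variant_ids).to_csv(
            path, sep=delimiter
        )


@dataclass
class InstrumentSet:
    """Selected instruments with their F statistics and selection provenance."""

    variant_ids: list[str]
    f_stats: dict[str, float]
    provenance: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.variant_ids)) != len(self.variant_ids):
            raise ValueError("instrument list contains duplicates")

    def __len__(self) -> int:
        return len(self.variant_ids)


def genome_wide_filter(dataset: SummaryDataset, p_threshold: float = DEFAULT_P_THRESHOLD) -> list[str]:
    """Variants with ``pval`` strictly below ``p_threshold``, in dataset order."""
    if not 0 < p_threshold <= 1:
        raise ValueError(f"p_threshold must be in (0, 1], got {p_threshold}")
    hits = [v for v, rec in dataset.records.items() if rec.pval < p_threshold]
    if not hits:
        warnings.warn(
            f"{dataset.trait_label}: no variant passes p < {p_threshold:g}", stacklevel=2
        )
    return hits


def ld_clump(
    candidates: Sequence[str],
    dataset: SummaryDataset,
    ld: LDMatrix | None = None,
    r2_max: float = DEFAULT_CLUMP_R2,
    window_kb: float = DEFAULT_CLUMP_KB,
) -> list[str]:
    """Greedy LD clumping of ``candidates`` by ascending p-value.

    The best remaining variant becomes an index; every remaining variant on
    the same chromosome within ``window_kb`` kilobases with r^2 >= ``r2_max``
    against the index is removed.  Ties on p-value break lexicographically on
    variant_id so the output is independent of input order.  Variants missing
    from the LD matrix are treated as uncorrelated (r^2 = 0).
    """
    if not 0 < r2_max <= 1:
        raise ValueError(f"r2_max must be in (0, 1], got {r2_max}")
    if not window_kb > 0:
        raise ValueError(f"window_kb must be > 0, got {window_kb}")
    if ld is None:
        ld = LDMatrix.identity(list(candidates))

    pool = sorted(set(candidates), key=lambda v: (dataset[v].pval, v))
    selected: list[str] = []
    while pool:
        index = pool.pop(0)
        selected.append(index)
        idx_rec = dataset[index]
        survivors = []
        for v in pool:
            rec = dataset[v]
            same_chrom = (idx_rec.chrom is not None and rec.chrom is not None
                          and idx_rec.chrom == rec.chrom)
            if idx_rec.chrom is None or rec.chrom is None:
                same_chrom = True  # unplaced variants: be conservative
            within = True
            if same_chrom and idx_rec.pos is not None and rec.pos is not None:
                within = abs(idx_rec.pos - rec.pos) <= window_kb * 1000.0
            if same_chrom and within and ld.lookup(index, v) >= r2_max:
                continue
            survivors.append(v)
        pool = survivors
    return selected


def f_statistic(beta, se):
    """Single-variant instrument-strength approximation F = (beta/se)^2."""
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("se must be > 0")
    out = (beta / se) ** 2
    return float(out) if out.ndim == 0 else out


def select_instruments(
    dataset: SummaryDataset,
    ld: LDMatrix | None = None,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    r2_max: float = DEFAULT_CLUMP_R2,
    window_kb: float = DEFAULT_CLUMP_KB,
    f_min: float = DEFAULT_F_MIN,
) -> InstrumentSet:
    """Compose significance filter -> LD clump -> weak-instrument filter.

    The order is part of the contract: the F filter runs after clumping, so a
    weak index variant can still shadow stronger neighbours.  Raises
    :class:`NoInstrumentsError` when nothing survives.
    """
    hits = genome_wide_filter(dataset, p_threshold)
    clumped = ld_clump(hits, dataset, ld, r2_max, window_kb)
    kept = []
    f_stats = {}
    for v in clumped:
        rec = dataset[v]
        f = f_statistic(rec.beta, rec.se)
        if f > f_min:
            kept.append(v)
            f_stats[v] = f
    if not kept:
        raise NoInstrumentsError(
            f"{dataset.trait_label}: no instrument survives selection "
            f"(p<{p_threshold:g}, r2<{r2_max:g}, {window_kb:g} kb, F>{f_min:g})"
        )
    return InstrumentSet(
        variant_ids=kept,
        f_stats=f_stats,
        provenance={
            "p_threshold": p_threshold,
            "r2_max": r2_max,
            "window_kb": window_kb,
            "f_min": f_min,
        },
    )
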