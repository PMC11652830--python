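"""GWAS summary-statistics I/O, allele harmonisation and scale conversion.

Summary statistics are tab- or comma-delimited text with a header row, one
record per variant.  The canonical column names are ``variant_id``, ``chrom``,
``pos``, ``effect_allele``, ``other_allele``, ``eaf``, ``beta``, ``se``,
``pval`` and ``n``; a ``column_map`` translates other layouts onto these.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "VariantAssociation",
    "SummaryDataset",
    "HarmonisedSet",
    "OddsRatio",
    "MissingColumnError",
    "read_sumstats",
    "write_sumstats",
    "harmonise",
    "beta_to_or",
]

VALID_ALLELES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: canonical field -> source column, identity by default
MANDATORY_FIELDS = ("variant_id", "effect_allele", "other_allele", "beta", "se", "pval")
OPTIONAL_FIELDS = ("chrom", "pos", "eaf", "n")

Z_95 = 1.959964  # two-sided 95% normal critical value


class MissingColumnError(ValueError):
    """A mandatory summary-statistics column is absent from the input."""


@dataclass(frozen=True)
class VariantAssociation:
    """One variant's association record for a single trait."""

    variant_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pval: float
    chrom: str | None = None
    pos: int | None = None
    eaf: float | None = None
    n: int | None = None

    def __post_init__(self) -> None:
        if self.effect_allele not in VALID_ALLELES or self.other_allele not in VALID_ALLELES:
            raise ValueError(
                f"{self.variant_id}: alleles must be single bases in ACGT, "
                f"got {self.effect_allele}/{self.other_allele}"
            )
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.variant_id}: effect and other allele are identical")
        if not self.se > 0:
            raise ValueError(f"{self.variant_id}: se must be > 0, got {self.se}")
        if not (0 < self.pval <= 1):
            raise ValueError(f"{self.variant_id}: pval must be in (0, 1], got {self.pval}")
        if self.eaf is not None and not (0 <= self.eaf <= 1):
            raise ValueError(f"{self.variant_id}: eaf must be in [0, 1], got {self.eaf}")

    @property
    def is_palindromic(self) -> bool:
        """True for A/T and C/G variants, whose strand is unresolvable from alleles."""
        return self.other_allele == _COMPLEMENT[self.effect_allele]


@dataclass
class SummaryDataset:
    """Summary statistics for one trait, keyed by variant identifier."""

    trait_label: str
    records: dict[str, VariantAssociation] = field(default_factory=dict)
    n_dropped: int = 0  # unparseable data lines discarded at read time

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self.records

    def __getitem__(self, variant_id: str) -> VariantAssociation:
        return self.records[variant_id]

    def variant_ids(self) -> list[str]:
        return list(self.records)

    def add(self, rec: VariantAssociation) -> None:
        if rec.variant_id in self.records:
            raise ValueError(f"duplicate variant_id {rec.variant_id!r} in {self.trait_label!r}")
        self.records[rec.variant_id] = rec

    def to_frame(self) -> pd.DataFrame:
        cols = MANDATORY_FIELDS + OPTIONAL_FIELDS
        rows = [{c: getattr(r, c) for c in cols} for r in self.records.values()]
        return pd.DataFrame(rows, columns=list(cols))


@dataclass
class HarmonisedSet:
    """Instruments with exposure and outcome effects aligned to one effect allele.

    ``bx``/``sx`` have shape ``(n_snp, n_exposures)``; ``by``/``sy`` have shape
    ``(n_snp,)``.  ``dropped`` records instruments that could not be aligned,
    as ``(variant_id, reason)`` pairs.
    """

    exposure_labels: list[str]
    outcome_label: str
    variant_ids: list[str]
    bx: np.ndarray
    sx: np.ndarray
    by: np.ndarray
    sy: np.ndarray
    effect_alleles: list[str]
    other_alleles: list[str]
    dropped: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.bx = np.atleast_2d(np.asarray(self.bx, dtype=float))
        self.sx = np.atleast_2d(np.asarray(self.sx, dtype=float))
        if self.bx.shape[0] == 1 and len(self.variant_ids) != 1:
            self.bx = self.bx.T
            self.sx = self.sx.T
        self.by = np.asarray(self.by, dtype=float)
        self.sy = np.asarray(self.sy, dtype=float)
        n = len(self.variant_ids)
        if self.bx.shape != (n, len(self.exposure_labels)):
            raise ValueError(f"bx shape {self.bx.shape} inconsistent with "
                             f"{n} variants x {len(self.exposure_labels)} exposures")
        kept = set(self.variant_ids)
        for vid, _ in self.dropped:
            if vid in kept:
                raise ValueError(f"variant {vid!r} both kept and dropped")

    @property
    def n_snp(self) -> int:
        return len(self.variant_ids)

    @property
    def n_exposures(self) -> int:
        return len(self.exposure_labels)

    def subset(self, index: Sequence[int] | np.ndarray) -> "HarmonisedSet":
        """Return a new set restricted to the given row positions."""
        idx = np.asarray(index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return HarmonisedSet(
            exposure_labels=list(self.exposure_labels),
            outcome_label=self.outcome_label,
            variant_ids=[self.variant_ids[i] for i in idx],
            bx=self.bx[idx],
            sx=self.sx[idx],
            by=self.by[idx],
            sy=self.sy[idx],
            effect_alleles=[self.effect_alleles[i] for i in idx],
            other_alleles=[self.other_alleles[i] for i in idx],
            dropped=[],
        )

    def oriented(self, exposure_index: int = 0) -> "HarmonisedSet":
        """Copy with rows flipped so the chosen exposure's beta is >= 0.

        Flipping a row negates every trait's beta for that variant and swaps
        the row's allele labels, which is the standard reorientation required
        before fitting an intercept model.
        """
        flip = self.bx[:, exposure_index] < 0
        sign = np.where(flip, -1.0, 1.0)
        ea = [o if f else e for e, o, f in zip(self.effect_alleles, self.other_alleles, flip)]
        oa = [e if f else o for e, o, f in zip(self.effect_alleles, self.other_alleles, flip)]
        return HarmonisedSet(
            exposure_labels=list(self.exposure_labels),
            outcome_label=self.outcome_label,
            variant_ids=list(self.variant_ids),
            bx=self.bx * sign[:, None],
            sx=self.sx.copy(),
            by=self.by * sign,
            sy=self.sy.copy(),
            effect_alleles=ea,
            other_alleles=oa,
            dropped=list(self.dropped),
        )

    def to_frame(self) -> pd.DataFrame:
        data: dict[str, object] = {"variant_id": self.variant_ids,
                                   "effect_allele": self.effect_alleles,
                                   "other_allele": self.other_alleles}
        for j, lab in enumerate(self.exposure_labels):
            data[f"beta.{lab}"] = self.bx[:, j]
            data[f"se.{lab}"] = self.sx[:, j]
        data[f"beta.{self.outcome_label}"] = self.by
        data[f"se.{self.outcome_label}"] = self.sy
        return pd.DataFrame(data)

    def dropped_report(self) -> pd.DataFrame:
        return pd.DataFrame(self.dropped, columns=["variant_id", "reason"])


def _resolve_columns(header: Iterable[str], column_map: dict[str, str] | None) -> dict[str, str]:
    header = list(header)
    cmap = dict(column_map or {})
    resolved: dict[str, str] = {}
    for fld in MANDATORY_FIELDS + OPTIONAL_FIELDS:
        src = cmap.get(fld, fld)
        if src in header:
            resolved[fld] = src
        elif fld in MANDATORY_FIELDS:
            raise MissingColumnError(
                f"mandatory column {fld!r} (source name {src!r}) not found in header {header}"
            )
    return resolved


def read_sumstats(
    path,
    column_map: dict[str, str] | None = None,
    trait_label: str | None = None,
    delimiter: str | None = None,
) -> SummaryDataset:
    """Read a delimited summary-statistics file into a :class:`SummaryDataset`.

    Parameters
    ----------
    path : path-like
        Tab- or comma-delimited file with a header row.
    column_map : dict, optional
        Maps canonical field names to the file's column names for files that
        do not use the canonical layout.
    trait_label : str, optional
        Label for the dataset; defaults to the file stem.
    delimiter : str, optional
        Explicit delimiter; sniffed from the header line when omitted.

    Lines whose beta, se or pval cannot be parsed (or violate their domain)
    are dropped and counted in ``SummaryDataset.n_dropped``.
    """
    path = str(path)
    if delimiter is None:
        with open(path) as fh:
            first = fh.readline()
        delimiter = "\t" if first.count("\t") >= first.count(",") else ","
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    cols = _resolve_columns(df.columns, column_map)

    label = trait_label
    if label is None:
        import os
        label = os.path.splitext(os.path.basename(path))[0]

    ds = SummaryDataset(trait_label=label)
    n_drop = 0
    for _, row in df.iterrows():
        try:
            kwargs: dict[str, object] = {
                "variant_id": row[cols["variant_id"]],
                "effect_allele": str(row[cols["effect_allele"]]).upper(),
                "other_allele": str(row[cols["other_allele"]]).upper(),
                "beta": float(row[cols["beta"]]),
                "se": float(row[cols["se"]]),
                "pval": float(row[cols["pval"]]),
            }
            if "chrom" in cols and row[cols["chrom"]] != "":
                kwargs["chrom"] = str(row[cols["chrom"]])
            if "pos" in cols and row[cols["pos"]] != "":
                kwargs["pos"] = int(float(row[cols["pos"]]))
            if "eaf" in cols and row[cols["eaf"]] not in ("", "NA"):
                kwargs["eaf"] = float(row[cols["eaf"]])
            if "n" in cols and row[cols["n"]] not in ("", "NA"):
                kwargs["n"] = int(float(row[cols["n"]]))
            rec = VariantAssociation(**kwargs)  # type: ignore[arg-type]
        except (ValueError, TypeError):
            n_drop += 1
            continue
        ds.add(rec)
    ds.n_dropped = n_drop
    if n_drop:
        warnings.warn(f"{path}: dropped {n_drop} unparseable line(s)", stacklevel=2)
    return ds


def write_sumstats(dataset: SummaryDataset, path, delimiter: str = "\t") -> None:
    """Write a dataset in the canonical delimited layout (lossless round trip)."""
    df = dataset.to_frame()
    df.to_csv(path, sep=delimiter, index=False, na_rep="")


def _align_record(
    ref: VariantAssociation, rec: VariantAssociation
) -> tuple[float, float | None] | None:
    """Align ``rec`` onto ``ref``'s effect allele.

    Returns ``(signed beta, aligned eaf)`` or None when the alleles are
    irreconcilable even after strand complementation.
    """
    ea, oa = rec.effect_allele, rec.other_allele
    for flip_strand in (False, True):
        if flip_strand:
            ea, oa = _COMPLEMENT[ea], _COMPLEMENT[oa]
        if (ea, oa) == (ref.effect_allele, ref.other_allele):
            return rec.beta, rec.eaf
        if (ea, oa) == (ref.other_allele, ref.effect_allele):
            return -rec.beta, None if rec.eaf is None else 1.0 - rec.eaf
    return None


def harmonise(
    exposures: SummaryDataset | Sequence[SummaryDataset],
    outcome: SummaryDataset,
    instrument_ids: Sequence[str] | None = None,
    palindromic_eaf_window: float = 0.08,
) -> HarmonisedSet:
    """Align instrument effects across datasets onto a shared effect allele.

    The first exposure dataset defines the reference allele per variant.  For
    every other dataset the record is kept as-is when the alleles match,
    sign-flipped when effect/other are swapped, and mapped through the
    A<->T / C<->G complement first when the datasets are on opposite strands.

    Palindromic variants (A/T or C/G) are dropped when any dataset's effect
    allele frequency lies within ``palindromic_eaf_window`` of 0.5 or is
    missing; otherwise allele-frequency concordance resolves their strand.
    Variants absent from any dataset are dropped with reason ``"missing"``;
    irreconcilable alleles with reason ``"allele_mismatch"``.
    """
    if isinstance(exposures, SummaryDataset):
        exposures = [exposures]
    exposures = list(exposures)
    if not exposures:
        raise ValueError("at least one exposure dataset required")
    if not 0 <= palindromic_eaf_window <= 0.5:
        raise ValueError("palindromic_eaf_window must be in [0, 0.5]")
    if instrument_ids is None:
        instrument_ids = exposures[0].variant_ids()

    kept_ids: list[str] = []
    bx_rows: list[list[float]] = []
    sx_rows: list[list[float]] = []
    by_l: list[float] = []
    sy_l: list[float] = []
    ea_l: list[str] = []
    oa_l: list[str] = []
    dropped: list[tuple[str, str]] = []

    for vid in instrument_ids:
        if any(vid not in ds for ds in exposures) or vid not in outcome:
            dropped.append((vid, "missing"))
            continue
        ref = exposures[0][vid]
        others = [ds[vid] for ds in exposures[1:]] + [outcome[vid]]

        if ref.is_palindromic:
            eafs = [ref.eaf] + [r.eaf for r in others]
            if any(e is None for e in eafs):
                dropped.append((vid, "palindromic_ambiguous"))
                continue
            if any(abs(e - 0.5) <= palindromic_eaf_window for e in eafs):  # type: ignore[arg-type]
                dropped.append((vid, "palindromic_ambiguous"))
                continue

        betas: list[float] = [ref.beta]
        aligned_ok = True
        for rec in others:
            aligned = _align_record(ref, rec)
            if aligned is None:
                dropped.append((vid, "allele_mismatch"))
                aligned_ok = False
                break
            beta, eaf = aligned
            # palindromic alleles carry no strand signal; trust frequency
            # concordance instead of the nominal match
            if ref.is_palindromic and eaf is not None and ref.eaf is not None:
                if (eaf - 0.5) * (ref.eaf - 0.5) < 0:
                    beta = -beta
            betas.append(beta)
        if not aligned_ok:
            continue

        kept_ids.append(vid)
        bx_rows.append([betas[0]] + betas[1:-1])
        sx_rows.append([ref.se] + [r.se for r in others[:-1]])
        by_l.append(betas[-1])
        sy_l.append(others[-1].se)
        ea_l.append(ref.effect_allele)
        oa_l.append(ref.other_allele)

    k = len(exposures)
    return HarmonisedSet(
        exposure_labels=[ds.trait_label for ds in exposures],
        outcome_label=outcome.trait_label,
        variant_ids=kept_ids,
        bx=np.asarray(bx_rows, dtype=float).reshape(len(kept_ids), k),
        sx=np.asarray(sx_rows, dtype=float).reshape(len(kept_ids), k),
        by=np.asarray(by_l, dtype=float),
        sy=np.asarray(sy_l, dtype=float),
        effect_alleles=ea_l,
        other_alleles=oa_l,
        dropped=dropped,
    )


class OddsRatio(NamedTuple):
    odds_ratio: float
    ci_low: float
    ci_high: float


def beta_to_or(beta: float, se: float, z: float = Z_95) -> OddsRatio:
    """Convert a log-odds effect and its standard error to an OR with CI."""
    if not se >= 0:
        raise ValueError(f"se must be >= 0, got {se}")
    return OddsRatio(math.exp(beta), math.exp(beta - z * se), math.exp(beta + z * se))
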