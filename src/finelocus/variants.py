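"""Variant data model, delimited-table I/O, and sequencing QC filters.

The central table format mirrors a published per-variant summary: one row per
variant with genomic coordinates (1-based, hg19 labels carried as opaque
strings), REF/ALT alleles, gene region, optional protein change, and one
column per cohort holding allele counts.  Count cells are written as
``k/N`` and may additionally carry a printed percentage, ``k/N (pct)``;
percentages in inputs are never trusted — allele frequencies are always
recomputed as ``alt_count / total_alleles`` with the denominator equal to
2 x the number of diploid individuals.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import pandas as pd

from .exceptions import QCError, TableParseError

__all__ = [
    "AlleleCount",
    "VariantRecord",
    "TableDialect",
    "read_variant_table",
    "write_variant_table",
    "qc_filter_sequencing",
]

#: Valid gene-region labels, 5' to 3'.
REGIONS = ("promoter", "utr5", "exon", "intron", "utr3", "downstream")


@dataclass(frozen=True)
class AlleleCount:
    """Alternative-allele count out of a total number of chromosomes.

    ``total_alleles`` is 2 x the number of diploid individuals in the cohort.
    """

    alt_count: int
    total_alleles: int

    def __post_init__(self) -> None:
        if self.total_alleles <= 0:
            raise ValueError("total_alleles must be > 0")
        if not 0 <= self.alt_count <= self.total_alleles:
            raise ValueError(
                f"alt_count {self.alt_count} outside [0, {self.total_alleles}]"
            )

    @property
    def frequency(self) -> float:
        """Alternative-allele frequency in [0, 1]."""
        return self.alt_count / self.total_alleles

    @property
    def percent(self) -> float:
        """Alternative-allele frequency as a percentage."""
        return 100.0 * self.frequency

    @property
    def minor_frequency(self) -> float:
        """Folded (minor) allele frequency, <= 0.5."""
        f = self.frequency
        return min(f, 1.0 - f)


@dataclass
class VariantRecord:
    """One sequenced variant with per-cohort allele counts.

    ``counts`` maps canonical cohort names (e.g. ``cases``, ``g1000_eur``,
    ``nhlbi_ea``) to :class:`AlleleCount`.  ``extras`` holds non-count columns
    preserved verbatim from the source table (e.g. a published composite
    functionality score, kept as documentation only).
    """

    variant_id: str
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    region: str
    protein_change: str | None = None
    counts: dict[str, AlleleCount] = field(default_factory=dict)
    qual: float | None = None
    depth: int | None = None
    is_indel: bool = False
    extras: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos <= 0:
            raise ValueError(f"{self.variant_id}: pos must be positive (1-based)")
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"{self.variant_id}: ref and alt alleles are identical")
        if self.region not in REGIONS:
            raise ValueError(
                f"{self.variant_id}: unknown region {self.region!r}; "
                f"expected one of {REGIONS}"
            )
        if self.protein_change and self.region != "exon":
            raise ValueError(
                f"{self.variant_id}: protein_change requires region 'exon'"
            )

    @property
    def is_missense(self) -> bool:
        return self.region == "exon" and bool(self.protein_change)

    def frequency(self, cohort: str) -> float:
        return self.counts[cohort].frequency


# Cohort-name aliases accepted in table headers, mapped to canonical names.
COHORT_ALIASES: dict[str, str] = {
    "cases": "cases",
    "case": "cases",
    "g1000": "g1000_eur",
    "g1000_eur": "g1000_eur",
    "1000g": "g1000_eur",
    "1000g_eur": "g1000_eur",
    "nhlbi": "nhlbi_ea",
    "nhlbi_ea": "nhlbi_ea",
    "gwas_cases": "gwas_cases",
    "gwas_controls": "gwas_controls",
    "controls": "controls",
    "control": "controls",
}

_RESERVED = {
    "variant_id",
    "chrom",
    "pos",
    "ref",
    "alt",
    "ref_allele",
    "alt_allele",
    "region",
    "protein_change",
    "qual",
    "depth",
    "indel",
    "is_indel",
}

# "k/N (pct)" | "k/N" | "k (pct)" | "k"
_COUNT_CELL = re.compile(
    r"^\s*(?P<k>\d+)\s*(?:/\s*(?P<n>\d+))?\s*(?:\(\s*(?P<pct>[0-9.eE+\-]+)\s*\))?\s*$"
)
_MISSING_TOKENS = {"", "-", "--", "—", "na", "n/a", "."}
# optional default denominator in a cohort header, e.g. "nhlbi_ea[8600]"
_HEADER_DENOM = re.compile(r"^(?P<name>[^\[\]]+?)\s*\[\s*(?P<n>\d+)\s*\]$")


@dataclass(frozen=True)
class TableDialect:
    """Dialect of a variant count table: delimiter and cohort-name aliases."""

    sep: str = "\t"
    cohort_aliases: dict[str, str] = field(default_factory=lambda: dict(COHORT_ALIASES))


def _parse_count_cell(
    cell: object, default_denom: int | None, row: str, col: str
) -> AlleleCount | None:
    text = "" if cell is None or (isinstance(cell, float) and pd.isna(cell)) else str(cell)
    if text.strip().lower() in _MISSING_TOKENS:
        return None
    m = _COUNT_CELL.match(text)
    if m is None:
        raise TableParseError(
            f"malformed allele-count cell {text!r} at row {row!r}, column {col!r}"
        )
    k = int(m.group("k"))
    n = int(m.group("n")) if m.group("n") else default_denom
    if n is None:
        raise TableParseError(
            f"count cell {text!r} at row {row!r}, column {col!r} has no denominator "
            f"and the column header declares no default (use 'name[N]')"
        )
    try:
        return AlleleCount(k, n)
    except ValueError as exc:
        raise TableParseError(f"row {row!r}, column {col!r}: {exc}") from exc


def read_variant_table(path, dialect: TableDialect | None = None) -> list[VariantRecord]:
    """Read a delimited variant count table into :class:`VariantRecord` rows.

    Required columns: ``variant_id``, ``chrom``, ``pos``, ``ref``, ``alt``,
    ``region``.  Optional: ``protein_change``, ``qual``, ``depth``, ``indel``.
    Every other column is treated as a cohort count column if its non-empty
    cells parse as count cells, otherwise it is preserved in ``extras``.
    Percentages inside count cells are ignored (recomputed downstream).
    """
    dialect = dialect or TableDialect()
    df = pd.read_csv(path, sep=dialect.sep, dtype=str, keep_default_na=False)
    df.columns = [c.strip() for c in df.columns]
    required = {"variant_id", "chrom", "pos", "ref", "alt", "region"}
    missing = required - set(df.columns)
    if missing:
        raise TableParseError(f"missing required columns: {sorted(missing)}")

    # classify non-reserved columns as cohort (count cells) or extra
    cohort_cols: dict[str, tuple[str, int | None]] = {}  # raw col -> (canonical, denom)
    extra_cols: list[str] = []
    for col in df.columns:
        if col in _RESERVED:
            continue
        raw = col
        denom = None
        m = _HEADER_DENOM.match(col)
        if m:
            raw, denom = m.group("name").strip(), int(m.group("n"))
        canonical = dialect.cohort_aliases.get(raw.lower(), raw)
        nonblank = [
            v for v in df[col] if str(v).strip().lower() not in _MISSING_TOKENS
        ]
        # A known cohort alias is always a count column (malformed cells
        # there are errors).  An unknown column is a cohort column only if
        # it looks like counts AND carries a denominator somewhere (k/N
        # cells or a name[N] header) — this keeps bare-integer annotation
        # columns out of the counts.
        if raw.lower() in dialect.cohort_aliases:
            cohort_cols[col] = (canonical, denom)
            continue
        looks_counts = bool(nonblank) and all(
            _COUNT_CELL.match(str(v)) for v in nonblank
        )
        has_denom = denom is not None or any("/" in str(v) for v in nonblank)
        if looks_counts and has_denom:
            cohort_cols[col] = (canonical, denom)
        else:
            extra_cols.append(col)

    records: list[VariantRecord] = []
    seen: set[str] = set()
    for _, r in df.iterrows():
        vid = str(r["variant_id"]).strip()
        if vid in seen:
            raise TableParseError(f"duplicate variant_id {vid!r}")
        seen.add(vid)
        counts: dict[str, AlleleCount] = {}
        for col, (canonical, denom) in cohort_cols.items():
            ac = _parse_count_cell(r[col], denom, vid, col)
            if ac is not None:
                counts[canonical] = ac
        pc = str(r.get("protein_change", "")).strip() or None
        qual = r.get("qual", "")
        depth = r.get("depth", "")
        indel = str(r.get("indel", "")).strip().lower()
        records.append(
            VariantRecord(
                variant_id=vid,
                chrom=str(r["chrom"]).strip(),
                pos=int(str(r["pos"]).replace(" ", "")),
                ref_allele=str(r["ref"]).strip(),
                alt_allele=str(r["alt"]).strip(),
                region=str(r["region"]).strip(),
                protein_change=pc,
                counts=counts,
                qual=float(qual) if str(qual).strip() else None,
                depth=int(float(depth)) if str(depth).strip() else None,
                is_indel=indel in {"1", "true", "yes"},
                extras={c: str(r[c]) for c in extra_cols},
            )
        )
    return records


def write_variant_table(variants: list[VariantRecord], path, sep: str = "\t") -> None:
    """Write records back to a delimited table; counts round-trip exactly."""
    cohorts: list[str] = []
    extras: list[str] = []
    for v in variants:
        for c in v.counts:
            if c not in cohorts:
                cohorts.append(c)
        for e in v.extras:
            if e not in extras:
                extras.append(e)
    rows = []
    for v in variants:
        row: dict[str, object] = {
            "variant_id": v.variant_id,
            "chrom": v.chrom,
            "pos": v.pos,
            "ref": v.ref_allele,
            "alt": v.alt_allele,
            "region": v.region,
            "protein_change": v.protein_change or "",
            "qual": "" if v.qual is None else v.qual,
            "depth": "" if v.depth is None else v.depth,
            "indel": int(v.is_indel),
        }
        for c in cohorts:
            ac = v.counts.get(c)
            row[c] = "" if ac is None else f"{ac.alt_count}/{ac.total_alleles}"
        for e in extras:
            row[e] = v.extras.get(e, "")
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)


def qc_filter_sequencing(
    variants: list[VariantRecord],
    min_qual: float = 20.0,
    min_depth: int = 5,
    drop_indels: bool = True,
) -> list[VariantRecord]:
    """Sequencing-stage QC: drop low-quality sites, low-coverage sites, indels.

    Exclusion thresholds are strict 'less than' rules — a site with
    qual == min_qual or depth == min_depth passes.  Records missing ``qual``
    or ``depth`` while the corresponding filter is active raise
    :class:`~finelocus.exceptions.QCError` rather than passing silently.
    The filter is idempotent.
    """
    kept: list[VariantRecord] = []
    for v in variants:
        if drop_indels and v.is_indel:
            continue
        if min_qual is not None:
            if v.qual is None:
                raise QCError(f"{v.variant_id}: qual missing but min_qual filter active")
            if v.qual < min_qual:
                continue
        if min_depth is not None:
            if v.depth is None:
                raise QCError(f"{v.variant_id}: depth missing but min_depth filter active")
            if v.depth < min_depth:
                continue
        kept.append(v)
    return kept


def copy_record(v: VariantRecord, **changes) -> VariantRecord:
    """Shallow copy of a record with field overrides."""
    return replace(v, **changes)
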