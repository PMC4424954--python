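"""Rare-variant collapsing (burden) analysis.

Variants with folded minor-allele frequency below a threshold in cases
and/or in a chosen control panel are pooled into a single case/control
comparison tested with Fisher's exact test.  Two pooling units are offered:

``allele``
    pooled alt-allele counts over 2 x individuals chromosomes;
``carrier`` (default)
    each pooled alt allele counts one carrier individual over the individual
    denominator — exact when no individual carries two rare alleles, and the
    unit under which published rare-variant odds ratios for this locus are
    reproduced from printed counts.

Variants absent from the control panel contribute 0 alt alleles over the
full panel denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

from .association import (
    AssociationResult,
    ContingencyTable2x2,
    fisher_exact,
)
from .variants import AlleleCount, VariantRecord

__all__ = ["BurdenSpec", "BurdenResult", "select_rare", "pool_burden"]


def missense_only(v: VariantRecord) -> bool:
    return v.is_missense


def all_variants(v: VariantRecord) -> bool:
    return True


@dataclass
class BurdenSpec:
    """Configuration of the collapsing test.

    ``maf_threshold`` is a folded minor-allele frequency; a variant
    qualifies when its MAF is strictly below the threshold in cases OR in
    the chosen control panel.
    """

    maf_threshold: float = 0.01
    unit: str = "carrier"  # or "allele"
    variant_filter: Callable[[VariantRecord], bool] = field(default=all_variants)

    def __post_init__(self) -> None:
        if not 0.0 <= self.maf_threshold < 0.5:
            raise ValueError("maf_threshold must lie in [0, 0.5)")
        if self.unit not in {"allele", "carrier"}:
            raise ValueError(f"unknown pooling unit {self.unit!r}")


@dataclass
class BurdenResult:
    pooled_table: ContingencyTable2x2
    included_variants: list[str]
    result: AssociationResult
    unit: str


def _maf(ac: AlleleCount | None) -> float | None:
    return None if ac is None else ac.minor_frequency


def select_rare(
    variants: list[VariantRecord],
    spec: BurdenSpec,
    control_cohort: str,
    case_cohort: str = "cases",
) -> list[VariantRecord]:
    """Variants passing the filter with MAF < threshold in cases and/or controls.

    Strict inequality.  A variant with no recorded count for the control
    cohort is treated as unobserved there (frequency 0), hence rare.
    """
    out = []
    for v in variants:
        if not spec.variant_filter(v):
            continue
        maf_case = _maf(v.counts.get(case_cohort))
        maf_ctrl = _maf(v.counts.get(control_cohort))
        if maf_ctrl is None:
            maf_ctrl = 0.0
        qualifies = (maf_case is not None and maf_case < spec.maf_threshold) or (
            maf_ctrl < spec.maf_threshold
        )
        if qualifies:
            out.append(v)
    return out


def pool_burden(
    variants: list[VariantRecord],
    spec: BurdenSpec,
    n_case_individuals: int,
    n_control_individuals: int,
    control_cohort: str,
    case_cohort: str = "cases",
    preselected: bool = False,
) -> BurdenResult:
    """Pool rare alt alleles across variants and test the collapsed 2x2.

    Unless ``preselected``, :func:`select_rare` is applied first.  In the
    carrier unit, pooled alt-allele totals are interpreted as carrier
    individuals (valid while no individual carries two rare alleles); a
    carrier total exceeding the individual count raises ValueError.
    """
    if not preselected:
        variants = select_rare(variants, spec, control_cohort, case_cohort=case_cohort)
    case_alt = sum(
        v.counts[case_cohort].alt_count for v in variants if case_cohort in v.counts
    )
    ctrl_alt = sum(
        v.counts[control_cohort].alt_count
        for v in variants
        if control_cohort in v.counts
    )
    if spec.unit == "allele":
        table = ContingencyTable2x2(
            a=case_alt,
            b=2 * n_case_individuals - case_alt,
            c=ctrl_alt,
            d=2 * n_control_individuals - ctrl_alt,
        )
    else:  # carrier
        if case_alt > n_case_individuals:
            raise ValueError(
                f"pooled case carrier count {case_alt} exceeds "
                f"{n_case_individuals} case individuals"
            )
        if ctrl_alt > n_control_individuals:
            raise ValueError(
                f"pooled control carrier count {ctrl_alt} exceeds "
                f"{n_control_individuals} control individuals"
            )
        table = ContingencyTable2x2(
            a=case_alt,
            b=n_case_individuals - case_alt,
            c=ctrl_alt,
            d=n_control_individuals - ctrl_alt,
        )
    return BurdenResult(
        pooled_table=table,
        included_variants=[v.variant_id for v in variants],
        result=fisher_exact(table),
        unit=spec.unit,
    )
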