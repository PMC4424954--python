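"""Genotype/dosage matrices: VCF-subset and dosage-matrix readers, imputation QC.

A :class:`GenotypeMatrix` is an individuals x variants matrix of alternative-
allele dosages.  Hard-called genotypes are exactly 0/1/2; imputed dosages are
fractional in [0, 2].  Missing genotypes are stored as NaN and excluded
pairwise from downstream counts — they are never imputed internally.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import TableParseError
from .variants import AlleleCount, VariantRecord

__all__ = [
    "GenotypeMatrix",
    "read_genotypes",
    "write_dosage_matrix",
    "qc_filter_imputation",
    "genotypes_to_variant_records",
]

CASE = "case"
CONTROL = "control"


@dataclass
class GenotypeMatrix:
    """Samples x variants dosage matrix with optional phenotype labels.

    Attributes
    ----------
    sample_ids, variant_ids
        Row and column labels.
    dosages
        float array of shape (n_samples, n_variants); NaN marks missing.
    phenotype
        optional array of ``"case"`` / ``"control"`` labels per sample.
    impute_quality
        optional per-variant estimated imputed-vs-true correlation r^2.
    """

    sample_ids: list[str]
    variant_ids: list[str]
    dosages: np.ndarray
    phenotype: np.ndarray | None = None
    impute_quality: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.sample_ids), len(self.variant_ids)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.variant_ids)} variants"
            )
        finite = self.dosages[np.isfinite(self.dosages)]
        if finite.size and (finite.min() < 0 or finite.max() > 2):
            raise ValueError("dosages must lie in [0, 2]")
        if self.phenotype is not None:
            self.phenotype = np.asarray(self.phenotype, dtype=object)
            if self.phenotype.shape[0] != len(self.sample_ids):
                raise ValueError("phenotype length must equal number of samples")
            bad = set(self.phenotype) - {CASE, CONTROL}
            if bad:
                raise ValueError(f"unknown phenotype labels: {sorted(bad)}")
        if self.impute_quality is not None:
            self.impute_quality = np.asarray(self.impute_quality, dtype=float)
            if self.impute_quality.shape[0] != len(self.variant_ids):
                raise ValueError("impute_quality length must equal number of variants")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variant_ids)

    def column(self, variant_id: str) -> np.ndarray:
        try:
            j = self.variant_ids.index(variant_id)
        except ValueError:
            raise KeyError(f"variant {variant_id!r} not in matrix") from None
        return self.dosages[:, j]

    def maf(self) -> np.ndarray:
        """Per-variant folded minor-allele frequency from mean dosage / 2."""
        with np.errstate(invalid="ignore"):
            af = np.nanmean(self.dosages, axis=0) / 2.0
        return np.minimum(af, 1.0 - af)

    def is_case(self) -> np.ndarray:
        if self.phenotype is None:
            raise ValueError("GenotypeMatrix has no phenotype labels")
        return np.asarray([p == CASE for p in self.phenotype])

    def subset_samples(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask, dtype=bool)
        return GenotypeMatrix(
            sample_ids=[s for s, m in zip(self.sample_ids, mask) if m],
            variant_ids=list(self.variant_ids),
            dosages=self.dosages[mask].copy(),
            phenotype=None if self.phenotype is None else self.phenotype[mask].copy(),
            impute_quality=None
            if self.impute_quality is None
            else self.impute_quality.copy(),
        )

    def subset_variants(self, variant_ids: list[str]) -> "GenotypeMatrix":
        idx = [self.variant_ids.index(v) for v in variant_ids]
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            variant_ids=list(variant_ids),
            dosages=self.dosages[:, idx].copy(),
            phenotype=None if self.phenotype is None else self.phenotype.copy(),
            impute_quality=None
            if self.impute_quality is None
            else self.impute_quality[idx].copy(),
        )


def _read_vcf_subset(path, pheno_path=None) -> GenotypeMatrix:
    # cyvcf2 is an optional dependency; imported lazily so the rest of the
    # package works without it.
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    variant_ids: list[str] = []
    rows: list[np.ndarray] = []
    for var in vcf:
        vid = var.ID or f"{var.CHROM}:{var.POS}:{var.REF}:{var.ALT[0] if var.ALT else '.'}"
        dos = np.full(len(samples), np.nan)
        for i, gt in enumerate(var.genotypes):
            # cyvcf2 genotype entry: [allele_0, ..., phased]; diploid => length 3
            alleles = gt[:-1]
            if len(alleles) != 2:
                raise TableParseError(
                    f"{vid}: non-diploid genotype for sample {samples[i]!r}"
                )
            if any(a < 0 for a in alleles):
                continue  # missing -> NaN
            dos[i] = float(sum(1 for a in alleles if a > 0))
        variant_ids.append(vid)
        rows.append(dos)
    dosages = (
        np.column_stack(rows) if rows else np.empty((len(samples), 0))
    )
    phenotype = None
    if pheno_path is not None:
        ph = pd.read_csv(pheno_path, sep="\t", dtype=str)
        mapping = dict(zip(ph.iloc[:, 0], ph.iloc[:, 1]))
        phenotype = np.array([mapping[s] for s in samples], dtype=object)
    return GenotypeMatrix(samples, variant_ids, dosages, phenotype=phenotype)


def _read_dosage_matrix(path) -> GenotypeMatrix:
    with open(path, "rt", encoding="utf-8") as fh:
        text = fh.read()
    lines = text.splitlines()
    rsq = None
    if lines and lines[0].startswith("#RSQ"):
        fields = lines[0].split("\t")[2:]  # skip '#RSQ' and phenotype placeholder
        rsq = np.array([float(x) for x in fields])
        lines = lines[1:]
    df = pd.read_csv(io.StringIO("\n".join(lines)), sep="\t", dtype=str)
    if df.columns[0] != "sample_id":
        raise TableParseError("dosage matrix must start with a 'sample_id' column")
    has_pheno = len(df.columns) > 1 and df.columns[1] == "phenotype"
    first_var = 2 if has_pheno else 1
    variant_ids = list(df.columns[first_var:])
    sample_ids = list(df["sample_id"])
    raw = df.iloc[:, first_var:].replace({"": np.nan, "NA": np.nan, ".": np.nan})
    dosages = raw.to_numpy(dtype=float)
    finite = dosages[np.isfinite(dosages)]
    if finite.size and (finite.min() < 0 or finite.max() > 2):
        raise TableParseError("dosage outside [0, 2] in dosage matrix")
    phenotype = df["phenotype"].to_numpy(dtype=object) if has_pheno else None
    if rsq is not None and rsq.shape[0] != len(variant_ids):
        raise TableParseError(
            f"#RSQ row has {rsq.shape[0]} entries for {len(variant_ids)} variants"
        )
    return GenotypeMatrix(
        sample_ids, variant_ids, dosages, phenotype=phenotype, impute_quality=rsq
    )


def read_genotypes(path, format: str = "dosage_matrix", pheno_path=None) -> GenotypeMatrix:
    """Read genotypes from a GT-only VCF subset or a dosage-matrix TSV.

    The dosage-matrix format is tab-separated with columns
    ``sample_id  phenotype  <variant ...>`` and an optional leading
    ``#RSQ`` row carrying per-variant imputation quality aligned with the
    variant columns.  Diploid VCF GTs map to dosages 0/1/2; missing
    genotypes become NaN and are excluded pairwise downstream.
    """
    if format == "vcf_subset":
        return _read_vcf_subset(path, pheno_path=pheno_path)
    if format == "dosage_matrix":
        return _read_dosage_matrix(path)
    raise ValueError(f"unknown genotype format {format!r}")


def write_dosage_matrix(gm: GenotypeMatrix, path) -> None:
    """Write a GenotypeMatrix in the dosage-matrix TSV format."""
    with open(path, "wt", encoding="utf-8") as fh:
        if gm.impute_quality is not None:
            fh.write("#RSQ\t\t" + "\t".join(f"{q:.6g}" for q in gm.impute_quality) + "\n")
        header = ["sample_id"]
        if gm.phenotype is not None:
            header.append("phenotype")
        header += gm.variant_ids
        fh.write("\t".join(header) + "\n")
        for i, sid in enumerate(gm.sample_ids):
            row = [sid]
            if gm.phenotype is not None:
                row.append(str(gm.phenotype[i]))
            for x in gm.dosages[i]:
                row.append("NA" if not np.isfinite(x) else f"{x:.6g}")
            fh.write("\t".join(row) + "\n")


def qc_filter_imputation(
    gm: GenotypeMatrix, min_maf: float = 0.01, min_rsq: float = 0.3
) -> GenotypeMatrix:
    """Post-imputation QC: drop variants with MAF < min_maf or r^2 < min_rsq.

    MAF is computed from mean dosage / 2, folded to <= 0.5.  Thresholds are
    strict 'less than' exclusions, so equality passes.  Requires
    ``impute_quality`` to be present.
    """
    if gm.impute_quality is None:
        raise ValueError("qc_filter_imputation requires impute_quality")
    keep = (gm.maf() >= min_maf) & (gm.impute_quality >= min_rsq)
    kept_ids = [v for v, k in zip(gm.variant_ids, keep) if k]
    return gm.subset_variants(kept_ids)


def genotypes_to_variant_records(
    gm: GenotypeMatrix,
    chrom: str = "14",
) -> list[VariantRecord]:
    """Summarize hard genotypes into per-variant case/control allele counts.

    Convenience bridge from a simulated or observed cohort matrix to the
    count-table representation used by the association and burden layers.
    Missing genotypes are dropped pairwise (per variant).
    """
    if gm.phenotype is None:
        raise ValueError("phenotype labels required to build case/control counts")
    is_case = gm.is_case()
    records = []
    for j, vid in enumerate(gm.variant_ids):
        col = gm.dosages[:, j]
        ok = np.isfinite(col)
        counts = {}
        for name, mask in (("cases", is_case & ok), ("controls", ~is_case & ok)):
            if mask.sum():
                counts[name] = AlleleCount(int(col[mask].sum()), int(2 * mask.sum()))
        records.append(
            VariantRecord(
                variant_id=vid,
                chrom=chrom,
                pos=j + 1,
                ref_allele="R",
                alt_allele="A",
                region="exon",
                protein_change=None,
                counts=counts,
            )
        )
    return records
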