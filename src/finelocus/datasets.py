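"""Packaged reference data: the published RIN3 variant count table.

The table is a hand-transcribed copy of the published summary of all
missense and candidate regulatory variants found by resequencing the RIN3
locus: 18 rows (16 missense + 2 regulatory), with alt-allele counts for the
sequenced cases (n = 246 individuals, 492 chromosomes), the 1000 Genomes
European panel (n = 379, 758 chromosomes) and the NHLBI European-American
exomes (n = 4300, 8600 chromosomes).  The published per-row p-values and
composite functionality scores ride along as documentation columns
(``extras``); all statistics in this package are recomputed from the raw
counts.
"""

from __future__ import annotations

from importlib import resources

from .variants import VariantRecord, read_variant_table

__all__ = [
    "rin3_variant_table",
    "N_SEQUENCED_CASES",
    "N_G1000_EUR",
    "N_NHLBI_EA",
    "N_GWAS_CASES",
    "N_GWAS_CONTROLS",
]

# cohort sizes (diploid individuals)
N_SEQUENCED_CASES = 246
N_G1000_EUR = 379
N_NHLBI_EA = 4300
N_GWAS_CASES = 741
N_GWAS_CONTROLS = 2699

# published GWAS-cohort risk-haplotype frequencies (rs10498635C–rs117068593C)
RISK_HAP_FREQ_CASES = 0.864
RISK_HAP_FREQ_CONTROLS = 0.812


def rin3_variant_table() -> list[VariantRecord]:
    """Load the packaged RIN3 variant table as :class:`VariantRecord` rows."""
    ref = resources.files("finelocus").joinpath("data/rin3_variants.tsv")
    with resources.as_file(ref) as path:
        return read_variant_table(path)
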