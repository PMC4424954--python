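"""EM haplotype-frequency estimation, LD metrics, and haplotype association.

Unphased hard genotypes over k <= 8 loci are resolved into the 2^k possible
haplotypes by the classical EM algorithm under Hardy–Weinberg equilibrium:
the E-step distributes each individual's genotype over its compatible
haplotype pairs in proportion to current pair probabilities, the M-step
re-estimates frequencies from the expected pair counts.  Initialization is
uniform so results are deterministic; the per-iteration log-likelihood is
asserted non-decreasing.

Haplotypes are encoded as strings of '0' (REF) / '1' (ALT) characters, one
per locus in the order given.  The LD coefficient D is reported relative to
the ALT–ALT haplotype.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .association import AssociationResult, ContingencyTable2x2, chisq_allelic
from .exceptions import DegenerateTableError
from .genotypes import GenotypeMatrix

__all__ = [
    "HaplotypeDistribution",
    "LDMetrics",
    "em_haplotypes",
    "ld_metrics",
    "haplotype_association",
    "haplotype_background",
]

MAX_LOCI = 8


@dataclass
class HaplotypeDistribution:
    loci: list[str]
    haplotypes: dict[str, float]
    loglik: float
    n_iterations: int
    converged: bool

    def frequency(self, hap: str) -> float:
        return self.haplotypes.get(hap, 0.0)


@dataclass(frozen=True)
class LDMetrics:
    """Two-locus linkage disequilibrium: D, normalized D', and r-squared."""

    d: float
    d_prime: float
    r2: float


def _hard_genotype_rows(gm: GenotypeMatrix, loci: list[str]) -> np.ndarray:
    cols = np.column_stack([gm.column(v) for v in loci])
    keep = np.all(np.isfinite(cols), axis=1)  # missing drops the individual
    cols = cols[keep]
    if cols.size and not np.all(np.isin(cols, (0.0, 1.0, 2.0))):
        raise ValueError("EM haplotype estimation requires hard genotypes (0/1/2)")
    return cols.astype(np.int8)


def _compatible_pairs(geno: tuple[int, ...]) -> list[tuple[int, int]]:
    """Unordered haplotype pairs (as bit patterns) compatible with a genotype.

    Bit i of a haplotype is the ALT indicator at locus i.  With m
    heterozygous loci there are 2^(m-1) distinct unordered pairs (m >= 1);
    the first heterozygous locus is fixed to ALT on the first haplotype to
    avoid double counting.
    """
    het = [i for i, g in enumerate(geno) if g == 1]
    base = 0
    for i, g in enumerate(geno):
        if g == 2:
            base |= 1 << i
    if not het:
        return [(base, base)]
    first, rest = het[0], het[1:]
    pairs = []
    for bits in itertools.product((0, 1), repeat=len(rest)):
        h1 = base | (1 << first)
        h2 = base
        for locus, b in zip(rest, bits):
            if b:
                h1 |= 1 << locus
            else:
                h2 |= 1 << locus
        pairs.append((h1, h2))
    return pairs


def _hap_string(h: int, k: int) -> str:
    return "".join("1" if h >> i & 1 else "0" for i in range(k))


def em_haplotypes(
    gm: GenotypeMatrix,
    loci: list[str],
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> HaplotypeDistribution:
    """Estimate haplotype frequencies from unphased genotypes by EM.

    Convergence is declared when the largest frequency change falls below
    ``tol``.  Monomorphic loci are handled naturally (haplotypes carrying
    the absent allele converge to frequency 0).  Raises for k > 8 loci and
    for non-hard genotypes.
    """
    k = len(loci)
    if k == 0:
        raise ValueError("at least one locus required")
    if k > MAX_LOCI:
        raise ValueError(f"at most {MAX_LOCI} loci supported (2^k enumeration)")
    rows = _hard_genotype_rows(gm, loci)
    if rows.shape[0] == 0:
        raise ValueError("no individuals with complete genotypes at the loci")
    uniq, counts = np.unique(rows, axis=0, return_counts=True)

    pair_h1, pair_h2, pair_row = [], [], []
    for r, geno in enumerate(map(tuple, uniq)):
        for h1, h2 in _compatible_pairs(geno):
            pair_h1.append(h1)
            pair_h2.append(h2)
            pair_row.append(r)
    pair_h1 = np.array(pair_h1)
    pair_h2 = np.array(pair_h2)
    pair_row = np.array(pair_row)
    het_mult = np.where(pair_h1 != pair_h2, 2.0, 1.0)
    n_rows = uniq.shape[0]
    n_ind = counts.sum()

    freqs = np.full(2**k, 1.0 / 2**k)
    loglik_prev = -np.inf
    n_iter = 0
    converged = False
    for n_iter in range(1, max_iter + 1):
        pair_w = het_mult * freqs[pair_h1] * freqs[pair_h2]
        row_tot = np.bincount(pair_row, weights=pair_w, minlength=n_rows)
        loglik = float(counts @ np.log(np.maximum(row_tot, 1e-300)))
        if loglik < loglik_prev - 1e-9:
            raise AssertionError(
                f"EM log-likelihood decreased: {loglik_prev} -> {loglik}"
            )
        post = pair_w / row_tot[pair_row] * counts[pair_row]
        new = np.bincount(pair_h1, weights=post, minlength=2**k) + np.bincount(
            pair_h2, weights=post, minlength=2**k
        )
        new /= 2.0 * n_ind
        delta = np.max(np.abs(new - freqs))
        freqs = new
        loglik_prev = loglik
        if delta < tol:
            converged = True
            break

    return HaplotypeDistribution(
        loci=list(loci),
        haplotypes={_hap_string(h, k): float(f) for h, f in enumerate(freqs)},
        loglik=loglik_prev,
        n_iterations=n_iter,
        converged=converged,
    )


def ld_metrics(hd: HaplotypeDistribution) -> LDMetrics:
    """D, D', r^2 for a two-locus haplotype distribution.

    D = p11 - p1. * p.1 (ALT–ALT convention); D' = |D| / Dmax with
    Dmax = min(p1.*p.0, p0.*p.1) when D > 0 else min(p1.*p.1, p0.*p.0);
    r^2 = D^2 / (p1. p0. p.1 p.0).  Raises for monomorphic loci.
    """
    if len(hd.loci) != 2:
        raise ValueError("ld_metrics requires exactly two loci")
    p11 = hd.frequency("11")
    p10 = hd.frequency("10")
    p01 = hd.frequency("01")
    pa = p10 + p11  # ALT frequency at locus 1
    pb = p01 + p11  # ALT frequency at locus 2
    if pa <= 0 or pa >= 1 or pb <= 0 or pb >= 1:
        raise DegenerateTableError("monomorphic locus: LD undefined")
    d = p11 - pa * pb
    if d > 0:
        dmax = min(pa * (1 - pb), (1 - pa) * pb)
    else:
        dmax = min(pa * pb, (1 - pa) * (1 - pb))
    d_prime = 0.0 if dmax == 0 else abs(d) / dmax
    r2 = d * d / (pa * (1 - pa) * pb * (1 - pb))
    return LDMetrics(d=d, d_prime=float(d_prime), r2=float(r2))


def haplotype_association(
    freq_case: float,
    freq_control: float,
    n_case: int,
    n_control: int,
    integer_counts: bool = False,
) -> AssociationResult:
    """Case-control association of one haplotype from published frequencies.

    Reconstructs the 2x2 haplotype-count table (denominators 2n chromosomes)
    and returns the OR with Woolf CI and the chi-squared p.  By default the
    reconstructed cells are kept real-valued (frequency x 2n), which
    preserves the odds ratio implied by the frequencies exactly;
    ``integer_counts=True`` rounds cells to the nearest whole haplotype.
    """
    for f in (freq_case, freq_control):
        if not 0.0 < f < 1.0:
            raise DegenerateTableError(
                "haplotype frequency must be strictly between 0 and 1"
            )
    a = freq_case * 2 * n_case
    b = (1 - freq_case) * 2 * n_case
    c = freq_control * 2 * n_control
    d = (1 - freq_control) * 2 * n_control
    if integer_counts:
        a, b, c, d = (round(x) for x in (a, b, c, d))
    res = chisq_allelic(ContingencyTable2x2(a, b, c, d))
    res.test = "haplotype_chisq"
    return res


def haplotype_background(
    gm: GenotypeMatrix,
    rare_variant: str,
    backbone_loci: list[str],
    background: str,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> float:
    """Expected fraction of rare-allele copies on a designated backbone haplotype.

    Runs EM over ``backbone_loci + [rare_variant]``, then, for every carrier,
    weights each compatible phase by its posterior probability under the
    fitted frequencies and counts the rare copies that land on the
    ``background`` allele-string (e.g. ``"00"`` for the REF–REF backbone).
    Returns (expected rare copies on background) / (total rare copies).
    """
    k_b = len(backbone_loci)
    if len(background) != k_b or any(ch not in "01" for ch in background):
        raise ValueError(
            f"background must be a 0/1 string of length {k_b}, got {background!r}"
        )
    loci = list(backbone_loci) + [rare_variant]
    k = len(loci)
    hd = em_haplotypes(gm, loci, tol=tol, max_iter=max_iter)
    freqs = np.array([hd.haplotypes[_hap_string(h, k)] for h in range(2**k)])

    bg_bits = 0
    for i, ch in enumerate(background):
        if ch == "1":
            bg_bits |= 1 << i
    backbone_mask = (1 << k_b) - 1
    rare_bit = 1 << k_b

    rows = _hard_genotype_rows(gm, loci)
    carriers = rows[rows[:, -1] >= 1]
    if carriers.shape[0] == 0:
        raise ValueError(f"no carriers of {rare_variant!r} in the matrix")

    def on_background(h: int) -> bool:
        return bool(h & rare_bit) and (h & backbone_mask) == bg_bits

    expected_on = 0.0
    total_copies = 0.0
    for geno in map(tuple, carriers):
        pairs = _compatible_pairs(geno)
        w = np.array(
            [
                (2.0 if h1 != h2 else 1.0) * freqs[h1] * freqs[h2]
                for h1, h2 in pairs
            ]
        )
        tot = w.sum()
        if tot <= 0:  # degenerate under fitted freqs; weight phases equally
            w = np.ones(len(pairs))
            tot = w.sum()
        w /= tot
        copies = float(geno[-1])
        total_copies += copies
        for wi, (h1, h2) in zip(w, pairs):
            expected_on += wi * (int(on_background(h1)) + int(on_background(h2)))
    return expected_on / total_copies
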