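"""Synthetic case-control cohorts with a two-SNP risk-haplotype architecture.

The generator emulates the population structure the fine-mapping analysis
assumes: a two-locus backbone (a GWAS tag SNP and a common missense variant
in near-perfect LD) whose risk haplotype segregates at ~81% in controls,
plus a panel of rare variants whose allele copies fall preferentially
(default 96%) on the risk haplotype background.  Disease status follows a
logistic model on allele counts:

    log-odds = logit(prevalence) + ln(OR_hap) * (risk-haplotype copies)
               + sum_v ln(OR_v) * (copies of rare variant v)

Cases and controls are accumulated by rejection sampling, mirroring
retrospective case-control ascertainment.  All randomness flows through a
single seeded generator, so equal seeds give identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, logit

from .exceptions import SimulationError
from .genotypes import CASE, CONTROL, GenotypeMatrix

__all__ = ["RareVariantSpec", "CohortSpec", "SimTruth", "simulate_cohort"]

#: Backbone haplotype labels in bit order (locus1, locus2); 'C' = REF = 0.
_HAP_KEYS = ("CC", "TC", "CT", "TT")  # index = bits (locus1 + 2*locus2)

#: Control-population backbone haplotype frequencies (risk haplotype CC).
DEFAULT_BACKBONE = {"CC": 0.812, "TT": 0.182, "CT": 0.004, "TC": 0.002}


@dataclass(frozen=True)
class RareVariantSpec:
    """One simulated rare variant: population AF, placement, and effect."""

    variant_id: str
    allele_frequency: float
    odds_ratio: float = 1.0
    on_risk_background_prob: float = 0.96

    def __post_init__(self) -> None:
        if not 0.0 < self.allele_frequency < 0.5:
            raise ValueError("rare allele_frequency must lie in (0, 0.5)")
        if not 0.0 <= self.on_risk_background_prob <= 1.0:
            raise ValueError("on_risk_background_prob must lie in [0, 1]")
        if self.odds_ratio <= 0:
            raise ValueError("odds_ratio must be positive")


def default_rare_variants(
    n: int = 15,
    allele_frequency: float = 0.002,
    odds_ratio: float = 3.72,
    on_risk_background_prob: float = 0.96,
) -> list[RareVariantSpec]:
    """Default rare-variant panel: 15 variants at AF 0.2%, per-allele OR 3.72."""
    return [
        RareVariantSpec(
            variant_id=f"rare{i + 1:02d}",
            allele_frequency=allele_frequency,
            odds_ratio=odds_ratio,
            on_risk_background_prob=on_risk_background_prob,
        )
        for i in range(n)
    ]


@dataclass
class CohortSpec:
    """Study conditions for one simulated cohort."""

    n_cases: int
    n_controls: int
    seed: int
    backbone_loci: tuple[str, str] = ("rs10498635", "rs117068593")
    backbone_haplotypes: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BACKBONE)
    )
    risk_haplotype: str = "CC"
    rare_variants: list[RareVariantSpec] = field(default_factory=default_rare_variants)
    common_variant_or: float = 1.48  # per risk-haplotype copy
    baseline_prevalence: float = 0.02

    def __post_init__(self) -> None:
        if set(self.backbone_haplotypes) != set(_HAP_KEYS):
            raise ValueError(f"backbone haplotypes must be keyed by {_HAP_KEYS}")
        total = sum(self.backbone_haplotypes.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"backbone haplotype frequencies sum to {total}, not 1")
        if self.risk_haplotype not in _HAP_KEYS:
            raise ValueError(f"unknown risk haplotype {self.risk_haplotype!r}")
        if not 0.0 < self.baseline_prevalence < 1.0:
            raise ValueError("baseline_prevalence must lie in (0, 1)")
        if self.common_variant_or <= 0:
            raise ValueError("common_variant_or must be positive")
        if self.n_cases < 0 or self.n_controls < 0 or self.n_cases + self.n_controls == 0:
            raise ValueError("need a positive number of individuals")


@dataclass
class SimTruth:
    """Full generating truth for a simulated cohort.

    ``hap_copies`` holds the two phased backbone haplotype indices per kept
    individual (bit order CC,TC,CT,TT); ``rare_copies`` the phased rare-allele
    indicator array (n, 2, n_rare); ``case_probability`` the logistic
    probability each kept individual was assigned; ``realized_counts`` the
    per-variant alt-allele counts split by phenotype.
    """

    hap_copies: np.ndarray
    rare_copies: np.ndarray
    case_probability: np.ndarray
    realized_counts: dict[str, dict[str, int]]
    rare_on_risk_copies: int
    rare_total_copies: int


def _placement_probs(spec: CohortSpec) -> tuple[np.ndarray, np.ndarray]:
    """Per-copy rare-allele probabilities on risk vs non-risk backbones."""
    q = spec.backbone_haplotypes[spec.risk_haplotype]
    p_on, p_off = [], []
    for rv in spec.rare_variants:
        pi = rv.on_risk_background_prob
        on = rv.allele_frequency * pi / q if q > 0 else 0.0
        off = rv.allele_frequency * (1 - pi) / (1 - q) if q < 1 else 0.0
        if on > 1 or off > 1:
            raise SimulationError(
                f"{rv.variant_id}: infeasible placement (AF too high for the "
                f"requested background split)"
            )
        p_on.append(on)
        p_off.append(off)
    return np.array(p_on), np.array(p_off)


def simulate_cohort(spec: CohortSpec) -> tuple[GenotypeMatrix, SimTruth]:
    """Draw a case-control cohort under the given generative conditions.

    Returns the unphased genotype matrix (backbone loci first, then rare
    variants) and the full phased truth.  Raises
    :class:`~finelocus.exceptions.SimulationError` when the requested sizes
    cannot be filled within a bounded number of draws.
    """
    rng = np.random.default_rng(spec.seed)
    hap_freqs = np.array([spec.backbone_haplotypes[k] for k in _HAP_KEYS])
    risk_idx = _HAP_KEYS.index(spec.risk_haplotype)
    p_on, p_off = _placement_probs(spec)
    n_rare = len(spec.rare_variants)
    log_or_common = np.log(spec.common_variant_or)
    log_or_rare = np.array([np.log(rv.odds_ratio) for rv in spec.rare_variants])
    base = logit(spec.baseline_prevalence)

    need_cases, need_controls = spec.n_cases, spec.n_controls
    batch = max(1024, 2 * (need_cases + need_controls))
    max_draws = 500 * (need_cases + need_controls) + 100_000

    kept_haps, kept_rare, kept_prob, kept_case = [], [], [], []
    drawn = 0
    while (need_cases > 0 or need_controls > 0) and drawn < max_draws:
        m = min(batch, max_draws - drawn)
        drawn += m
        haps = rng.choice(4, size=(m, 2), p=hap_freqs)
        is_risk = haps == risk_idx
        if n_rare:
            u = rng.random(size=(m, 2, n_rare))
            thresh = np.where(is_risk[:, :, None], p_on, p_off)
            rare = u < thresh
        else:
            rare = np.zeros((m, 2, 0), dtype=bool)
        risk_copies = is_risk.sum(axis=1)
        eta = base + log_or_common * risk_copies + rare.sum(axis=1) @ log_or_rare
        prob = expit(eta)
        is_case = rng.random(m) < prob

        for want_case in (True, False):
            need = need_cases if want_case else need_controls
            if need <= 0:
                continue
            idx = np.flatnonzero(is_case == want_case)[:need]
            if idx.size:
                kept_haps.append(haps[idx])
                kept_rare.append(rare[idx])
                kept_prob.append(prob[idx])
                kept_case.append(np.full(idx.size, want_case))
                if want_case:
                    need_cases -= idx.size
                else:
                    need_controls -= idx.size

    if need_cases > 0 or need_controls > 0:
        raise SimulationError(
            f"could not fill {spec.n_cases} cases / {spec.n_controls} controls "
            f"within {max_draws} draws (prevalence too extreme?)"
        )

    haps = np.concatenate(kept_haps)
    rare = np.concatenate(kept_rare)
    prob = np.concatenate(kept_prob)
    is_case = np.concatenate(kept_case)
    # stable ordering: cases first, then controls (draw order within group)
    order = np.argsort(~is_case, kind="stable")
    haps, rare, prob, is_case = haps[order], rare[order], prob[order], is_case[order]

    n = haps.shape[0]
    # backbone bit i of haplotype index: locus1 = idx & 1, locus2 = idx >> 1
    backbone_dos = np.column_stack([(haps & 1).sum(axis=1), (haps >> 1).sum(axis=1)])
    rare_dos = rare.sum(axis=1).astype(float)
    dosages = np.column_stack([backbone_dos.astype(float), rare_dos])
    variant_ids = list(spec.backbone_loci) + [rv.variant_id for rv in spec.rare_variants]
    phenotype = np.where(is_case, CASE, CONTROL).astype(object)
    gm = GenotypeMatrix(
        sample_ids=[f"S{i + 1:06d}" for i in range(n)],
        variant_ids=variant_ids,
        dosages=dosages,
        phenotype=phenotype,
    )

    realized: dict[str, dict[str, int]] = {}
    for j, vid in enumerate(variant_ids):
        realized[vid] = {
            "cases": int(dosages[is_case, j].sum()),
            "controls": int(dosages[~is_case, j].sum()),
        }
    on_risk = int((rare & (haps == risk_idx)[:, :, None]).sum())
    truth = SimTruth(
        hap_copies=haps,
        rare_copies=rare,
        case_probability=prob,
        realized_counts=realized,
        rare_on_risk_copies=on_risk,
        rare_total_copies=int(rare.sum()),
    )
    return gm, truth
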