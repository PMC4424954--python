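"""Composite missense pathogenicity scoring and the ddG destabilization rule.

Six predictor outputs are consumed as verdicts (running the upstream tools
is out of scope) and aggregated into a 0–6 functionality score: one point
each for SIFT 'damaging', PolyPhen-2 'possibly' or 'probably damaging',
Condel 'deleterious', MutationTaster 'disease causing', GERP strictly > 2.0,
and Grantham distance strictly > 50.  Missing outputs score 0 points and are
tallied separately rather than raising.  A predicted folding free-energy
change ddG strictly > 1.6 kcal/mol classifies a substitution as severely
destabilizing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .grantham import grantham_distance

__all__ = [
    "PredictorPanel",
    "FunctionalityScore",
    "functionality_score",
    "ddg_classify",
    "GERP_THRESHOLD",
    "GRANTHAM_THRESHOLD",
    "DDG_THRESHOLD",
]

GERP_THRESHOLD = 2.0
GRANTHAM_THRESHOLD = 50.0
DDG_THRESHOLD = 1.6  # kcal/mol

_SIFT = {"damaging", "tolerated", None}
_POLYPHEN2 = {"probably_damaging", "possibly_damaging", "benign", None}
_CONDEL = {"deleterious", "neutral", None}
_MUTATION_TASTER = {"disease_causing", "polymorphism", None}


@dataclass
class PredictorPanel:
    """The six predictor outputs for one missense variant.

    Categorical fields take the verdict strings above or None for missing.
    ``grantham`` is looked up from the amino-acid pair when absent.
    """

    aa_ref: str
    aa_alt: str
    sift: str | None = None
    polyphen2: str | None = None
    condel: str | None = None
    mutation_taster: str | None = None
    gerp: float | None = None
    grantham: float | None = None

    def __post_init__(self) -> None:
        if self.aa_ref.upper() == self.aa_alt.upper():
            raise ValueError("aa_ref and aa_alt must differ for a missense variant")
        for value, allowed, name in (
            (self.sift, _SIFT, "sift"),
            (self.polyphen2, _POLYPHEN2, "polyphen2"),
            (self.condel, _CONDEL, "condel"),
            (self.mutation_taster, _MUTATION_TASTER, "mutation_taster"),
        ):
            if value not in allowed:
                raise ValueError(f"invalid {name} verdict {value!r}")
        if self.grantham is None:
            self.grantham = grantham_distance(self.aa_ref, self.aa_alt)
        if self.grantham < 0:
            raise ValueError("grantham distance must be >= 0")


@dataclass(frozen=True)
class FunctionalityScore:
    score: int
    criteria_met: frozenset[str]
    n_missing: int

    def __post_init__(self) -> None:
        assert self.score == len(self.criteria_met)


def functionality_score(panel: PredictorPanel) -> FunctionalityScore:
    """One point per satisfied criterion across the six assessment tools.

    Numeric thresholds are strict: GERP > 2.0 and Grantham > 50 exactly
    score nothing at the boundary.  Missing tools contribute no point and
    are counted in ``n_missing``.
    """
    met: set[str] = set()
    n_missing = 0

    if panel.sift is None:
        n_missing += 1
    elif panel.sift == "damaging":
        met.add("sift")

    if panel.polyphen2 is None:
        n_missing += 1
    elif panel.polyphen2 in {"probably_damaging", "possibly_damaging"}:
        met.add("polyphen2")

    if panel.condel is None:
        n_missing += 1
    elif panel.condel == "deleterious":
        met.add("condel")

    if panel.mutation_taster is None:
        n_missing += 1
    elif panel.mutation_taster == "disease_causing":
        met.add("mutation_taster")

    if panel.gerp is None:
        n_missing += 1
    elif panel.gerp > GERP_THRESHOLD:
        met.add("gerp")

    if panel.grantham is None:  # only if lookup was bypassed explicitly
        n_missing += 1
    elif panel.grantham > GRANTHAM_THRESHOLD:
        met.add("grantham")

    return FunctionalityScore(
        score=len(met), criteria_met=frozenset(met), n_missing=n_missing
    )


def ddg_classify(ddg_kcal_mol: float, threshold: float = DDG_THRESHOLD) -> str:
    """Classify a predicted stability change: strictly > threshold destabilizes."""
    if not math.isfinite(ddg_kcal_mol):
        raise ValueError("ddG must be finite")
    return "destabilizing" if ddg_kcal_mol > threshold else "not_destabilizing"
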