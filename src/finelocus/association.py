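"""Case-control association statistics on 2x2 allele-count tables and dosages.

Implements the allelic association toolkit used throughout the package:

* Pearson chi-squared allelic test (1 df, no continuity correction),
* Fisher's exact test by direct hypergeometric enumeration, with the
  point-probability rule for the two-sided p-value,
* odds ratios with Woolf (log-OR) confidence intervals and the
  Haldane–Anscombe +0.5 correction when any cell is zero,
* cohort combination by naive pooling or Cochran–Mantel–Haenszel,
* dosage-based (optionally conditional) logistic regression fitted by
  iteratively reweighted least squares with explicit detection of
  separation and singular designs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import expit, gammaln
from scipy.stats import chi2 as chi2_dist
from scipy.stats import norm as norm_dist

from .exceptions import (
    ConvergenceError,
    DegenerateTableError,
    SeparationError,
    SingularDesignError,
)
from .genotypes import GenotypeMatrix
from .variants import AlleleCount

__all__ = [
    "ContingencyTable2x2",
    "AssociationResult",
    "table_from_counts",
    "odds_ratio_ci",
    "chisq_allelic",
    "fisher_exact",
    "combine_tables",
    "auto_test",
    "logistic_dosage",
]

_Z = {}  # cached normal quantiles


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Case/control x alt/ref (or carrier/non-carrier) counts.

    Layout::

                 alt (carrier)   ref (non-carrier)
        cases         a                 b
        controls      c                 d

    Cells may be real-valued (frequency-reconstructed tables); the exact
    test requires integer cells.
    """

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")
        if self.a + self.b <= 0 or self.c + self.d <= 0:
            raise ValueError("each row of the 2x2 table must have positive total")

    @property
    def n(self) -> float:
        return self.a + self.b + self.c + self.d

    def cells(self) -> tuple[float, float, float, float]:
        return (self.a, self.b, self.c, self.d)

    def transpose_rows(self) -> "ContingencyTable2x2":
        """Swap the case and control rows (inverts the odds ratio)."""
        return ContingencyTable2x2(self.c, self.d, self.a, self.b)

    def int_cells(self) -> tuple[int, int, int, int]:
        cells = self.cells()
        rounded = tuple(int(round(x)) for x in cells)
        if any(abs(x - r) > 1e-9 for x, r in zip(cells, rounded)):
            raise ValueError("exact test requires integer cell counts")
        return rounded


@dataclass
class AssociationResult:
    """Odds ratio, Woolf CI, and p-value for one association test."""

    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    test: str
    n_effective: int
    haldane: bool = False
    statistic: float | None = None
    beta: float | None = None
    se: float | None = None


def table_from_counts(
    case_counts: AlleleCount, control_counts: AlleleCount
) -> ContingencyTable2x2:
    """Build the allelic 2x2 table: alt vs ref alleles in cases vs controls."""
    return ContingencyTable2x2(
        a=case_counts.alt_count,
        b=case_counts.total_alleles - case_counts.alt_count,
        c=control_counts.alt_count,
        d=control_counts.total_alleles - control_counts.alt_count,
    )


def _zcrit(alpha: float) -> float:
    if alpha not in _Z:
        _Z[alpha] = float(norm_dist.isf(alpha / 2.0))
    return _Z[alpha]


def odds_ratio_ci(t: ContingencyTable2x2, alpha: float = 0.05) -> AssociationResult:
    """Sample odds ratio with the Woolf log-interval.

    OR = ad/bc; CI = exp(ln OR +/- z * sqrt(1/a + 1/b + 1/c + 1/d)).
    Any zero cell triggers the Haldane–Anscombe +0.5 correction on all four
    cells, flagged via ``haldane=True`` in the result.  The p-value slot is
    NaN — combine with :func:`chisq_allelic` or :func:`fisher_exact`.
    """
    a, b, c, d = t.cells()
    if (a + c == 0) or (b + d == 0):
        raise DegenerateTableError("all-zero column margin: odds ratio undefined")
    haldane = min(a, b, c, d) == 0
    if haldane:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_ = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = _zcrit(alpha)
    return AssociationResult(
        odds_ratio=or_,
        ci_low=math.exp(math.log(or_) - z * se),
        ci_high=math.exp(math.log(or_) + z * se),
        p_value=float("nan"),
        test="odds_ratio",
        n_effective=int(round(t.n)),
        haldane=haldane,
    )


def chisq_allelic(t: ContingencyTable2x2, alpha: float = 0.05) -> AssociationResult:
    """Pearson chi-squared allelic test, 1 df, no continuity correction."""
    a, b, c, d = t.cells()
    n = t.n
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    if c1 == 0 or c2 == 0:
        raise DegenerateTableError("all-zero column margin: chi-squared undefined")
    stat = n * (a * d - b * c) ** 2 / (r1 * r2 * c1 * c2)
    p = float(chi2_dist.sf(stat, 1))
    res = odds_ratio_ci(t, alpha=alpha)
    res.p_value = p
    res.test = "chisq_allelic"
    res.statistic = stat
    return res


def _log_hypergeom_pmf(r1: int, r2: int, c1: int) -> tuple[np.ndarray, np.ndarray]:
    """Log pmf of cell `a` over its feasible range, for fixed table margins."""
    n = r1 + r2
    amin = max(0, c1 - r2)
    amax = min(r1, c1)
    avals = np.arange(amin, amax + 1)
    logp = (
        gammaln(r1 + 1)
        - gammaln(avals + 1)
        - gammaln(r1 - avals + 1)
        + gammaln(r2 + 1)
        - gammaln(c1 - avals + 1)
        - gammaln(r2 - c1 + avals + 1)
        - (gammaln(n + 1) - gammaln(c1 + 1) - gammaln(n - c1 + 1))
    )
    return avals, logp


def fisher_pvalues_for_margins(
    r1: int, r2: int, c1: int, sided: str = "two"
) -> tuple[np.ndarray, np.ndarray]:
    """Exact p-values for every feasible value of cell `a` at fixed margins.

    Vectorized core of :func:`fisher_exact`; also handy for exhaustive
    verification sweeps.  Two-sided p sums hypergeometric point
    probabilities <= the observed one within relative tolerance 1e-12.
    """
    avals, logp = _log_hypergeom_pmf(r1, r2, c1)
    probs = np.exp(logp - logp.max())
    total = probs.sum()
    if sided == "two":
        order = np.argsort(probs, kind="stable")
        sorted_p = probs[order]
        cum = np.cumsum(sorted_p)
        # for each table, sum of probabilities <= its own (with tie tolerance)
        thresh = probs * (1.0 + 1e-12)
        idx = np.searchsorted(sorted_p, thresh, side="right") - 1
        pvals = cum[np.clip(idx, 0, len(cum) - 1)] / total
    elif sided == "greater":
        pvals = (probs[::-1].cumsum()[::-1]) / total
    elif sided == "less":
        pvals = probs.cumsum() / total
    else:
        raise ValueError(f"unknown sidedness {sided!r}")
    return avals, np.minimum(pvals, 1.0)


def fisher_exact(
    t: ContingencyTable2x2, sided: str = "two", alpha: float = 0.05
) -> AssociationResult:
    """Fisher's exact test by direct enumeration over the feasible range of a.

    The two-sided p-value follows the point-probability rule: the sum of
    hypergeometric probabilities of all tables (margins fixed) whose point
    probability is <= that of the observed table, with relative tolerance
    1e-12 for ties.
    """
    a, b, c, d = t.int_cells()
    avals, pvals = fisher_pvalues_for_margins(a + b, c + d, a + c, sided=sided)
    p = float(pvals[a - avals[0]])
    try:
        res = odds_ratio_ci(t, alpha=alpha)
    except DegenerateTableError:
        # a monomorphic column leaves the OR undefined but the exact p is
        # still well-defined (p = 1)
        res = AssociationResult(
            odds_ratio=float("nan"),
            ci_low=float("nan"),
            ci_high=float("nan"),
            p_value=p,
            test="fisher_exact",
            n_effective=int(round(t.n)),
        )
        return res
    res.p_value = p
    res.test = "fisher_exact"
    return res


def auto_test(t: ContingencyTable2x2, alpha: float = 0.05) -> AssociationResult:
    """Chi-squared when every expected cell count is >= 5, else Fisher exact."""
    a, b, c, d = t.cells()
    n = t.n
    expected = [
        (a + b) * (a + c) / n,
        (a + b) * (b + d) / n,
        (c + d) * (a + c) / n,
        (c + d) * (b + d) / n,
    ]
    if min(expected) >= 5:
        return chisq_allelic(t, alpha=alpha)
    return fisher_exact(t, alpha=alpha)


def combine_tables(
    tables: list[ContingencyTable2x2], method: str = "cmh", alpha: float = 0.05
) -> AssociationResult:
    """Combine per-cohort 2x2 tables.

    ``pool``
        element-wise sum of cells, then the auto-selected single-table test.
        Commutes with permutation of the input and doubles cells (leaving
        the OR unchanged) when identical tables are pooled.
    ``cmh``
        Cochran–Mantel–Haenszel common odds ratio and 1-df statistic across
        strata — the default for panels with different base frequencies,
        where naive pooling can produce Simpson-style artefacts.
    """
    if not tables:
        raise ValueError("combine_tables requires at least one table")
    if method == "pool":
        a = sum(t.a for t in tables)
        b = sum(t.b for t in tables)
        c = sum(t.c for t in tables)
        d = sum(t.d for t in tables)
        res = auto_test(ContingencyTable2x2(a, b, c, d), alpha=alpha)
        res.test = f"pool+{res.test}"
        return res
    if method == "cmh":
        # standard stratified 2x2 machinery from statsmodels
        from statsmodels.stats.contingency_tables import StratifiedTable

        strata = np.array([[[t.a, t.b], [t.c, t.d]] for t in tables]).T
        st = StratifiedTable(strata.astype(float))
        or_ = float(st.oddsratio_pooled)
        lcb, ucb = st.oddsratio_pooled_confint(alpha=alpha)
        test = st.test_null_odds(correction=False)
        return AssociationResult(
            odds_ratio=or_,
            ci_low=float(lcb),
            ci_high=float(ucb),
            p_value=float(test.pvalue),
            test="cmh",
            n_effective=int(round(sum(t.n for t in tables))),
            statistic=float(test.statistic),
        )
    raise ValueError(f"unknown combination method {method!r}")


# ---------------------------------------------------------------------------
# dosage-based logistic regression


def _irls(
    X: np.ndarray, y: np.ndarray, tol: float = 1e-8, max_iter: int = 100
) -> tuple[np.ndarray, np.ndarray]:
    """Logistic MLE by iteratively reweighted least squares.

    Returns (beta, covariance).  Raises SingularDesignError for rank-deficient
    designs, SeparationError when the MLE diverges (complete separation), and
    ConvergenceError if max_iter is exhausted.
    """
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise SingularDesignError("design matrix is rank deficient")
    beta = np.zeros(p)
    for _ in range(max_iter):
        eta = X @ beta
        mu = expit(eta)
        # perfect fit with extreme probabilities => the MLE diverges
        if np.all(np.abs(y - mu) < 1e-6):
            raise SeparationError(
                "complete separation: fitted probabilities reached 0/1 "
                "for every observation"
            )
        w = mu * (1.0 - mu)
        w = np.maximum(w, 1e-12)
        XtW = X.T * w
        H = XtW @ X
        grad = X.T @ (y - mu)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError as exc:
            raise SingularDesignError("weighted normal equations singular") from exc
        beta_new = beta + step
        if np.max(np.abs(beta_new)) > 50.0:
            raise SeparationError(
                "coefficients diverging: (quasi-)complete separation suspected"
            )
        delta = np.max(np.abs(beta_new - beta))
        beta = beta_new
        if delta < tol:
            cov = np.linalg.inv(H)
            return beta, cov
    raise ConvergenceError(f"IRLS did not converge in {max_iter} iterations")


def logistic_dosage(
    gm: GenotypeMatrix,
    target_variant: str,
    condition_on: str | None = None,
    alpha: float = 0.05,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> AssociationResult:
    """Per-allele logistic association of case status on allelic dosage.

    Fits ``logit P(case) = b0 + b1 * dose_target (+ b2 * dose_condition)``
    and reports exp(b1) with the Wald CI and p-value.  Fractional imputed
    dosages are supported directly, which is how imputation uncertainty is
    propagated into the test.  Conditioning on a perfect sample proxy of the
    target (r^2 = 1) makes the design singular — the conditional-analysis
    signature of a fully absorbed signal — and is reported as
    :class:`~finelocus.exceptions.SingularDesignError`.
    """
    if condition_on == target_variant:
        raise ValueError("conditioning variant must differ from the target")
    y = gm.is_case().astype(float)
    if y.min() == y.max():
        raise ValueError("phenotype must contain both cases and controls")
    cols = [gm.column(target_variant)]
    if condition_on is not None:
        cols.append(gm.column(condition_on))
    design = np.column_stack([np.ones(gm.n_samples)] + cols)
    ok = np.all(np.isfinite(design), axis=1)
    design, yy = design[ok], y[ok]
    beta, cov = _irls(design, yy, tol=tol, max_iter=max_iter)
    b1 = float(beta[1])
    se = float(math.sqrt(cov[1, 1]))
    z = _zcrit(alpha)
    wald = b1 / se
    return AssociationResult(
        odds_ratio=math.exp(b1),
        ci_low=math.exp(b1 - z * se),
        ci_high=math.exp(b1 + z * se),
        p_value=float(2.0 * norm_dist.sf(abs(wald))),
        test="logistic_wald",
        n_effective=int(ok.sum()),
        statistic=wald,
        beta=b1,
        se=se,
    )
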