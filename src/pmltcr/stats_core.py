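"""Statistical machinery shared by every analysis stage.

Wraps the exact 2x2 test, BH-FDR, rank tests, one-way ANOVA with Tukey HSD,
permutation p-values, correlation, and the mixed-model association used to
adjust for repeated sampling of the same patient. Each routine returns a
:class:`TestResult` so downstream code handles every test uniformly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TwoByTwo",
    "TestResult",
    "fisher_exact_2x2",
    "bh_fdr",
    "mann_whitney_u",
    "anova_tukey",
    "permutation_p",
    "lmm_association",
    "correlation",
    "haldane_odds_ratio",
]


@dataclass(frozen=True)
class TwoByTwo:
    """A 2x2 contingency table, cells row-major: [[a, b], [c, d]]."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        cells = (self.a, self.b, self.c, self.d)
        if any(int(x) != x or x < 0 for x in cells):
            raise ValueError(f"cells must be nonnegative integers, got {cells}")
        if sum(cells) < 1:
            raise ValueError("all-zero 2x2 table")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass
class TestResult:
    """Outcome of a statistical test.

    ``estimate`` carries the effect size natural to the method (odds ratio,
    slope, correlation coefficient); ``extra`` holds method-specific detail.
    """

    __test__ = False  # keep pytest from collecting this as a test class

    statistic: float
    p_value: float
    estimate: float | None = None
    method: str = ""
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ValueError(f"p-value outside [0, 1]: {self.p_value}")


def haldane_odds_ratio(t: TwoByTwo) -> float:
    """Sample odds ratio (a*d)/(b*c), adding 0.5 to every cell only when some
    cell is zero (Haldane-Anscombe correction)."""
    a, b, c, d = t.a, t.b, t.c, t.d
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a * d) / (b * c)


def fisher_exact_2x2(t: TwoByTwo, alternative: str = "two-sided") -> TestResult:
    """Fisher's exact test on a 2x2 table.

    The two-sided p-value sums hypergeometric probabilities, over tables with
    the observed margins, of every table at most as probable as the observed
    one. The reported estimate is the Haldane-corrected sample odds ratio; the
    conditional-MLE odds ratio is available under ``extra["cmle_or"]``.
    """
    res = sps.fisher_exact([[t.a, t.b], [t.c, t.d]], alternative=alternative)
    return TestResult(
        statistic=res.statistic,
        p_value=float(min(1.0, res.pvalue)),
        estimate=haldane_odds_ratio(t),
        method="fisher_exact",
        extra={"cmle_or": float(sps.contingency.odds_ratio([[t.a, t.b], [t.c, t.d]]).statistic)},
    )


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def mann_whitney_u(x, y, alternative: str = "two-sided") -> TestResult:
    """Two-sided Mann-Whitney U test.

    Exact p by enumeration when the pooled sample size is at most 12 and there
    are no ties; otherwise the normal approximation with tie and continuity
    corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([x, y])
    tie_free = np.unique(pooled).size == pooled.size
    method = "exact" if (pooled.size <= 12 and tie_free) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative=alternative, method=method, use_continuity=True)
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(min(1.0, res.pvalue)),
        method=f"mann_whitney_u_{method}",
    )


def anova_tukey(groups: dict) -> tuple[TestResult, dict]:
    """One-way ANOVA followed by Tukey HSD pairwise comparisons.

    Parameters
    ----------
    groups
        Mapping of group label to a sequence of values; every group needs at
        least two values.

    Returns
    -------
    (anova_result, pairwise)
        ``pairwise`` maps each unordered label pair to a :class:`TestResult`
        whose statistic is the mean difference (first minus second label).
    """
    labels = list(groups)
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(groups[k], dtype=float) for k in labels]
    if any(a.size < 2 for a in arrays):
        raise ValueError("every group needs at least two values")

    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:  # all values identical: no variance anywhere
        anova = TestResult(statistic=0.0, p_value=1.0, method="anova_oneway_degenerate")
        pairwise = {
            (labels[i], labels[j]): TestResult(0.0, 1.0, method="tukey_hsd_degenerate")
            for i in range(len(labels))
            for j in range(i + 1, len(labels))
        }
        return anova, pairwise

    f_res = sps.f_oneway(*arrays)
    anova = TestResult(statistic=float(f_res.statistic), p_value=float(f_res.pvalue), method="anova_oneway")
    hsd = sps.tukey_hsd(*arrays)
    pairwise = {}
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            pairwise[(labels[i], labels[j])] = TestResult(
                statistic=float(hsd.statistic[i, j]),
                p_value=float(min(1.0, hsd.pvalue[i, j])),
                method="tukey_hsd",
            )
    return anova, pairwise


def permutation_p(observed: float, null_draws, tail: str = "ge") -> float:
    """Permutation p-value with the add-one rule: (1 + #{draws >= obs}) / (1 + B).

    Never returns 0; ties between draws and the observed value count toward
    the tail.
    """
    draws = np.asarray(null_draws, dtype=float)
    if draws.size < 1:
        raise ValueError("need at least one null draw")
    if tail == "ge":
        k = int(np.sum(draws >= observed))
    elif tail == "le":
        k = int(np.sum(draws <= observed))
    else:
        raise ValueError(f"unknown tail {tail!r}")
    return (1 + k) / (1 + draws.size)


def _demeaned_ols(y: np.ndarray, x: np.ndarray, codes: np.ndarray) -> TestResult:
    # Within-patient (fixed-effect) regression: demean both variables inside
    # each patient, then slope + t-test with df = n - n_patients - 1.
    n_groups = codes.max() + 1
    ym = y - np.bincount(codes, weights=y)[codes] / np.bincount(codes)[codes]
    xm = x - np.bincount(codes, weights=x)[codes] / np.bincount(codes)[codes]
    sxx = float(xm @ xm)
    if sxx <= 0:
        return TestResult(np.nan, 1.0, estimate=0.0, method="lmm_fallback_demeaned_ols_degenerate")
    slope = float(xm @ ym) / sxx
    resid = ym - slope * xm
    df = y.size - n_groups - 1
    if df <= 0:
        return TestResult(np.nan, 1.0, estimate=slope, method="lmm_fallback_demeaned_ols_degenerate")
    se = np.sqrt(float(resid @ resid) / df / sxx)
    if se == 0:
        p = 0.0 if slope != 0 else 1.0
        return TestResult(np.inf if slope else 0.0, p, estimate=slope, method="lmm_fallback_demeaned_ols")
    tstat = slope / se
    p = 2 * sps.t.sf(abs(tstat), df)
    return TestResult(float(tstat), float(p), estimate=slope, method="lmm_fallback_demeaned_ols")


def lmm_association(y, x, group) -> TestResult:
    """Association of y with x adjusting for patient as a random intercept.

    Fits ``y ~ x + (1 | patient)`` by maximum likelihood and tests the slope
    with a likelihood-ratio test against the intercept-only model (chi-square,
    1 df). A singular or non-converging fit falls back to patient-demeaned
    ordinary regression, flagged in ``method``.
    """
    import statsmodels.api as sm

    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    uniques, codes = np.unique(np.asarray(group), return_inverse=True)
    if uniques.size < 2:
        raise ValueError("need at least two patients")
    counts = np.bincount(codes)
    if np.sum(counts >= 2) < 2:
        raise ValueError("need at least two patients with two or more samples")

    exog_full = sm.add_constant(x)
    exog_null = np.ones((y.size, 1))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            full = sm.MixedLM(y, exog_full, groups=codes).fit(reml=False)
            null = sm.MixedLM(y, exog_null, groups=codes).fit(reml=False)
            llf_full, llf_null = float(full.llf), float(null.llf)
        if not np.isfinite(llf_full) or not np.isfinite(llf_null):
            raise np.linalg.LinAlgError("non-finite log-likelihood")
        lr = max(0.0, 2.0 * (llf_full - llf_null))
        p = float(sps.chi2.sf(lr, df=1))
        slope = float(full.params[1])
        return TestResult(statistic=lr, p_value=p, estimate=slope, method="lmm_lrt")
    except (np.linalg.LinAlgError, ValueError):
        return _demeaned_ols(y, x, codes)


def correlation(x, y, method: str = "pearson") -> TestResult:
    """Pearson r or Spearman rho with a two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length vectors with at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero-variance input")
    if method == "pearson":
        res = sps.pearsonr(x, y)
    elif method == "spearman":
        res = sps.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(min(1.0, res.pvalue)),
        estimate=float(res.statistic),
        method=method,
    )
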