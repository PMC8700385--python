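"""Cohort-level diagnostic statistics for ROI-summarized IVIM parameters.

Covers the comparisons a lesion-vs-contralateral prostate study reports:
Mann-Whitney group tests (exact enumeration at small n), paired t /
Wilcoxon for lesion-normal pairs, Spearman rank correlation against age,
ROC analysis with DeLong confidence intervals and Youden-index cutoffs,
confusion-matrix accuracy measures, and age-adjusted odds ratios from
logistic regression with complete-separation handling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats as sps

__all__ = [
    "GroupComparison",
    "DiagnosticTable",
    "ROCResult",
    "ORResult",
    "mann_whitney",
    "paired_test",
    "spearman_vs_age",
    "roc_analysis",
    "confusion_metrics",
    "age_adjusted_or",
]

EXACT_MAX_N = 12


def _summary(values: np.ndarray) -> dict:
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    return {"median": float(med), "q1": float(q1), "q3": float(q3), "n": len(values)}


@dataclass
class GroupComparison:
    """Result of a two-group or paired comparison."""

    statistic_name: str
    statistic: float
    p_value: float
    summaries: list[dict] = field(default_factory=list)
    degenerate: bool = False
    companion: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value out of [0, 1]: {self.p_value}")


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """Mann-Whitney U for group a (ties counted 1/2) via midranks."""
    combined = np.concatenate([a, b])
    ranks = sps.rankdata(combined)
    ra = ranks[: len(a)].sum()
    return float(ra - len(a) * (len(a) + 1) / 2)


def mann_whitney(a, b) -> GroupComparison:
    """Two-sided Mann-Whitney U test.

    For combined n <= 12 the null distribution of U is enumerated exactly
    over all group assignments (ties handled by midranks); otherwise the
    normal approximation with tie and continuity corrections is used.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    u = _u_statistic(a, b)
    n1, n2 = len(a), len(b)
    if n1 + n2 <= EXACT_MAX_N:
        ranks = sps.rankdata(np.concatenate([a, b]))
        n = n1 + n2
        us = np.array(
            [sum(ranks[list(idx)]) - n1 * (n1 + 1) / 2
             for idx in combinations(range(n), n1)]
        )
        p_le = np.mean(us <= u + 1e-12)
        p_ge = np.mean(us >= u - 1e-12)
        p = min(1.0, 2.0 * min(p_le, p_ge))
    else:
        res = sps.mannwhitneyu(a, b, alternative="two-sided",
                               method="asymptotic", use_continuity=True)
        p = float(res.pvalue)
    return GroupComparison("mann_whitney_u", u, p, [_summary(a), _summary(b)])


def paired_test(lesion, normal) -> GroupComparison:
    """Paired t test of matched lesion / contralateral-normal values, with a
    Wilcoxon signed-rank companion.

    Degenerate conventions: identical pairs (zero-variance, zero-mean
    differences) report p = 1; zero-variance nonzero-mean differences
    report p = 0.  Both are flagged.
    """
    lesion = np.asarray(lesion, dtype=float)
    normal = np.asarray(normal, dtype=float)
    if lesion.shape != normal.shape:
        raise ValueError("paired samples must have equal length")
    if len(lesion) < 3:
        raise ValueError("paired test needs >= 3 matched pairs")
    diffs = lesion - normal
    summaries = [_summary(lesion), _summary(normal)]
    if np.std(diffs, ddof=1) == 0:
        if np.mean(diffs) == 0:
            return GroupComparison("paired_t", 0.0, 1.0, summaries, degenerate=True)
        return GroupComparison("paired_t", np.inf, 0.0, summaries, degenerate=True)
    t, p = sps.ttest_rel(lesion, normal)
    companion = {}
    if np.any(diffs != 0):
        w = sps.wilcoxon(lesion, normal, zero_method="wilcox")
        companion = {"wilcoxon_statistic": float(w.statistic),
                     "wilcoxon_p": float(w.pvalue)}
    return GroupComparison("paired_t", float(t), float(p), summaries,
                           companion=companion)


def spearman_vs_age(values, ages) -> GroupComparison:
    """Spearman rank correlation of a parameter against age (average ranks
    for ties, p via the t approximation)."""
    values = np.asarray(values, dtype=float)
    ages = np.asarray(ages, dtype=float)
    if len(values) != len(ages):
        raise ValueError("values and ages must have equal length")
    if len(values) < 5:
        raise ValueError("Spearman correlation needs n >= 5")
    if np.all(values == values[0]) or np.all(ages == ages[0]):
        return GroupComparison("spearman_rho", np.nan, np.nan, degenerate=True)
    rho, p = sps.spearmanr(values, ages)
    return GroupComparison("spearman_rho", float(rho), float(p))


@dataclass
class DiagnosticTable:
    """2x2 diagnostic confusion table at a cutoff."""

    tp: int
    fn: int
    fp: int
    tn: int
    cutoff: float = np.nan
    orientation: str = "lower_is_positive"

    def __post_init__(self) -> None:
        for c in (self.tp, self.fn, self.fp, self.tn):
            if c < 0 or int(c) != c:
                raise ValueError("counts must be non-negative integers")

    @property
    def positives(self) -> int:
        return self.tp + self.fn

    @property
    def negatives(self) -> int:
        return self.fp + self.tn

    @classmethod
    def from_rates(cls, sens_pct: float, spec_pct: float,
                   n_pos: int, n_neg: int, **kw) -> "DiagnosticTable":
        """Reconstruct integer counts from printed sensitivity/specificity
        percentages and known class sizes."""
        tp = round(sens_pct / 100.0 * n_pos)
        tn = round(spec_pct / 100.0 * n_neg)
        return cls(tp=tp, fn=n_pos - tp, fp=n_neg - tn, tn=tn, **kw)


def confusion_metrics(table: DiagnosticTable) -> dict:
    """Sensitivity, specificity, PPV, NPV and accuracy, all in percent.

    PPV is ``None`` (not available) when no positives are called
    (TP + FP = 0); likewise NPV when TN + FN = 0.  Requires at least one
    true positive case and one true negative case in the table.
    """
    if table.positives < 1 or table.negatives < 1:
        raise ValueError("need >= 1 positive and >= 1 negative case")
    tp, fn, fp, tn = table.tp, table.fn, table.fp, table.tn
    total = tp + fn + fp + tn
    return {
        "sensitivity": 100.0 * tp / (tp + fn),
        "specificity": 100.0 * tn / (tn + fp),
        "ppv": 100.0 * tp / (tp + fp) if (tp + fp) > 0 else None,
        "npv": 100.0 * tn / (tn + fn) if (tn + fn) > 0 else None,
        "accuracy": 100.0 * (tp + tn) / total,
    }


@dataclass
class ROCResult:
    auc: float
    ci_low: float
    ci_high: float
    cutoff: float
    orientation: str
    youden_j: float
    table: DiagnosticTable
    degenerate: bool = False


def _delong_variance(pos_scores: np.ndarray, neg_scores: np.ndarray) -> float:
    """DeLong variance of the empirical AUC (single-curve case)."""
    m, n = len(pos_scores), len(neg_scores)
    # structural components: V10_i = mean_j psi(x_i, y_j), V01_j likewise
    diff = pos_scores[:, None] - neg_scores[None, :]
    psi = np.where(diff > 0, 1.0, np.where(diff == 0, 0.5, 0.0))
    v10 = psi.mean(axis=1)
    v01 = psi.mean(axis=0)
    s10 = np.var(v10, ddof=1) if m > 1 else 0.0
    s01 = np.var(v01, ddof=1) if n > 1 else 0.0
    return s10 / m + s01 / n


def roc_analysis(lesion, normal, orientation: str | None = None) -> ROCResult:
    """ROC analysis of one parameter for lesion-vs-normal discrimination.

    The AUC is the rank (Mann-Whitney) statistic with ties counted 1/2;
    the 95% CI comes from the DeLong variance; the reported cutoff
    maximizes Youden's J = sensitivity + specificity - 1 and is placed at
    the midpoint between adjacent distinct observed values.  With
    ``orientation=None`` the direction (lower- or higher-is-positive) is
    chosen so AUC >= 0.5.
    """
    lesion = np.asarray(lesion, dtype=float)
    normal = np.asarray(normal, dtype=float)
    if len(lesion) == 0 or len(normal) == 0:
        raise ValueError("both classes must be non-empty")

    def auc_for(orient: str) -> float:
        score_pos = -lesion if orient == "lower_is_positive" else lesion
        score_neg = -normal if orient == "lower_is_positive" else normal
        u = _u_statistic(score_pos, score_neg)
        return u / (len(lesion) * len(normal))

    if orientation is None:
        orientation = (
            "higher_is_positive"
            if auc_for("higher_is_positive") >= 0.5
            else "lower_is_positive"
        )
    auc = auc_for(orientation)
    degenerate = len(np.unique(np.concatenate([lesion, normal]))) == 1

    sign = -1.0 if orientation == "lower_is_positive" else 1.0
    pos, neg = sign * lesion, sign * normal
    var = _delong_variance(pos, neg)
    half = 1.959963984540054 * np.sqrt(var)
    ci = (max(0.0, auc - half), min(1.0, auc + half))

    # Youden-optimal cutoff over midpoints of adjacent distinct pooled values
    pooled = np.unique(np.concatenate([lesion, normal]))
    if len(pooled) == 1:
        cuts = np.array([pooled[0]])
    else:
        cuts = (pooled[:-1] + pooled[1:]) / 2.0
    best_j, best_cut, best_table = -np.inf, cuts[0], None
    for c in cuts:
        if orientation == "lower_is_positive":
            tp = int(np.sum(lesion <= c))
            fp = int(np.sum(normal <= c))
        else:
            tp = int(np.sum(lesion >= c))
            fp = int(np.sum(normal >= c))
        fn = len(lesion) - tp
        tn = len(normal) - fp
        j = tp / len(lesion) + tn / len(normal) - 1.0
        if j > best_j + 1e-12:
            best_j, best_cut = j, float(c)
            best_table = DiagnosticTable(tp=tp, fn=fn, fp=fp, tn=tn,
                                         cutoff=float(c), orientation=orientation)
    return ROCResult(
        auc=float(auc), ci_low=float(ci[0]), ci_high=float(ci[1]),
        cutoff=best_cut, orientation=orientation, youden_j=float(best_j),
        table=best_table, degenerate=degenerate,
    )


@dataclass
class ORResult:
    """Age-adjusted odds ratio from logistic regression."""

    odds_ratio: float | None
    ci_low: float | None
    ci_high: float | None
    available: bool
    reason: str = ""
    age_coefficient: float | None = None


def age_adjusted_or(outcome, exposure, age) -> ORResult:
    """Odds ratio of a dichotomized parameter for the tissue-class outcome,
    adjusted for age via logistic regression (Newton-Raphson MLE).

    Complete separation (or a degenerate design) is reported as
    not-available rather than an arbitrarily large estimate.
    """
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    outcome = np.asarray(outcome, dtype=float)
    exposure = np.asarray(exposure, dtype=float)
    age = np.asarray(age, dtype=float)
    if len(outcome) < 10:
        raise ValueError("age-adjusted OR needs >= 10 observations")
    if len(np.unique(outcome)) < 2:
        raise ValueError("both outcome levels must be present")
    # perfect separation of the outcome by the dichotomized exposure
    p1 = outcome[exposure == 1]
    p0 = outcome[exposure == 0]
    if len(p1) == 0 or len(p0) == 0:
        return ORResult(None, None, None, False, "constant exposure")
    if (p1.min() > p0.max()) or (p0.min() > p1.max()):
        return ORResult(None, None, None, False, "complete separation")
    cols = [exposure]
    use_age = len(np.unique(age)) > 1
    if use_age:
        cols.append(age)
    design = sm.add_constant(np.column_stack(cols))
    try:
        with np.errstate(all="ignore"):
            import warnings as _w

            with _w.catch_warnings():
                _w.simplefilter("ignore")
                fit = sm.Logit(outcome, design).fit(disp=0, method="newton", maxiter=100)
    except (PerfectSeparationError, np.linalg.LinAlgError):
        return ORResult(None, None, None, False, "complete separation")
    beta = fit.params[1]
    if not np.isfinite(beta) or abs(beta) > 15:
        return ORResult(None, None, None, False, "quasi-separation")
    se = np.sqrt(fit.cov_params()[1, 1])
    if not np.isfinite(se):
        return ORResult(None, None, None, False, "non-identified")
    z = 1.959963984540054
    return ORResult(
        odds_ratio=float(np.exp(beta)),
        ci_low=float(np.exp(beta - z * se)),
        ci_high=float(np.exp(beta + z * se)),
        available=True,
        age_coefficient=float(fit.params[2]) if use_age else None,
    )
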