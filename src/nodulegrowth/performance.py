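"""Diagnostic-performance and agreement statistics.

Operating points (sensitivity/specificity) carry 95% confidence intervals
computed with a hybrid rule: the Wald interval ``p +- 1.96 sqrt(p(1-p)/n)``
clipped to [0, 100] for interior counts, falling back to the exact
Clopper-Pearson interval when the Wald interval degenerates (k = 0 or
k = n).  Both pure methods are also selectable.

Paired comparisons of sensitivities/specificities use McNemar's test on the
discordant pairs; correlated AUCs are compared with the DeLong
placement-value machinery.  Inter-rater agreement statistics: Cohen's kappa
(with the Fleiss-Cohen-Everitt asymptotic CI, via statsmodels), raw percent
agreement, the two-way random-effects absolute-agreement single-measurement
ICC, i.e. ICC(2,1), and Bland-Altman limits of agreement.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import stats
from sklearn.metrics import roc_curve as _sk_roc_curve
from statsmodels.stats.inter_rater import cohens_kappa as _sm_cohens_kappa

from .errors import (
    DegenerateLabelsError,
    InsufficientDataError,
    UndefinedProportionError,
)

CIMethod = Literal["hybrid", "wald_clipped", "clopper_pearson"]


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 classification counts against pathology-proven cancer status."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def n_cancer(self) -> int:
        return self.tp + self.fn

    @property
    def n_benign(self) -> int:
        return self.tn + self.fp


@dataclass(frozen=True)
class ProportionEstimate:
    """A percentage with its 95% CI and the raw counts behind it."""

    value: float
    ci_low: float
    ci_high: float
    numerator: int
    denominator: int
    method: str


@dataclass(frozen=True)
class PairedComparison:
    statistic: float
    p_value: float
    method: str


@dataclass(frozen=True)
class ROCResult:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    auc_ci_low: float
    auc_ci_high: float


@dataclass(frozen=True)
class KappaResult:
    kappa: float
    ci_low: float
    ci_high: float
    se: float
    degenerate: bool = False


@dataclass(frozen=True)
class ICCResult:
    icc: float
    ci_low: float
    ci_high: float
    degenerate: bool = False


@dataclass(frozen=True)
class BlandAltmanResult:
    mean_diff: float
    loa_low: float
    loa_high: float
    sd_diff: float


# ---------------------------------------------------------------------------
# proportions


def proportion_ci(k: int, n: int, method: CIMethod = "hybrid") -> ProportionEstimate:
    """95% CI for a binomial proportion, reported in percent.

    ``hybrid`` (default): clipped Wald for 0 < k < n, exact Clopper-Pearson
    at the degenerate boundary counts.
    """
    if n == 0:
        raise UndefinedProportionError("proportion with zero denominator")
    if not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    p = k / n
    use_cp = method == "clopper_pearson" or (method == "hybrid" and k in (0, n))
    if use_cp:
        lo = 0.0 if k == 0 else stats.beta.ppf(0.025, k, n - k + 1)
        hi = 1.0 if k == n else stats.beta.ppf(0.975, k + 1, n - k)
        used = "clopper_pearson"
    else:
        se = np.sqrt(p * (1.0 - p) / n)
        lo = max(0.0, p - 1.959963984540054 * se)
        hi = min(1.0, p + 1.959963984540054 * se)
        used = "wald_clipped"
    return ProportionEstimate(
        value=100.0 * p,
        ci_low=100.0 * lo,
        ci_high=100.0 * hi,
        numerator=int(k),
        denominator=int(n),
        method=used,
    )


def sensitivity_specificity(
    counts: ConfusionCounts, method: CIMethod = "hybrid"
) -> tuple[ProportionEstimate, ProportionEstimate]:
    """Sensitivity and specificity with CIs from a 2x2 table."""
    if counts.n_cancer == 0:
        raise UndefinedProportionError("sensitivity undefined: no cancer cases (tp+fn=0)")
    if counts.n_benign == 0:
        raise UndefinedProportionError("specificity undefined: no benign cases (tn+fp=0)")
    sens = proportion_ci(counts.tp, counts.n_cancer, method)
    spec = proportion_ci(counts.tn, counts.n_benign, method)
    return sens, spec


# ---------------------------------------------------------------------------
# paired tests


def mcnemar_test(
    decisions_a, decisions_b, method: Literal["exact", "cc"] = "exact"
) -> PairedComparison:
    """McNemar's test on two aligned binary decision vectors.

    ``exact``: two-sided binomial on the discordant pairs,
    ``p = min(1, 2 P(X <= min(b, c)))`` with ``X ~ Bin(b + c, 1/2)``.
    ``cc``: continuity-corrected chi-square ``(|b - c| - 1)^2 / (b + c)``.
    """
    a = np.asarray(decisions_a, dtype=bool)
    b = np.asarray(decisions_b, dtype=bool)
    if a.shape != b.shape or a.ndim != 1 or a.size < 1:
        raise ValueError("decision vectors must be aligned, 1-D and non-empty")
    n_ab = int(np.sum(a & ~b))  # a positive, b negative
    n_ba = int(np.sum(~a & b))
    n_disc = n_ab + n_ba
    if method == "exact":
        if n_disc == 0:
            return PairedComparison(statistic=0.0, p_value=1.0, method="mcnemar_exact")
        p = min(1.0, 2.0 * stats.binom.cdf(min(n_ab, n_ba), n_disc, 0.5))
        return PairedComparison(
            statistic=float(min(n_ab, n_ba)), p_value=float(p), method="mcnemar_exact"
        )
    if method == "cc":
        if n_disc == 0:
            return PairedComparison(statistic=0.0, p_value=1.0, method="mcnemar_cc")
        chi2 = (abs(n_ab - n_ba) - 1.0) ** 2 / n_disc
        return PairedComparison(
            statistic=float(chi2), p_value=float(stats.chi2.sf(chi2, 1)), method="mcnemar_cc"
        )
    raise ValueError(f"unknown McNemar variant: {method!r}")


# ---------------------------------------------------------------------------
# ROC / DeLong


def _check_two_classes(labels: np.ndarray) -> None:
    if labels.all() or not labels.any():
        raise DegenerateLabelsError("ROC requires both classes present")


def _placements(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Midrank placement values (DeLong's structural components).

    ``v10[i]`` is the fraction of negatives scored below positive ``i``
    (ties half-credit); ``v01[j]`` the fraction of positives scored above
    negative ``j``.  ``v10.mean() == v01.mean() ==`` the Mann-Whitney AUC.
    """
    pos = scores[labels]
    neg = scores[~labels]
    m, n = pos.size, neg.size
    all_ranks = stats.rankdata(np.concatenate([pos, neg]))
    v10 = (all_ranks[:m] - stats.rankdata(pos)) / n
    v01 = 1.0 - (all_ranks[m:] - stats.rankdata(neg)) / m
    return v10, v01


def empirical_roc(scores, labels) -> ROCResult:
    """Empirical ROC curve; AUC equals the tie-corrected Mann-Whitney statistic.

    The DeLong CI is attached when both classes have at least two members,
    otherwise the CI is reported as NaN.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    _check_two_classes(labels)
    fpr, tpr, thresholds = _sk_roc_curve(labels, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    if labels.sum() >= 2 and (~labels).sum() >= 2:
        auc_d, lo, hi = delong_auc_ci(scores, labels)
        # same estimator; use the placement-value AUC for exact agreement
        auc = auc_d
    else:
        lo = hi = float("nan")
    return ROCResult(
        fpr=fpr, tpr=tpr, thresholds=thresholds, auc=auc, auc_ci_low=lo, auc_ci_high=hi
    )


def delong_auc_ci(scores, labels) -> tuple[float, float, float]:
    """AUC with DeLong 95% CI from placement-value variances, clipped to [0,1]."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    _check_two_classes(labels)
    m, n = int(labels.sum()), int((~labels).sum())
    if m < 2 or n < 2:
        raise InsufficientDataError("DeLong variance needs >= 2 cases per class")
    v10, v01 = _placements(scores, labels)
    auc = float(v10.mean())
    var = float(np.var(v10, ddof=1) / m + np.var(v01, ddof=1) / n)
    se = np.sqrt(max(var, 0.0))
    lo = max(0.0, auc - 1.959963984540054 * se)
    hi = min(1.0, auc + 1.959963984540054 * se)
    return auc, float(lo), float(hi)


def delong_paired_test(scores_a, scores_b, labels) -> PairedComparison:
    """Two-sided DeLong test for two correlated AUCs on the same cases."""
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores_a.shape != scores_b.shape or scores_a.shape != labels.shape:
        raise ValueError("score and label vectors must be aligned")
    _check_two_classes(labels)
    m, n = int(labels.sum()), int((~labels).sum())
    if m < 2 or n < 2:
        raise InsufficientDataError("DeLong variance needs >= 2 cases per class")
    va10, va01 = _placements(scores_a, labels)
    vb10, vb01 = _placements(scores_b, labels)
    auc_a, auc_b = float(va10.mean()), float(vb10.mean())
    var_diff = float(
        np.var(va10 - vb10, ddof=1) / m + np.var(va01 - vb01, ddof=1) / n
    )
    diff = auc_a - auc_b
    if var_diff <= 0.0:
        if diff == 0.0:
            return PairedComparison(statistic=0.0, p_value=1.0, method="delong")
        return PairedComparison(
            statistic=float(np.sign(diff) * np.inf), p_value=0.0, method="delong"
        )
    z = diff / np.sqrt(var_diff)
    p = 2.0 * stats.norm.sf(abs(z))
    return PairedComparison(statistic=float(z), p_value=float(p), method="delong")


# ---------------------------------------------------------------------------
# agreement


def percent_agreement(labels_a, labels_b) -> float:
    """Raw percentage of concordant paired calls."""
    a = np.asarray(labels_a, dtype=bool)
    b = np.asarray(labels_b, dtype=bool)
    if a.shape != b.shape or a.size < 1:
        raise ValueError("label vectors must be aligned and non-empty")
    return 100.0 * float(np.mean(a == b))


def cohens_kappa(labels_a, labels_b) -> KappaResult:
    """Cohen's kappa for two binary raters, 95% CI clipped to [-1, 1].

    When both raters are constant and identical, chance agreement is 1 and
    kappa is undefined; a perfect-agreement sentinel (kappa = 1, degenerate
    flag) is reported instead.
    """
    a = np.asarray(labels_a, dtype=bool)
    b = np.asarray(labels_b, dtype=bool)
    if a.shape != b.shape or a.size < 1:
        raise ValueError("label vectors must be aligned and non-empty")
    table = np.array(
        [
            [np.sum(~a & ~b), np.sum(~a & b)],
            [np.sum(a & ~b), np.sum(a & b)],
        ],
        dtype=float,
    )
    n = table.sum()
    p_e = float((table.sum(axis=1) * table.sum(axis=0)).sum() / n**2)
    if p_e >= 1.0:  # both raters constant and identical
        return KappaResult(kappa=1.0, ci_low=1.0, ci_high=1.0, se=0.0, degenerate=True)
    res = _sm_cohens_kappa(table, return_results=True)
    se = float(np.sqrt(res.var_kappa))
    return KappaResult(
        kappa=float(res.kappa),
        ci_low=max(-1.0, float(res.kappa_low)),
        ci_high=min(1.0, float(res.kappa_upp)),
        se=se,
    )


def icc_absolute_agreement(matrix) -> ICCResult:
    """ICC(2,1): two-way random effects, absolute agreement, single measurement.

    ``matrix`` is subjects x raters (2 raters expected, any k accepted), no
    missing cells.  The point estimate comes from the classical ANOVA mean
    squares and the CI from the McGraw & Wong F-based formula.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 3 or x.shape[1] < 2:
        raise InsufficientDataError("ICC needs >= 3 subjects and >= 2 raters")
    if np.isnan(x).any():
        raise InsufficientDataError("ICC input has missing cells")
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    sse = np.sum((x - row_means[:, None] - col_means[None, :] + grand) ** 2)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if np.isclose(denom, 0.0):
        return ICCResult(icc=float("nan"), ci_low=float("nan"), ci_high=float("nan"),
                         degenerate=True)
    icc = (msr - mse) / denom
    if mse == 0.0:
        # perfect within-subject reproducibility: F machinery degenerates
        return ICCResult(icc=float(icc), ci_low=float(icc), ci_high=float(icc))
    alpha = 0.05
    fc = msc / mse
    a = k * icc / (n * (1.0 - icc)) if icc < 1.0 else np.inf
    b = 1.0 + k * icc * (n - 1.0) / (n * (1.0 - icc)) if icc < 1.0 else np.inf
    v_num = (a * msc + b * mse) ** 2
    v_den = (a * msc) ** 2 / (k - 1.0) + (b * mse) ** 2 / ((n - 1.0) * (k - 1.0))
    v = v_num / v_den
    f_u = stats.f.ppf(1.0 - alpha / 2.0, n - 1.0, v)
    f_l = stats.f.ppf(1.0 - alpha / 2.0, v, n - 1.0)
    lo = n * (msr - f_u * mse) / (f_u * (k * msc + (k * n - k - n) * mse) + n * msr)
    hi = n * (f_l * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f_l * msr)
    return ICCResult(
        icc=float(icc), ci_low=float(max(-1.0, lo)), ci_high=float(min(1.0, hi))
    )


def bland_altman(pairs) -> BlandAltmanResult:
    """Mean difference and 95% limits of agreement (d_bar +- 1.96 SD, ddof=1)."""
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise InsufficientDataError("Bland-Altman needs >= 2 measurement pairs")
    d = arr[:, 0] - arr[:, 1]
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltmanResult(
        mean_diff=mean,
        loa_low=mean - 1.96 * sd,
        loa_high=mean + 1.96 * sd,
        sd_diff=sd,
    )
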