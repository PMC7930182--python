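"""Diagnostic evaluation of a response predictor.

Confusion-table metrics with Jeffreys (Beta(x+1/2, n-x+1/2)) intervals, Woolf
odds-ratio intervals with the Haldane-Anscombe fallback, the standard
two-sided Fisher exact test, the empirical ROC with DeLong AUC interval,
the Youden-optimal cut-point, a univariate logistic fit, and the Mann-Whitney
U comparison. Proportions are returned on the [0, 1] scale; percentages are a
display concern.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve
import statsmodels.api as sm

from .errors import ValidationError

RATE_NAMES = ("sensitivity", "specificity", "ppv", "npv", "accuracy")


@dataclass(frozen=True)
class ConfusionTable:
    """2x2 counts: predicted-positive/negative vs responder/non-responder."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        cells = (self.tp, self.fp, self.fn, self.tn)
        if any(c < 0 for c in cells):
            raise ValidationError("confusion counts must be non-negative")
        if sum(cells) == 0:
            raise ValidationError("empty confusion table")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def as_2x2(self) -> np.ndarray:
        return np.array([[self.tp, self.fn], [self.fp, self.tn]])


@dataclass
class DiagnosticReport:
    table: ConfusionTable
    rates: dict
    rate_intervals: dict
    odds_ratio: float
    odds_ratio_interval: tuple
    odds_ratio_corrected: bool
    fisher_p: float
    level: float
    auc: float | None = None
    auc_interval: tuple | None = None
    auc_degenerate: bool | None = None
    youden_cutoff: float | None = None
    extras: dict = field(default_factory=dict)


def confusion_table(decisions, labels) -> ConfusionTable:
    """Counts from parallel boolean decision and responder-label vectors."""
    decisions = np.asarray(decisions, dtype=bool)
    labels = np.asarray(labels, dtype=bool)
    if decisions.shape != labels.shape or decisions.size == 0:
        raise ValidationError("decisions and labels must be equal-length and non-empty")
    return ConfusionTable(
        tp=int((decisions & labels).sum()),
        fp=int((decisions & ~labels).sum()),
        fn=int((~decisions & labels).sum()),
        tn=int((~decisions & ~labels).sum()),
    )


def rates(t: ConfusionTable) -> dict:
    """Sensitivity, specificity, PPV, NPV, accuracy; NaN where the denominator is 0."""

    def frac(num, den):
        return num / den if den > 0 else float("nan")

    return {
        "sensitivity": frac(t.tp, t.tp + t.fn),
        "specificity": frac(t.tn, t.tn + t.fp),
        "ppv": frac(t.tp, t.tp + t.fp),
        "npv": frac(t.tn, t.tn + t.fn),
        "accuracy": frac(t.tp + t.tn, t.n),
    }


def rate_counts(t: ConfusionTable) -> dict:
    """(successes, trials) pairs backing each rate, for interval estimation."""
    return {
        "sensitivity": (t.tp, t.tp + t.fn),
        "specificity": (t.tn, t.tn + t.fp),
        "ppv": (t.tp, t.tp + t.fp),
        "npv": (t.tn, t.tn + t.fn),
        "accuracy": (t.tp + t.tn, t.n),
    }


def jeffreys_interval(x: int, n: int, level: float = 0.95) -> tuple:
    """Jeffreys-prior binomial interval from Beta(x+1/2, n-x+1/2) quantiles.

    The lower bound is forced to 0 when x = 0 and the upper to 1 when x = n.
    """
    if n < 1 or not 0 <= x <= n:
        raise ValidationError(f"invalid binomial counts x={x}, n={n}")
    alpha = 1.0 - level
    lower = 0.0 if x == 0 else float(stats.beta.ppf(alpha / 2, x + 0.5, n - x + 0.5))
    upper = 1.0 if x == n else float(stats.beta.ppf(1 - alpha / 2, x + 0.5, n - x + 0.5))
    return lower, upper


def odds_ratio_woolf(t: ConfusionTable, level: float = 0.95):
    """Odds ratio with the Woolf log-scale interval.

    Any zero cell triggers the Haldane-Anscombe +0.5 continuity correction on
    all four cells; the returned flag marks corrected estimates.
    """
    cells = np.array([t.tp, t.fp, t.fn, t.tn], dtype=float)
    corrected = bool((cells == 0).any())
    if corrected:
        cells = cells + 0.5
    tp, fp, fn, tn = cells
    or_ = (tp * tn) / (fp * fn)
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt((1.0 / cells).sum())
    return float(or_), (float(or_ * np.exp(-half)), float(or_ * np.exp(half))), corrected


def fisher_exact_two_sided(t: ConfusionTable) -> float:
    """Two-sided Fisher exact p: total probability of tables at most as likely."""
    return float(stats.fisher_exact(t.as_2x2(), alternative="two-sided")[1])


def _split_classes(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape or scores.size == 0:
        raise ValidationError("scores and labels must be equal-length and non-empty")
    if labels.all() or not labels.any():
        raise ValidationError("both classes must be present")
    return scores, labels


def roc_auc(scores, labels):
    """Empirical AUC (pair-counting with half credit for ties) and ROC points.

    Returns (auc, points) where points is an array of (fpr, tpr) at every
    threshold between distinct scores.
    """
    scores, labels = _split_classes(scores, labels)
    auc = float(roc_auc_score(labels, scores))
    fpr, tpr, _ = roc_curve(labels, scores, drop_intermediate=False)
    return auc, np.column_stack([fpr, tpr])


def delong_ci(scores, labels, level: float = 0.95):
    """DeLong structural-components Wald interval for the empirical AUC.

    Returns (lower, upper, degenerate). A zero variance (perfect or inverted
    separation) collapses the interval to the AUC point with the flag set.
    """
    scores, labels = _split_classes(scores, labels)
    x = scores[labels]
    y = scores[~labels]
    m, n = len(x), len(y)
    if m < 2 or n < 2:
        raise ValidationError("need >= 2 members per class for the DeLong variance")
    psi = (x[:, None] > y[None, :]).astype(float) + 0.5 * (x[:, None] == y[None, :])
    auc = float(psi.mean())
    v10 = psi.mean(axis=1)
    v01 = psi.mean(axis=0)
    var = float(v10.var(ddof=1) / m + v01.var(ddof=1) / n)
    if var <= 0:
        return auc, auc, True
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(var)
    return max(0.0, auc - half), min(1.0, auc + half), False


def youden_cutoff(scores, labels):
    """Cut-point maximizing J = sensitivity + specificity - 1.

    Candidates are the distinct observed scores under the rule
    score >= cutoff -> positive; exact ties in J favour the smallest cutoff
    (the sensitivity-maximizing choice).
    """
    scores, labels = _split_classes(scores, labels)
    best = None
    for c in np.unique(scores):
        positive = scores >= c
        sens = float(positive[labels].mean())
        spec = float((~positive[~labels]).mean())
        j = sens + spec - 1.0
        if best is None or j > best[0] + 1e-12:
            best = (j, float(c), sens, spec)
    _, cutoff, sens, spec = best
    return cutoff, sens, spec


@dataclass
class LogisticFit:
    intercept: float | None
    slope: float | None
    probabilities: np.ndarray | None
    separated: bool


def logistic_fit(scores, labels, tol: float = 1e-10, maxiter: int = 100) -> LogisticFit:
    """Univariate ML logistic regression of response on the score.

    Fitted by iteratively reweighted least squares (Newton scoring) to a
    log-likelihood tolerance of 1e-10 or 100 iterations. Complete separation
    is detected up front and flagged instead of fitted; callers fall back to
    the empirical ROC.
    """
    scores, labels = _split_classes(scores, labels)
    if scores[labels].min() > scores[~labels].max() or scores[labels].max() < scores[~labels].min():
        return LogisticFit(None, None, None, separated=True)
    design = sm.add_constant(scores)
    result = sm.Logit(labels.astype(float), design).fit(
        disp=0, method="newton", tol=tol, maxiter=maxiter
    )
    intercept, slope = result.params
    return LogisticFit(float(intercept), float(slope),
                       np.asarray(result.predict(design)), separated=False)


def mann_whitney_u(group_a, group_b):
    """Mann-Whitney U with exact enumeration for small samples.

    Exact null distribution when both groups have n <= 8, otherwise the
    tie-corrected normal approximation. Returns (U of group A, two-sided p).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValidationError("both groups must be non-empty")
    method = "exact" if (len(a) <= 8 and len(b) <= 8) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def evaluate_binary(decisions, labels, level: float = 0.95) -> DiagnosticReport:
    """Full confusion-based report for a binary rule."""
    t = confusion_table(decisions, labels)
    or_, or_ci, corrected = odds_ratio_woolf(t, level)
    return DiagnosticReport(
        table=t,
        rates=rates(t),
        rate_intervals={
            name: jeffreys_interval(x, n, level) if n > 0 else (float("nan"), float("nan"))
            for name, (x, n) in rate_counts(t).items()
        },
        odds_ratio=or_,
        odds_ratio_interval=or_ci,
        odds_ratio_corrected=corrected,
        fisher_p=fisher_exact_two_sided(t),
        level=level,
    )


def evaluate_score(scores, labels, level: float = 0.95) -> dict:
    """ROC/AUC block: empirical AUC, DeLong interval, Youden cut-point, logistic fit."""
    auc, points = roc_auc(scores, labels)
    lower, upper, degenerate = delong_ci(scores, labels, level)
    cutoff, sens, spec = youden_cutoff(scores, labels)
    fit = logistic_fit(scores, labels)
    return {
        "auc": auc,
        "auc_interval": (lower, upper),
        "auc_degenerate": degenerate,
        "roc_points": points,
        "youden_cutoff": cutoff,
        "youden_sensitivity": sens,
        "youden_specificity": spec,
        "logistic": fit,
    }
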