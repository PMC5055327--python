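"""Two-sample comparison and ROC analysis.

The validation design is simple: a continuous image metric (entropy or an
edge statistic) against a binary reading (radiologist label or IDH1
status). Group means are compared with the classic pooled-variance
Student t-test; discrimination is quantified by the area under the
empirical ROC curve.

AUC is the midrank Mann-Whitney statistic — ties between a positive and a
negative score count half — which equals the trapezoidal area under the
empirical ROC curve swept over all thresholds. Its standard error uses the
DeLong placement-value (structural-component) estimator; the 95% CI is
``auc +/- 1.96 * se`` clamped to [0, 1], and the p-value against the
chance line is a two-sided normal test of ``(auc - 0.5) / se``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as _st

from .errors import ValidationError

__all__ = ["TTestResult", "ROCResult", "two_sample_ttest", "roc_auc"]

_TINY = float(np.finfo(np.float64).tiny)


@dataclass(frozen=True)
class TTestResult:
    """Unpaired pooled-variance Student t-test on two groups."""

    mean_difference: float
    ci95: tuple[float, float]
    t_statistic: float
    degrees_of_freedom: int
    p_two_sided: float
    n1: int
    n2: int

    @property
    def significant(self) -> bool:
        """Two-sided significance at the conventional alpha = 0.05."""
        return self.p_two_sided < 0.05


@dataclass(frozen=True)
class ROCResult:
    """Empirical ROC curve with midrank AUC and DeLong-based uncertainty."""

    auc: float
    se: float
    ci95: tuple[float, float]
    p_vs_half: float
    curve: np.ndarray  # (k, 2) ordered (FPR, TPR) points from (0,0) to (1,1)
    n_positive: int
    n_negative: int

    @property
    def significant(self) -> bool:
        return self.p_vs_half < 0.05


def two_sample_ttest(group1, group2) -> TTestResult:
    """Pooled-variance two-sample t-test; difference is mean(group1) - mean(group2).

    The 95% CI of the difference uses the t(n1 + n2 - 2) quantile. With zero
    pooled variance the test degenerates: equal means give p = 1 and CI (0, 0);
    unequal means give p = 0 and a point CI at the difference.
    """
    g1 = np.asarray(group1, dtype=np.float64)
    g2 = np.asarray(group2, dtype=np.float64)
    if g1.ndim != 1 or g2.ndim != 1 or g1.size < 2 or g2.size < 2:
        raise ValidationError("each group needs at least 2 values")
    if not (np.isfinite(g1).all() and np.isfinite(g2).all()):
        raise ValidationError("groups must be finite")
    n1, n2 = g1.size, g2.size
    dof = n1 + n2 - 2
    diff = float(g1.mean() - g2.mean())
    pooled_var = ((n1 - 1) * g1.var(ddof=1) + (n2 - 1) * g2.var(ddof=1)) / dof
    se = float(np.sqrt(pooled_var * (1.0 / n1 + 1.0 / n2)))
    if se == 0.0:
        if diff == 0.0:
            return TTestResult(0.0, (0.0, 0.0), 0.0, dof, 1.0, n1, n2)
        return TTestResult(diff, (diff, diff), float(np.sign(diff)) * np.inf, dof, _TINY, n1, n2)
    t = diff / se
    p = float(2.0 * _st.t.sf(abs(t), dof))
    half_width = float(_st.t.ppf(0.975, dof)) * se
    return TTestResult(
        mean_difference=diff,
        ci95=(diff - half_width, diff + half_width),
        t_statistic=float(t),
        degrees_of_freedom=dof,
        p_two_sided=max(p, _TINY),
        n1=n1,
        n2=n2,
    )


def _roc_curve(scores: np.ndarray, positive: np.ndarray) -> np.ndarray:
    """Empirical (FPR, TPR) points over thresholds 'score >= t', t descending.

    Includes the +inf endpoint so the curve always starts at (0, 0) and ends
    at (1, 1); tied scores move both coordinates at once (diagonal segment).
    """
    thresholds = np.concatenate(([np.inf], np.unique(scores)[::-1]))
    n_pos = positive.sum()
    n_neg = positive.size - n_pos
    tpr = [(scores[positive] >= t).sum() / n_pos for t in thresholds]
    fpr = [(scores[~positive] >= t).sum() / n_neg for t in thresholds]
    return np.column_stack([fpr, tpr])


def roc_auc(scores, labels, positive_high: bool = True) -> ROCResult:
    """Midrank AUC of ``scores`` against binary ``labels`` with DeLong uncertainty.

    ``positive_high=True`` scores the convention "higher value predicts the
    positive class"; pass False to flip the orientation (equivalent to
    negating the scores).
    """
    s = np.asarray(scores, dtype=np.float64)
    y = np.asarray(labels).astype(bool)
    if s.shape != y.shape or s.ndim != 1:
        raise ValidationError("scores and labels must be 1D and equal length")
    if not np.isfinite(s).all():
        raise ValidationError("scores must be finite")
    if y.all() or not y.any():
        raise ValidationError("both classes must be present")
    if not positive_high:
        s = -s

    pos, neg = s[y], s[~y]
    m, n = pos.size, neg.size
    # placement matrix psi[i, j] compares positive i with negative j
    diff = pos[:, None] - neg[None, :]
    psi = (diff > 0).astype(np.float64) + 0.5 * (diff == 0)
    auc = float(psi.mean())
    v10 = psi.mean(axis=1)  # per-positive placement values
    v01 = psi.mean(axis=0)  # per-negative placement values
    var = 0.0
    if m > 1:
        var += v10.var(ddof=1) / m
    if n > 1:
        var += v01.var(ddof=1) / n
    se = float(np.sqrt(var))
    ci = (max(0.0, auc - 1.96 * se), min(1.0, auc + 1.96 * se))
    if se > 0.0:
        p = float(2.0 * _st.norm.sf(abs(auc - 0.5) / se))
    else:
        p = 1.0 if auc == 0.5 else 0.0
    return ROCResult(
        auc=auc,
        se=se,
        ci95=ci,
        p_vs_half=max(p, _TINY),
        curve=_roc_curve(s, y),
        n_positive=m,
        n_negative=n,
    )
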