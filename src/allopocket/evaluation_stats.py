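"""Ranking metrics, top-n classification metrics and the statistical
comparison harness.

Model quality is measured on per-split metric distributions (typically 51
grouped validation splits): average precision and ROC AUC for ranking,
and F1/precision/recall after declaring each protein's top-n pockets
predicted-positive.  Distributions from two models are compared with a
pooled-variance one-sided Student t-test and Cohen's d (with the usual
small/medium/large labels), and summarized with t-based mean confidence
intervals and notch-convention median intervals.  Feature-analysis helpers
(per-feature one-way ANOVA F and a Pearson correlation matrix) and the
dataset class-ratio summary round out the module.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.feature_selection import f_classif
from sklearn.metrics import average_precision_score, roc_auc_score

from .containers import FeatureMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "MetricDistribution",
    "ComparisonResult",
    "average_precision",
    "roc_auc",
    "topn_classification_metrics",
    "one_sided_t_test",
    "cohens_d",
    "mean_median_ci",
    "anova_f_scores",
    "pearson_correlation_matrix",
    "class_ratio_summary",
    "repeated_split_evaluation",
    "compare_distributions",
]


@dataclass(frozen=True)
class MetricDistribution:
    """Per-split values of one metric over a split plan."""

    metric_name: str
    values: np.ndarray
    split_ids: tuple[int, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "split_ids", tuple(self.split_ids))
        if len(self.split_ids) != v.size:
            raise ValueError("split_ids length must match values")
        if not np.all(np.isfinite(v)):
            raise ValueError(f"{self.metric_name}: non-finite metric values")

    @property
    def mean(self) -> float:
        return float(self.values.mean())

    @property
    def median(self) -> float:
        return float(np.median(self.values))


@dataclass(frozen=True)
class ComparisonResult:
    t_statistic: float
    p_value: float
    cohens_d: float
    effect_label: str


# ---------------------------------------------------------------------------
# Ranking metrics


def _scores_labels(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be 1-d arrays of equal length")
    return s, y


def average_precision(scores, labels) -> float:
    """Average precision by the step-interpolation rule:
    AP = sum_k (R_k - R_{k-1}) * P_k over descending-score thresholds."""
    s, y = _scores_labels(scores, labels)
    if y.sum() == 0:
        raise ValueError("average precision undefined without positive labels")
    return float(average_precision_score(y, s))


def roc_auc(scores, labels) -> float:
    """Probability that a random positive outranks a random negative,
    ties counted one half."""
    s, y = _scores_labels(scores, labels)
    if len(np.unique(y)) < 2:
        raise ValueError("ROC AUC needs both classes present")
    return float(roc_auc_score(y, s))


def topn_classification_metrics(groups, scores, labels, n: int) -> dict[str, float]:
    """Classification metrics after marking each protein's n top-ranked
    pockets predicted-positive and pooling all pockets.

    ``proportion_top_n`` is the fraction of proteins whose top-n contains
    at least one true allosteric pocket.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    s, y = _scores_labels(scores, labels)
    groups = np.asarray(groups)
    if groups.shape != s.shape:
        raise ValueError("groups must align with scores")
    predicted = np.zeros_like(y)
    hit_proteins = 0
    unique_groups = pd.unique(groups)
    for g in unique_groups:
        idx = np.flatnonzero(groups == g)
        if idx.size == 0:
            continue
        top = idx[np.argsort(-s[idx], kind="stable")[:n]]
        predicted[top] = 1
        if y[top].sum() > 0:
            hit_proteins += 1
    tp = int(((predicted == 1) & (y == 1)).sum())
    fp = int(((predicted == 1) & (y == 0)).sum())
    fn = int(((predicted == 0) & (y == 1)).sum())
    precision = tp / (tp + fp) if (tp + fp) else 0.0
    recall = tp / (tp + fn) if (tp + fn) else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if (precision + recall)
        else 0.0
    )
    return {
        "f1": f1,
        "precision": precision,
        "recall": recall,
        "proportion_top_n": hit_proteins / len(unique_groups),
    }


# ---------------------------------------------------------------------------
# Statistical comparison tools


def one_sided_t_test(a, b, alternative: str = "a_greater") -> tuple[float, float]:
    """Two-sample pooled-variance Student t with a one-sided p-value.

    With zero pooled variance and equal means the test is uninformative
    and (t, p) = (0, 0.5) by convention.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs n >= 2")
    if alternative not in ("a_greater", "a_less"):
        raise ValueError("alternative must be 'a_greater' or 'a_less'")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 0.5
    side = "greater" if alternative == "a_greater" else "less"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(a, b, equal_var=True, alternative=side)
    if np.isnan(t):
        return 0.0, 0.5
    return float(t), float(p)


_EFFECT_THRESHOLDS = ((0.8, "large"), (0.5, "medium"))


def cohens_d(a, b) -> tuple[float, str]:
    """Cohen's d with pooled (n-1 denominator) standard deviation and the
    conventional |d| labels: <0.5 small, >=0.5 medium, >=0.8 large."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs n >= 2")
    na, nb = a.size, b.size
    pooled_var = (
        (na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1)
    ) / (na + nb - 2)
    if pooled_var == 0:
        if a.mean() == b.mean():
            return 0.0, "small"
        raise ValueError("zero pooled standard deviation with unequal means")
    d = float((a.mean() - b.mean()) / np.sqrt(pooled_var))
    label = "small"
    for threshold, name in _EFFECT_THRESHOLDS:
        if abs(d) >= threshold:
            label = name
            break
    return d, label


def compare_distributions(
    a: MetricDistribution | np.ndarray, b: MetricDistribution | np.ndarray
) -> ComparisonResult:
    """Full comparison of two metric distributions: one-sided t (a > b),
    Cohen's d and its effect label."""
    av = a.values if isinstance(a, MetricDistribution) else np.asarray(a, float)
    bv = b.values if isinstance(b, MetricDistribution) else np.asarray(b, float)
    t, p = one_sided_t_test(av, bv)
    d, label = cohens_d(av, bv)
    return ComparisonResult(t_statistic=t, p_value=p, cohens_d=d, effect_label=label)


def mean_median_ci(values, level: float = 0.95) -> dict[str, tuple[float, float]]:
    """Mean CI via the t-interval; median CI via the box-plot notch
    convention, median +/- 1.57 * IQR / sqrt(n)."""
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise ValueError("need n >= 3")
    n = v.size
    mean = v.mean()
    sem = v.std(ddof=1) / np.sqrt(n)
    tq = stats.t.ppf(0.5 + level / 2, df=n - 1)
    median = float(np.median(v))
    q1, q3 = np.percentile(v, [25, 75])
    half = 1.57 * (q3 - q1) / np.sqrt(n)
    return {
        "mean_ci": (float(mean - tq * sem), float(mean + tq * sem)),
        "median_ci": (median - half, median + half),
    }


# ---------------------------------------------------------------------------
# Feature analysis


def anova_f_scores(matrix: FeatureMatrix) -> pd.Series:
    """One-way ANOVA F per feature between the two label groups.

    Features with zero within-group variance but differing group means
    yield +inf (flagged by a warning)."""
    if len(np.unique(matrix.labels)) < 2:
        raise ValueError("ANOVA F needs both classes present")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f, _ = f_classif(matrix.values, matrix.labels)
    f = np.nan_to_num(f, nan=0.0)
    if np.isinf(f).any():
        logger.warning(
            "%d feature(s) have zero within-group variance (F = +inf)",
            int(np.isinf(f).sum()),
        )
    return pd.Series(f, index=list(matrix.feature_names), name="anova_f")


def pearson_correlation_matrix(
    matrix: FeatureMatrix, features: list[str] | None = None
) -> pd.DataFrame:
    """Pearson correlation for every feature pair (diagonal 1, symmetric).

    Constant features have undefined correlations; those entries are
    emitted as 0 with a warning, and the diagonal stays 1.
    """
    names = list(features) if features is not None else list(matrix.feature_names)
    X = matrix.select(names)
    if X.shape[0] < 3:
        raise ValueError("need at least 3 samples")
    constant = X.std(axis=0) == 0
    if constant.any():
        logger.warning(
            "constant feature(s) in correlation matrix: %s",
            [n for n, c in zip(names, constant) if c],
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(X, rowvar=False)
    corr = np.atleast_2d(corr)
    corr[np.isnan(corr)] = 0.0
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=names, columns=names)


def class_ratio_summary(n_pockets: int, n_allosteric: int) -> float:
    """Allosteric-site ratio of a dataset, in percent to 3 decimals."""
    if n_pockets <= 0:
        raise ValueError("n_pockets must be positive")
    if not (0 < n_allosteric <= n_pockets):
        raise ValueError("need 0 < n_allosteric <= n_pockets")
    return round(100.0 * n_allosteric / n_pockets, 3)


# ---------------------------------------------------------------------------
# Repeated-split evaluation

_METRIC_FNS = {
    "average_precision": average_precision,
    "roc_auc": roc_auc,
}


def repeated_split_evaluation(
    model_builder,
    matrix: FeatureMatrix,
    plan,
    metrics: tuple[str, ...] = ("average_precision", "roc_auc"),
) -> dict[str, MetricDistribution]:
    """Train/score a model over every split of a grouped plan.

    ``model_builder(train_matrix, seed)`` must return a callable mapping a
    FeatureMatrix to per-sample probabilities.  Splits whose validation
    side is single-class are skipped with a warning.
    """
    per_metric: dict[str, list[float]] = {m: [] for m in metrics}
    split_ids: list[int] = []
    for k, (train_groups, val_groups) in enumerate(plan.splits):
        train = matrix.subset(matrix.rows_in_groups(train_groups))
        val = matrix.subset(matrix.rows_in_groups(val_groups))
        if len(np.unique(val.labels)) < 2 or len(np.unique(train.labels)) < 2:
            logger.warning("split %d skipped: single-class side", k)
            continue
        predict = model_builder(train, int(plan.seeds[k]))
        probs = np.asarray(predict(val), dtype=float)
        for m in metrics:
            per_metric[m].append(_METRIC_FNS[m](probs, val.labels))
        split_ids.append(k)
    return {
        m: MetricDistribution(
            metric_name=m, values=np.array(vals), split_ids=tuple(split_ids)
        )
        for m, vals in per_metric.items()
    }
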