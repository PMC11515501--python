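"""Candidate feature-subset generation.

Two selection families are run for each of four tree-ensemble classifiers
(gradient boosting, random forest, extra trees, AdaBoost), yielding eight
candidate feature sets:

* **Boruta** — an all-relevant procedure: every iteration appends a
  permuted "shadow" copy of each feature, fits the classifier, and counts
  for each real feature how often its impurity importance beats the best
  shadow importance.  Features whose hit counts are significantly above
  (below) the Binomial(n_iter, 1/2) null, with a Bonferroni-corrected
  two-sided level, are confirmed (rejected); undecided features count as
  rejected.

* **Model-based ranking + forward stepwise** — features are ranked by
  impurity importance, then prefixes of the ranking are scored by mean
  validation average precision over a grouped split plan; the shortest
  prefix attaining the best mean score is kept.

The resulting sets are the inputs of the multimodel ensemble stage, which
trains one base model per set and prunes sets by backward elimination.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats
from sklearn.ensemble import (
    AdaBoostClassifier,
    ExtraTreesClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)

from .containers import FeatureMatrix
from .evaluation_stats import average_precision

logger = logging.getLogger(__name__)

__all__ = [
    "CLASSIFIER_NAMES",
    "FeatureSet",
    "SelectionConfig",
    "BorutaNoFeaturesError",
    "make_classifier",
    "rank_features_by_importance",
    "forward_stepwise",
    "boruta_select",
    "generate_candidate_sets",
    "save_feature_sets",
    "load_feature_sets",
]

CLASSIFIER_NAMES = (
    "gradient_boosting",
    "random_forest",
    "extra_trees",
    "adaboost",
)

_CLASSIFIERS = {
    "gradient_boosting": GradientBoostingClassifier,
    "random_forest": RandomForestClassifier,
    "extra_trees": ExtraTreesClassifier,
    "adaboost": AdaBoostClassifier,
}


class BorutaNoFeaturesError(RuntimeError):
    """Boruta confirmed nothing; callers should fall back to the top-k
    importance ranking."""


def make_classifier(name: str, seed: int, params: dict | None = None):
    """Instantiate one of the four tree-ensemble classifiers.

    Library defaults are used unless ``params`` overrides them; the random
    state is always pinned.
    """
    if name not in _CLASSIFIERS:
        raise ValueError(f"unknown classifier {name!r}; choose from {CLASSIFIER_NAMES}")
    return _CLASSIFIERS[name](random_state=seed, **(params or {}))


@dataclass(frozen=True)
class FeatureSet:
    """An ordered, named feature subset with selection provenance."""

    set_name: str
    features: tuple[str, ...]
    method: str  # "boruta" | "model_based"
    classifier_name: str
    ranking: tuple[float, ...] = ()
    note: str = ""

    def __post_init__(self) -> None:
        if not self.features:
            raise ValueError(f"{self.set_name}: empty feature set")
        if len(set(self.features)) != len(self.features):
            raise ValueError(f"{self.set_name}: duplicate features")
        if self.method not in ("boruta", "model_based"):
            raise ValueError(f"{self.set_name}: unknown method {self.method!r}")

    def to_dict(self) -> dict:
        return {
            "set_name": self.set_name,
            "method": self.method,
            "classifier_name": self.classifier_name,
            "features": list(self.features),
            "ranking": list(self.ranking),
            "note": self.note,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureSet":
        return cls(
            set_name=d["set_name"],
            features=tuple(d["features"]),
            method=d["method"],
            classifier_name=d["classifier_name"],
            ranking=tuple(d.get("ranking", ())),
            note=d.get("note", ""),
        )


@dataclass(frozen=True)
class SelectionConfig:
    """Hyperparameters shared by both selection families."""

    n_iterations: int = 100
    alpha: float = 0.05
    rng_seed: int = 0
    stepwise_metric: str = "average_precision"
    split_plan: object | None = None  # SplitPlan; required for stepwise
    patience: int = 3
    classifier_params: dict = field(default_factory=dict)
    fallback_top_k: int = 20

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        if self.n_iterations < 10:
            raise ValueError("n_iterations must be >= 10")

    def params_for(self, classifier_name: str) -> dict | None:
        return self.classifier_params.get(classifier_name)


def _require_two_classes(matrix: FeatureMatrix) -> None:
    if len(np.unique(matrix.labels)) < 2:
        raise ValueError("feature matrix labels contain a single class")


def rank_features_by_importance(
    matrix: FeatureMatrix,
    classifier_name: str,
    seed: int,
    params: dict | None = None,
) -> list[tuple[str, float]]:
    """All features sorted by impurity importance (descending), ties broken
    by feature name for determinism."""
    _require_two_classes(matrix)
    clf = make_classifier(classifier_name, seed, params)
    clf.fit(matrix.values, matrix.labels)
    importances = clf.feature_importances_
    order = sorted(
        zip(matrix.feature_names, importances), key=lambda t: (-t[1], t[0])
    )
    return [(name, float(score)) for name, score in order]


def _mean_validation_metric(
    features: list[str],
    matrix: FeatureMatrix,
    classifier_name: str,
    plan,
    seed: int,
    params: dict | None,
) -> float:
    """Mean validation average precision of one candidate feature list over
    a grouped split plan; splits whose validation side is single-class are
    skipped."""
    cols = matrix.column_index(features)
    scores = []
    for k, (train_groups, val_groups) in enumerate(plan.splits):
        train_mask = matrix.rows_in_groups(train_groups)
        val_mask = matrix.rows_in_groups(val_groups)
        y_val = matrix.labels[val_mask]
        if len(np.unique(y_val)) < 2 or len(np.unique(matrix.labels[train_mask])) < 2:
            continue
        clf = make_classifier(classifier_name, seed + k, params)
        clf.fit(matrix.values[np.ix_(train_mask, cols)], matrix.labels[train_mask])
        probs = clf.predict_proba(matrix.values[np.ix_(val_mask, cols)])[:, 1]
        scores.append(average_precision(probs, y_val))
    if not scores:
        return float("-inf")
    return float(np.mean(scores))


def forward_stepwise(
    ranked: list[tuple[str, float]],
    matrix: FeatureMatrix,
    config: SelectionConfig,
    classifier_name: str,
) -> FeatureSet:
    """Choose the shortest prefix of an importance ranking that maximizes
    the mean validation metric, stopping after ``patience`` consecutive
    non-improving prefixes."""
    if not ranked:
        raise ValueError("ranked feature list is empty")
    if config.split_plan is None:
        raise ValueError("forward stepwise requires a split plan")
    names = [n for n, _ in ranked]
    scores = {n: s for n, s in ranked}
    best_k, best_score = 0, float("-inf")
    stale = 0
    for k in range(1, len(names) + 1):
        score = _mean_validation_metric(
            names[:k], matrix, classifier_name, config.split_plan,
            config.rng_seed, config.params_for(classifier_name),
        )
        if score > best_score:
            best_k, best_score = k, score
            stale = 0
        else:
            stale += 1
            if stale >= config.patience:
                break
    selected = tuple(names[:best_k])
    return FeatureSet(
        set_name=f"model_based_{classifier_name}",
        features=selected,
        method="model_based",
        classifier_name=classifier_name,
        ranking=tuple(scores[n] for n in selected),
    )


def boruta_hits(
    matrix: FeatureMatrix,
    classifier_name: str,
    config: SelectionConfig,
) -> np.ndarray:
    """Per-feature count of iterations in which the real importance beat
    the maximum shadow importance."""
    _require_two_classes(matrix)
    rng = np.random.default_rng(config.rng_seed)
    X = matrix.values
    y = matrix.labels
    n_features = X.shape[1]
    hits = np.zeros(n_features, dtype=int)
    params = config.params_for(classifier_name)
    for it in range(config.n_iterations):
        shadow = np.column_stack(
            [rng.permutation(X[:, j]) for j in range(n_features)]
        )
        clf = make_classifier(
            classifier_name, int(rng.integers(0, 2**31 - 1)), params
        )
        clf.fit(np.hstack([X, shadow]), y)
        imp = clf.feature_importances_
        shadow_max = imp[n_features:].max()
        hits += imp[:n_features] > shadow_max
    return hits


def boruta_select(
    matrix: FeatureMatrix,
    classifier_name: str,
    config: SelectionConfig,
) -> FeatureSet:
    """Boruta all-relevant selection with a Bonferroni-corrected two-sided
    binomial decision; undecided features are treated as rejected."""
    if matrix.n_samples < 20:
        raise ValueError("Boruta needs at least 20 samples")
    hits = boruta_hits(matrix, classifier_name, config)
    n = config.n_iterations
    n_features = len(hits)
    threshold = config.alpha / (2 * n_features)
    p_confirm = stats.binom.sf(hits - 1, n, 0.5)
    confirmed_mask = p_confirm < threshold
    confirmed = [
        (matrix.feature_names[j], int(hits[j]))
        for j in np.flatnonzero(confirmed_mask)
    ]
    if not confirmed:
        raise BorutaNoFeaturesError(
            f"Boruta with {classifier_name} confirmed no features; fall back "
            f"to the top-{config.fallback_top_k} importance ranking"
        )
    confirmed.sort(key=lambda t: (-t[1], t[0]))
    return FeatureSet(
        set_name=f"boruta_{classifier_name}",
        features=tuple(name for name, _ in confirmed),
        method="boruta",
        classifier_name=classifier_name,
        ranking=tuple(float(h) / n for _, h in confirmed),
    )


def generate_candidate_sets(
    matrix: FeatureMatrix, config: SelectionConfig
) -> list[FeatureSet]:
    """The eight candidate sets: for each of the four classifiers, one
    Boruta set and one model-based (ranking + forward stepwise) set.

    A Boruta run that confirms nothing falls back to the classifier's
    top-k ranked features (flagged in the set's ``note``).
    """
    sets: list[FeatureSet] = []
    failures: list[str] = []
    for name in CLASSIFIER_NAMES:
        ranked = rank_features_by_importance(
            matrix, name, config.rng_seed, config.params_for(name)
        )
        try:
            sets.append(boruta_select(matrix, name, config))
        except BorutaNoFeaturesError:
            logger.warning(
                "Boruta confirmed no features for %s; using top-%d ranking",
                name, config.fallback_top_k,
            )
            top = ranked[: config.fallback_top_k]
            sets.append(
                FeatureSet(
                    set_name=f"boruta_{name}",
                    features=tuple(n for n, _ in top),
                    method="boruta",
                    classifier_name=name,
                    ranking=tuple(s for _, s in top),
                    note=f"fallback: top-{config.fallback_top_k} importance ranking",
                )
            )
        except Exception as exc:  # pragma: no cover - defensive
            logger.error("Boruta failed for %s: %s", name, exc)
            failures.append(f"boruta_{name}")
        try:
            sets.append(forward_stepwise(ranked, matrix, config, name))
        except Exception as exc:  # pragma: no cover - defensive
            logger.error("forward stepwise failed for %s: %s", name, exc)
            failures.append(f"model_based_{name}")
    if not sets:
        raise RuntimeError(f"all selectors failed: {failures}")
    return sets


def save_feature_sets(sets: list[FeatureSet], out_dir: str | Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for s in sets:
        (out_dir / f"{s.set_name}.json").write_text(
            json.dumps(s.to_dict(), indent=2) + "\n"
        )


def load_feature_sets(in_dir: str | Path) -> list[FeatureSet]:
    paths = sorted(Path(in_dir).glob("*.json"))
    if not paths:
        raise FileNotFoundError(f"no feature-set JSON files in {in_dir}")
    return [FeatureSet.from_dict(json.loads(p.read_text())) for p in paths]
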