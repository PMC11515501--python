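"""Multimodel ensemble: per-set base models, backward elimination over
grouped validation splits, and equal-weight probability averaging.

One base model is trained per candidate feature set.  The set of base
models is then pruned greedily: on each round, every single-member
removal is evaluated by the ensemble's mean validation average precision
over a grouped split plan (members are refit on each split's training
side so the validation side never leaks into training), and the removal
with the largest strict improvement is kept.  Surviving members predict
with equal coefficients; the final pocket score is the arithmetic mean of
member probabilities, and pockets are reranked by that score.

Training data are rebalanced per protein beforehand: every positive
pocket is kept and negatives are randomly undersampled to at most
``ratio`` per positive (proteins without a positive are dropped).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier

from .containers import FeatureMatrix
from .evaluation_stats import average_precision
from .feature_selection import FeatureSet

logger = logging.getLogger(__name__)

__all__ = [
    "SplitPlan",
    "GradientBoostedCommittee",
    "BaseModel",
    "EnsembleModel",
    "make_split_plan",
    "undersample_per_protein",
    "train_base_models",
    "predict_ensemble",
    "backward_stepwise_models",
    "rank_pockets",
    "save_ensemble",
    "load_ensemble",
]


@dataclass(frozen=True)
class SplitPlan:
    """Repeated random group-wise partitions: every pocket of a protein
    falls on the same side of every split."""

    n_splits: int
    val_fraction: float
    groups: tuple[str, ...]
    splits: tuple[tuple[tuple[str, ...], tuple[str, ...]], ...]
    seeds: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.splits) != self.n_splits or len(self.seeds) != self.n_splits:
            raise ValueError("splits/seeds length must equal n_splits")
        for train_g, val_g in self.splits:
            if set(train_g) & set(val_g):
                raise ValueError("split sides overlap")
            if set(train_g) | set(val_g) != set(self.groups):
                raise ValueError("split does not partition the groups")
            if not val_g:
                raise ValueError("empty validation side")


def make_split_plan(
    group_ids,
    n_splits: int = 51,
    val_fraction: float = 0.20,
    master_seed: int = 0,
) -> SplitPlan:
    """Draw ``n_splits`` independent random group partitions holding out
    ``round(val_fraction * n_groups)`` (at least one) proteins each."""
    seen: dict[str, None] = {}
    for g in group_ids:
        seen.setdefault(str(g), None)
    groups = tuple(seen)
    if len(groups) < 5:
        raise ValueError(
            f"need at least 5 protein groups to hold out {val_fraction:.0%}, "
            f"got {len(groups)}"
        )
    n_val = max(1, round(val_fraction * len(groups)))
    rng = np.random.default_rng(master_seed)
    seeds = tuple(int(s) for s in rng.integers(0, 2**31 - 1, size=n_splits))
    splits = []
    for seed in seeds:
        split_rng = np.random.default_rng(seed)
        val = set(split_rng.choice(len(groups), size=n_val, replace=False))
        val_g = tuple(g for i, g in enumerate(groups) if i in val)
        train_g = tuple(g for i, g in enumerate(groups) if i not in val)
        splits.append((train_g, val_g))
    return SplitPlan(
        n_splits=n_splits,
        val_fraction=val_fraction,
        groups=groups,
        splits=tuple(splits),
        seeds=seeds,
    )


def undersample_per_protein(
    matrix: FeatureMatrix, ratio: int = 5, seed: int = 0
) -> FeatureMatrix:
    """Per protein: keep every positive pocket and at most ``ratio``
    negatives per positive, sampled without replacement.  Proteins with no
    positive pocket are dropped."""
    rng = np.random.default_rng(seed)
    keep: list[int] = []
    for g in matrix.groups:
        idx = np.flatnonzero(matrix.rows_in_groups([g]))
        pos = idx[matrix.labels[idx] == 1]
        neg = idx[matrix.labels[idx] == 0]
        if pos.size == 0:
            logger.info("protein %s dropped: no positive pocket", g)
            continue
        keep.extend(pos.tolist())
        quota = ratio * pos.size
        if neg.size > quota:
            neg = rng.choice(neg, size=quota, replace=False)
        keep.extend(sorted(int(i) for i in neg))
    return matrix.subset(np.array(sorted(keep), dtype=int))


class GradientBoostedCommittee:
    """Default base-learner backend: a small bagged committee of
    gradient-boosted tree classifiers.

    Each committee member is fit on a bootstrap resample with its own
    random state; predicted probabilities are averaged.  Deterministic
    given the fit seed.  Any object with the same ``fit``/``predict_proba``
    surface can stand in as a backend.
    """

    backend_name = "gb_committee"

    def __init__(
        self,
        n_members: int = 3,
        n_estimators: int = 60,
        max_depth: int = 2,
        learning_rate: float = 0.1,
    ) -> None:
        self.n_members = n_members
        self.n_estimators = n_estimators
        self.max_depth = max_depth
        self.learning_rate = learning_rate
        self._members: list[GradientBoostingClassifier] = []
        self._constant: float | None = None

    def get_params(self) -> dict:
        return {
            "n_members": self.n_members,
            "n_estimators": self.n_estimators,
            "max_depth": self.max_depth,
            "learning_rate": self.learning_rate,
        }

    def clone(self) -> "GradientBoostedCommittee":
        return type(self)(**self.get_params())

    def fit(self, X: np.ndarray, y: np.ndarray, seed: int) -> "GradientBoostedCommittee":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        self._members = []
        if len(np.unique(y)) < 2:
            # degenerate training side: predict the prevalence
            self._constant = float(y.mean())
            return self
        self._constant = None
        rng = np.random.default_rng(seed)
        n = X.shape[0]
        for _ in range(self.n_members):
            boot = rng.integers(0, n, size=n)
            # a bootstrap draw can lose the minority class; resample until not
            while len(np.unique(y[boot])) < 2:
                boot = rng.integers(0, n, size=n)
            clf = GradientBoostingClassifier(
                n_estimators=self.n_estimators,
                max_depth=self.max_depth,
                learning_rate=self.learning_rate,
                random_state=int(rng.integers(0, 2**31 - 1)),
            )
            clf.fit(X[boot], y[boot])
            self._members.append(clf)
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self._constant is not None:
            return np.full(X.shape[0], self._constant)
        if not self._members:
            raise RuntimeError("backend is not fitted")
        return np.mean([m.predict_proba(X)[:, 1] for m in self._members], axis=0)


@dataclass
class BaseModel:
    """One fitted base model bound to its feature set."""

    feature_set: FeatureSet
    backend: GradientBoostedCommittee
    seed: int
    metadata: dict = field(default_factory=dict)

    @property
    def set_name(self) -> str:
        return self.feature_set.set_name

    def predict(self, matrix: FeatureMatrix) -> np.ndarray:
        return self.backend.predict_proba(matrix.select(self.feature_set.features))


@dataclass
class EnsembleModel:
    """Equal-weight linear combination of base-model probabilities."""

    members: list[BaseModel]
    coefficients: np.ndarray = None  # type: ignore[assignment]
    elimination_trace: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("ensemble needs at least one member")
        if self.coefficients is None:
            self.coefficients = np.ones(len(self.members))
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.coefficients.shape != (len(self.members),):
            raise ValueError("one coefficient per member required")


def train_base_models(
    feature_sets: list[FeatureSet],
    matrix: FeatureMatrix,
    backend_factory=None,
    seed: int = 0,
    metadata: dict | None = None,
) -> list[BaseModel]:
    """Fit one backend per feature set on the (already undersampled)
    training matrix restricted to that set's columns."""
    backend_factory = backend_factory or GradientBoostedCommittee
    models: list[BaseModel] = []
    for i, fset in enumerate(feature_sets):
        backend = backend_factory()
        model_seed = seed + i
        try:
            backend.fit(matrix.select(fset.features), matrix.labels, model_seed)
        except Exception as exc:
            raise RuntimeError(
                f"backend failed for feature set {fset.set_name!r}: {exc}"
            ) from exc
        models.append(
            BaseModel(
                feature_set=fset,
                backend=backend,
                seed=model_seed,
                metadata=dict(metadata or {}),
            )
        )
    return models


def predict_ensemble(ensemble: EnsembleModel, matrix: FeatureMatrix) -> np.ndarray:
    """Coefficient-weighted mean of member probabilities (the arithmetic
    mean under the default all-ones coefficients)."""
    probs = np.stack([m.predict(matrix) for m in ensemble.members])
    c = ensemble.coefficients
    return (c[:, None] * probs).sum(axis=0) / c.sum()


def _member_split_predictions(
    models: list[BaseModel],
    matrix: FeatureMatrix,
    plan: SplitPlan,
) -> tuple[list[np.ndarray], list[np.ndarray], list[int]]:
    """Refit every member on each split's training side and predict its
    validation side.

    Returns per usable split: the members-by-validation-pockets probability
    block, the validation labels, and the split id.  Splits with a
    single-class side are skipped.  Per-split refitting means the greedy
    elimination below never scores a member on pockets it trained on.
    """
    prob_blocks: list[np.ndarray] = []
    label_blocks: list[np.ndarray] = []
    used: list[int] = []
    for k, (train_groups, val_groups) in enumerate(plan.splits):
        train_mask = matrix.rows_in_groups(train_groups)
        val_mask = matrix.rows_in_groups(val_groups)
        y_train = matrix.labels[train_mask]
        y_val = matrix.labels[val_mask]
        if len(np.unique(y_val)) < 2 or len(np.unique(y_train)) < 2:
            logger.warning("split %d skipped in backward stepwise", k)
            continue
        train = matrix.subset(train_mask)
        val = matrix.subset(val_mask)
        block = []
        for m in models:
            backend = m.backend.clone()
            backend.fit(
                train.select(m.feature_set.features), train.labels,
                int(plan.seeds[k]) + m.seed,
            )
            block.append(backend.predict_proba(val.select(m.feature_set.features)))
        prob_blocks.append(np.stack(block))
        label_blocks.append(y_val)
        used.append(k)
    if not prob_blocks:
        raise RuntimeError("no usable split: every validation side single-class")
    return prob_blocks, label_blocks, used


def _mean_metric(
    member_idx: tuple[int, ...],
    prob_blocks: list[np.ndarray],
    label_blocks: list[np.ndarray],
    metric_fn,
) -> float:
    idx = list(member_idx)
    vals = [
        metric_fn(block[idx].mean(axis=0), y)
        for block, y in zip(prob_blocks, label_blocks)
    ]
    return float(np.mean(vals))


def backward_stepwise_models(
    models: list[BaseModel],
    matrix: FeatureMatrix,
    plan: SplitPlan,
    metric_fn=average_precision,
    tol: float = 1e-6,
) -> EnsembleModel:
    """Greedy backward elimination of base models.

    Starting from all members, each round evaluates the ensemble's mean
    validation metric without each single member and removes the member
    whose removal improves the mean most (strictly, beyond ``tol``); ties
    are broken by removing the member with the larger feature set, then by
    set name.  Stops when no removal improves the mean or one member
    remains.  The mean metric along the elimination trace is
    non-decreasing by construction.
    """
    if len(models) < 2:
        raise ValueError("backward stepwise needs at least 2 models")
    prob_blocks, label_blocks, used_splits = _member_split_predictions(
        models, matrix, plan
    )
    current = tuple(range(len(models)))
    trace: list[dict] = []
    current_score = _mean_metric(current, prob_blocks, label_blocks, metric_fn)
    while len(current) > 1:
        candidates = []
        for j in current:
            remaining = tuple(i for i in current if i != j)
            score = _mean_metric(remaining, prob_blocks, label_blocks, metric_fn)
            candidates.append((score, j))
        best_score = max(score for score, _ in candidates)
        if best_score <= current_score + tol:
            break
        tied = [j for score, j in candidates if score == best_score]
        removed = min(
            tied,
            key=lambda j: (-len(models[j].feature_set.features),
                           models[j].set_name),
        )
        current = tuple(i for i in current if i != removed)
        trace.append(
            {
                "removed": models[removed].set_name,
                "mean_metric_before": current_score,
                "mean_metric_after": best_score,
                "n_members_after": len(current),
                "splits_used": len(used_splits),
            }
        )
        current_score = best_score
    return EnsembleModel(
        members=[models[i] for i in current],
        elimination_trace=trace,
    )


def rank_pockets(
    matrix: FeatureMatrix,
    ensemble: EnsembleModel,
    pocket_ids: list[int] | None = None,
) -> pd.DataFrame:
    """Rerank pockets by ensemble probability, per protein.

    Ties are broken by ascending pocket id, i.e. the cavity detector's own
    rank.  Returns structure_id, pocket_id, probability and the 1-based
    per-protein rank.
    """
    probs = predict_ensemble(ensemble, matrix)
    if pocket_ids is None:
        pocket_ids = []
        for i, s in enumerate(matrix.sample_ids):
            tail = s.rsplit(":", 1)[-1]
            digits = "".join(ch for ch in tail if ch.isdigit())
            pocket_ids.append(int(digits) if digits else i + 1)
    df = pd.DataFrame(
        {
            "structure_id": list(matrix.group_ids),
            "pocket_id": pocket_ids,
            "probability": probs,
            "label": matrix.labels,
        }
    )
    df = df.sort_values(
        ["structure_id", "probability", "pocket_id"],
        ascending=[True, False, True],
        kind="stable",
    ).reset_index(drop=True)
    df["rank"] = df.groupby("structure_id").cumcount() + 1
    return df


# ---------------------------------------------------------------------------
# Persistence


def save_ensemble(ensemble: EnsembleModel, out_dir: str | Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "coefficients": ensemble.coefficients.tolist(),
        "elimination_trace": ensemble.elimination_trace,
        "members": [],
    }
    for i, m in enumerate(ensemble.members):
        fname = f"member_{i}.joblib"
        joblib.dump(m.backend, out_dir / fname)
        manifest["members"].append(
            {
                "file": fname,
                "seed": m.seed,
                "metadata": m.metadata,
                "feature_set": m.feature_set.to_dict(),
            }
        )
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")


def load_ensemble(in_dir: str | Path) -> EnsembleModel:
    in_dir = Path(in_dir)
    manifest = json.loads((in_dir / "manifest.json").read_text())
    members = [
        BaseModel(
            feature_set=FeatureSet.from_dict(entry["feature_set"]),
            backend=joblib.load(in_dir / entry["file"]),
            seed=entry["seed"],
            metadata=entry.get("metadata", {}),
        )
        for entry in manifest["members"]
    ]
    return EnsembleModel(
        members=members,
        coefficients=np.array(manifest["coefficients"]),
        elimination_trace=manifest["elimination_trace"],
    )
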