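"""The pockets-by-features matrix consumed by selection, training and
evaluation.

Each row is one pocket; rows carry a binary allosteric label, a protein
group id (so splits never separate pockets of the same protein) and a
sample id.  The container is a thin, validated wrapper over a numpy value
block plus pandas round-trips for the TSV interchange format
(structure_id, pocket_id, label, then feature columns).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class FeatureMatrix:
    values: np.ndarray
    feature_names: tuple[str, ...]
    labels: np.ndarray
    group_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        labels = np.asarray(self.labels, dtype=int)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "feature_names", tuple(self.feature_names))
        object.__setattr__(self, "group_ids", tuple(self.group_ids))
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        n, p = values.shape
        if len(self.feature_names) != p:
            raise ValueError("feature_names length does not match values")
        if len(set(self.feature_names)) != p:
            raise ValueError("feature names must be unique")
        if labels.shape != (n,):
            raise ValueError("labels length does not match values")
        if not set(np.unique(labels)) <= {0, 1}:
            raise ValueError("labels must be binary")
        if len(self.group_ids) != n or len(self.sample_ids) != n:
            raise ValueError("group/sample ids length does not match values")
        if np.isnan(values).any():
            raise ValueError("feature matrix contains missing values")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def groups(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for g in self.group_ids:
            seen.setdefault(g, None)
        return tuple(seen)

    def column_index(self, features: list[str] | tuple[str, ...]) -> np.ndarray:
        pos = {name: i for i, name in enumerate(self.feature_names)}
        missing = [f for f in features if f not in pos]
        if missing:
            raise KeyError(f"missing feature column(s): {missing}")
        return np.array([pos[f] for f in features], dtype=int)

    def select(self, features: list[str] | tuple[str, ...]) -> np.ndarray:
        """Value block restricted to the named columns, in that order."""
        return self.values[:, self.column_index(features)]

    def subset(self, row_indices: np.ndarray) -> "FeatureMatrix":
        idx = np.asarray(row_indices)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return FeatureMatrix(
            values=self.values[idx],
            feature_names=self.feature_names,
            labels=self.labels[idx],
            group_ids=tuple(self.group_ids[i] for i in idx),
            sample_ids=tuple(self.sample_ids[i] for i in idx),
        )

    def rows_in_groups(self, groups) -> np.ndarray:
        wanted = set(groups)
        return np.array([g in wanted for g in self.group_ids], dtype=bool)

    # -- interchange ------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.feature_names))
        df.insert(0, "label", self.labels)
        df.insert(0, "pocket_id", [s.rsplit(":", 1)[-1] for s in self.sample_ids])
        df.insert(0, "structure_id", list(self.group_ids))
        return df

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FeatureMatrix":
        meta = ["structure_id", "pocket_id", "label"]
        missing = [c for c in meta if c not in df.columns]
        if missing:
            raise ValueError(f"feature table missing column(s) {missing}")
        features = [c for c in df.columns if c not in meta]
        return cls(
            values=df[features].to_numpy(dtype=float),
            feature_names=tuple(features),
            labels=df["label"].to_numpy(dtype=int),
            group_ids=tuple(str(g) for g in df["structure_id"]),
            sample_ids=tuple(
                f"{g}:{p}" for g, p in zip(df["structure_id"], df["pocket_id"])
            ),
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FeatureMatrix":
        return cls.from_frame(pd.read_csv(path, sep="\t"))
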