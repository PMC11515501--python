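"""End-to-end orchestration: dataset preparation, selection, training,
elimination, ranking and evaluation behind one config object.

Dataset preparation applies, in order: PDB parse, structure cleaning,
chain selection, Fpocket run parsing, residue completion, nucleotide-only
pocket removal, labelling, removal of proteins without a positive pocket,
the optional TM-score redundancy filter (strictly greater than the
threshold excludes), the optional resolution filter, and featurization.
Every excluded protein or pocket is logged once with a machine-readable
reason code.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import structure_io as sio
from .containers import FeatureMatrix
from .evaluation_stats import repeated_split_evaluation
from .feature_selection import SelectionConfig, generate_candidate_sets
from .mef_ensemble import (
    GradientBoostedCommittee,
    backward_stepwise_models,
    make_split_plan,
    predict_ensemble,
    rank_pockets,
    save_ensemble,
    train_base_models,
    undersample_per_protein,
)
from .seq_descriptors import (
    DescriptorConfig,
    EmptySequenceError,
    QSOParams,
    featurize_pocket,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "prepare_dataset", "run_full_pipeline", "read_tm_table"]


@dataclass
class RunConfig:
    """Declarative description of one pipeline run."""

    structures: list[dict] = field(default_factory=list)
    # each: {"structure_id": ..., "pdb": path, "fpocket_dir": path}
    annotations: str = ""
    chain_mode: str = "all-chains"
    tm_table: str | None = None
    tm_score_threshold: float = 0.5
    max_resolution: float | None = None
    undersample_ratio: int = 5
    n_splits: int = 51
    val_fraction: float = 0.2
    seed: int = 0
    qso_maxlag: int = 30
    qso_weight: float = 0.1
    kgap_ks: tuple[int, ...] = (1, 2)
    ph: float = 7.0
    boruta_iterations: int = 100
    alpha: float = 0.05
    stepwise_splits: int = 5
    patience: int = 3
    classifier_params: dict = field(default_factory=dict)
    output_dir: str = "allopocket_run"

    def __post_init__(self) -> None:
        if self.chain_mode not in ("all-chains", "allosteric-chains-only"):
            raise ValueError(f"invalid chain_mode {self.chain_mode!r}")
        if not (0 < self.val_fraction < 1):
            raise ValueError("val_fraction must be in (0, 1)")
        if self.tm_score_threshold < 0:
            raise ValueError("tm_score_threshold must be >= 0")
        self.kgap_ks = tuple(self.kgap_ks)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def descriptor_config(self) -> DescriptorConfig:
        return DescriptorConfig(
            qso_params=QSOParams(maxlag=self.qso_maxlag, weight=self.qso_weight),
            kgap_ks=self.kgap_ks,
            ph=self.ph,
        )

    def config_hash(self) -> str:
        payload = asdict(self)
        payload["kgap_ks"] = list(self.kgap_ks)
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def read_tm_table(path: str | Path) -> dict[str, float]:
    """Read a precomputed TM-score table.

    Accepts either (structure_id, tm_score) rows or pairwise
    (structure_id, reference_id, tm_score) rows; returns the maximum score
    per structure.
    """
    df = pd.read_csv(path, sep="\t")
    if "structure_id" not in df.columns or "tm_score" not in df.columns:
        raise ValueError("TM table needs columns structure_id and tm_score")
    return {
        str(sid): float(grp["tm_score"].max())
        for sid, grp in df.groupby("structure_id")
    }


def prepare_dataset(
    config: RunConfig, tm_table: dict[str, float] | None = None
) -> tuple[FeatureMatrix, list[dict]]:
    """Run the full preparation/filter chain and featurize what survives.

    Returns the feature matrix and the provenance log: one entry per
    exclusion with a machine-readable ``reason`` code.
    """
    if tm_table is None and config.tm_table:
        tm_table = read_tm_table(config.tm_table)
    annotations = sio.read_annotations(config.annotations)
    dconfig = config.descriptor_config()

    exclusions: list[dict] = []
    rows: list[dict] = []

    def exclude(level: str, sid: str, reason: str, **extra) -> None:
        exclusions.append({"level": level, "structure_id": sid,
                           "reason": reason, **extra})

    for entry in config.structures:
        sid = str(entry["structure_id"])
        annotation = annotations.get(
            sid, sio.AllostericAnnotation(sid, frozenset())
        )
        if config.max_resolution is not None:
            resolution = sio.read_resolution(entry["pdb"])
            if resolution is not None and resolution > config.max_resolution:
                exclude("protein", sid, "resolution_above_threshold",
                        resolution=resolution)
                continue
        structure = sio.clean_structure(sio.parse_pdb(entry["pdb"], sid))
        if config.chain_mode == "allosteric-chains-only" and not annotation.residues:
            exclude("protein", sid, "no_annotation_for_chain_selection")
            continue
        structure = sio.select_chains(structure, annotation, config.chain_mode)
        pockets = sio.parse_fpocket_run(entry["fpocket_dir"], structure)
        pockets = [
            p for p in pockets
            if all(r.key in structure.residue_map() for r in p.residues)
        ] if config.chain_mode == "allosteric-chains-only" else pockets
        completed = []
        for p in pockets:
            try:
                completed.append(sio.complete_residues(p, structure))
            except LookupError:
                exclude("pocket", sid, "residue_absent_from_parent",
                        pocket_id=p.pocket_id)
        n_before = len(completed)
        pockets = sio.filter_nucleotide_pockets(completed)
        for p in completed:
            if p not in pockets:
                exclude("pocket", sid, "nucleotide_only", pocket_id=p.pocket_id)
        pockets, has_positive = sio.label_pockets(pockets, annotation)
        if not has_positive:
            exclude("protein", sid, "no_positive_label", n_pockets=len(pockets))
            continue
        if tm_table is not None and tm_table.get(sid, 0.0) > config.tm_score_threshold:
            exclude("protein", sid, "tm_score_above_threshold",
                    tm_score=tm_table[sid])
            continue
        for p in pockets:
            try:
                features = featurize_pocket(p, dconfig)
            except EmptySequenceError:
                exclude("pocket", sid, "empty_sequence", pocket_id=p.pocket_id)
                continue
            row = {"structure_id": sid, "pocket_id": p.pocket_id,
                   "label": p.label}
            row.update(features)
            rows.append(row)

    if not rows:
        raise RuntimeError("no pockets survive dataset preparation")
    matrix = FeatureMatrix.from_frame(pd.DataFrame(rows))
    return matrix, exclusions


def run_full_pipeline(
    config: RunConfig,
    matrix: FeatureMatrix | None = None,
    backend_factory=None,
) -> dict:
    """prepare -> select -> train -> backward-eliminate -> evaluate.

    ``matrix`` may be supplied directly (e.g. a synthetic table); otherwise
    it is built by :func:`prepare_dataset`.  Writes the feature table,
    feature sets, model bundle, ranks, metric report and run manifest
    under ``config.output_dir``.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    backend_factory = backend_factory or GradientBoostedCommittee

    exclusions: list[dict] = []
    if matrix is None:
        matrix, exclusions = prepare_dataset(config)
    matrix.to_tsv(out_dir / "features.tsv")

    train_matrix = undersample_per_protein(
        matrix, ratio=config.undersample_ratio, seed=config.seed
    )
    stepwise_plan = make_split_plan(
        train_matrix.group_ids,
        n_splits=config.stepwise_splits,
        val_fraction=config.val_fraction,
        master_seed=config.seed + 1,
    )
    selection_config = SelectionConfig(
        n_iterations=config.boruta_iterations,
        alpha=config.alpha,
        rng_seed=config.seed,
        split_plan=stepwise_plan,
        patience=config.patience,
        classifier_params=config.classifier_params,
    )
    feature_sets = generate_candidate_sets(train_matrix, selection_config)
    from .feature_selection import save_feature_sets

    save_feature_sets(feature_sets, out_dir / "sets")

    models = train_base_models(
        feature_sets,
        train_matrix,
        backend_factory=backend_factory,
        seed=config.seed,
        metadata={"undersample_ratio": config.undersample_ratio,
                  "undersample_seed": config.seed},
    )
    plan = make_split_plan(
        train_matrix.group_ids,
        n_splits=config.n_splits,
        val_fraction=config.val_fraction,
        master_seed=config.seed + 2,
    )
    ensemble = backward_stepwise_models(models, train_matrix, plan)
    save_ensemble(ensemble, out_dir / "model")

    ranks = rank_pockets(matrix, ensemble)
    ranks.to_csv(out_dir / "ranks.tsv", sep="\t", index=False)

    surviving = {m.set_name for m in ensemble.members}

    def builder_for(subset_names):
        def build(train: FeatureMatrix, seed: int):
            sets = [s for s in feature_sets if s.set_name in subset_names]
            ms = train_base_models(
                sets, train, backend_factory=backend_factory, seed=seed
            )
            from .mef_ensemble import EnsembleModel

            ens = EnsembleModel(members=ms)
            return lambda val: predict_ensemble(ens, val)

        return build

    distributions = repeated_split_evaluation(
        builder_for(surviving), train_matrix, plan
    )
    base_means = {}
    for fset in feature_sets:
        d = repeated_split_evaluation(
            builder_for({fset.set_name}), train_matrix, plan,
            metrics=("average_precision",),
        )
        base_means[fset.set_name] = d["average_precision"].mean

    report = {
        "mean_validation_ap": distributions["average_precision"].mean,
        "mean_validation_roc_auc": distributions["roc_auc"].mean,
        "base_model_mean_ap": base_means,
        "n_members": len(ensemble.members),
        "elimination_trace": ensemble.elimination_trace,
        "per_split": {
            name: dist.values.tolist() for name, dist in distributions.items()
        },
    }
    (out_dir / "metrics.json").write_text(json.dumps(report, indent=2) + "\n")

    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_pockets": matrix.n_samples,
        "n_proteins": len(matrix.groups),
        "n_training_pockets": train_matrix.n_samples,
        "exclusions": exclusions,
        "surviving_members": sorted(surviving),
    }
    (out_dir / "run_manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return {
        "matrix": matrix,
        "train_matrix": train_matrix,
        "feature_sets": feature_sets,
        "ensemble": ensemble,
        "ranks": ranks,
        "distributions": distributions,
        "report": report,
        "exclusions": exclusions,
    }
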