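"""Undersampling, split plans, base models, backward elimination, ranking."""

import numpy as np
import pytest

from allopocket.containers import FeatureMatrix
from allopocket.evaluation_stats import average_precision
from allopocket.feature_selection import FeatureSet
from allopocket.mef_ensemble import (
    BaseModel,
    EnsembleModel,
    GradientBoostedCommittee,
    backward_stepwise_models,
    load_ensemble,
    make_split_plan,
    predict_ensemble,
    rank_pockets,
    save_ensemble,
    train_base_models,
    undersample_per_protein,
)
from allopocket.synthetic_fixtures import SyntheticSpec, generate_feature_matrix
from conftest import planted_matrix


def fast_backend():
    return GradientBoostedCommittee(n_members=2, n_estimators=30)


class TestUndersampling:
    def _protein(self, n_pos, n_neg, seed=0):
        rng = np.random.default_rng(seed)
        n = n_pos + n_neg
        return FeatureMatrix(
            values=rng.normal(size=(n, 3)),
            feature_names=("a", "b", "c"),
            labels=np.array([1] * n_pos + [0] * n_neg),
            group_ids=("P1",) * n,
            sample_ids=tuple(f"P1:{i+1}" for i in range(n)),
        )

    def test_one_positive_thirty_negatives(self):
        m = self._protein(1, 30)
        out = undersample_per_protein(m, ratio=5, seed=3)
        assert out.n_samples == 6
        assert out.labels.sum() == 1

    def test_below_ratio_kept_whole(self):
        m = self._protein(1, 3)
        out = undersample_per_protein(m, ratio=5, seed=3)
        assert out.n_samples == 4

    def test_positives_kept_and_deterministic(self):
        m = self._protein(3, 40, seed=5)
        a = undersample_per_protein(m, ratio=5, seed=7)
        b = undersample_per_protein(m, ratio=5, seed=7)
        assert a.labels.sum() == 3
        assert a.n_samples == 3 + 15
        assert a.sample_ids == b.sample_ids

    def test_no_positive_protein_dropped(self):
        rng = np.random.default_rng(8)
        m = FeatureMatrix(
            values=rng.normal(size=(6, 2)),
            feature_names=("a", "b"),
            labels=np.array([1, 0, 0, 0, 0, 0]),
            group_ids=("P1",) * 3 + ("P2",) * 3,
            sample_ids=tuple(f"S{i}" for i in range(6)),
        )
        out = undersample_per_protein(m, seed=0)
        assert set(out.group_ids) == {"P1"}


class TestSplitPlan:
    def test_holdout_size_and_partition(self):
        groups = [f"P{i}" for i in range(10)]
        plan = make_split_plan(groups, n_splits=7, val_fraction=0.2, master_seed=1)
        for train_g, val_g in plan.splits:
            assert len(val_g) == 2
            assert set(train_g) | set(val_g) == set(groups)
            assert not set(train_g) & set(val_g)

    def test_single_split(self):
        plan = make_split_plan([f"P{i}" for i in range(6)], n_splits=1,
                               val_fraction=0.2, master_seed=2)
        assert plan.n_splits == 1

    def test_reproducible(self):
        groups = [f"P{i}" for i in range(12)]
        a = make_split_plan(groups, n_splits=5, master_seed=4)
        b = make_split_plan(groups, n_splits=5, master_seed=4)
        assert a.splits == b.splits

    def test_too_few_groups(self):
        with pytest.raises(ValueError):
            make_split_plan(["P1", "P2"], n_splits=3)

    def test_group_integrity_exhaustive(self):
        spec = SyntheticSpec(n_proteins=15, seed=5)
        m = generate_feature_matrix(spec)
        plan = make_split_plan(m.group_ids, n_splits=20, master_seed=5)
        for train_g, val_g in plan.splits:
            train = m.rows_in_groups(train_g)
            val = m.rows_in_groups(val_g)
            assert not np.any(train & val)
            assert np.all(train | val)


def toy_sets(matrix, k=4):
    return [
        FeatureSet(
            set_name=f"set_{i}",
            features=matrix.feature_names,
            method="model_based",
            classifier_name="gradient_boosting",
        )
        for i in range(k)
    ]


class TestBaseModels:
    def test_one_model_per_set_and_training_quality(self, small_planted):
        sets = toy_sets(small_planted, 3)
        models = train_base_models(sets, small_planted,
                                   backend_factory=fast_backend, seed=1)
        assert [m.set_name for m in models] == ["set_0", "set_1", "set_2"]
        for m in models:
            ap = average_precision(m.predict(small_planted), small_planted.labels)
            assert ap >= 0.95

    def test_same_seed_identical_predictions(self, small_planted):
        sets = toy_sets(small_planted, 2)
        a = train_base_models(sets, small_planted, backend_factory=fast_backend,
                              seed=9)
        b = train_base_models(sets, small_planted, backend_factory=fast_backend,
                              seed=9)
        assert np.array_equal(a[0].predict(small_planted),
                              b[0].predict(small_planted))


class TestPredictEnsemble:
    def test_single_member_identity(self, small_planted):
        models = train_base_models(toy_sets(small_planted, 1), small_planted,
                                   backend_factory=fast_backend, seed=2)
        ens = EnsembleModel(members=models)
        assert np.array_equal(predict_ensemble(ens, small_planted),
                              models[0].predict(small_planted))

    def test_mean_of_members(self, small_planted):
        models = train_base_models(toy_sets(small_planted, 5), small_planted,
                                   backend_factory=fast_backend, seed=3)
        ens = EnsembleModel(members=models)
        combined = predict_ensemble(ens, small_planted)
        brute = sum(m.predict(small_planted) for m in models) / 5
        assert np.allclose(combined, brute, atol=1e-12)
        stacked = np.stack([m.predict(small_planted) for m in models])
        assert np.all(combined >= stacked.min(axis=0) - 1e-12)
        assert np.all(combined <= stacked.max(axis=0) + 1e-12)

    def test_member_permutation_invariance(self, small_planted):
        models = train_base_models(toy_sets(small_planted, 3), small_planted,
                                   backend_factory=fast_backend, seed=4)
        a = predict_ensemble(EnsembleModel(members=models), small_planted)
        b = predict_ensemble(EnsembleModel(members=models[::-1]), small_planted)
        assert np.allclose(a, b, atol=1e-12)

    def test_missing_column_errors(self, small_planted):
        models = train_base_models(toy_sets(small_planted, 1), small_planted,
                                   backend_factory=fast_backend, seed=5)
        reduced = FeatureMatrix(
            values=small_planted.values[:, :-1],
            feature_names=small_planted.feature_names[:-1],
            labels=small_planted.labels,
            group_ids=small_planted.group_ids,
            sample_ids=small_planted.sample_ids,
        )
        with pytest.raises(KeyError, match=small_planted.feature_names[-1]):
            predict_ensemble(EnsembleModel(members=models), reduced)


class _InvertingBackend(GradientBoostedCommittee):
    """Adversarial backend: always trains against inverted labels."""

    def fit(self, X, y, seed):
        return super().fit(X, 1 - np.asarray(y), seed)


class TestBackwardStepwise:
    def test_adversarial_member_removed_first(self):
        m = planted_matrix(n_samples=200, n_noise=10, effect=3.0, seed=51)
        sets = toy_sets(m, 4)
        models = train_base_models(sets[:3], m, backend_factory=fast_backend,
                                   seed=6)
        bad_backend = _InvertingBackend(n_members=2, n_estimators=30)
        bad_backend.fit(m.select(sets[3].features), m.labels, 99)
        models.append(BaseModel(feature_set=sets[3], backend=bad_backend, seed=99))
        plan = make_split_plan(m.group_ids, n_splits=5, master_seed=6)
        ens = backward_stepwise_models(models, m, plan)
        assert ens.elimination_trace
        assert ens.elimination_trace[0]["removed"] == "set_3"
        assert "set_3" not in [mm.set_name for mm in ens.members]

    def test_identical_members_nothing_removed(self, small_planted):
        sets = toy_sets(small_planted, 3)
        models = train_base_models(sets, small_planted,
                                   backend_factory=fast_backend, seed=7)
        # identical backends: same features, same seed
        for mm in models:
            mm.seed = 7
        plan = make_split_plan(small_planted.group_ids, n_splits=4,
                               master_seed=7)
        ens = backward_stepwise_models(models, small_planted, plan)
        assert ens.elimination_trace == []
        assert len(ens.members) == 3

    def test_trace_mean_metric_non_decreasing(self):
        m = planted_matrix(n_samples=250, n_noise=20, effect=1.0, seed=52)
        sets = toy_sets(m, 5)
        models = train_base_models(sets, m, backend_factory=fast_backend, seed=8)
        plan = make_split_plan(m.group_ids, n_splits=5, master_seed=8)
        ens = backward_stepwise_models(models, m, plan)
        for step in ens.elimination_trace:
            assert step["mean_metric_after"] >= step["mean_metric_before"]

    def test_needs_two_models(self, small_planted):
        models = train_base_models(toy_sets(small_planted, 1), small_planted,
                                   backend_factory=fast_backend, seed=9)
        plan = make_split_plan(small_planted.group_ids, n_splits=2,
                               master_seed=9)
        with pytest.raises(ValueError):
            backward_stepwise_models(models, small_planted, plan)


class TestRankPockets:
    def test_descending_with_fpocket_tiebreak(self, small_planted):
        models = train_base_models(toy_sets(small_planted, 1), small_planted,
                                   backend_factory=fast_backend, seed=10)
        ens = EnsembleModel(members=models)
        ranks = rank_pockets(small_planted, ens)
        for _, grp in ranks.groupby("structure_id"):
            probs = grp["probability"].to_numpy()
            assert np.all(np.diff(probs) <= 1e-12)
            ties = grp[grp["probability"].duplicated(keep=False)]
            for _, tie_grp in ties.groupby("probability"):
                assert tie_grp["pocket_id"].is_monotonic_increasing
        top = ranks[ranks["rank"] == 1]
        probs = predict_ensemble(ens, small_planted)
        for sid, grp_max in top.set_index("structure_id")["probability"].items():
            mask = np.array([g == sid for g in small_planted.group_ids])
            assert grp_max == pytest.approx(probs[mask].max())


def test_ensemble_roundtrip(tmp_path, small_planted):
    models = train_base_models(toy_sets(small_planted, 2), small_planted,
                               backend_factory=fast_backend, seed=11)
    ens = EnsembleModel(members=models)
    save_ensemble(ens, tmp_path / "bundle")
    loaded = load_ensemble(tmp_path / "bundle")
    assert np.allclose(
        predict_ensemble(ens, small_planted),
        predict_ensemble(loaded, small_planted),
    )
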