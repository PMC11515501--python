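import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from allopocket.containers import FeatureMatrix
from allopocket.synthetic_fixtures import generate_fpocket_fixture

#: Cheap classifier hyperparameters used throughout the suite; the
#: selection procedures are size-agnostic, so tests run them on small
#: tree ensembles.
FAST_CLASSIFIER_PARAMS = {
    "random_forest": {"n_estimators": 30, "max_depth": 5},
    "extra_trees": {"n_estimators": 30, "max_depth": 5},
    "gradient_boosting": {"n_estimators": 25, "max_depth": 2},
    "adaboost": {"n_estimators": 20},
}


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """A miniature protein + Fpocket run + annotations, with manifest."""
    d = tmp_path_factory.mktemp("toy_fixture")
    manifest = generate_fpocket_fixture(d, seed=7)
    return d, manifest


def planted_matrix(
    n_samples: int = 300,
    n_informative: int = 5,
    n_noise: int = 45,
    effect: float = 2.0,
    seed: int = 0,
    group_size: int = 10,
) -> FeatureMatrix:
    """Balanced-label planted-signal matrix for selection tests."""
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, n_samples)
    X = rng.normal(size=(n_samples, n_informative + n_noise))
    X[:, :n_informative] += effect * y[:, None]
    names = tuple(
        [f"inf_{i+1}" for i in range(n_informative)]
        + [f"noise_{i+1}" for i in range(n_noise)]
    )
    groups = tuple(f"G{i // group_size:03d}" for i in range(n_samples))
    samples = tuple(f"G{i // group_size:03d}:{i % group_size + 1}" for i in range(n_samples))
    return FeatureMatrix(
        values=X, feature_names=names, labels=y, group_ids=groups,
        sample_ids=samples,
    )


@pytest.fixture
def small_planted():
    return planted_matrix(n_samples=200, n_noise=15, seed=3)


@pytest.fixture
def three_protein_config(fixture_dir, tmp_path):
    """Pipeline config over three copies of the toy fixture: toyprot
    (kept), toyprot2 (no positive labels), toyprot3 (TM-score redundant)."""
    import shutil

    from allopocket.pipeline import RunConfig

    d, manifest = fixture_dir
    p2 = shutil.copytree(d, tmp_path / "p2")
    p3 = shutil.copytree(d, tmp_path / "p3")
    ann = tmp_path / "annotations.tsv"
    lines = ["structure_id\tchain_id\tresidue_number"]
    for c, n in manifest["annotated_residues"]:
        lines.append(f"toyprot\t{c}\t{n}")
        lines.append(f"toyprot3\t{c}\t{n}")
    # toyprot2 gets no annotated residues at all
    ann.write_text("\n".join(lines) + "\n")
    tm = tmp_path / "tm_scores.tsv"
    tm.write_text("structure_id\ttm_score\ntoyprot\t0.50\ntoyprot3\t0.51\n")
    config = RunConfig(
        structures=[
            {"structure_id": "toyprot", "pdb": str(d / "toyprot.pdb"),
             "fpocket_dir": str(d / manifest["run_dir"])},
            {"structure_id": "toyprot2", "pdb": str(p2 / "toyprot.pdb"),
             "fpocket_dir": str(p2 / manifest["run_dir"])},
            {"structure_id": "toyprot3", "pdb": str(p3 / "toyprot.pdb"),
             "fpocket_dir": str(p3 / manifest["run_dir"])},
        ],
        annotations=str(ann),
        tm_table=str(tm),
        output_dir=str(tmp_path / "run"),
    )
    return config, manifest
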