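"""Self-contained synthetic inputs for every stage of the pipeline.

Three generators:

* :func:`generate_feature_matrix` — a pockets-by-features table with a
  planted signal.  Proteins get a uniform random pocket count (3-41 by
  default, matching the spread of cavity counts on real training
  proteins) with one allosteric pocket each; informative features are
  shifted Gaussians (standardized mean shift ``effect_size`` between
  classes), noise features are standard Gaussians.

* :func:`generate_fpocket_fixture` — a miniature PDB file with deliberate
  blemishes (incomplete residues, waters, an ion, a ligand, a nucleotide
  chain), an Fpocket-style run directory with per-pocket atom files and a
  19-key descriptor report, an annotation TSV, and a ground-truth
  manifest.

* :func:`generate_metric_cases` — random score/label vectors bundled with
  brute-force average-precision / ROC-AUC oracle values (the naive
  implementations live here and are deliberately loop-based, independent
  of the metric module).

All generators are pure functions of their spec and seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .containers import FeatureMatrix
from .structure_io import FPOCKET_FIELDS

__all__ = [
    "SyntheticSpec",
    "generate_feature_matrix",
    "generate_fpocket_fixture",
    "generate_metric_cases",
    "naive_average_precision",
    "naive_roc_auc",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for the planted-signal feature matrix."""

    n_proteins: int = 90
    pockets_per_protein: tuple[int, int] = (3, 41)
    positives_per_protein: int = 1
    n_informative: int = 5
    n_noise: int = 45
    effect_size: float = 2.0
    label_noise_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.pockets_per_protein
        if not (1 <= lo <= hi <= 200):
            raise ValueError("pockets_per_protein range must lie in [1, 200]")
        if self.positives_per_protein < 1 or self.positives_per_protein > lo:
            raise ValueError(
                "positives_per_protein must be >= 1 and fit the smallest protein"
            )
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if not (0.0 <= self.label_noise_rate < 1.0):
            raise ValueError("label_noise_rate must be in [0, 1)")
        if self.n_informative < 0 or self.n_noise < 0:
            raise ValueError("feature counts must be nonnegative")


def generate_feature_matrix(spec: SyntheticSpec) -> FeatureMatrix:
    """Draw a feature matrix under ``spec``; bitwise reproducible from
    ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.pockets_per_protein
    rows = []
    labels = []
    groups = []
    samples = []
    for p in range(spec.n_proteins):
        gid = f"SYN{p:04d}"
        n_pockets = int(rng.integers(lo, hi + 1))
        y = np.zeros(n_pockets, dtype=int)
        pos = rng.choice(n_pockets, size=spec.positives_per_protein, replace=False)
        y[pos] = 1
        if spec.label_noise_rate > 0:
            flips = rng.random(n_pockets) < spec.label_noise_rate
            y = np.where(flips, 1 - y, y)
        informative = (
            rng.normal(size=(n_pockets, spec.n_informative))
            + spec.effect_size * y[:, None]
        )
        noise = rng.normal(size=(n_pockets, spec.n_noise))
        rows.append(np.hstack([informative, noise]))
        labels.append(y)
        groups.extend([gid] * n_pockets)
        samples.extend(f"{gid}:{j + 1}" for j in range(n_pockets))
    names = tuple(
        [f"inf_{i + 1}" for i in range(spec.n_informative)]
        + [f"noise_{i + 1}" for i in range(spec.n_noise)]
    )
    return FeatureMatrix(
        values=np.vstack(rows),
        feature_names=names,
        labels=np.concatenate(labels),
        group_ids=tuple(groups),
        sample_ids=tuple(samples),
    )


# ---------------------------------------------------------------------------
# Miniature PDB / Fpocket fixtures

_AA_CYCLE = ("GLY", "ALA", "SER", "LEU", "LYS", "ASP", "PHE", "THR", "VAL", "GLU")
_FULL_BACKBONE = ("N", "CA", "C", "O", "CB")
_INCOMPLETE = ("N", "CA")

_ELEMENT = {"N": "N", "CA": "C", "C": "C", "O": "O", "CB": "C",
            "P": "P", "OW": "O", "NA": "NA"}


def _pdb_line(
    record: str, serial: int, name: str, resname: str, chain: str,
    resnum: int, x: float, y: float, z: float, element: str, icode: str = ""
) -> str:
    return (
        f"{record:<6s}{serial:5d} {name:^4s}{'':1s}{resname:>3s} {chain:1s}"
        f"{resnum:4d}{icode or '':1s}   {x:8.3f}{y:8.3f}{z:8.3f}"
        f"{1.00:6.2f}{20.00:6.2f}          {element:>2s}"
    )


def generate_fpocket_fixture(
    out_dir: str | Path,
    n_residues: int = 24,
    incomplete_residues: tuple[int, ...] = (3, 7),
    with_nucleotide_chain: bool = True,
    seed: int = 0,
) -> dict:
    """Write a toy protein PDB, an Fpocket-style run directory, an
    annotation TSV and a ground-truth manifest under ``out_dir``.

    Layout of the toy system (structure id ``toyprot``):

    * chain A: ``n_residues`` amino acids numbered from 1; residues in
      ``incomplete_residues`` carry only N and CA atoms; plus two waters,
      one sodium ion and one 3-atom LIG heteroligand;
    * chain B (optional): four DNA nucleotides;
    * pocket 1 (allosteric): amino acids 2-6 of chain A, written with
      backbone-only atoms so completion has something to restore;
    * pocket 2 (negative): amino acids 10-14 of chain A;
    * pocket 3 (nucleotide-only, present when chain B is): residues B:1-3.

    Returns the manifest dict (also written as ``manifest.json``).
    """
    rng = np.random.default_rng(seed)
    out_dir = Path(out_dir)
    run_dir = out_dir / "toyprot_out"
    run_dir.mkdir(parents=True, exist_ok=True)

    coords: dict[tuple[str, int], dict[str, tuple[float, float, float]]] = {}

    def coord(chain: str, resnum: int, name: str) -> tuple[float, float, float]:
        res = coords.setdefault((chain, resnum), {})
        if name not in res:
            base = np.array([resnum * 3.8, 0.0, 0.0])
            res[name] = tuple(
                float(v) for v in base + rng.normal(scale=0.5, size=3)
            )
        return res[name]

    lines = ["REMARK   2 RESOLUTION.    1.80 ANGSTROMS."]
    serial = 1
    protein_atoms: dict[tuple[str, int], list[str]] = {}
    for i in range(1, n_residues + 1):
        resname = _AA_CYCLE[(i - 1) % len(_AA_CYCLE)]
        atom_names = _INCOMPLETE if i in incomplete_residues else _FULL_BACKBONE
        if resname == "GLY":
            atom_names = tuple(a for a in atom_names if a != "CB")
        protein_atoms[("A", i)] = list(atom_names)
        for name in atom_names:
            x, y, z = coord("A", i, name)
            lines.append(
                _pdb_line("ATOM", serial, name, resname, "A", i, x, y, z,
                          _ELEMENT[name])
            )
            serial += 1
    nucleotide_residues = []
    if with_nucleotide_chain:
        for j, resname in enumerate(("DA", "DT", "DG", "DC"), start=1):
            nucleotide_residues.append(("B", j, resname))
            for name in ("P", "C", "N"):
                x, y, z = coord("B", j, name)
                lines.append(
                    _pdb_line("ATOM", serial, name, resname, "B", j, x, y, z,
                              _ELEMENT.get(name, name))
                )
                serial += 1
    waters = [901, 902]
    for w in waters:
        x, y, z = coord("W", w, "O")
        lines.append(_pdb_line("HETATM", serial, "O", "HOH", "A", w, x, y, z, "O"))
        serial += 1
    ion_resnum = 903
    x, y, z = coord("W", ion_resnum, "NA")
    lines.append(_pdb_line("HETATM", serial, "NA", "NA", "A", ion_resnum, x, y, z, "NA"))
    serial += 1
    ligand_resnum = 904
    for name in ("C1", "C2", "O1"):
        x, y, z = coord("L", ligand_resnum, name)
        lines.append(
            _pdb_line("HETATM", serial, name, "LIG", "A", ligand_resnum, x, y, z,
                      name[0])
        )
        serial += 1
    lines.append("END")
    pdb_path = out_dir / "toyprot.pdb"
    pdb_path.write_text("\n".join(lines) + "\n")

    # pocket atom files: backbone-only so residue completion is observable
    pockets = {1: [("A", r) for r in range(2, 7)],
               2: [("A", r) for r in range(10, 15)]}
    if with_nucleotide_chain:
        pockets[3] = [("B", j) for j in range(1, 4)]
    for pid, residues in pockets.items():
        plines = []
        pserial = 1
        for chain, resnum in residues:
            if chain == "A":
                resname = _AA_CYCLE[(resnum - 1) % len(_AA_CYCLE)]
                names = [n for n in ("N", "CA") if n in protein_atoms[(chain, resnum)]]
            else:
                resname = nucleotide_residues[resnum - 1][2]
                names = ["P", "C"]
            for name in names:
                x, y, z = coord(chain, resnum, name)
                plines.append(
                    _pdb_line("ATOM", pserial, name, resname, chain, resnum,
                              x, y, z, _ELEMENT.get(name, name[0]))
                )
                pserial += 1
        plines.append("END")
        (run_dir / f"pocket{pid}_atm.pdb").write_text("\n".join(plines) + "\n")

    descriptor_values: dict[int, dict[str, float]] = {}
    info_lines = []
    for pid in sorted(pockets):
        info_lines.append(f"Pocket {pid} :")
        vals = {}
        for k, fname in enumerate(FPOCKET_FIELDS):
            if fname == "n_alpha_spheres":
                v = float(int(rng.integers(5, 40)))
            else:
                v = round(float(rng.uniform(0.0, 10.0)), 4)
            vals[fname] = v
        descriptor_values[pid] = vals
        label_map = {
            "score": "Score", "druggability_score": "Druggability Score",
            "n_alpha_spheres": "Number of Alpha Spheres",
            "total_sasa": "Total SASA", "polar_sasa": "Polar SASA",
            "apolar_sasa": "Apolar SASA", "volume": "Volume",
            "mean_local_hydrophobic_density": "Mean local hydrophobic density",
            "mean_alpha_sphere_radius": "Mean alpha sphere radius",
            "mean_alpha_sphere_solvent_access": "Mean alp. sph. solvent access",
            "apolar_alpha_sphere_proportion": "Apolar alpha sphere proportion",
            "hydrophobicity_score": "Hydrophobicity score",
            "volume_score": "Volume score", "polarity_score": "Polarity score",
            "charge_score": "Charge score",
            "proportion_polar_atoms": "Proportion of polar atoms",
            "alpha_sphere_density": "Alpha sphere density",
            "com_alpha_sphere_max_dist": "Cent. of mass - Alpha Sphere max dist",
            "flexibility": "Flexibility",
        }
        for fname in FPOCKET_FIELDS:
            info_lines.append(f"\t{label_map[fname]} : \t{vals[fname]}")
        info_lines.append("")
    (run_dir / "toyprot_info.txt").write_text("\n".join(info_lines) + "\n")

    # annotation: two residues inside pocket 1
    annotated = [("A", 3), ("A", 5)]
    ann_lines = ["structure_id\tchain_id\tresidue_number"]
    ann_lines += [f"toyprot\t{c}\t{n}" for c, n in annotated]
    (out_dir / "annotations.tsv").write_text("\n".join(ann_lines) + "\n")

    manifest = {
        "structure_id": "toyprot",
        "pdb": pdb_path.name,
        "run_dir": run_dir.name,
        "n_protein_residues": n_residues,
        "incomplete_residues": [["A", r] for r in incomplete_residues],
        "waters": [["A", w] for w in waters],
        "ions": [["A", ion_resnum]],
        "ligands": [["A", ligand_resnum]],
        "nucleotide_residues": [[c, n] for c, n, _ in nucleotide_residues],
        "pockets": {
            str(pid): [[c, n] for c, n in residues]
            for pid, residues in pockets.items()
        },
        "descriptors": {str(pid): v for pid, v in descriptor_values.items()},
        "allosteric_pocket": 1,
        "nucleotide_only_pockets": [3] if with_nucleotide_chain else [],
        "annotated_residues": [[c, n] for c, n in annotated],
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest


# ---------------------------------------------------------------------------
# Brute-force metric oracles


def naive_average_precision(scores, labels) -> float:
    """Step-interpolated AP by explicit threshold sweep (oracle)."""
    scores = list(map(float, scores))
    labels = list(map(int, labels))
    n_pos = sum(labels)
    if n_pos == 0:
        raise ValueError("no positives")
    order = sorted(range(len(scores)), key=lambda i: (-scores[i], i))
    thresholds = sorted({s for s in scores}, reverse=True)
    ap = 0.0
    prev_recall = 0.0
    for t in thresholds:
        pred = [i for i in order if scores[i] >= t]
        tp = sum(1 for i in pred if labels[i] == 1)
        precision = tp / len(pred)
        recall = tp / n_pos
        ap += (recall - prev_recall) * precision
        prev_recall = recall
    return ap


def naive_roc_auc(scores, labels) -> float:
    """Exhaustive concordant-pair count with half credit for ties (oracle)."""
    scores = list(map(float, scores))
    labels = list(map(int, labels))
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    if not pos or not neg:
        raise ValueError("need both classes")
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def generate_metric_cases(seed: int, n_cases: int = 200) -> list[dict]:
    """Random score/label vectors with oracle AP and AUC values attached.

    Includes degenerate cases: an all-ties vector (AUC exactly 0.5) and an
    all-positive vector (AP 1.0, AUC undefined -> ``auc`` is None).
    """
    rng = np.random.default_rng(seed)
    cases: list[dict] = []
    for _ in range(n_cases - 2):
        n = int(rng.integers(4, 40))
        scores = rng.random(n)
        if rng.random() < 0.3:  # introduce ties
            scores = np.round(scores, 1)
        labels = (rng.random(n) < rng.uniform(0.1, 0.6)).astype(int)
        if labels.sum() == 0:
            labels[int(rng.integers(0, n))] = 1
        if labels.sum() == n:
            labels[int(rng.integers(0, n))] = 0
        cases.append(
            {
                "scores": scores.tolist(),
                "labels": labels.tolist(),
                "ap": naive_average_precision(scores, labels),
                "auc": naive_roc_auc(scores, labels),
            }
        )
    ties_scores = [0.5] * 8
    ties_labels = [1, 0, 1, 0, 0, 1, 0, 0]
    cases.append(
        {
            "scores": ties_scores,
            "labels": ties_labels,
            "ap": naive_average_precision(ties_scores, ties_labels),
            "auc": 0.5,
        }
    )
    cases.append(
        {"scores": [0.9, 0.4, 0.2], "labels": [1, 1, 1], "ap": 1.0, "auc": None}
    )
    return cases
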