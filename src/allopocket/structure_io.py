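"""Reading, cleaning and labelling protein structures and Fpocket output.

The pocket-ranking pipeline starts from a PDB structure and an Fpocket run
directory.  This module parses both into plain in-memory records, removes
the material Fpocket should never see (waters, free ions, free atoms,
bound ligands), restores incompletely resolved pocket residues from the
parent structure, drops nucleotide-only pockets, applies chain-selection
modes, and assigns the binary allosteric label: a pocket is positive iff
it shares at least one residue with the annotated allosteric site.

PDB parsing is delegated to Biopython; only the first MODEL is used and,
for alternate locations, the first-listed conformer of each atom is kept.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd
from Bio.PDB import PDBParser

from .aa_data import (
    ION_NAMES,
    NUCLEOTIDE_NAMES,
    STANDARD_AA_NAMES,
    THREE_TO_ONE,
    WATER_NAMES,
)

logger = logging.getLogger(__name__)

__all__ = [
    "AtomRecord",
    "Residue",
    "ProteinStructure",
    "FpocketDescriptors",
    "Pocket",
    "AllostericAnnotation",
    "StructureFormatError",
    "FpocketFormatError",
    "parse_pdb",
    "clean_structure",
    "parse_fpocket_run",
    "complete_residues",
    "filter_nucleotide_pockets",
    "label_pockets",
    "select_chains",
    "residue_kind",
    "read_annotations",
    "write_pocket_pdb",
    "pocket_table",
]


class StructureFormatError(ValueError):
    """Raised for unparseable or empty structure input."""


class FpocketFormatError(ValueError):
    """Raised when an Fpocket run directory is malformed."""


ResidueKey = tuple[str, int, str]


@dataclass(frozen=True)
class AtomRecord:
    serial: int
    atom_name: str
    residue_name: str
    chain_id: str
    residue_number: int
    insertion_code: str
    x: float
    y: float
    z: float
    element: str
    is_hetero: bool

    def __post_init__(self) -> None:
        if self.serial < 1:
            raise ValueError(f"atom serial must be >= 1, got {self.serial}")
        if not all(math.isfinite(c) for c in (self.x, self.y, self.z)):
            raise ValueError(f"non-finite coordinates for atom {self.serial}")


RESIDUE_KINDS = ("standard-aa", "nucleotide", "water", "ion", "other-hetero")


def residue_kind(residue_name: str) -> str:
    """Classify a residue name against the bundled name tables."""
    name = residue_name.strip().upper()
    if name in WATER_NAMES:
        return "water"
    if name in STANDARD_AA_NAMES:
        return "standard-aa"
    if name in NUCLEOTIDE_NAMES:
        return "nucleotide"
    if name in ION_NAMES:
        return "ion"
    return "other-hetero"


@dataclass(frozen=True)
class Residue:
    chain_id: str
    residue_number: int
    insertion_code: str
    residue_name: str
    atoms: tuple[AtomRecord, ...]
    kind: str = field(init=False)

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError("residue must contain at least one atom")
        key = (self.chain_id, self.residue_number, self.insertion_code)
        for a in self.atoms:
            if (a.chain_id, a.residue_number, a.insertion_code) != key:
                raise ValueError(f"atom {a.serial} does not belong to residue {key}")
        object.__setattr__(self, "kind", residue_kind(self.residue_name))

    @property
    def key(self) -> ResidueKey:
        return (self.chain_id, self.residue_number, self.insertion_code)

    @property
    def one_letter(self) -> str | None:
        return THREE_TO_ONE.get(self.residue_name.strip().upper())


@dataclass(frozen=True)
class ProteinStructure:
    structure_id: str
    residues: tuple[Residue, ...]

    def __post_init__(self) -> None:
        keys = [r.key for r in self.residues]
        if len(keys) != len(set(keys)):
            raise ValueError(f"{self.structure_id}: duplicate residue keys")

    @property
    def chain_ids(self) -> set[str]:
        return {r.chain_id for r in self.residues}

    def residue_map(self) -> dict[ResidueKey, Residue]:
        return {r.key: r for r in self.residues}


#: The 19 Fpocket per-pocket descriptors, in report order.
FPOCKET_FIELDS = (
    "score",
    "druggability_score",
    "n_alpha_spheres",
    "total_sasa",
    "polar_sasa",
    "apolar_sasa",
    "volume",
    "mean_local_hydrophobic_density",
    "mean_alpha_sphere_radius",
    "mean_alpha_sphere_solvent_access",
    "apolar_alpha_sphere_proportion",
    "hydrophobicity_score",
    "volume_score",
    "polarity_score",
    "charge_score",
    "proportion_polar_atoms",
    "alpha_sphere_density",
    "com_alpha_sphere_max_dist",
    "flexibility",
)


@dataclass(frozen=True)
class FpocketDescriptors:
    score: float
    druggability_score: float
    n_alpha_spheres: float
    total_sasa: float
    polar_sasa: float
    apolar_sasa: float
    volume: float
    mean_local_hydrophobic_density: float
    mean_alpha_sphere_radius: float
    mean_alpha_sphere_solvent_access: float
    apolar_alpha_sphere_proportion: float
    hydrophobicity_score: float
    volume_score: float
    polarity_score: float
    charge_score: float
    proportion_polar_atoms: float
    alpha_sphere_density: float
    com_alpha_sphere_max_dist: float
    flexibility: float

    def __post_init__(self) -> None:
        for name in FPOCKET_FIELDS:
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"descriptor {name} is not finite")
        if self.n_alpha_spheres < 1:
            raise ValueError("n_alpha_spheres must be >= 1")

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in FPOCKET_FIELDS}


@dataclass(frozen=True)
class Pocket:
    pocket_id: int
    residues: tuple[Residue, ...]
    descriptors: FpocketDescriptors
    label: int | None = None
    completed: bool = False

    def __post_init__(self) -> None:
        keys = [r.key for r in self.residues]
        if keys != sorted(keys):
            raise ValueError(
                f"pocket {self.pocket_id}: residues not in canonical order"
            )
        if len(keys) != len(set(keys)):
            raise ValueError(f"pocket {self.pocket_id}: duplicate residues")

    @property
    def residue_keys(self) -> tuple[ResidueKey, ...]:
        return tuple(r.key for r in self.residues)


@dataclass(frozen=True)
class AllostericAnnotation:
    structure_id: str
    residues: frozenset[tuple[str, int]]


# ---------------------------------------------------------------------------
# PDB parsing


def _canonical_residues(residues: list[Residue]) -> tuple[Residue, ...]:
    return tuple(sorted(residues, key=lambda r: r.key))


def parse_pdb(path: str | Path, structure_id: str | None = None) -> ProteinStructure:
    """Parse a PDB file into a :class:`ProteinStructure`.

    Only the first MODEL is read; for atoms with alternate locations the
    first-listed conformer is kept.  Residue order follows the file.
    """
    path = Path(path)
    sid = structure_id or path.stem
    parser = PDBParser(QUIET=True)
    try:
        structure = parser.get_structure(sid, str(path))
    except Exception as exc:  # Biopython raises assorted errors on garbage
        raise StructureFormatError(f"{path}: cannot parse PDB ({exc})") from exc
    models = list(structure.get_models())
    if not models:
        raise StructureFormatError(f"{path}: no ATOM records")
    model = models[0]

    residues: list[Residue] = []
    for chain in model:
        for res in chain:
            hetfield, resseq, icode = res.id
            is_hetero = bool(hetfield.strip())
            icode = icode.strip()
            # for altloc duplicates keep the first-listed conformer; the
            # unpacked list may be altloc-sorted, but serials follow the file
            by_name: dict[str, object] = {}
            for atom in res.get_unpacked_list():
                prev = by_name.get(atom.name)
                if prev is None or atom.serial_number < prev.serial_number:
                    by_name[atom.name] = atom
            atoms: list[AtomRecord] = []
            for atom in sorted(by_name.values(), key=lambda a: a.serial_number):
                atoms.append(
                    AtomRecord(
                        serial=int(atom.serial_number),
                        atom_name=atom.name,
                        residue_name=res.resname.strip(),
                        chain_id=chain.id,
                        residue_number=int(resseq),
                        insertion_code=icode,
                        x=float(atom.coord[0]),
                        y=float(atom.coord[1]),
                        z=float(atom.coord[2]),
                        element=(atom.element or "").strip(),
                        is_hetero=is_hetero,
                    )
                )
            if atoms:
                residues.append(
                    Residue(
                        chain_id=chain.id,
                        residue_number=int(resseq),
                        insertion_code=icode,
                        residue_name=res.resname.strip(),
                        atoms=tuple(atoms),
                    )
                )
    if not residues:
        raise StructureFormatError(f"{path}: no ATOM records")
    return ProteinStructure(structure_id=sid, residues=tuple(residues))


def clean_structure(structure: ProteinStructure) -> ProteinStructure:
    """Drop waters, ions, free atoms and bound ligands.

    Only standard amino acids and nucleotides survive; Fpocket is run on
    the cleaned structure.  The input is not mutated and residue order is
    preserved.
    """
    kept = tuple(
        r for r in structure.residues if r.kind in ("standard-aa", "nucleotide")
    )
    if not kept:
        logger.warning("%s: cleaning removed every residue", structure.structure_id)
    return ProteinStructure(structure_id=structure.structure_id, residues=kept)


# ---------------------------------------------------------------------------
# Fpocket run parsing

# Fpocket report key -> descriptor field (keys lowercased, whitespace
# normalized).  Both historical spellings of the solvent-access and
# centre-of-mass keys are accepted.
_FPOCKET_KEY_MAP = {
    "score": "score",
    "druggability score": "druggability_score",
    "number of alpha spheres": "n_alpha_spheres",
    "total sasa": "total_sasa",
    "polar sasa": "polar_sasa",
    "apolar sasa": "apolar_sasa",
    "volume": "volume",
    "mean local hydrophobic density": "mean_local_hydrophobic_density",
    "mean alpha sphere radius": "mean_alpha_sphere_radius",
    "mean alp. sph. solvent access": "mean_alpha_sphere_solvent_access",
    "mean alpha sphere solvent access": "mean_alpha_sphere_solvent_access",
    "apolar alpha sphere proportion": "apolar_alpha_sphere_proportion",
    "hydrophobicity score": "hydrophobicity_score",
    "volume score": "volume_score",
    "polarity score": "polarity_score",
    "charge score": "charge_score",
    "proportion of polar atoms": "proportion_polar_atoms",
    "alpha sphere density": "alpha_sphere_density",
    "cent. of mass - alpha sphere max dist": "com_alpha_sphere_max_dist",
    "center of mass - alpha sphere max dist": "com_alpha_sphere_max_dist",
    "flexibility": "flexibility",
}

_POCKET_HEADER_RE = re.compile(r"^\s*pocket\s+(\d+)\s*:?\s*$", re.IGNORECASE)
_ATM_FILE_RE = re.compile(r"^pocket(\d+)_atm\.pdb$")
_INFO_FILE_RE = re.compile(r"^pocket(\d+)_info\.txt$")


def _normalize_key(raw: str) -> str:
    return " ".join(raw.strip().lower().split())


def _parse_info_block(lines: list[str], pocket_id: int) -> FpocketDescriptors:
    values: dict[str, float] = {}
    for line in lines:
        if ":" not in line:
            continue
        key, _, value = line.partition(":")
        field_name = _FPOCKET_KEY_MAP.get(_normalize_key(key))
        if field_name is None:
            continue
        try:
            values[field_name] = float(value.strip())
        except ValueError as exc:
            raise FpocketFormatError(
                f"pocket {pocket_id}: bad value for {field_name!r}: {value!r}"
            ) from exc
    missing = [f for f in FPOCKET_FIELDS if f not in values]
    if missing:
        raise FpocketFormatError(
            f"pocket {pocket_id}: missing descriptor key(s) {missing}"
        )
    return FpocketDescriptors(**values)


def _parse_info_report(path: Path) -> dict[int, FpocketDescriptors]:
    blocks: dict[int, list[str]] = {}
    current: list[str] | None = None
    for line in path.read_text().splitlines():
        m = _POCKET_HEADER_RE.match(line)
        if m:
            current = blocks.setdefault(int(m.group(1)), [])
        elif current is not None:
            current.append(line)
    return {pid: _parse_info_block(lines, pid) for pid, lines in blocks.items()}


def parse_fpocket_run(
    run_dir: str | Path, parent: ProteinStructure
) -> list[Pocket]:
    """Parse an Fpocket run directory into a list of :class:`Pocket`.

    Expects ``pocketN_atm.pdb`` atom files (directly in ``run_dir`` or
    under a ``pockets/`` subdirectory) plus the 19-descriptor report,
    either a single ``*_info.txt`` with ``Pocket N`` block headers or
    per-pocket ``pocketN_info.txt`` files.
    """
    run_dir = Path(run_dir)
    if not run_dir.is_dir():
        raise FpocketFormatError(f"{run_dir} is not a directory")

    descriptors: dict[int, FpocketDescriptors] = {}
    per_pocket_infos = sorted(
        p for p in run_dir.rglob("pocket*_info.txt") if _INFO_FILE_RE.match(p.name)
    )
    if per_pocket_infos:
        for p in per_pocket_infos:
            pid = int(_INFO_FILE_RE.match(p.name).group(1))
            descriptors[pid] = _parse_info_block(
                p.read_text().splitlines(), pid
            )
    else:
        reports = sorted(run_dir.glob("*_info.txt"))
        if not reports:
            return []
        for report in reports:
            descriptors.update(_parse_info_report(report))
    if not descriptors:
        return []

    atom_files: dict[int, Path] = {}
    for p in run_dir.rglob("pocket*_atm.pdb"):
        m = _ATM_FILE_RE.match(p.name)
        if m:
            atom_files[int(m.group(1))] = p

    pockets: list[Pocket] = []
    for pid in sorted(descriptors):
        atm = atom_files.get(pid)
        if atm is None:
            raise FpocketFormatError(f"pocket {pid}: missing atom file")
        pocket_struct = parse_pdb(atm, structure_id=f"{parent.structure_id}_p{pid}")
        unique: dict[ResidueKey, Residue] = {}
        for res in pocket_struct.residues:
            unique.setdefault(res.key, res)
        pockets.append(
            Pocket(
                pocket_id=pid,
                residues=_canonical_residues(list(unique.values())),
                descriptors=descriptors[pid],
            )
        )
    return pockets


# ---------------------------------------------------------------------------
# Pocket post-processing


def complete_residues(pocket: Pocket, parent: ProteinStructure) -> Pocket:
    """Replace each pocket residue's atoms with the parent structure's full
    atom list for that residue.

    Fpocket's cavity files may carry only the atoms contacting alpha
    spheres; sequence descriptors should see whole residues.  The 19
    Fpocket descriptor values are left untouched.
    """
    parent_map = parent.residue_map()
    completed = []
    for res in pocket.residues:
        full = parent_map.get(res.key)
        if full is None:
            raise LookupError(
                f"pocket {pocket.pocket_id}: residue {res.key} absent from "
                f"parent structure {parent.structure_id}"
            )
        completed.append(full)
    return replace(pocket, residues=_canonical_residues(completed), completed=True)


def filter_nucleotide_pockets(pockets: list[Pocket]) -> list[Pocket]:
    """Drop pockets whose residues are all nucleotides.

    Such cavities cannot be protein allosteric sites.  Pocket ids are not
    renumbered so Fpocket's original ranks stay meaningful.
    """
    return [
        p
        for p in pockets
        if not all(r.kind == "nucleotide" for r in p.residues)
    ]


def label_pockets(
    pockets: list[Pocket], annotation: AllostericAnnotation
) -> tuple[list[Pocket], bool]:
    """Assign the binary allosteric label to each pocket.

    A pocket is positive iff any of its residues (matched on chain id and
    residue number) appears in the annotated allosteric-site residue set.
    Returns the labelled pockets and a protein-level ``has_positive`` flag;
    proteins without a positive are excluded from training downstream.
    """
    labelled = []
    any_positive = False
    for p in pockets:
        hit = any(
            (r.chain_id, r.residue_number) in annotation.residues
            for r in p.residues
        )
        any_positive = any_positive or hit
        labelled.append(replace(p, label=int(hit)))
    return labelled, any_positive


def select_chains(
    structure: ProteinStructure,
    annotation: AllostericAnnotation,
    mode: str,
) -> ProteinStructure:
    """Apply a chain-selection mode.

    ``allosteric-chains-only`` keeps exactly the chains that carry at least
    one annotated residue (the easier, chain-resolved evaluation setting);
    ``all-chains`` returns the structure unchanged (the realistic setting
    where the allosteric chain is unknown).
    """
    if mode == "all-chains":
        return structure
    if mode != "allosteric-chains-only":
        raise ValueError(f"unknown chain mode {mode!r}")
    chains = {c for (c, _n) in annotation.residues}
    if not chains:
        raise ValueError(
            f"{structure.structure_id}: empty annotation, no chain selectable"
        )
    kept = tuple(r for r in structure.residues if r.chain_id in chains)
    return ProteinStructure(structure_id=structure.structure_id, residues=kept)


# ---------------------------------------------------------------------------
# Tabular I/O


def read_annotations(path: str | Path) -> dict[str, AllostericAnnotation]:
    """Read an annotation TSV (structure_id, chain_id, residue_number)."""
    df = pd.read_csv(path, sep="\t", dtype={"chain_id": str})
    required = {"structure_id", "chain_id", "residue_number"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"annotation file must have columns {sorted(required)}"
        )
    out: dict[str, AllostericAnnotation] = {}
    for sid, grp in df.groupby("structure_id"):
        out[str(sid)] = AllostericAnnotation(
            structure_id=str(sid),
            residues=frozenset(
                (str(c), int(n))
                for c, n in zip(grp["chain_id"], grp["residue_number"])
            ),
        )
    return out


def write_pocket_pdb(pocket: Pocket, path: str | Path) -> None:
    """Write a pocket's residues as a minimal PDB file."""
    lines = []
    serial = 1
    for res in pocket.residues:
        record = "HETATM" if res.atoms[0].is_hetero else "ATOM  "
        for a in res.atoms:
            lines.append(
                f"{record}{serial:5d} {a.atom_name:^4s}{'':1s}{a.residue_name:>3s} "
                f"{a.chain_id:1s}{a.residue_number:4d}{a.insertion_code or '':1s}   "
                f"{a.x:8.3f}{a.y:8.3f}{a.z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
                f"{a.element:>2s}"
            )
            serial += 1
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def pocket_table(structure_id: str, pockets: list[Pocket]) -> pd.DataFrame:
    """Tabulate labelled pockets: id, label and the 19 descriptors."""
    rows = []
    for p in pockets:
        row = {"structure_id": structure_id, "pocket_id": p.pocket_id,
               "label": p.label}
        row.update(p.descriptors.as_dict())
        rows.append(row)
    return pd.DataFrame(rows)


def read_resolution(path: str | Path) -> float | None:
    """Extract the REMARK 2 resolution from a PDB file, if present."""
    pattern = re.compile(
        r"^REMARK\s+2\s+RESOLUTION\.\s+([0-9.]+)\s+ANGSTROM", re.IGNORECASE
    )
    for line in Path(path).read_text().splitlines():
        m = pattern.match(line)
        if m:
            return float(m.group(1))
    return None
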