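"""Bundled amino-acid reference tables.

Everything downstream descriptor code needs about the 20 canonical amino
acids lives here: three-class physicochemical groupings for the CTD
(composition / transition / distribution) descriptor family, and the two
pairwise distance matrices used by the sequence-order coupling numbers and
quasi-sequence-order descriptors.

The Grantham matrix is generated from Grantham's published composition /
polarity / molecular-volume scales and distance formula

    D(i, j) = rho * sqrt(alpha*(c_i-c_j)^2 + beta*(p_i-p_j)^2 + gamma*(v_i-v_j)^2)

with alpha=1.833, beta=0.1018, gamma=0.000399 and rho=50.723 (which scales
the mean pairwise distance to 100), rounded to integers as in the familiar
published table (e.g. D(Ala, Cys) = 195, D(Leu, Ile) = 5).

The second matrix is a Schneider-Wrede-style normalized physicochemical
distance: it is computed here from standardized hydrophobicity,
hydrophilicity and side-chain-mass scales (the classic triple used for
sequence-order coupling), scaled to [0, 1], rather than transcribed from
the original publication.  Its exact values therefore differ from other
codebases' tables; all uses in this package are self-consistent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Canonical one-letter codes, alphabetical.
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}

#: Three-letter -> one-letter map for the 20 canonical residues plus
#: selenomethionine (MSE), which is treated as methionine.
THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "MSE": "M",
}

STANDARD_AA_NAMES = frozenset(THREE_TO_ONE)

#: Residue names accepted as nucleotides (ribo- and deoxy- forms plus inosine).
NUCLEOTIDE_NAMES = frozenset({"A", "U", "G", "C", "I", "DA", "DT", "DG", "DC", "DI"})

WATER_NAMES = frozenset({"HOH", "WAT", "DOD", "H2O"})

#: Common monoatomic ions seen as single-residue HETATM entries.
ION_NAMES = frozenset({
    "LI", "NA", "K", "RB", "CS", "MG", "CA", "SR", "BA", "MN", "FE", "FE2",
    "CO", "NI", "CU", "CU1", "ZN", "CD", "HG", "CL", "BR", "IOD", "F",
    "AL", "PB", "PT", "AU", "AG", "TL", "YB", "GA",
})


@dataclass(frozen=True)
class PropertyGrouping:
    """A three-class partition of the 20 amino acids for one physicochemical
    property (the CTD convention)."""

    property_name: str
    classes: tuple[str, str, str]
    class_of: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        mapping: dict[str, int] = {}
        for k, members in enumerate(self.classes, start=1):
            if not members:
                raise ValueError(
                    f"{self.property_name}: class {k} is empty"
                )
            for aa in members:
                if aa in mapping:
                    raise ValueError(
                        f"{self.property_name}: {aa} assigned to two classes"
                    )
                mapping[aa] = k
        if set(mapping) != set(AMINO_ACIDS):
            missing = set(AMINO_ACIDS) - set(mapping)
            raise ValueError(
                f"{self.property_name}: unassigned amino acids {sorted(missing)}"
            )
        object.__setattr__(self, "class_of", mapping)


def _grouping(name: str, c1: str, c2: str, c3: str) -> PropertyGrouping:
    return PropertyGrouping(name, (c1, c2, c3))


#: The seven standard CTD property groupings (Dubchak-style tables).
CTD_GROUPINGS: dict[str, PropertyGrouping] = {
    g.property_name: g
    for g in (
        _grouping("hydrophobicity", "RKEDQN", "GASTPHY", "CLVIMFW"),
        _grouping("normalized_vdw_volume", "GASCTPD", "NVEQIL", "MHKFRYW"),
        _grouping("polarity", "LIFWCMVY", "PATGS", "HQRKNED"),
        _grouping("polarizability", "GASDT", "CPNVEQIL", "KMHFRYW"),
        _grouping("charge", "KR", "ANCQGHILMFPSTWYV", "DE"),
        _grouping("secondary_structure", "EALMQKRH", "VIYCWFT", "GNPSD"),
        _grouping("solvent_accessibility", "ALFCGIVW", "RKQEND", "MSPTHY"),
    )
}

CTD_PROPERTIES: tuple[str, ...] = tuple(CTD_GROUPINGS)


@dataclass(frozen=True)
class AADistanceMatrix:
    """Symmetric 20x20 amino-acid distance matrix with zero diagonal."""

    matrix_name: str
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (20, 20):
            raise ValueError("distance matrix must be 20x20")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(v < 0):
            raise ValueError("distances must be nonnegative")
        object.__setattr__(self, "values", v)

    def d(self, a: str, b: str) -> float:
        return float(self.values[AA_INDEX[a], AA_INDEX[b]])


# Grantham (composition, polarity, molecular volume) per amino acid.
_GRANTHAM_PROPERTIES = {
    "A": (0.0, 8.1, 31.0), "C": (2.75, 5.5, 55.0), "D": (1.38, 13.0, 54.0),
    "E": (0.92, 12.3, 83.0), "F": (0.0, 5.2, 132.0), "G": (0.74, 9.0, 3.0),
    "H": (0.58, 10.4, 96.0), "I": (0.0, 5.2, 111.0), "K": (0.33, 11.3, 119.0),
    "L": (0.0, 4.9, 111.0), "M": (0.0, 5.7, 105.0), "N": (1.33, 11.6, 56.0),
    "P": (0.39, 8.0, 32.5), "Q": (0.89, 10.5, 85.0), "R": (0.65, 10.5, 124.0),
    "S": (1.42, 9.2, 32.0), "T": (0.71, 8.6, 61.0), "V": (0.0, 5.9, 84.0),
    "W": (0.13, 5.4, 170.0), "Y": (0.2, 6.2, 136.0),
}

_GRANTHAM_ALPHA = 1.833
_GRANTHAM_BETA = 0.1018
_GRANTHAM_GAMMA = 0.000399
_GRANTHAM_RHO = 50.723


def _build_grantham() -> np.ndarray:
    m = np.zeros((20, 20))
    for i, a in enumerate(AMINO_ACIDS):
        ca, pa, va = _GRANTHAM_PROPERTIES[a]
        for j, b in enumerate(AMINO_ACIDS):
            if i == j:
                continue
            cb, pb, vb = _GRANTHAM_PROPERTIES[b]
            d = _GRANTHAM_RHO * np.sqrt(
                _GRANTHAM_ALPHA * (ca - cb) ** 2
                + _GRANTHAM_BETA * (pa - pb) ** 2
                + _GRANTHAM_GAMMA * (va - vb) ** 2
            )
            m[i, j] = round(d)
    return m


# Hydrophobicity, hydrophilicity (Hopp-Woods) and side-chain mass scales
# for the normalized physicochemical distance matrix.
_HYDROPHOBICITY = {
    "A": 0.62, "C": 0.29, "D": -0.90, "E": -0.74, "F": 1.19, "G": 0.48,
    "H": -0.40, "I": 1.38, "K": -1.50, "L": 1.06, "M": 0.64, "N": -0.78,
    "P": 0.12, "Q": -0.85, "R": -2.53, "S": -0.18, "T": -0.05, "V": 1.08,
    "W": 0.81, "Y": 0.26,
}
_HYDROPHILICITY = {
    "A": -0.5, "C": -1.0, "D": 3.0, "E": 3.0, "F": -2.5, "G": 0.0,
    "H": -0.5, "I": -1.8, "K": 3.0, "L": -1.8, "M": -1.3, "N": 0.2,
    "P": 0.0, "Q": 0.2, "R": 3.0, "S": 0.3, "T": -0.4, "V": -1.5,
    "W": -3.4, "Y": -2.3,
}
_SIDECHAIN_MASS = {
    "A": 15.0, "C": 47.0, "D": 59.0, "E": 73.0, "F": 91.0, "G": 1.0,
    "H": 81.0, "I": 57.0, "K": 73.0, "L": 57.0, "M": 75.0, "N": 58.0,
    "P": 42.0, "Q": 72.0, "R": 101.0, "S": 31.0, "T": 45.0, "V": 43.0,
    "W": 130.0, "Y": 107.0,
}


def _standardize(scale: dict[str, float]) -> np.ndarray:
    v = np.array([scale[a] for a in AMINO_ACIDS])
    return (v - v.mean()) / v.std()


def _build_schneider_wrede_style() -> np.ndarray:
    props = np.stack(
        [_standardize(s) for s in (_HYDROPHOBICITY, _HYDROPHILICITY, _SIDECHAIN_MASS)],
        axis=1,
    )
    diff = props[:, None, :] - props[None, :, :]
    m = np.sqrt((diff**2).mean(axis=2))
    return m / m.max()


GRANTHAM = AADistanceMatrix("grantham", _build_grantham())
SCHNEIDER_WREDE = AADistanceMatrix("schneider_wrede", _build_schneider_wrede_style())

DISTANCE_MATRICES: dict[str, AADistanceMatrix] = {
    "grantham": GRANTHAM,
    "schneider_wrede": SCHNEIDER_WREDE,
}
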