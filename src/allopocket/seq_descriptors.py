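"""Amino-acid-based descriptors for pocket sequences.

A pocket detected on a protein surface is, for these descriptors, just the
multiset/sequence of its standard amino acids in a fixed canonical order
(chain id, residue number, insertion code).  From that short sequence the
module computes the descriptor families used alongside the 19 Fpocket
structural descriptors:

* amino-acid composition (20 fractions),
* CTD composition / transition / distribution over seven three-class
  physicochemical groupings,
* sequence-order coupling numbers (SOCN) and quasi-sequence-order (QSO)
  descriptors for two amino-acid distance matrices,
* k-gap dipeptide composition, and
* whole-sequence physicochemical properties (molecular weight,
  aromaticity, isoelectric point, instability index, net charge at a pH),
  delegated to Biopython's ProtParam.

All descriptors are order-independent up to the canonical residue order,
and defined for the short sequences typical of binding pockets (QSO/SOCN
lags are clamped to the sequence length and padded with zeros so feature
vectors keep a fixed width).
"""

from __future__ import annotations

import logging
from collections import OrderedDict
from dataclasses import dataclass, field

import numpy as np
from Bio.SeqUtils.ProtParam import ProteinAnalysis
from scipy.optimize import brentq

from .aa_data import (
    AMINO_ACIDS,
    AADistanceMatrix,
    CTD_GROUPINGS,
    CTD_PROPERTIES,
    DISTANCE_MATRICES,
    PropertyGrouping,
)
from .structure_io import FPOCKET_FIELDS, Pocket

logger = logging.getLogger(__name__)

__all__ = [
    "QSOParams",
    "DescriptorConfig",
    "EmptySequenceError",
    "pocket_sequence",
    "aa_composition",
    "ctd_composition",
    "ctd_transition",
    "ctd_distribution",
    "socn",
    "qso",
    "kgap_composition",
    "global_properties",
    "featurize_pocket",
    "feature_names",
]


class EmptySequenceError(ValueError):
    """Raised when a pocket contributes no standard amino acids."""


def _check_sequence(seq: str, drop_noncanonical: bool = False) -> str:
    if drop_noncanonical:
        seq = "".join(a for a in seq if a in AMINO_ACIDS)
    if not seq:
        raise EmptySequenceError("empty amino-acid sequence")
    bad = sorted({a for a in seq if a not in AMINO_ACIDS})
    if bad:
        raise ValueError(f"non-canonical amino acid letter(s) {bad}")
    return seq


@dataclass(frozen=True)
class QSOParams:
    """Quasi-sequence-order parameters: maximum lag and coupling weight."""

    maxlag: int = 30
    weight: float = 0.1

    def __post_init__(self) -> None:
        if self.maxlag < 1:
            raise ValueError("maxlag must be >= 1")
        if self.weight < 0:
            raise ValueError("weight must be nonnegative")


def pocket_sequence(pocket: Pocket) -> str:
    """One-letter sequence of the pocket's standard amino acids in
    canonical residue order.  Nucleotides and other residues are skipped."""
    letters = [
        r.one_letter
        for r in pocket.residues
        if r.kind == "standard-aa" and r.one_letter
    ]
    if not letters:
        raise EmptySequenceError(
            f"pocket {pocket.pocket_id} has no standard amino acids"
        )
    return "".join(letters)


def aa_composition(seq: str) -> OrderedDict[str, float]:
    """Fraction of each of the 20 amino acids; sums to 1."""
    seq = _check_sequence(seq)
    n = len(seq)
    counts = {a: 0 for a in AMINO_ACIDS}
    for a in seq:
        counts[a] += 1
    return OrderedDict((a, counts[a] / n) for a in AMINO_ACIDS)


def _classes(seq: str, grouping: PropertyGrouping) -> list[int]:
    return [grouping.class_of[a] for a in seq]


def ctd_composition(seq: str, grouping: PropertyGrouping) -> tuple[float, float, float]:
    """Fraction of residues in each of the grouping's three classes."""
    seq = _check_sequence(seq)
    cls = _classes(seq, grouping)
    n = len(cls)
    return tuple(sum(1 for c in cls if c == k) / n for k in (1, 2, 3))


def ctd_transition(seq: str, grouping: PropertyGrouping) -> tuple[float, float, float]:
    """Frequency of adjacent-position class transitions for the unordered
    class pairs (1,2), (1,3), (2,3), normalized by N-1."""
    seq = _check_sequence(seq)
    if len(seq) < 2:
        raise ValueError("transition descriptors need sequence length >= 2")
    cls = _classes(seq, grouping)
    pairs = {(1, 2): 0, (1, 3): 0, (2, 3): 0}
    for a, b in zip(cls, cls[1:]):
        if a != b:
            pairs[(min(a, b), max(a, b))] += 1
    denom = len(cls) - 1
    return tuple(pairs[p] / denom for p in ((1, 2), (1, 3), (2, 3)))


_DISTRIBUTION_QUANTILES = (0.25, 0.50, 0.75)


def ctd_distribution(seq: str, grouping: PropertyGrouping) -> tuple[float, ...]:
    """Positional distribution of each class: relative position (in %) of
    the first, 25th-, 50th-, 75th-percentile and last occurrence.

    The q-th percentile occurrence is occurrence number ``ceil(q * count)``
    (at least 1).  Classes absent from the sequence yield five zeros.
    """
    seq = _check_sequence(seq)
    cls = _classes(seq, grouping)
    n = len(cls)
    out: list[float] = []
    for k in (1, 2, 3):
        positions = [i + 1 for i, c in enumerate(cls) if c == k]
        if not positions:
            out.extend([0.0] * 5)
            continue
        count = len(positions)
        vals = [positions[0]]
        for q in _DISTRIBUTION_QUANTILES:
            occ = max(1, int(np.ceil(q * count)))
            vals.append(positions[occ - 1])
        vals.append(positions[-1])
        out.extend(100.0 * v / n for v in vals)
    return tuple(out)


def socn(seq: str, matrix: AADistanceMatrix, maxlag: int) -> np.ndarray:
    """Sequence-order coupling numbers tau_1..tau_maxlag:
    tau_lag = sum_i d(R_i, R_{i+lag})^2."""
    seq = _check_sequence(seq)
    if maxlag >= len(seq):
        raise ValueError(
            f"maxlag ({maxlag}) must be smaller than sequence length ({len(seq)})"
        )
    idx = np.array([AMINO_ACIDS.index(a) for a in seq])
    out = np.empty(maxlag)
    for lag in range(1, maxlag + 1):
        d = matrix.values[idx[:-lag], idx[lag:]]
        out[lag - 1] = float((d**2).sum())
    return out


def qso(seq: str, matrix: AADistanceMatrix, params: QSOParams) -> np.ndarray:
    """Quasi-sequence-order descriptors (20 + maxlag values, summing to 1).

    The first 20 entries weight amino-acid counts, the rest weight the
    coupling numbers:  X_r = f_r / (N + w*T),
    X_{20+lag} = w*tau_lag / (N + w*T), with T = sum of tau over lags.
    """
    seq = _check_sequence(seq)
    tau = socn(seq, matrix, params.maxlag)
    n = len(seq)
    t = float(tau.sum())
    denom = n + params.weight * t
    counts = np.array([seq.count(a) for a in AMINO_ACIDS], dtype=float)
    return np.concatenate([counts / denom, params.weight * tau / denom])


def kgap_composition(seq: str, k: int) -> OrderedDict[str, float]:
    """Frequency of ordered residue pairs separated by exactly k positions.

    Pair (a, b) counts occurrences at positions (i, i+k+1), normalized by
    the number of windows N-k-1; all zeros when the sequence is too short.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    seq = _check_sequence(seq)
    out = OrderedDict(
        (f"{a}{b}", 0.0) for a in AMINO_ACIDS for b in AMINO_ACIDS
    )
    n_windows = len(seq) - k - 1
    if n_windows <= 0:
        return out
    for i in range(n_windows):
        out[f"{seq[i]}{seq[i + k + 1]}"] += 1.0
    for key in out:
        out[key] /= n_windows
    return out


def global_properties(seq: str, ph: float = 7.0) -> OrderedDict[str, float]:
    """Whole-sequence physicochemical properties via Biopython ProtParam:
    average molecular weight (residue masses + one water), aromaticity
    (fraction F/W/Y), isoelectric point, Guruprasad instability index and
    Henderson-Hasselbalch net charge at ``ph``."""
    seq = _check_sequence(seq)
    if len(seq) < 2:
        raise ValueError("instability index needs sequence length >= 2")
    pa = ProteinAnalysis(seq)
    # net charge is monotone decreasing in pH, so the isoelectric point is
    # the unique root of charge_at_pH on [0, 14]
    isoelectric = float(brentq(pa.charge_at_pH, 0.0, 14.0, xtol=1e-3))
    return OrderedDict(
        (
            ("mw", float(pa.molecular_weight())),
            ("aromaticity", float(pa.aromaticity())),
            ("isoelectric_point", isoelectric),
            ("instability", float(pa.instability_index())),
            ("charge_at_ph", float(pa.charge_at_pH(ph))),
        )
    )


# ---------------------------------------------------------------------------
# Full featurization


@dataclass(frozen=True)
class DescriptorConfig:
    """Declares which descriptor families are computed and in which order,
    fixing the feature-vector layout."""

    groupings: tuple[str, ...] = CTD_PROPERTIES
    matrices: tuple[str, ...] = ("grantham", "schneider_wrede")
    qso_params: QSOParams = field(default_factory=QSOParams)
    kgap_ks: tuple[int, ...] = (1, 2)
    ph: float = 7.0
    drop_noncanonical: bool = False

    @property
    def n_features(self) -> int:
        return (
            len(FPOCKET_FIELDS)
            + 20
            + len(self.groupings) * (3 + 3 + 15)
            + len(self.matrices) * self.qso_params.maxlag
            + len(self.matrices) * (20 + self.qso_params.maxlag)
            + len(self.kgap_ks) * 400
            + 5
        )

    def manifest(self) -> dict:
        return {
            "families": [
                "fpocket",
                "aa_composition",
                "ctd",
                "socn",
                "qso",
                "kgap",
                "global",
            ],
            "groupings": list(self.groupings),
            "matrices": list(self.matrices),
            "qso": {"maxlag": self.qso_params.maxlag, "weight": self.qso_params.weight},
            "kgap_ks": list(self.kgap_ks),
            "ph": self.ph,
            "n_features": self.n_features,
        }


def feature_names(config: DescriptorConfig | None = None) -> list[str]:
    """The full ordered feature-name list declared by ``config``."""
    config = config or DescriptorConfig()
    names = [f"fpocket_{f}" for f in FPOCKET_FIELDS]
    names += [f"aac_{a}" for a in AMINO_ACIDS]
    for prop in config.groupings:
        names += [f"ctdc_{prop}_{k}" for k in (1, 2, 3)]
        names += [f"ctdt_{prop}_{p}" for p in ("12", "13", "23")]
        for k in (1, 2, 3):
            names += [
                f"ctdd_{prop}_{k}_{q}" for q in ("first", "q25", "q50", "q75", "last")
            ]
    maxlag = config.qso_params.maxlag
    for m in config.matrices:
        names += [f"socn_{m}_{lag}" for lag in range(1, maxlag + 1)]
    for m in config.matrices:
        names += [f"qso_{m}_{a}" for a in AMINO_ACIDS]
        names += [f"qso_{m}_lag{lag}" for lag in range(1, maxlag + 1)]
    for k in config.kgap_ks:
        names += [f"kgap{k}_{a}{b}" for a in AMINO_ACIDS for b in AMINO_ACIDS]
    names += [f"global_{g}" for g in
              ("mw", "aromaticity", "isoelectric_point", "instability",
               "charge_at_ph")]
    return names


def featurize_pocket(
    pocket: Pocket, config: DescriptorConfig | None = None
) -> OrderedDict[str, float]:
    """Concatenate all descriptor families for one (completed) pocket.

    SOCN/QSO lags beyond the sequence length are emitted as zeros so every
    pocket yields a vector of exactly ``config.n_features`` values.
    """
    config = config or DescriptorConfig()
    seq = pocket_sequence(pocket)
    seq = _check_sequence(seq, drop_noncanonical=config.drop_noncanonical)

    out: OrderedDict[str, float] = OrderedDict()
    for name, value in pocket.descriptors.as_dict().items():
        out[f"fpocket_{name}"] = float(value)
    for a, v in aa_composition(seq).items():
        out[f"aac_{a}"] = v
    for prop in config.groupings:
        grouping = CTD_GROUPINGS[prop]
        for k, v in zip((1, 2, 3), ctd_composition(seq, grouping)):
            out[f"ctdc_{prop}_{k}"] = v
        for p, v in zip(("12", "13", "23"), ctd_transition(seq, grouping)):
            out[f"ctdt_{prop}_{p}"] = v
        dist = ctd_distribution(seq, grouping)
        i = 0
        for k in (1, 2, 3):
            for q in ("first", "q25", "q50", "q75", "last"):
                out[f"ctdd_{prop}_{k}_{q}"] = dist[i]
                i += 1

    maxlag = config.qso_params.maxlag
    eff_lag = min(maxlag, len(seq) - 1)
    eff_params = QSOParams(maxlag=eff_lag, weight=config.qso_params.weight)
    for m in config.matrices:
        matrix = DISTANCE_MATRICES[m]
        tau = np.zeros(maxlag)
        tau[:eff_lag] = socn(seq, matrix, eff_lag)
        for lag in range(1, maxlag + 1):
            out[f"socn_{m}_{lag}"] = float(tau[lag - 1])
    for m in config.matrices:
        matrix = DISTANCE_MATRICES[m]
        q = np.zeros(20 + maxlag)
        qv = qso(seq, matrix, eff_params)
        q[:20] = qv[:20]
        q[20 : 20 + eff_lag] = qv[20:]
        for a, v in zip(AMINO_ACIDS, q[:20]):
            out[f"qso_{m}_{a}"] = float(v)
        for lag in range(1, maxlag + 1):
            out[f"qso_{m}_lag{lag}"] = float(q[20 + lag - 1])

    for k in config.kgap_ks:
        for pair, v in kgap_composition(seq, k).items():
            out[f"kgap{k}_{pair}"] = v

    for g, v in global_properties(seq, ph=config.ph).items():
        out[f"global_{g}"] = v

    assert list(out) == feature_names(config)
    return out
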