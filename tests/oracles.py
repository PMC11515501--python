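"""Independent brute-force reference implementations for descriptor tests.

Deliberately naive, loop-based and written directly from the descriptor
definitions so they share no code path with the package's vectorized
implementations.
"""

from __future__ import annotations

import math

from allopocket.aa_data import AMINO_ACIDS


def naive_aa_composition(seq: str) -> dict[str, float]:
    return {a: sum(1 for c in seq if c == a) / len(seq) for a in AMINO_ACIDS}


def naive_ctd_composition(seq, grouping):
    counts = [0, 0, 0]
    for c in seq:
        counts[grouping.class_of[c] - 1] += 1
    return tuple(v / len(seq) for v in counts)


def naive_ctd_transition(seq, grouping):
    pairs = {(1, 2): 0, (1, 3): 0, (2, 3): 0}
    for i in range(len(seq) - 1):
        a = grouping.class_of[seq[i]]
        b = grouping.class_of[seq[i + 1]]
        if a != b:
            pairs[(min(a, b), max(a, b))] += 1
    return tuple(pairs[p] / (len(seq) - 1) for p in ((1, 2), (1, 3), (2, 3)))


def naive_ctd_distribution(seq, grouping):
    n = len(seq)
    out = []
    for k in (1, 2, 3):
        positions = [i + 1 for i, c in enumerate(seq) if grouping.class_of[c] == k]
        if not positions:
            out.extend([0.0] * 5)
            continue
        count = len(positions)
        picks = [positions[0]]
        for q in (0.25, 0.50, 0.75):
            occ = max(1, math.ceil(q * count))
            picks.append(positions[occ - 1])
        picks.append(positions[count - 1])
        out.extend(100.0 * p / n for p in picks)
    return tuple(out)


def naive_socn(seq, matrix, maxlag):
    out = []
    for lag in range(1, maxlag + 1):
        total = 0.0
        for i in range(len(seq) - lag):
            total += matrix.d(seq[i], seq[i + lag]) ** 2
        out.append(total)
    return out


def naive_qso(seq, matrix, maxlag, weight):
    tau = naive_socn(seq, matrix, maxlag)
    t = sum(tau)
    denom = len(seq) + weight * t
    first = [sum(1 for c in seq if c == a) / denom for a in AMINO_ACIDS]
    rest = [weight * tl / denom for tl in tau]
    return first + rest


def naive_kgap(seq, k):
    counts = {a + b: 0 for a in AMINO_ACIDS for b in AMINO_ACIDS}
    windows = 0
    for i in range(len(seq)):
        j = i + k + 1
        if j < len(seq):
            counts[seq[i] + seq[j]] += 1
            windows += 1
    if windows == 0:
        return {pair: 0.0 for pair in counts}
    return {pair: v / windows for pair, v in counts.items()}
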