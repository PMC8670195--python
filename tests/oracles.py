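"""Independent oracles used to cross-check the implementation.

These deliberately share no code with the package: local alignment is
re-derived by exhaustive path enumeration (small inputs) and by a separate
affine-gap dynamic program, and aggregate statistics are recomputed by
brute force.
"""

from __future__ import annotations

import numpy as np
from numba import njit


def enum_local_score(a: str, b: str, score: dict, gap_open: int = 11, gap_extend: int = 1) -> int:
    """Best local alignment score by exhaustive enumeration of paths.

    Every alignment is a walk of match/insert/delete moves starting at any
    (i, j) and stopping anywhere; a gap of length L costs open + L*extend.
    Exponential: only for tiny sequences.
    """
    best = 0

    def walk(i: int, j: int, state: str, acc: int) -> None:
        nonlocal best
        if acc > best:
            best = acc
        if i < len(a) and j < len(b):
            walk(i + 1, j + 1, "M", acc + score[a[i], b[j]])
        if i < len(a):
            cost = gap_extend if state == "X" else gap_open + gap_extend
            walk(i + 1, j, "X", acc - cost)
        if j < len(b):
            cost = gap_extend if state == "Y" else gap_open + gap_extend
            walk(i, j + 1, "Y", acc - cost)

    for i in range(len(a)):
        for j in range(len(b)):
            walk(i, j, "start", 0)
    return best


@njit(cache=True)
def _sw_affine(a, b, S, go, ge):  # pragma: no cover - numba
    n, m = len(a), len(b)
    NEG = -1.0e18
    M = np.zeros((n + 1, m + 1))
    X = np.full((n + 1, m + 1), NEG)
    Y = np.full((n + 1, m + 1), NEG)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            diag = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1], 0.0)
            M[i, j] = diag + S[a[i - 1], b[j - 1]]
            X[i, j] = max(M[i - 1, j] - go - ge, X[i - 1, j] - ge)
            Y[i, j] = max(M[i, j - 1] - go - ge, Y[i, j - 1] - ge)
            if M[i, j] > best:
                best = M[i, j]
    return best


_AA_ORDER = "ARNDCQEGHILKMFPSTWYVX"


def matrix_as_dict(blosum) -> dict:
    return {(x, y): int(blosum[x, y]) for x in _AA_ORDER for y in _AA_ORDER}


def dp_local_score(a: str, b: str, blosum, gap_open: int = 11, gap_extend: int = 1) -> int:
    """Independent affine-gap Smith-Waterman dynamic program."""
    S = np.zeros((21, 21))
    for i, x in enumerate(_AA_ORDER):
        for j, y in enumerate(_AA_ORDER):
            S[i, j] = float(blosum[x, y])
    idx = {c: i for i, c in enumerate(_AA_ORDER)}
    ea = np.array([idx[c] for c in a], dtype=np.int64)
    eb = np.array([idx[c] for c in b], dtype=np.int64)
    return int(round(_sw_affine(ea, eb, S, float(gap_open), float(gap_extend))))


def encode_for_dp(seq: str) -> np.ndarray:
    idx = {c: i for i, c in enumerate(_AA_ORDER)}
    return np.array([idx[c] for c in seq], dtype=np.int64)


def dp_score_matrix(blosum) -> np.ndarray:
    S = np.zeros((21, 21))
    for i, x in enumerate(_AA_ORDER):
        for j, y in enumerate(_AA_ORDER):
            S[i, j] = float(blosum[x, y])
    return S


def sw_affine_encoded(ea, eb, S, gap_open=11.0, gap_extend=1.0) -> int:
    return int(round(_sw_affine(ea, eb, S, gap_open, gap_extend)))


def brute_force_og_means(counts_by_gene: dict, labels: dict) -> dict:
    """Per-(OG, TF) means recomputed the long way."""
    sums: dict = {}
    ns: dict = {}
    for gene, per_tf in counts_by_gene.items():
        og = labels[gene]
        for tf, c in per_tf.items():
            sums[(og, tf)] = sums.get((og, tf), 0) + c
            ns[(og, tf)] = ns.get((og, tf), 0) + 1
    return {k: sums[k] / ns[k] for k in sums}


def hand_chain_tandem(starts: list[int], max_gap: int) -> list[list[int]]:
    """Transitive chaining of sorted start positions, the pencil-paper way."""
    arrays: list[list[int]] = []
    cur = [starts[0]]
    for s in starts[1:]:
        if s - cur[-1] <= max_gap:
            cur.append(s)
        else:
            if len(cur) >= 2:
                arrays.append(cur)
            cur = [s]
    if len(cur) >= 2:
        arrays.append(cur)
    return arrays
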