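"""Progressive multiple alignment and conserved-block cleaning.

The aligner is a deterministic MUSCLE-like first iteration: a guide tree is
built by UPGMA on 3-mer count distances, then profiles are merged along the
tree with affine-gap profile-profile dynamic programming.  Cleaning follows
a simplified Gblocks scheme based on identity fractions; the relaxed
parameter set mirrors the three standard relaxations (smaller final blocks,
gaps inside blocks, less strict flanks).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .pairwise_align import ScoringScheme

AA = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AA)}
GAP = 20


def encode(seq: str) -> np.ndarray:
    # unknown residues (X etc.) get a neutral extra index 21 scored 0
    return np.array([AA_INDEX.get(c, 21) for c in seq.upper()], dtype=np.int8)


@dataclass
class MultipleAlignment:
    """Equal-length gapped rows keyed by sequence id."""

    rows: dict[str, str]

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.rows.values()}
        if len(lengths) > 1:
            raise ValueError("alignment rows have unequal lengths")

    @property
    def ncols(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    def ungapped(self, seq_id: str) -> str:
        return self.rows[seq_id].replace("-", "")

    def column(self, j: int) -> list[str]:
        return [s[j] for s in self.rows.values()]


@dataclass
class CleanParams:
    """Block-cleaning thresholds.

    ``c1`` (conserved) defaults to 0.5 + 1/n over non-gap rows; ``c2``
    (highly conserved) is the flank requirement in strict mode.
    """

    c1: float | None = None
    c2: float = 0.85
    max_gap_frac: float = 0.5
    min_block: int = 5
    relaxed: bool = True

    def resolve_c1(self, n_rows: int) -> float:
        return self.c1 if self.c1 is not None else 0.5 + 1.0 / n_rows


@dataclass
class CleanedAlignment:
    source: MultipleAlignment
    retained: list[int]
    params: CleanParams = field(default_factory=CleanParams)

    def __post_init__(self) -> None:
        if sorted(self.retained) != list(self.retained):
            raise ValueError("retained columns must be ascending")
        if self.retained and not (0 <= self.retained[0] and self.retained[-1] < self.source.ncols):
            raise ValueError("retained column out of range")

    @property
    def n_retained(self) -> int:
        return len(self.retained)

    def matrix(self) -> np.ndarray:
        """Retained columns as an integer matrix (rows in id order)."""
        ids = list(self.source.rows)
        full = np.array(
            [[AA_INDEX.get(c, 21) if c != "-" else GAP for c in self.source.rows[i]] for i in ids],
            dtype=np.int8,
        )
        return full[:, self.retained]


# ---------------------------------------------------------------------------
# profile-profile alignment core
# ---------------------------------------------------------------------------

NEG = -1.0e30


@njit(cache=True)
def _align_profiles(colscore, go, ge):  # pragma: no cover - numba
    """Affine-gap DP over a precomputed column-pair score matrix.

    Returns traceback as two arrays of column indices (-1 = gap).
    """
    n, m = colscore.shape
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)  # gap in profile 2 (consume profile-1 col)
    Y = np.full((n + 1, m + 1), NEG)  # gap in profile 1
    ptrM = np.zeros((n + 1, m + 1), dtype=np.int8)
    ptrX = np.zeros((n + 1, m + 1), dtype=np.int8)
    ptrY = np.zeros((n + 1, m + 1), dtype=np.int8)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = -(go + ge * i)
        ptrX[i, 0] = 1
    for j in range(1, m + 1):
        Y[0, j] = -(go + ge * j)
        ptrY[0, j] = 2
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = colscore[i - 1, j - 1]
            # match state
            best = M[i - 1, j - 1]
            p = 0
            if X[i - 1, j - 1] > best:
                best = X[i - 1, j - 1]
                p = 1
            if Y[i - 1, j - 1] > best:
                best = Y[i - 1, j - 1]
                p = 2
            M[i, j] = best + s
            ptrM[i, j] = p
            # gap in profile 2
            bx = M[i - 1, j] - go - ge
            px = 0
            if X[i - 1, j] - ge > bx:
                bx = X[i - 1, j] - ge
                px = 1
            if Y[i - 1, j] - go - ge > bx:
                bx = Y[i - 1, j] - go - ge
                px = 2
            X[i, j] = bx
            ptrX[i, j] = px
            # gap in profile 1
            by = M[i, j - 1] - go - ge
            py = 0
            if Y[i, j - 1] - ge > by:
                by = Y[i, j - 1] - ge
                py = 1
            if X[i, j - 1] - go - ge > by:
                by = X[i, j - 1] - go - ge
                py = 2
            Y[i, j] = by
            ptrY[i, j] = py
    # traceback from best final state
    state = 0
    best = M[n, m]
    if X[n, m] > best:
        best = X[n, m]
        state = 1
    if Y[n, m] > best:
        best = Y[n, m]
        state = 2
    path1 = np.empty(n + m, dtype=np.int32)
    path2 = np.empty(n + m, dtype=np.int32)
    k = 0
    i, j = n, m
    while i > 0 or j > 0:
        if state == 0:
            path1[k] = i - 1
            path2[k] = j - 1
            state = ptrM[i, j]
            i -= 1
            j -= 1
        elif state == 1:
            path1[k] = i - 1
            path2[k] = -1
            prev = ptrX[i, j]
            if prev == 0:
                state = 0
            elif prev == 1:
                state = 1
            else:
                state = 2
            i -= 1
        else:
            path1[k] = -1
            path2[k] = j - 1
            prev = ptrY[i, j]
            if prev == 0:
                state = 0
            elif prev == 1:
                state = 2
            else:
                state = 1
            j -= 1
        k += 1
    return path1[:k][::-1].copy(), path2[:k][::-1].copy()


def _substitution_array(scheme: ScoringScheme) -> np.ndarray:
    """22x22 float score table over the internal alphabet (20 aa, gap, X)."""
    m = scheme.substitution
    S = np.zeros((22, 22), dtype=np.float64)
    for i, a in enumerate(AA):
        for j, b in enumerate(AA):
            S[i, j] = float(m[a, b])
    return S


def _profile(rows: np.ndarray) -> np.ndarray:
    """Per-column residue frequency matrix (L x 20), gaps carry no mass."""
    L = rows.shape[1]
    prof = np.zeros((L, 20), dtype=np.float64)
    n = rows.shape[0]
    for k in range(20):
        prof[:, k] = (rows == k).sum(axis=0) / n
    return prof


def _merge(rows1: np.ndarray, rows2: np.ndarray, S: np.ndarray, go: float, ge: float):
    prof1, prof2 = _profile(rows1), _profile(rows2)
    colscore = prof1 @ S[:20, :20] @ prof2.T
    p1, p2 = _align_profiles(colscore, go, ge)
    L = len(p1)
    out1 = np.full((rows1.shape[0], L), GAP, dtype=np.int8)
    out2 = np.full((rows2.shape[0], L), GAP, dtype=np.int8)
    mask1 = p1 >= 0
    mask2 = p2 >= 0
    out1[:, mask1] = rows1[:, p1[mask1]]
    out2[:, mask2] = rows2[:, p2[mask2]]
    return out1, out2


def kmer_distance_matrix(seqs: list[str], k: int = 3) -> np.ndarray:
    """Guide-tree distance: 1 minus the shared-k-mer fraction.

    The shared fraction is |kmers(a) & kmers(b)| / min(|kmers(a)|, |kmers(b)|).
    """
    sets = [{s[i : i + k] for i in range(len(s) - k + 1)} for s in seqs]
    n = len(seqs)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            denom = min(len(sets[i]), len(sets[j])) or 1
            shared = len(sets[i] & sets[j]) / denom
            D[i, j] = D[j, i] = 1.0 - shared
    return D


def progressive_msa(
    seqs: dict[str, str],
    scheme: ScoringScheme = ScoringScheme(),
) -> MultipleAlignment:
    """Progressively align protein sequences along a UPGMA guide tree.

    Input order is fixed by sorting ids, so the result is deterministic for
    a given sequence set.  With two sequences this reduces to a plain
    pairwise global alignment.
    """
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences")
    for sid, s in seqs.items():
        if len(s) == 0:
            raise ValueError(f"empty sequence: {sid}")
    ids = sorted(seqs)
    encoded = {sid: encode(seqs[sid])[None, :].astype(np.int8) for sid in ids}
    S = _substitution_array(scheme)
    go, ge = float(scheme.gap_open), float(scheme.gap_extend)

    if len(ids) == 2:
        a, b = _merge(encoded[ids[0]], encoded[ids[1]], S, go, ge)
        return MultipleAlignment({ids[0]: _decode_row(a[0]), ids[1]: _decode_row(b[0])})

    D = kmer_distance_matrix([seqs[i] for i in ids])
    Z = linkage(squareform(D, checks=False), method="average")
    clusters: dict[int, tuple[list[str], np.ndarray]] = {
        i: ([sid], encoded[sid]) for i, sid in enumerate(ids)
    }
    nxt = len(ids)
    for a_idx, b_idx in Z[:, :2].astype(int):
        ids_a, rows_a = clusters.pop(a_idx)
        ids_b, rows_b = clusters.pop(b_idx)
        out_a, out_b = _merge(rows_a, rows_b, S, go, ge)
        clusters[nxt] = (ids_a + ids_b, np.vstack([out_a, out_b]))
        nxt += 1
    (final_ids, final_rows), = clusters.values()
    order = {sid: i for i, sid in enumerate(final_ids)}
    return MultipleAlignment({sid: _decode_row(final_rows[order[sid]]) for sid in ids})


def _decode_row(row: np.ndarray) -> str:
    lookup = AA + "-" + "X"
    return "".join(lookup[v] for v in row)


# ---------------------------------------------------------------------------
# block cleaning
# ---------------------------------------------------------------------------

def clean_blocks(
    aln: MultipleAlignment, params: CleanParams | None = None
) -> CleanedAlignment:
    """Extract conserved alignment blocks, Gblocks-style.

    A column is *conserved* when its most frequent residue (over non-gap
    rows) reaches c1 and its gap fraction is within the allowed maximum
    (strict mode allows no gaps).  Blocks are maximal runs of conserved
    columns; blocks shorter than the minimum length are dropped, and in
    strict mode block flanks are trimmed back to highly conserved columns.
    """
    params = params or CleanParams()
    if not aln.rows:
        raise ValueError("empty alignment")
    n = len(aln.rows)
    c1 = params.resolve_c1(n)
    max_gap = params.max_gap_frac if params.relaxed else 0.0
    ncols = aln.ncols
    rows = list(aln.rows.values())

    conserved = np.zeros(ncols, dtype=bool)
    highly = np.zeros(ncols, dtype=bool)
    for j in range(ncols):
        col = [r[j] for r in rows]
        residues = [c for c in col if c != "-"]
        gap_frac = 1.0 - len(residues) / n
        if not residues or gap_frac > max_gap:
            continue
        top = max(residues.count(c) for c in set(residues))
        frac = top / len(residues)
        conserved[j] = frac >= c1
        highly[j] = frac >= params.c2

    retained: list[int] = []
    j = 0
    while j < ncols:
        if not conserved[j]:
            j += 1
            continue
        k = j
        while k < ncols and conserved[k]:
            k += 1
        block = list(range(j, k))
        if not params.relaxed:
            while block and not highly[block[0]]:
                block.pop(0)
            while block and not highly[block[-1]]:
                block.pop()
        if len(block) >= params.min_block:
            retained.extend(block)
        j = k
    return CleanedAlignment(aln, retained, params)
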