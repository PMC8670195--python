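"""Pairwise protein alignment and hit ranking.

Local Smith-Waterman alignment with affine gaps stands in for the BLASTp /
tBLASTn searches of the original survey: ranking is by raw score (no
E-values), BLOSUM62 with BLAST-style gap penalties 11/1 (a gap of length L
costs 11 + L), and the ambiguous residue X scores 0 against everything.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices


def _blosum62_x_neutral() -> substitution_matrices.Array:
    m = substitution_matrices.load("BLOSUM62").copy()
    for a in m.alphabet:
        m["X", a] = 0.0
        m[a, "X"] = 0.0
    return m


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution matrix plus affine gap penalties.

    ``gap_open``/``gap_extend`` follow the BLAST convention: a gap of length
    L costs ``gap_open + L * gap_extend``.
    """

    matrix_name: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1

    def __post_init__(self) -> None:
        if not (self.gap_open >= self.gap_extend >= 0):
            raise ValueError("require gap_open >= gap_extend >= 0")

    @property
    def substitution(self) -> substitution_matrices.Array:
        return _load_matrix(self.matrix_name)


@lru_cache(maxsize=4)
def _load_matrix(name: str) -> substitution_matrices.Array:
    if name == "BLOSUM62":
        return _blosum62_x_neutral()
    return substitution_matrices.load(name)


@lru_cache(maxsize=8)
def _aligner(scheme: ScoringScheme, mode: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = scheme.substitution
    # PairwiseAligner charges open_gap_score for the first gapped position,
    # so open+extend reproduces the 11 + L convention.
    aligner.open_gap_score = -(scheme.gap_open + scheme.gap_extend)
    aligner.extend_gap_score = -scheme.gap_extend
    return aligner


@dataclass
class LocalHit:
    query_id: str
    subject_id: str
    score: int
    query_span: tuple[int, int] = (0, 0)
    subject_span: tuple[int, int] = (0, 0)
    query_aln: str = ""
    subject_aln: str = ""

    def __post_init__(self) -> None:
        if self.score < 0:
            raise ValueError("local hit score must be >= 0")


def _sanitize(seq: str) -> str:
    return seq.upper()


def sw_score(a: str, b: str, scheme: ScoringScheme = ScoringScheme()) -> int:
    """Score of the best local alignment (0 if no positive alignment exists)."""
    if not a or not b:
        return 0
    score = _aligner(scheme, "local").score(_sanitize(a), _sanitize(b))
    return max(0, int(round(score)))


def smith_waterman(
    a: str,
    b: str,
    scheme: ScoringScheme = ScoringScheme(),
    query_id: str = "query",
    subject_id: str = "subject",
) -> LocalHit:
    """Maximum-scoring local alignment of two proteins under affine gaps."""
    a, b = _sanitize(a), _sanitize(b)
    if not a or not b:
        return LocalHit(query_id, subject_id, 0)
    aligner = _aligner(scheme, "local")
    score = max(0, int(round(aligner.score(a, b))))
    if score <= 0:
        return LocalHit(query_id, subject_id, 0)
    aln = next(iter(aligner.align(a, b)))
    blocks_a, blocks_b = aln.aligned
    qa_parts: list[str] = []
    sa_parts: list[str] = []
    for i, ((qs, qe), (ss, se)) in enumerate(zip(blocks_a, blocks_b)):
        if i > 0:
            pqs, pss = blocks_a[i - 1][1], blocks_b[i - 1][1]
            qa_parts.append(a[pqs:qs] + "-" * (ss - pss))
            sa_parts.append("-" * (qs - pqs) + b[pss:ss])
        qa_parts.append(a[qs:qe])
        sa_parts.append(b[ss:se])
    return LocalHit(
        query_id,
        subject_id,
        score,
        query_span=(int(blocks_a[0][0]), int(blocks_a[-1][1])),
        subject_span=(int(blocks_b[0][0]), int(blocks_b[-1][1])),
        query_aln="".join(qa_parts),
        subject_aln="".join(sa_parts),
    )


def global_score(a: str, b: str, scheme: ScoringScheme = ScoringScheme()) -> int:
    """Needleman-Wunsch global score under the same scheme (used by tests)."""
    return int(round(_aligner(scheme, "global").score(_sanitize(a), _sanitize(b))))


def rank_hits(
    query_id: str,
    query: str,
    subjects: dict[str, str],
    scheme: ScoringScheme = ScoringScheme(),
) -> list[LocalHit]:
    """Score a query against every subject and rank the hits.

    Hits are sorted by descending score; ties break on subject id so the
    ranking is independent of database order.
    """
    if not subjects:
        raise ValueError("subject database is empty")
    hits = [
        LocalHit(query_id, sid, sw_score(query, seq, scheme))
        for sid, seq in subjects.items()
    ]
    hits.sort(key=lambda h: (-h.score, h.subject_id))
    return hits
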