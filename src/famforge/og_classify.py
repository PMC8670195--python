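"""Orthogroup assignment by top-k hit consensus.

A family protein is assigned to an orthologous group (OG) when its k
best-scoring hits against a labeled reference database all carry the same OG
label; otherwise it stays UNASSIGNED.  Score ties spanning the k-th rank are
resolved conservatively: every member of the tied block must agree, which
makes the outcome independent of database order.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .config import PipelineConfig
from .core_io import GeneModel
from .pairwise_align import LocalHit, ScoringScheme, rank_hits

logger = logging.getLogger("famforge")

UNASSIGNED = "UNASSIGNED"

#: The 40 orthologous-group labels of the reference NAC classification.
OG_LABELS: tuple[str, ...] = tuple(
    f"{fam}{sub}"
    for fam, subs in (
        (1, "abcdefgh"),
        (2, "abcdef"),
        (3, "abcde"),
        (4, "abcdefg"),
        (5, "abc"),
        (6, "abc"),
        (7, "abcdef"),
        (8, "ab"),
    )
    for sub in subs
)


@dataclass
class RefEntry:
    protein_id: str
    species: str
    og_label: str
    sequence: str


@dataclass
class ReferenceDB:
    entries: list[RefEntry]
    og_labels: tuple[str, ...] = OG_LABELS

    def __post_init__(self) -> None:
        ids = [e.protein_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate protein ids in reference database")
        for e in self.entries:
            if e.og_label not in self.og_labels:
                raise ValueError(f"{e.protein_id}: unknown OG label {e.og_label}")

    def sequences(self) -> dict[str, str]:
        return {e.protein_id: e.sequence for e in self.entries}

    def label_of(self, protein_id: str) -> str:
        for e in self.entries:
            if e.protein_id == protein_id:
                return e.og_label
        raise KeyError(protein_id)

    @classmethod
    def from_fasta(cls, path: str | Path) -> "ReferenceDB":
        """Read a reference database whose headers are ``id|species|og``."""
        from .core_io import read_fasta

        entries = []
        for header, seq in read_fasta(path).items():
            try:
                pid, species, og = header.split("|")
            except ValueError as exc:
                raise ValueError(f"bad reference header {header!r}") from exc
            entries.append(RefEntry(pid, species, og, seq))
        return cls(entries)

    def to_fasta(self, path: str | Path) -> None:
        from .core_io import write_fasta

        write_fasta(
            {f"{e.protein_id}|{e.species}|{e.og_label}": e.sequence for e in self.entries},
            path,
        )


@dataclass
class OGAssignment:
    gene_id: str
    og_label: str
    top_hits: list[tuple[str, str, int]] = field(default_factory=list)
    rule: str = "none"
    note: str = ""


def assign_og(
    gene_id: str,
    protein: str,
    db: ReferenceDB,
    k: int = 3,
    scheme: ScoringScheme = ScoringScheme(),
) -> OGAssignment:
    """Assign one protein to an OG by the top-k consensus rule.

    Self-hits (a database entry with the query's own id) are excluded.  If
    ranks k and k+1 tie in score, the whole score-tied block must share one
    label; disagreement leaves the gene unassigned.
    """
    if len(db.entries) < k:
        raise ValueError("reference database smaller than consensus k")
    if len(protein) < 10:
        logger.warning("%s: query shorter than 10 aa, left unassigned", gene_id)
        return OGAssignment(gene_id, UNASSIGNED, rule="none")
    subjects = {e.protein_id: e.sequence for e in db.entries if e.protein_id != gene_id}
    labels = {e.protein_id: e.og_label for e in db.entries}
    hits = rank_hits(gene_id, protein, subjects, scheme)
    top = [(h.subject_id, labels[h.subject_id], h.score) for h in hits[:k]]
    if len(hits) < k:
        return OGAssignment(gene_id, UNASSIGNED, top, rule="none")
    kth = hits[k - 1].score
    block = [h for h in hits if h.score >= kth]
    block_labels = {labels[h.subject_id] for h in block}
    if len(block_labels) == 1 and kth > 0:
        return OGAssignment(gene_id, block_labels.pop(), top, rule="consensus")
    return OGAssignment(gene_id, UNASSIGNED, top, rule="none")


def assign_all(
    genes: list[GeneModel],
    db: ReferenceDB,
    cfg: PipelineConfig = PipelineConfig(),
    scheme: ScoringScheme | None = None,
) -> tuple[list[OGAssignment], dict]:
    """Assign every functional gene; return assignments plus a summary.

    The summary counts genes per OG label (the per-OG tally table of the
    survey), the number of distinct labels used, and lists unassigned genes.
    """
    scheme = scheme or ScoringScheme(gap_open=cfg.gap_open, gap_extend=cfg.gap_extend)
    assignments = [
        assign_og(g.gene_id, g.protein, db, cfg.consensus_k, scheme)
        for g in genes
        if g.status == "functional"
    ]
    counts = Counter(a.og_label for a in assignments if a.og_label != UNASSIGNED)
    summary = {
        "per_og": dict(sorted(counts.items())),
        "n_assigned": sum(counts.values()),
        "n_distinct_labels": len(counts),
        "unassigned": sorted(a.gene_id for a in assignments if a.og_label == UNASSIGNED),
    }
    return assignments, summary


def assignments_table(assignments: list[OGAssignment], k: int = 3) -> pd.DataFrame:
    rows = []
    for a in assignments:
        row: dict = {"gene_id": a.gene_id, "og_label": a.og_label, "rule": a.rule}
        for i in range(k):
            sid, lab, score = a.top_hits[i] if i < len(a.top_hits) else ("", "", "")
            row[f"top{i + 1}_subject"] = sid
            row[f"top{i + 1}_label"] = lab
            row[f"top{i + 1}_score"] = score
        if a.note:
            row["note"] = a.note
        rows.append(row)
    return pd.DataFrame(rows)


def write_assignments(assignments: list[OGAssignment], path: str | Path, k: int = 3) -> None:
    assignments_table(assignments, k).to_csv(path, sep="\t", index=False)
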