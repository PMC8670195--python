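"""Tandem arrays, WGD paralog pairs, and chromosome distribution summaries.

Tandem duplications are same-orthogroup genes on one chromosome whose
consecutive start positions lie within a distance cutoff (default 100 kb),
chained transitively so arrays of three or more genes are recovered.  WGD
paralogs are same-OG genes sitting inside the two sides of previously
described duplicated genomic blocks, which are an input, not inferred.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .config import PipelineConfig
from .core_io import GeneModel
from .og_classify import UNASSIGNED
from .pairwise_align import ScoringScheme, sw_score

logger = logging.getLogger("famforge")


@dataclass
class TandemArray:
    chromosome: str
    og_label: str
    members: list[str]  # gene ids ordered by start
    span: tuple[int, int]

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError("tandem array needs >= 2 members")


@dataclass
class DuplicationBlock:
    """One pair of duplicated genomic intervals (chrom, start, end)."""

    side1: tuple[str, int, int]
    side2: tuple[str, int, int]
    block_id: str
    score: float = 0.0


@dataclass
class ParalogPair:
    gene_a: str
    gene_b: str
    og_label: str
    block_id: str

    def __post_init__(self) -> None:
        if self.gene_a == self.gene_b:
            raise ValueError("paralog pair genes must be distinct")


def detect_tandem_arrays(
    genes: list[GeneModel],
    assignments: dict[str, str],
    cfg: PipelineConfig = PipelineConfig(),
) -> list[TandemArray]:
    """Chain same-OG neighbours within ``tandem_max_gap`` into arrays.

    Distance is start-to-start between consecutive same-OG genes on a
    chromosome; chaining is transitive, so genes at 0, 90 kb and 180 kb form
    one three-gene array.  Unassigned genes are excluded.
    """
    arrays: list[TandemArray] = []
    by_group: dict[tuple[str, str], list[GeneModel]] = {}
    for g in genes:
        og = assignments.get(g.gene_id, UNASSIGNED)
        if og == UNASSIGNED:
            continue
        by_group.setdefault((g.chromosome, og), []).append(g)
    for (chrom, og), members in sorted(by_group.items()):
        members.sort(key=lambda g: g.start)
        chain: list[GeneModel] = []
        for g in members:
            if chain and g.start - chain[-1].start > cfg.tandem_max_gap:
                if len(chain) >= 2:
                    arrays.append(_chain_to_array(chrom, og, chain))
                chain = []
            chain.append(g)
        if len(chain) >= 2:
            arrays.append(_chain_to_array(chrom, og, chain))
    return arrays


def _chain_to_array(chrom: str, og: str, chain: list[GeneModel]) -> TandemArray:
    return TandemArray(
        chromosome=chrom,
        og_label=og,
        members=[g.gene_id for g in chain],
        span=(chain[0].start, chain[-1].end),
    )


def _inside(gene: GeneModel, side: tuple[str, int, int]) -> bool:
    chrom, s, e = side
    return gene.chromosome == chrom and s <= gene.start and gene.end <= e


def pair_wgd_paralogs(
    genes: list[GeneModel],
    assignments: dict[str, str],
    blocks: list[DuplicationBlock],
    scheme: ScoringScheme | None = None,
) -> list[ParalogPair]:
    """Pair same-OG genes across the two sides of each duplication block.

    When one side holds several same-OG candidates, the partner with the
    highest local-alignment score wins (greedy, each gene pairs at most once
    per block); pairs are deduplicated across blocks.
    """
    scheme = scheme or ScoringScheme()
    proteins = {g.gene_id: g.protein for g in genes}
    pairs: list[ParalogPair] = []
    seen: set[tuple[str, str]] = set()
    for block in blocks:
        side1 = [g for g in genes if _inside(g, block.side1)]
        side2 = [g for g in genes if _inside(g, block.side2)]
        ogs = {assignments.get(g.gene_id) for g in side1} & {
            assignments.get(g.gene_id) for g in side2
        }
        ogs.discard(None)
        ogs.discard(UNASSIGNED)
        for og in sorted(ogs):
            cand1 = [g.gene_id for g in side1 if assignments.get(g.gene_id) == og]
            cand2 = [g.gene_id for g in side2 if assignments.get(g.gene_id) == og]
            scored = sorted(
                (
                    (-sw_score(proteins[a], proteins[b], scheme), a, b)
                    for a in cand1
                    for b in cand2
                    if a != b
                ),
            )
            used: set[str] = set()
            for _, a, b in scored:
                if a in used or b in used:
                    continue
                used.update((a, b))
                key = tuple(sorted((a, b)))
                if key in seen:
                    continue
                seen.add(key)
                pairs.append(ParalogPair(a, b, og, block.block_id))
    return pairs


def chromosome_distribution(genes: list[GeneModel]) -> dict:
    """Per-chromosome gene counts with percentages and argmax/argmin sets."""
    counts: dict[str, int] = {}
    for g in genes:
        counts[g.chromosome] = counts.get(g.chromosome, 0) + 1
    if not counts:
        return {"counts": {}, "percent": {}, "max_chromosomes": set(), "min_chromosomes": set()}
    total = sum(counts.values())
    hi, lo = max(counts.values()), min(counts.values())
    return {
        "counts": dict(sorted(counts.items())),
        "percent": {c: 100.0 * n / total for c, n in sorted(counts.items())},
        "max_chromosomes": {c for c, n in counts.items() if n == hi},
        "min_chromosomes": {c for c, n in counts.items() if n == lo},
    }


# ---------------------------------------------------------------------------
# block-pair BED-like I/O (8 columns)
# ---------------------------------------------------------------------------

BLOCK_COLUMNS = ["chrom1", "start1", "end1", "chrom2", "start2", "end2", "block_id", "score"]


def read_blocks(path: str | Path) -> list[DuplicationBlock]:
    df = pd.read_csv(path, sep="\t", header=0)
    missing = set(BLOCK_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"block file missing columns: {sorted(missing)}")
    return [
        DuplicationBlock(
            (r.chrom1, int(r.start1), int(r.end1)),
            (r.chrom2, int(r.start2), int(r.end2)),
            str(r.block_id),
            float(r.score),
        )
        for r in df.itertuples()
    ]


def write_blocks(blocks: list[DuplicationBlock], path: str | Path) -> None:
    pd.DataFrame(
        [
            [*b.side1, *b.side2, b.block_id, b.score]
            for b in blocks
        ],
        columns=BLOCK_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


def arrays_table(arrays: list[TandemArray]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chromosome": [a.chromosome for a in arrays],
            "og_label": [a.og_label for a in arrays],
            "members": [",".join(a.members) for a in arrays],
            "start": [a.span[0] for a in arrays],
            "end": [a.span[1] for a in arrays],
        }
    )


def pairs_table(pairs: list[ParalogPair]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_a": [p.gene_a for p in pairs],
            "gene_b": [p.gene_b for p in pairs],
            "og_label": [p.og_label for p in pairs],
            "block_id": [p.block_id for p in pairs],
        }
    )
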