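"""Family-locus mining from genomic sequence and exon-structure typing.

Mining is a translated search: all six reading frames of each chromosome
are scanned for regions similar to reference family proteins (shared-4-mer
seeding confirmed by Smith-Waterman), and nearby hits are merged into loci.
A stop codon inside a merged hit or a frame change across a tiny genomic
gap are the pseudogene signals (internal stop / frameshift).

Exon-structure typing compares a gene against the family's canonical
three-exon architecture: exon 1 carries subdomains A and B and ends one
nucleotide into a codon (intron phase 1), exon 2 carries C and D and ends
on a codon boundary (phase 0), exon 3 starts with subdomain E and holds the
C-terminal regulatory region.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from Bio.Seq import Seq

from .core_io import GeneModel, GenomeAnnotation, revcomp
from .pairwise_align import ScoringScheme, smith_waterman

logger = logging.getLogger("famforge")

SUBDOMAINS = ("A", "B", "C", "D", "E")

#: genomic gap (bp) below which a frame change between merged translated
#: hits is called a frameshift rather than an intron
FRAMESHIFT_MAX_GAP = 60


@dataclass
class MinedLocus:
    chromosome: str
    strand: str
    start: int
    end: int
    best_query: str
    score: int
    frames: set[int] = field(default_factory=set)
    flags: set[str] = field(default_factory=set)
    linked_gene: str | None = None

    @property
    def intact(self) -> bool:
        return not self.flags


@dataclass
class _FrameHit:
    query_id: str
    chromosome: str
    strand: str
    frame: int
    g_start: int
    g_end: int
    q_start: int
    q_end: int
    score: int
    query_aln: str
    subject_aln: str


def _frame_translations(seq: str):
    """Yield (strand, frame, protein) for all six frames."""
    rc = revcomp(seq)
    for strand, s in (("+", seq), ("-", rc)):
        for frame in range(3):
            sub = s[frame:]
            sub = sub[: len(sub) - len(sub) % 3]
            yield strand, frame, str(Seq(sub).translate())


def _candidate_segments(prot: str, query_kmers: set[str], qlen: int,
                        k: int = 4, min_hits: int = 4, cluster_gap: int = 200):
    """Spans of the frame translation seeded by shared query k-mers."""
    positions = [i for i in range(len(prot) - k + 1) if prot[i : i + k] in query_kmers]
    segments = []
    run: list[int] = []
    for pos in positions:
        if run and pos - run[-1] > cluster_gap:
            if len(run) >= min_hits:
                segments.append((max(0, run[0] - 50), min(len(prot), run[-1] + qlen + 50)))
            run = []
        run.append(pos)
    if len(run) >= min_hits:
        segments.append((max(0, run[0] - 50), min(len(prot), run[-1] + qlen + 50)))
    return segments


def _aa_to_genomic(strand: str, frame: int, chrom_len: int, aa_start: int, aa_end: int):
    if strand == "+":
        return frame + 3 * aa_start, frame + 3 * aa_end
    end = chrom_len - frame - 3 * aa_start
    return end - 3 * (aa_end - aa_start), end


def mine_loci(
    genome: dict[str, str],
    queries: dict[str, str],
    scheme: ScoringScheme = ScoringScheme(),
    min_score: int = 70,
    merge_gap: int = 10_000,
) -> list[MinedLocus]:
    """Six-frame translated search of a genome for family loci."""
    if not genome or not queries:
        raise ValueError("genome and queries must be non-empty")
    query_kmers = {
        qid: {q[i : i + 4] for i in range(len(q) - 3)} for qid, q in queries.items()
    }
    hits: list[_FrameHit] = []
    for chrom, seq in genome.items():
        if len(seq) < 3:
            logger.warning("chromosome %s shorter than 3 bp: skipped", chrom)
            continue
        for strand, frame, prot in _frame_translations(seq):
            for qid, q in queries.items():
                for s, e in _candidate_segments(prot, query_kmers[qid], len(q)):
                    hit = smith_waterman(q, prot[s:e], scheme, qid, chrom)
                    if hit.score < min_score:
                        continue
                    trim = _trim_alignment(hit.query_aln, hit.subject_aln)
                    if trim is None:
                        continue
                    left, right, q_l, s_l, q_r, s_r = trim
                    aa_s = s + hit.subject_span[0] + s_l
                    aa_e = s + hit.subject_span[1] - s_r
                    if aa_e <= aa_s:
                        continue
                    g_s, g_e = _aa_to_genomic(strand, frame, len(seq), aa_s, aa_e)
                    hits.append(
                        _FrameHit(
                            qid, chrom, strand, frame, g_s, g_e,
                            hit.query_span[0] + q_l, hit.query_span[1] - q_r,
                            hit.score,
                            hit.query_aln[left:right], hit.subject_aln[left:right],
                        )
                    )
    return _merge_hits(hits, merge_gap)


def _merge_hits(hits: list[_FrameHit], merge_gap: int) -> list[MinedLocus]:
    loci: list[MinedLocus] = []
    by_key: dict[tuple[str, str], list[_FrameHit]] = {}
    for h in hits:
        by_key.setdefault((h.chromosome, h.strand), []).append(h)
    for (chrom, strand), group in sorted(by_key.items()):
        group.sort(key=lambda h: (h.g_start, h.g_end))
        cluster: list[_FrameHit] = []
        for h in group:
            if cluster and h.g_start - max(x.g_end for x in cluster) > merge_gap:
                loci.append(_cluster_to_locus(chrom, strand, cluster))
                cluster = []
            cluster.append(h)
        if cluster:
            loci.append(_cluster_to_locus(chrom, strand, cluster))
    loci.sort(key=lambda l: (l.chromosome, l.start))
    return loci


def _trim_alignment(query_aln: str, subject_aln: str, window: int = 10, min_matches: int = 7):
    """Trim low-identity alignment tails (HSP tidying).

    Local alignments can drift past exon boundaries on chance matches; the
    retained region runs between the outermost windows with at least
    ``min_matches`` identities out of ``window`` columns.  Returns the
    trimmed column range plus the number of query/subject residues removed
    on each side, or None when no confident window exists.
    """
    n = len(query_aln)
    matches = [query_aln[i] == subject_aln[i] != "-" for i in range(n)]
    left = None
    for i in range(n - window + 1):
        if sum(matches[i : i + window]) >= min_matches:
            left = i
            break
    if left is None:
        return None
    right = None
    for i in range(n, window - 1, -1):
        if sum(matches[i - window : i]) >= min_matches:
            right = i
            break
    q_left = sum(c != "-" for c in query_aln[:left])
    s_left = sum(c != "-" for c in subject_aln[:left])
    q_right = sum(c != "-" for c in query_aln[right:])
    s_right = sum(c != "-" for c in subject_aln[right:])
    return left, right, q_left, s_left, q_right, s_right


def _has_credible_stop(
    query_aln: str,
    subject_aln: str,
    margin: int = 15,
    window: int = 8,
    min_identity: float = 0.6,
) -> bool:
    """True when a subject stop sits in high-identity context on BOTH sides.

    A pseudogene lesion interrupts an otherwise-intact coding alignment;
    chance matches trailing off an exon end only have one good flank.
    """
    n = len(query_aln)
    for i in range(margin, n - margin):
        if subject_aln[i] != "*" or query_aln[i] == "-":
            continue
        good = True
        for lo, hi in ((max(0, i - window), i), (i + 1, min(n, i + window + 1))):
            matches = total = 0
            for j in range(lo, hi):
                if query_aln[j] == "-" or subject_aln[j] == "-":
                    continue
                total += 1
                matches += query_aln[j] == subject_aln[j]
            if not total or matches / total < min_identity:
                good = False
                break
        if good:
            return True
    return False


def _cluster_to_locus(chrom: str, strand: str, cluster: list[_FrameHit]) -> MinedLocus:
    flags: set[str] = set()
    # Pseudogene evidence is judged on the best-matching query only: weak
    # cross-subfamily hits have unreliable alignment boundaries that can
    # drift into intron translation.
    best_qid = max(cluster, key=lambda h: h.score).query_id
    best_hits = [h for h in cluster if h.query_id == best_qid]
    # A stop aligned against a query residue inside an otherwise
    # well-matching stretch is pseudogene evidence.  Stops under query gaps
    # or in low-identity stretches are intron translation that the local
    # aligner happened to bridge, not lesions.
    if any(_has_credible_stop(h.query_aln, h.subject_aln) for h in best_hits):
        flags.add("internal_stop")
    # Frameshift: two best-query segments in different frames that cover
    # complementary parts of the query and are genomically adjacent.
    # Exon hits separated by introns are farther apart, and a bridged
    # whole-gene alignment nests the query span of any exon hit, so
    # neither pattern is mistaken for a lesion.
    for i, a in enumerate(best_hits):
        for b in best_hits[i + 1 :]:
            if a.frame == b.frame:
                continue
            union = max(a.q_end, b.q_end) - min(a.q_start, b.q_start)
            longest = max(a.q_end - a.q_start, b.q_end - b.q_start)
            if union < longest + 20:
                continue
            g_gap = max(a.g_start, b.g_start) - min(a.g_end, b.g_end)
            if g_gap < FRAMESHIFT_MAX_GAP:
                flags.add("frameshift")
    best = max(cluster, key=lambda h: h.score)
    return MinedLocus(
        chromosome=chrom,
        strand=strand,
        start=min(h.g_start for h in cluster),
        end=max(h.g_end for h in cluster),
        best_query=best.query_id,
        score=best.score,
        frames={h.frame for h in cluster},
        flags=flags,
    )


def link_loci_to_genes(loci: list[MinedLocus], ann: GenomeAnnotation) -> None:
    """Attach annotated gene ids to loci overlapping them (same strand)."""
    for locus in loci:
        for g in ann.genes:
            if (
                g.chromosome == locus.chromosome
                and g.strand == locus.strand
                and g.start < locus.end
                and locus.start < g.end
            ):
                locus.linked_gene = g.gene_id
                break


# ---------------------------------------------------------------------------
# exon/intron structure
# ---------------------------------------------------------------------------

@dataclass
class StructureCall:
    gene_id: str
    n_exons: int
    intron_phases: list[int]
    subdomain_exon_map: dict[str, int]
    label: str


def _exon_cds_lengths(gene: GeneModel) -> list[int]:
    return [e - s for s, e in gene.transcription_order_exons()]


def intron_phases(gene: GeneModel) -> list[int]:
    """Phase of each intron: cumulative CDS length before it, mod 3."""
    lengths = _exon_cds_lengths(gene)
    cum = 0
    phases = []
    for ln in lengths[:-1]:
        cum += ln
        phases.append(cum % 3)
    return phases


def _aa_exon_index(aa_pos: int, exon_cds_lengths: list[int]) -> int:
    """1-based exon index containing the first nucleotide of codon aa_pos."""
    nt = 3 * aa_pos
    cum = 0
    for i, ln in enumerate(exon_cds_lengths, 1):
        cum += ln
        if nt < cum:
            return i
    return len(exon_cds_lengths)


def classify_structure(
    gene: GeneModel, subdomain_spans: dict[str, tuple[int, int]]
) -> StructureCall:
    """Type a gene's exon architecture against the canonical 3-exon model.

    ``subdomain_spans`` maps subdomains A..E to half-open protein intervals
    (typically derived from motif occurrences).
    """
    if not gene.exons:
        raise ValueError(f"{gene.gene_id}: gene has no exons")
    missing = [s for s in SUBDOMAINS if s not in subdomain_spans]
    if missing:
        raise ValueError(f"{gene.gene_id}: missing subdomain spans {missing}")
    plen = len(gene.protein)
    for name, (s, e) in subdomain_spans.items():
        if not (0 <= s < e <= plen):
            raise ValueError(f"{gene.gene_id}: subdomain {name} span outside protein")
    lengths = _exon_cds_lengths(gene)
    phases = intron_phases(gene)
    n = len(lengths)
    sd_exon = {
        name: _aa_exon_index(subdomain_spans[name][0], lengths) for name in SUBDOMAINS
    }
    label = _structure_label(n, phases, sd_exon)
    return StructureCall(gene.gene_id, n, phases, sd_exon, label)


def _structure_label(n: int, phases: list[int], sd: dict[str, int]) -> str:
    basic_map = {"A": 1, "B": 1, "C": 2, "D": 2, "E": 3}
    if n == 3 and phases == [1, 0] and sd == basic_map:
        return "basic"
    if n >= 2 and sd["A"] == sd["B"] == sd["C"] == sd["D"] == 1 and sd["E"] == 2:
        return "merged_1_2"
    shift = sd["A"] - 1
    if shift >= 1 and all(sd[k] == basic_map[k] + shift for k in basic_map):
        return "extra_nterm"
    if n > sd["E"]:  # at least one exon wholly 3' of subdomain E
        if (
            sd["E"] == 3
            and len(phases) >= 2
            and phases[:2] == [1, 0]
            and {k: sd[k] for k in basic_map} == basic_map
        ):
            return "basic_plus_cterm"
        return "extra_cterm"
    return "noncanonical"


def structure_table(calls: list[StructureCall]):
    import pandas as pd

    return pd.DataFrame(
        {
            "gene_id": [c.gene_id for c in calls],
            "n_exons": [c.n_exons for c in calls],
            "intron_phases": [",".join(map(str, c.intron_phases)) for c in calls],
            "label": [c.label for c in calls],
        }
    )
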