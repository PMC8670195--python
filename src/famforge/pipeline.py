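"""End-to-end orchestration of the family-analysis stages.

``run_pipeline`` executes the whole chain on in-memory inputs (or inputs
loaded from a simulated-data directory): orthogroup assignment, translated
locus mining with pseudogene flagging, duplication analysis, motif
discovery with architecture typing, exon-structure calls, promoter TFBS
profiling and differential-expression candidate selection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .config import PipelineConfig
from .core_io import GenomeAnnotation, read_fasta, read_gff3
from .duplication import (
    DuplicationBlock,
    ParalogPair,
    TandemArray,
    chromosome_distribution,
    detect_tandem_arrays,
    pair_wgd_paralogs,
    read_blocks,
)
from .expression import CandidateCall, categorize, records_from_frame
from .gene_structure import (
    MinedLocus,
    StructureCall,
    classify_structure,
    link_loci_to_genes,
    mine_loci,
)
from .motifs import (
    MotifArchitecture,
    MotifModel,
    SubdomainMap,
    classify_architecture,
    discover_motifs,
    map_subdomains,
)
from .og_classify import OGAssignment, ReferenceDB, assign_all
from .pairwise_align import ScoringScheme
from .promoters import NucPWM, extract_promoter, og_tfbs_matrix, read_pwms, scan_all

logger = logging.getLogger("famforge")

SUBDOMAINS = ("A", "B", "C", "D", "E")


@dataclass
class PipelineInputs:
    annotation: GenomeAnnotation
    genome: dict[str, str]
    refdb: ReferenceDB
    pwms: list[NucPWM] = field(default_factory=list)
    wgd_blocks: list[DuplicationBlock] = field(default_factory=list)
    de_table: pd.DataFrame | None = None

    @classmethod
    def from_dir(cls, datadir: str | Path) -> "PipelineInputs":
        d = Path(datadir)
        ann = read_gff3(d / "annotation.gff3", d / "genome.fasta")
        genome = read_fasta(d / "genome.fasta")
        refdb = ReferenceDB.from_fasta(d / "reference_db.fasta")
        pwms = read_pwms(d / "pwms.meme.txt") if (d / "pwms.meme.txt").exists() else []
        blocks = read_blocks(d / "wgd_blocks.tsv") if (d / "wgd_blocks.tsv").exists() else []
        de = (
            pd.read_csv(d / "de_table.tsv", sep="\t")
            if (d / "de_table.tsv").exists()
            else None
        )
        return cls(ann, genome, refdb, pwms, blocks, de)


@dataclass
class PipelineResult:
    assignments: list[OGAssignment]
    summary: dict
    loci: list[MinedLocus]
    tandem_arrays: list[TandemArray]
    wgd_pairs: list[ParalogPair]
    chrom_distribution: dict
    motif_models: list[MotifModel]
    architectures: list[MotifArchitecture]
    subdomain_map: SubdomainMap | None
    structure_calls: list[StructureCall]
    tfbs_matrix: pd.DataFrame | None
    de_calls: list[CandidateCall]


def motif_subdomain_spans(
    models: list[MotifModel], subdomain_map: SubdomainMap
) -> dict[str, dict[str, tuple[int, int]]]:
    """Per-protein subdomain spans derived from discovered motif occurrences."""
    index_of = {}
    for m in models:
        index_of[m.index] = m
    spans: dict[str, dict[str, tuple[int, int]]] = {}
    for number, subdomain in subdomain_map.mapping.items():
        if subdomain not in SUBDOMAINS or number not in index_of:
            continue
        model = index_of[number]
        for pid, off in model.occurrences:
            cur = spans.setdefault(pid, {}).get(subdomain)
            iv = (off, off + model.width)
            if cur is None:
                spans[pid][subdomain] = iv
            else:
                spans[pid][subdomain] = (min(cur[0], iv[0]), max(cur[1], iv[1]))
    return spans


def run_pipeline(
    inputs: PipelineInputs,
    cfg: PipelineConfig = PipelineConfig(),
    discover: bool = True,
) -> PipelineResult:
    scheme = ScoringScheme(gap_open=cfg.gap_open, gap_extend=cfg.gap_extend)
    genes = [g for g in inputs.annotation.genes if g.status == "functional"]

    logger.info("assigning %d genes to orthogroups", len(genes))
    assignments, summary = assign_all(genes, inputs.refdb, cfg, scheme)
    label_of = {a.gene_id: a.og_label for a in assignments}

    logger.info("mining loci from %d chromosomes", len(inputs.genome))
    queries = {e.protein_id: e.sequence for e in inputs.refdb.entries if e.species == "Vvi"}
    if not queries:  # fall back to one representative per OG
        seen: set[str] = set()
        queries = {}
        for e in inputs.refdb.entries:
            if e.og_label not in seen:
                queries[e.protein_id] = e.sequence
                seen.add(e.og_label)
    loci = mine_loci(
        inputs.genome, queries, scheme, cfg.min_locus_score, cfg.locus_merge_gap
    )
    link_loci_to_genes(loci, inputs.annotation)

    tandem = detect_tandem_arrays(genes, label_of, cfg)
    wgd = pair_wgd_paralogs(genes, label_of, inputs.wgd_blocks, scheme)
    distribution = chromosome_distribution(genes)

    models: list[MotifModel] = []
    architectures: list[MotifArchitecture] = []
    sd_map: SubdomainMap | None = None
    structure_calls: list[StructureCall] = []
    if discover:
        proteins = {g.gene_id: g.protein for g in genes}
        wmax = min(cfg.motif_wmax, min(len(p) for p in proteins.values()))
        logger.info("discovering %d motifs (widths %d-%d)", cfg.motif_count, cfg.motif_wmin, wmax)
        models = discover_motifs(
            proteins, cfg.motif_count, cfg.motif_wmin, wmax, seed=cfg.rng_seed
        )
        if len(models) == 10:
            sd_map = map_subdomains(models)
            renumber = {m.index: num for num, m in _match_map(models, sd_map).items()}
            presence = {}
            for m in models:
                for pid, _ in m.occurrences:
                    presence.setdefault(pid, set()).add(renumber.get(m.index, m.index))
            architectures = [
                classify_architecture(pid, present)
                for pid, present in sorted(presence.items())
            ]
            spans = motif_subdomain_spans(
                [_renumbered(m, renumber) for m in models], sd_map
            )
            for g in genes:
                sd = spans.get(g.gene_id)
                if sd and all(s in sd for s in SUBDOMAINS):
                    try:
                        structure_calls.append(classify_structure(g, sd))
                    except ValueError as exc:
                        logger.warning("structure call failed for %s: %s", g.gene_id, exc)

    tfbs = None
    if inputs.pwms:
        promoters = {
            g.gene_id: extract_promoter(g, inputs.genome, cfg.promoter_len) for g in genes
        }
        counts = scan_all(promoters, inputs.pwms, cfg.tfbs_threshold_frac)
        tfbs = og_tfbs_matrix(counts, assignments)

    de_calls: list[CandidateCall] = []
    if inputs.de_table is not None:
        de_calls = categorize(records_from_frame(inputs.de_table), cfg)

    return PipelineResult(
        assignments=assignments,
        summary=summary,
        loci=loci,
        tandem_arrays=tandem,
        wgd_pairs=wgd,
        chrom_distribution=distribution,
        motif_models=models,
        architectures=architectures,
        subdomain_map=sd_map,
        structure_calls=structure_calls,
        tfbs_matrix=tfbs,
        de_calls=de_calls,
    )


def _match_map(models: list[MotifModel], sd_map: SubdomainMap) -> dict[int, MotifModel]:
    """Invert the subdomain numbering back onto the discovered models."""
    by_consensus = {}
    for m in models:
        by_consensus.setdefault(m.consensus, m)
    return {
        num: by_consensus[cons]
        for num, cons in sd_map.consensus.items()
        if cons in by_consensus
    }


def _renumbered(model: MotifModel, renumber: dict[int, int]) -> MotifModel:
    out = MotifModel(
        index=renumber.get(model.index, model.index),
        width=model.width,
        pwm=model.pwm,
        background=model.background,
        occurrences=model.occurrences,
        llr=model.llr,
    )
    return out
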