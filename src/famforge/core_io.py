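"""Readers and writers for the on-disk formats used by the pipeline.

Internally all coordinates are 0-based half-open intervals on the forward
genome strand; the GFF3 1-based closed convention is converted at the
boundary.  One :class:`GeneModel` is kept per gene (the isoform with the
longest CDS when a gene has several mRNAs).
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path

import gffutils
import skbio
from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger("famforge")

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def translate_cds(cds: str) -> str:
    """Translate a CDS, returning the protein without a trailing stop."""
    prot = str(Seq(cds[: len(cds) - len(cds) % 3]).translate())
    if prot.endswith("*"):
        prot = prot[:-1]
    return prot


@dataclass
class GeneModel:
    """A single protein-coding gene model.

    ``exons`` are half-open genomic intervals in genomic (ascending) order;
    for minus-strand genes the 5'-most exon is therefore the last one.
    """

    gene_id: str
    chromosome: str
    strand: str
    exons: list[tuple[int, int]]
    cds: str = ""
    protein: str = ""
    status: str = "functional"
    cds_phase_per_exon: list[int] = field(default_factory=list)

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def cds_start(self) -> int:
        """Genomic position of the first CDS base (the A of ATG)."""
        return self.start if self.strand == "+" else self.end - 1

    def transcription_order_exons(self) -> list[tuple[int, int]]:
        return self.exons if self.strand == "+" else list(reversed(self.exons))


@dataclass
class GenomeAnnotation:
    chromosomes: dict[str, int]
    genes: list[GeneModel]

    def __post_init__(self) -> None:
        for g in self.genes:
            if g.chromosome not in self.chromosomes:
                raise ValueError(f"{g.gene_id}: unknown chromosome {g.chromosome}")
            length = self.chromosomes[g.chromosome]
            if g.start < 0 or g.end > length:
                raise ValueError(f"{g.gene_id}: interval outside chromosome")
            for (s1, e1), (s2, e2) in zip(g.exons, g.exons[1:]):
                if s2 < e1:
                    raise ValueError(f"{g.gene_id}: exons overlap or are unsorted")

    def gene(self, gene_id: str) -> GeneModel:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def read_gff3(gff_path: str | Path, genome_path: str | Path) -> GenomeAnnotation:
    """Load gene models from a GFF3 file plus the matching genome FASTA.

    Coordinates are converted to 0-based half-open intervals.  Proteins are
    translated from the spliced, strand-corrected CDS.  A CDS whose length is
    not a multiple of 3, or whose translation has an internal stop, marks the
    gene as a pseudogene candidate rather than raising.
    """
    genome = read_fasta(genome_path)
    db = gffutils.create_db(
        str(gff_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene", order_by=("seqid", "start")):
        if gene.seqid not in genome:
            logger.warning("gene %s on unknown sequence %s: skipped", gene.id, gene.seqid)
            continue
        chrom_len = len(genome[gene.seqid])
        best: GeneModel | None = None
        mrnas = list(db.children(gene, featuretype="mRNA")) or [gene]
        for mrna in mrnas:
            cds_feats = sorted(db.children(mrna, featuretype="CDS"), key=lambda f: f.start)
            exon_feats = sorted(db.children(mrna, featuretype="exon"), key=lambda f: f.start)
            if not cds_feats:
                continue
            if any(f.start - 1 < 0 or f.end > chrom_len for f in cds_feats):
                logger.warning("%s: CDS outside chromosome, record rejected", gene.id)
                continue
            exons = [(f.start - 1, f.end) for f in (exon_feats or cds_feats)]
            cds_ivs = [(f.start - 1, f.end) for f in cds_feats]
            phases = []
            for f in cds_feats:
                try:
                    phases.append(int(f.frame))
                except (TypeError, ValueError):
                    phases.append(0)
            cds = "".join(genome[gene.seqid][s:e] for s, e in cds_ivs)
            if gene.strand == "-":
                cds = revcomp(cds)
                phases = list(reversed(phases))
            model = GeneModel(
                gene_id=gene.id,
                chromosome=gene.seqid,
                strand=gene.strand,
                exons=exons,
                cds=cds,
                cds_phase_per_exon=phases,
            )
            if len(cds) % 3 != 0:
                model.status = "pseudogene"
                model.protein = translate_cds(cds)
            else:
                prot = translate_cds(cds)
                model.protein = prot
                if "*" in prot:
                    model.status = "pseudogene"
            if best is None or len(model.cds) > len(best.cds):
                best = model
        if best is not None:
            genes.append(best)
    chromosomes = {name: len(seq) for name, seq in genome.items()}
    return GenomeAnnotation(chromosomes=chromosomes, genes=genes)


def write_gff3(ann: GenomeAnnotation, path: str | Path) -> None:
    """Write gene models back to GFF3 (gene/mRNA/exon/CDS, 1-based closed)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for name, length in ann.chromosomes.items():
            fh.write(f"##sequence-region {name} 1 {length}\n")
        for g in ann.genes:
            s, e = g.start + 1, g.end
            base = f"{g.chromosome}\tfamforge\t"
            fh.write(base + f"gene\t{s}\t{e}\t.\t{g.strand}\t.\tID={g.gene_id}\n")
            mrna = f"{g.gene_id}.t1"
            fh.write(base + f"mRNA\t{s}\t{e}\t.\t{g.strand}\t.\tID={mrna};Parent={g.gene_id}\n")
            phases = g.cds_phase_per_exon or [0] * len(g.exons)
            if g.strand == "-":
                phases = list(reversed(phases))
            for i, ((xs, xe), ph) in enumerate(zip(g.exons, phases), 1):
                fh.write(
                    base
                    + f"exon\t{xs + 1}\t{xe}\t.\t{g.strand}\t.\tID={mrna}.exon{i};Parent={mrna}\n"
                )
                fh.write(
                    base
                    + f"CDS\t{xs + 1}\t{xe}\t.\t{g.strand}\t{ph}\tID={mrna}.cds{i};Parent={mrna}\n"
                )


# ---------------------------------------------------------------------------
# newick
# ---------------------------------------------------------------------------

def write_newick(tree: "skbio.TreeNode", path: str | Path) -> None:
    """Serialize a tree with branch lengths; internal-node supports (the
    ``support`` attribute) become internal labels."""
    leaves = [t.name for t in tree.tips()]
    if len(leaves) < 2:
        raise ValueError("tree must have at least 2 leaves")
    if len(set(leaves)) != len(leaves):
        raise ValueError("duplicate leaf names")
    tree.write(str(path), format="newick")  # skbio serializes node.support


def read_newick(path: str | Path) -> "skbio.TreeNode":
    """Read a newick tree, interpreting numeric internal labels as supports."""
    tree = skbio.TreeNode.read(str(path), format="newick")
    tree.assign_supports()
    return tree


def newick_from_string(newick: str) -> "skbio.TreeNode":
    return skbio.TreeNode.read(io.StringIO(newick), format="newick")
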