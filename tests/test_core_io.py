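"""Gene-model I/O: coordinate conventions, translation, round-trips."""

import numpy as np
import pytest

from famforge.config import PipelineConfig
from famforge.core_io import (
    GeneModel,
    GenomeAnnotation,
    newick_from_string,
    read_fasta,
    read_gff3,
    read_newick,
    revcomp,
    translate_cds,
    write_fasta,
    write_gff3,
    write_newick,
)


def _write_mini_genome(tmp_path, chrom_seq, gff_body):
    genome = tmp_path / "g.fasta"
    genome.write_text(">chr1\n" + chrom_seq + "\n")
    gff = tmp_path / "a.gff3"
    gff.write_text("##gff-version 3\n" + gff_body)
    return gff, genome


def test_two_exon_gene_translates_to_protein(tmp_path):
    # CDS = ATGGCT + TGA split over two exons -> protein MA
    seq = "NNNNNATGGCTNNNNNNNNNNTGANNNNN".replace("N", "A")
    body = "\n".join(
        [
            "chr1\tx\tgene\t6\t24\t.\t+\t.\tID=g1",
            "chr1\tx\tmRNA\t6\t24\t.\t+\t.\tID=m1;Parent=g1",
            "chr1\tx\texon\t6\t11\t.\t+\t.\tID=e1;Parent=m1",
            "chr1\tx\texon\t22\t24\t.\t+\t.\tID=e2;Parent=m1",
            "chr1\tx\tCDS\t6\t11\t.\t+\t0\tID=c1;Parent=m1",
            "chr1\tx\tCDS\t22\t24\t.\t+\t0\tID=c2;Parent=m1",
        ]
    )
    gff, genome = _write_mini_genome(tmp_path, seq, body + "\n")
    ann = read_gff3(gff, genome)
    (gene,) = ann.genes
    assert gene.protein == "MA"
    assert gene.status == "functional"
    # 1-based closed "6..11" becomes [5, 11)
    assert gene.exons[0] == (5, 11)


def test_minus_strand_gene_gives_same_protein(tmp_path):
    cds = "ATGGCTTGA"
    flank = "ACGT" * 5
    seq = flank + revcomp(cds) + flank
    s, e = len(flank) + 1, len(flank) + len(cds)  # 1-based closed
    body = "\n".join(
        [
            f"chr1\tx\tgene\t{s}\t{e}\t.\t-\t.\tID=g1",
            f"chr1\tx\tmRNA\t{s}\t{e}\t.\t-\t.\tID=m1;Parent=g1",
            f"chr1\tx\texon\t{s}\t{e}\t.\t-\t.\tID=e1;Parent=m1",
            f"chr1\tx\tCDS\t{s}\t{e}\t.\t-\t0\tID=c1;Parent=m1",
        ]
    )
    gff, genome = _write_mini_genome(tmp_path, seq, body + "\n")
    ann = read_gff3(gff, genome)
    assert ann.genes[0].protein == "MA"


def test_cds_not_multiple_of_three_marks_pseudogene(tmp_path):
    seq = "A" * 5 + "ATGGCTTG" + "A" * 20
    body = "\n".join(
        [
            "chr1\tx\tgene\t6\t13\t.\t+\t.\tID=g1",
            "chr1\tx\tmRNA\t6\t13\t.\t+\t.\tID=m1;Parent=g1",
            "chr1\tx\texon\t6\t13\t.\t+\t.\tID=e1;Parent=m1",
            "chr1\tx\tCDS\t6\t13\t.\t+\t0\tID=c1;Parent=m1",
        ]
    )
    gff, genome = _write_mini_genome(tmp_path, seq, body + "\n")
    ann = read_gff3(gff, genome)
    assert ann.genes[0].status == "pseudogene"


def test_gff3_round_trip_preserves_coordinates(default_sim, tmp_path):
    write_gff3(default_sim.annotation, tmp_path / "out.gff3")
    write_fasta(default_sim.genome, tmp_path / "out.fasta")
    back = read_gff3(tmp_path / "out.gff3", tmp_path / "out.fasta")
    orig = {g.gene_id: g for g in default_sim.annotation.genes}
    assert set(orig) == {g.gene_id for g in back.genes}
    for g in back.genes:
        o = orig[g.gene_id]
        assert g.exons == o.exons
        assert g.strand == o.strand
        assert g.protein == o.protein
        assert g.status == "functional"


def test_fasta_round_trip(tmp_path):
    seqs = {"a": "ACGT" * 30, "b": "TTTT"}
    write_fasta(seqs, tmp_path / "x.fasta")
    assert read_fasta(tmp_path / "x.fasta") == seqs


def test_translate_cds_strips_stop():
    assert translate_cds("ATGGCTTGA") == "MA"


def test_annotation_rejects_out_of_bounds_gene():
    g = GeneModel("g", "chr1", "+", [(90, 120)])
    with pytest.raises(ValueError):
        GenomeAnnotation({"chr1": 100}, [g])


# ---------------------------------------------------------------------------
# newick
# ---------------------------------------------------------------------------

def test_newick_three_leaf_star(tmp_path):
    tree = newick_from_string("(A:1,B:2,C:3);")
    path = tmp_path / "t.nwk"
    write_newick(tree, path)
    back = read_newick(path)
    assert {t.name: t.length for t in back.tips()} == {"A": 1.0, "B": 2.0, "C": 3.0}


def test_newick_round_trip_random_tree(tmp_path):
    rng = np.random.default_rng(5)
    from famforge.phylo import nj_tree

    n = 8
    d = rng.uniform(0.5, 2.0, size=(n, n))
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0.0)
    ids = [f"L{i}" for i in range(n)]
    tree = nj_tree(d, ids)
    path = tmp_path / "t.nwk"
    write_newick(tree, path)
    back = read_newick(path)
    from famforge.phylo import bipartitions

    assert set(bipartitions(back)) == set(bipartitions(tree))
    orig = {t.name: t.length for t in tree.tips()}
    readback = {t.name: t.length for t in back.tips()}
    for name in orig:
        assert abs(orig[name] - readback[name]) < 1e-9


def test_newick_support_label_round_trips(tmp_path):
    tree = newick_from_string("((A:1,B:1):1,(C:1,D:1):1);")
    internal = [n for n in tree.non_tips(include_self=False)]
    internal[0].support = 0.97
    path = tmp_path / "t.nwk"
    write_newick(tree, path)
    assert "0.97" in path.read_text()
    back = read_newick(path)
    sups = [getattr(n, "support", None) for n in back.non_tips(include_self=False)]
    assert 0.97 in sups


def test_newick_duplicate_leaves_rejected(tmp_path):
    tree = newick_from_string("(A:1,A:2,C:3);")
    with pytest.raises(ValueError):
        write_newick(tree, tmp_path / "t.nwk")


# ---------------------------------------------------------------------------
# config
# ---------------------------------------------------------------------------

def test_config_yaml_round_trip(tmp_path):
    cfg = PipelineConfig(consensus_k=4, tandem_max_gap=50_000)
    cfg.to_yaml(tmp_path / "c.yaml")
    back = PipelineConfig.from_yaml(tmp_path / "c.yaml")
    assert back == cfg


@pytest.mark.parametrize(
    "kwargs",
    [
        {"consensus_k": 0},
        {"tandem_max_gap": -1},
        {"motif_wmin": 30, "motif_wmax": 20},
        {"de_p_threshold": 0.0},
    ],
)
def test_config_validation_rejects_bad_values(kwargs):
    with pytest.raises(ValueError):
        PipelineConfig(**kwargs)
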