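"""Translated locus mining and exon-architecture typing."""

import numpy as np
import pytest

from famforge.core_io import GeneModel, revcomp
from famforge.gene_structure import (
    classify_structure,
    intron_phases,
    link_loci_to_genes,
    mine_loci,
)
from famforge.synthetic_data import backtranslate

AA = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture(scope="module")
def planted():
    rng = np.random.default_rng(0)
    prot = "M" + "".join(np.array(list(AA))[rng.integers(0, 20, 120)])
    cds = backtranslate(prot) + "TGA"

    def bg(n):
        return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])

    return prot, cds, bg


def test_exact_planted_copy_mined_intact(planted):
    prot, cds, bg = planted
    genome = {"chr1": bg(3000) + cds + bg(3000)}
    loci = mine_loci(genome, {"q": prot})
    assert len(loci) == 1
    (locus,) = loci
    assert locus.intact
    # the locus covers the aligned coding region (the stop codon itself is
    # not part of the protein alignment)
    assert (locus.start, locus.end) == (3000, 3000 + len(cds) - 3)
    assert locus.strand == "+"


def test_internal_stop_flagged(planted):
    prot, cds, bg = planted
    mid = (len(cds) // 2) // 3 * 3
    broken = cds[:mid] + "TAA" + cds[mid + 3 :]
    loci = mine_loci({"chr1": bg(2000) + broken + bg(2000)}, {"q": prot})
    assert len(loci) == 1
    assert "internal_stop" in loci[0].flags


def test_one_bp_deletion_flagged_frameshift(planted):
    prot, cds, bg = planted
    mid = (len(cds) // 2) // 3 * 3
    broken = cds[:mid] + cds[mid + 1 :]
    loci = mine_loci({"chr1": bg(2000) + broken + bg(2000)}, {"q": prot})
    assert len(loci) == 1
    assert "frameshift" in loci[0].flags


def test_minus_strand_copy_found(planted):
    prot, cds, bg = planted
    loci = mine_loci({"chr1": bg(2000) + revcomp(cds) + bg(2000)}, {"q": prot})
    assert len(loci) == 1
    assert loci[0].strand == "-"
    assert loci[0].intact


def test_two_distant_copies_give_two_loci(planted):
    prot, cds, bg = planted
    genome = {"chr1": bg(1000) + cds + bg(1_000_000) + cds + bg(1000)}
    loci = mine_loci(genome, {"q": prot})
    assert len(loci) == 2
    assert all(l.intact for l in loci)


def test_tiny_chromosome_skipped(planted):
    prot, _, _ = planted
    assert mine_loci({"chr1": "AC"}, {"q": prot}) == []


def test_mining_rejects_empty_inputs():
    with pytest.raises(ValueError):
        mine_loci({}, {"q": "MKVT"})


def test_locus_linking_and_pseudogene_truth(default_sim, pipeline_result):
    """Mined loci equal planted genes + pseudogenes; flags match the truth."""
    loci = pipeline_result.loci
    n_genes = len(default_sim.annotation.genes)
    n_pseudo = len(default_sim.truth.pseudogenes)
    assert len(loci) == n_genes + n_pseudo
    linked = {l.linked_gene for l in loci if l.linked_gene}
    assert linked == {g.gene_id for g in default_sim.annotation.genes}
    assert all(l.intact for l in loci if l.linked_gene)
    unlinked = [l for l in loci if l.linked_gene is None]
    assert len(unlinked) == n_pseudo
    for truth in default_sim.truth.pseudogenes:
        match = [
            l
            for l in unlinked
            if l.chromosome == truth["chromosome"]
            and l.start < truth["end"]
            and truth["start"] < l.end
        ]
        assert len(match) == 1
        assert truth["flag"] in match[0].flags


# ---------------------------------------------------------------------------
# exon structure
# ---------------------------------------------------------------------------

def _gene(exon_lengths, strand="+", intron=100):
    """Gene with the given CDS lengths per exon (transcription order)."""
    exons = []
    pos = 0
    for ln in exon_lengths:
        exons.append((pos, pos + ln))
        pos += ln + intron
    total = sum(exon_lengths)
    protein_len = total // 3 - 1
    if strand == "-":
        end = exons[-1][1]
        exons = sorted((end - e, end - s) for s, e in exons)
    return GeneModel(
        "g", "chr1", strand, exons, cds="A" * total, protein="M" * protein_len
    )


BASIC_SPANS = {"A": (5, 14), "B": (20, 29), "C": (35, 60), "D": (66, 84), "E": (90, 99)}


def _basic_lengths(spans, protein_len):
    b1 = 3 * spans["B"][1] + 1
    b2 = 3 * spans["E"][0]
    total = 3 * (protein_len + 1)
    return [b1, b2 - b1, total - b2]


def test_basic_three_exon_structure():
    lengths = _basic_lengths(BASIC_SPANS, 150)
    call = classify_structure(_gene(lengths), BASIC_SPANS)
    assert call.label == "basic"
    assert call.intron_phases == [1, 0]
    assert call.subdomain_exon_map == {"A": 1, "B": 1, "C": 2, "D": 2, "E": 3}


def test_basic_structure_minus_strand():
    lengths = _basic_lengths(BASIC_SPANS, 150)
    call = classify_structure(_gene(lengths, strand="-"), BASIC_SPANS)
    assert call.label == "basic"
    assert call.intron_phases == [1, 0]


def test_merged_first_two_exons():
    b2 = 3 * BASIC_SPANS["E"][0]
    total = 3 * 151
    call = classify_structure(_gene([b2, total - b2]), BASIC_SPANS)
    assert call.label == "merged_1_2"


def test_extra_nterm_leading_exon():
    lengths = _basic_lengths(BASIC_SPANS, 150)
    lengths = [12, lengths[0] - 12, lengths[1], lengths[2]]
    call = classify_structure(_gene(lengths), BASIC_SPANS)
    assert call.label == "extra_nterm"


def test_basic_plus_cterm_extra_exons():
    lengths = _basic_lengths(BASIC_SPANS, 150)
    tail = lengths[2]
    lengths = lengths[:2] + [tail - 60, 30, 30]
    call = classify_structure(_gene(lengths), BASIC_SPANS)
    assert call.label == "basic_plus_cterm"


def test_noncanonical_structure():
    total = 3 * 151
    call = classify_structure(_gene([total // 3 * 3 - 99, 99]), BASIC_SPANS)
    assert call.label in ("noncanonical", "extra_cterm")


def test_span_outside_protein_rejected():
    lengths = _basic_lengths(BASIC_SPANS, 150)
    bad = dict(BASIC_SPANS, E=(140, 160))
    with pytest.raises(ValueError):
        classify_structure(_gene(lengths), bad)


def test_intron_phase_strand_invariant():
    lengths = [100, 233, 162]
    assert intron_phases(_gene(lengths)) == intron_phases(_gene(lengths, strand="-"))


def test_structure_truth_recovered_with_planted_spans(default_sim):
    """Every simulated gene recovers its planted structure label when typed
    with the generator's subdomain spans."""
    for g in default_sim.annotation.genes:
        call = classify_structure(g, default_sim.truth.subdomain_spans[g.gene_id])
        assert call.label == default_sim.truth.structure_labels[g.gene_id], g.gene_id
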