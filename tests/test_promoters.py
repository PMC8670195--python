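"""Promoter extraction, PWM scanning and OG-level TFBS matrices."""

import numpy as np
import pandas as pd
import pytest

from famforge.core_io import GeneModel, revcomp
from famforge.promoters import (
    NucPWM,
    extract_promoter,
    og_tfbs_matrix,
    read_pwms,
    scan_all,
    scan_promoter,
    write_pwms,
)

from .oracles import brute_force_og_means


def _sharp(consensus, p=0.97):
    mat = np.full((len(consensus), 4), (1 - p) / 3)
    for i, b in enumerate(consensus):
        mat[i, "ACGT".index(b)] = p
    return NucPWM("m1", "TF1", mat)


PWM = _sharp("GCCGCCTC")


def _random_dna(rng, n):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def _clean_background(rng, n, consensus):
    seq = _random_dna(rng, n)
    while consensus in seq or revcomp(consensus) in seq:
        seq = _random_dna(rng, n)
    return seq


# ---------------------------------------------------------------------------
# extraction
# ---------------------------------------------------------------------------

def test_plus_strand_promoter_is_upstream_window():
    rng = np.random.default_rng(0)
    chrom = _random_dna(rng, 8000)
    gene = GeneModel("g", "chr1", "+", [(5000, 5900)], cds="ATG")
    assert extract_promoter(gene, {"chr1": chrom}, 2000) == chrom[3000:5000]


def test_minus_strand_promoter_reverse_complemented():
    rng = np.random.default_rng(1)
    chrom = _random_dna(rng, 8000)
    gene = GeneModel("g", "chr1", "-", [(4100, 5000)], cds="ATG")
    assert extract_promoter(gene, {"chr1": chrom}, 2000) == revcomp(chrom[5000:7000])


def test_promoter_truncated_at_chromosome_edge(caplog):
    rng = np.random.default_rng(2)
    chrom = _random_dna(rng, 3000)
    gene = GeneModel("g", "chr1", "+", [(800, 1700)], cds="ATG")
    prom = extract_promoter(gene, {"chr1": chrom}, 2000)
    assert prom == chrom[:800]
    assert len(prom) == 800


def test_gene_without_cds_rejected():
    gene = GeneModel("g", "chr1", "+", [(100, 200)])
    with pytest.raises(ValueError):
        extract_promoter(gene, {"chr1": "A" * 300})


# ---------------------------------------------------------------------------
# scanning
# ---------------------------------------------------------------------------

def test_single_planted_site_counted_once():
    rng = np.random.default_rng(3)
    seq = _clean_background(rng, 500, PWM.consensus)
    planted = seq[:200] + PWM.consensus + seq[208:]
    assert scan_promoter(planted, PWM) == 1


def test_reverse_complement_site_counted():
    rng = np.random.default_rng(4)
    seq = _clean_background(rng, 500, PWM.consensus)
    planted = seq[:200] + revcomp(PWM.consensus) + seq[208:]
    assert scan_promoter(planted, PWM) == 1


def test_scan_is_strand_invariant():
    rng = np.random.default_rng(5)
    for _ in range(10):
        seq = _random_dna(rng, 300)
        assert scan_promoter(seq, PWM) == scan_promoter(revcomp(seq), PWM)


def test_n_bases_score_as_background():
    seq = "N" * 100
    assert scan_promoter(seq, PWM) == 0


def test_sequence_shorter_than_pwm_gives_zero():
    assert scan_promoter("ACGT", PWM) == 0


def test_raising_threshold_never_increases_hits():
    rng = np.random.default_rng(6)
    seq = _random_dna(rng, 2000)
    seq = seq[:100] + PWM.consensus + seq[108:]
    counts = [scan_promoter(seq, PWM, t) for t in (0.5, 0.7, 0.8, 0.9, 1.0)]
    assert counts == sorted(counts, reverse=True)


def test_planted_counts_recovered_across_promoters():
    """Total hits over seeded promoters equal the planted site count."""
    rng = np.random.default_rng(7)
    total_planted = 0
    total_found = 0
    for _ in range(50):
        k = int(rng.integers(0, 4))
        seq = _clean_background(rng, 1000, PWM.consensus)
        seq = list(seq)
        for slot in range(k):
            off = 50 + slot * 100
            seq[off : off + 8] = PWM.consensus
        seq = "".join(seq)
        if seq.count(PWM.consensus) + seq.count(revcomp(PWM.consensus)) != k:
            continue  # planting collision; skip this draw
        total_planted += k
        total_found += scan_promoter(seq, PWM)
    assert total_found == total_planted


# ---------------------------------------------------------------------------
# OG matrix
# ---------------------------------------------------------------------------

def test_og_mean_of_two_genes():
    counts = pd.DataFrame({"TF1": [2, 4]}, index=["g1", "g2"]).rename_axis("gene_id")
    m = og_tfbs_matrix(counts, {"g1": "1a", "g2": "1a"})
    assert m.loc["1a", "TF1"] == 3.0


def test_single_gene_og_mean_is_count():
    counts = pd.DataFrame({"TF1": [5]}, index=["g1"]).rename_axis("gene_id")
    assert og_tfbs_matrix(counts, {"g1": "2a"}).loc["2a", "TF1"] == 5.0


def test_matrix_equals_brute_force_means(default_sim, pipeline_result):
    truth = default_sim.truth
    counts_by_gene = truth.promoter_sites.to_dict(orient="index")
    labels = truth.og_labels
    brute = brute_force_og_means(counts_by_gene, labels)
    matrix = pipeline_result.tfbs_matrix
    for (og, tf), val in brute.items():
        assert matrix.loc[og, tf] == pytest.approx(val)


def test_planted_enrichment_is_matrix_maximum(default_sim, pipeline_result):
    """The OG with five extra planted AP2 sites tops its row and column."""
    m = pipeline_result.tfbs_matrix
    cell = m.loc["8b", "AP2"]
    assert cell == m["AP2"].max()
    assert cell == m.loc["8b"].max()


def test_unassigned_counted_gene_rejected():
    counts = pd.DataFrame({"TF1": [1]}, index=["mystery"]).rename_axis("gene_id")
    with pytest.raises(ValueError):
        og_tfbs_matrix(counts, {})


def test_pwm_file_round_trip(tmp_path, default_sim):
    write_pwms(default_sim.pwms, tmp_path / "p.txt")
    back = read_pwms(tmp_path / "p.txt")
    assert [(p.name, p.tf_family) for p in back] == [
        (p.name, p.tf_family) for p in default_sim.pwms
    ]
    for a, b in zip(back, default_sim.pwms):
        assert np.allclose(a.matrix, b.matrix, atol=1e-6)


def test_pwm_rows_must_sum_to_one():
    with pytest.raises(ValueError):
        NucPWM("bad", "TF", np.full((4, 4), 0.3))
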