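"""Neighbor-joining, bootstrap support and iterative refinement."""

import numpy as np
import pytest
import skbio

from famforge.config import PipelineConfig
from famforge.msa_clean import MultipleAlignment, CleanedAlignment, CleanParams
from famforge.phylo import (
    bipartitions,
    bootstrap_support,
    iterative_refine,
    nj_tree,
    p_distance_matrix,
)
from famforge.synthetic_data import make_divergent_family


def random_additive_case(rng, n=6):
    """Random binary tree with positive branch lengths and its distances."""
    nodes = [skbio.TreeNode(name=f"L{i}") for i in range(n)]
    for node in nodes:
        node.length = float(rng.uniform(0.5, 2.0))
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = skbio.TreeNode()
        parent.length = float(rng.uniform(0.5, 2.0))
        b = nodes.pop(j)
        a = nodes.pop(i)
        parent.extend([a, b])
        nodes.append(parent)
    root = skbio.TreeNode()
    nodes[0].length = nodes[0].length or 1.0
    root.extend(nodes)
    tips = list(root.tips())
    ids = [t.name for t in tips]
    D = np.zeros((len(ids), len(ids)))
    for x in range(len(ids)):
        for y in range(x + 1, len(ids)):
            D[x, y] = D[y, x] = tips[x].distance(tips[y])
    return root, D, ids


def test_three_taxon_closed_form():
    d = np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], dtype=float)
    tree = nj_tree(d, ["A", "B", "C"])
    lengths = {t.name: t.length for t in tree.tips()}
    assert abs(lengths["A"] - 1) < 1e-9
    assert abs(lengths["B"] - 1) < 1e-9
    assert abs(lengths["C"] - 3) < 1e-9


def test_four_taxon_additive_recovery():
    # distances generated from ((A:1,B:2):1,(C:3,D:1))
    ids = ["A", "B", "C", "D"]
    d = np.array(
        [[0, 3, 5, 3], [3, 0, 6, 4], [5, 6, 0, 4], [3, 4, 4, 0]], dtype=float
    )
    tree = nj_tree(d, ids)
    assert frozenset({"A", "B"}) in bipartitions(tree)
    for x in ids:
        for y in ids:
            if x < y:
                expect = d[ids.index(x), ids.index(y)]
                assert abs(tree.find(x).distance(tree.find(y)) - expect) < 1e-9


def test_zero_distance_pair_are_siblings():
    ids = list("ABCDE")
    rng = np.random.default_rng(0)
    d = rng.uniform(2, 4, size=(5, 5))
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0)
    d[0, 1] = d[1, 0] = 0.0
    tree = nj_tree(d, ids)
    assert frozenset({"A", "B"}) in bipartitions(tree)


def test_topology_recovery_on_random_additive_matrices():
    rng = np.random.default_rng(42)
    hits = 0
    for _ in range(50):
        true_tree, D, ids = random_additive_case(rng)
        est = nj_tree(D, ids)
        if set(bipartitions(est)) == set(bipartitions(true_tree)):
            hits += 1
    assert hits == 50


def test_nj_agrees_with_independent_implementation():
    """Cross-check against scikit-bio's neighbor joining on additive input."""
    rng = np.random.default_rng(7)
    for _ in range(10):
        _, D, ids = random_additive_case(rng)
        ours = nj_tree(D, ids)
        theirs = skbio.tree.nj(skbio.DistanceMatrix(D, ids))
        assert set(bipartitions(ours)) == set(bipartitions(theirs))


def test_asymmetric_matrix_rejected():
    d = np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0]], dtype=float)
    with pytest.raises(ValueError):
        nj_tree(d, list("ABC"))


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def _two_group_alignment():
    rows = {}
    g1 = "MKVTLHEWAQ" * 5 + "RNDGFYIPSC" * 5
    g2 = "MKVTLHEWAQ" * 5 + "WWHHYYPPCC" * 5
    for i in range(4):
        rows[f"x{i}"] = g1
        rows[f"y{i}"] = g2
    aln = MultipleAlignment(rows)
    return CleanedAlignment(aln, list(range(100)), CleanParams())


def test_clean_between_group_split_gets_full_support():
    tree = bootstrap_support(_two_group_alignment(), n_reps=50, seed=3)
    parts = bipartitions(tree)
    key = frozenset({"x0", "x1", "x2", "x3"})
    key2 = frozenset({"y0", "y1", "y2", "y3"})
    found = parts.get(key) or parts.get(key2)
    assert found is not None and found.support == 1.0


def test_single_replicate_gives_binary_supports():
    tree = bootstrap_support(_two_group_alignment(), n_reps=1, seed=0)
    for node in tree.non_tips(include_self=False):
        sup = getattr(node, "support", None)
        if sup is not None:
            assert sup in (0.0, 1.0)


def test_bootstrap_deterministic_for_fixed_seed():
    t1 = bootstrap_support(_two_group_alignment(), n_reps=25, seed=11)
    t2 = bootstrap_support(_two_group_alignment(), n_reps=25, seed=11)
    s1 = {frozenset(x.name for x in n.tips()): getattr(n, "support", None) for n in t1.non_tips()}
    s2 = {frozenset(x.name for x in n.tips()): getattr(n, "support", None) for n in t2.non_tips()}
    assert s1 == s2


def test_supports_in_unit_interval_and_no_trivial_split(default_sim):
    from famforge.msa_clean import clean_blocks, progressive_msa

    prots = {g.gene_id: g.protein for g in default_sim.annotation.genes[:10]}
    cleaned = clean_blocks(progressive_msa(prots))
    tree = bootstrap_support(cleaned, n_reps=20, seed=1)
    all_leaves = frozenset(prots)
    for key, node in bipartitions(tree).items():
        assert key != all_leaves
        sup = getattr(node, "support", None)
        if sup is not None:
            assert 0.0 <= sup <= 1.0


# ---------------------------------------------------------------------------
# iterative refinement
# ---------------------------------------------------------------------------

def test_homogeneous_family_single_round():
    rng = np.random.default_rng(5)
    from famforge.synthetic_data import mutate_protein, _random_protein

    core = _random_protein(rng, 120)
    seqs = {f"s{i}": mutate_protein(core, 0.08, rng) for i in range(10)}
    rounds = iterative_refine(seqs, PipelineConfig(bootstrap_reps=25))
    assert len(rounds) == 1
    assert rounds[0].split_clusters == []


def test_divergent_subfamily_split_and_retained_gain():
    seqs, divergent = make_divergent_family(seed=2)
    cfg = PipelineConfig(bootstrap_reps=50, rng_seed=2)
    rounds = iterative_refine(seqs, cfg)
    assert any(set(s) == divergent for s in rounds[0].split_clusters)
    sub = [r for r in rounds if set(r.member_ids) == divergent]
    assert sub and sub[0].retained_positions > rounds[0].retained_positions


def test_infinite_stem_threshold_disables_splitting():
    seqs, _ = make_divergent_family(seed=3)
    cfg = PipelineConfig(refine_min_stem=float("inf"), bootstrap_reps=10)
    rounds = iterative_refine(seqs, cfg)
    assert len(rounds) == 1


def test_refinement_round_count_bounded():
    seqs, _ = make_divergent_family(seed=4)
    rounds = iterative_refine(seqs, PipelineConfig(bootstrap_reps=10))
    assert len(rounds) <= len(seqs)
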