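"""Distance trees, bootstrap support, and iterative divergent-cluster refinement.

Trees are built by canonical neighbor-joining on p-distances computed over
the retained columns of a cleaned alignment; internal-edge support is the
bootstrap fraction of column resamples that reproduce the bipartition.  The
refinement loop re-aligns sharply divergent clusters separately: reduced
divergence improves the alignment, which increases the number of retained
positions available for the next tree.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from skbio import TreeNode

from .config import PipelineConfig
from .msa_clean import GAP, CleanParams, CleanedAlignment, clean_blocks, progressive_msa
from .pairwise_align import ScoringScheme

logger = logging.getLogger("famforge")


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def nj_tree(d: np.ndarray, ids: list[str]) -> TreeNode:
    """Canonical neighbor-joining on a symmetric distance matrix.

    Negative branch-length estimates are clamped to zero and the deficit is
    moved to the sibling branch, preserving the pair's summed length.
    """
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    if d.shape != (n, n) or n != len(ids):
        raise ValueError("distance matrix shape does not match ids")
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0.0):
        raise ValueError("distance matrix diagonal must be zero")
    if n < 3:
        raise ValueError("need at least 3 taxa")

    nodes: list[TreeNode] = [TreeNode(name=i) for i in ids]
    D = d.copy()
    active = list(range(n))
    while len(active) > 2:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        i_loc, j_loc = divmod(int(np.argmin(Q)), m)
        if i_loc > j_loc:
            i_loc, j_loc = j_loc, i_loc
        dij = sub[i_loc, j_loc]
        li = 0.5 * dij + (r[i_loc] - r[j_loc]) / (2 * (m - 2))
        lj = dij - li
        if li < 0:
            lj, li = dij, 0.0
        if lj < 0:
            li, lj = dij, 0.0
        gi, gj = active[i_loc], active[j_loc]
        parent = TreeNode()
        child_i, child_j = nodes[gi], nodes[gj]
        child_i.length = float(li)
        child_j.length = float(lj)
        parent.extend([child_i, child_j])
        new_row = 0.5 * (D[gi, :] + D[gj, :] - dij)
        D = np.vstack([D, new_row])
        new_col = np.append(new_row, 0.0)
        D = np.column_stack([D, new_col])
        nodes.append(parent)
        active = [a for a in active if a not in (gi, gj)] + [len(nodes) - 1]
    gi, gj = active
    a, b = nodes[gi], nodes[gj]
    if a.is_tip():  # root at an internal node (unrooted representation)
        a, b = b, a
    b.length = max(float(D[gi, gj]), 0.0)
    a.append(b)
    return a


# ---------------------------------------------------------------------------
# p-distance
# ---------------------------------------------------------------------------

def p_distance_matrix(mat: np.ndarray) -> np.ndarray:
    """Normalized p-distance over an integer alignment matrix.

    Columns where either sequence has a gap are ignored for that pair; a
    pair with no comparable columns gets distance 1.
    """
    n = mat.shape[0]
    D = np.zeros((n, n))
    nongap = mat != GAP
    for i in range(n):
        for j in range(i + 1, n):
            ok = nongap[i] & nongap[j]
            total = int(ok.sum())
            if total == 0:
                D[i, j] = D[j, i] = 1.0
            else:
                diff = int((mat[i, ok] != mat[j, ok]).sum())
                D[i, j] = D[j, i] = diff / total
    return D


# ---------------------------------------------------------------------------
# bootstrap support
# ---------------------------------------------------------------------------

def bipartitions(tree: TreeNode) -> dict[frozenset, TreeNode]:
    """Non-trivial bipartitions of an (effectively unrooted) tree.

    Each internal edge is keyed by the smaller leaf-id side (ties broken by
    sorted order) so that rootings do not change the key.
    """
    all_leaves = frozenset(t.name for t in tree.tips())
    out: dict[frozenset, TreeNode] = {}
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        other = all_leaves - side
        if len(side) < 2 or len(other) < 2:
            continue
        key = min(side, other, key=lambda s: (len(s), tuple(sorted(s))))
        out[key] = node
    return out


def bootstrap_support(
    cleaned: CleanedAlignment, n_reps: int = 100, seed: int = 0
) -> TreeNode:
    """NJ tree on retained columns with bootstrap supports on internal edges."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    ids = list(cleaned.source.rows)
    mat = cleaned.matrix()
    if mat.shape[1] == 0:
        raise ValueError("no retained columns")
    tree = nj_tree(p_distance_matrix(mat), ids)
    if len(ids) < 4:
        return tree
    target = bipartitions(tree)
    counts = {key: 0 for key in target}
    rng = np.random.default_rng(seed)
    ncol = mat.shape[1]
    for _ in range(n_reps):
        cols = rng.integers(0, ncol, size=ncol)
        rep_tree = nj_tree(p_distance_matrix(mat[:, cols]), ids)
        rep_parts = set(bipartitions(rep_tree))
        for key in counts:
            if key in rep_parts:
                counts[key] += 1
    for key, node in target.items():
        node.support = counts[key] / n_reps
    return tree


# ---------------------------------------------------------------------------
# iterative refinement
# ---------------------------------------------------------------------------

@dataclass
class RefinementRound:
    index: int
    member_ids: list[str]
    retained_positions: int
    tree: TreeNode | None
    split_clusters: list[set[str]] = field(default_factory=list)


def median_internal_branch(tree: TreeNode) -> float:
    lengths = [
        node.length
        for node in tree.non_tips(include_self=False)
        if node.length is not None
    ]
    return float(np.median(lengths)) if lengths else 0.0


def find_divergent_clusters(tree: TreeNode, cfg: PipelineConfig) -> list[set[str]]:
    """Clades hanging off long, well-supported stems.

    A clade qualifies when its stem branch is at least ``refine_min_stem``
    times the median internal branch length, its support reaches
    ``refine_min_support`` and it has at least ``refine_min_size`` members
    (leaving at least as many behind).  Overlapping candidates are resolved
    by keeping the larger (outermost) clade.
    """
    n = len(list(tree.tips()))
    med = median_internal_branch(tree)
    if med <= 0:
        return []
    candidates = []
    for node in tree.non_tips(include_self=False):
        if node.length is None:
            continue
        support = getattr(node, "support", None)
        leaves = {t.name for t in node.tips()}
        if (
            node.length >= cfg.refine_min_stem * med
            and support is not None
            and support >= cfg.refine_min_support
            and cfg.refine_min_size <= len(leaves) <= n - cfg.refine_min_size
        ):
            candidates.append(leaves)
    candidates.sort(key=len, reverse=True)
    chosen: list[set[str]] = []
    for cand in candidates:
        if all(cand.isdisjoint(c) for c in chosen):
            chosen.append(cand)
    return chosen


def align_clean_tree(
    seqs: dict[str, str],
    cfg: PipelineConfig,
    scheme: ScoringScheme,
    clean_params: CleanParams | None = None,
    seed: int = 0,
) -> tuple[CleanedAlignment, TreeNode | None]:
    aln = progressive_msa(seqs, scheme)
    cleaned = clean_blocks(aln, clean_params)
    if cleaned.n_retained == 0 or len(seqs) < 3:
        return cleaned, None
    tree = bootstrap_support(cleaned, cfg.bootstrap_reps, seed)
    return cleaned, tree


def iterative_refine(
    seqs: dict[str, str],
    cfg: PipelineConfig = PipelineConfig(),
    scheme: ScoringScheme = ScoringScheme(),
    clean_params: CleanParams | None = None,
    min_set_size: int = 8,
) -> list[RefinementRound]:
    """Align-clean-tree rounds with divergent-cluster splitting.

    Round 0 analyses the full set; any qualifying divergent cluster and the
    remainder re-enter as separate rounds.  Sets smaller than
    ``min_set_size`` are not re-analysed, so the loop always terminates.
    """
    if len(seqs) < min_set_size:
        raise ValueError(f"need at least {min_set_size} sequences")
    rounds: list[RefinementRound] = []
    queue: list[set[str]] = [set(seqs)]
    idx = 0
    while queue:
        members = queue.pop(0)
        subset = {k: seqs[k] for k in sorted(members)}
        cleaned, tree = align_clean_tree(
            subset, cfg, scheme, clean_params, seed=cfg.rng_seed + idx
        )
        splits = find_divergent_clusters(tree, cfg) if tree is not None else []
        rounds.append(
            RefinementRound(
                index=idx,
                member_ids=sorted(members),
                retained_positions=cleaned.n_retained,
                tree=tree,
                split_clusters=splits,
            )
        )
        if splits:
            remainder = members - set().union(*splits)
            for part in [*splits, remainder]:
                if len(part) >= min_set_size:
                    queue.append(set(part))
                else:
                    logger.info("refinement: set of %d members not re-analysed", len(part))
        idx += 1
        if idx > len(seqs):  # safety net; splitting strictly shrinks sets
            break
    return rounds


def nearest_assigned_cluster(tree: TreeNode, labels: dict[str, str]) -> dict[str, str]:
    """Annotate unlabeled leaves with the label of their nearest labeled leaf.

    This is annotation only (a ``nearest_cluster`` note), never a hard
    assignment: divergent genes stay unassigned.
    """
    tip_map = {t.name: t for t in tree.tips()}
    labeled = {name: lab for name, lab in labels.items() if name in tip_map}
    notes: dict[str, str] = {}
    for name, tip in tip_map.items():
        if name in labeled:
            continue
        best, best_d = "", np.inf
        for other, lab in labeled.items():
            dist = tip.distance(tip_map[other])
            if dist < best_d or (dist == best_d and lab < best):
                best, best_d = lab, dist
        if best:
            notes[name] = best
    return notes


def rounds_summary(rounds: list[RefinementRound]):
    import pandas as pd

    return pd.DataFrame(
        {
            "round": [r.index for r in rounds],
            "n_seqs": [len(r.member_ids) for r in rounds],
            "retained_positions": [r.retained_positions for r in rounds],
            "n_splits": [len(r.split_clusters) for r in rounds],
        }
    )
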