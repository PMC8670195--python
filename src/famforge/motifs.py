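"""EM discovery of ungapped protein motifs and motif-architecture typing.

The discovery model is ZOOPS (zero or one occurrence per sequence): each
sequence contributes at most one motif site, sites are described by a
position-probability matrix over the 20 amino acids, and everything else is
background.  Models are fitted by expectation-maximisation with seeded
restarts over a width grid; after each motif is accepted its occurrences
are masked and the search repeats, MEME-style, until the requested number
of motifs is reached.

Per-protein motif presence is then typed into the family's four motif
architectures: A (motifs 1-8), B (like A but without motif 4), C (carries
the distinctive motif 9), and D (carries the C-terminal motif 10);
precedence is D > C > B > A.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger("famforge")

AA = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AA)}

PSEUDOCOUNT = 0.1
EM_TOL = 1e-5
EM_MAX_ITER = 200
N_RESTARTS = 8
WIDTH_GRID = (6, 9, 12, 15, 20, 29, 50)
#: per-column free parameters of a 20-letter PPM; the model-selection
#: penalty across the width grid is AIC-style: LLR - AIC_ALPHA * width
AIC_ALPHA = 19.0
PRESENCE_THRESHOLD = 0.5

#: subdomain anchor consensi (Z={Q,E}, B={N,D} are treated as 2-letter classes)
ANCHOR_PATTERNS = {
    5: ("C", re.compile(r"GYWK[AT]TG.D.{1,2}[IV]")),
    6: ("D", re.compile(r"G.KK.LVFY")),
    7: ("D", re.compile(r"T.W.MHEY")),
}


@dataclass
class MotifModel:
    index: int
    width: int
    pwm: np.ndarray  # width x 20 probabilities
    background: np.ndarray
    occurrences: list[tuple[str, int]] = field(default_factory=list)
    llr: float = 0.0

    def __post_init__(self) -> None:
        if not np.allclose(self.pwm.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("pwm rows must sum to 1")

    @property
    def consensus(self) -> str:
        return "".join(AA[i] for i in self.pwm.argmax(axis=1))

    @property
    def information_content(self) -> float:
        """Mean information content per column in bits."""
        p = np.clip(self.pwm, 1e-12, 1.0)
        b = np.clip(self.background, 1e-12, 1.0)
        return float((p * np.log2(p / b)).sum(axis=1).mean())


@dataclass
class MotifArchitecture:
    protein_id: str
    present_motifs: tuple[int, ...]
    structure: str


@dataclass
class SubdomainMap:
    mapping: dict[int, str]  # motif index -> subdomain (A-E or TRR)
    consensus: dict[int, str]

    def __post_init__(self) -> None:
        if set(self.mapping) != set(range(1, 11)):
            raise ValueError("subdomain map must cover motif indices 1-10")


# ---------------------------------------------------------------------------
# ZOOPS EM
# ---------------------------------------------------------------------------

def _encode(seq: str) -> np.ndarray:
    return np.array([AA_INDEX.get(c, -1) for c in seq.upper()], dtype=np.int64)


def _windows(enc: np.ndarray, w: int) -> np.ndarray:
    """All valid (X-free) windows of width w as an (m, w) index matrix."""
    if len(enc) < w:
        return np.empty((0, w), dtype=np.int64)
    win = np.lib.stride_tricks.sliding_window_view(enc, w)
    return win[(win >= 0).all(axis=1)]


class ZoopsResult:
    def __init__(self, pwm, gamma, objective, trace, posteriors):
        self.pwm = pwm
        self.gamma = gamma
        self.objective = objective
        self.trace = trace  # per-iteration objective values (non-decreasing)
        self.posteriors = posteriors  # per sequence: (best offset, posterior mass)


def zoops_em(
    window_sets: list[np.ndarray],
    w: int,
    background: np.ndarray,
    init_pwm: np.ndarray,
    max_iter: int = EM_MAX_ITER,
    tol: float = EM_TOL,
) -> ZoopsResult:
    """Fit one ZOOPS motif model by EM.

    The tracked objective is the MAP objective (data log-likelihood ratio to
    background plus the Dirichlet pseudocount prior on the PPM), which EM
    increases monotonically.
    """
    pwm = init_pwm.copy()
    gamma = 0.5
    log_bg = np.log(background)
    trace: list[float] = []
    prev = -np.inf
    for _ in range(max_iter):
        log_pwm = np.log(np.clip(pwm, 1e-300, 1.0))
        post_list = []
        obj = 0.0
        for win in window_sets:
            m = len(win)
            if m == 0:
                post_list.append(np.zeros(0))
                obj += np.log(max(1.0 - gamma, 1e-300))
                continue
            # log-likelihood ratio of each window under motif vs background
            llr = (
                np.take_along_axis(log_pwm[None, :, :], win[:, :, None], axis=2)
                .squeeze(-1)
                .sum(axis=1)
                - log_bg[win].sum(axis=1)
            )
            site_lik = gamma / m * np.exp(llr)
            denom = (1.0 - gamma) + site_lik.sum()
            post_list.append(site_lik / denom)
            obj += np.log(max(denom, 1e-300))
        obj += PSEUDOCOUNT * np.log(np.clip(pwm, 1e-300, 1.0)).sum()
        trace.append(obj)
        # M-step
        counts = np.full((w, 20), PSEUDOCOUNT)
        total_post = 0.0
        n_seq = len(window_sets)
        for win, post in zip(window_sets, post_list):
            if len(win) == 0:
                continue
            for k in range(w):
                np.add.at(counts[k], win[:, k], post)
            total_post += post.sum()
        pwm = counts / counts.sum(axis=1, keepdims=True)
        gamma = min(max(total_post / n_seq, 1e-6), 1.0 - 1e-6)
        if obj - prev < tol and len(trace) > 1:
            break
        prev = obj
    posteriors = [
        (int(p.argmax()), float(p.sum())) if len(p) else (-1, 0.0) for p in post_list
    ]
    return ZoopsResult(pwm, gamma, trace[-1], trace, posteriors)


def _seed_pwm(window: np.ndarray, w: int) -> np.ndarray:
    pwm = np.full((w, 20), 0.5 / 19)
    for k, a in enumerate(window):
        pwm[k, a] = 0.5
    return pwm


def _candidate_seeds(
    window_sets: list[np.ndarray], w: int, rng: np.random.Generator, n_eval: int = 200
) -> list[np.ndarray]:
    """Rank candidate seed windows by summed best-match counts.

    Every sequence votes with its best-matching window, so a window shared
    (approximately) by many sequences scores highest; the top candidates
    seed the EM restarts.
    """
    nonempty = [win for win in window_sets if len(win)]
    if not nonempty:
        return []
    all_windows = np.vstack(nonempty)
    idx = np.arange(len(all_windows))
    if len(idx) > n_eval:
        idx = rng.choice(len(all_windows), size=n_eval, replace=False)
    cands = all_windows[idx]
    scores = np.zeros(len(cands))
    for win in nonempty:
        # matches[c, j] = identity between candidate c and window j
        matches = (cands[:, None, :] == win[None, :, :]).sum(axis=2)
        scores += matches.max(axis=1)
    order = np.argsort(-scores, kind="stable")
    return [cands[i] for i in order[:N_RESTARTS]]


def discover_motifs(
    proteins: dict[str, str],
    n: int = 10,
    wmin: int = 6,
    wmax: int = 50,
    seed: int = 0,
    background: np.ndarray | None = None,
) -> list[MotifModel]:
    """Discover up to ``n`` ungapped motifs by iterated ZOOPS EM + masking.

    Width is selected on a grid between ``wmin`` and ``wmax`` by the
    AIC-penalised log-likelihood ratio.  Deterministic for a fixed seed.
    """
    if n == 0:
        return []
    if len(proteins) < 5:
        raise ValueError("need at least 5 proteins")
    shortest = min(len(s) for s in proteins.values())
    if wmin > shortest:
        raise ValueError("wmin exceeds shortest protein length")
    ids = sorted(proteins)
    seqs = {pid: _encode(proteins[pid]) for pid in ids}
    if background is None:
        concat = np.concatenate([seqs[pid] for pid in ids])
        concat = concat[concat >= 0]
        background = np.bincount(concat, minlength=20) + 1.0
        background = background / background.sum()
    widths = sorted({w for w in WIDTH_GRID if wmin <= w <= wmax} | {wmin})
    widths = [w for w in widths if w <= shortest]
    rng = np.random.default_rng(seed)
    masked = {pid: seqs[pid].copy() for pid in ids}
    models: list[MotifModel] = []
    for index in range(1, n + 1):
        best: tuple[float, ZoopsResult, int] | None = None
        for w in widths:
            window_sets = [_windows(masked[pid], w) for pid in ids]
            if all(len(win) == 0 for win in window_sets):
                continue
            for seed_win in _candidate_seeds(window_sets, w, rng):
                res = zoops_em(window_sets, w, background, _seed_pwm(seed_win, w))
                llr = _model_llr(res, window_sets, background)
                penalized = llr - AIC_ALPHA * w
                if best is None or penalized > best[0]:
                    best = (penalized, res, w)
        if best is None:
            break
        _, res, w = best
        occurrences = []
        for pid, (offset, post) in zip(ids, res.posteriors):
            if post >= PRESENCE_THRESHOLD and offset >= 0:
                # offset is an index into the X-free window list; map back
                enc = masked[pid]
                valid = np.nonzero(
                    (np.lib.stride_tricks.sliding_window_view(enc, w) >= 0).all(axis=1)
                )[0]
                occurrences.append((pid, int(valid[offset])))
        model = MotifModel(
            index=index,
            width=w,
            pwm=res.pwm,
            background=background,
            occurrences=occurrences,
            llr=_model_llr(res, [_windows(masked[pid], w) for pid in ids], background),
        )
        models.append(model)
        for pid, off in occurrences:  # mask found sites before the next round
            masked[pid][off : off + w] = -1
    return models


def _model_llr(res: ZoopsResult, window_sets, background) -> float:
    """Data log-likelihood ratio of the fitted model vs pure background."""
    log_pwm = np.log(np.clip(res.pwm, 1e-300, 1.0))
    log_bg = np.log(background)
    total = 0.0
    for win in window_sets:
        if len(win) == 0:
            continue
        llr = (
            np.take_along_axis(log_pwm[None, :, :], win[:, :, None], axis=2)
            .squeeze(-1)
            .sum(axis=1)
            - log_bg[win].sum(axis=1)
        )
        denom = (1.0 - res.gamma) + res.gamma / len(win) * np.exp(llr).sum()
        total += np.log(max(denom, 1e-300))
    return total


# ---------------------------------------------------------------------------
# architecture typing
# ---------------------------------------------------------------------------

STRUCTURE_A_SET = frozenset(range(1, 9))
STRUCTURE_B_SET = frozenset({1, 2, 3, 5, 6, 7, 8})


def classify_architecture(protein_id: str, present: set[int]) -> MotifArchitecture:
    """Type a protein's ordered motif content into structures A-D.

    Precedence D > C > B > A: motif 10 defines D, motif 9 defines C,
    the A set minus motif 4 defines B, and the full 1-8 set defines A.
    """
    if present and not all(1 <= m <= 10 for m in present):
        raise ValueError("motif indices must be in 1..10")
    if 10 in present:
        structure = "D"
    elif 9 in present:
        structure = "C"
    elif STRUCTURE_B_SET <= present and 4 not in present:
        structure = "B"
    elif STRUCTURE_A_SET <= present:
        structure = "A"
    else:
        structure = "other"
    return MotifArchitecture(protein_id, tuple(sorted(present)), structure)


# ---------------------------------------------------------------------------
# subdomain mapping
# ---------------------------------------------------------------------------

def _expand_ambiguity(consensus: str) -> str:
    # Z means Q or E, B means N or D in the family's motif logos
    return consensus  # argmax consensi never contain Z/B; patterns handle classes


def map_subdomains(models: list[MotifModel]) -> SubdomainMap:
    """Number discovered motifs 1-10 and map them onto subdomains A-E/TRR.

    Models matching the family's published anchor consensi become motifs
    5 (subdomain C), 6 and 7 (subdomain D); the remaining models are
    numbered by mean occurrence offset and mapped 1->A, 2->B, 3,4->C, 8->E,
    9->C-like, 10->TRR.
    """
    if len(models) != 10:
        raise ValueError("subdomain mapping expects exactly 10 motif models")
    assigned: dict[int, MotifModel] = {}
    remaining = list(models)
    for target, (_, pattern) in ANCHOR_PATTERNS.items():
        matches = [m for m in remaining if pattern.search(m.consensus)]
        if not matches:
            continue
        if len(matches) > 1:
            logger.warning(
                "motif anchor for index %d matched %d models; keeping highest IC",
                target,
                len(matches),
            )
            matches.sort(key=lambda m: -m.information_content)
        assigned[target] = matches[0]
        remaining.remove(matches[0])
    free_indices = [i for i in range(1, 11) if i not in assigned]

    def mean_offset(m: MotifModel) -> float:
        return float(np.mean([o for _, o in m.occurrences])) if m.occurrences else 1e9

    remaining.sort(key=mean_offset)
    for idx, model in zip(free_indices, remaining):
        assigned[idx] = model
    subdomain_of = {1: "A", 2: "B", 3: "C", 4: "C", 5: "C", 6: "D", 7: "D", 8: "E", 9: "C", 10: "TRR"}
    return SubdomainMap(
        mapping={i: subdomain_of[i] for i in range(1, 11)},
        consensus={i: assigned[i].consensus if i in assigned else "" for i in range(1, 11)},
    )


# ---------------------------------------------------------------------------
# minimal MEME-text-like I/O
# ---------------------------------------------------------------------------

def write_motifs(models: list[MotifModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("MEME-like motif file\n\nALPHABET= " + AA + "\n\n")
        for m in models:
            fh.write(f"MOTIF motif_{m.index} {m.consensus}\n")
            fh.write(
                f"letter-probability matrix: alength= 20 w= {m.width} nsites= {len(m.occurrences)}\n"
            )
            for row in m.pwm:
                fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")
            fh.write("\n")


def occurrences_table(models: list[MotifModel]):
    import pandas as pd

    rows = [
        {"motif": m.index, "protein_id": pid, "offset": off, "width": m.width}
        for m in models
        for pid, off in m.occurrences
    ]
    return pd.DataFrame(rows, columns=["motif", "protein_id", "offset", "width"])
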