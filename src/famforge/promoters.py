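"""Promoter extraction, PWM scanning, and per-OG TFBS frequency matrices.

Promoters are the fixed-length window immediately 5' of the CDS start on
the coding strand.  Scanning is log-odds against a uniform background on
both strands, with a hit threshold expressed as a fraction of the maximum
attainable score (per-matrix cut-offs of the source databases are not
published, so a relative threshold keeps the scan reproducible).  Hit
counts from multiple matrices of the same TF family are summed per family
before averaging within orthogroups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core_io import GeneModel, revcomp
from .og_classify import UNASSIGNED, OGAssignment

logger = logging.getLogger("famforge")

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}


@dataclass
class NucPWM:
    name: str
    tf_family: str
    matrix: np.ndarray  # width x 4 probabilities
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self) -> None:
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError(f"{self.name}: pwm rows must sum to 1")

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    def log_odds(self) -> np.ndarray:
        """width x 5 log2-odds table; the 5th column scores N as background."""
        lo = np.log2(np.clip(self.matrix, 1e-9, 1.0) / self.background)
        return np.hstack([lo, np.zeros((self.width, 1))])

    @property
    def max_score(self) -> float:
        return float(self.log_odds()[:, :4].max(axis=1).sum())

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.matrix.argmax(axis=1))


def extract_promoter(gene: GeneModel, genome: dict[str, str], length: int = 2000) -> str:
    """The ``length`` bp immediately upstream of the CDS start, coding strand.

    Truncated (with a warning) where the chromosome ends.
    """
    if not gene.cds:
        raise ValueError(f"{gene.gene_id}: gene has no CDS")
    chrom = genome[gene.chromosome]
    if gene.strand == "+":
        start = gene.start - length
        if start < 0:
            logger.warning("%s: promoter truncated at chromosome start", gene.gene_id)
            start = 0
        return chrom[start : gene.start]
    end = gene.end + length
    if end > len(chrom):
        logger.warning("%s: promoter truncated at chromosome end", gene.gene_id)
        end = len(chrom)
    return revcomp(chrom[gene.end : end])


def _encode_dna(seq: str) -> np.ndarray:
    return np.array([BASE_INDEX.get(c, 4) for c in seq.upper()], dtype=np.int64)


def _hit_offsets(enc: np.ndarray, lo: np.ndarray, threshold: float) -> np.ndarray:
    w = lo.shape[0]
    if len(enc) < w:
        return np.empty(0, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(enc, w)
    scores = np.take_along_axis(lo.T[None, :, :], windows[:, None, :], axis=1)
    scores = lo[np.arange(w)[None, :], windows].sum(axis=1)
    return np.nonzero(scores >= threshold)[0]


def scan_promoter(seq: str, pwm: NucPWM, threshold_frac: float = 0.8) -> int:
    """Count PWM hits on both strands of a promoter.

    A hit is a window whose log-odds score reaches ``threshold_frac`` times
    the maximum attainable score.  A window hit on both strands counts once,
    so a sequence and its reverse complement give identical counts.
    """
    w = pwm.width
    if len(seq) < w:
        return 0
    lo = pwm.log_odds()
    threshold = threshold_frac * pwm.max_score
    fwd = _hit_offsets(_encode_dna(seq), lo, threshold)
    rev = _hit_offsets(_encode_dna(revcomp(seq)), lo, threshold)
    # map reverse-strand offsets to forward window starts
    rev_mapped = len(seq) - w - rev
    return len(set(fwd.tolist()) | set(rev_mapped.tolist()))


def scan_all(
    promoters: dict[str, str],
    pwms: list[NucPWM],
    threshold_frac: float = 0.8,
) -> pd.DataFrame:
    """Per-gene, per-TF-family hit counts (matrices of one family summed)."""
    families = sorted({p.tf_family for p in pwms})
    data = {
        fam: [
            sum(
                scan_promoter(promoters[g], p, threshold_frac)
                for p in pwms
                if p.tf_family == fam
            )
            for g in sorted(promoters)
        ]
        for fam in families
    }
    return pd.DataFrame(data, index=sorted(promoters)).rename_axis("gene_id")


def og_tfbs_matrix(
    counts: pd.DataFrame, assignments: list[OGAssignment] | dict[str, str]
) -> pd.DataFrame:
    """Mean per-gene TFBS counts for each orthogroup.

    Rows are OG labels with at least one counted gene; columns TF families.
    """
    if isinstance(assignments, list):
        label_of = {a.gene_id: a.og_label for a in assignments}
    else:
        label_of = dict(assignments)
    genes = [g for g in counts.index if label_of.get(g, UNASSIGNED) != UNASSIGNED]
    missing = set(counts.index) - set(label_of)
    if missing:
        raise ValueError(f"counted genes without assignment: {sorted(missing)[:5]}")
    sub = counts.loc[genes]
    ogs = pd.Series({g: label_of[g] for g in genes}, name="og_label")
    matrix = sub.groupby(ogs).mean()
    return matrix.rename_axis("og_label")


# ---------------------------------------------------------------------------
# minimal MEME-text-like nucleotide PWM format with a tf_family keyword
# ---------------------------------------------------------------------------

def write_pwms(pwms: list[NucPWM], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("MEME-like nucleotide motif file\n\nALPHABET= ACGT\n\n")
        for p in pwms:
            fh.write(f"MOTIF {p.name} tf_family= {p.tf_family}\n")
            fh.write(f"letter-probability matrix: alength= 4 w= {p.width}\n")
            for row in p.matrix:
                fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")
            fh.write("\n")


def read_pwms(path: str | Path) -> list[NucPWM]:
    pwms: list[NucPWM] = []
    name = family = None
    rows: list[list[float]] = []
    expect = 0
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line.startswith("MOTIF"):
            parts = line.split()
            name = parts[1]
            family = parts[parts.index("tf_family=") + 1] if "tf_family=" in parts else name
        elif line.startswith("letter-probability matrix"):
            expect = int(line.split("w=")[1].split()[0])
            rows = []
        elif expect and line:
            rows.append([float(v) for v in line.split()])
            if len(rows) == expect:
                pwms.append(NucPWM(name, family, np.array(rows)))
                expect = 0
    return pwms
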