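"""Differential-expression candidate calls across the four line/stage contrasts.

The expression design compares an early-senescence and a delayed-senescence
line at anthesis and post-anthesis: each gene carries a log2 ratio and a
p-value for four contrasts.  A gene is up (down) in a contrast when its
log2 ratio is at least the threshold above (below) zero and the p-value is
under the cut-off; senescence-associated means differentially expressed in
at least one contrast, and genotype-contrasting means up in one line's
post-anthesis/anthesis contrast and down in the other's.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .config import PipelineConfig

logger = logging.getLogger("famforge")

COMPARISONS = ("R453_PA_vs_A", "B481_PA_vs_A", "R453_vs_B481_A", "R453_vs_B481_PA")
PA_CONTRASTS = ("R453_PA_vs_A", "B481_PA_vs_A")


@dataclass
class DERecord:
    gene_id: str
    comparison: str
    log2_ratio: float
    p_value: float

    def __post_init__(self) -> None:
        if self.comparison not in COMPARISONS:
            raise ValueError(f"unknown comparison {self.comparison}")
        if not (math.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value must be in [0, 1]")


@dataclass
class CandidateCall:
    gene_id: str
    status: dict[str, str]  # comparison -> up/down/ns
    senescence_associated: bool
    genotype_contrasting: bool


def call_status(rec: DERecord, cfg: PipelineConfig = PipelineConfig()) -> str:
    """up/down/ns for one record under the log2-ratio and p-value thresholds."""
    if math.isnan(rec.p_value):
        logger.warning("%s/%s: missing p-value treated as ns", rec.gene_id, rec.comparison)
        return "ns"
    if rec.p_value >= cfg.de_p_threshold:
        return "ns"
    if rec.log2_ratio >= cfg.de_lfc_threshold:
        return "up"
    if rec.log2_ratio <= -cfg.de_lfc_threshold:
        return "down"
    return "ns"


def categorize(
    records: list[DERecord], cfg: PipelineConfig = PipelineConfig()
) -> list[CandidateCall]:
    """Per-gene candidate calls from at most one record per (gene, comparison)."""
    seen: set[tuple[str, str]] = set()
    by_gene: dict[str, dict[str, str]] = {}
    for rec in records:
        key = (rec.gene_id, rec.comparison)
        if key in seen:
            raise ValueError(f"duplicate record for {key}")
        seen.add(key)
        by_gene.setdefault(rec.gene_id, {})[rec.comparison] = call_status(rec, cfg)
    calls = []
    for gene_id in sorted(by_gene):
        status = {c: by_gene[gene_id].get(c, "ns") for c in COMPARISONS}
        pa = {status[c] for c in PA_CONTRASTS}
        calls.append(
            CandidateCall(
                gene_id=gene_id,
                status=status,
                senescence_associated=any(s != "ns" for s in status.values()),
                genotype_contrasting=pa == {"up", "down"},
            )
        )
    return calls


# ---------------------------------------------------------------------------
# table I/O
# ---------------------------------------------------------------------------

def read_de_table(path: str | Path) -> list[DERecord]:
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "comparison", "log2_ratio", "p_value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"DE table missing columns: {sorted(missing)}")
    return [
        DERecord(r.gene_id, r.comparison, float(r.log2_ratio), float(r.p_value))
        for r in df.itertuples()
    ]


def records_from_frame(df: pd.DataFrame) -> list[DERecord]:
    return [
        DERecord(r.gene_id, r.comparison, float(r.log2_ratio), float(r.p_value))
        for r in df.itertuples()
    ]


def calls_table(calls: list[CandidateCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        row = {"gene_id": c.gene_id}
        row.update(c.status)
        row["senescence_associated"] = c.senescence_associated
        row["genotype_contrasting"] = c.genotype_contrasting
        rows.append(row)
    return pd.DataFrame(rows)


def wide_matrix(records: list[DERecord], cfg: PipelineConfig = PipelineConfig()) -> pd.DataFrame:
    """Heatmap-ready genes x comparisons log2 table, masked at p >= cut-off."""
    rows: dict[str, dict[str, float]] = {}
    for rec in records:
        val = rec.log2_ratio if rec.p_value < cfg.de_p_threshold else float("nan")
        rows.setdefault(rec.gene_id, {})[rec.comparison] = val
    return pd.DataFrame.from_dict(rows, orient="index").reindex(
        columns=list(COMPARISONS)
    ).rename_axis("gene_id")
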