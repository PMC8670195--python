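"""Pipeline configuration.

All numeric knobs of the pipeline live in one dataclass so that every stage
(classification, duplication calling, motif discovery, promoter scanning,
expression filtering) reads its thresholds from a single validated place.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    """Tunable parameters of the family-analysis pipeline.

    Parameters
    ----------
    consensus_k
        Number of best-ranked database hits that must agree on one
        orthogroup label for a gene to be assigned (top-k consensus rule).
    tandem_max_gap
        Maximum start-to-start distance in bp between consecutive same-OG
        genes chained into a tandem array.
    promoter_len
        Length in bp of the promoter extracted upstream of the CDS start.
    motif_count
        Number of ungapped protein motifs discovered by the EM search.
    motif_wmin, motif_wmax
        Inclusive bounds of the motif width search grid.
    de_lfc_threshold, de_p_threshold
        |log2 ratio| and p-value cut-offs for differential-expression calls.
    refine_min_support
        Minimum bootstrap support for a cluster to be split off during
        iterative phylogenetic refinement.
    refine_min_stem
        Stem-branch-length multiplier: a cluster qualifies when its stem is
        at least this many times the median internal branch length.
    refine_min_size
        Minimum number of members of a split-off cluster.
    """

    consensus_k: int = 3
    tandem_max_gap: int = 100_000
    promoter_len: int = 2000
    motif_count: int = 10
    motif_wmin: int = 6
    motif_wmax: int = 200
    de_lfc_threshold: float = 1.5
    de_p_threshold: float = 0.05
    refine_min_support: float = 0.95
    refine_min_stem: float = 2.0
    refine_min_size: int = 3
    rng_seed: int = 0
    # alignment / mining
    gap_open: int = 11
    gap_extend: int = 1
    # chosen so chance translated hits stay below threshold on Mb-scale
    # genomes (Karlin-Altschul expectation well under 1 for BLOSUM62)
    min_locus_score: int = 70
    locus_merge_gap: int = 10_000
    # promoter scanning
    tfbs_threshold_frac: float = 0.8
    # tree support
    bootstrap_reps: int = 100

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        positive = (
            "consensus_k", "tandem_max_gap", "promoter_len", "motif_count",
            "motif_wmin", "motif_wmax", "de_lfc_threshold", "de_p_threshold",
            "refine_min_support", "refine_min_stem", "refine_min_size",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.consensus_k < 1:
            raise ValueError("consensus_k must be >= 1")
        if self.motif_wmin > self.motif_wmax:
            raise ValueError("motif_wmin must be <= motif_wmax")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.__dict__, sort_keys=True))
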