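"""Seeded generator of a toy genome with a fully known transcription-factor
family, so that every pipeline stage can be tested against planted truth.

The default scenario emulates the statistical structure the analysis
assumes: 8 orthogroups x 5 genes on 3 chromosomes, founder proteins built
from the family's motif blocks (subdomains A-E plus a variable C-terminal
region), members mutated to a target within-OG identity, canonical and
variant exon structures, two tandem arrays (plus a same-OG pair beyond the
tandem distance), two mirrored WGD block pairs, two pseudogene remnants
(one internal stop, one 1-bp frameshift), promoters with planted TFBS and
a differential-expression table with planted up/down/contrasting profiles.

Everything derives from one seeded RNG; regenerating with the same seed
yields byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core_io import GeneModel, GenomeAnnotation, revcomp, write_fasta, write_gff3
from .duplication import DuplicationBlock, write_blocks
from .expression import COMPARISONS
from .og_classify import RefEntry, ReferenceDB
from .promoters import NucPWM, write_pwms

AA = "ACDEFGHIKLMNPQRSTVWY"

#: most frequent plant codon per amino acid (used for back-translation)
FREQUENT_CODON = {
    "A": "GCT", "R": "AGA", "N": "AAT", "D": "GAT", "C": "TGT",
    "Q": "CAA", "E": "GAA", "G": "GGT", "H": "CAT", "I": "ATT",
    "L": "CTT", "K": "AAG", "M": "ATG", "F": "TTT", "P": "CCT",
    "S": "TCT", "T": "ACT", "W": "TGG", "Y": "TAT", "V": "GTT",
}
STOP_CODON = "TGA"

#: family motif blocks; motifs 1-8 build subdomains A-E, motif 9 is the
#: C-like motif of the divergent subfamily, motif 10 sits in the TRR
MOTIF_CONSENSI = {
    1: "SDEELVVHY",
    2: "GEREWYFFS",
    3: "PWDLPSKAK",
    4: "NGSRPNRAT",
    5: "GYWKATGRDLI",   # matches the G-Y-W-K-A/T-T-G-x-D-x(1,2)-I/V anchor
    6: "GEKKALVFY",     # matches the G-x-K-K-x-L-V-F-Y anchor
    7: "TRWIMHEYR",     # matches the T-x-W-x-M-H-E-Y anchor
    8: "LDDWVLCRI",
    9: "HQNKFPNQV",
    10: "QTPSSMMNF",
}

#: which motifs each subdomain is built from, in founder order
SUBDOMAIN_MOTIFS = {"A": (1,), "B": (2,), "C": (3, 4, 5), "D": (6, 7), "E": (8,)}

#: per-OG motif content (architecture plans A, B, C and D)
OG_MOTIF_PLAN = {
    "1a": (1, 2, 3, 4, 5, 6, 7, 8),
    "1h": (1, 2, 3, 4, 5, 6, 7, 8),
    "2a": (1, 2, 3, 4, 5, 6, 7, 8),
    "3c": (1, 2, 3, 4, 5, 6, 7, 8),
    "4b": (1, 2, 3, 4, 5, 6, 7, 8),
    "7e": (1, 2, 3, 5, 6, 7, 8),        # structure B: no motif 4
    "7a": (1, 2, 9, 6, 7, 8),           # structure C: carries motif 9
    "7f": (1, 2, 3, 4, 5, 6, 7, 8, 10), # structure D: carries motif 10
}

#: per-OG exon-structure plan
OG_EXON_PLAN = {
    "1a": "basic", "1h": "basic", "2a": "basic", "3c": "basic",
    "4b": "basic", "7e": "basic_plus_cterm", "7a": "extra_nterm", "7f": "basic",
}

#: promoter TFBS consensi (width 8, sharp matrices)
PWM_CONSENSI = {
    "AP2": "GCCGCCTC",
    "WRKY": "TTGACCAT",
    "MYB": "CAACCAGT",
    "NAC": "TACGTGTC",
    "Dof": "AAAGCGGT",
    "bZIP": "CACGTGGC",
}
PWM_SHARP = 0.97

#: extra planted sites per OG on top of one NAC + one WRKY site per gene
OG_SITE_PLAN = {
    "8b": {"AP2": 5},   # planted enrichment scenario
    "7e": {"Dof": 2},
    "3c": {"MYB": 1},
}


@dataclass
class Scenario:
    """Parameters of the simulated study conditions."""

    n_chromosomes: int = 3
    og_labels: tuple[str, ...] = ("1a", "1h", "2a", "3c", "4b", "7e", "7a", "8b")
    genes_per_og: int = 5
    within_og_identity: float = 0.85
    ref_identity: float = 0.95
    ref_relatives_per_og: int = 3
    promoter_len: int = 2000
    default_gap: int = 15_000
    tandem_gaps: tuple[int, ...] = (60_000, 90_000)
    non_tandem_gap: int = 120_000
    n_pseudogenes: int = 2
    n_de_genes: int = 12

    def __post_init__(self) -> None:
        if self.within_og_identity <= 0.4:
            raise ValueError("within-OG identity must exceed the between-OG ceiling")
        # the divergent-subfamily label 7f replaces 8b when present
        for og in self.og_labels:
            if og not in OG_MOTIF_PLAN and og not in ("8b",):
                raise ValueError(f"no motif plan for OG {og}")


# 8b shares the common architecture
OG_MOTIF_PLAN.setdefault("8b", (1, 2, 3, 4, 5, 6, 7, 8))
OG_EXON_PLAN.setdefault("8b", "basic")


@dataclass
class SimulationTruth:
    og_labels: dict[str, str]
    tandem_arrays: list[dict]
    wgd_pairs: list[tuple[str, str, str]]
    structure_labels: dict[str, str]
    subdomain_spans: dict[str, dict[str, tuple[int, int]]]
    pseudogenes: list[dict]
    motif_content: dict[str, tuple[int, ...]]
    promoter_sites: pd.DataFrame
    de_status: dict[str, dict[str, str]]


@dataclass
class SimulatedFamily:
    scenario: Scenario
    seed: int
    genome: dict[str, str]
    annotation: GenomeAnnotation
    refdb: ReferenceDB
    pwms: list[NucPWM]
    wgd_blocks: list[DuplicationBlock]
    de_table: pd.DataFrame
    truth: SimulationTruth


# ---------------------------------------------------------------------------
# protein construction
# ---------------------------------------------------------------------------

def _random_protein(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list(AA))[rng.integers(0, 20, n)])


def make_founder(og: str, rng: np.random.Generator) -> tuple[str, dict[str, tuple[int, int]]]:
    """Founder protein = motif blocks joined by random linkers + TRR tail.

    Returns the sequence and the protein spans of subdomains A-E.
    """
    plan = OG_MOTIF_PLAN[og]
    parts = ["M" + _random_protein(rng, 5)]
    pos = len(parts[0])
    spans: dict[str, tuple[int, int]] = {}
    for sub in "ABCDE":
        sub_start = None
        members = SUBDOMAIN_MOTIFS[sub]
        used = [m for m in members if m in plan]
        if sub == "C" and 9 in plan:
            used = [9]
        for m in used:
            linker = _random_protein(rng, int(rng.integers(4, 8)))
            parts.append(linker)
            pos += len(linker)
            if sub_start is None:
                sub_start = pos
            parts.append(MOTIF_CONSENSI[m])
            pos += len(MOTIF_CONSENSI[m])
        if sub_start is None:  # subdomain with no planted motif: linker stand-in
            linker = _random_protein(rng, 9)
            parts.append(linker)
            sub_start = pos
            pos += len(linker)
        spans[sub] = (sub_start, pos)
    tail = _random_protein(rng, int(rng.integers(35, 50)))
    parts.append(tail)
    pos += len(tail)
    if 10 in plan:
        parts.append(MOTIF_CONSENSI[10])
        parts.append(_random_protein(rng, 8))
    return "".join(parts), spans


def mutate_protein(protein: str, rate: float, rng: np.random.Generator) -> str:
    """Substitute residues at the given per-site rate (position 0 kept)."""
    out = list(protein)
    for i in range(1, len(out)):
        if rng.random() < rate:
            choices = AA.replace(out[i], "")
            out[i] = choices[rng.integers(0, 19)]
    return "".join(out)


def mutation_rate_for_identity(pairwise_identity: float) -> float:
    """Per-site substitution rate giving the target member-member identity."""
    return 1.0 - float(np.sqrt(pairwise_identity))


def backtranslate(protein: str) -> str:
    return "".join(FREQUENT_CODON[a] for a in protein)


# ---------------------------------------------------------------------------
# exon structure imposition
# ---------------------------------------------------------------------------

def exon_cds_lengths(
    plan: str, protein: str, spans: dict[str, tuple[int, int]]
) -> list[int]:
    """CDS lengths per exon implementing the canonical structure variants.

    The basic structure ends exon 1 one nucleotide after the first codon
    following subdomain B (intron phase 1) and exon 2 on the codon boundary
    before subdomain E (phase 0).
    """
    total = 3 * (len(protein) + 1)  # + stop codon
    b1 = 3 * spans["B"][1] + 1
    b2 = 3 * spans["E"][0]
    if plan == "basic":
        return [b1, b2 - b1, total - b2]
    if plan == "merged_1_2":
        return [b2, total - b2]
    if plan == "extra_nterm":
        lead = 12  # four codons
        return [lead, b1 - lead, b2 - b1, total - b2]
    if plan == "basic_plus_cterm":
        tail_start = 3 * (spans["E"][1] + 3)
        rest = total - tail_start
        cut = (rest // 2) // 3 * 3
        return [b1, b2 - b1, tail_start - b2, cut, rest - cut]
    raise ValueError(f"unknown exon plan {plan}")


def _gff_phases(lengths: list[int]) -> list[int]:
    phases, cum = [], 0
    for ln in lengths:
        phases.append((3 - cum % 3) % 3)
        cum += ln
    return phases


# ---------------------------------------------------------------------------
# promoters
# ---------------------------------------------------------------------------

def _sharp_pwm(consensus: str) -> np.ndarray:
    mat = np.full((len(consensus), 4), (1 - PWM_SHARP) / 3)
    for i, b in enumerate(consensus):
        mat[i, "ACGT".index(b)] = PWM_SHARP
    return mat


def make_pwms() -> list[NucPWM]:
    return [
        NucPWM(f"{fam}_1", fam, _sharp_pwm(cons)) for fam, cons in PWM_CONSENSI.items()
    ]


def _count_exact(seq: str, consensus: str) -> int:
    rc = revcomp(consensus)
    n = 0
    for i in range(len(seq) - len(consensus) + 1):
        window = seq[i : i + len(consensus)]
        if window == consensus or window == rc:
            n += 1
    return n


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def make_promoter(
    site_counts: dict[str, int], length: int, rng: np.random.Generator
) -> str:
    """Random promoter carrying exactly the planted number of TFBS per family.

    The background is scrubbed of chance consensus matches so planted
    counts are exact.
    """
    consensi = PWM_CONSENSI
    for _ in range(50):
        seq = list(_random_dna(rng, length))
        # scrub chance matches
        for _ in range(20):
            dirty = False
            s = "".join(seq)
            for cons in consensi.values():
                rc = revcomp(cons)
                for i in range(length - len(cons) + 1):
                    if s[i : i + len(cons)] in (cons, rc):
                        seq[i : i + len(cons)] = _random_dna(rng, len(cons))
                        dirty = True
                        break
                if dirty:
                    break
            if not dirty:
                break
        total_sites = sum(site_counts.values())
        if total_sites:
            w = max(len(c) for c in consensi.values())
            slots = np.sort(
                rng.choice(
                    np.arange(10, length - w - 10, 2 * w), size=total_sites, replace=False
                )
            )
            k = 0
            for fam in sorted(site_counts):
                for _ in range(site_counts[fam]):
                    cons = consensi[fam]
                    seq[slots[k] : slots[k] + len(cons)] = cons
                    k += 1
        out = "".join(seq)
        if all(
            _count_exact(out, consensi[fam]) == site_counts.get(fam, 0)
            for fam in consensi
        ):
            return out
    raise RuntimeError("could not build a clean promoter")


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

@dataclass
class _Placement:
    og: str
    member: int
    chrom: int
    forced_start_gap: int | None = None  # start-to-start distance to previous gene
    strand: str = "+"


def _placement_plan(sc: Scenario, rng: np.random.Generator) -> list[list[_Placement]]:
    """Per-chromosome ordered placements implementing the default layout."""
    ogs = sc.og_labels
    plan: list[list[_Placement]] = [[] for _ in range(sc.n_chromosomes)]
    used: set[tuple[str, int]] = set()

    def take(og: str, member: int, chrom: int, gap=None, strand="+"):
        used.add((og, member))
        plan[chrom].append(_Placement(og, member, chrom, gap, strand))

    # tandem arrays: a pair and a triple within the tandem distance
    take(ogs[0], 0, 0)
    take(ogs[0], 1, 0, gap=sc.tandem_gaps[0])
    take(ogs[2], 0, 1 % sc.n_chromosomes)
    take(ogs[2], 1, 1 % sc.n_chromosomes, gap=sc.tandem_gaps[1])
    take(ogs[2], 2, 1 % sc.n_chromosomes, gap=sc.tandem_gaps[1])
    # same-OG pair beyond the tandem distance (not an array)
    far_chrom = 2 % sc.n_chromosomes
    take(ogs[1], 0, far_chrom)
    take(ogs[1], 1, far_chrom, gap=sc.non_tandem_gap)
    # WGD pairs (different chromosomes; blocks drawn around them later)
    take(ogs[4], 0, 0)
    take(ogs[4], 1, far_chrom)
    take(ogs[5], 0, 1 % sc.n_chromosomes)
    take(ogs[5], 1, far_chrom)
    # remaining members round-robin, alternating strand
    chrom = 0
    flip = False
    for og in ogs:
        for member in range(sc.genes_per_og):
            if (og, member) in used:
                continue
            take(og, member, chrom, strand="-" if flip else "+")
            chrom = (chrom + 1) % sc.n_chromosomes
            flip = not flip
    return plan


def _build_gene(
    protein: str,
    og: str,
    member: int,
    spans: dict[str, tuple[int, int]],
    promoter: str,
    rng: np.random.Generator,
    exon_plan: str,
) -> tuple[str, list[tuple[int, int]], list[int], str]:
    """Return (plus-strand cassette, exon intervals within cassette on the
    plus orientation, phases in transcription order, cds)."""
    cds = backtranslate(protein) + STOP_CODON
    lengths = exon_cds_lengths(exon_plan, protein, spans)
    assert sum(lengths) == len(cds)
    introns = [_random_dna(rng, int(rng.integers(150, 400))) for _ in lengths[:-1]]
    body_parts: list[str] = []
    exon_ivs: list[tuple[int, int]] = []
    off = 0
    cds_off = 0
    for i, ln in enumerate(lengths):
        exon_ivs.append((off, off + ln))
        body_parts.append(cds[cds_off : cds_off + ln])
        off += ln
        cds_off += ln
        if i < len(introns):
            body_parts.append(introns[i])
            off += len(introns[i])
    cassette = promoter + "".join(body_parts)
    p = len(promoter)
    exon_ivs = [(s + p, e + p) for s, e in exon_ivs]
    return cassette, exon_ivs, _gff_phases(lengths), cds


def simulate_family(scenario: Scenario | None = None, seed: int = 17) -> SimulatedFamily:
    """Generate the toy genome, reference database, PWMs, DE table and truth."""
    sc = scenario or Scenario()
    rng = np.random.default_rng(seed)
    ogs = sc.og_labels

    # founders, members, reference database -------------------------------
    founders: dict[str, str] = {}
    spans_by_og: dict[str, dict[str, tuple[int, int]]] = {}
    for og in ogs:
        founders[og], spans_by_og[og] = make_founder(og, rng)
    member_rate = mutation_rate_for_identity(sc.within_og_identity)
    ref_rate = 1.0 - sc.ref_identity
    members: dict[tuple[str, int], str] = {
        (og, m): mutate_protein(founders[og], member_rate, rng)
        for og in ogs
        for m in range(sc.genes_per_og)
    }
    species = ("Vvi", "Ath", "Osa", "Mac")
    entries = []
    for og in ogs:
        entries.append(RefEntry(f"VvNAC-{og}", "Vvi", og, founders[og]))
        for r in range(sc.ref_relatives_per_og):
            sp = species[1 + r % 3]
            entries.append(
                RefEntry(
                    f"{sp}NAC-{og}-{r}", sp, og, mutate_protein(founders[og], ref_rate, rng)
                )
            )
    refdb = ReferenceDB(entries)

    # gene placement -------------------------------------------------------
    pwms = make_pwms()
    plan = _placement_plan(sc, rng)
    chrom_names = [f"chr{i + 1}" for i in range(sc.n_chromosomes)]
    placed: list[dict] = []
    merged_member = (ogs[3], sc.genes_per_og - 1)  # one first-two-exons-merged gene
    for ci, placements in enumerate(plan):
        cursor = int(rng.integers(3000, 6000))
        last_any_start: int | None = None
        last_og_start: dict[str, int] = {}
        for pl in placements:
            protein = members[(pl.og, pl.member)]
            exon_plan = (
                "merged_1_2" if (pl.og, pl.member) == merged_member else OG_EXON_PLAN[pl.og]
            )
            site_counts = {"NAC": 1, "WRKY": 1}
            for fam, extra in OG_SITE_PLAN.get(pl.og, {}).items():
                site_counts[fam] = site_counts.get(fam, 0) + extra
            promoter = make_promoter(site_counts, sc.promoter_len, rng)
            cassette, exon_ivs, phases, cds = _build_gene(
                protein, pl.og, pl.member, spans_by_og[pl.og], promoter, rng, exon_plan
            )
            gene_off = sc.promoter_len if pl.strand == "+" else 0
            if pl.forced_start_gap is not None and last_any_start is not None:
                gene_start = last_any_start + pl.forced_start_gap
            else:
                gene_start = cursor + sc.default_gap + gene_off
                prev = last_og_start.get(pl.og)
                if prev is not None and gene_start - prev <= 110_000:
                    gene_start = prev + 110_000
            cass_start = gene_start - gene_off
            if cass_start < cursor:
                raise RuntimeError("placement collision")
            placed.append(
                {
                    "og": pl.og,
                    "member": pl.member,
                    "chrom": ci,
                    "strand": pl.strand,
                    "cass_start": cass_start,
                    "cassette": cassette if pl.strand == "+" else revcomp(cassette),
                    "exon_ivs_plus": exon_ivs,
                    "cass_len": len(cassette),
                    "phases": phases,
                    "cds": cds,
                    "protein": protein,
                    "exon_plan": exon_plan,
                    "sites": site_counts,
                    "gene_start": gene_start,
                }
            )
            cursor = cass_start + len(cassette)
            last_any_start = gene_start
            last_og_start[pl.og] = gene_start

    # pseudogene remnants (intronless founder copies with a lesion) --------
    pseudo_specs = []
    lesions = ("internal_stop", "frameshift")
    for i in range(sc.n_pseudogenes):
        og = ogs[(3 + 4 * i) % len(ogs)]
        cds = backtranslate(founders[og]) + STOP_CODON
        lesion = lesions[i % 2]
        mid = (len(cds) // 2) // 3 * 3
        if lesion == "internal_stop":
            cds = cds[:mid] + "TAA" + cds[mid + 3 :]
        else:
            cds = cds[:mid] + cds[mid + 1 :]
        pseudo_specs.append({"og": og, "seq": cds, "flag": lesion, "chrom": i % sc.n_chromosomes})

    # assemble chromosomes -------------------------------------------------
    genome: dict[str, str] = {}
    pseudo_truth: list[dict] = []
    for ci, name in enumerate(chrom_names):
        parts: list[str] = []
        cursor = 0
        for rec in [p for p in placed if p["chrom"] == ci]:
            gap = rec["cass_start"] - cursor
            parts.append(_random_dna(rng, gap))
            parts.append(rec["cassette"])
            cursor = rec["cass_start"] + rec["cass_len"]
        for spec in [s for s in pseudo_specs if s["chrom"] == ci]:
            parts.append(_random_dna(rng, sc.default_gap))
            start = cursor + sc.default_gap
            parts.append(spec["seq"])
            cursor = start + len(spec["seq"])
            pseudo_truth.append(
                {
                    "pseudo_id": f"pseudo_{spec['og']}_{spec['flag']}",
                    "chromosome": name,
                    "strand": "+",
                    "start": start,
                    "end": cursor,
                    "flag": spec["flag"],
                    "og": spec["og"],
                }
            )
        parts.append(_random_dna(rng, 5000))
        genome[name] = "".join(parts)

    # gene models, numbered by genome position -----------------------------
    placed.sort(key=lambda r: (r["chrom"], r["gene_start"]))
    gene_models: list[GeneModel] = []
    truth_og: dict[str, str] = {}
    truth_structure: dict[str, str] = {}
    truth_spans: dict[str, dict[str, tuple[int, int]]] = {}
    truth_motifs: dict[str, tuple[int, ...]] = {}
    site_rows: dict[str, dict[str, int]] = {}
    member_to_gene: dict[tuple[str, int], str] = {}
    for i, rec in enumerate(placed, 1):
        gid = f"HaNAC{i:03d}"
        member_to_gene[(rec["og"], rec["member"])] = gid
        cass_start = rec["cass_start"]
        L = rec["cass_len"]
        if rec["strand"] == "+":
            exons = [(cass_start + s, cass_start + e) for s, e in rec["exon_ivs_plus"]]
        else:
            exons = sorted(
                (cass_start + L - e, cass_start + L - s) for s, e in rec["exon_ivs_plus"]
            )
        gene_models.append(
            GeneModel(
                gene_id=gid,
                chromosome=chrom_names[rec["chrom"]],
                strand=rec["strand"],
                exons=exons,
                cds=rec["cds"],
                protein=rec["protein"],
                cds_phase_per_exon=rec["phases"],
            )
        )
        truth_og[gid] = rec["og"]
        truth_structure[gid] = rec["exon_plan"]
        truth_spans[gid] = spans_by_og[rec["og"]]
        truth_motifs[gid] = OG_MOTIF_PLAN[rec["og"]]
        site_rows[gid] = {fam: rec["sites"].get(fam, 0) for fam in PWM_CONSENSI}
    annotation = GenomeAnnotation(
        chromosomes={n: len(s) for n, s in genome.items()}, genes=gene_models
    )

    # truth for duplications ----------------------------------------------
    tandem_truth = [
        {
            "chromosome": gene_models[0].chromosome,
            "og": ogs[0],
            "members": [member_to_gene[(ogs[0], 0)], member_to_gene[(ogs[0], 1)]],
        },
        {
            "chromosome": chrom_names[1 % sc.n_chromosomes],
            "og": ogs[2],
            "members": [member_to_gene[(ogs[2], m)] for m in range(3)],
        },
    ]
    for t in tandem_truth:
        t["chromosome"] = annotation.gene(t["members"][0]).chromosome
        t["members"].sort(key=lambda g: annotation.gene(g).start)

    blocks: list[DuplicationBlock] = []
    wgd_truth: list[tuple[str, str, str]] = []
    for bi, og in enumerate((ogs[4], ogs[5]), 1):
        ga = annotation.gene(member_to_gene[(og, 0)])
        gb = annotation.gene(member_to_gene[(og, 1)])
        blocks.append(
            DuplicationBlock(
                (ga.chromosome, max(0, ga.start - 3000), ga.end + 3000),
                (gb.chromosome, max(0, gb.start - 3000), gb.end + 3000),
                f"wgd_block_{bi}",
                1.0,
            )
        )
        wgd_truth.append((ga.gene_id, gb.gene_id, og))

    # differential-expression table ----------------------------------------
    de_gene_ids = [member_to_gene[(og, 0)] for og in ogs] + [
        member_to_gene[(ogs[i], 1)] for i in (0, 2, 3, 6)
    ]
    de_gene_ids = de_gene_ids[: sc.n_de_genes]
    contrasting = member_to_gene[(ogs[3], 0)]
    de_status: dict[str, dict[str, str]] = {}
    rows = []
    for g in sorted(truth_og):
        de_status[g] = {}
        for comp in COMPARISONS:
            if g == contrasting and comp in ("R453_PA_vs_A", "B481_PA_vs_A"):
                status = "up" if comp == "R453_PA_vs_A" else "down"
            elif g in de_gene_ids:
                draw = rng.random()
                status = "up" if draw < 0.35 else ("down" if draw < 0.6 else "ns")
            else:
                status = "ns"
            if status == "up":
                lfc = float(rng.uniform(1.5, 4.0))
                p = float(rng.uniform(1e-6, 0.01))
            elif status == "down":
                lfc = float(-rng.uniform(1.5, 4.0))
                p = float(rng.uniform(1e-6, 0.01))
            else:
                if rng.random() < 0.1:  # large ratio but not significant
                    lfc = float(rng.uniform(1.5, 3.0) * (1 if rng.random() < 0.5 else -1))
                    p = float(rng.uniform(0.06, 0.9))
                else:
                    lfc = float(rng.uniform(-1.2, 1.2))
                    p = float(rng.uniform(0.0, 1.0))
            de_status[g][comp] = status
            rows.append({"gene_id": g, "comparison": comp, "log2_ratio": lfc, "p_value": p})
    # guarantee every planted DE gene is differential somewhere
    for g in de_gene_ids:
        if all(s == "ns" for s in de_status[g].values()):
            comp = COMPARISONS[0]
            de_status[g][comp] = "up"
            for row in rows:
                if row["gene_id"] == g and row["comparison"] == comp:
                    row["log2_ratio"] = 2.0
                    row["p_value"] = 0.001
    de_table = pd.DataFrame(rows)

    truth = SimulationTruth(
        og_labels=truth_og,
        tandem_arrays=tandem_truth,
        wgd_pairs=wgd_truth,
        structure_labels=truth_structure,
        subdomain_spans=truth_spans,
        pseudogenes=pseudo_truth,
        motif_content=truth_motifs,
        promoter_sites=pd.DataFrame.from_dict(site_rows, orient="index")
        .rename_axis("gene_id")
        .sort_index(),
        de_status=de_status,
    )
    return SimulatedFamily(
        scenario=sc,
        seed=seed,
        genome=genome,
        annotation=annotation,
        refdb=refdb,
        pwms=pwms,
        wgd_blocks=blocks,
        de_table=de_table,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# refinement test family
# ---------------------------------------------------------------------------

def make_divergent_family(
    seed: int, n_main: int = 12, n_divergent: int = 8, identity: float = 0.85
) -> tuple[dict[str, str], set[str]]:
    """A family with one sharply divergent subfamily for refinement tests.

    Both subfamilies share the common motif blocks (so the joint alignment
    retains some columns) but have unrelated cores, and the divergent
    subfamily carries a long shared insertion.  Returns the sequences and
    the divergent member ids.
    """
    rng = np.random.default_rng(seed)
    shared = "".join(MOTIF_CONSENSI[m] for m in (5, 6, 7, 8))
    core_a = _random_protein(rng, 40) + shared + _random_protein(rng, 40)
    core_b = (
        _random_protein(rng, 40)
        + shared
        + _random_protein(rng, 15)  # long shared indel relative to family A
        + _random_protein(rng, 40)
    )
    rate = mutation_rate_for_identity(identity)
    seqs = {f"main{i:02d}": mutate_protein(core_a, rate, rng) for i in range(n_main)}
    divergent = {f"div{i:02d}": mutate_protein(core_b, rate, rng) for i in range(n_divergent)}
    seqs.update(divergent)
    return seqs, set(divergent)


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def write_all(sim: SimulatedFamily, outdir: str | Path) -> dict[str, Path]:
    """Write the simulated dataset plus truth tables; returns the paths."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": out / "genome.fasta",
        "gff3": out / "annotation.gff3",
        "refdb": out / "reference_db.fasta",
        "pwms": out / "pwms.meme.txt",
        "blocks": out / "wgd_blocks.tsv",
        "de_table": out / "de_table.tsv",
    }
    write_fasta(sim.genome, paths["genome"])
    write_gff3(sim.annotation, paths["gff3"])
    sim.refdb.to_fasta(paths["refdb"])
    write_pwms(sim.pwms, paths["pwms"])
    write_blocks(sim.wgd_blocks, paths["blocks"])
    sim.de_table.to_csv(paths["de_table"], sep="\t", index=False)
    truth_dir = out / "truth"
    truth_dir.mkdir(exist_ok=True)
    t = sim.truth
    pd.Series(t.og_labels, name="og_label").rename_axis("gene_id").to_csv(
        truth_dir / "og_labels.tsv", sep="\t"
    )
    pd.DataFrame(
        [
            {"chromosome": a["chromosome"], "og": a["og"], "members": ",".join(a["members"])}
            for a in t.tandem_arrays
        ]
    ).to_csv(truth_dir / "tandem_arrays.tsv", sep="\t", index=False)
    pd.DataFrame(t.wgd_pairs, columns=["gene_a", "gene_b", "og"]).to_csv(
        truth_dir / "wgd_pairs.tsv", sep="\t", index=False
    )
    pd.Series(t.structure_labels, name="label").rename_axis("gene_id").to_csv(
        truth_dir / "structure_labels.tsv", sep="\t"
    )
    pd.DataFrame(t.pseudogenes).to_csv(truth_dir / "pseudogenes.tsv", sep="\t", index=False)
    t.promoter_sites.to_csv(truth_dir / "promoter_sites.tsv", sep="\t")
    pd.DataFrame(t.de_status).T.rename_axis("gene_id").to_csv(
        truth_dir / "de_status.tsv", sep="\t"
    )
    return paths
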