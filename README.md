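# famforge

Genome-wide cataloguing of a plant transcription-factor family, packaged as
a reusable, tested pipeline.  The motivating use case is the NAC family
(NAM/ATAF/CUC) in a newly sequenced crop genome: NAC proteins carry a
conserved N-terminal DNA-binding domain split into subdomains A–E and a
variable C-terminal transcription-regulatory region (TRR), and family
members are organised into orthologous groups (OGs) — clades descending
from single ancestral genes predating the monocot/dicot split — that allow
function to be transferred from model species to the new genome.

Given a genome (FASTA + GFF3), a reference database of family proteins
labelled with OGs, a nucleotide PWM collection and a differential-expression
table, the pipeline performs:

1. **Locus mining** — six-frame translated search of the genome against
   reference proteins (shared-4-mer seeding confirmed by Smith–Waterman
   local alignment, BLOSUM62, affine gaps 11/1), merging nearby hits into
   loci and flagging pseudogene evidence (`internal_stop`, `frameshift`).
2. **Orthogroup classification** — a gene is assigned to OG *L* when its
   *k* = 3 best database hits (score ties resolved conservatively) all
   carry label *L*; otherwise it stays UNASSIGNED.
3. **Iterative phylogenetic refinement** — progressive multiple alignment
   (UPGMA guide tree on 3-mer distances, profile–profile affine DP),
   conserved-block cleaning, neighbor-joining on p-distances with bootstrap
   support; clades hanging off long, well-supported stems are split off and
   re-analysed separately, which increases the number of alignment
   positions retained for their trees.
4. **Duplication analysis** — tandem arrays (same-OG genes ≤ 100 kb apart,
   chained transitively), WGD paralog pairs inside externally supplied
   duplicated-block pairs, and per-chromosome distributions.
5. **Exon-structure typing** — intron phases and subdomain→exon maps
   compared with the family's canonical three-exon architecture (exon 1:
   subdomains A+B, phase-1 intron; exon 2: C+D, phase-0 intron; exon 3:
   E + TRR) and its variants (merged exons 1–2, extra N-terminal exon,
   extra C-terminal exons).
6. **Motif architectures** — ZOOPS (zero-or-one occurrence per sequence)
   EM discovery of 10 ungapped protein motifs, mapping onto subdomains via
   published anchor consensi (G-Y-W-K-A/T-T-G-x-D-x₁₋₂-I/V;
   G-x-K-K-x-L-V-F-Y; T-x-W-x-M-H-E-Y), and typing of per-protein motif
   content into structures A–D.
7. **Promoter TFBS profiling** — 2000-bp promoters upstream of the ATG,
   log-odds PWM scanning of both strands at 80% of the maximum attainable
   score, and an OG × TF-family matrix of mean hit counts.
8. **Expression candidates** — up/down/ns calls per contrast
   (|log₂ ratio| ≥ 1.5, p < 0.05) across the four line/stage comparisons
   of an early- vs delayed-senescence design, flagging
   senescence-associated and genotype-contrasting genes.

A seeded synthetic-data generator (`famforge.synthetic_data`) emulates the
full study design — orthogroups with controlled within/between identity,
canonical and variant exon structures, tandem arrays, mirrored WGD blocks,
pseudogene remnants, promoters with planted TFBS and a DE table with
planted profiles — with exhaustive planted truth, so every stage is
testable end to end without downloads.

## Worked example

Simulate the default scenario (8 OGs × 5 genes on 3 chromosomes) and run
every stage:

```bash
famforge --seed 7 simulate --out demo/data
famforge --seed 7 all --data demo/data --out demo/out
```

`demo/out/assignments.tsv` starts:

```
gene_id   og_label  rule       top1_subject  top1_label  top1_score  top2_subject  top2_label  top2_score
HaNAC001  1a        consensus  VvNAC-1a      1a          876         OsaNAC-1a-1   1a          855
HaNAC002  1a        consensus  VvNAC-1a      1a          846         MacNAC-1a-2   1a          815
HaNAC003  4b        consensus  VvNAC-4b      4b          836         OsaNAC-4b-1   4b          790
```

Each gene's three best hits agree on one orthogroup, so the consensus rule
assigns it; the scores are raw Smith–Waterman scores against the labelled
reference set.  `demo/out/tfbs_og_matrix.tsv` holds the promoter profile:

```
og_label  AP2  Dof  MYB  NAC  WRKY  bZIP
1a        0.0  0.0  0.0  1.0  1.0   0.0
1h        0.0  0.0  0.0  1.0  1.0   0.0
2a        0.0  0.0  0.0  1.0  1.0   0.0
```

Every promoter carries one NAC and one WRKY site in this scenario; the OG
with planted AP2 enrichment shows 5.0 in the AP2 column.  `loci.tsv` lists
42 mined loci — the 40 annotated genes (all `intact`) plus the two
unannotated pseudogene remnants flagged `internal_stop` and `frameshift`.

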