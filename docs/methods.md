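# Methods

This note documents the models and procedures implemented in famforge, the
parameters that matter, the numerical choices, and what the synthetic-data
tests do and do not demonstrate.

## Pairwise alignment and locus mining

All protein similarity is raw Smith–Waterman local alignment under
BLOSUM62 with BLAST-convention affine gaps (a gap of length L costs
`gap_open + L·gap_extend`, defaults 11/1).  The ambiguous residue X scores
0 against everything.  Raw scores, not E-values, drive every downstream
rule: classification uses hit *order*, and E-value calibration would add
constants that cannot be verified at this scale.

Translated mining scans all six reading frames of each chromosome.  For
tractability a seeding heuristic restricts alignment to regions sharing at
least four 4-mers with the query within a 200-residue window (the same
word-seeding idea translated-search tools use); candidate regions are then
confirmed by full local alignment.  Hits below `min_locus_score` (default
70) are dropped.  The threshold is set from Karlin–Altschul statistics: on
a megabase-scale genome the expected number of chance translated hits
scoring ≥ 50 is of order 1, while at 70 it is below 0.01; genuine family
loci score in the hundreds, so the margin is wide on both sides.

Hits are tail-trimmed before interpretation (the retained region is
bounded by the outermost 10-column windows containing ≥ 7 identities),
because local alignments drift a handful of residues past exon boundaries
on chance matches.  Same-strand hits within `locus_merge_gap` (10 kb, a
generous intron allowance) merge into loci.  Pseudogene evidence is judged
on the locus's best-matching query only:

* `internal_stop` — a stop aligned against a query residue with ≥ 60%
  identity in both 8-column flanks.  Stops under query gaps, or with only
  one good flank, are intron translation that the aligner bridged (an
  intron whose length is divisible by 3 lets the same reading frame
  continue) or overrun past an exon end, not lesions.
* `frameshift` — two best-query segments in different frames covering
  complementary parts of the query (union ≥ longest span + 20 aa) with a
  genomic gap under 60 bp.  Introns leave larger gaps; a bridged
  whole-gene alignment nests the query span of any exon hit and is
  therefore not mistaken for a lesion.

A frameshifted pseudogene genuinely accumulates downstream in-frame stops,
so both flags on one remnant are biologically coherent.

## Orthogroup classification

A gene is assigned to orthogroup L when its k best-ranked hits (default
k = 3) against the labelled reference database all carry L.  Ties are
handled conservatively: if the k-th and (k+1)-th hits tie in score, the
whole score-tied block must agree, which makes the outcome independent of
database order and monotone in k (raising k can only move genes from
assigned to UNASSIGNED).  Database entries with the query's own id are
excluded.  Unassigned genes can receive a `nearest_cluster` annotation
from the tree, never a hard label — divergent genes are a real biological
category, not a classification failure.

## Multiple alignment and block cleaning

The aligner is a deterministic MUSCLE-like first iteration: guide tree by
UPGMA on the distance 1 − shared-3-mer fraction (shared fraction =
intersection size over the smaller 3-mer set), then profile–profile global
alignment with affine gaps along the guide tree, with input order fixed by
id sort.  Iterative MSA refinement stages are out of scope; the alignments
this feeds (p-distance trees on cleaned columns) are insensitive to the
fine placement of gaps in variable regions.

Cleaning is a simplified, hand-checkable Gblocks: a column is *conserved*
when its most frequent residue reaches c1 = 0.5 + 1/n of the non-gap rows
(the fraction is taken over non-gap rows — otherwise the gap allowance
below could never be used) and its gap fraction is within the allowed
maximum.  Relaxed mode (the default, mirroring the standard relaxations
for divergent families) allows gaps in up to 50% of a retained column,
accepts blocks of ≥ 5 columns, and requires flanks only to be conserved;
strict mode allows no gaps, requires 10-column blocks and trims flanks to
highly conserved columns (c2 = 0.85).  Blocks are maximal runs of
conserved columns.

## Trees and iterative refinement

Trees are canonical neighbor-joining on normalised p-distances over the
retained columns, ignoring pairwise-gapped positions; a pair with no
comparable columns gets distance 1.  Negative branch-length estimates are
clamped to zero with the deficit moved to the sibling branch, preserving
the pair's summed length; on additive matrices the algorithm is exact.
Support is the bootstrap fraction of column resamples (default 100)
reproducing each internal bipartition.  NJ + bootstrap stands in for
maximum-likelihood + aLRT: the refinement procedure is independent of the
tree engine, and a distance method is exactly reproducible at desk scale.

Refinement: round 0 aligns, cleans and builds a tree on the full set; any
clade whose stem branch is at least `refine_min_stem` (2.0) times the
median internal branch length, with support ≥ `refine_min_support` (0.95)
and between `refine_min_size` (3) and n − 3 members, is split off;
overlapping candidates resolve to the outermost clade.  Split sets and the
remainder re-enter as new rounds; sets under 8 members are not re-analysed
(below that, block cleaning and bootstrap are uninformative), so the loop
terminates.  Each round records its retained-positions count — on a family
with a divergent subfamily, the subfamily's own round retains strictly more
positions than the joint round, which is the point of iterating.

## Motif discovery and architectures

Discovery is ZOOPS EM: each sequence holds 0 or 1 motif site, a
position-probability matrix over the 20 amino acids describes sites, and
everything else is dataset-frequency background.  Per width, candidate
seed windows are ranked by the summed best-match identity across
sequences, the top 8 seed EM restarts (pseudocount 0.1, tolerance 1e-5,
≤ 200 iterations), and the tracked objective — data log-likelihood ratio
plus the Dirichlet pseudocount prior — is monotone under EM and asserted
so.  Width is chosen on the grid {6, 9, 12, 15, 20, 29, 50} ∩ [wmin, wmax]
by the AIC-penalised log-likelihood ratio (penalty 19 free parameters per
column), which prevents wider models from winning on overfit noise
columns.  After a motif is accepted its occurrences (posterior ≥ 0.5) are
masked and the search repeats.

Motif numbering follows the family convention: models matching the
published anchor consensi become motifs 5 (subdomain C), 6 and 7
(subdomain D); remaining models are numbered by mean occurrence offset and
mapped 1→A, 2→B, 3,4→C, 8→E, 9→C-like, 10→TRR.  Architecture typing is a
pure function of the presence set with precedence D (motif 10) > C (motif
9) > B (A-set minus motif 4) > A (motifs 1–8); anything else is `other`.
In the motif logos of the source material Z and B denote Q/E and N/D
equivalence; anchor matching treats them as two-letter classes.

## Promoters and expression

Promoters are the `promoter_len` (2000 bp) window immediately 5' of the
CDS start on the coding strand, truncated with a warning at chromosome
edges.  Scanning computes log₂-odds against a uniform background at every
offset on both strands; N scores 0.  A window is a hit at ≥ 80% of the
maximum attainable score — a relative threshold because per-matrix
cut-offs of public PWM collections are not published; scanning a sequence
and its reverse complement gives identical counts by construction.  Counts
from matrices of one TF family are summed per family, then averaged per
orthogroup into the OG × family matrix.  Counts are reported rather than
per-kb rates; for fixed-length promoters the two differ by a constant.

Expression calls apply the thresholds exactly: up ⇔ log₂ ratio ≥ 1.5 and
p < 0.05; down symmetric; ns otherwise, with missing p-values warned and
treated as ns.  P-values are taken as given (no multiple-testing
correction, matching the upstream analysis this consumes; a BH option
could be added but is off by default).  Senescence-associated =
differential in ≥ 1 of the four contrasts; genotype-contrasting = opposite
post-anthesis/anthesis calls in the two lines.

## The synthetic generator: what it does and does not show

The default scenario plants 8 orthogroups × 5 genes on 3 chromosomes.
Founder proteins are motif blocks joined by random linkers plus a random
TRR tail; members are derived by per-site substitution at a rate chosen so
mean pairwise member identity hits the target (0.85; the rate is
1 − √target, since two members are independent mutants of one founder).
Between-OG identity of random founders stays below 0.4 even with the
shared subdomain motifs.  CDSs are back-translated with the most frequent
plant codon per amino acid; exon structures implement the canonical rules
(exon 1 ends one nucleotide into the first codon after subdomain B, exon 2
on the codon boundary before E), introns are uniform random DNA of
150–400 bp, and intergenic background is i.i.d. uniform.  Tandem arrays
are planted at 60 and 90 kb start-to-start spacings with a control
same-OG pair at 120 kb; WGD blocks mirror two genes on different
chromosomes; two pseudogene remnants are intronless founder copies with a
single stop substitution or a single 1-bp deletion — the minimal lesions
the miner's flags must detect.  Promoter backgrounds are scrubbed of
chance consensus matches before sites are planted, so planted counts are
exact.

Passing on this generator shows the *procedures* are correct: rules fire
exactly where planted truth says they should.  It does not show
performance on real genomes, which have repeats, transposon-derived family
fragments, non-uniform base composition, alternative splicing, tandem
arrays with recent gene conversion, and much older pseudogenes — all
outside the generator's scope.  Real annotations also carry multiple
transcripts per gene; the pipeline keeps the longest CDS per gene, a
choice (not a fact about the data) recorded here because the source
procedure does not state which isoform it used.

## Defaults at a glance

| parameter | default | meaning |
|---|---|---|
| `consensus_k` | 3 | hits that must agree for OG assignment |
| `tandem_max_gap` | 100 000 bp | start-to-start tandem chaining distance |
| `promoter_len` | 2000 bp | promoter window upstream of ATG |
| `motif_count` | 10 | motifs discovered |
| `motif_wmin/wmax` | 6 / 200 | motif width bounds (tests use 6/20) |
| `de_lfc_threshold` | 1.5 | \|log₂ ratio\| cut-off |
| `de_p_threshold` | 0.05 | p-value cut-off |
| `refine_min_stem` | 2.0 × median | stem length multiplier for splitting |
| `refine_min_support` | 0.95 | support required to split a clade |
| `refine_min_size` | 3 | minimum split-clade size |
| `min_locus_score` | 70 | mining score threshold (see above) |
| `locus_merge_gap` | 10 000 bp | hit-merging distance within a locus |
| `tfbs_threshold_frac` | 0.8 | fraction of max PWM score for a hit |
| `bootstrap_reps` | 100 | bootstrap replicates per tree |

Problem sizes in the test suite and the acceptance script (40-gene family,
~1.8 Mb genome, 20-sequence motif datasets, 50 random 6-leaf trees, 10
refinement replicates) are the package's desk-scale verification setting;
all are configurable upward through `PipelineConfig` and `Scenario`.

## Known limitations

* No heuristic is complete: the k-mer seeding can in principle miss a
  highly diverged locus a full translated search would find.
* Distance trees underestimate support structure relative to ML on real,
  rate-heterogeneous families; the refinement loop is engine-agnostic but
  the supports themselves are bootstrap-NJ supports.
* The miner flags lesions; it does not curate.  Distinguishing recent
  pseudogenes from annotation errors requires manual review.
* WGD blocks are consumed, not inferred; synteny detection is a different
  tool's job.
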