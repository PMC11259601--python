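# Methods

## Problem setting

Cell-free RNA (cfRNA) in plasma is short (roughly 20–200 nt) and dominated
by fragments of ribosomal and mitochondrial RNA, which in untreated
libraries account for on the order of 92% of reads. Because the input is
fragmented, RNA-level depletion kits are ineffective; the DASH strategy
(Depletion of Abundant Sequences by Hybridisation) instead cleaves the
double-stranded cDNA of unwanted species with Cas9 between amplification
stages, so cleaved inserts cannot amplify. cfdash implements the
computational side of such a workflow: sgRNA pool design, an in-silico
model of the depletion step, the early-barcoding/UMI logic that allows
3–5-plex multiplexed libraries, the hierarchical assignment of reads to
source classes and RNA biotypes, and the sample-level QC gates. All of it
runs on synthetic data produced by the `fixtures` module.

## Guide design (`guide_design`)

**Model.** An SpCas9 site is a 20-nt protospacer immediately followed 3'
by an NGG PAM; cleavage is blunt, 3 bp 5' of the PAM (between protospacer
positions 17 and 18). The design goal is a pool whose cut sites tile each
target so that the maximum distance between consecutive cuts (and from the
target ends to the nearest cut) is at most `tile_interval` = 50 bp: any
cDNA insert of length ≥ 2 tile intervals drawn from the target then
contains at least one complete, cleavable site.

**Candidate scanning** enumerates every site on both strands. Candidates
containing N are dropped (an ambiguous base cannot be synthesised as an
oligo). Coordinates are 0-based; a minus-strand candidate's `start` is the
plus-strand coordinate of its 5' end, and its protospacer is reported
5'→3' on its own strand.

**Structural filters** flag guides likely to fold or synthesise badly:

- GC count outside [5, 15] of 20 (`gc_low` / `gc_high`);
- a single-base run longer than 5 (`homopolymer`);
- a dinucleotide unit XY (X ≠ Y) repeated consecutively more than 3 times
  (`dinucleotide_repeat`);
- a hairpin: the reverse complement of any 5-nt substring of the first 8
  bases occurring within the last 8 bases. Stem length and window size are
  configurable; 5-within-8 is our operationalisation of "complementary
  subsequences near the start and end of a binding site", since no
  published numbers exist for this rule. We deliberately avoid
  thermodynamic folding models; the string rule is reproducible and
  library-free.

Candidates are annotated, never silently dropped, so a design report can
account for every scanned site.

**Scoring.** The on-target score is the exact count of protospacer+PAM
occurrences across the whole target set, rewarding guides that hit
repeated regions; the off-target count is an exact 20-mer+PAM lookup
against an index of the background (e.g. a transcriptome with rRNA/mtRNA
removed). Off-target tolerance defaults to zero hits with exact matching —
the conservative choice, reproducible without a proprietary scorer; an
optional 1-mismatch query mode exists but is off by default.

**Tiling selection** is a left-to-right greedy sweep per target: starting
from coordinate 0, repeatedly pick the eligible candidate whose cut is the
largest not exceeding `last_cut + tile_interval` (first pick ≤
`tile_interval`); ties are broken by higher on-target score, lower
off-target count, smaller start, then + before −. Where a window holds no
eligible cut, the gap is recorded as uncovered and the sweep restarts at
the next eligible cut (provenance `gap_fill`). This greedy is the
classical furthest-point rule and provably minimises the number of
selected cuts over the span it can reach; redundancy removal is implicit
(at most one guide per tile window). Declared SNP positions must end up
within `tile_interval/2` of a selected cut; if an eligible candidate
permits, the nearest one is added (`variant_fill`), otherwise the variant
is reported uncovered. Residual gaps are reported, never silently patched.

**Export.** Each selected spacer becomes an in-vitro-transcription
template: T7 promoter + spacer + sgRNA scaffold. T7 initiation requires a
5' G, so a single G is prepended to spacers that do not start with one
(flagged in the output). Outputs are a TSV of all guide fields, a BED of
protospacer intervals, a template FASTA, and a JSON design report with
per-target gap statistics.

We make no attempt to reproduce any published guide list: that depends on
reference sequence versions, proprietary scores and manual curation. The
structure of the pool (tiling guarantee, exclusion soundness, determinism)
is the tested contract.

## In-silico depletion (`depletion_sim`)

A fragment is treated as double-stranded cDNA; a pool guide cuts wherever
its protospacer occurs exactly on either strand with a PAM-pattern match
immediately 3'. A site straddling a fragment end does not count — both
protospacer and PAM must be intact within the insert. Cleaved fragments
are removed entirely (the model of "cannot amplify further"); cleavage is
100% efficient. Real libraries retain a residual percentage of abundant
reads from chemistry effects (incomplete cleavage, PAM-free regions) that
this model intentionally does not reproduce. The depletion report carries
pre/post class compositions (fractions summing to 1) and satisfies
`n_input = n_cut + n_retained` by construction, where `n_cut` counts
removed fragments, not cut events.

## Barcodes and UMIs (`barcode_umi`)

**Code design.** Sample barcodes are 4-nt with minimum pairwise Hamming
distance 3, built greedily over lexicographically ordered 4-mers.
Composition filters: no self-complementary barcode (reverse complement
equals itself), no triplet (≥ 3 identical consecutive bases — the usual
reading of "triplets" in barcode-design practice), and GC balance with
G+C count in [1, 3] for length 4 (the boundaries are configurable; "not
all-AT and not all-GC" is our reading of "unbalanced ratio"). Distance 3
corrects any single sequencing error in the barcode, so demultiplexing
defaults to `max_mismatch = 1`; a read whose observed barcode is not
within 1 of exactly one codeword goes to the unassigned stream. A
no-mismatch mode is available.

**UMIs** are 8-nt, carried on the template-switch side (mate 2 by default;
the layout — which mate, offset, length — is a config block since the
chemistry does not fix read geometry). Extraction moves the UMI into the
read name (`<id>_<UMI>`) and clips it with its qualities; reads shorter
than the UMI span go to a counted too-short sink.

**Deduplication** groups reads by (alignment position, sample) — or by
exact-sequence bucket in unaligned tests — and applies the directional
network rule: an edge a→b exists between UMIs at Hamming distance 1 with
count(a) ≥ 2·count(b) − 1, components are grown breadth-first from
high-count seeds, and the molecule count is the number of components. One
representative (highest count, then lexicographically smallest UMI) is
kept per component. `cluster` (plain distance-1 components) and `unique`
(distinct UMIs) methods are provided as alternatives.

## Read assignment (`read_assignment`)

Reads are resolved by a fixed tier order — spike-in, UniVec, rRNA, mtRNA,
genome, circRNA — taking the first tier that claims the read; unclaimed
reads are `unmapped` (exported for external microbial classification,
which is out of scope). Alignment itself is consumed, not performed:
inputs are per-tier SAM/BAM (primary alignments only) or a flag table.

Within the genome tier a read pair is assigned to a gene if at least one
mate overlaps (≥ 1 bp, same strand by default since the library is
stranded; `ignore_strand` available) an exonic feature. Among overlapped
features the priority order mRNA > lncRNA > pseudogene > tRNA > srpRNA >
snoRNA > snRNA > Y_RNA > misc_RNA > other_exon decides; equal-priority
ties go to the gene with the larger total overlap, then the
lexicographically smaller gene id (the original pipeline's tie rule is
unknown; ours is deterministic and order-independent). Pairs without
exonic overlap are tallied as intronic (inside a gene body) or intergenic.

circRNA support is counted at back-splice junctions: a read supports a
junction iff its alignment covers the junction point with at least
`min_anchor` = 5 aligned bases on each side, boundary inclusive (the
anchor length is our choice; configurable).

TPM removes rRNA/mtRNA genes before normalisation:
TPM_g = (c_g/l_g) · 10⁶ / Σ_h (c_h/l_h), so each expressed sample column
sums to 10⁶. Gene filtering keeps genes with TPM strictly > 1 in at least
50% of samples (inclusive at exactly half; TPM exactly 1 is dropped).

## QC engine (`qc_engine`)

Sequencing gates (all strict, boundary values fail): raw reads > 4 M;
clean reads > 3.8 M; rRNA fraction < 20% and mtRNA fraction < 20% of
mapped reads; genome-aligned reads > 2 M; deduplicated reads > 0.1 M. All
six rules are evaluated independently and all verdicts reported; a
missing metric fails its rule defensively. qPCR exclusions: ACTB
exon–exon Ct > 32 (too little RNA), ACTB intron Ct < 35 (DNA
contamination), ACTB-ee − 16S-V4 Ct difference > 5 (bacterial
contamination).

Pooling sorts samples by ACTB-ee Ct and chunks greedily into pools of
3–5 with within-pool Ct range < 1 cycle; leftovers are reported unpooled.
The wet-lab practice this encodes is not an algorithm, so any valid
grouping would do; sort-then-chunk is deterministic.

Saturation analysis subsamples the read table at nested depths (one
seeded shuffle, prefix per depth), so detected-gene and detected-UMI
curves are monotone by construction.

## Synthetic data (`fixtures`)

Defaults encode the study conditions the package targets: library
composition ≈ 92% rRNA+mtRNA (80/12), 4% genome, the remainder split over
circRNA/spike-in/vector/microbial; fragment lengths log-normal
(median ≈ 100 nt, σ = 0.35 on the log scale) clipped to [20, 200] nt — a
bounded log-normal stand-in for the published length traces, which are
figures rather than tables. Fragment sampling is uniform along sources;
real coverage is non-uniform, so passing depletion tests demonstrate the
cut-site guarantee, not coverage realism.

Two generator choices deserve emphasis:

- `make_tileable_targets` plants a structurally clean protospacer+AGG
  site every 40 bp with random filler between sites. Real rRNA/mtRNA
  references are PAM-dense, but unconstrained random sequence occasionally
  contains a PAM desert longer than the tile interval, which would break
  the premise of the 100%-depletion property rather than test it.
- `simulate_umi_groups` draws true per-position UMIs without replacement
  and rejects draws within Hamming distance 1 of an existing UMI at that
  position. Distance-1 merging is exactly what directional dedup is meant
  to do, so distance-1 true molecules would make "exact recovery"
  ill-posed; the guard keeps ground truth unambiguous. Observed UMIs still
  receive independent per-base errors.

Read simulation places the barcode at the start of mate 1 and the UMI at
the start of mate 2, applies uniform PCR duplication factors and i.i.d.
substitution errors, and emits a ground-truth table for round-trip tests.
Quality strings are constant; quality-score profiles, indels and adapter
read-through are not modelled.

## Problem sizes and numerical choices

The test suite and the acceptance script run at desk scale: 100 × 2-kb
targets for the scanning oracle, 10,000 random 20-mers for the filter
oracle, 50 tiling instances ≤ 300 nt against exhaustive minimum covers,
10,000-fragment depletion libraries, 200 UMI positions × 5 molecules, and
2,000 simulated read pairs for demultiplexing — sizes at which the
independent brute-force oracles remain exact and the whole suite completes
in well under a minute. Composition fractions are validated to 1 ± 1e-9;
TPM column sums to 10⁶ ± 1e-3. All randomness flows through
`numpy.random.default_rng` with explicit seeds; identical inputs and seeds
give byte-identical outputs.

## Known limitations

- Depletion is all-or-nothing; no Cas9 kinetics, stoichiometry or partial
  cleavage, hence no residual abundant fraction.
- Off-target matching is exact by default; mismatch-tolerant scoring
  beyond the optional 1-mismatch query is out of scope.
- Alignment (STAR-class), microbial classification, differential
  expression, enrichment, deconvolution and classification downstream of
  the count matrices are out of scope; unmapped reads and count tables are
  exported for external tools.
- The barcode greedy yields a good, valid code (12 barcodes under the
  default filters), not a provably maximum one; the exhaustive upper bound
  (16 for length 4, distance 3) is only used in tests.
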