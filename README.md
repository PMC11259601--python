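# cfdash

CRISPR-Cas9 depletion toolkit for multiplexed cell-free total RNA
sequencing.

Plasma cell-free RNA (cfRNA) is fragmented (~20–200 nt) and dominated by
ribosomal and mitochondrial RNA — around 92% of reads in an untreated
library. Because the input is fragmented, RNA-level depletion kits do not
work; the DASH approach (Depletion of Abundant Sequences by Hybridisation)
instead directs Cas9 to cleave the unwanted double-stranded cDNA between
amplification stages, so those inserts cannot amplify. cfdash is the
computational toolkit for that workflow, aimed at people building or
evaluating cfRNA-seq pipelines:

- **Guide design** (`cfdash design`): scan every protospacer+PAM site on
  the rRNA/mtRNA targets, drop structurally poor guides (GC outside 5–15
  of 20, homopolymers > 5, dinucleotide units repeated > 3×, terminal
  hairpins), exclude guides with exact off-target hits, then greedily
  select cut sites so that no stretch of a target longer than 50 bp lacks
  a cut — the tiling that guarantees any fragment ≥ 2 tile intervals is
  cleavable. Residual gaps and uncovered SNPs are reported, and each
  spacer is exported as a T7 promoter + spacer + scaffold transcription
  template.
- **In-silico depletion** (`cfdash deplete`): predict which library
  fragments a pool cleaves (exact protospacer match with adjacent PAM,
  either strand) and report pre/post class composition.
- **Barcodes and UMIs** (`cfdash barcodes`, `demux`, `dedup`): a 4-nt
  sample-barcode code with minimum Hamming distance 3 (corrects any single
  sequencing error), error-correcting demultiplexing, 8-nt UMI extraction
  into read names, and directional-network UMI deduplication
  (edge a→b iff distance 1 and count(a) ≥ 2·count(b) − 1).
- **Read assignment** (`cfdash assign`, `tpm`): sequential tier resolution
  (spike-in → UniVec → rRNA → mtRNA → genome → circRNA → unmapped),
  biotype-priority gene assignment (mRNA > lncRNA > pseudogene > tRNA >
  srpRNA > snoRNA > snRNA > Y_RNA > misc_RNA > other_exon, one overlapping
  mate suffices), anchored back-splice-junction counting for circRNAs, and
  TPM with rRNA/mtRNA removed before normalisation
  (TPM_g = (c_g/l_g)·10⁶ / Σ_h c_h/l_h).
- **QC** (`cfdash qc`, `pool-plan`, `saturation`): the six sequencing
  gates (raw > 4 M, clean > 3.8 M, rRNA < 20%, mtRNA < 20%, aligned > 2 M,
  deduplicated > 0.1 M; all strict), the three qPCR exclusion rules
  (ACTB-ee Ct > 32, ACTB-i Ct < 35, ΔCt(ACTB-ee − 16S-V4) > 5), the
  3–5-plex pooling rule (Ct range < 1), and saturation subsampling curves.
- **Fixtures** (`cfdash fixtures ...`): seeded synthetic targets,
  fragment libraries with controlled composition and length profiles,
  barcoded/UMI-tagged paired reads with ground truth, toy GTF annotations
  and BSJ references — the whole toolkit runs with no downloads.

See `docs/methods.md` for the models, defaults and their rationale.

## Worked example

Design guides for a synthetic abundant target, build a 5,000-fragment
library that is ~92% abundant, and deplete it:

```sh
python - <<'EOF'
from cfdash.fixtures import make_tileable_targets, make_targets, write_targets_fasta
write_targets_fasta(make_tileable_targets(1, 2000, seed=11, class_label="rRNA"), "targets.fa")
write_targets_fasta(make_targets(1, [2000], seed=12, prefix="bg", class_label="custom"), "background.fa")
EOF
cfdash design --targets targets.fa --background background.fa -o design_out
cfdash fixtures make-library --targets targets.fa --background background.fa \
    --n 5000 --seed 2 -o library.fa
cfdash deplete --fragments library.fa --pool design_out/guides.tsv -o deplete_out
```

which prints:

```
designed 48 guides -> design_out
5000 fragments -> library.fa
4451/5000 fragments cut; 549 retained -> deplete_out
```

The 48 guides tile the 2-kb target with a maximum inter-cut gap of ≤ 50 bp
(`design_out/design_report.json`). `deplete_out/depletion_report.json`
shows the library went from 91.8% abundant-class fragments to 25.7% *of
the retained 549*: every abundant fragment long enough to contain a
complete 23-nt cut site was removed, and the survivors are the short tail
of the 20–200 nt length distribution plus the guide-free background. With
fragments ≥ 100 nt (twice the tile interval) removal of the abundant class
is complete — that guarantee is asserted in the test suite.

`design_out/guides.tsv` holds one row per guide:

```
target_id  strand  start  end  protospacer           pam  cut_pos  on_target_score  off_target_hits  provenance  prepended_g
target1    -       33     53   ATTGCAGGTTTATCCTCTGA  TGG  36       1                0                tiling      True
target1    +       57     77   TGCCAAATCAGAAGTATAAA  AGG  74       1                0                tiling      True
```

`prepended_g = True` means the in-vitro-transcription template received a
single 5' G because the spacer does not begin with one (T7 requirement).

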