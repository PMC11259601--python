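"""Hierarchical read-to-class resolution, biotype assignment, TPM.

Reads are mapped sequentially against ordered reference tiers (spike-in,
UniVec vector contaminants, rRNA, mtRNA, genome, circRNA back-splice
junctions): a read claimed by an earlier tier is never considered by a
later one. Genome-tier read pairs are then assigned to genes by biotype
priority — a pair belongs to an RNA type if at least one mate overlaps the
corresponding exonic regions — and expression is summarised as TPM with
rRNA/mtRNA reads removed before normalisation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

TIERS = ("spikein", "univec", "rRNA", "mtRNA", "genome", "circRNA")

# Highest priority first; a pair overlapping both an mRNA exon and a snoRNA
# exon is counted as mRNA. Exons of biotypes outside this list fall into the
# other_exon catch-all.
BIOTYPE_PRIORITY = ("mRNA", "lncRNA", "pseudogene", "tRNA", "srpRNA",
                    "snoRNA", "snRNA", "Y_RNA", "misc_RNA", "other_exon")

# GENCODE gene_type spellings mapped onto the priority vocabulary.
_BIOTYPE_ALIASES = {
    "protein_coding": "mRNA",
    "lincRNA": "lncRNA",
    "processed_pseudogene": "pseudogene",
    "unprocessed_pseudogene": "pseudogene",
    "Mt_tRNA": "tRNA",
    "scaRNA": "snoRNA",
    "RNY": "Y_RNA",
}


def canonical_biotype(gene_type: str) -> str:
    bt = _BIOTYPE_ALIASES.get(gene_type, gene_type)
    return bt if bt in BIOTYPE_PRIORITY else "other_exon"


@dataclass
class AlignmentEvidence:
    """Per-read alignment evidence across tiers.

    ``genome_alignments`` holds (chrom, start, end, strand, mate_index)
    with 0-based half-open intervals; ``bsj_alignments`` holds
    (junction_id, junction-relative start, aligned length).
    """

    read_id: str
    tier_flags: dict[str, bool] = field(default_factory=dict)
    genome_alignments: list[tuple[str, int, int, str, int]] = field(default_factory=list)
    bsj_alignments: list[tuple[str, int, int]] = field(default_factory=list)


def resolve_hierarchy(evidence: AlignmentEvidence) -> str:
    """First tier (in the fixed order) whose flag is true, else 'unmapped'."""
    for tier in TIERS:
        if evidence.tier_flags.get(tier, False):
            return tier
    return "unmapped"


class GenomeAnnotation:
    """Exon/gene interval lookup built from a GENCODE-dialect GTF."""

    def __init__(self):
        self._exons: dict[tuple[str, str], IntervalTree] = {}
        self._genes: dict[tuple[str, str], IntervalTree] = {}
        self.gene_biotype: dict[str, str] = {}

    @classmethod
    def from_gtf(cls, path) -> "GenomeAnnotation":
        """Parse a GTF (requires gene_id and gene_type attributes)."""
        import gffutils
        db = gffutils.create_db(
            str(path), ":memory:", force=True, keep_order=True,
            disable_infer_genes=True, disable_infer_transcripts=True,
        )
        ann = cls()
        for feat in db.all_features():
            if feat.featuretype not in {"exon", "gene"}:
                continue
            try:
                gene_id = feat.attributes["gene_id"][0]
                gene_type = feat.attributes["gene_type"][0]
            except KeyError as exc:
                raise ValueError(
                    f"GTF feature at {feat.seqid}:{feat.start} missing {exc} attribute")
            ann._add(feat.featuretype, feat.seqid, feat.start - 1, feat.end,
                     feat.strand, gene_id, gene_type)
        return ann

    def _add(self, kind: str, chrom: str, start: int, end: int, strand: str,
             gene_id: str, gene_type: str) -> None:
        self.gene_biotype[gene_id] = canonical_biotype(gene_type)
        store = self._exons if kind == "exon" else self._genes
        tree = store.setdefault((chrom, strand), IntervalTree())
        tree[start:end] = gene_id

    def add_gene(self, chrom: str, start: int, end: int, strand: str,
                 gene_id: str, gene_type: str,
                 exons: Sequence[tuple[int, int]] | None = None) -> None:
        """Programmatic construction (used by fixtures and tests)."""
        self._add("gene", chrom, start, end, strand, gene_id, gene_type)
        for es, ee in (exons if exons is not None else [(start, end)]):
            self._add("exon", chrom, es, ee, strand, gene_id, gene_type)

    def exon_overlaps(self, chrom: str, start: int, end: int, strand: str,
                      ignore_strand: bool = False):
        keys = [(chrom, s) for s in ("+", "-")] if ignore_strand else [(chrom, strand)]
        for key in keys:
            tree = self._exons.get(key)
            if tree is None:
                continue
            for iv in tree.overlap(start, end):
                yield iv.data, max(0, min(end, iv.end) - max(start, iv.begin))

    def gene_overlaps(self, chrom: str, start: int, end: int, strand: str,
                      ignore_strand: bool = False) -> bool:
        keys = [(chrom, s) for s in ("+", "-")] if ignore_strand else [(chrom, strand)]
        return any(self._genes.get(key) is not None
                   and self._genes[key].overlaps(start, end) for key in keys)


@dataclass(frozen=True)
class BiotypeAssignment:
    gene_id: str | None
    biotype: str          # priority biotype, or 'unassigned'
    location: str         # exonic | intronic | intergenic


def assign_biotype(alignments: Sequence[tuple[str, int, int, str, int]],
                   annotation: GenomeAnnotation,
                   ignore_strand: bool = False) -> BiotypeAssignment:
    """Assign a genome-tier read pair to a gene by biotype priority.

    All exon features overlapped (>=1 bp, same strand unless
    ``ignore_strand``) by EITHER mate are pooled; the highest-priority
    biotype wins; within equal priority the gene with the largest total
    overlap, then the lexicographically smallest gene id. Pairs with no
    exonic overlap are 'unassigned' and located as intronic (inside a gene
    body) or intergenic.
    """
    overlap_by_gene: dict[str, int] = {}
    for chrom, start, end, strand, _mate in alignments:
        for gene_id, ov in annotation.exon_overlaps(chrom, start, end, strand,
                                                    ignore_strand):
            if ov > 0:
                overlap_by_gene[gene_id] = overlap_by_gene.get(gene_id, 0) + ov
    if overlap_by_gene:
        def key(gene_id: str):
            bt = annotation.gene_biotype[gene_id]
            return (BIOTYPE_PRIORITY.index(bt), -overlap_by_gene[gene_id], gene_id)
        winner = min(overlap_by_gene, key=key)
        return BiotypeAssignment(gene_id=winner,
                                 biotype=annotation.gene_biotype[winner],
                                 location="exonic")
    in_gene = any(annotation.gene_overlaps(c, s, e, st, ignore_strand)
                  for c, s, e, st, _m in alignments)
    return BiotypeAssignment(gene_id=None, biotype="unassigned",
                             location="intronic" if in_gene else "intergenic")


def count_bsj(bsj_alignments: Iterable[tuple[str, int, int]],
              junction_offsets: Mapping[str, int],
              min_anchor: int = 5) -> dict[str, int]:
    """Count reads supporting circRNA back-splice junctions.

    A read supports a junction iff its alignment interval covers the
    junction point with at least ``min_anchor`` aligned bases on each side
    (boundary inclusive). Alignments are (junction_id, start, length) in
    junction-reference coordinates.
    """
    if min_anchor < 1:
        raise ValueError("min_anchor must be >= 1")
    counts: dict[str, int] = {j: 0 for j in junction_offsets}
    for junction_id, start, length in bsj_alignments:
        off = junction_offsets.get(junction_id)
        if off is None:
            continue
        if start <= off - min_anchor and start + length >= off + min_anchor:
            counts[junction_id] += 1
    return counts


@dataclass
class AssignmentTable:
    """Resolved classes and gene-level counts for one sample."""

    per_read_class: dict[str, str]
    gene_table: pd.DataFrame          # index gene_id; columns biotype, reads, umis
    class_totals: dict[str, int]
    biotype_totals: dict[str, int]
    location_totals: dict[str, int]   # exonic / intronic / intergenic

    def validate(self) -> None:
        assert sum(self.class_totals.values()) == len(self.per_read_class)
        assert (self.gene_table[["reads", "umis"]] >= 0).all().all()


def build_assignment_table(evidences: Iterable[AlignmentEvidence],
                           annotation: GenomeAnnotation | None = None,
                           ignore_strand: bool = False) -> AssignmentTable:
    """Resolve each read through the tier hierarchy and, for genome-tier
    reads, assign genes by biotype priority. UMIs are taken from the
    ``_<UMI>`` read-name suffix when present (gene UMI counts are the
    number of distinct UMIs per gene)."""
    per_read: dict[str, str] = {}
    class_totals: dict[str, int] = {}
    biotype_totals: dict[str, int] = {}
    location_totals: dict[str, int] = {}
    gene_rows: dict[str, dict] = {}
    for ev in evidences:
        cls = resolve_hierarchy(ev)
        per_read[ev.read_id] = cls
        class_totals[cls] = class_totals.get(cls, 0) + 1
        if cls != "genome" or annotation is None:
            continue
        res = assign_biotype(ev.genome_alignments, annotation, ignore_strand)
        biotype_totals[res.biotype] = biotype_totals.get(res.biotype, 0) + 1
        location_totals[res.location] = location_totals.get(res.location, 0) + 1
        if res.gene_id is not None:
            row = gene_rows.setdefault(res.gene_id, {
                "biotype": res.biotype, "reads": 0, "umis": set()})
            row["reads"] += 1
            umi = ev.read_id.rsplit("_", 1)[-1] if "_" in ev.read_id else ev.read_id
            row["umis"].add(umi)
    gene_table = pd.DataFrame(
        [{"gene_id": g, "biotype": r["biotype"], "reads": r["reads"],
          "umis": len(r["umis"])} for g, r in sorted(gene_rows.items())],
        columns=["gene_id", "biotype", "reads", "umis"],
    ).set_index("gene_id")
    table = AssignmentTable(
        per_read_class=per_read, gene_table=gene_table,
        class_totals=class_totals, biotype_totals=biotype_totals,
        location_totals=location_totals,
    )
    table.validate()
    return table


def evidence_from_flag_table(path_or_df) -> list[AlignmentEvidence]:
    """Build evidence from a TSV flag table (read_id + one boolean column
    per tier) — the test-scale alternative to per-tier SAM input."""
    df = path_or_df if isinstance(path_or_df, pd.DataFrame) else \
        pd.read_csv(path_or_df, sep="\t")
    out = []
    for _, row in df.iterrows():
        flags = {t: bool(row[t]) for t in TIERS if t in df.columns}
        out.append(AlignmentEvidence(read_id=str(row["read_id"]), tier_flags=flags))
    return out


def evidence_from_sams(tier_paths: Mapping[str, str]) -> list[AlignmentEvidence]:
    """Build evidence from per-tier SAM/BAM files (primary alignments only).

    Mapped read names in each tier file set that tier's flag. For the
    genome tier, primary alignment intervals are collected per mate; for
    the circRNA tier, junction-reference alignments are collected as
    (junction id, start, aligned length).
    """
    import pysam
    ev: dict[str, AlignmentEvidence] = {}

    def get(read_id: str) -> AlignmentEvidence:
        if read_id not in ev:
            ev[read_id] = AlignmentEvidence(read_id=read_id)
        return ev[read_id]

    for tier in TIERS:
        path = tier_paths.get(tier)
        if path is None:
            continue
        mode = "rb" if str(path).endswith(".bam") else "r"
        with pysam.AlignmentFile(str(path), mode) as fh:
            for aln in fh:
                if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                    continue
                e = get(aln.query_name)
                e.tier_flags[tier] = True
                if tier == "genome":
                    mate = 2 if (aln.is_paired and aln.is_read2) else 1
                    e.genome_alignments.append((
                        aln.reference_name, aln.reference_start,
                        aln.reference_end, "-" if aln.is_reverse else "+", mate))
                elif tier == "circRNA":
                    e.bsj_alignments.append((
                        aln.reference_name, aln.reference_start,
                        aln.reference_end - aln.reference_start))
    return [ev[k] for k in sorted(ev)]


@dataclass
class ExpressionMatrix:
    """Gene x sample TPM with companion raw counts and effective lengths."""

    tpm: pd.DataFrame
    counts: pd.DataFrame
    lengths: pd.Series

    def validate(self) -> None:
        sums = self.tpm.sum(axis=0)
        nonzero = self.counts.sum(axis=0) > 0
        assert np.allclose(sums[nonzero], 1e6, atol=1e-3)


def compute_tpm(counts: pd.DataFrame, lengths: Mapping[str, float] | pd.Series,
                gene_classes: Mapping[str, str] | None = None,
                exclude: set[str] = frozenset({"rRNA", "mtRNA"})) -> ExpressionMatrix:
    """Transcripts per million with abundant classes removed first.

    ``counts`` is gene x sample; ``lengths`` are effective gene lengths in
    nt (> 0). Genes whose class (per ``gene_classes``) is in ``exclude``
    are dropped before normalisation, so the remaining TPM column sums to
    1e6. A sample with zero total expression yields an all-zero column.
    """
    lengths = pd.Series(lengths, dtype=float)
    if gene_classes:
        keep = [g for g in counts.index if gene_classes.get(g) not in exclude]
        counts = counts.loc[keep]
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = list(lengths[lengths.isna()].index)
        raise ValueError(f"missing effective length for genes: {missing}")
    if (lengths <= 0).any():
        raise ValueError("effective lengths must be positive")
    rate = counts.div(lengths, axis=0)
    denom = rate.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        tpm = rate.div(denom, axis=1) * 1e6
    tpm = tpm.fillna(0.0)
    for sample in counts.columns:
        if denom[sample] == 0:
            tpm[sample] = 0.0
    matrix = ExpressionMatrix(tpm=tpm, counts=counts.copy(), lengths=lengths)
    matrix.validate()
    return matrix


def filter_genes(matrix: ExpressionMatrix, tpm_threshold: float = 1.0,
                 sample_fraction: float = 0.5) -> list[str]:
    """Genes with TPM strictly above the threshold in at least the given
    fraction of samples (inclusive at exactly the boundary fraction)."""
    if matrix.tpm.shape[1] < 1:
        raise ValueError("need at least one sample")
    frac = (matrix.tpm > tpm_threshold).sum(axis=1) / matrix.tpm.shape[1]
    return list(matrix.tpm.index[frac >= sample_fraction])
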