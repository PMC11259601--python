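"""Inline sample barcodes and UMIs: code design, demultiplexing, dedup.

Early barcoding places a short sample barcode on the random primer and an
8-nt UMI on the template-switching oligo, so several samples can be pooled
into one library before amplification. The 4-nt barcode code has minimum
pairwise Hamming distance 3, which corrects any single sequencing error in
the barcode; UMIs identify original molecules so PCR duplicates can be
collapsed with the directional-network rule.
"""

from __future__ import annotations

import gzip
import json
from collections import Counter
from dataclasses import dataclass, replace
from itertools import product
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from cfdash._seq import hamming, revcomp


@dataclass(frozen=True)
class ReadLayout:
    """Where the barcode and UMI sit in a read pair.

    Default geometry: the sample barcode is the first ``barcode_len`` bases
    of mate 1 (random-primer side); the UMI is the first ``umi_len`` bases
    of mate 2 (template-switch side).
    """

    barcode_mate: int = 1
    barcode_offset: int = 0
    barcode_len: int = 4
    umi_mate: int = 2
    umi_offset: int = 0
    umi_len: int = 8


@dataclass(frozen=True)
class ReadRecord:
    """A read pair with optional extracted barcode / UMI."""

    id: str
    mate1: tuple[str, str]  # (sequence, quality)
    mate2: tuple[str, str]
    sample_barcode: str | None = None
    umi: str | None = None
    layout: ReadLayout = ReadLayout()

    def __post_init__(self):
        for mate in (self.mate1, self.mate2):
            if len(mate[0]) != len(mate[1]):
                raise ValueError(f"read {self.id!r}: quality length != sequence length")


@dataclass(frozen=True)
class BarcodeSet:
    """An error-correcting set of fixed-length sample barcodes."""

    barcodes: tuple[str, ...]
    length: int
    min_distance: int
    filters_applied: dict

    def __post_init__(self):
        for b in self.barcodes:
            if len(b) != self.length:
                raise ValueError("all barcodes must share the declared length")
        for i, a in enumerate(self.barcodes):
            for b in self.barcodes[i + 1:]:
                if hamming(a, b) < self.min_distance:
                    raise ValueError(
                        f"barcodes {a} and {b} violate min distance {self.min_distance}")


@dataclass
class MoleculeGroup:
    """UMI deduplication result for one (position, sample) group."""

    key: tuple
    members: list[tuple[str, int]]  # (umi, read count)
    n_molecules: int
    representatives: list[str]  # one UMI per inferred molecule

    def validate(self) -> None:
        assert self.n_molecules <= len(self.members) <= sum(c for _, c in self.members)


class ReadTooShortError(ValueError):
    """A mate is shorter than the span the layout requires."""


def design_barcodes(length: int = 4, min_distance: int = 3,
                    self_complementary: bool = True, triplet: bool = True,
                    gc_balance: tuple[int, int] | None = None) -> BarcodeSet:
    """Greedy lexicographic construction of a distance-``min_distance`` code.

    Candidates are all 4^length k-mers in lexicographic (ACGT) order; one is
    accepted iff it passes the enabled composition filters and is at Hamming
    distance >= min_distance from every barcode accepted so far. Filters:
    self-complementary (reverse complement equals the barcode itself),
    triplet (>=3 identical consecutive bases), GC balance (G+C count outside
    [1, length-1] by default, i.e. all-AT or all-GC barcodes are rejected).
    """
    if not 1 <= min_distance <= length:
        raise ValueError("require 1 <= min_distance <= length")
    if gc_balance is None:
        gc_balance = (1, length - 1)
    lo, hi = gc_balance
    accepted: list[str] = []
    for tup in product("ACGT", repeat=length):
        cand = "".join(tup)
        if self_complementary and revcomp(cand) == cand:
            continue
        if triplet and any(cand[i] == cand[i + 1] == cand[i + 2]
                           for i in range(length - 2)):
            continue
        gc = cand.count("G") + cand.count("C")
        if not lo <= gc <= hi:
            continue
        if all(hamming(cand, b) >= min_distance for b in accepted):
            accepted.append(cand)
    return BarcodeSet(
        barcodes=tuple(accepted), length=length, min_distance=min_distance,
        filters_applied={"self_complementary": self_complementary,
                         "triplet": triplet, "gc_balance": gc_balance},
    )


def decode_barcode(observed: str, barcodes: Sequence[str], max_mismatch: int = 1
                   ) -> str | None:
    """Return the unique barcode within ``max_mismatch`` of ``observed``,
    or None when no barcode — or, defensively, more than one — qualifies."""
    matches = [b for b in barcodes if hamming(observed, b) <= max_mismatch]
    return matches[0] if len(matches) == 1 else None


def demultiplex(reads: Iterable[ReadRecord],
                barcodes: BarcodeSet | Mapping[str, str],
                max_mismatch: int = 1,
                extract_umis: bool = True,
                ) -> tuple[dict[str, list[ReadRecord]], list[ReadRecord], dict]:
    """Assign reads to samples by inline barcode with single-error correction.

    ``barcodes`` is a BarcodeSet (samples named after their barcode) or a
    mapping sample_id -> barcode. A read is assigned to the unique barcode
    within ``max_mismatch`` of its observed barcode and has the barcode
    clipped; otherwise it goes to the unassigned stream. Reads too short for
    the declared barcode/UMI spans go to a too-short sink. Returns
    (per-sample reads, unassigned reads, counts).
    """
    if isinstance(barcodes, BarcodeSet):
        sample_of = {b: b for b in barcodes.barcodes}
        code = list(barcodes.barcodes)
        bc_len = barcodes.length
    else:
        sample_of = {bc: sid for sid, bc in barcodes.items()}
        code = list(sample_of)
        bc_len = len(code[0]) if code else 0
    if not code:
        raise ValueError("empty barcode set")
    if len({len(b) for b in code}) != 1:
        raise ValueError("barcodes of unequal length")

    assigned: dict[str, list[ReadRecord]] = {s: [] for s in sample_of.values()}
    unassigned: list[ReadRecord] = []
    counts = {"input": 0, "assigned": 0, "unassigned": 0, "too_short": 0,
              "per_sample": Counter()}
    for read in reads:
        counts["input"] += 1
        layout = read.layout
        if layout.barcode_len != bc_len:
            raise ValueError("layout barcode length does not match barcode set")
        mate_seq, mate_qual = read.mate1 if layout.barcode_mate == 1 else read.mate2
        lo = layout.barcode_offset
        hi = lo + bc_len
        if len(mate_seq) < hi:
            counts["too_short"] += 1
            continue
        observed = mate_seq[lo:hi]
        word = decode_barcode(observed, code, max_mismatch)
        if word is None:
            counts["unassigned"] += 1
            unassigned.append(read)
            continue
        clipped_seq = mate_seq[:lo] + mate_seq[hi:]
        clipped_qual = mate_qual[:lo] + mate_qual[hi:]
        new_mates = {"mate1": read.mate1, "mate2": read.mate2}
        new_mates[f"mate{layout.barcode_mate}"] = (clipped_seq, clipped_qual)
        out = replace(read, sample_barcode=word, **new_mates)
        if extract_umis:
            try:
                out = extract_umi(out)
            except ReadTooShortError:
                counts["too_short"] += 1
                continue
        sample = sample_of[word]
        assigned[sample].append(out)
        counts["assigned"] += 1
        counts["per_sample"][sample] += 1
    counts["per_sample"] = dict(counts["per_sample"])
    return assigned, unassigned, counts


def extract_umi(read: ReadRecord) -> ReadRecord:
    """Move the UMI from the read sequence into the read id (``<id>_<UMI>``).

    The UMI bases and their qualities are clipped from the declared mate.
    Raises ReadTooShortError when the mate is shorter than the UMI span.
    """
    layout = read.layout
    mate_seq, mate_qual = read.mate1 if layout.umi_mate == 1 else read.mate2
    lo = layout.umi_offset
    hi = lo + layout.umi_len
    if len(mate_seq) < hi:
        raise ReadTooShortError(
            f"read {read.id!r}: mate{layout.umi_mate} shorter than UMI span")
    umi = mate_seq[lo:hi]
    clipped = (mate_seq[:lo] + mate_seq[hi:], mate_qual[:lo] + mate_qual[hi:])
    new_mates = {"mate1": read.mate1, "mate2": read.mate2}
    new_mates[f"mate{layout.umi_mate}"] = clipped
    return replace(read, id=f"{read.id}_{umi}", umi=umi, **new_mates)


def _directional_components(counts: Mapping[str, int]) -> list[list[str]]:
    """Directional-network clustering of UMIs within one group.

    An edge a->b exists when Hamming(a, b) == 1 and count(a) >= 2*count(b)-1.
    Components are grown breadth-first from un-clustered UMIs in decreasing
    count order (ties broken lexicographically), following outgoing edges
    transitively — the de-facto standard duplicate-collapsing rule.
    """
    umis = sorted(counts, key=lambda u: (-counts[u], u))
    lengths = {len(u) for u in umis}
    if len(lengths) > 1:
        raise ValueError("UMIs of unequal length within one group")
    adj: dict[str, list[str]] = {u: [] for u in umis}
    for i, a in enumerate(umis):
        for b in umis:
            if a != b and hamming(a, b) == 1 and counts[a] >= 2 * counts[b] - 1:
                adj[a].append(b)
    visited: set[str] = set()
    components: list[list[str]] = []
    for seed in umis:
        if seed in visited:
            continue
        comp = [seed]
        visited.add(seed)
        queue = [seed]
        while queue:
            node = queue.pop(0)
            for nb in adj[node]:
                if nb not in visited:
                    visited.add(nb)
                    comp.append(nb)
                    queue.append(nb)
        components.append(comp)
    return components


def dedup_umis(groups: Mapping[tuple, Mapping[str, int] | Sequence[str]],
               method: str = "directional") -> list[MoleculeGroup]:
    """Collapse PCR duplicates within (position, sample) groups.

    ``groups`` maps a grouping key (alignment coordinate and sample; for
    unaligned tests an exact-sequence bucket) to either a Counter of
    UMI -> read count or a plain sequence of observed UMIs. Methods:

    - ``directional`` (default): connected components of the directional
      network (edge a->b iff distance 1 and count(a) >= 2*count(b)-1);
    - ``cluster``: components of the plain distance-1 graph;
    - ``unique``: every distinct UMI is its own molecule.

    One representative UMI (highest count, then lexicographically smallest)
    is retained per component.
    """
    out: list[MoleculeGroup] = []
    for key in sorted(groups, key=repr):
        raw = groups[key]
        counts = Counter(raw) if not isinstance(raw, Mapping) else dict(raw)
        if not counts:
            out.append(MoleculeGroup(key=key, members=[], n_molecules=0,
                                     representatives=[]))
            continue
        if method == "unique":
            comps = [[u] for u in sorted(counts)]
        elif method == "cluster":
            sym = {u: c for u, c in counts.items()}
            # symmetric distance-1 graph: same machinery with the count
            # condition always satisfied by making all counts equal
            comps = _directional_components({u: 1 for u in sym})
        elif method == "directional":
            comps = _directional_components(counts)
        else:
            raise ValueError(f"unknown dedup method {method!r}")
        reps = [min(comp, key=lambda u: (-counts[u], u)) for comp in comps]
        out.append(MoleculeGroup(
            key=key,
            members=sorted(counts.items()),
            n_molecules=len(comps),
            representatives=sorted(reps),
        ))
        out[-1].validate()
    return out


# ---------------------------------------------------------------------------
# File-level helpers (FASTQ / SAM plumbing used by the CLI)

def _open_maybe_gzip(path, mode="rt"):
    path = str(path)
    return gzip.open(path, mode) if path.endswith(".gz") else open(path, mode)


def read_fastq_pairs(fq1, fq2, layout: ReadLayout = ReadLayout()
                     ) -> Iterable[ReadRecord]:
    """Stream paired FASTQ files as ReadRecords."""
    from Bio.SeqIO.QualityIO import FastqGeneralIterator
    with _open_maybe_gzip(fq1) as h1, _open_maybe_gzip(fq2) as h2:
        for (id1, seq1, q1), (id2, seq2, q2) in zip(
                FastqGeneralIterator(h1), FastqGeneralIterator(h2)):
            rid = id1.split()[0]
            yield ReadRecord(id=rid, mate1=(seq1.upper(), q1),
                             mate2=(seq2.upper(), q2), layout=layout)


def write_fastq_pairs(reads: Sequence[ReadRecord], fq1, fq2) -> None:
    with _open_maybe_gzip(fq1, "wt") as h1, _open_maybe_gzip(fq2, "wt") as h2:
        for r in reads:
            h1.write(f"@{r.id}\n{r.mate1[0]}\n+\n{r.mate1[1]}\n")
            h2.write(f"@{r.id}\n{r.mate2[0]}\n+\n{r.mate2[1]}\n")


def demultiplex_fastq(fq1, fq2, barcodes: Mapping[str, str] | BarcodeSet,
                      outdir, max_mismatch: int = 1,
                      layout: ReadLayout = ReadLayout()) -> dict:
    """Demultiplex paired FASTQ into per-sample FASTQ pairs plus an
    unassigned pair; writes a JSON summary and returns the counts."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    reads = read_fastq_pairs(fq1, fq2, layout)
    assigned, unassigned, counts = demultiplex(reads, barcodes, max_mismatch)
    for sample, rs in assigned.items():
        write_fastq_pairs(rs, outdir / f"{sample}_R1.fq", outdir / f"{sample}_R2.fq")
    write_fastq_pairs(unassigned, outdir / "unassigned_R1.fq",
                      outdir / "unassigned_R2.fq")
    with open(outdir / "demux_summary.json", "w") as fh:
        json.dump(counts, fh, indent=2, sort_keys=True)
    return counts


def dedup_sam(in_path, out_path, method: str = "directional") -> dict:
    """Deduplicate an aligned SAM/BAM whose read names end in ``_<UMI>``.

    Reads are grouped by (reference, leftmost position, strand); one
    representative alignment per inferred molecule is written. Returns
    summary counts.
    """
    import pysam
    mode_in = "rb" if str(in_path).endswith(".bam") else "r"
    mode_out = "wb" if str(out_path).endswith(".bam") else "wh"
    groups: dict[tuple, Counter] = {}
    records: dict[tuple, dict[str, list]] = {}
    with pysam.AlignmentFile(str(in_path), mode_in) as inp:
        header = inp.header.to_dict()
        for aln in inp:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            if aln.is_paired and not aln.is_read1:
                continue  # one record per pair drives the grouping
            umi = aln.query_name.rsplit("_", 1)[-1]
            key = (aln.reference_name, aln.reference_start,
                   "-" if aln.is_reverse else "+")
            groups.setdefault(key, Counter())[umi] += 1
            records.setdefault(key, {}).setdefault(umi, []).append(aln.to_string())
    kept: list[str] = []
    n_molecules = 0
    for mg in dedup_umis(groups, method=method):
        n_molecules += mg.n_molecules
        for rep in mg.representatives:
            kept.append(records[mg.key][rep][0])
    n_input = sum(sum(c.values()) for c in groups.values())
    with pysam.AlignmentFile(str(out_path), mode_out,
                             header=pysam.AlignmentHeader.from_dict(header)) as out:
        hdr = pysam.AlignmentHeader.from_dict(header)
        for line in kept:
            out.write(pysam.AlignedSegment.fromstring(line, hdr))
    return {"n_input": n_input, "n_molecules": n_molecules,
            "n_positions": len(groups)}
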