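"""Synthetic inputs for every stage of the toolkit.

Generates depletion targets, fragmented cfRNA libraries with a realistic
class composition (~92% rRNA+mtRNA, emulating untreated plasma libraries)
and bounded fragment lengths (20-200 nt, log-normal mode near 100 nt),
barcoded/UMI-tagged paired reads with controlled substitution errors and
PCR duplication, toy GENCODE-dialect annotations with back-splice-junction
references, and UMI group simulations for dedup benchmarking. Everything
is deterministic per seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from cfdash._seq import revcomp
from cfdash.barcode_umi import ReadLayout, ReadRecord
from cfdash.depletion_sim import Fragment
from cfdash.guide_design import TargetSet

BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class LibrarySpec:
    """Composition and fragment-length profile of a synthetic cfRNA library.

    Defaults emulate an untreated plasma library: rRNA+mtRNA ~92% of
    fragments, ~4% genome (mRNA/lncRNA), the remainder split over other
    classes; lengths are log-normal, clipped to [20, 200] nt.
    """

    composition: Mapping[str, float] = field(default_factory=lambda: {
        "rRNA": 0.80, "mtRNA": 0.12, "genome": 0.04,
        "circRNA": 0.02, "spikein": 0.01, "univec": 0.005, "microbial": 0.005,
    })
    length_min: int = 20
    length_max: int = 200
    length_log_mean: float = 4.6   # exp(4.6) ~ 100 nt
    length_log_sd: float = 0.35
    n_fragments: int = 10_000
    seed: int = 0

    def __post_init__(self):
        total = sum(self.composition.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"composition fractions sum to {total}, not 1")
        if not 0 < self.length_min <= self.length_max:
            raise ValueError("invalid fragment length bounds")


@dataclass(frozen=True)
class ReadSimSpec:
    """Read-simulation parameters: sample mix, UMI geometry, error model."""

    sample_barcodes: Mapping[str, str] = field(default_factory=dict)
    umi_len: int = 8
    read_len: int = 75
    error_rate: float = 0.0
    duplication_min: int = 1
    duplication_max: int = 1
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.error_rate < 1:
            raise ValueError("error rate must be in [0, 1)")
        if not 1 <= self.duplication_min <= self.duplication_max:
            raise ValueError("duplication factors must be >= 1")


def random_sequence(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(BASES, size=length, p=probs))


def make_targets(n: int, lengths: Sequence[int], gc: float = 0.5,
                 seed: int = 0, class_label: str = "rRNA",
                 prefix: str = "target") -> TargetSet:
    """Seeded random depletion targets with the requested GC content."""
    if not 0 < gc < 1:
        raise ValueError("gc fraction must be in (0, 1)")
    for L in lengths:
        if L < 100:
            raise ValueError("target lengths must be >= 100")
    rng = np.random.default_rng(seed)
    entries = []
    for i in range(n):
        L = lengths[i % len(lengths)]
        entries.append((f"{prefix}{i + 1}", random_sequence(rng, L, gc), class_label))
    return TargetSet(entries=tuple(entries))


def make_tileable_targets(n: int, length: int, site_interval: int = 40,
                          seed: int = 0, class_label: str = "rRNA",
                          prefix: str = "target") -> TargetSet:
    """Targets guaranteed to support a <=50-bp cut tiling.

    Real rRNA/mtRNA references carry dense NGG sites, but purely random
    sequence occasionally has a PAM desert longer than the tile interval.
    This constructor emulates the dense case: every ``site_interval`` bases
    it plants a structurally clean 20-nt protospacer followed by AGG, with
    random filler between sites, so an eligible cut exists every
    ``site_interval`` bp by construction.
    """
    from cfdash.guide_design import GuideCandidate, structural_filter
    if site_interval < 40:
        raise ValueError("site_interval must be >= 40 (23-nt site + filler)")
    rng = np.random.default_rng(seed)

    def clean_protospacer() -> str:
        while True:
            proto = random_sequence(rng, 20)
            probe = GuideCandidate(target_id="x", strand="+", start=0,
                                   protospacer=proto, pam="AGG", cut_pos=0)
            if not structural_filter(probe).fail_reasons:
                return proto

    entries = []
    for i in range(n):
        blocks = []
        filled = 0
        while filled + site_interval <= length:
            filler = random_sequence(rng, site_interval - 23)
            blocks.append(filler + clean_protospacer() + "AGG")
            filled += site_interval
        blocks.append(random_sequence(rng, length - filled))
        entries.append((f"{prefix}{i + 1}", "".join(blocks), class_label))
    return TargetSet(entries=tuple(entries))


def write_targets_fasta(targets: TargetSet, path) -> None:
    with open(path, "w") as fh:
        for tid, seq, label in targets.entries:
            fh.write(f">{tid} class={label}\n{seq}\n")


def make_library(sources: Mapping[str, Sequence[str]], spec: LibrarySpec
                 ) -> list[Fragment]:
    """Draw fragments uniformly from per-class source sequences.

    ``sources`` maps each class in the composition to one or more source
    sequences; fragment start positions are uniform along the chosen
    source, lengths log-normal clipped to the declared bounds (and to the
    source length). Class labels are embedded in fragment ids/headers.
    """
    for cls in spec.composition:
        if spec.composition[cls] > 0 and not sources.get(cls):
            raise ValueError(f"composition class {cls!r} has no source sequences")
    rng = np.random.default_rng(spec.seed)
    classes = sorted(c for c in spec.composition if spec.composition[c] > 0)
    probs = np.array([spec.composition[c] for c in classes], dtype=float)
    probs /= probs.sum()
    fragments: list[Fragment] = []
    for i in range(spec.n_fragments):
        cls = classes[rng.choice(len(classes), p=probs)]
        seqs = sources[cls]
        src = seqs[rng.integers(len(seqs))]
        L = int(np.clip(round(rng.lognormal(spec.length_log_mean, spec.length_log_sd)),
                        spec.length_min, spec.length_max))
        L = min(L, len(src))
        start = int(rng.integers(0, len(src) - L + 1))
        fragments.append(Fragment(id=f"frag{i + 1}", sequence=src[start:start + L],
                                  true_class=cls))
    return fragments


def write_fragments_fasta(fragments: Sequence[Fragment], path) -> None:
    with open(path, "w") as fh:
        for f in fragments:
            label = f" class={f.true_class}" if f.true_class else ""
            fh.write(f">{f.id}{label}\n{f.sequence}\n")


def _with_errors(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    chars = list(seq)
    for i, b in enumerate(chars):
        if b in "ACGT" and rng.random() < rate:
            chars[i] = rng.choice([x for x in "ACGT" if x != b])
    return "".join(chars)


def make_reads(fragments: Sequence[Fragment], spec: ReadSimSpec
               ) -> tuple[list[ReadRecord], pd.DataFrame]:
    """Simulate barcoded, UMI-tagged paired reads from fragments.

    Each fragment is assigned a sample (round-robin over the barcode set)
    and a UMI per original molecule; PCR duplicates replicate the same UMI.
    Mate 1 = barcode + fragment 5' sequence; mate 2 = UMI + reverse
    complement of the fragment 3' end. Substitution errors are applied at
    the declared rate across all read bases (barcode and UMI included).
    Returns the reads plus a ground-truth table (read_id -> sample, umi,
    fragment, class).
    """
    if not spec.sample_barcodes:
        raise ValueError("read simulation requires at least one sample barcode")
    rng = np.random.default_rng(spec.seed)
    samples = sorted(spec.sample_barcodes)
    bc_len = len(next(iter(spec.sample_barcodes.values())))
    layout = ReadLayout(barcode_len=bc_len, umi_len=spec.umi_len)
    reads: list[ReadRecord] = []
    truth_rows = []
    counter = 0
    for fi, frag in enumerate(fragments):
        sample = samples[fi % len(samples)]
        barcode = spec.sample_barcodes[sample]
        umi = random_sequence(rng, spec.umi_len)
        n_copies = int(rng.integers(spec.duplication_min, spec.duplication_max + 1))
        insert = frag.sequence
        r1_payload = insert[:spec.read_len - bc_len]
        r2_payload = revcomp(insert)[:spec.read_len - spec.umi_len]
        for _copy in range(n_copies):
            counter += 1
            rid = f"read{counter}"
            seq1 = _with_errors(rng, barcode + r1_payload, spec.error_rate)
            seq2 = _with_errors(rng, umi + r2_payload, spec.error_rate)
            reads.append(ReadRecord(
                id=rid, mate1=(seq1, "I" * len(seq1)), mate2=(seq2, "I" * len(seq2)),
                layout=layout))
            truth_rows.append({"read_id": rid, "sample": sample, "umi": umi,
                               "fragment": frag.id, "true_class": frag.true_class})
    truth = pd.DataFrame(truth_rows,
                         columns=["read_id", "sample", "umi", "fragment", "true_class"])
    return reads, truth


def simulate_umi_groups(n_positions: int, molecules_per_position: int,
                        umi_len: int = 8, duplication_max: int = 20,
                        error_rate: float = 0.0, seed: int = 0
                        ) -> tuple[dict[tuple, list[str]], int]:
    """Simulate UMI observations for dedup benchmarking.

    Per position, ``molecules_per_position`` true molecules receive UMIs
    drawn uniformly without replacement, rejecting draws within Hamming
    distance 1 of an existing UMI at that position so the ground-truth
    molecule count is unambiguous (distance-1 UMIs are exactly what
    directional dedup is meant to merge). Each molecule is observed
    1..duplication_max times (uniform), each observation independently
    corrupted per base at ``error_rate``. Returns (groups keyed by
    position, total true molecules).
    """
    rng = np.random.default_rng(seed)
    groups: dict[tuple, list[str]] = {}
    total = n_positions * molecules_per_position
    for pos in range(n_positions):
        true_umis: list[str] = []
        while len(true_umis) < molecules_per_position:
            cand = random_sequence(rng, umi_len)
            if all(sum(a != b for a, b in zip(cand, u)) > 1 for u in true_umis):
                true_umis.append(cand)
        observed: list[str] = []
        for umi in true_umis:
            for _ in range(int(rng.integers(1, duplication_max + 1))):
                observed.append(_with_errors(rng, umi, error_rate))
        groups[("pos", pos)] = observed
    return groups, total


def make_annotation(genome_length: int,
                    genes: Sequence[tuple[str, str, int, int, str]],
                    chrom: str = "chr1"):
    """Build a toy annotation plus GTF text.

    ``genes`` rows are (gene_id, biotype, start, end, strand) with 0-based
    half-open intervals; each gene gets one gene record and one exon
    record. Returns (GenomeAnnotation, gtf_text). Duplicate gene ids are
    rejected.
    """
    from cfdash.read_assignment import GenomeAnnotation
    ids = [g[0] for g in genes]
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate gene ids in annotation")
    ann = GenomeAnnotation()
    lines = []
    for gene_id, biotype, start, end, strand in genes:
        if not 0 <= start < end <= genome_length:
            raise ValueError(f"gene {gene_id} interval outside genome")
        ann.add_gene(chrom, start, end, strand, gene_id, biotype)
        attrs = f'gene_id "{gene_id}"; gene_type "{biotype}";'
        for feature in ("gene", "exon"):
            lines.append("\t".join([chrom, "cfdash", feature, str(start + 1),
                                    str(end), ".", strand, ".", attrs]))
    return ann, "\n".join(lines) + "\n"


def make_bsj_reference(circ_sources: Mapping[str, str], flank: int = 50,
                       seed: int = 0) -> tuple[dict[str, str], dict[str, int]]:
    """Back-splice-junction references for circRNA counting.

    For each circular source sequence the junction reference is the last
    ``flank`` bases joined head-to-tail to the first ``flank`` bases, with
    the junction point at offset ``flank``. Returns (junction sequences,
    junction offsets).
    """
    seqs: dict[str, str] = {}
    offsets: dict[str, int] = {}
    for name, seq in circ_sources.items():
        if len(seq) < 2 * flank:
            raise ValueError(f"circRNA source {name!r} shorter than 2*flank")
        jid = f"{name}_bsj"
        seqs[jid] = seq[-flank:] + seq[:flank]
        offsets[jid] = flank
    return seqs, offsets


def write_gtf(gtf_text: str, path) -> None:
    Path(path).write_text(gtf_text)
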