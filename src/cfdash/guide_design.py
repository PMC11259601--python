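"""sgRNA pool design for DASH-style depletion of abundant cfRNA sequences.

The goal is a pool of SpCas9 guides whose cut sites tile the ribosomal and
mitochondrial RNA reference sequences roughly every ``tile_interval`` (50 bp
by default), so that any cDNA insert longer than ~2 tile intervals derived
from those targets is guaranteed to contain a cleavable site and is removed
from the library between amplification stages.

The design proceeds in four steps:

1. :func:`scan_candidates` enumerates every protospacer+PAM site on both
   strands of every target.
2. :func:`structural_filter` flags guides likely to fold or synthesise badly
   (extreme GC, homopolymers, dinucleotide repeats, terminal hairpins).
3. :func:`score_guides` counts exact on-target occurrences and exact hits
   against an off-target background index (:func:`build_offtarget_index`).
4. :func:`select_tiling_pool` greedily picks cut sites left-to-right so that
   consecutive cuts are at most ``tile_interval`` apart wherever eligible
   candidates permit, fills residual gaps and SNP positions, and reports any
   region that remains uncovered.

All coordinates are 0-based; intervals are half-open; minus-strand
protospacers are reported 5'->3' on their own strand.
"""

from __future__ import annotations

import bisect
import json
from collections import Counter
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

from cfdash._seq import (
    gc_count,
    hamming,
    matches_iupac,
    max_dinucleotide_repeats,
    max_homopolymer_run,
    revcomp,
    revcomp_iupac,
    validate_nucleotides,
)

# T7 RNA polymerase promoter; transcription starts at the final G.
T7_PROMOTER = "TAATACGACTCACTATAG"
# Canonical SpCas9 sgRNA scaffold appended 3' of the spacer.
SGRNA_SCAFFOLD = (
    "GTTTTAGAGCTAGAAATAGCAAGTTAAAATAAGGCTAGTCCGTTATCAACTTGAAAAAGTGGCACCGAGTCGGTGCTTTT"
)

FAIL_REASONS = {"gc_high", "gc_low", "homopolymer", "dinucleotide_repeat", "hairpin"}


@dataclass(frozen=True)
class TargetSet:
    """Named depletion-target sequences with class labels and optional SNPs.

    Parameters
    ----------
    entries : list of (id, sequence, class_label)
        class_label is one of ``rRNA``, ``mtRNA`` or ``custom``.
    variants : list of (target_id, position), optional
        0-based SNP positions that the pool should place a cut near.
    """

    entries: tuple[tuple[str, str, str], ...]
    variants: tuple[tuple[str, int], ...] = ()

    def __post_init__(self):
        ids = [e[0] for e in self.entries]
        if len(ids) != len(set(ids)):
            raise ValueError("target ids must be unique")
        lengths = {}
        for tid, seq, label in self.entries:
            validate_nucleotides(seq, name=f"target {tid!r}")
            if label not in {"rRNA", "mtRNA", "custom"}:
                raise ValueError(f"unknown class label {label!r} for target {tid!r}")
            lengths[tid] = len(seq)
        for tid, pos in self.variants:
            if tid not in lengths:
                raise ValueError(f"variant references unknown target {tid!r}")
            if not 0 <= pos < lengths[tid]:
                raise ValueError(f"variant position {pos} outside target {tid!r}")

    @classmethod
    def from_fasta(cls, path, class_label: str = "custom",
                   variants: Sequence[tuple[str, int]] = ()) -> "TargetSet":
        """Load targets from FASTA. A ``class=`` token in the description
        overrides ``class_label`` per record."""
        entries = []
        for rec in SeqIO.parse(str(path), "fasta"):
            label = class_label
            for token in rec.description.split():
                if token.startswith("class="):
                    label = token.split("=", 1)[1]
            entries.append((rec.id, str(rec.seq).upper(), label))
        return cls(entries=tuple(entries), variants=tuple(variants))

    def sequence(self, target_id: str) -> str:
        for tid, seq, _ in self.entries:
            if tid == target_id:
                return seq
        raise KeyError(target_id)

    def class_of(self, target_id: str) -> str:
        for tid, _, label in self.entries:
            if tid == target_id:
                return label
        raise KeyError(target_id)


@dataclass(frozen=True)
class DesignParams:
    """Tunable guide-design parameters.

    Defaults follow common DASH practice: 20-nt protospacer with NGG PAM,
    cut sites every <=50 bp, GC between 5/20 and 15/20, homopolymer runs
    <=5, dinucleotide units repeated <=3 times, hairpin stems of 5 nt
    searched within 8-nt terminal windows, zero tolerated off-target hits,
    blunt cut 3 bp 5' of the PAM.
    """

    protospacer_len: int = 20
    pam: str = "NGG"
    tile_interval: int = 50
    gc_min: int = 5
    gc_max: int = 15
    homopolymer_max: int = 5
    dinucleotide_max_repeats: int = 3
    hairpin_stem: int = 5
    hairpin_window: int = 8
    offtarget_max_hits: int = 0
    offtarget_max_mismatches: int = 0
    cut_offset: int = 3

    def __post_init__(self):
        if not (0 < self.gc_min <= self.gc_max <= self.protospacer_len):
            raise ValueError("require 0 < gc_min <= gc_max <= protospacer_len")
        if self.tile_interval <= 0:
            raise ValueError("tile_interval must be positive")
        if not 0 <= self.cut_offset < self.protospacer_len:
            raise ValueError("cut_offset must lie within the protospacer")
        for code in self.pam:
            if code not in "ACGTRYSWKMBDHVN":
                raise ValueError(f"invalid IUPAC code {code!r} in PAM pattern")


@dataclass(frozen=True)
class GuideCandidate:
    """A scanned protospacer+PAM site.

    ``start`` is the plus-strand coordinate of the protospacer's 5' end
    (for minus-strand guides this is the rightmost base of the occupied
    interval). ``cut_pos`` is the plus-strand coordinate of the first base
    3' of the blunt cut. ``protospacer`` and ``pam`` are 5'->3' on the
    guide's own strand.
    """

    target_id: str
    strand: str
    start: int
    protospacer: str
    pam: str
    cut_pos: int
    fail_reasons: frozenset[str] = frozenset()
    on_target_score: int = 0
    off_target_hits: int = 0

    @property
    def interval(self) -> tuple[int, int]:
        """Plus-strand half-open interval occupied by the protospacer."""
        w = len(self.protospacer)
        left = self.start if self.strand == "+" else self.start - w + 1
        return (left, left + w)

    @property
    def passes_structure(self) -> bool:
        return not self.fail_reasons


@dataclass(frozen=True)
class TargetCoverage:
    cut_positions: tuple[int, ...]
    max_gap: int
    uncovered: tuple[tuple[int, int], ...]
    uncovered_variants: tuple[int, ...] = ()


@dataclass
class GuidePool:
    """Selected tiling pool with per-target coverage accounting."""

    selected: list[GuideCandidate]
    params: DesignParams
    coverage: dict[str, TargetCoverage]
    provenance: list[str]  # parallel to `selected`: tiling | gap_fill | variant_fill

    def validate(self) -> None:
        """Assert pool invariants; raises AssertionError on violation."""
        assert len(self.selected) == len(self.provenance)
        for g in self.selected:
            assert not g.fail_reasons, f"selected guide with fail_reasons {g.fail_reasons}"
            assert g.off_target_hits <= self.params.offtarget_max_hits
        by_target: dict[str, list[int]] = {}
        for g in self.selected:
            by_target.setdefault(g.target_id, []).append(g.cut_pos)
        for tid, cuts in by_target.items():
            assert all(a < b for a, b in zip(cuts, cuts[1:])), \
                f"cut positions not strictly increasing for {tid}"
            assert tuple(cuts) == self.coverage[tid].cut_positions

    def guides_for(self, target_id: str) -> list[GuideCandidate]:
        return [g for g in self.selected if g.target_id == target_id]


def _scan_sites(seq: str, params: DesignParams):
    """Yield (strand, left, protospacer, pam_seq) for every full-length
    protospacer immediately followed 3' by a PAM match, on both strands.
    ``left`` is the plus-strand leftmost coordinate of the protospacer.
    Sites containing N anywhere in protospacer or PAM are skipped.
    """
    w = params.protospacer_len
    p = len(params.pam)
    rc_pam = revcomp_iupac(params.pam)
    n = len(seq)
    # plus strand: protospacer [i, i+w), PAM [i+w, i+w+p)
    for i in range(0, n - w - p + 1):
        proto = seq[i:i + w]
        pam_seq = seq[i + w:i + w + p]
        if "N" in proto or "N" in pam_seq:
            continue
        if matches_iupac(pam_seq, params.pam):
            yield ("+", i, proto, pam_seq)
    # minus strand: protospacer occupies plus [a, a+w), PAM plus [a-p, a)
    for a in range(p, n - w + 1):
        plus_proto = seq[a:a + w]
        plus_pam = seq[a - p:a]
        if "N" in plus_proto or "N" in plus_pam:
            continue
        if matches_iupac(plus_pam, rc_pam):
            yield ("-", a, revcomp(plus_proto), revcomp(plus_pam))


def scan_candidates(targets: TargetSet, params: DesignParams | None = None) -> list[GuideCandidate]:
    """Enumerate every protospacer+PAM site on both strands of every target.

    The blunt cut coordinate is ``cut_offset`` bases 5' of the PAM (between
    protospacer positions 17 and 18 for the defaults), mapped to plus-strand
    coordinates. Output is ordered by (target_id, start, strand).
    """
    params = params or DesignParams()
    w = params.protospacer_len
    out: list[GuideCandidate] = []
    for tid, seq, _label in targets.entries:
        for strand, left, proto, pam_seq in _scan_sites(seq, params):
            if strand == "+":
                start = left
                cut = left + w - params.cut_offset
            else:
                start = left + w - 1
                cut = left + params.cut_offset
            out.append(GuideCandidate(
                target_id=tid, strand=strand, start=start,
                protospacer=proto, pam=pam_seq, cut_pos=cut,
            ))
    out.sort(key=lambda g: (g.target_id, g.start, g.strand))
    return out


def structural_filter(candidate: GuideCandidate, params: DesignParams | None = None) -> GuideCandidate:
    """Annotate a candidate with structural failure reasons (never drops it).

    Rules: GC count outside [gc_min, gc_max]; a single-base run longer than
    homopolymer_max; a dinucleotide unit XY (X != Y) repeated consecutively
    more than dinucleotide_max_repeats times; a hairpin, i.e. the reverse
    complement of some hairpin_stem-length substring of the first
    hairpin_window bases occurring within the last hairpin_window bases.
    """
    params = params or DesignParams()
    proto = candidate.protospacer
    reasons = set()
    gc = gc_count(proto)
    if gc > params.gc_max:
        reasons.add("gc_high")
    if gc < params.gc_min:
        reasons.add("gc_low")
    if max_homopolymer_run(proto) > params.homopolymer_max:
        reasons.add("homopolymer")
    if max_dinucleotide_repeats(proto) > params.dinucleotide_max_repeats:
        reasons.add("dinucleotide_repeat")
    prefix = proto[:params.hairpin_window]
    suffix = proto[-params.hairpin_window:]
    stem = params.hairpin_stem
    for i in range(len(prefix) - stem + 1):
        if revcomp(prefix[i:i + stem]) in suffix:
            reasons.add("hairpin")
            break
    return replace(candidate, fail_reasons=frozenset(reasons))


class OfftargetIndex:
    """Exact-lookup index of protospacer sites in a background sequence set.

    Stores a count per protospacer of sites where that 20-mer is immediately
    followed 3' by a PAM match, on either strand of the background. Queries
    are exact by default; ``max_mismatches=1`` additionally sums counts of
    all single-mismatch protospacer variants.
    """

    def __init__(self, counts: Counter, params: DesignParams):
        self._counts = counts
        self.params = params

    @classmethod
    def from_sequences(cls, sequences: Iterable[tuple[str, str]],
                       params: DesignParams | None = None) -> "OfftargetIndex":
        params = params or DesignParams()
        counts: Counter = Counter()
        empty = True
        for name, seq in sequences:
            empty = False
            validate_nucleotides(seq, name=f"background {name!r}")
            for _strand, _left, proto, _pam in _scan_sites(seq, params):
                counts[proto] += 1
        if empty:
            raise ValueError("background is empty: no sequences to index")
        return cls(counts, params)

    @classmethod
    def from_fasta(cls, path, params: DesignParams | None = None) -> "OfftargetIndex":
        records = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]
        if not records:
            raise ValueError(f"unreadable or empty background FASTA: {path}")
        return cls.from_sequences(records, params)

    def query(self, protospacer: str, max_mismatches: int = 0) -> int:
        if max_mismatches == 0:
            return self._counts.get(protospacer, 0)
        if max_mismatches == 1:
            total = self._counts.get(protospacer, 0)
            for i, base in enumerate(protospacer):
                for alt in "ACGT":
                    if alt != base:
                        total += self._counts.get(
                            protospacer[:i] + alt + protospacer[i + 1:], 0)
            return total
        # fall back to a full scan for larger mismatch budgets
        return sum(c for p, c in self._counts.items()
                   if hamming(p, protospacer) <= max_mismatches)


def build_offtarget_index(background, params: DesignParams | None = None) -> OfftargetIndex:
    """Build an :class:`OfftargetIndex` from a FASTA path or (id, seq) pairs."""
    if isinstance(background, (str, Path)):
        return OfftargetIndex.from_fasta(background, params)
    return OfftargetIndex.from_sequences(background, params)


def score_guides(candidates: Sequence[GuideCandidate], targets: TargetSet,
                 index: OfftargetIndex | None = None,
                 params: DesignParams | None = None) -> list[GuideCandidate]:
    """Attach on-target occurrence counts and off-target hit counts.

    on_target_score counts exact protospacer+PAM occurrences across the
    whole target set (>1 rewards guides hitting repeated regions);
    off_target_hits is the background index count for the protospacer.
    """
    params = params or DesignParams()
    on_counts: Counter = Counter()
    for _tid, seq, _label in targets.entries:
        for _strand, _left, proto, _pam in _scan_sites(seq, params):
            on_counts[proto] += 1
    mm = params.offtarget_max_mismatches
    out = []
    for c in candidates:
        off = index.query(c.protospacer, max_mismatches=mm) if index is not None else 0
        out.append(replace(c, on_target_score=on_counts[c.protospacer],
                           off_target_hits=off))
    return out


def _best_at_cut(cands: list[GuideCandidate]) -> GuideCandidate:
    # tie-break: higher on-target, lower off-target, smaller start, + before -
    return min(cands, key=lambda g: (-g.on_target_score, g.off_target_hits,
                                     g.start, 0 if g.strand == "+" else 1))


def select_tiling_pool(candidates: Sequence[GuideCandidate], targets: TargetSet,
                       params: DesignParams | None = None) -> GuidePool:
    """Greedy left-to-right tiling selection over eligible candidates.

    Per target: repeatedly select the eligible candidate whose cut position
    is the largest not exceeding ``last_cut + tile_interval`` (first pick:
    <= tile_interval). When no candidate falls in the window but candidates
    remain further right, the gap is recorded as uncovered and the sweep
    restarts at the next eligible cut (provenance ``gap_fill``). Afterwards
    each declared SNP position must have a cut within ``tile_interval/2``;
    if not, the nearest eligible candidate within that radius is added
    (provenance ``variant_fill``), else the variant is reported uncovered.

    Deterministic for fixed input; ties at one cut position are broken by
    higher on-target score, lower off-target hits, smaller start, + before -.
    """
    params = params or DesignParams()
    tile = params.tile_interval
    selected: list[GuideCandidate] = []
    provenance: list[str] = []
    coverage: dict[str, TargetCoverage] = {}
    variants_by_target: dict[str, list[int]] = {}
    for tid, pos in targets.variants:
        variants_by_target.setdefault(tid, []).append(pos)

    for tid, seq, _label in targets.entries:
        tlen = len(seq)
        eligible = [c for c in candidates
                    if c.target_id == tid and not c.fail_reasons
                    and c.off_target_hits <= params.offtarget_max_hits]
        by_cut: dict[int, list[GuideCandidate]] = {}
        for c in eligible:
            by_cut.setdefault(c.cut_pos, []).append(c)
        cuts = sorted(by_cut)

        chosen: list[tuple[GuideCandidate, str]] = []
        uncovered: list[tuple[int, int]] = []
        last: int | None = None
        i = 0  # index of first cut > last
        while i < len(cuts):
            window_hi = tile if last is None else last + tile
            j = bisect.bisect_right(cuts, window_hi) - 1
            if j >= i:
                cut = cuts[j]
                chosen.append((_best_at_cut(by_cut[cut]), "tiling"))
                last = cut
                i = j + 1
            else:
                gap_start = 0 if last is None else last
                nxt = cuts[i]
                uncovered.append((gap_start, nxt))
                chosen.append((_best_at_cut(by_cut[nxt]), "gap_fill"))
                last = nxt
                i += 1
        if last is None:
            if tlen > 0:
                uncovered.append((0, tlen))
        elif tlen - last > tile:
            uncovered.append((last, tlen))

        # variant (SNP) proximity fill
        half = tile / 2
        sel_cuts = sorted(g.cut_pos for g, _ in chosen)
        uncovered_variants: list[int] = []
        for v in sorted(variants_by_target.get(tid, [])):
            if any(abs(c - v) <= half for c in sel_cuts):
                continue
            near = [c for c in cuts if abs(c - v) <= half]
            if near:
                cut = min(near, key=lambda c: (abs(c - v), c))
                chosen.append((_best_at_cut(by_cut[cut]), "variant_fill"))
                sel_cuts.append(cut)
                sel_cuts.sort()
            else:
                uncovered_variants.append(v)

        chosen.sort(key=lambda item: item[0].cut_pos)
        cuts_final = tuple(g.cut_pos for g, _ in chosen)
        if cuts_final:
            gaps = [cuts_final[0]] + [b - a for a, b in zip(cuts_final, cuts_final[1:])] \
                + [tlen - cuts_final[-1]]
            max_gap = max(gaps)
        else:
            max_gap = tlen
        coverage[tid] = TargetCoverage(
            cut_positions=cuts_final, max_gap=max_gap,
            uncovered=tuple(uncovered),
            uncovered_variants=tuple(uncovered_variants),
        )
        for g, prov in chosen:
            selected.append(g)
            provenance.append(prov)

    pool = GuidePool(selected=selected, params=params,
                     coverage=coverage, provenance=provenance)
    pool.validate()
    return pool


def design_pool(targets: TargetSet, background=None,
                params: DesignParams | None = None) -> GuidePool:
    """Convenience end-to-end design: scan, filter, score, select."""
    params = params or DesignParams()
    cands = [structural_filter(c, params) for c in scan_candidates(targets, params)]
    index = build_offtarget_index(background, params) if background is not None else None
    cands = score_guides(cands, targets, index, params)
    return select_tiling_pool(cands, targets, params)


def export_guides(pool: GuidePool, promoter: str = T7_PROMOTER,
                  scaffold: str = SGRNA_SCAFFOLD) -> dict:
    """Build the oligo/export tables for a pool.

    Returns a dict with:

    - ``table``: one row per guide (target_id, strand, start, end,
      protospacer, pam, cut_pos, on_target_score, off_target_hits,
      provenance, prepended_g) where start/end are the plus-strand
      half-open protospacer interval;
    - ``bed``: BED6 rows (chrom, start, end, name, score, strand);
    - ``templates``: (name, sequence, prepended_g) in-vitro-transcription
      templates promoter + spacer + scaffold, with a single G prepended when
      the spacer does not begin with G (T7 initiation requires a 5' G).
    """
    rows = []
    bed = []
    templates = []
    for g, prov in zip(pool.selected, pool.provenance):
        left, right = g.interval
        name = f"{g.target_id}_{left}_{g.strand}"
        spacer = g.protospacer
        prepended = not spacer.startswith("G")
        template = promoter + ("G" if prepended else "") + spacer + scaffold
        rows.append({
            "target_id": g.target_id, "strand": g.strand,
            "start": left, "end": right,
            "protospacer": g.protospacer, "pam": g.pam, "cut_pos": g.cut_pos,
            "on_target_score": g.on_target_score,
            "off_target_hits": g.off_target_hits,
            "provenance": prov, "prepended_g": prepended,
        })
        bed.append({"chrom": g.target_id, "start": left, "end": right,
                    "name": name, "score": g.on_target_score, "strand": g.strand})
        templates.append((name, template, prepended))
    return {"table": rows, "bed": bed, "templates": templates}


GUIDE_TSV_COLUMNS = ["target_id", "strand", "start", "end", "protospacer", "pam",
                     "cut_pos", "on_target_score", "off_target_hits",
                     "provenance", "prepended_g"]


def write_design_outputs(pool: GuidePool, outdir,
                         promoter: str = T7_PROMOTER,
                         scaffold: str = SGRNA_SCAFFOLD) -> dict:
    """Write guides.tsv, guides.bed, templates.fa and design_report.json.

    Returns the design report (per-target gap statistics, provenance counts,
    warnings for residual uncovered regions). Empty pools produce files with
    headers only.
    """
    import pandas as pd
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    exported = export_guides(pool, promoter, scaffold)
    df = pd.DataFrame(exported["table"], columns=GUIDE_TSV_COLUMNS)
    df.to_csv(outdir / "guides.tsv", sep="\t", index=False)
    bed = pd.DataFrame(exported["bed"],
                       columns=["chrom", "start", "end", "name", "score", "strand"])
    bed.to_csv(outdir / "guides.bed", sep="\t", index=False, header=False)
    with open(outdir / "templates.fa", "w") as fh:
        for name, template, _flag in exported["templates"]:
            fh.write(f">{name}\n{template}\n")
    prov_counts = Counter(pool.provenance)
    warnings = []
    report = {"n_guides": len(pool.selected),
              "provenance_counts": dict(prov_counts),
              "targets": {}}
    for tid, cov in pool.coverage.items():
        report["targets"][tid] = {
            "n_cuts": len(cov.cut_positions),
            "max_gap": cov.max_gap,
            "uncovered_intervals": [list(u) for u in cov.uncovered],
            "uncovered_variants": list(cov.uncovered_variants),
        }
        for u in cov.uncovered:
            warnings.append(f"target {tid}: uncovered interval {u[0]}-{u[1]}")
        for v in cov.uncovered_variants:
            warnings.append(f"target {tid}: variant at {v} has no nearby cut")
    report["warnings"] = warnings
    with open(outdir / "design_report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report


def load_pool_tsv(path, params: DesignParams | None = None) -> GuidePool:
    """Reload a guide pool from a guides.tsv written by write_design_outputs.

    Coverage statistics are not recoverable from the TSV alone; the returned
    pool carries empty coverage and is intended for depletion simulation.
    """
    import pandas as pd
    params = params or DesignParams()
    df = pd.read_csv(path, sep="\t", dtype={"target_id": str})
    selected = []
    provenance = []
    for _, row in df.iterrows():
        w = len(row["protospacer"])
        start = int(row["start"]) if row["strand"] == "+" else int(row["end"]) - 1
        selected.append(GuideCandidate(
            target_id=row["target_id"], strand=row["strand"], start=start,
            protospacer=row["protospacer"], pam=row["pam"],
            cut_pos=int(row["cut_pos"]),
            on_target_score=int(row["on_target_score"]),
            off_target_hits=int(row["off_target_hits"]),
        ))
        provenance.append(str(row["provenance"]))
    return GuidePool(selected=selected, params=params, coverage={},
                     provenance=provenance)
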