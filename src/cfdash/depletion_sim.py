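"""In-silico Cas9 depletion of a cDNA fragment library.

DASH acts on the double-stranded cDNA insert between amplification stages:
a fragment is cleaved wherever a pool guide's protospacer occurs exactly in
the fragment (either strand) with a PAM-pattern match immediately 3', and a
cleaved insert can no longer amplify. Cleavage is modelled as 100%
efficient and cleaved fragments are removed entirely; a cut site straddling
a fragment end does not count, since both protospacer and PAM must be
intact within the insert.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

from cfdash._seq import matches_iupac, revcomp, revcomp_iupac, validate_nucleotides
from cfdash.guide_design import GuidePool

FRAGMENT_CLASSES = ("rRNA", "mtRNA", "genome", "spikein", "univec", "circRNA",
                    "microbial")

COMPOSITION_CLASSES = ("spikein", "univec", "rRNA", "mtRNA", "genome",
                       "circRNA", "unmapped")


@dataclass(frozen=True)
class Fragment:
    """A cDNA insert with an optional ground-truth class label."""

    id: str
    sequence: str
    true_class: str | None = None

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"fragment {self.id!r} has empty sequence")
        validate_nucleotides(self.sequence, name=f"fragment {self.id!r}")


@dataclass
class DepletionReport:
    """Before/after accounting for one in-silico depletion run."""

    n_input: int
    n_cut: int
    n_retained: int
    composition_pre: dict[str, float]
    composition_post: dict[str, float]
    cut_records: list[tuple[str, str, int]]  # (fragment id, guide name, cut coord)

    def validate(self) -> None:
        assert self.n_input == self.n_cut + self.n_retained
        for comp, n in ((self.composition_pre, self.n_input),
                        (self.composition_post, self.n_retained)):
            if n > 0 and comp:
                assert abs(sum(comp.values()) - 1.0) < 1e-9

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({
                "n_input": self.n_input, "n_cut": self.n_cut,
                "n_retained": self.n_retained,
                "composition_pre": self.composition_pre,
                "composition_post": self.composition_post,
                "n_cut_records": len(self.cut_records),
            }, fh, indent=2, sort_keys=True)


def read_fragments_fasta(path) -> list[Fragment]:
    """Load fragments; a ``class=`` token in the description sets true_class."""
    frags = []
    for rec in SeqIO.parse(str(path), "fasta"):
        label = None
        for token in rec.description.split():
            if token.startswith("class="):
                label = token.split("=", 1)[1]
        frags.append(Fragment(id=rec.id, sequence=str(rec.seq).upper(),
                              true_class=label))
    return frags


def find_cut_sites(fragment: Fragment, pool: GuidePool) -> list[tuple[str, int, str]]:
    """All (guide name, cut coordinate, strand) cut sites in a fragment.

    The fragment is treated as double-stranded cDNA: a guide cuts wherever
    its protospacer occurs exactly on either strand with a PAM-pattern
    match immediately 3'. Coordinates are 0-based on the fragment's given
    strand, ordered by coordinate.
    """
    seq = fragment.sequence
    n = len(seq)
    params = pool.params
    pam_pat = params.pam
    rc_pam_pat = revcomp_iupac(pam_pat)
    p = len(pam_pat)
    w = params.protospacer_len
    hits: list[tuple[str, int, str]] = []
    for g in pool.selected:
        name = f"{g.target_id}_{g.interval[0]}_{g.strand}"
        proto = g.protospacer
        # plus strand of the fragment: proto at i, PAM at [i+w, i+w+p)
        i = seq.find(proto)
        while i != -1:
            pam_seq = seq[i + w:i + w + p]
            if len(pam_seq) == p and "N" not in pam_seq and matches_iupac(pam_seq, pam_pat):
                hits.append((name, i + w - params.cut_offset, "+"))
            i = seq.find(proto, i + 1)
        # minus strand: revcomp(proto) at plus [j, j+w), PAM plus [j-p, j)
        rc = revcomp(proto)
        j = seq.find(rc)
        while j != -1:
            pam_seq = seq[j - p:j]
            if j - p >= 0 and "N" not in pam_seq and matches_iupac(pam_seq, rc_pam_pat):
                hits.append((name, j + params.cut_offset, "-"))
            j = seq.find(rc, j + 1)
    hits.sort(key=lambda h: (h[1], h[2], h[0]))
    return hits


def _composition(fragments: Sequence[Fragment]) -> dict[str, float]:
    if not fragments:
        return {}
    counts: dict[str, int] = {}
    for f in fragments:
        label = f.true_class if f.true_class is not None else "unlabelled"
        counts[label] = counts.get(label, 0) + 1
    total = len(fragments)
    return {k: v / total for k, v in sorted(counts.items())}


def deplete_library(fragments: Sequence[Fragment], pool: GuidePool
                    ) -> tuple[list[Fragment], DepletionReport]:
    """Remove every fragment carrying >=1 cut site; report the composition
    of the library before and after (over true_class labels when present)."""
    retained: list[Fragment] = []
    cut_records: list[tuple[str, str, int]] = []
    n_cut = 0
    for frag in fragments:
        sites = find_cut_sites(frag, pool)
        if sites:
            n_cut += 1
            for name, coord, _strand in sites:
                cut_records.append((frag.id, name, coord))
        else:
            retained.append(frag)
    report = DepletionReport(
        n_input=len(fragments), n_cut=n_cut, n_retained=len(retained),
        composition_pre=_composition(fragments),
        composition_post=_composition(retained),
        cut_records=cut_records,
    )
    report.validate()
    return retained, report


def composition_report(class_counts: dict[str, int]) -> dict[str, float]:
    """Fractions of reads per source class (stacked-composition report).

    ``class_counts`` maps class labels (spikein, univec, rRNA, mtRNA,
    genome, circRNA, unmapped) to read counts; returns fractions summing
    to 1 over all classes present in the input (absent classes are 0).
    """
    if any(v < 0 for v in class_counts.values()):
        raise ValueError("negative class count")
    total = sum(class_counts.values())
    if total == 0:
        raise ValueError("empty library")
    out = {cls: 0.0 for cls in COMPOSITION_CLASSES}
    for cls, count in class_counts.items():
        out[cls] = count / total
    return out


def insert_size_summary(fragments: Sequence[Fragment],
                        bin_width: int = 10) -> dict:
    """Per-class insert-size histogram (report plumbing for length plots).

    Returns {class: {"n": count, "mean": float, "histogram": {bin_start:
    count}}} with bins of ``bin_width`` nt.
    """
    by_class: dict[str, list[int]] = {}
    for f in fragments:
        label = f.true_class if f.true_class is not None else "unlabelled"
        by_class.setdefault(label, []).append(len(f.sequence))
    out: dict[str, dict] = {}
    for label, lengths in sorted(by_class.items()):
        hist: dict[int, int] = {}
        for L in lengths:
            b = (L // bin_width) * bin_width
            hist[b] = hist.get(b, 0) + 1
        out[label] = {"n": len(lengths),
                      "mean": sum(lengths) / len(lengths),
                      "histogram": dict(sorted(hist.items()))}
    return out


def write_depletion_outputs(retained: Sequence[Fragment], report: DepletionReport,
                            outdir) -> None:
    """Write retained.fa, depletion_report.json and composition.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "retained.fa", "w") as fh:
        for f in retained:
            label = f" class={f.true_class}" if f.true_class else ""
            fh.write(f">{f.id}{label}\n{f.sequence}\n")
    report.to_json(outdir / "depletion_report.json")
    with open(outdir / "composition.tsv", "w") as fh:
        fh.write("class\tfraction_pre\tfraction_post\n")
        classes = sorted(set(report.composition_pre) | set(report.composition_post))
        for cls in classes:
            fh.write(f"{cls}\t{report.composition_pre.get(cls, 0.0):.6f}"
                     f"\t{report.composition_post.get(cls, 0.0):.6f}\n")
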