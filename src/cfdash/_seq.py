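"""Small nucleotide-sequence helpers shared across modules."""

from __future__ import annotations

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# IUPAC nucleotide codes -> the set of concrete bases each matches.
# A literal N base in the *sequence* never matches (ambiguity cannot be
# synthesised as an oligo), so N is deliberately absent from every set.
IUPAC = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"},
    "B": {"C", "G", "T"}, "D": {"A", "G", "T"}, "H": {"A", "C", "T"},
    "V": {"A", "C", "G"}, "N": {"A", "C", "G", "T"},
}

_IUPAC_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGTN sequence."""
    return seq.translate(_COMPLEMENT)[::-1]


def revcomp_iupac(pattern: str) -> str:
    """Reverse complement of an IUPAC pattern (e.g. NGG -> CCN)."""
    return pattern.translate(_IUPAC_COMPLEMENT)[::-1]


def matches_iupac(seq: str, pattern: str) -> bool:
    """True iff `seq` (concrete ACGT; N never matches) fits the IUPAC pattern."""
    if len(seq) != len(pattern):
        return False
    for base, code in zip(seq, pattern):
        allowed = IUPAC.get(code)
        if allowed is None:
            raise ValueError(f"invalid IUPAC code {code!r} in pattern {pattern!r}")
        if base not in allowed:
            return False
    return True


def gc_count(seq: str) -> int:
    return seq.count("G") + seq.count("C")


def max_homopolymer_run(seq: str) -> int:
    """Length of the longest single-base run."""
    best = run = 0
    prev = None
    for b in seq:
        run = run + 1 if b == prev else 1
        prev = b
        best = max(best, run)
    return best


def max_dinucleotide_repeats(seq: str) -> int:
    """Max number of consecutive repeats of any 2-base unit XY with X != Y.

    "ATATAT" counts as 3 repeats of AT.
    """
    best = 0
    n = len(seq)
    for i in range(n - 1):
        if seq[i] == seq[i + 1]:
            continue
        unit = seq[i:i + 2]
        k = 1
        j = i + 2
        while j + 1 < n + 1 and seq[j:j + 2] == unit:
            k += 1
            j += 2
        best = max(best, k)
    return best


def validate_nucleotides(seq: str, name: str = "sequence") -> None:
    """Raise ValueError naming the offending offset for non-ACGTN characters."""
    for off, ch in enumerate(seq):
        if ch not in "ACGTN":
            raise ValueError(
                f"invalid character {ch!r} at offset {off} in {name}: "
                "sequences must be uppercase over A,C,G,T,N"
            )


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal-length strings")
    return sum(x != y for x, y in zip(a, b))
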