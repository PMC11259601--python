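"""Independent brute-force oracles used by the test suite.

These deliberately share no code with the implementation: PAM matching is
regex-based, reverse complements come from Biopython, run/repeat scans are
written longhand, and the tiling optimum is found by exhaustive subset
search. They exist to verify the package, never to stand in for it.
"""

import re
from itertools import combinations

from Bio.Seq import Seq

_IUPAC_RE = {"A": "A", "C": "C", "G": "G", "T": "T", "R": "[AG]", "Y": "[CT]",
             "S": "[CG]", "W": "[AT]", "K": "[GT]", "M": "[AC]", "B": "[CGT]",
             "D": "[AGT]", "H": "[ACT]", "V": "[ACG]", "N": "[ACGT]"}


def pam_regex(pattern):
    return re.compile("".join(_IUPAC_RE[c] for c in pattern))


def rc(seq):
    return str(Seq(seq).reverse_complement())


def naive_scan(seq, protospacer_len=20, pam="NGG", cut_offset=3):
    """Both-strand sliding-window site enumeration.

    Returns a set of (strand, start5prime, protospacer, pam, cut_pos) using
    the same coordinate conventions the package documents: start is the
    plus-strand coordinate of the protospacer 5' end, cut_pos the
    plus-strand coordinate of the first base 3' of the blunt cut.
    """
    w, p = protospacer_len, len(pam)
    pat = pam_regex(pam)
    sites = set()
    n = len(seq)
    for i in range(n):
        # plus strand
        proto, pm = seq[i:i + w], seq[i + w:i + w + p]
        if len(pm) == p and "N" not in proto + pm and pat.fullmatch(pm):
            sites.add(("+", i, proto, pm, i + w - cut_offset))
        # minus strand: protospacer occupies plus [i, i+w), PAM plus [i-p, i)
        pm_minus = seq[i - p:i] if i - p >= 0 else ""
        if len(proto) == w and len(pm_minus) == p and "N" not in proto + pm_minus:
            mproto, mpam = rc(proto), rc(pm_minus)
            if pat.fullmatch(mpam):
                sites.add(("-", i + w - 1, mproto, mpam, i + cut_offset))
    return sites


def oracle_gc_high(proto, gc_max=15):
    return sum(1 for b in proto if b in "GC") > gc_max


def oracle_gc_low(proto, gc_min=5):
    return sum(1 for b in proto if b in "GC") < gc_min


def oracle_homopolymer(proto, max_run=5):
    return re.search(r"(.)\1{%d,}" % max_run, proto) is not None


def oracle_dinucleotide(proto, max_repeats=3):
    for i in range(len(proto) - 1):
        x, y = proto[i], proto[i + 1]
        if x == y:
            continue
        unit = x + y
        reps = 0
        j = i
        while proto[j:j + 2] == unit:
            reps += 1
            j += 2
        if reps > max_repeats:
            return True
    return False


def oracle_hairpin(proto, stem=5, window=8):
    head, tail = proto[:window], proto[-window:]
    for i in range(len(head) - stem + 1):
        if rc(head[i:i + stem]) in tail:
            return True
    return False


def oracle_fail_reasons(proto):
    reasons = set()
    if oracle_gc_high(proto):
        reasons.add("gc_high")
    if oracle_gc_low(proto):
        reasons.add("gc_low")
    if oracle_homopolymer(proto):
        reasons.add("homopolymer")
    if oracle_dinucleotide(proto):
        reasons.add("dinucleotide_repeat")
    if oracle_hairpin(proto):
        reasons.add("hairpin")
    return reasons


def tiling_components(cuts, tile):
    """Split sorted eligible cut positions into maximal sweep components:
    a new component starts wherever the previous cut is > tile away."""
    comps = []
    for c in sorted(cuts):
        if comps and c - comps[-1][-1] <= tile:
            comps[-1].append(c)
        else:
            comps.append([c])
    return comps


def brute_force_min_pool(cuts, tile):
    """Exhaustive minimum selection size matching the sweep's feasible set.

    Per component the selection must include the component's last cut (the
    sweep always reaches it), must start at most `tile` into the component
    (first component: first selected cut <= tile; later components: the
    entry cut is forced), and consecutive selected cuts must be <= tile
    apart. Minimum found by trying subset sizes in increasing order.
    """
    total = 0
    for ci, comp in enumerate(tiling_components(cuts, tile)):
        last = comp[-1]
        best = None
        for size in range(1, len(comp) + 1):
            for sub in combinations(comp, size):
                if sub[-1] != last:
                    continue
                if ci == 0 and comp[0] <= tile:
                    if sub[0] > tile:
                        continue
                elif sub[0] != comp[0]:
                    # gap restart: the component's first cut is forced
                    continue
                if all(b - a <= tile for a, b in zip(sub, sub[1:])):
                    best = size
                    break
            if best is not None:
                break
        total += best
    return total


def naive_fragment_cuts(fragment_seq, guides, pam="NGG", cut_offset=3):
    """Brute-force cut-site scan of a fragment against pool protospacers."""
    pat = pam_regex(pam)
    w = len(guides[0]) if guides else 0
    p = len(pam)
    hits = []
    for proto in set(guides):
        for i in range(len(fragment_seq) - w + 1):
            if fragment_seq[i:i + w] == proto:
                pm = fragment_seq[i + w:i + w + p]
                if len(pm) == p and "N" not in pm and pat.fullmatch(pm):
                    hits.append((i + w - cut_offset, "+"))
            if fragment_seq[i:i + w] == rc(proto):
                pm = rc(fragment_seq[i - p:i]) if i - p >= 0 else ""
                if len(pm) == p and "N" not in pm and pat.fullmatch(pm):
                    hits.append((i + cut_offset, "-"))
    return sorted(set(hits))
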