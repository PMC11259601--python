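"""Guide design: scanning, structural filters, scoring, tiling, export."""

import numpy as np
import pytest

from cfdash.guide_design import (
    DesignParams,
    GuideCandidate,
    TargetSet,
    build_offtarget_index,
    design_pool,
    scan_candidates,
    score_guides,
    select_tiling_pool,
    structural_filter,
    export_guides,
    write_design_outputs,
    load_pool_tsv,
)
from conftest import random_seq
from oracles import brute_force_min_pool, naive_scan, oracle_fail_reasons


def _cand(proto, target_id="t", strand="+", start=0, cut_pos=0, pam="AGG",
          on=1, off=0, fail=frozenset()):
    return GuideCandidate(target_id=target_id, strand=strand, start=start,
                          protospacer=proto, pam=pam, cut_pos=cut_pos,
                          fail_reasons=frozenset(fail), on_target_score=on,
                          off_target_hits=off)


class TestScanCandidates:
    @pytest.mark.parametrize("seq,expected", [
        # single plus-strand site at the very start
        ("A" * 20 + "AGG", [("+", 0, "A" * 20, "AGG", 17)]),
        # plus-strand CCN context is a minus-strand NGG site
        ("CCT" + "T" * 20, [("-", 22, "A" * 20, "AGG", 6)]),
        # too short for protospacer + PAM
        ("A" * 22, []),
    ])
    def test_worked_examples(self, seq, expected):
        targets = TargetSet(entries=(("t", seq, "rRNA"),))
        got = [(c.strand, c.start, c.protospacer, c.pam, c.cut_pos)
               for c in scan_candidates(targets)]
        assert got == expected

    def test_n_excluded_and_bad_character_rejected(self):
        targets = TargetSet(entries=(("t", "N" * 20 + "AGG", "rRNA"),))
        assert scan_candidates(targets) == []
        with pytest.raises(ValueError, match="offset 2"):
            TargetSet(entries=(("t", "AAxAA", "rRNA"),))

    def test_matches_naive_oracle_on_random_sequences(self, rng):
        for _ in range(20):
            seq = random_seq(rng, 400)
            targets = TargetSet(entries=(("t", seq, "rRNA"),))
            got = {(c.strand, c.start, c.protospacer, c.pam, c.cut_pos)
                   for c in scan_candidates(targets)}
            assert got == naive_scan(seq)

    def test_output_ordering(self, small_targets):
        cands = scan_candidates(small_targets)
        keys = [(c.target_id, c.start, c.strand) for c in cands]
        assert keys == sorted(keys)


class TestStructuralFilter:
    @pytest.mark.parametrize("proto,expected", [
        ("GGCAGCGGCAGCGGCAGCGG", {"gc_high"}),            # 17 G/C > 15
        # 18 G/C, and revcomp of the prefix stem CCGGC recurs in the tail
        ("GCCGGCGCCGGCGCCGGCAT", {"gc_high", "hairpin"}),
        ("A" * 20, {"homopolymer", "gc_low"}),
        ("ATATATAT" + "CGGCAGTCAGTC", {"dinucleotide_repeat"}),
        ("GGCGA" + "ACTGTACTGA" + "TCGCC", {"hairpin"}),  # revcomp(GGCGA)=TCGCC
        ("GATCGATCGGATCCATGCAT", set()),                  # clean guide
    ])
    def test_crafted_cases(self, proto, expected):
        got = structural_filter(_cand(proto)).fail_reasons
        assert got == frozenset(expected)
        assert got == oracle_fail_reasons(proto)

    def test_matches_per_rule_oracles_on_random_20mers(self, rng):
        for _ in range(2000):
            proto = random_seq(rng, 20, gc=rng.uniform(0.1, 0.9))
            got = structural_filter(_cand(proto)).fail_reasons
            assert got == oracle_fail_reasons(proto), proto

    def test_boundaries(self):
        # exactly 15 GC passes the high gate; exactly 5 passes the low gate
        assert "gc_high" not in structural_filter(_cand("G" * 15 + "A" * 5)).fail_reasons
        assert "gc_low" not in structural_filter(
            _cand("GCGCG" + "ATATA" + "TTTTT" + "AATTA")).fail_reasons
        # run of exactly 5 passes; 3 dinucleotide repeats pass
        ok = structural_filter(_cand("CCCCC" + "GATCGATTACGATCG"))
        assert "homopolymer" not in ok.fail_reasons
        assert "dinucleotide_repeat" not in structural_filter(
            _cand("ATATAT" + "GCGGACCTGACGTG")).fail_reasons


class TestOfftargetIndex:
    def test_exact_hit_counting(self):
        idx = build_offtarget_index([("bg", "A" * 20 + "AGG")])
        assert idx.query("A" * 20) == 1
        assert idx.query("C" * 20) == 0

    def test_pam_required(self):
        # protospacer present but followed by TAA: no site
        proto = ("GATTACA" * 3)[:20]
        idx = build_offtarget_index([("bg", proto + "TAA" + "C" * 25)])
        assert idx.query(proto) == 0

    def test_empty_background_rejected(self, tmp_path):
        fa = tmp_path / "bg.fa"
        fa.write_text("")
        with pytest.raises(ValueError, match="empty"):
            build_offtarget_index(fa)

    def test_one_mismatch_mode(self):
        idx = build_offtarget_index([("bg", "A" * 20 + "AGG")])
        near = "A" * 19 + "C"
        assert idx.query(near) == 0
        assert idx.query(near, max_mismatches=1) == 1


class TestScoreGuides:
    def test_multicopy_on_target_and_offtarget(self, rng):
        core = random_seq(rng, 30)
        site = core[:20]
        seq = core[:20] + "TGG" + "A" * 10
        targets = TargetSet(entries=(("t1", seq, "rRNA"), ("t2", seq, "mtRNA")))
        idx = build_offtarget_index([("bg", seq)])
        cands = scan_candidates(targets)
        scored = score_guides(cands, targets, idx)
        focal = [c for c in scored if c.protospacer == site]
        assert focal and all(c.on_target_score == 2 for c in focal)
        assert all(c.off_target_hits == 1 for c in focal)

    def test_unique_guide_scores(self, small_targets):
        idx = build_offtarget_index([("bg", "T" * 200)])
        scored = score_guides(scan_candidates(small_targets), small_targets, idx)
        assert all(c.on_target_score >= 1 for c in scored)
        assert all(c.off_target_hits == 0 for c in scored)


def _tiling_instance(cuts, target_len, tile=50):
    """Synthetic eligible candidates with the given cut positions."""
    targets = TargetSet(entries=(("t", "A" * target_len, "rRNA"),))
    cands = [_cand("GATCGATCGGATCCATGCAT", target_id="t", start=max(0, c - 17),
                   cut_pos=c) for c in cuts]
    params = DesignParams(tile_interval=tile)
    return targets, cands, params


class TestTilingSelection:
    def test_worked_example_cuts_every_10(self):
        cuts = list(range(10, 200, 10))  # 10..190
        targets, cands, params = _tiling_instance(cuts, 200)
        pool = select_tiling_pool(cands, targets, params)
        assert pool.coverage["t"].cut_positions == (50, 100, 150, 190)
        assert pool.coverage["t"].max_gap <= 50
        assert len(pool.selected) == brute_force_min_pool(cuts, 50)

    def test_no_eligible_candidates(self):
        targets, _, params = _tiling_instance([], 120)
        pool = select_tiling_pool([], targets, params)
        assert pool.selected == []
        assert pool.coverage["t"].uncovered == ((0, 120),)
        assert pool.coverage["t"].max_gap == 120

    def test_tie_break_prefers_higher_on_target(self):
        targets = TargetSet(entries=(("t", "A" * 100, "rRNA"),))
        a = _cand("GATCGATCGGATCCATGCAT", target_id="t", start=10, cut_pos=27, on=2)
        b = _cand("GATCGATCGGATCCATGCCT", target_id="t", start=11, cut_pos=27, on=1)
        pool = select_tiling_pool([b, a], targets, DesignParams(tile_interval=50))
        assert pool.selected[0].on_target_score == 2

    def test_gap_recorded_and_restart(self):
        # cuts at 20 and then 150: window after 20 is empty -> gap + restart
        targets, cands, params = _tiling_instance([20, 150], 200)
        pool = select_tiling_pool(cands, targets, params)
        cov = pool.coverage["t"]
        assert cov.cut_positions == (20, 150)
        assert (20, 150) in cov.uncovered
        assert pool.provenance == ["tiling", "gap_fill"]

    def test_ineligible_candidates_never_selected(self, rng):
        targets = TargetSet(entries=(("t", "A" * 300, "rRNA"),))
        good = [_cand("GATCGATCGGATCCATGCAT", target_id="t", start=c - 17, cut_pos=c)
                for c in (40, 90, 140)]
        bad_struct = _cand("A" * 20, target_id="t", start=30, cut_pos=47,
                           fail={"homopolymer"})
        bad_off = _cand("GATCGATCGGATCCATGCAT", target_id="t", start=50,
                        cut_pos=67, off=3)
        pool = select_tiling_pool(good + [bad_struct, bad_off], targets,
                                  DesignParams(tile_interval=50))
        assert all(not g.fail_reasons and g.off_target_hits == 0
                   for g in pool.selected)

    def test_greedy_matches_brute_force_on_random_instances(self, rng):
        tile = 50
        for _ in range(30):
            target_len = int(rng.integers(100, 301))
            n_cuts = int(rng.integers(1, 13))
            cuts = sorted(rng.choice(np.arange(5, target_len), size=n_cuts,
                                     replace=False).tolist())
            targets, cands, params = _tiling_instance(cuts, target_len, tile)
            pool = select_tiling_pool(cands, targets, params)
            assert len(pool.selected) == brute_force_min_pool(cuts, tile), cuts

    def test_max_gap_bounded_when_dense(self, rng):
        # cuts spanning the target at spacing <= tile -> max gap <= tile
        for _ in range(10):
            target_len = int(rng.integers(150, 301))
            cuts, pos = [], int(rng.integers(5, 40))
            while pos < target_len - 45:
                cuts.append(pos)
                pos += int(rng.integers(5, 46))
            targets, cands, params = _tiling_instance(cuts, target_len)
            pool = select_tiling_pool(cands, targets, params)
            if cuts and cuts[0] <= 50 and target_len - cuts[-1] <= 50:
                assert pool.coverage["t"].max_gap <= 50

    def test_variant_fill(self):
        # tiling keeps only cut 50 (largest in the first window); the SNP at
        # 20 is 30 away from it, so the skipped candidate at 30 is added back
        targets = TargetSet(entries=(("t", "A" * 120, "rRNA"),),
                            variants=(("t", 20), ("t", 110)))
        cands = [_cand("GATCGATCGGATCCATGCAT", target_id="t", start=13, cut_pos=30),
                 _cand("GATCGATCGGATCCATGCAT", target_id="t", start=33, cut_pos=50)]
        pool = select_tiling_pool(cands, targets, DesignParams(tile_interval=50))
        cov = pool.coverage["t"]
        assert cov.cut_positions == (30, 50)
        assert pool.provenance == ["variant_fill", "tiling"]
        # the SNP at 110 has no eligible cut within 25: reported uncovered
        assert cov.uncovered_variants == (110,)


class TestExport:
    def test_templates_and_prepended_g(self, small_targets):
        pool = design_pool(small_targets)
        out = export_guides(pool, promoter="PROM"[0:4], scaffold="SCAF")
        assert len(out["table"]) == len(pool.selected)
        for row, (name, template, flag) in zip(out["table"], out["templates"]):
            spacer = row["protospacer"]
            if spacer.startswith("G"):
                assert not flag and template == "PROM" + spacer + "SCAF"
            else:
                assert flag and template == "PROM" + "G" + spacer + "SCAF"

    def test_bed_within_bounds_and_row_conservation(self, small_targets, tmp_path):
        pool = design_pool(small_targets)
        report = write_design_outputs(pool, tmp_path)
        tsv = (tmp_path / "guides.tsv").read_text().splitlines()
        assert len(tsv) - 1 == len(pool.selected) == report["n_guides"]
        lengths = {tid: len(seq) for tid, seq, _ in small_targets.entries}
        for line in (tmp_path / "guides.bed").read_text().splitlines():
            chrom, start, end = line.split("\t")[:3]
            assert 0 <= int(start) < int(end) <= lengths[chrom]

    def test_empty_pool_writes_headers(self, tmp_path):
        targets = TargetSet(entries=(("t", "A" * 150, "rRNA"),))
        pool = select_tiling_pool([], targets, DesignParams())
        write_design_outputs(pool, tmp_path)
        assert (tmp_path / "guides.tsv").read_text().startswith("target_id\t")
        assert (tmp_path / "templates.fa").read_text() == ""

    def test_deterministic_bytes_and_tsv_round_trip(self, small_targets, tmp_path):
        pool = design_pool(small_targets)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        write_design_outputs(pool, d1)
        write_design_outputs(pool, d2)
        for name in ("guides.tsv", "guides.bed", "templates.fa"):
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes()
        reloaded = load_pool_tsv(d1 / "guides.tsv")
        assert [(g.target_id, g.strand, g.start, g.protospacer, g.cut_pos)
                for g in reloaded.selected] == \
            [(g.target_id, g.strand, g.start, g.protospacer, g.cut_pos)
             for g in pool.selected]
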