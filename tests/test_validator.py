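"""Pair classification, variant calling, cross-pool confirmation, verdicts."""
import math

import numpy as np
import pytest

from fostag.mapping import (UNFLIPPED_REF, AlignmentHit, cigar_ops,
                            map_pair)
from fostag.read_simulator import _stream
from fostag.synthetic import random_dna
from fostag.validator import (CloneReference, PairObservation,
                              PoolCloneEvidence, ValidationParams, _Pileup,
                              anchored_coverage, call_variants, classify_clone,
                              classify_pair, cross_confirm, mutation_histogram,
                              percent, phred_binomial_score, remove_duplicates,
                              summarize_library, validate_pools,
                              verdicts_table)


def _hit(rid, pos, strand, length=100, read_id="r/1", ed=0):
    return AlignmentHit(read_id, rid, pos, strand, length, f"{length}=",
                        ed, True, "A" * length)


@pytest.fixture(scope="module")
def refs(small_run):
    return small_run["refs"]


@pytest.fixture(scope="module")
def clone(refs):
    ref = refs.clones["clone000"]
    assert ref.strand == "+"
    return ref


@pytest.fixture(scope="module")
def refseq():
    rng = _stream(21, "pileup_ref")
    seq = random_dna(rng, 200)
    # pin a CTAA context at 49..53 so the two alignment paths of the same
    # 2-bp deletion are realisable in the pileup tests
    return seq[:49] + "CTAA" + seq[53:]


class TestPhredBinomialScore:
    def test_unanimous_support_closed_form(self):
        # P(X >= 10 | n=10, e=0.01) = 0.01^10 -> phred 200
        assert phred_binomial_score(10, 10, 0.01) == pytest.approx(200.0)

    def test_singleton_error_closed_form(self):
        # P(X >= 1 | n=30, e=0.01) = 1 - 0.99^30
        expect = -10.0 * math.log10(1.0 - 0.99 ** 30)
        assert phred_binomial_score(1, 30, 0.01) == pytest.approx(expect)
        assert expect < 20.0  # a lone error never reaches the cutoff

    def test_zero_support_and_cap(self):
        assert phred_binomial_score(0, 100, 0.01) == 0.0
        assert phred_binomial_score(500, 500, 0.01) == 1000.0

    def test_monotone_in_support(self):
        scores = [phred_binomial_score(s, 40, 0.01) for s in range(1, 10)]
        assert scores == sorted(scores)


class TestClassifyPair:
    def test_tag_anchored_at_3000(self, refs, clone):
        ts, _ = clone.tag_interval
        left = _hit("clone000", ts + 10, "-")
        right = _hit("clone000", ts + 10 + 2900, "+", read_id="r/2")
        o = classify_pair(left, right, refs)
        assert o.kind == "tag_anchored" and o.clone_id == "clone000"
        assert o.insert == 3000

    def test_insert_5000_discordant(self, refs, clone):
        ts, _ = clone.tag_interval
        o = classify_pair(_hit("clone000", ts + 10, "-"),
                          _hit("clone000", ts + 10 + 4900, "+"), refs)
        assert o.kind == "discordant" and o.insert == 5000

    def test_wrong_orientation_discordant(self, refs, clone):
        ts, _ = clone.tag_interval
        o = classify_pair(_hit("clone000", ts + 10, "+"),
                          _hit("clone000", ts + 10 + 2900, "+"), refs)
        assert o.kind == "discordant"

    def test_window_boundaries_inclusive(self, refs, clone):
        ts, _ = clone.tag_interval
        for span, kind in ((2200, "tag_anchored"), (2199, "discordant"),
                           (3700, "tag_anchored"), (3701, "discordant")):
            o = classify_pair(_hit("clone000", ts + 10, "-"),
                              _hit("clone000", ts + 10 + span - 100, "+"), refs)
            assert o.kind == kind, span

    def test_genomic_only_pair(self, refs, clone):
        o = classify_pair(_hit("clone000", 100, "-"),
                          _hit("clone000", 2400, "+"), refs)
        assert o.kind == "genomic_only" and o.clone_id == "clone000"

    def test_mates_on_different_clones_discordant(self, refs):
        o = classify_pair(_hit("clone000", 100, "-"),
                          _hit("clone002", 2400, "+"), refs)
        assert o.kind == "discordant" and o.clone_id is None

    def test_missing_or_ambiguous_mate_unmapped(self, refs):
        assert classify_pair(_hit("clone000", 100, "-"), None,
                             refs).kind == "unmapped"
        multi = AlignmentHit("r/2", "clone000", 2400, "+", 100, "100=", 0,
                             False, "A" * 100)
        assert classify_pair(_hit("clone000", 100, "-"), multi,
                             refs).kind == "unmapped"

    def test_unflipped_evidence_span_window(self, refs, clone):
        ts, _ = clone.tag_interval
        m_start = ts + clone.unflipped_marker_offset
        marker = _hit(UNFLIPPED_REF, 0, "+")
        good = classify_pair(marker, _hit("clone000", m_start - 2900, "-"),
                             refs)
        assert good.kind == "unflipped_evidence"
        assert good.clone_id == "clone000" and good.insert == 3000
        far = classify_pair(marker, _hit("clone000", m_start - 4900, "-"),
                            refs)
        assert far.kind == "discordant"


class TestRemoveDuplicates:
    def _obs(self, pid, pos1, pos2, rid="clone000"):
        return PairObservation(pid, "tag_anchored", rid,
                               _hit(rid, pos1, "-", read_id=pid + "/1"),
                               _hit(rid, pos2, "+", read_id=pid + "/2"), 3000)

    def test_identical_placement_collapsed(self):
        obs = [self._obs("a", 100, 3000), self._obs("b", 100, 3000),
               self._obs("c", 100, 3001)]
        out = remove_duplicates(obs)
        assert [o.pair_id for o in out] == ["a", "c"]

    def test_mate_order_irrelevant(self):
        a = self._obs("a", 100, 3000)
        b = PairObservation("b", "tag_anchored", "clone000", a.hit2, a.hit1,
                            3000)
        assert [o.pair_id for o in remove_duplicates([a, b])] == ["a"]

    def test_unmapped_pairs_always_kept(self):
        obs = [PairObservation("a", "unmapped", None, None, None, None),
               PairObservation("b", "unmapped", None, None, None, None)]
        assert remove_duplicates(obs) == obs

    def test_idempotent(self):
        obs = [self._obs("a", 100, 3000), self._obs("b", 100, 3000)]
        once = remove_duplicates(obs)
        assert remove_duplicates(once) == once


class TestPileupAndCalling:
    def _read_hit(self, refseq, pos, cigar, seq, read_id="r", ed=1):
        ref_span = sum(n for n, op in cigar_ops(cigar) if op in "=XD")
        return AlignmentHit(read_id, "c", pos, "+", ref_span, cigar, ed,
                            True, seq)

    def test_unanimous_substitution_called(self, refseq):
        pile = _Pileup(len(refseq))
        alt = "ACGT".replace(refseq[50], "")[0]
        seq = refseq[:50] + alt + refseq[51:100]
        for i in range(10):
            pile.add_hit(self._read_hit(refseq, 0, "50=1X49=", seq, f"r{i}"),
                         refseq)
        calls = call_variants(pile, "c", "p", (0, 200), ValidationParams())
        assert len(calls) == 1
        c = calls[0]
        assert c.key() == (50, "sub", refseq[50], alt)
        assert c.support == 10 and c.coverage == 10
        assert c.score == pytest.approx(200.0)

    def test_single_error_among_30_filtered(self, refseq):
        pile = _Pileup(len(refseq))
        alt = "ACGT".replace(refseq[50], "")[0]
        for i in range(29):
            pile.add_hit(self._read_hit(refseq, 0, "100=", refseq[:100],
                                        f"r{i}", ed=0), refseq)
        pile.add_hit(self._read_hit(refseq, 0, "50=1X49=",
                                    refseq[:50] + alt + refseq[51:100], "e"),
                     refseq)
        assert call_variants(pile, "c", "p", (0, 200),
                             ValidationParams()) == []
        assert pile.events[(50, "sub", refseq[50], alt)] == 1

    def test_event_outside_roi_excluded(self, refseq):
        pile = _Pileup(len(refseq))
        alt = "ACGT".replace(refseq[50], "")[0]
        seq = refseq[:50] + alt + refseq[51:100]
        for i in range(10):
            pile.add_hit(self._read_hit(refseq, 0, "50=1X49=", seq, f"r{i}"),
                         refseq)
        assert call_variants(pile, "c", "p", (60, 200),
                             ValidationParams()) == []

    def test_ambiguous_deletion_paths_share_one_key(self, refseq):
        """refseq[49:53] == 'CTAA': deleting TA at 50 and deleting positions
        50 and 52 around a kept A give the same molecule, and edlib may
        return either path; both must pile up as the same canonical event."""
        assert refseq[49:53] == "CTAA"
        direct = refseq[:50] + refseq[52:102]   # 2D path
        pile = _Pileup(len(refseq))
        pile.add_hit(self._read_hit(refseq, 0, "50=2D50=", direct, "a", ed=2),
                     refseq)
        pile.add_hit(self._read_hit(refseq, 0, "50=1D1=1D48=",
                                    refseq[:50] + refseq[51] + refseq[53:102],
                                    "b", ed=2), refseq)
        assert pile.events == {(50, "del", "TA", ""): 2}

    def test_coverage_from_diff_array(self, refseq):
        pile = _Pileup(len(refseq))
        pile.add_hit(self._read_hit(refseq, 0, "100=", refseq[:100], ed=0),
                     refseq)
        pile.add_hit(self._read_hit(refseq, 50, "100=", refseq[50:150],
                                    "r2", ed=0), refseq)
        cov = pile.coverage()
        assert cov[0] == 1 and cov[75] == 2 and cov[120] == 1 and cov[150] == 0


class TestCrossConfirm:
    def _call(self, pool, support, pos=50, coverage=None):
        from fostag.validator import VariantCall
        return VariantCall("c", pool, pos, "sub", "A", "T", support,
                           coverage if coverage is not None else support, 99.0)

    def test_three_and_three_confirmed(self):
        out = cross_confirm([self._call("row", 3)], [self._call("col", 3)])
        assert len(out) == 1

    def test_three_and_two_rejected(self):
        assert cross_confirm([self._call("row", 3)],
                             [self._call("col", 2)]) == []

    def test_single_pool_rejected(self):
        assert cross_confirm([self._call("row", 10)], []) == []

    def test_allele_must_match(self):
        from fostag.validator import VariantCall
        other = VariantCall("c", "col", 50, "sub", "A", "G", 5, 5, 99.0)
        assert cross_confirm([self._call("row", 5)], [other]) == []

    def test_site_depth_semantics(self):
        row = [self._call("row", 2, coverage=5)]
        col = [self._call("col", 2, coverage=5)]
        assert cross_confirm(row, col, support_semantics="support") == []
        assert len(cross_confirm(row, col,
                                 support_semantics="site_depth")) == 1


class TestAnchoredCoverage:
    def _ref(self):
        return CloneReference("c", "A" * 6000, (3000, 3900), "+",
                              (2000, 4900), 0)

    def _obs(self, pid, pos1, pos2):
        return PairObservation(pid, "tag_anchored", "c",
                               _hit("c", pos1, "-", read_id=pid + "/1"),
                               _hit("c", pos2, "+", read_id=pid + "/2"), None)

    def test_20_base_overlap_counts_19_does_not(self):
        ref = self._ref()
        # tag-side mate ends exactly `ov` bases into the tag at 3000
        for ov, expect in ((20, 1), (19, 0)):
            obs = [self._obs("p", 3000 + ov - 100, 500)]
            cov = anchored_coverage(obs, ref, min_anchor=20)
            assert cov[3000 - 2000] == expect, ov

    def test_matches_bruteforce(self):
        ref = self._ref()
        rng = _stream(22, "anchored_brute")
        obs = []
        for i in range(200):
            p1 = int(rng.integers(2000, 4800))
            p2 = int(rng.integers(2000, 4800))
            obs.append(self._obs(f"p{i}", p1, p2))
        cov = anchored_coverage(obs, ref, min_anchor=20)
        ts, te = ref.tag_interval
        lo, hi = ref.roi
        brute = np.zeros(hi - lo, dtype=int)
        for o in obs:
            ovs = [min(h.pos + 100, te) - max(h.pos, ts)
                   for h in (o.hit1, o.hit2)]
            if max(ovs) < 20:
                continue
            for h in (o.hit1, o.hit2):
                for x in range(max(h.pos, lo), min(h.pos + 100, hi)):
                    brute[x - lo] += 1
        assert np.array_equal(cov, brute)

    def test_non_anchored_kinds_ignored(self):
        ref = self._ref()
        o = self._obs("p", 3100, 500)
        genomic = PairObservation("g", "genomic_only", "c", o.hit1, o.hit2,
                                  None)
        assert anchored_coverage([genomic], ref).sum() == 0


class TestClassifyClone:
    def _ref(self):
        return CloneReference("c", "A" * 6000, (3000, 3900), "+",
                              (2000, 4900), 0)

    def _ev(self, pool, tag=10, unflipped=0, calls=(), cov_value=1):
        ref = self._ref()
        n = ref.roi[1] - ref.roi[0]
        return PoolCloneEvidence("c", pool, n_pairs=tag,
                                 n_tag_anchored=tag, n_unflipped=unflipped,
                                 calls=list(calls),
                                 anchored_cov=np.full(n, cov_value,
                                                      dtype=np.int32))

    def _confirmed_calls(self):
        from fostag.validator import VariantCall
        return [VariantCall("c", "p", 3050, "sub", "A", "T", 5, 5, 99.0)]

    def test_no_data_beats_unflipped(self):
        v = classify_clone("c", self._ev("r", tag=0, unflipped=3),
                           self._ev("k", tag=0, unflipped=3), self._ref(),
                           ValidationParams())
        assert v.category == "no_data"

    def test_unflipped_beats_mutated(self):
        calls = self._confirmed_calls()
        v = classify_clone("c", self._ev("r", unflipped=2, calls=calls),
                           self._ev("k", unflipped=2, calls=calls),
                           self._ref(), ValidationParams())
        assert v.category == "unflipped"

    def test_mutated_beats_mutation_free(self):
        calls = self._confirmed_calls()
        v = classify_clone("c", self._ev("r", calls=calls),
                           self._ev("k", calls=calls), self._ref(),
                           ValidationParams())
        assert v.category == "mutated"
        assert v.confirmed_keys() == [(3050, "sub", "A", "T")]

    def test_full_versus_partial_coverage(self):
        full = classify_clone("c", self._ev("r"), self._ev("k"), self._ref(),
                              ValidationParams())
        assert full.category == "mutation_free_full"
        assert full.tag_coverage_fraction == 1.0
        ref = self._ref()
        holey = self._ev("k")
        holey.anchored_cov[:] = 0   # both pools dark over part of the tag
        partial = classify_clone("c", self._ev("r", cov_value=0), holey, ref,
                                 ValidationParams())
        assert partial.category == "mutation_free_partial"
        assert partial.tag_coverage_fraction == 0.0

    def test_unflipped_modes(self):
        one_sided = (self._ev("r", unflipped=2), self._ev("k", unflipped=0))
        cross = classify_clone("c", *one_sided, self._ref(),
                               ValidationParams(unflipped_mode="cross_pool"))
        single = classify_clone("c", *one_sided, self._ref(),
                                ValidationParams(unflipped_mode="single_pool"))
        assert cross.category == "mutation_free_full"
        assert single.category == "unflipped"


class TestSummary:
    def test_percent_half_up_rounding(self):
        assert percent(1, 8) == 12.5
        assert percent(1, 400) == 0.3   # 0.25 rounds up, not to even
        assert percent(0, 10) == 0.0
        with pytest.raises(ValueError):
            percent(1, 0)

    def test_published_style_counts(self):
        """9580 of 10995 mutation-free -> 87.1 %; 8005 full -> 72.8 %."""
        cats = {}
        i = 0
        for cat, n in (("mutation_free_full", 8005),
                       ("mutation_free_partial", 1575),
                       ("mutated", 1000), ("unflipped", 415),
                       ("no_data", 37)):
            for _ in range(n):
                cats[f"c{i}"] = cat
                i += 1
        s = summarize_library(cats)
        assert s["total_with_data"] == 10995
        assert s["percent"]["mutation_free"] == 87.1
        assert s["percent"]["mutation_free_full"] == 72.8

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            summarize_library({})


class TestEndToEnd:
    def test_all_verdicts_match_truth(self, small_run):
        sc = small_run["scenario"]
        got = {cid: v.category for cid, v in small_run["verdicts"].items()}
        assert got == sc.expected_category

    def test_confirmed_variants_match_injected_truth(self, small_run):
        sc = small_run["scenario"]
        for cid, clone in sc.defective.items():
            v = small_run["verdicts"][cid]
            if clone.unflipped:
                continue
            assert sorted(v.confirmed_keys()) == \
                sorted(m.key() for m in clone.mutations), cid

    def test_mutation_histogram_strata(self, small_run):
        hist = mutation_histogram(small_run["verdicts"], small_run["refs"])
        assert hist == {"arm": 1, "junction": 1, "internal": 0, "flank": 0}

    def test_verdicts_table_shape(self, small_run):
        df = verdicts_table(small_run["verdicts"])
        assert len(df) == 8
        assert set(df["category"]) <= set(
            ("mutation_free_full", "mutation_free_partial", "mutated",
             "unflipped", "no_data"))

    def test_wider_window_keeps_anchored_pairs_superset(self, small_run):
        """Every pair concordant under the 2200-3700 window stays concordant
        under 2000-4000 (the looser 3000 +/- 1000 reading)."""
        refs = small_run["refs"]
        pairs = small_run["by_pool"]["plate1:col5"][:300]
        narrow, wide = set(), set()
        for p in pairs:
            h1, h2 = map_pair(p.pair_id, p.read1, p.read2, refs.index)
            for window, bag in (((2200, 3700), narrow), ((2000, 4000), wide)):
                o = classify_pair(h1, h2, refs, insert_window=window)
                if o.kind in ("tag_anchored", "unflipped_evidence"):
                    bag.add(p.pair_id)
        assert narrow and narrow <= wide

    def test_dedup_count_matches_truth_fragments(self, small_run):
        from fostag.validator import map_and_classify
        pairs = small_run["by_pool"]["plate1:col1"]
        obs = map_and_classify(pairs, small_run["refs"], ValidationParams())
        dedup = remove_duplicates(obs)
        n_none = sum(1 for o in obs if o.hit1 is None or o.hit2 is None)
        frags = {(p.clone_id, p.frag_start, p.frag_len)
                 for p, o in zip(pairs, obs)
                 if o.hit1 is not None and o.hit2 is not None}
        assert len(dedup) == n_none + len(frags)
        assert len(dedup) < len(obs)   # duplicates were present and removed
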