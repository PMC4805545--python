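"""Pooled-sequencing validation of engineered clone libraries.

Implements the NGS validation logic for row/column-pooled mate-pair
libraries of tagged fosmids:

* map pairs against the clone reference set (flipped constructs) plus the
  un-flipped-specific cassette sequence;
* classify pairs — tag-anchored (one mate in the tag, the other in
  clone-unique genomic flank, concordant ~3 kb apart), genomic-only,
  un-flipped evidence, discordant;
* remove PCR duplicates (identical placement of both mates);
* call substitutions and short indels in the region of interest (tag
  ± 1000 bp) per pool, scoring each candidate with a phred-scaled binomial
  tail against the sequencing-error null and filtering at score < 20;
* confirm variants between the row pool and the column pool of the same
  well (same position and allele, >= 3 supporting reads in each pool);
* count tag coverage from pairs anchored in the tag by >= 20 aligned bases;
* emit one verdict per clone: mutation-free with full tag coverage,
  mutation-free with partial coverage, mutated, un-flipped, or no data.

Random PCR/sequencing errors appear in one pool only, so cross-pool
confirmation suppresses them; real clone defects are present in both
aliquots of the same culture and survive.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from ._util import normalize_indel
from .cassettes import TagCassette
from .mapping import (UNFLIPPED_REF, AlignmentHit, KmerIndex, cigar_ops,
                      map_pair)
from .plate_pooling import PoolSet
from .read_simulator import MatePair
from .recombineering import EngineeredConstruct

CATEGORIES = ("mutation_free_full", "mutation_free_partial", "mutated",
              "unflipped", "no_data")


@dataclass(frozen=True)
class ValidationParams:
    """All thresholds of the validation pipeline (logged with every run).

    ``insert_window`` is the concordant mate-pair outer-distance window;
    the default matches the explicit mapping parameters (2200–3700 bp)
    rather than the looser 3000 ± 1000 description — both are selectable.
    ``unflipped_mode`` defaults to cross-pool confirmation for symmetry
    with variant confirmation; ``single_pool`` flags a clone on any
    evidence pair, the literal reading of the original rule.
    """

    insert_window: tuple[int, int] = (2200, 3700)
    min_anchor: int = 20
    min_cov: int = 3
    min_score: float = 20.0
    assumed_error: float = 0.01
    max_edits: int = 6
    kmer: int = 21
    roi_pad: int = 1000
    unflipped_mode: str = "cross_pool"     # or "single_pool"
    support_semantics: str = "support"     # or "site_depth"
    orientation: str = "rf"

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


@dataclass
class CloneReference:
    clone_id: str
    sequence: str              # intended tagged_flipped construct
    tag_interval: tuple[int, int]
    strand: str
    roi: tuple[int, int]
    unflipped_marker_offset: int   # tag-coords offset of the FRT-marker-FRT
                                   # block within the un-flipped insert


class ReferenceSet:
    """Per-clone flipped references, the shared un-flipped cassette sequence
    and the mapping index over both."""

    def __init__(self, constructs: dict[str, EngineeredConstruct],
                 cassette: TagCassette, roi_pad: int = 1000, kmer: int = 21):
        self.cassette = cassette
        u = cassette.unflipped_form
        frt_at = u.find(cassette.frt)
        marker_block_len = len(u) - len(cassette.flipped_form) + len(cassette.frt)
        self.unflipped_seq = u[frt_at:frt_at + marker_block_len]
        self.clones: dict[str, CloneReference] = {}
        refs = {UNFLIPPED_REF: self.unflipped_seq}
        for cid, c in constructs.items():
            s, e = c.tag_interval
            roi = (max(0, s - roi_pad), min(len(c.sequence), e + roi_pad))
            self.clones[cid] = CloneReference(cid, c.sequence, (s, e),
                                              c.strand, roi, frt_at)
            refs[cid] = c.sequence
        self.refs = refs
        self.index = KmerIndex(refs, k=kmer)

    def implied_unflipped_span(self, clone_id: str, marker_hit: AlignmentHit,
                               genomic_hit: AlignmentHit) -> int:
        """Outer distance of a (marker-mate, genomic-mate) pair computed in
        the coordinates of the clone's un-flipped molecule."""
        ref = self.clones[clone_id]
        s, e = ref.tag_interval
        u_len = len(self.cassette.unflipped_form)
        if ref.strand == "+":
            m_start = s + ref.unflipped_marker_offset + marker_hit.pos
        else:
            m_start = (s + u_len - ref.unflipped_marker_offset
                       - marker_hit.pos - marker_hit.aligned_len)
        m_end = m_start + marker_hit.aligned_len
        delta = u_len - (e - s)
        g_start = genomic_hit.pos + (delta if genomic_hit.pos >= e else 0)
        g_end = g_start + genomic_hit.aligned_len
        return max(m_end, g_end) - min(m_start, g_start)


@dataclass(frozen=True)
class PairObservation:
    pair_id: str
    kind: str        # tag_anchored | genomic_only | unflipped_evidence |
                     # discordant | unmapped
    clone_id: str | None
    hit1: AlignmentHit | None
    hit2: AlignmentHit | None
    insert: int | None


def classify_pair(hit1: AlignmentHit | None, hit2: AlignmentHit | None,
                  refs: ReferenceSet,
                  insert_window: tuple[int, int] = (2200, 3700),
                  orientation: str = "rf") -> PairObservation:
    """Classify one mapped pair.

    tag-anchored: one mate overlaps the tag interval, the other lies in the
    genomic flank, outer distance inside the window, reverse-forward
    orientation.  Un-flipped evidence: one mate on the un-flipped cassette
    sequence, the other on a clone at a distance consistent with the
    un-flipped molecule.
    """
    pid = (hit1 or hit2).read_id.rsplit("/", 1)[0] if (hit1 or hit2) else ""
    if hit1 is None or hit2 is None or not (hit1.unique and hit2.unique):
        return PairObservation(pid, "unmapped", None, hit1, hit2, None)
    r1, r2 = hit1.reference_id, hit2.reference_id
    lo, hi = insert_window
    if UNFLIPPED_REF in (r1, r2):
        marker, genomic = (hit1, hit2) if r1 == UNFLIPPED_REF else (hit2, hit1)
        if genomic.reference_id == UNFLIPPED_REF:
            return PairObservation(pid, "discordant", None, hit1, hit2, None)
        cid = genomic.reference_id
        span = refs.implied_unflipped_span(cid, marker, genomic)
        kind = "unflipped_evidence" if lo <= span <= hi else "discordant"
        return PairObservation(pid, kind, cid, hit1, hit2, span)
    if r1 != r2:
        return PairObservation(pid, "discordant", None, hit1, hit2, None)
    cid = r1
    left, right = sorted((hit1, hit2), key=lambda h: h.pos)
    span = right.pos + right.aligned_len - left.pos
    concordant_strands = ((left.strand, right.strand) == ("-", "+")
                          if orientation == "rf"
                          else (left.strand, right.strand) == ("+", "-"))
    if not concordant_strands or not lo <= span <= hi:
        return PairObservation(pid, "discordant", cid, hit1, hit2, span)
    ts, te = refs.clones[cid].tag_interval
    in_tag = [min(h.pos + h.aligned_len, te) - max(h.pos, ts) > 0
              for h in (left, right)]
    kind = "tag_anchored" if any(in_tag) else "genomic_only"
    return PairObservation(pid, kind, cid, hit1, hit2, span)


def map_and_classify(pairs: list[MatePair], refs: ReferenceSet,
                     params: ValidationParams) -> list[PairObservation]:
    out = []
    for p in pairs:
        h1, h2 = map_pair(p.pair_id, p.read1, p.read2, refs.index,
                          max_edits=params.max_edits)
        out.append(classify_pair(h1, h2, refs, params.insert_window,
                                 params.orientation))
    return out


def remove_duplicates(obs: list[PairObservation]) -> list[PairObservation]:
    """Keep one pair per identical (reference, position, strand) placement
    of both mates; idempotent."""
    seen = set()
    out = []
    for o in obs:
        if o.hit1 is None or o.hit2 is None:
            out.append(o)
            continue
        key = tuple(sorted(((h.reference_id, h.pos, h.strand)
                            for h in (o.hit1, o.hit2))))
        if key in seen:
            continue
        seen.add(key)
        out.append(o)
    return out


# ---------------------------------------------------------------------------
# variant calling

@dataclass(frozen=True)
class VariantCall:
    clone_id: str
    pool_id: str
    pos: int         # 0-based on the clone's flipped reference
    kind: str        # sub | del | ins
    ref: str
    alt: str
    support: int
    coverage: int
    score: float

    def key(self) -> tuple:
        return (self.pos, self.kind, self.ref, self.alt)




def phred_binomial_score(support: int, coverage: int, error_rate: float) -> float:
    """Phred-scaled probability of >= support error reads among coverage
    draws under the sequencing-error null."""
    if support == 0:
        return 0.0
    p = float(stats.binom.sf(support - 1, coverage, error_rate))
    if p <= 0.0:
        return 1000.0
    return min(1000.0, -10.0 * math.log10(p))


class _Pileup:
    """Coverage (difference array) and per-event support for one clone/pool."""

    def __init__(self, ref_len: int):
        self.diff = np.zeros(ref_len + 1, dtype=np.int32)
        self.events: dict[tuple, int] = {}
        self._cov = None

    def add_hit(self, hit: AlignmentHit, refseq: str, max_indel: int = 10,
                merge_gap: int = 3):
        """Record one aligned read.

        Alignment paths through indels are not unique (a 2-bp deletion in a
        repeat-free context can still come back as 1D1=1D), so non-match
        operations within ``merge_gap`` reference bases of an indel are
        merged into a single replacement event, trimmed to its minimal
        allele and left-aligned — every path then yields the same key.
        """
        self.diff[hit.pos] += 1
        self.diff[hit.pos + hit.aligned_len] -= 1
        self._cov = None
        # (ref_start, ref_end, read_start, read_end, has_indel)
        events: list[list] = []
        rpos, qpos = hit.pos, 0
        for n, op in cigar_ops(hit.cigar):
            if op in "=M":
                rpos += n
                qpos += n
            elif op == "X":
                events.append([rpos, rpos + n, qpos, qpos + n, False])
                rpos += n
                qpos += n
            elif op == "D":
                events.append([rpos, rpos + n, qpos, qpos, True])
                rpos += n
            elif op == "I":
                events.append([rpos, rpos, qpos, qpos + n, True])
                qpos += n
        merged: list[list] = []
        for ev in events:
            if merged and (ev[4] or merged[-1][4]) \
                    and ev[0] - merged[-1][1] <= merge_gap:
                merged[-1][1], merged[-1][3] = ev[1], ev[3]
                merged[-1][4] = merged[-1][4] or ev[4]
            else:
                merged.append(ev)
        for rs, re_, qs, qe, has_indel in merged:
            if not has_indel:
                for i in range(re_ - rs):
                    self._count((rs + i, "sub", refseq[rs + i], hit.seq[qs + i]))
                continue
            ref_a, alt_a = refseq[rs:re_], hit.seq[qs:qe]
            while ref_a and alt_a and ref_a[0] == alt_a[0]:
                rs += 1
                ref_a, alt_a = ref_a[1:], alt_a[1:]
            while ref_a and alt_a and ref_a[-1] == alt_a[-1]:
                ref_a, alt_a = ref_a[:-1], alt_a[:-1]
            if not ref_a and not alt_a:
                continue
            if len(ref_a) == 1 and len(alt_a) == 1:
                self._count((rs, "sub", ref_a, alt_a))
            elif not alt_a and len(ref_a) <= max_indel:
                p, r, a = normalize_indel(refseq, rs, "del", ref_a, "")
                self._count((p, "del", r, a))
            elif not ref_a and len(alt_a) <= max_indel:
                p, r, a = normalize_indel(refseq, rs, "ins", "", alt_a)
                self._count((p, "ins", r, a))
            elif len(ref_a) <= max_indel and len(alt_a) <= max_indel:
                self._count((rs, "mnp", ref_a, alt_a))

    def _count(self, key: tuple) -> None:
        self.events[key] = self.events.get(key, 0) + 1

    def coverage(self) -> np.ndarray:
        if self._cov is None:
            self._cov = np.cumsum(self.diff[:-1])
        return self._cov


def call_variants(pileup: _Pileup, clone_id: str, pool_id: str,
                  roi: tuple[int, int], params: ValidationParams
                  ) -> list[VariantCall]:
    """Score pileup events in the ROI and keep those with score >= cutoff."""
    cov = pileup.coverage()
    calls = []
    for (pos, kind, ref, alt), support in sorted(pileup.events.items()):
        if not roi[0] <= pos < roi[1]:
            continue
        n = int(cov[pos])
        if n <= 0:
            continue
        score = phred_binomial_score(min(support, n), n, params.assumed_error)
        if score >= params.min_score:
            calls.append(VariantCall(clone_id, pool_id, pos, kind, ref, alt,
                                     support, n, score))
    return calls


def cross_confirm(row_calls: list[VariantCall], col_calls: list[VariantCall],
                  min_cov: int = 3, support_semantics: str = "support"
                  ) -> list[tuple[VariantCall, VariantCall]]:
    """Variants present with identical (position, allele) in both pools,
    each with >= min_cov supporting reads (or site depth, if configured)."""
    def strong(c: VariantCall) -> bool:
        v = c.support if support_semantics == "support" else c.coverage
        return v >= min_cov

    by_key = {c.key(): c for c in row_calls if strong(c)}
    out = []
    for c in col_calls:
        if strong(c) and c.key() in by_key:
            out.append((by_key[c.key()], c))
    return out


# ---------------------------------------------------------------------------
# anchored coverage and verdicts

def anchored_coverage(obs: list[PairObservation], ref: CloneReference,
                      min_anchor: int = 20) -> np.ndarray:
    """Per-base coverage over the ROI from pairs whose tag-side mate
    overlaps the tag by >= min_anchor aligned bases."""
    ts, te = ref.tag_interval
    lo, hi = ref.roi
    diff = np.zeros(hi - lo + 1, dtype=np.int32)
    for o in obs:
        if o.kind != "tag_anchored":
            continue
        overlaps = [min(h.pos + h.aligned_len, te) - max(h.pos, ts)
                    for h in (o.hit1, o.hit2)]
        if max(overlaps) < min_anchor:
            continue
        for h in (o.hit1, o.hit2):
            a = max(h.pos, lo)
            b = min(h.pos + h.aligned_len, hi)
            if a < b:
                diff[a - lo] += 1
                diff[b - lo] -= 1
    return np.cumsum(diff[:-1])


@dataclass
class PoolCloneEvidence:
    """What one pool says about one clone."""

    clone_id: str
    pool_id: str
    n_pairs: int = 0
    n_tag_anchored: int = 0
    n_unflipped: int = 0
    calls: list[VariantCall] = field(default_factory=list)
    anchored_cov: np.ndarray | None = None


@dataclass
class CloneVerdict:
    clone_id: str
    category: str
    confirmed: list[tuple[VariantCall, VariantCall]]
    tag_coverage_fraction: float
    evidence: dict[str, dict]    # per pool: counts

    def confirmed_keys(self) -> list[tuple]:
        return [r.key() for r, _ in self.confirmed]


def classify_clone(clone_id: str, row_ev: PoolCloneEvidence,
                   col_ev: PoolCloneEvidence, ref: CloneReference,
                   params: ValidationParams) -> CloneVerdict:
    confirmed = cross_confirm(row_ev.calls, col_ev.calls, params.min_cov,
                              params.support_semantics)
    ts, te = ref.tag_interval
    lo = ref.roi[0]
    tag_cov = np.zeros(te - ts, dtype=np.int64)
    for ev in (row_ev, col_ev):
        if ev.anchored_cov is not None:
            tag_cov += ev.anchored_cov[ts - lo:te - lo]
    frac = float(np.mean(tag_cov > 0)) if len(tag_cov) else 0.0
    if params.unflipped_mode == "cross_pool":
        unflipped = row_ev.n_unflipped >= 1 and col_ev.n_unflipped >= 1
    else:
        unflipped = row_ev.n_unflipped + col_ev.n_unflipped >= 1
    if row_ev.n_tag_anchored == 0 and col_ev.n_tag_anchored == 0:
        category = "no_data"
    elif unflipped:
        category = "unflipped"
    elif confirmed:
        category = "mutated"
    elif frac >= 1.0:
        category = "mutation_free_full"
    else:
        category = "mutation_free_partial"
    evidence = {ev.pool_id: {"pairs": ev.n_pairs,
                             "tag_anchored": ev.n_tag_anchored,
                             "unflipped": ev.n_unflipped,
                             "calls": len(ev.calls)}
                for ev in (row_ev, col_ev)}
    return CloneVerdict(clone_id, category, confirmed, frac, evidence)


# ---------------------------------------------------------------------------
# library summary

def _round1_half_up(x: float) -> float:
    from decimal import ROUND_HALF_UP, Decimal

    return float(Decimal(repr(x)).quantize(Decimal("0.1"),
                                           rounding=ROUND_HALF_UP))


def percent(count: int, total: int) -> float:
    """Percentage rounded half-up to one decimal, as printed in reports."""
    if total <= 0:
        raise ValueError("total must be positive")
    return _round1_half_up(100.0 * count / total)


def summarize_library(verdicts: dict[str, CloneVerdict] | dict[str, str]) -> dict:
    """Per-category counts and percentages over clones with any data."""
    if not verdicts:
        raise ValueError("no verdicts to summarize")
    cats = {cid: (v.category if isinstance(v, CloneVerdict) else v)
            for cid, v in verdicts.items()}
    counts = {c: 0 for c in CATEGORIES}
    for c in cats.values():
        counts[c] += 1
    total = sum(n for c, n in counts.items() if c != "no_data")
    summary = {"counts": counts, "total_with_data": total,
               "total_clones": len(cats)}
    if total > 0:
        free = counts["mutation_free_full"] + counts["mutation_free_partial"]
        summary["percent"] = {
            "mutation_free": percent(free, total),
            "mutation_free_full": percent(counts["mutation_free_full"], total),
            "mutation_free_partial": percent(counts["mutation_free_partial"],
                                             total),
            "mutated": percent(counts["mutated"], total),
            "unflipped": percent(counts["unflipped"], total),
        }
    return summary


# ---------------------------------------------------------------------------
# pipeline

def _pool_evidence(obs: list[PairObservation], pool_id: str,
                   refs: ReferenceSet, params: ValidationParams
                   ) -> dict[str, PoolCloneEvidence]:
    """Dedup one pool's observations and reduce them per clone."""
    dedup = remove_duplicates(obs)
    by_clone: dict[str, list[PairObservation]] = {}
    for o in dedup:
        if o.clone_id is not None:
            by_clone.setdefault(o.clone_id, []).append(o)
    out: dict[str, PoolCloneEvidence] = {}
    for cid, clone_obs in by_clone.items():
        ref = refs.clones[cid]
        ev = PoolCloneEvidence(cid, pool_id, n_pairs=len(clone_obs))
        pile = _Pileup(len(ref.sequence))
        for o in clone_obs:
            if o.kind == "unflipped_evidence":
                ev.n_unflipped += 1
            elif o.kind in ("tag_anchored", "genomic_only"):
                if o.kind == "tag_anchored":
                    ev.n_tag_anchored += 1
                for h in (o.hit1, o.hit2):
                    if h.reference_id == cid:
                        pile.add_hit(h, ref.sequence)
        ev.calls = call_variants(pile, cid, pool_id, ref.roi, params)
        ev.anchored_cov = anchored_coverage(clone_obs, ref, params.min_anchor)
        out[cid] = ev
    return out


def validate_pools(by_pool: dict[str, list[MatePair]], refs: ReferenceSet,
                   pools: PoolSet,
                   params: ValidationParams = ValidationParams()
                   ) -> dict[str, CloneVerdict]:
    """Run the full validation on per-pool mate pairs; one verdict per
    clone on the plate (clones with no reads at all come out no_data)."""
    pool_ev: dict[str, dict[str, PoolCloneEvidence]] = {}
    for pool_id, pairs in by_pool.items():
        obs = map_and_classify(pairs, refs, params)
        pool_ev[pool_id] = _pool_evidence(obs, pool_id, refs, params)
    verdicts: dict[str, CloneVerdict] = {}
    for cid in pools.well_of:
        row_pool, col_pool = pools.pools_of(cid)
        ref = refs.clones[cid]
        row = pool_ev.get(row_pool, {}).get(cid) \
            or PoolCloneEvidence(cid, row_pool,
                                 anchored_cov=np.zeros(ref.roi[1] - ref.roi[0],
                                                       dtype=np.int32))
        col = pool_ev.get(col_pool, {}).get(cid) \
            or PoolCloneEvidence(cid, col_pool,
                                 anchored_cov=np.zeros(ref.roi[1] - ref.roi[0],
                                                       dtype=np.int32))
        verdicts[cid] = classify_clone(cid, row, col, ref, params)
    return verdicts


def mutation_histogram(verdicts: dict[str, CloneVerdict],
                       refs: ReferenceSet, arm_len: int = 50,
                       junction_width: int = 10) -> dict[str, int]:
    """Confirmed-variant counts stratified by arm / junction / cassette
    interior / flank position relative to the tag insert."""
    hist = {"arm": 0, "junction": 0, "internal": 0, "flank": 0}
    for v in verdicts.values():
        ref = refs.clones[v.clone_id]
        s, e = ref.tag_interval
        for (pos, _, _, _) in v.confirmed_keys():
            if s - arm_len <= pos < s or e <= pos < e + arm_len:
                hist["arm"] += 1
            elif s <= pos < s + junction_width or e - junction_width <= pos < e:
                hist["junction"] += 1
            elif s <= pos < e:
                hist["internal"] += 1
            else:
                hist["flank"] += 1
    return hist


def verdicts_table(verdicts: dict[str, CloneVerdict]):
    import pandas as pd

    rows = []
    for cid in sorted(verdicts):
        v = verdicts[cid]
        rows.append({
            "clone_id": cid,
            "category": v.category,
            "tag_coverage_fraction": round(v.tag_coverage_fraction, 4),
            "n_confirmed_variants": len(v.confirmed),
            "confirmed": ";".join(
                f"{p}:{k}:{r}>{a}" for p, k, r, a in v.confirmed_keys()),
        })
    return pd.DataFrame(rows)
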