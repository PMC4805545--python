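"""Simplified seed-and-extend read mapping with pair-aware resolution.

The validation logic needs placements, not a production aligner: reads are
seeded with exact k-mers into an index over the clone reference set and
extended with banded edit-distance alignment (edlib), keeping the unique
best hit.  The tag cassette is identical across all clones, so tag-internal
reads are inherently multi-mapping; as in concordant-only paired mapping,
the pair is resolved through the mate that lands in clone-unique genomic
sequence — the essence of the mate-pair validation strategy.

Real-data mode ingests standard SAM records instead (``ingest_sam``).
"""
from __future__ import annotations

import re
from dataclasses import dataclass

import edlib

from ._util import revcomp

#: reference id of the un-flipped-specific sequence (the FRT-flanked
#: selection operon); reads mapping here are evidence the cassette was
#: never excised.
UNFLIPPED_REF = "unflipped_cassette"

_CIG_RE = re.compile(r"(\d+)([=XIDM])")


@dataclass(frozen=True)
class AlignmentHit:
    """One read placement. ``seq`` is the read oriented to the reference
    forward strand (SAM convention); ``cigar`` uses =/X/I/D operations with
    I consuming read bases and D consuming reference bases."""

    read_id: str
    reference_id: str
    pos: int
    strand: str
    aligned_len: int       # reference span
    cigar: str
    edit_distance: int
    unique: bool
    seq: str

    def __post_init__(self):
        if self.aligned_len > len(self.seq) + self.edit_distance:
            raise ValueError("aligned length inconsistent with read length")


def cigar_ops(cigar: str):
    return [(int(n), op) for n, op in _CIG_RE.findall(cigar)]


def _ref_span(cigar: str) -> int:
    return sum(n for n, op in cigar_ops(cigar) if op in "=XDM")


class KmerIndex:
    """Exact k-mer index over a reference set (forward strand)."""

    def __init__(self, refs: dict[str, str], k: int = 21):
        self.refs = refs
        self.k = k
        self.index: dict[str, list[tuple[str, int]]] = {}
        for rid, seq in refs.items():
            for i in range(len(seq) - k + 1):
                self.index.setdefault(seq[i:i + k], []).append((rid, i))

    def seed_candidates(self, read: str, n_seeds: int = 5
                        ) -> dict[tuple[str, str], set[int]]:
        """Candidate (ref, strand) -> approximate start diagonals."""
        k = self.k
        cands: dict[tuple[str, str], set[int]] = {}
        for strand, seq in (("+", read), ("-", revcomp(read))):
            span = len(seq) - k
            if span < 0:
                continue
            step = max(1, span // max(1, n_seeds - 1))
            for off in range(0, span + 1, step):
                for rid, pos in self.index.get(seq[off:off + k], ()):
                    diags = cands.setdefault((rid, strand), set())
                    diag = pos - off
                    # collapse diagonals that differ only by small indels
                    if not any(abs(diag - d) <= 8 for d in diags):
                        diags.add(diag)
        return cands


def _align_at(read_id: str, oriented: str, rid: str, ref: str, diag: int,
              max_edits: int, pad: int = 12) -> AlignmentHit | None:
    lo = max(0, diag - pad)
    hi = min(len(ref), diag + len(oriented) + pad)
    res = edlib.align(oriented, ref[lo:hi], mode="HW", task="path", k=max_edits)
    if res["editDistance"] < 0:
        return None
    start, end = res["locations"][0]
    return AlignmentHit(read_id, rid, lo + start, "+", end - start + 1,
                        res["cigar"], res["editDistance"], True, oriented)


def _strandify(hit: AlignmentHit, strand: str) -> AlignmentHit:
    if strand == "+":
        return hit
    return AlignmentHit(hit.read_id, hit.reference_id, hit.pos, "-",
                        hit.aligned_len, hit.cigar, hit.edit_distance,
                        hit.unique, hit.seq)


def align_read(read_id: str, read: str, index: KmerIndex, max_edits: int = 6,
               restrict_refs: set[str] | None = None) -> list[AlignmentHit]:
    """All best-scoring placements of one read (empty list if unmapped)."""
    cands = index.seed_candidates(read)
    hits: list[AlignmentHit] = []
    for (rid, strand), diags in cands.items():
        if restrict_refs is not None and rid not in restrict_refs:
            continue
        oriented = read if strand == "+" else revcomp(read)
        for diag in diags:
            h = _align_at(read_id, oriented, rid, index.refs[rid], diag, max_edits)
            if h is not None:
                hits.append(_strandify(h, strand))
    if not hits:
        return []
    best = min(h.edit_distance for h in hits)
    out, seen = [], set()
    for h in sorted(hits, key=lambda h: (h.edit_distance, h.reference_id, h.pos)):
        if h.edit_distance > best:
            break
        key = (h.reference_id, h.pos, h.strand)
        if key not in seen:
            seen.add(key)
            out.append(h)
    if len(out) > 1:
        out = [AlignmentHit(h.read_id, h.reference_id, h.pos, h.strand,
                            h.aligned_len, h.cigar, h.edit_distance, False,
                            h.seq) for h in out]
    return out


def map_reads(reads: list[tuple[str, str]], index: KmerIndex,
              max_edits: int = 6) -> dict[str, list[AlignmentHit]]:
    """Best unique placement (or multi/unmapped) for each (read_id, seq)."""
    return {rid: align_read(rid, seq, index, max_edits) for rid, seq in reads}


def map_pair(pair_id: str, read1: str, read2: str, index: KmerIndex,
             max_edits: int = 6, anchor_limit: int = 6
             ) -> tuple[AlignmentHit | None, AlignmentHit | None]:
    """Pair-aware mapping: anchor on the mate with fewer candidate
    references (clone-unique genomic sequence), then place the other mate
    on the anchor's reference or the un-flipped cassette reference.

    Returns the chosen (hit1, hit2); a mate is None when unmapped, and a
    hit with ``unique=False`` marks an unresolvable multi-mapper.
    """
    c1 = index.seed_candidates(read1)
    c2 = index.seed_candidates(read2)
    nrefs1 = len({rid for rid, _ in c1})
    nrefs2 = len({rid for rid, _ in c2})
    if min(nrefs1, nrefs2, 10**9) > anchor_limit or (not c1 and not c2):
        return (None, None)
    if nrefs1 <= nrefs2 and c1:
        anchor_read, other_read, anchor_first = read1, read2, True
    else:
        anchor_read, other_read, anchor_first = read2, read1, False
    a_hits = align_read(pair_id + ("/1" if anchor_first else "/2"),
                        anchor_read, index, max_edits)
    if not a_hits:
        return (None, None)
    if not a_hits[0].unique:
        return (a_hits[0], None) if anchor_first else (None, a_hits[0])
    anchor = a_hits[0]
    if anchor.reference_id == UNFLIPPED_REF:
        allowed = None  # genomic mate is clone-unique; let it pick its clone
    else:
        allowed = {anchor.reference_id, UNFLIPPED_REF}
    o_hits = align_read(pair_id + ("/2" if anchor_first else "/1"),
                        other_read, index, max_edits, restrict_refs=allowed)
    other = o_hits[0] if o_hits else None
    if other is not None and not other.unique:
        # prefer the placement on the anchor's reference when tied
        on_anchor = [h for h in o_hits if h.reference_id == anchor.reference_id]
        if len(on_anchor) == 1:
            other = AlignmentHit(other.read_id, on_anchor[0].reference_id,
                                 on_anchor[0].pos, on_anchor[0].strand,
                                 on_anchor[0].aligned_len, on_anchor[0].cigar,
                                 on_anchor[0].edit_distance, True,
                                 on_anchor[0].seq)
        else:
            other = None
    return (anchor, other) if anchor_first else (other, anchor)


# ---------------------------------------------------------------------------
# SAM interchange (real-data mode)

def write_sam(hits: list[AlignmentHit], refs: dict[str, str], path: str) -> None:
    import pysam

    names = list(refs)
    header = {"HD": {"VN": "1.6", "SO": "unknown"},
              "SQ": [{"SN": n, "LN": len(refs[n])} for n in names]}
    with pysam.AlignmentFile(path, "w", header=header) as out:
        for h in hits:
            a = pysam.AlignedSegment(out.header)
            a.query_name = h.read_id
            a.query_sequence = h.seq
            a.reference_id = names.index(h.reference_id)
            a.reference_start = h.pos
            a.cigarstring = h.cigar
            a.mapping_quality = 60 if h.unique else 0
            a.flag = 16 if h.strand == "-" else 0
            a.set_tag("NM", h.edit_distance)
            out.write(a)


def ingest_sam(path: str) -> list[AlignmentHit]:
    """Convert pre-aligned SAM records to AlignmentHits.

    Secondary and supplementary alignments are dropped; unmapped records
    are skipped.  Malformed records raise with the record name."""
    import pysam

    hits = []
    with pysam.AlignmentFile(path, "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_secondary or rec.is_supplementary or rec.is_unmapped:
                continue
            try:
                nm = rec.get_tag("NM") if rec.has_tag("NM") else 0
                hits.append(AlignmentHit(
                    rec.query_name, rec.reference_name, rec.reference_start,
                    "-" if rec.is_reverse else "+",
                    rec.reference_length or _ref_span(rec.cigarstring),
                    rec.cigarstring, int(nm), rec.mapping_quality > 0,
                    rec.query_sequence))
            except (TypeError, ValueError) as exc:
                raise ValueError(f"malformed SAM record {rec.query_name!r}: {exc}")
    return hits
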