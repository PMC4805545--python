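"""In-silico two-step C-terminal tagging of fosmid clones.

The engineering pipeline mirrors liquid-culture recombineering in E. coli:

1. design 50-bp homology arms abutting the stop codon of the target gene;
2. insert a selectable pre-tagging cassette between the last sense codon and
   the stop codon (homologous recombination with the synthetic oligo arms —
   the step where oligo synthesis errors enter real clones);
3. exchange the pre-tag marker for the full tag cassette via the shared
   flank epitopes (restriction-fragment exchange, no PCR, hence no new
   mutations at this step);
4. excise the FRT-flanked selection operon with Flp recombinase, leaving a
   single in-frame FRT scar ("flip-out").

The endogenous stop codon and 3'UTR remain immediately downstream of the
tag, so the fusion keeps its native regulation.  All constructs carry an
edit log that replays from the base fosmid to the engineered sequence.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ._util import STOP_CODONS, has_inframe_stop, revcomp
from .cassettes import PreTagCassette, TagCassette
from .gene_models import FosmidClone, GeneModel, TagSite, tag_site


class EngineeringError(ValueError):
    pass


@dataclass(frozen=True)
class HomologyArms:
    """50-nt oligo arms in coding orientation.

    ``upstream`` ends immediately before the stop codon; ``downstream``
    starts at the stop codon.  ``insert_local`` is the construct-local
    coordinate of the insertion boundary; ``strand`` the gene strand.
    """

    upstream: str
    downstream: str
    insert_local: int
    strand: str

    @property
    def arm_len(self) -> int:
        return len(self.upstream)


@dataclass(frozen=True)
class Edit:
    """Replace ``removed`` with ``added`` at ``pos`` (coords at time of edit)."""

    pos: int
    removed: str
    added: str
    note: str = ""

    def apply(self, seq: str) -> str:
        if seq[self.pos:self.pos + len(self.removed)] != self.removed:
            raise EngineeringError(f"edit log out of sync at {self.pos}")
        return seq[:self.pos] + self.added + seq[self.pos + len(self.removed):]


@dataclass(frozen=True)
class EngineeredConstruct:
    base: FosmidClone
    gene_id: str
    strand: str
    state: str  # pretagged | tagged_unflipped | tagged_flipped
    sequence: str
    tag_interval: tuple[int, int]  # inserted cassette, construct coords
    edit_log: tuple[Edit, ...] = field(default_factory=tuple)

    @property
    def clone_id(self) -> str:
        return self.base.clone_id

    def replay(self) -> str:
        seq = self.base.sequence
        for edit in self.edit_log:
            seq = edit.apply(seq)
        return seq

    def tag_deleted(self) -> str:
        """Sequence with the inserted cassette removed (arms retained)."""
        s, e = self.tag_interval
        return self.sequence[:s] + self.sequence[e:]


def design_homology_arms(site: TagSite, fosmid: FosmidClone,
                         arm_len: int = 50) -> HomologyArms:
    """Arms flanking the insertion point, reported in coding orientation."""
    local = site.insert_at - fosmid.interval[0]
    if local < arm_len or local > len(fosmid.sequence) - arm_len:
        raise EngineeringError(
            f"{fosmid.clone_id}: tag site {local} within {arm_len} bp of clone edge")
    seq = fosmid.sequence
    if site.strand == "+":
        up = seq[local - arm_len:local]
        down = seq[local:local + arm_len]
    else:
        up = revcomp(seq[local:local + arm_len])
        down = revcomp(seq[local - arm_len:local])
    # the arm's 3' end abuts the stop codon, hence sits on a codon boundary;
    # read codons from that end when checking for premature stops
    if has_inframe_stop(up[len(up) % 3:]):
        raise EngineeringError(
            f"{fosmid.clone_id}: upstream arm contains an in-frame stop codon")
    return HomologyArms(up, down, local, site.strand)


def corrupt_oligo(arms: HomologyArms, sub_rate: float, indel_rate: float,
                  seed: int) -> HomologyArms:
    """Simulate oligonucleotide synthesis errors within the arms.

    Deterministic under ``seed``; substitutions and single-base indels are
    drawn independently per base, confined to the arm sequences.
    """
    rng = np.random.default_rng(seed)

    def mutate(arm: str) -> str:
        out = []
        for b in arm:
            if rng.random() < indel_rate:
                if rng.random() < 0.5:
                    continue  # deletion
                out.append("ACGT"[rng.integers(4)])  # insertion before base
            if rng.random() < sub_rate:
                b = "ACGT"[(("ACGT".index(b)) + 1 + int(rng.integers(3))) % 4]
            out.append(b)
        return "".join(out)

    return replace(arms, upstream=mutate(arms.upstream),
                   downstream=mutate(arms.downstream))


def _orient(seq: str, strand: str) -> str:
    return seq if strand == "+" else revcomp(seq)


def _count_mismatch(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def insert_pretag(fosmid: FosmidClone, gene: GeneModel, pretag: PreTagCassette,
                  arms: HomologyArms,
                  max_arm_mismatch: int = 2) -> EngineeredConstruct:
    """Insert the pre-tagging cassette between the last sense codon and the stop.

    Arm matching is exact-string comparison against the fosmid; up to
    ``max_arm_mismatch`` substitutions per arm are tolerated (recombineering
    proceeds on slightly imperfect oligos) and the oligo's bases are then
    propagated into the construct, which is how synthesis errors end up in
    real clones.  Length-changing oligo defects abort the insertion.
    """
    local, strand = arms.insert_local, arms.strand
    seq = fosmid.sequence
    if strand == "+":
        ref_up, ref_down = seq[local - arms.arm_len:local], seq[local:local + arms.arm_len]
        oligo_up, oligo_down = arms.upstream, arms.downstream
    else:
        ref_up = revcomp(seq[local:local + arms.arm_len])
        ref_down = revcomp(seq[local - arms.arm_len:local])
        oligo_up, oligo_down = arms.upstream, arms.downstream
    for name, ref, oligo in (("upstream", ref_up, oligo_up),
                             ("downstream", ref_down, oligo_down)):
        if len(oligo) != len(ref):
            raise EngineeringError(
                f"{fosmid.clone_id}: {name} arm length {len(oligo)} != {len(ref)} "
                "(indel in oligo), recombineering failed")
        mm = _count_mismatch(ref, oligo)
        if mm > max_arm_mismatch:
            raise EngineeringError(
                f"{fosmid.clone_id}: {name} arm has {mm} mismatches "
                f"(> {max_arm_mismatch}), recombineering failed")

    insert = _orient(pretag.sequence, strand)
    # genomic-orientation arm replacements (propagate oligo errors)
    if strand == "+":
        g_up, g_down = oligo_up, oligo_down
    else:
        g_up, g_down = revcomp(oligo_down), revcomp(oligo_up)
    removed = seq[local - arms.arm_len:local + arms.arm_len]
    added = g_up + insert + g_down
    edit = Edit(local - arms.arm_len, removed, added, note="insert_pretag")
    new_seq = edit.apply(seq)
    return EngineeredConstruct(
        base=fosmid, gene_id=gene.gene_id, strand=strand, state="pretagged",
        sequence=new_seq, tag_interval=(local, local + len(insert)),
        edit_log=(edit,))


def exchange_tag(construct: EngineeredConstruct,
                 cassette: TagCassette) -> EngineeredConstruct:
    """Replace the pre-tag with the full (un-flipped) tag cassette.

    The pre-tag flanks are shared with the cassette's terminal segments, so
    the exchange retains them exactly once.  Exchanging twice fails: the
    pre-tag marker is consumed by the first exchange.
    """
    if construct.state != "pretagged":
        raise EngineeringError(f"exchange_tag on state {construct.state}")
    strand = construct.strand
    s, e = construct.tag_interval
    present = _orient(construct.sequence[s:e], strand)
    if not (present.startswith(cassette.flank5) and present.endswith(cassette.flank3)):
        raise EngineeringError(
            f"{construct.clone_id}: pre-tag flanks not found; cassette exchange failed")
    new_insert = _orient(cassette.unflipped_form, strand)
    edit = Edit(s, construct.sequence[s:e], new_insert, note="exchange_tag")
    return replace(construct, state="tagged_unflipped",
                   sequence=edit.apply(construct.sequence),
                   tag_interval=(s, s + len(new_insert)),
                   edit_log=construct.edit_log + (edit,))


def flip_out(construct: EngineeredConstruct,
             cassette: TagCassette) -> EngineeredConstruct:
    """Flp-mediated excision of the selection operon between the two FRTs.

    Requires exactly two direct-orientation FRT sites; one FRT (the coding
    5' one) remains in frame after the tag.  Applying flip_out twice fails
    because only one FRT is left.
    """
    if construct.state != "tagged_unflipped":
        raise EngineeringError(f"flip_out on state {construct.state}")
    strand = construct.strand
    frt = _orient(cassette.frt, strand)
    seq = construct.sequence
    hits = []
    i = seq.find(frt)
    while i != -1:
        hits.append(i)
        i = seq.find(frt, i + 1)
    if len(hits) != 2:
        raise EngineeringError(
            f"{construct.clone_id}: expected 2 FRT sites, found {len(hits)}")
    i1, i2 = hits
    flen = len(frt)
    if strand == "+":
        # keep the genomic-left FRT (coding 5')
        edit = Edit(i1 + flen, seq[i1 + flen:i2 + flen], "", note="flip_out")
    else:
        # coding 5' FRT is the genomic-right one
        edit = Edit(i1, seq[i1:i2], "", note="flip_out")
    new_seq = edit.apply(seq)
    s = construct.tag_interval[0]
    flipped_len = len(cassette.flipped_form)
    new = replace(construct, state="tagged_flipped", sequence=new_seq,
                  tag_interval=(s, s + flipped_len),
                  edit_log=construct.edit_log + (edit,))
    assert _orient(new.sequence[s:s + flipped_len], strand) == cassette.flipped_form
    return new


@dataclass(frozen=True)
class FrameReport:
    length_in_frame: bool
    no_internal_stop: bool
    stop_codon_intact: bool
    utr3_intact: bool

    @property
    def ok(self) -> bool:
        return (self.length_in_frame and self.no_internal_stop
                and self.stop_codon_intact and self.utr3_intact)


def verify_frame(construct: EngineeredConstruct, gene: GeneModel) -> FrameReport:
    """Check the tagged_flipped construct forms a clean in-frame fusion.

    (a) inserted length is a multiple of three; (b) the insert, read in
    coding frame 0, has no stop codon; (c) the endogenous stop codon sits
    immediately downstream of the insert; (d) everything downstream of the
    insertion point (stop codon and 3'UTR included) is identical to the
    base fosmid.
    """
    if construct.state != "tagged_flipped":
        raise EngineeringError("verify_frame expects a tagged_flipped construct")
    s, e = construct.tag_interval
    strand = construct.strand
    insert = _orient(construct.sequence[s:e], strand)
    length_ok = (len(construct.sequence) - len(construct.base.sequence)) % 3 == 0 \
        and len(insert) % 3 == 0
    no_stop = not has_inframe_stop(insert)

    site = tag_site(gene)
    local = site.insert_at - construct.base.interval[0]
    if strand == "+":
        downstream_now = construct.sequence[e:]
        downstream_base = construct.base.sequence[local:]
        stop_now = downstream_now[:3]
    else:
        downstream_now = construct.sequence[:s]
        downstream_base = construct.base.sequence[:local]
        stop_now = revcomp(construct.sequence[s - 3:s])
    stop_ok = stop_now in STOP_CODONS and \
        stop_now == _orient(downstream_base[:3] if strand == "+"
                            else downstream_base[-3:], strand)
    utr_ok = downstream_now == downstream_base
    return FrameReport(length_ok, no_stop, stop_ok, utr_ok)


def engineer(gene: GeneModel, fosmid: FosmidClone, cassette: TagCassette,
             pretag: PreTagCassette, arm_len: int = 50,
             arms: HomologyArms | None = None) -> EngineeredConstruct:
    """Run design -> pre-tag -> exchange -> flip on one gene/clone pair."""
    site = tag_site(gene)
    if arms is None:
        arms = design_homology_arms(site, fosmid, arm_len)
    c = insert_pretag(fosmid, gene, pretag, arms)
    c = exchange_tag(c, cassette)
    return flip_out(c, cassette)
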