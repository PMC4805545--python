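"""Gene-model handling: annotation parsing, tag-site choice and clone selection.

C-terminal tagging places the tag immediately 5' of a gene's stop codon so
that the endogenous promoter, UTRs and stop codon keep regulating the fusion
protein.  For genes with several isoforms the tag goes to the most commonly
used C-terminus, i.e. the stop codon shared by the largest number of
isoforms.  A genomic clone is suitable for tagging a gene when it covers the
whole gene model plus a regulatory flank on each side (default 2.5 kb).

Coordinates are 0-based half-open internally; GFF3 (1-based, closed) is
converted at the I/O boundary.
"""
from __future__ import annotations

import os
import tempfile
from dataclasses import dataclass, field

import gffutils


class GFFParseError(ValueError):
    """Raised for malformed GFF3 input; the message names the offending line."""


@dataclass(frozen=True)
class Isoform:
    """One transcript's coding structure.

    ``cds_segments`` are 0-based half-open genomic intervals sorted by
    coordinate; the stop codon is assumed to be part of the terminal CDS
    segment.  ``stop_codon_pos`` is the genomic coordinate of the last CDS
    base with respect to the strand (the 3'-most coding base).
    """

    isoform_id: str
    cds_segments: tuple[tuple[int, int], ...]
    strand: str
    utr3: tuple[int, int] | None = None

    def __post_init__(self):
        segs = sorted(self.cds_segments)
        if any(s >= e for s, e in segs):
            raise ValueError(f"{self.isoform_id}: empty CDS segment")
        for (_, e1), (s2, _) in zip(segs, segs[1:]):
            if s2 < e1:
                raise ValueError(f"{self.isoform_id}: overlapping CDS segments")
        object.__setattr__(self, "cds_segments", tuple(segs))

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds_segments)

    @property
    def stop_codon_pos(self) -> int:
        """Genomic coordinate of the 3'-most CDS base w.r.t. strand."""
        if self.strand == "+":
            return self.cds_segments[-1][1] - 1
        return self.cds_segments[0][0]


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    strand: str
    isoforms: tuple[Isoform, ...]
    seqid: str = "."
    frame_ok: bool = True   # every isoform CDS length divisible by 3

    @property
    def span(self) -> tuple[int, int]:
        """Genomic span of the union of all isoform CDS (and 3'UTR) intervals."""
        starts, ends = [], []
        for iso in self.isoforms:
            starts.append(iso.cds_segments[0][0])
            ends.append(iso.cds_segments[-1][1])
            if iso.utr3 is not None:
                starts.append(iso.utr3[0])
                ends.append(iso.utr3[1])
        return min(starts), max(ends)


@dataclass(frozen=True)
class FosmidClone:
    """A single-copy genomic clone: an interval of the reference plus its sequence."""

    clone_id: str
    interval: tuple[int, int]
    sequence: str
    seqid: str = "."

    def __post_init__(self):
        s, e = self.interval
        if len(self.sequence) != e - s:
            raise ValueError(
                f"{self.clone_id}: sequence length {len(self.sequence)} != "
                f"interval length {e - s}")


@dataclass(frozen=True)
class TagSite:
    """Chosen C-terminal tagging site for a gene.

    ``stop_codon_pos`` is the 3'-most coding base of the winning stop;
    ``insert_at`` is the genomic coordinate at which the cassette is placed,
    i.e. the boundary between the last sense codon and the stop codon
    (cassette inserted before this coordinate on the plus strand, after it in
    genomic terms for minus-strand genes the arithmetic is symmetric).
    ``tie`` flags genes whose isoforms split evenly between several stops.
    """

    stop_codon_pos: int
    insert_at: int
    strand: str
    n_supporting: int
    tie: bool = False


def _check_gff_lines(path: str) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if len(line.split("\t")) != 9:
                raise GFFParseError(
                    f"{path}: line {lineno} is not 9 tab-separated fields: {line!r}")


def parse_gff(path: str | os.PathLike) -> tuple[list[GeneModel], list[str]]:
    """Parse a GFF3 file into gene models.

    Returns ``(genes, warnings)``.  Genes whose isoform CDS lengths are not
    divisible by 3 are returned with ``frame_ok=False`` and a warning record
    rather than silently dropped; downstream design excludes them.
    """
    path = os.fspath(path)
    _check_gff_lines(path)
    with open(path) as fh:
        if not any(line.strip() and not line.startswith("#") for line in fh):
            return [], []
    try:
        db = gffutils.create_db(path, ":memory:", merge_strategy="create_unique",
                                keep_order=True)
    except Exception as exc:  # gffutils raises several concrete types
        raise GFFParseError(f"{path}: {exc}") from exc

    genes: list[GeneModel] = []
    warnings: list[str] = []
    for g in db.features_of_type("gene"):
        isoforms = []
        frame_ok = True
        for t in db.children(g, featuretype=("mRNA", "transcript"), order_by="start"):
            cds = [(c.start - 1, c.end) for c in
                   db.children(t, featuretype="CDS", order_by="start")]
            if not cds:
                continue
            utr = [(u.start - 1, u.end) for u in
                   db.children(t, featuretype=("three_prime_UTR",), order_by="start")]
            iso = Isoform(t.id, tuple(cds), g.strand,
                          utr3=utr[0] if utr else None)
            if iso.cds_length % 3 != 0:
                frame_ok = False
                warnings.append(
                    f"{g.id}/{t.id}: CDS length {iso.cds_length} not divisible by 3")
            isoforms.append(iso)
        if not isoforms:
            warnings.append(f"{g.id}: no coding isoforms, skipped")
            continue
        genes.append(GeneModel(g.id, g.strand, tuple(isoforms),
                               seqid=g.seqid, frame_ok=frame_ok))
    return genes, warnings


def tag_site(gene: GeneModel) -> TagSite:
    """Choose the tagging site: the stop codon used by most isoforms.

    Ties are broken toward the 3'-most stop with respect to the strand and
    flagged, so a designer can review them.
    """
    if not gene.isoforms:
        raise ValueError(f"{gene.gene_id}: no isoforms")
    counts: dict[int, int] = {}
    for iso in gene.isoforms:
        counts[iso.stop_codon_pos] = counts.get(iso.stop_codon_pos, 0) + 1
    best_n = max(counts.values())
    winners = [p for p, n in counts.items() if n == best_n]
    tie = len(winners) > 1
    pos = max(winners) if gene.strand == "+" else min(winners)
    insert_at = pos - 2 if gene.strand == "+" else pos + 3
    return TagSite(pos, insert_at, gene.strand, best_n, tie)


def select_fosmid(gene: GeneModel, clones: list[FosmidClone],
                  min_flank: int = 2500) -> FosmidClone | None:
    """Pick a clone containing the gene span with >= min_flank on both sides.

    Among qualifying clones the one maximising the smaller of the two flanks
    wins; ties break lexicographically on clone_id.
    """
    gs, ge = gene.span
    best: tuple[int, str, FosmidClone] | None = None
    for clone in clones:
        if clone.seqid != gene.seqid:
            continue
        cs, ce = clone.interval
        up, down = gs - cs, ce - ge
        if up >= min_flank and down >= min_flank:
            key = (min(up, down), clone.clone_id)
            if best is None or key[0] > best[0] or (key[0] == best[0]
                                                    and key[1] < best[1]):
                best = (key[0], key[1], clone)
    if best is None:
        return None
    clone = best[2]
    cs, ce = clone.interval
    assert gs - cs >= min_flank and ce - ge >= min_flank
    return clone


def coverage_stats(genes: list[GeneModel], clones: list[FosmidClone],
                   min_flank: int = 2500) -> dict:
    """Fraction of genes covered by at least one suitable clone."""
    if not genes:
        raise ValueError("empty gene list")
    covered = sum(1 for g in genes
                  if select_fosmid(g, clones, min_flank) is not None)
    return {"covered": covered, "total": len(genes),
            "fraction": covered / len(genes)}


def is_single_exon_cds(gene: GeneModel) -> bool:
    """True iff every isoform's ORF is encoded in a single CDS segment."""
    return all(len(iso.cds_segments) == 1 for iso in gene.isoforms)


def has_alternative_c_termini(gene: GeneModel) -> bool:
    """True iff the gene's isoforms use >= 2 distinct stop codon positions."""
    return len({iso.stop_codon_pos for iso in gene.isoforms}) >= 2


def classification_report(genes: list[GeneModel], clones: list[FosmidClone],
                          min_flank: int = 2500) -> "pandas.DataFrame":
    """Per-gene TSV-ready report: selected clone and gene-model classes."""
    import pandas as pd

    rows = []
    for g in genes:
        clone = select_fosmid(g, clones, min_flank) if g.frame_ok else None
        site = tag_site(g)
        rows.append({
            "gene_id": g.gene_id,
            "strand": g.strand,
            "frame_ok": g.frame_ok,
            "clone_id": clone.clone_id if clone else "",
            "covered": clone is not None,
            "tag_stop_pos": site.stop_codon_pos,
            "tag_tie": site.tie,
            "single_exon_cds": is_single_exon_cds(g),
            "alternative_c_termini": has_alternative_c_termini(g),
        })
    return pd.DataFrame(rows)
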