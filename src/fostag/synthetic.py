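"""Deterministic synthetic genomes, gene models and plate scenarios.

These builders produce the inputs the toolkit is exercised on: random
genomic fosmids with embedded ORFs (clean coding frame, stop codon, UTRs
implicit in the flanks), multi-isoform variants with alternative
C-termini, and fully engineered 96-well plate scenarios with targeted
defects whose ground truth is known exactly.  Everything is a pure
function of the seed.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._util import revcomp
from .cassettes import load_registry
from .gene_models import FosmidClone, GeneModel, Isoform
from .plate_pooling import COLS, ROWS, PlateLayout, PoolSet, make_pools
from .read_simulator import (DefectiveClone, DefectSpec, Mutation,
                             apply_defects, make_mutation, realize_defective,
                             _stream)
from .recombineering import EngineeredConstruct, engineer

_STOPS = {"TAA", "TAG", "TGA"}
_SENSE = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
          if a + b + c not in _STOPS]


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(np.frombuffer(b"ACGT", "S1")[rng.integers(4, size=n)]
                   .tobytes().decode())


def random_orf(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + sense codons + TAA; total length 3 * n_codons."""
    body = "".join(np.array(_SENSE)[rng.integers(len(_SENSE), size=n_codons - 2)])
    return "ATG" + body + "TAA"


def make_gene_and_clone(rng: np.random.Generator, gene_id: str, clone_id: str,
                        strand: str = "+", fosmid_len: int = 8000,
                        cds_codons: int = 200,
                        alt_termini: bool = False
                        ) -> tuple[GeneModel, FosmidClone]:
    """One synthetic gene embedded mid-fosmid, with >= 2.5 kb flanks.

    ``alt_termini`` adds a second isoform whose terminal CDS exon ends at a
    different (genomically interior) stop position, modelling alternative
    C-termini; the 3'-most stop keeps a clean ORF context so tagging at the
    tie-broken site stays well-defined.
    """
    seqid = f"ref_{clone_id}"
    orf = random_orf(rng, cds_codons)
    L = len(orf)
    a = (fosmid_len - L) // 2
    genome = random_dna(rng, fosmid_len)
    insert = orf if strand == "+" else revcomp(orf)
    genome = genome[:a] + insert + genome[a + L:]
    iso1 = Isoform(f"{gene_id}.1", ((a, a + L),), strand)
    isoforms = [iso1]
    if alt_termini:
        # shared 5' CDS chunk plus a distinct, genomically interior last exon
        s = 3 * (cds_codons // 2)
        if strand == "+":
            seg2 = (a + s + 30, a + s + 30 + 3 * 10)
            iso2 = Isoform(f"{gene_id}.2", ((a, a + s), seg2), strand)
        else:
            seg2 = (a + L - s - 60, a + L - s - 30)
            iso2 = Isoform(f"{gene_id}.2", (seg2, (a + L - s, a + L)), strand)
        isoforms.append(iso2)
    gene = GeneModel(gene_id, strand, tuple(isoforms), seqid=seqid)
    clone = FosmidClone(clone_id, (0, fosmid_len), genome, seqid=seqid)
    return gene, clone


def engineering_fixture(seed: int = 0, n_genes: int = 20, fosmid_len: int = 8000
                        ) -> list[tuple[GeneModel, FosmidClone]]:
    """A mixed fixture: plus and minus strands and alternative-termini genes."""
    rng = _stream(seed, "engineering_fixture")
    out = []
    for i in range(n_genes):
        strand = "-" if i % 3 == 2 else "+"
        alt = i in (4, 11)
        out.append(make_gene_and_clone(
            rng, f"g{i:03d}", f"clone{i:03d}", strand=strand,
            fosmid_len=fosmid_len, alt_termini=alt))
    return out


def write_gff(genes: list[GeneModel], clones: list[FosmidClone],
              path: str) -> None:
    """Serialize gene models as GFF3 (1-based, closed intervals)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            gs, ge = g.span
            fh.write(f"{g.seqid}\t.\tgene\t{gs + 1}\t{ge}\t.\t{g.strand}\t."
                     f"\tID={g.gene_id}\n")
            for iso in g.isoforms:
                ts = iso.cds_segments[0][0]
                te = iso.cds_segments[-1][1]
                fh.write(f"{g.seqid}\t.\tmRNA\t{ts + 1}\t{te}\t.\t{g.strand}\t."
                         f"\tID={iso.isoform_id};Parent={g.gene_id}\n")
                for s, e in iso.cds_segments:
                    fh.write(f"{g.seqid}\t.\tCDS\t{s + 1}\t{e}\t.\t{g.strand}\t0"
                             f"\tID={iso.isoform_id}.cds;Parent={iso.isoform_id}\n")


def write_fasta(clones: list[FosmidClone], path: str) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    recs = [SeqRecord(Seq(c.sequence), id=c.seqid, description=c.clone_id)
            for c in clones]
    SeqIO.write(recs, path, "fasta")


@dataclass
class PlateScenario:
    """A fully realised plate: constructs, defects, pools and truth."""

    genes: dict[str, GeneModel]
    clones: dict[str, FosmidClone]
    constructs: dict[str, EngineeredConstruct]   # intended flipped references
    cassette: object
    pretag: object
    plate: PlateLayout
    pools: PoolSet
    defective: dict[str, DefectiveClone]
    expected_category: dict[str, str]


#: defect assignment used by the standard validation scenario: three clones
#: with a single homology-arm substitution, two with an un-excised selection
#: cassette, one with a 2-bp deletion at the arm/cassette junction.
STANDARD_DEFECTS = {5: "arm_sub", 20: "arm_sub", 40: "arm_sub",
                    10: "unflipped", 70: "unflipped", 55: "junction_del2"}


def _targeted_defect(kind: str, construct: EngineeredConstruct,
                     rng: np.random.Generator) -> tuple[list[Mutation], bool]:
    s, e = construct.tag_interval
    seq = construct.sequence
    cid = construct.clone_id
    if kind == "unflipped":
        return [], True
    if kind == "arm_sub":
        pos = int(s - 1 - rng.integers(40))   # inside the upstream-of-insert arm
        alt = "ACGT".replace(seq[pos], "")[rng.integers(3)]
        return [Mutation(cid, pos, "sub", seq[pos], alt, "arm")], False
    if kind == "junction_del2":
        pos = int(s + 2 + rng.integers(5))    # within the 10-bp junction stratum
        return [make_mutation(seq, cid, pos, "del", seq[pos:pos + 2], "",
                              "junction")], False
    raise ValueError(kind)


def build_plate_scenario(n_clones: int = 96, seed: int = 0,
                         defect_assignment: dict[int, str] | None = None,
                         defect_spec: DefectSpec | None = None,
                         fosmid_len: int = 8000,
                         plate_id: str = "plate1") -> PlateScenario:
    """Engineer ``n_clones`` synthetic genes, plate them row-major and apply
    defects.

    ``defect_assignment`` maps well index -> defect kind (targeted, known
    truth); alternatively ``defect_spec`` draws random stratified defects.
    """
    if n_clones > 96:
        raise ValueError("one plate holds at most 96 clones")
    registry = load_registry()
    cassette = registry["tags"]["sgfp_tag"]
    pretag = registry["pretag"]
    rng = _stream(seed, "scenario")
    genes, clones, constructs, defective, expected = {}, {}, {}, {}, {}
    plate = PlateLayout(plate_id)
    assignment = defect_assignment or {}
    for i in range(n_clones):
        strand = "-" if i % 4 == 3 else "+"
        gene, clone = make_gene_and_clone(rng, f"g{i:03d}", f"clone{i:03d}",
                                          strand=strand, fosmid_len=fosmid_len)
        construct = engineer(gene, clone, cassette, pretag)
        genes[gene.gene_id] = gene
        clones[clone.clone_id] = clone
        constructs[clone.clone_id] = construct
        row, col = ROWS[i // 12], COLS[i % 12]
        plate.place(row, col, clone.clone_id)
        if i in assignment:
            muts, unflipped = _targeted_defect(assignment[i], construct, rng)
            defective[clone.clone_id] = realize_defective(
                construct, cassette, muts, unflipped)
        elif defect_spec is not None:
            defective[clone.clone_id] = apply_defects(
                construct, cassette, defect_spec, seed)
        else:
            defective[clone.clone_id] = realize_defective(
                construct, cassette, [], False)
        d = defective[clone.clone_id]
        if d.unflipped:
            expected[clone.clone_id] = "unflipped"
        elif d.mutations:
            expected[clone.clone_id] = "mutated"
        else:
            expected[clone.clone_id] = "mutation_free_full"
    pools = make_pools(plate)
    return PlateScenario(genes, clones, constructs, cassette, pretag,
                         plate, pools, defective, expected)
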