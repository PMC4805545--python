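"""96-well plates and the 8-row + 12-column pooling design.

Each clone grows in one well of a 96-well plate; the wells are pooled into
8 row pools (A..H) and 12 column pools (1..12), each receiving its own
barcode, so every clone is sequenced in exactly two independent pools.
Because each fosmid carries a unique genomic insert, clone identity inside
a pool is resolved by mapping location; the row/column design is used to
cross-confirm observations between the two pools of the same well (a
variant, or un-flipped evidence, must recur in both to be believed).
"""
from __future__ import annotations

import csv
from dataclasses import dataclass, field

ROWS = "ABCDEFGH"
COLS = tuple(range(1, 13))


@dataclass
class PlateLayout:
    plate_id: str
    wells: dict[tuple[str, int], str] = field(default_factory=dict)

    def place(self, row: str, col: int, clone_id: str) -> None:
        if row not in ROWS or col not in COLS:
            raise ValueError(f"invalid well {row}{col}")
        self.wells[(row, col)] = clone_id

    def validate(self) -> None:
        clones = [c for c in self.wells.values() if c]
        if len(clones) != len(set(clones)):
            raise ValueError(f"{self.plate_id}: duplicate clone in plate")

    @classmethod
    def from_csv(cls, path: str, plate_id: str = "plate1") -> "PlateLayout":
        """CSV columns: row letter, column number, clone_id."""
        plate = cls(plate_id)
        with open(path, newline="") as fh:
            for rec in csv.reader(fh):
                if not rec or rec[0].startswith("#") or rec[0] == "row":
                    continue
                plate.place(rec[0].strip(), int(rec[1]), rec[2].strip())
        plate.validate()
        return plate

    def to_csv(self, path: str) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["row", "col", "clone_id"])
            for (r, c), clone in sorted(self.wells.items()):
                w.writerow([r, c, clone])


@dataclass(frozen=True)
class PoolSet:
    """Row and column pools of one plate, with barcodes and membership."""

    plate_id: str
    row_pools: tuple[str, ...]   # pool ids, order A..H
    col_pools: tuple[str, ...]   # pool ids, order 1..12
    barcode: dict[str, str]      # pool id -> barcode label
    membership: dict[str, frozenset[str]]   # pool id -> clone ids
    well_of: dict[str, tuple[str, int]]     # clone id -> (row, col)

    def pools_of(self, clone_id: str) -> tuple[str, str]:
        """(row pool, column pool) of a clone — the unit of cross-confirmation."""
        r, c = self.well_of[clone_id]
        return (self.row_pools[ROWS.index(r)], self.col_pools[COLS.index(c)])

    def to_manifest_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("pool\tbarcode\tmembers\n")
            for pid in (*self.row_pools, *self.col_pools):
                fh.write(f"{pid}\t{self.barcode[pid]}\t"
                         f"{','.join(sorted(self.membership[pid]))}\n")


def make_pools(plate: PlateLayout) -> PoolSet:
    """Pool a plate into 8 row + 12 column pools with distinct barcodes."""
    plate.validate()
    row_ids = tuple(f"{plate.plate_id}:row{r}" for r in ROWS)
    col_ids = tuple(f"{plate.plate_id}:col{c}" for c in COLS)
    barcode = {pid: f"BC{i:02d}" for i, pid in enumerate((*row_ids, *col_ids), 1)}
    membership = {pid: set() for pid in (*row_ids, *col_ids)}
    well_of = {}
    for (r, c), clone in plate.wells.items():
        if not clone:
            continue
        membership[row_ids[ROWS.index(r)]].add(clone)
        membership[col_ids[COLS.index(c)]].add(clone)
        well_of[clone] = (r, c)
    return PoolSet(plate.plate_id, row_ids, col_ids, barcode,
                   {k: frozenset(v) for k, v in membership.items()}, well_of)


def deconvolve(evidence: dict[str, bool | int]) -> set[tuple[str, int]]:
    """Candidate wells from per-pool signals for one clone-level observation.

    ``evidence`` maps pool id (as produced by :func:`make_pools`) to a
    boolean or count; the result is the Cartesian intersection of positive
    rows and positive columns.  A singleton means unambiguous assignment;
    empty means no data.
    """
    pos_rows = [p.rsplit("row", 1)[1] for p, v in evidence.items()
                if "row" in p and v]
    pos_cols = [int(p.rsplit("col", 1)[1]) for p, v in evidence.items()
                if "col" in p and v]
    return {(r, c) for r in pos_rows for c in pos_cols}
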