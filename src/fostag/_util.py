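"""Small sequence helpers shared across modules."""
from __future__ import annotations

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def codons(seq: str):
    """Frame-0 codons of ``seq`` (trailing partial codon dropped)."""
    return (seq[i:i + 3] for i in range(0, len(seq) - len(seq) % 3, 3))


def has_inframe_stop(seq: str) -> bool:
    return any(c in STOP_CODONS for c in codons(seq))


def interval_overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """Length of the overlap between two half-open intervals."""
    return max(0, min(a_end, b_end) - max(a_start, b_start))


def normalize_indel(refseq: str, pos: int, kind: str, ref: str, alt: str
                    ) -> tuple[int, str, str]:
    """Left-align an indel against the reference so equivalent events from
    different alignment paths (or the simulator truth) share one key."""
    if kind == "del":
        L = len(ref)
        while pos > 0 and refseq[pos - 1] == refseq[pos + L - 1]:
            pos -= 1
        return pos, refseq[pos:pos + L], ""
    if kind == "ins":
        while pos > 0 and alt and alt[-1] == refseq[pos - 1]:
            alt = refseq[pos - 1] + alt[:-1]
            pos -= 1
        return pos, "", alt
    return pos, ref, alt
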