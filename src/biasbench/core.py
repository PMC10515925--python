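"""Shared primitives: intervals, CIGAR handling, lightweight alignment records.

All internal coordinates are 0-based half-open. Conversion to/from 1-based
formats (VCF, SAM, mpileup) happens only in the I/O layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: CIGAR operation codes used internally (subset of SAM).
CIGAR_MATCH = "M"
CIGAR_INS = "I"
CIGAR_DEL = "D"
CIGAR_SOFTCLIP = "S"

_REF_CONSUMING = {CIGAR_MATCH, CIGAR_DEL}
_READ_CONSUMING = {CIGAR_MATCH, CIGAR_INS, CIGAR_SOFTCLIP}


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def intervals_overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> bool:
    """Half-open interval intersection test."""
    return a_start < b_end and b_start < a_end


def cigar_to_string(cigar: list[tuple[str, int]]) -> str:
    return "".join(f"{n}{op}" for op, n in cigar)


def cigar_from_string(text: str) -> list[tuple[str, int]]:
    out: list[tuple[str, int]] = []
    num = ""
    for ch in text:
        if ch.isdigit():
            num += ch
        else:
            out.append((ch, int(num)))
            num = ""
    if num:
        raise ValueError(f"truncated CIGAR string: {text!r}")
    return out


def merge_cigar(cigar: list[tuple[str, int]]) -> list[tuple[str, int]]:
    """Coalesce adjacent operations of the same type; drop zero-length ops."""
    out: list[tuple[str, int]] = []
    for op, n in cigar:
        if n == 0:
            continue
        if out and out[-1][0] == op:
            out[-1] = (op, out[-1][1] + n)
        else:
            out.append((op, n))
    return out


@dataclass
class Alignment:
    """One aligned read in reference-forward orientation.

    ``seq`` is stored in reference orientation (as SAM does), so CIGAR walks
    over it directly.
    """

    read_id: str
    mate: int  # 1 or 2; 0 for unpaired
    chrom: str
    pos: int  # 0-based leftmost reference position
    cigar: list[tuple[str, int]]
    seq: str
    mapq: int
    is_reverse: bool = False
    tags: dict = field(default_factory=dict)

    @property
    def key(self) -> tuple[str, int]:
        return (self.read_id, self.mate)

    @property
    def ref_end(self) -> int:
        return self.pos + sum(n for op, n in self.cigar if op in _REF_CONSUMING)

    @property
    def ref_span(self) -> tuple[int, int]:
        return (self.pos, self.ref_end)

    def overlaps(self, start: int, end: int) -> bool:
        return intervals_overlap(self.pos, self.ref_end, start, end)

    def aligned_pairs(self) -> Iterator[tuple[int, int]]:
        """Yield (read_index, ref_position) for every M-op base."""
        rpos = self.pos
        qpos = 0
        for op, n in self.cigar:
            if op == CIGAR_MATCH:
                for i in range(n):
                    yield (qpos + i, rpos + i)
                rpos += n
                qpos += n
            elif op == CIGAR_DEL:
                rpos += n
            elif op in (CIGAR_INS, CIGAR_SOFTCLIP):
                qpos += n
            else:
                raise ValueError(f"unsupported CIGAR op {op!r}")

    def read_index_at(self, ref_pos: int) -> int | None:
        """Read index of the base aligned at ref_pos, or None (gap/outside)."""
        rpos = self.pos
        qpos = 0
        for op, n in self.cigar:
            if op == CIGAR_MATCH:
                if rpos <= ref_pos < rpos + n:
                    return qpos + (ref_pos - rpos)
                rpos += n
                qpos += n
            elif op == CIGAR_DEL:
                if rpos <= ref_pos < rpos + n:
                    return None
                rpos += n
            elif op in (CIGAR_INS, CIGAR_SOFTCLIP):
                qpos += n
        return None

    def base_at(self, ref_pos: int) -> str | None:
        idx = self.read_index_at(ref_pos)
        return None if idx is None else self.seq[idx]

    def sequence_over(self, start: int, end: int) -> str | None:
        """Read sequence aligned across reference footprint [start, end).

        Includes inserted bases whose anchor lies strictly inside (start, end].
        Returns None when the alignment does not fully bracket the footprint
        (no aligned base at or before ``start`` and at or after ``end``).
        """
        if not (self.pos <= start and self.ref_end >= end):
            return None
        pieces: list[str] = []
        rpos = self.pos
        qpos = 0
        for op, n in self.cigar:
            if op == CIGAR_MATCH:
                lo = max(rpos, start)
                hi = min(rpos + n, end)
                if lo < hi:
                    pieces.append(self.seq[qpos + (lo - rpos) : qpos + (hi - rpos)])
                rpos += n
                qpos += n
            elif op == CIGAR_DEL:
                rpos += n
            elif op == CIGAR_INS:
                if start < rpos <= end:
                    pieces.append(self.seq[qpos : qpos + n])
                qpos += n
            elif op == CIGAR_SOFTCLIP:
                qpos += n
        return "".join(pieces)

    def copy(self) -> "Alignment":
        return replace(self, cigar=list(self.cigar), tags=dict(self.tags))
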