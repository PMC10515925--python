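"""Self-contained synthetic data: reference, phased VCF, diploid consensus,
truth-tagged paired-end reads, an idealized aligner, and bias injectors.

Everything is seeded and deterministic; no external tool is invoked.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import (
    CIGAR_DEL,
    CIGAR_INS,
    CIGAR_MATCH,
    Alignment,
    intervals_overlap,
    merge_cigar,
    revcomp,
)
from .variants import PhasedVariant

BASES = "ACGT"


# ---------------------------------------------------------------------------
# Reference generation


def random_reference(length: int, seed: int, chrom: str = "chrS") -> tuple[str, str]:
    """(chrom_name, sequence) with i.i.d. uniform bases."""
    rng = random.Random(seed)
    return chrom, "".join(rng.choice(BASES) for _ in range(length))


def plant_tandem_repeat(
    sequence: str, pos: int, unit: str, copies: int
) -> tuple[str, tuple[int, int]]:
    """Overwrite sequence at ``pos`` with ``unit * copies``; returns new
    sequence and the repeat tract interval."""
    tract = unit * copies
    if pos + len(tract) > len(sequence):
        raise ValueError("repeat tract exceeds sequence end")
    # guard: keep the flanking base unequal to the unit edge so the tract
    # does not silently extend
    new = sequence[:pos] + tract + sequence[pos + len(tract) :]
    return new, (pos, pos + len(tract))


def plant_duplication(
    sequence: str, src: tuple[int, int], dest_pos: int
) -> tuple[str, tuple[int, int]]:
    """Copy sequence[src] over the same-length window starting at dest_pos."""
    s, e = src
    seg = sequence[s:e]
    if dest_pos + len(seg) > len(sequence):
        raise ValueError("duplication exceeds sequence end")
    new = sequence[:dest_pos] + seg + sequence[dest_pos + len(seg) :]
    return new, (dest_pos, dest_pos + len(seg))


def random_phased_variants(
    reference: str,
    chrom: str,
    n_snv: int,
    n_indel: int,
    seed: int,
    max_indel: int = 12,
    min_spacing: int = 150,
) -> list[PhasedVariant]:
    """Well-separated random HET variants (phase assigned at random)."""
    rng = random.Random(seed)
    n = n_snv + n_indel
    slots = range(min_spacing, len(reference) - min_spacing, min_spacing)
    if len(slots) < n:
        raise ValueError("reference too short for requested variant count")
    positions = sorted(rng.sample(slots, n))
    kinds = ["SNV"] * n_snv + ["INDEL"] * n_indel
    rng.shuffle(kinds)
    out = []
    for pos0, kind in zip(positions, kinds):
        ref_base = reference[pos0]
        if ref_base not in BASES:
            continue
        gt = rng.choice([(0, 1), (1, 0)])
        if kind == "SNV":
            alt = rng.choice([b for b in BASES if b != ref_base])
            out.append(PhasedVariant(chrom, pos0 + 1, ref_base, alt, gt))
        else:
            ln = rng.randint(1, max_indel)
            if rng.random() < 0.5:  # insertion
                ins = "".join(rng.choice(BASES) for _ in range(ln))
                out.append(PhasedVariant(chrom, pos0 + 1, ref_base, ref_base + ins, gt))
            else:  # deletion
                ref = reference[pos0 : pos0 + 1 + ln]
                out.append(PhasedVariant(chrom, pos0 + 1, ref, ref[0], gt))
    return out


# ---------------------------------------------------------------------------
# Diploid consensus with exact coordinate maps


@dataclass
class _Segment:
    """Alignment block between one haplotype and the reference."""

    h0: int
    h1: int
    r0: int
    r1: int  # h1-h0 == r1-r0 for match blocks; ins: r0==r1; del: h0==h1


@dataclass
class HaplotypeConsensus:
    """One haplotype sequence plus an exact map back to the reference."""

    hap_id: int
    chrom: str
    sequence: str
    segments: list[_Segment] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._h0s = np.array([s.h0 for s in self.segments])

    def _first_segment(self, hap_pos: int) -> int:
        """Index of the first segment whose hap range may contain hap_pos."""
        i = int(np.searchsorted(self._h0s, hap_pos, side="right")) - 1
        while i > 0 and self.segments[i - 1].h1 > hap_pos:
            i -= 1
        return max(i, 0)

    def to_ref(self, hap_pos: int) -> int | None:
        """Reference position of a haplotype base; None inside an insertion."""
        for seg in self.segments[self._first_segment(hap_pos) :]:
            if seg.h0 > hap_pos:
                break
            if seg.h0 <= hap_pos < seg.h1:
                if seg.r1 == seg.r0:  # inserted block
                    return None
                return seg.r0 + (hap_pos - seg.h0)
        raise IndexError(f"haplotype position {hap_pos} out of range")

    def lift_interval(self, start: int, end: int) -> tuple[int, int]:
        """Lift a haplotype half-open interval to reference coordinates.

        Endpoints inside insertions snap to the insertion's reference anchor.
        """
        return (self._lift_point(start), self._lift_point(end))

    def _lift_point(self, hap_pos: int) -> int:
        for seg in self.segments[self._first_segment(hap_pos) :]:
            if seg.h0 <= hap_pos < seg.h1 or (hap_pos == seg.h1 and seg is self.segments[-1]):
                if seg.r1 == seg.r0:
                    return seg.r0
                return seg.r0 + min(hap_pos - seg.h0, seg.r1 - seg.r0)
        raise IndexError(f"haplotype position {hap_pos} out of range")

    def cigar_between(self, start: int, end: int) -> list[tuple[str, int]]:
        """CIGAR of haplotype interval [start, end) against the reference."""
        ops: list[tuple[str, int]] = []
        for seg in self.segments[self._first_segment(start) :]:
            if seg.h0 >= end and seg.h1 >= end:
                if not (seg.h0 == seg.h1 == end):
                    break
            lo, hi = max(seg.h0, start), min(seg.h1, end)
            if seg.h0 == seg.h1:  # deletion block (consumes ref only)
                if start < seg.h0 < end:  # strictly inside the interval
                    ops.append((CIGAR_DEL, seg.r1 - seg.r0))
                continue
            if lo >= hi:
                continue
            if seg.r0 == seg.r1:
                ops.append((CIGAR_INS, hi - lo))
            else:
                ops.append((CIGAR_MATCH, hi - lo))
        return merge_cigar(_trim_edge_gaps(ops))


def _trim_edge_gaps(ops: list[tuple[str, int]]) -> list[tuple[str, int]]:
    """A read should not start or end with D; leading/trailing I become S-free
    soft alignment by converting to M is wrong, so turn edge I into M only when
    impossible — here we simply trim edge deletions (they consume no read)."""
    while ops and ops[0][0] == CIGAR_DEL:
        ops.pop(0)
    while ops and ops[-1][0] == CIGAR_DEL:
        ops.pop()
    return ops


def build_diploid_consensus(
    reference: str,
    chrom: str,
    variants: list[PhasedVariant],
) -> tuple[HaplotypeConsensus, HaplotypeConsensus]:
    """Apply each variant's phased alleles to produce the two haplotypes.

    Variants must be sorted and non-overlapping. Raises if a REF allele does
    not match the reference sequence.
    """
    for v in variants:
        if reference[v.start : v.end] != v.ref:
            raise ValueError(
                f"REF allele mismatch at {v.chrom}:{v.pos}: VCF says {v.ref!r}, "
                f"reference has {reference[v.start:v.end]!r}"
            )
    haps = []
    for hap in (1, 2):
        pieces: list[str] = []
        segments: list[_Segment] = []
        cursor = 0  # ref
        hcur = 0  # hap
        for v in variants:
            if v.chrom != chrom:
                continue
            if v.start > cursor:
                ln = v.start - cursor
                pieces.append(reference[cursor : v.start])
                segments.append(_Segment(hcur, hcur + ln, cursor, v.start))
                hcur += ln
                cursor = v.start
            allele = v.allele_on(hap)
            if allele == v.ref:
                pieces.append(v.ref)
                segments.append(_Segment(hcur, hcur + len(v.ref), v.start, v.end))
                hcur += len(v.ref)
            elif v.var_class == "SNV" or len(allele) == len(v.ref):
                pieces.append(allele)
                segments.append(_Segment(hcur, hcur + len(allele), v.start, v.end))
                hcur += len(allele)
            elif v.var_length > 0:  # insertion: shared first base, then I block
                pieces.append(allele)
                segments.append(_Segment(hcur, hcur + len(v.ref), v.start, v.end))
                hcur += len(v.ref)
                segments.append(_Segment(hcur, hcur + v.var_length, v.end, v.end))
                hcur += v.var_length
            else:  # deletion: shared prefix kept, remainder dropped
                pieces.append(allele)
                segments.append(_Segment(hcur, hcur + len(allele), v.start, v.start + len(allele)))
                hcur += len(allele)
                segments.append(_Segment(hcur, hcur, v.start + len(allele), v.end))
            cursor = v.end
        if cursor < len(reference):
            ln = len(reference) - cursor
            pieces.append(reference[cursor:])
            segments.append(_Segment(hcur, hcur + ln, cursor, len(reference)))
            hcur += ln
        haps.append(HaplotypeConsensus(hap, chrom, "".join(pieces), segments))
    return haps[0], haps[1]


# ---------------------------------------------------------------------------
# Read simulation


@dataclass
class ReadTruth:
    read_id: str
    mate: int
    hap_id: int
    chrom: str
    hap_start: int
    hap_end: int
    ref_start: int
    ref_end: int
    is_reverse: bool


@dataclass
class SimRead:
    read_id: str
    mate: int
    seq_sequencer: str  # as it comes off the machine (mate2 revcomp'd)
    seq_forward: str  # reference-forward orientation
    is_reverse: bool


def simulate_reads(
    hap1: HaplotypeConsensus,
    hap2: HaplotypeConsensus,
    coverage_per_hap: float = 15.0,
    read_len: int = 150,
    fragment_mean: float = 400.0,
    fragment_sd: float = 50.0,
    error_rate: float = 0.0,
    seed_hap1: int = 1,
    seed_hap2: int = 2,
) -> tuple[list[SimRead], list[ReadTruth]]:
    """Uniform paired-end sampling per haplotype with i.i.d. substitutions.

    The two haplotypes use distinct seeds so their coverage profiles are
    uncorrelated. Truth rows carry haplotype origin and both haplotype and
    lifted reference intervals.
    """
    if seed_hap1 == seed_hap2:
        raise ValueError("per-haplotype seeds must differ")
    if not 0 <= error_rate < 1:
        raise ValueError("error_rate must be in [0, 1)")
    reads: list[SimRead] = []
    truths: list[ReadTruth] = []
    for hap, seed in ((hap1, seed_hap1), (hap2, seed_hap2)):
        L = len(hap.sequence)
        if read_len > L:
            raise ValueError("read length exceeds haplotype length")
        rng = np.random.default_rng(seed)
        n_pairs = int(round(coverage_per_hap * L / (2 * read_len)))
        frags = np.clip(
            rng.normal(fragment_mean, fragment_sd, n_pairs).round().astype(int),
            read_len,
            L,
        )
        starts = rng.integers(0, np.maximum(L - frags, 0) + 1)
        for k in range(n_pairs):
            fs, fl = int(starts[k]), int(frags[k])
            rid = f"h{hap.hap_id}_{k}"
            for mate, (s, e, rev) in enumerate(
                [(fs, fs + read_len, False), (fs + fl - read_len, fs + fl, True)], start=1
            ):
                frag = list(hap.sequence[s:e])
                if error_rate > 0:
                    hits = np.flatnonzero(rng.random(read_len) < error_rate)
                    for i in hits:
                        frag[i] = BASES[(BASES.index(frag[i]) + rng.integers(1, 4)) % 4]
                fwd = "".join(frag)
                reads.append(
                    SimRead(rid, mate, revcomp(fwd) if rev else fwd, fwd, rev)
                )
                rs, re_ = hap.lift_interval(s, e)
                truths.append(
                    ReadTruth(rid, mate, hap.hap_id, hap.chrom, s, e, rs, re_, rev)
                )
    return reads, truths


class TruthTable:
    """Indexed view over ReadTruth rows: lookup by read key, query by region."""

    def __init__(self, rows: list[ReadTruth]):
        self.rows = rows
        self._by_key = {(r.read_id, r.mate): r for r in rows}
        order = sorted(range(len(rows)), key=lambda i: rows[i].ref_start)
        self._starts = np.array([rows[i].ref_start for i in order])
        self._order = order
        self._max_len = max((r.ref_end - r.ref_start for r in rows), default=0)

    def __len__(self) -> int:
        return len(self.rows)

    def get(self, read_id: str, mate: int) -> ReadTruth | None:
        return self._by_key.get((read_id, mate))

    def overlapping(self, chrom: str, start: int, end: int) -> list[ReadTruth]:
        lo = np.searchsorted(self._starts, start - self._max_len)
        hi = np.searchsorted(self._starts, end)
        out = []
        for i in range(lo, hi):
            r = self.rows[self._order[i]]
            if r.chrom == chrom and intervals_overlap(r.ref_start, r.ref_end, start, end):
                out.append(r)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "read_id": r.read_id,
                    "mate": r.mate,
                    "hap": r.hap_id,
                    "chrom": r.chrom,
                    "ref_start": r.ref_start,
                    "ref_end": r.ref_end,
                    "hap_start": r.hap_start,
                    "hap_end": r.hap_end,
                    "is_reverse": int(r.is_reverse),
                }
                for r in self.rows
            ]
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TruthTable":
        rows = [
            ReadTruth(
                str(t.read_id),
                int(t.mate),
                int(t.hap),
                str(t.chrom),
                int(t.hap_start),
                int(t.hap_end),
                int(t.ref_start),
                int(t.ref_end),
                bool(t.is_reverse),
            )
            for t in df.itertuples()
        ]
        return cls(rows)


# ---------------------------------------------------------------------------
# Idealized aligner


def perfect_align(
    reads: list[SimRead],
    truth: TruthTable,
    hap1: HaplotypeConsensus,
    hap2: HaplotypeConsensus,
    mapq: int = 42,
) -> list[Alignment]:
    """Place each read at its true origin with the variant-implied CIGAR."""
    haps = {1: hap1, 2: hap2}
    out = []
    for rd in reads:
        t = truth.get(rd.read_id, rd.mate)
        if t is None:
            raise KeyError(f"no truth for read {rd.read_id}/{rd.mate}")
        hap = haps[t.hap_id]
        cigar = hap.cigar_between(t.hap_start, t.hap_end)
        out.append(
            Alignment(
                read_id=rd.read_id,
                mate=rd.mate,
                chrom=t.chrom,
                pos=t.ref_start,
                cigar=cigar,
                seq=rd.seq_forward,
                mapq=mapq,
                is_reverse=rd.is_reverse,
            )
        )
    out.sort(key=lambda a: (a.chrom, a.pos))
    return out


# ---------------------------------------------------------------------------
# Bias injection


def inject_drop_alt(
    alignments: list[Alignment],
    truth: TruthTable,
    variant: PhasedVariant,
    fraction: float,
    seed: int = 0,
) -> list[Alignment]:
    """Remove a fraction of reads truly originating from the ALT haplotype at
    the site (a 'loss' scenario). Truth table is left untouched, so SB keeps
    its pre-injection value while MB/AB shift toward REF."""
    rng = random.Random(seed)
    alt_hap = variant.alt_hap
    victims = []
    for a in alignments:
        t = truth.get(a.read_id, a.mate)
        if (
            t is not None
            and t.hap_id == alt_hap
            and t.chrom == variant.chrom
            and intervals_overlap(t.ref_start, t.ref_end, variant.start, variant.end)
        ):
            victims.append(a.key)
    if not victims:
        raise ValueError(f"no ALT-haplotype reads overlap {variant!r}")
    n_drop = int(round(fraction * len(victims)))
    dropped = set(rng.sample(victims, n_drop))
    return [a for a in alignments if a.key not in dropped]


def inject_mismapped(
    alignments: list[Alignment],
    truth: TruthTable,
    variant: PhasedVariant,
    reference: str,
    n_reads: int,
    mapq: int = 3,
    read_len: int = 150,
    seed: int = 0,
    carry: str = "ref",
) -> tuple[list[Alignment], TruthTable]:
    """Add ``n_reads`` foreign reads over the site (a 'flux' scenario).

    With ``carry="ref"`` each new read carries the local REF sequence
    (shifting AB toward REF); with ``carry="other"`` the sequence is lightly
    corrupted so the assigner calls it OTHER and only the mismapped tally
    moves. Truth origin is placed far away either way, so MB ignores the
    read. Returns updated alignments and an extended truth table.
    """
    if carry not in ("ref", "other"):
        raise ValueError("carry must be 'ref' or 'other'")
    rng = random.Random(seed)
    new_al = list(alignments)
    new_truth = list(truth.rows)
    far = (variant.start + len(reference) // 2) % (len(reference) - read_len)
    for i in range(n_reads):
        offset = rng.randint(max(0, variant.end - read_len + 1), variant.start)
        pos = offset
        seq = reference[pos : pos + read_len]
        if carry == "other":
            chars = list(seq)
            for j in range(0, len(chars), 7):
                chars[j] = BASES[(BASES.index(chars[j]) + 1) % 4]
            seq = "".join(chars)
        rid = f"flux_{variant.pos}_{i}"
        new_al.append(
            Alignment(rid, 1, variant.chrom, pos, [(CIGAR_MATCH, len(seq))], seq, mapq)
        )
        new_truth.append(
            ReadTruth(rid, 1, 1, variant.chrom, far, far + read_len, far, far + read_len, False)
        )
    new_al.sort(key=lambda a: (a.chrom, a.pos))
    return new_al, TruthTable(new_truth)


def inject_read_errors(
    alignments: list[Alignment],
    truth: TruthTable,
    variant: PhasedVariant,
    fraction: float,
    seed: int = 0,
) -> list[Alignment]:
    """Corrupt the variant-window base of a fraction of ALT-haplotype reads
    (a 'local' scenario: errors disrupt the exact-match evidence).

    The corrupted reads still map and still count toward MB — but both
    assignment methods now call them OTHER, so AB drifts toward REF while
    MB stays put."""
    rng = random.Random(seed)
    alt_hap = variant.alt_hap
    victims = []
    for a in alignments:
        t = truth.get(a.read_id, a.mate)
        if (
            t is not None
            and t.hap_id == alt_hap
            and t.chrom == variant.chrom
            and t.ref_start <= variant.start
            and t.ref_end >= variant.end
            and a.read_index_at(variant.start) is not None
        ):
            victims.append(a)
    n_hit = int(round(fraction * len(victims)))
    hit = set(id(a) for a in rng.sample(victims, n_hit))
    out = []
    for a in alignments:
        if id(a) in hit:
            b = a.copy()
            idx = b.read_index_at(variant.start)
            wrong = next(
                x for x in BASES if x != variant.ref[0] and x != variant.alt[0]
            )
            b.seq = b.seq[:idx] + wrong + b.seq[idx + 1 :]
            out.append(b)
        else:
            out.append(a)
    return out


def inject_gap_shift(
    alignments: list[Alignment],
    variant: PhasedVariant,
    shift: int,
) -> list[Alignment]:
    """Move the indel gap of alignments spanning ``variant`` left by ``shift``
    bases without changing the mapped span (a 'local' ambiguity scenario).

    Only meaningful inside a tandem repeat, where the shifted placement scores
    identically. The read sequence is untouched: context-aware assignment is
    expected to be invariant while the naive method changes.
    """
    if variant.var_class not in ("INS", "DEL"):
        raise ValueError("gap shift applies to indel variants only")
    out = []
    for a in alignments:
        moved = _shift_gap_in_cigar(a, variant, shift)
        out.append(moved if moved is not None else a)
    return out


def _shift_gap_in_cigar(
    a: Alignment, variant: PhasedVariant, shift: int
) -> Alignment | None:
    """Rebuild the CIGAR with the gap nearest the variant moved ``shift`` bp
    left. Returns None when the alignment has no gap near the variant or the
    shift would cross a block edge."""
    rpos = a.pos
    new_ops: list[tuple[str, int]] = []
    done = False
    ops = list(a.cigar)
    for i, (op, n) in enumerate(ops):
        if (
            not done
            and op in (CIGAR_INS, CIGAR_DEL)
            and abs(rpos - variant.start) <= max(len(variant.ref), len(variant.alt)) + abs(shift)
        ):
            if not new_ops or new_ops[-1][0] != CIGAR_MATCH or new_ops[-1][1] <= shift:
                return None
            prev_op, prev_n = new_ops.pop()
            new_ops.append((prev_op, prev_n - shift))
            new_ops.append((op, n))
            new_ops.append((CIGAR_MATCH, shift))
            done = True
        else:
            new_ops.append((op, n))
        if op in (CIGAR_MATCH, CIGAR_DEL):
            rpos += n
    if not done:
        return None
    b = a.copy()
    b.cigar = merge_cigar(new_ops)
    return b


def inject_collapsed_duplication(
    alignments: list[Alignment],
    truth: TruthTable,
    src: tuple[int, int],
    dest: tuple[int, int],
) -> list[Alignment]:
    """Remap reads originating inside ``src`` onto ``dest`` (same length),
    mimicking a donor duplication collapsed onto one reference copy. Doubles
    depth over ``dest`` and creates non-diploid pileup columns wherever the
    two copies differ."""
    if src[1] - src[0] != dest[1] - dest[0]:
        raise ValueError("source and destination intervals must have equal length")
    delta = dest[0] - src[0]
    out = []
    for a in alignments:
        t = truth.get(a.read_id, a.mate)
        if t is not None and src[0] <= t.ref_start and t.ref_end <= src[1]:
            b = a.copy()
            b.pos = a.pos + delta
            out.append(b)
        else:
            out.append(a)
    out.sort(key=lambda x: (x.chrom, x.pos))
    return out
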