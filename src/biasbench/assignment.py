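"""Read-to-haplotype assignment at HET sites.

Two algorithms are provided. The *naive* method trusts the aligner's
base-level placement: it reads the pileup over the variant's reference
footprint. The *context-aware* method re-examines the raw read sequence,
searching for the REF and ALT alleles embedded in phased flanking sequence
("allelic context"), anchored at either boundary of the variant so that the
aligner's gap placement cannot change the outcome. Variants inside tandem
repeats are extended to an "effective variant" until the two contexts are no
longer prefix/suffix/substring of one another.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .core import Alignment
from .variants import PhasedVariant, VariantCohort


class Call(str, Enum):
    REF = "REF"
    ALT = "ALT"
    BOTH = "BOTH"
    OTHER = "OTHER"


@dataclass
class ReadAssignment:
    read_id: str
    mate: int
    call: Call
    anchor: str  # left | right | cohort | none


@dataclass
class AllelicContext:
    """REF/ALT alleles with phased flanks over the (possibly extended) span."""

    variant: PhasedVariant
    span: tuple[int, int]  # effective variant, reference half-open
    ref_core: str
    alt_core: str
    ref_context: str
    alt_context: str
    flank_left: int  # realized flank lengths (may be truncated at contig edge)
    flank_right: int
    extended: bool
    disregarded: bool = False
    reason: str = ""


def _apply_alleles(
    reference: str,
    variants: list[PhasedVariant],
    hap: int,
    lo: int,
    hi: int,
) -> str:
    """Haplotype sequence over reference window [lo, hi): each variant whose
    footprint lies fully inside contributes its phased allele."""
    pieces: list[str] = []
    cursor = lo
    for v in variants:
        if v.start < cursor or v.end > hi:
            continue
        pieces.append(reference[cursor : v.start])
        pieces.append(v.allele_on(hap))
        cursor = v.end
    pieces.append(reference[cursor:hi])
    return "".join(pieces)


def _unresolved(a: str, b: str) -> bool:
    """True while one allele string is a prefix/suffix/substring of the other
    (or they are equal) — i.e. the span cannot discriminate REF from ALT."""
    if a == b:
        return True
    short, long_ = (a, b) if len(a) < len(b) else (b, a)
    return short in long_


def _extension_cost(
    reference: str,
    neighbors: list[PhasedVariant],
    hap_r: int,
    hap_a: int,
    s: int,
    e: int,
    direction: int,
    cap: int,
) -> int | None:
    """Steps of one-base extension in ``direction`` (+1 right / -1 left) until
    the span discriminates, or None if the cap or a contig edge is reached."""
    for step in range(1, cap + 1):
        if direction > 0:
            e2, s2 = e + step, s
            if e2 > len(reference):
                return None
        else:
            s2, e2 = s - step, e
            if s2 < 0:
                return None
        r = _apply_alleles(reference, neighbors, hap_r, s2, e2)
        a = _apply_alleles(reference, neighbors, hap_a, s2, e2)
        if not _unresolved(r, a):
            return step
    return None


def build_context(
    variant: PhasedVariant,
    reference: str,
    phased_neighbors: list[PhasedVariant] | None = None,
    flank: int = 5,
    max_effective: int = 70,
) -> AllelicContext:
    """Construct the allelic context, extending through repetitive sequence.

    Extension policy: while one allele string over the span is a prefix of the
    other, grow rightward to the first discriminating base; while a suffix,
    grow leftward; when it is an interior substring (two-sided ambiguity), the
    side needing the shorter extension is grown. Spans longer than
    ``max_effective`` are disregarded.
    """
    if variant.ref_hap is None:
        raise ValueError(f"{variant!r} is not HET; context assignment needs a HET site")
    neighbors = [
        v
        for v in (phased_neighbors or [])
        if v.chrom == variant.chrom and v.footprint != variant.footprint
    ]
    neighbors = sorted(neighbors + [variant], key=lambda v: v.start)
    hap_r, hap_a = variant.ref_hap, variant.alt_hap
    s, e = variant.start, variant.end
    disregarded, reason = False, ""
    while True:
        if e - s > max_effective:
            disregarded, reason = True, f"effective span {e - s} > {max_effective}"
            break
        r_core = _apply_alleles(reference, neighbors, hap_r, s, e)
        a_core = _apply_alleles(reference, neighbors, hap_a, s, e)
        if not _unresolved(r_core, a_core):
            break
        short, long_ = (r_core, a_core) if len(r_core) < len(a_core) else (a_core, r_core)
        is_prefix = long_.startswith(short)
        is_suffix = long_.endswith(short)
        if is_prefix or r_core == a_core:
            e += 1
        elif is_suffix:
            s -= 1
        else:  # interior substring: grow the cheaper side
            cap = max_effective - (e - s) + 1
            cost_r = _extension_cost(reference, neighbors, hap_r, hap_a, s, e, +1, cap)
            cost_l = _extension_cost(reference, neighbors, hap_r, hap_a, s, e, -1, cap)
            if cost_r is None and cost_l is None:
                disregarded, reason = True, "ambiguity unresolved within cap"
                break
            if cost_l is None or (cost_r is not None and cost_r <= cost_l):
                e += cost_r
            else:
                s -= cost_l
        if s < 0 or e > len(reference):
            disregarded, reason = True, "extension reached contig end"
            s, e = max(s, 0), min(e, len(reference))
            break
    r_core = _apply_alleles(reference, neighbors, hap_r, s, e)
    a_core = _apply_alleles(reference, neighbors, hap_a, s, e)
    lf = min(flank, s)
    rf = min(flank, len(reference) - e)
    ref_ctx = (
        _apply_alleles(reference, neighbors, hap_r, s - lf, s)
        + r_core
        + _apply_alleles(reference, neighbors, hap_r, e, e + rf)
    )
    alt_ctx = (
        _apply_alleles(reference, neighbors, hap_a, s - lf, s)
        + a_core
        + _apply_alleles(reference, neighbors, hap_a, e, e + rf)
    )
    return AllelicContext(
        variant=variant,
        span=(s, e),
        ref_core=r_core,
        alt_core=a_core,
        ref_context=ref_ctx,
        alt_context=alt_ctx,
        flank_left=lf,
        flank_right=rf,
        extended=(s, e) != variant.footprint,
        disregarded=disregarded,
        reason=reason,
    )


# ---------------------------------------------------------------------------
# Naive assignment


def naive_assign(alignment: Alignment, variant: PhasedVariant) -> ReadAssignment:
    """Pileup-trusting assignment over the variant's exact VCF footprint."""
    if not alignment.overlaps(variant.start, variant.end):
        raise ValueError(f"read {alignment.read_id} does not overlap {variant!r}")
    if variant.var_class == "SNV":
        base = alignment.base_at(variant.start)
        if base == variant.ref:
            call = Call.REF
        elif base == variant.alt:
            call = Call.ALT
        else:
            call = Call.OTHER
    else:
        observed = alignment.sequence_over(variant.start, variant.end)
        if observed == variant.ref:
            call = Call.REF
        elif observed == variant.alt:
            call = Call.ALT
        else:
            call = Call.OTHER
    return ReadAssignment(alignment.read_id, alignment.mate, call, "none")


# ---------------------------------------------------------------------------
# Context-aware assignment


def _project_left(aln: Alignment, ref_pos: int, search: int) -> int | None:
    """Read index of the base at ``ref_pos``, projecting forward from the
    nearest aligned base at or before it (robust to a gap at the boundary)."""
    for d in range(search + 1):
        idx = aln.read_index_at(ref_pos - d)
        if idx is not None:
            return idx + d
    return None


def _project_right(aln: Alignment, ref_pos: int, search: int) -> int | None:
    for d in range(search + 1):
        idx = aln.read_index_at(ref_pos + d)
        if idx is not None:
            return idx - d
    return None


def _cmp_at(seq: str, start: int, ctx: str) -> bool:
    """Compare context against read with edge truncation; exact match only."""
    ra, rb = max(start, 0), min(start + len(ctx), len(seq))
    if rb <= ra:
        return False
    ca = ra - start
    cb = ca + (rb - ra)
    window = seq[ra:rb]
    if "N" in window:
        return False
    return window == ctx[ca:cb]


def _anchored_match(
    aln: Alignment,
    span: tuple[int, int],
    contexts: dict[str, str],
    lf: int,
    rf: int,
) -> tuple[set[str], str]:
    """Labels whose context matches the read, trying the left anchor of the
    span first and the right anchor only when the left finds nothing."""
    s, e = span
    search = max(lf, rf) + 2
    idx0 = _project_left(aln, s, search) if aln.pos <= s else None
    left: set[str] = set()
    if idx0 is not None:
        left = {lab for lab, ctx in contexts.items() if _cmp_at(aln.seq, idx0 - lf, ctx)}
    if left:
        return left, "left"
    idx_e = _project_right(aln, e, search) if aln.ref_end >= e else None
    right: set[str] = set()
    if idx_e is not None:
        right = {
            lab
            for lab, ctx in contexts.items()
            if _cmp_at(aln.seq, idx_e + rf - len(ctx), ctx)
        }
    if right:
        return right, "right"
    return set(), "none"


def context_assign(alignment: Alignment, context: AllelicContext) -> ReadAssignment:
    """Sequence-searching assignment against the allelic context.

    A read that does not fully cover the effective span of a repeat-extended
    variant is BOTH (its origin is genuinely ambiguous). Otherwise exact
    matches to the REF/ALT contexts decide the call; prefix/suffix matches
    suffice when the read ends inside the context.
    """
    if context.disregarded:
        raise ValueError("context was disregarded; exclude the site upstream")
    s, e = context.span
    if not alignment.overlaps(context.variant.start, context.variant.end) and not alignment.overlaps(s, e):
        raise ValueError(f"read {alignment.read_id} does not overlap the variant")
    # a read that does not cover the whole effective variant cannot place its
    # evidence on one haplotype
    if not (alignment.pos <= s and alignment.ref_end >= e):
        return ReadAssignment(alignment.read_id, alignment.mate, Call.BOTH, "none")
    matched, anchor = _anchored_match(
        alignment,
        (s, e),
        {"REF": context.ref_context, "ALT": context.alt_context},
        context.flank_left,
        context.flank_right,
    )
    if matched == {"REF"}:
        call = Call.REF
    elif matched == {"ALT"}:
        call = Call.ALT
    elif len(matched) == 2:
        call = Call.BOTH
    else:
        call = Call.OTHER
    return ReadAssignment(alignment.read_id, alignment.mate, call, anchor)


def cohort_assign(
    alignment: Alignment,
    cohort: VariantCohort,
    contexts: dict[tuple[int, int], AllelicContext],
    reference: str,
    flank: int = 5,
) -> list[tuple[PhasedVariant, ReadAssignment]]:
    """Assign one read against a multi-variant cohort.

    If the read covers the whole cohort span and exactly matches one
    haplotype's cohort string (with flanks, anchored at either cohort end),
    every member it covers is tallied with the member's allele on that
    haplotype. Otherwise each overlapped member falls back to
    :func:`context_assign`.
    """
    members_hit = [v for v in cohort.variants if alignment.overlaps(v.start, v.end)]
    if not members_hit:
        return []
    cs, ce = cohort.ref_span
    if len(cohort) > 1 and alignment.pos <= cs and alignment.ref_end >= ce:
        lf = min(flank, cs)
        rf = min(flank, len(reference) - ce)
        strings = {}
        for hap in (1, 2):
            core = cohort.hap_string(reference, hap)
            strings[hap] = (
                _apply_alleles(reference, cohort.variants, hap, cs - lf, cs)
                + core
                + _apply_alleles(reference, cohort.variants, hap, ce, ce + rf)
            )
        if strings[1] != strings[2]:
            matched, _anchor = _anchored_match(
                alignment, (cs, ce), {1: strings[1], 2: strings[2]}, lf, rf
            )
            if len(matched) == 1:
                hap = matched.pop()
                out = []
                for v in cohort.variants:
                    call = Call.ALT if v.genotype[hap - 1] == 1 else Call.REF
                    out.append(
                        (v, ReadAssignment(alignment.read_id, alignment.mate, call, "cohort"))
                    )
                return out
    out = []
    for v in members_hit:
        ctx = contexts.get(v.footprint)
        if ctx is None or ctx.disregarded:
            continue
        out.append((v, context_assign(alignment, ctx)))
    return out


# ---------------------------------------------------------------------------
# Batch driver


class AlignmentIndex:
    """Sorted-by-position region lookup over a list of alignments."""

    def __init__(self, alignments: list[Alignment]):
        self.alignments = sorted(alignments, key=lambda a: (a.chrom, a.pos))
        self._starts = np.array([a.pos for a in self.alignments])
        self._max_span = max((a.ref_end - a.pos for a in self.alignments), default=0)

    def overlapping(self, chrom: str, start: int, end: int) -> list[Alignment]:
        lo = np.searchsorted(self._starts, start - self._max_span)
        hi = np.searchsorted(self._starts, end)
        return [
            a
            for a in self.alignments[int(lo) : int(hi)]
            if a.chrom == chrom and a.overlaps(start, end)
        ]


def build_all_contexts(
    variants: list[PhasedVariant],
    reference: str,
    flank: int = 5,
    max_effective: int = 70,
    neighbor_window: int = 200,
) -> dict[tuple[int, int], AllelicContext]:
    """Contexts for every HET variant, with nearby variants (HOM included)
    contributing phased flanking sequence."""
    out: dict[tuple[int, int], AllelicContext] = {}
    svars = sorted(variants, key=lambda v: v.start)
    for i, v in enumerate(svars):
        if not v.is_het:
            continue
        neighbors = [
            u
            for u in svars
            if u is not v and abs(u.start - v.start) <= neighbor_window
        ]
        out[v.footprint] = build_context(
            v, reference, neighbors, flank=flank, max_effective=max_effective
        )
    return out


def assign_reads(
    alignments: list[Alignment] | AlignmentIndex,
    variants: list[PhasedVariant],
    reference: str,
    method: str = "context",
    flank: int = 5,
    cohort_distance: int = 25,
    max_effective: int = 70,
) -> dict[tuple[int, int], list[ReadAssignment]]:
    """Per-HET-site read assignments across a whole variant set.

    Returns a mapping from variant footprint to the list of assignments of
    reads overlapping that footprint. Sites whose context was disregarded map
    to an empty list. ``method`` is "context" or "naive".
    """
    from .variants import build_cohorts

    index = alignments if isinstance(alignments, AlignmentIndex) else AlignmentIndex(alignments)
    hets = [v for v in variants if v.is_het]
    result: dict[tuple[int, int], list[ReadAssignment]] = {v.footprint: [] for v in hets}
    if method == "naive":
        for v in hets:
            for a in index.overlapping(v.chrom, v.start, v.end):
                result[v.footprint].append(naive_assign(a, v))
        return result
    if method != "context":
        raise ValueError(f"unknown assignment method {method!r}")
    contexts = build_all_contexts(variants, reference, flank=flank, max_effective=max_effective)
    for cohort in build_cohorts(sorted(variants, key=lambda v: (v.chrom, v.start)), cohort_distance):
        span_lo = min(v.start for v in cohort.variants)
        span_hi = max(v.end for v in cohort.variants)
        for a in index.overlapping(cohort.chrom, span_lo, span_hi):
            for v, ra in cohort_assign(a, cohort, contexts, reference, flank=flank):
                if v.is_het and v.footprint in result and a.overlaps(v.start, v.end):
                    result[v.footprint].append(ra)
    return result


def assignments_frame(result: dict[tuple[int, int], list[ReadAssignment]], variants):
    """Flat per-read assignment table (chrom, pos, read_id, mate, call, anchor)."""
    import pandas as pd

    by_fp = {v.footprint: v for v in variants}
    rows = []
    for fp, assigns in result.items():
        v = by_fp.get(fp)
        for ra in assigns:
            rows.append(
                {
                    "chrom": v.chrom if v else "?",
                    "pos": v.pos if v else fp[0] + 1,
                    "read_id": ra.read_id,
                    "mate": ra.mate,
                    "call": ra.call.value,
                    "anchor": ra.anchor,
                }
            )
    return pd.DataFrame(rows, columns=["chrom", "pos", "read_id", "mate", "call", "anchor"])
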