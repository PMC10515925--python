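"""Phased diploid variant parsing, overlap removal, and cohort grouping.

VCF input is 1-based inclusive; every structure in this module uses 0-based
half-open coordinates. ``PhasedVariant.pos`` retains the VCF 1-based position
for reporting; ``start``/``end`` are the internal footprint.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pysam

log = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGT")


@dataclass
class PhasedVariant:
    """One biallelic record with an ordered diploid genotype (hap1|hap2)."""

    chrom: str
    pos: int  # 1-based VCF coordinate of the first REF base
    ref: str
    alt: str
    genotype: tuple[int, int]
    phased: bool = True
    filter_status: str = "PASS"
    #: set for records that must be discarded together with anything they
    #: touch (./.-style half calls, 1|2 splits)
    conflicted: bool = False

    def __post_init__(self) -> None:
        if not self.ref or not self.alt:
            raise ValueError(f"empty allele at {self.chrom}:{self.pos}")
        if self.pos < 1:
            raise ValueError(f"non-positive position {self.pos}")

    @property
    def start(self) -> int:
        """0-based start of the reference footprint."""
        return self.pos - 1

    @property
    def end(self) -> int:
        """0-based exclusive end of the reference footprint."""
        return self.pos - 1 + len(self.ref)

    @property
    def footprint(self) -> tuple[int, int]:
        return (self.start, self.end)

    @property
    def is_het(self) -> bool:
        return self.genotype[0] != self.genotype[1]

    @property
    def var_length(self) -> int:
        return len(self.alt) - len(self.ref)

    @property
    def var_class(self) -> str:
        if len(self.ref) == 1 and len(self.alt) == 1:
            return "SNV"
        if self.var_length > 0:
            return "INS"
        if self.var_length < 0:
            return "DEL"
        return "MNV"

    @property
    def is_gap(self) -> bool:
        return self.var_length != 0

    def allele_on(self, hap: int) -> str:
        """Sequence this variant contributes on haplotype ``hap`` (1 or 2)."""
        return self.alt if self.genotype[hap - 1] == 1 else self.ref

    @property
    def ref_hap(self) -> int | None:
        """Haplotype (1/2) carrying the REF allele; None unless HET."""
        if not self.is_het:
            return None
        return 1 if self.genotype[0] == 0 else 2

    @property
    def alt_hap(self) -> int | None:
        if not self.is_het:
            return None
        return 2 if self.genotype[0] == 0 else 1

    def __repr__(self) -> str:  # compact for logs
        g = ("|" if self.phased else "/").join(str(a) for a in self.genotype)
        return f"PhasedVariant({self.chrom}:{self.pos} {self.ref}>{self.alt} {g})"


@dataclass
class VariantCohort:
    """Maximal single-linkage cluster of nearby variants on one chromosome."""

    variants: list[PhasedVariant]
    ref_span: tuple[int, int] = field(init=False)

    def __post_init__(self) -> None:
        if not self.variants:
            raise ValueError("empty cohort")
        chroms = {v.chrom for v in self.variants}
        if len(chroms) != 1:
            raise ValueError("cohort spans multiple chromosomes")
        self.ref_span = (self.variants[0].start, max(v.end for v in self.variants))

    @property
    def chrom(self) -> str:
        return self.variants[0].chrom

    def __len__(self) -> int:
        return len(self.variants)

    def hap_string(self, reference: str, hap: int) -> str:
        """Span sequence with each member's phased allele applied (hap 1/2)."""
        start, end = self.ref_span
        out: list[str] = []
        cursor = start
        for v in self.variants:
            out.append(reference[cursor : v.start])
            out.append(v.allele_on(hap))
            cursor = v.end
        out.append(reference[cursor:end])
        return "".join(out)

    def ref_string(self, reference: str) -> str:
        return reference[self.ref_span[0] : self.ref_span[1]]


class VcfParseError(ValueError):
    pass


def _gt_of(sample) -> tuple | None:
    alleles = sample.get("GT")
    if alleles is None:
        return None
    return tuple(alleles)


def load_phased_variants(
    vcf_source: str,
    region: str | None = None,
    sample: str | int = 0,
) -> list[PhasedVariant]:
    """Read PASS biallelic records with a diploid GT from a VCF.

    Multi-allelic records are split into per-ALT biallelic records; a 1|2
    genotype yields two records flagged ``conflicted`` so that
    :func:`remove_overlapping_variants` discards the site. ``./.`` and half
    calls are likewise flagged. Symbolic ALTs and breakends are skipped.
    Unphased HETs are flagged conflicted as well: without phase the
    haplotype-aware machinery downstream cannot use them.
    """
    out: list[PhasedVariant] = []
    n_skipped_gt = 0
    n_skipped_symbolic = 0
    try:
        vf = pysam.VariantFile(vcf_source)
    except (OSError, ValueError) as exc:
        raise VcfParseError(f"cannot open VCF {vcf_source}: {exc}") from exc
    with vf:
        if region:
            try:
                it = vf.fetch(region=region)
            except ValueError:  # no index: stream and filter by contig name
                it = (rec for rec in vf if rec.chrom == region.split(":")[0])
        else:
            it = vf
        for rec in it:
            filt = list(rec.filter.keys())
            status = filt[0] if filt else "PASS"
            if filt and filt != ["PASS"]:
                continue
            try:
                smp = rec.samples[sample if isinstance(sample, str) else list(rec.samples)[sample]]
            except (KeyError, IndexError):
                n_skipped_gt += 1
                continue
            gt = _gt_of(smp)
            if gt is None or len(gt) != 2:
                n_skipped_gt += 1
                continue
            phased = bool(smp.phased)
            half_call = any(a is None for a in gt)
            alts = rec.alts or ()
            if any(a is None or a.startswith("<") or "[" in a or "]" in a for a in alts):
                n_skipped_symbolic += 1
                continue
            multi_nonref = sum(1 for a in gt if a not in (None, 0)) > 1 and len(set(
                a for a in gt if a not in (None, 0)
            )) > 1
            for alt_index, alt in enumerate(alts, start=1):
                if alt_index not in gt and not half_call:
                    continue  # untouched ALT of a multiallelic record
                genotype = tuple(1 if a == alt_index else 0 for a in gt)
                if genotype == (0, 0) and not half_call:
                    continue
                conflicted = half_call or multi_nonref or (
                    genotype[0] != genotype[1] and not phased
                )
                try:
                    out.append(
                        PhasedVariant(
                            chrom=rec.chrom,
                            pos=rec.pos,
                            ref=rec.ref,
                            alt=alt,
                            genotype=genotype if not half_call else (0, 0),
                            phased=phased,
                            filter_status=status,
                            conflicted=conflicted,
                        )
                    )
                except ValueError as exc:
                    raise VcfParseError(f"malformed record at {rec.chrom}:{rec.pos}: {exc}") from exc
    if n_skipped_gt:
        log.warning("skipped %d records without usable GT", n_skipped_gt)
    if n_skipped_symbolic:
        log.info("skipped %d symbolic/breakend records", n_skipped_symbolic)
    out.sort(key=lambda v: (v.chrom, v.start, v.end))
    return out


def remove_overlapping_variants(
    variants: list[PhasedVariant],
) -> tuple[list[PhasedVariant], list[PhasedVariant]]:
    """Drop every group of variants whose reference footprints intersect.

    Removal is by transitive closure: if A overlaps B and B overlaps C, all
    three go. Records flagged ``conflicted`` are removed unconditionally,
    dragging along anything they touch.
    """
    kept: list[PhasedVariant] = []
    removed: list[PhasedVariant] = []
    i = 0
    svars = sorted(variants, key=lambda v: (v.chrom, v.start, v.end))
    n = len(svars)
    while i < n:
        group = [svars[i]]
        group_end = svars[i].end
        j = i + 1
        while j < n and svars[j].chrom == svars[i].chrom and svars[j].start < group_end:
            group.append(svars[j])
            group_end = max(group_end, svars[j].end)
            j += 1
        if len(group) > 1 or group[0].conflicted:
            removed.extend(group)
        else:
            kept.append(group[0])
        i = j
    return kept, removed


def build_cohorts(
    variants: list[PhasedVariant],
    distance: int = 25,
) -> list[VariantCohort]:
    """Single-linkage chaining of non-overlapping variants into cohorts.

    Two consecutive variants join one cohort when the gap between their
    reference footprints is smaller than ``distance``; the cohort extends
    until no further variant is reachable. ``distance=0`` makes every variant
    a singleton.
    """
    for a, b in zip(variants, variants[1:]):
        if a.chrom == b.chrom and b.start < a.end:
            raise ValueError(
                f"overlapping variants {a!r} / {b!r}: run remove_overlapping_variants first"
            )
    cohorts: list[VariantCohort] = []
    current: list[PhasedVariant] = []
    for v in sorted(variants, key=lambda x: (x.chrom, x.start)):
        if current and v.chrom == current[-1].chrom and v.start - current[-1].end < distance:
            current.append(v)
        else:
            if current:
                cohorts.append(VariantCohort(current))
            current = [v]
    if current:
        cohorts.append(VariantCohort(current))
    return cohorts


def variant_report(kept: list[PhasedVariant], removed: list[PhasedVariant]):
    """Kept/removed site lists as a tidy table (chrom, pos, ref, alt, reason)."""
    import pandas as pd

    rows = [
        {"chrom": v.chrom, "pos": v.pos, "ref": v.ref, "alt": v.alt, "reason": "kept"}
        for v in kept
    ]
    rows += [
        {
            "chrom": v.chrom,
            "pos": v.pos,
            "ref": v.ref,
            "alt": v.alt,
            "reason": "conflicted" if v.conflicted else "overlap",
        }
        for v in removed
    ]
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "reason"])
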