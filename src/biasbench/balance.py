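"""Allelic-balance measures at HET sites.

Three REF-fraction measures are taken at successive pipeline stages:
SB from the simulation truth, MB from truth-restricted aligned reads, and AB
from an assignment algorithm's REF/ALT tallies. NMB = MB - SB and
NAB = AB - SB isolate the bias added by alignment, and by alignment plus
assignment, respectively.

"Overlapping the site" always means intersecting the variant's reference
footprint (for insertions, the single anchor base: a half-open interval of
length 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .assignment import AlignmentIndex, Call, ReadAssignment
from .core import Alignment, intervals_overlap
from .fixtures import TruthTable
from .variants import PhasedVariant

NAN = float("nan")


def _defined(x: float) -> bool:
    return not math.isnan(x)


@dataclass
class SiteBalance:
    site: PhasedVariant
    SB: float = NAN
    MB: float = NAN
    AB_naive: float = NAN
    AB_context: float = NAN
    n_mismapped: int = 0
    avg_mapq: float = NAN
    n_overlapping: int = 0
    tallies: dict = field(default_factory=dict)  # assigner -> {call: count}
    disregarded: bool = False

    @property
    def NMB(self) -> float:
        return self.MB - self.SB

    @property
    def NAB(self) -> float:
        return self.AB_context - self.SB

    @property
    def NAB_naive(self) -> float:
        return self.AB_naive - self.SB


def compute_SB(
    truth: TruthTable,
    site: PhasedVariant,
    span: tuple[int, int] | None = None,
) -> float:
    """REF fraction among truth reads whose lifted origin covers the site.

    ``span`` defaults to the variant footprint; when the site has an extended
    effective variant, pass its span so that reads which only partially cover
    it — which no assignment method can place — are left out of every balance
    measure consistently.
    """
    ref_hap = site.ref_hap
    if ref_hap is None:
        raise ValueError(f"{site!r} is not HET")
    s, e = span if span is not None else site.footprint
    n_ref = n_tot = 0
    for t in truth.overlapping(site.chrom, s, e):
        if not (t.ref_start <= s and t.ref_end >= e):
            continue
        n_tot += 1
        if t.hap_id == ref_hap:
            n_ref += 1
    return n_ref / n_tot if n_tot else NAN


def compute_MB(
    alignments: list[Alignment] | AlignmentIndex,
    truth: TruthTable,
    site: PhasedVariant,
    span: tuple[int, int] | None = None,
) -> tuple[float, int]:
    """(MB, n_mismapped) at a HET site.

    MB counts only reads that truly originated covering the site AND aligned
    covering it; reads aligned over the site but simulated from elsewhere are
    not counted in MB — they are reported as mismapped.
    """
    index = alignments if isinstance(alignments, AlignmentIndex) else AlignmentIndex(alignments)
    ref_hap = site.ref_hap
    if ref_hap is None:
        raise ValueError(f"{site!r} is not HET")
    s, e = span if span is not None else site.footprint
    n_ref = n_tot = n_mis = 0
    for a in index.overlapping(site.chrom, s, e):
        t = truth.get(a.read_id, a.mate)
        if t is None:
            raise KeyError(f"aligned read {a.read_id}/{a.mate} absent from truth table")
        if t.chrom != site.chrom or not intervals_overlap(
            t.ref_start, t.ref_end, site.start, site.end
        ):
            n_mis += 1
            continue
        if (
            t.ref_start <= s
            and t.ref_end >= e
            and a.pos <= s
            and a.ref_end >= e
        ):
            n_tot += 1
            if t.hap_id == ref_hap:
                n_ref += 1
    return (n_ref / n_tot if n_tot else NAN), n_mis


def compute_AB(assignments: list[ReadAssignment]) -> float:
    """REF / (REF + ALT); BOTH and OTHER calls are excluded."""
    n_ref = sum(1 for a in assignments if a.call == Call.REF)
    n_alt = sum(1 for a in assignments if a.call == Call.ALT)
    return n_ref / (n_ref + n_alt) if (n_ref + n_alt) else NAN


def tally(assignments: list[ReadAssignment]) -> dict[str, int]:
    out = {c.value: 0 for c in Call}
    for a in assignments:
        out[a.call.value] += 1
    return out


def site_balances(
    variants: list[PhasedVariant],
    alignments: list[Alignment] | AlignmentIndex,
    truth: TruthTable | None,
    assignments_context: dict[tuple[int, int], list[ReadAssignment]] | None = None,
    assignments_naive: dict[tuple[int, int], list[ReadAssignment]] | None = None,
    disregarded: set[tuple[int, int]] | None = None,
    effective_spans: dict[tuple[int, int], tuple[int, int]] | None = None,
) -> list[SiteBalance]:
    """Assemble per-HET SiteBalance records from the available inputs.

    ``truth`` may be None (real-read predict mode): SB/MB stay undefined.
    ``effective_spans`` maps footprints to effective-variant spans so that
    SB/MB count the same read population the assigner can decide on.
    avg_mapq averages over all aligned reads overlapping the footprint,
    BOTH/OTHER included.
    """
    index = alignments if isinstance(alignments, AlignmentIndex) else AlignmentIndex(alignments)
    disregarded = disregarded or set()
    effective_spans = effective_spans or {}
    out = []
    for v in variants:
        if not v.is_het:
            continue
        sb = SiteBalance(site=v)
        over = index.overlapping(v.chrom, v.start, v.end)
        sb.n_overlapping = len(over)
        if over:
            sb.avg_mapq = float(np.mean([a.mapq for a in over]))
        span = effective_spans.get(v.footprint, v.footprint)
        if truth is not None:
            sb.SB = compute_SB(truth, v, span)
            sb.MB, sb.n_mismapped = compute_MB(index, truth, v, span)
        fp = v.footprint
        sb.disregarded = fp in disregarded
        if assignments_context is not None and not sb.disregarded:
            asg = assignments_context.get(fp, [])
            sb.AB_context = compute_AB(asg)
            sb.tallies["context"] = tally(asg)
        if assignments_naive is not None:
            asg = assignments_naive.get(fp, [])
            sb.AB_naive = compute_AB(asg)
            sb.tallies["naive"] = tally(asg)
        out.append(sb)
    return out


def balance_frame(balances: list[SiteBalance]) -> pd.DataFrame:
    """Flat per-site table mirroring the TSV interface."""
    rows = []
    for b in balances:
        v = b.site
        row = {
            "chrom": v.chrom,
            "pos": v.pos,
            "ref": v.ref,
            "alt": v.alt,
            "var_class": v.var_class,
            "var_length": v.var_length,
            "SB": b.SB,
            "MB": b.MB,
            "AB_naive": b.AB_naive,
            "AB_context": b.AB_context,
            "NMB": b.NMB,
            "NAB": b.NAB,
            "n_mismapped": b.n_mismapped,
            "avg_mapq": b.avg_mapq,
            "n_overlapping": b.n_overlapping,
            "disregarded": int(b.disregarded),
        }
        for assigner in ("context", "naive"):
            t = b.tallies.get(assigner, {})
            for call in ("REF", "ALT", "BOTH", "OTHER"):
                row[f"{assigner}_{call}"] = t.get(call, 0)
        rows.append(row)
    return pd.DataFrame(rows)


def alt_fraction_by_length(
    balances: list[SiteBalance],
    cap: int = 25,
    measures: tuple[str, ...] = ("SB", "MB", "AB_naive", "AB_context"),
) -> pd.DataFrame:
    """Median/quartile ALT fraction per signed indel-length stratum.

    Lengths are clamped to [-cap, cap]; 0 is the SNV stratum. ALT fraction is
    1 - (REF fraction measure). Also reports the per-stratum site count.
    """
    rows = []
    for b in balances:
        stratum = int(np.clip(b.site.var_length, -cap, cap))
        row = {"stratum": stratum}
        for m in measures:
            val = getattr(b, m)
            row[m] = (1.0 - val) if _defined(val) else NAN
        rows.append(row)
    if not rows:
        return pd.DataFrame(columns=["stratum", "n"])
    df = pd.DataFrame(rows)
    agg = df.groupby("stratum").agg(
        **{
            f"{m}_{stat}": pd.NamedAgg(m, q)
            for m in measures
            for stat, q in (
                ("median", "median"),
                ("q1", lambda x: x.quantile(0.25)),
                ("q3", lambda x: x.quantile(0.75)),
            )
        },
        n=pd.NamedAgg("stratum", "size"),
    )
    return agg.reset_index()
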