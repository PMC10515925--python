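"""Reference-free windowed bias scan over pileups.

Per position, alleles are bases above a 15% frequency threshold; a position
with >= 2 alleles is an SNV, and it is non-diploid when >= 3 alleles pass the
threshold or the top allele is more than twice as frequent as the second.
Sliding windows (default 400 bp, step 100 bp) summarize read depth (RD), SNV
density (VD) and non-diploid density (ND); each is Z-scored against a sampled
baseline and truncated (z_rd < 1 -> 0; z_vd, z_nd < 0 -> 0), and the sum is
the window's bias score. Windows with score >= 5 seed "biased" regions and
[3, 5) "suspicious" regions; same-label regions within 1 kbp are chained.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import CIGAR_DEL, CIGAR_INS, CIGAR_MATCH, CIGAR_SOFTCLIP, Alignment

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass
class Pileup:
    """Per-position base counts for one chromosome (0-based positions)."""

    chrom: str
    counts: np.ndarray  # (L, 4) int32, ACGT

    @property
    def length(self) -> int:
        return len(self.counts)

    @property
    def depth(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def mean_depth(self) -> float:
        """Average depth over the whole contig (zero-coverage included)."""
        return float(self.depth.mean()) if self.length else 0.0


_BASE_LUT = np.full(256, -1, dtype=np.int8)
for _b, _i in _BASE_INDEX.items():
    _BASE_LUT[ord(_b)] = _i
    _BASE_LUT[ord(_b.lower())] = _i


def pileup_from_alignments(
    alignments: list[Alignment], chrom: str, length: int
) -> Pileup:
    counts = np.zeros((length, 4), dtype=np.int32)
    for a in alignments:
        if a.chrom != chrom:
            continue
        codes = _BASE_LUT[np.frombuffer(a.seq.encode(), dtype=np.uint8)]
        rpos, qpos = a.pos, 0
        for op, n in a.cigar:
            if op == CIGAR_MATCH:
                pos = np.arange(rpos, rpos + n)
                seg = codes[qpos : qpos + n]
                ok = (seg >= 0) & (pos >= 0) & (pos < length)
                np.add.at(counts, (pos[ok], seg[ok]), 1)
                rpos += n
                qpos += n
            elif op == CIGAR_DEL:
                rpos += n
            elif op in (CIGAR_INS, CIGAR_SOFTCLIP):
                qpos += n
    return Pileup(chrom, counts)


def _parse_mpileup_bases(bases: str, ref_base: str) -> list[str]:
    """Expand one mpileup base string into upper-case nucleotides.

    Indels, deletion placeholders (*), reference skips and read start/end
    markers are dropped; '.'/',' become the reference base.
    """
    out: list[str] = []
    i = 0
    n = len(bases)
    while i < n:
        c = bases[i]
        if c == "^":
            i += 2
            continue
        if c == "$":
            i += 1
            continue
        if c in "+-":
            i += 1
            num = ""
            while i < n and bases[i].isdigit():
                num += bases[i]
                i += 1
            i += int(num)
            continue
        if c in ".,":
            out.append(ref_base.upper())
        elif c.upper() in _BASE_INDEX:
            out.append(c.upper())
        # '*', '>', '<', 'N' etc.: not a counted nucleotide
        i += 1
    return out


def parse_mpileup(source) -> dict[str, Pileup]:
    """Read samtools-style 6-column mpileup text into per-chrom pileups.

    ``source`` is a path or an iterable of lines. Positions are 1-based in
    the file. Contig length is taken as the highest position seen.
    """
    close = False
    if isinstance(source, str):
        source = open(source)
        close = True
    per_chrom: dict[str, dict[int, np.ndarray]] = {}
    try:
        for lineno, line in enumerate(source, 1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 5:
                raise ValueError(f"malformed mpileup line {lineno}: {line!r}")
            chrom, pos, ref_base, _depth, bases = fields[:5]
            col = np.zeros(4, dtype=np.int32)
            for b in _parse_mpileup_bases(bases, ref_base):
                idx = _BASE_INDEX.get(b)
                if idx is not None:
                    col[idx] += 1
            per_chrom.setdefault(chrom, {})[int(pos) - 1] = col
    finally:
        if close:
            source.close()
    out = {}
    for chrom, cols in per_chrom.items():
        length = max(cols) + 1
        counts = np.zeros((length, 4), dtype=np.int32)
        for p, col in cols.items():
            counts[p] = col
        out[chrom] = Pileup(chrom, counts)
    return out


# ---------------------------------------------------------------------------
# Position-level calls


def call_position_alleles(
    counts: np.ndarray, allele_freq: float = 0.15
) -> tuple[list[str], bool, bool]:
    """(alleles, is_snv, is_nondiploid) for a single pileup column."""
    total = int(counts.sum())
    if total == 0:
        return [], False, False
    freqs = counts / total
    order = np.argsort(counts)[::-1]
    alleles = ["ACGT"[i] for i in order if freqs[i] > allele_freq]
    is_snv = len(alleles) >= 2
    nondip = False
    if is_snv:
        top, second = counts[order[0]], counts[order[1]]
        nondip = len(alleles) >= 3 or top > 2 * second
    return alleles, is_snv, nondip


def position_flags(
    pileup: Pileup, allele_freq: float = 0.15
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized (covered, is_snv, is_nondiploid) boolean arrays."""
    counts = pileup.counts
    total = counts.sum(axis=1)
    covered = total > 0
    safe_total = np.where(covered, total, 1)
    freqs = counts / safe_total[:, None]
    allele_mask = freqs > allele_freq
    n_alleles = allele_mask.sum(axis=1)
    sorted_counts = np.sort(counts, axis=1)[:, ::-1]
    top, second = sorted_counts[:, 0], sorted_counts[:, 1]
    is_snv = covered & (n_alleles >= 2)
    is_nondip = is_snv & ((n_alleles >= 3) | (top > 2 * second))
    return covered, is_snv, is_nondip


# ---------------------------------------------------------------------------
# Windowed measures and scores


def window_measures(
    pileup: Pileup,
    window: int = 400,
    step: int = 100,
    allele_freq: float = 0.15,
) -> pd.DataFrame:
    """Raw per-window RD / VD / ND.

    RD = mean depth over covered positions in the window; VD and ND are SNV
    and non-diploid positions per covered base. Windows with no covered
    position are skipped.
    """
    covered, is_snv, is_nondip = position_flags(pileup, allele_freq)
    depth = pileup.depth.astype(np.float64)
    L = pileup.length

    def csum(x):
        return np.concatenate([[0], np.cumsum(x)])

    c_cov = csum(covered)
    c_depth = csum(depth)
    c_snv = csum(is_snv)
    c_nd = csum(is_nondip)
    rows = []
    for start in range(0, max(L - 1, 0) + 1, step):
        end = min(start + window, L)
        ncov = c_cov[end] - c_cov[start]
        if ncov == 0:
            if end == L:
                break
            continue
        rows.append(
            {
                "chrom": pileup.chrom,
                "start": start,
                "end": end,
                "RD": (c_depth[end] - c_depth[start]) / ncov,
                "VD": (c_snv[end] - c_snv[start]) / ncov,
                "ND": (c_nd[end] - c_nd[start]) / ncov,
            }
        )
        if end == L:
            break
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "RD", "VD", "ND"])


@dataclass(frozen=True)
class Baseline:
    """Sampled mean/std per measure; compared by value across runs."""

    mean: tuple[float, float, float]  # RD, VD, ND
    std: tuple[float, float, float]
    n_windows: int

    def as_dict(self) -> dict:
        return {
            "RD": {"mean": self.mean[0], "std": self.std[0]},
            "VD": {"mean": self.mean[1], "std": self.std[1]},
            "ND": {"mean": self.mean[2], "std": self.std[2]},
            "n_windows": self.n_windows,
        }


def sample_baseline(
    pileups: list[Pileup],
    fraction: float = 1.0 / 1000,
    seed: int = 0,
    window: int = 400,
    step: int = 100,
    allele_freq: float = 0.15,
) -> Baseline:
    """Estimate per-measure mean/std from uniformly sampled whole windows.

    With two pileup sources (two workflows under comparison), half the
    sampled windows come from each, producing one joint parameter set.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if not pileups:
        raise ValueError("at least one pileup required")
    rng = np.random.default_rng(seed)
    frames = []
    for p in pileups:
        wm = window_measures(p, window=window, step=step, allele_freq=allele_freq)
        if fraction >= 1.0:
            frames.append(wm)
        else:
            want = max(3, int(round(fraction * len(wm) / len(pileups))))
            take = rng.choice(len(wm), size=min(want, len(wm)), replace=False)
            frames.append(wm.iloc[np.sort(take)])
    sample = pd.concat(frames, ignore_index=True)
    means = tuple(float(sample[m].mean()) for m in ("RD", "VD", "ND"))
    stds = tuple(float(sample[m].std(ddof=0)) for m in ("RD", "VD", "ND"))
    for name, s in zip(("RD", "VD", "ND"), stds):
        if s == 0:
            raise ValueError(
                f"sampled std of {name} is 0; enlarge the sample fraction or "
                "supply explicit baseline parameters"
            )
    return Baseline(means, stds, len(sample))


def combine_scores(measures: pd.DataFrame, baseline: Baseline) -> pd.DataFrame:
    """Attach truncated Z-scores and the summed bias score to window rows."""
    df = measures.copy()
    for i, m in enumerate(("RD", "VD", "ND")):
        z = (df[m] - baseline.mean[i]) / baseline.std[i]
        if m == "RD":
            z = z.where(z >= 1, 0.0)  # interest is depth well above average
        else:
            z = z.clip(lower=0.0)
        df[f"z_{m.lower()}"] = z
    df["bias_score"] = df["z_rd"] + df["z_vd"] + df["z_nd"]
    return df


# ---------------------------------------------------------------------------
# Region calling


@dataclass
class BiasRegion:
    chrom: str
    start: int
    end: int
    label: str  # biased | suspicious
    peak_score: float
    n_windows: int


def _merge_windows(rows: pd.DataFrame, chain_gap: int, label: str) -> list[BiasRegion]:
    regions: list[BiasRegion] = []
    for _, r in rows.sort_values(["chrom", "start"]).iterrows():
        if (
            regions
            and regions[-1].chrom == r["chrom"]
            and r["start"] - regions[-1].end <= chain_gap
        ):
            last = regions[-1]
            last.end = max(last.end, int(r["end"]))
            last.peak_score = max(last.peak_score, float(r["bias_score"]))
            last.n_windows += 1
        else:
            regions.append(
                BiasRegion(
                    str(r["chrom"]),
                    int(r["start"]),
                    int(r["end"]),
                    label,
                    float(r["bias_score"]),
                    1,
                )
            )
    return regions


def call_regions(
    window_scores: pd.DataFrame,
    biased_min: float = 5.0,
    susp_min: float = 3.0,
    chain_gap: int = 1000,
) -> list[BiasRegion]:
    """Merge qualifying windows into labeled regions and chain nearby ones.

    Biased (score >= biased_min) and suspicious (score in [susp_min,
    biased_min)) regions are chained independently; a suspicious region
    swallowed by a biased one is dropped (biased wins on overlap).
    """
    if len(window_scores) == 0:
        return []
    biased = _merge_windows(
        window_scores[window_scores["bias_score"] >= biased_min], chain_gap, "biased"
    )
    susp = _merge_windows(
        window_scores[
            (window_scores["bias_score"] >= susp_min)
            & (window_scores["bias_score"] < biased_min)
        ],
        chain_gap,
        "suspicious",
    )
    keep_susp = [
        s
        for s in susp
        if not any(
            b.chrom == s.chrom and s.start < b.end and b.start < s.end for b in biased
        )
    ]
    return sorted(biased + keep_susp, key=lambda r: (r.chrom, r.start))


def regions_frame(regions: list[BiasRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": r.chrom,
                "start": r.start,
                "end": r.end,
                "label": r.label,
                "peak_score": r.peak_score,
                "n_windows": r.n_windows,
            }
            for r in regions
        ],
        columns=["chrom", "start", "end", "label", "peak_score", "n_windows"],
    )


# ---------------------------------------------------------------------------
# Whole-run container and two-workflow comparison


@dataclass
class ScanResult:
    pileup: Pileup
    windows: pd.DataFrame
    regions: list[BiasRegion]
    baseline: Baseline
    mean_depth: float = field(default=0.0)

    @property
    def biased(self) -> list[BiasRegion]:
        return [r for r in self.regions if r.label == "biased"]


def run_scan(
    pileup: Pileup,
    baseline: Baseline | None = None,
    window: int = 400,
    step: int = 100,
    allele_freq: float = 0.15,
    fraction: float = 1.0 / 1000,
    seed: int = 0,
    biased_min: float = 5.0,
    susp_min: float = 3.0,
    chain_gap: int = 1000,
) -> ScanResult:
    """Full scan of one pileup: measures -> Z scores -> regions."""
    if baseline is None:
        baseline = sample_baseline(
            [pileup], fraction=fraction, seed=seed, window=window, step=step,
            allele_freq=allele_freq,
        )
    wm = window_measures(pileup, window=window, step=step, allele_freq=allele_freq)
    scored = combine_scores(wm, baseline)
    regions = call_regions(scored, biased_min, susp_min, chain_gap)
    return ScanResult(pileup, scored, regions, baseline, pileup.mean_depth())


def _covered_mask(length: int, regions: list[BiasRegion], chrom: str) -> np.ndarray:
    mask = np.zeros(length, dtype=bool)
    for r in regions:
        if r.chrom == chrom:
            mask[max(r.start, 0) : min(r.end, length)] = True
    return mask


def compare_runs(
    run_a: ScanResult,
    run_b: ScanResult,
    improve_frac: float = 0.25,
    depth_frac: float = 0.2,
) -> pd.DataFrame:
    """Which of each run's biased regions the other workflow improves.

    A region biased in A is improved by B when at least ``improve_frac`` of
    its bases are, under B, both covered above ``depth_frac`` of B's overall
    mean depth and outside B's biased regions. Regions poorly covered in both
    runs are excluded. Both runs must share one jointly sampled baseline.
    """
    if run_a.baseline != run_b.baseline:
        raise ValueError("runs were scored with different baselines; rescan jointly")
    rows = []
    for direction, src, other in (("A_by_B", run_a, run_b), ("B_by_A", run_b, run_a)):
        chrom = other.pileup.chrom
        depth_other = other.pileup.depth
        depth_src = src.pileup.depth
        well_other = depth_other > depth_frac * other.mean_depth
        well_src = depth_src > depth_frac * src.mean_depth
        biased_other = _covered_mask(other.pileup.length, other.biased, chrom)
        for r in src.biased:
            lo, hi = max(r.start, 0), min(r.end, other.pileup.length)
            length = r.end - r.start
            good = well_other[lo:hi] & ~biased_other[lo:hi]
            n_improved = int(good.sum())
            frac_well_src = float(well_src[lo:hi].mean()) if hi > lo else 0.0
            frac_well_other = float(well_other[lo:hi].mean()) if hi > lo else 0.0
            excluded = frac_well_src < improve_frac and frac_well_other < improve_frac
            rows.append(
                {
                    "direction": direction,
                    "chrom": r.chrom,
                    "start": r.start,
                    "end": r.end,
                    "length": length,
                    "improved_bases": n_improved,
                    "improved_frac": n_improved / length if length else 0.0,
                    "excluded": excluded,
                    "improved": (not excluded) and n_improved >= improve_frac * length,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "direction",
            "chrom",
            "start",
            "end",
            "length",
            "improved_bases",
            "improved_frac",
            "excluded",
            "improved",
        ],
    )


def overlap_features(
    regions: list[BiasRegion],
    features: pd.DataFrame,
    margin: int = 100,
) -> pd.DataFrame:
    """Flag each BED feature as inside/outside the biased regions.

    A feature is "inside" when any position within ``margin`` of its extent
    intersects a biased region. ``features`` needs chrom/start/end columns.
    """
    biased = [r for r in regions if r.label == "biased"]
    out = features.copy()
    flags = []
    for t in features.itertuples():
        lo, hi = int(t.start) - margin, int(t.end) + margin
        flags.append(
            any(r.chrom == t.chrom and lo < r.end and r.start < hi for r in biased)
        )
    out["inside"] = flags
    return out


def overlap_summary(flagged: pd.DataFrame) -> pd.DataFrame:
    n_in = int(flagged["inside"].sum()) if len(flagged) else 0
    n_out = len(flagged) - n_in
    return pd.DataFrame(
        [{"inside": n_in, "outside": n_out, "total": len(flagged)}]
    )
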