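"""Geometric bias-event classification on the (NMB, NAB) plane.

Rules, applied in order to sites with defined NMB and NAB:

1. balanced  — inside the circle of radius 0.1 about the origin;
2. loss      — NMB and NAB share a sign and NAB/NMB lies in [1/2, 2]
               (the wedge around the diagonal, both quadrants);
3. flux      — |NMB| <= radius, |NAB| > radius, and more than ``flux_reads``
               mismapped reads overlap the site;
   local     — same region with few mismapped reads;
4. outlier   — everything else.

The balanced region is a circle (not a square); boundary ties go to the
earlier rule, so wedge-boundary points are loss.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .balance import SiteBalance, _defined

CATEGORIES = ("balanced", "loss", "flux", "local", "outlier")

CATEGORY_COLORS = {
    "balanced": "tab:green",
    "loss": "tab:orange",
    "flux": "tab:blue",
    "local": "tab:purple",
    "outlier": "grey",
}


@dataclass
class BiasCategory:
    category: str
    radius_from_origin: float
    in_loss_wedge: bool
    in_flux_band: bool


def classify_site(
    nmb: float,
    nab: float,
    n_mismapped: int,
    radius: float = 0.1,
    slope_hi: float = 2.0,
    slope_lo: float = 0.5,
    flux_reads: int = 5,
) -> BiasCategory:
    if not (_defined(nmb) and _defined(nab)):
        raise ValueError("classify_site requires defined NMB and NAB")
    r = math.hypot(nmb, nab)
    in_wedge = nmb * nab > 0 and slope_lo <= nab / nmb <= slope_hi
    in_band = abs(nmb) <= radius and abs(nab) > radius
    if r <= radius:
        cat = "balanced"
    elif in_wedge:
        cat = "loss"
    elif in_band:
        cat = "flux" if n_mismapped > flux_reads else "local"
    else:
        cat = "outlier"
    return BiasCategory(cat, r, in_wedge, in_band)


def classify_all(
    balances: list[SiteBalance],
    assigner: str = "context",
    radius: float = 0.1,
    slope_hi: float = 2.0,
    slope_lo: float = 0.5,
    flux_reads: int = 5,
) -> pd.DataFrame:
    """Per-site categories; sites with undefined measures are excluded.

    ``assigner`` picks which AB feeds NAB ("context" or "naive").
    """
    rows = []
    for b in balances:
        nab = b.NAB if assigner == "context" else b.NAB_naive
        if not (_defined(b.NMB) and _defined(nab)):
            continue
        cat = classify_site(
            b.NMB, nab, b.n_mismapped, radius, slope_hi, slope_lo, flux_reads
        )
        rows.append(
            {
                "chrom": b.site.chrom,
                "pos": b.site.pos,
                "var_class": b.site.var_class,
                "is_gap": int(b.site.is_gap),
                "NMB": b.NMB,
                "NAB": nab,
                "n_mismapped": b.n_mismapped,
                "category": cat.category,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom",
            "pos",
            "var_class",
            "is_gap",
            "NMB",
            "NAB",
            "n_mismapped",
            "category",
        ],
    )


def summarize_categories(categorized: pd.DataFrame) -> pd.DataFrame:
    """Category counts split by SNV vs gap, one row per (split, category)."""
    rows = []
    for split, sub in (
        ("SNV", categorized[categorized.get("is_gap", pd.Series(dtype=int)) == 0]),
        ("gap", categorized[categorized.get("is_gap", pd.Series(dtype=int)) == 1]),
    ):
        counts = sub["category"].value_counts() if len(sub) else {}
        for cat in CATEGORIES:
            rows.append(
                {"split": split, "category": cat, "count": int(counts.get(cat, 0))}
            )
    return pd.DataFrame(rows)


def plot_nmb_nab(
    categorized: pd.DataFrame,
    out_path: str,
    radius: float = 0.1,
    slope_hi: float = 2.0,
    slope_lo: float = 0.5,
    title: str | None = None,
) -> None:
    """NMB-NAB scatter colored by category, with the balanced circle and the
    loss-wedge boundary lines drawn. One panel per SNV/gap split."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(11, 5), sharex=True, sharey=True)
    for ax, (split, gap_flag) in zip(axes, (("SNV", 0), ("gap", 1))):
        sub = (
            categorized[categorized["is_gap"] == gap_flag]
            if len(categorized)
            else categorized
        )
        for cat in CATEGORIES:
            pts = sub[sub["category"] == cat] if len(sub) else sub
            if len(pts):
                ax.scatter(
                    pts["NMB"], pts["NAB"], s=6, alpha=0.6,
                    color=CATEGORY_COLORS[cat], label=cat,
                )
        theta = np.linspace(0, 2 * np.pi, 200)
        ax.plot(radius * np.cos(theta), radius * np.sin(theta), "k--", lw=0.8)
        xs = np.linspace(-1, 1, 2)
        ax.plot(xs, slope_hi * xs, color="0.6", lw=0.6)
        ax.plot(xs, slope_lo * xs, color="0.6", lw=0.6)
        ax.set_xlim(-1.05, 1.05)
        ax.set_ylim(-1.05, 1.05)
        ax.set_xlabel("NMB")
        ax.set_ylabel("NAB")
        ax.set_title(split)
        if ax.get_legend_handles_labels()[0]:
            ax.legend(loc="lower right", fontsize=7)
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
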