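"""Reference-free per-site bias prediction from two features.

Without simulation truth only the assignment balance and the mapping quality
of overlapping reads are available. The two printed score forms are

    mul:  (avg_mapq - max_mapq) / max_mapq * assigned_balance
    add:  (avg_mapq - max_mapq) / max_mapq * 1.5 + assigned_balance

with max_mapq = 42 for Bowtie2/BWA-class aligners and 60 for Giraffe. Lower
(more negative) scores rank as more biased for both forms: a biased site
combines depressed MAPQ (negative first factor) with the balance term.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.metrics import precision_recall_curve, roc_curve

from .balance import SiteBalance, _defined

SCORE_METHODS = ("mul", "add")


def score_site(
    avg_mapq: float,
    assigned_balance: float,
    max_mapq: int = 42,
    method: str = "mul",
    fold_balance: bool = False,
) -> float:
    """One of the two printed two-feature scores.

    ``fold_balance`` substitutes the folded deviation 2*|AB - 0.5| for the raw
    balance (optional variant; raw is the default).
    """
    if not 0 <= avg_mapq <= max_mapq:
        raise ValueError(
            f"avg_mapq {avg_mapq} outside [0, {max_mapq}]: wrong max_mapq for this aligner?"
        )
    if not 0 <= assigned_balance <= 1:
        raise ValueError(f"assigned_balance {assigned_balance} outside [0, 1]")
    ab = 2 * abs(assigned_balance - 0.5) if fold_balance else assigned_balance
    mapq_term = (avg_mapq - max_mapq) / max_mapq
    if method == "mul":
        return mapq_term * ab
    if method == "add":
        return mapq_term * 1.5 + ab
    raise ValueError(f"unknown score method {method!r}")


def filter_affected_hets(
    balances: list[SiteBalance],
    assigner: str = "context",
    other_hi: float = 0.9,
    other_lo: float = 0.4,
) -> tuple[list[SiteBalance], pd.DataFrame]:
    """Drop sites whose tallies look like phasing/representation artifacts.

    Rule 1: more than ``other_hi`` of overlapping reads carry an OTHER allele.
    Rule 2: one HET allele has zero support and more than ``other_lo`` of
    reads carry OTHER. Returns (kept, drop report).
    """
    kept, dropped = [], []
    for b in balances:
        t = b.tallies.get(assigner)
        if not t:
            kept.append(b)
            continue
        total = sum(t.values())
        if total == 0:
            kept.append(b)
            continue
        other_frac = t.get("OTHER", 0) / total
        reason = None
        if other_frac > other_hi:
            reason = "other_gt_90"
        elif (t.get("REF", 0) == 0 or t.get("ALT", 0) == 0) and other_frac > other_lo:
            reason = "allele_absent_other_gt_40"
        if reason:
            dropped.append(
                {
                    "chrom": b.site.chrom,
                    "pos": b.site.pos,
                    "other_frac": other_frac,
                    "reason": reason,
                }
            )
        else:
            kept.append(b)
    return kept, pd.DataFrame(dropped, columns=["chrom", "pos", "other_frac", "reason"])


def rank_sites(
    balances: list[SiteBalance],
    max_mapq: int = 42,
    assigner: str = "context",
    fold_balance: bool = False,
) -> pd.DataFrame:
    """Scored, ranked site table. Rank 1 = most biased (lowest score)."""
    rows = []
    for b in balances:
        ab = b.AB_context if assigner == "context" else b.AB_naive
        if not (_defined(ab) and _defined(b.avg_mapq)):
            continue
        rows.append(
            {
                "chrom": b.site.chrom,
                "pos": b.site.pos,
                "var_class": b.site.var_class,
                "avg_mapq": b.avg_mapq,
                "AB": ab,
                "score_mul": score_site(b.avg_mapq, ab, max_mapq, "mul", fold_balance),
                "score_add": score_site(b.avg_mapq, ab, max_mapq, "add", fold_balance),
            }
        )
    df = pd.DataFrame(
        rows, columns=["chrom", "pos", "var_class", "avg_mapq", "AB", "score_mul", "score_add"]
    )
    if len(df):
        df["rank_mul"] = df["score_mul"].rank(method="first").astype(int)
        df["rank_add"] = df["score_add"].rank(method="first").astype(int)
        df = df.sort_values("score_mul").reset_index(drop=True)
    return df


def evaluate_predictions(
    scores: np.ndarray | pd.Series,
    labels: np.ndarray | pd.Series,
) -> dict:
    """ROC and PR curves over the score ranking, with trapezoid-rule areas.

    ``labels``: 1 = biased, 0 = balanced. Lower scores mean more biased, so
    the negated score is used as the decision function for the positive
    (biased) class.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(set(labels.tolist())) < 2:
        raise ValueError("evaluation needs both biased and balanced labels")
    decision = -scores
    fpr, tpr, _ = roc_curve(labels, decision)
    precision, recall, _ = precision_recall_curve(labels, decision)
    auc = float(np.trapezoid(tpr, fpr))
    # PR points come sorted by decreasing recall
    auprc = float(np.trapezoid(precision[::-1], recall[::-1]))
    return {
        "roc": pd.DataFrame({"fpr": fpr, "tpr": tpr}),
        "pr": pd.DataFrame({"precision": precision, "recall": recall}),
        "auc": auc,
        "auprc": auprc,
    }


def plot_roc_pr(evaluations: dict[str, dict], out_path: str) -> None:
    """ROC and PR panels for named evaluations (e.g. {"mul": ..., "add": ...})."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax_roc, ax_pr) = plt.subplots(1, 2, figsize=(10, 4.5))
    for name, ev in evaluations.items():
        ax_roc.plot(ev["roc"]["fpr"], ev["roc"]["tpr"], label=f"{name} (auc={ev['auc']:.3f})")
        ax_pr.plot(
            ev["pr"]["recall"], ev["pr"]["precision"], label=f"{name} (auprc={ev['auprc']:.3f})"
        )
    ax_roc.plot([0, 1], [0, 1], "k--", lw=0.6)
    ax_roc.set_xlabel("FPR")
    ax_roc.set_ylabel("TPR")
    ax_roc.legend()
    ax_pr.set_xlabel("recall")
    ax_pr.set_ylabel("precision")
    ax_pr.legend()
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
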