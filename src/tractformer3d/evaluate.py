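"""Segmentation evaluation.

Per-tract, per-subject Dice similarity coefficient (DSC) and relative
volume difference (RVD), aggregate statistics, tract-size stratification,
and a paired two-tailed Wilcoxon signed-rank test over the flattened
(subject x tract) metric table.

Conventions (recorded here because the field uses several):

* DSC = 2|P & G| / (|P| + |G|); both masks empty -> 1, exactly one empty -> 0.
* RVD = | |P| - |G| | / |G| (absolute volume difference normalized by the
  ground-truth volume; nonnegative). Undefined for an empty ground truth.
* Wilcoxon: zero differences are dropped (classical method), ties receive
  mid-ranks, the statistic is the smaller of the positive/negative rank
  sums. The two-tailed p value is exact — computed from the full
  distribution of the rank sum over all 2^n sign patterns — for n <= 25
  after zero removal, and uses a normal approximation with continuity and
  tie correction above.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

__all__ = ["EvalResult", "WilcoxonResult", "dice_score", "rvd_score",
           "wilcoxon_signed_rank", "evaluate_dataset"]

EXACT_WILCOXON_MAX_N = 25


def _check_pair(pred, gt) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(pred).astype(bool)
    g = np.asarray(gt).astype(bool)
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {g.shape}")
    return p, g


def dice_score(pred: np.ndarray, gt: np.ndarray) -> float:
    """Overlap metric 2|P&G|/(|P|+|G|) in [0, 1]."""
    p, g = _check_pair(pred, gt)
    np_, ng = int(p.sum()), int(g.sum())
    if np_ + ng == 0:
        return 1.0
    return 2.0 * int(np.logical_and(p, g).sum()) / (np_ + ng)


def rvd_score(pred: np.ndarray, gt: np.ndarray) -> float:
    """Size metric | |P|-|G| | / |G|; requires a nonempty ground truth."""
    p, g = _check_pair(pred, gt)
    ng = int(g.sum())
    if ng == 0:
        raise ValueError("RVD is undefined for an empty ground-truth mask")
    return abs(int(p.sum()) - ng) / ng


@dataclass(frozen=True)
class WilcoxonResult:
    n_used: int
    statistic: float
    p_value: float
    method: str  # "exact" | "normal" | "degenerate"


def _rank_sum_distribution(scaled_ranks: np.ndarray) -> np.ndarray:
    """PMF (unnormalized counts) of the positive rank sum over all 2^n sign
    assignments; ranks are pre-scaled by 2 so mid-ranks become integers."""
    total = int(scaled_ranks.sum())
    counts = np.zeros(total + 1, dtype=np.float64)
    counts[0] = 1.0
    for r in scaled_ranks:
        r = int(r)
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[:total + 1 - r]
        counts += shifted
    return counts


def wilcoxon_signed_rank(a, b) -> WilcoxonResult:
    """Paired two-tailed Wilcoxon signed-rank test of median(a-b) = 0."""
    a = np.asarray(a, dtype=np.float64).ravel()
    b = np.asarray(b, dtype=np.float64).ravel()
    if a.shape != b.shape or a.size == 0:
        raise ValueError("inputs must be paired and non-empty")
    d = a - b
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        warnings.warn("all paired differences are zero; test is degenerate",
                      stacklevel=2)
        return WilcoxonResult(0, 0.0, 1.0, "degenerate")
    ranks = rankdata(np.abs(d))  # mid-ranks for ties
    w_pos = float(ranks[d > 0].sum())
    w_neg = float(ranks[d < 0].sum())
    stat = min(w_pos, w_neg)
    total = n * (n + 1) / 2.0
    if n <= EXACT_WILCOXON_MAX_N:
        scaled = np.rint(2.0 * ranks).astype(int)
        counts = _rank_sum_distribution(scaled)
        w2 = int(round(2.0 * stat))
        # sign flips map W+ to total-W+, so the distribution is symmetric
        # and the two-tailed p doubles the lower tail of the min statistic
        p = float(2.0 * counts[:w2 + 1].sum() / 2.0 ** n)
        return WilcoxonResult(n, stat, min(p, 1.0), "exact")
    mean = total / 2.0
    tie_counts = np.unique(np.rint(2.0 * ranks).astype(int),
                           return_counts=True)[1]
    var = n * (n + 1) * (2 * n + 1) / 24.0 - (
        (tie_counts ** 3 - tie_counts).sum() / 48.0)
    z = (stat - mean + 0.5) / np.sqrt(var)  # continuity correction
    p = float(min(2.0 * norm.cdf(z), 1.0))
    return WilcoxonResult(n, stat, p, "normal")


@dataclass
class EvalResult:
    """Per-(subject, tract) metric table with aggregate statistics."""

    table: pd.DataFrame
    mean_dsc: float
    std_dsc: float
    mean_rvd: float
    std_rvd: float
    size_table: pd.DataFrame = field(default=None)

    def as_dict(self) -> dict:
        return {
            "mean_dsc": self.mean_dsc, "std_dsc": self.std_dsc,
            "mean_rvd": self.mean_rvd, "std_rvd": self.std_rvd,
            "n_pairs": int(len(self.table)),
            "rvd_definition": "abs(|pred|-|gt|)/|gt|",
        }


def evaluate_dataset(preds, gts) -> EvalResult:
    """Evaluate paired prediction/ground-truth multi-label volumes.

    Returns the per-pair table (subjects x tracts rows), aggregates with
    sample standard deviation, and a tract-size stratification mapping each
    tract's mean ground-truth volume to its mean DSC and RVD across
    subjects (the tract-size versus performance view).
    """
    if len(preds) != len(gts) or not preds:
        raise ValueError("need equal, nonzero numbers of predictions and truths")
    rows = []
    for s, (pv, gv) in enumerate(zip(preds, gts)):
        pd_ = np.asarray(pv if isinstance(pv, np.ndarray) else pv.data)
        gd = np.asarray(gv if isinstance(gv, np.ndarray) else gv.data)
        if pd_.shape != gd.shape:
            raise ValueError(f"subject {s}: shape mismatch "
                             f"{pd_.shape} vs {gd.shape}")
        for t in range(gd.shape[-1]):
            g = gd[..., t]
            p = pd_[..., t]
            gvol = int(g.sum())
            rvd = rvd_score(p, g) if gvol else np.nan
            rows.append({"subject": s, "tract": t,
                         "dsc": dice_score(p, g), "rvd": rvd,
                         "gt_volume": gvol})
    table = pd.DataFrame(rows)
    size_table = (table.groupby("tract")
                  .agg(mean_gt_volume=("gt_volume", "mean"),
                       mean_dsc=("dsc", "mean"),
                       mean_rvd=("rvd", "mean"))
                  .reset_index())
    rvd_vals = table["rvd"].dropna()
    return EvalResult(
        table=table,
        mean_dsc=float(table["dsc"].mean()),
        std_dsc=float(table["dsc"].std(ddof=1)) if len(table) > 1 else 0.0,
        mean_rvd=float(rvd_vals.mean()) if len(rvd_vals) else np.nan,
        std_rvd=float(rvd_vals.std(ddof=1)) if len(rvd_vals) > 1 else 0.0,
        size_table=size_table,
    )
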