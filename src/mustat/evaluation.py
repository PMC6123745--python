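"""Power-evaluation protocol for sweep scans.

A run (one replicate's score track) is summarised by its maximum mu and the
leftmost bp midpoint attaining it.  Accuracy is the distance of that location
from the known selection target as a percentage of the region length; the
success rate is the fraction of runs landing within 1% of the region length.
Significance cutoffs are empirical order statistics of neutral best scores
(95th percentile for a 5% false-positive level); TPR/FPR count runs whose
best score strictly exceeds the cutoff.  ROC curves sweep the cutoff over all
observed scores.  Scores can be interpolated onto an external grid of
positions (nearest evaluated midpoint) to compare against grid-based scanners,
and model-misspecification effects are expressed as log10 ratios of the
matched-model rate over the rate under the misspecified model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .mu_statistic import MuScore
from .snp_core import InputError

__all__ = [
    "RunSummary",
    "EvalMetrics",
    "summarize_run",
    "best_of_run",
    "distance_pct",
    "success_rate",
    "cutoff_at",
    "tpr_fpr",
    "roc_curve",
    "tpr_at_fpr",
    "roc_auc",
    "interpolate_at",
    "misspec_ratio",
]


@dataclass
class RunSummary:
    best_score: float
    best_position: float
    region_length: int
    true_target: Optional[float] = None

    @property
    def distance_pct(self) -> Optional[float]:
        if self.true_target is None:
            return None
        return distance_pct(self.best_position, self.true_target, self.region_length)


@dataclass
class EvalMetrics:
    cutoff: float
    fpr_pct: float
    tpr_pct: float
    mean_distance_pct: float
    success_rate_pct: float
    roc_fpr_pct: np.ndarray
    roc_tpr_pct: np.ndarray


def best_of_run(scores: Sequence[MuScore]) -> tuple[float, float]:
    """(max mu, leftmost argmax midpoint) over the unmasked score track."""
    usable = [sc for sc in scores if not sc.masked]
    if not usable:
        raise InputError("run has no (unmasked) scores")
    best = max(sc.mu for sc in usable)
    for sc in usable:  # leftmost tie-break
        if sc.mu == best:
            return best, sc.position
    raise AssertionError("unreachable")


def summarize_run(
    scores: Sequence[MuScore],
    region_length: int,
    true_target: Optional[float] = None,
) -> RunSummary:
    score, position = best_of_run(scores)
    return RunSummary(score, position, region_length, true_target)


def distance_pct(best_position: float, true_target: float, region_length: int) -> float:
    """|reported - true| as a percentage of the region length."""
    if region_length <= 0:
        raise InputError("region_length must be positive")
    return 100.0 * abs(best_position - true_target) / region_length


def success_rate(distances_pct: Sequence[float], threshold_pct: float = 1.0) -> float:
    """Percentage of runs whose best location lies closer than the threshold."""
    d = np.asarray(distances_pct, dtype=float)
    if d.size == 0:
        raise InputError("no distances given")
    return 100.0 * float((d < threshold_pct).mean())


def cutoff_at(neutral_best_scores: Sequence[float], fpr_level: float = 0.05) -> float:
    """Tightest empirical cutoff: smallest observed score c with
    #(scores > c) / n <= fpr_level (the 95th-percentile order statistic for
    the default 5% level; level 0 returns the maximum)."""
    scores = np.sort(np.asarray(neutral_best_scores, dtype=float))
    n = scores.size
    if n == 0:
        raise InputError("no neutral scores given")
    if not 0.0 <= fpr_level < 1.0:
        raise InputError("fpr_level must lie in [0, 1)")
    k = math.ceil(n * (1.0 - fpr_level))  # order statistic rank, 1-based
    return float(scores[k - 1])


def tpr_fpr(
    selection_best_scores: Sequence[float],
    neutral_best_scores: Sequence[float],
    cutoff: float,
) -> tuple[float, float]:
    """Percent of runs with best score strictly above the cutoff, per class."""
    sel = np.asarray(selection_best_scores, dtype=float)
    neu = np.asarray(neutral_best_scores, dtype=float)
    if sel.size == 0 or neu.size == 0:
        raise InputError("both score sets must be non-empty")
    return 100.0 * float((sel > cutoff).mean()), 100.0 * float((neu > cutoff).mean())


def roc_curve(
    selection_best_scores: Sequence[float], neutral_best_scores: Sequence[float]
) -> tuple[np.ndarray, np.ndarray]:
    """(FPR%, TPR%) points from sweeping the cutoff over all observed scores,
    anchored at (0, 0) and (100, 100), non-decreasing in both coordinates."""
    sel = np.asarray(selection_best_scores, dtype=float)
    neu = np.asarray(neutral_best_scores, dtype=float)
    if sel.size == 0 or neu.size == 0:
        raise InputError("both score sets must be non-empty")
    cutoffs = np.unique(np.concatenate([sel, neu]))[::-1]
    fpr = [0.0]
    tpr = [0.0]
    for c in cutoffs:
        fpr.append(100.0 * float((neu > c).mean()))
        tpr.append(100.0 * float((sel > c).mean()))
    fpr.append(100.0)
    tpr.append(100.0)
    return np.asarray(fpr), np.asarray(tpr)


def tpr_at_fpr(
    roc_fpr_pct: np.ndarray, roc_tpr_pct: np.ndarray, fpr_pct: float
) -> float:
    """Read the curve at the largest achieved FPR <= the requested level."""
    fpr = np.asarray(roc_fpr_pct, dtype=float)
    tpr = np.asarray(roc_tpr_pct, dtype=float)
    eligible = fpr <= fpr_pct
    if not eligible.any():
        return 0.0
    best_fpr = fpr[eligible].max()
    return float(tpr[(fpr == best_fpr)].max())


def roc_auc(roc_fpr_pct: np.ndarray, roc_tpr_pct: np.ndarray) -> float:
    """Area under the ROC curve on the [0, 1] x [0, 1] scale."""
    return float(np.trapezoid(roc_tpr_pct / 100.0, roc_fpr_pct / 100.0))


def interpolate_at(
    scores: Sequence[MuScore], grid_positions: Sequence[float]
) -> np.ndarray:
    """Scores at external grid positions by nearest evaluated midpoint
    (ties -> leftmost midpoint; out-of-span positions clamp to the ends)."""
    usable = [sc for sc in scores if not sc.masked]
    if not usable:
        raise InputError("no scores to interpolate")
    pos = np.asarray([sc.position for sc in usable], dtype=float)
    mu = np.asarray([sc.mu for sc in usable], dtype=float)
    order = np.argsort(pos, kind="stable")
    pos, mu = pos[order], mu[order]
    grid = np.asarray(grid_positions, dtype=float)
    right = np.searchsorted(pos, grid, side="left")
    out = np.empty(grid.size, dtype=float)
    for j, (g, r) in enumerate(zip(grid, right)):
        if r == 0:
            out[j] = mu[0]
        elif r == pos.size:
            out[j] = mu[-1]
        else:
            # equidistant -> left midpoint
            out[j] = mu[r - 1] if g - pos[r - 1] <= pos[r] - g else mu[r]
    return out


def misspec_ratio(rate_matched: float, rate_actual: float) -> float:
    """log10(matched-model rate / misspecified-model rate) — one heatmap cell;
    0 on the diagonal, negative when misspecification inflates the rate."""
    if rate_matched <= 0 or rate_actual <= 0:
        raise InputError("rates must be positive; flag the cell instead")
    return math.log10(rate_matched / rate_actual)


def evaluate(
    selection_runs: Sequence[RunSummary],
    neutral_runs: Sequence[RunSummary],
    fpr_level: float = 0.05,
    success_threshold_pct: float = 1.0,
) -> EvalMetrics:
    """Full per-model benchmark from run summaries."""
    sel_scores = [r.best_score for r in selection_runs]
    neu_scores = [r.best_score for r in neutral_runs]
    cutoff = cutoff_at(neu_scores, fpr_level)
    tpr, fpr = tpr_fpr(sel_scores, neu_scores, cutoff)
    distances = [r.distance_pct for r in selection_runs if r.distance_pct is not None]
    if not distances:
        raise InputError("selection runs lack true targets")
    roc_f, roc_t = roc_curve(sel_scores, neu_scores)
    return EvalMetrics(
        cutoff=cutoff,
        fpr_pct=fpr,
        tpr_pct=tpr,
        mean_distance_pct=float(np.mean(distances)),
        success_rate_pct=success_rate(distances, success_threshold_pct),
        roc_fpr_pct=roc_f,
        roc_tpr_pct=roc_t,
    )


def save_roc_plot(
    roc_fpr_pct: np.ndarray, roc_tpr_pct: np.ndarray, path: str, label: str = "mu scan"
) -> None:
    """Optional ROC figure (PNG/PDF by extension)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(roc_fpr_pct, roc_tpr_pct, label=label)
    ax.plot([0, 100], [0, 100], ls="--", c="gray", lw=0.8, label="random")
    ax.set_xlabel("FPR (%)")
    ax.set_ylabel("TPR (%)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
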