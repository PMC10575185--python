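"""Diagnostic-performance metrics for dichotomous sorting trials.

sens = tp / (tp + fn), spc = tn / (tn + fp), and the Youden index
J = sens + spc - 1 summarise a single trial; a set of trials is summarised
as a ROC scatter of unique (1-spc, sens) points with trial multiplicities,
and two conditions are compared by the ratio of their mean J values and a
Welch two-sample t-test.

Aggregate J values are always computed from full-precision per-trial
results, never from rounded averages: recomputing J from printed-precision
mean sens/spc can legitimately differ from the mean of per-trial Js.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")


@dataclass(frozen=True)
class EvalResult:
    """sens/spc in [0,1] and J = sens + spc - 1 (exactly) for one trial."""

    sens: float
    spc: float
    j: float
    config: object | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.sens <= 1 and 0 <= self.spc <= 1):
            raise ValueError("sens and spc must lie in [0, 1]")
        if abs(self.j - (self.sens + self.spc - 1)) > 1e-12:
            raise ValueError("J must equal sens + spc - 1")


@dataclass(frozen=True)
class RocPoint:
    fpr: float
    tpr: float
    multiplicity: int


@dataclass(frozen=True)
class ComparisonResult:
    mean_j_a: float
    mean_j_b: float
    ratio: float
    p_value: float
    alpha: float
    significant: bool
    test_name: str = "Welch two-sample t-test (two-sided)"


def confusion(predictions: Mapping[str, str] | pd.Series,
              truth: Mapping[str, str] | pd.Series,
              positive_label: str = "positive") -> ConfusionCounts:
    """Exact confusion counts from per-spot predicted and true labels."""
    pred = pd.Series(predictions)
    true = pd.Series(truth)
    if set(pred.index) != set(true.index):
        raise ValueError("predictions and truth must cover the same spot ids")
    pred = pred.reindex(true.index)
    p = pred == positive_label
    t = true == positive_label
    return ConfusionCounts(
        tp=int((p & t).sum()),
        fp=int((p & ~t).sum()),
        tn=int((~p & ~t).sum()),
        fn=int((~p & t).sum()),
    )


def sens_spc_j(c: ConfusionCounts, config: object | None = None) -> EvalResult:
    """Sensitivity, specificity and Youden index from confusion counts.

    Raises on an empty class: the corresponding metric is undefined and is
    never silently reported as 0.
    """
    if c.tp + c.fn == 0:
        raise ValueError("no true-positive samples in the score set; sens undefined")
    if c.tn + c.fp == 0:
        raise ValueError("no true-negative samples in the score set; spc undefined")
    sens = c.tp / (c.tp + c.fn)
    spc = c.tn / (c.tn + c.fp)
    return EvalResult(sens=sens, spc=spc, j=sens + spc - 1, config=config)


def roc_scatter(results: Sequence[EvalResult]) -> list[RocPoint]:
    """Unique (fpr, tpr) points with the number of trials observed at each.

    This reproduces the dichotomous-trial ROC scatter (each trial contributes
    one point), not a threshold-swept ROC curve.
    """
    if not results:
        raise ValueError("roc_scatter needs at least one result")
    counts: dict[tuple[float, float], int] = {}
    for r in results:
        key = (1.0 - r.spc, r.sens)
        counts[key] = counts.get(key, 0) + 1
    return [RocPoint(fpr=f, tpr=t, multiplicity=m)
            for (f, t), m in sorted(counts.items())]


def compare_conditions(js_a: Sequence[float], js_b: Sequence[float],
                       alpha: float = 0.05) -> ComparisonResult:
    """Compare two conditions' per-trial J values.

    Reports mean J per condition, the ratio mean_a/mean_b, and a two-sided
    Welch (unequal-variance) two-sample t-test.  Degenerate zero-variance
    identical lists get p = 1 by convention.
    """
    a = np.asarray(js_a, dtype=float)
    b = np.asarray(js_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each condition needs at least 2 trials")
    mean_a, mean_b = float(a.mean()), float(b.mean())
    if a.std() == 0 and b.std() == 0:
        p = 1.0 if mean_a == mean_b else 0.0
        logger.info("compare_conditions: zero-variance inputs, p=%g by convention", p)
    else:
        p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
    return ComparisonResult(
        mean_j_a=mean_a,
        mean_j_b=mean_b,
        ratio=mean_a / mean_b,
        p_value=p,
        alpha=alpha,
        significant=bool(p < alpha),
    )


def results_frame(results: Sequence[EvalResult]) -> pd.DataFrame:
    """Per-trial sens/spc/J table (with config fields where available)."""
    rows = []
    for i, r in enumerate(results):
        row: dict[str, object] = {"trial": i, "sens": r.sens, "spc": r.spc, "j": r.j}
        cfg = r.config
        if cfg is not None:
            for name in ("n_trees", "learning_rate", "n_feature_bins", "seed"):
                if hasattr(cfg, name):
                    row[name] = getattr(cfg, name)
        rows.append(row)
    return pd.DataFrame(rows)


def summarize(results: Sequence[EvalResult]) -> dict[str, float]:
    """Full-precision means over trials, plus J recomputed from mean
    sens/spc for comparison (labelled distinctly)."""
    sens = np.array([r.sens for r in results])
    spc = np.array([r.spc for r in results])
    js = np.array([r.j for r in results])
    return {
        "n_trials": int(len(results)),
        "mean_sens": float(sens.mean()),
        "mean_spc": float(spc.mean()),
        "mean_j": float(js.mean()),
        "max_j": float(js.max()),
        "j_of_mean_sens_spc": float(sens.mean() + spc.mean() - 1.0),
    }


def plot_roc_scatter(points_by_condition: Mapping[str, Sequence[RocPoint]],
                     path: str | Path, title: str = "") -> None:
    """ROC scatter figure with trial-multiplicity annotations per point."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    colors = {"intact": "tab:green", "digested": "tab:blue"}
    for i, (name, points) in enumerate(points_by_condition.items()):
        color = colors.get(name, f"C{i}")
        xs = [p.fpr for p in points]
        ys = [p.tpr for p in points]
        ax.scatter(xs, ys, label=name, color=color, zorder=3)
        for p in points:
            ax.annotate(str(p.multiplicity), (p.fpr, p.tpr),
                        textcoords="offset points", xytext=(5, 3), fontsize=8)
    ax.plot([0, 1], [0, 1], ls="--", color="grey", lw=0.8, zorder=1)
    ax.set_xlim(-0.05, 1.05)
    ax.set_ylim(-0.05, 1.05)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    if title:
        ax.set_title(title)
    ax.legend(loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
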