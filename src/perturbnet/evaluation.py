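"""Score position predictions against functional reference sets.

Precision is the percentage of predicted (structurally sensitive)
positions that are functionally sensitive; recall the percentage of
functionally sensitive positions recovered.  Under random prediction the
expected precision equals the functional percentage and the expected
recall the prediction percentage, so the improvement factor

    improvement = TP · total / (|FSP| · |SSP|)

equals both precision/null_precision and recall/null_recall.  ROC curves
are traced by sweeping a uniform perturbation cutoff; the per-threshold
and per-cutoff sweep helpers produce tidy tables for parameter studies.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .prediction import (
    PredictionParams,
    scored_positions,
    select_fsps,
    sensitive_positions,
)
from .scoring import position_mean, standardize_table

__all__ = [
    "EvaluationReport",
    "ROCResult",
    "evaluate",
    "roc_curve",
    "spearman_by_position",
    "sweep_cutoffs",
    "sweep_thresholds",
    "default_cutoff_grid",
    "default_roc_grid",
]


@dataclass(frozen=True)
class EvaluationReport:
    """Precision/recall bookkeeping for one prediction.

    Percentages are on the 0–100 scale.  ``precision`` and ``improvement``
    are None when no position was predicted (undefined, not zero).
    """

    tp: int
    fp: int
    fn: int
    total_positions: int
    precision: float | None
    recall: float
    prediction_percentage: float
    functional_percentage: float
    null_precision: float
    null_recall: float
    improvement: float | None

    def as_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass(frozen=True)
class ROCResult:
    """ROC points (FPR, TPR) over a cutoff grid, with trapezoid AUC."""

    points: tuple[tuple[float, float], ...]  # sorted by FPR, endpoint-augmented
    auc: float
    cutoffs: tuple[float, ...]


def evaluate(
    predicted: set[int], reference: set[int], total_positions: int
) -> EvaluationReport:
    """Compare a predicted position set with a reference set.

    ``total_positions`` is the size of the scored-position universe both
    sets live in.
    """
    if total_positions <= 0:
        raise ValueError("total_positions must be positive")
    tp = len(predicted & reference)
    fp = len(predicted - reference)
    fn = len(reference - predicted)
    precision = 100.0 * tp / len(predicted) if predicted else None
    recall = 100.0 * tp / len(reference) if reference else 0.0
    prediction_pct = 100.0 * len(predicted) / total_positions
    functional_pct = 100.0 * len(reference) / total_positions
    improvement = (
        tp * total_positions / (len(reference) * len(predicted))
        if predicted and reference
        else None
    )
    return EvaluationReport(
        tp=tp,
        fp=fp,
        fn=fn,
        total_positions=total_positions,
        precision=precision,
        recall=recall,
        prediction_percentage=prediction_pct,
        functional_percentage=functional_pct,
        null_precision=functional_pct,
        null_recall=prediction_pct,
        improvement=improvement,
    )


def default_cutoff_grid() -> list[float]:
    """51 perturbation cutoffs from 1.0 to 2.0 in steps of 0.02."""
    return [round(c, 2) for c in np.linspace(1.0, 2.0, 51)]


def default_roc_grid(n: int = 100) -> list[float]:
    """Cutoff grid for ROC tracing: evenly spaced from 0.03 to 3."""
    return list(np.linspace(0.03, 3.0, n))


def roc_curve(
    table: pd.DataFrame,
    func: pd.DataFrame,
    params: PredictionParams,
    cutoff_grid: Sequence[float] | None = None,
) -> ROCResult:
    """ROC curve of SSP predictions as the uniform cutoff is swept.

    For each cutoff c the SSP set is predicted with cutoff vector
    (c, …, c) over ``params.measures_used`` at ``params.min_count``;
    TPR = TP/|FSP| and FPR = FP/(total − |FSP|) over the scored-position
    universe.  The curve is augmented with (0, 0) and (1, 1) and the AUC
    is the trapezoid area of the FPR-sorted points.
    """
    if cutoff_grid is None:
        cutoff_grid = default_roc_grid()
    cutoff_grid = list(cutoff_grid)
    if not cutoff_grid or sorted(cutoff_grid) != cutoff_grid:
        raise ValueError("cutoff_grid must be non-empty and ascending")
    universe = scored_positions(table, params.threshold_t) & set(
        func.index.astype(int)
    )
    if not universe:
        raise ValueError("no position has both structural and functional scores")
    func_universe = func.loc[sorted(universe)]
    fsps = select_fsps(func_universe, params.functional_percent) & universe
    total = len(universe)
    if not fsps or len(fsps) == total:
        raise ValueError("degenerate reference: all or no positions functional")
    pts = []
    for c in cutoff_grid:
        ssps = sensitive_positions(table, params.with_uniform_cutoff(c)) & universe
        tp = len(ssps & fsps)
        fp = len(ssps - fsps)
        pts.append((fp / (total - len(fsps)), tp / len(fsps)))
    pts.extend([(0.0, 0.0), (1.0, 1.0)])
    pts.sort()
    fpr = np.array([p[0] for p in pts])
    tpr = np.array([p[1] for p in pts])
    auc = float(np.trapezoid(tpr, fpr))
    return ROCResult(points=tuple(pts), auc=auc, cutoffs=tuple(cutoff_grid))


def _exact_spearman_pvalue(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact p-value by enumerating permutations of one ranking."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    perms = np.array(list(permutations(ry)))
    rxc = rx - rx.mean()
    pc = perms - perms.mean(axis=1, keepdims=True)
    denom = np.sqrt((rxc**2).sum() * (pc**2).sum(axis=1))
    rhos = pc @ rxc / denom
    return float(np.mean(np.abs(rhos) >= abs(rho_obs) - 1e-12))


def spearman_by_position(
    structural_means: Mapping[int, float],
    functional_means: Mapping[int, float],
) -> tuple[float, float]:
    """|Spearman rho| between per-position structural and functional means.

    Computed on the positions present in both maps (ties get average
    ranks).  Stronger perturbation accompanies stronger functional loss,
    so the raw correlation is negative; the absolute value is reported
    with a two-sided p-value (exact by permutation for n < 10, asymptotic
    otherwise).
    """
    shared = sorted(set(structural_means) & set(functional_means))
    if len(shared) < 3:
        raise ValueError("need at least 3 shared positions")
    x = np.array([structural_means[p] for p in shared], dtype=float)
    y = np.array([functional_means[p] for p in shared], dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    res = stats.spearmanr(x, y)
    rho = float(res.statistic)
    if len(shared) < 10:
        p = _exact_spearman_pvalue(x, y, rho)
    else:
        p = float(res.pvalue)
    return abs(rho), p


def sweep_cutoffs(
    table: pd.DataFrame,
    func: pd.DataFrame,
    params: PredictionParams,
    min_counts: Sequence[int] = (1, 2, 3),
    cutoffs: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Evaluation grid over (minimum count, uniform cutoff).

    Default cutoff grid is 1.0–2.0 in steps of 0.02 (51 values).  Returns
    a tidy frame with one :class:`EvaluationReport` per combination.
    """
    if cutoffs is None:
        cutoffs = default_cutoff_grid()
    universe = scored_positions(table, params.threshold_t) & set(
        func.index.astype(int)
    )
    func_universe = func.loc[sorted(universe)]
    fsps = select_fsps(func_universe, params.functional_percent) & universe
    rows = []
    for mc in min_counts:
        base = PredictionParams(
            threshold_t=params.threshold_t,
            cutoffs=params.cutoffs,
            min_count=mc,
            measures_used=params.measures_used,
            functional_percent=params.functional_percent,
        )
        for c in cutoffs:
            ssps = sensitive_positions(table, base.with_uniform_cutoff(c)) & universe
            report = evaluate(ssps, fsps, len(universe))
            rows.append({"min_count": mc, "cutoff": c, **report.as_dict()})
    return pd.DataFrame(rows)


def sweep_thresholds(
    raw_avg: pd.DataFrame,
    func: pd.DataFrame,
    params: PredictionParams,
) -> pd.DataFrame:
    """Per-threshold correlations and evaluation reports.

    ``raw_avg`` is a chain-averaged raw score table spanning several
    distance thresholds.  For each threshold the scores are standardized,
    the per-position mean of each measure is correlated (Spearman,
    absolute value) with the functional position means, and the SSP
    prediction under ``params`` (at that threshold) is evaluated.
    """
    from .prediction import functional_position_means

    table = standardize_table(raw_avg)
    func_means = dict(functional_position_means(func).items())
    rows = []
    for t in sorted(table["threshold"].unique()):
        at_t = PredictionParams(
            threshold_t=float(t),
            cutoffs=params.cutoffs,
            min_count=params.min_count,
            measures_used=params.measures_used,
            functional_percent=params.functional_percent,
        )
        universe = scored_positions(table, float(t)) & set(func.index.astype(int))
        func_universe = func.loc[sorted(universe)]
        fsps = select_fsps(func_universe, params.functional_percent) & universe
        ssps = sensitive_positions(table, at_t) & universe
        report = evaluate(ssps, fsps, len(universe))
        row = {"threshold": float(t), **report.as_dict()}
        for m in params.measures_used:
            struct_means = position_mean(table, m, float(t))
            rho, p = spearman_by_position(struct_means, func_means)
            row[f"spearman_{m}"] = rho
            row[f"spearman_{m}_pvalue"] = p
        rows.append(row)
    return pd.DataFrame(rows)
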