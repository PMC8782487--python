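"""Turn raw perturbation measures into standardized per-mutation scores.

The raw measures of a perturbation network (nodes, edges, weight,
diameter) live on different scales and grow with the distance threshold,
so scores are standardized per threshold and per measure before any
cross-measure comparison: for multichain proteins the measures are first
averaged over chains to give one score per (position, mutant amino acid);
synonymous "mutations" (mutant equals wild type, perturbation identically
zero) are removed so they do not compress the scale; the remaining values
are z-scored with the population standard deviation.  A positive z means
a stronger-than-average structural perturbation.

Tables are tidy :class:`pandas.DataFrame` objects.  The standardized
mutation score table has columns ``position, mut_aa, threshold, measure,
raw, zscore`` and is the input to the prediction module.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd

from .networks import MEASURES

__all__ = [
    "DegenerateDistributionError",
    "average_over_chains",
    "standardize",
    "standardize_table",
    "position_mean",
    "sign_consensus",
]


class DegenerateDistributionError(ValueError):
    """A score column has zero spread and cannot be standardized."""


def average_over_chains(raw: pd.DataFrame) -> pd.DataFrame:
    """Average raw measures over chains to one score per (position, mutant).

    ``raw`` is the output of :func:`perturbnet.networks.score_mutant_set`
    with a ``chain`` column.  When a mutation was scored on some chains
    only, the mean runs over the available chains.  Single-chain input
    passes through with the chain column dropped.
    """
    value_cols = [m for m in MEASURES if m in raw.columns]
    grouped = (
        raw.groupby(["position", "wt_aa", "mut_aa", "threshold"], as_index=False)[
            value_cols
        ].mean()
    )
    return grouped


def standardize(values: pd.Series | Iterable[float]) -> pd.Series:
    """Z-score a column with the population (divide-by-N) standard deviation.

    Missing values stay missing and do not enter the mean or the spread.
    Raises :class:`DegenerateDistributionError` when fewer than two values
    are present or all present values coincide.
    """
    s = pd.Series(values, dtype=float)
    present = s.dropna()
    if len(present) < 2:
        raise DegenerateDistributionError("need at least 2 values to standardize")
    sd = float(present.std(ddof=0))
    if sd == 0.0:
        raise DegenerateDistributionError("zero spread: all values identical")
    return (s - float(present.mean())) / sd


def standardize_table(raw_avg: pd.DataFrame) -> pd.DataFrame:
    """Build the tidy standardized mutation score table.

    ``raw_avg`` is the chain-averaged raw table (columns position, wt_aa,
    mut_aa, threshold, and the four measures).  Synonymous rows are dropped
    before z-scoring; each (threshold, measure) column is standardized
    independently.

    Returns a tidy frame with columns ``position, mut_aa, threshold,
    measure, raw, zscore``.
    """
    nonsyn = raw_avg[raw_avg["wt_aa"] != raw_avg["mut_aa"]]
    value_cols = [m for m in MEASURES if m in raw_avg.columns]
    long = nonsyn.melt(
        id_vars=["position", "mut_aa", "threshold"],
        value_vars=value_cols,
        var_name="measure",
        value_name="raw",
    )
    parts = []
    for (_, _), grp in long.groupby(["threshold", "measure"]):
        grp = grp.copy()
        grp["zscore"] = standardize(grp["raw"])
        parts.append(grp)
    table = pd.concat(parts, ignore_index=True)
    return table.sort_values(
        ["threshold", "measure", "position", "mut_aa"], ignore_index=True
    )


def position_mean(
    table: pd.DataFrame, measure: str, t: float
) -> dict[int, float]:
    """Mean standardized score per position for one measure and threshold.

    Positions whose scores are all missing are absent from the result.
    """
    sel = table[(table["measure"] == measure) & (table["threshold"] == t)]
    means = sel.groupby("position")["zscore"].mean().dropna()
    return {int(p): float(v) for p, v in means.items()}


def sign_consensus(
    table: pd.DataFrame, measure: str, t: float
) -> tuple[dict[int, float], float, float]:
    """Percentage of same-sign standardized scores per position.

    For each position, counts positive and negative z-scores among its
    mutations (exact zeros count toward neither sign) and reports
    100 · max(#positive, #negative) / (#positive + #negative).  High values
    mean most mutations at the position perturb the structure in the same
    direction relative to the average mutation, i.e. the effect is a
    property of the position rather than of the mutant amino acid.

    Returns (per-position percentages, mean over positions, sd over
    positions).
    """
    sel = table[(table["measure"] == measure) & (table["threshold"] == t)]
    out: dict[int, float] = {}
    for pos, grp in sel.groupby("position"):
        z = grp["zscore"].dropna()
        npos = int((z > 0).sum())
        nneg = int((z < 0).sum())
        if npos + nneg == 0:
            continue
        out[int(pos)] = 100.0 * max(npos, nneg) / (npos + nneg)
    values = np.array(list(out.values()), dtype=float)
    if values.size == 0:
        return out, float("nan"), float("nan")
    return out, float(values.mean()), float(values.std(ddof=0))
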