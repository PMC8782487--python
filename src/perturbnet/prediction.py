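"""Classify sequence positions as structurally or functionally sensitive.

Structural side: a mutation is *sensitive* for a measure when its
standardized perturbation score lies strictly above that measure's cutoff
(in standard deviations above the mean); a position is a structurally
sensitive position (SSP) when it has at least one sensitive mutation for
at least ``min_count`` of the measures in use.  Structurally robust
positions (SRPs) are the complement within the scored positions.  The
diameter is computed and reported but excluded from prediction by
default because of its erratic response to single-edge changes.

Functional side: from a deep-mutational-scanning table, functionally
sensitive positions (FSPs) are the bottom ``percent`` (default 40%) of
positions by mean functional score — strongest loss of function — and
functionally robust positions (FRPs) the top percent.  The functional
scores are used as published, never standardized.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import math

import pandas as pd

__all__ = [
    "AA_ORDER",
    "PredictionParams",
    "EmptySelectionError",
    "read_functional_table",
    "write_functional_table",
    "functional_position_means",
    "select_fsps",
    "select_frps",
    "sensitive_mutations",
    "sensitive_positions",
    "robust_positions",
    "scored_positions",
    "prediction_frame",
]

AA_ORDER = tuple("ACDEFGHIKLMNPQRSTVWY")

DEFAULT_CUTOFFS: Mapping[str, float] = {"nodes": 1.5, "edges": 1.5, "weight": 1.5}


class EmptySelectionError(ValueError):
    """A percentile selection produced no positions."""


@dataclass(frozen=True)
class PredictionParams:
    """Parameters of an SSP prediction.

    threshold_t:
        Distance threshold (Å) whose standardized scores are used;
        9 Å balances precision and recall.
    cutoffs:
        Per-measure sensitivity cutoffs in standard deviations above the
        mean.  The default (1.5, 1.5, 1.5) over nodes/edges/weight with
        ``min_count=2`` balances precision against recall.
    min_count:
        Number of measures for which a position must have at least one
        sensitive mutation to be called an SSP.
    measures_used:
        Measures entering the vote; diameter is excluded by default.
    functional_percent:
        Percentage of positions taken as functionally sensitive (and,
        symmetrically, robust).
    """

    threshold_t: float = 9.0
    cutoffs: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_CUTOFFS))
    min_count: int = 2
    measures_used: tuple[str, ...] = ("nodes", "edges", "weight")
    functional_percent: float = 40.0

    def validate(self) -> None:
        if not 1 <= self.min_count <= len(self.measures_used):
            raise ValueError(
                f"min_count must be in 1..{len(self.measures_used)}, got {self.min_count}"
            )
        for m in self.measures_used:
            if m not in self.cutoffs:
                raise ValueError(f"no cutoff given for measure {m!r}")

    def with_uniform_cutoff(self, c: float) -> "PredictionParams":
        return replace(self, cutoffs={m: c for m in self.measures_used})


# ---------------------------------------------------------------- functional

def read_functional_table(path: str | Path) -> pd.DataFrame:
    """Read a functional score table from CSV.

    Expected columns: ``position``, ``wt_aa``, then one column per mutant
    amino acid (single-letter code); empty cells are missing scores.
    Returns a frame indexed by position.
    """
    df = pd.read_csv(path)
    required = {"position", "wt_aa"}
    if not required <= set(df.columns):
        raise ValueError(f"functional CSV must have columns {sorted(required)}")
    df = df.set_index("position").sort_index()
    return df


def write_functional_table(func: pd.DataFrame, path: str | Path) -> None:
    func.reset_index().to_csv(path, index=False)


def functional_position_means(func: pd.DataFrame) -> pd.Series:
    """Mean functional score per position, ignoring missing entries.

    Positions with no data at all are dropped.
    """
    aa_cols = [c for c in func.columns if c in AA_ORDER]
    return func[aa_cols].mean(axis=1, skipna=True).dropna()


def _select_percentile(
    func: pd.DataFrame, percent: float, lowest: bool
) -> set[int]:
    if not 0 < percent < 100:
        raise ValueError(f"percent must be in (0, 100), got {percent}")
    means = functional_position_means(func)
    n = len(means)
    k = math.floor(n * percent / 100.0)
    if k == 0:
        raise EmptySelectionError(
            f"selecting {percent}% of {n} positions yields an empty set"
        )
    # deterministic tie-break at the boundary: lower position number first
    order = means.reset_index()
    order.columns = ["position", "mean"]
    order = order.sort_values(
        ["mean", "position"], ascending=[lowest, True], kind="mergesort"
    )
    return set(order["position"].head(k).astype(int))


def select_fsps(func: pd.DataFrame, percent: float = 40.0) -> set[int]:
    """Functionally sensitive positions: lowest mean functional score.

    Takes floor(n · percent/100) positions with the greatest loss of
    function; ties at the boundary resolve to the lower position number.
    """
    return _select_percentile(func, percent, lowest=True)


def select_frps(func: pd.DataFrame, percent: float = 40.0) -> set[int]:
    """Functionally robust positions: highest mean functional score."""
    return _select_percentile(func, percent, lowest=False)


# ---------------------------------------------------------------- structural

def _scores_at(table: pd.DataFrame, t: float) -> pd.DataFrame:
    sel = table[table["threshold"] == t]
    if sel.empty:
        raise ValueError(f"no standardized scores at threshold {t}")
    return sel


def scored_positions(table: pd.DataFrame, t: float) -> set[int]:
    """Positions with at least one non-missing standardized score at ``t``."""
    sel = _scores_at(table, t)
    return set(sel.dropna(subset=["zscore"])["position"].astype(int))


def sensitive_mutations(
    table: pd.DataFrame, params: PredictionParams
) -> dict[str, set[tuple[int, str]]]:
    """Per measure, the set of (position, mut_aa) strictly above its cutoff."""
    params.validate()
    sel = _scores_at(table, params.threshold_t)
    out: dict[str, set[tuple[int, str]]] = {}
    for m in params.measures_used:
        cut = params.cutoffs[m]
        hits = sel[(sel["measure"] == m) & (sel["zscore"] > cut)]
        out[m] = {(int(p), str(a)) for p, a in zip(hits["position"], hits["mut_aa"])}
    return out


def sensitive_positions(table: pd.DataFrame, params: PredictionParams) -> set[int]:
    """Structurally sensitive positions under a cutoff vector and minimum count."""
    per_measure = sensitive_mutations(table, params)
    counts: dict[int, int] = {}
    for m, muts in per_measure.items():
        for pos in {p for p, _ in muts}:
            counts[pos] = counts.get(pos, 0) + 1
    return {p for p, c in counts.items() if c >= params.min_count}


def robust_positions(table: pd.DataFrame, params: PredictionParams) -> set[int]:
    """Structurally robust positions: scored positions that are not SSPs."""
    return scored_positions(table, params.threshold_t) - sensitive_positions(
        table, params
    )


def prediction_frame(table: pd.DataFrame, params: PredictionParams) -> pd.DataFrame:
    """Tidy per-position prediction output.

    Columns: position, one sensitive flag per measure in use, count of
    sensitive measures, and ``is_ssp``.
    """
    per_measure = sensitive_mutations(table, params)
    positions = sorted(scored_positions(table, params.threshold_t))
    rows = []
    for pos in positions:
        flags = {
            f"sensitive_{m}": pos in {p for p, _ in muts}
            for m, muts in per_measure.items()
        }
        count = sum(flags.values())
        rows.append(
            {
                "position": pos,
                **flags,
                "count": count,
                "is_ssp": count >= params.min_count,
            }
        )
    return pd.DataFrame(rows)
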