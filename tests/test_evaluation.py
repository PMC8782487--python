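"""Precision/recall reports, improvement identities, ROC, Spearman, sweeps."""

import numpy as np
import pytest

from perturbnet.evaluation import (
    default_cutoff_grid,
    evaluate,
    roc_curve,
    spearman_by_position,
    sweep_cutoffs,
    sweep_thresholds,
)
from perturbnet.prediction import PredictionParams
from test_prediction import functional_from_means, score_table


class TestEvaluate:
    def test_hand_computed_example(self):
        report = evaluate({1, 2, 3, 4}, {1, 2, 3, 5}, total_positions=10)
        assert (report.tp, report.fp, report.fn) == (3, 1, 1)
        assert report.precision == 75.0
        assert report.recall == 75.0
        assert report.improvement == pytest.approx(1.875)

    def test_perfect_prediction(self):
        report = evaluate({1, 2, 3}, {1, 2, 3}, total_positions=12)
        assert report.precision == 100.0 and report.recall == 100.0
        assert report.improvement == pytest.approx(12 / 3)

    def test_disjoint_sets(self):
        report = evaluate({1, 2}, {3, 4}, total_positions=10)
        assert report.precision == 0.0 and report.recall == 0.0

    def test_empty_prediction_has_undefined_precision(self):
        report = evaluate(set(), {1, 2}, total_positions=10)
        assert report.precision is None
        assert report.recall == 0.0
        assert report.improvement is None

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            evaluate({1}, {1}, total_positions=0)

    def test_improvement_identities_on_random_sets(self):
        rng = np.random.default_rng(99)
        for _ in range(100):
            total = int(rng.integers(5, 200))
            universe = np.arange(1, total + 1)
            predicted = set(rng.choice(universe, size=rng.integers(1, total), replace=False))
            reference = set(rng.choice(universe, size=rng.integers(1, total), replace=False))
            r = evaluate(predicted, reference, total)
            expected = r.tp * total / (len(reference) * len(predicted))
            assert r.improvement == pytest.approx(expected, abs=1e-12)
            if r.tp > 0:
                assert r.improvement == pytest.approx(
                    r.precision / r.null_precision, abs=1e-12
                )
                assert r.improvement == pytest.approx(
                    r.recall / r.null_recall, abs=1e-12
                )
            assert r.null_precision == r.functional_percentage
            assert r.null_recall == r.prediction_percentage

    def test_permutation_invariance(self):
        rng = np.random.default_rng(5)
        universe = np.arange(1, 51)
        predicted = set(rng.choice(universe, 20, replace=False))
        reference = set(rng.choice(universe, 20, replace=False))
        relabel = {p: int(q) for p, q in zip(universe, rng.permutation(universe))}
        a = evaluate(predicted, reference, 50)
        b = evaluate({relabel[p] for p in predicted},
                     {relabel[p] for p in reference}, 50)
        assert a == b


def separable_dataset(n_positions=20, shift=3.0, seed=2):
    """Score table where FSP z-scores are shifted up; functional means match."""
    rng = np.random.default_rng(seed)
    fsp = set(range(1, int(n_positions * 0.4) + 1))
    zmap = {}
    means = {}
    for pos in range(1, n_positions + 1):
        base = shift if pos in fsp else 0.0
        zmap[pos] = {
            m: list(base + rng.normal(scale=0.3, size=6))
            for m in ("nodes", "edges", "weight")
        }
        means[pos] = -2.0 if pos in fsp else 0.0
    return score_table(zmap), functional_from_means(means), fsp


class TestROC:
    def test_extreme_cutoffs_hit_the_corners(self):
        table, func, _ = separable_dataset()
        low = roc_curve(table, func, PredictionParams(), cutoff_grid=[-10.0])
        assert low.points.count((1.0, 1.0)) == 2  # computed point + endpoint
        high = roc_curve(table, func, PredictionParams(), cutoff_grid=[10.0])
        assert high.points.count((0.0, 0.0)) == 2

    def test_separable_data_gives_high_auc(self):
        table, func, _ = separable_dataset()
        roc = roc_curve(table, func, PredictionParams())
        assert roc.auc > 0.95

    def test_points_monotone_in_cutoff(self):
        table, func, _ = separable_dataset()
        grid = list(np.linspace(-1, 4, 30))
        params = PredictionParams()
        rates = []
        for c in grid:
            sub = roc_curve(table, func, params, cutoff_grid=[c])
            raw_pts = [p for p in sub.points if p not in ((0.0, 0.0), (1.0, 1.0))]
            rates.append(raw_pts[0] if raw_pts else None)
        seen = [r for r in rates if r is not None]
        for earlier, later in zip(seen, seen[1:]):
            assert later[0] <= earlier[0] and later[1] <= earlier[1]

    def test_random_scores_give_half_auc(self):
        rng = np.random.default_rng(1234)
        aucs = []
        for _ in range(50):
            n = 30
            zmap = {
                pos: {m: list(rng.normal(size=5))
                      for m in ("nodes", "edges", "weight")}
                for pos in range(1, n + 1)
            }
            means = {pos: float(rng.normal()) for pos in range(1, n + 1)}
            roc = roc_curve(
                score_table(zmap), functional_from_means(means),
                PredictionParams(),
                cutoff_grid=list(np.linspace(-2.5, 2.5, 21)),
            )
            aucs.append(roc.auc)
        assert abs(np.mean(aucs) - 0.5) < 0.05

    def test_auc_matches_sklearn_trapezoid(self):
        from sklearn.metrics import auc as sk_auc

        table, func, _ = separable_dataset()
        roc = roc_curve(table, func, PredictionParams())
        fpr = [p[0] for p in roc.points]
        tpr = [p[1] for p in roc.points]
        assert roc.auc == pytest.approx(sk_auc(fpr, tpr), abs=1e-12)

    def test_degenerate_reference_rejected(self):
        table, _, _ = separable_dataset()
        func = functional_from_means({p: 0.0 for p in range(1, 21)})
        with pytest.raises(ValueError, match="no position|degenerate"):
            roc_curve(table, func.iloc[0:0], PredictionParams())


class TestSpearman:
    def test_perfect_antimonotone(self):
        struct = {p: float(p) for p in range(1, 21)}
        func = {p: -float(p) for p in range(1, 21)}
        rho, p = spearman_by_position(struct, func)
        assert rho == pytest.approx(1.0)
        assert p < 1e-6

    def test_independent_noise_uncorrelated(self):
        rng = np.random.default_rng(77)
        struct = {p: float(rng.normal()) for p in range(1, 201)}
        func = {p: float(rng.normal()) for p in range(1, 201)}
        rho, _ = spearman_by_position(struct, func)
        assert rho < 0.2

    def test_ties_use_average_ranks(self):
        rho, _ = spearman_by_position(
            {1: 1.0, 2: 1.0, 3: 2.0}, {1: 3.0, 2: 3.0, 3: 4.0}
        )
        assert rho == pytest.approx(1.0)

    def test_exact_small_n_pvalue(self):
        # n = 4, perfectly concordant: 2 of 24 orderings reach |rho| = 1
        rho, p = spearman_by_position(
            {1: 1.0, 2: 2.0, 3: 3.0, 4: 4.0}, {1: 1.0, 2: 4.0, 3: 9.0, 4: 16.0}
        )
        assert rho == pytest.approx(1.0)
        assert p == pytest.approx(2 / 24)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spearman_by_position({1: 1.0, 2: 1.0, 3: 1.0}, {1: 1.0, 2: 2.0, 3: 3.0})

    def test_too_few_shared_positions_rejected(self):
        with pytest.raises(ValueError, match="shared"):
            spearman_by_position({1: 1.0, 2: 2.0}, {1: 1.0, 2: 2.0})


class TestSweeps:
    def test_default_cutoff_grid_length(self):
        grid = default_cutoff_grid()
        assert len(grid) == 51
        assert grid[0] == 1.0 and grid[-1] == 2.0

    def test_cutoff_sweep_shape_and_trends(self):
        table, func, _ = separable_dataset(n_positions=30, shift=1.5, seed=4)
        grid = sweep_cutoffs(table, func, PredictionParams())
        assert len(grid) == 3 * 51
        means = grid.groupby("min_count")[["precision", "recall"]].mean()
        assert means["precision"].is_monotonic_increasing
        assert means["recall"].is_monotonic_decreasing

    def test_threshold_sweep_rows_and_content(self, small_multithreshold):
        raw_avg, func, _ = small_multithreshold
        out = sweep_thresholds(raw_avg, func, PredictionParams())
        assert list(out["threshold"]) == [8.0, 9.0, 10.0]
        assert {"precision", "recall", "spearman_nodes"} <= set(out.columns)
        assert out["spearman_nodes"].between(0, 1).all()
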