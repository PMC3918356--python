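"""R-value overlap scoring, RFS ranking and ReliefF weights."""

import numpy as np
import pytest

from cordfa import (
    CohortConfig,
    expand_features,
    generate_feature_cohort,
    r_value,
    relieff_weights,
    rfs_rank,
    select_top,
)
from cordfa.errors import ConfigError

from conftest import make_table


def brute_force_r_value(x, y, k, threshold):
    """Exhaustive neighbor enumeration with index tie-break."""
    x = np.asarray(x, dtype=float)
    n = len(y)
    overlap = 0
    for i in range(n):
        pairs = sorted(
            (abs(x[j] - x[i]), j) for j in range(n) if j != i
        )
        nbrs = [j for _, j in pairs[:k]]
        if sum(y[j] != y[i] for j in nbrs) > threshold:
            overlap += 1
    return overlap / n


def naive_relieff(x, y, k):
    """Straightforward ReliefF trace visiting every record in order."""
    x = np.asarray(x, dtype=float)
    spans = x.max(axis=0) - x.min(axis=0)
    spans[spans == 0] = 1.0
    n, m = x.shape
    w = np.zeros(m)
    for i in range(n):
        d = np.linalg.norm(x - x[i], axis=1)
        order = sorted(j for j in range(n) if j != i)
        order.sort(key=lambda j: (d[j], j))
        hits = [j for j in order if y[j] == y[i]][:k]
        misses = [j for j in order if y[j] != y[i]][:k]
        w += np.abs(x[misses] - x[i]).mean(axis=0) / spans
        w -= np.abs(x[hits] - x[i]).mean(axis=0) / spans
    return w / n


class TestRValue:
    def test_distant_tight_clusters_score_zero(self):
        x = np.array([0.0, 0.01, 10.0, 10.01])
        y = np.array([0, 0, 1, 1])
        assert r_value(x, y, k_neighbors=1, threshold=0) == 0.0

    def test_interleaved_line_matches_brute_force(self):
        x = np.array([0.0, 1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([0, 1, 0, 1, 0, 1])
        got = r_value(x, y, k_neighbors=3, threshold=1)
        assert got == brute_force_r_value(x, y, 3, 1)

    def test_random_instances_match_brute_force(self):
        rng = np.random.default_rng(31)
        for _ in range(100):
            n = rng.integers(8, 25)
            x = rng.normal(size=n).round(2)  # rounding forces distance ties
            y = rng.integers(0, 2, size=n)
            if len(np.unique(y)) < 2:
                y[0] = 1 - y[0]
            k = int(rng.integers(1, min(7, n - 1) + 1))
            thr = int(rng.integers(0, k + 1))
            assert r_value(x, y, k, thr) == brute_force_r_value(x, y, k, thr)

    def test_score_times_n_is_integer(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            n = int(rng.integers(10, 40))
            x = rng.normal(size=n)
            y = rng.integers(0, 2, size=n)
            if len(np.unique(y)) < 2:
                y[0] = 1 - y[0]
            score = r_value(x, y, 5, 2)
            assert score * n == pytest.approx(round(score * n), abs=1e-9)

    def test_monotone_transform_invariance(self):
        """Affine maps preserve the 1-D neighbor ordering and the score."""
        rng = np.random.default_rng(14)
        x = rng.normal(size=30)
        y = rng.integers(0, 2, size=30)
        y[0] = 1 - y[0] if len(np.unique(y)) < 2 else y[0]
        base = r_value(x, y, 7, 3)
        assert r_value(3.5 * x + 2.0, y, 7, 3) == base

    def test_parameter_errors(self):
        x = np.arange(5.0)
        y = np.array([0, 0, 1, 1, 0])
        with pytest.raises(ConfigError):
            r_value(x, y, k_neighbors=5, threshold=0)
        with pytest.raises(ConfigError):
            r_value(x, y, k_neighbors=2, threshold=3)


class TestRfsRank:
    def separating_vs_noise_table(self, seed):
        rng = np.random.default_rng(seed)
        n = 40
        y = np.r_[np.zeros(20, int), np.ones(20, int)]
        sep = np.r_[rng.normal(0.0, 0.1, 20), rng.normal(5.0, 0.1, 20)]
        noise = rng.normal(0, 1, n)
        return make_table(
            np.c_[noise, sep], y, feature_names=["noise", "sep"]
        )

    def test_separating_feature_ranks_first(self):
        for seed in range(20):
            rk = rfs_rank(self.separating_vs_noise_table(seed), 5, 2)
            assert rk.names[0] == "sep"
            assert rk.names[-1] == "noise"

    def test_tie_break_by_feature_index(self):
        x = np.arange(10.0)
        y = np.array([0, 1] * 5)
        t = make_table(np.c_[x, x], y, feature_names=["first", "second"])
        rk = rfs_rank(t, 3, 1)
        assert [s for _, s in rk.ordered][0] == [s for _, s in rk.ordered][1]
        assert rk.names == ["first", "second"]

    def test_calibrated_cohort_composites_beat_posterior_alone(self):
        """Composite features involving A and R out-rank the single P
        feature in the median ranking over seeds."""
        ranks_alr, ranks_p = [], []
        for seed in range(20):
            cohort = generate_feature_cohort(
                CohortConfig(seed=100 + seed)
            )
            rk = rfs_rank(expand_features(cohort))
            names = rk.names
            ranks_alr.append(names.index("ALR"))
            ranks_p.append(names.index("P"))
        assert np.median(ranks_alr) < np.median(ranks_p)

    def test_scores_ascending(self):
        rk = rfs_rank(self.separating_vs_noise_table(0), 5, 2)
        scores = [s for _, s in rk.ordered]
        assert scores == sorted(scores)


class TestRelieff:
    def test_constant_feature_weight_zero(self):
        rng = np.random.default_rng(1)
        y = np.r_[np.zeros(10, int), np.ones(10, int)]
        t = make_table(
            np.c_[np.full(20, 0.5), rng.normal(size=20)],
            y,
            feature_names=["const", "var"],
        )
        rk = relieff_weights(t, k_neighbors=3)
        weights = dict(rk.ordered)
        assert weights["const"] == 0.0

    def test_separator_beats_noise_across_seeds(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            y = np.r_[np.zeros(15, int), np.ones(15, int)]
            sep = np.r_[rng.normal(0, 0.1, 15), rng.normal(3, 0.1, 15)]
            noise = rng.normal(size=30)
            t = make_table(np.c_[sep, noise], y, feature_names=["sep", "noise"])
            rk = relieff_weights(t, k_neighbors=5, n_iterations=20, seed=seed)
            w = dict(rk.ordered)
            assert w["sep"] > w["noise"]
            assert rk.names[0] == "sep"

    def test_matches_naive_full_trace(self):
        """8-record instance against an independent step-by-step trace."""
        x = np.array(
            [
                [0.1, 0.9],
                [0.2, 0.8],
                [0.15, 0.35],
                [0.3, 0.4],
                [0.8, 0.2],
                [0.9, 0.3],
                [0.85, 0.75],
                [0.7, 0.6],
            ]
        )
        y = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        t = make_table(x, y, feature_names=["f0", "f1"])
        rk = relieff_weights(t, k_neighbors=2, n_iterations=None)
        expected = naive_relieff(x, y, 2)
        got = dict(rk.ordered)
        assert got["f0"] == pytest.approx(expected[0], abs=1e-12)
        assert got["f1"] == pytest.approx(expected[1], abs=1e-12)

    def test_degenerate_class_sizes_rejected(self):
        t = make_table([[0.1], [0.2], [0.9]], [0, 0, 1])
        with pytest.raises(ConfigError):
            relieff_weights(t, k_neighbors=2)


class TestSelectTop:
    def test_full_and_single_selection(self):
        x = np.arange(12.0)
        y = np.array([0, 1] * 6)
        t = make_table(
            np.c_[x, (y * 10.0) + x * 0.01], y, feature_names=["noise", "sep"]
        )
        rk = rfs_rank(t, 3, 1)
        assert select_top(rk, 2) == rk.names
        assert select_top(rk, 1) == ["sep"]
        with pytest.raises(ConfigError):
            select_top(rk, 0)
        with pytest.raises(ConfigError):
            select_top(rk, 3)
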