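"""Filter feature selection: R-value class-overlap ranking and ReliefF.

The R-value of a feature measures class *congestion*: the fraction of
records whose local neighborhood (the k nearest records in that feature's
value space) is dominated by the other class.  A record is counted as
lying in the overlap area when **more than** ``threshold`` of its k nearest
neighbors carry a different label; the score is ``overlap_count / N`` and
is therefore always an integer multiple of 1/N.  R-value-based feature
selection (RFS) ranks features ascending by this score — lower means
cleaner class separation.

The exact neighborhood parameters used in the original clinical analysis
are not published; defaults are ``k_neighbors=7`` with a majority
``threshold=3``, and both are exposed.

ReliefF is provided as an independent comparator: feature weights are
accumulated over sampled instances as the mean distance to nearest misses
minus the mean distance to nearest hits, with per-feature differences
scaled to the observed range, so weights are *descending*-is-better.

All nearest-neighbor ties (equal distances) resolve by record index, which
makes every ranking deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError
from .types import FeatureTable


@dataclass
class FeatureRanking:
    """Ordered feature scores from one selection method.

    ``ordered`` lists (feature_name, score) best-first: ascending scores
    for RFS, descending weights for ReliefF.
    """

    ordered: list[tuple[str, float]]
    method: str
    params: dict = field(default_factory=dict)

    @property
    def names(self) -> list[str]:
        return [name for name, _ in self.ordered]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"rank": i + 1, "feature": name, "score": score}
                for i, (name, score) in enumerate(self.ordered)
            ]
        )

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "params": self.params,
            "ranking": self.to_frame().to_dict(orient="records"),
        }


def _neighbor_order(distances: np.ndarray) -> np.ndarray:
    # stable sort: equal distances resolve by record index
    return np.argsort(distances, kind="stable")


def r_value(
    values: np.ndarray,
    labels: np.ndarray,
    k_neighbors: int = 7,
    threshold: int = 3,
) -> float:
    """Class-overlap score of one feature: overlap count / N in [0, 1].

    ``values`` may be shape (N,) for a single feature or (N, d); neighbors
    are the k nearest other records by Euclidean distance.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    y = np.asarray(labels)
    n = len(y)
    if x.shape[0] != n:
        raise DataError("values and labels lengths disagree")
    if len(np.unique(y)) < 2:
        raise DataError("r_value needs two classes present")
    if k_neighbors >= n:
        raise ConfigError(f"k_neighbors={k_neighbors} must be < N={n}")
    if not 0 <= threshold <= k_neighbors:
        raise ConfigError("threshold must lie in [0, k_neighbors]")
    overlap = 0
    for i in range(n):
        d = np.linalg.norm(x - x[i], axis=1)
        d[i] = np.inf  # exclude self
        nbrs = _neighbor_order(d)[:k_neighbors]
        if np.sum(y[nbrs] != y[i]) > threshold:
            overlap += 1
    return overlap / n


def rfs_rank(
    table: FeatureTable, k_neighbors: int = 7, threshold: int = 3
) -> FeatureRanking:
    """Rank all features ascending by R-value; ties keep feature order."""
    labels = table.labels
    values = table.values
    scores = [
        r_value(values[:, j], labels, k_neighbors, threshold)
        for j in range(table.n_features)
    ]
    order = np.argsort(scores, kind="stable")
    ordered = [(table.feature_names[j], float(scores[j])) for j in order]
    return FeatureRanking(
        ordered=ordered,
        method="rfs",
        params={"k_neighbors": k_neighbors, "threshold": threshold},
    )


def relieff_weights(
    table: FeatureTable,
    k_neighbors: int = 5,
    n_iterations: int | None = None,
    seed: int = 0,
) -> FeatureRanking:
    """ReliefF feature weights, descending (higher = more discriminative).

    For each visited instance the k nearest same-class records (hits) and
    k nearest other-class records (misses) are found in the full feature
    space; each feature's weight moves by mean |diff| to misses minus mean
    |diff| to hits, with diffs scaled to the feature's observed range.
    ``n_iterations=None`` visits every record once in index order (fully
    deterministic); an integer samples that many records with ``seed``.
    """
    x = table.values
    y = table.labels
    n = len(y)
    for cls in np.unique(y):
        if np.sum(y == cls) < k_neighbors + 1:
            raise ConfigError(
                f"class {cls} has fewer than k_neighbors+1={k_neighbors + 1} records"
            )
    spans = x.max(axis=0) - x.min(axis=0)
    spans[spans == 0] = 1.0  # constant feature: diffs are 0 anyway
    if n_iterations is None:
        visits = np.arange(n)
    else:
        rng = np.random.default_rng(seed)
        visits = rng.integers(0, n, size=n_iterations)
    weights = np.zeros(table.n_features)
    for i in visits:
        d = np.linalg.norm(x - x[i], axis=1)
        d[i] = np.inf
        order = _neighbor_order(d)
        same = y[order] == y[i]
        hits = order[same][:k_neighbors]
        misses = order[~same][:k_neighbors]
        diff_hit = np.abs(x[hits] - x[i]) / spans
        diff_miss = np.abs(x[misses] - x[i]) / spans
        weights += diff_miss.mean(axis=0) - diff_hit.mean(axis=0)
    weights /= len(visits)
    order = np.argsort(-weights, kind="stable")
    ordered = [(table.feature_names[j], float(weights[j])) for j in order]
    return FeatureRanking(
        ordered=ordered,
        method="relieff",
        params={
            "k_neighbors": k_neighbors,
            "n_iterations": n_iterations,
            "seed": seed,
        },
    )


def select_top(ranking: FeatureRanking, n: int) -> list[str]:
    """The n best features per the ranking's orientation, best first."""
    if not 1 <= n <= len(ranking.ordered):
        raise ConfigError(
            f"n={n} outside [1, {len(ranking.ordered)}] for this ranking"
        )
    return ranking.names[:n]
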