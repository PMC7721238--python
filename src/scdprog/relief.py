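"""Ensemble ReliefF feature ranking.

ReliefF weights a feature by how much it differs between each subject and its
nearest neighbors of the opposite class (misses, rewarded) versus its nearest
neighbors of the same class (hits, penalized).  The variant implemented here
is deterministic: every subject serves as an anchor exactly once, distances
are Manhattan on range-normalized features, and neighbor ties in distance are
broken by subject index.

Because the appropriate neighbor count k is unknown a priori, weights are
computed over a grid of k values (default 1..20) and the resulting rank lists
are merged into one overall order by counting how often each feature lands in
the top-m (default top-50) of a list; ties are broken by mean rank across
lists, then by feature index.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .matrix import FeatureMatrix

__all__ = ["ReliefConfig", "RankingEnsemble", "relieff_weights", "rank_features", "ensemble_rank"]


@dataclass
class ReliefConfig:
    """Grid and aggregation settings for the ranking ensemble.

    ``k_min``..``k_max`` (step ``k_step``) is the neighbor-count grid;
    ``top_m`` is the list depth used when counting occurrences.
    """

    k_min: int = 1
    k_max: int = 20
    k_step: int = 1
    top_m: int = 50
    scaling: str = "range"

    def k_grid(self) -> list[int]:
        if not (1 <= self.k_min <= self.k_max):
            raise ValueError("require 1 <= k_min <= k_max")
        if self.k_step < 1:
            raise ValueError("k_step must be >= 1")
        return list(range(self.k_min, self.k_max + 1, self.k_step))


@dataclass
class RankingEnsemble:
    """Per-k ReliefF weights/rankings plus their aggregated overall order."""

    per_k_weights: dict[int, np.ndarray]
    per_k_ranking: dict[int, np.ndarray]
    occurrence_counts: np.ndarray
    mean_ranks: np.ndarray
    aggregated_order: np.ndarray
    feature_names: list[str] | None = None

    def to_table(self):
        """Feature-by-feature summary (occurrence count, mean rank, aggregate position)."""
        import pandas as pd

        d = len(self.occurrence_counts)
        position = np.empty(d, dtype=int)
        position[self.aggregated_order] = np.arange(d)
        names = self.feature_names or [f"f{i}" for i in range(d)]
        return pd.DataFrame(
            {
                "feature": names,
                "occurrence_count": self.occurrence_counts,
                "mean_rank": self.mean_ranks,
                "aggregate_position": position,
            }
        ).sort_values("aggregate_position")


def _as_xy(X, y):
    if isinstance(X, FeatureMatrix):
        if y is None:
            y = X.labels
        X = X.values
    X = np.asarray(X, dtype=float)
    if y is None:
        raise ValueError("labels are required for ReliefF")
    y = np.asarray(y, dtype=int)
    if X.ndim != 2 or y.shape != (X.shape[0],):
        raise ValueError("X must be 2-D with one label per row")
    if len(np.unique(y)) != 2:
        raise ValueError("ReliefF requires exactly two classes present")
    return X, y


def _range_normalize(X: np.ndarray) -> np.ndarray:
    # Constant features get zero columns: they contribute diff 0 everywhere
    # rather than dividing by zero, so their weight is exactly 0.
    lo = X.min(axis=0)
    rng = X.max(axis=0) - lo
    safe = np.where(rng > 0, rng, 1.0)
    Xn = (X - lo) / safe
    Xn[:, rng == 0] = 0.0
    return Xn


def _neighbor_tables(Xn: np.ndarray, y: np.ndarray):
    """Per-anchor hit/miss neighbor indices sorted by (distance, index)."""
    n = Xn.shape[0]
    from scipy.spatial.distance import squareform, pdist

    D = squareform(pdist(Xn, metric="cityblock")) if n > 1 else np.zeros((1, 1))
    hits, misses = [], []
    for i in range(n):
        same = np.flatnonzero((y == y[i]) & (np.arange(n) != i))
        diff = np.flatnonzero(y != y[i])
        # stable sort on distance preserves the index tie-break
        hits.append(same[np.argsort(D[i, same], kind="stable")])
        misses.append(diff[np.argsort(D[i, diff], kind="stable")])
    return hits, misses


def _weights_for_grid(X: np.ndarray, y: np.ndarray, ks: Sequence[int]) -> dict[int, np.ndarray]:
    """ReliefF weights for every k in ``ks``, sharing one distance computation.

    For each anchor the absolute feature differences to its sorted hits and
    misses are accumulated with a running cumulative sum, so all k values are
    read off a single pass.
    """
    n, d = X.shape
    counts = np.bincount(y, minlength=2)
    kmax = max(ks)
    if kmax > counts.min() - 1:
        raise ValueError(
            f"k={kmax} requires at least {kmax + 1} subjects in each class "
            f"(smallest class has {counts.min()})"
        )
    Xn = _range_normalize(X)
    hits, misses = _neighbor_tables(Xn, y)
    ks = sorted(set(ks))
    acc = {k: np.zeros(d) for k in ks}
    for i in range(n):
        hit_diffs = np.abs(Xn[hits[i][:kmax]] - Xn[i])     # (kmax, d)
        miss_diffs = np.abs(Xn[misses[i][:kmax]] - Xn[i])
        hit_cum = np.cumsum(hit_diffs, axis=0)
        miss_cum = np.cumsum(miss_diffs, axis=0)
        for k in ks:
            acc[k] += miss_cum[k - 1] / k - hit_cum[k - 1] / k
    return {k: acc[k] / n for k in ks}


def relieff_weights(X, y=None, k: int = 1) -> np.ndarray:
    """ReliefF feature weights for a single neighbor count ``k``.

    With range-normalized differences every weight lies in [-1, 1]; positive
    weights mark features whose values separate the classes locally.
    Deterministic: every subject is an anchor, no sampling.
    """
    X, y = _as_xy(X, y)
    if k < 1:
        raise ValueError("k must be >= 1")
    return _weights_for_grid(X, y, [k])[k]


def rank_features(weights: Sequence[float]) -> np.ndarray:
    """Order feature indices by descending weight, ties by ascending index."""
    w = np.asarray(weights, dtype=float)
    if np.isnan(w).any():
        raise ValueError("feature weights contain NaN")
    return np.lexsort((np.arange(len(w)), -w))


def ensemble_rank(X, y=None, cfg: ReliefConfig | None = None) -> RankingEnsemble:
    """Run ReliefF over the k grid and aggregate the rank lists.

    The overall order sorts features by descending top-m occurrence count,
    breaking ties by smaller mean rank across lists, then by feature index.
    """
    cfg = cfg or ReliefConfig()
    names = X.feature_names if isinstance(X, FeatureMatrix) else None
    X, y = _as_xy(X, y)
    d = X.shape[1]
    top_m = min(cfg.top_m, d)
    ks = cfg.k_grid()
    weights = _weights_for_grid(X, y, ks)
    rankings = {k: rank_features(weights[k]) for k in ks}
    counts = np.zeros(d, dtype=int)
    rank_positions = np.zeros(d, dtype=float)
    for k in ks:
        counts[rankings[k][:top_m]] += 1
        pos = np.empty(d)
        pos[rankings[k]] = np.arange(d)
        rank_positions += pos
    mean_ranks = rank_positions / len(ks)
    aggregated = np.lexsort((np.arange(d), mean_ranks, -counts))
    return RankingEnsemble(
        per_k_weights=weights,
        per_k_ranking=rankings,
        occurrence_counts=counts,
        mean_ranks=mean_ranks,
        aggregated_order=aggregated,
        feature_names=names,
    )
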