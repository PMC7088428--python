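"""Information-gain feature ranking and nested top-k subsets.

Each feature column is discretized into equal-width bins over its observed
range (a constant column collapses to one bin) and scored by the mutual
information between the binned feature and the class label, in bits:
IG = H(Y) - H(Y|X). Scores are non-negative; ranking is by descending
score with ascending feature index breaking ties, so top-k subsets are
nested and deterministic.

Ranking should be computed on training data only and the frozen index set
applied to held-out data; :func:`submitoloc.classifier.cross_validate`
re-ranks inside every training fold for exactly this reason.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


def _entropy_bits(counts: np.ndarray) -> float:
    total = counts.sum()
    if total == 0:
        return 0.0
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum())


def _discretize(column: np.ndarray, bins: int) -> np.ndarray:
    lo, hi = float(column.min()), float(column.max())
    if hi == lo:
        return np.zeros(len(column), dtype=int)
    idx = np.floor((column - lo) / (hi - lo) * bins).astype(int)
    return np.clip(idx, 0, bins - 1)


def information_gain(
    feature_column: np.ndarray,
    labels: np.ndarray,
    bins: int = 10,
) -> float:
    """Mutual information (bits) between a binned feature and the labels."""
    column = np.asarray(feature_column, dtype=float)
    labels = np.asarray(labels)
    if len(column) != len(labels):
        raise ValueError("feature column and labels differ in length")
    if len(column) < 2:
        raise ValueError("need at least 2 samples")
    classes, y = np.unique(labels, return_inverse=True)
    if len(classes) < 2:
        raise ValueError("information gain needs at least 2 distinct labels")
    if bins < 1:
        raise ValueError(f"bins must be >= 1, got {bins}")

    x = _discretize(column, bins)
    joint = np.zeros((bins, len(classes)))
    np.add.at(joint, (x, y), 1.0)

    h_y = _entropy_bits(joint.sum(axis=0))
    n = len(column)
    h_y_given_x = 0.0
    for bin_counts in joint:
        bin_total = bin_counts.sum()
        if bin_total > 0:
            h_y_given_x += (bin_total / n) * _entropy_bits(bin_counts)
    return max(h_y - h_y_given_x, 0.0)


@dataclass
class RankedFeatureSet:
    """Per-feature IG scores with a deterministic total order."""

    scores: np.ndarray = field(repr=False)
    order: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if np.any(self.scores < 0):
            raise ValueError("information-gain scores must be non-negative")
        if sorted(self.order) != list(range(len(self.scores))):
            raise ValueError("order must be a permutation of feature indices")

    def subset(self, k: int | None) -> np.ndarray:
        """Indices of the top-k features (all features when k is None)."""
        if k is None:
            return self.order.copy()
        if not (0 < k <= len(self.order)):
            raise ValueError(f"k must be in [1, {len(self.order)}], got {k}")
        return self.order[:k].copy()

    def to_frame(self, feature_names: list[str] | None = None):
        import pandas as pd

        names = (
            [feature_names[i] for i in self.order]
            if feature_names is not None
            else list(self.order)
        )
        return pd.DataFrame(
            {
                "feature": names,
                "information_gain_bits": self.scores[self.order],
                "rank": np.arange(1, len(self.order) + 1),
            }
        )


def rank_features(
    matrix: np.ndarray,
    labels: np.ndarray,
    bins: int = 10,
) -> RankedFeatureSet:
    """Score every column by information gain and rank descending."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2:
        raise ValueError("matrix must be 2-dimensional")
    scores = np.array(
        [information_gain(matrix[:, j], labels, bins) for j in range(matrix.shape[1])]
    )
    # descending score, ascending index on ties
    order = np.lexsort((np.arange(len(scores)), -scores))
    return RankedFeatureSet(scores=scores, order=order)
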