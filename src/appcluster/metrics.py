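"""Partition-quality scores: misclassification, per-cluster F1, silhouette.

Misclassification and F1 are computed *after* aligning predicted cluster
IDs to ground-truth IDs (see `label_transfer.match_cluster_labels`), so
all scores are invariant to cluster renaming.  The silhouette coefficient
is computed from scratch (chunked pairwise Euclidean distances) so that a
library implementation can serve as an independent cross-check; above
10,000 events it is evaluated on a fixed-seed subsample.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.metrics import adjusted_rand_score

__all__ = [
    "total_misclassification",
    "f1_per_cluster",
    "silhouette_mean",
    "adjusted_rand",
]


def _translated(pred_ids: np.ndarray, matching) -> np.ndarray:
    """Map predicted IDs through the matching; unmatched become -1."""
    out = np.full(len(pred_ids), -1, dtype=np.int64)
    for test_id, truth_id in matching.mapping.items():
        out[pred_ids == test_id] = truth_id
    return out


def total_misclassification(
    pred_ids: np.ndarray, truth_ids: np.ndarray, matching
) -> float:
    """Fraction of events whose matched predicted label differs from truth.

    Events in unmatched predicted clusters count as misclassified.
    """
    pred_ids = np.asarray(pred_ids)
    truth_ids = np.asarray(truth_ids)
    if len(pred_ids) != len(truth_ids):
        raise ValueError("label vectors must be aligned")
    return float(np.mean(_translated(pred_ids, matching) != truth_ids))


def f1_per_cluster(
    pred_ids: np.ndarray, truth_ids: np.ndarray, matching
) -> tuple[dict[int, float], float]:
    """Per-truth-cluster F1 after matching, plus the macro average.

    For a truth cluster t matched to predicted cluster s: precision =
    |s ∩ t| / |s|, recall = |s ∩ t| / |t|.  Unmatched truth clusters get
    F1 = 0.
    """
    pred_ids = np.asarray(pred_ids)
    truth_ids = np.asarray(truth_ids)
    inverse = {t: s for s, t in matching.mapping.items()}
    scores: dict[int, float] = {}
    for t in np.unique(truth_ids):
        t = int(t)
        if t not in inverse:
            scores[t] = 0.0
            continue
        s = inverse[t]
        tp = int(np.sum((pred_ids == s) & (truth_ids == t)))
        n_pred = int(np.sum(pred_ids == s))
        n_truth = int(np.sum(truth_ids == t))
        if tp == 0:
            scores[t] = 0.0
            continue
        precision = tp / n_pred
        recall = tp / n_truth
        scores[t] = 2 * precision * recall / (precision + recall)
    macro = float(np.mean(list(scores.values())))
    return scores, macro


def silhouette_mean(
    points: np.ndarray,
    ids: np.ndarray,
    max_events: int = 10_000,
    seed: int = 0,
    chunk: int = 512,
) -> float:
    """Mean silhouette coefficient with Euclidean distance.

    s(i) = (b_i - a_i) / max(a_i, b_i), with a_i the mean distance to the
    event's own cluster and b_i the smallest mean distance to another
    cluster.  Singleton clusters contribute 0.  Above ``max_events``
    events a fixed-seed subsample is scored instead.
    """
    points = np.asarray(points, dtype=float)
    ids = np.asarray(ids)
    if len(np.unique(ids)) < 2:
        raise ValueError("silhouette requires at least 2 clusters")
    n = len(ids)
    if n > max_events:
        rng = np.random.default_rng(seed)
        keep = rng.choice(n, size=max_events, replace=False)
        points, ids = points[keep], ids[keep]
        n = max_events
        if len(np.unique(ids)) < 2:
            raise ValueError("subsample collapsed to a single cluster")
    uniq, inv = np.unique(ids, return_inverse=True)
    sizes = np.bincount(inv)
    onehot = np.zeros((n, len(uniq)))
    onehot[np.arange(n), inv] = 1.0
    s = np.zeros(n)
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        D = cdist(points[lo:hi], points)
        cluster_sums = D @ onehot  # (hi-lo) x K
        own = inv[lo:hi]
        own_size = sizes[own]
        a = np.where(
            own_size > 1,
            cluster_sums[np.arange(hi - lo), own] / np.maximum(own_size - 1, 1),
            0.0,
        )
        means = cluster_sums / sizes[None, :]
        means[np.arange(hi - lo), own] = np.inf
        b = means.min(axis=1)
        denom = np.maximum(a, b)
        sl = np.where(denom > 0, (b - a) / denom, 0.0)
        sl = np.where(own_size > 1, sl, 0.0)
        s[lo:hi] = sl
    return float(s.mean())


def adjusted_rand(a: np.ndarray, b: np.ndarray) -> float:
    """Chance-corrected agreement between two partitions."""
    return float(adjusted_rand_score(a, b))
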