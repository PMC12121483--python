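"""Automated label transfer and clustering benchmark pipeline.

Four steps: (1) fit a supervised 2D embedding on a labeled (or partially
labeled) training sample, weighting features and labels equally, (2)
project a test sample into that embedding, (3) cluster the test sample in
the 2D embedding with an algorithm that assigns every event (no noise
label) and align its cluster IDs to the ground-truth IDs by
maximum-overlap one-to-one assignment, (4) count misclassified events per
cluster and in total.

Step 1 doubles as a quality check on the ground-truth labels themselves:
a label whose events are spread across separated regions of the embedding
(label/topology disagreement) is flagged by an intra-label distance
statistic, see `label_topology_check`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist
from sklearn.cluster import MeanShift
from sklearn.metrics.cluster import contingency_matrix
from sklearn.neighbors import NearestNeighbors

from .metrics import _translated, f1_per_cluster, silhouette_mean, total_misclassification

__all__ = [
    "EmbeddingModel",
    "LabelMatching",
    "MisclassReport",
    "fit_label_aware_embedding",
    "cluster_embedding",
    "match_cluster_labels",
    "misclassification_report",
    "label_topology_check",
    "transfer_labels",
]

UNLABELED = -1  # sentinel for events without a training label


@dataclass
class EmbeddingModel:
    """A fitted label-aware 2D embedding.

    Wraps the fitted reducer together with the training data it saw;
    `transform` maps new events into the same 2D space deterministically
    for a fixed fitted model.
    """

    reducer: object
    train_embedding: np.ndarray
    train_labels: np.ndarray
    seed: int

    def transform(self, X: np.ndarray) -> np.ndarray:
        emb = self.reducer.transform(np.asarray(X, dtype=float))
        return np.asarray(emb, dtype=float)


@dataclass
class LabelMatching:
    """One-to-one alignment of test cluster IDs to ground-truth IDs."""

    mapping: dict[int, int]
    table: np.ndarray = field(repr=False)
    test_ids_order: np.ndarray = field(repr=False)
    truth_ids_order: np.ndarray = field(repr=False)
    unmatched_test: tuple[int, ...] = ()
    unmatched_truth: tuple[int, ...] = ()


@dataclass
class MisclassReport:
    """Misclassification accounting against ground truth.

    Per-truth-cluster entries are ordered by cluster abundance
    (most abundant first).
    """

    total_misclassified: int
    total_rate: float
    per_cluster: list[dict]  # cluster, size, misclassified, rate, f1
    macro_f1: float
    silhouette: float | None = None

    def to_dict(self) -> dict:
        return {
            "total_misclassified": self.total_misclassified,
            "total_rate": self.total_rate,
            "macro_f1": self.macro_f1,
            "silhouette": self.silhouette,
            "per_cluster": self.per_cluster,
        }


def _encode_labels(labels) -> np.ndarray:
    """Integer-encode labels; None/NaN become the UNLABELED sentinel."""
    arr = np.asarray(labels, dtype=object)
    out = np.empty(len(arr), dtype=np.int64)
    seen: dict[object, int] = {}
    for i, v in enumerate(arr):
        if v is None or (isinstance(v, float) and np.isnan(v)):
            out[i] = UNLABELED
            continue
        iv = int(v) if not isinstance(v, str) else None
        key = v if iv is None else iv
        if iv is not None and iv == UNLABELED:
            out[i] = UNLABELED
            continue
        if key not in seen:
            seen[key] = iv if iv is not None else len(seen)
        out[i] = seen[key]
    return out


def fit_label_aware_embedding(
    X: np.ndarray, labels, seed: int, **umap_kwargs
) -> EmbeddingModel:
    """Fit a supervised 2D UMAP embedding with equal feature/label weight.

    ``labels`` may be partially missing (None/NaN/-1); unlabeled events
    participate through the feature term only.  The seed is required
    because the embedding is stochastic.
    """
    import umap  # deferred: numba compilation is slow at import time

    X = np.asarray(X, dtype=float)
    y = _encode_labels(labels)
    labeled = y[y != UNLABELED]
    if len(np.unique(labeled)) < 2:
        raise ValueError("need at least 2 distinct training labels")
    kwargs = dict(
        n_components=2, target_weight=0.5, random_state=seed, target_metric="categorical"
    )
    kwargs.update(umap_kwargs)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        reducer = umap.UMAP(**kwargs)
        emb = reducer.fit_transform(X, y=y)
    return EmbeddingModel(
        reducer=reducer, train_embedding=np.asarray(emb), train_labels=y, seed=seed
    )


def _stable_bandwidth(emb2d: np.ndarray, seed: int, n_steps: int = 12) -> float:
    """Pick a mean-shift bandwidth by cluster-count stability.

    The right bandwidth is larger than the spread of one density mode but
    smaller than the gaps between modes — an unknown, data-dependent
    scale.  A geometric ladder of bandwidths (2%-40% of the bounding-box
    diagonal) is scanned; the cluster count holding over the longest
    consecutive stretch of the ladder wins (ties favour the coarser
    count), and the middle bandwidth of that stretch is returned.
    """
    diag = float(np.linalg.norm(emb2d.max(axis=0) - emb2d.min(axis=0)))
    if diag <= 0:
        return 0.0
    pts = emb2d
    if len(pts) > 2000:  # ladder scan on a subsample; the final fit sees all
        rng = np.random.default_rng(seed)
        pts = pts[rng.choice(len(pts), 2000, replace=False)]
    ladder = diag * np.geomspace(0.02, 0.4, n_steps)
    counts = [
        len(np.unique(MeanShift(bandwidth=bw, bin_seeding=True, cluster_all=True)
                      .fit_predict(pts)))
        for bw in ladder
    ]
    best = (0, 0, 0.0)  # (run length, -count, middle bandwidth)
    i = 0
    while i < n_steps:
        j = i
        while j + 1 < n_steps and counts[j + 1] == counts[i]:
            j += 1
        cand = (j - i + 1, -counts[i], float(ladder[(i + j) // 2]))
        if cand[:2] >= best[:2]:
            best = cand
        i = j + 1
    return best[2]


def cluster_embedding(
    emb2d: np.ndarray, seed: int = 0, clusterer=None
) -> np.ndarray:
    """Cluster 2D embedded coordinates; every event gets a cluster ID.

    The clusterer is pluggable (any callable coords -> integer IDs); the
    default is mean-shift mode seeking with full assignment, which never
    produces a noise label.  Its bandwidth is chosen by the stability
    scan of `_stable_bandwidth`.
    """
    emb2d = np.asarray(emb2d, dtype=float)
    if emb2d.ndim != 2 or emb2d.shape[1] != 2:
        raise ValueError("expected n x 2 embedded coordinates")
    if clusterer is not None:
        ids = np.asarray(clusterer(emb2d), dtype=np.int64)
    else:
        bw = _stable_bandwidth(emb2d, seed)
        if bw <= 0:
            return np.zeros(len(emb2d), dtype=np.int64)
        ms = MeanShift(bandwidth=bw, bin_seeding=True, cluster_all=True)
        ids = ms.fit_predict(emb2d).astype(np.int64)
    if np.any(ids < 0):
        raise ValueError("clusterer produced a noise label; full assignment required")
    return ids


def match_cluster_labels(test_ids: np.ndarray, truth_ids: np.ndarray) -> LabelMatching:
    """Align test cluster IDs to truth IDs by maximum total overlap.

    Builds the overlap contingency table over the shared events and solves
    a one-to-one assignment maximizing total overlap; zero-overlap pairs
    and surplus clusters on either side remain unmatched.
    """
    test_ids = np.asarray(test_ids)
    truth_ids = np.asarray(truth_ids)
    if len(test_ids) != len(truth_ids):
        raise ValueError("label vectors must cover the same events")
    table = contingency_matrix(test_ids, truth_ids)
    test_order = np.unique(test_ids)
    truth_order = np.unique(truth_ids)
    rows, cols = linear_sum_assignment(table, maximize=True)
    mapping = {
        int(test_order[r]): int(truth_order[c])
        for r, c in zip(rows, cols)
        if table[r, c] > 0
    }
    unmatched_test = tuple(int(t) for t in test_order if int(t) not in mapping)
    matched_truth = set(mapping.values())
    unmatched_truth = tuple(int(t) for t in truth_order if int(t) not in matched_truth)
    return LabelMatching(
        mapping=mapping,
        table=table,
        test_ids_order=test_order,
        truth_ids_order=truth_order,
        unmatched_test=unmatched_test,
        unmatched_truth=unmatched_truth,
    )


def misclassification_report(
    matching: LabelMatching,
    test_ids: np.ndarray,
    truth_ids: np.ndarray,
    points: np.ndarray | None = None,
) -> MisclassReport:
    """Count misclassified events per ground-truth cluster and in total.

    An event is misclassified iff its matched-and-translated test label
    differs from its truth label; events in unmatched test clusters count
    as misclassified.  Per-cluster rows are ordered by abundance.  When
    ``points`` is given and the test labeling has >= 2 clusters, the mean
    silhouette of the test labeling is included.
    """
    test_ids = np.asarray(test_ids)
    truth_ids = np.asarray(truth_ids)
    translated = _translated(test_ids, matching)
    wrong = translated != truth_ids
    f1s, macro = f1_per_cluster(test_ids, truth_ids, matching)
    per_cluster = []
    uniq, counts = np.unique(truth_ids, return_counts=True)
    for t in uniq[np.argsort(-counts, kind="stable")]:
        mask = truth_ids == t
        m = int(wrong[mask].sum())
        per_cluster.append(
            {
                "cluster": int(t),
                "size": int(mask.sum()),
                "misclassified": m,
                "rate": m / int(mask.sum()),
                "f1": f1s[int(t)],
            }
        )
    sil = None
    if points is not None and len(np.unique(test_ids)) >= 2:
        sil = silhouette_mean(points, test_ids)
    return MisclassReport(
        total_misclassified=int(wrong.sum()),
        total_rate=float(wrong.mean()),
        per_cluster=per_cluster,
        macro_f1=macro,
        silhouette=sil,
    )


def label_topology_check(
    emb2d: np.ndarray, labels: np.ndarray, threshold: float = 3.0, max_per_label: int = 500, seed: int = 0
) -> dict[int, dict]:
    """Flag labels whose events are spread across separated embedding regions.

    For each label the mean intra-label pairwise embedded distance is
    computed (on a fixed-seed subsample above ``max_per_label`` events)
    and divided by the median of that statistic across the *other* labels
    (leave-one-out, so a badly spread label cannot inflate its own
    reference).  A ratio above ``threshold`` flags disagreement between
    the label and the data topology — e.g. one nominal population
    actually spanning two separated blobs.
    """
    emb2d = np.asarray(emb2d, dtype=float)
    labels = np.asarray(_encode_labels(labels))
    rng = np.random.default_rng(seed)
    spreads: dict[int, float] = {}
    for lab in np.unique(labels):
        if lab == UNLABELED:
            continue
        pts = emb2d[labels == lab]
        if len(pts) < 2:
            spreads[int(lab)] = 0.0
            continue
        if len(pts) > max_per_label:
            pts = pts[rng.choice(len(pts), max_per_label, replace=False)]
        D = cdist(pts, pts)
        spreads[int(lab)] = float(D[np.triu_indices(len(pts), k=1)].mean())
    out = {}
    for lab, spread in spreads.items():
        others = [v for k, v in spreads.items() if k != lab]
        ref = float(np.median(others)) if others else spread
        ratio = spread / ref if ref > 0 else (np.inf if spread > 0 else 0.0)
        out[lab] = {"spread": spread, "ratio": ratio, "flagged": bool(ratio > threshold)}
    return out


def intra_inter_gap(emb2d: np.ndarray, labels: np.ndarray, seed: int = 0, max_n: int = 2000) -> float:
    """Mean inter-label minus mean intra-label embedded distance (>0 means
    same-label events sit closer together than different-label events)."""
    emb2d = np.asarray(emb2d, dtype=float)
    labels = np.asarray(labels)
    if len(emb2d) > max_n:
        rng = np.random.default_rng(seed)
        keep = rng.choice(len(emb2d), max_n, replace=False)
        emb2d, labels = emb2d[keep], labels[keep]
    D = cdist(emb2d, emb2d)
    same = labels[:, None] == labels[None, :]
    iu = np.triu_indices(len(labels), k=1)
    same_u = same[iu]
    return float(D[iu][~same_u].mean() - D[iu][same_u].mean())


def transfer_labels(
    train_X: np.ndarray,
    train_labels,
    test_X: np.ndarray,
    test_labels=None,
    seed: int = 0,
    clusterer=None,
) -> tuple[np.ndarray, LabelMatching, MisclassReport | None, EmbeddingModel]:
    """End-to-end pipeline: embed, project, cluster, align, score.

    When ``test_labels`` is given (benchmark mode) the matching and the
    misclassification report are computed against it.  Otherwise a
    provisional per-event truth is derived by 1-nearest-neighbour lookup
    against the training events in the embedding, the matching aligns the
    test clusters to the training label set, and no misclassification
    report is produced (there is no ground truth to score against).

    Returns (transferred labels, matching, report-or-None, model).
    """
    model = fit_label_aware_embedding(train_X, train_labels, seed=seed)
    test_emb = model.transform(test_X)
    test_ids = cluster_embedding(test_emb, seed=seed, clusterer=clusterer)
    if test_labels is not None:
        truth = _encode_labels(test_labels)
        report_truth = truth
    else:
        nn = NearestNeighbors(n_neighbors=1).fit(model.train_embedding)
        _, idx = nn.kneighbors(test_emb)
        report_truth = model.train_labels[idx[:, 0]]
    matching = match_cluster_labels(test_ids, report_truth)
    transferred = _translated(test_ids, matching)
    report = None
    if test_labels is not None:
        report = misclassification_report(matching, test_ids, report_truth, points=test_emb)
    return transferred, matching, report, model
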