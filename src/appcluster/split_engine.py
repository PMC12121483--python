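"""Recursive divisive clustering driven by boundary candidates.

At each recursion step every orthogonal 2D projection of the current subset
is scanned for minimum-density boundary candidates (in both orientations:
the boundary as a function of each axis).  Each surviving candidate — both
sides at least ``min_cluster_size`` events — is scored with the
Calinski–Harabasz index of the induced 2-way split in the unit-square
projection, and the globally best candidate is used to split.  A branch
with fewer than ``2 * min_cluster_size`` events, or with no surviving
candidate, becomes a final cluster.  Leaf IDs are assigned depth-first,
below-side first, so the labelling is reproducible run to run.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from joblib import Parallel, delayed

from .boundary_search import BoundaryPath, scan_gravity_levels
from .density_grid import (
    UnitSquareProjection,
    build_smoothed_histogram,
    mann_bin_count,
    normalize_projection,
)

__all__ = [
    "APPConfig",
    "SplitRecord",
    "ClusterTree",
    "calinski_harabasz_2d",
    "split_assignment",
    "candidates_for_projection",
    "app_cluster",
]


@dataclass(frozen=True)
class APPConfig:
    """Tuning parameters of the projection pursuit search.

    ``min_cluster_size`` is the only required input: the smallest
    population the user expects to detect.  Everything else has a default:
    smoothing width ``sigma`` (bin units), gravity strength ``beta``,
    gravity-scan step ``dq``, an optional fixed per-axis bin count
    ``bins_override`` replacing Mann's rule, the per-column row-move bound
    ``step_limit`` of the path search, a safety ``max_depth`` (off by
    default; the size rule already guarantees termination), and ``n_jobs``
    for evaluating projections concurrently (the reduction is
    deterministic regardless of worker count).
    """

    min_cluster_size: int
    sigma: float = 1.0
    beta: float = 0.1
    dq: float = 0.1
    bins_override: Optional[int] = None
    step_limit: int = 1
    max_depth: Optional[int] = None
    n_jobs: int = 1

    def __post_init__(self) -> None:
        if self.min_cluster_size < 1:
            raise ValueError("min_cluster_size must be >= 1")
        if not 0.0 < self.dq < 1.0:
            raise ValueError("dq must lie in (0, 1)")
        if self.beta < 0:
            raise ValueError("beta must be nonnegative")


@dataclass(frozen=True)
class SplitRecord:
    """One accepted split: where it was found and what it produced."""

    dim_x: int
    dim_y: int
    orientation: str  # 'x': boundary over the pair as given; 'y': axes swapped
    q0: float
    boundary: BoundaryPath
    ch_score: float
    below_idx: np.ndarray = field(repr=False)
    above_idx: np.ndarray = field(repr=False)

    @property
    def dim_pair(self) -> tuple[int, int]:
        return tuple(sorted((self.dim_x, self.dim_y)))


@dataclass
class _Node:
    record: Optional[SplitRecord] = None
    below: Optional["_Node"] = None
    above: Optional["_Node"] = None
    cluster_id: Optional[int] = None
    indices: Optional[np.ndarray] = None

    @property
    def is_leaf(self) -> bool:
        return self.record is None


@dataclass
class ClusterTree:
    """The recursive split record; leaves carry final cluster IDs."""

    root: _Node
    n_events: int

    @property
    def n_clusters(self) -> int:
        return sum(1 for _ in self.leaves())

    def leaves(self):
        stack = [self.root]
        out = []
        while stack:
            node = stack.pop()
            if node.is_leaf:
                out.append(node)
            else:
                stack.extend([node.above, node.below])
        return sorted(out, key=lambda nd: nd.cluster_id)

    def to_dict(self) -> dict:
        """JSON-serializable split-tree report."""

        def rec(node: _Node) -> dict:
            if node.is_leaf:
                return {
                    "leaf": True,
                    "cluster_id": node.cluster_id,
                    "size": int(len(node.indices)),
                }
            r = node.record
            return {
                "leaf": False,
                "dims": [int(r.dim_x), int(r.dim_y)],
                "orientation": r.orientation,
                "q0": float(r.q0),
                "ch_score": None if np.isinf(r.ch_score) else float(r.ch_score),
                "child_sizes": [int(len(r.below_idx)), int(len(r.above_idx))],
                "below": rec(node.below),
                "above": rec(node.above),
            }

        return {"n_events": self.n_events, "tree": rec(self.root)}


def calinski_harabasz_2d(points2d: np.ndarray, below: np.ndarray) -> float:
    """Calinski–Harabasz index of a binary split of 2D points.

    CH = [B / (K-1)] / [W / (n-K)] with K = 2, where B is the
    size-weighted squared distance of group centroids to the grand
    centroid and W the pooled within-group sum of squared distances.
    Returns +inf when W is zero (each group a point mass), which ranks
    such a split above every finite score.
    """
    n = points2d.shape[0]
    if n < 3:
        raise ValueError("need at least 3 points")
    g0 = points2d[below]
    g1 = points2d[~below]
    if len(g0) == 0 or len(g1) == 0:
        raise ValueError("both groups must be nonempty")
    grand = points2d.mean(axis=0)
    B = 0.0
    W = 0.0
    for g in (g0, g1):
        c = g.mean(axis=0)
        B += len(g) * float(((c - grand) ** 2).sum())
        W += float(((g - c) ** 2).sum())
    if W == 0.0:
        return float("inf")
    return (B / 1.0) / (W / (n - 2))


def split_assignment(proj: UnitSquareProjection, path: BoundaryPath) -> np.ndarray:
    """Boolean mask: True where an event falls below (or on) the boundary.

    The event's x-coordinate selects a column; it goes below iff its
    unit-square y does not exceed the path's bin-center ordinate there.
    """
    coords = proj.coords
    N = len(path.rows)
    cols = np.clip((coords[:, 0] * N).astype(np.int64), 0, N - 1)
    return coords[:, 1] <= path.boundary_y[cols]


def _candidates_one_orientation(
    X: np.ndarray,
    rows_idx: np.ndarray,
    dim_x: int,
    dim_y: int,
    orientation: str,
    config: APPConfig,
) -> list[SplitRecord]:
    proj = normalize_projection(X, dim_x, dim_y, rows_idx)
    if proj.degenerate:
        return []
    N = (
        config.bins_override
        if config.bins_override is not None
        else mann_bin_count(proj.n_points, config.sigma)
    )
    grid = build_smoothed_histogram(proj, N, config.sigma)
    found = scan_gravity_levels(grid, config.beta, config.dq, config.step_limit)
    records: list[SplitRecord] = []
    for q0, path in found:
        below = split_assignment(proj, path)
        n_below = int(below.sum())
        n_above = len(below) - n_below
        if min(n_below, n_above) < config.min_cluster_size:
            continue
        ch = calinski_harabasz_2d(proj.coords, below)
        records.append(
            SplitRecord(
                dim_x=dim_x,
                dim_y=dim_y,
                orientation=orientation,
                q0=q0,
                boundary=BoundaryPath(path.rows, q0, path.action, orientation),
                ch_score=ch,
                below_idx=rows_idx[below],
                above_idx=rows_idx[~below],
            )
        )
    return records


def _candidate_sort_key(rec: SplitRecord):
    # CH descending, then dim pair, orientation ('x' first), q0 ascending
    return (-rec.ch_score, rec.dim_pair, rec.orientation, rec.q0)


def candidates_for_projection(
    X: np.ndarray,
    rows_idx: np.ndarray,
    dim_a: int,
    dim_b: int,
    config: APPConfig,
) -> Optional[SplitRecord]:
    """Best surviving boundary for one dimension pair, both orientations.

    The pair is analysed twice — the boundary as a function of the first
    axis, then of the second (axes swapped) — and candidates whose smaller
    side is under ``min_cluster_size`` are discarded.  Returns None when
    nothing survives (including degenerate projections).
    """
    records = _candidates_one_orientation(X, rows_idx, dim_a, dim_b, "x", config)
    records += _candidates_one_orientation(X, rows_idx, dim_b, dim_a, "y", config)
    if not records:
        return None
    return min(records, key=_candidate_sort_key)


def app_cluster(
    X: np.ndarray, config: APPConfig
) -> tuple[ClusterTree, np.ndarray]:
    """Cluster an events-by-features matrix by projection pursuit.

    Returns the split tree and a per-event integer label vector with
    contiguous IDs starting at 0.  The procedure is deterministic: for
    fixed data and configuration the tree and labels are identical across
    runs and across worker counts.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("X must be 2D with at least 2 feature columns")
    if not np.all(np.isfinite(X)):
        raise ValueError("X contains non-finite values")
    n, d = X.shape
    pairs = [(a, b) for a in range(d) for b in range(a + 1, d)]
    parallel = Parallel(n_jobs=config.n_jobs) if config.n_jobs != 1 else None
    next_id = [0]

    def best_split(rows_idx: np.ndarray) -> Optional[SplitRecord]:
        if parallel is not None:
            cands = parallel(
                delayed(candidates_for_projection)(X, rows_idx, a, b, config)
                for a, b in pairs
            )
        else:
            cands = [
                candidates_for_projection(X, rows_idx, a, b, config)
                for a, b in pairs
            ]
        cands = [c for c in cands if c is not None]
        if not cands:
            return None
        return min(cands, key=_candidate_sort_key)

    def recurse(rows_idx: np.ndarray, depth: int) -> _Node:
        stop = len(rows_idx) < 2 * config.min_cluster_size or (
            config.max_depth is not None and depth >= config.max_depth
        )
        rec = None if stop else best_split(rows_idx)
        if rec is None:
            node = _Node(cluster_id=next_id[0], indices=rows_idx)
            next_id[0] += 1
            return node
        below = recurse(rec.below_idx, depth + 1)
        above = recurse(rec.above_idx, depth + 1)
        return _Node(record=rec, below=below, above=above)

    root = recurse(np.arange(n), 0)
    tree = ClusterTree(root=root, n_events=n)
    labels = np.empty(n, dtype=np.int64)
    for leaf in tree.leaves():
        labels[leaf.indices] = leaf.cluster_id
    return tree, labels
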