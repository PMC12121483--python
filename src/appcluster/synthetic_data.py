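"""Synthetic event-matrix generators for exercising the clustering stack.

Three regimes cover the situations the clustering algorithm is designed
for: well-separated Gaussian blobs (the easy sanity case), imbalanced
mixtures in which a rare population is separable from an abundant mass
along a single axis (the regime where 2D projection search pays off), and
uniform hypercube samples demonstrating the empty-space phenomenon that
motivates working in low-dimensional projections in the first place.

All generators are pure functions of their specification and seed:
component allocation is exact (largest-remainder), not multinomial, so
fixture sizes are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Component",
    "MixtureSpec",
    "make_blobs",
    "four_blob_spec",
    "make_rare_mixture",
    "labeled_mixture_spec",
    "hypercube_fraction",
]


@dataclass(frozen=True)
class Component:
    mean: tuple[float, ...]
    scales: tuple[float, ...]
    proportion: float


@dataclass(frozen=True)
class MixtureSpec:
    """A Gaussian mixture: components, total event count and seed."""

    components: tuple[Component, ...]
    n_total: int
    seed: int

    @property
    def d(self) -> int:
        return len(self.components[0].mean)

    def __post_init__(self) -> None:
        props = [c.proportion for c in self.components]
        if abs(sum(props) - 1.0) > 1e-9:
            raise ValueError("component proportions must sum to 1")
        for c in self.components:
            if any(s <= 0 for s in c.scales):
                raise ValueError("component scales must be positive")
            if c.proportion * self.n_total < 1:
                raise ValueError("every component must receive at least 1 event")
            if len(c.mean) != self.d or len(c.scales) != self.d:
                raise ValueError("all components must share the dimensionality")


def _allocate(n_total: int, proportions: list[float]) -> np.ndarray:
    """Exact largest-remainder allocation of n_total among proportions."""
    raw = np.asarray(proportions) * n_total
    counts = np.floor(raw).astype(int)
    remainder = n_total - counts.sum()
    order = np.argsort(-(raw - counts), kind="stable")
    counts[order[:remainder]] += 1
    return counts


def make_blobs(spec: MixtureSpec) -> tuple[np.ndarray, np.ndarray]:
    """Sample the mixture; returns (X, labels), reproducible from seed."""
    rng = np.random.default_rng(spec.seed)
    counts = _allocate(spec.n_total, [c.proportion for c in spec.components])
    parts, labels = [], []
    for lab, (comp, cnt) in enumerate(zip(spec.components, counts)):
        parts.append(
            rng.normal(np.asarray(comp.mean), np.asarray(comp.scales), (cnt, spec.d))
        )
        labels.append(np.full(cnt, lab, dtype=np.int64))
    return np.vstack(parts), np.concatenate(labels)


def four_blob_spec(n_total: int = 2000, separation: float = 10.0, seed: int = 0) -> MixtureSpec:
    """Four equal unit-variance 3D blobs, pairwise >= `separation` sigma apart."""
    s = separation
    means = [(0.0, 0.0, 0.0), (s, 0.0, 0.0), (0.0, s, 0.0), (0.0, 0.0, s)]
    comps = tuple(Component(m, (1.0, 1.0, 1.0), 0.25) for m in means)
    return MixtureSpec(components=comps, n_total=n_total, seed=seed)


def labeled_mixture_spec(
    n_components: int = 8,
    d: int = 5,
    n_total: int = 4000,
    separation: float = 8.0,
    seed: int = 0,
) -> MixtureSpec:
    """Equal-proportion unit-variance mixture with component means placed
    on a scaled simplex-like lattice so every pair is >= `separation` sigma
    apart along some axis subset."""
    rng = np.random.default_rng(seed)
    # spread means on a grid over the first dimensions; jitter the rest
    means = []
    for i in range(n_components):
        m = np.zeros(d)
        m[i % d] = separation * (1 + i // d)
        m[(i + 1) % d] = separation * 0.5 * (i // d)
        means.append(tuple(m + rng.normal(0, 0.01, d)))
    comps = tuple(
        Component(m, tuple([1.0] * d), 1.0 / n_components) for m in means
    )
    return MixtureSpec(components=comps, n_total=n_total, seed=seed)


def make_rare_mixture(
    abundant: int,
    rare: int,
    d: int,
    sep_dim: int,
    seed: int,
    separation: float = 10.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Abundant mass plus a rare population separable along one axis only.

    Both components are unit-variance Gaussians overlapping on every axis
    except ``sep_dim``, where the rare component sits ``separation`` sigma
    away — a clear one-dimensional density valley amid otherwise
    uninformative dimensions.  Labels: 0 = abundant, 1 = rare.
    """
    if rare < 1:
        raise ValueError("rare must be >= 1")
    if not 0 <= sep_dim < d:
        raise ValueError("sep_dim out of range")
    rng = np.random.default_rng(seed)
    Xa = rng.normal(0.0, 1.0, (abundant, d))
    mean_r = np.zeros(d)
    mean_r[sep_dim] = separation
    Xr = rng.normal(mean_r, 1.0, (rare, d))
    X = np.vstack([Xa, Xr])
    labels = np.concatenate(
        [np.zeros(abundant, dtype=np.int64), np.ones(rare, dtype=np.int64)]
    )
    # interleave deterministically so row order carries no label signal
    perm = rng.permutation(abundant + rare)
    return X[perm], labels[perm]


def hypercube_fraction(
    d: int, t: float, n: int, seed: int
) -> tuple[float, float]:
    """Monte-Carlo and closed-form fraction of uniform [-1,1]^d samples
    with every coordinate within [-t, t].

    Demonstrates the empty-space phenomenon: for d = 10 and t = 0.63 the
    inner cube holds only about 1% of the data.  Returns
    (mc_estimate, t**d).
    """
    if not 0.0 < t < 1.0:
        raise ValueError("t must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    inside = 0
    remaining = n
    chunk = 200_000
    while remaining > 0:
        m = min(chunk, remaining)
        X = rng.uniform(-1.0, 1.0, (m, d))
        inside += int(np.all(np.abs(X) <= t, axis=1).sum())
        remaining -= m
    return inside / n, t**d
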