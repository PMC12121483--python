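"""Minimum-density decision boundaries on a 2D density grid.

A candidate decision boundary is a path y = f_q(x) across the grid that
minimizes the integrated density along itself.  Searching all start/end
ordinates directly is expensive, so a parabolic "gravity" potential

    H_g(y, q) = (y - y0)^2,   y0 = q * y_max + (1 - q) * y_min

is added to the density (H1 = H + k * H_g) to anchor the path at level y0
and partially straighten it.  The coupling k = beta * (max H - min H) /
max(H_g) balances data against gravity; beta defaults to 0.1 (10% gravity).
For each q on a lattice the extremal path is found by dynamic programming
over grid columns, and its action S(q) — the integral of the *raw* density
along the path — is recorded.  Strict interior local minima of S(q) mark
true density valleys and are returned as boundary candidates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import minimum_filter1d

from .density_grid import DensityGrid

__all__ = [
    "GravityField",
    "BoundaryPath",
    "gravity_potential",
    "coupling_constant",
    "combined_density",
    "find_extremal_path",
    "path_action",
    "scan_gravity_levels",
]


@dataclass(frozen=True)
class GravityField:
    """Parabolic anchor potential at gravity level q (unit coordinates)."""

    q: float
    y0: float
    beta: float
    k: float
    Hg: np.ndarray = field(repr=False)  # N x N, [x_bin, y_bin]


@dataclass(frozen=True)
class BoundaryPath:
    """An extremal path across the grid, one y-bin per x-column.

    ``boundary_y`` holds the path's bin-center ordinates in unit
    coordinates and is what point assignment uses.  ``orientation`` records
    whether the path was found as a function of the projection's x axis
    ('x') or on the axis-swapped projection ('y').
    """

    rows: np.ndarray  # length N, y-bin index per x-column
    q: float
    action: float
    orientation: str = "x"

    @property
    def boundary_y(self) -> np.ndarray:
        N = len(self.rows)
        return (self.rows + 0.5) / N


def gravity_potential(grid: DensityGrid, q: float, beta: float = 0.1) -> GravityField:
    """Build H_g for gravity level q; y0 = q in unit coordinates."""
    if not 0.0 <= q <= 1.0:
        raise ValueError("q must lie in [0, 1]")
    y0 = float(q)  # q * y_max + (1 - q) * y_min with y_min=0, y_max=1
    centers = grid.bin_centers
    hg_row = (centers - y0) ** 2
    Hg = np.broadcast_to(hg_row, (grid.N, grid.N)).copy()
    k = coupling_constant(grid.H, Hg, beta)
    return GravityField(q=q, y0=y0, beta=beta, k=k, Hg=Hg)


def coupling_constant(H: np.ndarray, Hg: np.ndarray, beta: float) -> float:
    """k = beta * (max(H) - min(H)) / max(Hg); zero for flat H or flat Hg."""
    if beta < 0:
        raise ValueError("beta must be nonnegative")
    span = float(H.max() - H.min())
    hg_max = float(Hg.max())
    if span == 0.0 or hg_max == 0.0:
        return 0.0
    return beta * span / hg_max


def combined_density(grid: DensityGrid, fld: GravityField) -> np.ndarray:
    """H1 = H + k * H_g (elementwise; H1 >= H since k, Hg >= 0)."""
    return grid.H + fld.k * fld.Hg


def find_extremal_path(
    H1: np.ndarray, start_row: int, step_limit: int = 1, y0: float | None = None
) -> np.ndarray:
    """Minimum-cost path across columns of H1, anchored at start_row.

    Dynamic programming over x-columns; the row index may change by at most
    ``step_limit`` between consecutive columns.  Only the start is anchored
    (the end row is free).  Cost ties are broken toward the row whose bin
    center is nearest y0, then toward the lower row index, which keeps the
    search fully deterministic.
    """
    N = H1.shape[0]
    if not 0 <= start_row < N:
        raise ValueError("start_row out of range")
    if y0 is None:
        y0 = (start_row + 0.5) / N
    size = 2 * step_limit + 1

    # cost[c, r]: cheapest total H1 from column c to the last, entering row r
    cost = np.empty_like(H1)
    cost[-1] = H1[-1]
    for c in range(N - 2, -1, -1):
        # 'nearest' padding replicates edge values, matching the clipped window
        cost[c] = H1[c] + minimum_filter1d(cost[c + 1], size=size, mode="nearest")

    centers = (np.arange(N) + 0.5) / N
    rows = np.empty(N, dtype=np.int64)
    rows[0] = start_row
    for c in range(1, N):
        lo = max(0, rows[c - 1] - step_limit)
        hi = min(N - 1, rows[c - 1] + step_limit)
        window = np.arange(lo, hi + 1)
        c_cost = cost[c, lo : hi + 1]
        best = c_cost.min()
        tied = window[c_cost <= best]
        rows[c] = tied[np.argmin(np.abs(centers[tied] - y0))] if len(tied) > 1 else tied[0]
    return rows


def path_action(grid: DensityGrid, rows: np.ndarray) -> float:
    """Action S = (1/N) * sum_c H[c, rows[c]] over the *raw* smoothed H.

    The gravity term is deliberately excluded: S scores the density valley
    itself, and must not be contaminated by the anchoring potential.
    """
    N = grid.N
    if len(rows) != N:
        raise ValueError("path length must equal the grid size")
    return float(grid.H[np.arange(N), rows].sum() / N)


def _q_lattice(dq: float) -> np.ndarray:
    n_steps = int(round(1.0 / dq))
    return np.linspace(0.0, 1.0, n_steps + 1)


def gravity_scan_profile(
    grid: DensityGrid, beta: float = 0.1, dq: float = 0.1, step_limit: int = 1
) -> tuple[np.ndarray, np.ndarray, list[np.ndarray]]:
    """S(q) and the extremal path for every q on the lattice."""
    if not 0.0 < dq < 1.0:
        raise ValueError("dq must lie in (0, 1)")
    qs = _q_lattice(dq)
    actions = np.empty(len(qs))
    paths: list[np.ndarray] = []
    for i, q in enumerate(qs):
        fld = gravity_potential(grid, q, beta)
        H1 = combined_density(grid, fld)
        start = min(int(q * grid.N), grid.N - 1)  # bin containing y0
        rows = find_extremal_path(H1, start, step_limit, y0=fld.y0)
        paths.append(rows)
        actions[i] = path_action(grid, rows)
    return qs, actions, paths


def scan_gravity_levels(
    grid: DensityGrid, beta: float = 0.1, dq: float = 0.1, step_limit: int = 1
) -> list[tuple[float, BoundaryPath]]:
    """Boundary candidates: q values that are strict local minima of S(q).

    Both neighbours on the q lattice must be strictly greater
    (S(q0 - dq) > S(q0) < S(q0 + dq)), so lattice endpoints are never
    candidates.  Returns an empty list when S is monotone.
    """
    qs, actions, paths = gravity_scan_profile(grid, beta, dq, step_limit)
    out: list[tuple[float, BoundaryPath]] = []
    for i in range(1, len(qs) - 1):
        if actions[i - 1] > actions[i] < actions[i + 1]:
            q0 = float(qs[i])
            out.append(
                (q0, BoundaryPath(rows=paths[i], q=q0, action=float(actions[i])))
            )
    return out
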