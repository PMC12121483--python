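"""Unit-square projections and Gaussian-smoothed 2D density histograms.

Every recursion step of projection pursuit clustering looks at the current
data subset through one pair of feature axes.  The subset is affinely mapped
onto the unit square (each axis rescaled by its own subset-local min/max),
binned on an N x N grid, and smoothed with an isotropic Gaussian kernel.
The per-axis bin count N follows Mann's rule for the optimal total number of
histogram bins, scaled by the smoothing width so that smoothing buys back
resolution lost to noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "UnitSquareProjection",
    "DensityGrid",
    "normalize_projection",
    "mann_bin_count",
    "build_smoothed_histogram",
]


@dataclass(frozen=True)
class UnitSquareProjection:
    """A 2D view of a data subset mapped onto the unit square.

    The mapping is affine per axis using the *current subset's* min/max, so
    it is recomputed at every recursion step.  ``degenerate`` is set (and
    ``coords`` is None) when an axis has zero range and no meaningful
    projection exists.
    """

    dim_x: int
    dim_y: int
    x_min: float
    x_max: float
    y_min: float
    y_max: float
    coords: np.ndarray | None  # n x 2 in [0, 1]^2, or None when degenerate
    degenerate: bool = False

    @property
    def n_points(self) -> int:
        return 0 if self.coords is None else self.coords.shape[0]


@dataclass(frozen=True)
class DensityGrid:
    """Gaussian-smoothed N x N histogram of a unit-square projection.

    ``H`` is indexed ``[x_bin, y_bin]``.  Smoothing is mass preserving:
    ``H.sum()`` equals the number of binned events to float precision.
    """

    H: np.ndarray
    N: int
    sigma: float
    n_points: int
    bin_edges: np.ndarray = field(repr=False)  # length N+1 over [0, 1]

    @property
    def bin_centers(self) -> np.ndarray:
        return (self.bin_edges[:-1] + self.bin_edges[1:]) / 2.0


def normalize_projection(
    X: np.ndarray, dim_x: int, dim_y: int, rows: np.ndarray | None = None
) -> UnitSquareProjection:
    """Map the (sub)set of events onto the unit square along two axes.

    Parameters
    ----------
    X : ndarray of shape (n, d)
        The full event matrix.
    dim_x, dim_y : int
        Column indices of the projection axes; must differ.
    rows : ndarray of int, optional
        Row indices selecting the current subset (default: all rows).

    Returns
    -------
    UnitSquareProjection
        With ``degenerate=True`` when either axis has zero range.

    Raises
    ------
    ValueError
        If the subset is empty, the axes coincide, or a selected column
        contains non-finite values.
    """
    if dim_x == dim_y:
        raise ValueError("dim_x and dim_y must differ")
    sub = X if rows is None else X[rows]
    if sub.shape[0] < 1:
        raise ValueError("projection requires at least one event")
    x = np.asarray(sub[:, dim_x], dtype=float)
    y = np.asarray(sub[:, dim_y], dtype=float)
    for name, col in ((dim_x, x), (dim_y, y)):
        if not np.all(np.isfinite(col)):
            raise ValueError(f"non-finite values in column {name}")
    x_min, x_max = float(x.min()), float(x.max())
    y_min, y_max = float(y.min()), float(y.max())
    if x_max <= x_min or y_max <= y_min:
        return UnitSquareProjection(
            dim_x, dim_y, x_min, x_max, y_min, y_max, None, degenerate=True
        )
    coords = np.column_stack(
        ((x - x_min) / (x_max - x_min), (y - y_min) / (y_max - y_min))
    )
    return UnitSquareProjection(dim_x, dim_y, x_min, x_max, y_min, y_max, coords)


def mann_bin_count(n_points: int, sigma: float) -> int:
    """Per-axis bin count: ``round(4 * sigma * [3(n-1)^2 / 4]^0.1)``.

    The square root of Mann's optimal total 2D bin count, scaled by the
    Gaussian smoothing width.  Rounding is half away from zero and the
    result is clamped to a floor of 4 (a smaller grid cannot host a
    boundary path).
    """
    if n_points < 2:
        raise ValueError("mann_bin_count requires at least 2 points")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    raw = 4.0 * sigma * (3.0 * (n_points - 1) ** 2 / 4.0) ** 0.1
    return max(4, int(math.floor(raw + 0.5)))


def _smoothing_matrix(N: int, sigma: float) -> np.ndarray:
    """1D mass-preserving Gaussian smoothing operator on N bins.

    Column j holds the truncated Gaussian kernel centered at bin j,
    renormalized to sum to 1, so each source bin's mass is fully
    redistributed inside the grid.
    """
    idx = np.arange(N)
    K = np.exp(-((idx[:, None] - idx[None, :]) ** 2) / (2.0 * sigma**2))
    return K / K.sum(axis=0, keepdims=True)


def build_smoothed_histogram(
    proj: UnitSquareProjection, N: int, sigma: float
) -> DensityGrid:
    """Bin a unit-square projection and smooth it with a Gaussian kernel.

    Bins are half-open ``[e_i, e_{i+1})`` with the final bin closed (the
    numpy 2D-histogram convention on an explicit [0, 1] range).  Smoothing
    applies the renormalized truncated kernel separably along both axes;
    total mass equals the number of events.
    """
    if proj.degenerate or proj.coords is None:
        raise ValueError("cannot build a histogram from a degenerate projection")
    if N < 2:
        raise ValueError("N must be at least 2")
    edges = np.linspace(0.0, 1.0, N + 1)
    H, _, _ = np.histogram2d(
        proj.coords[:, 0], proj.coords[:, 1], bins=[edges, edges]
    )
    K = _smoothing_matrix(N, sigma)
    H = K @ H @ K.T
    return DensityGrid(H=H, N=N, sigma=sigma, n_points=proj.n_points, bin_edges=edges)


def dump_grid_tsv(grid: DensityGrid, path) -> None:
    # debug helper: H as a plain TSV matrix, x bins as rows
    np.savetxt(path, grid.H, delimiter="\t", fmt="%.6g")
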