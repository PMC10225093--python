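"""Per-subject region-level connectivity networks.

Two modalities are supported:

* **morphological** — similarity of regional cortical-thickness
  distributions, computed as ``1 - JSD`` where JSD is the Jensen-Shannon
  divergence (base-2 logarithm, hence bounded in [0, 1]) between
  Gaussian-kernel density estimates of the two regions' thickness
  samples, evaluated on a grid shared by the pair;
* **functional** — Pearson correlation between regional mean fMRI time
  series, with the Fisher z transform available as the working scale for
  averaging and harmonization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "RegionDensity",
    "RegionNetwork",
    "estimate_density",
    "pair_grid",
    "jsd",
    "jsd_similarity",
    "morph_network",
    "func_network",
    "fisher_z",
    "fisher_z_inv",
]

_SQRT2PI = np.sqrt(2.0 * np.pi)

#: Floor on the kernel bandwidth, used when a sample is (near-)constant.
MIN_BANDWIDTH = 1e-3


@dataclass
class RegionDensity:
    """A kernel density estimate on an explicit evaluation grid."""

    grid: np.ndarray
    density: np.ndarray

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if self.grid.shape != self.density.shape:
            raise ValueError("grid and density must have the same shape")

    @property
    def mass(self) -> float:
        return float(np.trapezoid(self.density, self.grid))


@dataclass
class RegionNetwork:
    """A region-level connectivity matrix with its row/column identifiers.

    ``block`` is ``"cerebellar"`` (24x24, symmetric) or
    ``"cerebello-cerebral"`` (24x400, rectangular).
    """

    matrix: np.ndarray
    row_ids: list[str]
    col_ids: list[str]
    modality: str
    block: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (len(self.row_ids), len(self.col_ids)):
            raise ValueError("matrix shape does not match region id lists")


def scott_bandwidth(values: np.ndarray) -> float:
    """Scott's rule bandwidth ``sd * n**(-1/5)`` with a fixed floor."""
    values = np.asarray(values, dtype=float)
    sd = float(np.std(values, ddof=1)) if values.size > 1 else 0.0
    h = sd * values.size ** (-0.2)
    if h < MIN_BANDWIDTH:
        warnings.warn(
            "degenerate sample spread; falling back to minimum bandwidth",
            stacklevel=2,
        )
        h = MIN_BANDWIDTH
    return h


def pair_grid(
    values_a: np.ndarray,
    values_b: np.ndarray,
    n_points: int = 256,
    pad_bandwidths: float = 3.0,
) -> np.ndarray:
    """Shared evaluation grid spanning the pooled range of a region pair.

    The pooled min/max is padded by ``pad_bandwidths`` times the larger of
    the two Scott bandwidths so that the kernel tails are captured.
    """
    values_a = np.asarray(values_a, float)
    values_b = np.asarray(values_b, float)
    h = max(scott_bandwidth(values_a), scott_bandwidth(values_b))
    lo = min(values_a.min(), values_b.min()) - pad_bandwidths * h
    hi = max(values_a.max(), values_b.max()) + pad_bandwidths * h
    return np.linspace(lo, hi, n_points)


def estimate_density(values: Sequence[float], grid: np.ndarray) -> RegionDensity:
    """Gaussian-kernel density of a thickness sample on a shared grid.

    The estimate is renormalized so its trapezoid integral over the grid
    is exactly 1, which makes downstream divergences insensitive to grid
    truncation.

    Raises
    ------
    ValueError
        If fewer than 10 finite positive values are supplied, or the grid
        does not cover the sample support.
    """
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size < 10:
        raise ValueError("need at least 10 finite values for density estimation")
    if np.any(values <= 0):
        raise ValueError("thickness values must be positive")
    grid = np.asarray(grid, dtype=float)
    if values.min() < grid[0] or values.max() > grid[-1]:
        raise ValueError("evaluation grid does not cover the sample support")
    h = scott_bandwidth(values)
    z = (grid[:, None] - values[None, :]) / h
    dens = np.exp(-0.5 * z * z).sum(axis=1) / (values.size * h * _SQRT2PI)
    mass = np.trapezoid(dens, grid)
    if mass <= 0:
        raise ValueError("density mass vanished on the supplied grid")
    return RegionDensity(grid=grid, density=dens / mass)


def _trapezoid_weights(grid: np.ndarray) -> np.ndarray:
    w = np.empty_like(grid)
    w[1:-1] = (grid[2:] - grid[:-2]) / 2.0
    w[0] = (grid[1] - grid[0]) / 2.0
    w[-1] = (grid[-1] - grid[-2]) / 2.0
    return w


def _discrete_probs(p: RegionDensity) -> np.ndarray:
    q = p.density * _trapezoid_weights(p.grid)
    total = q.sum()
    if total <= 0:
        raise ValueError("degenerate density: zero total mass")
    return q / total


def jsd(p: RegionDensity | np.ndarray, q: RegionDensity | np.ndarray) -> float:
    """Jensen-Shannon divergence, base-2 logarithm, bounded in [0, 1].

    Densities are reduced to discrete probabilities via trapezoid
    quadrature on their (shared) grid; plain probability vectors are also
    accepted.  ``0 log 0`` terms contribute zero.
    """
    if isinstance(p, RegionDensity) or isinstance(q, RegionDensity):
        if not (isinstance(p, RegionDensity) and isinstance(q, RegionDensity)):
            raise TypeError("mixing RegionDensity and raw vectors is ambiguous")
        if p.grid.shape != q.grid.shape or not np.allclose(p.grid, q.grid):
            raise ValueError("densities must share a common evaluation grid")
        pv, qv = _discrete_probs(p), _discrete_probs(q)
    else:
        pv = np.asarray(p, dtype=float)
        qv = np.asarray(q, dtype=float)
        pv = pv / pv.sum()
        qv = qv / qv.sum()
    m = 0.5 * (pv + qv)
    # rel_entr handles 0 log 0 -> 0 and returns nats; convert to bits.
    from scipy.special import rel_entr

    val = 0.5 * (rel_entr(pv, m).sum() + rel_entr(qv, m).sum()) / np.log(2.0)
    return float(min(max(val, 0.0), 1.0))


def jsd_similarity(
    p: RegionDensity | np.ndarray,
    q: RegionDensity | np.ndarray,
    sqrt_metric: bool = False,
) -> float:
    """Similarity ``1 - JSD`` (default) or ``1 - sqrt(JSD)`` (metric variant)."""
    d = jsd(p, q)
    if sqrt_metric:
        d = np.sqrt(d)
    return float(1.0 - d)


def _batched_jsd_similarity(
    values_rows: list[np.ndarray],
    values_cols: list[np.ndarray],
    pairs: np.ndarray,
    grid_points: int,
    sqrt_metric: bool,
) -> np.ndarray:
    """JSD similarity for many (row, col) sample pairs, vectorized per pair."""
    out = np.empty(len(pairs))
    for k, (i, j) in enumerate(pairs):
        va, vb = values_rows[i], values_cols[j]
        grid = pair_grid(va, vb, grid_points)
        pa = estimate_density(va, grid)
        pb = estimate_density(vb, grid)
        out[k] = jsd_similarity(pa, pb, sqrt_metric=sqrt_metric)
    return out


def morph_network(
    thickness: Mapping[str, np.ndarray],
    row_ids: Sequence[str],
    col_ids: Sequence[str] | None = None,
    *,
    grid_points: int = 256,
    sqrt_metric: bool = False,
) -> RegionNetwork:
    """Morphological (thickness-distribution similarity) network.

    With ``col_ids=None`` the symmetric within-block network over
    ``row_ids`` is built (unit diagonal); otherwise the rectangular
    between-block network.

    Parameters
    ----------
    thickness:
        Mapping from region id to its vector of vertex-wise thickness
        values.
    """
    row_ids = list(row_ids)
    missing = [r for r in row_ids if r not in thickness]
    symmetric = col_ids is None
    col_ids = row_ids if symmetric else list(col_ids)
    missing += [c for c in col_ids if c not in thickness and c not in missing]
    if missing:
        raise KeyError(f"thickness missing for regions: {missing[:5]}")

    rows = [np.asarray(thickness[r], float) for r in row_ids]
    cols = rows if symmetric else [np.asarray(thickness[c], float) for c in col_ids]
    n, m = len(rows), len(cols)
    mat = np.empty((n, m))
    if symmetric:
        iu = np.transpose(np.triu_indices(n, k=1))
        vals = _batched_jsd_similarity(rows, cols, iu, grid_points, sqrt_metric)
        mat[:] = 0.0
        mat[iu[:, 0], iu[:, 1]] = vals
        mat += mat.T
        np.fill_diagonal(mat, 1.0)
        block = "cerebellar"
    else:
        pairs = np.array([(i, j) for i in range(n) for j in range(m)])
        mat = _batched_jsd_similarity(rows, cols, pairs, grid_points, sqrt_metric).reshape(n, m)
        block = "cerebello-cerebral"
    return RegionNetwork(mat, row_ids, col_ids, "morphological", block)


def func_network(
    timeseries: np.ndarray,
    region_ids: Sequence[str],
    row_ids: Sequence[str] | None = None,
    col_ids: Sequence[str] | None = None,
) -> RegionNetwork:
    """Functional (Pearson-correlation) network from a T x R series matrix.

    ``row_ids``/``col_ids`` select the block (defaults: full symmetric
    matrix over all regions).  Edges touching a zero-variance series are
    returned as NaN with a warning; callers treat them as missing.
    """
    ts = np.asarray(timeseries, dtype=float)
    if ts.ndim != 2 or ts.shape[0] < 2:
        raise ValueError("need a T x R matrix with at least 2 timepoints")
    if not np.all(np.isfinite(ts)):
        raise ValueError("time series contain non-finite values")
    region_ids = list(region_ids)
    if ts.shape[1] != len(region_ids):
        raise ValueError("column count does not match region ids")

    sd = ts.std(axis=0)
    degenerate = sd == 0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} zero-variance series; their edges are NaN",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (ts - ts.mean(axis=0)) / sd
        full = (z.T @ z) / ts.shape[0]
    full[degenerate, :] = np.nan
    full[:, degenerate] = np.nan
    full = np.clip(full, -1.0, 1.0, out=full)

    index = {r: k for k, r in enumerate(region_ids)}
    rows = region_ids if row_ids is None else list(row_ids)
    symmetric = col_ids is None and row_ids is None
    cols = rows if col_ids is None else list(col_ids)
    ri = [index[r] for r in rows]
    ci = [index[c] for c in cols]
    mat = full[np.ix_(ri, ci)]
    block = "cerebellar" if symmetric or set(cols) == set(rows) else "cerebello-cerebral"
    return RegionNetwork(mat, rows, cols, "functional", block)


def fisher_z(r: np.ndarray) -> np.ndarray:
    """Fisher z transform ``atanh(r)``, clipped away from the poles."""
    r = np.clip(np.asarray(r, dtype=float), -1 + 1e-12, 1 - 1e-12)
    return np.arctanh(r)


def fisher_z_inv(z: np.ndarray) -> np.ndarray:
    return np.tanh(np.asarray(z, dtype=float))
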