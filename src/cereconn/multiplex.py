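"""Multiplex community detection with stability selection.

The cerebellar module architecture is identified on a two-layer multiplex
network — group-mean morphological and functional within-cerebellar
connectivity — by maximizing the multilayer modularity

    Q = (1/2mu) * sum_{ijs} [A_ijs - gamma * k_is k_js / (2 m_s)] delta(g_is, g_js)
        + (1/2mu) * sum_{i, s != r} omega * delta(g_is, g_ir)

(categorical node-to-node inter-layer coupling of strength ``omega``,
per-layer configuration null with resolution ``gamma``, ``2mu`` = total
supra-weight) with a greedy Louvain-type optimizer on the supra-modularity
matrix.  Stability over the (omega, gamma) plane is assessed with the
variation of information between neighbouring partitions; the final
architecture is a representative of the largest low-VI plateau.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .connectivity import fisher_z, fisher_z_inv

__all__ = [
    "Multiplex",
    "MultilayerPartition",
    "StabilityMap",
    "build_group_multiplex",
    "multilayer_quality",
    "supra_modularity_matrix",
    "louvain_optimize",
    "variation_of_information",
    "sweep_parameters",
    "select_stable_partition",
]


@dataclass
class Multiplex:
    """L layers of symmetric non-negative weight matrices on shared nodes."""

    layers: dict[str, np.ndarray]
    nodes: list[str]

    def __post_init__(self):
        n = len(self.nodes)
        clean = {}
        for name, a in self.layers.items():
            a = np.asarray(a, dtype=float)
            if a.shape != (n, n):
                raise ValueError(f"layer {name!r} has shape {a.shape}, expected ({n},{n})")
            if not np.allclose(a, a.T, atol=1e-10):
                raise ValueError(f"layer {name!r} is not symmetric")
            a = a.copy()
            np.fill_diagonal(a, 0.0)  # self-weight plays no role in modularity
            clean[name] = a
        self.layers = clean

    @property
    def layer_names(self) -> list[str]:
        return list(self.layers)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    def stacked(self) -> np.ndarray:
        return np.stack([self.layers[k] for k in self.layers])


@dataclass
class MultilayerPartition:
    """Node x layer module labels with the quality and parameters used."""

    labels: np.ndarray  # (n_nodes, n_layers) contiguous ints
    quality: float
    omega: float
    gamma: float
    nodes: list[str] = field(default_factory=list)
    layer_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        # relabel to contiguous integers in order of first appearance
        _, inv = np.unique(self.labels.ravel(), return_inverse=True)
        order = {}
        out = np.empty(self.labels.size, dtype=int)
        for k, v in enumerate(self.labels.ravel()):
            if v not in order:
                order[v] = len(order)
            out[k] = order[v]
        self.labels = out.reshape(self.labels.shape)

    @property
    def n_modules(self) -> int:
        return int(self.labels.max()) + 1

    def layer_labels(self, layer: str) -> dict[str, int]:
        j = self.layer_names.index(layer)
        return {node: int(self.labels[i, j]) for i, node in enumerate(self.nodes)}


@dataclass
class StabilityMap:
    """Partitions and neighbour-mean VI over an (omega, gamma) grid."""

    omega_grid: np.ndarray
    gamma_grid: np.ndarray
    partitions: list[list[MultilayerPartition]]  # [i_omega][j_gamma]
    vi: np.ndarray  # (n_omega, n_gamma) mean VI to grid neighbours


def build_group_multiplex(
    morph_mats: list[np.ndarray],
    func_mats: list[np.ndarray],
    nodes: list[str],
    clip_negative: bool = True,
) -> Multiplex:
    """Group-mean two-layer multiplex from per-subject cerebellar networks.

    The morphological layer is the element-wise mean of the subjects'
    similarity matrices; the functional layer is averaged on the Fisher-z
    scale and back-transformed.  Negative functional weights are zeroed
    before the (unsigned) modularity computation.
    """
    if len(morph_mats) == 0 or len(func_mats) == 0:
        raise ValueError("need at least one subject per layer")
    morph = np.mean([np.asarray(m, float) for m in morph_mats], axis=0)
    fz = np.mean([fisher_z(np.asarray(m, float)) for m in func_mats], axis=0)
    func = fisher_z_inv(fz)
    np.fill_diagonal(func, 0.0)
    if clip_negative:
        if np.all(func <= 0) and np.any(func < 0):
            warnings.warn("functional layer entirely non-positive; layer is all zeros")
        func = np.clip(func, 0.0, None)
    np.fill_diagonal(morph, 0.0)
    morph = (morph + morph.T) / 2
    func = (func + func.T) / 2
    return Multiplex({"morphological": morph, "functional": func}, list(nodes))


def _layer_terms(mx: Multiplex):
    out = []
    for name in mx.layers:
        a = mx.layers[name]
        k = a.sum(axis=1)
        two_m = k.sum()
        if two_m == 0:
            warnings.warn(f"layer {name!r} has no weight; it contributes 0 to Q")
        out.append((a, k, two_m))
    return out


def total_supra_weight(mx: Multiplex, omega: float) -> float:
    two_m = sum(t[2] for t in _layer_terms(mx))
    return two_m + omega * mx.n_nodes * mx.n_layers * (mx.n_layers - 1)


def multilayer_quality(
    mx: Multiplex, labels: np.ndarray, omega: float, gamma: float
) -> float:
    """Multilayer modularity of a node x layer labelling.

    At ``omega = 0`` this reduces to the strength-weighted mean of the
    per-layer Newman-Girvan modularities.
    """
    labels = np.asarray(labels, dtype=int)
    if labels.shape != (mx.n_nodes, mx.n_layers):
        raise ValueError("labels must be (n_nodes, n_layers)")
    q = 0.0
    for s, (a, k, two_m) in enumerate(_layer_terms(mx)):
        g = labels[:, s]
        same = g[:, None] == g[None, :]
        if two_m > 0:
            b = a - gamma * np.outer(k, k) / two_m
            q += b[same].sum()
    for s in range(mx.n_layers):
        for r in range(mx.n_layers):
            if s == r:
                continue
            q += omega * np.count_nonzero(labels[:, s] == labels[:, r])
    denom = total_supra_weight(mx, omega)
    if denom == 0:
        return 0.0
    return float(q / denom)


def supra_modularity_matrix(mx: Multiplex, omega: float, gamma: float) -> np.ndarray:
    """(N·L) x (N·L) modularity matrix; node (i, s) maps to index s*N + i."""
    n, L = mx.n_nodes, mx.n_layers
    b = np.zeros((n * L, n * L))
    for s, (a, k, two_m) in enumerate(_layer_terms(mx)):
        blk = a if two_m == 0 else a - gamma * np.outer(k, k) / two_m
        b[s * n:(s + 1) * n, s * n:(s + 1) * n] = blk
    eye = omega * np.eye(n)
    for s in range(L):
        for r in range(L):
            if s != r:
                b[s * n:(s + 1) * n, r * n:(r + 1) * n] = eye
    return b


def _louvain_on_matrix(b: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Greedy move + aggregation phases on a symmetric modularity matrix."""
    n0 = b.shape[0]
    node_map = np.arange(n0)  # supra-node -> current community id
    cur = b
    while True:
        n = cur.shape[0]
        labels = np.arange(n)
        improved = True
        moved_any = False
        while improved:
            improved = False
            for u in rng.permutation(n):
                row = cur[u]
                gains = np.bincount(labels, weights=row, minlength=labels.max() + 1)
                gains[labels[u]] -= row[u]  # removing u's self-term symmetric pair
                best = int(np.argmax(gains))
                if gains[best] > gains[labels[u]] + 1e-13 and best != labels[u]:
                    labels[u] = best
                    improved = True
                    moved_any = True
        if not moved_any:
            break
        # aggregate communities
        uniq, inv = np.unique(labels, return_inverse=True)
        m = len(uniq)
        s = np.zeros((cur.shape[0], m))
        s[np.arange(cur.shape[0]), inv] = 1.0
        cur = s.T @ cur @ s
        node_map = inv[node_map]
        if m == 1:
            break
    return node_map


def louvain_optimize(
    mx: Multiplex,
    omega: float,
    gamma: float,
    restarts: int = 100,
    seed: int | np.random.Generator = 0,
) -> MultilayerPartition:
    """Best-of-restarts greedy maximization of the multilayer modularity."""
    if restarts < 1:
        raise ValueError("restarts must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    b = supra_modularity_matrix(mx, omega, gamma)
    n, L = mx.n_nodes, mx.n_layers
    best_q, best_labels = -np.inf, None
    for _ in range(restarts):
        flat = _louvain_on_matrix(b, rng)
        labels = flat.reshape(L, n).T
        q = multilayer_quality(mx, labels, omega, gamma)
        if q > best_q + 1e-15:
            best_q, best_labels = q, labels
    return MultilayerPartition(
        best_labels, best_q, omega, gamma, list(mx.nodes), mx.layer_names
    )


def variation_of_information(p1, p2) -> float:
    """VI between two labelings, in bits; 0 iff identical up to relabeling.

    Accepts label arrays or :class:`MultilayerPartition` (flattened over
    node x layer).
    """
    a = p1.labels.ravel() if isinstance(p1, MultilayerPartition) else np.asarray(p1).ravel()
    b = p2.labels.ravel() if isinstance(p2, MultilayerPartition) else np.asarray(p2).ravel()
    if a.shape != b.shape:
        raise ValueError("partitions must label the same node set")
    n = a.size
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    cont = np.zeros((ai.max() + 1, bi.max() + 1))
    np.add.at(cont, (ai, bi), 1.0)
    pij = cont / n
    pi = pij.sum(axis=1)
    pj = pij.sum(axis=0)
    # VI = sum_ij pij [log2(pi/pij) + log2(pj/pij)]: every term vanishes
    # exactly when the partitions coincide up to relabeling
    nz = pij > 0
    ratio = (pi[:, None] * pj[None, :])[nz] / pij[nz] ** 2
    return float(np.sum(pij[nz] * np.log2(ratio)))


def default_omega_grid(step: float = 0.05) -> np.ndarray:
    return np.unique(np.r_[0.01, np.round(np.arange(step, 1.0 + 1e-9, step), 10)])


def default_gamma_grid(step: float = 0.1) -> np.ndarray:
    return np.unique(np.r_[0.01, np.round(np.arange(step, 3.0 + 1e-9, step), 10)])


def sweep_parameters(
    mx: Multiplex,
    omega_grid: np.ndarray | None = None,
    gamma_grid: np.ndarray | None = None,
    restarts: int = 100,
    seed: int = 0,
) -> StabilityMap:
    """Community detection over the (omega, gamma) plane with VI stability.

    For each grid cell the optimizer is run and the mean VI between the
    cell's partition and its 4-neighbours' partitions is recorded.
    """
    omega_grid = default_omega_grid() if omega_grid is None else np.asarray(omega_grid, float)
    gamma_grid = default_gamma_grid() if gamma_grid is None else np.asarray(gamma_grid, float)
    rng = np.random.default_rng(seed)
    parts = [
        [louvain_optimize(mx, float(w), float(g), restarts, rng) for g in gamma_grid]
        for w in omega_grid
    ]
    n_w, n_g = len(omega_grid), len(gamma_grid)
    vi = np.zeros((n_w, n_g))
    for i in range(n_w):
        for j in range(n_g):
            vals = []
            for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                ii, jj = i + di, j + dj
                if 0 <= ii < n_w and 0 <= jj < n_g:
                    vals.append(variation_of_information(parts[i][j], parts[ii][jj]))
            vi[i, j] = np.mean(vals) if vals else 0.0
    return StabilityMap(omega_grid, gamma_grid, parts, vi)


def select_stable_partition(stability: StabilityMap, percentile: float = 10.0) -> MultilayerPartition:
    """Representative partition from the largest low-VI plateau.

    Cells with neighbour-mean VI at or below the given percentile form
    candidate plateaus (4-connected components); the minimum-VI cell of
    the largest plateau is returned.  If no plateau exists the global
    minimum-VI cell is returned with a warning.
    """
    vi = stability.vi
    if vi.size == 0:
        raise ValueError("empty stability map")
    if vi.size == 1:
        return stability.partitions[0][0]
    thresh = np.percentile(vi, percentile)
    mask = vi <= thresh
    if not mask.any():
        warnings.warn("no low-VI plateau found; returning the global minimum-VI cell")
        i, j = np.unravel_index(np.argmin(vi), vi.shape)
        return stability.partitions[i][j]
    # connected components of the candidate mask (4-adjacency)
    comp = -np.ones(vi.shape, dtype=int)
    n_comp = 0
    for i in range(vi.shape[0]):
        for j in range(vi.shape[1]):
            if mask[i, j] and comp[i, j] < 0:
                stack = [(i, j)]
                comp[i, j] = n_comp
                while stack:
                    a, b = stack.pop()
                    for da, db in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                        aa, bb = a + da, b + db
                        if (
                            0 <= aa < vi.shape[0]
                            and 0 <= bb < vi.shape[1]
                            and mask[aa, bb]
                            and comp[aa, bb] < 0
                        ):
                            comp[aa, bb] = n_comp
                            stack.append((aa, bb))
                n_comp += 1
    sizes = np.bincount(comp[comp >= 0].ravel(), minlength=n_comp)
    target = int(np.argmax(sizes))
    cells = np.argwhere(comp == target)
    best = min(cells.tolist(), key=lambda c: (vi[c[0], c[1]], c[0], c[1]))
    return stability.partitions[best[0]][best[1]]
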