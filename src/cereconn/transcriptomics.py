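"""Transcriptomic correlates of connectivity alterations.

Regional gene co-expression (Pearson correlation of two regions' expression
profiles across genes) is decomposed exactly into per-gene contributions
``z_i(g) * z_j(g) / (G - 1)`` (z = within-region standardized expression),
which sum over genes to the co-expression value.  Contributions are
aggregated to module-level edges, used as predictors of the patients'
connectivity-alteration vector in a partial-least-squares regression, and
the first component's gene weights are standardized to Z scores; genes with
|Z| > 1.64 form the associated gene set, which is tested for class
over-representation with a hypergeometric test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .inference import bh_fdr

__all__ = [
    "PLSResult",
    "regional_coexpression",
    "gene_edge_contributions",
    "module_contribution_matrix",
    "pls_fit",
    "pls1_significance",
    "enrichment_test",
]

Z_THRESHOLD = 1.64


@dataclass
class PLSResult:
    """First PLS component relating gene contributions to alterations."""

    scores: np.ndarray  # PLS1 score per observation (module edge)
    r: float  # Pearson correlation of scores with the alteration vector
    weights: pd.Series  # raw per-gene weight
    z: pd.Series  # standardized weight
    selected: pd.Index  # genes with |Z| > 1.64
    p: float | None = None
    meta: dict = field(default_factory=dict)


def _standardized(expr: pd.DataFrame) -> np.ndarray:
    """Within-region standardization across genes (ddof=1)."""
    x = expr.to_numpy(float)
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = list(expr.columns[sd == 0][:5])
        raise ValueError(f"zero-variance expression profile in regions: {bad}")
    return (x - mu) / sd


def regional_coexpression(
    expr: pd.DataFrame, pairs: list[tuple[str, str]]
) -> np.ndarray:
    """Pearson co-expression between region pairs across genes."""
    if expr.shape[0] < 3:
        raise ValueError("need at least 3 genes")
    z = _standardized(expr)
    col = {c: k for k, c in enumerate(expr.columns)}
    g = expr.shape[0]
    out = np.empty(len(pairs))
    for k, (a, b) in enumerate(pairs):
        out[k] = z[:, col[a]] @ z[:, col[b]] / (g - 1)
    return out


def gene_edge_contributions(
    expr: pd.DataFrame, pairs: list[tuple[str, str]]
) -> pd.DataFrame:
    """Gene x edge contribution matrix; columns sum to the edge co-expression.

    Contribution of gene g to edge (i, j) is ``z_i(g) z_j(g) / (G - 1)``,
    an exact additive decomposition of the Pearson correlation.
    """
    if expr.shape[0] < 3:
        raise ValueError("need at least 3 genes")
    z = _standardized(expr)
    col = {c: k for k, c in enumerate(expr.columns)}
    g = expr.shape[0]
    mat = np.empty((g, len(pairs)))
    for k, (a, b) in enumerate(pairs):
        mat[:, k] = z[:, col[a]] * z[:, col[b]] / (g - 1)
    names = [f"{a}~{b}" for a, b in pairs]
    return pd.DataFrame(mat, index=expr.index, columns=names)


def module_contribution_matrix(
    contributions: pd.DataFrame,
    pairs: list[tuple[str, str]],
    labels: dict[str, str],
    module_order: list[str] | None = None,
) -> pd.DataFrame:
    """Mean gene contribution per module pair (same pooling as the networks).

    Returns a gene x module-edge matrix whose columns are the unordered
    module pairs (including within-module) present among ``pairs``.
    """
    modules = module_order or sorted(set(labels.values()))
    edge_module = []
    for a, b in pairs:
        ma, mb = labels[a], labels[b]
        key = tuple(sorted((ma, mb), key=modules.index))
        edge_module.append(key)
    cols = {}
    arr = contributions.to_numpy(float)
    for k, key in enumerate(edge_module):
        cols.setdefault(key, []).append(k)
    for key, members in cols.items():
        if not members:
            raise ValueError(f"module pair {key} has no region edges")
    keys = [
        (modules[i], modules[j])
        for i in range(len(modules))
        for j in range(i, len(modules))
        if (modules[i], modules[j]) in cols
    ]
    out = np.column_stack([arr[:, cols[k]].mean(axis=1) for k in keys])
    names = [f"{a}~{b}" for a, b in keys]
    return pd.DataFrame(out, index=contributions.index, columns=names)


def pls_fit(x: pd.DataFrame, y: np.ndarray) -> PLSResult:
    """First partial-least-squares component of gene contributions vs. alterations.

    With a univariate response the PLS1 weight vector is the centered
    cross-covariance ``X_c' y_c`` normalized to unit length (equivalently
    the leading singular direction of the cross-covariance); scores are
    ``X_c w``.  Gene weights are standardized across genes to Z scores and
    genes with |Z| > 1.64 are selected.
    """
    xm = x.to_numpy(float)
    y = np.asarray(y, float)
    if xm.shape[1] < 5:
        raise ValueError("need at least 5 observations (module edges)")
    if not np.all(np.isfinite(y)):
        raise ValueError("alteration vector must be finite")
    if np.ptp(y) == 0:
        raise ValueError("constant alteration vector")
    # observations are the module edges: X is edges x genes
    xo = xm.T  # edges x genes
    xc = xo - xo.mean(axis=0)
    yc = y - y.mean()
    w = xc.T @ yc
    norm = np.linalg.norm(w)
    if norm == 0:
        raise ValueError("degenerate weights: predictors uncorrelated with response")
    w_unit = w / norm
    scores = xc @ w_unit
    denom = np.linalg.norm(scores) * np.linalg.norm(yc)
    r = float(scores @ yc / denom) if denom > 0 else 0.0
    weights = pd.Series(w, index=x.index, name="weight")
    sd = weights.std(ddof=0)
    if sd == 0:
        raise ValueError("zero spread of gene weights")
    z = (weights - weights.mean()) / sd
    selected = z.index[np.abs(z) > Z_THRESHOLD]
    return PLSResult(scores=scores, r=r, weights=weights, z=z.rename("Z"), selected=selected)


def pls1_significance(
    x: pd.DataFrame, y: np.ndarray, B: int = 1000, seed: int | np.random.Generator = 0
) -> tuple[PLSResult, float]:
    """Permutation significance of the PLS1 association.

    The alteration vector is permuted over module edges, the component is
    refit, and ``p = (1 + #{r_perm >= r_obs}) / (B + 1)``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    result = pls_fit(x, y)
    y = np.asarray(y, float)
    n = y.size
    xo = x.to_numpy(float).T
    xc = xo - xo.mean(axis=0)
    perms = np.stack([rng.permutation(n) for _ in range(B)])
    yp = y[perms]  # B x n
    ypc = yp - yp.mean(axis=1, keepdims=True)
    w = xc.T @ ypc.T  # genes x B
    scores = xc @ w  # n x B
    sc = scores - scores.mean(axis=0)
    num = (sc * ypc.T).sum(axis=0)
    denom = np.linalg.norm(sc, axis=0) * np.linalg.norm(ypc, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r_perm = np.where(denom > 0, num / denom, 0.0)
    p = float((1.0 + np.count_nonzero(r_perm >= result.r - 1e-12)) / (B + 1.0))
    result.p = p
    return result, p


def enrichment_test(
    selected, annotation: pd.Series, background
) -> pd.DataFrame:
    """Hypergeometric over-representation of gene classes in a selected set.

    ``annotation`` maps gene -> class label; classes absent from the
    background are skipped.  Returns per-class overlap counts, upper-tail
    hypergeometric p and BH q.
    """
    background = pd.Index(background)
    selected = pd.Index(selected)
    if not selected.isin(background).all():
        raise ValueError("selected genes must be a subset of the background")
    ann = annotation[annotation.index.isin(background)]
    n_bg = len(background)
    n_sel = len(selected)
    rows = []
    for cls, genes in ann.groupby(ann).groups.items():
        k_cls = len(genes)
        overlap = len(selected.intersection(genes))
        # P(X >= overlap), X ~ Hypergeom(N=n_bg, K=k_cls, n=n_sel)
        p = float(stats.hypergeom.sf(overlap - 1, n_bg, k_cls, n_sel)) if n_sel else 1.0
        rows.append({"class": cls, "class_size": k_cls, "selected": n_sel,
                     "overlap": overlap, "p": p})
    out = pd.DataFrame(rows).sort_values("p").reset_index(drop=True)
    out["q"] = bh_fdr(out["p"].to_numpy())
    return out
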