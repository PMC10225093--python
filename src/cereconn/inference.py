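"""Covariate-adjusted nonparametric group inference.

Continuous measures are compared across groups with permutation tests on
covariate-adjusted residuals (Freedman-Lane style: the measure is
residualized against the nuisance covariates fitted on the pooled sample,
and group labels are permuted on the residuals), followed by
Benjamini-Hochberg FDR correction and post-hoc pairwise permutation tests
whose significant directions are summarized into pattern labels such as
``"MS > [NMOSD = HCs]"``.  Spearman partial correlation and Pearson
chi-squared tests cover clinical associations and dichotomous variables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GroupComparisonResult",
    "residualize",
    "perm_group_test",
    "posthoc_pairwise",
    "pattern_label",
    "bh_fdr",
    "spearman_partial",
    "chi_square_test",
    "compare_measures",
]

#: Display names used in post-hoc pattern labels.
DISPLAY = {"HC": "HCs", "MS": "MS", "NMOSD": "NMOSD"}


@dataclass
class GroupComparisonResult:
    measure: str
    statistic: float
    p: float
    q: float | None = None
    pattern: str | None = None
    pairwise_p: dict | None = None


def _design(covariates, n: int) -> np.ndarray:
    if covariates is None:
        return np.ones((n, 1))
    if isinstance(covariates, pd.DataFrame):
        parts = [np.ones((n, 1))]
        for col in covariates.columns:
            s = covariates[col]
            if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
                parts.append(pd.get_dummies(s, drop_first=True).to_numpy(float))
            else:
                parts.append(s.to_numpy(float)[:, None])
        x = np.hstack(parts)
    else:
        x = np.column_stack([np.ones(n), np.asarray(covariates, float)])
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("rank-deficient covariate design")
    return x


def residualize(values, covariates) -> np.ndarray:
    """Least-squares residuals of ``values`` against covariates (+intercept)."""
    y = np.asarray(values, float)
    x = _design(covariates, y.shape[0])
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    return y - x @ beta


def _f_stat(resid: np.ndarray, onehot: np.ndarray) -> float:
    n, g = onehot.shape
    counts = onehot.sum(axis=0)
    sums = resid @ onehot
    grand = resid.mean()
    ssb = np.sum(sums**2 / counts) - n * grand**2
    sst = np.sum(resid**2) - n * grand**2
    ssw = sst - ssb
    if ssw <= 0:
        return np.inf if ssb > 0 else 0.0
    return float((ssb / (g - 1)) / (ssw / (n - g)))


def _perm_f_pvalue(resid, onehot, B, rng) -> tuple[float, float]:
    obs = _f_stat(resid, onehot)
    n, g = onehot.shape
    counts = onehot.sum(axis=0)
    grand = resid.mean()
    sst = np.sum(resid**2) - n * grand**2
    perms = np.empty((B, n))
    base = np.tile(resid, (B, 1))
    perms = rng.permuted(base, axis=1)
    sums = perms @ onehot  # B x g
    ssb = (sums**2 / counts).sum(axis=1) - n * grand**2
    ssw = sst - ssb
    with np.errstate(divide="ignore", invalid="ignore"):
        fs = (ssb / (g - 1)) / (ssw / (n - g))
    fs = np.where(ssw <= 0, np.inf, fs)
    p = (1.0 + np.count_nonzero(fs >= obs - 1e-12)) / (B + 1.0)
    return obs, float(p)


def perm_group_test(
    values, groups, covariates=None, B: int = 10000, seed: int | np.random.Generator = 0
) -> tuple[float, float]:
    """Omnibus permutation test of a group effect on covariate residuals.

    Returns the observed between-group F on residuals and the permutation
    p-value ``(1 + #{F_perm >= F_obs}) / (B + 1)``.
    """
    y = np.asarray(values, float)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    if min((groups == g).sum() for g in labels) < 2:
        raise ValueError("need at least two subjects per group")
    if np.ptp(y) == 0:
        warnings.warn("constant measure; p = 1")
        return 0.0, 1.0
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    resid = residualize(y, covariates)
    onehot = (groups[:, None] == labels[None, :]).astype(float)
    return _perm_f_pvalue(resid, onehot, B, rng)


def pattern_label(means: dict[str, float], significant: dict[frozenset, bool]) -> str | None:
    """Synthesize a post-hoc pattern label from pairwise significances.

    ``means`` maps group name to its adjusted mean; ``significant`` maps
    unordered group pairs to whether their difference survived FDR.
    Returns e.g. ``"MS > [NMOSD = HCs]"``, ``"[MS = NMOSD] < HCs"``,
    a full ordering, a single-pair label, or ``None`` when nothing is
    significant.
    """
    names = list(means)
    disp = {g: DISPLAY.get(g, g) for g in names}
    sig_pairs = [p for p, s in significant.items() if s]
    if not sig_pairs:
        return None
    if len(names) != 3:
        a, b = sorted(names, key=lambda g: -means[g])
        return f"{disp[a]} > {disp[b]}"
    if len(sig_pairs) == 1:
        a, b = list(sig_pairs[0])
        hi, lo = (a, b) if means[a] > means[b] else (b, a)
        return f"{disp[hi]} > {disp[lo]}"
    if len(sig_pairs) == 2:
        # the group present in both significant pairs differs from the other two
        common = set(sig_pairs[0]) & set(sig_pairs[1])
        if len(common) == 1:
            x = common.pop()
            # equal pair reads high-to-low inside the brackets
            others = sorted((g for g in names if g != x), key=lambda g: -means[g])
            if means[x] > max(means[g] for g in others):
                return f"{disp[x]} > [{disp[others[0]]} = {disp[others[1]]}]"
            if means[x] < min(means[g] for g in others):
                return f"{disp[x]} < [{disp[others[0]]} = {disp[others[1]]}]"
            # x sits between the two others: report both relations
            hi = max(others, key=lambda g: means[g])
            lo = min(others, key=lambda g: means[g])
            return f"{disp[hi]} > {disp[x]} > {disp[lo]}"
    order = sorted(names, key=lambda g: -means[g])
    return " > ".join(disp[g] for g in order)


def posthoc_pairwise(
    values,
    groups,
    covariates=None,
    B: int = 10000,
    seed: int | np.random.Generator = 0,
    alpha: float = 0.05,
) -> tuple[dict, str | None]:
    """Pairwise permutation tests between all group pairs + pattern label.

    Pairwise p-values are BH-corrected within the post-hoc family; a pair
    is declared different when its q < ``alpha``.  Means entering the
    direction calls are covariate-adjusted.
    """
    y = np.asarray(values, float)
    groups = np.asarray(groups)
    labels = list(pd.unique(groups))
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    resid = residualize(y, covariates)
    pairs = [(labels[i], labels[j]) for i in range(len(labels)) for j in range(i + 1, len(labels))]
    pvals = {}
    for a, b in pairs:
        mask = (groups == a) | (groups == b)
        sub = resid[mask]
        if np.ptp(sub) == 0:
            pvals[(a, b)] = 1.0
            continue
        onehot = (groups[mask, None] == np.array([a, b])[None, :]).astype(float)
        _, p = _perm_f_pvalue(sub, onehot, B, rng)
        pvals[(a, b)] = p
    q = bh_fdr(list(pvals.values()))
    significant = {frozenset(pair): qi < alpha for pair, qi in zip(pvals, q)}
    means = {g: float(resid[groups == g].mean()) for g in labels}
    return pvals, pattern_label(means, significant)


def bh_fdr(p_list) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone in p)."""
    p = np.asarray(p_list, float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def spearman_partial(x, y, covariates=None) -> tuple[float, float]:
    """Spearman partial correlation: midrank the variables and every
    covariate column, residualize the variable ranks on the covariate ranks,
    Pearson on the residuals; p from the t approximation."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    k = 0
    ranked_cov = None
    if covariates is not None:
        cov = np.asarray(covariates, float)
        if cov.ndim == 1:
            cov = cov[:, None]
        k = cov.shape[1]
        ranked_cov = np.column_stack([stats.rankdata(cov[:, j]) for j in range(k)])
    if n < k + 3:
        raise ValueError("too few observations for the requested partial correlation")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    ex = residualize(rx, ranked_cov)
    ey = residualize(ry, ranked_cov)
    denom = np.linalg.norm(ex) * np.linalg.norm(ey)
    if denom == 0:
        return 0.0, 1.0
    rho = float(np.clip(ex @ ey / denom, -1.0, 1.0))
    df = n - 2 - k
    t = rho * np.sqrt(df / max(1e-300, 1.0 - rho**2))
    p = float(2 * stats.t.sf(abs(t), df))
    return rho, p


def chi_square_test(contingency) -> tuple[float, float]:
    """Pearson chi-squared test of independence (no continuity correction)."""
    table = np.asarray(contingency, float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("contingency table has an empty margin")
    res = stats.chi2_contingency(table, correction=False)
    return float(res.statistic), float(res.pvalue)


def compare_measures(
    measures: pd.DataFrame,
    groups,
    covariates=None,
    B: int = 10000,
    seed: int = 0,
    alpha: float = 0.05,
    posthoc_B: int | None = None,
) -> pd.DataFrame:
    """Omnibus + FDR + post-hoc over a panel of measures (one column each).

    Returns a table with measure, F, p, q, and the post-hoc pattern label
    for measures whose omnibus q < ``alpha``.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for col in measures.columns:
        y = measures[col].to_numpy(float)
        f, p = perm_group_test(y, groups, covariates, B=B, seed=rng)
        rows.append({"measure": col, "statistic": f, "p": p})
    out = pd.DataFrame(rows)
    out["q"] = bh_fdr(out["p"].to_numpy())
    patterns = []
    for _, row in out.iterrows():
        if row["q"] < alpha:
            _, label = posthoc_pairwise(
                measures[row["measure"]].to_numpy(float), groups, covariates,
                B=posthoc_B or B, seed=rng, alpha=alpha,
            )
            patterns.append(label)
        else:
            patterns.append(None)
    out["pattern"] = patterns
    return out
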