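"""Multi-site harmonization of edge-wise connectivity features.

Implements the canonical parametric empirical-Bayes location/scale batch
adjustment (ComBat): per feature, per site, a site-specific additive and
multiplicative effect is estimated after regressing out the biological
design (group, age, sex, ...), shrunk toward common priors (normal for
locations, inverse-gamma for scales), and removed.  The biological signal
captured by the design is re-added, so planted group effects survive
harmonization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["FeatureTable", "combat_adjust", "site_effect_metric"]


@dataclass
class FeatureTable:
    """Subjects x features matrix with site labels and biological covariates.

    ``covariates`` holds the columns to protect during harmonization;
    categorical columns are dummy-coded internally.
    """

    values: pd.DataFrame  # subjects x features
    site: pd.Series  # per-subject site labels
    covariates: pd.DataFrame | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.site = pd.Series(self.site)
        if len(self.site) != len(self.values):
            raise ValueError("site labels must match the number of subjects")
        if self.covariates is not None and len(self.covariates) != len(self.values):
            raise ValueError("covariates must match the number of subjects")


def _design_matrix(table: FeatureTable) -> np.ndarray | None:
    """Dummy-coded biological design (no intercept; ComBat adds site dummies)."""
    cov = table.covariates
    if cov is None or cov.shape[1] == 0:
        return None
    parts = []
    for col in cov.columns:
        s = cov[col]
        if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
            d = pd.get_dummies(s, drop_first=True).to_numpy(float)
            parts.append(d)
        else:
            parts.append(s.to_numpy(float)[:, None])
    x = np.hstack(parts)
    if np.any(~np.isfinite(x)):
        raise ValueError("covariates contain missing values")
    return x


def _aprior(delta_hat: np.ndarray) -> float:
    m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
    return (2 * s2 + m**2) / s2


def _bprior(delta_hat: np.ndarray) -> float:
    m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
    return (m * s2 + m**3) / s2


def _it_sol(s_data, g_hat, d_hat, g_bar, t2, a, b, conv=1e-4):
    """Iterative solution for the empirical-Bayes batch effect posteriors."""
    n = s_data.shape[1]
    g_old, d_old = g_hat.copy(), d_hat.copy()
    change = 1.0
    while change > conv:
        g_new = (t2 * n * g_hat + d_old * g_bar) / (t2 * n + d_old)
        sum2 = ((s_data - g_new[:, None]) ** 2).sum(axis=1)
        d_new = (0.5 * sum2 + b) / (n / 2.0 + a - 1.0)
        # convergence ratios use the signed previous value (canonical recipe)
        change = max(
            np.max(np.abs(g_new - g_old) / g_old),
            np.max(np.abs(d_new - d_old) / d_old),
        )
        g_old, d_old = g_new, d_new
    return g_old, d_old


def combat_adjust(table: FeatureTable) -> FeatureTable:
    """Remove site effects from a feature table (parametric empirical Bayes).

    Single-site input is returned unchanged.  A site with fewer than two
    subjects is rejected (its scale effect is unidentifiable) with a
    suggestion to merge it into a neighbouring site.
    """
    values = table.values
    y = values.to_numpy(float).T  # features x subjects, ComBat orientation
    sites = pd.Categorical(table.site)
    levels = list(sites.categories)
    if len(levels) == 1:
        return FeatureTable(values.copy(), table.site.copy(),
                            None if table.covariates is None else table.covariates.copy(),
                            dict(table.meta, harmonized=True))
    counts = pd.Series(sites).value_counts()
    small = counts[counts < 2]
    if len(small):
        raise ValueError(
            f"sites with a single subject cannot be harmonized: {list(small.index)}; "
            "consider merging them with another site"
        )

    n_array = y.shape[1]
    batch_design = pd.get_dummies(pd.Series(sites)).to_numpy(float)  # n x n_batch
    n_batch = batch_design.shape[1]
    n_batches = batch_design.sum(axis=0)
    bio = _design_matrix(table)
    design = batch_design if bio is None else np.hstack([batch_design, bio])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("confounded design: biological covariates collinear with site")

    # Feature-wise OLS of data on [site dummies, biological design]
    b_hat = np.linalg.solve(design.T @ design, design.T @ y.T)  # p x features
    grand_mean = (n_batches / n_array) @ b_hat[:n_batch]
    resid = y - (design @ b_hat).T
    var_pooled = (resid**2).mean(axis=1)  # ML variance, per feature
    var_pooled = np.where(var_pooled == 0, 1e-12, var_pooled)

    stand_mean = grand_mean[:, None] * np.ones((1, n_array))
    if bio is not None:
        tmp = design.copy()
        tmp[:, :n_batch] = 0
        stand_mean = stand_mean + (tmp @ b_hat).T
    s_data = (y - stand_mean) / np.sqrt(var_pooled)[:, None]

    # Site-wise location/scale estimates and EB shrinkage
    gamma_star = np.empty((n_batch, y.shape[0]))
    delta_star = np.empty((n_batch, y.shape[0]))
    for i in range(n_batch):
        mask = batch_design[:, i] == 1
        sd_i = s_data[:, mask]
        g_hat = sd_i.mean(axis=1)
        d_hat = sd_i.var(axis=1, ddof=1)
        g_bar, t2 = g_hat.mean(), g_hat.var(ddof=1)
        a, b = _aprior(d_hat), _bprior(d_hat)
        gamma_star[i], delta_star[i] = _it_sol(sd_i, g_hat, d_hat, g_bar, t2, a, b)

    bayes = s_data.copy()
    for i in range(n_batch):
        mask = batch_design[:, i] == 1
        bayes[:, mask] = (bayes[:, mask] - gamma_star[i][:, None]) / np.sqrt(
            delta_star[i]
        )[:, None]
    adjusted = bayes * np.sqrt(var_pooled)[:, None] + stand_mean

    out = pd.DataFrame(adjusted.T, index=values.index, columns=values.columns)
    return FeatureTable(out, table.site.copy(),
                        None if table.covariates is None else table.covariates.copy(),
                        dict(table.meta, harmonized=True))


def site_effect_metric(table: FeatureTable) -> pd.Series:
    """Per-feature fraction of variance explained by site (one-way R²)."""
    y = table.values.to_numpy(float)
    sites = pd.Categorical(table.site)
    if len(sites.categories) == 1:
        return pd.Series(0.0, index=table.values.columns)
    grand = y.mean(axis=0)
    ss_tot = ((y - grand) ** 2).sum(axis=0)
    ss_between = np.zeros(y.shape[1])
    for lev in sites.categories:
        mask = np.asarray(sites == lev)
        ss_between += mask.sum() * (y[mask].mean(axis=0) - grand) ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(ss_tot > 0, ss_between / ss_tot, 0.0)
    return pd.Series(r2, index=table.values.columns)
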