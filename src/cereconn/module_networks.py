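"""Region-level to module-level network conversion.

Region-level cerebellar networks (24x24 within-cerebellar, 24x400
cerebello-cerebral) are reduced to module-level networks by averaging the
edges between module pairs: a 5x5 matrix over the detected cerebellar
modules and a 5x7 matrix against a cerebral taxonomy (seven
cytoarchitectonic classes or seven resting-state networks, each ROI
assigned to the module with maximal voxel overlap).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .connectivity import RegionNetwork, fisher_z, fisher_z_inv

logger = logging.getLogger(__name__)

__all__ = [
    "CerebralTaxonomy",
    "ModuleNetwork",
    "assign_cerebral_modules",
    "within_cerebellar_module_network",
    "cerebello_cerebral_module_network",
]


@dataclass
class CerebralTaxonomy:
    """ROI -> cerebral module assignment for one taxonomy."""

    taxonomy: str
    assignment: pd.Series  # ROI id -> module name
    modules: list[str]

    def rois_of(self, module: str) -> list[str]:
        return list(self.assignment.index[self.assignment == module])


@dataclass
class ModuleNetwork:
    """Module x module mean connectivity."""

    matrix: np.ndarray
    row_modules: list[str]
    col_modules: list[str]
    modality: str
    taxonomy: str | None = None
    meta: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.row_modules, columns=self.col_modules)


def assign_cerebral_modules(overlap_counts: pd.DataFrame, taxonomy: str) -> CerebralTaxonomy:
    """Maximum-voxel-overlap assignment of each cerebral ROI to one module.

    Ties are broken by the declared column order of the overlap table and
    logged.  An ROI with no positive overlap is rejected.
    """
    counts = overlap_counts.to_numpy(float)
    if (counts < 0).any():
        raise ValueError("overlap counts must be non-negative")
    zero = counts.sum(axis=1) == 0
    if zero.any():
        bad = list(overlap_counts.index[zero][:5])
        raise ValueError(f"ROIs with no overlap in any module: {bad}")
    winners = counts.argmax(axis=1)
    row_max = counts.max(axis=1)
    ties = (counts == row_max[:, None]).sum(axis=1) > 1
    for roi in overlap_counts.index[ties]:
        logger.info("overlap tie for ROI %s resolved by declared module order", roi)
    modules = list(overlap_counts.columns)
    assignment = pd.Series(
        [modules[w] for w in winners], index=overlap_counts.index, name="module"
    )
    return CerebralTaxonomy(taxonomy, assignment, modules)


def _mean_pool(values: np.ndarray, modality: str) -> float:
    values = values[np.isfinite(values)]
    if values.size == 0:
        return np.nan
    if modality == "functional":
        return float(fisher_z_inv(np.mean(fisher_z(values))))
    return float(np.mean(values))


def within_cerebellar_module_network(
    net: RegionNetwork, labels: dict[str, str], module_order: list[str] | None = None
) -> ModuleNetwork:
    """5x5 mean connectivity between (and within) cerebellar modules.

    ``labels`` maps each of the 24 regions to its module for the network's
    modality; the diagonal averages within-module edges excluding
    self-edges.  Functional edges are pooled on the Fisher-z scale.
    """
    missing = [r for r in net.row_ids if r not in labels]
    if missing:
        raise ValueError(f"partition does not cover regions: {missing[:5]}")
    modules = module_order or sorted(set(labels[r] for r in net.row_ids))
    idx = {m: [i for i, r in enumerate(net.row_ids) if labels[r] == m] for m in modules}
    for m, members in idx.items():
        if not members:
            raise ValueError(f"module {m!r} has no member regions")
    k = len(modules)
    out = np.full((k, k), np.nan)
    a = net.matrix
    for i, mi in enumerate(modules):
        for j, mj in enumerate(modules):
            if i == j:
                ii = idx[mi]
                pair_vals = np.array(
                    [a[p, q] for x, p in enumerate(ii) for q in ii[x + 1:]]
                )
                out[i, j] = _mean_pool(pair_vals, net.modality)
            else:
                out[i, j] = _mean_pool(a[np.ix_(idx[mi], idx[mj])].ravel(), net.modality)
    return ModuleNetwork(out, modules, modules, net.modality, taxonomy="cerebellar")


def cerebello_cerebral_module_network(
    net: RegionNetwork,
    labels: dict[str, str],
    taxonomy: CerebralTaxonomy,
    module_order: list[str] | None = None,
) -> ModuleNetwork:
    """5x7 mean connectivity between cerebellar and cerebral modules."""
    missing = [r for r in net.row_ids if r not in labels]
    if missing:
        raise ValueError(f"partition does not cover regions: {missing[:5]}")
    cb_modules = module_order or sorted(set(labels[r] for r in net.row_ids))
    row_idx = {m: [i for i, r in enumerate(net.row_ids) if labels[r] == m] for m in cb_modules}
    col_idx = {}
    for m in taxonomy.modules:
        members = [j for j, c in enumerate(net.col_ids) if taxonomy.assignment.get(c) == m]
        if not members:
            raise ValueError(f"cerebral module {m!r} has no ROI in this network")
        col_idx[m] = members
    for m, members in row_idx.items():
        if not members:
            raise ValueError(f"cerebellar module {m!r} has no member regions")
    out = np.full((len(cb_modules), len(taxonomy.modules)), np.nan)
    for i, mi in enumerate(cb_modules):
        for j, mj in enumerate(taxonomy.modules):
            out[i, j] = _mean_pool(net.matrix[np.ix_(row_idx[mi], col_idx[mj])].ravel(), net.modality)
    return ModuleNetwork(out, cb_modules, list(taxonomy.modules), net.modality, taxonomy.taxonomy)
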