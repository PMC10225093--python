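"""End-to-end orchestration of the cerebellar connectome analysis.

Stages run in dependency order: synthetic cohort (or fixtures on disk) →
per-subject connectivity → site harmonization → multiplex module
detection on the healthy controls → module-level networks → group
inference → transcriptomic association → pairwise classification.  A
manifest records seeds, parameters and SHA-256 hashes of every result
table, so a rerun with the same configuration is verifiably identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import atlas, synth
from .classify import build_features, classify_pair
from .connectivity import RegionNetwork, fisher_z, fisher_z_inv, func_network, morph_network
from .harmonize import FeatureTable, combat_adjust, site_effect_metric
from .inference import compare_measures
from .module_networks import (
    assign_cerebral_modules,
    cerebello_cerebral_module_network,
    within_cerebellar_module_network,
)
from .multiplex import (
    build_group_multiplex,
    select_stable_partition,
    sweep_parameters,
)
from .transcriptomics import (
    gene_edge_contributions,
    module_contribution_matrix,
    pls1_significance,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "validate_config", "run_pipeline"]

ALL_STAGES = ("connectivity", "harmonize", "modules", "aggregate", "stats", "genes", "classify")


@dataclass
class PipelineConfig:
    """Validated run configuration with the documented statistical defaults."""

    synth: synth.SynthConfig = field(default_factory=synth.SynthConfig)
    input_dir: str | None = None  # fixtures on disk instead of in-memory synthesis
    out_dir: str = "results"
    seed: int = 0
    n_perm: int = 10000  # group-comparison permutations
    n_class_perm: int = 1000  # classifier label permutations
    cv_folds: int = 10
    cv_repeats: int = 100
    louvain_restarts: int = 100
    omega_step: float = 0.05
    gamma_step: float = 0.1
    fdr_alpha: float = 0.05
    stages: tuple[str, ...] = ALL_STAGES
    include_cerebral: bool = True

    def __post_init__(self):
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")


_SCHEMA_TYPES = {
    "input_dir": (str, type(None)),
    "out_dir": str,
    "seed": int,
    "n_perm": int,
    "n_class_perm": int,
    "cv_folds": int,
    "cv_repeats": int,
    "louvain_restarts": int,
    "omega_step": float,
    "gamma_step": float,
    "fdr_alpha": float,
    "include_cerebral": bool,
}


def validate_config(source: str | Path | dict) -> PipelineConfig:
    """Schema-check a JSON/YAML/dict configuration and fill defaults."""
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
        if str(source).endswith((".yaml", ".yml")):
            import yaml

            raw = yaml.safe_load(text)
        else:
            raw = json.loads(text)
    else:
        raw = dict(source)
    known = set(_SCHEMA_TYPES) | {"synth", "stages"}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
    kwargs = {}
    for key, typ in _SCHEMA_TYPES.items():
        if key in raw:
            val = raw[key]
            if typ is float and isinstance(val, int):
                val = float(val)
            if not isinstance(val, typ):
                raise TypeError(f"config key {key!r} must be {typ}, got {type(val).__name__}")
            kwargs[key] = val
    if "stages" in raw:
        kwargs["stages"] = tuple(raw["stages"])
    if "synth" in raw:
        s = dict(raw["synth"])
        if "effect_map" in s:
            s["effect_map"] = [
                synth.EffectSpec(tuple(tuple(e) for e in m["edges"]),
                                 m["modality"], m["group"], m["effect"])
                for m in s["effect_map"]
            ]
        kwargs["synth"] = synth.SynthConfig(**s)
    return PipelineConfig(**kwargs)


# ---------------------------------------------------------------------------
# edge vectorization helpers


def vectorize_symmetric(mat: np.ndarray, ids: list[str]) -> pd.Series:
    iu = np.triu_indices(len(ids), k=1)
    names = [f"{ids[i]}~{ids[j]}" for i, j in zip(*iu)]
    return pd.Series(mat[iu], index=names)


def unvectorize_symmetric(vec: pd.Series, ids: list[str], diag: float = 1.0) -> np.ndarray:
    n = len(ids)
    mat = np.full((n, n), diag, dtype=float)
    iu = np.triu_indices(n, k=1)
    mat[iu] = vec.to_numpy(float)
    mat[(iu[1], iu[0])] = vec.to_numpy(float)
    return mat


def vectorize_rect(mat: np.ndarray, rows: list[str], cols: list[str]) -> pd.Series:
    names = [f"{a}~{b}" for a in rows for b in cols]
    return pd.Series(mat.ravel(), index=names)


# ---------------------------------------------------------------------------
# stage helpers


def subject_networks(
    data: synth.SynthCohort, include_cerebral: bool = True
) -> dict[str, dict[str, list[RegionNetwork]]]:
    """Per-subject morphological and functional networks for both blocks."""
    cfg = data.config
    cb = cfg.cerebellar_regions
    cx = cfg.cerebral_regions
    out = {"morphological": {}, "functional": {}}
    for sid, regmap in data.thickness.items():
        nets = [morph_network(regmap, cb)]
        if include_cerebral:
            nets.append(morph_network(regmap, cb, cx))
        out["morphological"][sid] = nets
    for sid, ts in data.timeseries.items():
        nets = [func_network(ts, cfg.regions, cb, cb)]
        if include_cerebral:
            nets.append(func_network(ts, cfg.regions, cb, cx))
        out["functional"][sid] = nets
    return out


def networks_to_feature_tables(
    nets: dict[str, dict[str, list[RegionNetwork]]],
    cohort: pd.DataFrame,
    include_cerebral: bool = True,
) -> dict[tuple[str, str], FeatureTable]:
    """Edge-wise feature tables per (modality, block), on the working scale.

    Functional correlations are carried as Fisher z for harmonization;
    morphological similarities on their native [0, 1] scale.
    """
    cohort = cohort.set_index("id")
    tables = {}
    blocks = ["cerebellar"] + (["cerebello-cerebral"] if include_cerebral else [])
    for modality, per_subject in nets.items():
        for bi, block in enumerate(blocks):
            rows = {}
            for sid, subject_nets in per_subject.items():
                net = subject_nets[bi]
                if block == "cerebellar":
                    vec = vectorize_symmetric(net.matrix, net.row_ids)
                else:
                    vec = vectorize_rect(net.matrix, net.row_ids, net.col_ids)
                if modality == "functional":
                    vec = pd.Series(fisher_z(vec.to_numpy()), index=vec.index)
                rows[sid] = vec
            values = pd.DataFrame(rows).T
            meta = cohort.loc[values.index]
            covs = {"group": meta["group"], "age": meta["age"], "sex": meta["sex"]}
            if modality == "functional":
                covs["fd"] = meta["fd"]
            tables[(modality, block)] = FeatureTable(
                values, meta["site"], pd.DataFrame(covs),
                meta={"modality": modality, "block": block},
            )
    return tables


def harmonized_matrices(
    table: FeatureTable, ids_rows: list[str], ids_cols: list[str] | None, modality: str
) -> dict[str, np.ndarray]:
    """Back-transform a harmonized feature table into per-subject matrices."""
    out = {}
    for sid in table.values.index:
        vec = table.values.loc[sid]
        if modality == "functional":
            vec = pd.Series(fisher_z_inv(vec.to_numpy()), index=vec.index)
        if ids_cols is None:
            out[sid] = unvectorize_symmetric(vec, ids_rows, diag=1.0)
        else:
            out[sid] = vec.to_numpy(float).reshape(len(ids_rows), len(ids_cols))
    return out


def _hash_frame(df: pd.DataFrame) -> str:
    return hashlib.sha256(df.to_csv().encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# driver


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all configured stages and write result tables + manifest.

    Returns the manifest dictionary; all tables are written under
    ``config.out_dir``.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "parameters": {
            k: v for k, v in dataclasses.asdict(config).items() if k not in ("synth",)
        },
        "synth_seed": config.synth.seed,
        "stages_run": [],
        "hashes": {},
    }

    logger.info("stage: synthesis")
    if config.input_dir:
        data = synth.read_fixtures(config.input_dir)
    else:
        data = synth.generate_all(config.synth)
    cohort = data.cohort
    cohort.to_csv(out_dir / "cohort.csv", index=False)
    manifest["hashes"]["cohort"] = _hash_frame(cohort)
    cb = data.config.cerebellar_regions
    cx = data.config.cerebral_regions

    tables = {}
    if "connectivity" in config.stages:
        logger.info("stage: connectivity")
        nets = subject_networks(data, config.include_cerebral)
        tables = networks_to_feature_tables(nets, cohort, config.include_cerebral)
        manifest["stages_run"].append("connectivity")

    if "harmonize" in config.stages and tables:
        logger.info("stage: harmonize")
        site_r2 = {}
        for key in list(tables):
            pre = site_effect_metric(tables[key]).mean()
            tables[key] = combat_adjust(tables[key])
            post = site_effect_metric(tables[key]).mean()
            site_r2["|".join(key)] = {"pre": float(pre), "post": float(post)}
        manifest["site_r2"] = site_r2
        manifest["stages_run"].append("harmonize")

    partition_labels = {}
    if "modules" in config.stages and tables:
        logger.info("stage: module detection (HC multiplex)")
        hc_ids = cohort.loc[cohort["group"] == "HC", "id"]
        morph_tab = tables[("morphological", "cerebellar")]
        func_tab = tables[("functional", "cerebellar")]
        morph_mats = harmonized_matrices(
            FeatureTable(morph_tab.values.loc[hc_ids], morph_tab.site.loc[hc_ids]),
            cb, None, "morphological",
        )
        func_mats = harmonized_matrices(
            FeatureTable(func_tab.values.loc[hc_ids], func_tab.site.loc[hc_ids]),
            cb, None, "functional",
        )
        mx = build_group_multiplex(list(morph_mats.values()), list(func_mats.values()), cb)
        from .multiplex import default_gamma_grid, default_omega_grid

        stability = sweep_parameters(
            mx,
            default_omega_grid(config.omega_step),
            default_gamma_grid(config.gamma_step),
            restarts=config.louvain_restarts,
            seed=config.seed,
        )
        part = select_stable_partition(stability)
        rows = []
        for j, layer in enumerate(part.layer_names):
            for i, node in enumerate(part.nodes):
                rows.append({"node": node, "layer": layer, "module": int(part.labels[i, j])})
        pdf = pd.DataFrame(rows)
        pdf.to_csv(out_dir / "partition.tsv", sep="\t", index=False)
        manifest["hashes"]["partition"] = _hash_frame(pdf)
        manifest["modularity_Q"] = part.quality
        manifest["n_modules"] = part.n_modules
        manifest["omega_gamma"] = [part.omega, part.gamma]
        for layer in part.layer_names:
            partition_labels[layer] = {
                n: f"M{v}" for n, v in part.layer_labels(layer).items()
            }
        manifest["stages_run"].append("modules")
    elif tables:
        # fall back to the reference five-module architecture
        for layer in ("morphological", "functional"):
            partition_labels[layer] = atlas.reference_partition(layer)

    module_nets: dict[str, list] = {}
    taxonomies = {}
    if "aggregate" in config.stages and tables and partition_labels:
        logger.info("stage: module-level networks")
        if data.overlap and config.include_cerebral:
            taxonomies = {
                name: assign_cerebral_modules(table, name)
                for name, table in data.overlap.items()
            }
        for modality in ("morphological", "functional"):
            labels = partition_labels[modality]
            mats = harmonized_matrices(tables[(modality, "cerebellar")], cb, None, modality)
            rect = (
                harmonized_matrices(tables[(modality, "cerebello-cerebral")], cb, cx, modality)
                if config.include_cerebral else {}
            )
            for sid, mat in mats.items():
                net = RegionNetwork(mat, cb, cb, modality, "cerebellar")
                module_nets.setdefault(sid, []).append(
                    within_cerebellar_module_network(net, labels)
                )
                for name, tax in taxonomies.items():
                    rnet = RegionNetwork(rect[sid], cb, cx, modality, "cerebello-cerebral")
                    module_nets[sid].append(
                        cerebello_cerebral_module_network(rnet, labels, tax)
                    )
        manifest["stages_run"].append("aggregate")

    features = pd.DataFrame()
    if module_nets:
        features = build_features(module_nets)
        features.to_csv(out_dir / "module_features.tsv", sep="\t")
        manifest["hashes"]["module_features"] = _hash_frame(features)

    meta = cohort.set_index("id").loc[features.index] if len(features) else None
    if "stats" in config.stages and len(features):
        logger.info("stage: group inference")
        covs = pd.DataFrame({"age": meta["age"], "sex": meta["sex"], "fd": meta["fd"]})
        results = compare_measures(
            features, meta["group"].to_numpy(), covs,
            B=config.n_perm, seed=config.seed, alpha=config.fdr_alpha,
        )
        results.to_csv(out_dir / "group_differences.tsv", sep="\t", index=False)
        manifest["hashes"]["group_differences"] = _hash_frame(results)
        manifest["n_significant"] = int((results["q"] < config.fdr_alpha).sum())
        manifest["stages_run"].append("stats")

    if "genes" in config.stages and len(features) and data.expression is not None:
        logger.info("stage: transcriptomics")
        expr = data.expression
        pairs = [(cb[i], cb[j]) for i in range(len(cb)) for j in range(i + 1, len(cb))]
        contrib = gene_edge_contributions(expr, pairs)
        labels = partition_labels["functional"]
        modules = sorted(set(labels.values()))
        mc = module_contribution_matrix(contrib, pairs, labels, modules)
        gene_results = {}
        func_cols = [c for c in features.columns if c.startswith("functional|cerebellar|")]
        for patient in ("MS", "NMOSD"):
            y = (
                features.loc[meta["group"] == patient, func_cols].mean()
                - features.loc[meta["group"] == "HC", func_cols].mean()
            )
            # align alteration vector with the module-edge columns of mc
            y_vec = []
            for col in mc.columns:
                a, b = col.split("~")
                key = f"functional|cerebellar|{a}~{b}"
                alt = f"functional|cerebellar|{b}~{a}"
                y_vec.append(y.get(key, y.get(alt, np.nan)))
            y_vec = np.asarray(y_vec, float)
            keep = np.isfinite(y_vec)
            if keep.sum() < 5:
                warnings.warn(
                    f"PLS for {patient} skipped: only {int(keep.sum())} usable "
                    "module edges (coarse partition); need at least 5"
                )
                gene_results[patient] = {"r": None, "p": None, "n_selected": 0}
                continue
            res, p = pls1_significance(mc.loc[:, keep], y_vec[keep],
                                       B=config.n_class_perm, seed=config.seed)
            gene_results[patient] = {"r": res.r, "p": p, "n_selected": int(len(res.selected))}
            pd.DataFrame({"weight": res.weights, "Z": res.z,
                          "selected": res.z.abs() > 1.64}).to_csv(
                out_dir / f"pls_genes_{patient}.tsv", sep="\t")
        manifest["pls"] = gene_results
        manifest["stages_run"].append("genes")

    if "classify" in config.stages and len(features):
        logger.info("stage: classification")
        reports = {}
        for pair in (("MS", "HC"), ("NMOSD", "HC"), ("MS", "NMOSD")):
            rep = classify_pair(
                features, meta["group"].to_numpy(), pair,
                folds=config.cv_folds, repeats=config.cv_repeats,
                B=config.n_class_perm, seed=config.seed,
            )
            reports[" vs ".join(pair)] = {
                "accuracy": rep.accuracy, "p": rep.p,
                "modality_share": rep.modality_share,
                "module_share": rep.module_share,
            }
        manifest["classification"] = reports
        manifest["stages_run"].append("classify")

    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=float))
    return manifest
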