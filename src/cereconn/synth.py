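"""Synthetic multi-site cohort generator.

Emulates the statistical structure of a three-group (HC / MS / NMOSD),
multi-site imaging-transcriptomics study so that every downstream stage
of the pipeline can be exercised without any data download:

* a subject metadata table (site, group, disease phase, age, sex, head
  motion, EDSS, disease duration, lesion volume, neuropsychological
  scores with missingness);
* per-subject regional cortical-thickness samples drawn from two-component
  Gaussian mixtures, so that planted effects can alter distribution
  *shape* and not only location (the morphological similarity measure is
  sensitive to the full distribution);
* per-subject regional fMRI time series drawn from multivariate Gaussians
  whose population correlation matrices encode planted functional edges
  per group;
* a gene x region expression matrix with designated "driver" genes whose
  co-expression contribution profile is coupled to the planted
  connectivity alterations.

Everything is deterministic given ``SynthConfig.seed``.  Structural
parameters (per-region baselines, module memberships, site assignment of
nuisance shifts) are fixed constants independent of the seed, so changing
only the seed resamples noise without moving the marginal distributions.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import atlas

__all__ = [
    "EffectSpec",
    "SynthConfig",
    "SynthCohort",
    "module_edges",
    "generate_cohort",
    "generate_thickness",
    "generate_timeseries",
    "generate_expression",
    "generate_alteration",
    "generate_cerebral_overlap",
    "generate_all",
    "write_fixtures",
    "read_fixtures",
]

GROUPS = ["HC", "MS", "NMOSD"]

# Default cohort demographics: realistic group sizes, female-predominant
# patient groups, and age centres/spreads typical of MS/NMOSD cohorts.
DEFAULT_N_PER_GROUP = {"HC": 228, "MS": 208, "NMOSD": 200}
FEMALE_RATE = {"HC": 124 / 228, "MS": 135 / 208, "NMOSD": 175 / 200}
AGE_LOC = {"HC": 37.0, "MS": 36.0, "NMOSD": 41.0}
AGE_SCALE = {"HC": 14.0, "MS": 12.0, "NMOSD": 14.5}
RELAPSING_RATE = {"MS": 48 / 197, "NMOSD": 48 / 195}
PHASE_MISSING_RATE = 16 / 408

# Structural-parameter stream: fixed, deliberately NOT tied to config.seed.
_STRUCT_SEED = 20220327


def module_edges(
    module_a: str, module_b: str | None = None, layer: str = "functional"
) -> list[tuple[str, str]]:
    """All cerebellar region pairs between two modules of the reference partition."""
    part = atlas.reference_partition(layer)
    ra = [r for r, m in part.items() if m == module_a]
    rb = ra if module_b in (None, module_a) else [r for r, m in part.items() if m == module_b]
    if module_b in (None, module_a):
        return [(ra[i], ra[j]) for i in range(len(ra)) for j in range(i + 1, len(ra))]
    return [(a, b) for a in ra for b in rb]


@dataclass(frozen=True)
class EffectSpec:
    """One planted group alteration on a set of edges of one modality.

    ``effect`` is a signed size in pooled-SD units of the corresponding
    subject-level edge feature (morphological similarity, or Fisher-z
    functional correlation).
    """

    edges: tuple[tuple[str, str], ...]
    modality: str  # "morphological" | "functional"
    group: str
    effect: float

    def __post_init__(self):
        if self.modality not in ("morphological", "functional"):
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if not np.isfinite(self.effect):
            raise ValueError("effect size must be finite")


def default_effect_map() -> list[EffectSpec]:
    """Study-like planted alterations: an MS-specific morphological increase
    in the secondary-motor module, a shared patient decrease in the primary
    non-motor module, and group-specific functional decreases."""
    return [
        EffectSpec(tuple(module_edges("SM", layer="morphological")), "morphological", "MS", 0.8),
        EffectSpec(tuple(module_edges("PNM", layer="morphological")), "morphological", "MS", -0.8),
        EffectSpec(tuple(module_edges("PNM", layer="morphological")), "morphological", "NMOSD", -0.8),
        EffectSpec(tuple(module_edges("PNM")), "functional", "MS", -0.8),
        EffectSpec(tuple(module_edges("SM")), "functional", "NMOSD", -0.8),
    ]


@dataclass
class SynthConfig:
    """Full specification of a synthetic cohort; the seed determines everything."""

    n_per_group: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_N_PER_GROUP))
    n_sites: int = 7
    cerebellar_regions: list[str] = field(default_factory=lambda: list(atlas.CEREBELLAR_REGIONS))
    cerebral_regions: list[str] = field(default_factory=lambda: list(atlas.CEREBRAL_REGIONS))
    n_vertices_per_region: int = 100
    n_timepoints: int = 200
    n_genes: int = 15631
    effect_map: list[EffectSpec] = field(default_factory=default_effect_map)
    site_shift: float = 0.3  # SD of per-site additive thickness offsets (in within-region SD units)
    site_scale: float = 0.1  # SD of log per-site multiplicative factors
    n_driver_genes: int = 20
    driver_coupling: float = 0.6  # population correlation of alteration with driver signal
    missing_rate: float = 0.6  # MCAR rate for neuropsychological scores
    subject_z_sd: float = 0.1  # between-subject SD of true edge Fisher-z
    seed: int = 0

    def __post_init__(self):
        for g, n in self.n_per_group.items():
            if g not in GROUPS:
                raise ValueError(f"unknown group {g!r}")
            if n <= 0:
                raise ValueError("group sizes must be positive")
        if self.n_sites <= 0:
            raise ValueError("n_sites must be positive")
        if self.n_timepoints < 50:
            raise ValueError("need at least 50 timepoints")
        if self.n_genes < 100:
            raise ValueError("need at least 100 genes")
        if self.n_vertices_per_region < 10:
            raise ValueError("need at least 10 vertices per region")

    @property
    def regions(self) -> list[str]:
        return self.cerebellar_regions + self.cerebral_regions

    @property
    def gene_ids(self) -> list[str]:
        return [f"G{i:05d}" for i in range(1, self.n_genes + 1)]

    @property
    def driver_genes(self) -> list[str]:
        return self.gene_ids[: self.n_driver_genes]


@dataclass
class SynthCohort:
    """Bundle of everything the generator produces for one configuration."""

    config: SynthConfig
    cohort: pd.DataFrame
    thickness: dict[str, dict[str, np.ndarray]] | None = None
    timeseries: dict[str, np.ndarray] | None = None
    expression: pd.DataFrame | None = None
    overlap: dict[str, pd.DataFrame] | None = None


# ---------------------------------------------------------------------------
# cohort table


def generate_cohort(config: SynthConfig) -> pd.DataFrame:
    """One row per subject: id, site, group, phase, demographics, clinical scores.

    Covariate distributions are fixed by the module-level constants above;
    only sampling noise depends on ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    rows = []
    counter = 0
    for group in GROUPS:
        n = config.n_per_group.get(group, 0)
        for _ in range(n):
            counter += 1
            sid = f"sub-{counter:04d}"
            site = int(rng.integers(config.n_sites))
            age = float(np.clip(rng.normal(AGE_LOC[group], AGE_SCALE[group]), 18, 75))
            sex = "F" if rng.random() < FEMALE_RATE[group] else "M"
            fd = float(rng.lognormal(np.log(0.12), 0.4))
            if group == "HC":
                phase, edss, duration, lesion = "NA", np.nan, np.nan, np.nan
            else:
                if rng.random() < PHASE_MISSING_RATE:
                    phase = "NA"
                else:
                    phase = "relapsing" if rng.random() < RELAPSING_RATE[group] else "remitting"
                if group == "MS":
                    edss = float(np.round(np.clip(rng.lognormal(np.log(2.0), 0.6), 0, 9.5) * 2) / 2)
                    duration = float(rng.lognormal(np.log(19.0), 1.1))
                    lesion = float(rng.lognormal(np.log(7.6), 1.1))
                else:
                    edss = float(np.round(np.clip(rng.lognormal(np.log(3.5), 0.5), 0, 9.5) * 2) / 2)
                    duration = float(rng.lognormal(np.log(36.0), 1.0))
                    lesion = float(rng.lognormal(np.log(1.2), 1.2)) if rng.random() < 0.55 else 0.0
            scores = {}
            base = {"CVLT": (52.0, 8.0), "PASAT": (51.5, 10.0), "BVMT": (28.0, 4.5)}
            drop = {
                "HC": (0.0, 0.0, 0.0),
                "MS": (4.5, 11.5, 1.0),
                "NMOSD": (5.0, 11.5, 6.0),
            }[group]
            for k, (loc, sc), d in zip(base, base.values(), drop):
                val = rng.normal(loc - d, sc)
                scores[k] = np.nan if rng.random() < config.missing_rate else float(val)
            rows.append(
                dict(
                    id=sid, site=site, group=group, phase=phase, age=age, sex=sex,
                    fd=fd, edss=edss, duration=duration, lesion_volume=lesion, **scores,
                )
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# thickness


#: Module-level thickness centres (mm): pairwise-separated so that regions of
#: the same cerebellar module share similar distributions (high within-module
#: morphological similarity) while different modules diverge.
_MODULE_MU = {"PMA": 2.0, "PMB": 2.4, "PNM": 2.8, "SM": 3.2, "SNM": 3.75}


def _region_baselines(regions: list[str]) -> pd.DataFrame:
    """Fixed per-region mixture parameters (independent of the cohort seed).

    Cerebellar regions inherit their centre from their reference module
    (plus a small jitter), embedding the five-module community structure
    in the morphological layer; cerebral regions get independent centres.
    """
    srng = np.random.default_rng(_STRUCT_SEED)
    part = atlas.reference_partition("morphological")
    n = len(regions)
    mu = np.empty(n)
    for i, r in enumerate(regions):
        if r in part:
            mu[i] = _MODULE_MU[part[r]] + srng.normal(0.0, 0.02)
        else:
            mu[i] = srng.uniform(2.0, 3.2)
    sigma = srng.uniform(0.11, 0.14, n)
    delta = srng.uniform(0.1, 0.2, n)  # separation of the two mixture components
    w = srng.uniform(0.5, 0.65, n)  # weight of the first component
    return pd.DataFrame({"mu": mu, "sigma": sigma, "delta": delta, "w": w}, index=regions)


def _site_nuisance(config: SynthConfig) -> tuple[np.ndarray, np.ndarray]:
    srng = np.random.default_rng(_STRUCT_SEED + 1)
    shifts = srng.normal(0.0, 1.0, config.n_sites) * config.site_shift
    scales = np.exp(srng.normal(0.0, 1.0, config.n_sites) * config.site_scale)
    return shifts, scales


def _morph_perturbations(config: SynthConfig) -> dict[tuple[str, str], float]:
    """(group, region) -> planted mean shift in within-region SD units.

    A morphological edge effect is realised by perturbing the *second*
    region of each listed pair in the target group; similarity between the
    pair then departs from the control groups' value.
    """
    out: dict[tuple[str, str], float] = {}
    for spec in config.effect_map:
        if spec.modality != "morphological":
            continue
        for _, r2 in spec.edges:
            key = (spec.group, r2)
            out[key] = out.get(key, 0.0) + spec.effect
    return out


def generate_thickness(
    config: SynthConfig, cohort: pd.DataFrame
) -> dict[str, dict[str, np.ndarray]]:
    """Per-subject, per-region vertex-wise thickness samples.

    Each region follows a two-component Gaussian mixture; planted group
    effects shift the second component of the targeted regions, changing
    both location and shape of the distribution.  Per-site additive and
    multiplicative nuisance is applied on top.
    """
    base = _region_baselines(config.regions)
    shifts, scales = _site_nuisance(config)
    perturb = _morph_perturbations(config)
    rng = np.random.default_rng(config.seed + 1)
    nv = config.n_vertices_per_region
    out: dict[str, dict[str, np.ndarray]] = {}
    mu = base["mu"].to_numpy()
    sigma = base["sigma"].to_numpy()
    delta = base["delta"].to_numpy()
    w = base["w"].to_numpy()
    regions = config.regions
    n_reg = len(regions)
    for row in cohort.itertuples():
        subj_offset = rng.normal(0.0, 0.05)
        comp = rng.random((n_reg, nv)) >= w[:, None]  # True -> second component
        shift2 = np.array(
            [perturb.get((row.group, r), 0.0) for r in regions]
        ) * sigma  # planted effect on the second component, SD units
        means = mu[:, None] + subj_offset + comp * (delta + shift2)[:, None]
        vals = rng.normal(means, sigma[:, None])
        vals = (vals + shifts[row.site] * sigma[:, None]) * scales[row.site]
        vals = np.abs(vals) + 1e-6  # thickness is strictly positive
        out[row.id] = {r: vals[k] for k, r in enumerate(regions)}
    return out


# ---------------------------------------------------------------------------
# time series


def _nearest_psd_corr(corr: np.ndarray, warn: bool = True) -> np.ndarray:
    """Clip negative eigenvalues and renormalise to unit diagonal."""
    vals, vecs = np.linalg.eigh(corr)
    if vals.min() >= 1e-10:
        return corr
    if warn:
        warnings.warn("requested correlation matrix not PSD; projecting to nearest PSD")
    vals = np.clip(vals, 1e-8, None)
    fixed = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(fixed))
    return fixed / np.outer(d, d)


def _population_corr(config: SynthConfig, group: str) -> np.ndarray:
    """Group-level population correlation over all 424 regions.

    Baseline structure: modest within-module correlation on both the
    cerebellar reference modules and synthetic cerebral communities, weak
    background elsewhere; planted functional edges overwrite the baseline
    on a Fisher-z scale.
    """
    regions = config.regions
    idx = {r: i for i, r in enumerate(regions)}
    n = len(regions)
    labels = np.empty(n, dtype=object)
    part = atlas.reference_partition("functional")
    for r in config.cerebellar_regions:
        labels[idx[r]] = "cb_" + part.get(r, "?")
    n_ctx = len(config.cerebral_regions)
    for k, r in enumerate(config.cerebral_regions):
        labels[idx[r]] = "cx_" + str(k * 7 // max(n_ctx, 1))
    same = labels[:, None] == labels[None, :]
    corr = np.where(same, 0.35, 0.08)
    z = np.arctanh(np.clip(corr, -0.999, 0.999))
    dz = np.sqrt(1.0 / (config.n_timepoints - 3) + config.subject_z_sd**2)
    for spec in config.effect_map:
        if spec.modality != "functional":
            continue
        if spec.group != group:
            continue
        for r1, r2 in spec.edges:
            i, j = idx[r1], idx[r2]
            z[i, j] += spec.effect * dz
            z[j, i] = z[i, j]
    corr = np.tanh(z)
    np.fill_diagonal(corr, 1.0)
    return _nearest_psd_corr(corr)


def generate_timeseries(config: SynthConfig, cohort: pd.DataFrame) -> dict[str, np.ndarray]:
    """Per-subject T x 424 Gaussian series with group-specific correlation.

    Subject-level heterogeneity is added as a random Fisher-z perturbation
    of the group template (SD ``subject_z_sd``); per-site multiplicative
    scaling is applied to the series amplitude.
    """
    _, scales = _site_nuisance(config)
    rng = np.random.default_rng(config.seed + 2)
    chols = {}
    templates = {g: _population_corr(config, g) for g in cohort["group"].unique()}
    out = {}
    n = len(config.regions)
    for row in cohort.itertuples():
        base = templates[row.group]
        if config.subject_z_sd > 0:
            pert = rng.normal(0.0, config.subject_z_sd, (n, n))
            pert = (pert + pert.T) / np.sqrt(2.0)
            np.fill_diagonal(pert, 0.0)
            corr = np.tanh(np.arctanh(np.clip(base, -0.999, 0.999)) + pert)
            np.fill_diagonal(corr, 1.0)
            corr = _nearest_psd_corr(corr, warn=False)
            chol = np.linalg.cholesky(corr + 1e-9 * np.eye(n))
        else:
            key = row.group
            if key not in chols:
                chols[key] = np.linalg.cholesky(base + 1e-9 * np.eye(n))
            chol = chols[key]
        white = rng.standard_normal((config.n_timepoints, n))
        out[row.id] = (white @ chol.T) * scales[row.site]
    return out


# ---------------------------------------------------------------------------
# expression


def _alteration_template(config: SynthConfig) -> np.ndarray:
    """Region-level 24x24 planted functional alteration pattern (patients - HC)."""
    cb = config.cerebellar_regions
    idx = {r: i for i, r in enumerate(cb)}
    d = np.zeros((len(cb), len(cb)))
    for spec in config.effect_map:
        if spec.modality != "functional" or spec.group == "HC":
            continue
        for r1, r2 in spec.edges:
            if r1 in idx and r2 in idx:
                d[idx[r1], idx[r2]] += spec.effect
                d[idx[r2], idx[r1]] = d[idx[r1], idx[r2]]
    return d


def generate_expression(config: SynthConfig) -> pd.DataFrame:
    """Gene x cerebellar-region expression matrix with planted driver genes.

    Driver genes share a latent regional profile ``u`` chosen as the
    leading eigenvector of the planted alteration pattern, so that the
    drivers' pairwise-product contributions to regional co-expression
    align with the planted connectivity alterations.  Non-driver genes are
    independent noise.
    """
    genes = config.gene_ids
    drivers = set(config.driver_genes)
    if not drivers.issubset(genes):
        raise ValueError("driver_genes must be a subset of the gene list")
    rng = np.random.default_rng(config.seed + 3)
    n_cb = len(config.cerebellar_regions)
    d = _alteration_template(config)
    if np.any(d):
        vals, vecs = np.linalg.eigh(d)
        u = vecs[:, np.argmax(np.abs(vals))]
        u = u * np.sign(vals[np.argmax(np.abs(vals))])
    else:
        u = np.zeros(n_cb)
    u = (u - u.mean()) / (u.std() + 1e-12) if np.any(u) else u
    rho = 0.85  # profile correlation of each driver with the latent pattern
    mat = rng.standard_normal((config.n_genes, n_cb))
    if np.any(u):
        driver_idx = [genes.index(g) for g in config.driver_genes]
        noise = mat[driver_idx]
        mat[driver_idx] = rho * u[None, :] + np.sqrt(1 - rho**2) * noise
    return pd.DataFrame(mat, index=genes, columns=config.cerebellar_regions)


def generate_alteration(
    contributions: np.ndarray,
    driver_idx: np.ndarray,
    coupling: float,
    seed: int,
) -> np.ndarray:
    """Connectivity-alteration vector with an exact planted association.

    ``contributions`` is the gene x module-edge contribution matrix; the
    mean contribution profile of the driver genes is the signal, and
    Gaussian noise is mixed in so that the in-sample correlation between
    signal and alteration equals ``coupling`` exactly.
    """
    if not 0 <= coupling <= 1:
        raise ValueError("coupling must be in [0, 1]")
    rng = np.random.default_rng(seed)
    s = contributions[driver_idx].mean(axis=0)
    s = s - s.mean()
    ns = np.linalg.norm(s)
    if ns == 0:
        raise ValueError("driver signal is degenerate (all-zero contributions)")
    s = s / ns
    eps = rng.standard_normal(s.size)
    eps = eps - eps.mean()
    eps = eps - (eps @ s) * s  # orthogonalise to the signal
    eps /= np.linalg.norm(eps)
    return coupling * s + np.sqrt(1.0 - coupling**2) * eps


# ---------------------------------------------------------------------------
# cerebral taxonomy overlap counts


def generate_cerebral_overlap(config: SynthConfig) -> dict[str, pd.DataFrame]:
    """Voxel-overlap count tables for both cerebral taxonomies.

    Each ROI overlaps mostly (70-95%) with one dominant module; the
    remainder is spread over the others, mimicking a maximum-overlap
    assignment problem with an unambiguous argmax.
    """
    srng = np.random.default_rng(_STRUCT_SEED + 2)
    out = {}
    n_ctx = len(config.cerebral_regions)
    for name, modules in atlas.TAXONOMIES.items():
        counts = np.zeros((n_ctx, len(modules)), dtype=int)
        for i in range(n_ctx):
            dominant = srng.integers(len(modules))
            total = int(srng.integers(800, 1500))
            frac = srng.uniform(0.7, 0.95)
            main = int(total * frac)
            rest = srng.multinomial(total - main, np.ones(len(modules)) / len(modules))
            counts[i] = rest
            counts[i, dominant] += main
        out[name] = pd.DataFrame(counts, index=config.cerebral_regions, columns=modules)
    return out


def generate_all(config: SynthConfig) -> SynthCohort:
    """Run every generator stage for one configuration."""
    cohort = generate_cohort(config)
    return SynthCohort(
        config=config,
        cohort=cohort,
        thickness=generate_thickness(config, cohort),
        timeseries=generate_timeseries(config, cohort),
        expression=generate_expression(config),
        overlap=generate_cerebral_overlap(config),
    )


# ---------------------------------------------------------------------------
# fixtures on disk


def write_fixtures(data: SynthCohort, directory: str | Path) -> list[Path]:
    """Serialize a synthetic cohort to plain-text fixtures.

    Layout: ``cohort.csv``, ``thickness/<subject>.tsv`` (one row per
    region), ``timeseries/<subject>.tsv`` (T rows, header = region ids),
    ``expression.tsv``, ``overlap_<taxonomy>.csv`` and ``config.json``.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []

    def _w(path: Path):
        written.append(path)
        return path

    data.cohort.to_csv(_w(directory / "cohort.csv"), index=False)
    cfg = dataclasses.asdict(data.config)
    cfg["effect_map"] = [
        {"edges": [list(e) for e in s.edges], "modality": s.modality,
         "group": s.group, "effect": s.effect}
        for s in data.config.effect_map
    ]
    (_w(directory / "config.json")).write_text(json.dumps(cfg, indent=1))
    if data.thickness is not None:
        tdir = directory / "thickness"
        tdir.mkdir(exist_ok=True)
        for sid, regmap in data.thickness.items():
            df = pd.DataFrame.from_dict(regmap, orient="index")
            df.index.name = "region"
            df.to_csv(_w(tdir / f"{sid}.tsv"), sep="\t")
    if data.timeseries is not None:
        sdir = directory / "timeseries"
        sdir.mkdir(exist_ok=True)
        for sid, ts in data.timeseries.items():
            pd.DataFrame(ts, columns=data.config.regions).to_csv(
                _w(sdir / f"{sid}.tsv"), sep="\t", index=False
            )
    if data.expression is not None:
        data.expression.to_csv(_w(directory / "expression.tsv"), sep="\t")
    if data.overlap is not None:
        for name, table in data.overlap.items():
            table.to_csv(_w(directory / f"overlap_{name}.csv"))
    return written


def read_fixtures(directory: str | Path) -> SynthCohort:
    """Round-trip reader for :func:`write_fixtures` output."""
    directory = Path(directory)
    cfg = json.loads((directory / "config.json").read_text())
    cfg["effect_map"] = [
        EffectSpec(tuple(tuple(e) for e in s["edges"]), s["modality"], s["group"], s["effect"])
        for s in cfg["effect_map"]
    ]
    config = SynthConfig(**cfg)
    # "NA" is a literal disease-phase category for non-MS subjects, not a
    # missing value; true missingness is written as empty fields.
    cohort = pd.read_csv(
        directory / "cohort.csv", keep_default_na=False,
        na_values=[""], dtype={"phase": str}, float_precision="round_trip",
    )
    for col in ("age", "fd", "edss", "duration", "lesion_volume", "CVLT", "PASAT", "BVMT"):
        if col in cohort:
            cohort[col] = pd.to_numeric(cohort[col], errors="coerce")
    thickness = None
    if (directory / "thickness").is_dir():
        thickness = {}
        for f in sorted((directory / "thickness").glob("*.tsv")):
            df = pd.read_csv(f, sep="\t", index_col="region", float_precision="round_trip")
            thickness[f.stem] = {r: df.loc[r].to_numpy(float) for r in df.index}
    timeseries = None
    if (directory / "timeseries").is_dir():
        timeseries = {
            f.stem: pd.read_csv(f, sep="\t", float_precision="round_trip").to_numpy(float)
            for f in sorted((directory / "timeseries").glob("*.tsv"))
        }
    expression = None
    if (directory / "expression.tsv").exists():
        expression = pd.read_csv(
            directory / "expression.tsv", sep="\t", index_col=0,
            float_precision="round_trip",
        )
    overlap = {}
    for name in atlas.TAXONOMIES:
        f = directory / f"overlap_{name}.csv"
        if f.exists():
            overlap[name] = pd.read_csv(f, index_col=0)
    return SynthCohort(
        config=config,
        cohort=cohort,
        thickness=thickness,
        timeseries=timeseries,
        expression=expression,
        overlap=overlap or None,
    )
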