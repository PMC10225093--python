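"""Pairwise group classification from cerebellar connectivity profiles.

Linear support-vector classifiers discriminate each pair of groups from
the subjects' module-level connectivity features (within-cerebellar pairs
plus both cerebello-cerebral taxonomies, two modalities; 170 features for
the 5-module / 7+7-module layout).  Accuracy is estimated by stratified
tenfold cross-validation repeated and averaged, significance by label
permutation, and feature contributions are summarized from the mean
absolute SVM weights across folds.  Standardization is fit on training
folds only (no test-fold leakage).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .module_networks import ModuleNetwork

__all__ = [
    "CVResult",
    "ClassificationReport",
    "build_features",
    "crossval_classify",
    "permutation_significance",
    "feature_contributions",
    "classify_pair",
]


@dataclass
class CVResult:
    accuracy: float
    fold_accuracies: np.ndarray
    weights: pd.DataFrame  # one row per fitted fold model, |coef| not yet taken


@dataclass
class ClassificationReport:
    pair: tuple[str, str]
    accuracy: float
    p: float | None
    feature_weight: pd.Series  # mean |weight| per feature
    contributors: pd.Index
    modality_share: dict[str, float] = field(default_factory=dict)
    module_share: dict[str, float] = field(default_factory=dict)


def _vectorize_network(net: ModuleNetwork) -> pd.Series:
    m = net.to_frame()
    if net.taxonomy == "cerebellar" and list(m.index) == list(m.columns):
        names, vals = [], []
        mods = list(m.index)
        for i in range(len(mods)):
            for j in range(i, len(mods)):
                names.append(f"{net.modality}|cerebellar|{mods[i]}~{mods[j]}")
                vals.append(m.iloc[i, j])
        return pd.Series(vals, index=names)
    names = [
        f"{net.modality}|{net.taxonomy}|{a}~{b}" for a in m.index for b in m.columns
    ]
    return pd.Series(m.to_numpy().ravel(), index=names)


def build_features(module_networks: dict[str, list[ModuleNetwork]]) -> pd.DataFrame:
    """Subjects x features table from per-subject module-level networks.

    Every subject must supply the same set of module networks; a missing
    or non-finite measure is reported by subject and feature name.
    """
    rows = {}
    for sid, nets in module_networks.items():
        parts = [_vectorize_network(n) for n in nets]
        rows[sid] = pd.concat(parts)
    table = pd.DataFrame(rows).T
    # a feature undefined for every subject is structural (e.g. the diagonal
    # of a singleton module) and is dropped; partial missingness is an error
    all_nan = table.isna().all()
    if all_nan.any():
        warnings.warn(
            f"dropping {int(all_nan.sum())} structurally undefined feature(s): "
            f"{list(table.columns[all_nan])[:5]}"
        )
        table = table.loc[:, ~all_nan]
    if table.isna().any().any():
        bad = table.isna().stack()
        sid, feat = bad[bad].index[0]
        raise ValueError(f"missing measure {feat!r} for subject {sid!r}")
    const = (table.nunique() <= 1) if len(table) > 1 else pd.Series(False, index=table.columns)
    if const.any():
        warnings.warn(f"dropping {int(const.sum())} constant feature(s)")
        table = table.loc[:, ~const]
    return table


def _pipeline(C: float) -> object:
    return make_pipeline(StandardScaler(), SVC(kernel="linear", C=C))


def crossval_classify(
    features: pd.DataFrame,
    labels,
    folds: int = 10,
    repeats: int = 100,
    seed: int | np.random.Generator = 0,
    C: float = 1.0,
    collect_weights: bool = True,
) -> CVResult:
    """Repeated stratified k-fold accuracy of a linear SVM.

    Feature standardization is refit inside every training fold.  The
    returned weights table has one row per fitted fold model (used by
    :func:`feature_contributions`).
    """
    x = features.to_numpy(float)
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < folds:
        raise ValueError(
            f"class {classes[counts.argmin()]!r} has {counts.min()} subjects, fewer than {folds} folds"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    accs, weights = [], []
    for _ in range(repeats):
        skf = StratifiedKFold(n_splits=folds, shuffle=True,
                              random_state=int(rng.integers(2**31 - 1)))
        for tr, te in skf.split(x, y):
            clf = _pipeline(C)
            clf.fit(x[tr], y[tr])
            accs.append(clf.score(x[te], y[te]))
            if collect_weights:
                weights.append(clf.named_steps["svc"].coef_.ravel())
    accs = np.asarray(accs)
    wdf = pd.DataFrame(weights, columns=features.columns) if collect_weights else pd.DataFrame()
    return CVResult(float(accs.mean()), accs, wdf)


def permutation_significance(
    features: pd.DataFrame,
    labels,
    B: int = 1000,
    seed: int = 0,
    folds: int = 10,
    obs_repeats: int = 10,
    perm_repeats: int = 1,
    C: float = 1.0,
) -> tuple[float, float]:
    """Label-permutation significance of the cross-validated accuracy.

    ``p = (1 + #{acc_perm >= acc_obs}) / (B + 1)`` with the null accuracies
    obtained by re-running the cross-validation on shuffled labels.
    """
    rng = np.random.default_rng(seed)
    y = np.asarray(labels)
    obs = crossval_classify(features, y, folds, obs_repeats, rng, C, collect_weights=False).accuracy
    null = np.empty(B)
    for b in range(B):
        perm = rng.permutation(len(y))
        null[b] = crossval_classify(
            features, y[perm], folds, perm_repeats, rng, C, collect_weights=False
        ).accuracy
    p = float((1.0 + np.count_nonzero(null >= obs - 1e-12)) / (B + 1.0))
    return obs, p


def _cerebellar_modules_of(feature: str) -> list[str]:
    modality, block, edge = feature.split("|")
    a, b = edge.split("~")
    if block == "cerebellar":
        return [a] if a == b else [a, b]
    return [a]  # cerebello-cerebral: the cerebellar side


def feature_contributions(
    weights: pd.DataFrame, pair: tuple[str, str], accuracy: float, p: float | None = None
) -> ClassificationReport:
    """Summaries of contributing features from fold-wise SVM weights.

    Contributors are features whose mean absolute weight exceeds the mean
    plus one SD across features; shares are reported by modality and by
    cerebellar module (an off-diagonal within-cerebellar edge counts half
    toward each of its two modules, so shares sum to one).
    """
    mean_abs = weights.abs().mean(axis=0)
    thresh = mean_abs.mean() + mean_abs.std(ddof=0)
    contributors = mean_abs.index[mean_abs > thresh]
    report = ClassificationReport(pair, accuracy, p, mean_abs, contributors)
    if len(contributors) == 0:
        warnings.warn("no feature exceeds the contribution threshold; shares undefined")
        return report
    modality_counts: dict[str, float] = {}
    module_counts: dict[str, float] = {}
    for f in contributors:
        modality = f.split("|")[0]
        modality_counts[modality] = modality_counts.get(modality, 0.0) + 1.0
        mods = _cerebellar_modules_of(f)
        for m in mods:
            module_counts[m] = module_counts.get(m, 0.0) + 1.0 / len(mods)
    n = float(len(contributors))
    report.modality_share = {k: v / n for k, v in modality_counts.items()}
    report.module_share = {k: v / n for k, v in module_counts.items()}
    return report


def classify_pair(
    features: pd.DataFrame,
    groups,
    pair: tuple[str, str],
    folds: int = 10,
    repeats: int = 100,
    B: int = 1000,
    seed: int = 0,
    C: float = 1.0,
) -> ClassificationReport:
    """Full pairwise discrimination: accuracy, permutation p, contributions."""
    groups = np.asarray(groups)
    mask = np.isin(groups, pair)
    sub = features.loc[mask]
    y = groups[mask]
    cv = crossval_classify(sub, y, folds, repeats, seed, C)
    _, p = permutation_significance(sub, y, B=B, seed=seed + 1, folds=folds, C=C)
    return feature_contributions(cv.weights, pair, cv.accuracy, p)
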