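# Methods

This document records the models, assumptions, parameters and numerical
choices behind each component of `cereconn`, and its known limitations.
All problem sizes quoted here are the package's own defaults and can be
changed through `SynthConfig` / `PipelineConfig`.

## 1. Atlas and problem sizes

The cerebellar cortex is modeled as 24 regions: 12 lobules (I–II, III,
IV, V, VI, Crus I, Crus II, VIIb, VIIIa, VIIIb, IX, X) × 2 hemispheres.
The cerebral cortex is modeled as 210 regions. Two cerebral taxonomies
are supported for cerebello-cerebral aggregation: a 7-class
cytoarchitectonic grouping (PM, AC1, AC2, PSS, PS, LB, IC) and the
7-network functional grouping (VN, SMN, DAN, VAN, LN, FPN, DMN). The
reference cerebellar module architecture has five modules — PMA, PMB,
PNM, SM, SNM — with Lobule X assigned to PMA in the morphological layer
and SNM in the functional layer.

## 2. Synthetic cohort generator (`synth`)

The generator is the package's data source; its defaults define a
study-sized cohort: 228 HC, 208 MS, 200 NMOSD over 7 sites, 100
thickness vertices per region, 200 time points, 15 631 genes.

* **Demographics.** Age ~ truncated normal per group; sex with
  group-specific female fractions (both MS and NMOSD are
  female-predominant); head motion (mean framewise displacement) with
  small group shifts; EDSS, disease duration and lesion volume for
  patients; three cognitive scores (CVLT, PASAT, BVMT) observed in only a
  subset of subjects (60 % MCAR missingness by default, mimicking an
  optional assessment).
* **Thickness.** Per-region vertex samples from region-specific
  baselines; group effects perturb the thickness distribution of
  regions named in an effect map; sites add an additive offset (SD 0.3
  within-region SD units) and a multiplicative factor
  (log-SD 0.1).
* **Time series.** Multivariate Gaussian draws from a group-level
  correlation matrix built from the planted module architecture
  (higher within-module correlation), projected to the nearest
  positive-semidefinite correlation matrix when perturbations push it
  outside the cone; per-subject Fisher-z jitter (SD 0.1) and site
  effects on the z scale.
* **Expression.** Gene × region matrix, i.i.d. normal profiles except
  20 driver genes whose profiles correlate (ρ = 0.85) with a latent
  alteration template.
* **Alterations.** `generate_alteration` mixes the drivers' mean
  contribution profile with orthogonalized noise so that the in-sample
  correlation equals the requested coupling exactly.

Fixtures round-trip: `write_fixtures`/`read_fixtures` use
`float_precision="round_trip"` and explicit NA handling so a cohort
written to CSV and read back is bit-identical (verified by content
hashes in the pipeline manifest).

## 3. Connectivity (`connectivity`)

* **Morphological.** For each region, a Gaussian KDE (Scott's rule) of
  the thickness vertex samples is evaluated on a 256-point grid shared
  by the pair (spanning both regions' ranges plus 3 bandwidths).
  Connectivity is `1 − JSD(p, q)` with the Jensen-Shannon divergence in
  bits; JSD is clipped to [0, 1] against floating-point excursions.
  The optional `sqrt_metric` flag returns `1 − sqrt(JSD)` (the metric
  form); the default is the divergence form.
* **Functional.** Pearson correlation of regional time series. All
  averaging, harmonization and group statistics on functional edges
  happen on the Fisher-z scale (`arctanh`), back-transformed for
  display; morphological similarities are averaged on their natural
  scale.

## 4. Site harmonization (`harmonize`)

Parametric empirical-Bayes ComBat: feature-wise standardization against
a design matrix containing site indicators and protected biological
covariates (group, age, sex; categorical covariates dummy-coded),
empirical-Bayes shrinkage of per-site location (normal prior) and scale
(inverse-gamma prior) via the standard iterative solution (convergence
10⁻⁴ on the relative change, matching the reference parametric
implementation including its signed-denominator convergence criterion),
then adjustment and back-transformation. The implementation reproduces
the reference R implementation to < 10⁻⁶ on a frozen oracle fixture
(`tests/data/combat_*.csv`).

Notes: ComBat is *not* exactly idempotent — a second pass makes further
(much smaller) adjustments because shrunken estimates differ from
zero — and it does not drive the residual site R² exactly to zero; the
pipeline reports `site_effect_metric` (per-feature R² of site after
regressing out covariates) before and after instead of assuming
perfection.

## 5. Multiplex module detection (`multiplex`)

* **Group multiplex.** The morphological layer is the element-wise mean
  over HC subjects; the functional layer is averaged on the Fisher-z
  scale and back-transformed; negative functional weights are zeroed
  (unsigned modularity).
* **Multilayer modularity.** For layers s with adjacency A⁽ˢ⁾, degrees
  k, layer volume 2mₛ, resolution γ and categorical inter-layer
  coupling ω between every pair of layers,
  `Q = (1/2μ) Σ_ijs [A⁽ˢ⁾_ij − γ k_i k_j / 2mₛ] δ(g_is, g_js) + (1/2μ) Σ_i Σ_{s≠r} ω δ(g_is, g_ir)`
  with `2μ = Σ_s 2mₛ + ωNL(L−1)`. The supra-modularity matrix indexes
  node-layer (s·N + i).
* **Optimizer.** Greedy Louvain-style moves on the supra matrix with
  random node order and aggregation, best of `restarts` random
  restarts. On small instances it attains the exhaustive optimum over
  all set partitions of the node-layer set (verified in the acceptance
  tests).
* **Stability selection.** The (ω, γ) plane is swept on grids
  ({0.01} ∪ step…1) × ({0.01} ∪ step…3), default steps 0.05/0.1. For
  each cell the mean VI (bits) to its 4-neighbors is recorded; cells at
  or below the 10th percentile form plateaus (4-connected components);
  the minimum-VI cell of the largest plateau is selected.
* **VI.** `VI = Σ p_ij [log2(p_i/p_ij) + log2(p_j/p_ij)]`, a form whose
  terms vanish exactly on identical partitions (no catastrophic
  cancellation), invariant to label permutation, and a metric.

Limitation: the degenerate all-in-one-module solution is perfectly
stable at high ω and can win the plateau competition when the group
network is noisy (small cohorts); with ≥ 15–20 HC subjects at the
default grids the five-module architecture is recovered. Lobule X is
planted layer-dependent, but on the selected plateau the optimizer
favors layer-consistent assignments, so the recovered partition differs
from the planted one by the Lobule X pair (VI ≈ 0.28 bits); plateaus at
lower ω recover the planted labeling exactly.

## 6. Module-level networks (`module_networks`)

Within-cerebellar 5×5 networks average region-level edges between (and
within) modules, excluding self-edges on the diagonal; functional edges
are pooled on the Fisher-z scale. Cerebello-cerebral 5×7 networks do
the same for cerebellar-module × cerebral-class blocks, with cerebral
regions assigned to classes by argmax vertex overlap (ties logged).
A single-region module has an undefined (NaN) within-module diagonal;
downstream feature building drops such structurally undefined columns
with a warning.

## 7. Group inference (`inference`)

* **Omnibus.** Permutation F-test on covariate residuals
  (Freedman–Lane style: residualize y on covariates incl. intercept,
  permute residuals, recompute the between/within-group F), with
  `p = (1 + #{F* ≥ F}) / (B + 1)`; default B = 10 000. The test is
  calibrated: simulated type-I error at α = 0.05 is within ±0.01
  (verified in the acceptance tests).
* **FDR.** Benjamini–Hochberg step-up over the panel of measures.
* **Post-hoc.** Pairwise permutation tests with BH correction,
  condensed into pattern labels; groups that do not differ are
  bracketed, ordered by descending adjusted mean — e.g.
  `MS < [NMOSD = HCs]`, `[MS = NMOSD] < HCs`, or a full ordering.
* **Clinical correlations.** Spearman partial correlation: both the
  variables and the covariates are rank-transformed before
  residualization (matching standard partial-Spearman definitions);
  p from the t-distribution on n − 2 − k df.
* **Demographics.** Pearson chi-squared without Yates continuity
  correction.

## 8. Imaging transcriptomics (`transcriptomics`)

Gene expression is standardized per region across genes. The
co-expression of an edge (a, b) is `Σ_g z_ga z_gb / (G − 1)`; the
per-gene contribution `z_ga z_gb / (G − 1)` decomposes it exactly
(machine precision). Contributions are pooled to module edges by the
same pooling as the networks. PLS1 takes the gene × edge contribution
matrix X and an alteration vector y (edge-wise group difference of
functional connectivity): the single component has weights
`w ∝ X_c' y_c`, scores `X_c w`, and the component-score/alteration
correlation r is tested by permuting y over edges
(`p = (1 + #{r* ≥ r}) / (B + 1)`). Genes with |Z| > 1.64 on the
standardized weights are selected; hypergeometric tests give class
enrichment.

Limitation (identifiability): when the number of genes G far exceeds
the number of edges n and gene profiles are unstructured, X_c X_c' ≈ cI
and *any* y — including permuted ones — achieves a high in-sample r, so
the permutation test has no power even when driver genes rank first.
Significance requires shared (low-rank) structure across gene profiles
or G comparable to n. The gene ranking/recall is robust in both
regimes. The pipeline reports r and p descriptively and skips the PLS
with a warning when fewer than 5 usable module edges exist.

## 9. Classification (`classify`)

Features: within-cerebellar module pairs (15) plus 5×7 blocks for each
cerebral taxonomy (35 + 35), × 2 modalities = 170 features in the full
layout. Linear SVM (C = 1) with feature standardization fit inside each
training fold; stratified k-fold (default 10 folds, 100 repeats)
accuracy; label-permutation significance (default B = 1000).
Contributing features are those whose mean |weight| across fold models
exceeds the mean + 1 SD over features; shares are reported per modality
and per cerebellar module (an off-diagonal within-cerebellar edge
counts ½ toward each module). Chance level and fold-count constraints
are enforced (each class needs at least `folds` members).

## 10. Pipeline (`pipeline`, `cli`)

`run_pipeline` chains: synthesis (or fixture reading) → subject
networks → vectorized feature tables → ComBat per table → HC multiplex
and module detection → module-level networks → permutation inference
with FDR → PLS transcriptomics → pairwise classification. Outputs:
`cohort.csv`, `partition.tsv`, `module_features.tsv`,
`group_differences.tsv`, per-contrast PLS gene tables, and
`manifest.json` with stages run, site R² before/after, modularity,
classification summaries and content hashes (SHA-256 prefixes of the
serialized tables). Identical configurations reproduce all hashes bit
for bit. A single integer seed drives every stochastic step through
separate deterministic substreams.

Configuration is validated against a typed schema (unknown keys, wrong
types and unknown stages are rejected). The `cereconn` CLI exposes
`synth`, `run` and `check-config`; the importable API is the primary
interface.

## 11. Testing and verification

* Unit and property tests (hypothesis, derandomized) cover each module
  against hand-computed values and independent oracles (scipy,
  networkx modularity, pingouin partial correlations, a frozen
  reference ComBat fixture, exhaustive set-partition enumeration for
  multilayer modularity).
* `tests/test_acceptance.py` verifies the end-to-end claims: JSD
  identities against brute force, optimizer optimality, VI metric
  properties, five-module recovery with stability selection,
  harmonization efficacy and oracle agreement, permutation-test
  calibration and FDR control, exact gene decomposition, PLS driver
  recovery under a low-rank model, classifier sanity (separable, null,
  leakage canary), and demographic chi-squared values.
* `scripts/acceptance.py --seed S --out F` recomputes the headline
  quantities from scratch and writes them as JSON.
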