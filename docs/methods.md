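# Methods

`lymphomap` implements a modular transcriptome-mapping workflow for
bulk expression cohorts: a self-organizing map (SOM) compresses the
gene dimension into a two-dimensional grid of metagenes, every sample
becomes a grid-shaped "portrait" of its expression state, and the map
is then decomposed into spot modules of co-expressed genes that drive
sample stratification (pattern types), functional annotation
(enrichment, cancer hallmarks), prognosis (hazard-ratio maps) and
phenotype similarity structures (networks and trees).

## Preprocessing

The pipeline starts from a calibrated log2 gene × sample matrix.
Quantile normalization maps every sample onto the common reference
distribution (row mean of sorted columns; ties receive the mean of the
reference values at their tied ranks, making the transform idempotent
and deterministic). Centralization subtracts each gene's cohort mean
(median optional), so portraits render differential expression Δe.
Missing values are rejected at load time — with no principled
imputation rule for this data type, failing loudly beats guessing.

## SOM portraits

`train_som` runs the classic online Kohonen algorithm in sample space:
each gene's expression profile is presented in seeded random order, the
best-matching unit (Euclidean distance, ties to the lowest unit index)
and its Gaussian grid neighborhood move toward the profile. Defaults:

| parameter | default | note |
|---|---|---|
| grid | 50 × 50 (tests use 10–20 per side) | K = rows × cols metagenes |
| epochs | 20 | sweeps over all genes |
| learning rate | 0.3 → 0.05, exponential decay | |
| neighborhood radius | max(rows, cols)/2 → 0.7, exponential decay | radius 0 ⇒ online k-means |
| initialization | linear along the first two PCs | deterministic; seed only affects presentation order |

The schedule was chosen so the map spends comparable time at every
organization scale and keeps enough late plasticity for a tight cluster
of co-regulated genes to occupy several units rather than collapsing
into one; with a linear anneal and a timid learning rate (e.g.
0.05 → 0.01) planted 60-gene modules degenerate to single-unit spots
that no segmentation can size-filter robustly. Radius-0 equivalence to
online k-means is covered by a test against an independently coded
oracle.

A sample's portrait takes, per unit, the mean expression of the genes
assigned to it; units without genes inherit the trained codebook value
and are flagged *interpolated*. Group and PAT portraits are plain
element-wise means.

## Spot modules

Over-expression spots are connected components (8-connectivity;
4 optional) of units exceeding 90% of the portrait's maximum, computed
on class-mean portraits; components below `min_size` (default 2 units)
are dropped as speckle. Interpolated units are excluded from masks: a
unit that owns no genes cannot evidence a co-expression module, and its
codebook value interpolates between neighboring modules, which would
otherwise bridge two modules that are co-activated in the same class.

The per-class masks are unioned into the summary map. Because a spot
module is by definition a cluster of *correlated* metagenes, a
connected component whose units fall into clearly distinct profile
groups — two modules co-activated in one class and touching on the
grid — is split by complete-linkage clustering of the unit codebook
profiles at correlation 0.5 (`split_r`; complete linkage so that mixed
boundary units cannot chain two modules together). Modules are labeled
A, B, C, … by decreasing peak height, ties broken by the row-major
coordinate of the peak.

Per-sample spot calling is a different decision problem from boundary
drawing: class means are low-noise, single-sample portraits are not.
A module is called in a sample when the sample's own segmented spots
overlap the module's units, with a default per-sample threshold of 50%
of the portrait maximum and `min_size` 1 — on the centralized scale an
active module sits at the portrait maximum and an inactive one is
strongly negative, so the halfway point separates the two levels by
several standard errors in either direction, whereas a 90% per-sample
criterion sits on top of the noise and drops genuinely active modules
at an appreciable rate.

Spot statistics follow directly from the boolean sample × module
incidence: class-association fractions, per-class spot-count
distributions, and association-rule co-occurrence (joint probability,
confidence, lift; lift undefined at zero marginals).

## Pattern types (PATs)

A sample's raw PAT is its sorted called-module combination ("A B D").
A raw PAT is retained only if at least `min_cases` (default 5) samples
of at least one subtype carry it; carriers of rejected PATs and
spotless samples are rescued into the retained PAT whose centroid they
correlate with at Pearson r > 0.8 (`r_rescue`), else labeled ∅. The
rescue space is the module-expression vector (per-module mean over
member genes), chosen over full-portrait space for robustness and
speed; centroids are computed once from by-spot members (no iterative
reassignment), and the rare-PAT test runs once before any rescue.
PATs are grouped by their most characteristic module (highest member
support, ties alphabetical); ∅ samples can be distributed into groups
by nearest group-mean portrait (Euclidean, ties to the lowest-sorting
label).

## Enrichment and hallmarks

Spot-module gene lists are tested against GMT collections with the
right-tailed Fisher exact test (upper hypergeometric tail; universe =
all genes in the trained model), with Benjamini–Hochberg FDR reported
alongside the raw p-values. The gene-set Z-score (GSZ) used for
set-expression profiles is the parameter-free standardized mean:
z(s) = (mean over set members − mean over all genes) / (SD over all
genes / √n_set), per sample. Published GSZ variants add tunable
variance priors; the parameter-free form is used because it has a
closed form that tests can verify exactly.

Hallmark scoring pools each of the eight hallmark signatures
(angiogenesis, controlling genomic instability, glucose energetics,
inflammation, invasion and metastasis, proliferation, replicative
immortality, resisting death) into one gene list, scores it per sample
with GSZ, and averages per entity (sample-level by default; any
grouping such as PATs can be passed). Hallmark types are Ward/Euclidean
agglomerative clusters of the 8-vectors (deterministic, no random
initialization), cut at k (default 5) and labeled HT1…HTk by
decreasing mean proliferation score.

## Survival

The Cox proportional-hazards fit maximizes the Efron-tied partial
likelihood by Newton iteration with step halving, converging at
gradient ∞-norm < 1e-8; tie blocks are vectorized so the fit stays
around a millisecond at n ≈ 400, which the prognostic map needs (one
fit per grid unit, and 20 more maps for its permutation null).
Monotone likelihoods (perfect separation) are flagged rather than
reported as converged; zero events raise. lifelines serves as an
independent cross-check in the test suite and provides the
Kaplan–Meier estimator.

The prognostic map dichotomizes each unit's metagene value at the
cohort median (strictly greater → high arm; median ties fall low,
documented because ties are common on small grids) and stores the high
vs low hazard ratio and Wald p per unit. Units with fewer than 10
samples or 5 events per arm are flagged undefined. Therapy adjustment
(chemotherapy, rituximab as binary co-factors) is off by default; when
enabled, cases without therapy information are dropped from the
adjusted fits only. Pairwise stratum comparisons use an indicator
covariate per pair (1 for the alphabetically later stratum, so label
swaps invert the HR), flag significance at p < 0.01, and record
adjusted results separately.

## Similarity structures

The correlation network connects portrait pairs with Pearson r above a
threshold (default 0.5); constant portraits are flagged and isolated.
Phenotype trees are neighbor-joining trees on d = 1 − r (Euclidean
optional) — anti-correlated phenotypes are maximally distant, matching
the over/under-expression semantics — with negative branch lengths
clamped to zero. The same operation serves samples, class means and
PAT means.

## Synthetic cohorts

The generator plants the exact statistical structure the pipeline
assumes: disjoint modules of `genes_per_module` genes whose mean is
shifted additively by `module_effect` (log2) in samples of classes that
activate them, over a baseline of 8.0 log2 units (typical microarray
scale) with i.i.d. Gaussian noise; survival times are exponential with
hazard `baseline_hazard · exp(Σ active-module betas)` and independent
exponential censoring calibrated by bisection to the requested censored
fraction; binary therapy covariates are independent of hazard by
default (a confounded mode exists); a tonsil-contamination-like shared
module can be switched on. Everything is deterministic given the seed.

Default conditions: 5,000 genes, 8 modules × 60 genes, effect 2.0,
noise SD 0.5, six classes of 50 samples. The class design activates
every module in exactly two classes — four two-module classes and two
four-module classes with pairwise-distinct membership signatures — for
three reasons: equal module prevalence (1/3) gives equal centralized
spot heights within each class, which the 90% segmentation criterion
requires; distinct signatures keep every module statistically
identifiable; and the combination classes exercise the combinatorial
PAT machinery. The factorial survival configuration (4 modules, all
2⁴ activation combinations × 25 samples) serves hazard-recovery
studies: prevalence 1/2 aligns the HR map's median dichotomization with
module activation, and pairwise independence keeps the planted hazard
of one module out of the other modules' map regions — in a partition
design, a module complementary to the hazardous one would show
HR ≈ 1/exp(β) purely by anti-correlation.

What the generator does **not** emulate: probe-level effects, batch
structure, graded within-module amplitudes, correlated noise, realistic
immune-cell mixtures, non-exponential survival. Passing recovery tests
therefore demonstrates the machinery is correct under its own model
assumptions, not that real cohorts decompose this cleanly; on real
data, spot counts and PAT structure are data-dependent outcomes, not
targets.

## Numerical and degenerate-input choices

- BMU and nearest-centroid ties: lowest index / lowest-sorting label.
- Empty grid units: allowed, flagged, interpolated in portraits,
  excluded from segmentation masks.
- Segmentation with no positive value: empty result (no
  over-expression on the centralized scale), not an error.
- Cox: constant covariate columns rejected; |β| > 20 flags monotone
  likelihood; Hessian inversion failures yield NaN standard errors.
- GSZ requires ≥ 2 set members present in the matrix.
- NJ negative branch lengths clamped to 0 and logged.
- All randomness flows from `numpy.random.default_rng` seeded via
  `SeedSequence`; pipeline reruns are checksum-identical.

## Problem sizes used in the test and acceptance runs

Recovery studies run 5,000 genes × 300 samples on a 20 × 20 map
(40 epochs), the survival study 2,000 genes × 400 samples on 16 × 16,
and unit tests use 400–800-gene cohorts on 7–10-unit-wide maps; these
sizes keep each full study in the minutes range on a single CPU while
leaving every module with enough genes (and every unit with enough
members) for the statistics to be in their working regime.
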