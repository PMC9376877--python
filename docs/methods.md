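# Methods

`mxad` implements a two-layer (gray matter × amyloid) multiplex
connectome analysis for cross-sectional cohorts along the Alzheimer's
disease continuum, together with a synthetic cohort generator that makes
every stage testable without controlled-access subject data.

## Subject-level preprocessing

**CSF rules.** The Elecsys CSF Aβ42 immunoassay is not validated above
1700 pg/ml, so values above that ceiling are replaced by 1700 pg/ml
(`clamp_csf`). Amyloid positivity is CSF Aβ42 strictly below
976.6 pg/ml (`classify_abeta`). Both rules are exact thresholds, not
tunables.

**TIV adjustment.** Subcortical volumes (bilateral hippocampus and
amygdala) are corrected for head size by
`adjusted_i = observed_i − β·(TIV_i − mean TIV)`, where β is the
per-region least-squares slope of volume on TIV. The subjects defining β
are configurable; the default is the amyloid-negative control group, the
common choice for estimating a nuisance slope free of disease effects.
The centering mean is the TIV average over all analyzed subjects.

**Residualization.** Regional values are residualized on
[intercept, age, sex] by OLS before network construction, within each
diagnostic group independently (networks are per-group objects). Sex
coding is {0, 1}; residuals are affine-invariant to the coding, which is
asserted by test.

**Missing data** are rejected, never imputed.

## Network construction

Each layer's edge weight between two regions is the Pearson correlation
of their age/sex-residualized values across the subjects of one group —
equivalent to the partial correlation given those covariates. A full
72-node inverse-covariance estimate is deliberately *not* used: with
groups as small as 67 subjects a 72×72 precision matrix is ill-posed,
and only age and sex are controlled.

Binary layers keep exactly `round(D·N(N−1)/2)` edges at each density D
of the 2–30% grid (1% steps), ranking edges by signed weight descending
(strongest positive covariance first; absolute-value ranking is
available). Ties break by lexicographic node pair so edge sets are
reproducible. Both layers and all groups are therefore compared at
identical edge counts, and edge sets are nested along the grid. The 2%
lower bound keeps the edge count above the node count; the 30% upper
bound is where the layers still behave as small-world graphs
(σ = (C/C_rand)/(L/L_rand) > 1 against 20 Maslov–Sneppen
degree-preserving rewirings; path length uses the largest component,
flagged when it covers < 90% of nodes, as proportional thresholding of
block-structured covariance can split a layer into its modules).

## Multiplex measures

With M = 2 layers, per node i:

* **Overlapping strength** `s_i = s_i^[1] + s_i^[2]` (weighted). Negative
  partial correlations are zeroed by default before summing, matching
  the binarization convention and keeping s_i ≥ 0; raw and absolute
  handling are exposed as options since covariance studies differ here.
* **Degree overlap** `d_i = Σ_j a_ij^[1] a_ij^[2]` (binary): connections
  present in both layers.
* **Multiplex participation**
  `p_i = (M/(M−1))·[1 − Σ_α (k_i^[α]/o_i)²]` with overlapping degree
  `o_i = Σ_α k_i^[α]`; p = 1 for equal nonzero layer degrees, 0 when only
  one layer carries edges. Nodes isolated in both layers are a 0/0 case
  and are assigned p = 0, flaggable via o_i = 0.
* **Multiplex clustering** `c_i`: ratio of 2-triangles with a vertex in i
  (edges i–j and m–i in one layer, j–m in the other, summed over ordered
  layer and node pairs) to `(M−1)·Σ_α k_i^[α](k_i^[α]−1)` 1-triads; the
  cube root in the defining weighted expression is the identity for 0/1
  edges and is retained for weighted generality. c = 0 when the
  denominator vanishes.

All four are checked against exhaustive brute-force oracles to 1e−12.

## Multilayer communities

Community structure is found by maximizing the two-layer multilayer
modularity

    Q = (1/2μ) Σ_{supra pairs in same community} [ w_ij^[α] − γ·w0_ij^[α] + coupling ]

with Newman–Girvan nulls `w0_ij^[α] = s_i^[α] s_j^[α] / (2m^[α])` — the
closed-form expectation of a strength-preserving randomization of each
layer, used instead of explicit rewiring for determinism — an ω coupling
entry for each node's two replicas (contributing 2ω per node whose
labels agree across layers), and μ = m¹ + m² + ωN. Any positive global
rescaling of μ leaves the argmax unchanged; Q values are comparable
across implementations only up to this normalization convention, which
is recorded in the output metadata.

Optimization is a generalized Louvain over the 2N-node supra-modularity
matrix: greedy label moves to the best-gain community until a full sweep
makes no move, then community aggregation, repeated until the partition
is a fixed point. The best of 100 seed-controlled restarts (by Q, ties
to first found) is kept; runs are deterministic given the seed. The
ω = 0 limit is cross-checked against networkx single-layer modularity.

**Persistence** is the fraction of nodes keeping the same label in both
layers. **Partition distance** is the variation of information
H(A|B) + H(B|A), normalized by log of the number of elements; 0 iff the
partitions agree up to relabeling.

**(γ, ω) selection.** Partitions are computed over
γ ∈ {0.5, 0.8, 0.9, 1, 1.1, 1.2, 2} × ω ∈ {0.25, 0.5, 0.75, 1} and
compared pairwise by normalized VI. As an automatic rule the selected
grid point minimizes the mean VI to all other points (the most stable,
representative partition); this is a documented stand-in for a manual
reading of the VI matrix alongside the module counts, and the
study-like default (γ = 1, ω = 1) can always be imposed.

## Group inference

Group differences in nodal measures are tested by subject-reallocation
permutation: subjects (with their covariates and both modalities) are
randomly split into two pseudo-groups of the original sizes and the
*entire* construction — residualization, partial correlation,
binarization at every density — is rerun per replicate, since anything
less would change the null. Two-tailed p-values use the add-one
convention `p = (#{|null| ≥ |obs|} + 1)/(n_perm + 1)` (never exactly 0,
and equivalent at α = 0.05 to thresholding by the null's 95% critical
values). Binary-measure p-values are averaged across the 29 densities
per region; Benjamini–Hochberg FDR is then applied across the 72
regions at q = 0.05, separately per measure and contrast (families are
not pooled). Default 10,000 replicates with a fast mode (1,000) for
development-scale runs.

## Synthetic cohort generator

The generator emulates the *statistical* structure the pipeline
consumes, not real anatomy:

* four groups of 135/67/179/132 subjects, 72 regions;
* per group per layer, a planted-partition correlation matrix —
  within-module correlation 0.45, between-module 0.10, unit diagonal,
  projected to the nearest positive-definite matrix if needed. The
  MCI-like group carries 3 planted modules, the others 2, mirroring the
  module counts such a cohort is expected to show;
* cross-layer agreement of the planted partitions set per group
  (defaults 0.88/0.85/0.97/0.97, the persistence regime expected of such
  data): a `1 − agreement` fraction of regions is reassigned to a
  different module in the amyloid layer;
* amyloid-positive groups get every amyloid-layer correlation raised by
  `amyloid_effect` (default 0.15), planting a connectivity-strength
  group difference;
* regional values are Gaussian around modality-typical means (thickness
  2.5 ± 0.15 mm; hippocampus/amygdala volumes ~3.8/1.6 × 10³ mm³ ± 400;
  SUVR group means 1.05–1.40 ± 0.15) — Gaussianity is the minimal
  sufficient structure for Pearson-based edges;
* linear age/sex effects and multiplicative TIV scaling of subcortical
  volumes provide the confounding the preprocessing removes;
* CSF Aβ42 is drawn from truncated normals around group medians
  (1587/753/686/585 pg/ml) so amyloid-positive groups fall strictly
  below the 976.6 cutoff and the negative group above it — CSF
  stratification reproduces the configured group sizes exactly, while
  draws above 1700 pg/ml exercise the assay ceiling.

Everything is deterministic given the config seed.

### Test fixtures and what they show

**Calibration fixture** (`null_fixture_config`): one 160-subject group
split randomly in half; any two-group test must reject at its nominal
rate. At α = 0.05 with 1,000 replicates, per-region rejection rates over
20 seeds sit near 0.05 and BH across 72 regions essentially never
rejects.

**Connectivity-recovery fixture** (`power_fixture_config`): two
CN-sized groups (135 vs 67) identical in planted module layout and mean
amyloid burden, differing only by a planted amyloid-layer correlation
increase of 0.3 — a large connectivity effect. Matching the burden
means is deliberate: a between-group mean shift inflates correlations
in the *mixed* pseudo-groups of the permutation null (all regions move
together with the mixing proportion), widening the null and entangling
mean and connectivity effects. With means matched, the contrast
isolates the planted parameter, and the overlapping-strength test
recovers it after FDR in a majority of regions in ≥ 8/10 seeds. The
effect size is large because group-level covariance estimates from ~67
subjects carry substantial whole-layer sampling fluctuation; weaker
effects are genuinely hard to detect at these sample sizes, which is a
property of the design, not of the implementation.

Passing these tests shows the machinery is correct and calibrated under
the generator's Gaussian, block-structured world. It does not show that
real atrophy/amyloid covariance is block-structured, that real effects
are this large, or anything about spatial topography.

## Numerical choices

* Binarization tie-break: stable sort by (weight desc, node pair lex).
* Louvain move acceptance requires a gain > 1e−12 (strict improvement,
  guaranteeing termination); restart r uses child seed [seed, r].
* Layer matrices serialize at %.17g, which roundtrips float64 exactly
  (readers use round-trip parsing), so reloaded metrics agree bitwise.
* Degenerate inputs error early and descriptively: constant regions
  after residualization, single-sex groups, zero TIV variance,
  zero-weight layers, densities keeping no edges.
* Problem sizes in the test suite (e.g., 1,000 permutation replicates ×
  20 seeds for calibration, 10 seeds for recovery checks) are chosen so
  the full suite completes on a single CPU in a few minutes while the
  Monte-Carlo tolerances stated in each test remain meaningful.

## Known limitations

* Two layers only; the data structures generalize but Eq.-level code
  assumes M = 2.
* Group-level covariance networks yield no subject-level network, so
  no within-subject statistics or clinical correlations.
* The permutation null mixes groups and therefore inherits any
  between-group mean differences as correlation inflation in the
  pseudo-groups; this matches the standard procedure but means
  "connectivity" differences partly reflect mean-shift structure when
  burdens differ. The power fixture documents and sidesteps this; real
  analyses should interpret contrasts accordingly.
* The (γ, ω) stability rule is one defensible automation of a manual
  model-selection step.
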