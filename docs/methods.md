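# Methods

## Model and assumptions

The classifier is a hierarchical nearest-centroid rule in a supervised PCA
score space. "Supervised" refers solely to gene selection: each decision node
of the subtype hierarchy has a pre-derived list of classifier genes, and the
decomposition itself is an ordinary covariance PCA (no scaling to unit
variance) of the node's reference samples restricted to those genes. Samples
are observations; classifier genes are variables; component scores therefore
live in sample space and all distances are computed on scores.

The method assumes that (i) reference and unknown profiles are normalized
onto a common scale upstream (the package performs no normalization and
rejects non-finite values rather than imputing); (ii) each child subtype
forms a single cloud around its centroid in the node's classifier-gene
space; and (iii) the classifier gene lists actually discriminate the
children — the PCA will faithfully represent whatever structure the chosen
genes carry, including none.

Per node, for an unknown profile *x*:

- **Merge mode (default).** *x* is appended to the node's reference
  submatrix and the PCA is refit on the combined matrix. This is the
  published workflow; it makes the basis (and hence all reported numbers)
  depend slightly on the unknown, which is why centroids and σ are
  recomputed per prediction from the stored raw submatrix. **Project mode**
  freezes the basis, centroids and σ on the reference alone and projects
  *x* onto it; it is offered for users who need reference geometry
  independent of the query, and is the documented deviation from the
  original procedure.
- **Distance.** `d(u, v) = sqrt(Σ wᵢ (uᵢ − vᵢ)²)` with `wᵢ` the proportion
  of total variance of component *i*. The radical is applied to the weighted
  sum (standard weighted Euclidean distance); this choice matters because
  the membership probabilities are not invariant to squaring, and it is
  pinned by oracle tests.
- **Membership probability.** Normalized inverse distances over the node's
  children. This is an ordinal confidence share: it always sums to 1, is
  order-reversing in distance, and says nothing about absolute fit — a
  sample far from every centroid can still receive a high share. The
  relative distance exists precisely to catch that case. If exactly one
  distance is zero the probability of that child is 1 (the limit of the
  formula); several zero distances (coincident centroids) are an error.
- **Relative distance.** `r_D = d / σ`, with σ the standard deviation of the
  child's own reference-sample distances to its centroid. The population
  divisor (n) is the default; `sigma_divisor="n-1"` flips it. σ = 0 (all
  child samples coincident) is a degenerate-model error with guidance rather
  than an infinite score.
- **Descent and ties.** The child with the smallest distance wins (equal to
  the argmax of probability by construction). Exact ties are broken toward
  the first child in the node's declared order and noted in the result's
  warnings.

## Tunable parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `n_components` | all | — | The source procedure weights components by variance share but never truncates; retaining all components with weight `wᵢ` already down-weights noise directions smoothly. An integer truncates. |
| `mode` | merge | — | Faithful to the published merge-then-fit workflow. |
| `outlier_threshold` | 3 | multiples of σ | 3-sigma convention on `r_D` of the assigned child, at any level. See the caveat below. |
| `sigma_divisor` | n | — | Population standard deviation of within-child distances. |
| `coverage_threshold` | 0.05 | fraction | Classifier genes absent from an input are dropped (with a warning) below this fraction, an error at or above it. Cross-platform gene lists make occasional absence inevitable; wholesale absence means the input cannot be classified honestly. |

**Caveat on the outlier threshold.** `r_D` divides a distance by the
*spread* of distances, not by a typical distance. In a k-dimensional score
space the distances of in-class samples to their centroid concentrate (a
chi-like distribution whose mean grows like √k while its spread does not),
so even genuinely in-class unknowns routinely score `r_D` in the 2–5 range
when many components carry weight; the worked example in the README shows
exactly this. The flag is therefore a prompt for inspection, never a
suppression of the assignment, and the raw `r_D` values for every child are
always reported. Probes constructed to be far from every centroid score far
higher (the displaced probe in the acceptance run) and centroid-planted
probes score well below 1, so the ranking is informative even where the
absolute threshold is blunt.

## Synthetic cohorts

The generator emulates the *structure* the classifier assumes, not
microarray biology: per node a disjoint set of classifier genes; each child
subtype Gaussian around a child-specific mean on those genes; background
genes of pure noise; everything reproducible from one seed.

Geometry: a node's `g` classifier genes are partitioned round-robin into one
block per child; a child's mean is `delta_mu` on its own block and 0
elsewhere, so any two child means differ by `delta_mu` per differing gene
(Euclidean separation `delta_mu·sqrt(2g/m)` for m children). Samples not
under a node (e.g. G-type samples on the O node's genes) are pure noise
there. Defaults — 20 samples per leaf, 30 genes per node, `delta_mu = 4`,
`sigma_e = 1`, 100 background genes — are the package's standard study
conditions: six leaves give a 120-sample cohort of the same order as typical
published reference cohorts, 30 genes per node matches the size of curated
classifier lists, and a per-gene shift of 4 noise SDs makes the subtypes
cleanly separable so that label-recovery failures indicate implementation
faults rather than overlapping classes. The no-signal control sets
`delta_mu = 0`.

Displaced probes (`make_unknown(..., displacement=s)`) add, for every
hierarchy node independently, `s·sigma_e` times a random unit vector within
that node's classifier genes, so the probe is the stated multiple of
`sigma_e` away from where its subtype lives at *every* level; a single
whole-transcriptome direction would dilute the per-node displacement by the
subspace fraction and tie outlier behavior to the background gene count.

What passing tests on these cohorts shows: the algebra (decomposition,
distances, probabilities, σ), the hierarchy bookkeeping, and the qualitative
behavior (chance-level accuracy without signal, monotone accuracy in
separation, harder 4-way than 2-way splits). What it does not show:
performance on real tumor profiles, where clusters are non-spherical,
heteroskedastic, batch-affected and unevenly sized. Published accuracies on
the original glioma cohorts depend on those data and are not reproducible
here.

## Evaluation protocols

Accuracy is tabulated per hierarchy node, conditioned on the true parent
path: a sample whose true leaf is OA counts toward the root and O nodes
only. Each counted sample is classified *at* that node (against the node's
own model), isolating per-level accuracy from upstream mistakes; full
root-to-leaf descent is a separate operation. Two protocols: `train_test`
(classify an independent test cohort against the training reference) and
`loo` (leave-one-out within one cohort; the held-out sample never
contributes to the basis, centroids or σ of its own prediction — each child
must therefore keep ≥ 2 samples after holdout).

Two statistical quirks of these protocols are worth knowing. Under the
no-signal control, nodes with unbalanced children (the root: 40 O vs 80 G
samples) show a slight bias toward the majority child — its centroid is
estimated with less sampling error, so noise samples land nearer to it —
which nudges null "accuracy" a little above chance. And leave-one-out
predictions share centroids, so they are positively correlated and the
plain binomial interval around chance is approximate rather than exact.

## Numerical choices

- PCA via SVD of the centered matrix rather than forming the covariance
  matrix; equivalence with a direct eigendecomposition is asserted by tests
  to 1e-7 absolute on scores.
- Component signs are fixed by requiring the largest-magnitude gene loading
  of each component to be positive; all equality tests are stated up to this
  convention.
- At most `min(n_genes, n_samples − 1)` components exist after centering;
  "all" means that many. Zero-variance input (all samples identical) is a
  degenerate-model error.
- Weights are variance proportions of the *total* variance, so truncation
  leaves them summing to < 1 rather than renormalizing; with all components
  they sum to 1 within 1e-9.
- Reports embed tool version, configuration echo and SHA-256 input digests,
  and contain no timestamps, so identical inputs yield byte-identical
  output.

## Problem sizes

The test suite and the acceptance script run on the default 120-sample
cohorts (plus deliberately smaller cohorts for structural tests and a
10-replicate sweep at shift 3); a full leave-one-out pass over 120 samples
refits ~360 node models and completes in about a second on one core.

## Known limitations

- The membership probability is not calibrated; treat it as a ranking.
- The default outlier threshold is blunt in high-dimensional score spaces
  (see above); tune it to the reference cohort, or read the raw `r_D`.
- Gene matching is exact and case-sensitive; probe-set/symbol mapping is the
  caller's responsibility.
- In merge mode every reported number depends (weakly) on the unknown;
  use project mode when that is unacceptable.
- Batch classification loops sample-by-sample, each merged independently;
  there is no joint multi-sample mode.
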