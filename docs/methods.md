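# Methods

`cytoplex` types single cells from multiplexed-imaging cell-by-marker
tables and quantifies their spatial organisation.  This note records the
models, the parameters that matter, the synthetic study conditions, and
the design choices made where the design was genuinely open.

## Typing engine

### 1. Lineage assignment (EM mixture)

Cells are first assigned a major lineage with a hierarchical marker model.
For log intensities `y_nm = log1p(x_nm)`, each marker `m` has a background
location `mu_m`, a variance `sigma2_m`, and a non-negative over-expression
shift `d_m`.  Lineage `k` with defining set `M_k` has likelihood

    p(y_n | k) = prod_m  N(y_nm ; mu_m + d_m·1[m in M_k] + o_{b(n),m}, sigma2_m)

with optional additive per-batch offsets `o_b` (batch identifier column,
e.g. a TMA id; first batch pinned to zero for identifiability).  Mixing
weights and all parameters are fitted by EM; the M-step runs three
coordinate sweeps (each improves the EM Q-function, so the log-likelihood
trace is non-decreasing, asserted to 1e-8 relative tolerance in tests).
The cell-specific size factor is one; intensities are otherwise consumed
raw.  The non-negativity constraint on `d_m` realises the shrinkage
setting; `em_damping` (default 1.0 = plain EM) is the step-damping
analogue of a learning rate.  Zero-variance markers contribute no
likelihood term (logged).  Every cell receives its maximum-posterior
lineage, however low the probability; posteriors are normalised per cell.

*Degenerate inputs*: a single lineage yields posterior 1 everywhere;
non-convergence after `em_max_iter` (default 200) keeps the best iterate
with a warning.

### 2. Confidence (perturbed model + logistic regression)

A second model is fitted with one lineage removed from the definitions
and a drop-marker set removed from the input.  The drop set must cover
the excluded lineage's uniquely defining markers and intersect its
defining set, so that no remaining marker can identify it; for a lineage
defined by a single shared marker (the vimentin-only exemplar) the whole
defining set is dropped, which is also the default.  Cells keeping their
label across the two models are *stable*, cells changing are *variable*.
A binomial logistic regression on (assigned-lineage posterior, mean
log-intensity of the assigned lineage's defining markers) is trained on
these flags and applied to all cells: predicted probability ≥ 0.5 of
stable means **high** confidence (ties high — a symmetric default, since
no threshold is prescribed).  Confidence is required to be monotone in
the posterior; if the forced label flips of the excluded lineage drag the
posterior coefficient negative, the model is refitted without that term
(logged), preserving the invariant that raising a cell's posterior can
never flip it high→low.  Single-class training flags assign that class to
every cell with a warning.  One perturbation is built by default; a
per-lineage loop is available by calling `build_perturbed_labels` per
lineage.

### 3. Stratum clustering

Within each (lineage × confidence) group, a k-nearest-neighbour graph
(k = 30, Euclidean on raw intensities) is partitioned by seeded Leiden
modularity optimisation (optional Jaccard edge weights).  Groups smaller
than k+1 become one cluster.  Cluster ids are unique across groups, so
the three tiers form a partition of the cells.

### 4. Marker positivity (win probabilities and D-scores)

For every pair of clusters in a confidence group and every marker, the
*win probability* `p(A,B,m)` — the probability that a random cell of A
has higher intensity of `m` than a random cell of B — is computed from
rank sums (ties count half; identical to exhaustive pair enumeration,
asserted to 1e-12).  A cluster's multiset `P` of win probabilities
against all other clusters is compared with a background multiset `B`;
the **D-score** is the positive deviation of `P` above `B`:

* `area` mode (default): ∫ max(F_B − F_P, 0) dt over [0, 1];
* `max` mode: max_t (F_B(t) − F_P(t)), clamped at 0,

both evaluated on the empirical CDFs over the union of observed values,
giving D ∈ [0, 1] and D = 0 for anti-expressed clusters.  D-scores are
rank statistics: they are invariant under any strictly monotone
transform of a marker's intensities.

**Why area is the default.**  With a few dozen clusters, modularity
clustering inevitably splits homogeneous groups along sampling noise;
such sibling clusters consistently rank-dominate each other by small
margins, and a consistent shift of the whole `P` distribution drives the
maximum CDF gap to 0.3–0.55 — overlapping the gap of genuinely expressed
shared markers.  The integrated (area) statistic weights the gap by how
far the probabilities actually travel, so small consistent shifts score
near 0 while true positives (win probabilities near 1) score high; on
cleanly separated synthetic scenes only the area statistic admits a
separating cutoff.  `max` remains a config mode.

**Background choice.**  The default background pools the ordered-pair win
probabilities of *all* markers in the confidence group.  Under
exchangeability the distribution of a win probability does not depend on
the marker, so pooling across markers preserves the exact D = 0 null —
and it keeps the background representative for markers expressed by many
clusters (a per-marker background for CD45, positive on five of eight
lineages in the bundled panel, is contaminated by its own signal and
drives true D-scores toward zero).  `pooled-marker` and `uniform` remain
config modes.  A single-cluster confidence group has undefined D-scores;
its cells fall through to the annotation fallbacks (logged).

### 5. Automated cutoff

Positivity is called per cluster by strict comparison `D > cutoff`.  The
cutoff is selected per confidence group on a grid over [0, 1] (step 1e-4,
10,001 candidates): at each candidate, cells inherit their cluster's
reference-marker positivity vector (reference markers default CD3, CD4,
CD8a) and the configured populations are counted **in cells**, so large
clusters dominate.  Candidates at which any *dominant* population (e.g.
CD3+CD4+CD8a−, CD3+CD4−CD8a+) is empty are excluded; among the rest the
ratio Σrare/Σdominant is minimised (rare defaults: CD3−CD4−CD8a+ and
CD4+CD8a+).  *Variable* and *low-frequency* populations are tallied and
reported but never enter the objective.  The minimum is typically
attained on a plateau whose two edges are the documented failure
directions (too low → spurious double positives; too high → spurious
single positives), so the **centre of the widest minimal-ratio run** is
selected, maximising the margin to both.  If optimisation fails for one
confidence group (every candidate excluded — e.g. a tiny homogeneous
group), the pipeline reuses the other group's cutoff with a warning; the
operation itself raises when no group admits a cutoff.

### 6. Annotation

For a subtype `s` with defining set `D_s` and ancestral lineage markers
`L_s` (ancestry inferred from strict subset relations between defining
sets), the specificity score of a positive set `P` is

    score(s) = |P ∩ (D_s ∪ L_s)| / |D_s ∪ L_s| − λ·|P ∩ (U_other ∪ X_s)|

with λ = 1/|panel|, `U_other` the markers uniquely defining lineages
outside `s`'s chain, and `X_s` the subtype's excluded markers.  The
penalty makes contradictory unique markers count against a subtype by
one panel-normalised unit, which breaks ancestor/descendant ties in the
right direction.  This concrete formula is an in-house instantiation of
a "highest specificity wins" rule and is isolated in one operation for
easy replacement.

Resolution: unique positive maximum → direct; max ≤ 0 → Unassigned; tied
maximum → Ambiguous.  Unresolved cells of high confidence take the
lineage-model label (lineage-fallback, applied first); remaining
Ambiguous ties are resolved by the tissue compartment when masks and a
compartment→lineage mapping are configured (mask-fallback).  Compartments
label cells by the mask pixel containing the centroid (half-open, 0-based
pixel convention; overlap priority tumour > stroma by default; outside →
background).  Densities are count / compartment area (mm⁻²), with a
Total row per image × compartment; a zero-area compartment holding cells
is rejected as inconsistent input.

## Spatial analytics

Per cell type and image, DBSCAN (scikit-learn; verified against a
brute-force O(n²) oracle) clusters micron coordinates; `eps` and the
alpha radius have **no defaults** — they depend on tissue type and cell
density and must be supplied.  Cluster boundaries are alpha shapes
(Delaunay triangles with circumradius ≤ radius, unioned; convex hull in
the large-radius limit; collinear or <3-point clusters become buffered
segments of configurable half-width, default 1 µm).  Composition counts
every phenotype inside each boundary (boundary-inclusive) with
intracluster densities per mm²; signed distances to the nearest cluster
boundary are negative inside, positive outside, zero on the boundary,
NaN when no cluster exists.  Cluster masks are rasterised at a
configurable scale (default 1 µm/px, pixel-centre test) and compared by
Dice = 2|A∩B|/(|A|+|B|), defined as 0 when both masks are empty.
Border points reachable from several DBSCAN clusters go to the first
core point claiming them in index order (the classic ambiguity,
documented because no convention is prescribed).

## Barrier scoring

The cell graph is a Delaunay triangulation pruned at a maximum edge
length (default 50 µm, a scale at which adjacent cells in dense tissue
remain connected while empty regions break the graph; both knobs are
explicit and recorded), or a (mutual) kNN graph by flag.  Duplicate coordinates are separated by
stable 1e-6 µm lexicographic perturbations; degenerate collinear inputs
chain consecutive points (the 1-D limit of the triangulation), giving a
path graph for points on a line and a single edge for two points.

From each source-type cell, a breadth-first search (CPU; results
identical to any exact shortest-path algorithm) finds the distance to
the nearest target-type cell, and *all* shortest paths of that length
ending in a target cell are enumerated — capped at 1000 per source with
averaging over the enumerated subset (logged), since diamond lattices
explode combinatorially.  Per path, intermediates exclude both
endpoints; `barrier_count`/`barrier_fraction` count barrier-type
intermediates, and `adjacent_count`/`adjacent_fraction` ask whether the
intermediate whose next hop is the terminal target is of the barrier
type.  Single-path metrics use the lexicographically smallest node
sequence (determinism); all-paths metrics average over the enumerated
set.  Image summaries report mean, median and population (ddof = 0)
standard deviation over reachable sources only (unreachable sources are
flagged and counted); the headline score is the mean all-paths adjacent
barrier fraction.  Target cells can be restricted to members of spatial
clusters above a size threshold by feeding the spatial-clustering output
into the barrier stage.

## Synthetic study conditions

The generator plants subtypes with log-normal signal over log-normal
background (heavy-tailed, strictly positive, like mean-pixel
intensities): default signal `exp(N(2.5, 0.35))` (median ≈ 12) over
background `exp(N(0, 0.4))` (median ≈ 1) — high separation.  Counts are
prescribed exactly, never sampled.  Low-confidence cells are emulated by
a single knob: a multiplicative attenuation of the positive markers.
Spillover mixes marker pairs convexly at the marker level (spatial
spillover is out of scope).  Layouts are uniform discs (niches), an
optional annulus (planted barrier), and uniform scatter.

Bundled scenes (sizes chosen to exercise every stage in seconds on one
CPU; the methods scale linearly in cells for everything but the
pairwise win-probability step, which is quadratic in clusters):

* **demo** — 3,000 cells, the eight-lineage T-cell/stroma-style panel
  (Vimentin+, Endothelial, Epithelial, aSMA+, CD4 T, CD8 T, T-Other,
  Leukocytes-Other), three epithelial niches (r = 120 µm) over scatter.
  End-to-end label accuracy vs the planted truth is ≥ 99% across seeds.
* **tcell** — 2,600 cells for cutoff optimisation: the dominant
  CD3+CD4+ and CD3+CD8a+ populations planted, no rare combinations, plus
  epithelial/endothelial context, without which ubiquitous markers
  (CD45 on every cluster) would have no between-cluster contrast and no
  rank statistic could call them.
* **confidence** — 3,000 cells, vimentin-family panel, 20% of cells
  attenuated at 0.2.  Attenuated cells of the vimentin-sharing lineages
  gravitate to the weakest definition (the vimentin-only lineage) under
  the complete model and are forced to flip when it is excluded, so the
  planted flags are recoverable (sensitivity ≥ 80% is the acceptance
  bar; measured ≈ 99–100%).
* **barrier** — a central tumour niche, scattered CD8 T cells, and 350
  fibroblasts either ringing the tumour (annulus 150–190 µm) or
  scattered; counts identical, so the score contrast isolates geometry.

What the generator does **not** emulate: segmentation errors, spatial
intensity gradients, cell-size/area covariation, pixel-level spillover,
multi-image cohort heterogeneity.  Passing tests on these scenes shows
the machinery is correct and self-consistent under its stated model,
not that the defaults are optimal for any real cohort — on real data the
cutoffs, eps and alpha radius must be established per dataset.

## Numerical choices

Positivity is strict (`D > cutoff`, equality negative).  Ratio ties on
the cutoff grid resolve to the centre of the widest minimal run.  EM
variances are floored at 1e-8; mixing weights at 1e-12.  Win
probabilities use average ranks for ties.  Dice of two empty masks is 0.
Signed distance of a vertex point is 0 (sign positive).  The confidence
threshold is 0.5 with ties high.  All randomness (EM is deterministic;
Leiden and the generator are seeded) flows from the single `RunConfig`
seed, which is recorded in every manifest; reruns are byte-identical.

## Known limitations

* The specificity formula and the exact barrier score variants are this
  package's own instantiations of the stated contracts; both are
  isolated behind single operations so alternatives can be swapped in.
* Cohort-level statistics (Wilcoxon/Spearman across images) are out of
  scope; the pipeline emits the per-image tables such tests consume.
* No image-channel ingestion or segmentation: the cell table is the
  contract.  FlowSOM-style clustering is not implemented; the config
  rejects it with a clear message.
* Per-image cutoffs are deliberately not computed: thresholds are
  cohort-level per confidence group.
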