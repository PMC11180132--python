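# cytoplex

Automated cell phenotyping and spatial analysis for multiplexed tissue
imaging (IMC, CODEX, CosMx, ...), operating on plain cell-by-marker
tables — no raw images required.

Segmentation pipelines emit, for every cell, a centroid and a mean
intensity per antibody channel.  Turning that matrix into biology means
answering three questions: *which marker is actually expressed by which
cell* (positivity, without a global intensity threshold), *what cell
type is that* (a label consistent with a user-defined marker hierarchy),
and *how are the types organised in the tissue* (niches, exclusion,
barriers).  `cytoplex` answers all three with a tested library and CLI.

## What it computes

**Typing.**  Cells are stratified three ways: by major lineage (an EM
log-intensity mixture in which a lineage's defining markers carry a
shared non-negative over-expression shift, with optional per-batch
offsets), by confidence (a perturbed model with one lineage and its
identifying markers removed yields stable/variable training flags; a
logistic regression on posterior and defining-marker intensity then
predicts high/low), and by cluster (seeded Leiden communities of a
k = 30 nearest-neighbour graph per lineage × confidence group).

Positivity is a rank statistic.  For cluster A, marker m, and every
other cluster B, the win probability

    p(A, B, m) = P(random cell of A has higher m than random cell of B)

is the scaled Mann–Whitney U.  The deviation of A's win-probability
distribution above a pooled background distribution is the **D-score**
∈ [0, 1]; a cluster expressing m scores high.  One cutoff per confidence
group is selected automatically on a 10,001-point grid by minimising the
ratio of implausible ("rare", e.g. CD3−CD8a+) to expected ("dominant",
e.g. CD3+CD4+) reference-marker populations, never selecting a cutoff at
which a dominant population is empty.  Cells inherit their cluster's
calls; subtypes are assigned by a hierarchy-aware specificity score with
lineage- and mask-based fallbacks for Ambiguous/Unassigned cells; cell
densities per tissue compartment (mm⁻²) come from user-supplied binary
masks.

**Spatial.**  Per cell type: DBSCAN niches with alpha-shape boundaries,
intracluster composition and densities, signed distances to the nearest
niche boundary, rasterised niche masks and Dice overlap between types.
For any (source, barrier, target) triplet: shortest paths on a
length-pruned Delaunay cell graph, with barrier-content and
adjacent-barrier fractions averaged over **all** shortest paths; the
mean all-paths adjacent barrier fraction is the image-level barrier
score (e.g. how much αSMA+ fibroblasts stand between CD8 T cells and
tumour).

A seeded synthetic-tissue generator (planted lineages, positivity,
niches, barrier annuli, compartment masks) makes every stage testable
without any dataset; see `docs/methods.md` for the models and the
bundled study scenes.

## Worked example

```python
import cytoplex as cx
from cytoplex import scenes

# a bundled ~3,000-cell scene: 8 lineages, 3 epithelial niches + masks
spec, schema = scenes.demo_scene(seed=1)
cells, truth = cx.generate_scene(spec)
masks = cx.generate_masks(spec, microns_per_pixel=1.0)

config = cx.RunConfig(seed=1, compartment_lineages={"tumour": "Epithelial cells"})
result = cx.run_typing(cells, schema, config, masks=masks)

s = result["summary"]
print(f"cells typed:            {s['n_cells']}")
print(f"selected D-score cutoff: {s['selected_cutoffs']['high']:.4f}")
print(f"Ambiguous+Unassigned:    {s['ambiguous_unassigned_fraction']:.4f}")
```

prints

```
cells typed:            3000
selected D-score cutoff: 0.1262
Ambiguous+Unassigned:    0.0000
```

The cutoff 0.1262 is the centre of the plateau on which no implausible
T-cell combination survives while both dominant combinations are
populated; with it, 99.97% of cells receive their planted label, and the
density table reports e.g. 5550 epithelial cells/mm² inside the tumour
compartment (766 cells in 0.138 mm²).  Re-running with the same seed
reproduces every CSV byte for byte.

The same stages are available from the shell:

```sh
cytoplex synth --spec scene.yaml --seed 1 --out run/synth
cytoplex type  --cells run/synth/cells.csv --schema schema.yaml \
               --masks run/synth/masks --out run/typing --plots
cytoplex spatial --cells run/typing/cell_objects.csv \
                 --eps 30 --alpha-radius 60 \
                 --source "CD8 T cells" --barrier "aSMA+ cells" \
                 --target "Epithelial cells" --out run/spatial
```

Inputs are delimited text (cells), YAML (schema, config) and
single-channel TIFF/PNG (masks); outputs are CSVs plus a JSON run
manifest recording the seed, config hash, timings and warnings.

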