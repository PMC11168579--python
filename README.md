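# cellnerve

Nerve-based topological analysis and comparative morphometrics of 3D
cell-resolution segmentations.

Developmental biologists who segment whole organs at single-cell resolution
(e.g. with PlantSeg + MorphoGraphX-style pipelines) often need to ask: *do
two cohorts of organs — two species, genotypes, or conditions — differ in
their 3D cellular architecture, and at which developmental stage does the
difference appear?*  Visual inspection does not scale and cherry-picks;
single summary numbers (cell counts, volumes) miss how cells are assembled.
`cellnerve` answers the question with topology plus a multivariate
two-sample test, alongside the standard tissue morphometrics used to follow
up such findings.

## The method

**Nerve.**  For a labeled volume, each cell is a vertex and every set of
k+1 cells with a non-empty common intersection is a k-simplex (edge,
triangle, tetrahedron, …).  The 1-skeleton is the region adjacency graph;
higher simplices encode how corners and edges of cells meet.  The nerve of
a Voronoi tessellation of generic points is the Delaunay triangulation,
which the test suite exploits as an exact oracle.  On voxel data the nerve
is computed from the dual grid: the distinct labels in every 2×2×2 voxel
block span a simplex.

**Feature vectors.**  The *face-vector* of a cell counts the k-simplices in
its vertex star per dimension — a hexagonal cell with six ring neighbors
has face-vector (1, 6, 6).  Enumerating all face-vectors occurring in the
comparison set, each sample becomes the vector of proportions of its cells
having each face-vector.

**Two-sample test.**  Cohorts of feature vectors X₁..X_m, Y₁..Y_n are
compared with the Cramér / energy-distance statistic

T = mn/(m+n) · [ 1/(mn) Σᵢⱼ φ(‖Xᵢ−Yⱼ‖²) − 1/(2m²) Σᵢⱼ φ(‖Xᵢ−Xⱼ‖²) − 1/(2n²) Σᵢⱼ φ(‖Yᵢ−Yⱼ‖²) ]

with φ(z) = √z/2, so T ≥ 0 with equality iff the empirical distributions
coincide.  P-values are bootstrap estimates (fraction of resampled T* ≥ T,
no +1 correction, so p can be exactly 0).

**Morphometrics.**  Coefficient of variation of cell volume (CVcv),
stage-wise relative growth [y(n+1) − y(n)]/y(n) from cohort means, tissue
proportions, staging-threshold extrapolation, mitotic-division summaries,
and the 30 µm³ segmentation-artifact filter.

See `docs/methods.md` for assumptions, parameters and limitations.

## Worked example

```python
import numpy as np
from cellnerve import (GeneratorSpec, build_nerve, make_cohort_pair,
                       make_hex_fixture, compare_nerve_cohorts, spread)

# the hexagonal worked example: one cell ringed by six neighbors
nerve = build_nerve(make_hex_fixture())
print("simplex counts:", nerve.simplex_counts())
print("center face-vector:", nerve.face_vector(1))
print("ring face-vector:  ", nerve.face_vector(2))

# two cohorts of synthetic organs: space-filling vs epithelial-sheet architecture
bulk = GeneratorSpec(kind="voronoi_bulk", seed=0)
sheet = GeneratorSpec(kind="layered_sheet", seed=0)
vols_a, vols_b = make_cohort_pair(bulk, sheet, n_samples=10, seed=0)
nerves_a = [build_nerve(v) for v in vols_a]
nerves_b = [build_nerve(v) for v in vols_b]
result, fm = compare_nerve_cohorts(nerves_a, nerves_b,
                                   labels=("bulk", "sheet"), B=1000, seed=0)
print(f"alphabet size: {len(fm.alphabet)}")
print(f"T = {result.statistic:.4f}, p = {result.p_value}")
print(f"spread(bulk) = {spread(fm.cohort_values('bulk')):.4f}")
print(f"spread(sheet) = {spread(fm.cohort_values('sheet')):.4f}")
```

prints

```
simplex counts: (7, 12, 6)
center face-vector: (1, 6, 6)
ring face-vector:   (1, 3, 2)
alphabet size: 1228
T = 0.0572, p = 0.011
spread(bulk) = 0.1150
spread(sheet) = 0.1181
```

The fixture has 7 cells, 12 adjacencies and 6 triple points; the central
cell's face-vector (1, 6, 6) reads one vertex, six edges, six triangles.
For the cohorts, 1228 distinct face-vectors occur across the 20 samples;
the two architectures are distinguished at p ≈ 0.01 from ten samples each,
while the within-cohort spreads show both cohorts are internally variable.

## Command line

```sh
cellnerve simulate --kind layered_sheet --n-samples 10 --seed 1 --out data/
cellnerve nerve data/layered_sheet_000.h5 --out nerve.json
cellnerve features nerve.json --out features.csv
cellnerve compare --config plan.yaml --out results/
cellnerve morpho --config plan.yaml --out morpho/
```

`compare` executes a YAML plan (two cohorts of volumes + cell tables,
stages, tissue selections, bootstrap settings) and writes per-(stage,
tissue) test results, feature matrices, PCA scores and a reproducibility
manifest.  Exit codes: 0 success, 2 validation error, 3 degenerate input.

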