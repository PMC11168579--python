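# Methods

## The nerve of a segmented tissue

A 3D cell-resolution segmentation assigns every voxel an integer cell ID
(with one or more *background* labels for the exterior).  The nerve of such
a tessellation is the abstract simplicial complex whose vertices are the
cells and whose (k)-simplices are the sets of k+1 cells with a non-empty
common intersection: two touching cells span an edge, three cells meeting
along a line span a triangle, four cells meeting at a point span a
tetrahedron.  Its 1-skeleton is the unweighted region adjacency graph; the
higher simplices carry the extra incidence information needed to describe
the polyhedral structure of each cell.  For a Voronoi tessellation of
generic points the nerve is exactly the Delaunay triangulation — the
property this package uses as its analytic oracle.

On a hard voxel grid no two cells literally share a voxel, so intersection
is evaluated on the dual grid: every 2×2×2 block of voxels (2×2 for
single-slice images) samples a corner point where up to eight cell closures
meet, and the set of distinct non-background labels in the block spans a
simplex (`scheme="block2"`).  Consequences of this choice:

- Two cells meeting only at a grid corner **do** count as intersecting.
  When strict 6-connectivity face adjacency is wanted, the
  `scheme="pairwise_face"` construction returns just the region adjacency
  graph (vertices and edges).
- The simplex dimension is not capped; a degenerate block can contribute up
  to a 7-simplex.  The nerve is abstract, so this needs no special casing.
- Voxel spacing is ignored: anisotropy rescales geometry but does not
  change which cells meet.
- Cells touching the image border have truncated neighborhoods.  Their
  face-vectors are still computed but are not expected to satisfy the Euler
  relation below; comparisons against the Delaunay oracle are therefore
  made on simplices incident to *interior* cells (cells whose voxels do not
  touch the volume boundary).

## Face-vectors and feature vectors

The *vertex star* of a cell is the set of simplices containing it; the
*face-vector* counts the k-simplices of the star for each k.  A hexagonal
cell ringed by six neighbors has face-vector (1, 6, 6): one vertex, six
edges, six triangles.  For an interior cell of a simple polyhedral complex
with face-vector (1, x2, x3, x4), x2/x3/x4 are the faces/edges/vertices of
the cell's polyhedron, so Euler's formula gives x2 − x3 + x4 = 2.

A sample (one segmented organ or tissue) is summarized by the distribution
of its per-cell face-vectors.  All face-vectors occurring in *any* sample
under comparison are enumerated into a deterministic alphabet (padded with
zeros to a common length, sorted lexicographically), and each sample
becomes the vector of proportions of its cells with each face-vector.  The
alphabet must always be built from the full comparison set; feature
extraction fails loudly otherwise.  By default an alphabet is built per
comparison (one stage and tissue at a time); callers can share one alphabet
across stages by enumerating it themselves.

The *spread* of a set of feature vectors is the mean of the n(n−1)/2
unordered pairwise Euclidean distances (the ordered-pair variant differs
only by a factor of one).  PCA projection is a column-centered SVD with no
variance scaling — proportions already share a scale — with the sign of
each component fixed by making its largest-magnitude loading positive.

## The two-sample test

Cohorts of feature vectors are compared with the Cramér (energy-distance)
two-sample statistic: between-sample distances enter with positive weight
and within-sample distances with negative weight,

    T = mn/(m+n) · [ 1/(mn) Σ φ(‖Xi−Yj‖²) − 1/(2m²) Σ φ(‖Xi−Xj‖²)
                     − 1/(2n²) Σ φ(‖Yi−Yj‖²) ],

with the default kernel φ(z) = √z/2 so that the bracket is half the energy
distance; then T ≥ 0 with equality iff the empirical distributions
coincide, and the null is rejected for large T.  Any positive rescaling of
the kernel rescales T without changing p-values; φ is a plug-in argument.

P-values come from resampling with B replicates (default 1000): the
ordinary bootstrap (default) draws m+n points with replacement from the
pooled sample and splits them into pseudo-samples of sizes m and n; a
permutation mode reshuffles the pool instead.  The p-value is the plain
fraction of replicates with T* ≥ T_observed, with no +1 correction, so a
p-value of exactly zero is possible and means the observed statistic
exceeded every resampled one.  Per-(stage, tissue) p-values are reported
raw, without multiplicity adjustment, against a conventional 0.05 line; the
run manifest records how many tests a run performed so users can adjust
externally if they wish.

## Morphometrics

- **CVcv** — coefficient of variation of cell volume, sd/mean with the
  sample (n−1) standard deviation (`ddof` is configurable since the
  population variant differs only by √((n−1)/n)).  By default cells are
  pooled per (cohort, stage, tissue); a per-sample mode is available.
- **Relative growth** — organs are fixed, so growth is estimated
  *indirectly* from independent stage cohorts: for each tissue,
  [y(n+1) − y(n)]/y(n) on the stage-wise mean of the per-sample total
  tissue volume (µm³) or cell count.  A tissue absent at a stage yields a
  flagged missing row, never a silent zero.
- **Tissue proportions** — per-sample share of each tissue in total volume
  or cell count; shares sum to one per sample.
- **Staging extrapolation** — a stage's lower limit in a target cohort is
  estimated as (min_ref/max_ref)·max_target from a fully staged reference
  cohort.
- **Division summaries** — classified mitotic divisions (e.g. periclinal
  vs anticlinal per stage and layer) are tabulated into counts and
  percentages; percentages are kept exact and also rounded to integers for
  display.  Detection and orientation calling of mitotic figures is visual,
  upstream work; only tabulation is in scope.
- **Artifact filter** — cells with volume strictly below 30 µm³ are
  excluded before any cellular statistic (they are segmentation artifacts
  and empty spaces); a cell of exactly 30 µm³ is retained.

## Synthetic study conditions

Real inputs are confocal segmentations; the generators emulate them with
tessellations whose topology is known, so every claim the tests make is
checkable analytically:

- **voronoi_bulk** — uniform random seeds in a margin-shrunk box (default
  margin 0.15), each voxel labeled by its nearest seed, spacing-aware.
  Default 150 cells in a 48³ grid — a tissue-scale cell count.
- **layered_sheet** — the epithelial contrast: `n_layers` (default 2)
  single-cell-thick layers of roughly isotropic cells on a jittered
  in-plane grid, confined to a thin slab centered in the domain with
  background outside (the organ's exterior).
- **weighted_voronoi** — Laguerre tessellation (argmin ‖x−p_i‖² − w_i)
  whose weight dispersion dials the realized cell-volume CV, for
  volume-variability contrasts.
- **hex_fixture** — the single-slice seven-cell hexagonal worked example.
- **make_growth_series** — long-format cell tables with lognormal cell
  volumes of prescribed per-(tissue, stage) means and CV; CV 0 reproduces
  the means exactly.

All generators are pure functions of their parameters and seed; cohort
generation spawns independent child streams from one master seed.

**Resolvable genericity.**  A voxel grid cannot represent Voronoi features
finer than a voxel: two Voronoi vertices closer than the sampling distance
merge or vanish, and two non-adjacent cells separated by a sub-voxel gap
get bridged by a dual-grid block.  `make_voronoi_volume` therefore rejects
and resamples seed configurations whose smallest Voronoi feature — the
minimum of the shortest Voronoi edge (distance between circumcenters of
face-adjacent Delaunay tetrahedra) and the closest approach between Voronoi
edge segments not meeting at a common vertex — is below a clearance of
1.5× the largest voxel extent.  Under this criterion the rasterized nerve
reproduces the Delaunay complex exactly on interior-cell stars in every
validation run.  A fixed analytic tolerance (we first tried a relative
1e-9 cosphericity test) does not work: near-degeneracy must be measured
against the grid resolution, not machine precision.  Cohort generators
disable the rejection (`min_vertex_separation=0`): they are used
distributionally, where rare sub-voxel features merging the same way in
both cohorts is harmless, and rejection would be prohibitively strict at
realistic densities.

**What the generators do not emulate** — curved organ surfaces, wall
voxels between cells, segmentation errors, cell-size gradients, and
biological growth dynamics.  Passing tests demonstrate correctness of the
constructions and calibration of the statistics on known tessellations,
not biological validity on real organs.

## Numerical and design choices

- The brute-force Delaunay oracle enumerates every (d+1)-subset, solves the
  circumcenter linear system, and keeps simplices whose circumsphere is
  empty; near-cospherical neighbors (relative tolerance 1e-9 on the radius)
  raise instead of guessing, and near-flat subsets are skipped (they cannot
  be top simplices of a generic set).  It is O(n⁴) and capped at 25 points;
  scipy's Qhull-based triangulation serves as an independent cross-check of
  the oracle in the tests, never as the oracle itself.
- Face-vector alphabets order vectors zero-padded lexicographically;
  trailing zeros are trimmed for display.
- The bootstrap precomputes the pooled kernel matrix once per comparison;
  replicates only index into it.
- Degenerate inputs: empty tissue selections, all-background volumes,
  sub-minimum sample counts and invalid stage labels raise typed errors;
  pipeline cells with fewer than two samples per cohort are flagged
  `skipped` in the results table rather than dropped.
- Problem sizes in the test-suite and the acceptance script — 15-seed 64³
  volumes for oracle comparisons, 150-cell 48³ volumes with 10+10 samples
  and B=200 for cohort power, 200 null runs for calibration — were chosen
  as the smallest sizes at which the studied effects are stable.

## Known limitations

- The block2 scheme reads corner contacts as intersections; on noisy real
  segmentations this can add edges a mesh-based nerve would not have.
  Whether upstream pipelines reserve wall voxels between cells varies, so
  the background label set is configurable and `pairwise_face` offers a
  conservative alternative.
- Interior/border classification is per volume face; a tissue restricted
  out of a larger organ has many border cells, and their face-vectors are
  architecture- and crop-dependent (as they are in real data).
- The ordinary bootstrap with small m, n is only approximately calibrated;
  the permutation mode is exact under exchangeability and is recommended
  when m+n is small.
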