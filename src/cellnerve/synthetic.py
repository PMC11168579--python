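"""Synthetic tessellations and cohort tables with known ground truth.

Real inputs to this package are confocal segmentations of whole organs; the
generators here stand in for them with tessellations whose expected topology
is known analytically — the nerve of a Voronoi tessellation of generic
points is the Delaunay triangulation — so every downstream module can be
validated without microscopy data.

Generators are pure functions of their parameters and seed.  The Voronoi
generator enforces *resolvable genericity*: configurations in which two
adjacent Voronoi vertices (circumcenters of neighboring Delaunay
tetrahedra) are closer than a configurable clearance are rejected and
resampled, because the voxel grid cannot separate features finer than a
voxel and the rasterized nerve would not match the analytic one.
"""

from __future__ import annotations

import itertools
import math
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.spatial import Delaunay as _SciPyDelaunay
from scipy.spatial import cKDTree

from .errors import DegenerateInputError
from .io import DEFAULT_STAGE_ORDER, LabeledVolume, _validate_cell_table

__all__ = [
    "GeneratorSpec",
    "make_voronoi_volume",
    "make_weighted_voronoi_volume",
    "make_layered_sheet_volume",
    "make_hex_fixture",
    "make_volume",
    "make_cohort_pair",
    "make_growth_series",
    "brute_force_delaunay",
]

GENERATOR_KINDS = ("voronoi_bulk", "weighted_voronoi", "layered_sheet", "hex_fixture")


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of a synthetic labeled-volume generator.

    The seed fully determines the output.  ``volume_cv`` controls the weight
    dispersion of the weighted (Laguerre) tessellation; ``n_layers`` the
    sheet generator's layer count.
    """

    kind: str = "voronoi_bulk"
    n_cells: int = 150
    shape: tuple[int, int, int] = (48, 48, 48)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    volume_cv: float = 0.0
    n_layers: int = 2
    margin: float = 0.15
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in GENERATOR_KINDS:
            raise ValueError(f"kind must be one of {GENERATOR_KINDS}, got {self.kind!r}")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.volume_cv < 0:
            raise ValueError("volume_cv must be >= 0")


def _voxel_centers(shape: Sequence[int], spacing: Sequence[float]) -> np.ndarray:
    idx = np.indices(tuple(shape)).reshape(len(shape), -1).T
    return (idx + 0.5) * np.asarray(spacing, dtype=float)


def _segment_pair_distances(p1, q1, p2, q2):
    """Pairwise min distances between segments [p1,q1] and [p2,q2] (vectorized)."""
    d1, d2, r = q1 - p1, q2 - p2, p1 - p2
    a = (d1 * d1).sum(1)
    e = (d2 * d2).sum(1)
    b = (d1 * d2).sum(1)
    c = (d1 * r).sum(1)
    f = (d2 * r).sum(1)
    denom = a * e - b * b
    s = np.where(denom > 1e-12, np.clip((b * f - c * e) / np.where(denom > 0, denom, 1), 0, 1), 0.0)
    t = np.where(e > 1e-12, (b * s + f) / np.where(e > 0, e, 1), 0.0)
    s = np.where(t < 0, np.clip(-c / np.where(a > 0, a, 1), 0, 1), s)
    s = np.where(t > 1, np.clip((b - c) / np.where(a > 0, a, 1), 0, 1), s)
    t = np.clip(t, 0, 1)
    closest1 = p1 + s[:, None] * d1
    closest2 = p2 + t[:, None] * d2
    return np.linalg.norm(closest1 - closest2, axis=1)


def _voronoi_feature_clearance(points: np.ndarray) -> float:
    """Smallest geometric feature of the Voronoi diagram of the points.

    Takes the minimum of (a) the shortest Voronoi edge (distance between
    circumcenters of face-adjacent Delaunay tetrahedra) and (b) the closest
    approach between Voronoi edge segments that do not meet at a vertex.
    Features smaller than a voxel are not representable on the grid: (a)
    merges or drops Voronoi vertices, (b) lets a voxel block bridge two
    non-adjacent cells across a thin gap.
    """
    tri = _SciPyDelaunay(points)
    tets = tri.simplices
    centers = np.empty((len(tets), points.shape[1]))
    for i, tet in enumerate(tets):
        p = points[tet]
        A = 2 * (p[1:] - p[0])
        b = (p[1:] ** 2).sum(1) - (p[0] ** 2).sum()
        try:
            centers[i] = np.linalg.solve(A, b)
        except np.linalg.LinAlgError:
            return 0.0
    seg_idx = np.array([(i, j) for i, nbrs in enumerate(tri.neighbors)
                        for j in nbrs if j > i], dtype=int)
    if len(seg_idx) == 0:
        return np.inf
    edge_lengths = np.linalg.norm(centers[seg_idx[:, 0]] - centers[seg_idx[:, 1]], axis=1)
    best = float(edge_lengths.min())
    n_seg = len(seg_idx)
    if n_seg > 1:
        ai, bi = np.triu_indices(n_seg, k=1)
        # segments meeting at a shared tetrahedron meet at a real vertex
        shares = ((seg_idx[ai][:, :, None] == seg_idx[bi][:, None, :]).any((1, 2)))
        ai, bi = ai[~shares], bi[~shares]
        if len(ai):
            d = _segment_pair_distances(
                centers[seg_idx[ai, 0]], centers[seg_idx[ai, 1]],
                centers[seg_idx[bi, 0]], centers[seg_idx[bi, 1]],
            )
            best = min(best, float(d.min()))
    return best


def _label_nearest(points: np.ndarray, shape, spacing) -> np.ndarray:
    centers = _voxel_centers(shape, spacing)
    _, lab = cKDTree(points).query(centers)
    return (lab + 1).reshape(tuple(shape)).astype(np.int32)


def make_voronoi_volume(
    n_cells: int,
    shape: Sequence[int] = (64, 64, 64),
    spacing: Sequence[float] = (1.0, 1.0, 1.0),
    margin: float = 0.15,
    min_vertex_separation: float | None = None,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    max_retries: int = 500,
) -> tuple[LabeledVolume, np.ndarray]:
    """Voxelized Voronoi tessellation of random generic seed points.

    Seed points are drawn uniformly in the box shrunk by ``margin`` on every
    side; each voxel is labeled by its nearest seed (spacing-aware).  Labels
    are 1..n_cells, matching seed order.  ``min_vertex_separation`` is the
    resolvable-genericity clearance in physical units (default: 1.5× the
    largest voxel extent; pass 0 to disable rejection).  Returns the volume
    and the ground-truth seed coordinates in (z, y, x) µm.
    """
    if n_cells < 2:
        raise ValueError("need at least two cells for a tessellation")
    if not 0 <= margin < 0.5:
        raise ValueError(f"margin must be in [0, 0.5), got {margin}")
    rng = rng if rng is not None else np.random.default_rng(seed)
    spacing = tuple(float(s) for s in spacing)
    if min_vertex_separation is None:
        min_vertex_separation = 1.5 * max(spacing)
    extent = np.asarray(shape, dtype=float) * np.asarray(spacing)
    lo, hi = extent * margin, extent * (1 - margin)
    min_seed_dist = max(spacing)  # seeds at least one voxel apart
    for _ in range(max_retries):
        pts = rng.uniform(lo, hi, size=(n_cells, 3))
        d = np.linalg.norm(pts[:, None] - pts[None], axis=-1)
        np.fill_diagonal(d, np.inf)
        if d.min() < min_seed_dist:
            continue
        if min_vertex_separation > 0 and n_cells >= 5:
            if _voronoi_feature_clearance(pts) < min_vertex_separation:
                continue
        labels = _label_nearest(pts, shape, spacing)
        return LabeledVolume(labels, spacing=spacing), pts
    raise DegenerateInputError(
        f"no generic seed configuration found in {max_retries} attempts "
        f"(n_cells={n_cells}, clearance={min_vertex_separation})"
    )


def make_weighted_voronoi_volume(
    n_cells: int,
    shape: Sequence[int] = (64, 64, 64),
    spacing: Sequence[float] = (1.0, 1.0, 1.0),
    weight_cv: float = 0.5,
    margin: float = 0.1,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[LabeledVolume, np.ndarray, np.ndarray]:
    """Additively weighted (Laguerre) tessellation with dispersed cell sizes.

    Each voxel is labeled by argmin over seeds of ‖x − p_i‖² − w_i.  Weights
    are scaled so that ``weight_cv`` controls the dispersion of realized
    cell volumes: larger dispersion produces a larger cell-volume CV, which
    is how cohorts with contrasting volume variability are emulated.
    Returns the volume, seeds and weights.
    """
    if n_cells < 2:
        raise ValueError("need at least two cells for a tessellation")
    rng = rng if rng is not None else np.random.default_rng(seed)
    spacing = tuple(float(s) for s in spacing)
    extent = np.asarray(shape, dtype=float) * np.asarray(spacing)
    lo, hi = extent * margin, extent * (1 - margin)
    pts = rng.uniform(lo, hi, size=(n_cells, 3))
    # typical squared nearest-neighbor spacing sets the weight scale
    d2_typ = (np.prod(extent) / n_cells) ** (2 / 3)
    weights = rng.normal(0.0, weight_cv, size=n_cells) * d2_typ
    centers = _voxel_centers(shape, spacing)
    labels = np.empty(centers.shape[0], dtype=np.int32)
    chunk = 1 << 18
    for start in range(0, centers.shape[0], chunk):
        c = centers[start:start + chunk]
        d2 = ((c[:, None, :] - pts[None]) ** 2).sum(-1) - weights[None]
        labels[start:start + chunk] = d2.argmin(1) + 1
    vol = LabeledVolume(labels.reshape(tuple(shape)), spacing=spacing)
    return vol, pts, weights


def make_layered_sheet_volume(
    n_cells: int,
    shape: Sequence[int] = (64, 64, 64),
    spacing: Sequence[float] = (1.0, 1.0, 1.0),
    n_layers: int = 2,
    jitter: float = 0.25,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[LabeledVolume, np.ndarray]:
    """Layered epithelial-sheet architecture: a thin slab of cell layers.

    Emulates the sheet organization of integument-like tissues: ``n_layers``
    single-cell-thick layers of roughly isotropic cells, stacked along the
    first axis and centered in the domain; voxels outside the slab are
    background (the surrounding space of the organ).  This contrasts with
    the space-filling bulk tessellation.  Seeds sit on an in-plane grid
    jittered by ``jitter`` grid pitches; the realized cell count is
    ``n_cells`` rounded to a full layers × grid arrangement.
    """
    if n_layers < 1:
        raise ValueError("need at least one layer")
    rng = rng if rng is not None else np.random.default_rng(seed)
    spacing = tuple(float(s) for s in spacing)
    extent = np.asarray(shape, dtype=float) * np.asarray(spacing)
    per_layer = max(1, round(n_cells / n_layers))
    ny = max(1, round(math.sqrt(per_layer)))
    nx = max(1, round(per_layer / ny))
    pitch_y, pitch_x = extent[1] / ny, extent[2] / nx
    height = min((pitch_y + pitch_x) / 2, extent[0] / n_layers)  # isotropic cells
    z0 = (extent[0] - n_layers * height) / 2
    zs = z0 + (np.arange(n_layers) + 0.5) * height
    pts = []
    for z in zs:
        for iy in range(ny):
            for ix in range(nx):
                base = np.array([z, (iy + 0.5) * pitch_y, (ix + 0.5) * pitch_x])
                wiggle = rng.uniform(-jitter, jitter, size=3) * np.array(
                    [height, pitch_y, pitch_x]
                )
                pts.append(base + wiggle)
    pts = np.asarray(pts)
    labels = _label_nearest(pts, shape, spacing)
    # clip to the slab: outside is the organ's exterior
    z_centers = (np.arange(shape[0]) + 0.5) * spacing[0]
    outside = (z_centers < z0) | (z_centers > z0 + n_layers * height)
    labels[outside] = 0
    return LabeledVolume(labels, spacing=spacing), pts


def make_hex_fixture(size: int = 96, radius_frac: float = 0.3) -> LabeledVolume:
    """Single-slice fixture: a hexagonal cell ringed by six closed neighbors.

    Label 1 is the central cell; labels 2–7 the ring, each adjacent to the
    center and to its two ring neighbors only.  The central cell's
    face-vector is (1, 6, 6); every ring cell's is (1, 3, 2).
    """
    c = size / 2.0
    r = size * radius_frac
    seeds = [(c, c)] + [
        (c + r * math.cos(math.pi / 3 * k), c + r * math.sin(math.pi / 3 * k))
        for k in range(6)
    ]
    seeds = np.asarray(seeds)
    yy, xx = np.mgrid[0:size, 0:size]
    pts = np.stack([yy + 0.5, xx + 0.5], axis=-1).reshape(-1, 2)
    d2 = ((pts[:, None, :] - seeds[None]) ** 2).sum(-1)
    labels = (d2.argmin(1) + 1).astype(np.int32).reshape(1, size, size)
    return LabeledVolume(labels)


def make_volume(spec: GeneratorSpec, rng: np.random.Generator | None = None) -> LabeledVolume:
    """Generate a labeled volume from a :class:`GeneratorSpec`."""
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    if spec.kind == "voronoi_bulk":
        # distributional use: sub-voxel dual features merge consistently,
        # so skip the resolvable-genericity rejection
        vol, _ = make_voronoi_volume(
            spec.n_cells, spec.shape, spec.spacing, spec.margin,
            min_vertex_separation=0.0, rng=rng,
        )
        return vol
    if spec.kind == "weighted_voronoi":
        vol, _, _ = make_weighted_voronoi_volume(
            spec.n_cells, spec.shape, spec.spacing,
            weight_cv=spec.volume_cv, margin=spec.margin, rng=rng,
        )
        return vol
    if spec.kind == "layered_sheet":
        vol, _ = make_layered_sheet_volume(
            spec.n_cells, spec.shape, spec.spacing, n_layers=spec.n_layers, rng=rng,
        )
        return vol
    return make_hex_fixture()


def make_cohort_pair(
    spec_a: GeneratorSpec,
    spec_b: GeneratorSpec,
    n_samples: int,
    seed: int | None = None,
) -> tuple[list[LabeledVolume], list[LabeledVolume]]:
    """Two cohorts of independent volumes, one per generator spec.

    Per-sample RNG streams are spawned from the master seed, so the same
    master seed reproduces both cohorts exactly; with ``spec_a == spec_b``
    this is a null configuration (both cohorts from one distribution).
    """
    if n_samples < 2:
        raise ValueError("need at least two samples per cohort")
    children = np.random.SeedSequence(seed).spawn(2 * n_samples)
    cohort_a = [make_volume(spec_a, rng=np.random.default_rng(children[i]))
                for i in range(n_samples)]
    cohort_b = [make_volume(spec_b, rng=np.random.default_rng(children[n_samples + i]))
                for i in range(n_samples)]
    return cohort_a, cohort_b


def make_growth_series(
    stage_means: Mapping[str, Sequence[float]],
    stages: Sequence[str] | None = None,
    n_samples: int = 5,
    cells_per_tissue: int = 50,
    volume_cv: float = 0.0,
    cohort: str = "synthetic",
    seed: int | None = None,
) -> pd.DataFrame:
    """Synthetic long-format cell table across an ordered stage series.

    ``stage_means`` maps tissue → per-stage mean cell volume (µm³).  Each
    sample at each stage receives ``cells_per_tissue`` cells per tissue with
    lognormal volumes of the given mean and coefficient of variation
    (``volume_cv=0`` gives exactly the mean), so the growth statistics of
    the output are known from the inputs.
    """
    n_stages = {len(v) for v in stage_means.values()}
    if len(n_stages) != 1:
        raise ValueError("all tissues need the same number of stage means")
    k = n_stages.pop()
    if stages is None:
        stages = DEFAULT_STAGE_ORDER[:k]
    if len(stages) != k:
        raise ValueError(f"{k} stage means but {len(stages)} stage names")
    for tissue, means in stage_means.items():
        if any(m <= 0 for m in means):
            raise ValueError(f"non-positive mean volume for tissue {tissue!r}")
    if volume_cv < 0:
        raise ValueError("volume_cv must be >= 0")
    rng = np.random.default_rng(seed)
    sigma2 = math.log1p(volume_cv**2)
    rows = []
    for si, stage in enumerate(stages):
        for rep in range(n_samples):
            sample = f"{stage}_s{rep}"
            cell_id = 1
            for tissue, means in stage_means.items():
                m = float(means[si])
                if volume_cv == 0:
                    vols = np.full(cells_per_tissue, m)
                else:
                    mu = math.log(m) - sigma2 / 2
                    vols = rng.lognormal(mu, math.sqrt(sigma2), size=cells_per_tissue)
                for v in vols:
                    rows.append({
                        "sample_id": sample, "cohort": cohort, "stage": stage,
                        "cell_id": cell_id, "tissue_id": str(tissue), "volume": float(v),
                    })
                    cell_id += 1
    df = pd.DataFrame(rows)
    return _validate_cell_table(df, tuple(stages), origin="synthetic growth series")


def _circumsphere(p: np.ndarray) -> tuple[np.ndarray | None, float]:
    """Circumcenter and radius of d+1 points in d dims; (None, 0) if flat."""
    A = 2 * (p[1:] - p[0])
    b = (p[1:] ** 2).sum(1) - (p[0] ** 2).sum()
    scale = np.abs(A).max()
    if scale == 0 or abs(np.linalg.det(A)) < 1e-12 * scale ** p.shape[1]:
        return None, 0.0
    c = np.linalg.solve(A, b)
    return c, float(np.linalg.norm(p[0] - c))


def brute_force_delaunay(
    points: np.ndarray,
    spacing: Sequence[float] | None = None,
    rtol: float = 1e-9,
) -> frozenset[frozenset[int]]:
    """Delaunay simplices by exhaustive empty-circumsphere enumeration.

    A set of d+1 points spans a Delaunay d-simplex iff its circumsphere
    contains no other point strictly inside; lower simplices are the faces
    of those (the Delaunay complex of generic points is pure).  Returns
    frozensets of 0-based point indices, downward closed.  Intended as an
    independent oracle on ≤ 25 points; raises on near-cospherical
    configurations (within ``rtol`` relative to the radius).
    """
    pts = np.asarray(points, dtype=float)
    if spacing is not None:
        pts = pts * np.asarray(spacing, dtype=float)
    n, d = pts.shape
    if d not in (2, 3):
        raise ValueError(f"oracle supports 2D and 3D points, got d={d}")
    if n > 25:
        raise ValueError("exhaustive oracle is limited to 25 points")
    if n < d + 1:
        raise ValueError(f"need at least {d + 1} points in {d}D")
    top: list[tuple[int, ...]] = []
    for comb in itertools.combinations(range(n), d + 1):
        c, r = _circumsphere(pts[list(comb)])
        if c is None:
            continue  # flat subset: not a top simplex of a generic set
        dist = np.linalg.norm(pts - c, axis=1)
        others = np.setdiff1d(np.arange(n), comb)
        if others.size and np.any(np.abs(dist[others] - r) <= rtol * r):
            raise DegenerateInputError(
                f"points {comb} have a near-cospherical neighbor; "
                "perturb the input or loosen rtol"
            )
        if not others.size or np.all(dist[others] > r):
            top.append(comb)
    simplices: set[frozenset[int]] = set()
    for t in top:
        for k in range(1, d + 2):
            for comb in itertools.combinations(t, k):
                simplices.add(frozenset(comb))
    return frozenset(simplices)
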