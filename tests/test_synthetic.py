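"""Generators: determinism, ground truth, and the Delaunay oracle itself."""

import numpy as np
import pytest

from cellnerve import (
    GeneratorSpec,
    brute_force_delaunay,
    build_nerve,
    cvcv,
    make_cohort_pair,
    make_growth_series,
    make_hex_fixture,
    make_layered_sheet_volume,
    make_volume,
    make_voronoi_volume,
    make_weighted_voronoi_volume,
)
from cellnerve.errors import DegenerateInputError


def test_voronoi_two_seeds_planar_interface():
    vol, pts = make_voronoi_volume(2, shape=(16, 16, 16), seed=0,
                                   min_vertex_separation=0.0)
    assert vol.n_cells == 2
    n = build_nerve(vol)
    assert frozenset({1, 2}) in n.simplices


def test_voronoi_determinism_and_label_count():
    v1, p1 = make_voronoi_volume(20, shape=(32, 32, 32), seed=9,
                                 min_vertex_separation=0.0)
    v2, p2 = make_voronoi_volume(20, shape=(32, 32, 32), seed=9,
                                 min_vertex_separation=0.0)
    np.testing.assert_array_equal(v1.labels, v2.labels)
    np.testing.assert_array_equal(p1, p2)
    assert v1.n_cells == 20


def test_voronoi_margin_respected():
    _, pts = make_voronoi_volume(10, shape=(40, 40, 40), margin=0.2, seed=1,
                                 min_vertex_separation=0.0)
    assert pts.min() >= 8.0 and pts.max() <= 32.0


def test_voronoi_degenerate_configuration_raises():
    with pytest.raises((DegenerateInputError, ValueError)):
        # clearance larger than the box cannot be satisfied
        make_voronoi_volume(15, shape=(16, 16, 16), seed=0,
                            min_vertex_separation=100.0, max_retries=5)


def test_voronoi_refinement_stability():
    """Doubling resolution does not change the interior nerve."""
    _, pts = make_voronoi_volume(12, shape=(32, 32, 32), seed=21)
    from cellnerve.synthetic import _label_nearest
    from cellnerve import LabeledVolume

    v1 = LabeledVolume(_label_nearest(pts, (32, 32, 32), (1, 1, 1)))
    v2 = LabeledVolume(_label_nearest(pts * 2, (64, 64, 64), (1, 1, 1)),
                       spacing=(1.0, 1.0, 1.0))
    n1, n2 = build_nerve(v1), build_nerve(v2)
    interior = v1.interior_labels() & v2.interior_labels()
    assert {s for s in n1.simplices if s <= interior} == \
           {s for s in n2.simplices if s <= interior}


def test_hex_fixture_structure(hex_volume, hex_nerve):
    assert hex_volume.n_cells == 7
    assert hex_nerve.face_vector(1) == (1, 6, 6)
    ring = [hex_nerve.face_vector(c) for c in range(2, 8)]
    assert ring == [(1, 3, 2)] * 6
    # closed ring: consecutive ring cells adjacent, non-consecutive not
    for k in range(6):
        a, b = 2 + k, 2 + (k + 1) % 6
        assert frozenset({a, b}) in hex_nerve.simplices
        c = 2 + (k + 2) % 6
        assert frozenset({a, c}) not in hex_nerve.simplices


def test_layered_sheet_layers():
    vol, pts = make_layered_sheet_volume(32, shape=(32, 32, 32), n_layers=2, seed=4)
    assert vol.n_cells == len(pts)
    # seeds split into two z-bands
    z = pts[:, 0]
    assert (z < 16).sum() == (z >= 16).sum()


def test_weighted_voronoi_cv_monotone_in_dispersion():
    """Larger weight dispersion gives larger realized cell-volume CV (on average)."""

    def realized_cv(weight_cv, seed):
        vol, _, _ = make_weighted_voronoi_volume(
            30, shape=(32, 32, 32), weight_cv=weight_cv, seed=seed)
        counts = np.bincount(vol.labels.ravel())[1:]
        counts = counts[counts > 0]
        return cvcv(counts.astype(float))

    lo = np.mean([realized_cv(0.05, s) for s in range(4)])
    hi = np.mean([realized_cv(1.0, s) for s in range(4)])
    assert hi > lo


def test_cohort_pair_reproducible():
    spec = GeneratorSpec(kind="voronoi_bulk", n_cells=15, shape=(24, 24, 24))
    a1, b1 = make_cohort_pair(spec, spec, n_samples=2, seed=5)
    a2, b2 = make_cohort_pair(spec, spec, n_samples=2, seed=5)
    for v1, v2 in zip(a1 + b1, a2 + b2):
        np.testing.assert_array_equal(v1.labels, v2.labels)
    # cohorts are independent draws, not copies
    assert not np.array_equal(a1[0].labels, b1[0].labels)


def test_make_volume_kinds():
    assert make_volume(GeneratorSpec(kind="hex_fixture")).n_cells == 7
    sheet = make_volume(GeneratorSpec(kind="layered_sheet", n_cells=18,
                                      shape=(24, 24, 24), seed=1))
    assert sheet.n_cells >= 2


def test_growth_series_zero_noise_exact():
    table = make_growth_series({"L1": [10.0, 15.0]}, stages=("1-I", "1-II"),
                               n_samples=3, cells_per_tissue=4, volume_cv=0.0, seed=0)
    assert set(table["volume"]) == {10.0, 15.0}
    assert len(table) == 2 * 3 * 4


def test_growth_series_cv_recovered():
    table = make_growth_series({"L1": [50.0]}, stages=("1-I",), n_samples=1,
                               cells_per_tissue=500, volume_cv=0.3, seed=11)
    assert cvcv(table["volume"]) == pytest.approx(0.3, abs=0.03)
    # and the mean is as requested
    assert table["volume"].mean() == pytest.approx(50.0, rel=0.05)


def test_growth_series_determinism_and_validation():
    kw = dict(stages=("1-I",), n_samples=2, cells_per_tissue=10,
              volume_cv=0.2, seed=3)
    t1 = make_growth_series({"L1": [20.0]}, **kw)
    t2 = make_growth_series({"L1": [20.0]}, **kw)
    assert t1.equals(t2)
    with pytest.raises(ValueError):
        make_growth_series({"L1": [-5.0]}, stages=("1-I",))
    with pytest.raises(ValueError):
        make_growth_series({"L1": [1.0], "L2": [1.0, 2.0]})


# --- the brute-force empty-circumsphere oracle itself -----------------------

def test_oracle_triangle_2d():
    pts = np.array([[0.0, 0.0], [1.0, 0.0], [0.3, 0.8]])
    simp = brute_force_delaunay(pts)
    assert frozenset({0, 1, 2}) in simp
    assert len(simp) == 7  # 3 vertices + 3 edges + 1 triangle


def test_oracle_tetrahedron_3d():
    pts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1.0]]) \
        + np.array([0.01, 0.02, 0.03])
    simp = brute_force_delaunay(pts)
    assert frozenset({0, 1, 2, 3}) in simp
    assert len(simp) == 15  # full boundary complex of one tetrahedron


def test_oracle_near_cospherical_raises():
    # four points on the unit circle plus one almost on it
    ang = np.array([0.1, 1.7, 3.0, 4.6])
    pts = np.c_[np.cos(ang), np.sin(ang)]
    pts = np.vstack([pts, [np.cos(5.5) * (1 + 1e-12), np.sin(5.5) * (1 + 1e-12)]])
    with pytest.raises(DegenerateInputError):
        brute_force_delaunay(pts)


def test_oracle_matches_scipy_delaunay(rng):
    """Cross-check against an independently implemented triangulation."""
    from scipy.spatial import Delaunay

    for _ in range(3):
        pts = rng.uniform(0, 10, size=(10, 3))
        ours = brute_force_delaunay(pts)
        ref = set()
        for tet in Delaunay(pts).simplices:
            t = tuple(sorted(int(i) for i in tet))
            import itertools

            for k in range(1, 5):
                for comb in itertools.combinations(t, k):
                    ref.add(frozenset(comb))
        assert ours == ref


def test_oracle_size_guard(rng):
    with pytest.raises(ValueError):
        brute_force_delaunay(rng.uniform(size=(26, 3)))
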