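"""Voronoi tessellation and density segmentation against brute-force oracles."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sevenq import (
    DegenerateGeometryError,
    SegmentationParams,
    compute_voronoi,
    segment_clusters,
    tessellate,
)
from geometry_oracle import cell_areas, dense_components, shared_edge_adjacency
from conftest import make_blob

BOUNDS = (0.0, 0.0, 1000.0, 1000.0)


def test_quadrant_centers_split_roi_into_equal_cells():
    pts = np.array([[250.0, 250.0], [750.0, 250.0], [250.0, 750.0], [750.0, 750.0]])
    areas = compute_voronoi(pts, BOUNDS)
    assert np.allclose(areas, 250_000.0, rtol=1e-9)


def test_areas_match_bisector_clipping_oracle(rng):
    pts = rng.uniform(0.0, 1000.0, size=(100, 2))
    areas = compute_voronoi(pts, BOUNDS)
    expected = cell_areas(pts, BOUNDS)
    assert np.allclose(areas, expected, rtol=1e-6)
    assert np.isclose(areas.sum(), 1e6, rtol=1e-6)


@settings(deadline=None, derandomize=True, max_examples=25)
@given(st.integers(min_value=3, max_value=60), st.integers(min_value=0, max_value=2**31 - 1))
def test_cell_areas_always_tile_the_roi(n, seed):
    """Tessellation conservation: clipped cell areas sum to the ROI area."""
    pts = np.random.default_rng(seed).uniform(0.0, 1000.0, size=(n, 2))
    if len(np.unique(pts.round(6), axis=0)) < 3:
        return
    try:
        areas = compute_voronoi(pts, BOUNDS)
    except DegenerateGeometryError:
        return
    assert np.isclose(areas.sum(), 1e6, rtol=1e-6)
    assert (areas > 0).all()


def test_edge_adjacency_matches_polygon_oracle(rng):
    pts = rng.uniform(0.0, 1000.0, size=(60, 2))
    tess = tessellate(pts, BOUNDS)
    ours = {frozenset(map(int, e)) for e in tess.edges}
    assert ours == shared_edge_adjacency(pts, BOUNDS)


def test_segmentation_equals_bruteforce_components(rng):
    """Merged dense components equal an exhaustive shared-edge search."""
    pts = np.vstack(
        [
            make_blob(rng, (200, 200), 60),
            make_blob(rng, (800, 300), 70),
            rng.uniform(0.0, 1000.0, size=(120, 2)),
        ]
    )
    params = SegmentationParams(min_cluster_size=40, density_factor_alpha=2.0)
    tess = tessellate(pts, BOUNDS)
    clusters = segment_clusters(tess, params)
    ours = {frozenset(map(int, cl.member_indices)) for cl in clusters}
    oracle = {
        c
        for c in dense_components(pts, BOUNDS, tess.areas, params.density_factor_alpha)
        if len(c) >= params.min_cluster_size
    }
    assert ours == oracle


def test_three_separated_blobs_give_three_clusters(rng):
    pts = np.vstack(
        [
            make_blob(rng, (2000, 2000), 60),
            make_blob(rng, (7000, 2500), 60),
            make_blob(rng, (5000, 8000), 60),
            rng.uniform(0.0, 10_000.0, size=(60, 2)),
        ]
    )
    tess = tessellate(pts, (0, 0, 10_000, 10_000))
    clusters = segment_clusters(tess, SegmentationParams())
    assert len(clusters) == 3
    assert all(cl.n_loc >= 40 for cl in clusters)


def test_blob_below_min_size_is_discarded(rng):
    pts = np.vstack(
        [make_blob(rng, (5000, 5000), 39), rng.uniform(0.0, 10_000.0, size=(40, 2))]
    )
    tess = tessellate(pts, (0, 0, 10_000, 10_000))
    assert segment_clusters(tess, SegmentationParams(min_cluster_size=40)) == []
    # the same blob passes with the threshold lowered by one
    assert len(segment_clusters(tess, SegmentationParams(min_cluster_size=39))) == 1


def test_homogeneous_background_rarely_clusters():
    """Null calibration: a CSR background almost never yields a cluster."""
    params = SegmentationParams()
    n_rois_with_clusters = 0
    master = np.random.default_rng(987)
    for _ in range(100):
        pts = master.uniform(0.0, 10_000.0, size=(300, 2))
        clusters = segment_clusters(tessellate(pts, (0, 0, 10_000, 10_000)), params)
        n_rois_with_clusters += len(clusters) > 1
    assert n_rois_with_clusters <= 5


def test_membership_invariant_to_row_order(rng):
    pts = np.vstack(
        [make_blob(rng, (300, 700), 50), rng.uniform(0.0, 1000.0, size=(80, 2))]
    )
    perm = rng.permutation(len(pts))
    params = SegmentationParams(min_cluster_size=10)

    def member_coord_sets(points):
        clusters = segment_clusters(tessellate(points, BOUNDS), params)
        return {
            frozenset(map(tuple, np.round(points[cl.member_indices], 6)))
            for cl in clusters
        }

    assert member_coord_sets(pts) == member_coord_sets(pts[perm])


def test_raising_alpha_never_adds_clustered_points(rng):
    pts = np.vstack(
        [
            make_blob(rng, (400, 400), 80, sd_nm=40),
            make_blob(rng, (700, 800), 60, sd_nm=30),
            rng.uniform(0.0, 1000.0, size=(150, 2)),
        ]
    )
    tess = tessellate(pts, BOUNDS)
    totals = []
    for alpha in (0.5, 1.0, 2.0, 4.0, 8.0):
        clusters = segment_clusters(
            tess, SegmentationParams(min_cluster_size=10, density_factor_alpha=alpha)
        )
        totals.append(sum(cl.n_loc for cl in clusters))
    assert totals == sorted(totals, reverse=True)


def test_partition_discipline(rng):
    """Every localization belongs to at most one cluster."""
    pts = np.vstack(
        [make_blob(rng, (500, 500), 120, sd_nm=60), rng.uniform(0, 1000, (100, 2))]
    )
    clusters = segment_clusters(
        tessellate(pts, BOUNDS), SegmentationParams(min_cluster_size=10)
    )
    all_members = np.concatenate([cl.member_indices for cl in clusters]) if clusters else []
    assert len(all_members) == len(set(map(int, all_members)))


def test_boundary_touching_cells_are_flagged(rng):
    pts = np.vstack([[[1.0, 500.0]], rng.uniform(200, 800, (30, 2))])
    tess = tessellate(pts, BOUNDS)
    assert tess.boundary_mask[0]
    interior = np.argmin(np.sum((pts - 500.0) ** 2, axis=1))
    assert not tess.boundary_mask[interior]


@pytest.mark.parametrize(
    "pts",
    [
        np.array([[1.0, 1.0], [2.0, 2.0]]),
        np.array([[1.0, 1.0], [2.0, 2.0], [3.0, 3.0], [4.0, 4.0]]),
    ],
    ids=["too_few", "collinear"],
)
def test_degenerate_geometry_raises_with_roi_name(pts):
    with pytest.raises(DegenerateGeometryError, match="ROI 7"):
        tessellate(pts, BOUNDS, roi_id=7)


def test_duplicate_coordinates_are_tessellated(rng):
    base = rng.uniform(0, 1000, (20, 2))
    pts = np.vstack([base, base[:5]])  # 5 exact duplicates
    areas = compute_voronoi(pts, BOUNDS)
    assert np.isfinite(areas).all() and (areas > 0).all()
    assert np.isclose(areas.sum(), 1e6, rtol=1e-6)
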