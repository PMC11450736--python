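"""Voronoi tessellation and density-based segmentation of localization maps.

The tessellation of one ROI is computed by augmenting the point set with its
reflections across the four edges of the ROI rectangle. For any query point
inside the rectangle a reflected point is strictly farther away than its
original, so the Voronoi cells of the original points in the augmented
diagram, which are bounded by the edge lines themselves, are exactly the
cells of the original diagram clipped to the ROI. Cell areas are therefore
exact and sum to the ROI area, and cells bordered by a reflected point are
precisely those touching the ROI boundary.

Segmentation follows the usual SMLM density convention: a localization is
"dense" when its first-rank density 1/area exceeds alpha times the ROI mean
density N/ROI_area; dense cells sharing a Voronoi edge are merged by
connected components and components smaller than the minimum cluster size
(40 localizations) are discarded.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import Voronoi

from .config import SegmentationParams
from .errors import DegenerateGeometryError

Bounds = tuple[float, float, float, float]  # xmin, ymin, xmax, ymax


@dataclass
class Tessellation:
    """Clipped Voronoi tessellation of one ROI's localizations."""

    points: np.ndarray  # (N, 2), possibly jittered copies of the input
    bounds: Bounds
    areas: np.ndarray  # (N,) clipped cell areas, nm^2
    edges: np.ndarray  # (M, 2) indices of cells sharing a Voronoi edge
    boundary_mask: np.ndarray  # (N,) True where the cell touches the ROI edge

    @property
    def roi_area(self) -> float:
        xmin, ymin, xmax, ymax = self.bounds
        return (xmax - xmin) * (ymax - ymin)


@dataclass
class VoronoiCluster:
    """A segmented dense group of localizations."""

    roi_id: int
    cluster_id: int
    member_indices: np.ndarray
    n_loc: int
    centroid_xy_nm: tuple[float, float]
    mean_sq_radius_nm2: float
    touches_boundary: bool
    mean_precision_nm: float | None = None


def _dedup_jitter(points: np.ndarray, side: float) -> np.ndarray:
    """Deterministically jitter duplicated coordinates by <= 1e-6 nm.

    Degenerate tessellations with coincident sites are otherwise undefined;
    the displacement is a hash of the row index so it is independent of the
    random stream and reproducible.
    """
    _, first = np.unique(points.round(9), axis=0, return_index=True)
    dup = np.ones(len(points), bool)
    dup[first] = False
    if not dup.any():
        return points
    idx = np.flatnonzero(dup)
    mixed = (idx.astype(np.uint64) * np.uint64(2654435761)) % np.uint64(2_000_003)
    ang = mixed.astype(float) / 2_000_003.0 * 2 * np.pi
    mag = 1e-6 * (0.5 + (idx % 7) / 14.0)
    out = points.copy()
    out[idx, 0] += mag * np.cos(ang)
    out[idx, 1] += mag * np.sin(ang)
    return out


def _mirrored(points: np.ndarray, bounds: Bounds, subset: np.ndarray) -> np.ndarray:
    """Original points plus reflections of ``subset`` across the four edges."""
    xmin, ymin, xmax, ymax = bounds
    s = points[subset]
    left = s * [-1, 1] + [2 * xmin, 0]
    right = s * [-1, 1] + [2 * xmax, 0]
    down = s * [1, -1] + [0, 2 * ymin]
    up = s * [1, -1] + [0, 2 * ymax]
    return np.vstack([points, left, right, down, up])


def _needs_mirror(vor: Voronoi, n: int, bounds: Bounds) -> np.ndarray:
    """Sites whose raw (unmirrored) cell is unbounded or pokes past the box."""
    xmin, ymin, xmax, ymax = bounds
    v = vor.vertices
    vert_out = (
        (v[:, 0] < xmin) | (v[:, 0] > xmax) | (v[:, 1] < ymin) | (v[:, 1] > ymax)
    )
    needs = np.zeros(n, bool)
    for i in range(n):
        region = vor.regions[vor.point_region[i]]
        if -1 in region or vert_out[region].any():
            needs[i] = True
    return needs


def _polygon_areas(vor: Voronoi, n: int) -> np.ndarray:
    """Shoelace areas of the (finite, convex) cells of the first ``n`` sites."""
    regions = [vor.regions[vor.point_region[i]] for i in range(n)]
    counts = np.fromiter((len(r) for r in regions), int, n)
    flat = np.fromiter((v for r in regions for v in r), int, counts.sum())
    xy = vor.vertices[flat]
    rid = np.repeat(np.arange(n), counts)
    starts = np.r_[0, np.cumsum(counts)[:-1]]
    # convex cells: order vertices by angle around the per-cell vertex mean
    cen = np.add.reduceat(xy, starts, axis=0) / counts[:, None]
    d = xy - cen[rid]
    order = np.lexsort((np.arctan2(d[:, 1], d[:, 0]), rid))
    xs, ys = xy[order, 0], xy[order, 1]
    nxt = np.arange(flat.size) + 1
    ends = np.cumsum(counts) - 1
    nxt[ends] = starts
    cross = xs * ys[nxt] - ys * xs[nxt]
    return 0.5 * np.abs(np.add.reduceat(cross, starts))


def tessellate(points: np.ndarray, bounds: Bounds, roi_id: int | None = None) -> Tessellation:
    """Compute the box-clipped Voronoi tessellation of one ROI.

    Raises :class:`DegenerateGeometryError` for fewer than three points or an
    all-collinear configuration, naming the ROI when known.
    """
    pts = np.asarray(points, float).reshape(-1, 2)
    label = f"ROI {roi_id}" if roi_id is not None else "point set"
    if len(pts) < 3:
        raise DegenerateGeometryError(f"{label}: need >= 3 localizations, got {len(pts)}")
    xmin, ymin, xmax, ymax = bounds
    side = max(xmax - xmin, ymax - ymin)
    pts = _dedup_jitter(pts, side)
    centered = pts - pts.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-9 * side) < 2:
        raise DegenerateGeometryError(f"{label}: localizations are collinear")
    # sites exactly on the boundary would coincide with their mirror image
    eps = 1e-9 * side
    pts = np.clip(pts, [xmin + eps, ymin + eps], [xmax - eps, ymax - eps])

    n = len(pts)
    # pass 1: raw diagram identifies the cells that reach the box edge; only
    # those sites need their reflections added (cells strictly inside the box
    # are unaffected, since a reflection is never nearer than its original)
    raw = Voronoi(pts)
    subset = np.flatnonzero(_needs_mirror(raw, n, bounds))
    vor = Voronoi(_mirrored(pts, bounds, subset))
    areas = _polygon_areas(vor, n)

    rp = vor.ridge_points
    internal = (rp[:, 0] < n) & (rp[:, 1] < n)
    edges = np.sort(rp[internal], axis=1)
    boundary_mask = np.zeros(n, bool)
    with_mirror = rp[(rp[:, 0] < n) ^ (rp[:, 1] < n)]
    boundary_mask[with_mirror.min(axis=1)] = True
    return Tessellation(pts, bounds, areas, edges, boundary_mask)


def compute_voronoi(points: np.ndarray, bounds: Bounds, roi_id: int | None = None) -> np.ndarray:
    """Per-localization Voronoi cell areas (nm^2), clipped to the ROI bounds."""
    return tessellate(points, bounds, roi_id=roi_id).areas


def segment_clusters(
    tess: Tessellation,
    params: SegmentationParams,
    roi_id: int = 0,
    precisions: np.ndarray | None = None,
) -> list[VoronoiCluster]:
    """Merge edge-adjacent dense cells and keep components of >= min size.

    Clusters are ordered (and numbered) by centroid position so the output is
    invariant to the input row order.
    """
    n = len(tess.points)
    density = 1.0 / tess.areas
    mean_density = n / tess.roi_area
    dense = density > params.density_factor_alpha * mean_density

    e = tess.edges
    keep = dense[e[:, 0]] & dense[e[:, 1]]
    e = e[keep]
    adj = coo_matrix(
        (np.ones(len(e)), (e[:, 0], e[:, 1])), shape=(n, n)
    )
    n_comp, labels = connected_components(adj, directed=False)
    labels = np.where(dense, labels, -1)

    clusters = []
    for lab in np.unique(labels[labels >= 0]):
        members = np.flatnonzero(labels == lab)
        if len(members) < params.min_cluster_size:
            continue
        xy = tess.points[members]
        c = xy.mean(axis=0)
        msr = float(np.mean(np.sum((xy - c) ** 2, axis=1)))
        # a cluster is boundary-truncated when its footprint (3 rms radii)
        # crosses the ROI edge; raw cell adjacency would also flag central
        # clusters in sparse fields, whose outer cells stretch to the edge
        xmin, ymin, xmax, ymax = tess.bounds
        edge_dist = min(c[0] - xmin, xmax - c[0], c[1] - ymin, ymax - c[1])
        touches = edge_dist < 3.0 * np.sqrt(msr)
        clusters.append(
            VoronoiCluster(
                roi_id=roi_id,
                cluster_id=-1,
                member_indices=members,
                n_loc=len(members),
                centroid_xy_nm=(float(c[0]), float(c[1])),
                mean_sq_radius_nm2=msr,
                touches_boundary=bool(touches),
                mean_precision_nm=(
                    float(np.mean(precisions[members])) if precisions is not None else None
                ),
            )
        )
    clusters.sort(key=lambda cl: (cl.centroid_xy_nm[1], cl.centroid_xy_nm[0]))
    for i, cl in enumerate(clusters):
        cl.cluster_id = i
    return clusters
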