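"""Independent brute-force Voronoi oracle used by the tessellation tests.

Each cell is constructed by clipping the ROI rectangle with the
perpendicular-bisector half-plane against every other site (shapely), with
no shared code with the implementation under test. Adjacency is read off
the clipped polygons: two cells are edge-adjacent when their intersection
has positive length.
"""
from __future__ import annotations

import numpy as np
from shapely.geometry import Polygon, box

_BIG = 1e7


def _halfplane(pi: np.ndarray, pj: np.ndarray) -> Polygon:
    """Half-plane of points nearer to ``pi`` than ``pj``, as a big polygon."""
    u = pj - pi
    u = u / np.linalg.norm(u)
    perp = np.array([-u[1], u[0]])
    mid = (pi + pj) / 2.0
    a = mid + _BIG * perp
    b = mid - _BIG * perp
    return Polygon([a, b, b - _BIG * u, a - _BIG * u])


def clipped_cell(points: np.ndarray, i: int, bounds) -> Polygon:
    """Voronoi cell of site ``i`` clipped to the bounding rectangle."""
    xmin, ymin, xmax, ymax = bounds
    cell = box(xmin, ymin, xmax, ymax)
    for j in range(len(points)):
        if j == i:
            continue
        cell = cell.intersection(_halfplane(points[i], points[j]))
        if cell.is_empty:
            break
    return cell


def cell_areas(points: np.ndarray, bounds) -> np.ndarray:
    return np.array([clipped_cell(points, i, bounds).area for i in range(len(points))])


def shared_edge_adjacency(points: np.ndarray, bounds) -> set[frozenset]:
    """Pairs of sites whose clipped cells share a boundary segment.

    The separately clipped polygons agree on shared edges only to floating
    point, so sharing is detected by dilating one cell by ``eps``: a shared
    edge of length L overlaps with area ~ eps * L, whereas a corner touch
    gives only ~ eps^2.
    """
    eps = 1e-6
    cells = [clipped_cell(points, i, bounds) for i in range(len(points))]
    dilated = [c.buffer(eps) for c in cells]
    pairs = set()
    for i in range(len(points)):
        for j in range(i + 1, len(points)):
            if dilated[i].intersection(cells[j]).area > 1e3 * eps * eps:
                pairs.add(frozenset((i, j)))
    return pairs


def dense_components(
    points: np.ndarray, bounds, areas: np.ndarray, alpha: float
) -> list[frozenset]:
    """Connected components of dense cells via the brute-force adjacency."""
    xmin, ymin, xmax, ymax = bounds
    roi_area = (xmax - xmin) * (ymax - ymin)
    dense = (1.0 / areas) > alpha * len(points) / roi_area
    adj = shared_edge_adjacency(points, bounds)
    parent = list(range(len(points)))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for pair in adj:
        i, j = tuple(pair)
        if dense[i] and dense[j]:
            parent[find(i)] = find(j)
    comps: dict[int, set] = {}
    for i in np.flatnonzero(dense):
        comps.setdefault(find(i), set()).add(int(i))
    return [frozenset(c) for c in comps.values()]
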