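"""Spatial structures for point-referenced chamber data.

Two structures feed the spatial models: a Euclidean pairwise distance
matrix (geostatistical correlation) and a first-order neighbourhood
adjacency matrix derived from Thiessen (Voronoi) polygons clipped to the
field boundary (intrinsic CAR prior). Sites are planar metre coordinates;
no geodesy is applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Voronoi
from scipy.spatial.distance import pdist, squareform
from shapely.geometry import Polygon, box

logger = logging.getLogger(__name__)

#: shared Voronoi edges shorter than this (metres) are treated as point
#: contacts, not boundaries — the four-corner degeneracy tie-break
EDGE_LENGTH_TOL = 1e-9


@dataclass(frozen=True)
class SiteCoordinates:
    """Planar site locations (metres), origin at a field corner."""

    site_id: np.ndarray  # (Q,) integer labels
    x: np.ndarray  # (Q,) metres
    y: np.ndarray  # (Q,) metres

    def __post_init__(self):
        sid = np.asarray(self.site_id)
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if len(sid) != len(x) or len(x) != len(y):
            raise ValueError("site_id, x, y must have equal length")
        if len(sid) < 2:
            raise ValueError("need at least 2 sites")
        if len(np.unique(sid)) != len(sid):
            raise ValueError("site ids must be unique")
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
            raise ValueError("coordinates must be finite")
        object.__setattr__(self, "site_id", sid)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)

    @property
    def n_sites(self) -> int:
        return len(self.site_id)

    @property
    def xy(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric Euclidean distance matrix with its distinct-pair extremes."""

    d: np.ndarray  # (Q, Q) metres
    d_min: float
    d_max: float


@dataclass(frozen=True)
class SpatialWeights:
    """Binary first-order adjacency W from shared Thiessen-polygon edges."""

    w: np.ndarray  # (Q, Q) 0/1, zero diagonal, symmetric
    boundary: tuple = ()  # (xmin, ymin, xmax, ymax) clipping rectangle
    cells: tuple = field(default=(), repr=False, compare=False)

    @property
    def row_sums(self) -> np.ndarray:
        """Neighbour counts w_i+ per site."""
        return self.w.sum(axis=1)

    def neighbour_lists(self) -> list[np.ndarray]:
        return [np.flatnonzero(row) for row in self.w]

    def is_connected(self) -> bool:
        from scipy.sparse.csgraph import connected_components

        n_comp, _ = connected_components(self.w, directed=False)
        return n_comp == 1


def pairwise_distances(coords: SiteCoordinates) -> DistanceMatrix:
    """Euclidean distance matrix between all site pairs.

    Raises ``ValueError`` naming the first coincident pair, since a zero
    inter-site distance breaks the decay-parameter prior construction.
    """
    condensed = pdist(coords.xy)
    d = squareform(condensed)
    if np.any(condensed <= 0):
        q = coords.n_sites
        i, j = np.triu_indices(q, k=1)
        k = np.argmax(condensed <= 0)
        raise ValueError(
            f"sites {coords.site_id[i[k]]} and {coords.site_id[j[k]]} "
            "have coincident coordinates (zero distance)"
        )
    return DistanceMatrix(d=d, d_min=float(condensed.min()), d_max=float(condensed.max()))


def _expand_rect(rect: tuple, margin_frac: float) -> tuple:
    xmin, ymin, xmax, ymax = rect
    mx = (xmax - xmin) * margin_frac
    my = (ymax - ymin) * margin_frac
    return (xmin - mx, ymin - my, xmax + mx, ymax + my)


def _collinear(points: np.ndarray, tol: float = 1e-12) -> bool:
    if len(points) < 3:
        return True
    p0 = points[0]
    v = points - p0
    cross = v[:, 0, None] * v[None, :, 1] - v[:, 1, None] * v[None, :, 0]
    scale = max(1.0, float(np.abs(v).max()) ** 2)
    return bool(np.all(np.abs(cross) < tol * scale))


def _chain_adjacency(points: np.ndarray) -> np.ndarray:
    """1-D fallback for all-collinear layouts: neighbours along the line."""
    q = len(points)
    direction = points[-1] - points[0]
    if np.allclose(direction, 0):
        direction = points[1] - points[0]
    t = points @ direction
    order = np.argsort(t)
    w = np.zeros((q, q), dtype=int)
    for a, b in zip(order[:-1], order[1:]):
        w[a, b] = w[b, a] = 1
    return w


def voronoi_cells(points: np.ndarray, clip_rect: tuple) -> list[Polygon]:
    """Voronoi cells of ``points`` clipped to ``clip_rect``.

    Distant ghost sites are appended so every real cell is finite before
    clipping; the ghosts are far enough away that they cannot influence
    any cell inside the clip rectangle.
    """
    xmin, ymin, xmax, ymax = clip_rect
    cx, cy = (xmin + xmax) / 2.0, (ymin + ymax) / 2.0
    radius = 100.0 * max(xmax - xmin, ymax - ymin, 1.0)
    angles = np.linspace(0, 2 * np.pi, 8, endpoint=False)
    ghosts = np.column_stack([cx + radius * np.cos(angles), cy + radius * np.sin(angles)])
    vor = Voronoi(np.vstack([points, ghosts]))
    rect = box(xmin, ymin, xmax, ymax)
    cells = []
    for i in range(len(points)):
        region = vor.regions[vor.point_region[i]]
        if -1 in region or len(region) == 0:  # pragma: no cover - ghosts prevent this
            raise RuntimeError(f"unbounded Voronoi cell for site index {i}")
        poly = Polygon(vor.vertices[region])
        cells.append(poly.intersection(rect))
    return cells


def thiessen_adjacency(
    coords: SiteCoordinates,
    boundary: tuple | None = None,
    margin_frac: float = 0.10,
) -> SpatialWeights:
    """First-order adjacency: w_ij = 1 iff the clipped Thiessen polygons of
    sites i and j share an edge of positive length.

    ``boundary`` is the field rectangle ``(xmin, ymin, xmax, ymax)``; when
    omitted, the coordinate bounding box is used. The clip rectangle is the
    boundary expanded by ``margin_frac`` per side (the polygons are
    implicitly bounded by the field, but adjacency among interior sites is
    insensitive to the exact margin). Cells touching at a single point
    (four-corner degeneracy) are NOT neighbours.
    """
    pts = coords.xy
    if boundary is None:
        boundary = (pts[:, 0].min(), pts[:, 1].min(), pts[:, 0].max(), pts[:, 1].max())
    xmin, ymin, xmax, ymax = boundary
    eps = 1e-9
    inside = (
        (pts[:, 0] >= xmin - eps)
        & (pts[:, 0] <= xmax + eps)
        & (pts[:, 1] >= ymin - eps)
        & (pts[:, 1] <= ymax + eps)
    )
    if not np.all(inside):
        bad = coords.site_id[~inside]
        raise ValueError(f"sites outside boundary rectangle: {bad.tolist()}")
    clip_rect = _expand_rect(boundary, margin_frac)
    logger.info("Thiessen clipping rectangle %s (margin %.0f%%)", clip_rect, 100 * margin_frac)

    q = coords.n_sites
    if _collinear(pts):
        logger.warning("all sites collinear; falling back to 1-D chain adjacency")
        w = _chain_adjacency(pts)
        return SpatialWeights(w=w, boundary=clip_rect)

    cells = voronoi_cells(pts, clip_rect)
    w = np.zeros((q, q), dtype=int)
    for i in range(q):
        for j in range(i + 1, q):
            shared = cells[i].intersection(cells[j])
            if shared.length > EDGE_LENGTH_TOL:
                w[i, j] = w[j, i] = 1
    return SpatialWeights(w=w, boundary=clip_rect, cells=tuple(cells))


def write_edge_list(weights: SpatialWeights, coords: SiteCoordinates, path) -> None:
    """Adjacency as `site_i,site_j` per line, i < j by label order."""
    with open(path, "w") as fh:
        fh.write("site_i,site_j\n")
        q = len(weights.w)
        for i in range(q):
            for j in range(i + 1, q):
                if weights.w[i, j]:
                    fh.write(f"{coords.site_id[i]},{coords.site_id[j]}\n")


def write_distance_csv(dist: DistanceMatrix, coords: SiteCoordinates, path) -> None:
    import pandas as pd

    labels = [str(s) for s in coords.site_id]
    pd.DataFrame(dist.d, index=labels, columns=labels).to_csv(path)
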