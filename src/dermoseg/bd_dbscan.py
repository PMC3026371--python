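"""Boundary-driven density-based clustering (BD-DBSCAN) of pixel point sets.

Classic DBSCAN fires one radius-R region query per point of a growing
cluster.  BD-DBSCAN maintains, for every cluster, an explicit polygonal
boundary — an outer polygon plus hole polygons for the donut case — built by
unioning the convex hulls of accepted region queries.  A cluster member whose
query provably cannot enlarge the cluster is *skipped*: a point is skipped
iff it lies inside the filled region of the boundary and its distance to
every boundary curve (outer and holes) is at least R.  The closed R-ball of
such a point lies inside the filled region, and because every hull is the
hull of one query's result set (all within R of the query point, a convex
constraint) every dataset point inside the filled region is already a
labeled member — so pruning is lossless and the core-point partition equals
classic DBSCAN's.

Cluster membership is tracked by per-point labels exactly as in DBSCAN;
polygons are used only to prune queries, which avoids rasterization
ambiguity at polygon edges.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree
from shapely.geometry import GeometryCollection, MultiPoint, Point
from shapely.geometry.base import BaseGeometry
from shapely.ops import unary_union
from sklearn.base import BaseEstimator, ClusterMixin

__all__ = [
    "NOISE",
    "DBSCANParams",
    "PointSet",
    "ClusterBoundary",
    "ClusterLabeling",
    "region_query",
    "init_primitive_cluster",
    "select_leading_points",
    "merge_hull",
    "run_bd_dbscan",
    "run_dbscan_oracle",
    "labeling_to_mask",
    "BoundaryDrivenDBSCAN",
]

NOISE = -1
_UNLABELED = 0
_AREA_TOL = 1e-9


@dataclass(frozen=True)
class DBSCANParams:
    """Radius and density parameters shared by DBSCAN and BD-DBSCAN.

    R calibrates how far the neighborhood search reaches from a query point;
    MP is the minimum number of points within R needed to form (or extend) a
    cluster.  Defaults are the dermoscopy settings R=5, MP=60.
    """

    R: float = 5.0
    MP: int = 60

    def __post_init__(self) -> None:
        if self.R <= 0:
            raise ValueError(f"R must be positive, got {self.R}")
        if self.MP < 1:
            raise ValueError(f"MP must be >= 1, got {self.MP}")


class PointSet:
    """Unique 2-D integer pixel coordinates with a radius-query index.

    Points are stored as (x, y) pairs sorted lexicographically by (y, x),
    which fixes a deterministic processing and query-result order.
    """

    def __init__(self, points: Sequence) -> None:
        pts = np.asarray(points, dtype=np.int64)
        if pts.size == 0:
            pts = pts.reshape(0, 2)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError(f"expected (n, 2) integer coordinates, got {pts.shape}")
        pts = np.unique(pts, axis=0)
        order = np.lexsort((pts[:, 0], pts[:, 1]))  # sort by (y, x)
        self.points = pts[order]
        self._tree = cKDTree(self.points) if len(self.points) else None

    @classmethod
    def from_mask(cls, mask: np.ndarray) -> "PointSet":
        """Positive pixels of a binary mask as (x, y) points."""
        rows, cols = np.nonzero(np.asarray(mask, dtype=bool))
        return cls(np.column_stack([cols, rows]))

    def __len__(self) -> int:
        return len(self.points)

    def query_indices(self, p: Sequence[float], R: float) -> np.ndarray:
        """Indices of all points with Euclidean distance <= R of p, ascending.

        Distances are compared exactly on squared integer offsets, so
        boundary cases (e.g. sqrt(2) vs R=1.5) are deterministic.
        """
        if R <= 0:
            raise ValueError(f"query radius must be positive, got {R}")
        if self._tree is None:
            return np.empty(0, dtype=np.intp)
        cand = np.asarray(
            self._tree.query_ball_point(np.asarray(p, dtype=float), R * (1 + 1e-12) + 1e-9),
            dtype=np.intp,
        )
        if cand.size == 0:
            return cand
        d = self.points[cand] - np.asarray(p, dtype=float)
        keep = (d * d).sum(axis=1) <= R * R * (1 + 1e-12)
        return np.sort(cand[keep])


def region_query(ps: PointSet, p: Sequence[float], R: float) -> np.ndarray:
    """All points of ps within distance R of p (inclusive), lex-ordered by (y, x)."""
    return ps.points[ps.query_indices(p, R)]


class ClusterBoundary:
    """Polygonal boundary of a growing cluster: outer polygon plus holes.

    Wraps a shapely geometry.  The filled region is the outer polygon minus
    the union of its holes; the filled area never decreases across merges.
    Degenerate (collinear) hulls are retained as zero-area geometries whose
    every point counts as boundary.
    """

    def __init__(self, geom: BaseGeometry) -> None:
        self.geom = geom

    @classmethod
    def from_points(cls, points: np.ndarray) -> "ClusterBoundary":
        return cls(MultiPoint(np.asarray(points, dtype=float)).convex_hull)

    @property
    def area(self) -> float:
        return float(self.geom.area)

    @property
    def outer(self) -> np.ndarray:
        """Vertices of the outer polygon (largest part if split numerically)."""
        geom = self.geom
        if geom.geom_type == "MultiPolygon":
            geom = max(geom.geoms, key=lambda g: g.area)
        if geom.geom_type != "Polygon":
            return np.asarray(geom.coords, dtype=float) if hasattr(geom, "coords") else np.empty((0, 2))
        return np.asarray(geom.exterior.coords, dtype=float)

    @property
    def holes(self) -> List[np.ndarray]:
        geom = self.geom
        if geom.geom_type == "MultiPolygon":
            geom = max(geom.geoms, key=lambda g: g.area)
        if geom.geom_type != "Polygon":
            return []
        return [np.asarray(ring.coords, dtype=float) for ring in geom.interiors]

    def covers_point(self, p: Sequence[float]) -> bool:
        """True iff p lies in the filled region (boundary included)."""
        return bool(self.geom.covers(Point(p)))

    def boundary_distance(self, p: Sequence[float]) -> float:
        """Distance from p to the nearest boundary curve (outer or hole)."""
        if self.geom.area <= _AREA_TOL:
            return float(self.geom.distance(Point(p)))  # zero-area: all boundary
        return float(self.geom.boundary.distance(Point(p)))

    def merge(self, t: BaseGeometry) -> "ClusterBoundary":
        """Union a newly found convex hull into the boundary.

        Since the stored geometry is already outer-minus-holes, the union
        realizes (P1 ∪ T) − (holes − T): holes covered by T are absorbed and
        a union that encircles uncovered space creates a new hole.
        """
        t_geom = t.geom if isinstance(t, ClusterBoundary) else t
        merged = self.geom.union(t_geom)
        if isinstance(merged, GeometryCollection):
            polys = [g for g in merged.geoms if g.geom_type in ("Polygon", "MultiPolygon")]
            if polys:
                merged = unary_union(polys)
        if merged.geom_type == "MultiPolygon":
            merged = unary_union(merged)
        if merged.area < self.geom.area - 1e-6:
            raise RuntimeError(
                "cluster boundary area decreased during merge near "
                f"{np.asarray(t_geom.centroid.coords)}"
            )
        return ClusterBoundary(merged)


def init_primitive_cluster(s0: np.ndarray, mp: int) -> Optional[ClusterBoundary]:
    """Convex hull of a region-query result, or None if |s0| < MP.

    The hull of one accepted query is the primitive cluster that seeds a
    boundary; collinear results yield a retained zero-area hull.
    """
    s0 = np.asarray(s0)
    if len(s0) == 0:
        raise ValueError("primitive cluster requires a non-empty query result")
    if len(s0) < mp:
        return None
    return ClusterBoundary.from_points(s0)


def select_leading_points(
    c: ClusterBoundary, candidates: Sequence, R: float
) -> List[np.ndarray]:
    """Members whose region query may still enlarge the cluster.

    A candidate is skipped iff it lies inside the filled region and its
    distance to every boundary curve is >= R; points on the boundary
    (distance 0) are always leading.
    """
    leading = []
    for p in candidates:
        if not (c.covers_point(p) and c.boundary_distance(p) >= R):
            leading.append(np.asarray(p))
    return leading


def merge_hull(c: ClusterBoundary, t) -> ClusterBoundary:
    """Functional wrapper over :meth:`ClusterBoundary.merge`."""
    if not isinstance(t, BaseGeometry) and not isinstance(t, ClusterBoundary):
        t = MultiPoint(np.asarray(t, dtype=float)).convex_hull
    return c.merge(t)


@dataclass
class ClusterLabeling:
    """Result of a clustering run over a PointSet.

    ``labels[i]`` is the 1-based cluster id of ``points[i]`` or ``NOISE``;
    ``clusters`` holds one ClusterBoundary per cluster (empty for the plain
    DBSCAN oracle, which tracks no geometry); ``queries_fired`` counts
    region queries executed.
    """

    labels: np.ndarray
    clusters: List[ClusterBoundary] = field(default_factory=list)
    queries_fired: int = 0

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max(initial=0))

    def cluster_sizes(self) -> np.ndarray:
        return np.bincount(self.labels[self.labels > 0], minlength=self.n_clusters + 1)[1:]


def _verify_pruning(boundary: ClusterBoundary, p: np.ndarray, R: float) -> None:
    """Independent check that the closed R-ball of a skipped point lies inside
    the filled region: even-odd point-in-polygon plus a numpy segment-distance
    computation, both separate from the shapely predicates used for the skip
    decision itself."""
    geom = boundary.geom
    if geom.geom_type != "Polygon":  # pragma: no cover - skip only fires on areas
        raise AssertionError("skipped point recorded against non-polygonal boundary")
    rings = [np.asarray(geom.exterior.coords, float)] + [
        np.asarray(r.coords, float) for r in geom.interiors
    ]
    px, py = float(p[0]), float(p[1])
    crossings = 0
    dmin = np.inf
    for ring in rings:
        x1, y1 = ring[:-1, 0], ring[:-1, 1]
        x2, y2 = ring[1:, 0], ring[1:, 1]
        # even-odd crossing count over exterior and hole rings combined
        cond = ((y1 <= py) & (y2 > py)) | ((y2 <= py) & (y1 > py))
        if cond.any():
            xi = x1[cond] + (py - y1[cond]) * (x2[cond] - x1[cond]) / (y2[cond] - y1[cond])
            crossings += int(np.count_nonzero(xi > px))
        # exact distance to every ring segment
        ex, ey = x2 - x1, y2 - y1
        L2 = ex * ex + ey * ey
        tpar = np.clip(((px - x1) * ex + (py - y1) * ey) / np.where(L2 > 0, L2, 1), 0, 1)
        dx = x1 + tpar * ex - px
        dy = y1 + tpar * ey - py
        dmin = min(dmin, float(np.sqrt(dx * dx + dy * dy).min()))
    inside = bool(crossings % 2)
    if not inside or dmin < R * (1 - 1e-9):
        raise AssertionError(
            f"unsound skip at {p}: inside={inside}, boundary distance {dmin:.6f} < R={R}"
        )


def run_bd_dbscan(
    ps: PointSet,
    params: DBSCANParams = DBSCANParams(),
    *,
    check_pruning: bool = False,
) -> ClusterLabeling:
    """Boundary-driven DBSCAN over a point set.

    Iterates unlabeled points in (y, x) order as cluster seeds; an accepted
    seed's query hull becomes the primitive cluster, after which members are
    popped LIFO (depth-first over discovery order, lexicographic within each
    query result), queried only if leading, and each accepted query's hull is
    unioned into the boundary.  Depth-first order lets the covered region
    close around interior members before they are popped, which is what makes
    the leading-point test actually skip queries.  Points never associated with a cluster are
    labeled NOISE.  With ``check_pruning`` every skip is re-verified with an
    independent geometric predicate (slow; used by the test suite).
    """
    n = len(ps)
    labels = np.full(n, _UNLABELED, dtype=np.int64)
    boundaries: List[ClusterBoundary] = []
    queries = 0
    R, MP = params.R, params.MP

    for i in range(n):
        if labels[i] != _UNLABELED:
            continue
        idx0 = ps.query_indices(ps.points[i], R)
        queries += 1
        if len(idx0) < MP:
            labels[i] = NOISE
            continue
        cid = len(boundaries) + 1
        boundary = ClusterBoundary.from_points(ps.points[idx0])
        seeds = deque()
        for j in idx0:
            if labels[j] == _UNLABELED:
                labels[j] = cid
                if j != i:
                    seeds.append(j)
            elif labels[j] == NOISE:
                labels[j] = cid  # border point: claimed, not expanded
        while seeds:
            j = seeds.pop()
            p = ps.points[j]
            if boundary.covers_point(p) and boundary.boundary_distance(p) >= R:
                if check_pruning:
                    _verify_pruning(boundary, p, R)
                continue
            idxq = ps.query_indices(p, R)
            queries += 1
            if len(idxq) < MP:
                continue
            boundary = boundary.merge(
                MultiPoint(ps.points[idxq].astype(float)).convex_hull
            )
            for m in idxq:
                if labels[m] == _UNLABELED:
                    labels[m] = cid
                    seeds.append(m)
                elif labels[m] == NOISE:
                    labels[m] = cid
        boundaries.append(boundary)

    return ClusterLabeling(labels=labels, clusters=boundaries, queries_fired=queries)


def run_dbscan_oracle(
    ps: PointSet, params: DBSCANParams = DBSCANParams()
) -> ClusterLabeling:
    """Classic DBSCAN with the same distance, inclusivity and seed-order
    conventions as :func:`run_bd_dbscan`; fires one query per expanded member.

    Serves as the definitional reference the boundary-driven variant is
    checked against.
    """
    n = len(ps)
    labels = np.full(n, _UNLABELED, dtype=np.int64)
    queries = 0
    n_clusters = 0
    R, MP = params.R, params.MP

    for i in range(n):
        if labels[i] != _UNLABELED:
            continue
        idx0 = ps.query_indices(ps.points[i], R)
        queries += 1
        if len(idx0) < MP:
            labels[i] = NOISE
            continue
        n_clusters += 1
        cid = n_clusters
        seeds = deque()
        for j in idx0:
            if labels[j] == _UNLABELED:
                labels[j] = cid
                if j != i:
                    seeds.append(j)
            elif labels[j] == NOISE:
                labels[j] = cid
        while seeds:
            j = seeds.pop()
            idxq = ps.query_indices(ps.points[j], R)
            queries += 1
            if len(idxq) < MP:
                continue
            for m in idxq:
                if labels[m] == _UNLABELED:
                    labels[m] = cid
                    seeds.append(m)
                elif labels[m] == NOISE:
                    labels[m] = cid

    return ClusterLabeling(labels=labels, clusters=[], queries_fired=queries)


def labeling_to_mask(lab: ClusterLabeling, ps: PointSet, nc: int, nr: int) -> np.ndarray:
    """Binary mask of the single largest cluster (ties: smallest cluster id).

    With no clusters at all the mask is empty — the scene contained no
    sufficiently dense object.
    """
    mask = np.zeros((nr, nc), dtype=bool)
    if lab.n_clusters == 0:
        return mask
    sizes = lab.cluster_sizes()
    best = int(np.argmax(sizes)) + 1  # argmax returns the first (smallest id) maximum
    pts = ps.points[lab.labels == best]
    mask[pts[:, 1], pts[:, 0]] = True
    return mask


class BoundaryDrivenDBSCAN(ClusterMixin, BaseEstimator):
    """Scikit-learn style estimator facade over :func:`run_bd_dbscan`.

    Parameters
    ----------
    radius : float, default 5.0
        Region-query radius R in pixels.
    min_points : int, default 60
        Minimum neighborhood population MP for a query to extend a cluster.

    Attributes
    ----------
    labels_ : ndarray of shape (n_samples,)
        Cluster labels per input row; noise is ``-1`` (sklearn convention,
        cluster ids 0-based).
    boundaries_ : list of ClusterBoundary
        Final polygonal boundary of each cluster.
    queries_fired_ : int
        Number of region queries executed.
    """

    def __init__(self, radius: float = 5.0, min_points: int = 60) -> None:
        self.radius = radius
        self.min_points = min_points

    def fit(self, X, y=None):
        X = np.asarray(X)
        ps = PointSet(X)
        result = run_bd_dbscan(ps, DBSCANParams(R=self.radius, MP=self.min_points))
        # map back from the internal lex-sorted order to the input row order
        lookup = {tuple(pt): lbl for pt, lbl in zip(ps.points, result.labels)}
        raw = np.array([lookup[tuple(row)] for row in np.asarray(X, dtype=np.int64)])
        self.labels_ = np.where(raw == NOISE, -1, raw - 1)
        self.boundaries_ = result.clusters
        self.queries_fired_ = result.queries_fired
        self.n_clusters_ = result.n_clusters
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X, y).labels_
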