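"""Density-based spatial niches: DBSCAN per cell type, alpha-shape
boundaries, composition, signed boundary distances, raster masks and Dice
co-localisation.

eps and the alpha radius have no defaults — appropriate values depend on
tissue type and cell density and must be supplied by the caller.

Geometry conventions: polygons carry micron vertices; areas are square
microns (shoelace over rings, holes subtracted — as computed by shapely);
point-in-polygon tests are boundary-inclusive; signed distances are
negative strictly inside a cluster polygon, positive outside, zero on the
boundary.  Border points reachable from several DBSCAN clusters go to the
cluster that first claims them in deterministic index order (the classic
DBSCAN ambiguity).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from scipy.spatial import Delaunay, QhullError
from shapely.geometry import LineString, MultiPoint, Point, Polygon
from shapely.ops import unary_union

from .errors import MaskError, ValidationError

logger = logging.getLogger("cytoplex")

NO_CLUSTER = np.nan  # sentinel signed distance when a type formed no cluster


def spatial_clusters(coords: np.ndarray, eps: float, min_samples: int) -> np.ndarray:
    """DBSCAN labels on micron coordinates; noise is −1.

    Fewer points than ``min_samples`` → all noise (logged, not an error)."""
    if not eps > 0:
        raise ValidationError(f"eps must be > 0, got {eps}")
    coords = np.asarray(coords, dtype=float)
    if len(coords) == 0:
        return np.empty(0, dtype=int)
    if len(coords) < min_samples:
        logger.info("only %d point(s) for min_samples=%d: all noise",
                    len(coords), min_samples)
        return np.full(len(coords), -1, dtype=int)
    from sklearn.cluster import DBSCAN
    return DBSCAN(eps=eps, min_samples=min_samples).fit(coords).labels_


def _circumradius(pts: np.ndarray) -> float:
    (ax, ay), (bx, by), (cx, cy) = pts
    a = np.hypot(bx - cx, by - cy)
    b = np.hypot(ax - cx, ay - cy)
    c = np.hypot(ax - bx, ay - by)
    area2 = abs((bx - ax) * (cy - ay) - (cx - ax) * (by - ay))
    if area2 < 1e-12:
        return np.inf
    return a * b * c / (2.0 * area2)


def cluster_boundary(points: np.ndarray, alpha_radius: float,
                     collinear_half_width: float = 1.0):
    """Alpha shape of a point set at the given radius (microns).

    Delaunay triangles with circumradius ≤ ``alpha_radius`` are unioned; in
    the large-radius limit this is the convex hull.  Degenerate inputs
    (fewer than 3 points, or all collinear) yield a buffered point/segment
    polygon of the configured half-width (logged).
    """
    if not alpha_radius > 0:
        raise ValidationError(f"alpha_radius must be > 0, got {alpha_radius}")
    pts = np.asarray(points, dtype=float)
    if len(pts) == 0:
        raise ValidationError("cluster_boundary requires at least one point")

    def _degenerate():
        logger.info("degenerate cluster geometry (%d point(s)); buffering at "
                    "half-width %.3g", len(pts), collinear_half_width)
        geom = MultiPoint(pts).convex_hull  # point or segment
        return geom.buffer(collinear_half_width, quad_segs=8)

    if len(pts) < 3:
        return _degenerate()
    try:
        tri = Delaunay(pts)
    except QhullError:
        return _degenerate()
    keep = [Polygon(pts[s]) for s in tri.simplices
            if _circumradius(pts[s]) <= alpha_radius]
    if not keep:
        logger.info("alpha radius %.3g keeps no triangle; buffering members",
                    alpha_radius)
        return unary_union([Point(p).buffer(collinear_half_width, quad_segs=8)
                            for p in pts])
    return unary_union(keep)


@dataclass
class SpatialClusterSet:
    """DBSCAN clusters of one cell type in one image, with boundaries."""

    image_id: str
    cell_type: str
    eps: float
    min_samples: int
    alpha_radius: float
    cell_ids: np.ndarray                  # all typed cells, input order
    coords: np.ndarray
    labels: np.ndarray                    # −1 = noise
    polygons: dict[int, shapely.Geometry]  # cluster label -> boundary polygon

    @property
    def cluster_labels(self) -> list[int]:
        return sorted(self.polygons)

    def area(self, label: int) -> float:
        return float(self.polygons[label].area)

    def members(self, label: int) -> np.ndarray:
        return self.cell_ids[self.labels == label]

    @property
    def noise_ids(self) -> np.ndarray:
        return self.cell_ids[self.labels == -1]

    def union(self) -> shapely.Geometry:
        if not self.polygons:
            return Polygon()
        return unary_union(list(self.polygons.values()))

    def assignments_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"image_id": self.image_id, "cell_type": self.cell_type,
                             "cell_id": self.cell_ids, "cluster": self.labels})


def build_cluster_set(image_id: str, cell_type: str, cell_ids: np.ndarray,
                      coords: np.ndarray, eps: float, min_samples: int,
                      alpha_radius: float,
                      collinear_half_width: float = 1.0) -> SpatialClusterSet:
    """DBSCAN + alpha-shape boundary per cluster for one (image, type)."""
    labels = spatial_clusters(coords, eps, min_samples)
    polygons = {}
    for lab in sorted(set(labels) - {-1}):
        polygons[int(lab)] = cluster_boundary(coords[labels == lab], alpha_radius,
                                              collinear_half_width)
    return SpatialClusterSet(image_id, cell_type, eps, min_samples, alpha_radius,
                             np.asarray(cell_ids), np.asarray(coords, dtype=float),
                             labels, polygons)


def composition(cluster_set: SpatialClusterSet, annotations: pd.DataFrame
                ) -> pd.DataFrame:
    """Counts and intracluster densities of every phenotype inside each
    cluster boundary (boundary-inclusive point-in-polygon).

    ``annotations`` needs columns image_id, cell_id, label, x, y.  Densities
    are per square millimetre (count / polygon area)."""
    img = annotations[annotations["image_id"] == cluster_set.image_id]
    x = img["x"].to_numpy(dtype=float)
    y = img["y"].to_numpy(dtype=float)
    rows = []
    for lab in cluster_set.cluster_labels:
        poly = cluster_set.polygons[lab]
        inside = shapely.intersects_xy(poly, x, y)
        area = float(poly.area)
        n_members = int((cluster_set.labels == lab).sum())
        for phen, sub in img.loc[inside].groupby("label", sort=True):
            rows.append((cluster_set.image_id, cluster_set.cell_type, lab,
                         n_members, area, phen, len(sub),
                         len(sub) / area * 1e6))
    return pd.DataFrame(rows, columns=[
        "image_id", "cell_type", "cluster", "n_members", "area_um2",
        "phenotype", "count", "density_mm2"])


def signed_distances(cluster_set: SpatialClusterSet, points: np.ndarray
                     ) -> np.ndarray:
    """Signed micron distance of each point to the nearest cluster boundary.

    Negative inside a cluster polygon, positive outside, 0 on the boundary;
    NaN when the set has no clusters."""
    pts = np.asarray(points, dtype=float)
    if not cluster_set.polygons:
        return np.full(len(pts), NO_CLUSTER)
    boundary = unary_union([p.boundary if p.boundary.length > 0 else p.exterior
                            for p in cluster_set.polygons.values()])
    dist = shapely.distance(boundary, shapely.points(pts))
    inside = np.zeros(len(pts), dtype=bool)
    for poly in cluster_set.polygons.values():
        inside |= shapely.covers(poly, shapely.points(pts))
    on_boundary = dist == 0
    sign = np.where(inside & ~on_boundary, -1.0, 1.0)
    return sign * dist


def rasterise(cluster_set: SpatialClusterSet, scale: float,
              shape: tuple[int, int]) -> np.ndarray:
    """Binary raster of the union of cluster polygons.

    A pixel is foreground when it intersects the union (boundary-inclusive
    at pixel centres); ``scale`` is microns per pixel."""
    if not scale > 0:
        raise MaskError(f"scale must be > 0, got {scale}")
    nrow, ncol = shape
    geom = cluster_set.union()
    if geom.is_empty:
        return np.zeros(shape, dtype=np.uint8)
    cx = (np.arange(ncol) + 0.5) * scale
    cy = (np.arange(nrow) + 0.5) * scale
    gx, gy = np.meshgrid(cx, cy)
    return shapely.intersects_xy(geom, gx.ravel(), gy.ravel()) \
        .reshape(shape).astype(np.uint8)


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice overlap 2|A∩B|/(|A|+|B|) of two binary rasters; 0.0 when both
    are empty (logged convention)."""
    if mask_a.shape != mask_b.shape:
        raise MaskError(f"mask shapes differ: {mask_a.shape} vs {mask_b.shape}")
    a = mask_a > 0
    b = mask_b > 0
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        logger.info("both masks empty; Dice defined as 0.0")
        return 0.0
    return 2.0 * int((a & b).sum()) / denom


def cluster_masks_and_dice(set_a: SpatialClusterSet, set_b: SpatialClusterSet,
                           scale: float, shape: tuple[int, int]
                           ) -> tuple[np.ndarray, np.ndarray, float]:
    """Rasterise two cluster sets of one image at a shared scale and score
    their overlap."""
    if set_a.image_id != set_b.image_id:
        raise ValidationError("cluster sets come from different images")
    m_a = rasterise(set_a, scale, shape)
    m_b = rasterise(set_b, scale, shape)
    return m_a, m_b, dice(m_a, m_b)
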