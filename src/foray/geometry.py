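"""Territory geometry: minimum convex polygons, boundary distances, contiguity.

Social-group territories are represented as simple planar polygons in
metres (projected coordinates). The home-range estimator is the classical
percent minimum convex polygon (MCP): retain the fraction of fixes closest
to the arithmetic-mean centroid of all fixes, then take their convex hull.
A 95% MCP therefore discards the 5% of fixes farthest from the centroid
before hulling, which trims occasional long-range excursions out of the
territory estimate.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Point, Polygon
from shapely.geometry.polygon import orient
from shapely.strtree import STRtree

logger = logging.getLogger(__name__)

SUMMER_MONTHS = frozenset({6, 7, 8})


class DegenerateGeometryError(ValueError):
    """Raised when too few / collinear points preclude polygon construction."""


@dataclass(frozen=True)
class TerritoryPolygon:
    """One social group's territory in one calendar year."""

    group_id: str
    year: int
    polygon: Polygon
    source: str = "mcp"  # mcp | provided | voronoi

    def __post_init__(self) -> None:
        if self.source not in ("mcp", "provided", "voronoi"):
            raise ValueError(f"unknown territory source {self.source!r}")
        if not isinstance(self.polygon, Polygon) or self.polygon.is_empty:
            raise DegenerateGeometryError(
                f"group {self.group_id!r}: territory must be a non-empty polygon"
            )
        if not self.polygon.is_valid:
            raise DegenerateGeometryError(
                f"group {self.group_id!r}: territory ring is not simple"
            )
        if self.polygon.area <= 0:
            raise DegenerateGeometryError(
                f"group {self.group_id!r}: territory has zero area"
            )

    @property
    def vertices(self) -> np.ndarray:
        """Exterior ring vertices, counter-clockwise, closing point dropped."""
        ring = orient(self.polygon, sign=1.0).exterior.coords
        return np.asarray(ring)[:-1]


@dataclass
class TerritoryMap:
    """All territory polygons for one calendar year, keyed by group."""

    year: int
    polygons: dict[str, TerritoryPolygon] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for gid, tp in self.polygons.items():
            if tp.group_id != gid:
                raise ValueError(f"key {gid!r} does not match polygon group {tp.group_id!r}")

    def __contains__(self, group_id: str) -> bool:
        return group_id in self.polygons

    def __getitem__(self, group_id: str) -> TerritoryPolygon:
        return self.polygons[group_id]

    def __len__(self) -> int:
        return len(self.polygons)

    def groups(self) -> list[str]:
        return sorted(self.polygons)


def _retained_points(
    points: np.ndarray,
    retention_fraction: float,
    timestamps: np.ndarray | None = None,
) -> np.ndarray:
    """Points ranked by distance to the mean centroid; keep ceil(f*n).

    Ties at the retention cut are broken by earliest timestamp (when
    given), then lexicographically by (x, y), so output is deterministic.
    """
    n = len(points)
    k = math.ceil(retention_fraction * n)
    centroid = points.mean(axis=0)
    dist = np.hypot(points[:, 0] - centroid[0], points[:, 1] - centroid[1])
    if timestamps is not None:
        ts = np.asarray(timestamps).astype("datetime64[ns]").astype(np.int64)
        order = np.lexsort((points[:, 1], points[:, 0], ts, dist))
    else:
        order = np.lexsort((points[:, 1], points[:, 0], dist))
    return points[order[:k]]


def compute_mcp(
    points,
    retention_fraction: float = 0.95,
    *,
    group_id: str = "",
    year: int = 0,
    timestamps=None,
) -> TerritoryPolygon:
    """Percent minimum convex polygon of a set of planar fixes.

    Parameters
    ----------
    points
        (n, 2) array-like of planar coordinates in metres.
    retention_fraction
        Fraction of fixes retained, in (0, 1]; ``ceil(f * n)`` fixes
        nearest the arithmetic-mean centroid are hulled. 0.95 gives the
        conventional 95% MCP.
    timestamps
        Optional per-point timestamps used only to break ranking ties at
        the retention cut.
    """
    if not 0 < retention_fraction <= 1:
        raise ValueError("retention_fraction must be in (0, 1]")
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array")
    if not np.isfinite(pts).all():
        raise ValueError("points must be finite")
    label = f"group {group_id!r}" if group_id else "point set"
    if len(pts) < 3:
        raise DegenerateGeometryError(f"{label}: need >= 3 points, got {len(pts)}")
    retained = _retained_points(pts, retention_fraction, timestamps)
    if len(retained) < 3:
        raise DegenerateGeometryError(
            f"{label}: only {len(retained)} points retained at fraction {retention_fraction}"
        )
    hull = shapely.MultiPoint(retained).convex_hull
    if not isinstance(hull, Polygon):
        raise DegenerateGeometryError(f"{label}: retained points are collinear")
    return TerritoryPolygon(group_id=group_id, year=year, polygon=orient(hull, sign=1.0))


def build_territory_map(
    fixes: pd.DataFrame,
    year: int,
    *,
    retention_fraction: float = 0.95,
    summer_months=SUMMER_MONTHS,
    fallback_full_year: bool = True,
) -> TerritoryMap:
    """Per-group MCP territories for one calendar year.

    Each group's MCP is built from the pooled summer (default Jun-Aug)
    fixes of all its members; a group with no summer fixes that year falls
    back, if enabled, to all of its fixes from that calendar year. Groups
    with too few or collinear fixes are omitted with a warning.
    """
    if fixes.empty:
        raise ValueError("empty fix table: cannot build a territory map")
    ts = pd.to_datetime(fixes["timestamp"])
    year_fixes = fixes.loc[ts.dt.year == year]
    if year_fixes.empty:
        raise ValueError(f"no fixes in year {year}")
    year_ts = pd.to_datetime(year_fixes["timestamp"])
    summer = year_fixes.loc[year_ts.dt.month.isin(list(summer_months))]

    polygons: dict[str, TerritoryPolygon] = {}
    for gid, grp in year_fixes.groupby("group_id", sort=True):
        subset = summer.loc[summer["group_id"] == gid]
        if subset.empty:
            if not fallback_full_year:
                logger.warning("group %s: no summer fixes in %d; omitted", gid, year)
                continue
            subset = grp
        try:
            polygons[str(gid)] = compute_mcp(
                subset[["x", "y"]].to_numpy(),
                retention_fraction,
                group_id=str(gid),
                year=year,
                timestamps=subset["timestamp"].to_numpy(),
            )
        except DegenerateGeometryError as exc:
            logger.warning("group %s omitted from %d territory map: %s", gid, year, exc)
    return TerritoryMap(year=year, polygons=polygons)


def distance_beyond_boundary(point, polygon: TerritoryPolygon | Polygon) -> float:
    """Distance (m) from a fix to the territory; 0 inside or on the ring."""
    poly = polygon.polygon if isinstance(polygon, TerritoryPolygon) else polygon
    if not isinstance(poly, Polygon) or poly.is_empty or not poly.is_valid:
        raise DegenerateGeometryError("invalid territory polygon")
    return float(Point(point).distance(poly))


def distances_beyond_boundary(points: np.ndarray, polygon: TerritoryPolygon | Polygon) -> np.ndarray:
    """Vectorised :func:`distance_beyond_boundary` for an (n, 2) array."""
    poly = polygon.polygon if isinstance(polygon, TerritoryPolygon) else polygon
    if not isinstance(poly, Polygon) or poly.is_empty or not poly.is_valid:
        raise DegenerateGeometryError("invalid territory polygon")
    pts = shapely.points(np.asarray(points, dtype=float))
    return shapely.distance(pts, poly)


@dataclass(frozen=True)
class ContiguityReport:
    overlap_area: float
    gap_area: float
    is_contiguous: bool


def check_contiguity(
    territory_map: TerritoryMap,
    study_region: Polygon,
    tol: float = 1e-6,
) -> ContiguityReport:
    """Do the territories tile the study region?

    Contiguous means pairwise interior overlaps and the uncovered area of
    the study region are both below ``tol`` times the region area. In a
    contiguous mosaic, leaving the home territory necessarily means
    entering a neighbour's.
    """
    if len(territory_map) == 0:
        raise ValueError("empty territory map")
    polys = [territory_map[g].polygon for g in territory_map.groups()]
    clipped = [p.intersection(study_region) for p in polys]
    tree = STRtree(clipped)
    overlap = 0.0
    for i, a in enumerate(clipped):
        for j in tree.query(a):
            if j > i:
                overlap += a.intersection(clipped[j]).area
    union = shapely.unary_union(clipped)
    gap = study_region.area - union.area
    gap = max(gap, 0.0)
    limit = tol * study_region.area
    return ContiguityReport(
        overlap_area=overlap,
        gap_area=gap,
        is_contiguous=bool(overlap < limit and gap < limit),
    )
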