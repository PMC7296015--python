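"""Territory geometry: MCP construction, boundary distance, contiguity."""

import math

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Polygon, box

from foray.geometry import (
    DegenerateGeometryError,
    TerritoryPolygon,
    build_territory_map,
    check_contiguity,
    compute_mcp,
    distance_beyond_boundary,
    distances_beyond_boundary,
)
from foray.simulate import SimConfig, generate_territory_mosaic


# --- independent oracles -------------------------------------------------

def giftwrap_hull(points: np.ndarray) -> set[tuple[float, float]]:
    """Jarvis-march convex hull vertex set (brute force oracle)."""
    pts = [tuple(p) for p in np.unique(points, axis=0)]
    if len(pts) < 3:
        return set(pts)
    start = min(pts)
    hull = [start]
    current = start
    while True:
        candidate = pts[0] if pts[0] != current else pts[1]
        for p in pts:
            if p == current:
                continue
            cross = ((candidate[0] - current[0]) * (p[1] - current[1])
                     - (candidate[1] - current[1]) * (p[0] - current[0]))
            if cross < 0 or (
                cross == 0
                and math.dist(current, p) > math.dist(current, candidate)
            ):
                candidate = p
        if candidate == start:
            break
        hull.append(candidate)
        current = candidate
    # drop collinear interior-of-edge points for a canonical vertex set
    out = []
    n = len(hull)
    for i in range(n):
        a, b, c = hull[i - 1], hull[i], hull[(i + 1) % n]
        cross = (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])
        if cross != 0:
            out.append(b)
    return set(out)


def mcp_oracle_vertices(points: np.ndarray, fraction: float) -> set:
    """Sort by centroid distance, truncate at ceil(f*n), gift-wrap."""
    centroid = points.mean(axis=0)
    d = np.hypot(points[:, 0] - centroid[0], points[:, 1] - centroid[1])
    order = np.lexsort((points[:, 1], points[:, 0], d))
    k = math.ceil(fraction * len(points))
    return giftwrap_hull(points[order[:k]])


def sample_boundary(polygon: Polygon, n_samples: int = 1_000_000) -> np.ndarray:
    """n points spaced uniformly by arc length along the exterior ring."""
    ring = polygon.exterior
    ts = np.linspace(0, ring.length, n_samples, endpoint=False)
    coords = np.asarray(ring.coords)
    seg = np.diff(coords, axis=0)
    seg_len = np.hypot(seg[:, 0], seg[:, 1])
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    idx = np.clip(np.searchsorted(cum, ts, side="right") - 1, 0, len(seg) - 1)
    frac = (ts - cum[idx]) / seg_len[idx]
    # include the vertices themselves: at a corner the distance minimum is a
    # kink, where pure arc-length sampling converges only linearly
    return np.vstack([coords, coords[idx] + frac[:, None] * seg[idx]])


def boundary_sampling_distance(point, samples: np.ndarray) -> float:
    """Min distance from the point to densely sampled boundary points."""
    return float(np.min(np.hypot(samples[:, 0] - point[0], samples[:, 1] - point[1])))


def random_convex_polygon(rng, scale=100.0) -> Polygon:
    pts = rng.uniform(0, scale, (rng.integers(5, 15), 2))
    return Polygon(np.asarray(
        sorted(map(tuple, pts))
    )).convex_hull


# --- compute_mcp ---------------------------------------------------------

class TestComputeMcp:
    def test_unit_square_full_retention(self):
        tp = compute_mcp([(0, 0), (1, 0), (1, 1), (0, 1)], 1.0)
        assert tp.polygon.area == pytest.approx(1.0)
        assert len(tp.vertices) == 4

    def test_retention_count_is_ceiling(self, rng):
        pts = rng.uniform(0, 100, (20, 2))
        # ceil(0.95*20)=19: exactly one point (the farthest from centroid) dropped
        centroid = pts.mean(axis=0)
        d = np.hypot(*(pts - centroid).T)
        dropped = pts[np.argmax(d)]
        tp = compute_mcp(pts, 0.95)
        kept = {tuple(v) for v in tp.vertices}
        assert tuple(dropped) not in kept
        assert mcp_oracle_vertices(pts, 0.95) == kept

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_giftwrap_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 51))
        pts = rng.uniform(0, 100, (n, 2))
        frac = float(rng.choice([0.6, 0.8, 0.95, 1.0]))
        tp = compute_mcp(pts, frac)
        assert {tuple(v) for v in tp.vertices} == mcp_oracle_vertices(pts, frac)

    def test_full_retention_contains_all_points(self, rng):
        pts = rng.uniform(0, 50, (30, 2))
        tp = compute_mcp(pts, 1.0)
        assert distances_beyond_boundary(pts, tp).max() < 1e-9

    def test_area_nondecreasing_in_retention(self, rng):
        pts = rng.uniform(0, 50, (40, 2))
        areas = [compute_mcp(pts, f).polygon.area for f in (0.5, 0.7, 0.9, 1.0)]
        assert areas == sorted(areas)

    def test_partial_hull_within_full_hull(self, rng):
        pts = rng.uniform(0, 50, (40, 2))
        full = compute_mcp(pts, 1.0).polygon
        part = compute_mcp(pts, 0.7).polygon
        assert part.difference(full.buffer(1e-9)).area < 1e-9

    def test_degenerate_inputs_error(self):
        with pytest.raises(DegenerateGeometryError, match="G7"):
            compute_mcp([(0, 0), (1, 1)], 1.0, group_id="G7")
        with pytest.raises(DegenerateGeometryError, match="collinear"):
            compute_mcp([(0, 0), (1, 1), (2, 2), (3, 3)], 1.0)

    def test_vertices_counter_clockwise(self, rng):
        pts = rng.uniform(0, 10, (15, 2))
        v = compute_mcp(pts, 1.0).vertices
        area2 = np.sum(v[:, 0] * np.roll(v[:, 1], -1) - np.roll(v[:, 0], -1) * v[:, 1])
        assert area2 > 0


# --- distance_beyond_boundary -------------------------------------------

class TestDistanceBeyondBoundary:
    unit = Polygon([(0, 0), (1, 0), (1, 1), (0, 1)])

    def test_interior_and_boundary_are_zero(self):
        assert distance_beyond_boundary((0.5, 0.5), self.unit) == 0.0
        assert distance_beyond_boundary((1.0, 0.5), self.unit) == 0.0

    def test_axis_aligned_offset(self):
        assert distance_beyond_boundary((2, 0.5), self.unit) == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_dense_boundary_oracle(self, seed):
        from shapely.geometry import Point

        rng = np.random.default_rng(seed)
        poly = random_convex_polygon(rng)
        samples = sample_boundary(poly, n_samples=1_000_000)
        checked = 0
        while checked < 4:
            pt = rng.uniform(-100, 200, 2)
            if poly.covers(Point(pt)):
                continue
            got = distance_beyond_boundary(pt, poly)
            want = boundary_sampling_distance(pt, samples)
            assert got == pytest.approx(want, rel=1e-6)
            checked += 1

    def test_translation_lipschitz(self, rng):
        poly = random_convex_polygon(rng)
        pt = np.array([150.0, 150.0])
        base = distance_beyond_boundary(pt, poly)
        for _ in range(20):
            delta = rng.normal(0, 5, 2)
            moved = distance_beyond_boundary(pt + delta, poly)
            assert abs(moved - base) <= np.hypot(*delta) + 1e-9

    def test_invalid_polygon_rejected(self):
        bowtie = Polygon([(0, 0), (1, 1), (1, 0), (0, 1)])
        with pytest.raises(DegenerateGeometryError):
            distance_beyond_boundary((5, 5), bowtie)

    def test_vectorised_matches_scalar(self, rng):
        poly = random_convex_polygon(rng)
        pts = rng.uniform(-50, 150, (50, 2))
        vec = distances_beyond_boundary(pts, poly)
        for p, v in zip(pts, vec):
            assert v == pytest.approx(distance_beyond_boundary(p, poly), abs=1e-12)


# --- build_territory_map -------------------------------------------------

def _fixes_df(rows):
    return pd.DataFrame(rows, columns=["animal_id", "group_id", "timestamp", "x", "y"]).assign(
        timestamp=lambda d: pd.to_datetime(d["timestamp"]))


class TestBuildTerritoryMap:
    def test_summer_fixes_only_are_used(self):
        rows = [("a1", "G1", f"2012-07-{d:02d} 22:00", x, y)
                for d, (x, y) in enumerate(
                    [(0, 0), (100, 0), (100, 100), (0, 100), (50, 50)], start=1)]
        # an October outlier must not enter the summer MCP
        rows.append(("a1", "G1", "2012-10-01 22:00", 1000.0, 1000.0))
        tmap = build_territory_map(_fixes_df(rows), 2012, retention_fraction=1.0)
        assert tmap["G1"].polygon.area == pytest.approx(100 * 100)

    def test_fallback_to_full_year(self):
        rows = [("a1", "G1", f"2012-10-{d:02d} 22:00", x, y)
                for d, (x, y) in enumerate([(0, 0), (10, 0), (10, 10), (0, 10)], start=1)]
        tmap = build_territory_map(_fixes_df(rows), 2012, retention_fraction=1.0)
        assert "G1" in tmap
        assert tmap["G1"].polygon.area == pytest.approx(100)
        empty = build_territory_map(_fixes_df(rows), 2012, retention_fraction=1.0,
                                    fallback_full_year=False)
        assert "G1" not in empty

    def test_degenerate_group_omitted_with_warning(self, caplog):
        rows = [("a1", "G1", "2012-07-01 22:00", 0.0, 0.0),
                ("a1", "G1", "2012-07-02 22:00", 5.0, 5.0),
                ("a2", "G2", "2012-07-01 22:00", 0.0, 0.0),
                ("a2", "G2", "2012-07-02 22:00", 9.0, 0.0),
                ("a2", "G2", "2012-07-03 22:00", 0.0, 9.0)]
        with caplog.at_level("WARNING"):
            tmap = build_territory_map(_fixes_df(rows), 2012)
        assert "G1" not in tmap and "G2" in tmap
        assert any("G1" in r.message for r in caplog.records)

    def test_empty_table_errors(self):
        with pytest.raises(ValueError, match="empty"):
            build_territory_map(_fixes_df([]), 2012)


# --- check_contiguity ----------------------------------------------------

class TestCheckContiguity:
    region = box(0, 0, 10, 10)

    def _map(self, polys):
        from foray.geometry import TerritoryMap
        return TerritoryMap(year=2012, polygons={
            f"G{i}": TerritoryPolygon(group_id=f"G{i}", year=2012, polygon=p,
                                      source="provided")
            for i, p in enumerate(polys)})

    def test_perfect_tiling(self):
        report = check_contiguity(self._map([box(0, 0, 5, 10), box(5, 0, 10, 10)]),
                                  self.region)
        assert report.overlap_area == pytest.approx(0.0, abs=1e-9)
        assert report.gap_area == pytest.approx(0.0, abs=1e-9)
        assert report.is_contiguous

    def test_shrunk_tile_leaves_gap(self):
        report = check_contiguity(self._map([box(0, 0, 4.5, 10), box(5, 0, 10, 10)]),
                                  self.region)
        assert report.gap_area == pytest.approx(5.0)
        assert not report.is_contiguous

    def test_overlapping_tiles_flagged(self):
        report = check_contiguity(self._map([box(0, 0, 6, 10), box(5, 0, 10, 10)]),
                                  self.region)
        assert report.overlap_area == pytest.approx(10.0)
        assert not report.is_contiguous

    def test_voronoi_mosaic_is_contiguous(self):
        cfg = SimConfig(rng_seed=3)
        tmap, _ = generate_territory_mosaic(cfg)
        report = check_contiguity(tmap, cfg.region, tol=1e-6)
        assert report.is_contiguous
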