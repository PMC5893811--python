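"""Unstructured triangular meshing of labeled planar domains.

The generator is a compact distmesh-style scheme: the labeled boundary
polylines are resampled at the target edge length, the interior is seeded
with a hexagonal lattice, and a few Laplacian smoothing passes alternate
with Delaunay retriangulation.  Triangles whose centroid falls outside the
domain polygon are culled, which handles non-convex outlines (lobed
appendages) as long as ``h`` resolves the concave features.  The result is
fully deterministic for fixed inputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property
from typing import Sequence

import numpy as np
import shapely
from scipy.spatial import Delaunay
from shapely.geometry import LineString, Polygon

from .errors import (
    GeometryError,
    MeshQualityError,
    ResolutionError,
    TaggingError,
)

REGION_LA = "LA"
REGION_LAA = "LAA"

#: labels every mesh consumer understands
KNOWN_LABEL_PREFIXES = ("wall", "pv_inlet", "mitral_outlet")


@dataclass
class Mesh:
    """Simplicial 2-D mesh with boundary-facet labels and LA/LAA region tags.

    vertices : (N, 2) coordinates in metres
    cells : (M, 3) CCW-oriented triangles
    boundary_edges : (B, 2) directed vertex pairs; the interior lies on the
        left of ``a -> b``, so the outward normal is ``(dy, -dx)/len``
    boundary_labels : length-B label per boundary facet
    region : length-M array of {"LA", "LAA"} (or None when untagged)
    h : characteristic edge length used at generation time
    """

    vertices: np.ndarray
    cells: np.ndarray
    boundary_edges: np.ndarray
    boundary_labels: np.ndarray
    region: np.ndarray | None
    h: float

    @cached_property
    def cell_areas(self) -> np.ndarray:
        p = self.vertices[self.cells]
        d1 = p[:, 1] - p[:, 0]
        d2 = p[:, 2] - p[:, 0]
        return 0.5 * (d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0])

    @cached_property
    def cell_centroids(self) -> np.ndarray:
        return self.vertices[self.cells].mean(axis=1)

    @cached_property
    def boundary_edge_lengths(self) -> np.ndarray:
        d = self.vertices[self.boundary_edges[:, 1]] - self.vertices[self.boundary_edges[:, 0]]
        return np.hypot(d[:, 0], d[:, 1])

    @cached_property
    def boundary_edge_normals(self) -> np.ndarray:
        """Outward unit normals of the boundary facets."""
        d = self.vertices[self.boundary_edges[:, 1]] - self.vertices[self.boundary_edges[:, 0]]
        n = np.column_stack([d[:, 1], -d[:, 0]])
        return n / np.linalg.norm(n, axis=1, keepdims=True)

    @cached_property
    def min_quality(self) -> float:
        return float(triangle_quality(self.vertices, self.cells).min())

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def edges_with_label(self, label: str) -> np.ndarray:
        """Indices of boundary facets carrying exactly ``label``."""
        return np.flatnonzero(self.boundary_labels == label)

    def labels(self) -> list[str]:
        return sorted(set(self.boundary_labels.tolist()))

    def cells_in_region(self, region: str) -> np.ndarray:
        if self.region is None:
            raise TaggingError("mesh has no region tags")
        return np.flatnonzero(self.region == region)


def triangle_quality(vertices: np.ndarray, cells: np.ndarray) -> np.ndarray:
    """Radius-ratio quality 2*r_in/r_circ in (0, 1]; 1 for equilateral."""
    p = vertices[cells]
    a = np.linalg.norm(p[:, 1] - p[:, 2], axis=1)
    b = np.linalg.norm(p[:, 2] - p[:, 0], axis=1)
    c = np.linalg.norm(p[:, 0] - p[:, 1], axis=1)
    s = 0.5 * (a + b + c)
    area = np.sqrt(np.maximum(s * (s - a) * (s - b) * (s - c), 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        q = 8.0 * area * area / (s * a * b * c)
    return np.nan_to_num(q)


def _resample_polyline(coords: np.ndarray, h: float) -> np.ndarray:
    """Points along a polyline at spacing <= h.

    Endpoints and sharp interior vertices (turns above ~25 degrees) are
    preserved exactly — losing a corner would clip area off the domain.
    Smooth dense polylines are thinned to the target spacing.
    """
    coords = np.asarray(coords, dtype=float)
    line = LineString(coords)
    seg = np.linalg.norm(np.diff(coords, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    required = [0.0, line.length]
    if len(coords) > 2:
        d = np.diff(coords, axis=0)
        d = d / np.maximum(np.linalg.norm(d, axis=1, keepdims=True), 1e-30)
        cosang = (d[:-1] * d[1:]).sum(axis=1)
        sharp = np.flatnonzero(cosang < np.cos(np.deg2rad(25.0))) + 1
        required.extend(arc[sharp].tolist())
    required = np.unique(required)
    # uniform samples between consecutive required positions
    pos = []
    for a, b in zip(required[:-1], required[1:]):
        n = max(1, int(np.ceil((b - a) / h)))
        pos.append(np.linspace(a, b, n + 1)[:-1])
    pos = np.concatenate(pos + [[line.length]])
    pts = [line.interpolate(t) for t in pos]
    out = np.array([[p.x, p.y] for p in pts])
    # merge near-duplicates (keep first of each close pair, never endpoints)
    keep = np.ones(len(out), bool)
    d = np.linalg.norm(np.diff(out, axis=0), axis=1)
    too_close = np.flatnonzero(d < 0.3 * h) + 1
    keep[too_close[too_close < len(out) - 1]] = False
    return out[keep]


def _hex_lattice(poly: Polygon, h: float, margin: float) -> np.ndarray:
    minx, miny, maxx, maxy = poly.bounds
    dy = h * np.sqrt(3.0) / 2.0
    rows = np.arange(miny + margin, maxy, dy)
    pts = []
    for k, y in enumerate(rows):
        xs = np.arange(minx + margin + (0.5 * h if k % 2 else 0.0), maxx, h)
        pts.append(np.column_stack([xs, np.full_like(xs, y)]))
    if not pts:
        return np.empty((0, 2))
    pts = np.vstack(pts)
    keep_region = poly.buffer(-margin)
    inside = shapely.contains_xy(keep_region, pts[:, 0], pts[:, 1])
    return pts[inside]


def _delaunay_inside(points: np.ndarray, poly: Polygon) -> np.ndarray:
    tri = Delaunay(points)
    cells = tri.simplices
    cent = points[cells].mean(axis=1)
    keep = shapely.contains_xy(poly, cent[:, 0], cent[:, 1])
    cells = cells[keep]
    # enforce CCW orientation
    p = points[cells]
    area2 = (p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1]) - (
        p[:, 1, 1] - p[:, 0, 1]
    ) * (p[:, 2, 0] - p[:, 0, 0])
    flip = area2 < 0
    cells[flip] = cells[flip][:, ::-1]
    # drop degenerate slivers (can appear along the boundary resampling)
    keep = np.abs(area2) > 1e-14 * max(poly.area, 1e-30)
    return cells[keep]


def _boundary_edges_of(cells: np.ndarray) -> np.ndarray:
    """Directed edges used by exactly one triangle, interior on the left."""
    e = np.vstack([cells[:, [0, 1]], cells[:, [1, 2]], cells[:, [2, 0]]])
    key = e[:, 0].astype(np.int64) * (e.max() + 1) + e[:, 1]
    rkey = e[:, 1].astype(np.int64) * (e.max() + 1) + e[:, 0]
    has_twin = np.isin(key, rkey)
    return e[~has_twin]


def triangulate_domain(
    segments: Sequence[tuple[str, np.ndarray]],
    h: float,
    *,
    laa_region: Polygon | None = None,
    n_smooth: int = 6,
    quality_threshold: float = 0.1,
) -> Mesh:
    """Mesh the closed domain bounded by the ordered labeled polylines.

    ``segments`` traverse the boundary once, counter-clockwise; consecutive
    polylines share endpoints.  Each generated boundary facet inherits the
    label of the nearest source polyline.  Cells are tagged LAA when their
    centroid falls inside ``laa_region`` (LA otherwise).
    """
    if h <= 0:
        raise ResolutionError("mesh size h must be positive")
    if not segments:
        raise GeometryError("no boundary segments given")

    # --- closedness check and ring assembly
    ring_pts: list[np.ndarray] = []
    tol = 1e-12
    for i, (_, coords) in enumerate(segments):
        coords = np.asarray(coords, dtype=float)
        if coords.ndim != 2 or len(coords) < 2:
            raise GeometryError(f"segment {i} is not a polyline")
        nxt = np.asarray(segments[(i + 1) % len(segments)][1], dtype=float)
        if not np.allclose(coords[-1], nxt[0], atol=1e-9):
            raise GeometryError("boundary is not closed: segment endpoints do not chain")
        res = _resample_polyline(coords, h)
        ring_pts.append(res[:-1])  # drop joint, provided by next segment
    boundary_points = np.vstack(ring_pts)
    if len(boundary_points) < 3:
        raise GeometryError("boundary has fewer than 3 points")
    poly = Polygon(boundary_points)
    if (not poly.is_valid) or poly.area <= tol:
        raise GeometryError("boundary polygon is invalid or self-intersecting")

    nb = len(boundary_points)
    interior = _hex_lattice(poly, h, margin=0.65 * h)
    points = np.vstack([boundary_points, interior])

    # Laplacian smoothing of interior points with Delaunay reconnection
    keep_region = poly.buffer(-0.4 * h)
    for _ in range(n_smooth):
        if len(points) <= nb:
            break
        tri = Delaunay(points)
        # vertex adjacency from simplices
        sim = tri.simplices
        e = np.vstack([sim[:, [0, 1]], sim[:, [1, 2]], sim[:, [2, 0]]])
        e = np.vstack([e, e[:, ::-1]])
        order = np.lexsort((e[:, 1], e[:, 0]))
        e = e[order]
        counts = np.bincount(e[:, 0], minlength=len(points)).astype(float)
        sx = np.bincount(e[:, 0], weights=points[e[:, 1], 0], minlength=len(points))
        sy = np.bincount(e[:, 0], weights=points[e[:, 1], 1], minlength=len(points))
        new = points.copy()
        idx = np.arange(nb, len(points))
        good = counts[idx] > 0
        new[idx[good], 0] = sx[idx[good]] / counts[idx[good]]
        new[idx[good], 1] = sy[idx[good]] / counts[idx[good]]
        moved_ok = shapely.contains_xy(keep_region, new[nb:, 0], new[nb:, 1])
        points[nb:][moved_ok] = new[nb:][moved_ok]

    cells = _delaunay_inside(points, poly)
    if len(cells) == 0:
        raise GeometryError("triangulation produced no interior cells")

    # drop vertices unused after culling
    used = np.unique(cells)
    remap = -np.ones(len(points), dtype=int)
    remap[used] = np.arange(len(used))
    vertices = points[used]
    cells = remap[cells]

    bedges = _boundary_edges_of(cells)

    # facet labels by nearest source polyline
    seg_lines = [(label, LineString(np.asarray(c, dtype=float))) for label, c in segments]
    mids = 0.5 * (vertices[bedges[:, 0]] + vertices[bedges[:, 1]])
    mid_pts = shapely.points(mids[:, 0], mids[:, 1])
    dists = np.column_stack([shapely.distance(mid_pts, line) for _, line in seg_lines])
    labels = np.array([seg_lines[j][0] for j in dists.argmin(axis=1)])

    if laa_region is not None:
        cent = vertices[cells].mean(axis=1)
        in_laa = shapely.contains_xy(laa_region, cent[:, 0], cent[:, 1])
        region = np.where(in_laa, REGION_LAA, REGION_LA)
    else:
        region = np.full(len(cells), REGION_LA)

    mesh = Mesh(
        vertices=vertices,
        cells=cells,
        boundary_edges=bedges,
        boundary_labels=labels,
        region=region,
        h=float(h),
    )
    if mesh.min_quality < quality_threshold:
        raise MeshQualityError(
            f"minimum cell quality {mesh.min_quality:.3f} below threshold {quality_threshold}"
        )
    return mesh


def segments_from_polygon(coords: np.ndarray, label: str = "wall") -> list[tuple[str, np.ndarray]]:
    """Wrap a closed CCW polygon outline as a single labeled boundary segment."""
    coords = np.asarray(coords, dtype=float)
    if not np.allclose(coords[0], coords[-1]):
        coords = np.vstack([coords, coords[:1]])
    return [(label, coords)]


def generate_mesh(anatomy, h: float) -> Mesh:
    """Mesh a labeled anatomy at characteristic length ``h`` (metres)."""
    if h <= 0:
        raise ResolutionError("mesh size h must be positive")
    spec = getattr(anatomy, "provenance", None)
    if spec is not None and h >= spec.ostium_diameter:
        raise ResolutionError(
            f"h={h} does not resolve the ostium (diameter {spec.ostium_diameter})"
        )
    anatomy.validate()
    return triangulate_domain(anatomy.segments, h, laa_region=anatomy.laa_region)


def region_volumes(mesh: Mesh) -> dict[str, float]:
    """Areas (2-D volumes) of the LA and LAA regions and the whole domain.

    The sums are exact over cell measures, so V_LA + V_LAA == V_domain to
    rounding.
    """
    if mesh.region is None:
        raise TaggingError("mesh has no region tags")
    areas = mesh.cell_areas
    known = np.isin(mesh.region, [REGION_LA, REGION_LAA])
    if not known.all():
        raise TaggingError("mesh contains cells with unknown region tags")
    v_la = float(areas[mesh.region == REGION_LA].sum())
    v_laa = float(areas[mesh.region == REGION_LAA].sum())
    return {"V_LA": v_la, "V_LAA": v_laa, "V_domain": v_la + v_laa}
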