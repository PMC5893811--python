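"""Parametric planar left-atrium + appendage geometries.

The atrial body is an ellipse with straight labeled chords carved into its
boundary for the pulmonary-vein inlets (upper arc), the mitral orifice
(bottom) and the appendage ostium (left).  The appendage itself is built
per morphology class as a union of buffered centerline segments and lobe
ellipses in a local frame whose x-axis points out of the ostium:

* ``chicken_wing`` — a single tube whose heading turns by ``bend_angle``
  over its middle section;
* ``cactus`` — a central tube with ``n_lobes`` secondary lobes attached
  alternately along its sides;
* ``windsock`` — one dominant, gently curved tube tapering linearly to
  ``taper_ratio`` of the ostium width;
* ``cauliflower`` — a short, widening sac with ``n_lobes`` peripheral
  lobes and a seeded irregular outline.

All dimensions are SI metres: the atrial diameter defaults to 5 cm and
appendage lengths to the clinically reported 2–4 cm range.  A seed fully
determines the geometry, so equal specs give bit-identical models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely
from shapely import affinity
from shapely.geometry import LineString, Point, Polygon, box
from shapely.ops import unary_union

from .errors import GeometryError, InvalidSpecError

CHICKEN_WING = "chicken_wing"
CACTUS = "cactus"
WINDSOCK = "windsock"
CAULIFLOWER = "cauliflower"
MORPHOLOGY_CLASSES = (CHICKEN_WING, CACTUS, WINDSOCK, CAULIFLOWER)

#: ellipse aspect ratio of the atrial body (minor/major)
_LA_ASPECT = 0.85
#: intrusion of the appendage base into the atrium to guarantee a clean union
_BASE_INTRUSION_FRACTION = 0.35
_PV_SPAN_DEG = (40.0, 140.0)
#: boundary angle of the appendage ostium centre: anterolateral, adjacent
#: to the mitral annulus (the mitral chord spans ~237-303 degrees)
_OSTIUM_ANGLE_DEG = 200.0
_RING_POINTS = 512


@dataclass(frozen=True)
class AnatomySpec:
    """Parameter set that fully determines one synthetic anatomy."""

    morphology_class: str
    la_diameter: float = 0.05
    laa_length: float = 0.03
    ostium_diameter: float = 0.02
    bend_angle: float = 100.0  # degrees, chicken_wing only
    n_lobes: int = 3  # cactus / cauliflower
    taper_ratio: float = 0.4  # windsock tip/ostium width
    n_pv_inlets: int = 4
    pv_diameter: float = 0.009
    mitral_diameter: float = 0.025
    seed: int = 0

    def __post_init__(self):
        if self.morphology_class not in MORPHOLOGY_CLASSES:
            raise InvalidSpecError(f"unknown morphology class {self.morphology_class!r}")
        for name in ("la_diameter", "laa_length", "ostium_diameter", "pv_diameter",
                     "mitral_diameter"):
            if getattr(self, name) <= 0:
                raise InvalidSpecError(f"{name} must be positive")
        if self.ostium_diameter >= self.la_diameter:
            raise InvalidSpecError("ostium_diameter must be smaller than la_diameter")
        if not (2 <= self.n_pv_inlets <= 6):
            raise InvalidSpecError("n_pv_inlets must be between 2 and 6")
        if self.n_lobes < 1:
            raise InvalidSpecError("n_lobes must be at least 1")
        if not (0.05 < self.taper_ratio <= 1.0):
            raise InvalidSpecError("taper_ratio must lie in (0.05, 1]")


#: default anatomy per class; PV counts follow the anatomies the morphology
#: classes are typically reported with (chicken wing 4, cactus 5, windsock 6,
#: cauliflower 4), and the cauliflower is the short, multi-lobed one
#: vein width shrinks as the vein count grows (as in real drainage variants);
#: widths are near the physiological ~1 cm, limited by 2-D boundary packing
DEFAULT_SPECS: dict[str, AnatomySpec] = {
    CHICKEN_WING: AnatomySpec(CHICKEN_WING, laa_length=0.030, ostium_diameter=0.018,
                              bend_angle=100.0, n_pv_inlets=4, pv_diameter=0.011,
                              seed=11),
    CACTUS: AnatomySpec(CACTUS, laa_length=0.028, ostium_diameter=0.020, n_lobes=3,
                        n_pv_inlets=5, pv_diameter=0.0095, seed=12),
    WINDSOCK: AnatomySpec(WINDSOCK, laa_length=0.035, ostium_diameter=0.020,
                          taper_ratio=0.4, n_pv_inlets=6, pv_diameter=0.0075, seed=13),
    CAULIFLOWER: AnatomySpec(CAULIFLOWER, laa_length=0.018, ostium_diameter=0.022,
                             n_lobes=4, n_pv_inlets=4, pv_diameter=0.011, seed=14),
}


@dataclass
class AnatomyModel:
    """Labeled planar geometry ready for meshing.

    ``segments`` traverse the closed boundary counter-clockwise as
    (label, polyline) pairs; ``ostium_curve`` is the internal chord
    separating atrium from appendage; ``laa_region`` is the appendage-side
    polygon used for cell tagging.
    """

    dimension: int
    segments: list[tuple[str, np.ndarray]]
    ostium_curve: np.ndarray  # (2, 2) endpoints
    laa_region: Polygon
    domain: Polygon
    provenance: AnatomySpec | None = None

    def validate(self) -> None:
        if len(self.segments) < 1:
            raise GeometryError("anatomy has no boundary segments")
        for i, (_, coords) in enumerate(self.segments):
            nxt = self.segments[(i + 1) % len(self.segments)][1]
            if not np.allclose(np.asarray(coords)[-1], np.asarray(nxt)[0], atol=1e-9):
                raise GeometryError("anatomy boundary is not closed")
        if not self.domain.is_valid:
            raise GeometryError("anatomy outline is self-intersecting")

    @property
    def ostium_centroid(self) -> np.ndarray:
        return self.ostium_curve.mean(axis=0)


# ----------------------------------------------------------------------
# atrial body with boundary openings


def _ellipse_point(theta, rx, ry):
    return np.column_stack([rx * np.cos(theta), ry * np.sin(theta)])


def _opening_halfwidth(theta_c: float, width: float, rx: float, ry: float) -> float:
    """Angular half-extent of a straight chord of the given width."""

    def chord(delta):
        p = _ellipse_point(np.array([theta_c - delta, theta_c + delta]), rx, ry)
        return float(np.hypot(*(p[1] - p[0])))

    lo, hi = 1e-6, 0.45 * np.pi
    if chord(hi) < width:
        raise InvalidSpecError("opening too wide for the atrial body")
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if chord(mid) < width:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _pv_angles(n_pv: int) -> np.ndarray:
    a0, a1 = np.deg2rad(_PV_SPAN_DEG)
    if n_pv == 1:
        return np.array([0.5 * (a0 + a1)])
    return np.linspace(a0, a1, n_pv)


def _build_la_ring(spec: AnatomySpec):
    """Atrial ellipse outline with labeled openings.

    The mitral orifice is a flat chord (velocity is prescribed there).
    Each pulmonary vein is a short stub channel extruded radially from
    its chord, with wall sides and the open (p = 0) inlet at the far
    end — placing the open boundary in quasi-one-dimensional flow away
    from the atrial corner vortices, as the real vein geometry does.
    """
    rx = 0.5 * spec.la_diameter
    ry = _LA_ASPECT * rx
    openings = [("mitral_outlet", 1.5 * np.pi, spec.mitral_diameter)]
    for k, th in enumerate(_pv_angles(spec.n_pv_inlets)):
        openings.append((f"pv_inlet_{k}", th, spec.pv_diameter))

    spans = []
    for label, th, w in openings:
        d = _opening_halfwidth(th, w, rx, ry)
        spans.append((label, th - d, th + d))
    # overlap check (angles in [0, 2pi))
    for i, (la, a0, a1) in enumerate(spans):
        for lb, b0, b1 in spans[i + 1:]:
            if max(a0, b0) < min(a1, b1):
                raise InvalidSpecError(f"boundary openings {la} and {lb} overlap")

    theta = np.linspace(0.0, 2.0 * np.pi, _RING_POINTS, endpoint=False)
    keep = np.ones(len(theta), bool)
    margin = 0.6 * (2.0 * np.pi / _RING_POINTS)  # avoid slivers at chord ends
    for _, a0, a1 in spans:
        ang = np.mod(theta - (a0 - margin), 2.0 * np.pi)
        keep &= ~(ang < (a1 - a0 + 2.0 * margin))
    pts = list(zip(theta[keep], _ellipse_point(theta[keep], rx, ry)))
    chords = {}
    for label, a0, a1 in spans:
        p0 = _ellipse_point(np.array([a0]), rx, ry)[0]
        p1 = _ellipse_point(np.array([a1]), rx, ry)[0]
        if label.startswith("pv_inlet"):
            thc = 0.5 * (a0 + a1)
            n_out = np.array([np.cos(thc) / rx, np.sin(thc) / ry])
            n_out /= np.linalg.norm(n_out)
            L = 1.5 * spec.pv_diameter
            q0, q1 = p0 + L * n_out, p1 + L * n_out
            # pseudo-angles keep the stub points ordered along the walk
            da = (a1 - a0) / 3.0
            pts.append((np.mod(a0, 2 * np.pi), p0))
            pts.append((np.mod(a0 + da, 2 * np.pi), q0))
            pts.append((np.mod(a0 + 2 * da, 2 * np.pi), q1))
            pts.append((np.mod(a1, 2 * np.pi), p1))
            chords[label] = np.vstack([q0, q1])
        else:
            pts.append((np.mod(a0, 2 * np.pi), p0))
            pts.append((np.mod(a1, 2 * np.pi), p1))
            chords[label] = np.vstack([p0, p1])
    pts.sort(key=lambda item: item[0])
    ring = np.array([p for _, p in pts])
    return ring, chords, rx, ry


# ----------------------------------------------------------------------
# appendage outlines (local frame: base at origin, +x out of the ostium)


def _tube_polygon(centerline: np.ndarray, widths: np.ndarray) -> Polygon:
    """Union of buffered segments: a lobed-free tube with rounded tip."""
    pieces = []
    for i in range(len(centerline) - 1):
        seg = LineString(centerline[i:i + 2])
        w = 0.5 * (widths[i] + widths[i + 1])
        pieces.append(seg.buffer(0.5 * w, quad_segs=12))
    return unary_union(pieces)


def _bent_centerline(length: float, bend_rad: float, bend_window=(0.3, 0.9), n=48):
    """Polyline whose heading turns by ``bend_rad`` across the window."""
    t = np.linspace(0.0, 1.0, n)
    b0, b1 = bend_window
    frac = np.clip((t - b0) / (b1 - b0), 0.0, 1.0)
    heading = bend_rad * frac
    ds = length / (n - 1)
    pts = np.zeros((n, 2))
    for i in range(1, n):
        hm = 0.5 * (heading[i - 1] + heading[i])
        pts[i] = pts[i - 1] + ds * np.array([np.cos(hm), np.sin(hm)])
    return pts


def _ellipse_lobe(center, a, b, angle_deg, rng) -> Polygon:
    e = Point(0.0, 0.0).buffer(1.0, quad_segs=16)
    e = affinity.scale(e, a, b)
    e = affinity.rotate(e, angle_deg)
    return affinity.translate(e, center[0], center[1])


def _laa_polygon_local(spec: AnatomySpec) -> Polygon:
    rng = np.random.default_rng(spec.seed)
    L, w0 = spec.laa_length, spec.ostium_diameter
    intr = _BASE_INTRUSION_FRACTION * w0

    if spec.morphology_class == CHICKEN_WING:
        c = _bent_centerline(L, np.deg2rad(spec.bend_angle))
        widths = w0 * (1.0 - 0.45 * np.linspace(0, 1, len(c)))
        poly = _tube_polygon(c, widths)
    elif spec.morphology_class == WINDSOCK:
        c = _bent_centerline(L, np.deg2rad(18.0))
        widths = w0 * (1.0 - (1.0 - spec.taper_ratio) * np.linspace(0, 1, len(c)))
        poly = _tube_polygon(c, widths)
    elif spec.morphology_class == CACTUS:
        c = _bent_centerline(L, np.deg2rad(10.0))
        widths = w0 * (1.0 - 0.4 * np.linspace(0, 1, len(c)))
        pieces = [_tube_polygon(c, widths)]
        n = len(c)
        for k in range(spec.n_lobes):
            tk = 0.35 + 0.5 * k / max(spec.n_lobes - 1, 1)
            i = int(tk * (n - 1))
            tang = c[min(i + 1, n - 1)] - c[max(i - 1, 0)]
            tang /= np.linalg.norm(tang)
            nrm = np.array([-tang[1], tang[0]]) * (1 if k % 2 == 0 else -1)
            wloc = widths[i]
            a = (0.55 + 0.15 * rng.random()) * w0
            b = (0.30 + 0.10 * rng.random()) * w0
            center = c[i] + nrm * (0.5 * wloc + 0.55 * b)
            ang = np.degrees(np.arctan2(nrm[1], nrm[0])) + rng.normal(0.0, 8.0)
            pieces.append(_ellipse_lobe(center, a, b, ang, rng))
        poly = unary_union(pieces)
    else:  # cauliflower: short widening sac + peripheral lobes
        c = np.column_stack([np.linspace(0, L, 24), np.zeros(24)])
        widths = w0 * (1.0 + 0.45 * np.linspace(0, 1, len(c)))
        pieces = [_tube_polygon(c, widths)]
        tip = c[-1]
        for k in range(spec.n_lobes):
            ang = (-60.0 + 120.0 * k / max(spec.n_lobes - 1, 1)) + rng.normal(0.0, 10.0)
            ar = np.deg2rad(ang)
            r = 0.5 * widths[-1] * (0.85 + 0.2 * rng.random())
            center = tip + r * np.array([np.cos(ar), np.sin(ar)])
            a = (0.24 + 0.08 * rng.random()) * w0
            b = (0.18 + 0.08 * rng.random()) * w0
            pieces.append(_ellipse_lobe(center, a, b, ang, rng))
        poly = unary_union(pieces)

    # keep a slight intrusion behind the base plane for a clean union with
    # the atrium; everything further inward is discarded
    clip = box(-intr, -3.0 * L - w0, 3.0 * L + w0, 3.0 * L + w0)
    poly = poly.intersection(clip)
    if poly.geom_type == "MultiPolygon":
        poly = max(poly.geoms, key=lambda g: g.area)
    return Polygon(poly.exterior)


# ----------------------------------------------------------------------


def generate_anatomy(spec: AnatomySpec) -> AnatomyModel:
    """Build the labeled planar LA + LAA geometry for one spec.

    Deterministic: equal specs (including the seed) yield bit-identical
    geometry.  Raises :class:`InvalidSpecError` for inadmissible specs.
    """
    ring, chords, rx, ry = _build_la_ring(spec)
    la_poly = Polygon(ring)
    if not la_poly.is_valid:
        raise GeometryError("atrial outline is invalid")

    # place the appendage: the local +x axis exits the atrium along the
    # outward ellipse normal at the ostium angle
    th_o = np.deg2rad(_OSTIUM_ANGLE_DEG)
    origin = _ellipse_point(np.array([th_o]), rx, ry)[0]
    n_out = np.array([np.cos(th_o) / rx, np.sin(th_o) / ry])
    n_out /= np.linalg.norm(n_out)
    rot_deg = np.degrees(np.arctan2(n_out[1], n_out[0]))

    def _to_global(geom):
        return affinity.translate(
            affinity.rotate(geom, rot_deg, origin=(0, 0)), origin[0], origin[1]
        )

    laa_local = _laa_polygon_local(spec)
    laa_global = _to_global(laa_local)
    domain = unary_union([la_poly, laa_global])
    if domain.geom_type != "Polygon":
        raise GeometryError("appendage failed to merge with the atrial body")
    domain = Polygon(domain.exterior)
    domain = shapely.geometry.polygon.orient(domain, sign=1.0)

    # ostium chord: the base plane of the local frame
    w0 = spec.ostium_diameter
    t_hat = np.array([-n_out[1], n_out[0]])
    ostium = np.array([origin + 0.5 * w0 * t_hat, origin - 0.5 * w0 * t_hat])
    span = 6.0 * (spec.laa_length + w0)
    half_local = box(0.0, -span, span, span)  # x' >= 0 half-plane
    laa_region = _to_global(laa_local.intersection(half_local))
    if laa_region.geom_type == "MultiPolygon":
        laa_region = max(laa_region.geoms, key=lambda g: g.area)

    # split the union ring into labeled segments by chord proximity
    coords = np.asarray(domain.exterior.coords)[:-1]
    nseg = len(coords)
    mids = 0.5 * (coords + np.roll(coords, -1, axis=0))
    labels = np.full(nseg, "wall", dtype=object)
    tol = 1e-9
    for label, chord in chords.items():
        line = LineString(chord)
        d = shapely.distance(shapely.points(mids[:, 0], mids[:, 1]), line)
        labels[d < max(tol, 1e-6 * rx)] = label

    # rotate start so no labeled run wraps around the array end
    wall_idx = np.flatnonzero(labels == "wall")
    if len(wall_idx) == 0:
        raise GeometryError("no wall boundary found")
    shift = wall_idx[0]
    coords = np.roll(coords, -shift, axis=0)
    labels = np.roll(labels, -shift)

    segments: list[tuple[str, np.ndarray]] = []
    start = 0
    for i in range(1, nseg + 1):
        if i == nseg or labels[i] != labels[start]:
            seg_coords = coords[start: i + 1] if i < nseg else np.vstack([coords[start:], coords[:1]])
            segments.append((str(labels[start]), seg_coords))
            start = i

    model = AnatomyModel(
        dimension=2,
        segments=segments,
        ostium_curve=ostium,
        laa_region=laa_region,
        domain=domain,
        provenance=spec,
    )
    model.validate()
    return model


def default_anatomy(morphology_class: str) -> AnatomyModel:
    if morphology_class not in DEFAULT_SPECS:
        raise InvalidSpecError(f"unknown morphology class {morphology_class!r}")
    return generate_anatomy(DEFAULT_SPECS[morphology_class])
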