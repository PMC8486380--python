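"""Species range polygons from occurrence points.

Ranges are estimated as alpha-shapes of occurrence coordinates: the union of
Delaunay triangles whose circumradius (in degrees, planar in lon/lat) does
not exceed the alpha parameter. The alpha-shape converges to the convex hull
for large alpha and develops concavities and holes for small alpha. Taxa are
classified as terrestrial or marine by majority overlap of their occurrences
with landmass polygons, and ranges are clipped so terrestrial ranges do not
overrun oceans nor marine ranges landmasses. Areas are geodesic, evaluated
on a sphere of radius 6371 km.

Coordinates are WGS84 longitude/latitude degrees throughout; no projected
coordinate system is exposed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely
import shapely.affinity
from scipy.spatial import Delaunay, QhullError
from shapely.geometry import MultiPoint, Point, Polygon
from shapely.ops import unary_union

from .errors import (
    DegenerateGeometryError,
    EmptyRangeError,
    InvalidArgumentError,
    InvalidGeometryError,
)

__all__ = [
    "OccurrenceSet",
    "RangePolygon",
    "alpha_shape",
    "classify_realm",
    "clip_range",
    "polygon_area_km2",
    "buffer_points_km",
    "estimate_range",
    "split_at_antimeridian",
    "EARTH_RADIUS_KM",
    "DEFAULT_ALPHA",
]

EARTH_RADIUS_KM = 6371.0
KM_PER_DEGREE = EARTH_RADIUS_KM * np.pi / 180.0  # ~111.19 km along a meridian

#: Default alpha (degrees) by realm; marine occurrences are sparser, so the
#: marine default is more permissive.
DEFAULT_ALPHA = {"terrestrial": 6.0, "marine": 20.0}


@dataclass
class OccurrenceSet:
    """Occurrence coordinates for one species (lon/lat degrees, WGS84)."""

    species_id: str
    points: np.ndarray  # shape (n, 2): [longitude, latitude]

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 1:
            raise InvalidArgumentError("points must be a non-empty (n, 2) array")
        lon, lat = pts[:, 0], pts[:, 1]
        if np.any(np.abs(lon) > 180) or np.any(np.abs(lat) > 90):
            raise InvalidArgumentError("coordinates outside [-180,180] x [-90,90]")
        self.points = pts


@dataclass
class RangePolygon:
    """An estimated species range with its realm and geodesic area."""

    species_id: str
    geometry: shapely.Geometry
    realm: str
    area_km2: float
    alpha_used: float  # NaN when the buffer fallback was used


def _circumradii(points: np.ndarray, simplices: np.ndarray) -> np.ndarray:
    """Circumradius of each Delaunay triangle, R = abc / (4 * area)."""
    p = points[simplices]
    a = np.linalg.norm(p[:, 0] - p[:, 1], axis=1)
    b = np.linalg.norm(p[:, 1] - p[:, 2], axis=1)
    c = np.linalg.norm(p[:, 2] - p[:, 0], axis=1)
    cross = (p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1]) - (
        p[:, 1, 1] - p[:, 0, 1]
    ) * (p[:, 2, 0] - p[:, 0, 0])
    area2 = np.abs(cross)  # twice the triangle area
    with np.errstate(divide="ignore", invalid="ignore"):
        radii = a * b * c / (2.0 * area2)
    radii[area2 == 0] = np.inf
    return radii


def alpha_shape(occurrences: OccurrenceSet | np.ndarray, alpha: float) -> shapely.Geometry:
    """Alpha-shape of a point set: union of small-circumradius Delaunay triangles.

    Parameters
    ----------
    occurrences
        Point coordinates (lon/lat degrees) or an :class:`OccurrenceSet`.
    alpha
        Circumradius threshold in degrees. Triangles with circumradius
        greater than ``alpha`` are discarded; for alpha exceeding the
        largest circumradius the result is the convex hull.

    Raises
    ------
    DegenerateGeometryError
        Fewer than 3 distinct points, or all points collinear. Callers
        should fall back to :func:`buffer_points_km`.
    """
    if alpha <= 0:
        raise InvalidArgumentError("alpha must be > 0")
    pts = occurrences.points if isinstance(occurrences, OccurrenceSet) else np.asarray(occurrences, float)
    pts = np.unique(pts, axis=0)
    if len(pts) < 3:
        raise DegenerateGeometryError("need >= 3 distinct points for an alpha-shape")
    try:
        tri = Delaunay(pts)
    except QhullError as exc:
        raise DegenerateGeometryError(f"degenerate point configuration: {exc}") from exc
    keep = _circumradii(pts, tri.simplices) <= alpha
    if not np.any(keep):
        raise DegenerateGeometryError(
            "no Delaunay triangle has circumradius <= alpha; increase alpha "
            "or use the buffer fallback"
        )
    triangles = [Polygon(pts[s]) for s in tri.simplices[keep]]
    return unary_union(triangles)


def classify_realm(occurrences: OccurrenceSet, land: shapely.Geometry) -> str:
    """Terrestrial if at least half the occurrences fall on land, else marine.

    The tie at exactly 50% resolves to terrestrial.
    """
    pts = occurrences.points
    land = unary_union(land) if isinstance(land, (list, tuple)) else land
    on_land = shapely.intersects_xy(land, pts[:, 0], pts[:, 1])
    return "terrestrial" if on_land.mean() >= 0.5 else "marine"


def clip_range(
    geometry: shapely.Geometry, realm: str, land: shapely.Geometry
) -> shapely.Geometry:
    """Intersect terrestrial ranges with land; subtract land from marine ranges."""
    if realm not in ("terrestrial", "marine"):
        raise InvalidArgumentError(f"unknown realm {realm!r}")
    land = unary_union(land) if isinstance(land, (list, tuple)) else land
    clipped = geometry.intersection(land) if realm == "terrestrial" else geometry.difference(land)
    if clipped.is_empty:
        raise EmptyRangeError(f"clipping against land left an empty {realm} range")
    return clipped


def _ring_area_steradians(coords: np.ndarray) -> float:
    """Unsigned spherical area of a ring whose edges are linear in lon/lat.

    Uses the spherical-excess line integral
    ``A = R^2 |sum dlam * (2 + sin(phi1) + sin(phi2)) / 2|`` (here without
    the R^2 factor), which is exact for latitude-longitude cells and
    accurate for short edges; callers densify edges first.
    """
    lon = np.radians(coords[:, 0])
    lat = np.radians(coords[:, 1])
    dlon = np.diff(lon)
    # wrap longitude steps into (-pi, pi] so antimeridian-crossing edges work
    dlon = (dlon + np.pi) % (2 * np.pi) - np.pi
    s = np.sin(lat)
    return abs(np.sum(dlon * (2.0 + s[:-1] + s[1:]) / 2.0))


def _unwrap_if_crossing(geom: shapely.Geometry) -> shapely.Geometry:
    """Map longitudes to [0, 360) when the geometry straddles the antimeridian.

    A longitude jump over 180 degrees between consecutive vertices signals
    either a genuine antimeridian crossing (coordinates wrapped into
    [-180, 180]) or a legitimately wide polygon. The wrapped representation
    is adopted only when it is valid and strictly tighter (smaller planar
    area) than the original, which distinguishes the two cases; the shift
    keeps rings continuous so edge densification behaves.
    """
    def crosses(g: shapely.Geometry) -> bool:
        for ring in _rings(g):
            dl = np.abs(np.diff(ring[:, 0]))
            if np.any(dl > 180):
                return True
        return False

    if not crosses(geom):
        return geom
    candidate = shapely.transform(
        geom, lambda coords: np.column_stack([coords[:, 0] % 360.0, coords[:, 1]])
    )
    if candidate.is_valid and 0 < candidate.area < geom.area:
        return candidate
    return geom


def _rings(geom: shapely.Geometry):
    polys = geom.geoms if geom.geom_type.startswith("Multi") else [geom]
    for poly in polys:
        if poly.is_empty or poly.geom_type != "Polygon":
            continue
        yield np.asarray(poly.exterior.coords)
        for interior in poly.interiors:
            yield np.asarray(interior.coords)


def polygon_area_km2(geometry: shapely.Geometry, max_segment_deg: float = 0.25) -> float:
    """Geodesic area of a lon/lat (multi)polygon on a sphere of radius 6371 km.

    Edges are treated as linear in lon/lat and densified to at most
    ``max_segment_deg`` before integrating the spherical excess, so the
    result is additive over disjoint parts, invariant to longitude rotation,
    and exact for latitude-longitude cells. Hole areas are subtracted.

    Raises
    ------
    InvalidGeometryError
        If the polygon is self-intersecting or otherwise invalid.
    """
    if geometry.is_empty:
        return 0.0
    if not geometry.is_valid:
        raise InvalidGeometryError("self-intersecting or invalid polygon")
    geometry = _unwrap_if_crossing(geometry)
    geometry = shapely.segmentize(geometry, max_segment_deg)
    polys = geometry.geoms if geometry.geom_type.startswith("Multi") else [geometry]
    total = 0.0
    for poly in polys:
        if poly.is_empty:
            continue
        if poly.geom_type != "Polygon":
            raise InvalidGeometryError(f"expected polygonal geometry, got {poly.geom_type}")
        total += _ring_area_steradians(np.asarray(poly.exterior.coords))
        for interior in poly.interiors:
            total -= _ring_area_steradians(np.asarray(interior.coords))
    return EARTH_RADIUS_KM**2 * total


def split_at_antimeridian(geometry: shapely.Geometry) -> shapely.Geometry:
    """Split a geometry straddling +/-180 into canonical [-180, 180] pieces."""
    geometry = _unwrap_if_crossing(geometry)
    minx, _, maxx, _ = geometry.bounds
    if maxx <= 180.0:
        return geometry
    west = geometry.intersection(shapely.box(0.0, -90.0, 180.0, 90.0))
    east = geometry.intersection(shapely.box(180.0, -90.0, 360.0, 90.0))
    east = shapely.affinity.translate(east, xoff=-360.0)
    return unary_union([west, east])


def buffer_points_km(points: np.ndarray, radius_km: float = 100.0) -> shapely.Geometry:
    """Union of ~circular buffers of ``radius_km`` around each point.

    Buffers are drawn in degrees, with the east-west extent widened by
    1/cos(latitude) so the ground distance is approximately uniform. This is
    the fallback range for taxa whose occurrences cannot support an
    alpha-shape (fewer than three points, or collinear).
    """
    if radius_km <= 0:
        raise InvalidArgumentError("radius_km must be > 0")
    r_deg = radius_km / KM_PER_DEGREE
    discs = []
    for lon, lat in np.asarray(points, float):
        stretch = 1.0 / max(np.cos(np.radians(lat)), 0.05)
        disc = Point(lon, lat).buffer(r_deg, quad_segs=16)
        disc = shapely.affinity.scale(disc, xfact=stretch, yfact=1.0, origin=(lon, lat))
        discs.append(disc)
    return unary_union(discs)


def convex_hull(occurrences: OccurrenceSet | np.ndarray) -> shapely.Geometry:
    pts = occurrences.points if isinstance(occurrences, OccurrenceSet) else np.asarray(occurrences)
    return MultiPoint([tuple(p) for p in pts]).convex_hull


def estimate_range(
    occurrences: OccurrenceSet,
    land: shapely.Geometry | None = None,
    alpha: float | None = None,
    realm: str | None = None,
    buffer_km: float = 100.0,
) -> RangePolygon:
    """Full range-estimation pipeline for one species.

    Classifies the realm (if land polygons are given and ``realm`` is not
    forced), builds the alpha-shape with the realm's default alpha (or the
    supplied override), falls back to a 100 km buffer for degenerate point
    sets, clips against land, and computes the geodesic area.
    """
    if realm is None:
        realm = classify_realm(occurrences, land) if land is not None else "terrestrial"
    alpha_used = DEFAULT_ALPHA[realm] if alpha is None else alpha
    try:
        geom = alpha_shape(occurrences, alpha_used)
    except DegenerateGeometryError:
        geom = buffer_points_km(occurrences.points, buffer_km)
        alpha_used = float("nan")
    if land is not None:
        try:
            geom = clip_range(geom, realm, land)
        except EmptyRangeError:
            # Keep the unclipped shape rather than report a zero range; the
            # occurrences demonstrably exist somewhere.
            pass
    area = polygon_area_km2(geom)
    return RangePolygon(
        species_id=occurrences.species_id,
        geometry=geom,
        realm=realm,
        area_km2=area,
        alpha_used=alpha_used,
    )
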