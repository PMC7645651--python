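"""Map-projection distortion correction.

Cartographic projections of a curved embryo surface (sphere or prolate
spheroid) onto a flat pixel map distort lengths and areas in a
position-dependent way.  A :class:`MetricField` stores, per pixel, the local
physical length per map pixel along the two map axes ``(s_u, s_v)`` in
µm/px; every downstream measurement (cell area, perimeter, cable length,
tissue coverage) is integrated against it, so quantities are reported on the
curved surface rather than on the flat map.  The metric is diagonal, which
is exact for equirectangular/cylindrical projections.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import shapely
from scipy.integrate import quad

__all__ = [
    "MetricField",
    "flat_metric",
    "sphere_equirect_metric",
    "prolate_metric",
    "corrected_measures",
    "polygon_area_perimeter",
    "polyline_length",
    "masked_area",
    "tissue_area_series",
    "read_metric",
    "write_metric",
]


@dataclass(frozen=True)
class MetricField:
    """Per-pixel diagonal metric of a map projection.

    Attributes
    ----------
    s_u, s_v:
        2D arrays (same shape as the map raster) of physical µm per map
        pixel along the x (column) and y (row) axes.
    geometry:
        Descriptor dict, e.g. ``{"kind": "sphere", "radius_um": 250.0}`` or
        ``{"kind": "flat", "pixel_size_um": 0.5}``.
    """

    s_u: np.ndarray
    s_v: np.ndarray
    geometry: dict = field(default_factory=dict)

    def __post_init__(self):
        s_u = np.asarray(self.s_u, dtype=float)
        s_v = np.asarray(self.s_v, dtype=float)
        if s_u.shape != s_v.shape or s_u.ndim != 2:
            raise ValueError("s_u and s_v must be 2D arrays of equal shape")
        if not (np.all(s_u > 0) and np.all(s_v > 0)):
            raise ValueError("metric scale factors must be strictly positive")
        object.__setattr__(self, "s_u", s_u)
        object.__setattr__(self, "s_v", s_v)

    @property
    def shape(self) -> tuple[int, int]:
        return self.s_u.shape

    @property
    def pixel_area_um2(self) -> np.ndarray:
        """Physical area of each map pixel (µm²)."""
        return self.s_u * self.s_v

    @property
    def total_area_um2(self) -> float:
        """Physical area of the whole map domain (µm²)."""
        return float(self.pixel_area_um2.sum())

    @property
    def is_flat(self) -> bool:
        return self.geometry.get("kind") == "flat"

    def sample(self, x_px: np.ndarray, y_px: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Nearest-pixel metric at map positions (x, y) in pixel units."""
        h, w = self.shape
        c = np.clip(np.asarray(x_px).astype(int), 0, w - 1)
        r = np.clip(np.asarray(y_px).astype(int), 0, h - 1)
        return self.s_u[r, c], self.s_v[r, c]


def flat_metric(shape: tuple[int, int], pixel_size_um: float = 1.0) -> MetricField:
    """Identity metric: the map is the surface (s_u = s_v = pixel size)."""
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be positive")
    s = np.full(shape, float(pixel_size_um))
    return MetricField(s, s.copy(), {"kind": "flat", "pixel_size_um": float(pixel_size_um)})


def sphere_equirect_metric(radius_um: float, raster_shape: tuple[int, int]) -> MetricField:
    """Equirectangular (longitude–latitude) metric of a full sphere.

    The map covers lon ∈ [−π, π), lat ∈ [−π/2, π/2]; rows index latitude
    (top row = +π/2), columns longitude.  Per pixel, ``s_u = R·cos(lat)·Δlon``
    and ``s_v = R·Δlat`` evaluated at the pixel center.
    """
    if radius_um <= 0:
        raise ValueError("radius must be positive")
    h, w = raster_shape
    dlon = 2.0 * np.pi / w
    dlat = np.pi / h
    lat = np.pi / 2.0 - (np.arange(h) + 0.5) * dlat  # pixel-center latitude
    s_u = (radius_um * np.cos(lat) * dlon)[:, None] * np.ones((1, w))
    s_v = np.full((h, w), radius_um * dlat)
    # clamp the vanishing polar rows to keep the metric strictly positive
    s_u = np.maximum(s_u, 1e-12)
    return MetricField(s_u, s_v, {"kind": "sphere", "radius_um": float(radius_um)})


def prolate_metric(a_um: float, c_um: float, raster_shape: tuple[int, int]) -> MetricField:
    """Equirectangular-style metric of a prolate spheroid.

    Parameterized by longitude and reduced latitude β:
    ``x = a cosβ cosλ, y = a cosβ sinλ, z = c sinβ`` with equatorial radius
    ``a`` and polar semi-axis ``c ≥ a``.  The circumferential scale is
    ``a·cosβ·Δλ``; the meridional scale ``√(a² sin²β + c² cos²β)·Δβ`` (the
    general closed form; no numerical integration is needed per pixel, but
    the total surface area used for coverage fractions is integrated
    numerically).
    """
    if a_um <= 0 or c_um <= 0:
        raise ValueError("semi-axes must be positive")
    h, w = raster_shape
    dlam = 2.0 * np.pi / w
    dbeta = np.pi / h
    beta = np.pi / 2.0 - (np.arange(h) + 0.5) * dbeta
    s_u = (a_um * np.cos(beta) * dlam)[:, None] * np.ones((1, w))
    s_v = (np.sqrt(a_um**2 * np.sin(beta) ** 2 + c_um**2 * np.cos(beta) ** 2) * dbeta)[
        :, None
    ] * np.ones((1, w))
    s_u = np.maximum(s_u, 1e-12)
    area, _ = quad(
        lambda b: 2 * np.pi * a_um * np.cos(b) * np.sqrt(a_um**2 * np.sin(b) ** 2 + c_um**2 * np.cos(b) ** 2),
        -np.pi / 2,
        np.pi / 2,
    )
    return MetricField(
        s_u,
        s_v,
        {"kind": "prolate", "a_um": float(a_um), "c_um": float(c_um), "surface_area_um2": float(area)},
    )


def _as_vertices_px(polygon) -> np.ndarray:
    """Accept a CellPolygon (duck-typed) or an (N, 2) array of (x, y) px."""
    if hasattr(polygon, "vertices_px"):
        return np.asarray(polygon.vertices_px, dtype=float)
    return np.asarray(polygon, dtype=float)


def _pixel_coverage(verts_px: np.ndarray, shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Exact per-pixel coverage fractions of a polygon on the pixel grid.

    Returns (rows, cols, fraction) for every pixel the polygon overlaps.
    Interior pixels get fraction 1; boundary pixels are clipped exactly
    with shapely.
    """
    poly = shapely.Polygon(verts_px)
    if not poly.is_valid:
        poly = shapely.make_valid(poly)
    h, w = shape
    xmin, ymin, xmax, ymax = poly.bounds
    c0, c1 = max(int(np.floor(xmin)), 0), min(int(np.ceil(xmax)), w)
    r0, r1 = max(int(np.floor(ymin)), 0), min(int(np.ceil(ymax)), h)
    if c1 <= c0 or r1 <= r0:
        raise ValueError("polygon lies outside the metric domain")
    cols, rows = np.meshgrid(np.arange(c0, c1), np.arange(r0, r1))
    cols, rows = cols.ravel(), rows.ravel()
    boxes = shapely.box(cols, rows, cols + 1.0, rows + 1.0)
    frac = shapely.area(shapely.intersection(boxes, poly))
    keep = frac > 0
    return rows[keep], cols[keep], frac[keep]


def polygon_area_perimeter(verts_px: np.ndarray, metric: MetricField) -> tuple[float, float]:
    """Metric-corrected area (µm²) and perimeter (µm) of a polygon in px coords."""
    verts = np.asarray(verts_px, dtype=float)
    if verts.shape[0] < 3:
        raise ValueError("polygon needs at least 3 vertices")
    rows, cols, frac = _pixel_coverage(verts, metric.shape)
    area = float(np.sum(frac * metric.s_u[rows, cols] * metric.s_v[rows, cols]))
    closed = np.vstack([verts, verts[:1]])
    perim = polyline_length(closed, metric)
    return area, perim


def polyline_length(points_px: np.ndarray, metric: MetricField, max_seg_px: float = 1.0) -> float:
    """Metric-corrected length of a polyline given in map pixel coordinates.

    Segments longer than ``max_seg_px`` are subdivided so that the local
    metric is sampled densely enough.
    """
    pts = np.asarray(points_px, dtype=float)
    if pts.shape[0] < 2:
        raise ValueError("polyline needs at least 2 points")
    deltas = np.diff(pts, axis=0)
    seg_len = np.hypot(deltas[:, 0], deltas[:, 1])
    total = 0.0
    for (x0, y0), (dx, dy), L in zip(pts[:-1], deltas, seg_len):
        if L == 0:
            continue
        n = max(int(np.ceil(L / max_seg_px)), 1)
        t = (np.arange(n) + 0.5) / n
        mx, my = x0 + t * dx, y0 + t * dy
        su, sv = metric.sample(mx, my)
        total += float(np.sum(np.hypot(dx / n * su, dy / n * sv)))
    return total


def corrected_measures(polygon, metric: MetricField) -> tuple[float, float]:
    """Distortion-corrected (area_um2, perimeter_um) of a cell polygon.

    ``polygon`` is a :class:`~epifluid.rasters.CellPolygon` or an (N, 2)
    array of (x, y) vertices in map pixel coordinates.
    """
    return polygon_area_perimeter(_as_vertices_px(polygon), metric)


def masked_area(mask: np.ndarray, metric: MetricField) -> float:
    """Corrected area (µm²) of a boolean map mask."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != metric.shape:
        raise ValueError("mask shape does not match metric")
    return float(metric.pixel_area_um2[mask].sum())


def tissue_area_series(
    masks: Sequence[np.ndarray], metric: MetricField, reference_frame: int = 0
):
    """Per-frame corrected tissue area, surface coverage and normalized area.

    Returns a pandas DataFrame with columns ``frame, area_um2,
    fraction_of_surface, normalized_to_reference``; the normalized series is
    exactly 1.0 at ``reference_frame``.
    """
    import pandas as pd

    total = metric.geometry.get("surface_area_um2", metric.total_area_um2)
    areas = []
    for i, m in enumerate(masks):
        a = masked_area(m, metric)
        if a == 0:
            warnings.warn(f"frame {i}: empty tissue mask", stacklevel=2)
        areas.append(a)
    areas = np.asarray(areas)
    ref = areas[reference_frame]
    if ref == 0:
        raise ValueError("reference frame has zero tissue area")
    return pd.DataFrame(
        {
            "frame": np.arange(len(areas)),
            "area_um2": areas,
            "fraction_of_surface": areas / total,
            "normalized_to_reference": areas / ref,
        }
    )


def write_metric(metric: MetricField, path) -> None:
    """Serialize a metric as a 2-plane float TIFF plus a JSON geometry sidecar."""
    import tifffile

    path = str(path)
    tifffile.imwrite(path, np.stack([metric.s_u, metric.s_v]).astype(np.float64))
    with open(path + ".json", "w") as fh:
        json.dump(metric.geometry, fh, indent=2)


def read_metric(path) -> MetricField:
    import tifffile

    path = str(path)
    planes = tifffile.imread(path)
    try:
        with open(path + ".json") as fh:
            geometry = json.load(fh)
    except FileNotFoundError:
        geometry = {}
    return MetricField(planes[0], planes[1], geometry)
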