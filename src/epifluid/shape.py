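"""Per-cell morphometrics: area, perimeter, shape index and elongation.

The shape index ``p = P/sqrt(A)`` is the dimensionless, scale-invariant
cell-shape measure used to place epithelial cells on the solid (jammed)
versus fluid (unjammed) axis: compact hexagonal cells sit near 3.72, and
the isoperimetric inequality bounds p below by ``2*sqrt(pi) ≈ 3.545``
(a disk).  Elongation is the log-aspect of the cell's area-normalized
second-moment (gyration) tensor, a rotation-invariant anisotropy measure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from epifluid.cartography import MetricField, polygon_area_perimeter
from epifluid.rasters import CellPolygon

__all__ = ["CellMetrics", "shape_index", "cell_elongation", "metrics_table", "P_MIN"]

#: isoperimetric lower bound of the shape index (attained by a disk)
P_MIN = 2.0 * math.sqrt(math.pi)


@dataclass(frozen=True)
class CellMetrics:
    cell_id: int
    frame_index: int
    area_A_um2: float
    perimeter_P_um: float
    shape_index_p: float
    elongation_magnitude: float
    elongation_orientation_rad: float


def shape_index(area_A: float, perimeter_P: float) -> float:
    """Shape index ``p = P / sqrt(A)``.

    Dimensionless and invariant under uniform scaling
    (``p(k²A, kP) = p(A, P)``).
    """
    if area_A <= 0 or perimeter_P <= 0:
        raise ValueError("area and perimeter must be positive")
    return perimeter_P / math.sqrt(area_A)


def _polygon_gyration_tensor(verts: np.ndarray) -> np.ndarray:
    """Area-normalized second central moment tensor of a polygon's interior.

    Closed-form shoelace second moments about the area centroid; independent
    of vertex density along the boundary (unlike vertex-cloud moments).
    """
    x, y = verts[:, 0], verts[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    a = cross.sum() / 2.0
    if a == 0:
        raise ValueError("degenerate (zero-area) polygon")
    cx = ((x + xn) * cross).sum() / (6.0 * a)
    cy = ((y + yn) * cross).sum() / (6.0 * a)
    xs, ys = x - cx, y - cy
    xsn, ysn = np.roll(xs, -1), np.roll(ys, -1)
    cr = xs * ysn - xsn * ys
    ixx = (cr * (ys * ys + ys * ysn + ysn * ysn)).sum() / 12.0
    iyy = (cr * (xs * xs + xs * xsn + xsn * xsn)).sum() / 12.0
    ixy = (cr * (xs * ysn + 2 * xs * ys + 2 * xsn * ysn + xsn * ys)).sum() / 24.0
    # signed a cancels the orientation sign carried by cr
    return np.array([[iyy, ixy], [ixy, ixx]]) / a  # [[<x²>, <xy>], [<xy>, <y²>]]


def cell_elongation(polygon) -> tuple[float, float]:
    """Elongation (magnitude, orientation) of a cell outline.

    magnitude = ``(1/2)·ln(λ1/λ2)`` of the gyration-tensor eigenvalues
    (λ1 ≥ λ2); orientation = principal-axis angle in [0, π).  Zero for any
    shape with ≥ 3-fold symmetry; a rectangle with aspect k gives ln(k)...
    precisely magnitude ``ln(k)`` since eigenvalues scale with k².
    """
    verts = polygon.vertices if isinstance(polygon, CellPolygon) else np.asarray(polygon, float)
    t = _polygon_gyration_tensor(verts)
    evals, evecs = np.linalg.eigh(t)
    l2, l1 = float(evals[0]), float(evals[1])
    if l1 <= 0 or l2 <= 0:
        raise ValueError("degenerate polygon: non-positive gyration eigenvalues")
    mag = 0.5 * math.log(l1 / l2)
    vx, vy = evecs[0, 1], evecs[1, 1]
    theta = math.atan2(vy, vx) % math.pi
    if mag < 1e-12:
        theta = 0.0
    return mag, theta


def metrics_table(
    polygons: Sequence[CellPolygon],
    metric: Optional[MetricField] = None,
    include_border: bool = False,
) -> pd.DataFrame:
    """Morphometrics table for a set of cell polygons.

    Area and perimeter are distortion-corrected when a metric is supplied,
    flat-map Euclidean otherwise.  Cells cut by the map border are excluded
    unless ``include_border``; rows sorted by (frame, cell_id).
    """
    rows = []
    for poly in polygons:
        if poly.touches_border and not include_border:
            continue
        if metric is not None:
            A, P = polygon_area_perimeter(poly.vertices_px, metric)
        else:
            A, P = poly.area_um2, poly.perimeter_um
        mag, theta = cell_elongation(poly)
        rows.append(
            {
                "cell_id": poly.cell_id,
                "frame": poly.frame_index,
                "A_um2": A,
                "P_um": P,
                "p": shape_index(A, P),
                "elong_mag": mag,
                "elong_theta": theta,
            }
        )
    df = pd.DataFrame(
        rows, columns=["cell_id", "frame", "A_um2", "P_um", "p", "elong_mag", "elong_theta"]
    )
    return df.sort_values(["frame", "cell_id"], ignore_index=True)
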