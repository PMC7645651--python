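"""Solid/fluid tissue-state mapping from cell shape and local alignment.

Cells in a confluent epithelium jam (solid-like, no rearrangement) or
unjam (fluid-like, neighbor exchanges possible).  Vertex-model theory puts
the isotropic transition at shape index ``p = 3.81``; under anisotropic
tension the threshold shifts upward with the local cell-shape alignment
``Q`` as ``p_adj = p0 + 4·b·Q²`` (``p0 = 3.94``, ``b = 0.43``).  ``Q`` is
measured from the elongation ``q`` of triangles connecting adjacent cell
centers: per-cell, ``Q`` is the area-weighted average of ``q`` over the
incident triangles.  Tissue fluidity is ``f = p − p_adj``: positive means
fluid-like, negative solid-like.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np
import pandas as pd

from epifluid.rasters import AdjacencyGraph

log = logging.getLogger(__name__)

__all__ = [
    "FluidityConfig",
    "CenterMesh",
    "FluidityRecord",
    "build_center_mesh",
    "triangle_q",
    "cell_alignment_Q",
    "adjusted_threshold",
    "fluidity",
    "fluidity_map",
]


@dataclass(frozen=True)
class FluidityConfig:
    """Constants and options of the solid/fluid classification.

    ``p0`` and ``b`` parameterize the anisotropy-adjusted threshold
    ``p_adj = p0 + 4·b·Q²``; ``isotropic_threshold`` is the classical
    alignment-free critical shape index.  ``transition_band_epsilon`` is the
    half-width of the near-transition band reported as class
    ``"transition"``.
    """

    p0: float = 3.94
    b: float = 0.43
    isotropic_threshold: float = 3.81
    mode: Literal["adjusted", "isotropic"] = "adjusted"
    q_average: Literal["scalar", "tensor"] = "scalar"
    transition_band_epsilon: float = 0.02


@dataclass
class CenterMesh:
    """Triangulation of adjacent-cell centroids.

    ``triangles`` is an (T, 3) int array of cell-id triples; per triangle,
    elongation magnitude ``q``, flat-map ``area_um2`` and principal-axis
    ``orientation_rad`` are stored.
    """

    triangles: np.ndarray
    q: np.ndarray
    area_um2: np.ndarray
    orientation_rad: np.ndarray
    frame_index: int = 0
    _incidence: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        if len(self._incidence) == 0:
            inc: dict[int, list[int]] = {}
            for i, tri in enumerate(self.triangles):
                for c in tri:
                    inc.setdefault(int(c), []).append(i)
            self._incidence = inc

    @property
    def n_triangles(self) -> int:
        return int(len(self.triangles))

    def incident(self, cell_id: int) -> list[int]:
        """Indices of triangles having ``cell_id`` as a vertex."""
        return self._incidence.get(int(cell_id), [])


@dataclass(frozen=True)
class FluidityRecord:
    cell_id: int
    frame_index: int
    Q: float
    p_adj: float
    fluidity_f: float
    tissue_class: Literal["solid", "fluid", "transition"]


# reference equilateral triangle with unit area, fixed (counter-clockwise)
# vertex order, centroid at the origin
_REF_SIDE = math.sqrt(4.0 / math.sqrt(3.0))
_REF_TRI = _REF_SIDE * np.array(
    [
        [-0.5, -math.sqrt(3.0) / 6.0],
        [0.5, -math.sqrt(3.0) / 6.0],
        [0.0, math.sqrt(3.0) / 3.0],
    ]
)


def triangle_q(vertices) -> tuple[float, float]:
    """Elongation of a triangle relative to the equilateral reference.

    Let S be the 2×2 linear map sending the unit-area reference equilateral
    triangle to the observed one (both centered on their centroids).  With
    singular values σ1 ≥ σ2 of S, ``q = (1/2)·ln(σ1/σ2)`` and the
    orientation is the principal-stretch axis angle in [0, π).  q is
    invariant to rotation, translation, uniform scaling and vertex order,
    and zero iff the triangle is equilateral.
    """
    obs = np.asarray(vertices, dtype=float)
    if obs.shape != (3, 2):
        raise ValueError("triangle_q expects three (x, y) vertices")
    obs = obs - obs.mean(axis=0)
    u, v = obs[1] - obs[0], obs[2] - obs[0]
    area2 = abs(u[0] * v[1] - u[1] * v[0])
    if area2 < 1e-12 * max(1.0, np.abs(obs).max() ** 2):
        raise ValueError("degenerate (collinear) triangle")
    # S solves  obs.T = S @ ref.T  (exact: both sides rank 2)
    ref = _REF_TRI
    a = ref.T @ ref  # 2x2, invertible
    s = obs.T @ ref @ np.linalg.inv(a)
    # closed-form, cancellation-free 2x2 singular values:
    # σ1 = Q1 + Q2, σ2 = |Q1 − Q2| with Q1, Q2 built from rotations of S
    e = (s[0, 0] + s[1, 1]) / 2.0
    f = (s[0, 0] - s[1, 1]) / 2.0
    g = (s[1, 0] + s[0, 1]) / 2.0
    hh = (s[1, 0] - s[0, 1]) / 2.0
    q1 = math.hypot(e, hh)
    q2 = math.hypot(f, g)
    sig1 = q1 + q2
    sig2 = abs(q1 - q2)
    if sig2 == 0:
        raise ValueError("degenerate (collinear) triangle")
    q = 0.5 * math.log(sig1 / sig2)
    # principal stretch axis = leading left-singular vector of S:
    # eigenvector of S S^T for its larger eigenvalue
    mm = s @ s.T
    l1 = sig1 * sig1
    vx = mm[0, 1]
    vy = l1 - mm[0, 0]
    if abs(vx) < 1e-15 and abs(vy) < 1e-15:
        theta = 0.0
    else:
        theta = math.atan2(vy, vx) % math.pi
    if q < 1e-12:
        theta = 0.0
    return q, theta


def build_center_mesh(
    adjacency: AdjacencyGraph, centroids: dict[int, tuple[float, float]]
) -> CenterMesh:
    """Triangular mesh connecting centers of adjacent cells.

    Every tri-cellular junction (a 3-clique of the adjacency graph not
    contained in a larger clique) becomes one triangle; where k ≥ 4 cells
    meet (a k-clique), a deterministic fan of k−2 triangles is emitted with
    the apex at the lowest cell id and the remaining cells ordered by angle
    around it.  Cells without centroids are ignored with a warning.
    """
    import networkx as nx

    g = adjacency.graph
    missing = [n for n in g.nodes if n not in centroids]
    if missing:
        log.warning("center mesh: %d cells lack centroids, dropped", len(missing))
        g = g.subgraph([n for n in g.nodes if n in centroids])
    tris: set[tuple[int, int, int]] = set()
    if g.number_of_nodes() < 3:
        log.warning("center mesh: fewer than 3 cells, empty mesh")
    else:
        for clique in nx.find_cliques(g):
            if len(clique) < 3:
                continue
            if len(clique) == 3:
                tris.add(tuple(sorted(clique)))
            else:
                apex = min(clique)
                rest = [c for c in clique if c != apex]
                ax, ay = centroids[apex]
                rest.sort(key=lambda c: math.atan2(centroids[c][1] - ay, centroids[c][0] - ax))
                for u, v in zip(rest[:-1], rest[1:]):
                    tris.add(tuple(sorted((apex, u, v))))
    tri_list, qs, areas, thetas = [], [], [], []
    for tri in sorted(tris):
        pts = np.array([centroids[c] for c in tri], dtype=float)
        u, v = pts[1] - pts[0], pts[2] - pts[0]
        area = abs(u[0] * v[1] - u[1] * v[0]) / 2.0
        if area <= 0:
            continue
        try:
            q, theta = triangle_q(pts)
        except ValueError:
            continue
        tri_list.append(tri)
        qs.append(q)
        areas.append(area)
        thetas.append(theta)
    return CenterMesh(
        triangles=np.asarray(tri_list, dtype=int).reshape(-1, 3),
        q=np.asarray(qs, dtype=float),
        area_um2=np.asarray(areas, dtype=float),
        orientation_rad=np.asarray(thetas, dtype=float),
        frame_index=adjacency.frame_index,
    )


def cell_alignment_Q(
    mesh: CenterMesh, cell_id: int, config: FluidityConfig = FluidityConfig()
) -> float:
    """Cell-shape alignment index: weighted average of incident-triangle q.

    Scalar mode (default): ``Q = Σ area_i q_i / Σ area_i``.  Tensor mode:
    area-weighted average of the traceless symmetric elongation tensors
    (magnitude q_i, axis θ_i), then Q is the mean tensor's magnitude —
    always ≤ the scalar-mode Q (axes can cancel).
    """
    idx = mesh.incident(cell_id)
    if not idx:
        raise ValueError(f"cell {cell_id} is in no triangle; Q undefined")
    w = mesh.area_um2[idx]
    q = mesh.q[idx]
    if config.q_average == "scalar":
        return float(np.sum(w * q) / np.sum(w))
    th = mesh.orientation_rad[idx]
    qxx = np.sum(w * q * np.cos(2 * th)) / np.sum(w)
    qxy = np.sum(w * q * np.sin(2 * th)) / np.sum(w)
    return float(np.hypot(qxx, qxy))


def adjusted_threshold(Q: float, config: FluidityConfig = FluidityConfig()) -> float:
    """Anisotropy-adjusted solid-to-fluid threshold ``p0 + 4·b·Q²``."""
    if Q < 0:
        raise ValueError("Q must be non-negative")
    return config.p0 + 4.0 * config.b * Q * Q


def _classify(f: float, eps: float) -> str:
    if f > eps:
        return "fluid"
    if f < -eps:
        return "solid"
    return "transition"


def fluidity(
    p: float,
    Q: float,
    config: FluidityConfig = FluidityConfig(),
    cell_id: int = -1,
    frame_index: int = 0,
) -> FluidityRecord:
    """Tissue fluidity of one cell: ``f = p − p_adj(Q)``.

    In ``isotropic`` mode the threshold is the alignment-free critical value
    (3.81) regardless of Q.  Class is fluid for ``f > ε``, solid for
    ``f < −ε``, and ``transition`` inside the ±ε band.
    """
    if config.mode == "isotropic":
        thr = config.isotropic_threshold
    else:
        thr = adjusted_threshold(Q, config)
    f = p - thr
    return FluidityRecord(
        cell_id=cell_id,
        frame_index=frame_index,
        Q=Q,
        p_adj=thr,
        fluidity_f=f,
        tissue_class=_classify(f, config.transition_band_epsilon),
    )


def fluidity_table(
    metrics: pd.DataFrame, mesh: CenterMesh, config: FluidityConfig = FluidityConfig()
) -> pd.DataFrame:
    """Per-cell fluidity records for one frame's metrics table + mesh.

    Cells in no triangle (rim/isolated cells) are excluded with a count in
    the log.
    """
    rows, skipped = [], 0
    for row in metrics.itertuples(index=False):
        try:
            Q = cell_alignment_Q(mesh, int(row.cell_id), config)
        except ValueError:
            skipped += 1
            continue
        rec = fluidity(float(row.p), Q, config, cell_id=int(row.cell_id), frame_index=int(row.frame))
        rows.append(
            {
                "cell_id": rec.cell_id,
                "frame": rec.frame_index,
                "p": float(row.p),
                "Q": rec.Q,
                "p_adj": rec.p_adj,
                "fluidity": rec.fluidity_f,
                "class": rec.tissue_class,
            }
        )
    if skipped:
        log.info("fluidity table: %d cells outside the mesh skipped", skipped)
    return pd.DataFrame(rows, columns=["cell_id", "frame", "p", "Q", "p_adj", "fluidity", "class"])


def fluidity_map(
    metrics: pd.DataFrame,
    mesh: CenterMesh,
    config: FluidityConfig = FluidityConfig(),
    raster=None,
    out_map=None,
    out_scatter=None,
):
    """Fluidity table plus rendered map and Q-vs-p scatter with threshold curve.

    Returns ``(table, fig_map, fig_scatter)``; figures are None when the
    table is empty or (for the map) when no raster is given.  If ``out_map``
    / ``out_scatter`` paths are given the figures are saved and closed.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import TwoSlopeNorm

    table = fluidity_table(metrics, mesh, config)
    if table.empty:
        return table, None, None

    fig_map = None
    if raster is not None:
        fmap = np.full(raster.values.shape, np.nan)
        fvals = dict(zip(table.cell_id, table.fluidity))
        for cid, f in fvals.items():
            fmap[raster.values == cid] = f
        span = max(np.nanmax(np.abs(fmap)), 3 * config.transition_band_epsilon)
        fig_map, ax = plt.subplots(figsize=(6, 5))
        im = ax.imshow(
            fmap, cmap="PiYG_r", norm=TwoSlopeNorm(vcenter=0.0, vmin=-span, vmax=span)
        )
        fig_map.colorbar(im, ax=ax, label="fluidity  f = p − p_adj")
        ax.set_title(f"tissue fluidity (frame {mesh.frame_index})")
        ax.set_axis_off()
        if out_map:
            fig_map.savefig(out_map, dpi=150, bbox_inches="tight")
        plt.close(fig_map)

    fig_sc, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(table.Q, table.p, s=12, c=table.fluidity, cmap="PiYG_r")
    qq = np.linspace(0.0, max(float(table.Q.max()) * 1.1, 0.5), 200)
    if config.mode == "isotropic":
        ax.axhline(config.isotropic_threshold, color="tab:blue", label="p = 3.81")
    else:
        ax.plot(qq, config.p0 + 4 * config.b * qq**2, color="tab:blue", label="p = p0 + 4bQ²")
    ax.set_xlabel("cell shape alignment Q")
    ax.set_ylabel("shape index p")
    ax.legend(frameon=False)
    if out_scatter:
        fig_sc.savefig(out_scatter, dpi=150, bbox_inches="tight")
    plt.close(fig_sc)
    return table, fig_map, fig_sc
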