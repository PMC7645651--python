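"""Center mesh, triangle elongation q, alignment Q and solid/fluid mapping."""

import math

import numpy as np
import pytest

from epifluid.fluidity import (
    _REF_TRI,
    CenterMesh,
    FluidityConfig,
    adjusted_threshold,
    build_center_mesh,
    cell_alignment_Q,
    fluidity,
    fluidity_map,
    triangle_q,
)
from epifluid.rasters import build_adjacency, extract_polygons
from epifluid.shape import metrics_table


def svd_oracle_q(tri):
    """Independent brute-force oracle: least squares + numpy SVD."""
    obs = np.asarray(tri, float)
    obs = obs - obs.mean(axis=0)
    S, *_ = np.linalg.lstsq(_REF_TRI, obs, rcond=None)
    sv = np.linalg.svd(S.T, compute_uv=False)
    return 0.5 * math.log(sv[0] / sv[1])


def test_triangle_q_matches_svd_oracle():
    rng = np.random.default_rng(0)
    n_ok = 0
    while n_ok < 1000:
        tri = rng.normal(size=(3, 2)) * rng.uniform(0.5, 20)
        try:
            q, _ = triangle_q(tri)
        except ValueError:
            continue
        assert abs(q - svd_oracle_q(tri)) < 1e-10
        n_ok += 1


def test_triangle_q_equilateral_zero():
    for scale, rot in ((1.0, 0.0), (7.3, 0.9), (0.2, 2.0)):
        R = np.array([[math.cos(rot), -math.sin(rot)], [math.sin(rot), math.cos(rot)]])
        q, _ = triangle_q(_REF_TRI @ R.T * scale + [3, -5])
        assert q == pytest.approx(0.0, abs=1e-12)


def test_triangle_q_stretched_equilateral():
    for k in (1.5, 2.0, 4.0):
        tri = _REF_TRI.copy()
        tri[:, 0] *= k
        q, theta = triangle_q(tri)
        assert q == pytest.approx(math.log(k) / 2, rel=1e-12)
        assert theta == pytest.approx(0.0, abs=1e-9)


def test_triangle_q_invariances():
    rng = np.random.default_rng(3)
    tri = rng.normal(size=(3, 2))
    q0, th0 = triangle_q(tri)
    th = 0.7
    R = np.array([[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]])
    q_rot, th_rot = triangle_q(tri @ R.T * 3.7 + 11.0)
    assert q_rot == pytest.approx(q0, rel=1e-10)
    assert (th_rot - th0) % math.pi == pytest.approx(th, abs=1e-8)
    for perm in ((2, 0, 1), (1, 0, 2)):
        q_p, _ = triangle_q(tri[list(perm)])
        assert q_p == pytest.approx(q0, rel=1e-10)


def test_triangle_q_collinear_rejected():
    with pytest.raises(ValueError, match="degenerate"):
        triangle_q(np.array([[0, 0], [1, 1], [2, 2]], float))


# --- center mesh -----------------------------------------------------------


def test_hex_lattice_mesh_triangle_count(hex_raster):
    """Each tri-cellular junction of a hex lattice yields exactly one triangle.

    Interior combinatorics: T = 2·C − boundary corrections; checked per
    cell instead — every interior cell of a hexagonal lattice is in exactly
    6 triangles, and all triangles are near-equilateral (q ≈ 0).
    """
    adj = build_adjacency(hex_raster)
    polys = extract_polygons(hex_raster)
    cents = {p.cell_id: tuple(np.asarray(p.centroid_um) / p.pixel_size_um) for p in polys}
    mesh = build_center_mesh(adj, cents)
    border = {p.cell_id for p in polys if p.touches_border}
    inner = [
        c
        for c in cents
        if c not in border and not (set(adj.graph.neighbors(c)) & border)
    ]
    assert len(inner) > 30
    for c in inner:
        assert len(mesh.incident(c)) == 6
    inner_tris = [i for i, t in enumerate(mesh.triangles) if all(c in inner for c in t)]
    assert np.all(mesh.q[inner_tris] < 0.05)


def test_two_cell_tissue_empty_mesh():
    import networkx as nx

    from epifluid.rasters import AdjacencyGraph

    g = nx.Graph()
    g.add_edge(1, 2)
    mesh = build_center_mesh(AdjacencyGraph(g), {1: (0, 0), 2: (1, 0)})
    assert mesh.n_triangles == 0


def test_four_clique_fan_apex_lowest_id():
    import networkx as nx

    from epifluid.rasters import AdjacencyGraph

    g = nx.complete_graph([3, 5, 7, 9])
    cents = {3: (0.0, 0.0), 5: (1.0, 0.0), 7: (1.0, 1.0), 9: (0.0, 1.0)}
    mesh = build_center_mesh(AdjacencyGraph(g), cents)
    assert mesh.n_triangles == 2
    assert all(3 in t for t in mesh.triangles)


# --- alignment Q -----------------------------------------------------------


def test_Q_zero_when_triangles_equilateral():
    mesh = CenterMesh(
        triangles=np.array([[1, 2, 3], [1, 3, 4]]),
        q=np.zeros(2),
        area_um2=np.ones(2),
        orientation_rad=np.zeros(2),
    )
    assert cell_alignment_Q(mesh, 1) == 0.0
    assert cell_alignment_Q(mesh, 1, FluidityConfig(q_average="tensor")) == pytest.approx(0.0)


def test_Q_perpendicular_axes_cancel_in_tensor_mode():
    mesh = CenterMesh(
        triangles=np.array([[1, 2, 3], [1, 2, 4]]),
        q=np.array([0.4, 0.4]),
        area_um2=np.array([1.0, 1.0]),
        orientation_rad=np.array([0.0, math.pi / 2]),
    )
    assert cell_alignment_Q(mesh, 1) == pytest.approx(0.4)
    assert cell_alignment_Q(mesh, 1, FluidityConfig(q_average="tensor")) == pytest.approx(0.0, abs=1e-12)


def test_Q_isolated_cell_undefined():
    mesh = CenterMesh(
        triangles=np.array([[1, 2, 3]]), q=np.array([0.1]), area_um2=np.array([1.0]),
        orientation_rad=np.array([0.0]),
    )
    with pytest.raises(ValueError, match="Q undefined"):
        cell_alignment_Q(mesh, 99)


def test_uniformly_stretched_lattice_Q(hex_raster):
    """×k-stretched hexagonal lattice: scalar Q = ln(k)/2 for interior cells."""
    k = 2.0
    adj = build_adjacency(hex_raster)
    polys = extract_polygons(hex_raster)
    cents = {
        p.cell_id: (p.centroid_um[0] * k, p.centroid_um[1]) for p in polys
    }
    mesh = build_center_mesh(adj, cents)
    border = {p.cell_id for p in polys if p.touches_border}
    inner = [
        c for c in cents if c not in border and not (set(adj.graph.neighbors(c)) & border)
    ]
    Qs = [cell_alignment_Q(mesh, c) for c in inner]
    assert np.mean(Qs) == pytest.approx(math.log(k) / 2, rel=0.05)


def test_tensor_Q_never_exceeds_scalar_Q(band_tissue):
    raster, _ = band_tissue
    adj = build_adjacency(raster)
    polys = extract_polygons(raster)
    cents = {p.cell_id: tuple(np.asarray(p.centroid_um) / p.pixel_size_um) for p in polys}
    mesh = build_center_mesh(adj, cents)
    tensor_cfg = FluidityConfig(q_average="tensor")
    for c in list(cents)[::3]:
        if not mesh.incident(c):
            continue
        assert cell_alignment_Q(mesh, c, tensor_cfg) <= cell_alignment_Q(mesh, c) + 1e-12


def test_Q_invariant_under_similarity_transform(random_tissue):
    adj = build_adjacency(random_tissue)
    polys = extract_polygons(random_tissue)
    cents = {p.cell_id: np.asarray(p.centroid_um) for p in polys}
    mesh0 = build_center_mesh(adj, {c: tuple(v) for c, v in cents.items()})
    th = 0.6
    R = np.array([[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]])
    cents2 = {c: tuple(R @ v * 2.5 + np.array([40.0, -7.0])) for c, v in cents.items()}
    mesh1 = build_center_mesh(adj, cents2)
    ids = [c for c in cents if mesh0.incident(c) and mesh1.incident(c)]
    for c in ids[::5]:
        assert cell_alignment_Q(mesh1, c) == pytest.approx(cell_alignment_Q(mesh0, c), rel=1e-6)


# --- thresholds and classification ----------------------------------------


def test_adjusted_threshold_printed_constants():
    assert adjusted_threshold(0.0) == 3.94
    assert adjusted_threshold(0.3) == pytest.approx(4.0948)
    assert adjusted_threshold(0.5) > adjusted_threshold(0.4)


def test_adjusted_threshold_minimum_at_zero():
    rng = np.random.default_rng(1)
    for Q in rng.uniform(0, 1, 50):
        assert adjusted_threshold(float(Q)) >= 3.94
    with pytest.raises(ValueError):
        adjusted_threshold(-0.1)


def test_fluidity_printed_example():
    """p = 4.25 at Q = 0: f = 0.31, fluid (adjusted mode)."""
    rec = fluidity(4.25, 0.0)
    assert rec.fluidity_f == pytest.approx(0.31)
    assert rec.tissue_class == "fluid"


def test_fluidity_hexagon_is_solid_isotropic():
    rec = fluidity(3.722, 0.5, FluidityConfig(mode="isotropic"))
    assert rec.p_adj == 3.81
    assert rec.tissue_class == "solid"


def test_fluidity_boundary_is_transition():
    Q = 0.37
    rec = fluidity(adjusted_threshold(Q), Q)
    assert rec.tissue_class == "transition"
    assert rec.fluidity_f == 0.0


def test_classification_monotone_in_p():
    """At fixed Q, raising p never flips fluid → solid."""
    order = {"solid": 0, "transition": 1, "fluid": 2}
    for Q in (0.0, 0.2, 0.6):
        classes = [order[fluidity(p, Q).tissue_class] for p in np.linspace(3.6, 4.6, 60)]
        assert (np.diff(classes) >= 0).all()


def test_all_hexagonal_tissue_is_solid(hex_raster):
    polys = extract_polygons(hex_raster)
    t = metrics_table(polys)
    adj = build_adjacency(hex_raster)
    cents = {p.cell_id: tuple(np.asarray(p.centroid_um) / p.pixel_size_um) for p in polys}
    mesh = build_center_mesh(adj, cents)
    table, _, _ = fluidity_map(t, mesh)
    assert (table["class"] == "solid").all()


def test_planted_band_classification(band_tissue):
    """≥ 90% of planted-band cells fluid, ≥ 90% of relaxed bulk solid."""
    raster, in_band = band_tissue
    polys = extract_polygons(raster)
    t = metrics_table(polys)
    adj = build_adjacency(raster)
    cents = {p.cell_id: tuple(np.asarray(p.centroid_um) / p.pixel_size_um) for p in polys}
    mesh = build_center_mesh(adj, cents)
    table, _, _ = fluidity_map(t, mesh)
    cx = {p.cell_id: p.centroid_um[0] for p in polys}
    x = table.cell_id.map(cx)
    band = table[np.abs(x - 110) < 30]
    bulk = table[np.abs(x - 110) > 55]
    assert len(band) > 20 and len(bulk) > 20
    assert (band["class"] == "fluid").mean() >= 0.9
    assert (bulk["class"] == "solid").mean() >= 0.9


def test_fluidity_map_empty_table():
    mesh = CenterMesh(
        triangles=np.zeros((0, 3), int), q=np.zeros(0), area_um2=np.zeros(0),
        orientation_rad=np.zeros(0),
    )
    import pandas as pd

    table, fig_m, fig_s = fluidity_map(pd.DataFrame(columns=["cell_id", "frame", "p"]), mesh)
    assert table.empty and fig_m is None and fig_s is None
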