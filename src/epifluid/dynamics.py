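"""Time-resolved tissue behavior.

T1 neighbor exchanges (the elementary cell rearrangement of a fluidizing
epithelium), leading-edge (window-rim) cell counting with eviction events,
supracellular cable length/intensity metrics, and a nearest-centroid label
linker for untracked input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from epifluid.cartography import MetricField, polyline_length
from epifluid.rasters import AdjacencyGraph, LabelRaster, build_adjacency

log = logging.getLogger(__name__)

__all__ = [
    "T1Event",
    "RimSeries",
    "CableTrace",
    "detect_t1",
    "detect_t1_series",
    "rim_cells",
    "rim_series",
    "cable_metrics",
    "link_labels",
]


@dataclass(frozen=True)
class T1Event:
    """One neighbor exchange across frames t → t+1.

    ``lost_pair`` were adjacent at t and not at t+1; ``gained_pair`` the
    reverse, and were common neighbors of the lost pair at t.
    """

    frame_index: int
    lost_pair: tuple[int, int]
    gained_pair: tuple[int, int]


@dataclass
class RimSeries:
    """Leading-edge occupancy over a closure series."""

    rim_cell_count: list[int]
    rim_sets: list[set[int]]
    eviction_events: list[tuple[int, int]]  # (frame of rim exit start, cell id)


@dataclass
class CableTrace:
    frame_index: int
    polyline_px: np.ndarray  # (N, 2) map (x, y) in px
    length_um: float = 0.0
    total_intensity: float = 0.0
    intensity_per_length: float = 0.0


def detect_t1(adj_t: AdjacencyGraph, adj_t1: AdjacencyGraph) -> list[T1Event]:
    """T1 transitions between two adjacency graphs of tracked cells.

    A quartet (A, B | C, D) is reported when the A–B contact is lost, the
    C–D contact is gained, and C, D were common neighbors of both A and B
    before the exchange.  Cells appearing or disappearing between the two
    frames are ignored.  Events are ordered by (min lost id, max lost id).
    """
    g0, g1 = adj_t.graph, adj_t1.graph
    common = set(g0.nodes) & set(g1.nodes)
    lost = [
        (a, b)
        for a, b in g0.edges
        if a in common and b in common and not g1.has_edge(a, b)
    ]
    gained = {
        tuple(sorted((a, b)))
        for a, b in g1.edges
        if a in common and b in common and not g0.has_edge(a, b)
    }
    events = []
    for a, b in lost:
        cand = (set(g0.neighbors(a)) & set(g0.neighbors(b)) & common) - {a, b}
        for c, d in gained:
            if c in cand and d in cand and len({a, b, c, d}) == 4:
                events.append(
                    T1Event(
                        frame_index=adj_t.frame_index,
                        lost_pair=tuple(sorted((a, b))),
                        gained_pair=(c, d),
                    )
                )
    events.sort(key=lambda e: (e.lost_pair, e.gained_pair))
    return events


def detect_t1_series(
    frames: Sequence[LabelRaster], min_contact_px: int = 2
) -> list[T1Event]:
    """T1 events across a tracked label-raster series (pairwise detection)."""
    adjs = [build_adjacency(f, min_contact_px=min_contact_px) for f in frames]
    for i, (f, a) in enumerate(zip(frames, adjs)):
        a.frame_index = f.frame_index if f.frame_index else i
    events: list[T1Event] = []
    for a0, a1 in zip(adjs[:-1], adjs[1:]):
        events.extend(detect_t1(a0, a1))
    return events


def _window_component(raster: LabelRaster, window_seed: tuple[int, int]) -> Optional[np.ndarray]:
    """Boolean mask of the background component containing the seed (x, y).

    Returns None when the seed lies inside a cell (window closed).
    """
    x, y = int(round(window_seed[0])), int(round(window_seed[1]))
    v = raster.values
    if not (0 <= y < v.shape[0] and 0 <= x < v.shape[1]):
        raise ValueError("window seed outside the raster")
    if v[y, x] != 0:
        return None
    comp, _ = ndimage.label(v == 0)
    return comp == comp[y, x]


def rim_cells(raster: LabelRaster, window_seed: tuple[int, int]) -> set[int]:
    """Cells sharing ≥ 1 pixel-edge contact with the window component."""
    win = _window_component(raster, window_seed)
    if win is None:
        return set()
    grown = ndimage.binary_dilation(win, structure=[[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    v = raster.values
    return {int(l) for l in np.unique(v[grown & (v > 0)])}


def rim_series(
    frames: Sequence[LabelRaster], window_seed: tuple[int, int]
) -> RimSeries:
    """Rim-cell counts and eviction events over a closure series.

    An eviction at frame t is a cell in the rim set at t, absent from it at
    t+1, while still present in the tissue at t+1.  The window is the
    background component containing ``window_seed``; a frame whose seed
    pixel is occupied by a cell counts as closed (rim count 0).  A seed
    inside a cell already at the first frame is a configuration error.
    """
    if len(frames) == 0:
        raise ValueError("empty frame sequence")
    first = _window_component(frames[0], window_seed)
    if first is None and np.any(frames[0].values == 0):
        raise ValueError("window seed lies inside a cell at the first frame")
    sets, counts = [], []
    for fr in frames:
        s = rim_cells(fr, window_seed)
        sets.append(s)
        counts.append(len(s))
    evictions = []
    for t in range(len(frames) - 1):
        present_next = set(int(l) for l in frames[t + 1].labels)
        for cell in sorted(sets[t] - sets[t + 1]):
            if cell in present_next:
                evictions.append((t, cell))
    return RimSeries(rim_cell_count=counts, rim_sets=sets, eviction_events=evictions)


def cable_metrics(
    polyline_px: np.ndarray,
    intensity_raster: np.ndarray,
    metric: MetricField,
    half_width_px: int = 2,
) -> tuple[float, float]:
    """Metric-corrected cable length and intensity per unit length.

    Total intensity is summed over pixels within ``half_width_px`` of the
    polyline (a fixed-width band, default 2 px); the ratio
    ``total_intensity / length_um`` tracks e.g. myosin line density along a
    contractile cable.
    """
    pts = np.asarray(polyline_px, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise ValueError("cable polyline needs at least two points")
    length = polyline_length(pts, metric)
    if length <= 0:
        raise ValueError("zero-length cable polyline")
    img = np.asarray(intensity_raster, dtype=float)
    # rasterize the band: distance transform from the densified polyline
    mask = np.zeros(img.shape, dtype=bool)
    dense = _densify(pts, step=0.5)
    cc = np.clip(np.round(dense[:, 0]).astype(int), 0, img.shape[1] - 1)
    rr = np.clip(np.round(dense[:, 1]).astype(int), 0, img.shape[0] - 1)
    mask[rr, cc] = True
    dist = ndimage.distance_transform_edt(~mask)
    band = dist <= half_width_px
    total = float(img[band].sum())
    return length, total / length


def _densify(pts: np.ndarray, step: float) -> np.ndarray:
    out = [pts[:1]]
    for p0, p1 in zip(pts[:-1], pts[1:]):
        L = float(np.hypot(*(p1 - p0)))
        n = max(int(np.ceil(L / step)), 1)
        t = np.linspace(0, 1, n + 1)[1:, None]
        out.append(p0 + t * (p1 - p0))
    return np.vstack(out)


def link_labels(
    frames: Sequence[LabelRaster], max_displacement_px: float = 10.0
) -> list[LabelRaster]:
    """Track cells across frames by greedy nearest-centroid matching.

    Frame 0 keeps its labels; in each subsequent frame, cells are matched
    to the previous frame's cells by centroid distance (closest pairs
    first) within ``max_displacement_px``; unmatched cells receive fresh
    ids.  Deterministic; synthetic data is already tracked and skips this.
    """
    if not frames:
        return []
    out = [frames[0]]
    next_id = int(frames[0].values.max()) + 1
    for fr in frames[1:]:
        prev = out[-1]
        pc = prev.centroids_px()
        cc = fr.centroids_px()
        mapping: dict[int, int] = {}
        if pc and cc:
            prev_ids = sorted(pc)
            cur_ids = sorted(cc)
            tree = cKDTree([pc[i] for i in prev_ids])
            cand = []
            for ci in cur_ids:
                dists, idxs = tree.query(cc[ci], k=min(3, len(prev_ids)))
                for d, j in zip(np.atleast_1d(dists), np.atleast_1d(idxs)):
                    if d <= max_displacement_px:
                        cand.append((float(d), ci, prev_ids[int(j)]))
            cand.sort()
            used_prev: set[int] = set()
            for d, ci, pi in cand:
                if ci in mapping or pi in used_prev:
                    continue
                mapping[ci] = pi
                used_prev.add(pi)
        unmatched = [ci for ci in cc if ci not in mapping]
        if len(unmatched) > max(3, len(cc) // 4):
            log.warning("link_labels: %d of %d cells unmatched", len(unmatched), len(cc))
        for ci in sorted(unmatched):
            mapping[ci] = next_id
            next_id += 1
        lut = np.zeros(int(fr.values.max()) + 1, dtype=np.int32)
        for old, new in mapping.items():
            lut[old] = new
        out.append(
            LabelRaster(
                lut[fr.values],
                pixel_size_um=fr.pixel_size_um,
                frame_index=fr.frame_index,
                metric=fr.metric,
            )
        )
    return out
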