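"""Synthetic epithelium and recoil-trace generator with known ground truth.

Tissues are Voronoi tessellations of seeded random points on a pixel grid.
The generator exposes the statistical knobs the downstream analysis is
sensitive to:

* **Lloyd relaxation** moves the packing toward hexagonal order and is a
  clean monotone handle on the mean shape index (relaxed ≈ dorsal,
  unrelaxed ≈ ventral packing).
* **Anisotropic stretch** (a position-dependent 2×2 map) elongates cells
  and their center-triangles coherently, raising both p and the alignment
  Q — as in the radially stretched cells around a closing window.
* **Boundary wiggle** (smooth-noise perturbation of cell interfaces)
  raises the perimeter, hence p, *without* moving cell centers — the
  signature of fluid-like irregular cells; this is how a fluid region is
  planted without tripping the anisotropy-adjusted threshold.
* A **closing window** (shrinking background disk) with planted T1
  neighbor exchanges and rim-cell evictions provides exact ground truth
  for the dynamics detectors.  Seeds are rejected from the initial window
  disk, which makes rim sets nested over nested windows and rim counts
  monotone non-increasing by construction.

Recoil traces are sampled from ``d(t) = D·(t − t0)^α`` plus Gaussian noise,
split symmetrically over the two severed edges.

Everything is deterministic given the parameter set (one seeded generator
per call).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from epifluid.rasters import LabelRaster
from epifluid.recoil import RecoilTrace

log = logging.getLogger(__name__)

__all__ = [
    "SyntheticTissueParams",
    "RecoilSimParams",
    "generate_tissue",
    "generate_window_series",
    "generate_recoil_trace",
    "hexagonal_tissue",
    "suggest_t1_quartets",
    "suggest_evictions",
    "write_series",
]

StretchField = Union[None, np.ndarray, Callable]
AmpField = Union[float, Callable]


@dataclass
class SyntheticTissueParams:
    """Parameters of a synthetic tracked tissue.

    ``stretch_field`` maps map position (x, y) to a 2×2 stretch tensor
    (identity default); it may be a constant 2×2 array, a vectorized
    callable returning (..., 2, 2), or a per-position scalar callable.
    ``wiggle_amp`` (px) perturbs cell interfaces with smooth noise of
    correlation length ``wiggle_scale`` px.  ``planted_t1_events`` are
    ``(frame, (a, b, c, d))`` quartets — the a–b contact is lost, c–d
    gained, across frame → frame+1; ``planted_evictions`` are
    ``(frame, cell_id)`` rim exits.
    """

    n_cells: int
    domain_size: tuple[int, int]  # (width_px, height_px)
    pixel_size_um: float = 1.0
    lloyd_iterations: int = 0
    stretch_field: StretchField = None
    wiggle_amp: AmpField = 0.0
    wiggle_scale: float = 6.0
    window_center: Optional[tuple[float, float]] = None  # (x, y) px
    window_radius_schedule: Optional[Sequence[float]] = None
    planted_t1_events: Sequence[tuple[int, tuple[int, int, int, int]]] = field(
        default_factory=list
    )
    planted_evictions: Sequence[tuple[int, int]] = field(default_factory=list)
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_cells < 3:
            raise ValueError("need at least 3 cells")
        w, h = self.domain_size
        if w < 4 or h < 4:
            raise ValueError("domain too small")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.lloyd_iterations < 0:
            raise ValueError("lloyd_iterations must be non-negative")
        if self.window_radius_schedule is not None:
            sched = list(self.window_radius_schedule)
            if any(r < 0 for r in sched):
                raise ValueError("window radii must be non-negative")
            if any(b > a for a, b in zip(sched[:-1], sched[1:])):
                raise ValueError("window radius schedule must be monotone non-increasing")
            if self.window_center is None:
                raise ValueError("window schedule given without window_center")
            cx, cy = self.window_center
            r0 = sched[0]
            if cx - r0 < 0 or cy - r0 < 0 or cx + r0 > w or cy + r0 > h:
                raise ValueError("window larger than (or not contained in) the domain")


@dataclass
class RecoilSimParams:
    """Power-law recoil simulation: d(t) = D·(t − t0)^α + noise."""

    D: float
    alpha: float
    t0: float = 0.0
    dt: float = 0.5
    duration: float = 10.0
    noise_sd: float = 0.0
    n_tracks: int = 1
    rng_seed: int = 0

    def __post_init__(self):
        if self.D <= 0:
            raise ValueError("D must be positive")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.duration < self.dt:
            raise ValueError("duration must cover at least one sample")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.n_tracks < 1:
            raise ValueError("n_tracks must be ≥ 1")


# ---------------------------------------------------------------------------
# tessellation core


def _pixel_centers(shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    h, w = shape
    ys, xs = np.mgrid[0:h, 0:w]
    return xs + 0.5, ys + 0.5


def _draw_seeds(params: SyntheticTissueParams, rng: np.random.Generator) -> np.ndarray:
    w, h = params.domain_size
    margin = 1.0
    seeds = np.column_stack(
        [rng.uniform(margin, w - margin, params.n_cells), rng.uniform(margin, h - margin, params.n_cells)]
    )
    if params.window_center is not None and params.window_radius_schedule:
        cx, cy = params.window_center
        r_excl = params.window_radius_schedule[0] + 2.0
        for _ in range(200):
            inside = np.hypot(seeds[:, 0] - cx, seeds[:, 1] - cy) < r_excl
            if not inside.any():
                break
            seeds[inside] = np.column_stack(
                [rng.uniform(margin, w - margin, inside.sum()), rng.uniform(margin, h - margin, inside.sum())]
            )
        else:
            raise ValueError("could not place seeds outside the window disk")
    return seeds


def _lloyd(
    seeds: np.ndarray,
    shape: tuple[int, int],
    iterations: int,
    rng: np.random.Generator,
    exclude: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Lloyd relaxation on the pixel grid (Euclidean assignment)."""
    px, py = _pixel_centers(shape)
    pts = np.column_stack([px.ravel(), py.ravel()])
    keep = np.ones(len(pts), dtype=bool) if exclude is None else ~exclude.ravel()
    pts = pts[keep]
    n = len(seeds)
    for _ in range(iterations):
        _, idx = cKDTree(seeds).query(pts)
        counts = np.bincount(idx, minlength=n)
        sx = np.bincount(idx, weights=pts[:, 0], minlength=n)
        sy = np.bincount(idx, weights=pts[:, 1], minlength=n)
        empty = counts == 0
        if empty.any():
            log.warning("lloyd: %d empty regions kept in place", int(empty.sum()))
        counts = np.maximum(counts, 1)
        new = np.column_stack([sx / counts, sy / counts])
        new[empty] = seeds[empty]
        seeds = new
        # re-jitter exact overlaps (degenerate after relaxation)
        d, j = cKDTree(seeds).query(seeds, k=2)
        clash = d[:, 1] < 1e-6
        if clash.any():
            log.warning("lloyd: re-jittering %d overlapping seeds", int(clash.sum()))
            seeds[clash] += rng.uniform(-0.5, 0.5, (int(clash.sum()), 2))
    return seeds


def _stretch_inverse_grid(
    stretch_field: StretchField, shape: tuple[int, int]
) -> Optional[np.ndarray]:
    """Per-pixel inverse stretch tensors, or None for identity."""
    if stretch_field is None:
        return None
    px, py = _pixel_centers(shape)
    if isinstance(stretch_field, np.ndarray):
        s = np.broadcast_to(stretch_field, shape + (2, 2)).copy()
    else:
        try:
            s = np.asarray(stretch_field(px, py), dtype=float)
            if s.shape == (2, 2):
                s = np.broadcast_to(s, shape + (2, 2)).copy()
            elif s.shape != shape + (2, 2):
                raise ValueError
        except (ValueError, TypeError):
            s = np.empty(shape + (2, 2))
            for r in range(shape[0]):
                for c in range(shape[1]):
                    s[r, c] = stretch_field(c + 0.5, r + 0.5)
    det = s[..., 0, 0] * s[..., 1, 1] - s[..., 0, 1] * s[..., 1, 0]
    if np.any(np.abs(det) < 1e-12):
        raise ValueError("stretch field is singular somewhere")
    inv = np.empty_like(s)
    inv[..., 0, 0] = s[..., 1, 1] / det
    inv[..., 1, 1] = s[..., 0, 0] / det
    inv[..., 0, 1] = -s[..., 0, 1] / det
    inv[..., 1, 0] = -s[..., 1, 0] / det
    return inv


def _assign(
    seeds: np.ndarray,
    shape: tuple[int, int],
    inv_stretch: Optional[np.ndarray],
    wiggle_amp: AmpField,
    wiggle_scale: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Label each pixel by its (metric-)nearest seed, with boundary wiggle."""
    px, py = _pixel_centers(shape)
    best1 = np.full(shape, np.inf)
    best2 = np.full(shape, np.inf)
    lab1 = np.zeros(shape, dtype=np.int32)
    lab2 = np.zeros(shape, dtype=np.int32)
    for i, (sx, sy) in enumerate(seeds, start=1):
        dx, dy = px - sx, py - sy
        if inv_stretch is not None:
            ux = inv_stretch[..., 0, 0] * dx + inv_stretch[..., 0, 1] * dy
            uy = inv_stretch[..., 1, 0] * dx + inv_stretch[..., 1, 1] * dy
            d = ux * ux + uy * uy
        else:
            d = dx * dx + dy * dy
        m1 = d < best1
        m2 = ~m1 & (d < best2)
        best2 = np.where(m1, best1, np.where(m2, d, best2))
        lab2 = np.where(m1, lab1, np.where(m2, i, lab2))
        best1 = np.where(m1, d, best1)
        lab1 = np.where(m1, i, lab1)

    amp = wiggle_amp(px, py) if callable(wiggle_amp) else wiggle_amp
    if np.any(np.asarray(amp) > 0):
        # smooth random warp: wiggles cell interfaces coherently (raising
        # perimeter, hence p) while leaving cell centers nearly in place
        ux = ndimage.gaussian_filter(rng.standard_normal(shape), wiggle_scale)
        uy = ndimage.gaussian_filter(rng.standard_normal(shape), wiggle_scale)
        ux *= amp / max(ux.std(), 1e-12)
        uy *= amp / max(uy.std(), 1e-12)
        h, w = shape
        rr = np.clip(py - 0.5 + uy, 0, h - 1)
        cc = np.clip(px - 0.5 + ux, 0, w - 1)
        lab1 = ndimage.map_coordinates(lab1, [rr, cc], order=0, mode="nearest")
    return lab1


def _tessellate(params: SyntheticTissueParams) -> tuple[np.ndarray, np.ndarray]:
    """(base label raster without window, relaxed seed positions)."""
    rng = np.random.default_rng(params.rng_seed)
    w, h = params.domain_size
    shape = (h, w)
    seeds = _draw_seeds(params, rng)
    exclude = None
    if params.window_center is not None and params.window_radius_schedule:
        exclude = _disk_mask(shape, params.window_center, params.window_radius_schedule[0])
    seeds = _lloyd(seeds, shape, params.lloyd_iterations, rng, exclude=exclude)
    if exclude is not None:
        # keep relaxed seeds outside the initial window so every region
        # crosses the window rim from outside (nested rim sets)
        cx, cy = params.window_center
        r0 = params.window_radius_schedule[0]
        d = np.hypot(seeds[:, 0] - cx, seeds[:, 1] - cy)
        inside = d < r0 + 1.0
        if inside.any():
            scale = (r0 + 2.0) / np.maximum(d[inside], 1e-9)
            seeds[inside, 0] = cx + (seeds[inside, 0] - cx) * scale
            seeds[inside, 1] = cy + (seeds[inside, 1] - cy) * scale
    inv = _stretch_inverse_grid(params.stretch_field, shape)
    labels = _assign(seeds, shape, inv, params.wiggle_amp, params.wiggle_scale, rng)
    return labels, seeds


def _disk_mask(shape: tuple[int, int], center: tuple[float, float], radius: float) -> np.ndarray:
    if radius <= 0:
        return np.zeros(shape, dtype=bool)
    px, py = _pixel_centers(shape)
    return np.hypot(px - center[0], py - center[1]) <= radius


def generate_tissue(params: SyntheticTissueParams) -> LabelRaster:
    """Single-frame synthetic tissue (window disk of the first scheduled radius, if any)."""
    labels, _ = _tessellate(params)
    values = labels.copy()
    if params.window_center is not None and params.window_radius_schedule:
        values[_disk_mask(values.shape, params.window_center, params.window_radius_schedule[0])] = 0
    return LabelRaster(values, pixel_size_um=params.pixel_size_um, frame_index=0)


# ---------------------------------------------------------------------------
# planted events


def _contact_px(v: np.ndarray, a: int, b: int) -> int:
    m = 0
    for sl_a, sl_b in (((np.s_[:, :-1]), (np.s_[:, 1:])), ((np.s_[:-1, :]), (np.s_[1:, :]))):
        m += int(np.sum((v[sl_a] == a) & (v[sl_b] == b)))
        m += int(np.sum((v[sl_a] == b) & (v[sl_b] == a)))
    return m


def _t1_edit(v: np.ndarray, quartet: tuple[int, int, int, int], frame: int) -> np.ndarray:
    """Relabel the a–b contact strip to c/d, flipping the junction quartet.

    Returns the edited raster.  Validates the pre-state: a–b adjacent, c and
    d common neighbors of a and b, c–d not adjacent.
    """
    a, b, c, d = quartet
    for cid in quartet:
        if not np.any(v == cid):
            raise ValueError(f"planted T1 at frame {frame}: cell {cid} not present")
    if len(set(quartet)) != 4:
        raise ValueError(f"planted T1 at frame {frame}: quartet ids must be distinct")
    if _contact_px(v, a, b) == 0:
        raise ValueError(f"planted T1 at frame {frame}: cells {a},{b} are not adjacent")
    for x in (c, d):
        if _contact_px(v, a, x) == 0 or _contact_px(v, b, x) == 0:
            raise ValueError(
                f"planted T1 at frame {frame}: cell {x} is not a common neighbor of {a},{b}"
            )
    if _contact_px(v, c, d) > 0:
        raise ValueError(f"planted T1 at frame {frame}: cells {c},{d} already adjacent")
    out = v.copy()
    dist_to_b = ndimage.distance_transform_edt(v != b)
    dist_to_a = ndimage.distance_transform_edt(v != a)
    strip = ((v == a) & (dist_to_b <= 2.0)) | ((v == b) & (dist_to_a <= 2.0))
    dist_to_c = ndimage.distance_transform_edt(v != c)
    dist_to_d = ndimage.distance_transform_edt(v != d)
    out[strip] = np.where(dist_to_c[strip] <= dist_to_d[strip], c, d)
    if _contact_px(out, a, b) > 0 or _contact_px(out, c, d) == 0:
        raise ValueError(
            f"planted T1 at frame {frame}: quartet {quartet} could not be flipped cleanly"
        )
    return out


def _eviction_edit(v: np.ndarray, cell: int, window: np.ndarray, frame: int) -> np.ndarray:
    """Relabel the window-facing pixels of ``cell`` to its nearest neighbors."""
    if not np.any(v == cell):
        raise ValueError(f"planted eviction at frame {frame}: cell {cell} not present")
    dist_win = ndimage.distance_transform_edt(~window)
    facing = (v == cell) & (dist_win <= 2.0)
    if not facing.any():
        raise ValueError(f"planted eviction at frame {frame}: cell {cell} is not on the rim")
    if facing.sum() >= np.sum(v == cell):
        raise ValueError(
            f"planted eviction at frame {frame}: cell {cell} would vanish entirely"
        )
    donor = (v > 0) & (v != cell)
    _, (ir, ic) = ndimage.distance_transform_edt(~donor, return_indices=True)
    out = v.copy()
    rr, cc = np.nonzero(facing)
    out[rr, cc] = v[ir[rr, cc], ic[rr, cc]]
    return out


def generate_window_series(params: SyntheticTissueParams, return_truth: bool = False):
    """Tracked label-raster series of a tissue with a closing window.

    Labels persist across frames (the tessellation is static; the window
    disk shrinks per ``window_radius_schedule``).  Planted T1 events and
    evictions are burned into the rasters by local relabeling, validated
    against the evolving tissue, and persist once applied.

    With ``return_truth=True`` also returns a dict holding per-frame rim
    sets and all eviction events (planted and shrinkage-induced), computed
    from the generator's own window masks.
    """
    if params.window_radius_schedule is None:
        raise ValueError("window_radius_schedule is required for a closure series")
    schedule = list(params.window_radius_schedule)
    base, _ = _tessellate(params)
    n_frames = len(schedule)
    t1_by_frame: dict[int, list] = {}
    for f, quartet in params.planted_t1_events:
        if not 0 <= f < n_frames - 1:
            raise ValueError(f"planted T1 frame {f} outside the series")
        t1_by_frame.setdefault(f + 1, []).append(tuple(int(x) for x in quartet))
    ev_by_frame: dict[int, list] = {}
    for f, cell in params.planted_evictions:
        if not 0 <= f < n_frames - 1:
            raise ValueError(f"planted eviction frame {f} outside the series")
        ev_by_frame.setdefault(f + 1, []).append(int(cell))

    frames: list[LabelRaster] = []
    rim_sets: list[set[int]] = []
    state = base
    for t, r in enumerate(schedule):
        win = _disk_mask(state.shape, params.window_center, r)
        for quartet in t1_by_frame.get(t, []):
            state = _t1_edit(state, quartet, frame=t - 1)
        for cell in ev_by_frame.get(t, []):
            prev_win = _disk_mask(state.shape, params.window_center, schedule[t - 1])
            rim_prev = _rim_of(frames[-1].values, prev_win)
            if cell not in rim_prev:
                raise ValueError(
                    f"planted eviction at frame {t - 1}: cell {cell} is not a rim cell"
                )
            state = _eviction_edit(state, cell, win, frame=t - 1)
        values = state.copy()
        values[win] = 0
        frames.append(
            LabelRaster(values, pixel_size_um=params.pixel_size_um, frame_index=t)
        )
        rim_sets.append(_rim_of(values, win))

    if not return_truth:
        return frames
    evictions = []
    planted = {(f, int(c)) for f, c in params.planted_evictions}
    for t in range(n_frames - 1):
        present_next = set(int(l) for l in frames[t + 1].labels)
        for cell in sorted(rim_sets[t] - rim_sets[t + 1]):
            if cell in present_next:
                evictions.append(
                    {"frame": t, "cell_id": int(cell), "planted": (t, int(cell)) in planted}
                )
    truth = {
        "rim_sets": [sorted(int(c) for c in s) for s in rim_sets],
        "rim_counts": [len(s) for s in rim_sets],
        "eviction_events": evictions,
        "t1_events": [
            {"frame": int(f), "quartet": [int(x) for x in q]}
            for f, q in params.planted_t1_events
        ],
    }
    return frames, truth


def _rim_of(values: np.ndarray, window: np.ndarray) -> set[int]:
    if not window.any():
        return set()
    grown = ndimage.binary_dilation(window, structure=[[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    return {int(l) for l in np.unique(values[grown & (values > 0)])}


# ---------------------------------------------------------------------------
# event suggestion helpers (for building planted scenarios from a base tissue)


def suggest_t1_quartets(
    raster: LabelRaster,
    n: int,
    rng: np.random.Generator,
    exclude: Sequence[int] = (),
) -> list[tuple[int, int, int, int]]:
    """Pick ``n`` disjoint interior T1 quartets (a, b, c, d) from a tissue.

    The a–b pair is adjacent with exactly two common neighbors c, d that
    are themselves non-adjacent; all four cells are interior (no border or
    background contact) and quartets share no cells.
    """
    from epifluid.rasters import build_adjacency

    adj = build_adjacency(raster)
    border = set(
        int(l)
        for l in np.unique(
            np.concatenate(
                [raster.values[0], raster.values[-1], raster.values[:, 0], raster.values[:, -1]]
            )
        )
    )
    bg_touch = set(adj.background_contact_px)
    good = [
        nd
        for nd in adj.graph.nodes
        if nd not in border and nd not in bg_touch and nd not in exclude
    ]
    good_set = set(good)
    pairs = [
        (a, b) for a, b in adj.graph.edges if a in good_set and b in good_set
    ]
    order = rng.permutation(len(pairs))
    used: set[int] = set()
    out = []
    for k in order:
        a, b = pairs[k]
        if {a, b} & used:
            continue
        common = sorted((set(adj.graph.neighbors(a)) & set(adj.graph.neighbors(b))) - used)
        common = [c for c in common if c in good_set]
        if len(common) != 2:
            continue
        c, d = common
        if adj.graph.has_edge(c, d):
            continue
        out.append((int(a), int(b), int(c), int(d)))
        used |= {a, b, c, d}
        if len(out) == n:
            return out
    raise ValueError(f"only found {len(out)} of {n} requested T1 quartets")


def suggest_evictions(
    frames: Sequence[LabelRaster],
    window_center: tuple[float, float],
    at_frames: Sequence[int],
    rng: np.random.Generator,
) -> list[tuple[int, int]]:
    """Pick one rim cell per requested frame to evict (disjoint cells)."""
    from epifluid.dynamics import rim_cells

    used: set[int] = set()
    out = []
    for f in at_frames:
        rims = sorted(rim_cells(frames[f], window_center) - used)
        if not rims:
            raise ValueError(f"no rim cell available to evict at frame {f}")
        cell = int(rims[rng.integers(len(rims))])
        out.append((int(f), cell))
        used.add(cell)
    return out


# ---------------------------------------------------------------------------
# reference lattices and recoil traces


def fluid_band_tissue(
    rng_seed: int,
    shape: tuple[int, int] = (220, 220),
    n_cells: int = 160,
    band_halfwidth_px: float = 40.0,
    wiggle_amp_px: float = 3.5,
    lloyd_iterations: int = 8,
) -> tuple[LabelRaster, Callable]:
    """Two-region tissue: relaxed (solid-like) bulk with a planted fluid band.

    The central vertical band gets wiggled, irregular cell boundaries
    (high p, alignment Q barely changed); the bulk is Lloyd-relaxed toward
    hexagonal packing (low p).  Returns the raster and a predicate
    ``in_band(x_px)`` marking the planted region.
    """
    h, w = shape
    cx = w / 2.0

    def amp(x, y):
        return np.where(np.abs(x - cx) < band_halfwidth_px, wiggle_amp_px, 0.0)

    params = SyntheticTissueParams(
        n_cells=n_cells,
        domain_size=(w, h),
        lloyd_iterations=lloyd_iterations,
        wiggle_amp=amp,
        wiggle_scale=4.0,
        rng_seed=rng_seed,
    )
    return generate_tissue(params), (lambda x: abs(x - cx) < band_halfwidth_px)


def hexagonal_tissue(
    shape: tuple[int, int] = (220, 220), spacing_px: float = 18.0, pixel_size_um: float = 1.0
) -> LabelRaster:
    """Regular hexagonal tissue (Voronoi of a triangular seed lattice)."""
    h, w = shape
    seeds = []
    dy = spacing_px * math.sqrt(3.0) / 2.0
    row = 0
    y = -spacing_px
    while y < h + spacing_px:
        x0 = -spacing_px + (spacing_px / 2.0 if row % 2 else 0.0)
        x = x0
        while x < w + spacing_px:
            seeds.append((x, y))
            x += spacing_px
        y += dy
        row += 1
    labels = _assign(np.asarray(seeds), shape, None, 0.0, 1.0, np.random.default_rng(0))
    return LabelRaster(labels, pixel_size_um=pixel_size_um, frame_index=0)


def generate_recoil_trace(params: RecoilSimParams) -> RecoilTrace:
    """Noisy power-law recoil trace of two symmetric severed edges."""
    rng = np.random.default_rng(params.rng_seed)
    t = params.t0 + params.dt * np.arange(1, int(np.floor(params.duration / params.dt)) + 1)
    rows = []
    for track in range(1, params.n_tracks + 1):
        d = params.D * np.power(t - params.t0, params.alpha)
        if params.noise_sd > 0:
            d = d + rng.normal(0.0, params.noise_sd, size=d.shape)
        rows.append(
            pd.DataFrame(
                {
                    "time_s": t,
                    "edge1_pos_um": -d / 2.0,
                    "edge2_pos_um": d / 2.0,
                    "track_id": track,
                }
            )
        )
    return RecoilTrace(samples=pd.concat(rows, ignore_index=True), t0_s=params.t0)


# ---------------------------------------------------------------------------
# serialization


def write_series(frames: Sequence[LabelRaster], truth: Optional[dict], outdir) -> None:
    """Write frames as integer TIFFs plus a JSON ground-truth sidecar."""
    import pathlib

    import tifffile

    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for fr in frames:
        tifffile.imwrite(outdir / f"frame_{fr.frame_index:04d}.tif", fr.values.astype(np.int32))
    if truth is not None:
        with open(outdir / "ground_truth.json", "w") as fh:
            json.dump(truth, fh, indent=2)
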