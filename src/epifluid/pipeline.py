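"""Configuration-driven orchestration of the full analysis.

``run(config)`` drives synth → ingest → metrics → fluidity → dynamics →
recoil → report on a synthetic (or user-supplied) closure series, writing
per-stage CSV tables, map/scatter images and a JSON manifest that records
the seed, every defaulted choice, and the planted-truth checks.  Each stage
is also callable on its own against a run directory, which is what the CLI
subcommands do.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import pathlib
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from epifluid import __version__
from epifluid.cartography import MetricField, flat_metric, prolate_metric, sphere_equirect_metric
from epifluid.dynamics import detect_t1_series, rim_series
from epifluid.fluidity import FluidityConfig, build_center_mesh, fluidity_map
from epifluid.rasters import LabelRaster, build_adjacency, extract_polygons, read_label_raster
from epifluid.recoil import fit_power_law, interpret_alpha, recoil_velocity, write_recoil_csv
from epifluid.shape import metrics_table
from epifluid.stats import compare_groups
from epifluid.synth import (
    RecoilSimParams,
    SyntheticTissueParams,
    generate_recoil_trace,
    generate_window_series,
    suggest_evictions,
    suggest_t1_quartets,
    write_series,
)

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "run", "load_config"]


@dataclass
class RunConfig:
    """Serializable description of one analysis run."""

    seed: int = 0
    output_dir: str = "epifluid_run"
    geometry: dict = field(default_factory=lambda: {"kind": "flat", "pixel_size_um": 1.0})
    tissue: dict = field(
        default_factory=lambda: {
            "n_cells": 140,
            "domain_size": [220, 220],
            "lloyd_iterations": 3,
            "window_center": [110, 110],
            "window_radii": [34, 30, 26, 22, 18, 14, 10, 6, 3, 0],
            "planted_t1s": 3,
            "planted_evictions": 2,
        }
    )
    fluidity: dict = field(default_factory=dict)
    recoil: dict = field(
        default_factory=lambda: {"D": 2.0, "alpha": 0.5, "noise_sd": 0.1, "n_tracks": 3}
    )
    input_frames: Optional[list[str]] = None  # pre-segmented TIFFs instead of synth

    def fluidity_config(self) -> FluidityConfig:
        return FluidityConfig(**self.fluidity)


def load_config(path) -> RunConfig:
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)


def _metric_for(config: RunConfig, shape) -> MetricField:
    geo = dict(config.geometry or {})
    kind = geo.get("kind")
    if not kind:
        log.warning("config missing geometry; defaulting to flat metric")
        kind = "flat"
    if kind == "flat":
        return flat_metric(shape, geo.get("pixel_size_um", 1.0))
    if kind == "sphere":
        return sphere_equirect_metric(geo["radius_um"], shape)
    if kind == "ellipsoid":
        return prolate_metric(geo["a_um"], geo["c_um"], shape)
    raise ValueError(f"unknown geometry kind: {kind}")


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"stage '{name}' failed: {exc}") from exc

        wrapped.__name__ = fn.__name__
        return wrapped

    return deco


@_stage("synth")
def stage_synth(config: RunConfig, outdir: pathlib.Path):
    """Generate (or load) the tracked closure series; write frames + truth."""
    t = config.tissue
    if config.input_frames:
        px = config.geometry.get("pixel_size_um", 1.0)
        frames = [
            read_label_raster(p, pixel_size_um=px, frame_index=i)
            for i, p in enumerate(config.input_frames)
        ]
        return frames, None
    radii = t["window_radii"]
    base_params = SyntheticTissueParams(
        n_cells=t["n_cells"],
        domain_size=tuple(t["domain_size"]),
        pixel_size_um=config.geometry.get("pixel_size_um", 1.0),
        lloyd_iterations=t.get("lloyd_iterations", 3),
        wiggle_amp=t.get("wiggle_amp", 0.0),
        window_center=tuple(t["window_center"]),
        window_radius_schedule=radii,
        rng_seed=config.seed,
    )
    plain = generate_window_series(base_params)
    rng = np.random.default_rng(config.seed + 1)
    n_t1 = int(t.get("planted_t1s", 0))
    n_ev = int(t.get("planted_evictions", 0))
    t1_frames = sorted(rng.integers(0, len(radii) - 1, size=n_t1).tolist())
    quartets = suggest_t1_quartets(plain[0], n_t1, rng) if n_t1 else []
    ev_frames = sorted(rng.integers(0, max(len(radii) // 2, 1), size=n_ev).tolist())
    evictions = suggest_evictions(plain, tuple(t["window_center"]), ev_frames, rng) if n_ev else []
    params = dataclasses.replace(
        base_params,
        planted_t1_events=list(zip(t1_frames, quartets)),
        planted_evictions=evictions,
    )
    frames, truth = generate_window_series(params, return_truth=True)
    write_series(frames, truth, outdir / "frames")
    return frames, truth


@_stage("metrics")
def stage_metrics(config: RunConfig, outdir: pathlib.Path, frames):
    metric = _metric_for(config, frames[0].values.shape)
    all_polys = {}
    tables = []
    n_border = 0
    for fr in frames:
        polys = extract_polygons(fr)
        n_border += sum(p.touches_border for p in polys)
        all_polys[fr.frame_index] = polys
        tables.append(metrics_table(polys, metric=None if metric.is_flat else metric))
    cells = pd.concat(tables, ignore_index=True)
    cells.to_csv(outdir / "cell_metrics.csv", index=False)
    log.info("metrics: %d cell-frames, %d border cells excluded", len(cells), n_border)
    return metric, all_polys, cells


@_stage("fluidity")
def stage_fluidity(config: RunConfig, outdir: pathlib.Path, frames, all_polys, cells):
    fcfg = config.fluidity_config()
    tables = []
    for fr in frames:
        sub = cells[cells.frame == fr.frame_index]
        if sub.empty:
            continue
        adj = build_adjacency(fr)
        cents = {p.cell_id: tuple(np.asarray(p.centroid_um) / p.pixel_size_um) for p in all_polys[fr.frame_index]}
        mesh = build_center_mesh(adj, cents)
        is_last_full = fr.frame_index == frames[0].frame_index
        table, _, _ = fluidity_map(
            sub,
            mesh,
            fcfg,
            raster=fr,
            out_map=(outdir / "fluidity_map.png") if is_last_full else None,
            out_scatter=(outdir / "q_p_scatter.png") if is_last_full else None,
        )
        tables.append(table)
    flu = pd.concat(tables, ignore_index=True) if tables else pd.DataFrame()
    flu.to_csv(outdir / "fluidity.csv", index=False)
    return flu


@_stage("dynamics")
def stage_dynamics(config: RunConfig, outdir: pathlib.Path, frames, truth):
    events = detect_t1_series(frames)
    window_center = tuple(config.tissue["window_center"]) if not config.input_frames else None
    pd.DataFrame(
        [
            {
                "frame": e.frame_index,
                "lost_a": e.lost_pair[0],
                "lost_b": e.lost_pair[1],
                "gained_c": e.gained_pair[0],
                "gained_d": e.gained_pair[1],
            }
            for e in events
        ]
    ).to_csv(outdir / "t1_events.csv", index=False)
    rim = None
    if window_center is not None:
        rim = rim_series(frames, window_center)
        pd.DataFrame(
            {"frame": range(len(rim.rim_cell_count)), "rim_cell_count": rim.rim_cell_count}
        ).to_csv(outdir / "rim_counts.csv", index=False)
        pd.DataFrame(
            [{"frame": f, "cell_id": c} for f, c in rim.eviction_events]
        ).to_csv(outdir / "evictions.csv", index=False)
    checks = {}
    if truth is not None:
        planted = {(e["frame"], tuple(e["quartet"])) for e in truth["t1_events"]}
        detected = {
            (e.frame_index, (*e.lost_pair, *e.gained_pair)) for e in events
        }
        checks["t1_planted_recovered"] = all(
            any(f == df and set(q[:2]) == set(dq[:2]) and set(q[2:]) == set(dq[2:]) for df, dq in detected)
            for f, q in planted
        )
        checks["t1_false_positives"] = int(len(detected) - len(planted))
        truth_ev = {(e["frame"], e["cell_id"]) for e in truth["eviction_events"]}
        checks["evictions_match_truth"] = set(rim.eviction_events) == truth_ev if rim else None
        checks["rim_monotone_to_zero"] = (
            all(a >= b for a, b in zip(rim.rim_cell_count[:-1], rim.rim_cell_count[1:]))
            and rim.rim_cell_count[-1] == 0
            if rim
            else None
        )
    return events, rim, checks


@_stage("recoil")
def stage_recoil(config: RunConfig, outdir: pathlib.Path):
    r = config.recoil
    params = RecoilSimParams(
        D=r.get("D", 2.0),
        alpha=r.get("alpha", 0.5),
        noise_sd=r.get("noise_sd", 0.1),
        n_tracks=r.get("n_tracks", 3),
        rng_seed=config.seed + 2,
    )
    trace = generate_recoil_trace(params)
    write_recoil_csv(trace, outdir / "recoil_trace.csv")
    fit = fit_power_law(trace)
    v0 = recoil_velocity(trace)
    out = {
        "recoil_velocity_um_per_s": v0,
        "D": fit.D,
        "alpha": fit.alpha,
        "r_squared": fit.r_squared,
        "quantity_fitted": fit.quantity_fitted,
        "rheology": interpret_alpha(fit.alpha),
        "true_D": params.D,
        "true_alpha": params.alpha,
    }
    pd.DataFrame([out]).to_csv(outdir / "recoil_fits.csv", index=False)
    return out


@_stage("report")
def stage_report(config: RunConfig, outdir: pathlib.Path, flu: pd.DataFrame):
    """Group comparison: shape index of rim-proximal vs bulk cells (first frame)."""
    if flu.empty:
        return None
    first = flu[flu.frame == flu.frame.min()]
    fluid = first[first["class"] == "fluid"].p.to_numpy()
    solid = first[first["class"] == "solid"].p.to_numpy()
    if len(fluid) < 3 or len(solid) < 3:
        log.warning("report: too few cells per class for a group comparison")
        return None
    cmp = compare_groups(fluid, solid, test="rank_sum", labels=("fluid", "solid"))
    row = dataclasses.asdict(cmp)
    pd.DataFrame([row]).to_csv(outdir / "group_comparisons.csv", index=False)
    return cmp


def run(config: RunConfig) -> pathlib.Path:
    """Execute the full pipeline; returns the run directory."""
    outdir = pathlib.Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    frames, truth = stage_synth(config, outdir)
    metric, all_polys, cells = stage_metrics(config, outdir, frames)
    flu = stage_fluidity(config, outdir, frames, all_polys, cells)
    events, rim, checks = stage_dynamics(config, outdir, frames, truth)
    recoil_out = stage_recoil(config, outdir)
    cmp = stage_report(config, outdir, flu)
    manifest = {
        "epifluid_version": __version__,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "defaults": {
            "fluidity": dataclasses.asdict(config.fluidity_config()),
            "min_contact_px": 2,
            "contour_simplify_tol_px": 1.4,
            "contour_smoothing_sigma_px": 0.0,
            "cable_half_width_px": 2,
            "recoil_fit": {"quantity": "displacement", "window_s": 10.0},
        },
        "planted_truth_checks": checks,
        "recoil": recoil_out,
        "n_frames": len(frames),
        "n_t1_detected": len(events),
        "group_comparison_p": cmp.p_value if cmp else None,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return outdir
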