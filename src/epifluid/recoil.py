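"""Laser-ablation recoil analysis.

After a laser cut, the two severed tissue edges recoil apart.  The initial
recoil velocity is a proxy for local tension; the time course of the recoil
carries rheology: fitting the separation to a power law ``D·(t − t0)^α``
with α ∈ [0, 1] distinguishes elastic-solid behavior (α near 0) from
viscous-fluid behavior (α near 1).  The fitted quantity is the edge
*displacement* by default; a finite-difference *velocity* mode is provided
(the fitted quantity is recorded in every result).  Fits are restricted to
the first 10 s after ablation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "RecoilTrace",
    "PowerLawFit",
    "recoil_velocity",
    "fit_power_law",
    "interpret_alpha",
    "read_recoil_csv",
    "write_recoil_csv",
]

#: fitting window after ablation (s)
FIT_WINDOW_S = 10.0

#: alpha thresholds for the qualitative solid/fluid reading
ALPHA_SOLID_MAX = 1.0 / 3.0
ALPHA_FLUID_MIN = 2.0 / 3.0


@dataclass
class RecoilTrace:
    """Recoil tracks of the two severed edges of one cut.

    ``samples`` has columns ``time_s, edge1_pos_um, edge2_pos_um, track_id``
    (1–3 independent tracks per cut, averaged downstream).  ``setup_tag``
    names the ablation hardware; recoil statistics across different setups
    are not comparable and are refused by the reporting layer.
    """

    samples: pd.DataFrame
    t0_s: float = 0.0
    setup_tag: str = "default"

    def __post_init__(self):
        req = {"time_s", "edge1_pos_um", "edge2_pos_um", "track_id"}
        missing = req - set(self.samples.columns)
        if missing:
            raise ValueError(f"recoil samples missing columns: {sorted(missing)}")
        for tid, grp in self.samples.groupby("track_id"):
            t = grp.time_s.to_numpy()
            if not np.all(np.diff(t) > 0):
                raise ValueError(f"track {tid}: times must be strictly increasing")
            if t[0] <= self.t0_s:
                raise ValueError(f"track {tid}: first sample must follow the ablation time")

    @property
    def n_tracks(self) -> int:
        return int(self.samples.track_id.nunique())

    def separation(self) -> pd.DataFrame:
        """Track-averaged edge separation |edge2 − edge1| per sample time."""
        df = self.samples.copy()
        df["d_um"] = np.abs(df.edge2_pos_um - df.edge1_pos_um)
        return df.groupby("time_s", as_index=False)["d_um"].mean()


@dataclass(frozen=True)
class PowerLawFit:
    D: float
    alpha: float
    r_squared: float
    quantity_fitted: Literal["displacement", "velocity"]
    alpha_clipped: bool
    fit_window_s: tuple[float, float]
    n_points: int


def recoil_velocity(trace: RecoilTrace) -> float:
    """Initial recoil velocity (µm/s).

    Per track: total distance moved by the two edges between the first and
    second post-cut samples, divided by the inter-frame time; the per-track
    velocities are averaged.
    """
    vs = []
    for tid, grp in trace.samples.groupby("track_id"):
        if len(grp) < 2:
            raise ValueError(f"track {tid}: need at least two post-cut samples")
        g = grp.sort_values("time_s").iloc[:2]
        dt = float(g.time_s.iloc[1] - g.time_s.iloc[0])
        d1 = abs(float(g.edge1_pos_um.iloc[1] - g.edge1_pos_um.iloc[0]))
        d2 = abs(float(g.edge2_pos_um.iloc[1] - g.edge2_pos_um.iloc[0]))
        vs.append((d1 + d2) / dt)
    return float(np.mean(vs))


def fit_power_law(
    trace: RecoilTrace,
    quantity: Literal["displacement", "velocity"] = "displacement",
) -> PowerLawFit:
    """Fit ``D·(t − t0)^α`` to the recoil within 10 s post-ablation.

    Least-squares line in log–log space: ``D = exp(intercept)``,
    ``α = slope`` clipped to [0, 1] (clipping is flagged).  Displacement is
    the track-averaged edge separation; velocity is its centered finite
    difference.  Non-positive values are dropped with a warning.
    """
    sep = trace.separation()
    tau = sep.time_s.to_numpy() - trace.t0_s
    d = sep.d_um.to_numpy()
    if quantity == "displacement":
        tt, yy = tau, d
    elif quantity == "velocity":
        if len(tau) < 3:
            raise ValueError("velocity mode needs at least 3 samples")
        vv = np.gradient(d, tau)
        tt, yy = tau, vv
    else:
        raise ValueError("quantity must be 'displacement' or 'velocity'")
    window = (tt > 0) & (tt <= FIT_WINDOW_S)
    tt, yy = tt[window], yy[window]
    pos = yy > 0
    if np.any(~pos):
        log.warning("power-law fit: dropped %d non-positive samples", int((~pos).sum()))
    tt, yy = tt[pos], yy[pos]
    if len(tt) < 4:
        raise ValueError("need at least 4 usable samples within the 10 s fit window")
    lx, ly = np.log(tt), np.log(yy)
    slope, intercept = np.polyfit(lx, ly, 1)
    resid = ly - (slope * lx + intercept)
    ss_tot = float(np.sum((ly - ly.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    clipped = not (0.0 <= slope <= 1.0)
    if clipped:
        log.warning("power-law fit: alpha %.3f clipped into [0, 1]", slope)
    alpha = float(min(max(slope, 0.0), 1.0))
    return PowerLawFit(
        D=float(math.exp(intercept)),
        alpha=alpha,
        r_squared=r2,
        quantity_fitted=quantity,
        alpha_clipped=clipped,
        fit_window_s=(trace.t0_s, trace.t0_s + FIT_WINDOW_S),
        n_points=int(len(tt)),
    )


def interpret_alpha(alpha: float) -> str:
    """Qualitative rheology: α < 1/3 solid-like, α > 2/3 fluid-like."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    if alpha < ALPHA_SOLID_MAX:
        return "solid-like"
    if alpha > ALPHA_FLUID_MIN:
        return "fluid-like"
    return "intermediate"


def read_recoil_csv(path, t0_s: float = 0.0, setup_tag: str | None = None) -> RecoilTrace:
    """Read a recoil trace CSV (time_s, edge1_pos_um, edge2_pos_um, track_id[, setup_tag])."""
    df = pd.read_csv(path)
    tag = setup_tag
    if tag is None:
        tag = str(df["setup_tag"].iloc[0]) if "setup_tag" in df.columns else "default"
    cols = ["time_s", "edge1_pos_um", "edge2_pos_um", "track_id"]
    return RecoilTrace(samples=df[cols].copy(), t0_s=t0_s, setup_tag=tag)


def write_recoil_csv(trace: RecoilTrace, path) -> None:
    df = trace.samples.copy()
    df["setup_tag"] = trace.setup_tag
    df.to_csv(path, index=False)
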