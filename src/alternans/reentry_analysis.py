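"""2D re-entry detection via phase mapping and singularity tracking.

A per-node activation-recovery phase is built by time-delay embedding,
``theta(t) = atan2(V(t - tau) - V*, V(t) - V*)``; a phase singularity is a
plaquette around which the wrapped phase winds by +-2 pi, and a re-entry
episode is a singularity trajectory persisting for at least one full
rotation.  The rotation count is measured as the unwrapped phase advance at
a probe node adjacent to the trajectory's mean core position.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .biomarkers import detect_activations
from .errors import ConfigError, InsufficientDataError
from .ionic_models import CellModel, Trace
from .protocols import StimulusTrain, place_stimulus, supra_threshold_amplitude
from .synthetic_data import minimal_pde_cell
from .tissue_solver import (
    Geometry,
    SaveSpec,
    SpaceTimeField,
    assign_dead_cells,
    build_geometry,
    run_simulation,
)

__all__ = [
    "ReentryEpisode",
    "TransitionConfig",
    "phase_field",
    "phase_singularities",
    "detect_reentry_episodes",
    "find_reentry",
    "stimulus_response_ratio",
    "run_transition_experiment",
    "episodes_to_frame",
]


@dataclass
class ReentryEpisode:
    """One tracked phase-singularity trajectory."""

    onset: float                      # ms
    termination: Optional[float]      # ms; None = sustained at end of run
    trajectory: List[Tuple[float, float, float, int]]  # (t, x, y, chirality)
    rotations: float
    chirality: int

    @property
    def duration(self) -> float:
        end = self.trajectory[-1][0] if self.termination is None else self.termination
        return end - self.onset

    @property
    def mean_core(self) -> Tuple[float, float]:
        xs = [p[1] for p in self.trajectory]
        ys = [p[2] for p in self.trajectory]
        return float(np.mean(xs)), float(np.mean(ys))


def phase_field(
    fld: SpaceTimeField,
    tau: float = 10.0,
    v_star: Optional[float] = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Time-delay-embedded phase for each frame with enough history.

    Returns (phase, times): phase has shape (n_frames - k, ny, nx) where
    ``k = round(tau / dt_save)``; frames before t0 + tau are skipped.
    ``v_star`` defaults to the midpoint of the run's observed voltage range.
    """
    if fld.dt_save > tau / 2:
        raise ConfigError(
            f"dt_save {fld.dt_save} ms too coarse for tau {tau} ms (need <= tau/2)"
        )
    k = int(round(tau / fld.dt_save))
    if fld.v.shape[0] <= k:
        raise InsufficientDataError("not enough frames for the embedding delay")
    v = fld.v  # keep the stored dtype: float32 frames stay float32
    if v_star is None:
        v_star = 0.5 * (float(v.min()) + float(v.max()))
    v_star = np.asarray(v_star, dtype=v.dtype)
    phase = np.arctan2(v[:-k] - v_star, v[k:] - v_star)
    return phase, fld.t[k:]


def phase_singularities(
    phase_frame: np.ndarray, dx: float = 1.0, winding_tol: float = 0.1,
    valid_mask: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Phase singularities of one frame by plaquette winding number.

    Sums wrapped phase differences around every 2x2 plaquette; |winding| =
    2 pi marks a singularity.  Returns an (n, 3) array of (x, y, chirality)
    with positions at plaquette centres in mm.  ``valid_mask`` (True where
    the phase is meaningful) suppresses plaquettes touching invalid nodes,
    e.g. dead cells whose potential never moves.
    """

    def wrap(a):
        return (a + np.pi) % (2 * np.pi) - np.pi

    p = phase_frame
    # corners: a=(i,j) b=(i,j+1) c=(i+1,j+1) d=(i+1,j)
    a = p[:-1, :-1]
    b = p[:-1, 1:]
    c = p[1:, 1:]
    d = p[1:, :-1]
    winding = wrap(b - a) + wrap(c - b) + wrap(d - c) + wrap(a - d)
    hits = np.abs(np.abs(winding) - 2 * np.pi) < 2 * np.pi * winding_tol
    if valid_mask is not None:
        ok = (valid_mask[:-1, :-1] & valid_mask[:-1, 1:]
              & valid_mask[1:, 1:] & valid_mask[1:, :-1])
        hits &= ok
    iy, ix = np.nonzero(hits)
    if iy.size == 0:
        return np.zeros((0, 3))
    chir = np.sign(winding[iy, ix])
    return np.column_stack([(ix + 0.5) * dx, (iy + 0.5) * dx, chir])


def _link_trajectories(ps_per_frame, times, link_radius, max_gap=1):
    """Greedy nearest-neighbour linking across frames."""
    open_tracks: List[dict] = []
    done: List[List[Tuple[float, float, float, int]]] = []
    for t, ps in zip(times, ps_per_frame):
        ps = np.asarray(ps)
        used = np.zeros(len(ps), dtype=bool)
        for tr in open_tracks:
            if not ps.size:
                tr["gap"] += 1
                continue
            lx, ly = tr["pts"][-1][1], tr["pts"][-1][2]
            d = np.hypot(ps[:, 0] - lx, ps[:, 1] - ly)
            d[used] = np.inf
            same = ps[:, 2] != tr["pts"][-1][3]
            d[same] = np.inf
            k = int(np.argmin(d))
            if d[k] <= link_radius:
                tr["pts"].append((t, ps[k, 0], ps[k, 1], int(ps[k, 2])))
                tr["gap"] = 0
                used[k] = True
            else:
                tr["gap"] += 1
        still = []
        for tr in open_tracks:
            if tr["gap"] > max_gap:
                done.append(tr["pts"])
            else:
                still.append(tr)
        open_tracks = still
        for k in np.flatnonzero(~used):
            open_tracks.append(
                {"pts": [(t, ps[k, 0], ps[k, 1], int(ps[k, 2]))], "gap": 0}
            )
    ended_open = [tr["pts"] for tr in open_tracks]
    return done, ended_open


def _count_rotations(phase, times, dx, track) -> float:
    """Unwrapped phase advance (in turns) at a probe next to the mean core."""
    ts = np.array([p[0] for p in track])
    xs = np.array([p[1] for p in track])
    ys = np.array([p[2] for p in track])
    ny, nx = phase.shape[1:]
    # probe offset a few nodes from the core to avoid the undefined centre
    off = 3
    ix = int(np.clip(round(np.mean(xs) / dx) + off, 0, nx - 1))
    iy = int(np.clip(round(np.mean(ys) / dx), 0, ny - 1))
    sel = (times >= ts[0]) & (times <= ts[-1])
    if sel.sum() < 3:
        return 0.0
    series = np.unwrap(phase[sel, iy, ix])
    return float(abs(series[-1] - series[0]) / (2 * np.pi))


def detect_reentry_episodes(
    ps_per_frame: Sequence[np.ndarray],
    times: np.ndarray,
    phase: Optional[np.ndarray] = None,
    dx: float = 1.0,
    min_rotations: float = 1.0,
    link_radius: Optional[float] = None,
    end_time: Optional[float] = None,
) -> List[ReentryEpisode]:
    """Link singularities across frames and keep trajectories that rotate.

    ``link_radius`` defaults to 10 node spacings.  An episode whose
    trajectory is alive in the final frame is marked sustained
    (termination None).
    """
    times = np.asarray(times, float)
    if link_radius is None:
        link_radius = 10.0 * dx
    closed, open_ = _link_trajectories(ps_per_frame, times, link_radius)
    end_time = times[-1] if end_time is None else end_time
    episodes = []
    for pts, sustained in [(p, False) for p in closed] + [(p, True) for p in open_]:
        if len(pts) < 3:
            continue
        rot = (
            _count_rotations(phase, times, dx, pts)
            if phase is not None
            else (pts[-1][0] - pts[0][0]) * np.nan
        )
        if phase is None or rot >= min_rotations:
            chir = int(np.sign(np.mean([p[3] for p in pts])))
            sustained_now = sustained and pts[-1][0] >= end_time - 1e-9
            episodes.append(
                ReentryEpisode(
                    onset=pts[0][0],
                    termination=None if sustained_now else pts[-1][0],
                    trajectory=pts,
                    rotations=rot,
                    chirality=chir,
                )
            )
    return episodes


def find_reentry(
    fld: SpaceTimeField,
    tau: float = 10.0,
    min_rotations: float = 1.0,
    after: float = 0.0,
    exclude_margin: int = 0,
    dead_mask: Optional[np.ndarray] = None,
) -> List[ReentryEpisode]:
    """Convenience pipeline: phase -> singularities -> episodes for one run.

    ``after`` ignores frames before that time (pacing transient);
    ``exclude_margin`` masks singularities within that many nodes of the
    boundary (stimulus edge artefacts); ``dead_mask`` marks nodes whose
    phase is undefined (dead cells) so plaquettes touching them are skipped.
    """
    phase, times = phase_field(fld, tau)
    sel = times >= after
    phase, times = phase[sel], times[sel]
    valid = None if dead_mask is None else ~np.asarray(dead_mask, bool)
    ps = []
    ny, nx = phase.shape[1:]
    for k in range(phase.shape[0]):
        s = phase_singularities(phase[k], fld.dx, valid_mask=valid)
        if exclude_margin and s.size:
            m = exclude_margin * fld.dx
            keep = (
                (s[:, 0] > m)
                & (s[:, 0] < (nx - 1) * fld.dx - m)
                & (s[:, 1] > m)
                & (s[:, 1] < (ny - 1) * fld.dx - m)
            )
            s = s[keep]
        ps.append(s)
    return detect_reentry_episodes(
        ps, times, phase=phase, dx=fld.dx, min_rotations=min_rotations
    )


def stimulus_response_ratio(
    probes: Dict,
    stim_times: np.ndarray,
    transient_beats: int = 5,
    dvdt_threshold: float = 10.0,
) -> Dict:
    """Activations per delivered stimulus at each probe, post-transient."""
    stim_times = np.asarray(stim_times, float)
    if stim_times.size <= transient_beats:
        raise InsufficientDataError("no stimuli after the transient window")
    t_start = stim_times[transient_beats]
    n_stim = stim_times[stim_times >= t_start].size
    out = {}
    for key, tr in probes.items():
        ups = detect_activations(tr, dvdt_threshold)
        out[key] = float((ups >= t_start).sum() / n_stim)
    return out


@dataclass
class TransitionConfig:
    """Configuration of a 2D alternans-to-re-entry experiment.

    The desk-scale defaults drive the minimal 3-variable cell on a
    200 x 200 sheet; pass ``model`` to override the cell (e.g. the detailed
    myocyte at full scale).
    """

    tissue_kind: str = "homogeneous"   # homogeneous | inhomogeneous | anisotropic
    s_gna: float = 1.0
    pcl: float = 172.0
    d: float = 0.06
    duration: float = 4000.0
    shape: Tuple[int, int] = (200, 200)
    dx: float = 0.25
    dt: float = 0.2
    dt_save: float = 2.0
    dead_fraction: float = 0.10
    seed: Optional[int] = None
    delta_tau_v: float = 20.0
    n_beats: Optional[int] = None
    stim_extent: int = 8
    model: Optional[CellModel] = None
    # minimal-cell parameter overrides; the default raises excitability so
    # broken wavefront ends can curl into rotors at this domain size
    cell_overrides: Optional[dict] = field(default_factory=lambda: {"tau_d": 0.18})

    def __post_init__(self) -> None:
        if self.tissue_kind not in ("homogeneous", "inhomogeneous", "anisotropic"):
            raise ConfigError(f"unknown tissue_kind '{self.tissue_kind}'")
        if self.tissue_kind == "inhomogeneous" and self.seed is None:
            raise ConfigError("inhomogeneous tissue requires a seed for the dead mask")


def run_transition_experiment(
    cfg: TransitionConfig,
) -> Tuple[SpaceTimeField, List[ReentryEpisode], Dict]:
    """Pace a 2D sheet from the corner and track re-entry episodes.

    Returns (field, episodes, probes).  Probes sit on the sheet diagonal at
    1/4, 1/2 and 3/4 of the domain, mirroring the three registration sites
    of the 2D experiments.
    """
    model = cfg.model or minimal_pde_cell(
        "steep", s_gna=cfg.s_gna, delta_tau_v=cfg.delta_tau_v,
        **(cfg.cell_overrides or {}),
    )
    g = build_geometry(
        "sheet",
        shape=cfg.shape,
        dx=cfg.dx,
        d_par=cfg.d,
        anisotropic=cfg.tissue_kind == "anisotropic",
        fibers="elliptical" if cfg.tissue_kind == "anisotropic" else "uniform",
    )
    if cfg.tissue_kind == "inhomogeneous":
        g = assign_dead_cells(g, cfg.dead_fraction, cfg.seed)
    amp = supra_threshold_amplitude(model)
    n_beats = cfg.n_beats or max(1, int((cfg.duration - 20.0) // cfg.pcl))
    site = place_stimulus(g, "sheet_corner", cfg.stim_extent)
    train = StimulusTrain(amplitude=amp, pcl=cfg.pcl, count=n_beats,
                          onset=10.0, extent=cfg.stim_extent, site=site)
    ny, nx = cfg.shape
    probe_sites = [(ny - 1 - q * ny // 4, q * nx // 4) for q in (1, 2, 3)]
    fld, probes = run_simulation(
        model, g, train, SaveSpec(dt_save=cfg.dt_save, probes=probe_sites),
        dt=cfg.dt, duration=cfg.duration,
        provenance={"tissue_kind": cfg.tissue_kind, "s_gna": cfg.s_gna,
                    "pcl": cfg.pcl, "seed": cfg.seed},
    )
    episodes = find_reentry(fld, after=2 * cfg.pcl, exclude_margin=2,
                            dead_mask=g.dead_mask)
    return fld, episodes, probes


def episodes_to_frame(episodes: List[ReentryEpisode]) -> pd.DataFrame:
    rows = []
    for ep in episodes:
        cx, cy = ep.mean_core
        rows.append(
            {
                "onset_ms": ep.onset,
                "termination_ms": np.nan if ep.termination is None else ep.termination,
                "sustained": ep.termination is None,
                "rotations": ep.rotations,
                "mean_core_x_mm": cx,
                "mean_core_y_mm": cy,
                "chirality": ep.chirality,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["onset_ms", "termination_ms", "sustained", "rotations",
                 "mean_core_x_mm", "mean_core_y_mm", "chirality"],
    )
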