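"""Ground-truth fixtures for every pipeline stage.

* :class:`ToyMapCell` — an APD-restitution map ``APD = A - B exp(-DI/tau)``
  with a closed-form alternans onset, used as the brute-force oracle for the
  bifurcation detector;
* :func:`minimal_pde_cell` — a three-variable excitable cell (Fenton-Karma
  form: fast inward, slow inward, slow outward currents) conforming to the
  CellModel contract, ~20x cheaper per step than the detailed myocyte and
  tunable so the APD-restitution slope crosses 1;
* planted voltage traces, APD fields and rotating phase fields whose ground
  truth is known by construction.

The minimal cell is a test vehicle and a scaled-down experiment driver, not
a claim about any species' physiology.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from . import _kernels
from .alternans_classifier import APDField
from .errors import ConfigError, InvalidStateError
from .ionic_models import CellModel, NaChannelParams, Trace
from .tissue_solver import SpaceTimeField

__all__ = [
    "ToyMapCell",
    "toy_apd_map",
    "toy_alternans_onset_closed_form",
    "toy_fixed_point",
    "iterate_pacing_map",
    "map_alternans_onset",
    "minimal_pde_cell",
    "synth_voltage_trace",
    "synth_apd_field",
    "synth_rotor_frames",
]


# ---------------------------------------------------------------------------
# Restitution-map toy cell
# ---------------------------------------------------------------------------


@dataclass
class ToyMapCell:
    """Exponential-restitution APD map with a capture floor."""

    A: float = 200.0       # asymptotic APD (ms)
    B: float = 120.0       # restitution depth (ms)
    tau: float = 40.0      # recovery constant (ms)
    min_di: float = 2.0    # capture floor (ms)

    def __post_init__(self) -> None:
        if not (self.A > self.B > 0):
            raise InvalidStateError("need A > B > 0")
        if self.tau <= 0:
            raise InvalidStateError("tau must be > 0")


def toy_apd_map(cell: ToyMapCell, di: float) -> Optional[float]:
    """APD after a diastolic interval; None when capture fails (di < min_di)."""
    if di < 0:
        raise InvalidStateError(f"di must be >= 0, got {di}")
    if di < cell.min_di:
        return None
    return cell.A - cell.B * np.exp(-di / cell.tau)


def toy_alternans_onset_closed_form(cell: ToyMapCell) -> float:
    """PCL below which the fixed point of the pacing map loses stability.

    The map ``APD_{n+1} = f(PCL - APD_n)`` alternates when |f'| > 1 at the
    fixed point, i.e. when ``(B/tau) exp(-DI*/tau) > 1``; the critical DI is
    ``DI* = tau ln(B/tau)`` and the onset PCL is ``DI* + f(DI*)``.
    """
    if cell.B <= cell.tau:
        return -np.inf  # slope never exceeds 1: no alternans at any PCL
    di_star = cell.tau * np.log(cell.B / cell.tau)
    return float(di_star + toy_apd_map(cell, di_star))


def iterate_pacing_map(
    cell: ToyMapCell, pcl: float, n_beats: int = 200, apd0: Optional[float] = None
) -> np.ndarray:
    """Brute-force iteration of the pacing map with 2:1 skipping.

    ``DI_n = pcl - APD_n``; when the DI falls below the capture floor the
    beat is skipped and a further PCL is added (2:1 response).  Returns the
    APD sequence.
    """
    if pcl <= 0:
        raise InvalidStateError(f"pcl must be > 0, got {pcl}")
    apd = float(cell.A - cell.B) if apd0 is None else float(apd0)
    out = []
    for _ in range(n_beats):
        di = pcl - apd
        while di < cell.min_di:
            di += pcl  # skipped (non-captured) stimulus
        apd = toy_apd_map(cell, di)
        out.append(apd)
    return np.asarray(out)


def toy_fixed_point(cell: ToyMapCell, pcl: float) -> Optional[float]:
    """APD of the 1:1 fixed point ``APD = f(pcl - APD)``, or None if absent."""
    lo, hi = 0.0, pcl - cell.min_di
    if hi <= lo:
        return None

    def g(apd):
        return toy_apd_map(cell, pcl - apd) - apd

    if g(lo) < 0 or g(hi) > 0:
        return None
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if g(mid) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def map_alternans_onset(
    cell: ToyMapCell,
    pcl_grid: np.ndarray,
    epsilon: float = 1.0,
    n_beats: int = 300,
) -> Optional[float]:
    """Brute-force 2-cycle onset: largest grid PCL with sustained alternation.

    Iteration is seeded at the 1:1 fixed point plus a small perturbation so
    the local period-doubling is probed (the map with a capture floor is
    multistable: cold starts can land on a coexisting 2:1 orbit).
    """
    best = None
    for pcl in np.sort(pcl_grid)[::-1]:
        fp = toy_fixed_point(cell, float(pcl))
        if fp is None:
            continue
        seq = iterate_pacing_map(cell, float(pcl), n_beats, apd0=fp + 0.5)
        tail = seq[-6:]
        if np.all(np.abs(np.diff(tail)) > epsilon):
            best = float(pcl)
            break
    return best


# ---------------------------------------------------------------------------
# Minimal three-variable PDE cell
# ---------------------------------------------------------------------------

_FK_REST = -85.0
_FK_AMP = 100.0

# (tau_d, tau_r, tau_si, tau_0, tau_vp, tau_v1m, tau_v2m, tau_wp, tau_wm,
#  u_c, u_v, u_csi, k_si)
_FK_PRESETS = {
    # Beeler-Reuter-like fit of the original three-current formulation:
    # long APD, steep restitution at short DI.
    "mbr": (0.25, 33.33, 29.0, 12.5, 3.33, 1250.0, 19.6, 870.0, 41.0,
            0.13, 0.04, 0.85, 10.0),
    # shortened-APD steep variant (slow outward/inward time scales halved):
    # APD ~ 118 ms at slow rate, alternans for PCL in ~[160, 200] ms, 2:1 below
    "steep": (0.25, 16.7, 14.5, 12.5, 3.33, 1250.0, 19.6, 435.0, 41.0,
              0.13, 0.04, 0.85, 10.0),
    # flat restitution: fast v/w recovery, same APD plateau; never alternates
    "flat": (0.25, 16.7, 14.5, 12.5, 3.33, 30.0, 19.6, 435.0, 10.0,
             0.13, 0.04, 0.85, 10.0),
}


def _fk_currents(y: np.ndarray, p: np.ndarray) -> dict:
    u = (y[0] - p[13]) / p[14]
    v, w = y[1], y[2]
    if u >= p[9]:
        j_fi = -v * (1.0 - u) * (u - p[9]) / (p[0] / max(p[15], 1e-12))
        j_so = 1.0 / p[1]
    else:
        j_fi = 0.0
        j_so = u / p[3]
    j_si = -w * (1.0 + np.tanh(p[12] * (u - p[11]))) / (2.0 * p[2])
    return {
        "I_Na": float(p[14] * j_fi),   # fast inward plays the I_Na role
        "I_CaL": float(p[14] * j_si),  # slow inward plays the I_CaL role
        "I_K": float(p[14] * j_so),
    }


def minimal_pde_cell(
    preset: str = "steep",
    s_gna: float = 1.0,
    delta_tau_v: float = 0.0,
    v_mod_threshold: float = -70.0,
    **overrides,
) -> CellModel:
    """Three-variable minimal excitable cell conforming to the model contract.

    ``s_gna`` scales the fast inward current (the I_Na analogue) and
    ``delta_tau_v`` adds to the fast gate's recovery time constant below
    ``v_mod_threshold``, mirroring the detailed model's two knobs.
    Presets: ``steep`` (APD-restitution slope crosses 1), ``flat`` (never
    alternates), ``mbr`` (the original long-APD fit).
    """
    if preset not in _FK_PRESETS:
        raise ConfigError(f"unknown preset '{preset}'; have {sorted(_FK_PRESETS)}")
    base = list(_FK_PRESETS[preset])
    names = ["tau_d", "tau_r", "tau_si", "tau_0", "tau_vp", "tau_v1m",
             "tau_v2m", "tau_wp", "tau_wm", "u_c", "u_v", "u_csi", "k_si"]
    for k, val in overrides.items():
        if k not in names:
            raise ConfigError(f"unknown minimal-cell parameter '{k}'")
        base[names.index(k)] = float(val)
    params = np.array(base + [_FK_REST, _FK_AMP, s_gna, delta_tau_v,
                              v_mod_threshold])
    rest = np.array([_FK_REST, 1.0, 1.0])
    na = NaChannelParams(g_na=_FK_AMP / base[0], s_gna=s_gna, e_na=_FK_REST + _FK_AMP,
                         delta_tau_h=delta_tau_v, v_mod_threshold=v_mod_threshold)
    return CellModel(
        name=f"minimal3v_{preset}",
        state_names=("V", "v", "w"),
        cm=1.0,
        initial_state=rest,
        params=params,
        rhs_kernel=_kernels.fk_rhs,
        currents_fn=lambda y: _fk_currents(y, params),
        n_gates=2,
        n_concentrations=0,
        v_rest=_FK_REST,
        na=na,
    )


# ---------------------------------------------------------------------------
# Planted traces / fields / rotors
# ---------------------------------------------------------------------------


def _single_ap(tt: np.ndarray, apd90: float, rest: float, peak: float,
               plateau_frac: float = 0.3) -> np.ndarray:
    """One AP waveform sampled at times tt (0 = upstroke sample).

    The upstroke is a single-sample jump (the take-off sample itself stays
    at rest, so the maximal-dV/dt instant sits exactly at the planted
    upstroke time with take-off potential = rest), followed by a plateau and
    a linear repolarisation ramp whose 90% crossing relative to the
    take-off amplitude falls exactly ``apd90`` ms after the upstroke.
    """
    t1 = plateau_frac * apd90
    t_end = t1 + (apd90 - t1) / 0.9
    v = np.full(tt.shape, rest)
    plat = (tt > 0) & (tt <= t1)
    v[plat] = peak
    rep = (tt > t1) & (tt < t_end)
    v[rep] = peak - (peak - rest) * (tt[rep] - t1) / (t_end - t1)
    return v


def synth_voltage_trace(
    apd90: float = 150.0,
    n_beats: int = 5,
    pcl: float = 400.0,
    rest: float = -85.0,
    peak: float = 20.0,
    noise_sd: float = 0.0,
    dt: float = 0.1,
    onset: float = 10.0,
    apd_list: Optional[np.ndarray] = None,
    seed: int = 0,
) -> Tuple[Trace, dict]:
    """Piecewise-linear AP train with planted upstroke times and APD90s.

    Returns (trace, truth) where truth holds the planted upstroke times and
    per-beat APD90 values; ``apd_list`` overrides the common APD per beat
    (e.g. ``[200, 160]`` tiled for planted alternans).
    """
    if apd_list is None:
        apd_list = np.full(n_beats, float(apd90))
    else:
        apd_list = np.resize(np.asarray(apd_list, float), n_beats)
    if n_beats and np.max(apd_list, initial=0.0) >= pcl:
        raise InvalidStateError("planted APD must be < pcl")
    duration = onset + pcl * n_beats if n_beats else 50.0
    t = np.arange(0.0, duration, dt)
    v = np.full(t.shape, rest)
    # snap planted upstrokes to the sampling grid so they are exact
    ups = t[np.searchsorted(t, onset + pcl * np.arange(n_beats))]
    for k, up in enumerate(ups):
        sel = (t >= up) & (t < up + pcl)
        v[sel] = _single_ap(t[sel] - up, apd_list[k], rest, peak)
    if noise_sd > 0:
        v = v + np.random.default_rng(seed).normal(0.0, noise_sd, v.shape)
    truth = {"upstroke_times": ups, "apd90": apd_list.copy(),
             "rest": rest, "peak": peak, "seed": seed}
    return Trace(t, v, {"synthetic": True, **truth}), truth


def synth_apd_field(
    kind: str,
    node_position: float = 15.0,
    n_nodes: int = 200,
    n_beats: int = 12,
    dx: float = 0.15,
    pcl: float = 160.0,
    apd_mean: float = 120.0,
    apd_delta: float = 30.0,
    cv_mm_per_ms: float = 0.5,
    block_beat: Optional[int] = None,
    block_node: Optional[int] = None,
) -> Tuple[APDField, dict]:
    """Planted strand APD field of a requested class.

    ``concordant``: spatially uniform alternation; ``discordant``: the sign
    of the beat-to-beat APD difference flips at ``node_position`` (mm);
    ``block``: activations missing beyond a planted node from a planted beat
    onward.  Returns (field, truth).
    """
    if kind not in ("concordant", "discordant", "block"):
        raise ConfigError(f"unknown kind '{kind}'")
    x = np.arange(n_nodes) * dx
    stim_times = 10.0 + pcl * np.arange(n_beats)
    act = stim_times[:, None] + (x / cv_mm_per_ms)[None, :]
    parity = (-1.0) ** np.arange(n_beats)
    if kind == "discordant":
        spatial_sign = np.where(x < node_position, 1.0, -1.0)
    else:
        spatial_sign = np.ones(n_nodes)
    apd = apd_mean + 0.5 * apd_delta * parity[:, None] * spatial_sign[None, :]
    truth = {"kind": kind, "node_position_mm": node_position,
             "apd_mean": apd_mean, "apd_delta": apd_delta}
    if kind == "block":
        bb = n_beats - 2 if block_beat is None else block_beat
        bn = n_nodes // 2 if block_node is None else block_node
        act[bb:, bn + 1:] = np.nan
        apd[bb:, bn + 1:] = np.nan
        truth.update({"block_beat": bb, "block_node": bn})
    return APDField(apd=apd, activation=act, stim_times=stim_times, dx=dx), truth


def synth_rotor_frames(
    center: Tuple[float, float] = (15.0, 15.0),
    omega: float = 2 * np.pi / 100.0,
    duration: float = 300.0,
    grid: Tuple[int, int] = (100, 100),
    dx: float = 0.3,
    dt_save: float = 2.0,
    rest: float = -85.0,
    amp: float = 50.0,
    n_rotors: int = 1,
    second_center: Optional[Tuple[float, float]] = None,
) -> Tuple[SpaceTimeField, dict]:
    """Rigidly rotating phase pattern with known singularity location(s).

    ``V(x, y, t) = rest + amp cos(atan2(y - yc, x - xc) - omega t)``; a
    mirrored second rotor (opposite chirality) can be added for pair tests.
    """
    ny, nx = grid

    def snap(c):
        # place the core strictly inside a plaquette (between nodes): a core
        # sitting exactly on a node makes its winding number ill-defined
        return (np.floor(c / dx) + 0.5) * dx

    xc, yc = snap(center[0]), snap(center[1])
    if not (0 <= xc <= (nx - 1) * dx and 0 <= yc <= (ny - 1) * dx):
        raise ConfigError("rotor center outside the grid")
    center = (float(xc), float(yc))
    t = np.arange(0.0, duration + 0.5 * dt_save, dt_save)
    ys, xs = np.mgrid[0:ny, 0:nx] * dx
    theta = np.arctan2(ys - yc, xs - xc)
    if n_rotors == 2:
        # superpose the windings: +1 at the first core, -1 at the mirrored
        # one, smooth everywhere else
        xc2, yc2 = second_center if second_center else ((nx - 1) * dx - xc, yc)
        xc2, yc2 = snap(xc2), snap(yc2)
        second_center = (float(xc2), float(yc2))
        theta = theta - np.arctan2(ys - yc2, xs - xc2)
    v = rest + amp * np.cos(theta[None] - omega * t[:, None, None])
    truth = {"center": center, "omega": omega,
             "rotations": omega * duration / (2 * np.pi)}
    if n_rotors == 2:
        truth["second_center"] = second_center or ((nx - 1) * dx - xc, yc)
    fld = SpaceTimeField(v=v.astype(np.float32), dt_save=dt_save, dx=dx,
                         provenance={"synthetic": "rotor", **truth})
    return fld, truth
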