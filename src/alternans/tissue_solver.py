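"""Mono-domain tissue propagation in 1D strands and 2D sheets.

The tissue obeys ``dV/dt = div(D grad V) - I_ion/Cm`` on a regular lattice
with zero-flux (Neumann) outer boundaries.  The diffusion tensor is built
per node from a fibre angle theta as ``D = R(theta) diag(D_par, D_perp)
R(theta)^T``; dead nodes are modelled as zero link conductance (internal
no-flux), not as clamped potentials, so they neither activate nor sink
charge.  Time stepping is first-order operator splitting: an explicit
forward-Euler reaction substep per node followed by a Crank-Nicolson
diffusion solve on V.  The implicit matrix is constant per (geometry, dt)
and factorised once.

The discrete operator L is assembled in flux form (face fluxes applied with
opposite signs to the two adjacent nodes), which makes ``L @ const = 0``
exact and conserves ``sum(V)`` under pure diffusion to solver precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import _kernels
from .errors import ConfigError, NumericalBlowupError
from .ionic_models import CellModel, Trace

__all__ = [
    "Geometry",
    "SpaceTimeField",
    "SaveSpec",
    "fiber_angle_elliptical",
    "build_geometry",
    "assign_dead_cells",
    "assemble_diffusion_operator",
    "step_tissue",
    "run_simulation",
]


@dataclass
class Geometry:
    """1D/2D lattice with diffusion coefficients, fibre field and dead mask."""

    shape: Tuple[int, ...]
    dx: float
    d_par: float
    d_perp: float
    fiber_angle: Optional[np.ndarray] = None  # radians per node (2D only)
    dead_mask: Optional[np.ndarray] = None    # bool per node, True = dead

    def __post_init__(self) -> None:
        if self.dx <= 0:
            raise ConfigError(f"dx must be > 0, got {self.dx}")
        if any(n <= 0 for n in self.shape):
            raise ConfigError(f"non-positive grid shape {self.shape}")
        if self.d_perp > self.d_par:
            raise ConfigError("D_perp must be <= D_par")
        if self.dead_mask is None:
            self.dead_mask = np.zeros(self.shape, dtype=bool)
        if self.fiber_angle is not None:
            self.fiber_angle = np.broadcast_to(
                np.asarray(self.fiber_angle, dtype=float), self.shape
            ).copy()

    @property
    def ndim(self) -> int:
        return len(self.shape)

    @property
    def n_nodes(self) -> int:
        return int(np.prod(self.shape))

    @property
    def length_mm(self) -> float:
        return self.shape[-1] * self.dx

    @property
    def isotropic(self) -> bool:
        return self.d_par == self.d_perp


@dataclass
class SpaceTimeField:
    """V sampled on (frame x node) with uniform frame interval."""

    v: np.ndarray          # (n_frames, *shape), mV
    dt_save: float         # ms
    dx: float              # mm
    t0: float = 0.0
    stim_times: np.ndarray = field(default_factory=lambda: np.zeros(0))
    provenance: dict = field(default_factory=dict)

    @property
    def t(self) -> np.ndarray:
        return self.t0 + np.arange(self.v.shape[0]) * self.dt_save

    @property
    def n_frames(self) -> int:
        return self.v.shape[0]

    def node_trace(self, idx) -> Trace:
        """Frame-resolution voltage trace at one node index (int or (iy, ix))."""
        if np.isscalar(idx):
            return Trace(self.t, self.v[:, idx].astype(float))
        iy, ix = idx
        return Trace(self.t, self.v[:, iy, ix].astype(float))


@dataclass
class SaveSpec:
    """What run_simulation records: frame interval and full-rate probe sites."""

    dt_save: float = 5.0
    probes: Sequence = ()


def fiber_angle_elliptical(x0: float, y0: float) -> float:
    """Idealised elliptical fibre angle theta = arctan(-x0 / (4 y0)).

    Coordinates in mm, origin at the left-top corner.  On the singular line
    y0 = 0 the limit convention is theta = -(pi/2) sign(x0), and 0 at the
    origin.
    """
    if y0 == 0.0:
        return 0.0 if x0 == 0.0 else -np.pi / 2 * np.sign(x0)
    return float(np.arctan(-x0 / (4.0 * y0)))


def build_geometry(
    kind: str = "strand",
    n_nodes: int = 800,
    shape: Tuple[int, int] = (800, 800),
    dx: float = 0.15,
    d_par: float = 0.15,
    d_perp: Optional[float] = None,
    anisotropic: bool = False,
    fibers: str = "uniform",
    fiber_angle: float = 0.0,
) -> Geometry:
    """Construct a strand or sheet geometry with the full-scale defaults.

    Defaults: 1D strand of 800 nodes at dx 0.15 mm (120 mm) with D = 0.15
    mm^2/ms (a physiological ventricular conduction velocity); 2D sheet of
    800 x 800 nodes; anisotropic sheets use
    D_perp = D_par / 4 (the experimentally motivated 2:1 CV ratio).  Every
    size is overridable for scaled-down runs.
    """
    if kind == "strand":
        if n_nodes <= 0:
            raise ConfigError(f"n_nodes must be positive, got {n_nodes}")
        return Geometry(shape=(n_nodes,), dx=dx, d_par=d_par,
                        d_perp=d_par if d_perp is None else d_perp)
    if kind != "sheet":
        raise ConfigError(f"unknown geometry kind '{kind}' (strand|sheet)")
    ny, nx = shape
    if ny <= 0 or nx <= 0:
        raise ConfigError(f"non-positive sheet shape {shape}")
    if d_perp is None:
        d_perp = d_par / 4.0 if anisotropic else d_par
    angle = None
    if anisotropic:
        if fibers == "elliptical":
            ys, xs = np.mgrid[0:ny, 0:nx]
            angle = np.empty(shape)
            for iy in range(ny):
                for ix in range(nx):
                    angle[iy, ix] = fiber_angle_elliptical(xs[iy, ix] * dx,
                                                           ys[iy, ix] * dx)
        elif fibers == "uniform":
            angle = np.full(shape, fiber_angle)
        else:
            raise ConfigError(f"unknown fibre field '{fibers}'")
    return Geometry(shape=(ny, nx), dx=dx, d_par=d_par, d_perp=d_perp,
                    fiber_angle=angle)


def assign_dead_cells(g: Geometry, fraction: float, seed: int) -> Geometry:
    """Return a copy of g with round(fraction * N) random non-conducting nodes."""
    if not 0.0 <= fraction < 1.0:
        raise ConfigError(f"dead-cell fraction must be in [0, 1), got {fraction}")
    n_dead = int(round(fraction * g.n_nodes))
    rng = np.random.default_rng(seed)
    idx = rng.choice(g.n_nodes, size=n_dead, replace=False)
    mask = np.zeros(g.n_nodes, dtype=bool)
    mask[idx] = True
    return Geometry(shape=g.shape, dx=g.dx, d_par=g.d_par, d_perp=g.d_perp,
                    fiber_angle=g.fiber_angle, dead_mask=mask.reshape(g.shape))


# ---------------------------------------------------------------------------
# Discrete diffusion operator
# ---------------------------------------------------------------------------


def _laplacian_1d(g: Geometry) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Tridiagonal L (lower, diag, upper) for a strand; dead links removed."""
    n = g.shape[0]
    dead = g.dead_mask.ravel()
    cond = g.d_par / g.dx**2
    lo = np.zeros(n)
    di = np.zeros(n)
    up = np.zeros(n)
    for i in range(n - 1):
        if dead[i] or dead[i + 1]:
            continue
        up[i] += cond
        di[i] -= cond
        lo[i + 1] += cond
        di[i + 1] -= cond
    return lo, di, up


def _tensor_fields(g: Geometry):
    ny, nx = g.shape
    if g.fiber_angle is None:
        dxx = np.full(g.shape, g.d_par if g.isotropic else g.d_par)
        dyy = np.full(g.shape, g.d_perp)
        dxy = np.zeros(g.shape)
        if g.isotropic:
            dyy = np.full(g.shape, g.d_par)
        return dxx, dyy, dxy
    th = g.fiber_angle
    c, s = np.cos(th), np.sin(th)
    dxx = g.d_par * c**2 + g.d_perp * s**2
    dyy = g.d_par * s**2 + g.d_perp * c**2
    dxy = (g.d_par - g.d_perp) * c * s
    return dxx, dyy, dxy


def _laplacian_2d(g: Geometry) -> sp.csr_matrix:
    """Sparse L for a sheet: flux form, rotated tensor, cross terms averaged
    over face-adjacent nodes, no-flux at boundaries and at dead links."""
    ny, nx = g.shape
    n = ny * nx
    dead = g.dead_mask
    dxx, dyy, dxy = _tensor_fields(g)
    inv_h2 = 1.0 / g.dx**2
    rows, cols, vals = [], [], []

    def flat(iy, ix):
        return iy * nx + ix

    def add(r, c, v):
        rows.append(r)
        cols.append(c)
        vals.append(v)

    def cross_weights(iy, ix, axis):
        """Weights approximating the transverse derivative dV/d(axis) at a node,
        in units of 1/dx (one-sided at boundaries/dead neighbours)."""
        if axis == "y":
            up_ok = iy > 0 and not dead[iy - 1, ix]
            dn_ok = iy < ny - 1 and not dead[iy + 1, ix]
            upn, dnn = (iy - 1, ix), (iy + 1, ix)
        else:
            up_ok = ix > 0 and not dead[iy, ix - 1]
            dn_ok = ix < nx - 1 and not dead[iy, ix + 1]
            upn, dnn = (iy, ix - 1), (iy, ix + 1)
        w = {}
        if up_ok and dn_ok:
            w[flat(*dnn)] = 0.5
            w[flat(*upn)] = -0.5
        elif dn_ok:
            w[flat(*dnn)] = 1.0
            w[flat(iy, ix)] = -1.0
        elif up_ok:
            w[flat(iy, ix)] = 1.0
            w[flat(*upn)] = -1.0
        return w

    for iy in range(ny):
        for ix in range(nx):
            if dead[iy, ix]:
                continue
            # x-face to (iy, ix+1)
            if ix + 1 < nx and not dead[iy, ix + 1]:
                a, b = flat(iy, ix), flat(iy, ix + 1)
                cond = 0.5 * (dxx[iy, ix] + dxx[iy, ix + 1]) * inv_h2
                add(a, b, cond)
                add(a, a, -cond)
                add(b, a, cond)
                add(b, b, -cond)
                dxy_f = 0.5 * (dxy[iy, ix] + dxy[iy, ix + 1])
                if dxy_f != 0.0:
                    w = cross_weights(iy, ix, "y")
                    for col, wv in cross_weights(iy, ix + 1, "y").items():
                        w[col] = w.get(col, 0.0) + wv
                    for col, wv in w.items():
                        v = dxy_f * 0.5 * wv * inv_h2
                        add(a, col, v)
                        add(b, col, -v)
            # y-face to (iy+1, ix)
            if iy + 1 < ny and not dead[iy + 1, ix]:
                a, b = flat(iy, ix), flat(iy + 1, ix)
                cond = 0.5 * (dyy[iy, ix] + dyy[iy + 1, ix]) * inv_h2
                add(a, b, cond)
                add(a, a, -cond)
                add(b, a, cond)
                add(b, b, -cond)
                dxy_f = 0.5 * (dxy[iy, ix] + dxy[iy + 1, ix])
                if dxy_f != 0.0:
                    w = cross_weights(iy, ix, "x")
                    for col, wv in cross_weights(iy + 1, ix, "x").items():
                        w[col] = w.get(col, 0.0) + wv
                    for col, wv in w.items():
                        v = dxy_f * 0.5 * wv * inv_h2
                        add(a, col, v)
                        add(b, col, -v)

    return sp.csr_matrix(
        (vals, (rows, cols)), shape=(n, n)
    )


class DiffusionOperator:
    """The Crank-Nicolson pair (I - dt/2 L, I + dt/2 L) for a geometry."""

    def __init__(self, g: Geometry, dt: float):
        if dt <= 0:
            raise ConfigError(f"dt must be > 0, got {dt}")
        self.geometry = g
        self.dt = dt
        if g.ndim == 1:
            lo, di, up = _laplacian_1d(g)
            self.tridiag = (lo, di, up)
            self.imp = (-0.5 * dt * lo, 1.0 - 0.5 * dt * di, -0.5 * dt * up)
            self.exp = (0.5 * dt * lo, 1.0 + 0.5 * dt * di, 0.5 * dt * up)
            self.L = sp.diags([lo[1:], di, up[:-1]], offsets=[-1, 0, 1]).tocsr()
        else:
            L = _laplacian_2d(g)
            self.L = L
            n = L.shape[0]
            eye = sp.identity(n, format="csr")
            self.A_imp = (eye - 0.5 * dt * L).tocsc()
            self.A_exp = (eye + 0.5 * dt * L).tocsr()
            try:
                # the implicit matrix is SPD; the symmetric-pattern ordering
                # roughly halves the triangular-solve cost vs COLAMD, but it
                # degenerates badly on masks with isolated (dead) nodes
                permc = "COLAMD" if g.dead_mask.any() else "MMD_AT_PLUS_A"
                self._lu = spla.splu(self.A_imp, permc_spec=permc)
                self._solver = self._lu.solve
            except RuntimeError as exc:  # singular matrix
                raise ConfigError(f"implicit diffusion matrix not factorisable: {exc}")

    def apply_L(self, v: np.ndarray) -> np.ndarray:
        return self.L @ v.ravel()

    def diffuse(self, v: np.ndarray) -> np.ndarray:
        """One CN diffusion update of the (flattened) voltage field."""
        flat = v.ravel()
        if self.geometry.ndim == 1:
            el, ed, eu = self.exp
            rhs = ed * flat
            rhs[1:] += el[1:] * flat[:-1]
            rhs[:-1] += eu[:-1] * flat[1:]
            il, idg, iu = self.imp
            import scipy.linalg as sla

            ab = np.zeros((3, flat.size))
            ab[0, 1:] = iu[:-1]
            ab[1] = idg
            ab[2, :-1] = il[1:]
            out = sla.solve_banded((1, 1), ab, rhs)
        else:
            out = self._solver(self.A_exp @ flat)
        return out.reshape(v.shape)


def assemble_diffusion_operator(g: Geometry, dt: float) -> DiffusionOperator:
    """Build the CN implicit/explicit pair for geometry g at time step dt."""
    return DiffusionOperator(g, dt)


def step_tissue(
    model: CellModel,
    states: np.ndarray,
    op: DiffusionOperator,
    dt: float,
    stim_field: Optional[np.ndarray] = None,
) -> np.ndarray:
    """One operator-split step: per-node explicit reaction, then CN diffusion.

    ``states`` has shape (n_nodes, n_state); dead nodes are left untouched by
    the reaction and exchange no flux in the diffusion.
    """
    g = op.geometry
    n = g.n_nodes
    Y = states.reshape(n, model.n_state)
    ist = np.zeros(n) if stim_field is None else np.asarray(stim_field, float).ravel()
    dY = np.empty_like(Y)
    dead = g.dead_mask.ravel()
    _kernels.reaction_step(model.rhs_kernel, Y, ist, dY, dt, dead, model.params)
    v = op.diffuse(Y[:, 0])
    if not np.all(np.isfinite(v)):
        bad = int(np.flatnonzero(~np.isfinite(v))[0])
        raise NumericalBlowupError(f"non-finite V at node {bad}")
    Y[:, 0] = v
    return states


def _stim_indices(g: Geometry, site) -> np.ndarray:
    """Flat node indices for a stimulus site spec (slice-like or explicit)."""
    if site is None:
        return np.zeros(0, dtype=np.int64)
    arr = np.asarray(site)
    return arr.ravel().astype(np.int64)


def run_simulation(
    model: CellModel,
    g: Geometry,
    train,
    save: Optional[SaveSpec] = None,
    dt: float = 0.005,
    duration: Optional[float] = None,
    initial_states: Optional[np.ndarray] = None,
    t0: float = 0.0,
    reaction: bool = True,
    provenance: Optional[dict] = None,
) -> Tuple[SpaceTimeField, Dict]:
    """Run a paced tissue simulation and collect frames plus probe traces.

    ``train`` is a :class:`alternans.protocols.StimulusTrain` (or anything
    with the same fields).  Returns (field, probes) where ``probes`` maps
    each probe site to a full-time-resolution :class:`Trace`.  Deterministic
    given identical inputs.
    """
    save = save or SaveSpec()
    if duration is None:
        duration = train.onset + train.pcl * (train.count - 1) + max(
            2 * train.pcl, 400.0
        )
    n_steps = int(round(duration / dt))
    save_every = max(1, int(round(save.dt_save / dt)))
    stim_times = train.onset + train.pcl * np.arange(train.count)

    n = g.n_nodes
    if initial_states is None:
        Y0 = np.tile(model.initial_state, (n, 1))
    else:
        Y0 = initial_states.reshape(n, model.n_state).copy()
    dead = g.dead_mask.ravel()

    prov = dict(provenance or {})
    prov.setdefault("model", model.name)
    prov.setdefault("dt_ms", dt)
    prov.setdefault("dx_mm", g.dx)

    if g.ndim == 1:
        op = assemble_diffusion_operator(g, dt)
        if not reaction:
            raise ConfigError("pure-diffusion mode uses step-level API in 1D")
        lo_i, di_i, up_i = op.imp
        lo_e, di_e, up_e = op.exp
        probe_idx = np.asarray(
            [int(p) for p in save.probes], dtype=np.int64
        ) if len(save.probes) else np.zeros(0, dtype=np.int64)
        frames, probes_arr, _ = _kernels.run_fiber(
            model.rhs_kernel, Y0, model.params, dt, n_steps,
            lo_i, di_i, up_i, lo_e, di_e, up_e,
            dead, int(train.extent), stim_times.astype(float),
            float(train.pulse_duration), float(train.amplitude),
            save_every, probe_idx, t0,
        )
        field = SpaceTimeField(v=frames, dt_save=save_every * dt, dx=g.dx,
                               t0=t0, stim_times=stim_times, provenance=prov)
        tfull = t0 + np.arange(n_steps + 1) * dt
        probes = {
            int(p): Trace(tfull, probes_arr[:, k], {"node": int(p)})
            for k, p in enumerate(probe_idx)
        }
        return field, probes

    # --- 2D path -----------------------------------------------------------
    op = assemble_diffusion_operator(g, dt)
    stim_idx = _stim_indices(g, train.site)
    probe_flat = []
    nx = g.shape[1]
    for p in save.probes:
        if np.isscalar(p):
            probe_flat.append(int(p))
        else:
            probe_flat.append(int(p[0]) * nx + int(p[1]))
    Y = Y0
    dY = np.empty_like(Y)
    ist = np.zeros(n)
    n_frames = n_steps // save_every + 1
    frames = np.empty((n_frames, *g.shape), dtype=np.float32)
    frames[0] = Y[:, 0].reshape(g.shape).astype(np.float32)
    probes_arr = np.empty((n_steps + 1, len(probe_flat)))
    if probe_flat:
        probes_arr[0] = Y[probe_flat, 0]
    kf = 1
    stim_ptr = 0
    for step in range(n_steps):
        t = t0 + step * dt
        amp = 0.0
        while stim_ptr < len(stim_times) and t >= stim_times[stim_ptr] + train.pulse_duration:
            stim_ptr += 1
        if stim_ptr < len(stim_times) and stim_times[stim_ptr] <= t:
            amp = train.amplitude
        if reaction:
            if amp != 0.0 and stim_idx.size:
                ist[stim_idx] = amp
            _kernels.reaction_step(model.rhs_kernel, Y, ist, dY, dt, dead,
                                   model.params)
            if amp != 0.0 and stim_idx.size:
                ist[stim_idx] = 0.0
        Y[:, 0] = op._solver(op.A_exp @ Y[:, 0])
        if probe_flat:
            probes_arr[step + 1] = Y[probe_flat, 0]
        if (step + 1) % save_every == 0 and kf < n_frames:
            vv = Y[:, 0]
            if not np.isfinite(vv[0]) or not np.all(np.isfinite(vv)):
                bad = int(np.flatnonzero(~np.isfinite(vv))[0])
                raise NumericalBlowupError(f"non-finite V at node {bad}, t = {t:.2f} ms")
            frames[kf] = vv.reshape(g.shape).astype(np.float32)
            kf += 1
    field = SpaceTimeField(v=frames, dt_save=save_every * dt, dx=g.dx, t0=t0,
                           stim_times=stim_times, provenance=prov)
    tfull = t0 + np.arange(n_steps + 1) * dt
    probes = {
        tuple(p) if not np.isscalar(p) else int(p):
            Trace(tfull, probes_arr[:, k], {"node": p})
        for k, p in enumerate(save.probes)
    }
    return field, probes
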