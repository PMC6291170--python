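"""Cell-level electrophysiology.

The membrane obeys ``Cm dV/dt = -(I_ion + I_stim)`` with all currents
expressed per unit capacitance, so a negative stimulus depolarises.  The
headline model is the Luo-Rudy 1991 (LR91) biophysically detailed ventricular
myocyte — a Hodgkin-Huxley model whose fast sodium current has the classic
``I_Na = S_gNa * g_Na * m^3 * h * j * (V - E_Na)`` form — extended with two
knobs central to this package:

* ``s_gna``: dimensionless scaling of the macroscopic Na conductance
  (values < 1 mimic loss-of-function, > 1 gain-of-function channelopathies);
* ``delta_tau_h``: an increment (default 30 ms) added to the fast
  inactivation gate's time constant at potentials below ``v_mod_threshold``
  (default -70 mV), mimicking slowed sodium-channel recovery from
  inactivation as seen in some SCN5A-linked syndromes.  The slowed recovery
  widens the pacing-rate window that produces APD alternans.

A cheap three-variable minimal cell with the same interface lives in
:mod:`alternans.synthetic_data`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict

import numpy as np

from . import _kernels
from .errors import InstabilityError, InvalidStateError, NumericalBlowupError

__all__ = [
    "IonicState",
    "NaChannelParams",
    "CellModel",
    "Trace",
    "sodium_current",
    "modified_h_time_constant",
    "derivatives",
    "step_cell_fe",
    "luo_rudy_1991",
]


@dataclass
class NaChannelParams:
    """Fast sodium current parameters (conductance scaling and slowed recovery)."""

    g_na: float = 23.0
    s_gna: float = 1.0
    e_na: float = 54.4
    delta_tau_h: float = 0.0
    v_mod_threshold: float = -70.0

    def __post_init__(self) -> None:
        if self.s_gna < 0:
            raise InvalidStateError(f"s_gna must be >= 0, got {self.s_gna}")
        if self.delta_tau_h < 0:
            raise InvalidStateError(f"delta_tau_h must be >= 0, got {self.delta_tau_h}")


@dataclass
class IonicState:
    """Membrane potential plus gating variables and concentrations of one cell."""

    v: float
    gates: np.ndarray
    concentrations: np.ndarray

    def validate(self) -> None:
        if not np.isfinite(self.v) or not (-120.0 <= self.v <= 80.0):
            raise InvalidStateError(f"V = {self.v} mV outside valid range [-120, 80]")
        g = np.asarray(self.gates, dtype=float)
        if g.size and (g.min() < 0.0 or g.max() > 1.0):
            raise InvalidStateError(f"gate outside [0, 1]: {g}")

    def as_vector(self) -> np.ndarray:
        return np.concatenate(([self.v], self.gates, self.concentrations))


@dataclass
class CellModel:
    """A pluggable ionic model.

    ``rhs_kernel`` is a compiled function ``(Y, i_stim, dY, params)`` operating
    on ``(n_cells, n_state)`` arrays; ``currents_fn`` maps a state vector to
    named current densities (must include ``I_Na`` and ``I_CaL``).
    """

    name: str
    state_names: tuple
    cm: float
    initial_state: np.ndarray
    params: np.ndarray
    rhs_kernel: Callable
    currents_fn: Callable[[np.ndarray], Dict[str, float]]
    n_gates: int
    n_concentrations: int
    v_rest: float
    rest_tol: float = 1e-6
    na: NaChannelParams = field(default_factory=NaChannelParams)

    @property
    def n_state(self) -> int:
        return len(self.state_names)

    def state(self, y: np.ndarray) -> IonicState:
        y = np.asarray(y, dtype=float)
        return IonicState(
            v=float(y[0]),
            gates=y[1 : 1 + self.n_gates].copy(),
            concentrations=y[1 + self.n_gates :].copy(),
        )

    def rhs(self, y: np.ndarray, i_stim: float = 0.0) -> np.ndarray:
        """Time derivatives of the full state vector at (y, I_stim)."""
        Y = np.atleast_2d(np.asarray(y, dtype=float))
        dY = np.empty_like(Y)
        self.rhs_kernel(Y, np.array([float(i_stim)]), dY, self.params)
        return dY[0]

    def currents(self, y: np.ndarray) -> Dict[str, float]:
        return self.currents_fn(np.asarray(y, dtype=float))


# Simple full-resolution voltage trace container used by protocols/biomarkers.
@dataclass
class Trace:
    t: np.ndarray
    v: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.t.shape != self.v.shape:
            raise InvalidStateError("trace t and v must have equal shapes")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0]) if self.t.size > 1 else np.nan


def sodium_current(v: float, m: float, h: float, j: float, p: NaChannelParams) -> float:
    """Fast sodium current density (inward negative)."""
    for name, g in (("m", m), ("h", h), ("j", j)):
        if not 0.0 <= g <= 1.0:
            raise InvalidStateError(f"gate {name} = {g} outside [0, 1]")
    return p.s_gna * p.g_na * m**3 * h * j * (v - p.e_na)


def modified_h_time_constant(v: float, tau_h_base: float, p: NaChannelParams) -> float:
    """h-gate time constant with the slowed-recovery increment below threshold."""
    if tau_h_base <= 0:
        raise InvalidStateError(f"tau_h_base must be > 0, got {tau_h_base}")
    if v < p.v_mod_threshold:
        return tau_h_base + p.delta_tau_h
    return tau_h_base


def derivatives(model: CellModel, y: np.ndarray, i_stim: float = 0.0) -> np.ndarray:
    """State derivative; raises if any component is non-finite."""
    dy = model.rhs(y, i_stim)
    if not np.all(np.isfinite(dy)):
        bad = int(np.flatnonzero(~np.isfinite(dy))[0])
        raise NumericalBlowupError(
            f"non-finite derivative for state variable '{model.state_names[bad]}'"
        )
    return dy


def step_cell_fe(model: CellModel, y: np.ndarray, i_stim: float, dt: float) -> np.ndarray:
    """One explicit (forward-Euler) update of all state variables."""
    if dt <= 0:
        raise InvalidStateError(f"dt must be > 0, got {dt}")
    y1 = np.asarray(y, dtype=float) + dt * derivatives(model, y, i_stim)
    gates = y1[1 : 1 + model.n_gates]
    if gates.size and (gates.min() < -0.01 or gates.max() > 1.01):
        bad = int(np.argmax((gates < -0.01) | (gates > 1.01)))
        raise InstabilityError(
            f"gate '{model.state_names[1 + bad]}' left [0, 1] after an explicit "
            f"update (dt = {dt} ms); use a smaller dt"
        )
    return y1


# ---------------------------------------------------------------------------
# Luo-Rudy 1991
# ---------------------------------------------------------------------------

LR91_STATE_NAMES = ("V", "m", "h", "j", "d", "f", "X", "Cai")

# Quiescent steady states, computed by integrating the resting model to
# equilibrium (100 s, dt = 0.005 ms) and frozen here: one for the default
# short-APD restitution variant, one for the unmodified published model.
_LR91_REST = np.array(
    [
        -8.4617598059446195e+01,
        1.6470260790649161e-03,
        9.8356221374512542e-01,
        9.8967951969896661e-01,
        2.9597472153087201e-03,
        9.9998148713192792e-01,
        5.6044481090973715e-03,
        1.4562141912324405e-04,
    ]
)
_LR91_REST_CLASSIC = np.array(
    [
        -8.4547437141301344e+01,
        1.6663618963929207e-03,
        9.8330380841799159e-01,
        9.8952285115227945e-01,
        2.9773347622098845e-03,
        9.9998124129433019e-01,
        5.6432283011966893e-03,
        1.7836052747744962e-04,
    ]
)


def _lr91_currents(y: np.ndarray, p: np.ndarray) -> Dict[str, float]:
    v, m, h, j, d, f, x, cai = y
    i_na = p[0] * p[1] * m**3 * h * j * (v - p[2])
    e_si = 7.7 - 13.0287 * np.log(cai)
    i_si = 0.09 * p[5] * d * f * (v - e_si)
    xv = v + 77.0
    if abs(xv) < 1e-7:
        xi = 2.837 * 0.04 / np.exp(0.04 * (v + 35.0))
    elif v > -100.0:
        xi = 2.837 * (np.exp(0.04 * xv) - 1.0) / (xv * np.exp(0.04 * (v + 35.0)))
    else:
        xi = 1.0
    i_k = 0.282 * p[6] * x * xi * (v - _kernels.LR91_EK)
    ek1 = _kernels.LR91_EK1
    a_k1 = 1.02 / (1.0 + np.exp(0.2385 * (v - ek1 - 59.215)))
    b_k1 = (
        0.49124 * np.exp(0.08032 * (v - ek1 + 5.476))
        + np.exp(0.06175 * (v - ek1 - 594.31))
    ) / (1.0 + np.exp(-0.5143 * (v - ek1 + 4.753)))
    i_k1 = 0.6047 * (a_k1 / (a_k1 + b_k1)) * (v - ek1)
    kp = 1.0 / (1.0 + np.exp((7.488 - v) / 5.98))
    i_kp = 0.0183 * kp * (v - ek1)
    i_b = 0.03921 * (v + 59.87)
    return {
        "I_Na": float(i_na),
        "I_CaL": float(i_si),  # the slow inward Ca current plays the I_CaL role
        "I_K": float(i_k),
        "I_K1": float(i_k1),
        "I_Kp": float(i_kp),
        "I_b": float(i_b),
    }


def luo_rudy_1991(
    s_gna: float = 1.0,
    delta_tau_h: float = 30.0,
    v_mod_threshold: float = -70.0,
    g_si_scale: float = 0.578,
    g_k_scale: float = 1.2,
    ca_gate_speed: float = 1.0,
) -> CellModel:
    """Detailed ventricular myocyte (Luo & Rudy 1991) with slowed Na recovery.

    Defaults give the package's modified cell: control Na conductance
    (``s_gna = 1``), a 30 ms increment of the h-gate time constant below
    -70 mV, and a short-APD restitution variant in the spirit of the
    modified-LR91 alternans/spiral-breakup literature (slow inward
    conductance 0.052 mS/uF, G_K scaled 1.2x), which shortens the APD so
    the diastolic interval at pacing cycle lengths of 180-210 ms becomes
    comparable to the slowed h-gate recovery time; the cell then shows a
    period-doubling (alternans) cascade inside that window and 2:1 capture
    below it.  Pass ``delta_tau_h=0``,
    ``g_si_scale=1``, ``g_k_scale=1``, ``ca_gate_speed=1`` for the
    unmodified published model.
    """
    na = NaChannelParams(
        g_na=23.0,
        s_gna=s_gna,
        e_na=54.4,
        delta_tau_h=delta_tau_h,
        v_mod_threshold=v_mod_threshold,
    )
    params = np.array(
        [na.s_gna, na.g_na, na.e_na, na.delta_tau_h, na.v_mod_threshold,
         g_si_scale, g_k_scale, ca_gate_speed]
    )
    classic = g_si_scale == 1.0 and g_k_scale == 1.0 and ca_gate_speed == 1.0
    rest = _LR91_REST_CLASSIC if classic else _LR91_REST
    return CellModel(
        name="lr91",
        state_names=LR91_STATE_NAMES,
        cm=1.0,
        initial_state=rest.copy(),
        params=params,
        rhs_kernel=_kernels.lr91_rhs,
        currents_fn=lambda y: _lr91_currents(y, params),
        n_gates=6,
        n_concentrations=1,
        v_rest=float(_LR91_REST[0]),
        na=na,
    )
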