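"""Stimulation protocols: steady-state pacing, S1-S2 restitution, ERP search
and stimulus placement.

"Supra-threshold" is quantified as twice the diastolic capture threshold of
the cell model, found once by bisection at rest with the standard 2 ms
pulse; the value used is recorded in protocol results.  The stimulus sign
convention follows the membrane equation: negative current depolarises.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import _kernels
from .biomarkers import APDSeries, RestitutionCurve, detect_activations, measure_beats
from .errors import ConfigError, InvalidStateError
from .ionic_models import CellModel, Trace
from .tissue_solver import Geometry

__all__ = [
    "StimulusTrain",
    "SteadyStateResult",
    "capture_threshold",
    "supra_threshold_amplitude",
    "pace_cell",
    "steady_state_protocol",
    "s1s2_protocol",
    "erp_search",
    "place_stimulus",
]

NO_CAPTURE = float("inf")
"""Sentinel returned by erp_search when no interval up to the PCL captures."""


@dataclass
class StimulusTrain:
    """A periodic train of rectangular current pulses."""

    amplitude: float              # current density; negative = depolarising
    pulse_duration: float = 2.0   # ms
    pcl: float = 800.0            # ms
    count: int = 20
    onset: float = 10.0           # ms, time of first pulse
    extent: int = 5               # strand: first k nodes (single cell: 1)
    site: Optional[np.ndarray] = None  # explicit flat node indices (sheet)

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ConfigError(f"count must be >= 1, got {self.count}")
        if self.pulse_duration >= self.pcl:
            raise ConfigError(
                f"pulse_duration {self.pulse_duration} must be < pcl {self.pcl}"
            )

    @property
    def times(self) -> np.ndarray:
        return self.onset + self.pcl * np.arange(self.count)


_threshold_cache: Dict[bytes, float] = {}


def _run_cell(model, y0, t0, dt, n_steps, onsets, dur, amp, trace_every=10):
    tr, yf = _kernels.run_cell(
        model.rhs_kernel, np.asarray(y0, float), model.params, dt, n_steps,
        np.asarray(onsets, float), float(dur), float(amp), trace_every, t0,
    )
    t = t0 + np.arange(tr.shape[0]) * dt * trace_every
    return Trace(t, tr[:, 0]), tr, yf


def capture_threshold(
    model: CellModel,
    dt: float = 0.005,
    pulse_duration: float = 2.0,
    hi: float = 200.0,
    tol: float = 0.25,
) -> float:
    """Diastolic capture threshold magnitude, by bisection from rest.

    Returns the smallest pulse magnitude (to within ``tol``) whose 2 ms
    application at rest evokes an AP overshooting 0 mV.
    """
    key = model.params.tobytes() + np.float64([dt, pulse_duration]).tobytes()
    if key in _threshold_cache:
        return _threshold_cache[key]
    lo = 0.0
    n_steps = int(round(80.0 / dt))
    onsets = np.array([5.0])
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        trace, _, _ = _run_cell(model, model.initial_state, 0.0, dt, n_steps,
                                onsets, pulse_duration, -mid)
        if trace.v.max() > 0.0:
            hi = mid
        else:
            lo = mid
    _threshold_cache[key] = hi
    return hi


def supra_threshold_amplitude(model: CellModel, factor: float = 2.0, **kw) -> float:
    """Signed stimulus amplitude at ``factor`` times the capture threshold."""
    return -factor * capture_threshold(model, **kw)


def pace_cell(
    model: CellModel,
    pcl: float,
    n_beats: int,
    amplitude: Optional[float] = None,
    dt: float = 0.005,
    pulse_duration: float = 2.0,
    onset: float = 10.0,
    tail: Optional[float] = None,
    trace_every: int = 10,
    y0: Optional[np.ndarray] = None,
    t0: float = 0.0,
    extra_onsets: Sequence[float] = (),
) -> Tuple[Trace, np.ndarray, np.ndarray]:
    """Pace a single cell; returns (trace, full state trace, final state)."""
    if amplitude is None:
        amplitude = supra_threshold_amplitude(model, dt=dt,
                                              pulse_duration=pulse_duration)
    if tail is None:
        tail = max(pcl, 400.0)
    onsets = np.sort(np.concatenate(
        [t0 + onset + pcl * np.arange(n_beats), np.asarray(extra_onsets, float)]
    ))
    duration = (onsets[-1] - t0) + tail if onsets.size else tail
    n_steps = int(round(duration / dt))
    y0 = model.initial_state if y0 is None else y0
    return _run_cell(model, y0, t0, dt, n_steps, onsets, pulse_duration,
                     amplitude, trace_every)


@dataclass
class SteadyStateResult:
    """Outcome of the fixed-PCL steady-state pacing protocol."""

    trace: Trace
    series: APDSeries
    stim_times: np.ndarray
    last_two_apd: Tuple[float, float]
    failed_stimuli: List[float] = field(default_factory=list)
    amplitude: float = np.nan

    @property
    def alternating(self) -> bool:
        a, b = self.last_two_apd
        return np.isfinite(a) and np.isfinite(b) and abs(a - b) > 1.0


def steady_state_protocol(
    model: CellModel,
    pcl: float,
    n_beats: int = 20,
    dt: float = 0.005,
    amplitude: Optional[float] = None,
    trace_every: int = 10,
) -> SteadyStateResult:
    """Fixed-PCL pacing to steady state; records the final two APs.

    Stimuli that fail to evoke a regenerative AP are flagged (needed in 2:1
    regimes) but are not an error.  The last two *measured* APDs feed the
    alternans analysis.
    """
    trace, _, _ = pace_cell(model, pcl, n_beats, amplitude, dt,
                            trace_every=trace_every)
    series = measure_beats(trace)
    stim_times = 10.0 + pcl * np.arange(n_beats)
    failed = [
        float(s) for s in stim_times
        if not np.any((series.activation_time >= s)
                      & (series.activation_time < s + 20.0))
    ]
    finite = series.apd90[np.isfinite(series.apd90)]
    if finite.size >= 2:
        pair = (float(finite[-2]), float(finite[-1]))
    elif finite.size == 1:
        pair = (float(finite[-1]), np.nan)
    else:
        pair = (np.nan, np.nan)
    amp = amplitude if amplitude is not None else supra_threshold_amplitude(model, dt=dt)
    return SteadyStateResult(trace, series, stim_times, pair, failed, amp)


def _s1_snapshot(model, s1_pcl, n_s1, dt, amplitude):
    """State at the onset of the last S1 stimulus, plus that onset time."""
    t_last = 10.0 + s1_pcl * (n_s1 - 1)
    n_steps = int(round(t_last / dt))
    onsets = 10.0 + s1_pcl * np.arange(n_s1 - 1)
    _, _, y = _run_cell(model, model.initial_state, 0.0, dt, n_steps, onsets,
                        2.0, amplitude, max(1, n_steps))
    return y, t_last


def s1s2_protocol(
    model: CellModel,
    s1_pcl: float = 800.0,
    n_s1: int = 20,
    di_list: Sequence[float] = (400, 300, 250, 200, 150, 120, 100, 80, 60, 50,
                                40, 30, 25, 20, 15, 10, 5),
    dt: float = 0.005,
    amplitude: Optional[float] = None,
) -> RestitutionCurve:
    """APD restitution by the S1-S2 protocol.

    After 20 S1 beats at ``s1_pcl`` an S2 is delivered at each diastolic
    interval (measured from 90% repolarisation of the last S1 AP); the
    S2-evoked APD90 is recorded.  Non-captured S2s are kept in the curve but
    flagged, and excluded from slope computation.
    """
    if not np.all(np.diff(di_list) < 0):
        di_list = sorted(di_list, reverse=True)
    if amplitude is None:
        amplitude = supra_threshold_amplitude(model, dt=dt)
    y_snap, t_last = _s1_snapshot(model, s1_pcl, n_s1, dt, amplitude)

    # reference branch: last S1 beat alone, to time its repolarisation
    n_ref = int(round(700.0 / dt))
    trace, _, _ = _run_cell(model, y_snap, t_last, dt, n_ref,
                            np.array([t_last]), 2.0, amplitude)
    ref = measure_beats(trace)
    if len(ref) == 0 or not np.isfinite(ref.apd90[0]):
        raise InvalidStateError("last S1 beat not measurable; check amplitude")
    t_repol = ref.activation_time[0] + ref.apd90[0]

    dis, apds, captured = [], [], []
    for di in di_list:
        t_s2 = t_repol + di
        n_steps = int(round((t_s2 - t_last + 600.0) / dt))
        tr, _, _ = _run_cell(model, y_snap, t_last, dt, n_steps,
                             np.array([t_last, t_s2]), 2.0, amplitude)
        ser = measure_beats(tr)
        s2_beats = ser.activation_time >= t_s2 - 1.0
        dis.append(di)
        if np.any(s2_beats) and np.nanmax(ser.peak_v[s2_beats]) > 0.0:
            k = int(np.flatnonzero(s2_beats)[0])
            apds.append(ser.apd90[k])
            captured.append(np.isfinite(ser.apd90[k]))
        else:
            apds.append(np.nan)
            captured.append(False)
    return RestitutionCurve(np.array(dis), np.array(apds), protocol="s1s2",
                            kind="apd", captured=np.array(captured))


def erp_search(
    model: CellModel,
    conditioning_pcl: float,
    resolution: float = 1.0,
    n_s1: int = 20,
    dt: float = 0.005,
    amplitude: Optional[float] = None,
    refine: bool = False,
    coarse_step: float = 10.0,
) -> float:
    """Effective refractory period after steady pacing at ``conditioning_pcl``.

    Descending scan of the S1-S2 interval (coarse step first, then
    ``resolution``): the ERP is the smallest interval whose S2 evokes an AP
    overshooting 0 mV at the stimulated cell.  Returns the NO_CAPTURE
    sentinel when nothing up to the PCL captures.  ``refine=True`` adds a
    final bisection to 0.1 ms.
    """
    if resolution <= 0:
        raise ConfigError(f"resolution must be > 0, got {resolution}")
    if amplitude is None:
        amplitude = supra_threshold_amplitude(model, dt=dt)
    y_snap, t_last = _s1_snapshot(model, conditioning_pcl, n_s1, dt, amplitude)

    def captures(interval: float) -> bool:
        t_s2 = t_last + interval
        n_steps = int(round((interval + 400.0) / dt))
        tr, _, _ = _run_cell(model, y_snap, t_last, dt, n_steps,
                             np.array([t_last, t_s2]), 2.0, amplitude)
        ups = detect_activations(tr)
        ups = ups[ups >= t_s2]
        if ups.size == 0:
            return False
        i = int(round((ups[0] - tr.t[0]) / tr.dt))
        return bool(np.max(tr.v[i : i + int(60.0 / tr.dt)]) > 0.0)

    if not captures(conditioning_pcl):
        return NO_CAPTURE
    # coarse descending scan
    lo = conditioning_pcl
    iv = conditioning_pcl - coarse_step
    while iv > 0 and captures(iv):
        lo = iv
        iv -= coarse_step
    # fine descending scan from the last capturing coarse interval
    erp = lo
    iv = lo - resolution
    while iv > 0 and captures(iv):
        erp = iv
        iv -= resolution
    if refine:
        hi_f, lo_f = erp, max(erp - resolution, 0.0)
        while hi_f - lo_f > 0.1:
            mid = 0.5 * (hi_f + lo_f)
            if captures(mid):
                hi_f = mid
            else:
                lo_f = mid
        erp = hi_f
    return float(erp)


def place_stimulus(g: Geometry, mode: str, extent: int) -> np.ndarray:
    """Flat node indices of the stimulated region.

    ``strand_end``: first ``extent`` nodes.  ``sheet_corner``: square block
    of side ``extent`` at the left-bottom corner (row index grows downward,
    so the bottom rows are the last ones).
    """
    if extent < 1:
        raise ConfigError(f"stimulus extent must be >= 1 node, got {extent}")
    if mode == "strand_end":
        if g.ndim != 1 or extent > g.shape[0]:
            raise ConfigError("strand_end needs a 1D geometry with extent <= n_nodes")
        return np.arange(extent, dtype=np.int64)
    if mode == "sheet_corner":
        if g.ndim != 2:
            raise ConfigError("sheet_corner needs a 2D geometry")
        ny, nx = g.shape
        if extent > ny or extent > nx:
            raise ConfigError(f"extent {extent} exceeds sheet {g.shape}")
        iy, ix = np.mgrid[ny - extent : ny, 0:extent]
        return (iy * nx + ix).ravel().astype(np.int64)
    raise ConfigError(f"unknown stimulus mode '{mode}' (strand_end|sheet_corner)")
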