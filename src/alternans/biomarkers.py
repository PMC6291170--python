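"""Trace- and field-level measurements: activations, APD90, DI, dV/dt_max,
conduction velocity, restitution curves and the alternans bifurcation point.

Definitions (package-wide):

* upstroke time = instant of maximal dV/dt of a beat;
* APD90 = time from the upstroke to the first downward crossing of
  ``peak - 0.9 * (peak - takeoff)``, where takeoff is V at the upstroke
  instant (levels interpolated linearly between samples);
* DI = next activation time - (activation time + APD90);
* CV = distance / activation-time difference between two probe nodes,
  reported in cm/s.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, InvalidStateError
from .ionic_models import Trace
from .tissue_solver import SpaceTimeField

__all__ = [
    "APDSeries",
    "RestitutionCurve",
    "detect_activations",
    "apd90",
    "measure_beats",
    "conduction_velocity",
    "cv_from_activation_times",
    "max_restitution_slope",
    "bifurcation_point",
    "alternans_magnitudes",
]


@dataclass
class APDSeries:
    """Per-beat measurements of one trace (times ms, dV/dt mV/ms, V mV)."""

    activation_time: np.ndarray
    apd90: np.ndarray           # NaN where censored
    di: np.ndarray              # NaN for last beat / censored
    dvdt_max: np.ndarray
    peak_v: np.ndarray

    def __len__(self) -> int:
        return len(self.activation_time)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "activation_time_ms": self.activation_time,
                "apd90_ms": self.apd90,
                "di_ms": self.di,
                "dvdt_max_mV_per_ms": self.dvdt_max,
                "peak_V_mV": self.peak_v,
            }
        )


@dataclass
class RestitutionCurve:
    """(DI or PCL) vs (APD or CV) pairs from one protocol."""

    x: np.ndarray
    y: np.ndarray
    protocol: str = "s1s2"          # or "steady_state"
    kind: str = "apd"               # or "cv"
    captured: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        order = np.argsort(self.x)
        self.x = np.asarray(self.x, float)[order]
        self.y = np.asarray(self.y, float)[order]
        if self.captured is None:
            self.captured = np.isfinite(self.y)
        else:
            self.captured = np.asarray(self.captured, bool)[order]

    @property
    def max_slope(self) -> float:
        return max_restitution_slope(self)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"x_ms": self.x, "y": self.y, "captured": self.captured})


def detect_activations(
    trace: Trace,
    dvdt_threshold: float = 10.0,
    cross_level: float = 0.0,
    lockout: float = 5.0,
    cross_window: float = 30.0,
) -> np.ndarray:
    """Upstroke times of regenerative APs in a uniformly sampled trace.

    An activation is a local maximum of dV/dt exceeding ``dvdt_threshold``
    whose take-off potential lies below ``cross_level`` and whose V crosses
    ``cross_level`` within ``cross_window`` ms.  Sub-threshold stimulus
    artifacts fail one of the two voltage conditions.  A refractory lockout
    suppresses re-detection within ``lockout`` ms.
    """
    t, v = trace.t, trace.v
    if len(t) < 3:
        return np.zeros(0)
    dt = t[1] - t[0]
    dv = np.gradient(v, dt)
    above = dv > dvdt_threshold
    n = len(t)
    win = max(1, int(round(cross_window / dt)))
    # contiguous suprathreshold stretches of dV/dt
    edges = np.flatnonzero(np.diff(above.astype(np.int8)))
    starts = edges[::2] + 1 if not above[0] else np.r_[0, edges[1::2] + 1]
    out = []
    last = -np.inf
    for s in starts:
        e = s
        while e < n and above[e]:
            e += 1
        j = s + int(np.argmax(dv[s:e]))
        takeoff = v[max(s - 1, 0)]
        if (
            t[j] - last >= lockout
            and takeoff < cross_level
            and np.max(v[j : min(n, j + win)]) >= cross_level
        ):
            out.append(t[j])
            last = t[j]
    return np.asarray(out)


def apd90(
    trace: Trace,
    activation: float,
    next_activation: Optional[float] = None,
    repol_fraction: float = 0.9,
    amplitude_ref: str = "takeoff",
    resting_v: Optional[float] = None,
) -> float:
    """APD at ``repol_fraction`` repolarisation for one detected beat.

    Returns NaN (censored) when the repolarisation level is not reached
    before the next activation / end of trace.  ``amplitude_ref`` selects
    the amplitude baseline: the per-beat diastolic take-off potential just
    before the upstroke (default, robust under alternans where the take-off
    varies beat to beat) or a fixed resting potential.
    """
    t, v = trace.t, trace.v
    dt = t[1] - t[0]
    i0 = int(round((activation - t[0]) / dt))
    i0 = max(0, min(i0, len(t) - 1))
    i_end = len(t) if next_activation is None else max(
        i0 + 1, int(round((next_activation - t[0]) / dt))
    )
    seg = v[i0:i_end]
    if seg.size < 3:
        return np.nan
    i_peak = int(np.argmax(seg))
    peak = seg[i_peak]
    if amplitude_ref == "takeoff":
        # diastolic potential immediately before the upstroke; the sample at
        # the maximal-dV/dt instant already sits mid-upstroke
        w = max(1, int(round(3.0 / dt)))
        base = float(np.min(v[max(i0 - w, 0) : i0 + 1]))
    elif amplitude_ref == "resting":
        if resting_v is None:
            raise InvalidStateError("resting_v required for amplitude_ref='resting'")
        base = resting_v
    else:
        raise InvalidStateError(f"unknown amplitude_ref '{amplitude_ref}'")
    level = peak - repol_fraction * (peak - base)
    below = np.flatnonzero(seg[i_peak:] <= level)
    if below.size == 0:
        return np.nan
    k = i_peak + below[0]
    if k == 0:
        return 0.0
    # linear interpolation between samples k-1 and k
    v1, v2 = seg[k - 1], seg[k]
    frac = 0.0 if v1 == v2 else (v1 - level) / (v1 - v2)
    return (k - 1 + frac) * dt + t[i0] - activation


def measure_beats(
    trace: Trace,
    dvdt_threshold: float = 10.0,
    cross_level: float = 0.0,
    **apd_kwargs,
) -> APDSeries:
    """Detect all beats of a trace and measure APD90/DI/dV/dt_max/peak."""
    ups = detect_activations(trace, dvdt_threshold, cross_level)
    t, v = trace.t, trace.v
    dt = t[1] - t[0]
    dv = np.gradient(v, dt)
    n = len(ups)
    apd = np.full(n, np.nan)
    di = np.full(n, np.nan)
    dvdt = np.full(n, np.nan)
    peak = np.full(n, np.nan)
    for k, up in enumerate(ups):
        nxt = ups[k + 1] if k + 1 < n else None
        apd[k] = apd90(trace, up, nxt, **apd_kwargs)
        i0 = int(round((up - t[0]) / dt))
        i1 = len(t) if nxt is None else int(round((nxt - t[0]) / dt))
        dvdt[k] = np.max(dv[max(0, i0 - 2) : i0 + 3])
        peak[k] = np.max(v[i0:i1])
        if nxt is not None and np.isfinite(apd[k]):
            di[k] = nxt - (up + apd[k])
    return APDSeries(ups, apd, di, dvdt, peak)


def cv_from_activation_times(
    t_a: np.ndarray, t_b: np.ndarray, distance_mm: float
) -> np.ndarray:
    """Per-beat CV (cm/s) from paired activation times at two sites."""
    t_a = np.asarray(t_a, float)
    t_b = np.asarray(t_b, float)
    dt = t_b - t_a
    out = np.full(dt.shape, np.nan)
    ok = np.isfinite(dt) & (dt > 0)
    out[ok] = (distance_mm / dt[ok]) * 100.0  # mm/ms -> cm/s
    return out


def _pair_activations(t_a: np.ndarray, t_b: np.ndarray, max_delay: float):
    """Match each proximal activation to the first distal one within max_delay."""
    pairs = np.full(len(t_a), np.nan)
    for k, ta in enumerate(t_a):
        upper = t_a[k + 1] if k + 1 < len(t_a) else np.inf
        cand = t_b[(t_b > ta) & (t_b < min(ta + max_delay, upper + max_delay))]
        if cand.size:
            pairs[k] = cand[0]
    return pairs


def conduction_velocity(
    field: SpaceTimeField,
    node_a: int = 25,
    node_b: int = 75,
    dvdt_threshold: float = 10.0,
    max_delay: float = 100.0,
) -> np.ndarray:
    """Per-beat conduction velocity along a strand between two probe nodes.

    Waves must travel from low to high node index (strand pacing at node 0);
    a negative delay raises InvalidStateError.  Beats whose wavefront never
    reaches node_b produce NaN (conduction failure).
    """
    tr_a = field.node_trace(node_a)
    tr_b = field.node_trace(node_b)
    t_a = detect_activations(tr_a, dvdt_threshold)
    t_b = detect_activations(tr_b, dvdt_threshold)
    if t_a.size == 0:
        return np.zeros(0)
    paired = _pair_activations(t_a, t_b, max_delay)
    delays = paired - t_a
    if np.any(delays[np.isfinite(delays)] <= 0):
        raise InvalidStateError(
            "non-positive conduction delay: retrograde or simultaneous activation"
        )
    return cv_from_activation_times(t_a, paired, (node_b - node_a) * field.dx)


def max_restitution_slope(curve: RestitutionCurve) -> float:
    """Maximum finite-difference slope of a restitution curve.

    Centered differences over interior points, one-sided at the endpoints;
    requires at least 3 captured points.
    """
    x = curve.x[curve.captured]
    y = curve.y[curve.captured]
    if x.size < 3:
        raise InsufficientDataError(
            f"need >= 3 captured points for a slope, got {x.size}"
        )
    slopes = [(y[1] - y[0]) / (x[1] - x[0])]
    for i in range(1, x.size - 1):
        slopes.append((y[i + 1] - y[i - 1]) / (x[i + 1] - x[i - 1]))
    slopes.append((y[-1] - y[-2]) / (x[-1] - x[-2]))
    return float(np.max(slopes))


def bifurcation_point(
    pcls: Sequence[float],
    apd_pairs: Sequence,
    epsilon: float = 1.0,
) -> Optional[float]:
    """Largest PCL whose steady-state last-two APDs differ by more than epsilon.

    ``apd_pairs[i]`` holds the last two APDs measured at ``pcls[i]``; pairs
    containing NaN (loss of 1:1 capture) are ignored.  Returns None when no
    PCL alternates.
    """
    best = None
    for pcl, pair in zip(pcls, apd_pairs):
        a, b = pair
        if not (np.isfinite(a) and np.isfinite(b)):
            continue
        if abs(a - b) > epsilon:
            best = pcl if best is None else max(best, pcl)
    return best


def alternans_magnitudes(
    series_by_pcl: Dict[float, APDSeries],
    epsilon: float = 1.0,
    n_last: int = 6,
) -> Dict[str, float]:
    """Beat-to-beat alternans amplitudes over the alternating PCL range.

    For each PCL whose trailing beats alternate (|successive APD difference|
    > epsilon), collect the |large - small| differences of APD and dV/dt_max;
    report their max and mean across the whole range.  Empty dict when no
    PCL alternates.
    """
    d_apd, d_dvdt = [], []
    for pcl, ser in series_by_pcl.items():
        apd = ser.apd90[-n_last:]
        dvdt = ser.dvdt_max[-n_last:]
        ok = np.isfinite(apd)
        if ok.sum() < 2:
            continue
        diffs = np.abs(np.diff(apd[ok]))
        if diffs.size and np.all(diffs > epsilon):
            d_apd.extend(diffs)
            d_dvdt.extend(np.abs(np.diff(dvdt[ok])))
    if not d_apd:
        return {}
    return {
        "max_delta_apd": float(np.max(d_apd)),
        "mean_delta_apd": float(np.mean(d_apd)),
        "max_delta_dvdt": float(np.max(d_dvdt)),
        "mean_delta_dvdt": float(np.mean(d_dvdt)),
    }
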