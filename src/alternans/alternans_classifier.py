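"""Strand-level alternans classification.

Turns a paced 1D space-time voltage field into beat-resolved APD maps and a
concordant / discordant / block label, locates APD nodes (the singularity
points separating out-of-phase regions), measures the diastolic interval at
a conduction-block site, and sweeps the PCL x S_gNa plane into a phase map.

Label rules (applied in order, after dropping a pacing transient):

1. *block*    — some delivered beat's wavefront never reaches the distal
   probe node (N - distal_margin);
2. *discordant* — the beat-to-beat APD difference has opposite signs at two
   nodes (both above epsilon in magnitude);
3. *concordant* — alternation of uniform sign somewhere above epsilon; a
   non-alternating run is folded into *concordant* for the three-way map
   (the four-way sub-label is retained).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .biomarkers import apd90, detect_activations
from .errors import ConfigError, InsufficientDataError, NotApplicableError
from .ionic_models import Trace
from .tissue_solver import SpaceTimeField

__all__ = [
    "APDField",
    "ClassificationResult",
    "PhaseMap",
    "build_apd_field",
    "classify_strand",
    "locate_nodes",
    "block_site_di",
    "phase_map",
]


@dataclass
class APDField:
    """Per-beat, per-node activation times and APD90 for a strand run."""

    apd: np.ndarray          # (n_beats, n_nodes), ms; NaN where missing
    activation: np.ndarray   # (n_beats, n_nodes), ms; NaN where missing
    stim_times: np.ndarray   # (n_beats,), ms
    dx: float = 0.15         # mm

    @property
    def n_beats(self) -> int:
        return self.apd.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.apd.shape[1]


@dataclass
class ClassificationResult:
    label: str                                 # concordant | discordant | block
    sub_label: str                             # adds "no_alternans"
    node_positions: np.ndarray = field(default_factory=lambda: np.zeros(0))
    first_node_distance: Optional[float] = None
    block_beat: Optional[int] = None
    block_node: Optional[int] = None

    def __post_init__(self) -> None:
        if self.label == "block" and self.block_beat is None:
            raise ConfigError("block label requires block_beat")
        if self.label == "discordant" and self.node_positions.size == 0:
            raise ConfigError("discordant label requires node positions")


def build_apd_field(
    fld: SpaceTimeField,
    stim_times: Optional[np.ndarray] = None,
    dvdt_threshold: float = 10.0,
    max_resolution: float = 1.0,
) -> APDField:
    """Per-node activation time and APD90 for every delivered beat.

    Requires frames at ``dt_save <= max_resolution`` (default 1 ms) so the
    upstroke is localised well enough for beat-level analysis.  A beat's
    entry at a node is NaN when no activation follows that stimulus before
    the next one.
    """
    if fld.dt_save > max_resolution:
        raise ConfigError(
            f"frame interval {fld.dt_save} ms too coarse; need <= {max_resolution} ms"
        )
    if stim_times is None:
        stim_times = fld.stim_times
    stim_times = np.asarray(stim_times, float)
    if stim_times.size == 0:
        raise ConfigError("stim_times required to assign beats")
    n_nodes = fld.v.shape[1]
    n_beats = stim_times.size
    apd = np.full((n_beats, n_nodes), np.nan)
    act = np.full((n_beats, n_nodes), np.nan)
    pcl = float(np.median(np.diff(stim_times))) if n_beats > 1 else np.inf
    cross_v = -40.0  # upstroke timing level, interpolated to sub-frame accuracy
    for i in range(n_nodes):
        tr = fld.node_trace(i)
        t, v = tr.t, tr.v
        dt = tr.dt
        ups = detect_activations(tr, dvdt_threshold)
        # conduction delay at this node, from the first delivered beat; beat
        # windows are centred on stimulus + delay so that slow conduction
        # (delay approaching one PCL) cannot shift distal beats into the
        # next stimulus window
        first = ups[(ups >= stim_times[0]) & (ups < stim_times[0] + 1.5 * pcl)]
        delay = first[0] - stim_times[0] if first.size else 0.0
        for k in range(n_beats):
            centre = stim_times[k] + delay
            in_win = ups[(ups >= centre - 0.45 * pcl) & (ups < centre + 0.55 * pcl)]
            if in_win.size == 0:
                continue
            up = in_win[0]
            later = ups[ups > up]
            s = int(round((up - t[0]) / dt))
            e = len(t) if not later.size else int(round((later[0] - t[0]) / dt))
            # sub-frame upstroke time: interpolated crossing of cross_v
            s0 = max(s - 2, 0)
            seg = v[s0:e]
            above = np.flatnonzero(seg >= cross_v)
            if above.size == 0:
                continue
            a = above[0]
            if a == 0:
                t_up = t[s0]
            else:
                frac = (cross_v - seg[a - 1]) / (seg[a] - seg[a - 1])
                t_up = t[s0 + a - 1] + frac * dt
            # APD90 against the pre-upstroke (diastolic) baseline
            base = v[max(s - 2, 0)]
            peak = float(np.max(seg))
            level = peak - 0.9 * (peak - base)
            i_peak = int(np.argmax(seg))
            below = np.flatnonzero(seg[i_peak:] <= level)
            act[k, i] = t_up
            if below.size == 0:
                continue
            b = i_peak + below[0]
            if b == 0:
                continue
            v1, v2 = seg[b - 1], seg[b]
            frac = 0.0 if v1 == v2 else (v1 - level) / (v1 - v2)
            apd[k, i] = t[s0 + b - 1] + frac * dt - t_up
    return APDField(apd=apd, activation=act, stim_times=stim_times, dx=fld.dx)


def _beat_diffs(apd_field: APDField, transient: int) -> np.ndarray:
    """Signed beat-to-beat APD differences after the transient: (n-1, nodes)."""
    apd = apd_field.apd[transient:]
    if apd.shape[0] < 2:
        raise InsufficientDataError("need >= 2 post-transient beats")
    return np.diff(apd, axis=0)


def classify_strand(
    apd_field: APDField,
    epsilon: float = 1.0,
    distal_margin: int = 25,
    transient: int = 5,
) -> ClassificationResult:
    """Label a strand run as concordant / discordant / block."""
    n_beats, n_nodes = apd_field.apd.shape
    if n_beats - transient < 6:
        raise InsufficientDataError(
            f"need >= 6 beats after the {transient}-beat transient, have "
            f"{n_beats - transient}"
        )
    distal = n_nodes - 1 - distal_margin
    if distal < 0:
        raise ConfigError("distal_margin exceeds strand length")

    missing = np.isnan(apd_field.activation[transient:, distal])
    if np.any(missing):
        beat = transient + int(np.flatnonzero(missing)[0])
        # last node the failing beat's wavefront reached
        reached = np.flatnonzero(np.isfinite(apd_field.activation[beat]))
        block_node = int(reached[-1]) if reached.size else 0
        return ClassificationResult(
            label="block", sub_label="block",
            block_beat=beat, block_node=block_node,
        )

    diffs = _beat_diffs(apd_field, transient)
    # use the final beat pair for the spatial alternation pattern
    last = diffs[-1]
    big = np.abs(last) > epsilon
    if np.any(big):
        signs = np.sign(last[big])
        if signs.max() > 0 and signs.min() < 0:
            nodes = locate_nodes(apd_field, epsilon, transient=transient)
            if nodes.size:
                return ClassificationResult(
                    label="discordant", sub_label="discordant",
                    node_positions=nodes,
                    first_node_distance=float(nodes.min()),
                )
        return ClassificationResult(label="concordant", sub_label="concordant")
    return ClassificationResult(label="concordant", sub_label="no_alternans")


def locate_nodes(
    apd_field: APDField,
    epsilon: float = 1.0,
    transient: int = 5,
    stim_position_mm: float = 0.0,
) -> np.ndarray:
    """Positions (mm) where the beat-to-beat APD difference changes sign.

    Uses the final beat pair; zero crossings are linearly interpolated to
    sub-node positions.  Empty array when alternation never reverses phase.
    """
    diffs = _beat_diffs(apd_field, transient)
    last = diffs[-1]
    idx = np.flatnonzero(np.isfinite(last))
    x = idx * apd_field.dx
    y = last[idx]
    # walk the significant (|delta| > epsilon) nodes; a node position is the
    # interpolated zero crossing between consecutive significant nodes of
    # opposite sign — sub-epsilon jitter cannot create crossings
    sig = np.flatnonzero(np.abs(y) > epsilon)
    out = []
    for a, b in zip(sig[:-1], sig[1:]):
        if np.sign(y[a]) == np.sign(y[b]):
            continue
        for k in range(a, b):
            if np.sign(y[k]) != np.sign(y[k + 1]) and y[k] != 0.0:
                frac = abs(y[k]) / (abs(y[k]) + abs(y[k + 1]))
                out.append(x[k] + frac * (x[k + 1] - x[k]) - stim_position_mm)
                break
    return np.asarray(out)


def block_site_di(
    apd_field: APDField,
    result: Optional[ClassificationResult] = None,
    epsilon: float = 1.0,
    distal_margin: int = 25,
    transient: int = 5,
) -> Tuple[float, bool]:
    """DI between the failing wavefront and the previous beat at the block site.

    At the last node the failing beat's wavefront reached: DI = arrival time
    of the failing wavefront minus (previous activation + previous APD90)
    there.  Negative values are clipped to 0 with the collision flag set.
    """
    if result is None:
        result = classify_strand(apd_field, epsilon, distal_margin, transient)
    if result.label != "block":
        raise NotApplicableError("block-site DI requires a blocked run")
    beat, node = result.block_beat, result.block_node
    arrival = apd_field.activation[beat, node]
    if not np.isfinite(arrival):
        # the failing beat never launched a wavefront: reference the stimulus
        # itself at the pacing site
        node = 0
        arrival = apd_field.stim_times[beat]
    prev_act = apd_field.activation[beat - 1, node]
    prev_apd = apd_field.apd[beat - 1, node]
    if not (np.isfinite(arrival) and np.isfinite(prev_act) and np.isfinite(prev_apd)):
        raise InsufficientDataError("missing measurements around the block site")
    di = arrival - (prev_act + prev_apd)
    if di <= 0:
        return 0.0, True  # wavefront met the previous repolarisation tail
    return float(di), False


@dataclass
class PhaseMap:
    """Labels over the (PCL, S_gNa) grid."""

    pcl_values: np.ndarray
    s_gna_values: np.ndarray
    labels: np.ndarray        # (n_pcl, n_sgna) of str
    sub_labels: np.ndarray
    first_node_distance: np.ndarray   # mm, NaN where not discordant
    block_di: np.ndarray              # ms, NaN where not blocked

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, pcl in enumerate(self.pcl_values):
            for k, sg in enumerate(self.s_gna_values):
                rows.append(
                    {
                        "pcl_ms": pcl,
                        "s_gna": sg,
                        "label": self.labels[i, k],
                        "sub_label": self.sub_labels[i, k],
                        "first_node_distance_mm": self.first_node_distance[i, k],
                        "block_di_ms": self.block_di[i, k],
                    }
                )
        return pd.DataFrame(rows)


def phase_map(
    pcl_values: Sequence[float],
    s_gna_values: Sequence[float],
    run_cell_fn: Callable[[float, float], APDField],
    epsilon: float = 1.0,
    distal_margin: int = 25,
    transient: int = 5,
    cache: Optional[dict] = None,
) -> PhaseMap:
    """Simulate + classify one strand per (PCL, S_gNa) grid cell.

    ``run_cell_fn(pcl, s_gna)`` produces the APDField for one cell of the
    grid (the caller owns the simulation configuration); results may be
    cached/resumed through the ``cache`` dict keyed by (pcl, s_gna).  A cell
    whose simulation raises is labelled "failed" and the map is still
    returned.
    """
    pcls = np.asarray(list(pcl_values), float)
    sgs = np.asarray(list(s_gna_values), float)
    if pcls.size == 0 or sgs.size == 0:
        raise ConfigError("phase map grids must be non-empty")
    labels = np.empty((pcls.size, sgs.size), dtype=object)
    subs = np.empty_like(labels)
    nd = np.full(labels.shape, np.nan)
    bdi = np.full(labels.shape, np.nan)
    cache = cache if cache is not None else {}
    for i, pcl in enumerate(pcls):
        for k, sg in enumerate(sgs):
            key = (float(pcl), float(sg))
            try:
                fld = cache.get(key)
                if fld is None:
                    fld = run_cell_fn(pcl, sg)
                    cache[key] = fld
                res = classify_strand(fld, epsilon, distal_margin, transient)
                labels[i, k] = res.label
                subs[i, k] = res.sub_label
                if res.label == "discordant":
                    nd[i, k] = res.first_node_distance
                elif res.label == "block":
                    bdi[i, k] = block_site_di(fld, res)[0]
            except Exception:
                labels[i, k] = "failed"
                subs[i, k] = "failed"
    return PhaseMap(pcls, sgs, labels, subs, nd, bdi)
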