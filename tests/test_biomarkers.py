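"""APD/DI/CV/restitution measurements against planted ground truth."""

import numpy as np
import pytest

from alternans.biomarkers import (
    RestitutionCurve,
    alternans_magnitudes,
    apd90,
    bifurcation_point,
    cv_from_activation_times,
    detect_activations,
    max_restitution_slope,
    measure_beats,
)
from alternans.errors import InsufficientDataError
from alternans.ionic_models import Trace
from alternans.synthetic_data import (
    ToyMapCell,
    iterate_pacing_map,
    map_alternans_onset,
    synth_voltage_trace,
    toy_alternans_onset_closed_form,
    toy_fixed_point,
)


class TestDetection:
    def test_quiescent_trace_empty(self):
        tr = Trace(np.arange(0, 100, 0.1), np.full(1000, -85.0))
        assert detect_activations(tr).size == 0

    def test_planted_beats_found_at_planted_times(self):
        tr, truth = synth_voltage_trace(apd90=150.0, n_beats=5, pcl=400.0)
        ups = detect_activations(tr)
        assert len(ups) == 5
        assert np.abs(ups - truth["upstroke_times"]).max() <= tr.dt

    def test_subthreshold_artifact_not_detected(self):
        # a 10 mV bump never crossing 0 mV must not count as an activation
        t = np.arange(0, 200, 0.1)
        v = np.full_like(t, -85.0)
        v[(t >= 50) & (t < 52)] = -72.0
        assert detect_activations(Trace(t, v)).size == 0


class TestApd90:
    def test_planted_apd_recovered_exactly(self):
        tr, truth = synth_voltage_trace(apd90=150.0, n_beats=3, pcl=400.0)
        ser = measure_beats(tr)
        assert np.abs(ser.apd90 - 150.0).max() < 0.1

    def test_affine_voltage_rescaling_invariance(self):
        tr, _ = synth_voltage_trace(apd90=120.0, n_beats=2, pcl=400.0)
        a, b = 1.7, 12.0
        tr2 = Trace(tr.t, a * tr.v + b)
        ups = detect_activations(tr)
        ups2 = detect_activations(tr2, dvdt_threshold=10.0 * a,
                                  cross_level=a * 0.0 + b)
        assert np.array_equal(ups, ups2)
        for u, u2 in zip(ups, ups2):
            assert apd90(tr, u) == pytest.approx(apd90(tr2, u2), abs=1e-9)

    def test_identical_beats_identical_apd(self):
        tr, _ = synth_voltage_trace(apd90=140.0, n_beats=4, pcl=500.0)
        ser = measure_beats(tr)
        assert np.ptp(ser.apd90) == 0.0

    def test_censored_when_never_repolarising(self):
        t = np.arange(0, 100, 0.1)
        v = np.full_like(t, -85.0)
        v[t >= 20] = 10.0  # depolarises and stays up
        ser = measure_beats(Trace(t, v))
        assert len(ser) == 1 and np.isnan(ser.apd90[0])

    def test_di_additivity(self):
        tr, _ = synth_voltage_trace(apd_list=[200, 160], n_beats=6, pcl=400.0)
        ser = measure_beats(tr)
        for k in range(len(ser) - 1):
            assert ser.activation_time[k] + ser.apd90[k] + ser.di[k] == \
                pytest.approx(ser.activation_time[k + 1], abs=1e-9)


class TestConductionVelocity:
    def test_planted_delay_arithmetic(self):
        # 50 nodes at dx 0.15 mm traversed in 13.16 ms -> about 57 cm/s
        cv = cv_from_activation_times(np.array([100.0]), np.array([113.16]),
                                      50 * 0.15)
        assert cv[0] == pytest.approx(7.5 / 13.16 * 100, rel=1e-12)

    def test_simultaneous_activation_flagged_invalid(self):
        cv = cv_from_activation_times(np.array([100.0]), np.array([100.0]), 7.5)
        assert np.isnan(cv[0])

    def test_distance_linearity(self):
        ta, tb = np.array([0.0]), np.array([10.0])
        assert cv_from_activation_times(ta, tb, 15.0)[0] == pytest.approx(
            2 * cv_from_activation_times(ta, tb, 7.5)[0]
        )

    def test_missing_distal_activation_is_conduction_failure(self):
        cv = cv_from_activation_times(np.array([0.0, 200.0]),
                                      np.array([10.0, np.nan]), 7.5)
        assert np.isfinite(cv[0]) and np.isnan(cv[1])


class TestRestitutionSlope:
    def test_exact_line(self):
        x = np.linspace(10, 100, 12)
        c = RestitutionCurve(x, 0.5 * x + 30.0)
        assert c.max_slope == pytest.approx(0.5)

    def test_exponential_closed_form(self):
        A, B, tau = 200.0, 120.0, 60.0
        di = np.linspace(20.0, 300.0, 200)
        c = RestitutionCurve(di, A - B * np.exp(-di / tau))
        expect = (B / tau) * np.exp(-di[0] / tau)
        assert c.max_slope == pytest.approx(expect, rel=0.02)

    def test_too_few_points_rejected(self):
        with pytest.raises(InsufficientDataError):
            max_restitution_slope(RestitutionCurve(np.array([1.0, 2.0]),
                                                   np.array([1.0, 2.0])))


class TestBifurcation:
    def test_monotone_series_has_no_bifurcation(self):
        pcls = np.arange(200, 180, -1.0)
        pairs = [(100.0 - k, 100.0 - k) for k in range(len(pcls))]
        assert bifurcation_point(pcls, pairs) is None

    def test_largest_alternating_pcl_returned(self):
        pcls = [200.0, 195.0, 190.0, 185.0]
        pairs = [(100, 100), (100, 100.5), (102, 99), (105, 95)]
        assert bifurcation_point(pcls, pairs) == 190.0

    def test_toy_map_detector_agrees_with_brute_force_iteration(self, rng):
        """On 20 random map parameterisations the onset from last-two-APD
        scanning matches brute-force 2-cycle iteration within one step."""
        hits = 0
        for _ in range(20):
            B = rng.uniform(60, 150)
            cell = ToyMapCell(A=rng.uniform(160, 260), B=B,
                              tau=rng.uniform(25, B * 0.9), min_di=1.0)
            grid = np.arange(400.0, 40.0, -2.0)
            # both detectors probe the locally seeded orbit, iterated far
            # past the transient (the multiplier is near -1 close to onset)
            oracle = map_alternans_onset(cell, grid, n_beats=2000)

            def seeded_pair(p):
                fp = toy_fixed_point(cell, p)
                if fp is None:
                    return (np.nan, np.nan)
                return tuple(iterate_pacing_map(cell, p, 2000, apd0=fp + 0.5)[-2:])

            pairs = [seeded_pair(p) for p in grid]
            detected = bifurcation_point(grid, pairs)
            if oracle is None and detected is None:
                hits += 1
            elif oracle is not None and detected is not None:
                hits += abs(oracle - detected) <= 2.0
        assert hits == 20


class TestAlternansMagnitudes:
    def test_planted_two_cycle(self):
        tr, _ = synth_voltage_trace(apd_list=[200, 160], n_beats=10, pcl=500.0)
        mags = alternans_magnitudes({500.0: measure_beats(tr)})
        assert mags["max_delta_apd"] == pytest.approx(40.0, abs=0.1)
        assert mags["mean_delta_apd"] == pytest.approx(40.0, abs=0.1)

    def test_non_alternating_series_empty(self):
        tr, _ = synth_voltage_trace(apd90=150.0, n_beats=10, pcl=500.0)
        assert alternans_magnitudes({500.0: measure_beats(tr)}) == {}
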