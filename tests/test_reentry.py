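"""Phase mapping, singularity detection and episode tracking."""

import numpy as np
import pytest

from alternans.errors import ConfigError
from alternans.ionic_models import Trace
from alternans.reentry_analysis import (
    detect_reentry_episodes,
    find_reentry,
    phase_field,
    phase_singularities,
    stimulus_response_ratio,
)
from alternans.synthetic_data import synth_rotor_frames, synth_voltage_trace
from alternans.tissue_solver import SpaceTimeField


def planar_field(nx=50, ny=50, dx=0.3, wavelength=15.0, period=100.0,
                 duration=200.0, dt_save=2.0):
    t = np.arange(0, duration, dt_save)
    ys, xs = np.mgrid[0:ny, 0:nx] * dx
    v = -85 + 50 * np.cos(2 * np.pi * (xs[None] / wavelength - t[:, None, None] / period))
    return SpaceTimeField(v=v.astype(np.float32), dt_save=dt_save, dx=dx)


class TestPhaseField:
    def test_constant_field_has_no_singularities(self):
        fld = SpaceTimeField(v=np.full((40, 20, 20), -85.0, np.float32),
                             dt_save=2.0, dx=0.3)
        phase, times = phase_field(fld, tau=10.0)
        assert times[0] >= 10.0
        assert all(phase_singularities(phase[k], 0.3).shape[0] == 0
                   for k in range(phase.shape[0]))

    def test_rotor_phase_advances_monotonically_at_fixed_point(self):
        fld, truth = synth_rotor_frames(duration=200.0)
        phase, _ = phase_field(fld, tau=10.0)
        series = np.unwrap(phase[:, 20, 70])
        steps = np.diff(series)
        assert np.all(np.abs(np.sign(steps).sum()) == len(steps))  # one sign

    def test_planar_wave_has_straight_isolines_and_no_singularity(self):
        fld = planar_field()
        phase, _ = phase_field(fld, tau=10.0)
        total = sum(phase_singularities(phase[k], fld.dx).shape[0]
                    for k in range(phase.shape[0]))
        assert total == 0
        # isoline straightness: phase constant along y
        assert np.abs(np.diff(phase[5], axis=0)).max() < 1e-4

    def test_coarse_frames_rejected(self):
        fld = planar_field(dt_save=8.0)
        with pytest.raises(ConfigError):
            phase_field(fld, tau=10.0)


class TestSingularities:
    def test_rotor_core_localised_within_one_node(self):
        fld, truth = synth_rotor_frames(duration=120.0)
        eps = find_reentry(fld, tau=10.0)
        assert len(eps) == 1
        cx, cy = eps[0].mean_core
        assert abs(cx - truth["center"][0]) <= fld.dx
        assert abs(cy - truth["center"][1]) <= fld.dx

    def test_uniform_phase_gradient_yields_none(self):
        ys, xs = np.mgrid[0:30, 0:30] * 0.2
        phase = 0.7 * xs + 0.3 * ys - 1.0
        assert phase_singularities(phase, 0.2).shape[0] == 0

    def test_mirrored_pair_has_opposite_chirality(self):
        fld, truth = synth_rotor_frames(duration=250.0, n_rotors=2,
                                        grid=(100, 140), center=(12.0, 15.0))
        eps = find_reentry(fld, tau=10.0)
        assert len(eps) == 2
        assert sorted(e.chirality for e in eps) == [-1, 1]

    def test_random_placements_recovered(self, rng):
        for _ in range(20):
            c = tuple(rng.uniform(6, 24, 2))
            fld, truth = synth_rotor_frames(center=c, duration=150.0)
            eps = find_reentry(fld, tau=10.0)
            assert len(eps) == 1
            cx, cy = eps[0].mean_core
            assert np.hypot(cx - truth["center"][0], cy - truth["center"][1]) <= np.sqrt(2) * fld.dx


class TestEpisodes:
    def test_three_rotation_rotor_counted(self):
        fld, truth = synth_rotor_frames(duration=300.0)  # 3 turns at T=100
        eps = find_reentry(fld, tau=10.0)
        assert len(eps) == 1
        assert eps[0].rotations == pytest.approx(3.0, abs=0.15)
        assert eps[0].termination is None  # alive at end of run

    def test_sub_rotation_flicker_rejected(self):
        fld, _ = synth_rotor_frames(duration=30.0)  # 0.3 turns
        assert find_reentry(fld, tau=10.0) == []

    def test_static_pattern_no_episode(self):
        fld, _ = synth_rotor_frames(duration=200.0, omega=0.0)
        assert find_reentry(fld, tau=10.0) == []

    def test_two_separated_rotors_two_episodes(self):
        fld, _ = synth_rotor_frames(duration=250.0, n_rotors=2,
                                    grid=(100, 140), center=(12.0, 15.0))
        assert len(find_reentry(fld, tau=10.0)) == 2

    def test_rotation_count_insensitive_to_tau(self):
        fld, _ = synth_rotor_frames(duration=300.0)
        rots = [find_reentry(fld, tau=tau)[0].rotations
                for tau in (5.0, 10.0, 20.0)]
        assert np.ptp(rots) < 0.25

    def test_chirality_count_conserved_frame_to_frame(self):
        fld, _ = synth_rotor_frames(duration=250.0, n_rotors=2,
                                    grid=(100, 140), center=(12.0, 15.0))
        phase, _ = phase_field(fld, tau=10.0)
        counts = []
        for k in range(phase.shape[0]):
            s = phase_singularities(phase[k], fld.dx)
            counts.append((len(s), int(s[:, 2].sum()) if len(s) else 0))
        # rigid pair: two singularities, net chirality zero, in every frame
        assert all(c == (2, 0) for c in counts)


class TestResponseRatio:
    def test_full_capture_and_two_to_one(self):
        pcl = 300.0
        full, _ = synth_voltage_trace(apd90=120.0, n_beats=10, pcl=pcl)
        halved, _ = synth_voltage_trace(apd90=120.0, n_beats=5, pcl=2 * pcl)
        stim = 10.0 + pcl * np.arange(10)
        ratios = stimulus_response_ratio({"a": full, "b": halved}, stim,
                                         transient_beats=2)
        assert ratios["a"] == pytest.approx(1.0)
        assert ratios["b"] == pytest.approx(0.5)
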