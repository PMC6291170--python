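"""Geometry, the discrete diffusion operator and the operator-split stepper."""

import numpy as np
import pytest

from alternans.errors import ConfigError
from alternans.protocols import StimulusTrain, supra_threshold_amplitude
from alternans.tissue_solver import (
    SaveSpec,
    assemble_diffusion_operator,
    assign_dead_cells,
    build_geometry,
    fiber_angle_elliptical,
    run_simulation,
    step_tissue,
)


class TestFiberAngle:
    def test_on_axis_above_origin(self):
        assert fiber_angle_elliptical(0.0, 10.0) == 0.0

    def test_direct_evaluation(self):
        assert fiber_angle_elliptical(4.0, 1.0) == pytest.approx(-np.pi / 4)

    def test_odd_symmetry_in_x(self):
        assert fiber_angle_elliptical(-4.0, 1.0) == pytest.approx(np.pi / 4)

    def test_singular_line_limit_convention(self):
        assert fiber_angle_elliptical(3.0, 0.0) == pytest.approx(-np.pi / 2)
        assert fiber_angle_elliptical(-3.0, 0.0) == pytest.approx(np.pi / 2)
        assert fiber_angle_elliptical(0.0, 0.0) == 0.0


class TestGeometry:
    def test_strand_defaults_span_120_mm(self):
        g = build_geometry("strand")
        assert g.shape == (800,) and g.dx == 0.15 and g.d_par == 0.15
        assert g.length_mm == pytest.approx(120.0)

    def test_anisotropic_quarter_transverse_diffusion(self):
        g = build_geometry("sheet", shape=(20, 20), anisotropic=True)
        assert g.d_perp / g.d_par == pytest.approx(0.25)

    def test_small_test_strand(self):
        g = build_geometry("strand", n_nodes=50)
        assert g.length_mm == pytest.approx(7.5)

    def test_nonpositive_sizes_rejected(self):
        with pytest.raises(ConfigError):
            build_geometry("strand", n_nodes=0)
        with pytest.raises(ConfigError):
            build_geometry("sheet", shape=(0, 10))

    def test_dead_cell_count_and_determinism(self):
        g = build_geometry("sheet", shape=(40, 40))
        g1 = assign_dead_cells(g, 0.10, seed=7)
        g2 = assign_dead_cells(g, 0.10, seed=7)
        assert g1.dead_mask.sum() == round(0.10 * 1600)
        assert np.array_equal(g1.dead_mask, g2.dead_mask)
        assert assign_dead_cells(g, 0.0, seed=7).dead_mask.sum() == 0

    def test_dead_fraction_out_of_range(self):
        g = build_geometry("sheet", shape=(10, 10))
        with pytest.raises(ConfigError):
            assign_dead_cells(g, 1.0, seed=0)


class TestOperator:
    def test_1d_interior_stencil(self):
        g = build_geometry("strand", n_nodes=3, d_par=0.15)
        L = assemble_diffusion_operator(g, 0.005).L.toarray()
        c = 0.15 / 0.15**2
        assert np.allclose(L[1], [c, -2 * c, c])

    @pytest.mark.parametrize("aniso,fibers", [(False, "uniform"),
                                              (True, "uniform"),
                                              (True, "elliptical")])
    def test_constant_field_annihilated(self, aniso, fibers):
        g = build_geometry("sheet", shape=(25, 25), anisotropic=aniso,
                          fibers=fibers, fiber_angle=0.4)
        L = assemble_diffusion_operator(g, 0.1).L
        assert np.abs(L @ np.ones(625)).max() < 1e-12

    def test_discrete_conservation_for_random_fields(self, rng):
        g = build_geometry("sheet", shape=(25, 25), anisotropic=True,
                          fibers="elliptical")
        g = assign_dead_cells(g, 0.05, seed=3)
        L = assemble_diffusion_operator(g, 0.1).L
        for _ in range(5):
            v = rng.normal(size=625)
            assert abs((L @ v).sum()) < 1e-10 * np.abs(L @ v).max()

    def test_heat_kernel_widening(self):
        # pure diffusion of a Gaussian matches the closed-form solution
        g = build_geometry("strand", n_nodes=200, d_par=0.15)
        op = assemble_diffusion_operator(g, 0.005)
        x = np.arange(200) * 0.15
        x0, s0, D, T = 15.0, 1.0, 0.15, 50.0
        v = np.exp(-((x - x0) ** 2) / (2 * s0**2))
        for _ in range(int(T / 0.005)):
            v = op.diffuse(v)
        s2 = s0**2 + 2 * D * T
        exact = s0 / np.sqrt(s2) * np.exp(-((x - x0) ** 2) / (2 * s2))
        assert np.abs(v[20:180] - exact[20:180]).max() < 0.01 * exact.max()

    def test_sum_v_conserved_under_pure_diffusion(self, rng):
        g = build_geometry("strand", n_nodes=100)
        op = assemble_diffusion_operator(g, 0.01)
        v = rng.normal(size=100)
        total = v.sum()
        for _ in range(200):
            v = op.diffuse(v)
            assert abs(v.sum() - total) < 1e-8 * abs(total)


class TestStepper:
    def test_resting_tissue_stays_at_rest(self, fk_steep):
        g = build_geometry("strand", n_nodes=30, d_par=0.1)
        op = assemble_diffusion_operator(g, 0.1)
        states = np.tile(fk_steep.initial_state, (30, 1))
        for _ in range(100):
            step_tissue(fk_steep, states, op, 0.1)
        assert np.abs(states[:, 0] - fk_steep.v_rest).max() < 1e-4

    def test_dead_nodes_never_activate_and_wave_passes(self, fk_steep):
        g = build_geometry("strand", n_nodes=80, dx=0.25, d_par=0.1)
        dead = np.zeros(80, bool)
        dead[40] = True  # single dead node: zero-flux link, wave must stop
        g.dead_mask = dead
        amp = supra_threshold_amplitude(fk_steep, dt=0.1)
        train = StimulusTrain(amplitude=amp, pcl=500.0, count=1, extent=5)
        fld, _ = run_simulation(fk_steep, g, train, SaveSpec(dt_save=1.0),
                                dt=0.1, duration=250.0)
        v = fld.v
        assert v[:, 40].max() < fk_steep.v_rest + 1.0      # dead node silent
        assert v[:, 20].max() > 0.0                         # proximal activates
        assert v[:, 60].max() < -60.0                       # distal isolated

    def test_identical_configs_give_bit_identical_fields(self, fk_steep):
        g = build_geometry("strand", n_nodes=60, dx=0.25, d_par=0.1)
        amp = supra_threshold_amplitude(fk_steep, dt=0.1)
        train = StimulusTrain(amplitude=amp, pcl=300.0, count=2, extent=5)
        f1, _ = run_simulation(fk_steep, g, train, SaveSpec(dt_save=2.0),
                               dt=0.1, duration=500.0)
        f2, _ = run_simulation(fk_steep, g, train, SaveSpec(dt_save=2.0),
                               dt=0.1, duration=500.0)
        assert np.array_equal(f1.v, f2.v)

    def test_cn_matches_fine_step_explicit_oracle(self, fk_steep):
        """Operator-split CN vs a forward-Euler-diffusion oracle at dt/20 on
        a 50-node strand must agree within 0.5 mV everywhere — including on
        the travelling upstroke, which amplifies any wavefront-speed error."""
        n = 50
        dt, nsub = 0.02, 20
        g = build_geometry("strand", n_nodes=n, dx=0.25, d_par=0.1)
        amp = supra_threshold_amplitude(fk_steep, dt=0.1)
        train = StimulusTrain(amplitude=amp, pcl=400.0, count=1, extent=5)
        fld, _ = run_simulation(fk_steep, g, train, SaveSpec(dt_save=1.0),
                                dt=dt, duration=150.0)
        # independent diffusion oracle: identical operator splitting and
        # reaction stepping, but the CN solve replaced by 20 explicit Euler
        # diffusion substeps of dt/20
        L = assemble_diffusion_operator(g, dt).L.toarray()
        Y = np.tile(fk_steep.initial_state, (n, 1))
        ist = np.zeros(n)
        frames = [Y[:, 0].copy()]
        for k in range(int(150.0 / dt)):
            t = k * dt
            ist[:5] = amp if 10.0 <= t < 12.0 else 0.0
            dY = np.empty_like(Y)
            fk_steep.rhs_kernel(Y, ist, dY, fk_steep.params)
            Y += dt * dY
            for _ in range(nsub):
                Y[:, 0] += (dt / nsub) * (L @ Y[:, 0])
            if (k + 1) % int(1.0 / dt) == 0:
                frames.append(Y[:, 0].copy())
        oracle = np.asarray(frames)
        err = np.abs(oracle - fld.v.astype(float)).max()
        assert err < 0.5

    def test_cv_scales_with_sqrt_d(self, fk_steep):
        from alternans.biomarkers import cv_from_activation_times, detect_activations

        cvs = []
        for d in (0.15, 0.6):
            g = build_geometry("strand", n_nodes=150, dx=0.25, d_par=d)
            amp = supra_threshold_amplitude(fk_steep, dt=0.1)
            train = StimulusTrain(amplitude=amp, pcl=500.0, count=2, extent=5)
            _, probes = run_simulation(
                fk_steep, g, train, SaveSpec(dt_save=2.0, probes=[25, 75]),
                dt=0.1, duration=800.0,
            )
            ta = detect_activations(probes[25])
            tb = detect_activations(probes[75])
            cvs.append(cv_from_activation_times(ta, tb, 50 * 0.25)[-1])
        assert 1.9 < cvs[1] / cvs[0] < 2.1

    def test_cv_converged_in_dx(self, fk_steep):
        from alternans.biomarkers import cv_from_activation_times, detect_activations

        cvs = []
        for dx, n in ((0.25, 120), (0.125, 240)):
            g = build_geometry("strand", n_nodes=n, dx=dx, d_par=0.1)
            amp = supra_threshold_amplitude(fk_steep, dt=0.1)
            train = StimulusTrain(amplitude=amp, pcl=500.0, count=2, extent=int(1.25 / dx))
            _, probes = run_simulation(
                fk_steep, g, train,
                SaveSpec(dt_save=2.0, probes=[int(5 / dx), int(20 / dx)]),
                dt=0.05, duration=800.0,
            )
            pa, pb = sorted(probes)
            ta = detect_activations(probes[pa])
            tb = detect_activations(probes[pb])
            cvs.append(cv_from_activation_times(ta, tb, 15.0)[-1])
        assert abs(cvs[1] - cvs[0]) / cvs[0] < 0.03
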