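import math

import numpy as np
import pytest

from porevertex.flowfield import (
    FlowConfig,
    StressField,
    _velocity_and_gradient,
    poiseuille_shear,
    poiseuille_velocity,
    reynolds,
    shear_field,
    stream_function,
    stress_at_points,
    stress_for_cells,
    velocity_from_stream,
)
from porevertex.geometry import ChannelGeometry
from porevertex.simulation import init_single_cell


def straight_cfg(h=4.5):
    return FlowConfig(geom=ChannelGeometry(h=h, epsilon=0.0, x_min=0, x_max=120),
                      u0=1.0)


def wavy_cfg(eps=0.2, K=math.pi, h=1.0, phase=0.0, source="printed"):
    periods = 4.0 * math.pi / K
    geom = ChannelGeometry(h=h, epsilon=eps, wavenumber=K, phase=phase,
                           x_min=0.0, x_max=periods)
    return FlowConfig(geom=geom, u0=1.0, field_source=source)


class TestPoiseuille:
    def test_no_slip_at_walls(self):
        cfg = straight_cfg()
        assert poiseuille_velocity(4.5, cfg) == pytest.approx(0.0, abs=1e-14)
        assert poiseuille_velocity(-4.5, cfg) == pytest.approx(0.0, abs=1e-14)

    def test_centerline_maximum_and_symmetry(self):
        cfg = straight_cfg()
        assert poiseuille_velocity(0.0, cfg) == 1.0
        ys = np.linspace(-4.0, 4.0, 11)
        assert poiseuille_velocity(ys, cfg) == pytest.approx(
            poiseuille_velocity(-ys, cfg)
        )

    def test_pressure_gradient_form(self):
        # u0 = dpdx h^2 / (4 eta0)
        g = ChannelGeometry(h=2.0, epsilon=0.0, x_min=0, x_max=10)
        cfg = FlowConfig(geom=g, dpdx=1.0, eta0=0.5)
        assert cfg.u_center == pytest.approx(2.0)

    def test_outside_channel_rejected(self):
        with pytest.raises(ValueError):
            poiseuille_velocity(5.0, straight_cfg())

    def test_shear_zero_at_center_and_odd(self):
        cfg = straight_cfg()
        assert poiseuille_shear(0.0, cfg) == 0.0
        ys = np.linspace(-4.0, 4.0, 17)
        assert poiseuille_shear(-ys, cfg) == pytest.approx(-poiseuille_shear(ys, cfg))

    def test_shear_matches_velocity_gradient(self):
        cfg = straight_cfg()
        ys = np.linspace(-4.0, 4.0, 9)
        h = 1e-6
        fd = (poiseuille_velocity(ys + h, cfg) - poiseuille_velocity(ys - h, cfg)) / (2 * h)
        assert poiseuille_shear(ys, cfg) == pytest.approx(cfg.eta0 * fd, abs=1e-9)


class TestReynolds:
    def test_paper_scale_estimate(self):
        """Water through a 100-micron pore at 1 mm/s: Re = 0.1."""
        assert reynolds(1e-3, 1e-4, 1e-6) == pytest.approx(0.1)

    def test_linear_in_velocity(self):
        assert reynolds(2e-3, 1e-4, 1e-6) == 2 * reynolds(1e-3, 1e-4, 1e-6)
        assert reynolds(0.0, 1e-4, 1e-6) == 0.0


class TestStreamFunction:
    def test_flux_between_walls(self):
        cfg = straight_cfg()
        psi = stream_function(0.0, np.array([-1.0, 1.0]), cfg)
        assert psi[1] - psi[0] == pytest.approx(4.0 / 3.0, rel=1e-12)

    def test_odd_in_phi(self):
        cfg = wavy_cfg()
        phis = np.linspace(0, 1, 11)
        th = 0.37
        assert stream_function(th, -phis, cfg) == pytest.approx(
            -stream_function(th, phis, cfg)
        )

    def test_flux_independent_of_x(self):
        cfg = wavy_cfg()
        ths = np.linspace(0, 4, 21)
        flux = stream_function(ths, np.ones_like(ths), cfg) - stream_function(
            ths, -np.ones_like(ths), cfg
        )
        assert flux == pytest.approx(4.0 / 3.0, rel=1e-12)


class TestVelocityField:
    def test_straight_centerline(self):
        cfg = straight_cfg()
        u = velocity_from_stream(10.0, 0.0, cfg)
        assert u == pytest.approx([1.0, 0.0])

    def test_straight_channel_is_unidirectional(self):
        cfg = straight_cfg()
        ys = np.linspace(-4.4, 4.4, 13)
        u = velocity_from_stream(np.full_like(ys, 5.0), ys, cfg)
        assert np.abs(u[:, 1]).max() == 0.0

    def test_outside_channel_rejected(self):
        with pytest.raises(ValueError):
            velocity_from_stream(1.0, 1.5, wavy_cfg())

    @pytest.mark.parametrize("source", ["printed", "consistent"])
    def test_no_slip_on_wavy_walls(self, source):
        cfg = wavy_cfg(source=source)
        xs = np.linspace(0, 4, 50)
        w = 1.0 + 0.2 * np.sin(math.pi * xs)
        u = velocity_from_stream(xs, w * (1 - 1e-12), cfg)
        assert np.abs(u).max() < 1e-10

    @pytest.mark.parametrize("source", ["printed", "consistent"])
    def test_gradients_match_finite_differences(self, source):
        cfg = wavy_cfg(source=source)
        rng = np.random.default_rng(2)
        x = rng.uniform(0.5, 3.5, 40)
        y = rng.uniform(-0.6, 0.6, 40)
        ux, uy, dxx, dxy, dyx, dyy = _velocity_and_gradient(x, y, cfg)
        h = 1e-6
        for d, (dx, dy) in {
            0: ((dxx, dyx)), 1: ((dxy, dyy)),
        }.items():
            xp, yp = (x + h, y) if d == 0 else (x, y + h)
            xm, ym = (x - h, y) if d == 0 else (x, y - h)
            up = _velocity_and_gradient(xp, yp, cfg)[:2]
            um = _velocity_and_gradient(xm, ym, cfg)[:2]
            assert np.abs((up[0] - um[0]) / (2 * h) - dx).max() < 1e-6
            assert np.abs((up[1] - um[1]) / (2 * h) - dy).max() < 1e-6

    def test_incompressibility_on_grid(self):
        """Numerical divergence below 1e-6 on a 50x50 interior grid."""
        cfg = wavy_cfg()
        xs = np.linspace(0.1, 3.9, 50)
        ys = np.linspace(-0.7, 0.7, 50)
        X, Y = np.meshgrid(xs, ys)
        h = 1e-5
        uxp = _velocity_and_gradient(X + h, Y, cfg)[0]
        uxm = _velocity_and_gradient(X - h, Y, cfg)[0]
        uyp = _velocity_and_gradient(X, Y + h, cfg)[1]
        uym = _velocity_and_gradient(X, Y - h, cfg)[1]
        div = (uxp - uxm) / (2 * h) + (uyp - uym) / (2 * h)
        assert np.abs(div).max() < 1e-6


class TestShearField:
    def test_straight_limit_is_linear_profile(self):
        cfg = straight_cfg()
        ys = np.linspace(-4.4, 4.4, 23)
        tau = shear_field(np.full_like(ys, 30.0), ys, cfg)
        assert tau == pytest.approx(-ys / 4.5, abs=1e-12)

    def test_centerline_stress_vanishes(self):
        cfg = wavy_cfg()
        xs = np.linspace(0.2, 3.8, 11)
        assert np.abs(shear_field(xs, np.zeros_like(xs), cfg)).max() < 1e-12

    def test_eps_to_zero_collapse_is_linear(self):
        """Deviation from the Poiseuille profile shrinks linearly in eps."""
        xs = np.linspace(0.1, 3.9, 30)
        ys = np.linspace(-0.7, 0.7, 30)
        X, Y = np.meshgrid(xs, ys)
        err = {}
        for eps in (0.05, 0.01):
            tau = shear_field(X, Y, wavy_cfg(eps=eps))
            err[eps] = np.abs(tau + Y / 1.0).max()
        assert err[0.01] < err[0.05]
        assert err[0.01] == pytest.approx(err[0.05] / 5.0, rel=0.3)

    def test_antisymmetric_and_periodic(self):
        cfg = wavy_cfg()
        x = np.linspace(0.1, 1.9, 12)
        y = np.linspace(0.05, 0.6, 12)
        assert shear_field(x, -y, cfg) == pytest.approx(-shear_field(x, y, cfg))
        assert shear_field(x + 2.0, y, cfg) == pytest.approx(
            shear_field(x, y, cfg), rel=1e-9
        )

    def test_printed_field_peaks_in_expansion(self):
        """Wall stress is maximal where the channel widens and drops at
        the bottleneck, exceeding the straight-channel wall value."""
        field = StressField(wavy_cfg(source="printed"))
        xs, wt = field.wall_stress_profile()
        g = field.cfg.geom
        width_at_max = g.half_width(xs[np.argmax(wt)])
        assert width_at_max > g.h  # expansion section
        assert wt.max() > 1.0      # exceeds straight-channel wall stress
        bottleneck = np.abs(xs % 2.0 - 1.5) < 0.05  # sin = -1 stations
        assert wt[bottleneck].max() < 1.0

    def test_consistent_field_peaks_at_bottleneck(self):
        """The self-consistent first-order solution follows the
        lubrication rule: wall shear is largest at the throat."""
        field = StressField(wavy_cfg(source="consistent"))
        xs, wt = field.wall_stress_profile()
        g = field.cfg.geom
        assert g.half_width(xs[np.argmax(wt)]) < g.h

    def test_stokes_residual_selects_consistent_sign(self):
        """Independent oracle: Stokes flow has harmonic vorticity.  The
        consistent field's residual max|lap omega| scales as eps^2, the
        sign-flipped printed field's only as eps (it solves the problem
        of the phase-inverted channel)."""

        def residual(source, eps):
            geom = ChannelGeometry(h=1.0, epsilon=eps, wavenumber=math.pi,
                                   x_min=0.0, x_max=4.0)
            cfg = FlowConfig(geom=geom, u0=1.0, field_source=source)
            xs = np.linspace(0.3, 3.7, 50)
            ys = np.linspace(-0.55, 0.55, 50)
            X, Y = np.meshgrid(xs, ys)
            h = 1e-3

            def omega(x, y):
                _, _, _, dxy, dyx, _ = _velocity_and_gradient(x, y, cfg)
                return dyx - dxy

            lap = (omega(X + h, Y) + omega(X - h, Y) + omega(X, Y + h)
                   + omega(X, Y - h) - 4 * omega(X, Y)) / h ** 2
            return np.abs(lap).max()

        for source, expected_order in (("consistent", 2), ("printed", 1)):
            ratio = residual(source, 0.05) / residual(source, 0.025)
            assert ratio == pytest.approx(2 ** expected_order, rel=0.2)

    def test_first_order_profile_solves_the_ode(self):
        """Independent BVP oracle: f'''' - 2 b^2 f'' + b^4 f = 0 with
        f(+-1) = 0, f'(+-1) = 2, solved numerically, matches _profile."""
        from scipy.integrate import solve_bvp
        from porevertex.flowfield import _profile

        b = math.pi

        def ode(phi, y):
            return np.vstack([y[1], y[2], y[3],
                              2 * b * b * y[2] - b ** 4 * y[0]])

        def bc(ya, yb):
            return np.array([ya[0], ya[1] - 2.0, yb[0], yb[1] - 2.0])

        phis = np.linspace(-1, 1, 81)
        sol = solve_bvp(ode, bc, phis, np.zeros((4, len(phis))), tol=1e-8,
                        max_nodes=50000)
        assert sol.success
        f, _, _ = _profile(sol.x, b)
        assert np.abs(sol.y[0] - f).max() < 1e-6


class TestStressForCells:
    def test_zero_amplitude_recovers_uniform_growth(self):
        geom = ChannelGeometry(h=4.5, epsilon=0.2, wavenumber=1 / 6,
                               phase=-math.pi / 2)
        cfg = FlowConfig(geom=geom, u0=1.0, stress_amplitude=0.0)
        mesh = init_single_cell(geom)
        tau = stress_for_cells(mesh, cfg, tau_res=0.99)
        assert np.all(tau == 0.0)

    def test_axis_cell_feels_no_stress(self):
        geom = ChannelGeometry(h=4.5, epsilon=0.0)
        cfg = FlowConfig(geom=geom, u0=1.0)
        mesh = init_single_cell(geom)  # centroid on the axis
        tau = stress_for_cells(mesh, cfg, tau_res=0.99)
        assert tau[0] == pytest.approx(0.0, abs=1e-12)

    def test_calibration_peaks_at_amplitude_times_tau_res(self):
        field = StressField(wavy_cfg(), tau_res=0.98995)
        xs, _ = field.wall_stress_profile()
        g = field.cfg.geom
        w = g.h * (1 + g.epsilon * np.sin(g.wavenumber * xs + g.phase))
        vals = field.tau_res_units(xs, w * (1 - 1e-6))
        assert vals.max() == pytest.approx(0.98995, rel=1e-6)
        assert np.all(vals >= 0.0)

    def test_out_of_channel_points_clamped(self):
        field = StressField(wavy_cfg(), tau_res=1.0)
        v = stress_at_points(np.array([1.0]), np.array([5.0]), field)
        assert np.isfinite(v).all()
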