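"""Force model, wall collisions, release protocols and the integrator."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq

import emboflow as ef
from emboflow.particle_dynamics import (
    ParticleState,
    UniformField,
    _drag_linear_coefficient,
    advance_in_field,
)

from conftest import make_straight_tube


class TestParticleProperties:
    def test_mass_direct_value_and_scaling(self):
        spec = ef.ParticleSpec(500e-6, 1050.0)
        assert ef.particle_mass(spec) == pytest.approx(6.872e-8, rel=1e-3)
        doubled = ef.ParticleSpec(1000e-6, 1050.0)
        assert ef.particle_mass(doubled) == pytest.approx(8 * ef.particle_mass(spec), rel=1e-12)

    def test_table_mass_is_eight_times_sphere_mass(self):
        for label in ef.CASE_MATRIX:
            spec = ef.case_spec(label)
            assert ef.table_mass(spec) == pytest.approx(
                8 * ef.particle_mass(spec) * 1e6, rel=1e-12
            )

    def test_slip_reynolds_value_and_linearity(self, fluid):
        spec = ef.ParticleSpec(500e-6, 1050.0)
        assert ef.slip_reynolds(spec, fluid, 0.1) == pytest.approx(16.5, rel=1e-3)
        assert ef.slip_reynolds(spec, fluid, 0.0) == 0.0
        big = ef.ParticleSpec(1000e-6, 1050.0)
        assert ef.slip_reynolds(big, fluid, 0.1) == pytest.approx(
            2 * ef.slip_reynolds(spec, fluid, 0.1), rel=1e-12
        )


class TestDrag:
    def test_coefficient_schiller_naumann_and_caps(self):
        assert ef.drag_coefficient(1.0) == pytest.approx(27.6, rel=1e-12)
        assert ef.drag_coefficient(1e5) == 0.44
        assert ef.drag_coefficient(1.0, mode="literal_44") == 44.0
        with pytest.raises(ValueError):
            ef.drag_coefficient(0.0)

    def test_force_vanishes_with_slip_and_matches_stokes_limit(self, fluid):
        spec = ef.ParticleSpec(500e-6, 1050.0)
        f = ef.drag_force(spec, fluid, [0.2, 0, 0], [0.2, 0, 0])
        assert np.linalg.norm(f) == 0.0
        # Re <= 0.01: within 1% of Stokes 3 pi mu phi |U_s|
        u_s = 0.01 * fluid.viscosity / (fluid.density * spec.diameter)
        f = ef.drag_force(spec, fluid, [u_s, 0, 0], [0, 0, 0])
        stokes = 3 * math.pi * fluid.viscosity * spec.diameter * u_s
        assert np.linalg.norm(f) == pytest.approx(stokes, rel=1e-2)

    def test_force_magnitude_at_moderate_reynolds(self, fluid):
        spec = ef.ParticleSpec(500e-6, 1050.0)
        f = ef.drag_force(spec, fluid, [0.1, 0, 0], [0, 0, 0])
        assert np.linalg.norm(f) == pytest.approx(3.06e-6, rel=2e-3)


class TestBodyForces:
    def test_buoyancy_neutral_value_and_sign_flip(self, fluid):
        g = (0.0, 0.0, -9.81)
        neutral = ef.buoyancy_force(ef.ParticleSpec(500e-6, fluid.density), fluid, g)
        assert np.linalg.norm(neutral) == 0.0
        light = ef.buoyancy_force(ef.ParticleSpec(500e-6, 800.0), fluid, g)
        assert np.linalg.norm(light) == pytest.approx(1.644e-7, rel=1e-3)
        assert light[2] > 0  # antiparallel to g
        heavy = ef.buoyancy_force(ef.ParticleSpec(500e-6, 1300.0), fluid, g)
        assert heavy[2] < 0

    def test_pressure_gradient_force_value_and_cubic_scaling(self):
        spec = ef.ParticleSpec(500e-6, 1050.0)
        f = ef.pressure_gradient_force(spec, [1e4, 0, 0])
        assert np.linalg.norm(f) == pytest.approx(6.545e-7, rel=1e-3)
        assert f[0] < 0  # toward low pressure
        double = ef.pressure_gradient_force(ef.ParticleSpec(1000e-6, 1050.0), [1e4, 0, 0])
        assert np.linalg.norm(double) == pytest.approx(8 * np.linalg.norm(f), rel=1e-12)

    def test_added_mass_value_and_neutral_inertia(self, fluid):
        spec = ef.ParticleSpec(500e-6, fluid.density)
        am = ef.added_mass(spec, fluid, 0.5)
        assert am == pytest.approx(3.456e-8, rel=1e-3)
        assert ef.added_mass(spec, fluid, 0.0) == 0.0
        assert (spec.mass + am) == pytest.approx(1.5 * spec.mass, rel=1e-12)


class TestReflect:
    def test_elastic_specular_bounce_preserves_speed(self):
        v = np.array([0.3, -0.3, 0.0])  # 45 degree incidence on +y wall
        state = ParticleState(np.zeros(3), v)
        out = ef.reflect(state, [0.0, -1.0, 0.0], ef.CollisionCoefficients(1.0, 1.0))
        assert np.linalg.norm(out.velocity) == pytest.approx(np.linalg.norm(v), rel=1e-12)
        assert out.velocity == pytest.approx([0.3, 0.3, 0.0])
        assert out.bounces == 1

    def test_zero_restitution_deposits(self):
        state = ParticleState(np.zeros(3), np.array([0.1, -0.2, 0.0]))
        out = ef.reflect(state, [0.0, -1.0, 0.0], ef.CollisionCoefficients(0.0, 0.0))
        assert out.status is ef.ParticleStatus.DEPOSITED
        assert np.linalg.norm(out.velocity) == 0.0

    def test_partial_restitution_scales_kinetic_energy(self):
        state = ParticleState(np.zeros(3), np.array([0.25, -0.15, 0.1]))
        out = ef.reflect(state, [0.0, -1.0, 0.0], ef.CollisionCoefficients(0.8, 0.8))
        ke_ratio = np.sum(out.velocity**2) / np.sum(state.velocity**2)
        assert ke_ratio == pytest.approx(0.64, rel=1e-12)

    def test_non_unit_normal_rejected(self):
        state = ParticleState(np.zeros(3), np.ones(3))
        with pytest.raises(ValueError):
            ef.reflect(state, [0.0, -2.0, 0.0], ef.CollisionCoefficients())


@settings(deadline=None, max_examples=60)
@given(
    vx=st.floats(-1, 1), vy=st.floats(-1, 1), vz=st.floats(-1, 1),
    e=st.floats(0.05, 1.0),
    seed=st.integers(0, 100),
)
def test_reflect_energy_scaling_property(vx, vy, vz, e, seed):
    """Equal normal and tangential restitution scales kinetic energy by e^2."""
    v = np.array([vx, vy, vz])
    if np.linalg.norm(v) < 1e-6:
        return
    rng = np.random.default_rng(seed)
    n = rng.normal(size=3)
    n /= np.linalg.norm(n)
    state = ParticleState(np.zeros(3), v)
    out = ef.reflect(state, n, ef.CollisionCoefficients(e, e))
    assert np.sum(out.velocity**2) == pytest.approx(e**2 * np.sum(v**2), rel=1e-9)


class TestReleaseSchedule:
    def test_core_mode_releases_three_per_step(self, default_network):
        proto = ef.ReleaseProtocol(mode="core", window=100)
        sched = ef.make_release_schedule(proto, default_network, ef.SimConfig(seed=0))
        assert len(sched) == 300
        times = sorted({t for t, _ in sched})
        assert len(times) == 100

    def test_near_wall_mode_releases_six_per_step(self, default_network):
        proto = ef.ReleaseProtocol(mode="near_wall", window=10)
        sched = ef.make_release_schedule(proto, default_network, ef.SimConfig(seed=0))
        assert len(sched) == 60

    def test_schedule_deterministic_for_seed(self, default_network):
        proto = ef.ReleaseProtocol(mode="near_wall", window=5)
        a = ef.make_release_schedule(proto, default_network, ef.SimConfig(seed=9))
        b = ef.make_release_schedule(proto, default_network, ef.SimConfig(seed=9))
        for (ta, sa), (tb, sb) in zip(a, b):
            assert ta == tb
            assert np.array_equal(sa.position, sb.position)
            assert np.array_equal(sa.velocity, sb.velocity)

    def test_site_on_non_inlet_rejected(self, default_network):
        proto = ef.ReleaseProtocol(sites=(("R_MCA_O1", 0.0, 0.0),))
        with pytest.raises(ef.NetworkError):
            ef.make_release_schedule(proto, default_network, ef.SimConfig())


def _terminal_speed_oracle(spec, fluid, mode="standard_0.44"):
    """Root of |F_D| = |F_B| found by bracketing, independent of the stepper."""
    g = 9.81
    weight = spec.volume * abs(spec.density - fluid.density) * g

    def residual(v):
        return float(_drag_linear_coefficient(spec, fluid, v, mode)) * v - weight

    return brentq(residual, 1e-9, 10.0, xtol=1e-15)


class TestStepping:
    def test_uniform_comoving_fluid_is_force_free(self, fluid):
        field = UniformField(velocity=(0.12, 0.0, 0.0))
        state = ParticleState(np.zeros(3), np.array([0.12, 0.0, 0.0]))
        cfg = ef.SimConfig(gravity=(0, 0, 0))
        out = advance_in_field(state, ef.case_spec("B2"), field, fluid, cfg, duration=0.5)
        assert out.velocity == pytest.approx([0.12, 0.0, 0.0], rel=1e-12)
        assert out.position == pytest.approx([0.06, 0.0, 0.0], rel=1e-9)

    def test_settling_matches_drag_buoyancy_balance(self, fluid):
        """Heavy 200 um particle in quiescent fluid reaches the balance root;
        the Stokes closed form evaluates to 1.66e-3 m/s and bounds the speed."""
        spec = ef.ParticleSpec(200e-6, 1300.0)
        field = UniformField()
        cfg = ef.SimConfig(gravity=(0, 0, -9.81))
        state = ParticleState(np.zeros(3), np.zeros(3))
        out = advance_in_field(state, spec, field, fluid, cfg, duration=0.3)
        speed = np.linalg.norm(out.velocity)
        assert out.velocity[2] < 0
        oracle = _terminal_speed_oracle(spec, fluid)
        assert speed == pytest.approx(oracle, rel=5e-3)
        stokes = (spec.density - fluid.density) * 9.81 * spec.diameter**2 / (18 * fluid.viscosity)
        assert stokes == pytest.approx(1.66e-3, rel=1e-2)
        # the finite-Re drag correction slows settling slightly below Stokes
        assert 0.95 * stokes < speed < stokes

    def test_buoyant_particle_rises(self, fluid):
        spec = ef.ParticleSpec(500e-6, 800.0)
        out = advance_in_field(
            ParticleState(np.zeros(3), np.zeros(3)),
            spec,
            UniformField(),
            fluid,
            ef.SimConfig(gravity=(0, 0, -9.81)),
            duration=0.3,
        )
        assert out.velocity[2] > 0
        assert np.linalg.norm(out.velocity) == pytest.approx(
            _terminal_speed_oracle(spec, fluid), rel=5e-3
        )

    def test_tracer_stays_on_centerline(self, fluid):
        """Neutrally buoyant 10 um tracer on a straight-tube axis rides the
        centerline at twice the mean speed."""
        tube = make_straight_tube(length_mm=2400.0, radius_mm=2.0)
        sol = ef.solve_flow(tube, fluid, ef.BoundarySpec.default(tube, 0.2))
        field = ef.TubeField(tube, sol)
        spec = ef.ParticleSpec(10e-6, fluid.density)
        state = ParticleState(np.array([1e-3, 0.0, 0.0]), np.array([0.4, 0.0, 0.0]))
        out = advance_in_field(state, spec, field, fluid, ef.SimConfig(), duration=5.0)
        assert abs(out.position[1]) < 1e-6 and abs(out.position[2]) < 1e-6
        mean_speed = out.path_length / 5.0
        assert mean_speed == pytest.approx(0.4, rel=1e-3)

    def test_tracer_limit_deviation_monotone_in_diameter(self, default_network, default_solution, fluid):
        """On the curved carotid the deviation from the smallest-tracer path
        grows with particle diameter at matched density."""
        field = ef.TubeField(default_network, default_solution)
        seg = default_network.segment("R_ICA")
        entry = seg.centerline[0] * 1e-3
        t = seg.centerline[1] - seg.centerline[0]
        t = t / np.linalg.norm(t)
        finals = {}
        for d in (10e-6, 100e-6, 400e-6):
            spec = ef.ParticleSpec(d, fluid.density)
            state = ParticleState(entry.copy(), 0.4 * t)
            out = advance_in_field(state, spec, field, fluid, ef.SimConfig(), duration=0.3)
            finals[d] = out.position
        ref = finals[10e-6]
        dev = [np.linalg.norm(finals[d] - ref) for d in (100e-6, 400e-6)]
        assert dev[1] > dev[0]

    def test_step_advances_one_outer_step(self, default_network, default_solution, fluid):
        seg = default_network.segment("BA")
        entry = seg.centerline[0] * 1e-3
        t = seg.centerline[1] - seg.centerline[0]
        t = t / np.linalg.norm(t)
        state = ParticleState(entry, 0.2 * t)
        out = ef.step(state, ef.case_spec("B2"), default_network, default_solution, fluid, ef.SimConfig())
        assert out.time == pytest.approx(state.time + 0.01)
        assert out.path_length > 0


class TestRun:
    def test_particles_conserved_and_deterministic(self, b2_core_records, default_network,
                                                   default_solution, fluid):
        records = b2_core_records
        n = len(records)
        counts = {
            s: sum(r.outcome is s for r in records)
            for s in (ef.ParticleStatus.EXITED, ef.ParticleStatus.TRAPPED, ef.ParticleStatus.DEPOSITED)
        }
        assert sum(counts.values()) == n
        proto = ef.ReleaseProtocol(mode="core", window=34)
        again = ef.run(default_network, default_solution, ef.case_spec("B2"), proto,
                       ef.SimConfig(seed=7), fluid, case="B2")
        for a, b in zip(records, again):
            assert a.outcome is b.outcome and a.outlet == b.outlet
            assert a.path_length_m == b.path_length_m
            assert np.array_equal(a.samples, b.samples)

    def test_path_length_at_least_displacement(self, b2_core_records):
        for r in b2_core_records:
            if len(r.samples) < 2:
                continue
            start = r.samples[0][1:4]
            end = r.samples[-1][1:4]
            assert r.path_length_m >= np.linalg.norm(end - start) - 1e-12

    def test_exited_records_have_outlet_and_positive_residence(self, b2_core_records):
        for r in b2_core_records:
            if r.exited:
                assert r.outlet in ef.OUTLET_LABELS
                assert r.residence_s > 0
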