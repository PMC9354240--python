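"""Simulator unit and property tests: fuel map, wall mobility, membrane
permeation, the Brownian-dynamics stepper and ensemble generation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from guvmotors.params import (
    AcquisitionParams,
    CompartmentParams,
    ExperimentCondition,
    MotorParams,
    ParticleState,
    bulk_compartment,
)
from guvmotors.simulator import (
    crowding_factor,
    fuel_to_speed,
    permeate_fuel,
    rotational_time,
    simulate_condition,
    simulate_confined_mixture,
    simulate_ensemble_3d,
    simulate_trajectory,
    step,
    wall_mobility,
)


class TestFuelToSpeed:
    @pytest.mark.parametrize("fuel, v_max, k, expected", [
        (0.0, 0.5, 1.0, 0.0),                  # no fuel, no propulsion
        (1.0, 0.5, 1.0, 0.25),                 # half-saturation
        (3.4, 0.5, 1.0, 0.5 * 3.4 / 4.4),      # direct evaluation
    ])
    def test_saturating_law(self, fuel, v_max, k, expected):
        m = MotorParams(v_max=v_max, K_fuel=k)
        assert fuel_to_speed(fuel, m) == pytest.approx(expected, abs=1e-12)

    def test_negative_fuel_rejected(self, motor):
        with pytest.raises(ValueError):
            fuel_to_speed(-0.1, motor)

    @given(st.floats(0, 100), st.floats(0, 100))
    @settings(max_examples=50, deadline=None)
    def test_monotone_and_bounded(self, c1, c2):
        m = MotorParams(v_max=1.3, K_fuel=0.4)
        lo, hi = sorted([c1, c2])
        assert fuel_to_speed(lo, m) <= fuel_to_speed(hi, m) <= m.v_max


class TestWallMobility:
    def test_bulk_limit(self):
        comp = CompartmentParams(R_guv=1000.0, lambda_wall=2.0, m_min=0.1)
        assert wall_mobility(np.zeros(3), comp) == pytest.approx(1.0, abs=1e-2)

    def test_half_mobility_at_coupling_length(self):
        comp = CompartmentParams(R_guv=10.0, lambda_wall=2.0, m_min=1e-9)
        # gap d equals lambda_wall at r = R - radius_p - lambda_wall
        pos = np.array([10.0 - 0.6 - 2.0, 0.0, 0.0])
        assert wall_mobility(pos, comp) == pytest.approx(0.5, abs=1e-6)

    def test_disabled_coupling(self):
        comp = CompartmentParams(R_guv=10.0, lambda_wall=0.0)
        assert wall_mobility(np.array([9.0, 0, 0]), comp) == 1.0

    def test_outside_compartment_rejected(self):
        comp = CompartmentParams(R_guv=5.0)
        with pytest.raises(ValueError):
            wall_mobility(np.array([6.0, 0, 0]), comp)

    def test_monotone_in_gap(self):
        comp = CompartmentParams(R_guv=12.0, lambda_wall=3.0, m_min=0.05)
        radii = np.linspace(0, 11.0, 30)
        ms = [wall_mobility(np.array([r, 0, 0]), comp) for r in radii]
        assert np.all(np.diff(ms) <= 1e-12)
        assert all(comp.m_min <= m <= 1.0 for m in ms)


class TestPermeateFuel:
    def test_equilibrium_fixed_point(self):
        comp = CompartmentParams(R_guv=10.0)
        for t in (0.0, 1.0, 100.0):
            assert permeate_fuel(2.0, 2.0, comp, t) == pytest.approx(2.0)

    def test_exponential_relaxation_oracle(self):
        # closed form: c_in(t) = c_out + (c0 - c_out) exp(-3 P t / R)
        comp = CompartmentParams(R_guv=10.0, permeability=1.1e-6)
        tau = comp.R_guv / (3 * comp.permeability * 1e6)
        assert tau == pytest.approx(3.0303, rel=1e-3)
        for t in (0.5, 3.0, 10.0):
            expected = 3.4 * (1 - math.exp(-t / tau))
            assert permeate_fuel(0.0, 3.4, comp, t) == pytest.approx(expected, rel=1e-9)

    def test_pore_forming_membrane_equilibrates_within_frame(self):
        # alpha-hemolysin pores: >= 100x bilayer permeability
        comp = CompartmentParams(R_guv=10.0, permeability=1.1e-4)
        c = permeate_fuel(0.0, 3.4, comp, 0.2)
        assert c == pytest.approx(3.4, rel=2e-3)

    def test_bounded_between_endpoints(self):
        comp = CompartmentParams(R_guv=15.0)
        c = permeate_fuel(1.0, 3.0, comp, 2.0)
        assert 1.0 < c < 3.0


class TestCrowdingFactor:
    def test_disabled(self):
        for n in (1, 10, 100):
            assert crowding_factor(n, 10.0, 0.0) == 1.0

    def test_half_at_unit_density_product(self):
        r = 10.0
        vol = 4 / 3 * math.pi * r**3
        assert crowding_factor(50, r, vol / 50) == pytest.approx(0.5)

    def test_monotone_in_count(self):
        f = [crowding_factor(n, 12.0, 500.0) for n in (1, 5, 20, 80)]
        assert all(a > b for a, b in zip(f, f[1:]))


class TestRotationalTime:
    def test_stokes_einstein_debye_value(self):
        # independent evaluation of kT / (8 pi mu r^3) for r = 0.6 um,
        # water at 25 C (mu = 0.89 mPa s)
        kt = 1.380649e-23 * 298.15
        d_r = kt / (8 * math.pi * 0.89e-3 * (0.6e-6) ** 3)
        assert rotational_time(0.6) == pytest.approx(1.0 / d_r, rel=1e-9)
        assert rotational_time(0.6) == pytest.approx(1.17, abs=0.02)

    def test_cubic_scaling(self):
        assert rotational_time(1.2) == pytest.approx(8 * rotational_time(0.6), rel=1e-9)

    def test_upper_size_range_matches_seconds_band(self):
        # particles in the upper part of the 1.2 +/- 0.4 um size
        # distribution relax on the 1.5-3 s timescale
        assert 1.5 < rotational_time(0.8) < 3.0


class TestStep:
    def test_quiescent_particle_stays_put(self, small_guv):
        m = MotorParams(D_T0=1e-15, D_R=1e-15, v_max=1e-15, K_fuel=1.0)
        s = ParticleState(position=np.array([1.0, 0, 0]),
                          orientation=np.array([0, 0, 1.0]))
        out = step(s, m, small_guv, 0.01, np.random.default_rng(0), v=0.0)
        assert np.allclose(out.position, s.position, atol=1e-6)

    def test_deterministic_given_seed(self, motor, small_guv):
        s = ParticleState(position=np.zeros(3), orientation=np.array([1.0, 0, 0]))
        a = step(s, motor, small_guv, 0.01, np.random.default_rng(42), v=0.5)
        b = step(s, motor, small_guv, 0.01, np.random.default_rng(42), v=0.5)
        assert np.array_equal(a.position, b.position)
        assert np.array_equal(a.orientation, b.orientation)

    def test_orientation_stays_unit(self, motor, small_guv):
        rng = np.random.default_rng(3)
        s = ParticleState(position=np.zeros(3), orientation=np.array([1.0, 0, 0]))
        for _ in range(200):
            s = step(s, motor, small_guv, 0.01, rng, v=0.3)
        assert np.linalg.norm(s.orientation) == pytest.approx(1.0, abs=1e-9)

    def test_nan_state_rejected(self, motor, small_guv):
        s = ParticleState(position=np.zeros(3), orientation=np.array([1.0, 0, 0]))
        s.position = np.array([np.nan, 0, 0])
        with pytest.raises(ValueError):
            step(s, motor, small_guv, 0.01, np.random.default_rng(0))


class TestEnsemble:
    def test_free_brownian_law(self, motor, clean_acq, bulk):
        # <|dx_3D|^2> = 6 D t, closed-form oracle
        pos = simulate_ensemble_3d(200, motor, bulk, clean_acq, master_seed=7)
        t = 10 * clean_acq.frame_interval
        msd3 = np.mean(np.sum((pos[:, 10] - pos[:, 0]) ** 2, axis=1))
        assert msd3 == pytest.approx(6 * motor.D_T0 * t, rel=0.15)

    def test_orientation_decorrelation_rate(self, clean_acq, bulk):
        # <e(t).e(0)> = exp(-2 D_R t) for the isotropic rotor
        motor = MotorParams(D_R=2.0)
        n, dt, steps = 400, 0.01, 100
        rng = np.random.default_rng(5)
        from guvmotors.simulator import _ensemble_step, _random_orientations
        ori = _random_orientations(n, rng)
        ori0 = ori.copy()
        pos = np.zeros((n, 3))
        for _ in range(steps):
            _ensemble_step(pos, ori, rng.standard_normal((n, 3)),
                           rng.standard_normal((n, 3)), 0.0, motor, bulk, dt)
        corr = np.mean(np.sum(ori * ori0, axis=1))
        assert corr == pytest.approx(math.exp(-2 * motor.D_R * steps * dt), abs=0.08)


class TestSimulateTrajectory:
    def test_frame_count_and_duration(self, motor, clean_acq, small_guv):
        traj = simulate_trajectory(motor, small_guv, clean_acq, master_seed=1)
        assert len(traj) == 301
        assert traj.times[-1] == pytest.approx(60.0)

    def test_containment(self, motor, small_guv):
        acq = AcquisitionParams()  # localization noise on
        for seed in (1, 2, 3):
            traj = simulate_trajectory(motor, small_guv, acq, master_seed=seed)
            r = np.linalg.norm(traj.xy, axis=1)
            assert np.all(r <= small_guv.R_guv + 1e-12)

    def test_bit_identical_repeat(self, motor, clean_acq, small_guv):
        a = simulate_trajectory(motor, small_guv, clean_acq, v=0.4, master_seed=9)
        b = simulate_trajectory(motor, small_guv, clean_acq, v=0.4, master_seed=9)
        assert np.array_equal(a.xy, b.xy)


class TestSimulateCondition:
    def test_distinct_independent_particles(self):
        cond = ExperimentCondition(label="x", guv_diameter=20.0, n_particles=5,
                                   seed=4)
        acq = AcquisitionParams(duration=10.0)
        trajs = simulate_condition(cond, acq=acq)
        assert len(trajs) == 5
        for a, b in zip(trajs, trajs[1:]):
            assert not np.array_equal(a.xy, b.xy)

    def test_master_seed_reproducibility(self):
        cond = ExperimentCondition(label="x", guv_diameter=20.0, n_particles=3,
                                   seed=11)
        acq = AcquisitionParams(duration=10.0)
        t1 = simulate_condition(cond, acq=acq)
        t2 = simulate_condition(cond, acq=acq)
        for a, b in zip(t1, t2):
            assert np.array_equal(a.xy, b.xy)

    def test_crowding_off_equals_unit_factor(self):
        acq = AcquisitionParams(duration=10.0)
        base = ExperimentCondition(label="a", fuel=0.85, guv_diameter=20.0,
                                   n_particles=3, crowding_beta=0.0, seed=2)
        tiny = ExperimentCondition(label="b", fuel=0.85, guv_diameter=20.0,
                                   n_particles=3, crowding_beta=1e-12, seed=2)
        for a, b in zip(simulate_condition(base, acq=acq),
                        simulate_condition(tiny, acq=acq)):
            assert np.allclose(a.xy, b.xy)

    def test_mixture_is_deterministic(self):
        acq = AcquisitionParams(duration=10.0)
        a = simulate_confined_mixture(0.0, seed=3, n_particles=4, acq=acq)
        b = simulate_confined_mixture(0.0, seed=3, n_particles=4, acq=acq)
        for x, y in zip(a, b):
            assert np.array_equal(x.xy, y.xy)
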