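import math

import numpy as np
import pytest
from scipy.optimize import brentq

from asterdrag import (
    ModelError,
    MicrotubuleArray,
    baseline_geometry,
    baseline_params,
    generate_aster,
    grow_microtubules,
    make_geometry,
    max_length_to_cortex,
    run,
    slender_body_coefficient,
    solve_velocity,
    sphere_drag_coefficient,
    vesicle_axis_force_terms,
)

X = np.array([1.0, 0.0, 0.0])


def _mts(directions, lengths):
    directions = np.asarray(directions, dtype=float)
    return MicrotubuleArray(
        directions=directions,
        lengths=np.asarray(lengths, dtype=float),
        axis_cosines=directions @ X,
    )


def bisection_velocity(mts, geometry, params):
    """Independent root-find of the force-balance residual (no closed form)."""
    pull, back = vesicle_axis_force_terms(mts, params)
    centro = sphere_drag_coefficient(geometry.centrosome_radius)
    zeta = np.sum(slender_body_coefficient(mts.lengths, params.mt_radius, mts.axis_cosines))

    def residual(u):
        return (pull - back * u) - params.viscosity_ratio * (centro + zeta) * u

    return brentq(residual, -100.0, 100.0, xtol=1e-14, rtol=1e-15)


class TestSolveVelocity:
    def test_mirror_symmetric_aster_is_stationary(self):
        geometry = baseline_geometry()
        dirs = np.array([[1.0, 0, 0], [-1.0, 0, 0], [0.6, 0.8, 0], [-0.6, -0.8, 0]])
        mts = _mts(dirs, [7.0, 7.0, 3.0, 3.0])
        assert solve_velocity(mts, geometry, baseline_params()) == 0.0

    def test_single_rod_matches_bisection_oracle(self):
        geometry = baseline_geometry()
        params = baseline_params(viscosity_ratio=3.0)
        mts = _mts([[1.0, 0, 0]], [100.0])
        u = solve_velocity(mts, geometry, params)
        expected = (6 * math.pi * 0.05 * 2 * 200) / (
            6 * math.pi * 0.05 * 200
            + 3.0 * (12 * math.pi + 200 * math.pi / (math.log(16000.0) - 0.5))
        )
        assert u == pytest.approx(expected, rel=1e-14)
        assert u == pytest.approx(0.7437, abs=5e-4)
        assert u == pytest.approx(bisection_velocity(mts, geometry, params), rel=1e-12)

    def test_no_cargo_motion_means_no_centering_force(self):
        geometry = baseline_geometry()
        mts = _mts([[1.0, 0, 0], [0.0, 1.0, 0]], [50.0, 80.0])
        assert solve_velocity(mts, geometry, baseline_params(vesicle_speed=0.0)) == 0.0

    def test_closed_form_agrees_with_bisection_on_random_states(self, rng):
        geometry = baseline_geometry()
        _, frame = make_geometry(500.0, 2.0, 4.0)
        for _ in range(100):
            n = int(rng.integers(1, 60))
            params = baseline_params(
                mt_count=n,
                vesicle_radius=float(rng.uniform(0.02, 0.3)),
                vesicle_speed=float(rng.uniform(0.1, 3.0)),
                viscosity_ratio=float(rng.uniform(0.5, 10.0)),
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            mts = generate_aster(params, frame)
            mts.lengths[:] = rng.uniform(2.0, 400.0, size=n)
            u = solve_velocity(mts, geometry, params)
            assert u == pytest.approx(
                bisection_velocity(mts, geometry, params), rel=1e-10
            )

    def test_exactly_linear_in_cargo_speed(self):
        geometry = baseline_geometry()
        _, frame = make_geometry(500.0, 2.0, 4.0)
        mts = generate_aster(baseline_params(mt_count=30), frame, seed=4)
        mts.lengths[:] = np.linspace(2.0, 120.0, 30)
        u1 = solve_velocity(mts, geometry, baseline_params(vesicle_speed=1.3))
        u2 = solve_velocity(mts, geometry, baseline_params(vesicle_speed=2.6))
        assert u2 == pytest.approx(2.0 * u1, rel=1e-12)

    def test_empty_aster_rejected(self):
        mts = MicrotubuleArray(
            directions=np.zeros((0, 3)),
            lengths=np.zeros(0),
            axis_cosines=np.zeros(0),
        )
        with pytest.raises(ModelError):
            solve_velocity(mts, baseline_geometry(), baseline_params())

    def test_centering_speed_scales_as_vesicle_radius_over_viscosity_ratio(self):
        """In the regime where the cargo back-reaction is a small part of the
        denominator, u is proportional to R_v and inversely proportional to r."""
        geometry = baseline_geometry()
        _, frame = make_geometry(500.0, 2.0, 4.0)
        base = baseline_params(mt_count=50, vesicle_radius=0.002, viscosity_ratio=2.0)
        mts = generate_aster(base, frame, seed=9)
        mts.lengths[:] = np.linspace(5.0, 300.0, 50)
        pull, back = vesicle_axis_force_terms(mts, base)
        zeta = np.sum(slender_body_coefficient(mts.lengths, base.mt_radius, mts.axis_cosines))
        centro = sphere_drag_coefficient(geometry.centrosome_radius)
        denom = back + base.viscosity_ratio * (centro + zeta)
        assert back < 0.1 * denom  # regime guard
        u = solve_velocity(mts, geometry, base)
        u_2r = solve_velocity(
            mts, geometry, baseline_params(mt_count=50, vesicle_radius=0.002, viscosity_ratio=4.0)
        )
        u_2Rv = solve_velocity(
            mts, geometry, baseline_params(mt_count=50, vesicle_radius=0.004, viscosity_ratio=2.0)
        )
        # a back-reaction below 10% of the denominator bounds the deviation
        # from exact proportionality by ~5%
        assert u_2r == pytest.approx(u / 2.0, rel=0.06)
        assert u_2Rv == pytest.approx(2.0 * u, rel=0.06)


class TestGrowMicrotubules:
    def test_free_growth_step(self):
        geometry, frame = make_geometry(500.0, 2.0, 4.0)
        mts = _mts([[1.0, 0, 0]], [2.0])
        grown = grow_microtubules(mts, frame, geometry, baseline_params())
        assert grown.lengths[0] == pytest.approx(2.125)
        assert not grown.at_boundary[0]

    def test_clamped_at_near_wall(self):
        geometry, frame = make_geometry(500.0, 2.0, 4.0)
        mts = _mts([[-1.0, 0, 0]], [4.0])
        grown = grow_microtubules(mts, frame, geometry, baseline_params())
        assert grown.lengths[0] == pytest.approx(4.0)
        assert grown.at_boundary[0]

    def test_clamped_rod_resumes_growth_when_centrosome_advances(self):
        geometry, frame = make_geometry(500.0, 2.0, 4.0)
        mts = _mts([[-1.0, 0, 0]], [4.0])
        advanced = type(frame)(frame.origin, frame.axis_unit, 495.0)
        limit = max_length_to_cortex(advanced, geometry, np.array([-1.0, 0.0, 0.0]))
        assert limit == pytest.approx(5.0)
        grown = grow_microtubules(mts, advanced, geometry, baseline_params())
        assert grown.lengths[0] == pytest.approx(4.125)
        assert not grown.at_boundary[0]

    def test_lengths_never_exceed_wall_distance(self, rng):
        geometry, frame = make_geometry(500.0, 2.0, 4.0)
        params = baseline_params(mt_count=64, polymerization_rate=5.0)
        mts = generate_aster(params, frame, seed=5)
        for _ in range(30):
            mts = grow_microtubules(mts, frame, geometry, params)
        limits = max_length_to_cortex(frame, geometry, mts.directions)
        assert np.all(mts.lengths <= np.asarray(limits).reshape(-1) + 1e-9)


class TestRun:
    def test_zero_duration_single_point(self):
        traj = run(baseline_params(duration=0.0), baseline_geometry(), seed=1)
        assert len(traj) == 1
        assert traj.centrosome_coords[0] == pytest.approx(496.0)

    def test_deterministic_given_seed(self):
        p = baseline_params(duration=120.0)
        a = run(p, baseline_geometry(), seed=7)
        b = run(p, baseline_geometry(), seed=7)
        np.testing.assert_array_equal(a.centrosome_coords, b.centrosome_coords)
        np.testing.assert_array_equal(a.centrosome_speeds, b.centrosome_speeds)

    def test_trajectory_invariants(self, baseline_trajectories, geometry):
        for traj in baseline_trajectories:
            assert len(traj.times) == len(traj.centrosome_coords) == len(traj.centrosome_speeds)
            np.testing.assert_allclose(np.diff(traj.times), 0.5, rtol=1e-12)
            limit = geometry.cell_radius - geometry.centrosome_radius
            assert np.all(np.abs(traj.centrosome_coords) <= limit + 1e-9)

    def test_motion_toward_center_after_asymmetry_develops(self, baseline_trajectories):
        """Once the near-side rods clamp, far-side rods carry more cargo and the
        centrosome keeps moving toward the centre."""
        for traj in baseline_trajectories:
            after_transient = traj.times >= 60.0
            assert np.all(traj.centrosome_speeds[after_transient] > 0)

    def test_speed_ramps_up_then_slows_down(self, baseline_trajectories):
        for traj in baseline_trajectories:
            k_max = int(np.argmax(traj.centrosome_speeds))
            assert 0 < k_max < len(traj) - 1
            assert traj.centrosome_speeds[-1] < traj.centrosome_speeds[k_max]

    def test_first_sample_matches_solve_velocity(self):
        geometry, frame = make_geometry(500.0, 2.0, 4.0)
        params = baseline_params(duration=10.0)
        traj = run(params, geometry, seed=3)
        mts = generate_aster(params, frame, seed=3)
        assert traj.centrosome_speeds[0] == pytest.approx(
            solve_velocity(mts, geometry, params), rel=1e-12
        )

    def test_near_wall_contact_recorded_early(self, baseline_summaries):
        for s in baseline_summaries:
            assert s.near_touch_time is not None and s.near_touch_time < 60.0

    def test_drag_breakdown_recording(self):
        traj = run(baseline_params(duration=5.0), baseline_geometry(), seed=1, record_drag=True)
        assert traj.drag_breakdowns is not None
        assert len(traj.drag_breakdowns) == len(traj)
        b = traj.drag_breakdowns[0]
        assert b.centrosome_coefficient == pytest.approx(12.0 * math.pi)
        assert b.mt_coefficient_sum > 0
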