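import math

import numpy as np
import pytest

import axogrow as ax
from axogrow.errors import GeometryError, InvalidParameterError, SingularForceError
from axogrow.geometry import NodeLayout
from axogrow.growth import STATUS_MAX_STEPS, STATUS_SUCCESS


def _single_node_layout(x, y):
    """Layout exposing one center at (x, y) for closed-form force checks."""
    r = math.hypot(x, y)
    ang = math.atan2(y, x)
    return NodeLayout(
        radius=r, n_nodes=2, rho=0.0,
        base_angles=np.array([ang, ang + np.pi]),
        perturbations=np.zeros(2),
    )


class TestNetForce:
    def test_symmetric_layout_cancels_at_center(self):
        layout = ax.place_nodes(1.0, 4)
        f = ax.net_force(np.array([0.0, 0.0]), layout, beta=1.0)
        assert np.allclose(f, 0.0, atol=1e-14)

    @pytest.mark.parametrize(
        "node,expected",
        [((1.0, 0.0), (1.0, 0.0)), ((2.0, 0.0), (0.5, 0.0))],
    )
    def test_single_node_magnitude_is_distance_to_minus_beta(self, node, expected):
        # second (antipodal) node contributes in the opposite direction; cancel
        # it by measuring the difference from the antipodal-only contribution.
        layout = _single_node_layout(*node)
        f = ax.net_force(np.array([0.0, 0.0]), layout, beta=1.0)
        anti = -np.asarray(node) / np.linalg.norm(node) ** 2
        assert np.allclose(f - anti, expected, rtol=1e-12)

    @pytest.mark.parametrize("beta", [0.98, 1.0, 1.02])
    def test_matches_scalar_summation_oracle(self, small_layout, rng, beta):
        coords = small_layout.center_coords
        for _ in range(100):
            phi, rad = rng.uniform(0, 2 * np.pi), rng.uniform(0, 0.9) * small_layout.radius
            s = rad * np.array([np.cos(phi), np.sin(phi)])
            fx = fy = 0.0
            for cxy in coords:  # term-by-term scalar oracle
                dx, dy = cxy[0] - s[0], cxy[1] - s[1]
                d = math.hypot(dx, dy)
                fx += dx * d ** (-(beta + 1))
                fy += dy * d ** (-(beta + 1))
            assert np.allclose(ax.net_force(s, small_layout, beta), [fx, fy], rtol=1e-9)

    def test_singular_at_center_raises(self, small_layout):
        with pytest.raises(SingularForceError):
            ax.net_force(small_layout.center_coords[0], small_layout, beta=1.0)


class TestClampDirection:
    def test_within_theta_returns_desired(self):
        d = np.array([np.cos(np.radians(10)), np.sin(np.radians(10))])
        out = ax.clamp_direction(np.array([1.0, 0.0]), d, np.radians(15))
        assert np.allclose(out, d)

    def test_beyond_theta_clamps_to_theta(self):
        d = np.array([np.cos(np.radians(30)), np.sin(np.radians(30))])
        out = ax.clamp_direction(np.array([1.0, 0.0]), d, np.radians(15))
        assert np.allclose(out, [np.cos(np.radians(15)), np.sin(np.radians(15))])

    def test_antiparallel_rotates_counterclockwise(self):
        out = ax.clamp_direction(np.array([1.0, 0.0]), np.array([-1.0, 0.0]), np.radians(15))
        assert out[1] > 0  # ccw convention
        assert np.isclose(math.atan2(out[1], out[0]), np.radians(15))

    def test_zero_desired_falls_back_to_previous(self):
        prev = np.array([0.0, 1.0])
        assert np.allclose(ax.clamp_direction(prev, np.zeros(2), np.radians(15)), prev)


class TestGrowAxon:
    def test_long_step_terminates_in_one_step_on_far_arc(self, small_layout):
        cfg = ax.GrowthConfig(beta=1.0, step_length=3 * small_layout.radius, n_axons=1, seed=0)
        seed_pt = small_layout.radius * np.array([np.cos(0.3), np.sin(0.3)])
        traj = ax.grow_axon(seed_pt, small_layout, cfg)
        assert traj.successful and traj.n_steps == 1
        assert np.isclose(np.hypot(*traj.endpoint), small_layout.radius, rtol=1e-9)

    def test_interior_steps_have_exact_length(self, small_layout):
        cfg = ax.GrowthConfig(beta=1.0, step_length=0.7, n_axons=1, seed=0)
        seed_pt = small_layout.radius * np.array([np.cos(1.0), np.sin(1.0)])
        traj = ax.grow_axon(seed_pt, small_layout, cfg)
        steps = np.linalg.norm(np.diff(traj.positions, axis=0), axis=1)
        interior = steps[:-1] if traj.successful else steps
        assert np.allclose(interior, 0.7, rtol=1e-12)
        if traj.successful:
            assert steps[-1] <= 0.7 + 1e-12

    def test_angular_constraint_holds_at_every_step(self, small_layout):
        cfg = ax.GrowthConfig(beta=1.0, step_length=0.5, n_axons=1, seed=0)
        for phi in np.linspace(0.1, 5.9, 8):
            seed_pt = small_layout.radius * np.array([np.cos(phi), np.sin(phi)])
            traj = ax.grow_axon(seed_pt, small_layout, cfg)
            dirs = traj.step_directions
            if len(dirs) > 1:
                dots = np.clip(np.sum(dirs[1:] * dirs[:-1], axis=1), -1, 1)
                assert np.all(np.arccos(dots) <= cfg.theta + 1e-9)

    def test_seed_off_circumference_rejected(self, small_layout):
        cfg = ax.GrowthConfig(beta=1.0, step_length=1.0, n_axons=1, seed=0)
        with pytest.raises(GeometryError):
            ax.grow_axon(np.array([0.0, 0.0]), small_layout, cfg)

    def test_high_beta_forms_local_connections(self, default_layout_seeded):
        # strong decay hands control to nearby nodes: almost all axons stop
        # quickly and connect nodes within 2 cyclic positions of their origin
        layout = default_layout_seeded
        cfg = ax.GrowthConfig(beta=5.0, step_length=1.0, n_axons=2000, seed=4)
        res = ax.simulate_axons(layout, cfg)
        ok = res.status == STATUS_SUCCESS
        assert ok.mean() >= 0.95
        src = ax.assign_to_region(res.seed_points[ok], layout)
        dst = ax.assign_to_region(res.endpoints[ok], layout)
        sep = np.abs(src - dst)
        sep = np.minimum(sep, layout.n_nodes - sep)
        assert np.quantile(sep, 0.95) <= 2


class TestSimulateAxons:
    def test_zero_axons_gives_empty_result(self, small_layout):
        cfg = ax.GrowthConfig(beta=1.0, step_length=1.0, n_axons=0, seed=0)
        res = ax.simulate_axons(small_layout, cfg)
        assert res.n_axons == 0

    def test_status_conservation(self, default_layout_seeded):
        cfg = ax.GrowthConfig(beta=1.0, step_length=1.0, n_axons=5000, seed=8)
        res = ax.simulate_axons(default_layout_seeded, cfg)
        assert res.n_successful + res.n_unsuccessful == res.n_axons

    def test_default_parameters_lose_few_axons(self, default_layout_seeded):
        cfg = ax.GrowthConfig(beta=1.0, step_length=1.0, n_axons=20_000, seed=8)
        res = ax.simulate_axons(default_layout_seeded, cfg)
        assert res.n_unsuccessful / res.n_axons < 0.01

    def test_identical_seeds_identical_results(self, small_layout):
        cfg = ax.GrowthConfig(beta=1.0, step_length=0.8, n_axons=500, seed=11)
        a = ax.simulate_axons(small_layout, cfg)
        b = ax.simulate_axons(small_layout, cfg)
        assert np.array_equal(a.status, b.status)
        ok = a.status == STATUS_SUCCESS
        assert np.array_equal(a.endpoints[ok], b.endpoints[ok])

    def test_batch_matches_scalar_stepper(self, default_layout_seeded):
        # vectorized kernel vs pure-Python reference, trajectory for trajectory
        cfg = ax.GrowthConfig(beta=1.0, step_length=1.0, n_axons=300, seed=13)
        res = ax.simulate_axons(default_layout_seeded, cfg)
        for a in range(res.n_axons):
            traj = ax.grow_axon(res.seed_points[a], default_layout_seeded, cfg)
            assert (traj.status == "successful") == (res.status[a] == STATUS_SUCCESS)
            if traj.successful:
                assert np.allclose(traj.endpoint, res.endpoints[a], rtol=0, atol=1e-9)
            assert traj.n_steps == res.n_steps[a]

    def test_small_beta_black_hole_traps_axons(self, default_layout_seeded):
        # at beta = 0.9 a central trapping region emerges: a measurable
        # fraction of axons never reaches the circumference
        cfg = ax.GrowthConfig(beta=0.9, step_length=1.0, n_axons=2000, seed=2)
        res = ax.simulate_axons(default_layout_seeded, cfg)
        assert (res.status == STATUS_MAX_STEPS).mean() > 0.05

    def test_s_max_default_is_ceil_3r_over_ls(self):
        cfg = ax.GrowthConfig(beta=1.0, step_length=0.7, n_axons=1, seed=0)
        assert cfg.resolve_s_max(30.0) == math.ceil(3 * 30.0 / 0.7)


class TestRandomWalkNull:
    def test_small_theta_gives_straight_chords(self, small_layout):
        cfg = ax.GrowthConfig(beta=1.0, step_length=0.5, theta=1e-9, n_axons=50, seed=3)
        res = ax.simulate_random_walk_null(small_layout, cfg)
        for a in range(res.n_axons):
            traj = res.trajectory(a)
            if traj.n_steps > 2:
                dirs = traj.step_directions
                assert np.allclose(dirs, dirs[0], atol=1e-6)

    def test_turns_never_exceed_theta(self, small_layout):
        cfg = ax.GrowthConfig(beta=1.0, step_length=1.0, n_axons=100, seed=6)
        res = ax.simulate_random_walk_null(small_layout, cfg)
        for a in range(20):
            dirs = res.trajectory(a).step_directions
            if len(dirs) > 1:
                dots = np.clip(np.sum(dirs[1:] * dirs[:-1], axis=1), -1, 1)
                assert np.all(np.arccos(dots) <= cfg.theta + 1e-12)

    def test_scalar_replay_matches_batch(self, small_layout):
        cfg = ax.GrowthConfig(beta=1.0, step_length=0.9, n_axons=200, seed=21)
        res = ax.simulate_random_walk_null(small_layout, cfg)
        for a in range(0, 200, 7):
            traj = res.trajectory(a)
            if traj.successful:
                assert np.allclose(traj.endpoint, res.endpoints[a], atol=1e-9)
            assert traj.n_steps == res.n_steps[a]


class TestGrowthConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(beta=1.0, step_length=0.0),
            dict(beta=1.0, step_length=1.0, theta=0.0),
            dict(beta=1.0, step_length=1.0, theta=4.0),
            dict(beta=1.0, step_length=1.0, s_max=0),
            dict(beta=1.0, step_length=1.0, n_axons=-1),
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(InvalidParameterError):
            ax.GrowthConfig(**kwargs)
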