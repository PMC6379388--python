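"""Unit and property tests for the model terms and the reference step."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wormnet.core import (
    ModelParams,
    ParticleState,
    all_pairs_interactions,
    alignment_rate,
    minimum_image,
    ou_increment,
    pair_attraction,
    pair_repulsion,
    step,
)
from wormnet.fixtures import make_uniform_gas


class TestMinimumImage:
    @pytest.mark.parametrize(
        "pi, pj, L, expected",
        [
            ((0, 0), (63.5, 0), 64.0, (-0.5, 0.0)),  # wrap-around
            ((10, 10), (10.3, 10.4), 64.0, (0.3, 0.4)),  # interior
            ((5, 5), (5, 5), 64.0, (0.0, 0.0)),  # identity
        ],
    )
    def test_examples(self, pi, pj, L, expected):
        d = minimum_image(pi, pj, L)
        assert np.allclose(d, expected)

    def test_rejects_nonfinite(self):
        with pytest.raises(ValueError):
            minimum_image((np.nan, 0), (1, 1), 8.0)

    @given(
        xi=st.floats(0, 10), xj=st.floats(0, 10),
        yi=st.floats(0, 10), yj=st.floats(0, 10),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_components_in_half_open_box(self, xi, xj, yi, yj):
        d = minimum_image((xi, yi), (xj, yj), 10.0)
        assert np.all(d > -5.0) and np.all(d <= 5.0)


class TestPairForces:
    def test_repulsion_example(self):
        # r=0.1 inside the 0.2 shell with k_r=10: coefficient -1, away from j
        F = pair_repulsion(np.array([0.1, 0.0]), k_r=10.0, r_r=0.2)
        assert np.allclose(F, [-1.0, 0.0])

    def test_repulsion_vanishes_at_shell_edge(self):
        F = pair_repulsion(np.array([0.2 - 1e-12, 0.0]), k_r=10.0, r_r=0.2)
        assert np.linalg.norm(F) < 1e-10

    def test_repulsion_antisymmetric(self, rng):
        for _ in range(20):
            d = rng.uniform(-0.1, 0.1, 2)
            if np.linalg.norm(d) < 1e-3:
                continue
            Fij = pair_repulsion(d, 10.0, 0.2)
            Fji = pair_repulsion(-d, 10.0, 0.2)
            assert np.allclose(Fij, -Fji)

    def test_repulsion_outside_shell_rejected(self):
        with pytest.raises(ValueError):
            pair_repulsion(np.array([0.5, 0.0]), 10.0, 0.2)

    def test_attraction_example(self):
        F = pair_attraction(np.array([0.0, 0.5]), k_a=0.002)
        assert np.allclose(F, [0.0, 0.004])

    def test_attraction_zero_strength(self):
        assert np.allclose(pair_attraction(np.array([0.3, 0.4]), 0.0), 0.0)

    def test_attraction_inverse_distance_law(self):
        f1 = np.linalg.norm(pair_attraction(np.array([0.25, 0.0]), 0.01))
        f2 = np.linalg.norm(pair_attraction(np.array([0.75, 0.0]), 0.01))
        assert f1 / f2 == pytest.approx(3.0, rel=1e-12)

    def test_attraction_outside_shell_rejected(self):
        with pytest.raises(ValueError):
            pair_attraction(np.array([1.5, 0.0]), 0.01)


class TestAlignment:
    @pytest.mark.parametrize(
        "neighbors, expected",
        [
            ([np.pi / 4], 1.0),  # sin(pi/2)
            ([np.pi], 0.0),  # anti-aligned is a nematic fixed point
            ([np.pi / 6, -np.pi / 6], 0.0),  # symmetric pair cancels
            ([], 0.0),  # no neighbours
        ],
    )
    def test_examples(self, neighbors, expected):
        assert alignment_rate(0.0, neighbors) == pytest.approx(expected, abs=1e-12)

    def test_matches_direct_sum(self, rng):
        for _ in range(10):
            ti = rng.uniform(-np.pi, np.pi)
            nb = rng.uniform(-np.pi, np.pi, rng.integers(1, 8))
            direct = sum(np.sin(2 * (tj - ti)) for tj in nb) / len(nb)
            assert alignment_rate(ti, nb) == pytest.approx(direct, abs=1e-12)

    def test_nematic_symmetry(self, rng):
        ti = 0.3
        nb = rng.uniform(-np.pi, np.pi, 5)
        flipped = nb + np.pi * rng.integers(0, 2, 5)
        assert alignment_rate(ti, nb) == pytest.approx(
            alignment_rate(ti, flipped), abs=1e-12
        )

    def test_bounded(self, rng):
        for _ in range(20):
            r = alignment_rate(
                rng.uniform(-np.pi, np.pi),
                rng.uniform(-np.pi, np.pi, rng.integers(1, 20)),
            )
            assert -1.0 <= r <= 1.0


class TestOUIncrement:
    def test_fixed_point(self):
        p = ModelParams(k_a=0.0, sigma_omega=0.0, n_particles=1, box_side=8)
        assert ou_increment(np.array([p.omega0]), p, np.zeros(1))[0] == p.omega0

    def test_deterministic_decay(self):
        p = ModelParams(
            k_a=0.0, sigma_omega=0.0, tau=10.0, dt=0.001,
            omega0=0.0, n_particles=1, box_side=8,
        )
        out = ou_increment(np.array([1.0]), p, np.zeros(1))
        assert out[0] == pytest.approx(0.9999, abs=1e-15)

    def test_stationary_moments_short_run(self):
        # 1e5-step chain: mean and s.d. within 3 standard errors of closed form
        p = ModelParams(
            k_a=0.0, omega0=0.0035, sigma_omega=0.35, tau=10.0,
            n_particles=1, box_side=8,
        )
        rng = np.random.default_rng(0)
        n = 100_000
        om = np.empty(n)
        om[0] = p.omega0
        noise = rng.standard_normal(n)
        for k in range(1, n):
            om[k] = ou_increment(om[k - 1], p, noise[k])
        T = n * p.dt
        se_mean = p.sigma_omega * np.sqrt(2 * p.tau / T)
        assert abs(om.mean() - p.omega0) < 3 * se_mean
        n_eff = T / (2 * p.tau)
        se_sd = p.sigma_omega / np.sqrt(2 * n_eff)
        assert abs(om.std() - p.sigma_omega) < 3 * se_sd


class TestStep:
    def test_free_active_particle_moves_dt_per_step(self):
        p = ModelParams(k_a=0.002, n_particles=1, box_side=8.0)
        st0 = ParticleState(
            0.0, np.array([4.0]), np.array([4.0]), np.array([0.7]),
            np.array([0.1]), np.ones(1),
        )
        st1 = step(st0, p, noise=np.zeros(1))
        disp = np.hypot(st1.x[0] - st0.x[0], st1.y[0] - st0.y[0])
        assert disp == pytest.approx(p.dt, rel=1e-14)

    def test_inactive_particle_is_frozen_when_isolated(self):
        p = ModelParams(k_a=0.002, n_particles=1, box_side=8.0)
        st0 = ParticleState(
            0.0, np.array([4.0]), np.array([4.0]), np.array([0.7]),
            np.array([0.4]), np.zeros(1),
        )
        st1 = step(st0, p, noise=np.zeros(1))
        assert st1.x[0] == st0.x[0] and st1.y[0] == st0.y[0]
        assert st1.theta[0] == st0.theta[0]  # no propulsion, no intrinsic turn

    def test_momentum_conservation_of_internal_forces(self, small_gas):
        state, params = small_gas
        fx, fy, _ = all_pairs_interactions(state.x, state.y, state.theta, params)
        assert abs(fx.sum()) < 1e-10 and abs(fy.sum()) < 1e-10

    def test_nematic_symmetry_of_interactions(self, small_gas, rng):
        state, params = small_gas
        fx, fy, al = all_pairs_interactions(state.x, state.y, state.theta, params)
        flip = rng.integers(0, 2, state.n) * np.pi
        fx2, fy2, al2 = all_pairs_interactions(
            state.x, state.y, state.theta + flip, params
        )
        assert np.allclose(fx, fx2) and np.allclose(fy, fy2)
        assert np.allclose(al, al2, atol=1e-12)

    def test_translation_equivariance(self, small_gas):
        state, params = small_gas
        noise = np.random.default_rng(3).standard_normal(state.n)
        moved = state.copy()
        moved.x = np.mod(moved.x + 2.0, params.box_side)
        moved.y = np.mod(moved.y + 3.0, params.box_side)
        s1 = step(state, params, noise=noise)
        s2 = step(moved, params, noise=noise)
        dx = np.mod(s2.x - s1.x, params.box_side)
        dy = np.mod(s2.y - s1.y, params.box_side)
        assert np.allclose(dx, 2.0) and np.allclose(dy, 3.0)
        assert np.allclose(s1.theta, s2.theta)

    def test_rotation_equivariance_quarter_turn(self, small_gas):
        # rotate positions and headings by pi/2 about the box centre:
        # with the same noise stream the trajectory rotates identically
        state, params = small_gas
        L = params.box_side
        noise = np.random.default_rng(4).standard_normal(state.n)
        rot = state.copy()
        rot.x, rot.y = np.mod(L - state.y, L), state.x.copy()
        rot.theta = state.theta + np.pi / 2
        s1 = step(state, params, noise=noise)
        s2 = step(rot, params, noise=noise)
        assert np.allclose(np.mod(L - s1.y, L), s2.x)
        assert np.allclose(s1.x, s2.y)
        assert np.allclose(s1.theta + np.pi / 2, s2.theta)


class TestParamValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(k_a=0.002, r_r=1.5, n_particles=4, box_side=8),
            dict(k_a=0.002, dt=-0.1, n_particles=4, box_side=8),
            dict(k_a=0.002, tau=0.0, n_particles=4, box_side=8),
            dict(k_a=-1.0, n_particles=4, box_side=8),
            dict(k_a=0.002, box_side=1.5, n_particles=4),
            dict(k_a=0.002, box_side=8),  # neither N nor density
        ],
    )
    def test_invalid_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ModelParams(**kwargs)

    def test_density_to_count(self):
        p = ModelParams(k_a=0.001, box_side=24.0, density=4.0)
        assert p.n == 2304

    def test_state_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ParticleState(
                0.0, np.zeros(3), np.zeros(2), np.zeros(3),
                np.zeros(3), np.ones(3),
            )
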