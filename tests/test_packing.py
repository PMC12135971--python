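"""Hard-disk Monte Carlo: lattice geometry, cell list, moves, invariants."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from disksq import packing
from disksq.packing import (CLOSE_PACKING, ConsistencyError, DiskConfiguration,
                            PackingError, PackingSpec, StepPolicy,
                            attempt_move, build_tile_grid, collision_check,
                            hexagonal_init, hexagonal_spacing,
                            min_image_distance, run_simulation, tune_step_size)

from conftest import brute_force_collision, brute_force_min_distance


def _manual_config(l, positions, phi0=0.1):
    positions = np.asarray(positions, dtype=float)
    return DiskConfiguration(l=l, positions=positions, a=3.0, n_x=0, n_y=0,
                             phi0=phi0)


class TestHexagonalSpacing:
    @pytest.mark.parametrize("phi0, expected", [
        (CLOSE_PACKING - 1e-12, 2.0),          # touching at close packing
        (0.6, 2.458866),
        (0.15, 2 * 2.458866),                  # a ~ phi^(-1/2)
    ])
    def test_values(self, phi0, expected):
        assert hexagonal_spacing(phi0) == pytest.approx(expected, rel=1e-5)

    @pytest.mark.parametrize("bad", [0.0, -0.1, CLOSE_PACKING, 0.95])
    def test_domain_error_names_bound(self, bad):
        with pytest.raises(PackingError, match="close-packing"):
            hexagonal_spacing(bad)

    @given(st.floats(0.01, 0.85))
    @settings(max_examples=50, deadline=None)
    def test_exceeds_contact(self, phi0):
        assert hexagonal_spacing(phi0) > 2.0


class TestHexagonalInit:
    def test_reference_lattice_counts(self):
        config = hexagonal_init(PackingSpec(phi0=0.6, l=500.0))
        assert (config.n_x, config.n_y) == (203, 234)
        assert config.phi_actual == pytest.approx(203 * 234 * math.pi / 500**2)
        assert config.phi_actual == pytest.approx(0.5969, abs=2e-4)
        assert config.phi_actual <= 0.6

    def test_small_box_overlap_free(self):
        config = hexagonal_init(PackingSpec(phi0=0.05, l=20.0))
        assert config.n == config.n_x * config.n_y
        assert np.all(config.positions >= 0)
        assert np.all(config.positions < 20.0)
        assert brute_force_min_distance(config) >= 2.0

    @pytest.mark.parametrize("phi0", [0.2, 0.45, 0.71])
    def test_min_distance(self, phi0):
        config = hexagonal_init(PackingSpec(phi0=phi0, l=60.0))
        assert brute_force_min_distance(config) >= 2.0 - 1e-12

    def test_box_too_small(self):
        with pytest.raises(PackingError, match="too small"):
            hexagonal_init(PackingSpec(phi0=0.05, l=5.0))


class TestMinImage:
    @pytest.mark.parametrize("p, q, l, expected", [
        ((0.5, 0.5), (499.5, 0.5), 500.0, 1.0),   # wrap across the seam
        ((1.0, 2.0), (1.0, 2.0), 10.0, 0.0),
        ((0.0, 0.0), (3.0, 4.0), 500.0, 5.0),
    ])
    def test_values(self, p, q, l, expected):
        assert min_image_distance(p, q, l) == pytest.approx(expected)

    @given(st.floats(0, 99.999), st.floats(0, 99.999),
           st.floats(0, 99.999), st.floats(0, 99.999))
    @settings(max_examples=100, deadline=None)
    def test_symmetric_and_bounded(self, x1, y1, x2, y2):
        l = 100.0
        d = min_image_distance((x1, y1), (x2, y2), l)
        assert d == pytest.approx(min_image_distance((x2, y2), (x1, y1), l))
        assert 0 <= d <= l / math.sqrt(2) + 1e-9


class TestTileGrid:
    def test_tile_count_l500(self):
        config = hexagonal_init(PackingSpec(phi0=0.1, l=500.0))
        grid = build_tile_grid(config)
        assert grid.n_tiles_per_side == 354          # ceil(500 / sqrt 2)
        assert grid.tile_side == pytest.approx(500 / 354)
        assert grid.tile_side <= math.sqrt(2)
        assert (grid.occupancy >= 0).sum() == config.n

    def test_empty_configuration(self):
        config = _manual_config(20.0, np.empty((0, 2)))
        assert np.all(build_tile_grid(config).occupancy == -1)

    def test_shared_tile_raises(self):
        # two centers in one tile necessarily violate the hard core
        config = _manual_config(20.0, [[5.45, 5.45], [5.5, 5.5]])
        with pytest.raises(ConsistencyError):
            build_tile_grid(config)

    def test_incremental_update_equals_rebuild(self, melted_config):
        config = melted_config.copy()
        grid = build_tile_grid(config)
        rng = np.random.default_rng(3)
        policy = StepPolicy(sigma=0.4)
        for _ in range(500):
            attempt_move(config, grid, int(rng.integers(config.n)), policy, rng)
        fresh = build_tile_grid(config)
        assert np.array_equal(grid.occupancy, fresh.occupancy)


class TestCollisionCheck:
    def test_strict_inequality(self):
        config = _manual_config(30.0, [[10.0, 10.0], [15.0, 10.0]])
        grid = build_tile_grid(config)
        assert collision_check(grid, config, 0, (13.01, 10.0))          # d = 1.99
        assert not collision_check(grid, config, 0, (13.0, 10.0))       # d = 2.0

    def test_ignores_self(self, melted_config):
        config = melted_config
        grid = build_tile_grid(config)
        for i in (0, config.n // 2):
            p = (config.positions[i] + 0.01) % config.l
            assert collision_check(grid, config, i, p) == \
                brute_force_collision(config, i, p)

    def test_brute_force_oracle(self, melted_config):
        config = melted_config
        grid = build_tile_grid(config)
        rng = np.random.default_rng(17)
        for _ in range(1000):
            disk_id = int(rng.integers(config.n))
            proposed = rng.uniform(0, config.l, 2)
            assert collision_check(grid, config, disk_id, proposed) == \
                brute_force_collision(config, disk_id, proposed)


class TestAttemptMove:
    def test_single_disk_always_accepted(self):
        config = _manual_config(20.0, [[5.0, 5.0]])
        grid = build_tile_grid(config)
        rng = np.random.default_rng(0)
        assert all(attempt_move(config, grid, 0, StepPolicy(sigma=2.0), rng)
                   for _ in range(100))

    def test_rejection_leaves_state_unchanged(self):
        config = _manual_config(30.0, [[10.0, 10.0], [12.05, 10.0]])
        grid = build_tile_grid(config)
        before = config.positions.copy()
        occ_before = grid.occupancy.copy()
        rng = np.random.default_rng(5)
        policy = StepPolicy(sigma=0.02)
        for _ in range(200):
            attempt_move(config, grid, 0, policy, rng)
            assert brute_force_min_distance(config) >= 2.0
        # tiny sigma against a near-contact neighbor: most moves reject and
        # rejected attempts must not touch anything
        config2 = _manual_config(30.0, [[10.0, 10.0], [12.0, 10.0]])
        grid2 = build_tile_grid(config2)
        accepted = attempt_move(config2, grid2, 0, StepPolicy(sigma=1e-9),
                                np.random.default_rng(1))
        if not accepted:
            assert np.array_equal(config2.positions[0], [10.0, 10.0])
        assert np.array_equal(occ_before.shape, grid.occupancy.shape)

    def test_hard_core_invariant_scan(self):
        config = hexagonal_init(PackingSpec(phi0=0.4, l=20.0))
        grid = build_tile_grid(config)
        rng = np.random.default_rng(11)
        policy = StepPolicy(sigma=0.5)
        for k in range(10_000):
            attempt_move(config, grid, int(rng.integers(config.n)), policy, rng)
            if k % 20 == 0:
                assert brute_force_min_distance(config) >= 2.0
        assert brute_force_min_distance(config) >= 2.0


class TestKernel:
    def test_batch_kernel_preserves_invariants(self, melted_config):
        config = melted_config.copy()
        grid = build_tile_grid(config)
        rng = np.random.default_rng(23)
        packing._run_batch(config, grid, 0.3, 20_000, rng)
        assert brute_force_min_distance(config) >= 2.0
        assert np.array_equal(build_tile_grid(config).occupancy, grid.occupancy)
        assert np.all(config.positions >= 0) and np.all(config.positions < config.l)


class TestTuneStepSize:
    def test_dilute_sigma_unchanged(self):
        config = hexagonal_init(PackingSpec(phi0=0.05, l=60.0))
        grid = build_tile_grid(config)
        sigma0 = config.a / 2 - 1
        policy = tune_step_size(config, grid, StepPolicy(sigma=sigma0),
                                np.random.default_rng(2))
        assert policy.sigma == pytest.approx(sigma0)

    def test_oversized_sigma_shrinks_and_validates(self, melted_config):
        # an equilibrated fluid at phi = 0.3 rejects most 3-radius steps,
        # so the 0.8-shrink loop must engage
        config = melted_config.copy()
        grid = build_tile_grid(config)
        rng = np.random.default_rng(2)
        policy = tune_step_size(config, grid, StepPolicy(sigma=3.0), rng)
        assert policy.sigma < 3.0
        # a fresh window at the tuned sigma rejects at most ~half
        n_rej = packing._run_batch(config, grid, policy.sigma, 10 * config.n, rng)
        assert n_rej / (10 * config.n) <= 0.55


class TestRunSimulation:
    def test_sample_counting(self):
        spec = PackingSpec(phi0=0.1, l=20.0, seed=4)
        samples, _ = run_simulation(spec, n_sweeps=30, sample_interval=10,
                                    burn_in=30)
        assert samples == []
        samples, _ = run_simulation(spec, n_sweeps=50, sample_interval=10,
                                    burn_in=30)
        assert len(samples) == 2

    def test_moderate_density_run(self):
        spec = PackingSpec(phi0=0.3, l=60.0, seed=8)
        samples, info = run_simulation(spec, n_sweeps=500, sample_interval=100,
                                       burn_in=100)
        assert info["acceptance_rate"] > 0.5
        for config in samples:
            assert brute_force_min_distance(config) >= 2.0
            packing.assert_no_overlap(config)

    def test_determinism(self):
        spec = PackingSpec(phi0=0.4, l=40.0, seed=77)
        s1, i1 = run_simulation(spec, n_sweeps=200, sample_interval=50,
                                burn_in=100)
        s2, i2 = run_simulation(spec, n_sweeps=200, sample_interval=50,
                                burn_in=100)
        assert i1["sigma"] == i2["sigma"]
        for a, b in zip(s1, s2):
            assert np.array_equal(a.positions, b.positions)
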