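"""Field solver: geometry sampling, rasterization and the stationary solve."""

import math

import numpy as np
import pytest

from diffsurrogate import (
    GridSpec,
    SourceConfiguration,
    SourceDisk,
    diffusion_length,
    generate_dataset,
    rasterize,
    sample_configuration,
    solve_dirichlet,
    solve_steady_state,
)

from .oracles import jacobi_solve, strip_profile_closed_form


@pytest.mark.parametrize(
    "D,gamma,expected",
    [(1.0, 1.0 / 400.0, 20.0), (0.7, 0.7, 1.0), (4.0, 1.0, 2.0)],
)
def test_diffusion_length_closed_form(D, gamma, expected):
    assert diffusion_length(GridSpec(L=16, D=D, gamma=gamma)) == pytest.approx(
        expected, abs=1e-12
    )


class TestGridSpec:
    def test_rejects_degenerate_parameters(self):
        with pytest.raises(ValueError):
            GridSpec(L=4)
        with pytest.raises(ValueError):
            GridSpec(D=0.0)
        with pytest.raises(ValueError):
            GridSpec(gamma=-1.0)

    def test_disk_value_range_enforced(self):
        with pytest.raises(ValueError):
            SourceDisk(10, 10, 5, 0.0)
        with pytest.raises(ValueError):
            SourceDisk(10, 10, 5, 1.2)

    def test_configuration_rejects_overlap_and_escape(self):
        g = GridSpec(L=32)
        with pytest.raises(ValueError, match="overlap"):
            SourceConfiguration(
                (SourceDisk(10, 10, 4, 1.0), SourceDisk(10, 17, 4, 0.5)), g
            )
        with pytest.raises(ValueError, match="contained"):
            SourceConfiguration((SourceDisk(2, 10, 4, 1.0),), g)


class TestSampleConfiguration:
    def test_same_seed_is_reproducible(self):
        g = GridSpec(L=100)
        a = sample_configuration(77, g)
        b = sample_configuration(77, g)
        assert a == b

    def test_constraints_hold_over_many_draws(self):
        g = GridSpec(L=100)
        rng = np.random.default_rng(5)
        lo, hi = 5, 94  # admissible centers forced by containment
        for _ in range(10_000):
            cfg = sample_configuration(rng, g, radius=5.0, n_disks=2)
            (a, b) = cfg.disks
            assert lo <= a.center_row <= hi and lo <= a.center_col <= hi
            assert lo <= b.center_row <= hi and lo <= b.center_col <= hi
            assert math.hypot(
                a.center_row - b.center_row, a.center_col - b.center_col
            ) > 10.0
            assert a.value == 1.0 and 0.0 < b.value <= 1.0

    def test_center_bounds_are_attained(self):
        g = GridSpec(L=20)
        rng = np.random.default_rng(0)
        coords = set()
        for _ in range(500):
            cfg = sample_configuration(rng, g, radius=5.0, n_disks=1)
            coords.add(cfg.disks[0].center_row)
        assert min(coords) == 5 and max(coords) == 14

    def test_impossible_packing_fails_clearly(self):
        g = GridSpec(L=16)
        with pytest.raises(RuntimeError, match="attempts"):
            sample_configuration(0, g, radius=6.0, n_disks=3, max_attempts=200)


class TestRasterize:
    def test_empty_configuration_is_all_zero(self):
        cfg = SourceConfiguration((), GridSpec(L=16))
        assert not rasterize(cfg).any()

    def test_membership_matches_per_pixel_scan(self):
        g = GridSpec(L=32)
        disk = SourceDisk(14, 17, 5.0, 1.0)
        img = rasterize(SourceConfiguration((disk,), g))
        count = sum(
            1
            for r in range(32)
            for c in range(32)
            if (r - 14) ** 2 + (c - 17) ** 2 <= 25.0
        )
        assert int((img == 1.0).sum()) == count
        assert set(np.unique(img)) == {0.0, 1.0}

    def test_two_disk_values_present(self):
        g = GridSpec(L=40)
        cfg = SourceConfiguration(
            (SourceDisk(10, 10, 5, 1.0), SourceDisk(28, 28, 5, 0.3)), g
        )
        img = rasterize(cfg)
        vals = sorted(np.unique(img))
        assert vals == [0.0, 0.3, 1.0]
        assert img.max() == 1.0


class TestSteadyState:
    def test_no_sources_gives_zero_field(self):
        g = GridSpec(L=16)
        cfg = SourceConfiguration((), g)
        u = solve_steady_state(np.zeros((16, 16)), cfg)
        assert np.abs(u).max() == 0.0

    def test_mirror_symmetry(self):
        g = GridSpec(L=32)
        cfg = sample_configuration(3, g, radius=4)
        x = rasterize(cfg)
        u = solve_steady_state(x, cfg)
        mirrored = SourceConfiguration(
            tuple(
                SourceDisk(d.center_row, g.L - 1 - d.center_col, d.radius, d.value)
                for d in cfg.disks
            ),
            g,
        )
        um = solve_steady_state(rasterize(mirrored), mirrored)
        assert np.abs(um - u[:, ::-1]).max() <= 1e-9

    def test_agrees_with_jacobi_oracle(self):
        g = GridSpec(L=20)
        cfg = sample_configuration(9, g, radius=3, n_disks=1)
        x = rasterize(cfg)
        u = solve_steady_state(x, cfg)
        ref = jacobi_solve(x > 0, x, g.D, g.gamma)
        assert np.abs(u - ref).max() <= 1e-7

    def test_maximum_principle(self):
        g = GridSpec(L=28)
        rng = np.random.default_rng(17)
        for _ in range(5):
            cfg = sample_configuration(rng, g, radius=4)
            x = rasterize(cfg)
            u = solve_steady_state(x, cfg)
            assert u.min() >= 0.0
            assert u.max() <= max(d.value for d in cfg.disks) + 1e-12

    def test_single_centered_disk_decays_monotonically_along_rays(self):
        g = GridSpec(L=33)
        cfg = SourceConfiguration((SourceDisk(16, 16, 4, 1.0),), g)
        u = solve_steady_state(rasterize(cfg), cfg)
        for ray in (u[16, 16:], u[16, 16::-1], u[16:, 16], u[16::-1, 16]):
            assert np.all(np.diff(ray) <= 1e-12)

    def test_smaller_diffusion_length_gives_pointwise_smaller_field(self):
        cfgs = []
        for gamma in (1.0 / 400.0, 1.0 / 100.0):
            g = GridSpec(L=32, gamma=gamma)
            cfgs.append(SourceConfiguration((SourceDisk(15, 15, 4, 1.0),), g))
        u_slow, u_fast = (solve_steady_state(rasterize(c), c) for c in cfgs)
        outside = rasterize(cfgs[0]) == 0
        assert np.all(u_fast[outside] <= u_slow[outside] + 1e-12)
        assert u_fast[outside].sum() < u_slow[outside].sum()

    def test_superposition_of_far_apart_disks(self):
        # disks separated by many diffusion lengths interact negligibly, so
        # the two-disk field matches the sum of single-disk fields
        g = GridSpec(L=100, gamma=1.0 / 16.0)  # l_D = 4 pixels
        d1 = SourceDisk(25, 25, 5, 1.0)
        d2 = SourceDisk(75, 75, 5, 0.6)
        both = SourceConfiguration((d1, d2), g)
        u_both = solve_steady_state(rasterize(both), both)
        u_sum = sum(
            solve_steady_state(
                rasterize(SourceConfiguration((d,), g)), SourceConfiguration((d,), g)
            )
            for d in (d1, d2)
        )
        assert np.abs(u_both - u_sum).max() <= 1e-6

    def test_strip_profile_matches_1d_recurrence_closed_form(self):
        n, src, v = 40, 12, 0.8
        mask = np.zeros(n, dtype=bool)
        mask[src] = True
        vals = np.where(mask, v, 0.0)
        u = solve_dirichlet(mask, vals, D=1.0, gamma=1.0 / 400.0)
        ref = strip_profile_closed_form(n, src, v, 1.0, 1.0 / 400.0)
        assert np.abs(u - ref).max() <= 1e-8


class TestGenerateDataset:
    def test_deterministic_and_split_sizes(self, grid32):
        a = generate_dataset(10, 7, grid=grid32, radius=5)
        b = generate_dataset(10, 7, grid=grid32, radius=5)
        assert np.array_equal(a.inputs, b.inputs)
        assert np.array_equal(a.targets, b.targets)
        assert len(a.train_idx) == 8 and len(a.test_idx) == 2
        assert not set(a.train_idx) & set(a.test_idx)

    def test_targets_inherit_field_invariants(self, small_dataset, grid32):
        from .oracles import _stencil_sum

        assert small_dataset.targets.min() >= 0.0
        assert small_dataset.targets.max() <= 1.0 + 1e-6
        # zero-ghost-boundary consistency: the stencil balance holds at every
        # non-source pixel, edges included (missing neighbors contribute 0)
        for x, y in zip(small_dataset.inputs[:4], small_dataset.targets[:4]):
            u = y.astype(np.float64)
            residual = grid32.D * (_stencil_sum(u) - 4 * u) - grid32.gamma * u
            free = x == 0
            assert np.abs(residual[free]).max() < 1e-6  # float32 storage limit

    def test_inputs_are_rasterized_layouts(self, small_dataset):
        x = small_dataset.inputs
        assert ((x >= 0) & (x <= 1)).all()
        assert (x == 1.0).any(axis=(1, 2)).all()  # reference disk present
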