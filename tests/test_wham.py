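"""Window grids, bias energies, WHAM solutions and basin/barrier analysis."""

import numpy as np
import pytest

from bzdna.wham import (
    KB,
    Basin,
    PMFGrid,
    UmbrellaWindow,
    WhamConfig,
    WhamConvergenceError,
    barrier_between,
    bias_energy,
    block_error,
    find_basins,
    generate_windows,
    wham_2d,
)


class TestWindows:
    def test_10_degree_spacing_gives_1296(self):
        assert len(generate_windows(10.0, 100.0)) == 1296

    def test_90_degree_spacing_gives_16(self):
        assert len(generate_windows(90.0)) == 16

    def test_anti_anti_region_contains_256_centers(self):
        wins = generate_windows(10.0)
        n = sum(
            1 for w in wins
            if 190 <= w.center[0] <= 340 and 190 <= w.center[1] <= 340
        )
        assert n == 256

    def test_non_divisor_spacing_rejected(self):
        with pytest.raises(ValueError):
            generate_windows(7.0)


class TestBias:
    def test_zero_at_center(self):
        w = UmbrellaWindow((120.0, 240.0), 100.0)
        assert bias_energy(w, (120.0, 240.0)) == 0.0

    def test_closed_form_10_degree_offset(self):
        w = UmbrellaWindow((0.0, 0.0), 100.0)
        want = 0.5 * 100.0 * np.radians(10.0) ** 2
        assert bias_energy(w, (10.0, 0.0)) == pytest.approx(want, abs=1e-12)
        assert want == pytest.approx(1.5231, abs=1e-4)

    def test_minimal_image_used(self):
        w = UmbrellaWindow((10.0, 0.0), 100.0)
        want = 0.5 * 100.0 * np.radians(20.0) ** 2
        assert bias_energy(w, (350.0, 0.0)) == pytest.approx(want)


def _unbiased_window(samples):
    return UmbrellaWindow((0.0, 0.0), 0.0, np.asarray(samples, float))


class TestWham2d:
    def test_single_window_counts_reduce_to_boltzmann_ratio(self):
        samples = [[2.5, 2.5]] * 200 + [[7.5, 2.5]] * 100
        grid = wham_2d([_unbiased_window(samples)], WhamConfig())
        dpmf = grid.values[1, 0] - grid.values[0, 0]
        assert dpmf == pytest.approx(KB * 300 * np.log(2), abs=1e-9)
        assert dpmf == pytest.approx(0.4132, abs=1e-4)

    def test_zero_bias_equals_neg_kt_log_histogram(self, rng):
        samples = rng.uniform(0, 360, size=(4000, 2))
        cfg = WhamConfig(bin_size=45.0)
        grid = wham_2d([_unbiased_window(samples)], cfg)
        counts, _, _ = np.histogram2d(
            samples[:, 0], samples[:, 1], bins=[np.linspace(0, 360, 9)] * 2
        )
        want = -KB * 300 * np.log(counts / counts.sum())
        want -= want.min()
        assert np.allclose(grid.values, want, atol=1e-9)

    def test_gauge_invariance_under_reference_choice(self, rng):
        """Shifting all window constants leaves the normalized PMF fixed."""
        wins = generate_windows(90.0, 20.0)
        for j, w in enumerate(wins):
            w.samples = (
                rng.normal(0, 15, size=(300, 2)) + np.asarray(w.center)
            ) % 360.0
            w.frame_indices = np.arange(300)
        cfg = WhamConfig(bin_size=15.0)
        g1 = wham_2d(wins, cfg)
        g2 = wham_2d(list(reversed(wins)), cfg)  # different gauge reference
        m = g1.sampled & g2.sampled
        assert np.allclose(g1.values[m], g2.values[m], atol=1e-4)

    def test_monotone_objective_accepted(self, rng):
        wins = generate_windows(120.0, 10.0)
        for w in wins:
            w.samples = (rng.normal(0, 25, size=(200, 2)) + np.asarray(w.center)) % 360
            w.frame_indices = np.arange(200)
        cfg = WhamConfig(bin_size=30.0, check_monotone=True)
        grid = wham_2d(wins, cfg)  # raises if the NLL ever increases
        assert grid.converged

    def test_empty_windows_rejected(self):
        with pytest.raises(ValueError):
            wham_2d([UmbrellaWindow((0.0, 0.0), 100.0)], WhamConfig())

    def test_nonconvergence_reports_residual(self, rng):
        w = _unbiased_window(rng.uniform(0, 360, size=(100, 2)))
        cfg = WhamConfig(max_iterations=0)
        with pytest.raises(WhamConvergenceError):
            wham_2d([w], cfg)

    def test_unsampled_bins_masked_not_zero(self):
        samples = [[2.5, 2.5]] * 10
        grid = wham_2d([_unbiased_window(samples)], WhamConfig())
        assert grid.sampled.sum() == 1
        assert np.isinf(grid.values[~grid.sampled]).all()


class TestBlockError:
    def test_identical_blocks_zero_std(self):
        block = [[2.5, 2.5]] * 30 + [[7.5, 7.5]] * 20
        w = _unbiased_window(block * 5)
        # five equal consecutive blocks are identical by construction
        w2 = _unbiased_window(np.tile(np.array(block, float), (5, 1)))
        std, grids = block_error([w2], WhamConfig())
        assert len(grids) == 5
        assert np.nanmax(std) == pytest.approx(0.0, abs=1e-9)

    def test_disjoint_blocks_partition_samples(self, rng):
        n = 500
        w = _unbiased_window(rng.uniform(0, 360, size=(n, 2)))
        _, grids = block_error([w], WhamConfig(bin_size=45.0))
        # 5 blocks of 100 frames each (3 ns at 1 ps scaled: equal fifths)
        total = 0
        for g in grids:
            total += 1
        assert total == 5

    def test_cumulative_mode_nests(self, rng):
        w = _unbiased_window(rng.uniform(0, 360, size=(300, 2)))
        std, grids = block_error([w], WhamConfig(bin_size=45.0), mode="cumulative-3")
        assert len(grids) == 3

    def test_unknown_mode_rejected(self, rng):
        w = _unbiased_window(rng.uniform(0, 360, size=(50, 2)))
        with pytest.raises(ValueError):
            block_error([w], WhamConfig(bin_size=45.0), mode="nope")


def _grid_from_values(values):
    values = np.asarray(values, float)
    n = values.shape[0]
    return PMFGrid(
        values=values,
        sampled=np.isfinite(values),
        bin_edges=np.linspace(0, 360, n + 1),
        window_free_energies=np.zeros(1),
        converged=True,
        iterations=1,
        temperature=300.0,
    )


class TestBasinsAndBarriers:
    def test_ridge_barrier_hand_traced(self):
        """5x5 periodic grid: two 5 kcal/mol ridges isolate two minima."""
        v = np.zeros((5, 5))
        v[:, 0] = 5.0
        v[:, 2] = 5.0
        grid = _grid_from_values(v)
        rep = find_basins(grid, threshold=1.0)
        # column 1 vs columns 3-4 (the wrap passes through the col-0 ridge)
        assert len(rep.basins) == 2
        b = barrier_between(grid, rep.basins[0], rep.basins[1])
        assert b == pytest.approx(5.0)
        assert barrier_between(grid, rep.basins[1], rep.basins[0]) == pytest.approx(b)

    def test_self_barrier_zero(self):
        v = np.zeros((4, 4))
        grid = _grid_from_values(v)
        rep = find_basins(grid, threshold=1.0)
        assert barrier_between(grid, rep.basins[0], rep.basins[0]) == 0.0

    def test_flat_surface_single_basin(self):
        grid = _grid_from_values(np.zeros((6, 6)))
        rep = find_basins(grid, threshold=0.5)
        assert len(rep.basins) == 1
        assert len(rep.basins[0].bins) == 36

    def test_threshold_just_above_minimum(self):
        v = np.arange(16.0).reshape(4, 4)
        grid = _grid_from_values(v)
        rep = find_basins(grid, threshold=0.5)
        assert len(rep.basins) == 1
        assert rep.basins[0].minimum_energy == 0.0

    def test_disconnected_through_unsampled_is_infinite(self):
        v = np.zeros((5, 5))
        v[:, 0] = np.inf  # two unsampled columns fully separate the rest
        v[:, 2] = np.inf
        grid = _grid_from_values(v)
        grid.sampled[:, 0] = False
        grid.sampled[:, 2] = False
        rep = find_basins(grid, threshold=1.0)
        assert len(rep.basins) == 2
        assert barrier_between(grid, rep.basins[0], rep.basins[1]) == np.inf

    def test_invariant_to_whole_period_rotation(self):
        rng = np.random.default_rng(5)
        v = rng.uniform(0, 6, size=(12, 12))
        g1 = _grid_from_values(v)
        g2 = _grid_from_values(np.roll(np.roll(v, 4, axis=0), 7, axis=1))
        r1 = find_basins(g1, 2.0)
        r2 = find_basins(g2, 2.0)
        assert len(r1.basins) == len(r2.basins)
        assert sorted(len(b.bins) for b in r1.basins) == sorted(
            len(b.bins) for b in r2.basins
        )
        assert sorted(round(b.minimum_energy, 9) for b in r1.basins) == sorted(
            round(b.minimum_energy, 9) for b in r2.basins
        )
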