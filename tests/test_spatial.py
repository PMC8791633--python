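"""Occupancy/rate maps, spatial information, sparsity, 1D maps, stability."""

import numpy as np
import pytest
from scipy.stats import pearsonr

import optoplace as op
from optoplace.spatial import (LinearizedMap, OccupancyMap, RateMap,
                               SpatialError, _circular_gaussian_smooth,
                               compute_occupancy, compute_ratemap,
                               compute_speed, linearized_ratemap,
                               midpoint_position, peak_firing_rate,
                               skaggs_information, sparsity_index,
                               spatial_information, sparsity,
                               split_half_stability)


def uniform_occupancy(shape=(4, 4), z=1.0, mask=None):
    zmap = np.full(shape, z)
    valid = np.ones(shape, bool) if mask is None else mask
    return OccupancyMap(z=zmap, pixel_size_cm=2.5, dt=0.04, sigma_px=1.0,
                        valid=valid)


class TestMidpointAndSpeed:
    def test_midpoint_of_leds(self):
        t = np.arange(3) * 0.04
        led1 = np.array([[0.0, 0.0]] * 3)
        led2 = np.array([[2.0, 2.0]] * 3)
        tr = op.TrackingTrace(t=t, led1_xy=led1, led2_xy=led2)
        _, xy = midpoint_position(tr)
        np.testing.assert_allclose(xy, [[1.0, 1.0]] * 3)

    def test_frame_with_missing_led_dropped(self):
        t = np.arange(3) * 0.04
        led1 = np.array([[0.0, 0.0], [np.nan, 0.0], [0.0, 0.0]])
        led2 = np.zeros((3, 2))
        tv, xy = midpoint_position(op.TrackingTrace(t=t, led1_xy=led1, led2_xy=led2))
        assert xy.shape[0] == 2 and tv[1] == pytest.approx(0.08)

    def test_stationary_speed_is_zero(self):
        xy = np.zeros((100, 2))
        assert np.allclose(compute_speed(xy, 0.04), 0.0)

    def test_constant_velocity_speed(self):
        # 2 cm per 0.04 s frame along a fixed heading -> 50 cm/s
        xy = np.column_stack([np.arange(50) * 2.0, np.zeros(50)])
        speed = compute_speed(xy, 0.04, smooth_window_s=0.0)
        np.testing.assert_allclose(speed, 50.0)

    def test_single_sample_window_is_identity(self):
        rng = np.random.default_rng(0)
        xy = np.cumsum(rng.normal(size=(50, 2)), axis=0)
        raw = compute_speed(xy, 0.04, smooth_window_s=0.0)
        one = compute_speed(xy, 0.04, smooth_window_s=0.04)
        np.testing.assert_allclose(raw, one)


class TestOccupancy:
    def test_single_frame_mass(self, maze, config):
        occ = compute_occupancy(np.array([[35.0, 45.0]]), 0.04, maze, config)
        assert occ.total_time_s == pytest.approx(0.04, rel=1e-9)

    def test_grid_shape_from_arena(self, maze, config):
        occ = compute_occupancy(np.array([[35.0, 45.0]]), 0.04, maze, config)
        assert occ.z.shape == (20, 28)

    def test_occupancy_mask_threshold(self, maze, config):
        # one frame of 15 ms deposits < 20 ms everywhere -> fully masked
        occ = compute_occupancy(np.array([[35.0, 45.0]]), 0.015, maze, config)
        assert not occ.valid.any()

    def test_empty_positions_rejected(self, maze, config):
        with pytest.raises(SpatialError):
            compute_occupancy(np.empty((0, 2)), 0.04, maze, config)


class TestRateMap:
    def test_zero_spikes_zero_rate(self, maze, config, trajectory):
        xy = 0.5 * (trajectory.led1_xy + trajectory.led2_xy)
        occ = compute_occupancy(xy, trajectory.dt, maze, config)
        rmap = compute_ratemap(np.empty((0, 2)), occ, config)
        assert np.all(rmap.rate[occ.valid] == 0.0)

    def test_homogeneous_rate_recovered(self, maze, config):
        tr = op.simulate_trajectory(maze, 600.0, 25.0, seed=9)
        xy = 0.5 * (tr.led1_xy + tr.led2_xy)
        rng = np.random.default_rng(9)
        # homogeneous 2 Hz: spikes at uniformly chosen frames
        n = rng.poisson(2.0 * 600.0)
        frames = rng.integers(0, xy.shape[0], n)
        occ = compute_occupancy(xy, tr.dt, maze, config)
        rmap = compute_ratemap(xy[frames], occ, config)
        v = occ.valid
        weighted = np.sum(occ.z[v] * rmap.rate[v]) / np.sum(occ.z[v])
        assert weighted == pytest.approx(2.0, abs=0.1)

    def test_weighted_mean_equals_spikes_over_time(self, maze, config, trajectory):
        xy = 0.5 * (trajectory.led1_xy + trajectory.led2_xy)
        rng = np.random.default_rng(4)
        frames = rng.integers(0, xy.shape[0], 500)
        occ = compute_occupancy(xy, trajectory.dt, maze, config)
        rmap = compute_ratemap(xy[frames], occ, config)
        v = occ.valid
        weighted = np.sum(occ.z[v] * rmap.rate[v]) / np.sum(occ.z[v])
        expected = 500 / occ.total_time_s
        assert weighted == pytest.approx(expected, rel=0.02)


class TestInformationAndSparsity:
    def test_uniform_map_zero_information_unit_sparsity(self):
        occ = uniform_occupancy()
        rmap = RateMap(rate=np.full((4, 4), 3.0), valid=occ.valid, n_spikes=100)
        assert spatial_information(rmap, occ) == pytest.approx(0.0, abs=1e-12)
        assert sparsity(rmap, occ) == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("n", [2, 4, 8, 16])
    def test_one_of_n_closed_form(self, n):
        p = np.full(n, 1.0 / n)
        lam = np.zeros(n)
        lam[0] = 5.0
        assert skaggs_information(p, lam) == pytest.approx(np.log2(n), abs=1e-12)
        assert sparsity_index(p, lam) == pytest.approx(1.0 / n, abs=1e-12)

    def test_printed_formula_worked_example(self):
        p = np.array([0.5, 0.25, 0.25])
        lam = np.array([2.0, 1.0, 1.0])
        assert skaggs_information(p, lam) == pytest.approx(0.08170416, abs=1e-6)
        assert sparsity_index(p, lam) == pytest.approx(0.9, abs=1e-12)

    def test_masked_pixels_excluded_and_renormalized(self):
        mask = np.ones((4, 4), bool)
        mask[0, 0] = False
        occ = uniform_occupancy(mask=mask)
        rate = np.full((4, 4), 2.0)
        rate[0, 0] = 100.0  # masked: must not contribute
        rmap = RateMap(rate=rate, valid=mask, n_spikes=10)
        assert spatial_information(rmap, occ) == pytest.approx(0.0, abs=1e-12)

    def test_zero_spikes_rejected(self):
        occ = uniform_occupancy()
        rmap = RateMap(rate=np.zeros((4, 4)), valid=occ.valid, n_spikes=0)
        with pytest.raises(SpatialError):
            spatial_information(rmap, occ)


class TestPeakRate:
    def test_constant_map(self):
        occ = uniform_occupancy()
        rmap = RateMap(rate=np.full((4, 4), 2.0), valid=occ.valid, n_spikes=10)
        assert peak_firing_rate(rmap) == 2.0

    def test_masked_global_max_ignored(self):
        mask = np.ones((4, 4), bool)
        mask[2, 2] = False
        rate = np.full((4, 4), 2.0)
        rate[2, 2] = 50.0
        rmap = RateMap(rate=rate, valid=mask, n_spikes=10)
        assert peak_firing_rate(rmap) == 2.0

    def test_synthetic_field_peak_envelope(self, maze, config):
        peaks = []
        for seed in range(5):
            tr = op.simulate_trajectory(maze, 480.0, 25.0, seed=seed)
            xy = 0.5 * (tr.led1_xy + tr.led2_xy)
            s = op.linearize(xy, maze.midline)
            spec = op.PlaceFieldSpec(baseline_rate_Hz=1.0, field_gain_Hz=8.0,
                                     field_width_cm=10.0, field_center_cm=40.0,
                                     burst_probability=0.0)
            spikes = op.simulate_place_cell(spec, tr, s, maze.midline.perimeter,
                                            seed=seed)
            idx = np.clip(np.searchsorted(tr.t, spikes.times), 0, tr.t.size - 1)
            occ = compute_occupancy(xy, tr.dt, maze, config)
            rmap = compute_ratemap(xy[idx], occ, config)
            peaks.append(peak_firing_rate(rmap))
        assert all(6.0 <= p <= 12.0 for p in peaks)


class TestLinearizedMaps:
    def test_uniform_input_flat_map(self, config):
        perim = 160.0  # 64 bins of 2.5 cm; sample counts divisible by 64
        s_occ = np.linspace(0, perim, 6400, endpoint=False)
        s_spk = np.linspace(0, perim, 640, endpoint=False)
        m = linearized_ratemap(s_spk, s_occ, 0.04, perim, config)
        rates = m.rate[m.valid]
        assert np.allclose(rates, rates[0], rtol=1e-9)

    def test_normalized_map_peaks_at_one(self, config):
        perim = 160.0
        rng = np.random.default_rng(0)
        s_occ = rng.uniform(0, perim, 5000)
        s_spk = rng.normal(80, 5, 300) % perim
        m = linearized_ratemap(s_spk, s_occ, 0.04, perim, config, normalize=True)
        assert np.nanmax(m.rate) == pytest.approx(1.0)

    def test_field_center_recovered(self, maze, config):
        hits = 0
        for seed in range(10):
            tr = op.simulate_trajectory(maze, 480.0, 25.0, seed=100 + seed)
            xy = 0.5 * (tr.led1_xy + tr.led2_xy)
            s = op.linearize(xy, maze.midline)
            center = 60.0
            spec = op.PlaceFieldSpec(baseline_rate_Hz=0.3, field_gain_Hz=8.0,
                                     field_width_cm=8.0, field_center_cm=center,
                                     burst_probability=0.0)
            spikes = op.simulate_place_cell(spec, tr, s, maze.midline.perimeter,
                                            seed=seed)
            idx = np.clip(np.searchsorted(tr.t, spikes.times), 0, tr.t.size - 1)
            m = linearized_ratemap(s[idx], s, tr.dt, maze.midline.perimeter, config)
            peak_bin = np.nanargmax(np.where(m.valid, m.rate, -np.inf))
            bin_cm = m.bin_edges_cm[1] - m.bin_edges_cm[0]
            peak_s = (peak_bin + 0.5) * bin_cm
            d = abs((peak_s - center + m.bin_edges_cm[-1] / 2)
                    % m.bin_edges_cm[-1] - m.bin_edges_cm[-1] / 2)
            hits += d <= 2 * bin_cm
        assert hits >= 9

    def test_circular_smoother_preserves_mass(self):
        rng = np.random.default_rng(1)
        v = rng.uniform(0, 5, 64)
        sm = _circular_gaussian_smooth(v, 1.0)
        assert sm.sum() == pytest.approx(v.sum(), rel=1e-12)


class TestStability:
    def test_identical_halves_perfect_correlation(self, config):
        perim = 160.0
        # deterministic, repeated pattern in both halves
        s_cycle = np.tile(np.linspace(0, perim, 1000, endpoint=False), 4)
        t = np.arange(s_cycle.size) * 0.04
        moving = np.ones(s_cycle.size, bool)
        spike_idx = np.arange(0, s_cycle.size, 10)  # same positions each half
        r = split_half_stability(t, s_cycle, moving, t[spike_idx],
                                 s_cycle[spike_idx], 0.04, perim, config)
        assert r == pytest.approx(1.0, abs=1e-6)

    def test_anticorrelated_maps_give_minus_one(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = 5.0 - a  # negation about the mean
        assert pearsonr(a, b)[0] == pytest.approx(-1.0)

    def test_independent_poisson_halves_near_zero(self, maze, config):
        rs = []
        perim = maze.midline.perimeter
        for seed in range(30):
            rng = np.random.default_rng(seed)
            n = 6000
            s = rng.uniform(0, perim, n)
            t = np.arange(n) * 0.04
            moving = np.ones(n, bool)
            spike_idx = rng.integers(0, n, 150)
            rs.append(split_half_stability(t, s, moving, t[spike_idx],
                                           s[spike_idx], 0.04, perim, config))
        assert abs(np.mean(rs)) < 0.1

    def test_too_few_joint_bins_rejected(self, config):
        t = np.arange(10) * 0.04
        s = np.zeros(10)
        with pytest.raises(SpatialError):
            split_half_stability(t, s, np.ones(10, bool), t[:2], s[:2],
                                 0.04, 160.0, config)


class TestSessionSummary:
    def test_summary_fields_coherent(self, small_cohort, config):
        sessions, labels = small_cohort
        m = op.spatial_summary(sessions[0], config)
        assert m.n_spikes_included > 0
        assert 0 <= m.sparsity_index <= 1
        assert m.information_bits_per_spike >= 0
        assert m.mean_rate_overall_hz < 10

    def test_monotone_gain_discrimination(self, maze, config):
        """Median information rises and sparsity falls with field gain."""
        gains = [0.5, 2.0, 8.0]
        med_info, med_sp = [], []
        for gain in gains:
            infos, sps = [], []
            for seed in range(8):
                tr = op.simulate_trajectory(maze, 300.0, 25.0, seed=200 + seed)
                xy = 0.5 * (tr.led1_xy + tr.led2_xy)
                s = op.linearize(xy, maze.midline)
                spec = op.PlaceFieldSpec(baseline_rate_Hz=1.0, field_gain_Hz=gain,
                                         field_width_cm=8.0, field_center_cm=50.0,
                                         burst_probability=0.0)
                spikes = op.simulate_place_cell(spec, tr, s,
                                                maze.midline.perimeter, seed=seed)
                idx = np.clip(np.searchsorted(tr.t, spikes.times), 0, tr.t.size - 1)
                occ = compute_occupancy(xy, tr.dt, maze, config)
                rmap = compute_ratemap(xy[idx], occ, config)
                infos.append(spatial_information(rmap, occ))
                sps.append(sparsity(rmap, occ))
            med_info.append(np.median(infos))
            med_sp.append(np.median(sps))
        assert med_info[0] < med_info[1] < med_info[2]
        assert med_sp[0] > med_sp[1] > med_sp[2]
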