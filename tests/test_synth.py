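"""Synthetic-data generator: trajectories, spike trains, light responses."""

import numpy as np
import pytest

import optoplace as op
from optoplace.spatial import compute_speed
from optoplace.synth import (REFRACTORY_MS, ParameterError, SpeedParams,
                             _train_groups)


class TestTrajectory:
    def test_sample_count_and_containment(self, maze):
        tr = op.simulate_trajectory(maze, 600.0, 25.0, seed=0)
        assert tr.t.size == 15_000
        xy = 0.5 * (tr.led1_xy + tr.led2_xy)
        mid = maze.midline
        # radial distance from the midline ellipse stays inside the path
        rel = xy - np.asarray(mid.center)
        t_par = np.arctan2(mid.a * rel[:, 1], mid.b * rel[:, 0])
        dist = np.linalg.norm(xy - mid.point(t_par), axis=1)
        assert dist.max() <= maze.path_width_cm / 2 + 1e-6

    def test_deterministic_per_seed(self, maze):
        a = op.simulate_trajectory(maze, 60.0, 25.0, seed=42)
        b = op.simulate_trajectory(maze, 60.0, 25.0, seed=42)
        np.testing.assert_array_equal(a.led1_xy, b.led1_xy)
        c = op.simulate_trajectory(maze, 60.0, 25.0, seed=43)
        assert not np.array_equal(a.led1_xy, c.led1_xy)

    def test_run_fraction_recovered_from_positions(self, maze):
        sp = SpeedParams()
        fractions = []
        for seed in range(5):
            tr = op.simulate_trajectory(maze, 600.0, 25.0, sp, seed=seed)
            xy = 0.5 * (tr.led1_xy + tr.led2_xy)
            speed = compute_speed(xy, tr.dt)
            fractions.append(np.mean(speed > 1.0))
        assert abs(np.mean(fractions) - sp.run_fraction) < 0.05

    def test_zero_tracking_rate_rejected(self, maze):
        with pytest.raises(ParameterError):
            op.simulate_trajectory(maze, 10.0, 0.0)


class TestPlaceCell:
    def _linear(self, maze, tr):
        xy = 0.5 * (tr.led1_xy + tr.led2_xy)
        return op.linearize(xy, maze.midline)

    def test_silent_spec_gives_empty_train(self, maze, trajectory):
        spec = op.PlaceFieldSpec(baseline_rate_Hz=0.0, field_gain_Hz=0.0)
        out = op.simulate_place_cell(spec, trajectory,
                                     self._linear(maze, trajectory),
                                     maze.midline.perimeter, seed=0)
        assert out.n_spikes == 0

    def test_homogeneous_count_matches_poisson(self, maze):
        tr = op.simulate_trajectory(maze, 600.0, 25.0, seed=5)
        spec = op.PlaceFieldSpec(baseline_rate_Hz=2.0, field_gain_Hz=0.0,
                                 burst_probability=0.0)
        out = op.simulate_place_cell(spec, tr, self._linear(maze, tr),
                                     maze.midline.perimeter, seed=5)
        # 2 Hz * 600 s: within 3 SD of the Poisson expectation
        assert abs(out.n_spikes - 1200) < 3 * np.sqrt(1200)

    def test_burst_promotion_sets_burst_index(self, maze, trajectory):
        lin = self._linear(maze, trajectory)
        spec = op.PlaceFieldSpec(baseline_rate_Hz=3.0, field_gain_Hz=0.0,
                                 burst_probability=0.3, burst_size=2)
        bis = []
        for seed in range(10):
            out = op.simulate_place_cell(spec, trajectory, lin,
                                         maze.midline.perimeter, seed=seed)
            bis.append(op.burst_index(out))
        assert abs(np.mean(bis) - 0.3 / 1.3) < 0.05

    def test_refractory_period_enforced(self, maze, trajectory):
        spec = op.PlaceFieldSpec(baseline_rate_Hz=8.0, field_gain_Hz=0.0,
                                 burst_probability=0.5)
        out = op.simulate_place_cell(spec, trajectory,
                                     self._linear(maze, trajectory),
                                     maze.midline.perimeter, seed=1)
        assert np.diff(out.times).min() * 1000.0 >= REFRACTORY_MS - 1e-9

    def test_negative_rate_rejected(self):
        with pytest.raises(ParameterError):
            op.PlaceFieldSpec(baseline_rate_Hz=-1.0)


class TestOptoResponse:
    def _baseline(self, seed=0, rate=2.0, span=(0.0, 70.0)):
        rng = np.random.default_rng(seed)
        n = rng.poisson(rate * (span[1] - span[0]))
        return op.SpikeTrain(times=np.sort(rng.uniform(*span, n)), recording_span=span)

    def _pulses(self, n=50, rate_hz=1.0, start=10.0):
        return op.LightPulseTrain(onsets=start + np.arange(n) / rate_hz,
                                  duration_ms=1.0, power_mW=0.5,
                                  train_frequency_Hz=rate_hz)

    def test_nonresponder_identity(self):
        base = self._baseline()
        spec = op.OptoResponseSpec(responder_class="none", response_probability=0.0)
        out = op.simulate_opto_response(spec, base, self._pulses(), seed=0)
        np.testing.assert_array_equal(out.times, base.times)

    def test_direct_responder_latencies(self):
        spec = op.OptoResponseSpec(responder_class="direct", latency_mean_ms=2.5,
                                   latency_sd_ms=0.3, response_probability=1.0)
        base = op.SpikeTrain(times=np.array([0.5]), recording_span=(0.0, 70.0))
        pulses = self._pulses(50)
        out = op.simulate_opto_response(spec, base, pulses, seed=2)
        trials = op.first_spike_latencies(out, pulses, 20.0)
        lat = trials.latencies_ms
        assert np.sum(~np.isnan(lat)) == 50
        assert abs(np.nanmean(lat) - 2.5) < 0.15

    def test_facilitation_raises_late_pulse_response(self):
        # 10-pulse 25 Hz trains, p0 = 0.2, +0.1 per pulse within the train
        onsets = np.concatenate([10.0 + k * 5.0 + np.arange(10) * 0.04
                                 for k in range(3)])
        pulses = op.LightPulseTrain(onsets=onsets, duration_ms=1.0, power_mW=1.5,
                                    train_frequency_Hz=25.0)
        spec = op.OptoResponseSpec(responder_class="indirect", latency_mean_ms=7.5,
                                   latency_sd_ms=1.0, response_probability=0.2,
                                   facilitation_increment=0.1)
        empty = op.SpikeTrain(times=np.array([0.5]), recording_span=(0.0, 70.0))
        early, late = [], []
        for seed in range(100):
            out = op.simulate_opto_response(spec, empty, pulses, seed=seed)
            counts = [np.sum((out.times > o) & (out.times <= o + 0.02))
                      for o in onsets]
            counts = np.array(counts).reshape(3, 10)
            early.append(counts[:, :5].mean())
            late.append(counts[:, 5:].mean())
        assert np.mean(late) > np.mean(early)

    def test_train_grouping_by_gap(self):
        onsets = np.concatenate([np.arange(10) * 0.04, 5 + np.arange(10) * 0.04])
        pulses = op.LightPulseTrain(onsets=onsets, duration_ms=1.0, power_mW=1.0,
                                    train_frequency_Hz=25.0)
        groups = _train_groups(pulses)
        assert set(groups[:10]) == {0} and set(groups[10:]) == {1}

    def test_nonresponder_with_facilitation_rejected(self):
        with pytest.raises(ParameterError):
            op.OptoResponseSpec(responder_class="none", response_probability=0.0,
                                facilitation_increment=0.1)


class TestCohort:
    def test_counts_and_labels(self, small_cohort):
        sessions, labels = small_cohort
        assert len(sessions) == 5
        assert (labels.tuning_class == "tuned").sum() == 3
        assert (labels.tuning_class == "weak").sum() == 2
        assert (labels.responder_class == "direct").sum() == 2

    def test_byte_identical_regeneration(self, tmp_path):
        spec = op.default_cohort_spec(seed=21)
        spec.classes[0].n_cells, spec.classes[1].n_cells = 2, 1
        spec.session_duration_s = 60.0
        for d in ("a", "b"):
            sessions, labels = op.generate_cohort(spec)
            op.write_cohort(sessions, labels, tmp_path / d)
        for fa in sorted((tmp_path / "a").rglob("*.*")):
            fb = tmp_path / "b" / fa.relative_to(tmp_path / "a")
            assert fa.read_bytes() == fb.read_bytes()

    def test_empty_cohort_allowed(self):
        spec = op.CohortSpec(classes=[op.tuned_class(n=0)], rng_seed=0)
        sessions, labels = op.generate_cohort(spec)
        assert sessions == [] and len(labels) == 0

    def test_rate_realism_pyramidal_below_10hz(self):
        rates = []
        for seed in range(3):
            spec = op.default_cohort_spec(seed=seed)
            spec.classes[0].n_cells, spec.classes[1].n_cells = 3, 2
            spec.session_duration_s = 120.0
            sessions, _ = op.generate_cohort(spec)
            rates += [op.mean_firing_rate(s.spikes) for s in sessions]
        assert np.all(np.asarray(rates) < 10.0)
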