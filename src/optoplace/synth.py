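"""Synthetic cohorts with the statistical structure of the recordings.

No raw recordings accompany the study, so analyses are exercised on
synthetic sessions that emulate its conditions, with ground-truth labels for
recovery testing:

* exploration of the O-shaped maze (70 x 50 cm, 9 cm path) as a smooth
  run-and-pause process along the elliptical midline with lateral jitter;
* CA1 pyramidal spike trains as inhomogeneous Poisson processes (thinning)
  with mean rates well below 10 Hz, complex-spike bursts (short-ISI extra
  spikes) tuned to a burst index near 0.29, and a 2 ms absolute refractory
  period;
* place-tuned cells (localized Gaussian field on the circular coordinate)
  versus weakly modulated cells (broad, low-gain fields);
* light responses as per-pulse Bernoulli events with truncated-normal
  latencies: direct opsin-driven responses near 2.5 ms with high
  reliability, synaptically relayed responses near 7.5 ms with failures and
  optional within-train facilitation, or no response.

Everything is reproducible: one seed determines the full cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .core import LightPulseTrain, SessionRecord, SpikeTrain, TrackingTrace
from .geometry import MazeGeometry, linearize


class ParameterError(ValueError):
    pass


REFRACTORY_MS = 2.0  # absolute refractory period applied to all spike trains
LED_SEPARATION_CM = 2.0  # fixed head vector between the two LEDs


@dataclass
class SpeedParams:
    """Run-and-pause locomotion statistics."""

    run_speed_mean_cm_s: float = 15.0
    run_speed_sd_cm_s: float = 4.0
    run_speed_range: tuple = (5.0, 30.0)
    run_duration_mean_s: float = 25.0
    pause_duration_mean_s: float = 4.0
    pause_jitter_cm_s: float = 0.1
    speed_tau_s: float = 3.0
    lateral_sd_cm: float = 1.2
    lateral_max_cm: float = 3.0
    lateral_tau_s: float = 2.0
    reversal_rate_hz: float = 0.0005

    @property
    def run_fraction(self) -> float:
        return self.run_duration_mean_s / (self.run_duration_mean_s
                                           + self.pause_duration_mean_s)


@dataclass
class PlaceFieldSpec:
    """Gaussian place field on the linearized (circular) coordinate."""

    baseline_rate_Hz: float = 0.5
    field_center_cm: float = 0.0
    field_width_cm: float = 10.0
    field_gain_Hz: float = 8.0
    burst_probability: float = 0.41
    burst_isi_ms: tuple = (3.0, 6.0)
    burst_size: int = 2

    def __post_init__(self):
        if self.baseline_rate_Hz < 0 or self.field_gain_Hz < 0:
            raise ParameterError("rates must be non-negative")
        if self.field_width_cm <= 0:
            raise ParameterError("field_width_cm must be positive")
        if not 0 <= self.burst_probability <= 1:
            raise ParameterError("burst_probability must lie in [0, 1]")
        if self.burst_size < 2:
            raise ParameterError("burst_size must be at least 2")
        if self.burst_isi_ms[0] < REFRACTORY_MS:
            raise ParameterError("burst ISIs must exceed the refractory period")


@dataclass
class OptoResponseSpec:
    """Per-pulse light-response phenomenology."""

    responder_class: str = "direct"  # direct | indirect | none
    latency_mean_ms: float = 2.5
    latency_sd_ms: float = 0.3
    response_probability: float = 1.0
    facilitation_increment: float = 0.0

    def __post_init__(self):
        if self.responder_class not in ("direct", "indirect", "none"):
            raise ParameterError(f"unknown responder_class {self.responder_class!r}")
        if not 0 <= self.response_probability <= 1:
            raise ParameterError("response_probability must lie in [0, 1]")
        if self.responder_class == "none" and self.facilitation_increment != 0:
            raise ParameterError("a nonresponder cannot facilitate")
        if self.latency_sd_ms < 0:
            raise ParameterError("latency_sd_ms must be non-negative")


@dataclass
class OptoProtocol:
    """Stimulation delivered after exploration: n pulses at a fixed rate."""

    n_pulses: int = 50
    rate_hz: float = 1.0
    duration_ms: float = 1.0
    power_mW: float = 0.5
    gap_after_tracking_s: float = 10.0


@dataclass
class CellClassSpec:
    """Parameter ranges for one ground-truth cell class; per-cell parameters
    are drawn from these at generation time."""

    name: str
    n_cells: int
    responder_class: str = "none"  # direct | indirect | none
    tuning_class: str = "tuned"  # tuned | weak | untuned
    cell_type: str = "pyramidal"
    baseline_rate_range: tuple = (0.2, 0.8)
    field_gain_range: tuple = (5.0, 10.0)
    field_width_range: tuple = (5.0, 10.0)
    burst_probability_range: tuple = (0.15, 0.65)
    latency_mean_ms: float = 2.5
    latency_sd_between_cells_ms: float = 0.5
    latency_sd_ms: float = 0.3
    response_probability_range: tuple = (0.9, 1.0)
    facilitation_increment: float = 0.0
    power_mW: float = 0.5


@dataclass
class CohortSpec:
    """Generative description of a synthetic cohort."""

    classes: list
    session_duration_s: float = 480.0
    tracking_rate_Hz: float = 25.0
    maze: MazeGeometry = field(default_factory=MazeGeometry)
    speed: SpeedParams = field(default_factory=SpeedParams)
    protocol: OptoProtocol = field(default_factory=OptoProtocol)
    include_tracking: bool = True
    include_opto: bool = True
    rng_seed: int = 0


def tuned_class(name: str = "calb1_negative", n: int = 26, **kw) -> CellClassSpec:
    """Strongly place-tuned, light-nonresponsive cells (putative
    Calb1-negative population)."""
    defaults = dict(responder_class="none", tuning_class="tuned")
    defaults.update(kw)
    return CellClassSpec(name=name, n_cells=n, **defaults)


def weak_class(name: str = "calb1_positive", n: int = 12, **kw) -> CellClassSpec:
    """Weakly modulated, directly light-activated cells (putative
    Calb1-positive population)."""
    defaults = dict(
        responder_class="direct", tuning_class="weak",
        baseline_rate_range=(0.6, 1.5), field_gain_range=(0.2, 0.8),
        field_width_range=(20.0, 40.0), response_probability_range=(0.9, 1.0),
        latency_mean_ms=2.5, latency_sd_between_cells_ms=0.5,
    )
    defaults.update(kw)
    return CellClassSpec(name=name, n_cells=n, **defaults)


def indirect_class(name: str = "indirect", n: int = 50, **kw) -> CellClassSpec:
    """Synaptically (indirectly) light-activated cells."""
    defaults = dict(
        responder_class="indirect", tuning_class="tuned",
        latency_mean_ms=7.5, latency_sd_between_cells_ms=2.0,
        latency_sd_ms=1.0, response_probability_range=(0.65, 0.95),
        facilitation_increment=0.0, power_mW=1.5,
    )
    defaults.update(kw)
    return CellClassSpec(name=name, n_cells=n, **defaults)


def default_cohort_spec(seed: int = 0, **kw) -> CohortSpec:
    """The study's freely moving cohort: 26 strongly tuned nonresponders and
    12 weakly tuned direct responders."""
    return CohortSpec(classes=[tuned_class(), weak_class()], rng_seed=seed, **kw)


def optotag_benchmark_spec(n_per_class: int = 50, seed: int = 0) -> CohortSpec:
    """Cohort for classifier-recovery benchmarks: equal numbers of direct,
    indirect and nonresponsive cells, without tracking."""
    classes = [
        weak_class(name="direct", n=n_per_class, tuning_class="untuned"),
        indirect_class(name="indirect", n=n_per_class, tuning_class="untuned"),
        tuned_class(name="none", n=n_per_class, tuning_class="untuned"),
    ]
    return CohortSpec(classes=classes, include_tracking=False, rng_seed=seed)


# ---------------------------------------------------------------------------
# primitives


def _ar1(n: int, tau_s: float, sd: float, dt: float,
         rng: np.random.Generator) -> np.ndarray:
    """Stationary zero-mean Ornstein-Uhlenbeck (AR(1)) series."""
    phi = np.exp(-dt / tau_s)
    eps = rng.standard_normal(n) * sd * np.sqrt(1 - phi * phi)
    eps[0] = rng.standard_normal() * sd
    return lfilter([1.0], [1.0, -phi], eps)


def _enforce_refractory(times: np.ndarray, refractory_s: float) -> np.ndarray:
    """Greedy pass keeping each spike only if it follows the last kept spike
    by at least the refractory period."""
    if times.size < 2:
        return times
    kept = [times[0]]
    last = times[0]
    for t in times[1:]:
        if t - last >= refractory_s:
            kept.append(t)
            last = t
    return np.asarray(kept)


def simulate_trajectory(maze: MazeGeometry, duration_s: float,
                        tracking_rate_Hz: float,
                        speed_params: Optional[SpeedParams] = None,
                        seed: int = 0) -> TrackingTrace:
    """Smooth exploration of the maze midline.

    The animal alternates runs (OU-modulated speed clipped to the run range)
    and pauses (sub-threshold jitter), follows the elliptical midline with
    OU lateral jitter bounded well inside the path, and occasionally reverses
    direction.  The two LED tracks are offset from the body position by a
    fixed-length head vector along the heading.  Deterministic per seed.
    """
    if duration_s <= 0:
        raise ParameterError("duration_s must be positive")
    if tracking_rate_Hz <= 0:
        raise ParameterError("tracking_rate_Hz must be positive")
    sp = speed_params or SpeedParams()
    rng = np.random.default_rng(seed)
    dt = 1.0 / tracking_rate_Hz
    n = int(round(duration_s * tracking_rate_Hz))
    t = np.arange(n) * dt

    # run/pause state sequence from alternating exponential dwell times
    running = np.empty(n, dtype=bool)
    pos = 0
    state = rng.random() < sp.run_fraction
    while pos < n:
        mean = sp.run_duration_mean_s if state else sp.pause_duration_mean_s
        dur = max(1, int(round(rng.exponential(mean) / dt)))
        running[pos:pos + dur] = state
        pos += dur
        state = not state

    v_run = np.clip(sp.run_speed_mean_cm_s
                    + _ar1(n, sp.speed_tau_s, sp.run_speed_sd_cm_s, dt, rng),
                    *sp.run_speed_range)
    v_pause = np.abs(rng.standard_normal(n)) * sp.pause_jitter_cm_s
    speed = np.where(running, v_run, v_pause)

    # direction reversals as a thinned Poisson process
    flips = rng.random(n) < sp.reversal_rate_hz * dt
    direction = np.where(rng.random() < 0.5, 1.0, -1.0) * np.cumprod(
        np.where(flips, -1.0, 1.0))

    midline = maze.midline
    s = np.cumsum(direction * speed) * dt
    s -= s[0] - rng.uniform(0, midline.perimeter)

    lateral = np.clip(_ar1(n, sp.lateral_tau_s, sp.lateral_sd_cm, dt, rng),
                      -sp.lateral_max_cm, sp.lateral_max_cm)
    # the body is still while paused: hold the last running lateral offset
    last_run = np.maximum.accumulate(np.where(running, np.arange(n), -1))
    lateral = lateral[np.maximum(last_run, 0)]

    # invert arc length to the ellipse parameter via the arc table
    grid_t, grid_s = midline._table()
    t_par = np.interp(np.mod(s, midline.perimeter), grid_s, grid_t)
    body = midline.point(t_par) + lateral[:, None] * midline.normal(t_par)
    head = midline.tangent(t_par) * direction[:, None]
    half = 0.5 * LED_SEPARATION_CM
    return TrackingTrace(t=t, led1_xy=body + half * head, led2_xy=body - half * head)


def place_field_rate(spec: PlaceFieldSpec, linear_pos: np.ndarray,
                     perimeter: float) -> np.ndarray:
    """Instantaneous firing rate lambda(t) = baseline + gain * Gaussian of
    the wrapped distance to the field center."""
    d = np.abs(np.mod(linear_pos - spec.field_center_cm + perimeter / 2,
                      perimeter) - perimeter / 2)
    return spec.baseline_rate_Hz + spec.field_gain_Hz * np.exp(
        -d * d / (2 * spec.field_width_cm ** 2))


def simulate_place_cell(spec: PlaceFieldSpec, tracking: TrackingTrace,
                        linear_pos: np.ndarray, perimeter: float,
                        seed: int = 0) -> SpikeTrain:
    """Inhomogeneous-Poisson spikes (thinning) against the place-field rate,
    with burst promotion and a 2 ms refractory period."""
    rng = np.random.default_rng(seed)
    lam = place_field_rate(spec, linear_pos, perimeter)
    lam_max = spec.baseline_rate_Hz + spec.field_gain_Hz
    t0, t1 = tracking.span
    span = (t0, t1 + tracking.dt)
    if lam_max <= 0:
        return SpikeTrain(times=np.empty(0), recording_span=span)
    n_cand = rng.poisson(lam_max * (span[1] - span[0]))
    cand = np.sort(rng.uniform(span[0], span[1], n_cand))
    lam_at = np.interp(cand, tracking.t, lam)
    accepted = cand[rng.random(n_cand) * lam_max < lam_at]

    if spec.burst_probability > 0 and accepted.size:
        burst = rng.random(accepted.size) < spec.burst_probability
        extra_per = spec.burst_size - 1
        isis = rng.uniform(spec.burst_isi_ms[0], spec.burst_isi_ms[1],
                           (int(burst.sum()), extra_per)) / 1000.0
        extras = (accepted[burst][:, None] + np.cumsum(isis, axis=1)).ravel()
        accepted = np.sort(np.concatenate([accepted, extras]))

    accepted = _enforce_refractory(accepted, REFRACTORY_MS / 1000.0)
    accepted = accepted[(accepted >= span[0]) & (accepted <= span[1])]
    return SpikeTrain(times=accepted, recording_span=span)


def _train_groups(pulses: LightPulseTrain) -> np.ndarray:
    """Label pulses by train: a new train starts when the gap exceeds 1.5
    nominal periods of the pulse's labelled frequency."""
    n = pulses.n_pulses
    groups = np.zeros(n, dtype=int)
    for i in range(1, n):
        period = 1.0 / pulses.train_frequency_Hz[i]
        gap = pulses.onsets[i] - pulses.onsets[i - 1]
        groups[i] = groups[i - 1] + (1 if gap > 1.5 * period else 0)
    return groups


def simulate_opto_response(spec: OptoResponseSpec, baseline: SpikeTrain,
                           pulses: LightPulseTrain, seed: int = 0) -> SpikeTrain:
    """Add light-evoked spikes to a baseline train.

    Each pulse evokes at most one spike, with the per-pulse probability
    (plus within-train facilitation for synaptically driven cells) and a
    truncated-normal latency (> 0.5 ms).  Class ``none`` returns the baseline
    unchanged.
    """
    if spec.responder_class == "none" or pulses.n_pulses == 0:
        return baseline
    t0, t1 = baseline.recording_span
    if pulses.onsets[0] < t0 or pulses.onsets[-1] > t1:
        raise ParameterError("pulses fall outside the recording span")
    rng = np.random.default_rng(seed)

    groups = _train_groups(pulses)
    # position of each pulse within its train (0-based)
    pos_in_train = np.zeros(pulses.n_pulses, dtype=int)
    for g in np.unique(groups):
        idx = np.where(groups == g)[0]
        pos_in_train[idx] = np.arange(idx.size)
    prob = np.minimum(1.0, spec.response_probability
                      + spec.facilitation_increment * pos_in_train)
    fires = rng.random(pulses.n_pulses) < prob
    n_ev = int(fires.sum())
    lat = np.empty(n_ev)
    for i in range(n_ev):  # rejection-sampled truncated normal, latency > 0.5 ms
        while True:
            draw = rng.normal(spec.latency_mean_ms, spec.latency_sd_ms)
            if draw > 0.5:
                lat[i] = draw
                break
    evoked = pulses.onsets[fires] + lat / 1000.0
    merged = np.sort(np.concatenate([baseline.times, evoked]))
    merged = _enforce_refractory(merged, REFRACTORY_MS / 1000.0)
    merged = merged[(merged >= t0) & (merged <= t1)]
    return SpikeTrain(times=merged, recording_span=(t0, t1))


# ---------------------------------------------------------------------------
# cohort assembly


def _draw_place_spec(cls: CellClassSpec, perimeter: float,
                     rng: np.random.Generator) -> PlaceFieldSpec:
    baseline = rng.uniform(*cls.baseline_rate_range)
    if cls.tuning_class == "tuned":
        gain = rng.uniform(*cls.field_gain_range)
        width = rng.uniform(*cls.field_width_range)
    elif cls.tuning_class == "weak":
        gain = baseline * rng.uniform(*cls.field_gain_range)
        width = rng.uniform(*cls.field_width_range)
    else:  # untuned
        gain, width = 0.0, 10.0
    return PlaceFieldSpec(
        baseline_rate_Hz=baseline, field_center_cm=rng.uniform(0, perimeter),
        field_width_cm=width, field_gain_Hz=gain,
        burst_probability=rng.uniform(*cls.burst_probability_range),
    )


def _draw_opto_spec(cls: CellClassSpec, rng: np.random.Generator) -> OptoResponseSpec:
    if cls.responder_class == "none":
        return OptoResponseSpec(responder_class="none", response_probability=0.0)
    while True:
        mean = rng.normal(cls.latency_mean_ms, cls.latency_sd_between_cells_ms)
        if mean > 1.0:
            break
    return OptoResponseSpec(
        responder_class=cls.responder_class, latency_mean_ms=mean,
        latency_sd_ms=cls.latency_sd_ms,
        response_probability=rng.uniform(*cls.response_probability_range),
        facilitation_increment=cls.facilitation_increment,
    )


def generate_cohort(spec: CohortSpec):
    """Generate one session per cell plus a ground-truth table.

    Returns ``(sessions, ground_truth)`` where ``ground_truth`` is a
    DataFrame with session_id, class name, responder/tuning/cell-type labels
    and the drawn generative parameters.  Fully determined by
    ``spec.rng_seed``.
    """
    root = np.random.SeedSequence(spec.rng_seed)
    midline = spec.maze.midline
    perimeter = midline.perimeter

    n_total = sum(c.n_cells for c in spec.classes)
    child_seeds = root.spawn(max(n_total, 1))
    sessions, rows = [], []
    cell_idx = 0
    for cls in spec.classes:
        if cls.responder_class not in ("direct", "indirect", "none"):
            raise ParameterError(f"unknown responder_class {cls.responder_class!r}")
        for _ in range(cls.n_cells):
            ss = child_seeds[cell_idx]
            rng = np.random.default_rng(ss)
            sid = f"cell_{cell_idx:03d}"
            cell_idx += 1

            place = _draw_place_spec(cls, perimeter, rng)
            opto = _draw_opto_spec(cls, rng)
            if cls.cell_type == "interneuron":
                place = replace(place, baseline_rate_Hz=rng.uniform(12.0, 25.0),
                                field_gain_Hz=0.0, burst_probability=0.0)

            sub = ss.spawn(4)
            tracking = None
            if spec.include_tracking:
                tracking = simulate_trajectory(
                    spec.maze, spec.session_duration_s, spec.tracking_rate_Hz,
                    spec.speed, seed=sub[0])
                _, xy = _midpoints(tracking)
                s = linearize(xy, midline)
                spikes = simulate_place_cell(place, tracking, s, perimeter,
                                             seed=sub[1])
            else:
                # homogeneous activity at the cell's overall mean rate
                mean_rate = place.baseline_rate_Hz + 0.15 * place.field_gain_Hz
                spikes = _homogeneous_train(mean_rate, place,
                                            (0.0, spec.session_duration_s),
                                            np.random.default_rng(sub[1]))

            pulses = None
            if spec.include_opto:
                start = spec.session_duration_s + spec.protocol.gap_after_tracking_s
                pr = spec.protocol
                onsets = start + np.arange(pr.n_pulses) / pr.rate_hz
                span_end = onsets[-1] + 1.0
                pulses = LightPulseTrain(
                    onsets=onsets, duration_ms=pr.duration_ms,
                    power_mW=cls.power_mW, train_frequency_Hz=pr.rate_hz)
                # spontaneous activity continues during the tagging protocol
                rate_during = max(spikes.n_spikes / max(spec.session_duration_s, 1e-9), 0.1)
                spont_rng = np.random.default_rng(sub[2])
                n_sp = spont_rng.poisson(rate_during * (span_end - spec.session_duration_s))
                spont = np.sort(spont_rng.uniform(spec.session_duration_s, span_end, n_sp))
                all_times = _enforce_refractory(
                    np.sort(np.concatenate([spikes.times, spont])),
                    REFRACTORY_MS / 1000.0)
                spikes = SpikeTrain(times=all_times, recording_span=(0.0, span_end))
                spikes = simulate_opto_response(opto, spikes, pulses, seed=sub[3])

            session = SessionRecord(
                session_id=sid, spikes=spikes, tracking=tracking,
                pulses=pulses, arena=spec.maze,
                annotations={"histology_calb1": "unknown"})
            sessions.append(session)
            rows.append({
                "session_id": sid, "class_name": cls.name,
                "responder_class": cls.responder_class,
                "tuning_class": cls.tuning_class, "cell_type": cls.cell_type,
                "baseline_rate_hz": place.baseline_rate_Hz,
                "field_gain_hz": place.field_gain_Hz,
                "field_width_cm": place.field_width_cm,
                "field_center_cm": place.field_center_cm,
                "latency_mean_ms": opto.latency_mean_ms if opto.responder_class != "none" else np.nan,
                "response_probability": opto.response_probability,
            })
    return sessions, pd.DataFrame(rows)


def _midpoints(tracking: TrackingTrace):
    ok = ~(np.isnan(tracking.led1_xy).any(axis=1)
           | np.isnan(tracking.led2_xy).any(axis=1))
    return tracking.t[ok], 0.5 * (tracking.led1_xy[ok] + tracking.led2_xy[ok])


def _homogeneous_train(rate_hz: float, place: PlaceFieldSpec, span,
                       rng: np.random.Generator) -> SpikeTrain:
    n = rng.poisson(rate_hz * (span[1] - span[0]))
    times = np.sort(rng.uniform(span[0], span[1], n))
    if place.burst_probability > 0 and times.size:
        burst = rng.random(times.size) < place.burst_probability
        isis = rng.uniform(place.burst_isi_ms[0], place.burst_isi_ms[1],
                           (int(burst.sum()), place.burst_size - 1)) / 1000.0
        extras = (times[burst][:, None] + np.cumsum(isis, axis=1)).ravel()
        times = np.sort(np.concatenate([times, extras]))
    times = _enforce_refractory(times, REFRACTORY_MS / 1000.0)
    times = times[(times >= span[0]) & (times <= span[1])]
    return SpikeTrain(times=times, recording_span=span)
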