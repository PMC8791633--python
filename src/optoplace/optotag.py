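"""Light-response quantification and latency-based opto-tagging.

A cell expressing the opsin fires at short latency (< 4 ms mean) after a
brief blue-light pulse; a cell driven only synaptically fires later (~7-8 ms)
and with failures; an untagged cell shows no reliable response.  The
classifier measures, for each included pulse, the latency of the first spike
within a fixed window (20 ms), summarizes latencies across trials, and labels
the cell:

* ``direct``       — mean latency below the threshold and responses reliable
* ``indirect``     — reliable responses at longer mean latency
* ``nonresponsive``— response probability below the reliability floor

Pulse inclusion follows the recording protocol: interpulse interval >= 200 ms
(onset-to-onset), power <= 5 mW, and configurable exclusion of whole train
frequencies (40 Hz trains fail too often to be informative).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .config import AnalysisConfig
from .core import LightPulseTrain, SpikeTrain


class OptotagError(ValueError):
    pass


@dataclass
class PSTH:
    """Peristimulus time histogram: spike counts in fine bins aligned to
    pulse onset, summed over pulses."""

    bin_edges_ms: np.ndarray
    counts: np.ndarray
    n_pulses: int


@dataclass
class TrialLatencies:
    """Per-pulse first-spike latency in ms; NaN marks a failure trial."""

    latencies_ms: np.ndarray
    window_ms: float

    @property
    def n_trials(self) -> int:
        return int(self.latencies_ms.size)


@dataclass
class LatencySummary:
    mean_ms: float  # NaN when no trial had a spike
    sd_ms: float
    response_probability: float
    n_trials: int


@dataclass
class OptoClass:
    label: str  # direct | indirect | nonresponsive
    evidence: LatencySummary


def filter_pulses(pulses: LightPulseTrain, min_interpulse_ms: float = 200.0,
                  max_power_mW: float = 5.0,
                  exclude_train_hz: tuple = ()) -> LightPulseTrain:
    """Keep pulses eligible for latency analysis.

    A pulse is kept when the interval from the preceding pulse (onset to
    onset) is at least ``min_interpulse_ms`` (the first pulse is always
    eligible), its power does not exceed ``max_power_mW``, and its train
    frequency is not excluded.  Order is preserved; an empty result is legal.
    """
    if pulses.n_pulses == 0:
        return pulses
    interval_ok = np.ones(pulses.n_pulses, dtype=bool)
    interval_ok[1:] = np.diff(pulses.onsets) >= min_interpulse_ms / 1000.0 - 1e-12
    power_ok = pulses.power_mW <= max_power_mW + 1e-12
    freq_ok = ~np.isin(pulses.train_frequency_Hz, np.asarray(list(exclude_train_hz), dtype=float))
    return pulses.subset(interval_ok & power_ok & freq_ok)


def compute_psth(spikes: SpikeTrain, pulses: LightPulseTrain,
                 window_ms: float = 20.0, bin_ms: float = 0.1) -> PSTH:
    """Histogram of spike times relative to pulse onset.

    Bins are half-open [k*bin, (k+1)*bin) over [0, window); spikes before the
    onset or at/after the window edge are excluded.
    """
    if pulses.n_pulses == 0:
        raise OptotagError("PSTH undefined for an empty pulse train")
    n_bins = window_ms / bin_ms
    if abs(n_bins - round(n_bins)) > 1e-9:
        raise OptotagError("bin_ms must divide window_ms")
    n_bins = int(round(n_bins))
    edges = np.arange(n_bins + 1) * bin_ms
    counts = np.zeros(n_bins, dtype=int)
    window_s = window_ms / 1000.0
    t = spikes.times
    lo = np.searchsorted(t, pulses.onsets, side="left")
    hi = np.searchsorted(t, pulses.onsets + window_s, side="left")
    for onset, i, j in zip(pulses.onsets, lo, hi):
        rel_ms = (t[i:j] - onset) * 1000.0
        idx = np.floor(rel_ms / bin_ms).astype(int)
        idx = idx[(idx >= 0) & (idx < n_bins)]
        np.add.at(counts, idx, 1)
    return PSTH(bin_edges_ms=edges, counts=counts, n_pulses=pulses.n_pulses)


def first_spike_latencies(spikes: SpikeTrain, pulses: LightPulseTrain,
                          window_ms: float = 20.0) -> TrialLatencies:
    """Per-pulse latency of the first spike in (0, window] ms after onset.

    A spike exactly at the onset is excluded (latency must be positive); a
    spike exactly at the window edge is included.  Pulses must already be
    filtered so that windows cannot overlap.
    """
    if pulses.n_pulses > 1:
        if np.min(np.diff(pulses.onsets)) < window_ms / 1000.0 - 1e-12:
            raise OptotagError("pulse windows overlap; filter pulses before measuring latencies")
    window_s = window_ms / 1000.0
    lat = np.full(pulses.n_pulses, np.nan)
    if spikes.times.size == 0:
        return TrialLatencies(latencies_ms=lat, window_ms=window_ms)
    idx = np.searchsorted(spikes.times, pulses.onsets, side="right")
    has = idx < spikes.times.size
    first = np.where(has, spikes.times[np.minimum(idx, spikes.times.size - 1)], np.inf)
    rel = first - pulses.onsets
    within = has & (rel <= window_s + 1e-12)
    lat[within] = rel[within] * 1000.0
    return TrialLatencies(latencies_ms=lat, window_ms=window_ms)


def summarize_latency(trials: TrialLatencies) -> LatencySummary:
    """Mean/SD latency over spiking trials; response probability over all
    trials.  With no spiking trials the mean and SD are NaN."""
    if trials.n_trials == 0:
        raise OptotagError("latency summary requires at least one trial")
    ok = ~np.isnan(trials.latencies_ms)
    prob = float(ok.sum() / trials.n_trials)
    if ok.any():
        vals = trials.latencies_ms[ok]
        mean = float(vals.mean())
        sd = float(vals.std(ddof=0))
    else:
        mean = sd = float("nan")
    return LatencySummary(mean_ms=mean, sd_ms=sd, response_probability=prob,
                          n_trials=trials.n_trials)


def evoked_spikes_per_pulse(spikes: SpikeTrain, pulses: LightPulseTrain,
                            window_ms: float = 20.0) -> float:
    """Mean number of spikes in (onset, onset + window] across pulses."""
    if pulses.n_pulses == 0:
        raise OptotagError("evoked-spike count undefined for an empty pulse train")
    window_s = window_ms / 1000.0
    lo = np.searchsorted(spikes.times, pulses.onsets, side="right")
    hi = np.searchsorted(spikes.times, pulses.onsets + window_s, side="right")
    return float((hi - lo).mean())


def classify_optotag(summary: LatencySummary,
                     config: Optional[AnalysisConfig] = None) -> OptoClass:
    """Label a cell from its latency summary.

    direct: mean latency below the direct-activation threshold AND response
    probability at or above the reliability floor; nonresponsive: probability
    below the floor; indirect otherwise.
    """
    config = config or AnalysisConfig()
    if summary.response_probability < config.response_probability_min:
        label = "nonresponsive"
    elif summary.mean_ms < config.direct_latency_threshold_ms:
        label = "direct"
    else:
        label = "indirect"
    return OptoClass(label=label, evidence=summary)


def optotag_session(spikes: SpikeTrain, pulses: LightPulseTrain,
                    config: Optional[AnalysisConfig] = None) -> OptoClass:
    """Full chain: filter pulses, measure latencies, summarize, classify."""
    config = config or AnalysisConfig()
    kept = filter_pulses(pulses, config.min_interpulse_ms, config.max_power_mW,
                         config.exclude_train_hz)
    if kept.n_pulses == 0:
        summary = LatencySummary(mean_ms=float("nan"), sd_ms=float("nan"),
                                 response_probability=0.0, n_trials=0)
        return OptoClass(label="nonresponsive", evidence=summary)
    trials = first_spike_latencies(spikes, kept, config.latency_window_ms)
    return classify_optotag(summarize_latency(trials), config)
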