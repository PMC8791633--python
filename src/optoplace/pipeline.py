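"""Cell-level typing, inclusion filtering and cohort-level reporting.

Every recorded cell is summarized by its firing statistics (mean rate, burst
index), electrophysiological type (pyramidal below 10 Hz with a broad
waveform, interneuron above 10 Hz or with a peak-to-trough below 0.4 ms),
light-response class and spatial metrics.  Final molecular labels follow the
tagging logic: a directly light-activated cell is putative Calb1-positive, a
nonresponsive cell putative Calb1-negative, histology annotations override
when available (a direct responder annotated Calb1-negative is surfaced as a
conflict, never silently resolved), and interneurons are excluded from the
spatial group comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .config import AnalysisConfig
from .core import SessionRecord, SpikeTrain
from .io import read_cohort
from .optotag import OptoClass, optotag_session
from .spatial import SpatialError, SpatialMetrics, spatial_summary
from .stats import GroupComparison, compare_groups


class PipelineError(ValueError):
    pass


@dataclass
class CellSummary:
    session_id: str
    mean_rate_hz: float
    burst_index: float
    waveform_peak_to_trough_ms: Optional[float]
    cell_type: str  # pyramidal | interneuron
    opto: Optional[OptoClass]
    spatial: Optional[SpatialMetrics]
    included_spatial: bool
    final_label: str  # Calb1_positive | Calb1_negative | excluded
    conflict: bool = False
    error: Optional[str] = None


def mean_firing_rate(spikes: SpikeTrain) -> float:
    """Spike count over recording duration, in Hz."""
    if spikes.duration_s <= 0:
        raise PipelineError("recording duration must be positive")
    return spikes.n_spikes / spikes.duration_s


def burst_index(spikes: SpikeTrain, isi_threshold_ms: float = 6.0) -> float:
    """Fraction of spiking attributable to short inter-spike intervals:
    the number of ISIs at or below the threshold over the total spike count.
    Returns 0 for trains with fewer than two spikes."""
    if spikes.n_spikes < 2:
        return 0.0
    isis_ms = np.diff(spikes.times) * 1000.0
    return float((isis_ms <= isi_threshold_ms + 1e-9).sum() / spikes.n_spikes)


def classify_cell_type(mean_rate_hz: float,
                       waveform_peak_to_trough_ms: Optional[float] = None,
                       config: Optional[AnalysisConfig] = None) -> str:
    """Interneuron when the rate exceeds 10 Hz or the waveform is narrow
    (< 0.4 ms peak-to-trough); pyramidal otherwise."""
    config = config or AnalysisConfig()
    if mean_rate_hz > config.interneuron_rate_hz:
        return "interneuron"
    if (waveform_peak_to_trough_ms is not None
            and waveform_peak_to_trough_ms < config.narrow_waveform_ms):
        return "interneuron"
    return "pyramidal"


def spatial_inclusion(metrics: Optional[SpatialMetrics],
                      config: Optional[AnalysisConfig] = None) -> bool:
    """Spatial analysis inclusion: strictly more than ``min_spikes``
    movement-filtered spikes and at least ``min_laps`` laps."""
    config = config or AnalysisConfig()
    if metrics is None:
        return False
    return (metrics.n_spikes_included > config.min_spikes
            and metrics.n_laps >= config.min_laps)


def assign_final_label(opto: Optional[OptoClass], histology: str = "unknown",
                       cell_type: str = "pyramidal"):
    """Molecular label from the opto class and histology annotation.

    Returns ``(label, conflict)``.  Interneurons are excluded from the group
    analysis regardless of label; histology overrides a missing or
    uninformative opto label, and disagreement between a direct response and
    negative histology is flagged as a conflict.
    """
    if opto is None and histology not in ("positive", "negative"):
        raise PipelineError("cannot label a cell without opto response or histology")
    conflict = False
    if opto is not None and opto.label == "direct":
        label = "Calb1_positive"
        if histology == "negative":
            conflict = True
    elif histology == "positive":
        label = "Calb1_positive"
    elif opto is not None and opto.label == "nonresponsive":
        label = "Calb1_negative"
        if histology == "positive":
            label, conflict = "Calb1_positive", True
    elif histology == "negative":
        label = "Calb1_negative"
    else:  # indirect responder without informative histology
        label = "Calb1_negative"
    if cell_type == "interneuron":
        label = "excluded"
    return label, conflict


def summarize_cell(session: SessionRecord,
                   config: Optional[AnalysisConfig] = None) -> CellSummary:
    """Run the full per-cell chain; stage failures are recorded, not raised."""
    config = config or AnalysisConfig()
    rate = mean_firing_rate(session.spikes)
    bi = (burst_index(session.spikes, config.burst_isi_ms)
          if session.spikes.n_spikes > config.min_spikes else float("nan"))
    waveform = session.annotations.get("waveform_peak_to_trough_ms")
    waveform = float(waveform) if waveform is not None else None
    cell_type = classify_cell_type(rate, waveform, config)

    error = None
    opto = None
    if session.pulses is not None:
        opto = optotag_session(session.spikes, session.pulses, config)

    metrics = None
    if session.tracking is not None:
        try:
            metrics = spatial_summary(session, config)
        except (SpatialError, ValueError) as exc:
            error = f"spatial: {exc}"

    included = spatial_inclusion(metrics, config) and cell_type == "pyramidal"
    histology = str(session.annotations.get("histology_calb1", "unknown"))
    try:
        label, conflict = assign_final_label(opto, histology, cell_type)
    except PipelineError as exc:
        label, conflict = "excluded", False
        error = error or str(exc)

    return CellSummary(
        session_id=session.session_id, mean_rate_hz=rate, burst_index=bi,
        waveform_peak_to_trough_ms=waveform, cell_type=cell_type, opto=opto,
        spatial=metrics, included_spatial=included, final_label=label,
        conflict=conflict, error=error)


_METRIC_COLUMNS = {
    "information_bits_per_spike": "spatial_information",
    "sparsity_index": "sparsity",
    "stability_r": "stability",
    "peak_rate_hz": "peak_rate",
}


def cells_table(summaries) -> pd.DataFrame:
    rows = []
    for c in summaries:
        row = {
            "session_id": c.session_id,
            "mean_rate_hz": c.mean_rate_hz,
            "burst_index": c.burst_index,
            "cell_type": c.cell_type,
            "opto_label": c.opto.label if c.opto else "",
            "opto_mean_latency_ms": c.opto.evidence.mean_ms if c.opto else np.nan,
            "opto_sd_latency_ms": c.opto.evidence.sd_ms if c.opto else np.nan,
            "opto_response_probability": (c.opto.evidence.response_probability
                                          if c.opto else np.nan),
            "final_label": c.final_label,
            "included_spatial": c.included_spatial,
            "conflict": c.conflict,
            "error": c.error or "",
        }
        for attr, col in _METRIC_COLUMNS.items():
            row[col] = getattr(c.spatial, attr) if c.spatial else np.nan
        row["n_spikes_included"] = c.spatial.n_spikes_included if c.spatial else 0
        row["n_laps"] = c.spatial.n_laps if c.spatial else 0
        rows.append(row)
    return pd.DataFrame(rows)


def group_comparisons(table: pd.DataFrame) -> list:
    """Calb1-positive vs Calb1-negative comparisons: spatial metrics over
    spatially included pyramidal cells, rate and burst index over all
    pyramidal cells."""
    out = []
    pyr = table[table.cell_type == "pyramidal"]
    spatial = pyr[pyr.included_spatial]
    pos = spatial[spatial.final_label == "Calb1_positive"]
    neg = spatial[spatial.final_label == "Calb1_negative"]
    labels = ("Calb1_positive", "Calb1_negative")
    for col in ("spatial_information", "sparsity", "stability", "peak_rate"):
        a, b = pos[col].dropna(), neg[col].dropna()
        if len(a) and len(b):
            out.append(compare_groups(a, b, metric=col, labels=labels))
    pos_all = pyr[pyr.final_label == "Calb1_positive"]
    neg_all = pyr[pyr.final_label == "Calb1_negative"]
    for col in ("mean_rate_hz", "burst_index"):
        a, b = pos_all[col].dropna(), neg_all[col].dropna()
        if len(a) and len(b):
            out.append(compare_groups(a, b, metric=col, labels=labels))
    return out


def comparisons_table(comparisons) -> pd.DataFrame:
    rows = []
    for c in comparisons:
        rows.append({
            "metric": c.metric, "test": c.test,
            "group_a": c.group_labels[0], "group_b": c.group_labels[-1],
            "n_a": c.group_sizes[0], "n_b": c.group_sizes[-1],
            "statistic": c.statistic, "p_value": c.p_value,
        })
    return pd.DataFrame(rows)


def run_pipeline(cohort_dir: str | Path, config: Optional[AnalysisConfig] = None,
                 out_dir: Optional[str | Path] = None):
    """End-to-end cohort analysis.

    Reads every session under ``cohort_dir``, summarizes each cell (errors
    recorded per cell, the run continues), compares the labelled groups and,
    when ``out_dir`` is given, writes ``cells.csv``, ``comparisons.csv`` and
    ``run_log.txt``.  Deterministic given identical inputs and config.
    """
    config = config or AnalysisConfig()
    sessions, _ = read_cohort(cohort_dir)
    summaries = [summarize_cell(s, config) for s in sessions]
    table = cells_table(summaries)
    comparisons = group_comparisons(table)
    comp_table = comparisons_table(comparisons)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        table.to_csv(out_dir / "cells.csv", index=False, float_format="%.9g")
        comp_table.to_csv(out_dir / "comparisons.csv", index=False,
                          float_format="%.9g")
        lines = [f"optoplace {__version__}",
                 f"n_cells: {len(summaries)}", "config:"]
        lines += [f"  {k}: {v}" for k, v in sorted(config.to_dict().items())]
        (out_dir / "run_log.txt").write_text("\n".join(lines) + "\n")
    return table, comp_table
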