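# Methods

This note documents the models implemented in `optoplace`, the choices made
where the underlying procedures leave details open, and what the synthetic
cohorts do and do not establish about real recordings.

## Data model and units

A session is one recorded cell. Times are seconds (float64), positions
centimetres with the origin at the lower-left corner of the arena bounding
box. Spike times must be strictly increasing and lie within the recording
span; tracking frames must be regularly sampled (frame interval constant to
1%); missing LED samples are stored as empty CSV fields and dropped — never
interpolated — before analysis. Light pulses are typically delivered after
exploration, so the tracking and pulse spans need not overlap each other;
validation requires only that each lies within the spike recording span.
Tables are plain delimited text with fixed float precision (1 ns for times,
10 nm for positions), which makes write→read an identity far below analysis
resolution and repeated writes byte-identical.

## Opto-tagging

Pulse inclusion: interpulse interval ≥ 200 ms measured onset-to-onset (the
first pulse is always eligible), power ≤ 5 mW, and whole train frequencies
can be excluded (40 Hz by default, where spiking failures dominate).
Latency is the time from pulse onset to the first spike in (0, 20] ms; a
spike exactly at onset is excluded (latency must be positive), a spike
exactly at the window edge included. Failure trials do not contribute to
the mean latency; response probability is the fraction of trials with a
spike. Spontaneous spikes falling inside the window are counted like evoked
ones — the first-spike rule makes no distinction — and false positives are
controlled instead by the reliability floor: classification requires
response probability ≥ 0.5 (configurable) before a cell can be called
direct (mean latency < 4 ms) or indirect (otherwise). At a 2 Hz
spontaneous rate the chance of a coincidental spike in a 20 ms window is
about 4%, so untagged cells sit far below the floor. Whether the original
procedure applied the reliability criterion numerically or by inspection is
unknowable from the text; it is exposed as configuration.

PSTHs use half-open 0.1 ms bins over the 20 ms window; the evoked-spike
count averages spikes in (onset, onset + 20 ms] over included pulses.

## Spatial analysis

Position is the midpoint of the two head LEDs. Speed is a central
difference smoothed with a 0.25 s boxcar (the smoothing scale is a package
choice; it is config-exposed and results are insensitive between 0.1 and
0.5 s). Samples and spikes at ≤ 1 cm/s are excluded from maps.

The smoothing kernel is a 2D Gaussian with σ = 1 *pixel* (= 2.5 cm): the
printed formulas operate on the discretized grid and state σ = 1 without
units. The kernel is truncated at 4σ and renormalized per sample over the
in-grid pixels of its support, so Σ_x z(x) equals the included tracking
time exactly (mass is conserved at arena boundaries too) and Σ_x of the
rate numerator equals the included spike count. Smoothing sums over raw
tracking frames and raw spike positions, not over pre-binned histograms.
Pixels occupied < 20 ms are masked; information and sparsity are computed
over valid pixels only with p_n renormalized (an undefined rate cannot
enter the sums), and 0·log 0 := 0.

The sparsity formula as commonly typeset is ambiguous between
(Σpλ)²/Σpλ² and its reciprocal. The implemented form is (Σpλ)²/Σpλ²,
which lies in (0, 1], equals 1 for uniform firing and 1/N for firing
confined to one of N equally occupied pixels — so a *higher* index means
more diffuse firing, matching how the measure is reported.

Linearization fits the trajectory with a direct least-squares conic fit
constrained to ellipses (Halir–Flusser) and maps each position to the arc
length of its *radial* projection (the ellipse point on the ray from the
center through the sample). For near-track points on the low-eccentricity
track ellipse the difference from the true closest-point projection is far
below the 2.5 cm bin; this is an documented approximation, not an
optimization. Arc length is computed from an 8192-point cumulative
trapezoid table (relative perimeter error ~1e-8). A lap is one full
circuit: the circular coordinate is unwrapped as a phase and the lap count
is the floored net excursion in perimeter units, so back-and-forth running
below a full circuit contributes nothing.

Linearized rate maps use 2.5 cm arc-length bins (matching the 2D pixels),
circular Gaussian smoothing with σ = 1 bin applied to the occupancy and
spike histograms before division, and the same 20 ms occupancy mask.
Split-half stability splits the session at the temporal midpoint (not by
laps), builds the two linearized maps independently with the session-wide
ellipse, and correlates bins valid in both halves (Pearson).

Information and sparsity are computed on the 2D pixel maps; stability on
the linearized maps. Two mean rates are reported separately: the overall
rate over the full recording span (unfiltered, as mean rates are usually
quoted) and the movement-filtered rate underlying the maps.

## Cell typing and labels

Pyramidal vs interneuron: a cell is an interneuron if its mean rate exceeds
10 Hz or its (annotated) spike peak-to-trough is below 0.4 ms. The burst
index counts inter-spike intervals ≤ 6 ms over the total spike count; the
phrase "spikes with an ISI ≤ 6 ms" is ambiguous between interval- and
spike-counting conventions, and the interval-count reading is adopted (for
a burst of k spikes it contributes k−1 counts). Burst indices are computed
only for trains with > 50 spikes. Spatial inclusion requires > 50
movement-filtered spikes and ≥ 3 laps.

Final labels: a direct responder is putative Calb1-positive; a
nonresponsive pyramidal cell putative Calb1-negative; histology annotations
override an uninformative opto label, and a direct responder with negative
histology is surfaced as a conflict rather than silently resolved.
Interneurons never enter the spatial group comparison. The "deep pyramidal
layer" criterion is anatomical and enters only as an annotation.

## Statistics

Two-group comparisons use the two-sided Wilcoxon rank-sum test. When both
groups have fewer than 10 observations the p-value is exact: a subset-sum
dynamic program over doubled midranks yields the full null distribution of
the rank sum, and the two-sided p is P(|W − E[W]| ≥ |w_obs − E[W]|).
Larger groups use the normal approximation with tie-corrected variance and
no continuity correction. Three-group latency comparisons use
Kruskal–Wallis with pairwise rank-sum post-hocs under Bonferroni correction
(the multiple-comparison procedure is a package choice).

## Synthetic cohorts

The generator defines the study conditions used by all tests and by
`scripts/acceptance.py`; defaults were fixed once:

- **Arena**: 70 × 50 cm bounding box, 9 cm path; midline ellipse with
  semi-axes 30.5 × 20.5 cm.
- **Trajectory**: 480 s sessions tracked at 25 Hz (camera rate is a package
  choice). Locomotion alternates runs and pauses with exponential dwell
  times (means 25 s and 4 s, hence 86% run fraction); run speed is an
  Ornstein–Uhlenbeck process around 15 cm/s (SD 4, τ = 3 s) clipped to
  5–30 cm/s; pauses jitter below 1 cm/s with the lateral offset frozen.
  Lateral position is an OU offset (SD 1.2 cm, τ = 2 s) clipped to ±3 cm;
  direction reverses as a rare Poisson event (0.0005 /s). The two LEDs sit
  ±1 cm from the body along the heading.
- **Spikes**: inhomogeneous Poisson by thinning against
  λ(t) = baseline + gain·exp(−d(s,c)²/2w²) on the circular coordinate
  (wrapped distance), followed by burst promotion (probability drawn per
  cell from U(0.15, 0.65), one extra spike at 3–6 ms ISI) and a 2 ms
  absolute refractory period (needed to avoid zero-ISI artifacts; the
  underlying recordings are silent on this). With burst probability p and
  2-spike bursts the expected burst index is p/(1+p), so the default range
  centres the population near 0.28.
- **Tuned cells** (putative Calb1-negative): baseline U(0.2, 0.8) Hz, gain
  U(5, 10) Hz, field SD U(5, 10) cm. **Weakly modulated cells** (putative
  Calb1-positive, direct responders): baseline U(0.6, 1.5) Hz, gain =
  baseline·U(0.2, 0.8), field SD U(20, 40) cm. Both classes end up near
  2 Hz overall with statistically indistinguishable rates and burst
  indices, while differing strongly in information, sparsity and stability.
- **Light responses**: at most one evoked spike per pulse (the minimal
  single-spike regime; burst-evoking responses are reachable through the
  burst flag), latency drawn from a normal truncated at 0.5 ms. Direct
  cells: per-cell mean ~N(2.5, 0.5) ms, trial SD 0.3 ms, response
  probability U(0.9, 1.0). Indirect cells: mean ~N(7.5, 2.0) ms, trial SD
  1 ms, probability U(0.65, 0.95), optional additive facilitation per
  successive pulse within a train (trains delimited by gaps > 1.5 nominal
  periods). The default tagging protocol is 50 pulses at 1 Hz, 1 ms,
  0.5 mW (1.5 mW for indirect cells), 10 s after exploration ends, with
  spontaneous activity continuing at the session's mean rate.

**What the synthetic data does not capture.** Trajectories are smoother
and more stereotyped than real exploration; place fields are single,
stationary Gaussians without remapping, phase precession, directionality or
rate instability; latency distributions are exactly truncated-normal;
there are no photostimulation artifacts, electrode drift, cell damage or
lost tracking frames (though the format supports missing samples).
Passing recovery tests therefore shows that the estimators and the
classification logic are correct under the stated statistical structure —
not that real recordings satisfy that structure. Synthetic stability values
for tuned cells (~0.97) exceed typical in vivo values because the
generative fields are perfectly stationary.

## Problem sizes

Tests and the acceptance script use 480 s sessions at 25 Hz, cohorts of
38 (spatial) and 150 (opto benchmark) cells, 100 seeded cohort replicates
for the population-separation property and 200 replicates for the
three-group latency power; these sizes give stable Monte-Carlo estimates
while keeping a full run to a few minutes on one CPU.

## Known limitations

- The radial ellipse projection degrades for points far off the track or
  for highly eccentric ellipses; it is adequate for the O-maze geometry.
- The lap counter measures net circulation, so perfectly balanced
  back-and-forth running yields zero laps by design.
- Exact rank-sum enumeration is limited to both groups < 10 (beyond that
  the tie-corrected normal approximation is used).
- The pipeline assumes one cell per session; simultaneous units are out of
  scope, as are raw voltage traces, spike sorting and LFP analyses.
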