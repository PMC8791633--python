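# optoplace

Analysis toolkit for **opto-tagged juxtacellular recordings of hippocampal
CA1 neurons in freely moving mice**: latency-based classification of
light-evoked responses, electrophysiological cell typing, and quantification
of spatial modulation (rate maps, Skaggs information, sparsity,
linearization, split-half stability), together with a synthetic-cohort
generator that emulates the recording conditions and provides ground-truth
labels for recovery testing.

It is written for electrophysiologists analyzing single-cell recordings on a
closed (O-shaped) linear track, where each session is one cell: a spike
train, a two-LED head-tracking trace, and an optional blue-light stimulation
protocol delivered at the end of the session.

## The science

**Opto-tagging.** A neuron expressing channelrhodopsin fires at short
latency after a brief blue-light pulse; a neuron driven only synaptically by
tagged afferents fires later and less reliably. For each light pulse that
passes the inclusion filter (interpulse interval ≥ 200 ms, power ≤ 5 mW,
failure-prone 40 Hz trains excluded), the latency of the first spike within
a 20 ms window is measured. A cell is *directly light-activated* if its mean
latency is below 4 ms and responses are reliable (response probability
≥ 0.5 by default); reliable responders at longer latency are *indirect*;
the rest are *nonresponsive*. PSTHs use 0.1 ms bins.

**Spatial modulation.** The arena is discretized into 2.5 × 2.5 cm pixels.
Occupancy and firing rate are kernel-smoothed sums over raw tracking frames
and spike positions (Gaussian, σ = 1 pixel),

    z(x) = Σ_t w(|x − x_t|) Δt,        r(x) = Σ_i w(|x − x_i|) / z(x),

with pixels occupied less than 20 ms masked, only samples and spikes during
movement (speed > 1 cm/s) included. With p_n the occupancy probability of
pixel n, λ_n its rate and λ = Σ p_n λ_n:

    I_spike  = Σ_n p_n (λ_n/λ) log2(λ_n/λ)      [bits/spike]
    sparsity = (Σ_n p_n λ_n)² / Σ_n p_n λ_n²    [1 = diffuse, 1/N = compact]

Trajectories on the closed track are linearized by projecting positions onto
the best-fit ellipse (direct least-squares conic fit) and taking arc length;
stability is the Pearson correlation between linearized rate maps of the two
session halves. Cells enter the spatial comparison only with > 50 movement
spikes and ≥ 3 laps; cells firing above 10 Hz (or with spike peak-to-trough
< 0.4 ms) are classed as interneurons and excluded. Group differences use
the two-sided Wilcoxon rank-sum test (exact below n = 10 per group) and the
Kruskal–Wallis test for three-group latency comparisons.

## Worked example

The `analysis/` scripts run the whole study flow on synthetic cohorts:

```bash
python analysis/01_simulate_cohort.py --seed 0   # writes results/cohort_*
python analysis/02_optotag_classification.py
python analysis/03_spatial_tuning.py
python analysis/04_group_statistics.py
```

`02` classifies a 150-cell direct/indirect/nonresponsive benchmark and
prints, for seed 0:

```
accuracy: 99.3%
direct latency:   2.45 +/- 0.52 ms (n=50)
indirect latency: 7.74 +/- 2.01 ms (n=49)
Kruskal-Wallis across latency groups: H=74.06, p=8.29e-17
```

i.e. 149/150 ground-truth labels are recovered by the 4 ms rule, and the
recovered direct and indirect latency distributions are far apart. `03` and
`04` analyze the 38-cell spatial cohort (26 strongly tuned nonresponders vs
12 weakly tuned direct responders):

```
              spatial_information_bits_per_spike  sparsity  stability_r
tuned                                      0.815     0.366        0.975
weak                                       0.041     0.946        0.298

             metric   n_a  n_b  statistic   p_value
spatial_information    12   26         78 9.634e-07
           sparsity    12   26        390 9.634e-07
          stability    12   26         78 9.634e-07
       mean_rate_hz    12   26        272    0.2327
        burst_index    12   26        203    0.3303
```

Tagged (weakly tuned) cells convey less spatial information, fire more
diffusely (higher sparsity) and are less stable across session halves,
while overall firing rate and burstiness do not differ — the expected
population pattern. A `optoplace` command-line tool exposes the same steps
(`simulate`, `optotag`, `spatial`, `report`, `pipeline`) for single sessions
and cohorts on disk.

## Layout

- `src/optoplace/` — library: `core`/`io`/`config` (session data model and
  plain-text formats), `synth` (cohort generator), `optotag` (PSTH, latency,
  classification), `spatial` + `geometry` (maps, metrics, linearization),
  `stats` (rank-sum, Kruskal–Wallis), `pipeline` (cell typing, labels,
  cohort report), `cli`.
- `analysis/` — numbered narrative drivers writing tables under `results/`.
- `docs/methods.md` — models, assumptions, parameter choices, limitations.
- `tests/` — unit, property and acceptance suites.
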