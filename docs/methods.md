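# Methods

`ephyskit` implements four biomarker pipelines for a *Syngap1*
haploinsufficiency mouse study — telemetry-EEG spectral analysis,
epileptiform spike-train detection, four-stage sleep scoring, and HD-MEA
network-burst quantification — together with seeded synthetic generators
that emulate the study's recordings with known ground truth. This note
records the models, the tunable parameters and their defaults, the numerical
choices made where the published analysis left the design open, and what the
synthetic benchmarks do and do not demonstrate.

## Signals and epochs

Telemetry recordings carry EEG and EMG at 500 Hz (hardware band-passed
0.1–100 Hz upstream; no digital filter is applied by default) and an
integrated-accelerometer activity channel at 200 Hz. EEG/EMG are held in µV
throughout; EDF physical dimensions are honored on read.

All analyses run on contiguous, non-overlapping, half-open epochs
`[t, t + L)`; a sample on a boundary belongs to the later epoch. Spectral
estimation uses 30-s epochs, band averaging and sleep staging use 10-s
epochs, and a trailing partial epoch is discarded. An epoch is artifact when
the mean-removed amplitude reaches 0.2 mV on EEG or 1 mV on EMG (inclusive
comparison at the limit); artifact epochs are excluded from spectral
averages and from staging, and from the recording-wide normalizing means.

## Power spectral density and band powers

Each 30-s epoch yields a single Hamming-windowed periodogram of the
mean-removed signal — no Welch sub-segmentation, so the native resolution is
1/30 Hz. The density is renormalized per epoch so that the one-sided
integral over frequency equals the epoch's sample variance exactly
(Parseval); this makes the scale of every downstream band power independent
of the window's power correction. Spectra are truncated to 0–50 Hz; a 2-Hz
binned view (mean density per bin, reported at bin centers, with the 50-Hz
grid point folded into the top bin) exists for reporting and plotting, while
band powers always integrate the native-resolution density.

Bands are half-open `[low, high)` intervals — delta 0.5–4, theta 4–8, alpha
8–12, beta 12–30, gamma 30–50 Hz — so adjacent bands share an edge without
double counting and the five defaults tile [0.5, 50) exactly. The source
analysis is ambiguous between theta 4–8 and 5–9 Hz; the default follows the
band-figure convention (4–8) and the edges are configurable. Band
integration uses the rectangle rule on the periodogram grid, which makes the
partition property exact by construction.

## Epileptiform spikes and spike trains

A spike is a maximal contiguous run of samples with `|signal − mean| ≥
200 µV` ("absolute" read as rectified amplitude, catching both polarities
and making detection invariant to DC offset) whose duration lies in
[1, 200] ms. The run's signed extremum is the peak. Runs clipped by the
recording edge count if their observed duration already qualifies.

Trains chain greedily left to right on peak-to-peak intervals: a spike joins
the current chain iff its interval to the previous peak lies in
[0.05, 0.5] s, inclusive at both ends (with a 1-ns tolerance so that
inclusive boundaries survive floating-point subtraction of sample-grid
times); any interval outside the window closes the chain. A closed chain is
a train iff it has ≥ 3 spikes and spans ≥ 1 s from first to last peak —
"spiking time" is interpreted as this minimum span. Train start/end are peak
times, so the reported duration is the quantity the span rule tests. The
interval minimum gates train membership only; it is not a detector
refractory period.

## Sleep staging

Each clean 10-s epoch yields four dimensionless features: delta ratio
(epoch delta power / recording-mean delta power), theta:delta ratio
(within-epoch), EMG ratio (epoch EMG variance / recording mean), and mean
activity. The published scoring levels are dimensionless, so the
denominators — nowhere defined in the source — are taken as recording-wide
means over clean epochs (self-normalization). The consequence worth knowing:
a recording dominated by a single state is ill-posed (its epochs all sit at
ratio ≈ 1, which reads as slow-wave sleep); the anchors presuppose a mixed
recording, which 24-h+ telemetry always is.

Each feature contributes a piecewise-linear membership over the four stages,
saturating at the published anchors: delta votes SWS (0 at ratio ≤ 0.5, 1 at
≥ 1), theta:delta votes paradoxical (0 at ≤ 1.3, 1 at ≥ 3), EMG votes wake
(0 at ≤ 1, 1 at ≥ 2.4); activity votes active wake (1 above 0.1, else 0). In
each case the complementary mass splits equally among the stages the source
names jointly (e.g. the delta complement between wake and paradoxical). The
four evidence vectors average with equal weights. An undefined theta:delta
ratio (zero delta power) contributes a uniform vector and is logged.

Two overrides force Active Wake before the argmax: activity strictly above
0.1, or EMG ratio at or above 1.5 × the wake saturation anchor (3.6 by
default). Ties in the argmax resolve in the fixed order Wake > SWS >
Paradoxical > Active Wake. No temporal smoothing or minimum-bout rule is
applied; staging is epoch-local, so permuting epochs permutes the hypnogram.

## HD-MEA network bursts

Analysis begins at spike times (no spike sorting). A full-chip activity scan
rates each of 26,400 electrodes as count/30 s; the 1024 highest-rate
electrodes (ties at the cutoff broken by ascending id) form the network
assay. Pooled spike times are histogrammed at 10-ms bins on a grid padded by
4 kernel widths, then convolved with a unit-area Gaussian of sd 100 ms
(truncated at ±4σ and renormalized), giving a population rate whose integral
equals the pooled spike count to machine precision.

Bursts are local maxima of this rate above `mean + k·sd` of the series,
separated by ≥ 0.2 s. The source specifies Gaussian convolution but no
numeric parameters; the bin width, kernel sd, edge rule (rate falling below
10% of the peak or below threshold, whichever is crossed first), and the
50-spike participation floor are this package's defaults, all exposed in
configuration. The threshold multiplier defaults to **k = 5**: for a
homogeneous Poisson assay (1024 electrodes × 0.5 Hz × 300 s smoothed at
σ = 0.1 s) the expected number of upcrossings of mean + 3·sd is ≈ 3–4 per
recording (standard level-crossing theory for a smoothed Gaussian process),
so k = 3 would report spurious bursts on virtually every quiet culture,
while k = 5 yields ≈ 10⁻³ expected false peaks. The trade-off: because mean
and sd are computed over the whole series, recordings whose bursts occupy
more than roughly 10% of the time inflate the threshold and can mask
detection — dense-bursting cultures need a lower k or a robust
(median-based) location/scale, which the configuration allows. Overlapping
burst extents merge keeping the higher peak; spike and electrode counts are
tallied from raw events inside [start, end]. The inter-burst interval is
peak-to-peak, defined only with ≥ 2 bursts.

## Synthetic generators

The generators define the benchmark conditions; they are first-class, tested
code.

**Sleep recordings.** Per epoch, EEG = delta sinusoid (1.5 Hz) + theta
sinusoid (6.5 Hz) + broadband Gaussian noise; EMG is white noise at the
stage's muscle tone; activity sits at the stage's level with 0.01-unit
jitter truncated at zero. Phases are randomized per epoch from one seeded
generator (identical seeds ⇒ bit-identical output). The center frequencies
sit inside both candidate theta conventions. Default stage signatures (µV):

| stage        | delta | theta | broadband | EMG | activity |
|--------------|------:|------:|----------:|----:|---------:|
| SWS          |    90 |    20 |        15 |  15 |     0.00 |
| Paradoxical  |    20 |    90 |        15 |   5 |     0.00 |
| Wake         |    40 |    40 |        20 | 100 |     0.03 |
| Active wake  |    40 |    50 |        20 | 120 |     0.50 |

These were chosen by hand, before any recovery test was run, under two
constraints: no clean epoch may reach the 0.2 mV artifact limit (bounding
SWS delta at ~90 µV), and under self-normalization with a realistic stage
mix the four stages must land on the saturated side of their printed
anchors. Stage sequences come from an explicit list or a first-order Markov
chain whose default transitions give a sleep-heavy stationary mix (≈ 12%
active wake, 23% wake, 54% SWS, 11% paradoxical), matching how laboratory
mice distribute the day; wake-dominated mixes compress the EMG ratio toward
1 and erode the wake/SWS margin, which is a property of ratio
self-normalization, not of the generator.

**Spike plants.** Planted spikes are biphasic — a sharp half-sine main lobe
at the requested amplitude and width, followed by a slow undershoot at 10%
amplitude. The undershoot must stay sub-threshold even on a high-amplitude
slow-wave background: a symmetric biphasic wave at twice threshold would be
detected as two events ~5 ms apart, which the ≥ 50 ms interval minimum would
split into broken chains, whereas the real detector sees one event per
interictal spike. Default plants (5 spikes, 0.3-s ISI, 400 µV) satisfy every
train rule with margin; uniform placement uses a seeded jittered grid with
≥ 1 s clearance (> 2 × the maximum chaining interval) between trains.

**MEA rasters.** Per-electrode inhomogeneous Poisson processes: baseline
rate outside planted burst windows, baseline × multiplier (default 50)
inside. Ground truth is the window list.

**Cohorts.** The genotype power simulation gives each subject one short
recording (120 s, mixed stages at 0.6 × amplitude so the hottest subjects
clear the artifact screen), a lognormal between-subject amplitude scale
(sd 0.1 on the log scale, ≈ 20% CV on power), and a ×1.5 delta-power
multiplier for the affected group — Cohen's d ≈ 2 a priori, so an 8-vs-8
pooled t-test detects it in well over 80% of replicates.

What passing these benchmarks shows: the printed rules are implemented
exactly, and each pipeline inverts its own generator at realistic
signal-to-noise. What it does not show: robustness to real-world artifacts
(electrode pops, chewing EMG bleed-through, state transitions inside an
epoch, non-sinusoidal rhythms), since the generator models none of these.

## Statistics

Genotype contrasts use the two-tailed pooled Student's t-test (Welch by
flag); outliers are screened with the two-sided Grubbs test, critical value
`G = (n−1)/√n · √(t²/(n−2+t²))` with `t = t_{α/(2n), n−2}`, flagging at most
one point per invocation (iterative screening opt-in, off by default). At
α = 0.05 and n = 12 the empirical type-I rate over 10,000 seeded replicates
sits within [0.03, 0.07]. Repeated-measures ANOVA with post-hoc corrections
is out of scope; cross-age (DIV) trajectories are groupings of independent
recordings, not a time-series model.

## Problem sizes

Test and acceptance workloads use: 30-s/10-s epochs at 500 Hz; a 1-h quiet
recording with 40 planted trains; a 2-h sleep recording (720 epochs); 100
seeded 300-s network assays per planted-count condition {5, 10, 20} plus 100
homogeneous-Poisson assays; 10,000 Grubbs replicates at n = 12; and 100
8-vs-8 cohort simulations. These sizes give binomial/Monte-Carlo error well
inside every tolerance asserted.

## Known limitations

- EDF export (built-in writer) supports integer sampling rates and
  whole-second durations; reading mixed-rate EDFs through MNE returns all
  channels at the common (highest) rate.
- The burst threshold's global mean + k·sd statistic degrades on recordings
  that burst more than ~10% of the time (see above).
- Single-state recordings are ill-posed for ratio-based staging.
- The activity threshold (0.1) is meaningful only in the units the
  classifier consumes; the generator emits activity directly in those units.
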