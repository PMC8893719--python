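# Methods

`hierseq` reimplements, as tested and reusable code, an ECoG analysis of
hierarchical predictive auditory processing under the local-global oddball
paradigm: trial-sequence generation, ground-truthed synthetic multichannel
recordings, multitaper time-frequency analysis, cluster-based permutation
statistics, PARAFAC-derived per-trial component contributions, and the
within-/across-trial correlations between those contributions.  This note
documents the model, the parameters that matter, the numerical choices,
and what the synthetic-data experiments do and do not show.

## Paradigm model

A trial is a sequence of five 50-ms tones.  The ECoG protocol uses a
150 ms inter-tone interval (sequence duration 850 ms), 3 s sequence-onset
asynchrony, and 707/4000 Hz carriers; the fMRI-protocol variant uses
100 ms intervals (650 ms), 3.5 s asynchrony, and 800/6000 Hz.  Local
sequence types: `xx` (five identical tones), `xY` (deviant fifth tone),
`x_` (fifth tone omitted).  A run habituates one type (20 repetitions) and
then presents three 25-trial blocks with 80% standards and 20% deviants.
Deviant placement is drawn uniformly among admissible placements: no
deviant in the block-final slot and every deviant immediately followed by
a standard (no two consecutive deviants).  The sampler is rejection
sampling over uniform combinations, which is exactly uniform over the
admissible sets.  A dedicated omission-block run presents the four-tone
`xxxx` sequence only, providing *expected* omissions as the reference for
the omission contrasts.  Habituation trials are labelled and excluded from
all statistics.  Runs start at t = 0 with the first habituation sequence;
a leading rest (14 s in the fMRI protocol) is metadata only.

Deviants may occupy the first test-block position immediately after
habituation; nothing in the block rules forbids it.

## Synthetic recordings

The generator emulates the statistical structure the pipeline assumes, not
biophysics: no volume conduction, no evoked-potential waveforms, no
auditory-periphery model.  Channels carry independent 1/f^1.5 background
(spectrally shaped white noise, unit RMS; the exponent is configurable and
tested at 0 and 1 against a periodogram-regression oracle) plus an
optional 50 Hz line sinusoid (amplitude 0.1 by default).  The default
96-channel layout is partitioned into regions of interest — 12 auditory
core, 16 belt/parabelt, 8 STR, 24 frontal, 36 other — with counts
configurable (desk-scale experiments use a 16-channel version with counts
4/4/2/4/2).

Three condition-locked components are injected, each tied to a
ground-truth table (realized amplitude, envelope center, envelope start
per trial):

* **PE1** — gamma burst (60–110 Hz), envelope center 74 ms after the
  fifth-tone onset (jitter SD 10 ms), duration 100 ms, on any `xY`
  sequence, over auditory core + belt channels.
* **PE2** — gamma burst, center 242 ms, duration 120 ms, on global
  deviants (`xY|xx`, `xx|xY`), over belt + STR channels.
* **PRED** — long-lasting beta (12–30 Hz) power *decrease*: the ongoing
  beta-band background is multiplicatively suppressed (depth 0.7 ± 0.2,
  clipped to [0, 0.95]) under a Tukey plateau envelope starting 150 ms
  after the fifth tone and lasting 450 ms, over frontal + belt channels.
  Multiplicative suppression keeps power nonnegative, unlike negative
  addition.

Bursts are band-limited Gaussian-noise carriers under an amplitude
envelope; a pure sinusoid would ring in the TFR and bias latency
estimates.  The same carrier is shared across a component's target
channels, scaled by fixed per-channel gains drawn once from U(0.6, 1) —
this is what gives the rank-1 channel × frequency × time structure the
PARAFAC stage recovers.  Burst amplitudes are expressed in **power
units**: the enveloped carrier is energy-normalized and scaled by the
square root of the amplitude, so the realized burst energy tracks the
ground-truth value exactly and power-scale contributions are linear in
it.  Default gamma amplitude 0.0625 ± 0.04 power units (≈ 6× in-band
amplitude SNR at its peak, large trial-to-trial variability, and a
broadband peak contribution small enough that deviant trials do not trip
the amplitude-artifact rejection).  Realized amplitudes are clipped at
zero (a burst cannot have negative amplitude).

Envelope shapes: components anchored at their **center** (peak-latency
targets) use a Gaussian envelope with σ = duration/4.  Components
anchored at their **start** (onset-latency targets, e.g. the omission
response at 48 ms) use a Tukey plateau that is exactly zero before the
onset with a cosine attack over 30% of the duration — a Gaussian tail has
no defined start, and using its ±2σ point as "onset" biases onset
recovery early by tens of milliseconds.

Couplings: within a deviant trial, the PE2 amplitude follows PE1
(`pe1_to_pe2_gain`); the PRED depth on a deviant drives PE1/PE2 burst
amplitudes on the immediately following standard trial of the same block
(`pred_to_next_*_gain`), mirroring the deviant → post-deviant pairing used
by the correlation analysis.  A coupling target's amplitude is
`mean + gain·(source − source_mean) + N(0, noise_sd)`; with gain 1 and
noise 0 the amplitudes correlate perfectly.  Post-deviant standards
receive bursts only when a pred→next gain is nonzero, so latency-recovery
simulations (all gains 0) have clean standards.

## Preprocessing

Epoch −1 to +2 s around each first-tone onset (closed-open sample
windows); band-pass 1–240 Hz, zero-phase Butterworth of order 5;
polyphase resampling to 500 Hz preceded by an explicit zero-phase
anti-alias guard low-pass at 0.45·target rate (the resampler's own
transition band leaves percent-level leakage just above the new Nyquist);
zero-phase notch at 50 Hz.  All filtering is forward-backward so latency
estimates carry no filter delay.

Artifact screening replaces manual inspection with deterministic robust-z
rules: a channel is removed when its 70–240 Hz RMS exceeds the
median + 5·MAD across channels on more than 60% of trials; a trial is
removed when its peak amplitude or <2 Hz slow-wave power exceeds the
median + 8·MAD across trials.  Every removal is recorded with a reason
code.  Common-average re-referencing (over retained channels only),
linear detrend and demean follow; a run whose surviving deviant count
falls below 5 is excluded.  No ICA, no interpolation.

## Time-frequency analysis

Multitaper power on a fixed grid: 10–140 Hz in 1 Hz steps, −300 ms before
the first tone to +800 ms after the fifth-tone onset in 20 ms steps.  The
analysis window at frequency f is 4 cycles (4/f s) and the spectral
half-bandwidth is 0.5·f; together these fix `floor(2·T·W) − 1 = 3` DPSS
tapers at every frequency — the only reading under which the two
smoothing parameters cohere.  Power at a cell is the mean over tapers of
the squared tapered complex demodulate, scaled as one-sided spectral
density so that band-integrated power matches signal variance (tested to
10% on a band-limited probe).  Cells whose window would extend past the
epoch are missing (NaN), never extrapolated, and are excluded from all
statistics and projections.

Baseline correction is per trial (required downstream for per-trial
contributions): relative change against the −300–0 ms pre-first-tone
mean, with a dB option.

One intrinsic property of proportional-bandwidth smoothing deserves
mention: a pure tone's apparent spectral peak under density normalization
can sit up to half a bandwidth *below* its true frequency, because lower
frequencies use longer windows whose acceptance band still contains the
tone.  Baseline correction cancels this per frequency, and peak
localization in **time** is unbiased (tested to one grid step against an
independent multitaper implementation).

## Cluster-based permutation statistics

Per channel: a pooled-variance two-sample t statistic at every
(frequency, time) cell compares deviant against standard trials (an
unequal-variance option exists).  Cells with |t| above the two-sided
critical value at the cluster-forming alpha (0.05) form maximal
4-connected clusters of uniform sign; the cluster statistic is the signed
sum of t.  1000 label shuffles (500 in desk-scale experiments) build the
null as the maximum |mass| over clusters per shuffle — one null serves
both signs, since the analysis reports gamma increases and beta decreases
from a single procedure.  Cluster p = (1 + #{null ≥ |mass|})/(n_perm + 1),
so p is never zero.  Correction is over frequency × time within each
channel only; no cross-channel correction.  Zero-variance cells get t = 0;
missing cells propagate.

Consequence of per-channel correction: the nominal 5% family-wise rate
holds per channel-test, not per multi-channel recording (with 96
independent channels, some false channel is expected in nearly every
run).  The calibration experiment therefore reports the fraction of
channel-tests with any corrected p < 0.05, drawing Gaussian null datasets
directly at the tensor level (exchangeability of trial labels is the only
assumption the test makes).

Latency estimates per cluster: onset = earliest cluster time minus the
fifth-tone onset; peak = time of max |t| within the cluster.

## Components and contributions

Significant clusters are classified: PE1 = positive cluster with band
minimum ≥ 40 Hz peaking before 150 ms after the fifth tone; PE2 = same
but peaking at or after 150 ms (the split sits between the 74 ms and
242 ms peaks); PRED = negative cluster overlapping 12–30 Hz lasting at
least 300 ms.  Unmatched clusters are labelled OTHER and retained in the
report.  A component's mask is the union bounding box of its clusters'
cells, additionally clamped (on by default) to the component's defining
domain — the gamma band and pre/post-split times for PE1/PE2, the beta
band for PRED.  The clamp matters: when the early and late gamma bursts
merge into a single supra-threshold cluster, the raw bounding box hands
one component's cells to the other and the rank-1 pattern locks onto the
stronger burst.

The spatio-spectro-temporal pattern is a rank-1 PARAFAC of the 3-way
tensor (mask channels × frequencies × times) of the defining trial type's
baseline-corrected power, fitted by alternating least squares with 10
seeded random restarts (tolerance 1e-10, 200 iterations, best explained
variance kept; non-convergence returns the best iterate with a flag).
The tensor uses the trial **median**: single-trial relative power is a
heavy-tailed ratio statistic, and one extreme trial can otherwise dominate
the mean tensor and hence the pattern.  Loadings are unit-norm with the
frequency and time loadings constrained to nonnegative sums (sign flips
absorbed into the channel loading).  Rank is fixed at 1 — one
contribution value per component per trial; no nonnegativity constraints,
no core-consistency model selection.

A trial's contribution is the least-squares scalar fit of the fixed
pattern to that trial's masked TFR, ⟨X, a⊗b⊗c⟩ / ‖a⊗b⊗c‖², with missing
cells excluded from both inner products.  Contribution is linear in the
trial TFR and the fit is channel-permutation-equivariant (both are
property-tested).

## Correlations

Within a trial type, two components' contributions are compared by
Pearson correlation (two-sided p; pairwise deletion of missing values; p
undefined below n = 3).  Across trials, each deviant pairs with the
immediately following standard of the same block — under the paradigm's
placement rules every non-block-final deviant pairs.  Electrode-set
rules: a frontal prediction component is correlated with PE contributions
from all significant gamma electrodes; an auditory prediction component
only with auditory significant gamma electrodes (patterns are refitted on
the restricted channel sets).  No multiple-comparison correction across
the panel by default; a Benjamini–Hochberg option exists (validated
against statsmodels) but is off.

## Contrast orchestration

Condition labels encode sequence type and task, so a contrast is a pair
of condition selectors: `local_novelty` is the conjunction of
(xY|xx vs xx|xx) and (xY|xY vs xx|xY); `global_only` is xx|xY vs xY|xY;
`local_and_global` is xY|xx vs xx|xx; the omission contrasts compare rare
omissions with the expected omissions of the `xxxx` block and with each
other.  Conjunction is implemented as the intersection of per-channel
responsiveness with same-sign significant clusters across sub-contrasts —
an imaging-style conjunction transplanted to channel space, flagged as
such.  The full pipeline aligns channels across runs (intersection of
retained channel names), skips contrasts whose conditions are absent
(logged), derives PE1/PRED from the xx-task contrast and PE2 from the
global-only contrast, and emits a bundle (QC, cluster tables, component
report, contributions, correlation panel) with a provenance block
(package version, seed, config hash) sufficient to reproduce it
bit-for-bit.

## Desk-scale experiment sizes

The recovery and calibration experiments run the full pipeline at a
reduced problem size chosen for a single CPU: 16 channels, one 25-trial
test block per run (three blocks where per-trial statistics need more
trials), 2 Hz frequency spacing, 500 permutations, 20 simulated runs per
latency target.  The paradigm timing, component latencies, bands and
noise model are the full-scale study conditions; only array size, block
count and grid density are scaled.  Measured behavior at this scale:

* injected latencies (PE1 peak 74 ms, PE2 peak 242 ms, omission onset
  48 ms, zero jitter) are recovered by the cluster pipeline within the
  20 ms grid resolution on average;
* per-trial PARAFAC contributions of the gamma components correlate with
  ground-truth amplitudes at r ≈ 0.9;
* the beta suppression's per-trial contribution is intrinsically
  noise-limited (r ≈ 0.6–0.75 even with an oracle mask): the suppression
  multiplies ongoing beta whose own power fluctuates trial to trial, a
  limitation real single-trial beta estimates share;
* the cluster test's per-channel family-wise error sits at the nominal 5%
  under the global null, and the Pearson panel is calibrated at the
  nominal rate under independent contributions.

## What passing tests do and do not show

The generator realizes exactly the structure the analysis assumes:
independent 1/f channels, band-limited condition-locked components with
rank-1 spatial structure, Gaussian amplitude couplings.  Passing recovery
tests therefore demonstrate the pipeline's correctness and calibration,
not its performance on real recordings, where components are not rank-1,
backgrounds are correlated across electrodes and nonstationary, evoked
potentials leak into low gamma, and artifacts are not all robust-z
outliers.  Real-data activation maps are not reproducible at desk scale; the
reported component latencies serve here solely as injection/recovery
targets.
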