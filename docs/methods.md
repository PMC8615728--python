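# Methods

This note documents the models, estimators, and numerical choices behind
`meacomplex`, and what its synthetic-data tests do and do not demonstrate
about real recordings.

## Setting

The package analyzes recordings of dissociated cortical cultures grown on
planar micro-electrode arrays (8 × 8 grid minus corners: 60 analysis
slots, 59 physical electrodes, 200 µm pitch, 10 kHz acquisition).  Such
cultures spontaneously fall into a sleep-like regime: near-synchronous
network bursts recruiting most electrodes, separated by quiet periods, with
LFP power concentrated in the delta band.  Bath application of the
cholinergic agonist carbachol (CCh) mimics activating neuromodulation:
bursts fragment, firing becomes tonic and heterogeneous across electrodes,
and slow oscillations are suppressed — while the overall mean firing rate
stays roughly unchanged.  The pipeline quantifies this transition in
spontaneous activity (spectra, firing/burst statistics, synchrony, neural
complexity) and in responses to electrical stimulation (PSTH area, evoked
LFP spectra, perturbational complexity).

## Conventions

Time is in seconds from recording start; all bins are half-open
`[t, t + Δ)`, so any partition of an interval into bins conserves spike
counts.  Analog signals are in microvolts; raw traces at 10 kHz, LFPs at
1 kHz.  A 1e-9 epsilon is added before flooring bin indices so that a
spike exactly on a bin edge lands deterministically regardless of float
round-off; serialization carries microsecond precision.

## LFP analysis

Raw traces are band-passed 1–300 Hz with a zero-phase 4th-order
Butterworth filter and decimated ×10.  Zero-phase filtering was chosen
because the evoked analyses depend on latencies; a causal filter would
shift them.  Spectra use Welch's method (5 s windows, 50% overlap) and
band powers are trapezoidal integrals over half-open bands — delta 1–4,
theta 4–11, beta 11–30 Hz — so the shared 4 and 11 Hz edges are counted
once and disjoint bands add to the power of their union.  (An alternative
edge set, theta 5–9 / beta 10–30 Hz, circulates in figure material; it is
available as the `BANDS_FIGURE` preset, but the methods-text definition is
the default.)  Evoked spectra average the stimulus-locked response
(−100 ms to +900 ms) over trials on the 20 channels with the highest
basal spontaneous firing rate, then apply Welch with 200 ms windows up to
100 Hz.  The 10 ms after each pulse is linearly interpolated rather than
zero-filled: a hard step at the blanking edges would inject broadband
power into exactly the spectra being compared.

## Spike-level analysis

The spike detector thresholds the >300 Hz component at 7× the robust
noise SD (median(|x|)/0.6745) with a 1 ms dead time; a floor of one tenth
of the absolute maximum keeps near-noiseless traces from thresholding at
filter-ringing level.  Published work on these cultures used in-house
detectors whose parameters are not recoverable; the values here are the
common MEA defaults and are exposed as parameters.  Bursts use an
ISI-threshold detector (max intra-burst ISI 100 ms, min 5 spikes), for the
same reason.  Derived statistics: MFR (spikes/s per electrode), IBR (% of
spikes outside any burst), CV(MFR) (SD/mean over electrodes), and the
burstiness index BI = (f15 − 0.15)/0.85 where f15 is the fraction of all
spikes inside the fullest 15% of 1 s network bins — 0 for a uniform
network, 1 for a fully burst-dominated one.

Synchrony is measured twice, and regime contrasts are expected to agree in
sign between the measures.  The spike time tiling coefficient (STTC)
uses ±dt coincidence windows (default dt = 10 ms — half the neural-
complexity bin, a field-standard choice; the original description leaves
dt open) with tiling fractions clipped at the recording edges; pairs with
an empty train return NaN and are excluded from the network mean rather
than zero-filled, which would bias it downward.  SPIKE-synchronization is
the parameter-free multivariate coincidence rate with the adaptive window
τ = ½·min of the four inter-spike intervals surrounding a candidate
spike pair; edge spikes use the available ISIs only.

## Evoked spiking

PSTHs cover 400 ms post-stimulus in 4 ms bins, normalized to spikes/s by
trials × bin width; the area (spikes/trial) is conserved under rebinning
of the same window.  Channels with area < 1 spike/trial are excluded
(boundary inclusive).  The drug effect per channel is
ΔPA[%] = 100·(PA_drug − PA_basal)/PA_basal, classified three ways against
a stability threshold computed from a drug-free session split into two
5-minute halves (mean ± SD of the inter-half percentage change, pooled
over channels); without stability data the classification falls back to
the ±20% band established for this protocol.  The 10 ms artifact blanking
used for LFPs is applied to spiking by default as well — the description
of the protocol mandates it only for LFPs, but asymmetric treatment would
let residual artifact spikes masquerade as short-latency responses.

## Neural complexity

Per-electrode instantaneous firing rates (20 ms bins) are averaged within
random complementary bipartitions (n vs. the rest, n = 5…30 step 5, 100
bipartitions per n, drawn from a seeded generator); each averaged signal
is discretized into 6 levels and the mutual information between the two
sides is estimated with Panzeri–Treves bias correction.  NC is the sum
over n of the bipartition-averaged MI, computed per 5-minute segment.
Discretization uses equipopulated (quantile) levels by default — averaged
firing rates are heavy-tailed, and equally spaced levels would starve most
bins; equally spaced levels remain available.  Degenerate inputs
(constant signals, duplicate quantile edges) collapse to fewer levels and
yield MI = 0 in the fully constant case.  The bias term
(R̂_xy − R̂_x − R̂_y + 1)/(2N ln 2) uses the expected-occupancy estimate
of the number of relevant response bins.  Two analytic anchors: constant
activity gives NC = 0, and a network in which every electrode follows one
two-level signal with p = 0.5 gives MI = 1 bit at every partition size,
hence NC ≈ 6 bits.

## Perturbational complexity

Trials are spike counts in 5 ms bins from 1000 ms before to 500 ms after
each pulse (100 post-stimulus bins).  The activation threshold per channel
is the 95th percentile of 500 bootstrap maxima: each resample draws trials
with replacement, takes the trial-mean count per pre-stimulus bin, and
records the maximum across the 200 pre-stimulus bins.  Using the max
statistic controls the family-wise error across post-stimulus bins; a
channel silent throughout the pre-stimulus window borrows the pooled null
and is flagged.  The binary significant-source matrix SS(x, t) marks post
bins whose observed trial-mean exceeds the threshold; rows are sorted by
total activity (ties broken by row pattern, making the matrix invariant
to channel relabeling).  The sorted matrix is flattened time-major
(successive time columns concatenated — the convention of the source-level
perturbational-complexity literature; row-major is an option recorded in
every result) and parsed with the Lempel–Ziv 1976 exhaustive-history
procedure.  Then

    PCI = C · log2(L) / (L · Hsrc),   L = channels × bins,
    Hsrc = −p0·log2 p0 − p1·log2 p1,

with PCI = 0 when Hsrc = 0.  The base-2 form is used because it is the
only reading under which a maximally random matrix normalizes to ≈1 and
the entropy is in bits; the printed formula in circulation mixes natural
and base-2 logarithms, and a consistent natural-log variant is available
behind the `base` parameter.  On iid Bernoulli(0.5) 60 × 100 matrices the
implementation averages PCI ≈ 1.03, inside the asymptotic calibration
band.  The LFP variant applies the identical bootstrap/SS/LZ chain to the
per-bin mean absolute baseline-corrected amplitude, with the artifact bins
zeroed.

## Synthetic culture generator

The generator's presets define the study conditions for every downstream
test.  Network bursts are a doubly stochastic process: a mother Poisson
process of burst events (basal 0.2 events/s, CCh-like 0.02), thinned per
electrode by a recruitment probability (0.9 vs. 0.3), with Gaussian onset
jitter (SD 10 ms), log-normal duration jitter around 0.3 s, and
intra-burst Poisson firing at 80 spikes/s.  Tonic firing is log-normal
across electrodes — low variance around 0.5 spikes/s in basal, log-SD 0.8
in the CCh-like regime — and the CCh tonic mean is rescaled so both
presets share the same expected MFR (the reported contrast is not a rate
confound; empirically the rates match within ~15%).

The CCh-like preset additionally carries a shared slow multiplicative
rate modulation (log-SD 1.0, correlation time 0.15 s) applied to tonic
firing.  This is a deliberate modeling choice: fully independent tonic
trains would drive the partition-to-partition mutual information — and
hence NC — to zero, whereas desynchronized cultures retain population-rate
fluctuations; the shared modulation reproduces the empirically observed
pattern of fine-timescale desynchronization (lower STTC and
SPIKE-synchronization) coexisting with higher neural complexity.

The LFP proxy maps the population rate through a Gaussian kernel (total
width 0.3 s, negative-going, gain 10 µV per spike/s) plus per-channel 1/f
noise (2 µV), so burst-dominated input concentrates power in delta and
the desynchronized regime suppresses it.  Evoked sessions emit, per
responsive channel (40 of 60) and trial, an early stimulus-locked burst
(probability 0.8, 3 spikes, channel latency uniform in 5–50 ms, 2 ms
jitter) and a shared reverberant late burst (probability 0.3, 100–400 ms,
120 ms, 30 spikes/s, 50% participation) over 2 spikes/s background, 120
trials at 5 s intervals; the CCh-like regime multiplies both probabilities
by 0.5, shrinking response amplitude without changing its spatio-temporal
layout — which is exactly the regime in which PCI should move little while
NC moves a lot.

What the generator does *not* emulate: real electrode-to-electrode gain
differences, non-stationary drift, apparatus artifacts, spatially
structured (distance-dependent) correlations, and genuine causal network
interactions.  Passing regime-contrast tests therefore shows that the
pipeline recovers the programmed directions of effect at realistic rates
and trial counts — not that it would produce identical numbers on
biological recordings.

## Problem sizes and runtime choices

Direction-of-effect suites use 10 seeds of 600 s spontaneous recordings
(two 5-minute NC segments) and 120-trial stimulation sessions — the
protocol's own session sizes.  The bootstrap family-wise error simulation
uses 50 sessions of 15 channels; the acceptance script runs the full
study on 5 seeds.  These sizes keep a complete run in the minutes range
on one CPU while leaving every estimator at its default parameters.

## Known limitations

* The NC estimator's absolute value depends on the discretization scheme;
  only comparisons made with a fixed scheme are meaningful.
* The bootstrap null is conservative when the pre-stimulus window is
  longer than the post-stimulus window (max over 200 vs. 100 bins), so
  the realized false-positive rate sits below the nominal α.
* STTC is O(pairs × spikes log spikes); dense 60-channel hour-long
  recordings are feasible but not instantaneous.
* The statistics wrappers implement two-group comparisons with
  data-driven test selection; factorial designs should go directly to
  statsmodels.
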