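# Methods

`ticstate` analyzes the state dependence of motor tics and their striatal
neural correlates across a sleep-wake cycle, in the chronic
striatal-disinhibition model (continuous GABA_A blockade of motor striatum,
which produces ongoing motor tics).  Because no public recordings accompany
this kind of experiment, the package pairs the analysis chain with a
synthetic-session generator whose defaults encode the group-level quantities
the chain is expected to recover; correctness is established by parameter
recovery on those synthetic sessions plus property-based tests, not by
re-processing raw data.

## Signals and conventions

A session holds four modalities on a common clock (seconds from session
start; all state intervals half-open `[start, end)`):

* **gyro** — 3-axis head gyroscope (deg/s) at 1 kHz; tics are detected on
  the x axis only.
* **wideband / LFP** — striatal extracellular voltage (uV).  The LFP is the
  band below 100 Hz (here 1 kHz sampling, rendered directly or extracted
  from a 10 kHz wideband trace); the MUA band is above 300 Hz.
* **units** — sorted single-unit spike trains with a mean waveform.
* **states** — behavioral annotation: `quiet_waking`, `transition` (falling
  asleep), `sleep`, and `other` (movement / brief awakenings).  Events
  detected during `other` are reported but excluded from all state
  comparisons.

On disk a session is one HDF5 file (group per modality) with plain-text
sidecars: a BED-like TSV for state intervals and CSV tables for events.

## The generative model

Per session, in order:

1. **States.** One quiet-waking block (600 s), one transition block (240 s,
   split into drowsy micro-intervals that all carry the transition label),
   one sleep block (600 s) fragmented by brief awakenings (default two 10-s
   `other` segments carved out of sleep).
2. **LFP spikes** (the stereotyped field deflections that accompany tic
   generation) are a renewal process — exponential gaps plus a 0.5-s dead
   time, with the exponential rate chosen so the realized rate equals the
   target — at 68/min in quiet waking and transition, 60/min in sleep.
   Peak-to-peak amplitude is lognormal around the session mean (1054 uV in
   wake, 932 in sleep; per-event CV 0.24/0.26).
3. **Tics** arise in two ways.  Each LFP spike spawns a tic with
   state-dependent probability (0.90 quiet, 0.85 transition, 0 sleep), the
   tic onset lagging the LFP onset by 72 ms.  A small residual process adds
   tics with no detectable field correlate, at the rate needed to bring the
   total to the configured tic rate (65/62/3 per minute); these are placed
   away from existing tics (one refractory) *and* away from LFP-spike
   co-occurrence windows, which is what "no detectable correlate" means
   operationally.  Sleep tics are zero-inflated across sessions: a session
   expresses them with probability 7/18, at a lognormal rate with mean
   3/(7/18) per minute, reproducing both the group mean (3/min) and the
   across-session skew.
4. **Tic amplitude** is lognormal (positivity plus direct CV control) with
   state means 119 deg/s (quiet) and 5 deg/s (sleep) and per-event CV 0.45
   (0.49 in sleep).  Through the transition block the mean decays
   exponentially from the quiet toward the sleep value with time constant
   one third of the block duration; the decay is what drives the transition
   amplitude CV to ~0.85 without any extra parameter.
5. **Session-level jitter.**  Rates get a lognormal session factor (CV 0.29
   wake, 0.35 sleep, drawn independently per state); amplitudes get a
   *shared* lognormal gain (ln-SD 0.48) times signal-specific gains (tic
   0.26, LFP 0.15), all mean-1.  The shared gain reproduces the
   across-session SDs (≈73 deg/s, ≈548 uV) and couples session-mean tic and
   LFP magnitudes (across-session r² ≈ 0.7) while leaving per-event
   magnitudes uncorrelated within a session, matching the observation that
   the magnitude relation is an across-session phenomenon.
6. **Rendering.**  The tic kernel is a one-cycle damped-sinusoid shape
   (350 ms; positive lobe peaking 75 ms after onset, shallower negative
   lobe), the LFP kernel a biphasic sharp-negative (trough at 75 ms) / slow-
   positive deflection (540 ms) whose positive lobe rises fast and decays
   long, keeping its local maximum well inside the refractory distance of
   the trough.  Both are normalized to unit peak-to-peak *on the rendering
   grid*, so with zero noise the measured p2p equals the configured
   amplitude to float precision.  Gyro noise is white (SD 0.15 deg/s); LFP
   noise is pink, confined below 100 Hz (SD 25 uV).  The optional wideband
   trace adds >300 Hz noise (SD 5 uV) amplitude-modulated by
   `1 + gain(state) * burst(t)` where `burst` is a lognormal-shaped bump
   time-locked to each LFP onset; gains (4.6 wake / 1.25 sleep) put the
   envelope burst amplitude near the reported ~29 vs ~8 uV.
7. **Units.**  Inhomogeneous Poisson trains: a piecewise-constant baseline
   plus a narrow Gaussian burst kernel (SD 20 ms, peak 46 ms after each LFP
   onset) scaled by a per-unit, per-state locking magnitude (SPN 30 / FSI
   52.6 spikes/s in wake, reduced in sleep, with a per-unit lognormal spread
   CV 0.6).  The configured per-state rates (SPN 2.25, FSI 13.12 wake /
   7.72 sleep spikes/s, median across units) are *total* rates: the
   baseline is the configured rate minus the expected locked contribution,
   floored at 5% of the total.  In sleep a unit loses its locking entirely
   with probability 0.39 (SPN) / 0.48 (FSI), or shifts to a later-peaking
   kernel ("different pattern") with probability 0.3.  Because the rate is
   a sum of nonnegative components the train is simulated exactly by
   superposition (baseline process + per-event kernel-distributed spikes);
   no thinning and no rate clipping.

Determinism: a study derives one child seed per session from a root
`SeedSequence`; identical (config, seed) reproduce sessions bit for bit.

## Detection

Both detectors share one mechanism: robust center/scale (median and
1.4826·MAD), then the local maxima of `|x - median|` above `k` robust SDs
with a minimum peak separation of 0.45 s (`find_peaks` with a height and a
distance).  The separation collapses the lobes of one multiphasic deflection
onto its dominant extremum while keeping distinct events apart, and is
robust to noise excursions between events that would chain gap-based run
merging.  Onset is found by backtracking from the extremum to the last
sample within max(0.5 robust SD, 1% of the peak deviation) of baseline.
Peak-to-peak amplitude is always measured on the **raw** trace inside the
snippet window, so the detection filter never biases the intensity measure.

* Tics: detection on the 100-Hz low-passed gyro x axis (a high-pass leg is
  available for drifting recordings but off by default — its rebound tail
  after large tics reads as spurious events); baseline statistics from
  quiet-waking + sleep samples only, so movement segments cannot inflate
  the threshold; k = 5.
* LFP spikes: detection on the LFP trace directly, k = 4.5.  Both k values
  were calibrated on the generator's noise model against the two
  requirements that noiseless recall be total and the false-positive rate
  on event-free noise stay below 1/min (at k = 4 the level-crossing rate of
  band-limited noise at 1 kHz already exceeds that bound).
* A relative threshold floor (0.1% of the maximum deviation) only binds for
  near-noiseless inputs, where zero-phase filter ringing would otherwise
  count as micro-events.

With the default scenario the chain recovers injected events essentially
one for one (recall and precision both >99% in wake); onset times are
biased late by ~5–8 ms because the kernels leave baseline smoothly, so the
documented timing tolerances are ±5 ms for peaks and ±10 ms (median) for
onsets.

## Coupling metrics

* **Co-occurrence**: among LFP spikes of one state, the fraction with a tic
  onset inside `[onset, onset + 0.5 s]`, greedily matched one-to-one in
  time order.  The 500-ms window covers the observed ~147 ms tic lag with
  margin.
* **Duration / latency** are measured on the session-mean aligned trace.
  Latency is the time from onset to the global absolute extremum of the
  baseline-subtracted mean.  Duration is the length of the super-threshold
  run (|trace − baseline mean| > 2 baseline SD) containing the extremum,
  with two practical guards: runs shorter than 20 ms are treated as noise,
  and sub-threshold gaps up to 50 ms are bridged so the zero crossing of a
  biphasic deflection does not split the run; the threshold never drops
  below 5% of the peak deviation (a near-noiseless baseline would otherwise
  make the entire trace count).  The baseline window is −250…−50 ms
  relative to onset: at ~1 event/s the renewal train leaves systematic
  structure further out, which would inflate the baseline SD.  On smoothly
  tapering kernels the 2-SD criterion under-reads the nominal kernel
  support (measured ≈0.39 s for the 0.54-s LFP kernel, ≈0.28 s for the
  0.35-s tic kernel); the orderings — LFP longer than gyro, MUA before LFP
  before gyro — are preserved, which is what the state comparisons use.
* **Magnitude correlations**: Pearson r per session on greedily matched
  (LFP p2p, tic p2p) pairs; across sessions, OLS of session-mean tic
  amplitude on session-mean LFP magnitude, reported as r².

## MUA and single units

The MUA envelope is zero-phase high-pass (300 Hz) → analytic-signal
magnitude → zero-phase low-pass (50 Hz, a choice; the envelope must just be
slow relative to the burst), clipped at zero.  PLTHs use 1-ms bins smoothed
with a Gaussian of SD 10 ms (truncated at 4 SD, mass-preserving).  The
envelope SNR is reported in two forms: `snr_delta` (peak minus the mean of
the 150–200 ms pre-onset baseline, in uV — the form the reported values
carry) and `snr_ratio` (delta over the baseline-bin SD).  The ratio's
denominator is an estimation noise that depends on event count and residual
peri-event structure, so state comparisons in this package use the delta;
the ratio is kept as a secondary readout.  The SNR baseline is referenced
to the LFP-spike onset (the aligning event), resolving an ambiguity in how
the baseline is described relative to "the tic".

Unit classification: FSI if trough-to-peak width < 0.4 ms and rate
> 5 spikes/s; SPN if width ≥ 0.55 ms and rate < 5 spikes/s; else
unclassified (common striatal practice; thresholds in config).  Firing CV
uses ISIs within state intervals only.  Response significance requires the
smoothed PLTH to stay 2 baseline SDs above or below the 500–1000 ms
pre-onset baseline for ≥ 50 ms of consecutive bins within 0–500 ms
post-onset; the 50-ms run requirement is calibrated by Monte-Carlo so that
an unlocked Poisson unit is called significant ≤ 5% of the time (smoothed
noise excursions above 2 SD last ~15 ms on average, so a 10-ms requirement
would pass 30–40% of null units).  When both directions qualify, the larger
deviation wins.  A zero baseline SD falls back to the Poisson counting SD
of the smoothed estimate.  Magnitude is max post-onset PLTH minus baseline
mean.  Wake→sleep change classes: `lost` if the sleep response is not
significant; ratio < 0.8 → reduced (same vs different pattern by Pearson
correlation ≥ 0.5 between unit-norm baseline-subtracted response vectors);
ratio > 1.2 → increased; else unchanged.  The ratio and correlation
thresholds are conventions, exposed in config.

## Group statistics

Wake-vs-sleep comparisons across sessions use a paired t test (closed form;
p via the regularized incomplete beta) and the Wilcoxon signed rank test
(exact null distribution by dynamic programming for n ≤ 25 without ties,
normal approximation with tie and continuity corrections otherwise; zero
differences dropped).  Both are implemented from first principles so the
analysis chain has no hidden statistical dependencies; `scipy.stats`
versions serve as independent cross-checks in the test suite, and both
tests hold their nominal type-I error within [3%, 7%] at α = 0.05 in null
simulations.  No multiple-testing correction is applied (a deliberate
choice, recorded in the report provenance).  For the tic-intensity
comparison, a session with sleep time but no detected sleep tics enters as
zero intensity rather than missing.

## What the synthetic data does and does not establish

The generator reproduces the *statistical* structure the analysis assumes:
state-blocked rates and amplitudes, stereotyped kernels, probabilistic
pairing with a fixed lag, entrainment that collapses in sleep, session-level
heterogeneity.  It deliberately omits biophysics (no membrane or volume-
conduction model), real waveform variability (kernels are exactly
stereotyped, so shape-stability correlations sit near 1 rather than ~0.86),
behavior other than an `other` noise label, electrode-to-electrode
correlation structure, and REM/non-REM staging (not recoverable in this
preparation).  Passing tests therefore demonstrate that the chain recovers
known parameters under realistic noise and overlap — not that it would be
robust to artifacts absent from the model (chewing noise, electrode drift,
sorting errors).

## Problem sizes and runtime

The default study is 18 sessions of 10 min quiet + 4 min transition +
10 min sleep at 1 kHz (gyro and LFP), with the wideband/MUA path exercised
on shorter sessions and the unit population (2 SPN + 3 FSI per session,
~90 units over the study; 32 SPNs for the population-locking analysis)
simulated as point processes.  These sizes keep a full run in tens of
seconds while leaving every per-state estimate hundreds of events deep.

## Known limitations

* Detected onsets are systematically late by a few ms (smooth kernel feet);
  latencies inherit that bias.
* The group means of amplitude quantities are intrinsically noisy: with the
  across-session spread set to the reported SDs (CV ≈ 0.5–0.6), the
  18-session mean has a sampling SD of ~12–14% of its value, and the
  heavy-tailed session gains make a 2-SE interval cover the true mean in
  ~92% rather than 95% of studies.
* The duration metric under-reads smooth kernels (above); absolute
  durations should be compared only within this package's conventions.
* `snr_ratio` is not comparable across event counts; use `snr_delta` for
  state comparisons.
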