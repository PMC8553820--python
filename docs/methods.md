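# Methods

`ripplelearn` asks whether 256-ms windows of hippocampal CA1 LFP centered on
sharp-wave ripples (SWRs) carry enough learning-related structure for a 1-D
convolutional network to tell "before a learning session" from "after".  The
original recordings behind this question are not publicly deposited, so the
package ships a synthetic slow-wave-sleep (SWS) LFP generator that plants
ground-truth ripples with controllable condition contrasts, and every
downstream stage — detection, windowing, pooling, training, statistics — is
validated against that ground truth.

## Synthetic SWS LFP

A recording is background plus planted events:

* **Background** — pink (1/f) noise of unit SD plus a coherent 1-Hz slow
  oscillation (amplitude 3 in the same units): the minimal spectrum that
  exercises the ripple-band filter chain the way SWS LFP does.
* **Ripples** — Gaussian-windowed sinusoids, sigma = duration/4, carrier
  drawn from a truncated Gaussian inside (100, 250) Hz.  Condition
  "before" uses mean 140 Hz, "after" 150 Hz (the post-learning shift; the
  10-Hz default is a free parameter, as the source recordings' means are
  unpublished), SD 5 Hz.  Durations are truncated Gaussian 64 +/- 10 ms in
  (20, 100) ms, so a planted ripple occupies ~25% of its 256-ms window.
  (The detector's 2-SD crossings clip the Gaussian tails to ~0.65x the
  nominal duration, so *measured* bout extents average ~42 ms / ~16% of
  the window; a flatter template that measures longer would smear the
  envelope peak the window is anchored on.)  Event
  times are Poisson (0.5 events/s of SWS by default) thinned to a 278-ms
  spacing floor (one window plus two 10-ms guards), which guarantees every
  planted event can yield an admissible window.
* **Amplitude calibration** — the threshold detector works in envelope
  z-units, so each burst is iteratively rescaled until its ripple-band
  envelope peak, z-scored exactly the way the detector will z-score it,
  hits a target drawn uniformly from 6–9 (tolerance 0.4 z).
* **Session-gain normalization** — each finished recording is divided by
  its own SWS ripple-band envelope baseline SD.  Real pipelines absorb
  per-session amplifier gain the same way; without this step the
  recording's random composite amplitude scale acts as a recording-identity
  fingerprint, and because each animal contributes exactly one "before" and
  one "after" recording, that fingerprint perfectly confounds condition and
  lifts null-cohort classification above chance.
* **Peri-event signature** (optional) — a monophasic low-frequency
  deflection (Gaussian, sigma 10 ms) centered 20 ms before onset and 20 ms
  after offset, with condition-dependent amplitude (defaults 1 vs 2).  This
  emulates learning-related activity in the close vicinity of the ripple
  and gives the head/tail-masking experiments something to ablate.

Cohort modes: `WT_like` keeps the configured contrasts; `AD_like` equalizes
the condition frequency means, halves the ripple rate, and disables the
condition-dependent signature, so it is a strict no-class-information null.

What the generator does **not** emulate: spiking, multi-channel volume
conduction, REM/wake epochs, non-stationary sleep depth, electrode drift,
ripple-frequency/duration/amplitude correlations, and whatever real
"unknown features" distinguish pre/post-learning windows beyond the two
planted contrasts.  Passing tests therefore show that the pipeline recovers
the contrasts it is told to plant — they say nothing about which features
real recordings contain.

## Ripple detection

The chain is standard: optional polyphase decimation to 2 kHz; zero-phase
(forward–backward) band-pass; Hilbert-envelope; z-scoring against the
concatenated SWS baseline of the same recording; bouts = maximal runs with
envelope > 2 z that reach >= 5 z, onset/offset at the 2-z crossings; bouts
closer than 20 ms merged (merging first), bouts longer than 100 ms
discarded; peak time = envelope argmax (earliest on ties).

Numerical choices worth knowing:

* The band-pass is Chebyshev II, order 4, 40 dB stopband.  Chebyshev-II
  designs are specified by *stopband* edges; placing those at the nominal
  100/250 Hz band edges would shrink the usable passband to roughly
  130–210 Hz (forward–backward gain 0.15 at 120 Hz) and bias burst spectra
  toward the band center.  The stopband edges therefore sit a transition
  factor (default 1.5) outside the nominal band.
* **Intrinsic frequency** is the mean instantaneous frequency over the
  bout, computed as the angle of the summed lag-one autocorrelation of the
  analytic signal.  In-band background pulls any phase-derivative average
  toward the band's spectral centroid (measured +4 to +7 Hz for 120-Hz
  bursts at realistic SNR), so the baseline lag-one autocorrelation,
  estimated from the bout's padded flanks, is subtracted first; this
  cancels the pull to first order and leaves < 2 Hz bias at 120/150/200 Hz.
  On clean bursts, and for the mean of a linear chirp, the estimator agrees
  with the plain phase-derivative mean.  Results are clipped to (100, 250).
* z-scoring uses the SWS-only baseline (detection operates on SWS data);
  whether the original analysis used whole-recording or SWS-only baselines
  is unknowable from the text, and the choice is configurable.

A caution surfaced by property testing: the full merge-then-discard chain
is *not* monotone in the peak threshold (a lower threshold can merge
candidates into a bout long enough to be discarded), so monotonicity is
only asserted on well-separated bouts.

## Windows, pools, equalization, masks

An RCI (ripple-centered interval) is the 512-sample window centered on the
detected envelope peak.  Admission is greedy in temporal order: the window
must sit inside one SWS interval, contain no other detected ripple, keep
10 ms clear of every neighboring ripple's bounds, and not overlap an
already-accepted window.

Pools follow the cross-validation protocol: a fixed test pool (default
2000 windows per condition; 200 at the desk-scale profile) drawn once
across animals, and per-session training pools (200 windows per animal per
condition; 50 at desk scale) drawn fresh each session from windows outside
the test pool — sessions may reuse training windows, but never test ones.

Frequency equalization bins intrinsic frequency at 2 Hz and subsamples the
larger condition in every co-occupied bin to the smaller one's count,
dropping single-condition bins, so the pre/post frequency histograms of the
training pool match bin by bin.

Masking zeroes either everything outside the ripple bounds (`swr_only`,
the head/tail-elimination experiment) or everything inside
(`surround_only`, the ripple-removal control).  Windows are z-scored by the
training pool's global mean/SD *before* masking, so masked samples are
exactly zero — genuinely information-free — regardless of pool statistics.

## CNN and training

The network is written in numpy with analytic backprop (verified against
finite differences to < 1e-4 relative error).  The full architecture is 8
blocks of (conv, conv, maxpool-2) — 16 convolutional layers, 8 pooling
operations — followed by 2 ReLU fully connected layers and a softmax
output; with "same"-padded kernels of width 3 the 512-sample input
collapses to spatial length 2 before flattening.  Channel plan
8,8,16,16,32,32,64,64 and hidden widths 64/32 are the smallest plan
respecting the layer counts; kernel width, channels, learning rate and
initialization are otherwise free choices, exposed in the configuration.
Weights use He-style seeded initialization; biases start at zero.

Training is plain mini-batch gradient descent, w <- w - alpha * grad L,
alpha = 0.01, batch size 40 (the last partial batch is dropped), loss =
batch-mean cross-entropy -(1/40) sum log<y, y~> with a 1e-12 floor inside
the log; the pool is reshuffled into batches every epoch; 900 epochs at
full scale.  Prediction is the softmax argmax, ties resolved to "before".

A desk-scale profile (4 blocks / 8 conv layers, hidden widths 32/16, 100
epochs, float32 arithmetic) exists for the package's own studies; the full
profile remains available behind the `profile` switch.

## Experiments and statistics

One experiment = n_sessions independent sessions (10 at paper scale, 3 at
desk scale), each training a freshly initialized network on a freshly drawn
training pool and testing on the same fixed pool.  Reductions of the
per-window, per-session correctness matrix:

* **AR** (accuracy rate): percent of sessions a window is classified
  correctly; summarized per animal and per group.
* **HR fraction**: percent of windows correct in >= 8 of 10 sessions.
* **Recognition distribution**: percent of windows per correct-count 0..10.
* **Frequency–AR regressions**: ordinary least squares of AR (%) on
  intrinsic frequency (Hz), per animal and pooled, per condition; R^2 is
  the squared Pearson correlation.
* **Group comparisons**: equal-variance two-sample t-tests on per-animal
  means, Bonferroni-corrected over an explicitly passed family size (the
  original family sizes are not recoverable, so the family is a parameter).

Seeds: every stage derives its own integer stream from the master seed via
labeled `SeedSequence` folding, so a full pipeline run is bit-reproducible.

## Desk-scale study conditions

The package's own validation studies (tests and `scripts/acceptance.py`)
use: 6 animals per cohort, 300 s of SWS per recording (600 s for AD-like
cohorts, whose ripple rate is halved), a 200-window-per-condition test
pool, 50 training windows per animal per condition, the scaled CNN at 100
epochs, 3 sessions per experiment (10 for the null-distribution study),
and 3 replicate cohorts where a majority vote is reported.  These sizes
were fixed once as the smallest configuration at which the qualitative
contrasts are stable.

Measured behavior at these conditions: the AD-like null sits at a group
mean AR of 50 +/- 3% with a unimodal recognition distribution peaking at
4–6 correct sessions.  Its HR fraction lies between the independent-coin
binomial tail, P[Bin(10, 0.5) >= 8] = 5.47%, and roughly twice that:
sessions share one fixed test pool and overlapping training sources, so
per-window correctness is positively correlated across sessions and the
count distribution is overdispersed relative to the binomial — the
independent-coin value is a lower reference, not the expected value.  The
WT-like cohort trains to a mean AR in the high 50s–70s with pooled
frequency–AR slopes negative "before" and positive "after"; equalizing the
training-pool frequency histograms flattens both slopes by more than half
while the planted peri-event signature keeps AR above chance; and zeroing
the ripple (keeping only surround) returns AR to chance when frequency is
the only planted contrast.

## Known limitations

* Conclusions transfer to real recordings only insofar as the planted
  contrasts resemble the real ones; the generator's null is cleaner than
  any real null (no behavioral state drift, no electrode artifacts).
* The intrinsic-frequency estimator's noise correction assumes the bout's
  flanks are event-free background; overlapping events violate this but
  are largely excluded upstream by the merge rule and spacing floor.
* Vanilla gradient descent at a fixed learning rate is deliberately
  primitive (it is the training rule under study); it under-trains badly
  if the learning rate is lowered without raising the epoch count.
* At desk scale, per-session test accuracy carries binomial noise of a few
  percent (400-window test pool), so replicate studies vote by majority
  rather than asserting each replicate individually.
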