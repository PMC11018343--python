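# Methods

This note documents the models, conventions and numerical choices behind
`ripplecheck`, what the synthetic generators do and do not emulate, and
the known limitations of the pipeline.

## Conventions

Times are seconds from session start; sample indices are 0-based; event
intervals are half-open `[start, end)`; voltages are microvolts; maze
arms are numbered 1-based on their ring (arm 1 adjacent to arm 8 on the
eight-arm maze, positions 1–12 on the twelve-position maze). Every
"bandwidth" of a Gaussian kernel in this package is its standard
deviation (15 ms for the ripple envelope, 50 trials for learning
curves). All random draws go through `numpy.random.default_rng` seeded
from an explicit parameter; fixed seed implies bit-identical output.

## Online detector

The causal detector mirrors a real-time implementation: per channel a
forward-only Chebyshev type-II band-pass (order 20, 135–255 Hz, 40 dB
stopband — the attenuation is a free choice, 40 dB being a common
default), a trailing-window RMS (default 8 ms, roughly one ripple cycle;
short enough not to dominate latency), summed over hippocampal channels
into the ripple power RP. The adaptive threshold is
`RP − μ(t) > f·mad(t)` with exponential moving averages of span 7 s
(`α = 2/(N+1)`, `N = span·fs`). Statistics are initialized from the
first sample and detections are disabled during a 2 s warm-up while the
averages burn in. After each detection the averages are frozen for
50 ms; the same window also acts as a detection refractory — freezing
alone would re-trigger on the next sample of a suprathreshold event, so
suppressing re-detection is what actually makes one event yield one raw
detection.

The cortical channel runs the identical detector (same `f`; configurable
separately). A hippocampal detection is flagged vetoed when a cortical
detection falls within [−40, +1.5] ms of it; the 1.5 ms lookahead is a
deliberate, declared deviation from strict causality (a real
implementation defers the decision by 1.5 ms). The causality contract —
the log up to time t depends only on samples up to t (+1.5 ms) — is
verified by a truncation-equivalence test.

Scheduling: disruption stimulates 1 ms after detection (a fixed
round-trip latency stand-in) and discards detections within 150 ms of
the previous non-discarded detection; the stimulated control draws a
uniform 150–250 ms delay per detection and discards detections whose
stimulation would land within 150 ms of the previously scheduled one.
Per-detection delays are derived deterministically from
`(seed, detection sample)` so that modifying the signal *after* a
detection never changes that detection's delay — this is what lets the
closed-loop simulation converge by fixing one stimulation at a time.

## Closed loop

`closed_loop_session` generates the base signal open-loop, then
alternates detection and stimulation: each accepted stimulation adds a
biphasic artifact (0.2 ms per phase, ±1000 µV default) on the
hippocampal channels, multiplies the following 50 ms by a suppression
floor (default 0.05) with a 20 ms raised-cosine recovery, and — because
electrical stimulation terminates the ongoing ripple rather than pausing
it — removes the remainder of the generated burst that contains the
stimulation time. Since a stimulation only alters samples after itself
and the detector is causal and deterministic, re-running the detector
after each applied stimulation reproduces the detection prefix exactly;
the loop applies scheduled stimulations earliest-first until none remain
(at most duration/lockout iterations). The suppression depth and
recovery are free synthetic parameters, not empirical claims.

The artifact is **not** inserted on the cortical channel. A shared
artifact would let a stimulation triggered by a detection retroactively
veto that same detection through the +1.5 ms lookahead — a causal
paradox that a real system, where the veto is post-hoc labeling, does
not have. The cost is that the simulation never exercises
stimulus-artifact vetoes; the veto path is exercised instead by
injecting synchronous cortical bursts.

## Offline detector

Artifact removal replaces a 10 ms window around each stimulation (and,
for fairness, around the detection time in both stimulated conditions
when computing disruption efficacy) with a least-squares cubic fitted to
~2 ms of flanking samples per side; overlapping windows merge into one
span. A plain 4-point cubic through two tight anchor pairs amplifies
noise into large overshoots, which is why the fit uses wider flanks.

The envelope is `|hilbert(bandpass(x))|` per channel (zero-phase
4th-order Butterworth, 140–225 Hz, applied forward–backward), averaged
over channels, then Gaussian-smoothed (σ = 15 ms). The multi-unit
variant uses 300–2000 Hz; at 4 kHz sampling the upper edge sits at
Nyquist, so the filter degrades gracefully to a high-pass at 300 Hz.

Detection thresholds are robust and data-derived (median and upper
quartile of the envelope over the whole analyzed epoch for the event
threshold, of the −100..−70 ms pre-event window for the per-event
boundary threshold), which makes the detector exactly invariant to a
constant gain. If the pre-event window overlaps a previous event it is
used as-is; if it falls before the epoch start, epoch statistics are
substituted. Boundary extension walks outward from the suprathreshold
candidate to the contiguous region above the boundary threshold; events
separated by <20 ms merge; events shorter than 40 ms are dropped.

**Known limitation — boundary placement.** The boundary threshold
`med_w + 0.4·(Q3_w − med_w)` sits near the 61st percentile of the
envelope noise floor: for any unimodal envelope distribution the
0.4-upper-IQR offset is exceeded by noise ~39% of the time, *independent
of SNR and of the smoothing width*. Event edges therefore extend through
noise excursions well past the underlying burst: against the synthetic
ground truth (interval at 10% of the true peak envelope) the median
boundary error is ~50 ms, and measured event durations are inflated
accordingly (most events classify as "long" under a 100 ms split, and
detection delays measured from the offline start are ~40 ms larger than
delays measured from the true burst start). Recovery (≥90–100%), the
40 ms minimum-duration and 20 ms merge rules, and peak amplitudes are
unaffected. This is a property of the boundary rule itself, not of its
implementation; we keep the rule faithful and report the boundary error
rather than redefining the ground truth to hide it.

The 15 ms envelope smoothing also attenuates the measured peak of short
bursts (a Gaussian envelope of scale σ_env smoothed by σ_s scales by
`σ_env/√(σ_env²+σ_s²)`), so mean measured peak amplitude sits ~25–30%
below the generator's drawn peak for the default duration mix.

## Synthetic LFP

Background noise is FFT-shaped Gaussian noise with a 1/f^α spectrum
(α = 1 default, flattened below 1 Hz), scaled to 20 µV RMS — chosen for
controllable SNR rather than biophysical realism. Ripple bursts are a
uniform-random carrier (150–220 Hz) under a Gaussian envelope whose
10%-of-peak extent equals the drawn duration (40–150 ms; 26% drawn
above 100 ms), peak amplitude uniform in 110–210 µV (mean 160 µV),
shared across hippocampal channels over independent noise; the cortical
channel is independent noise. Burst times follow a state-dependent
Poisson process (defaults 0.5 Hz reward/immobile, 0.1 Hz center,
0.02 Hz running) with a 250 ms minimum gap; the gap rejection is
compensated as a non-paralyzable dead time so the requested rate equals
the realized rate. What this emulates: the rate, duration, amplitude and
state statistics the analyses consume, with unambiguous ground truth.
What it does not: spike content, sharp-wave polarity, theta/gamma
background, electrode drift, EMG artifacts or amplitude–duration
correlations — so green tests validate the *pipeline*, not detector
performance on real tissue.

## Behavioral agents and metrics

*NMTS* (15 trials): four random instructed arms per trial; at test the
agent recalls instruction j with probability (0.75, 0.85, 0.93, 0.98)
for j = 1..4 (1 = earliest) and visits a random permutation of the arms
it believes unvisited, stopping at the first error. This yields ~0.67
trial performance and a mean error order number ~1.7 — errors biased to
the arms instructed furthest back, as observed in rats. The error order
number convention is 1 = first-instructed.

*MTS* (25 trials): a 4-arm bait set excluding all-adjacent
configurations; per-trial correct-choice probability
`p(t) = a − (a − p₀)e^(−λt)` with a = 0.93, λ = 0.45, p₀ = 0.40, chosen
so the emergent learning trial (~9), final-10 visits (~4.2) and final-10
performance (~0.8) sit in the empirically reported ranges. A correct
choice follows a fixed per-session collection order with probability
0.75 (else any remaining bait), putting the stereotypy index near 0.6
while keeping its shuffle z-score far above chance. A correct *trial*
collects all four baits in exactly four visits (any unbaited entry or
re-entry is an error).

*SEQ*: four positions on the 12-ring with a random crossing (non-
circular) cyclic order; each visit's success probability steps from 0.5
to 0.9 (default) at that transition's onset visit (default 150); 220
visits per run epoch. The step-change experiments use 0.95 as the
learned level by construction.

Metric choices where the method left room: the stereotypy and
circularity nulls permute the visit order within each trial (2000
shuffles); `z = (obs − null mean)/null sd`. The circular-search score —
the direction-maximal fraction of transitions that step to the nearest
remaining arm clockwise or counterclockwise — is this package's own
construction and is labelled as such. Kernel learning curves truncate
the Gaussian at sequence edges and use the kernel mass as effective n;
the binomial test is one-sided and exact on rounded effective counts.
The learning visit defaults to the *sustained* reading (first visit from
which the criterion holds through session end), with the literal
first-crossing available via `sustained=False`. A symmetric 50-trial
kernel anticipates a step change by ~40 visits (future outcomes leak
into the estimate), which is why step-recovery is assessed with a ±50
visit tolerance. Per-transition outcomes are indexed by global visit
number, so per-transition learning visits are directly comparable and
their max−min spread measures staggered learning.

SEQ sessions require ≥150 visits in run 1 (else excluded), merge both
run epochs and analyze the first 400 visits; final summaries average the
last 100 visits.

## Statistics

Two groups: Mann–Whitney U (exact enumeration when both n ≤ 20 and no
ties, else normal approximation with tie/continuity correction; U
reported for the first-listed group). Three groups: Kruskal–Wallis with
tie correction and chi-square p. Both are delegated to scipy and checked
in the tests against exhaustive-enumeration oracles (total n ≤ 8) and
null calibration at α = 0.01. Descriptive summaries are means with
seeded percentile-bootstrap 99% CIs (10000 resamples), the CI method
being unspecified in the source analyses.

## Problem sizes

The validation suite uses 200 s recordings at 4 kHz (five seeds) for
detector checks, 60 s sessions for the 20+20 closed-loop disruption
batch, 100 seeds for step-change recovery and 500+ simulated trials for
the NMTS recency effect; `scripts/acceptance.py` uses two 200 s
recordings and an 8+8 closed-loop batch. These sizes give stable
estimates (binomial/Poisson sampling error well inside every asserted
margin) while keeping the whole suite fast on a single CPU.
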