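# Methods notes

This note documents the models and procedures implemented in `socoop`,
the conventions and numerical choices behind them, what the synthetic-data
generator does and does not emulate, and the known limitations.

## Time and data model

Time is integer milliseconds from session start; all intervals are
half-open `[onset, offset)`.  A session bundle couples a trial table
(pellet dispense `t_start`, cooperation onset `t_coop` when both animals
push together, trial end `t_end`, intertrial end), two session-long binary
push series in 100 ms bins, a 30 Hz gaze track with object tracks,
timestamped events, 1 ms-resolution spike times with electrode/area
metadata, and per-unit waveform matrices.  Bundle validation enforces
ordered disjoint trials, binary push values, event containment in
trial/intertrial windows, the 100 ms minimum fixation duration, and spike
trains only for known units.  The analysis epoch of a trial is
`[t_start, t_coop)`: activity between tray-movement onset and trial end is
never analysed.

## Behavioral coordination

Per-trial push series are cross-correlated over all integer bin lags with
coefficient normalization — the raw lag sums divided by the geometric mean
of the two zero-lag autocorrelations — so identical series give a peak of
exactly 1 at lag 0 and values lie in [-1, 1].  The sign convention is
`ccg(tau) = sum_t self(t) partner(t + tau)`: a positive peak lag means the
self-monkey leads.  Trial CCGs are averaged lag-wise into the session CCG
(lags present in longer trials are averaged over the trials that reach
them).  Peak ties are broken toward the smallest |lag| and then the
positive lag, making output deterministic.  The shuffle control permutes
each monkey's bins independently within each trial — coincidence-
destroying but exactly rate-preserving — with one permutation per trial by
default (configurable repetitions with averaging).  All-zero series make
the normalization undefined; such trials are skipped.  Conditional
cooperation probabilities are bin-fraction estimates per trial, averaged
over trials where the conditioning monkey pushed at all.

Whether behavioral series should end at cooperation onset or trial end is
genuinely open; both are supported (`end_at_coop`), with full-trial series
as the default for behavioral metrics.

## Gaze and fixations

The scene frame maps 640 x 480 px to 35 x 28 deg, giving per-axis
pixels-per-degree used for all conversions (the small-angle 5 deg ~ 90 x 80
px identity holds within rounding).  Eye speed is the Euclidean
visual-angle displacement between consecutive valid samples divided by the
inter-sample interval; invalid samples (crosshair lost, coordinates
zeroed) produce no speed values.  The fixation threshold sits at the
kernel-density valley between the two largest modes of the log-speed
distribution; if several minima exist the lowest is taken (conservative),
and a unimodal distribution falls back to a configured default with a
warning.  Fixations are maximal sub-threshold runs of at least 100 ms;
single-frame gaps inside a run are bridged, longer gaps split it.  Object
assignment uses a circular aperture of the area's receptive-field diameter
(V4 5 deg, dlPFC 9 deg by default) centred on the crosshair, a
majority-of-samples rule across the fixation, and the precedence
partner > reward > button > floor when several objects fall inside at
once — social cues are the analysis targets, so they win ties.  Sessions
with fewer than 30 fixations are excluded from neural analyses.

## Event transitions

Per-trial sequences over the four salient events are ordered by onset
(simultaneous onsets order pushes before fixations) and reduced to bigram
counts; transition probabilities are row-normalized counts.  Only trials
containing all four events are included, and the inclusion fraction is
reported.  Rows without outgoing transitions are missing (NaN), not zero,
and the session mean ignores missing entries — zero-filling would bias
probabilities downward.  Note that both the per-trial ratio averaging and
the all-states inclusion rule carry small-sample selection effects; for
recovery tests against a generator's known matrix, pooled session counts
are the unbiased measurement.

## Unit stability

All waveforms supplied (typically 100 samples per unit per session, all
sessions together) are projected on the first seven principal components
of one common PCA fit, so that cross-session distances live in a single
basis.  The distance between two units is the Mahalanobis distance between
cloud centroids under the pooled (sample-size-weighted) covariance of the
two clouds; this is the standard multivariate reading of the centroid
formula, is symmetric, zero iff centroids coincide, and invariant under
invertible linear maps of the space.  A singular covariance receives a
logged ridge term.  Within-session distances between distinct units,
pooled over sessions, form the "different neuron" null; its 5th percentile
(linear interpolation) is the stability threshold.  On each electrode,
units in consecutive sessions below threshold are linked as the same
neuron; chains break across gaps of more than one session (conservative
identity claims), and electrodes recorded in fewer than half the sessions
are excluded.  The stable fraction counts stably linked unit-sessions over
unit-sessions with an eligible next-session comparison.

## Event responses

Response windows: fixations use the 130 ms after onset shifted by the
area's visual delay (60 ms V4, 80 ms dlPFC); pushes use the 1000 ms before
onset; push events must be isolated by more than 1 s.  Each observation is
paired with a matched-duration baseline drawn from the window ending 4.5 s
before its trial's start.  Significance is the two-sided Wilcoxon
signed-rank (exact for small n; identical pairs give p = 1 by convention)
with Benjamini-Hochberg FDR at alpha 0.01 applied within each unit's
family of event tests (a global family is a configuration choice).  Cell
classes: mixed = at least one significant fixation and one significant
choice event; other = none.  d' uses the stated denominator
`0.5 sqrt(sigma_A^2 + sigma_B^2)` verbatim; the common RMS-sigma
convention is available behind a flag and differs by a factor sqrt(2).

## Decoding

The decoder is a linear-kernel SVM with regularization constant 1 and no
feature standardization (solver defaults differ across ecosystems; this is
the documented approximation of a stock linear SVM).  Each of the 100
iterations subsamples the larger class to balance, runs stratified
tenfold cross-validation, and trains on the same balanced data a second
decoder with freshly permuted labels; reported accuracies are means over
iterations of held-out percent correct, and shuffle-corrected accuracy is
actual minus shuffled.  Train-set accuracy is reported alongside as an
overfitting check.  Session weights come from a single model fit on one
balanced draw of all observations (per-fold averaging is an alternative);
they are normalized by the population Euclidean norm, and the
variance/kurtosis/skewness of their absolute values are computed with raw
(non-excess) kurtosis and bias-uncorrected skewness.  A caveat measured
during development: single-session cross-validated accuracy has a
dataset-level standard deviation of several points at n ~ 100, so
null-calibration statements are made on averages over sessions, and the
shuffled decoder — not 50% exactly — is the chance reference.

## Spike coordination

Raw pair correlograms follow
`C_jk(tau) = (1/M) sum_i sum_t x_j^i(t) x_k^i(t + tau)` on binary 1 ms
segments: 800 ms before choice (and random control) events, 200 ms after
fixation onset plus the visual delay (80 ms for inter-areal fixation
pairs).  The all-way shuffle predictor is computed as the
cross-correlation of the two units' PSTHs (the efficient equivalent of
averaging over all trial pairings) and subtracted; the result is divided
by the triangle function Theta(tau) = T - |tau| (in seconds) and by the
geometric mean of the segment-mean firing rates, yielding coincidences per
spike whose peak is insensitive to overall rate.  Significance: the peak
within the pairing's window (|tau| in 0-6 ms within an area, including 0;
15-60 ms between areas) must exceed 4.5 times the SD of the corrected CCG
in symmetric tail bands starting 60 ms beyond the window edge (25 ms for
fixation events).  The default maximum lag is 150 ms so that the
non-fixation inter-areal tail band (which begins at 120 ms) exists; tails
are taken on the corrected CCG.  Mean coordination per session, event, and
area pairing averages the peaks of significant pairs only; inter-areal
peak lags use positive = V4 leads.  Rates are segment means, not
whole-session means.

## Synthetic-data generator

The generator's defaults are the study conditions: 18 sessions of 100-130
trials, push coordination scheduled from 0.6 to 0.9 with lags shrinking
from 2 s to 0.3 s and response delays from 3 s to 0.3 s; 30 Hz gaze with
~75% valid frames; four-state event sequences from row-stochastic
matrices; Poisson baselines of 8-20 Hz with multiplicative event gains at
the visual delays; waveform clusters of 100 samples per unit.  Specific
constructions worth knowing:

- Dyadic pushing: the partner echoes a Bernoulli-thinned copy of the self
  series at the scheduled lag.  With copy probability c the
  coefficient-normalized CCG peak converges to sqrt(c), so a target peak p
  is hit by copying with probability p^2; the self-monkey stops pushing
  early enough that every echo lands inside the trial (otherwise truncation
  deflates the peak).  Target 0 switches to independent pushing.
- Spike coupling injects duplicated source spikes into the target at a
  fixed lag jittered +-1 ms — common-spike injection rather than common
  rate input — because it gives an analytically known CCG peak location.
  Coupling can be gated on event windows to construct event-specific
  coordination.
- Gaze: fixation frames sit on the target object with ~1.5 px jitter and
  inter-fixation frames jump 80-160 px, giving the bimodal speed profile;
  a planned fixation of duration d occupies floor(d/frame) + 1 frames so
  the 100 ms boundary behaves exactly (90 ms dwells are recorded as
  sub-threshold ground truth and must not be detected).  Frame drops are
  placed outside planned fixations, emulating a tracker that loses the
  crosshair during rapid movement; real data can drop frames inside
  fixations, which would split detections — the detector's single-frame
  bridging covers only part of that.
- Assembled neural sessions place fixations and isolated pushes in a
  12 s pre-cooperation epoch with a forced joint hold defining t_coop, and
  an 8 s intertrial interval (long enough for the 4.5 s baseline).

What passing recovery tests shows is that each estimator recovers the
generator's construction at the stated tolerances; it does not certify
behavior on real recordings, whose non-Poisson spiking, saccade dynamics,
overlapping events, and nonstationary rates the generator deliberately
does not model.

## Problem sizes

The shipped tests and the acceptance script run at desk scale, chosen as
the smallest sizes at which the estimators' sampling error is comfortably
inside the stated tolerances: 18 sessions x 100-130 trials for behavioral
recovery, 10^4 transitions for matrix recovery, 300 null unit pairs for
the 4.5-SD false-positive calibration, 500 planned fixations for detection
F1, 16 electrodes x 6 sessions for stability recovery, and 200
observations x 50 units x 100 iterations for decoder chance calibration.

## Known limitations

- No NWB/NEV/NSx readers; bundles are plain CSV directories.
- No latent-state HMM fitting: event labels are observed, so transition
  estimation is supervised counting by design.
- No jitter-window CCG correction variants, spike-field coupling, or
  communication-subspace analyses.
- The valley-finding threshold is one defensible reading of
  "movement-threshold identification"; Otsu on log-speed is provided as an
  alternative reading, and neither is asserted to be the original.
- Receptive-field apertures are circles parameterized only by diameter;
  true RF shapes are richer.
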