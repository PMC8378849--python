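# Methods

This note documents the models, parameter choices and numerical decisions
behind `pupilswitch`, and what the synthetic-data tests do and do not
establish about real recordings.

## The synthetic generator

The generator (`pupilswitch.synthetic`) produces binocular gaze + pupil
recordings with the statistical structure the analysis chain assumes. It is
first-class, tested code: its ground truth is what every downstream stage is
validated against.

**Percept dynamics.** A hidden two-state timeline tiles each trial with
i.i.d. gamma-distributed dominance durations (default shape 3, scale 1 s,
mean 3 s — a typical rivalry regime with a gamma-like duration
distribution). The last episode of a trial is truncated at the trial end;
each trial's initial percept is random. Defaults follow the emulated study
design: 12 trials of 60 s per condition, four conditions in a 2×2
stimulus (rivalry / on-screen replay) × task (report / ignore) layout, with
the on-screen timeline replaying the rivalry-report percept sequence shifted
earlier by the fixed 500 ms reaction-time convention.

**Gaze.** Horizontal gaze drifts at the slow-phase speed (4.1 screen
units/s, matching the dot speed) in the direction of the current percept and
is reset to straight-ahead by quick phases of 20–40 ms, drawn from a
renewal process with 0.6 s mean interval (gamma with shape 4, for
regularity). Quick phases are high-velocity linear ramps, giving the
saccade detector realistic targets. Both eyes are correlated copies of one
underlying trace plus independent per-sample noise of SD 0.02 screen units —
the RMS noise class of video-based trackers at 1000 Hz. The study reports no
empirical slow-phase gain or quick-phase statistics, so these are free
parameters, exposed in `SimConfig`. Vertical gaze is pure noise.

**Blinks** are Poisson events (0.2 Hz default) with uniform 150–450 ms
durations, inserted as missing samples (NaN) in both eyes — how trackers
emit signal loss — forcing downstream code to handle gaps rather than
sentinel values. Blinks are kept ≥300 ms apart so interpolation flanks are
well defined.

**Keypresses.** Report-mode presses lag each switch by a truncated-normal
reaction time (mean 0.5 s, SD 0.15 s, floor 0.1 s; presses falling after the
trial end are never emitted). Ignore-mode presses follow dot-size probe
onsets (gaps Uniform(3, 8) s) with the same RT model and a detection
probability of 0.8, leaving a realistic population of unreported probes.

**Pupil.** Per trial, the trace in kernel units is
`drift_amp·exp(−t/drift_tau) + Σᵢ aᵢ·K_con(t−tᵢ) + Σₖ K_dil(t−tₖ) + noise`,
with `aᵢ = 1 + β·z(log preceding dominance duration)`. The default kernels
are smooth Gaussian-lobe shapes (constriction dipping at 0.8 s with a mild
rebound, dilation peaking at 1.2 s), chosen band-limited below 1 Hz so the
Fourier basis can represent them essentially exactly — which makes exact-
recovery tests meaningful. β defaults to 0 (no duration dependence); the
covariate analyses are exercised at β = 0.5, i.e. deeper constrictions after
longer dominance episodes, the direction of the adaptation-like effect the
method is designed to detect. The recording-format trace is
`baseline + gain·(kernel units)` in tracker units, with NaN during blinks.

**What the generator does not emulate:** perceptual mixture periods
(switches are instantaneous), pupil foreshortening with gaze angle,
luminance responses, tracker-specific artefacts, smooth-pursuit intrusions,
or slow arousal drifts beyond the per-trial exponential. Passing tests
therefore demonstrate correctness of the algorithms under the model's
assumptions, not robustness to every artefact of real recordings.

## Gaze cleaning and OKN decoding

Saccade detection follows the velocity-threshold algorithm of Engbert &
Kliegl: velocities from a 5-sample moving-difference filter
(`v[i] = (p[i+2]+p[i+1]−p[i−1]−p[i−2]) / 6Δt`; the source method's standard
kernel), an elliptic criterion `(vx/ηx)² + (vy/ηy)² > 1` with
`ηₖ = 6 × median-based SD`, and a 6 ms minimum duration. A segment with zero
velocity variance yields no saccades rather than a division error. Only
contiguous gap-free runs of ≥5 samples are analysed.

Cross-eye events (saccades, and blinks defined as missing-sample runs per
eye) merge when they overlap in time, transitively, spanning the earliest
onset to the latest offset. "Closer than 20 ms to a saccade / 50 ms to a
blink" is implemented as symmetric padding of the event interval; within
padded windows gaze displacement is zeroed and later samples are shifted so
the signal stays continuous. When one eye is missing, the available eye is
used; when both are, the sample belongs to a loss run.

Decoding: windowed direction values (750 ms window, 38 ms step, assigned to
window centers; windows never span a trial boundary), blink patching
(centers within [blink−250 ms, blink+400 ms] replaced by the mean over the
100 ms flanks; one-sided if a flank is empty, masked if both are),
assignment at strict thresholds ±0.85, switches midway between adjacent
opposite-percept periods. The brief-episode rule deletes both switches
bounding any inter-switch interval < 500 ms, scanning left to right until
stable — the deletion order is not defined by the convention the decoder
follows, so a deterministic order is fixed and documented here. Episodes
bounded on one side by the trial edge are not subject to the rule (their
duration is not identified). Linear fits weight all cleaned samples
equally, including collated zero-displacement spans.

Decoder performance on default synthetic data: ≥90% of true switches
matched within ±500 ms with false alarms ≤10% of the true count (measured
by greedy one-to-one matching). Undetectable by construction are episodes
briefer than 500 ms (~1.4% of episodes at the default gamma) and switches
inside long blink-patch windows.

## Pupil preprocessing

Stage order is fixed: average eyes → interpolate blinks → detrend → filter →
z-score → downsample → (derivative). Choices worth noting:

* **Exponential detrend** per trial, `a·exp(−t/τ) + c` with
  τ ∈ [10 s, 1000 s], initialised at (first−last, trial length, last) and
  fit by bounded least squares; the lower bound keeps the fit on slow drift
  rather than event-locked transients. Non-convergence falls back to a
  linear detrend with a warning.
* **Zero-phase two-pass filtering** (third-order Butterworth, 6 Hz): phase
  handling is not dictated by the convention followed; two-pass filtering is
  chosen because it preserves event-locked latencies, standard in
  pupillometry. The effective magnitude response is the squared single-pass
  response.
* **z-scoring is per trial** (not per block): the convention sentence scopes
  the operation to each trial's residual; flagged as an interpretation.
* **Downsampling by 100 ms bin means** rather than decimation: the 6 Hz
  filter already prevents aliasing and bin means are deterministic. Between
  trials the concatenated trace is exactly 0.
* **Derivative**: backward first difference × 10 /s, in z/s.

## Deconvolution GLMs

Event responses are modeled per regressor over a fixed window (−3.5..6.5 s
for switches, keypresses and probes; −0.5..7.5 s blinks; −0.5..4.5 s
saccades; 0..6.5 s trial starts) in either an FIR basis (one coefficient
per 100 ms lag) or a Fourier basis: a constant plus sin/cos pairs at
k/window-length for k = 1..⌊max_freq·length⌋, so 21/17/11 terms at 1 Hz for
the 10/8/5 s windows. Event onsets snap to the nearest 10 Hz bin. Events
whose window would cross a trial edge are excluded (except trial-start
regressors, whose out-of-trial rows are clipped). Saccade pairs <100 ms
apart merge into one event; blink events outside 130–900 ms are dropped;
probes count as unreported when no keypress follows within 2 s.

All regressors are fit jointly by OLS (`numpy.linalg.lstsq`), which returns
the minimum-norm solution for rank-deficient designs — only tiny synthetic
cases are expected to be deficient. Covariate regressors stamp the same
basis weighted by the z-scored log dominance duration (z-scored within
observer, across that observer's included switch events, matching
per-observer fits); they are fit jointly with, not orthogonalized against,
the main switch regressor — an open choice, flagged here. Quantile grouping
sorts by (duration, time) and gives earlier groups the extra events when n
is not divisible by k.

Per-observer curves are estimated independently and aggregated across
observers (mean ± SE) for statistics, on the trace and on its derivative.

## Cluster-mass permutation statistics

Per-lag tests: one-sample t, paired t, or the 2×2 repeated-measures ANOVA,
whose effects each have one numerator df, so each per-lag F equals the
squared paired t of the corresponding within-observer contrast scores
(sphericity is moot with 1 df). Clusters are maximal runs of adjacent lags
with p < 0.05 and a common effect sign; F carries no sign, so F-map
clusters use the p criterion alone. Zero-variance lags yield NaN and break
clusters. Cluster mass is the summed statistic.

The null permutes per observer independently: sign flips of the whole curve
for one-sample tests, condition relabelling for paired tests and ANOVAs
(all four labels permuted per observer per iteration, all three F-maps
recomputed, one max-mass null kept per effect). "More extreme" is strictly
greater |mass|; reported p = (k+1)/(n_iter+1) with k the count of more
extreme null masses, so an observed mass beyond every null value is stored
as 1/(n_iter+1) rather than the printed 0, and p ∈ [1/(n_iter+1), 1].
Clusters are significant at p < 0.01.

Calibration on simulated null data (24 observers): any-cluster p < 0.01 in
≤2% of runs; an injected effect at twice the noise SD is detected in ≥90%.

## Problem sizes

The packaged analyses run at the sizes a desk reproduction warrants: the
raw-rate chain is exercised on observer-conditions of 12 trials × 60 s at
1000 Hz; GLM and statistics studies use the analysis-rate generator
(10 Hz, ground-truth events) with cohorts of 12–24 simulated observers and
reduced permutation counts (200) where many repetitions are needed, and the
full 1000 iterations for single analyses. These are the package's own
defaults for its synthetic studies; every size is a parameter.

## Known limitations

* The decoder has no mixture-period model; transitions are instantaneous.
* Kernel recovery after per-trial z-scoring is assessed up to a single
  amplitude scalar (z-scoring rescales each trial); recovery in kernel
  units is assessed on the analysis-rate path without z-scoring.
* The blink-patch rule can displace switch estimates near long blinks; such
  switches dominate the residual misses of the decoder.
* Replay schedules drop reported events whose 500 ms back-shift would leave
  the trial or break alternation; with jittered reaction times this affects
  a small number of closely spaced reports.
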