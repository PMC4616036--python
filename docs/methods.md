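# Methods

`crocvoice` re-implements, as a tested pipeline, an analysis of body-size
information in the distress calls of juvenile crocodilians: how the calls'
pitch and spectral energy distribution scale with body length, and how
synthetic playback stimuli built from printed pitch constraints are scored
against behavioural responses.  The original recordings are not publicly
deposited, so every statistical claim the package tests is exercised on a
synthetic call population whose structure is documented here.

## Acoustic descriptors

Each call is summarized by 13 descriptors.

Eight describe the averaged magnitude spectrum within 0–5 kHz (1024-sample
FFT frames, Hann window, 99 % overlap by default): the spectral mode
(frequency of maximal magnitude), the energy quartiles Q25 and Q75 (first
frequency at which the cumulative normalized magnitude reaches 0.25 / 0.75,
no interpolation), their difference IQR, the centroid (magnitude-weighted
mean frequency), the standardized skewness and kurtosis of the spectral
mass (kurtosis is the plain fourth standardized moment, ≈ 3 for a Gaussian
profile), and the spectral flatness (geometric over arithmetic mean of the
magnitudes; → 1 for noise, → 0 for a pure tone).  Moments and quartiles use
the unit-mass normalized spectrum; the flatness ratio uses raw magnitudes
and is scale-invariant, so every descriptor is invariant to recording gain.
Whether the source analysis used magnitude or power spectra and which
window it applied is not stated; magnitude + Hann is assumed and isolated
behind `SpectrumConfig`.  The 99 % overlap default is honoured but is
numerically indistinguishable from 75 % for these averaged descriptors.

Five descriptors summarize the F0 contour: start, maximum, minimum, mean
and end pitch.  Start/end are the F0 of the first/last voiced frame; the
mean is the arithmetic mean over voiced frames (unvoiced frames carry no
F0 — a deliberate interpretation, since a time-weighted alternative is
equally defensible).

## Pitch tracker

A frame-based normalized-autocorrelation tracker (frame 20 ms, hop 5 ms,
search band 100–1200 Hz, voicing threshold 0.45).  Per frame the signal
autocorrelation is divided by the autocorrelation of the analysis weighting
itself, `r(τ) = [A(τ)/A(0)] / [W(τ)/W(0)]`, which removes taper-induced
decay so a stationary tone peaks at its period with r ≈ 1.  Candidates are
scored with a small lag penalty (0.01 per octave) to break period-vs-octave
ties, and the winning lag is refined by parabolic interpolation.

Frame centers run from t = 0 to the end of the call so the first and last
voiced frames probe the call boundaries.  Overhanging frames use a window
tapered over the in-signal support: truncating a full-height window at the
signal edge leaves an oscillatory residual in the autocorrelation that
biases the edge lag estimate by several percent at low F0 (measured −0.9 %
at 500 Hz, −3.7 % at 200 Hz with naive zero-padding), while the
support-fitted taper brings pure-tone edge frames to within a fraction of
one hertz.  The known residual limitation: edge frames of a *strongly
frequency-modulated* call average the modulation over their support
(roughly uniformly, a consequence of the W-normalization), so tracked
start/end pitch of a call whose contour has nonzero slope at its endpoints
is biased toward the interior by about half a frame of sweep.

Interactive octave-jump correction is replaced by a deterministic
median-continuity rule: a voiced frame within 15 % (relative) of exactly
twice or half the median of its five nearest voiced neighbours is folded by
an octave; the rule is iterated to a fixed point and is idempotent.
Reproducibility requires removing the human from this loop; the heuristic
is a stand-in, not a reconstruction of manual candidate selection.

A frame length of 20 ms (rather than a more conventional 40 ms) is used
because the experimental stimuli sweep hundreds of hertz within 160 ms; a
40 ms frame averages a quarter of the call and cannot return the design
anchors within the 3 % round-trip tolerance the package guarantees.  20 ms
still holds two periods of the 100 Hz search floor at maximal lag.

## Stimulus contours

The three playback stimuli are specified only by start, mean and end pitch
and duration (630/638/350 Hz, 300/384/200 Hz, constant 500 Hz; 160 ms).
Three anchors do not fix a trajectory, so the contour family is a modeling
choice: a rise from `f_start` to a peak at fraction p = 0.25 of the
duration, then a descent to `f_end`, each segment shaped by a symmetric
seventh-order smoothstep.  Any ramp with s(u) + s(1−u) = 1 averages to the
midpoint of its endpoints, so the peak solves in closed form,

    f_peak = 2 f_mean − p f_start − (1 − p) f_end,

giving 856 Hz and 543 Hz for the two FM stimuli — inside the printed
natural maximum-pitch ranges (969 and 529 Hz) for the corresponding
size classes, which is why the rise-then-fall family was chosen.  The
smoothstep (zero slope *and* curvature at the endpoints) rather than a
straight line is what makes the synthesis-to-tracking round trip return
the printed anchors: with linear segments the low stimulus' ~6 kHz/s
onset sweep biases the first tracked frame by 4–7 %, breaking the 3 %
round-trip guarantee for any usable frame length.  This is a claim about
this package's stimuli, not about the original ones, whose FM shape
between the anchors is unknown.

If the requested mean is unreachable by the rise–fall family (solved peak
below both endpoints), the contour degenerates to a single monotone
segment and reports the achievable mean.  Stimuli get 5 ms raised-cosine
onset/offset ramps (click-free playback), an exact sample count of
`round(duration × sample_rate)`, and phase computed as the cumulative
integral of the instantaneous frequency.  Harmonic call mimics add
partials at integer multiples of the contour with a fixed dB-per-harmonic
spectral tilt.

## Synthetic call population

The generator emulates the statistical structure the analysis assumes,
anchored to a built-in table of per-size-class call statistics (mean pitch
and spectral centroid per 20 cm body-length class, with the number of
recorded individuals per class) for five species.  A weighted least-squares
fit (weights = class n) with per-species intercepts and one shared slope
turns the class means into the default allometric model: pitch slope
−1.90 Hz/cm, centroid slope −5.46 Hz/cm.  The class means are not exactly
collinear, so the fitted line passes within one class standard deviation of
the anchors rather than through them.  A shared slope mirrors the finding
that species scale alike; the relation is linear in length, not log-log,
matching the original regressions.  Age is deliberately not modeled.

Per call, mean pitch = species intercept + slope × length + an individual
random intercept (SD 50 Hz) + call-level noise (SD 30 Hz); start and end
pitch are fixed ratios of the mean (1.1 and 0.65, jittered ±5 % per call so
the five pitch descriptors are not collinear); duration is 160 ms.  The
within/between-individual SD split is an assumption — the printed class SDs
(47–93 Hz for Nile crocodile pitch) mix both levels.  The spectral side is
driven by a centroid target (species line + individual SD 200 Hz + call SD
120 Hz): the per-harmonic tilt of a 10-harmonic stack is solved by root
finding so that the analytic in-band centroid of the call equals the
target.  Since the spectrum is linear in the harmonic amplitudes, the
centroid as a function of tilt reduces to a weighted mean over per-harmonic
band moments, making the solve cheap and exact.

Calls per individual are a rounded normal (mean 15, SD 5) truncated to
[1, 20]; body lengths are uniform over 24–118 cm; the study-scale roster is
76 + 60 + 9 + 5 + 14 individuals across the five species.  Everything is
reproducible from (config, seed).

The generator has two output layers.  The *audio* layer renders each call
as a harmonic stack and is used wherever the signal chain itself is under
test.  The *analytic* layer skips rendering: pitch descriptors come
directly from the realized contour, and spectral descriptors are computed —
through the same descriptor code — from the call's analytic line spectrum
(contour sampled uniformly in time, so each harmonic spreads magnitude in
proportion to dwell time, convolved with the averaged magnitude response of
the Hann analysis window so spectral leakage is represented).  The two
layers agree with no systematic bias beyond ~1 % on pitch and ~3 % on the
centroid; replicate-based statistical checks use the analytic layer for
speed.  What the generator does *not* emulate: background noise,
propagation and microphone response, non-stationary harmonic structure
(e.g. the palatal-valve resonances), duration variation, and any
correlation structure among descriptors beyond what pitch, tilt and the
shape jitter induce.  Passing tests therefore demonstrate that the
*pipeline* recovers what it assumes, not that real calls satisfy those
assumptions.

## Size-coding statistics

The 13 descriptors are standardized (correlation-matrix PCA — the
variables mix Hz and dimensionless units) and the first two components are
kept as Acoustic Dimensions, with signs fixed so the centroid loads
positively on AD1 and mean pitch positively on AD2.  PCA is fitted on
call-level rows; per-individual means of the scores serve only for the
acoustic-space plot analogue and the allometric regressions.

For each dimension, likelihood-ratio tests with a per-individual random
intercept (maximum likelihood, not REML — REML likelihoods are not
comparable across fixed-effect structures): the size and species main
effects are tested by dropping them from the additive model, the
size × species interaction by comparing the crossed against the additive
model; df = 1 for size and (number of species − 1) for species and
interaction.  Likelihood surfaces are optimized by L-BFGS with a Powell
fallback on non-convergence; chi-square statistics are clipped at zero
(optimizer round-off can make the difference infinitesimally negative).
The chi-square reference for the individual-level size covariate is
calibrated only with enough individuals: at ~30 individuals the test is
measurably anticonservative (rejection ≈ 0.08 at nominal 0.05, an
F(1, ~27)-like correction being ignored), so null-calibration checks use
100-individual rosters.

Per-species allometric lines are ordinary least squares on individual
means.  Two species are compared in a pooled model with body length
centered on the pooled mean: the species term then tests the vertical
offset between the lines at a typical length (centering matters — with an
interaction in the model, the offset at 0 cm is an extrapolation with
little power), and the interaction term tests the slope difference.

## Playback analysis

Field responses are coded on the ordinal −2..+2 intensity scale; the
boundary cases follow the strict inequalities of the scale definition
(exactly half the distance → +1, exactly 5 m retreat → −1).  Captive
responses (orientation 0–2, number approaching, maximal approach 0–2) are
collapsed into the first principal component of the standardized criteria,
signed so that more approaching females score higher; constant criteria
are dropped with a warning.

The stimulus effect on the composite score is a Gaussian mixed model with
crossed random intercepts for experimental unit and playback order
(playback order has few levels; a fixed-effect fallback is available
behind a flag), tested by ML likelihood ratio.  Pairwise stimulus
contrasts come from the REML fit of the cell-means model; family-wise
adjusted p-values are single-step, based on the joint multivariate-t
distribution of all contrasts at the residual degrees of freedom,
evaluated by a fixed-seed Monte Carlo integration (deterministic; 2·10⁵
draws by default, ~0.2 % integration error).  The t reference rather than
the asymptotic normal matters at these sample sizes: with 8 units × 3
stimuli the normal version inflates the measured family-wise error to
≈ 0.14, the t version holds ≈ 0.06.  REML fits near a variance boundary
occasionally return an indefinite covariance; optimizers are tried in turn
and, failing all, the balanced-design OLS covariance is used with a
warning.

The simulated captive experiment maps a latent response strength (stimulus
mean + unit intercept + order intercept + noise) monotonically onto the
three ordinal criteria.  A latent shift of ~1.2 units reproduces the
magnitudes of the reported adjusted comparisons; the acceptance harness
uses a far-shifted category (2.0 units) to verify the qualitative
three-way pattern at high power.

## Problem sizes used in the test suite

Replicate-based checks are sized to hold statistical meaning at desk
scale: parameter recovery runs 50 study-scale replicates (164 individuals,
~15 calls each, analytic feature layer); type-I calibration runs 300
replicates of 100-individual null populations; the playback harness runs
40 effect and 100 null replicates.  Audio-path correctness is covered
separately by deterministic synthesis-to-tracking round trips and by
direct audio-vs-analytic feature comparisons on a small rendered
population.

## Known limitations

- Edge frames of strongly modulated calls are biased toward the interior
  (see above); summaries of natural-style calls with non-flat contour ends
  inherit this.
- The octave-fold heuristic assumes isolated jumps; a contour that is
  wrong by an octave over most of its length will be "corrected" the wrong
  way.
- The segmenter is an amplitude-envelope stand-in; how calls were
  delimited originally is unreported.
- The generator's descriptor correlation structure is simpler than real
  calls'; in particular the PCA rotation can split size information
  between the two dimensions differently from the original loadings, and
  the spectral axis (AD1) carries a weaker size signal than the pitch axis
  (AD2).
- Reported headline chi-squares of the original field and captive
  experiments depend on the undeposited recordings and live animals; they
  are covered only as qualitative patterns.
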