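# Methods

This note documents the models and procedures `neopain` implements, the
assumptions behind them, the parameters that matter, what the synthetic-data
generator does and does not emulate, and the numerical conventions adopted
where the underlying methodology leaves choices open.

## Signal conditioning

Continuous EEG (channels × samples, µV) is band-passed 0.5–70 Hz with a
zero-phase order-4 Butterworth filter (`sosfiltfilt`, reflect padding) plus
a second-order IIR notch at 50 Hz (Q = 30). The Butterworth response is
maximally flat (monotone passband, −3 dB at the band edges); after the
forward–backward pass the notch attenuates its centre frequency by far more
than 20 dB. Epochs are cut around stimulus markers (typically ±4 s) with
the sample at time 0 equal to the marker sample; markers without headroom
are skipped, never zero-padded. Baseline correction subtracts each
channel's mean over the half-open pre-stimulus interval [−t_pre, 0) and is
idempotent. Artefact handling is a fixed amplitude criterion (default
500 µV peak): offending channels are listed in `excluded_channels` and
masked downstream; a trial with no surviving channel is flagged unusable.
If the projection channel (Cz) is excluded, projection outcomes are
*unavailable*, which is distinct from a magnitude of zero.

## Single-trial template projection

A template is a unit-L2-norm waveform on a fixed post-stimulus window
(noxious-specific: 400–700 ms; sensory-evoked potential: 100–300 ms).
Woody filtering searches integer-sample lags within ±50 ms for the lag
maximising the Pearson correlation between the lagged data window and the
alignment reference; positive shift means the response occurs later in the
data than in the reference. Ties break toward the smaller |shift|, then the
negative one. For single-trial projection the reference is the template
itself; during sensory-template derivation it is the grand average.

The projection magnitude is the inner product of the aligned window with
the unit-norm template — its least-squares coefficient, which for a single
component coincides with an SVD-based projection. The occurrence threshold
is the 80th percentile (linear-interpolation quantile, numpy convention) of
magnitudes obtained from background epochs processed identically;
occurrence requires the magnitude to be *strictly* above threshold, so by
construction roughly 20% of fresh background epochs are called positive.
Background magnitudes are pooled across infants by default. The package
ships a synthetic noxious-specific template with the canonical 400–700 ms
support (the literature template derives from non-redistributable
term-infant data) and loads any user-supplied template from JSON.

The sensory-evoked-potential template is derived from a reference trial
set: trials are Woody-aligned to their grand average in the 100–300 ms
window, PCA is run over the aligned trials × samples matrix, components are
retained up to 95% cumulative variance, and the retained component whose
trial weights best separate stimulated from background trials
(Mann–Whitney U, two-sided, α = 0.05) becomes the template — unit-normed,
sign-fixed so its largest-|value| extremum is positive. The Mann–Whitney
selection test is a deliberate design choice: the synthetic reference sets
have no repeated-measures structure that would warrant a mixed-effects
formulation. If no component separates the groups the derivation raises an
explicit error rather than returning an arbitrary component.

## Delta-brush detection

Per channel, the slow signal is the 0.5–2 Hz band-pass and the fast
envelope is the magnitude of the analytic signal of the 8–22 Hz band-pass.
Slow-wave intervals are runs with |slow| above threshold for ≥ 0.25 s; fast
bursts are envelope runs above threshold for ≥ 0.1 s; a brush is emitted
when a fast burst starts inside a slow-wave interval and is timestamped by
the fast-burst onset (the slow deflection begins earlier and its onset is
ill-defined). Thresholds are 3 × the median absolute deviation of the
respective trace, floored at 0.1 × the peak of the channel's broadband
(0.5–22 Hz) signal. The published parameters of the original burst detector
are not available, so all four values (two multipliers, two minimum
durations) plus the floor are configuration keys and these defaults are a
documented reconstruction. The MAD makes detection invariant to rescaling
the signal; the broadband floor prevents two failure modes of purely
MAD-based thresholds — near-silent recordings whose MAD collapses to zero,
and cross-band filter leakage (the low-frequency sidelobes of a gated fast
burst) masquerading as a slow wave. A brush counts as stimulus-evoked when
its fast onset falls in the one-sided window [stimulus, stimulus + 2 s] at
any non-excluded electrode; pre-stimulus brushes never count.

Limitations: with 1/f background noise at low SNR the slow band carries
much of the noise power and brush sensitivity drops well below the evoked-
potential detection sensitivity; the detector is exact on planted events in
clean signal and is intended for the co-occurrence *rule*, not as a tuned
clinical burst detector.

## Maturity tree and discrimination

The decision tree splits on noxious-specific activity, then the
sensory-evoked potential, then delta brushes, giving an ordinal scale:
4 = noxious-specific AND sensory potential (most mature), 3 =
noxious-specific only, 2 = sensory potential only, 1 = delta brushes only
(least mature). The two extremes are anchored by the source analysis; the
relative order of the two intermediate leaves is a package choice and can
be overridden. All-false profiles are unclassifiable and excluded from
group analyses; profiles with an unknown field (e.g. Cz rejected) are
counted separately as unknown. The sensory-potential flag is true if the
SEP occurred to *either* stimulus. Discrimination = facial response to the
noxious stimulus AND none to the innocuous one. The
maturity–discrimination association is a per-infant Bernoulli GLM with
logit link on the numeric ordinal level; perfect separation is reported as
such rather than surfacing as a spuriously huge slope.

## Cohort statistics

Responder proportions use half-open 2-week windows [a, a+2) stepping 1 week
from 28 weeks; a window with fewer than 12 infants is merged forward
(extended by one step at a time) until it reaches 12, and trailing windows
that cannot are dropped — the merge rule is a package convention, flagged
via warning whenever triggered. The age trend is a binomial-count GLM of
(k, n−k) per window against the window midpoint; overlapping windows make
the observations correlated, which is deliberately ignored (the slope is
descriptive, as in the source analysis).

The paired duration comparison is the Wilcoxon signed-rank test: zero
differences are dropped, midranks handle ties, and for n ≤ 25 the two-sided
p-value comes from the exact null distribution computed by the
shift-algorithm DP over doubled midranks (which remains exact under ties);
larger n uses the normal approximation with tie and continuity corrections.
The point estimate is the Hodges–Lehmann median of all n(n+1)/2 Walsh
averages (zeros included), with the standard distribution-free CI from the
exact signed-rank critical value (normal-approximate above n = 50). The
exact-p and CI conventions were verified against an independent reference
implementation during development and are frozen in the test suite.

## Gaussian-process response model and divergence age

The probability that an infant responds to a stimulus is modelled over
gestational age with a zero-mean GP prior on a latent propensity f(a),
squared-exponential covariance σ² exp(−(a−a′)²/2ℓ²) with ℓ = 3.5 weeks and
σ = 1 (an ARD kernel with one input reduces to this), probit likelihood
Φ(y·f) for y ∈ {−1, +1}, and expectation-propagation inference with the
hyperparameters held fixed (no marginal-likelihood optimisation — the
lengthscale encodes the assumption that response propensity changes
smoothly over a few weeks). EP iterates site updates until the largest
site-parameter change is below 1e-6 or 100 sweeps, recomputing the
posterior from the sites after each sweep for numerical stability (kernel
jitter 1e-8); on non-convergence a damped retry (damping 0.5) precedes a
hard error. The predictive response probability is
p(a) = Φ(μ*(a)/√(1+v*(a))). With no data this reverts to the prior 0.5,
and far from data it decays back to 0.5 over the lengthscale. The model is
fitted to per-infant binary outcomes, not to windowed proportions; windows
serve only the GLM and plots.

For two fitted models (noxious, innocuous) evaluated on a shared age grid
(28–41 weeks, 0.1-week resolution), each predictive probability is treated
as a Gaussian with the delta-method SD φ(z)·√(v*/(1+v*)), z = μ*/√(1+v*),
and the one-sided p-value for "noxious ≤ innocuous" is Φ(−Δ/sd(Δ)) for the
difference of two independent Gaussians. These p-values are descriptive
model summaries, not independent tests, and no multiplicity correction is
applied across the grid. The divergence age at level α is the earliest grid
age after which the p-value stays below α; by construction the 99% age
never precedes the 95% age. The exact delta-method form used in the source
analysis is not published; this construction is a documented
reconstruction.

Accuracy: EP predictive probabilities were compared against brute-force
Gauss–Hermite integration of the exact posterior for 1–3 observations; the
agreement is ~1e-3, with a worst case of ~1.6e-3 for a single observation
(for one y = −1 observation the exact predictive at the training age is
1/3 while the Gaussian-averaged EP predictive is 0.3317). This residual is
the intrinsic Gaussianity error of EP's predictive average, not an
implementation artefact, and vanishes in practical cohort sizes.

## Synthetic-data generator

The generator defines the study conditions under which the pipeline is
validated.

**Cohorts.** Gestational ages are uniform on 28–41 weeks. Facial responses
are Bernoulli draws from two logistic curves: innocuous
p(a) = 0.08 + 0.42·expit(−0.35(a−32)) (gently declining, ~0.4 at 28 w to
~0.1 at 41 w) and noxious rising with slope 1.5/week to ceiling 0.95 from
floor 0.12, its midpoint solved so the two curves *cross* at the configured
divergence age (default 33.0 weeks). The crossing is the generative
definition of the true divergence age: before it the noxious curve lies
below the innocuous one, after it above, so the one-sided GP divergence
estimate converges to the crossing from above as the cohort grows — with a
gently separating noxious curve no single "divergence age" would be a
recoverable quantity, so the steep post-crossing rise (mirroring the rapid
developmental switch the literature describes around 33 weeks) is part of
the generator's definition of truth. Responder durations are Gaussian
(mean 8 s, SD 6 s) clipped into [0.5, 30] s — a responder by definition has
positive duration — and non-responders have duration 0. EEG maturity is a
monotone threshold map on age (31/33/35 weeks → levels 1–4) with Gaussian
age noise (SD 0.5 weeks): cohort studies report an association between age
and response maturity, not a deterministic law.

**Epochs.** Background noise is Gaussian with a 1/f^α spectrum (α = 1)
scaled to a configurable RMS — simple, and spectrally close enough to EEG
to stress the filters. Three canonical waveforms (analytic formulas in
`neopain.waveforms`, unit peak amplitude) are injected according to
maturity and stimulus: level-1 (immature) stimulated epochs receive a delta
brush starting 0.3 s post-stimulus on a random electrode; level-4 (mature)
noxious epochs receive the noxious-specific waveform plus the
sensory-evoked potential at Cz; mature innocuous epochs the SEP only.
Event latencies carry truncated-Gaussian jitter (SD 15 ms, bounded ±50 ms)
so Woody alignment is exercised across its full search range. Injected
amplitude is snr × noise RMS; the source study reports no evoked-response
amplitude statistics, so SNR is an uncalibrated free parameter (default 3,
at which template detection sensitivity exceeds 0.9 while the SEP-only
epochs stay at the background call rate in the noxious window). The default
sampling rate is 500 Hz; clinical recordings use 2000 Hz, but all windows
are specified in milliseconds so results are rate-agnostic and the lower
default keeps simulation cost small. Everything is bit-reproducible given
the seed.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: sleep-state structure, movement and electrode
artefacts (beyond what the amplitude criterion exercises), realistic brush
morphology variability, spatial covariance across electrodes, correlations
between facial behaviour and EEG maturity beyond their common dependence on
age, and real evoked-response amplitude distributions.

## Problem sizes used in the shipped checks

Divergence-age recovery uses 20 seeded cohorts of 120 infants per stimulus
(with a 500-infant variant for the consistency check), GLM sign recovery
20 cohorts of 200, and planted-signal detection 200 noxious epochs at SNR 3
against 200 calibration plus 400 evaluation background epochs — sizes
chosen to put the Monte-Carlo error of each check well inside its decision
margin.
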