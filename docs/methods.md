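# Methods

`bwmap` implements the statistical machinery used to build brain-wide
maps of task-variable correlates in a visual two-alternative
decision-making task: which brain regions carry information about the
stimulus side, the animal's choice, the trial outcome and the wheel
movement, assessed per region with nulls that respect the task's
temporal structure. Because chronic electrophysiology drifts slowly,
naive shuffle tests produce nonsense correlations; every analysis here
is therefore scored against a bespoke null distribution, and the whole
chain is exercised end-to-end on synthetic sessions with known ground
truth.

## The task generative model

A session starts with 90 unbiased trials in which the four non-zero
contrasts (100, 25, 12.5, 6.25%) appear exactly 10 times on each side
and the 0% contrast exactly 10 times with a uniformly random side
(contrast ratio 2:2:2:2:1). Subsequent trials come in alternating
biased blocks with the stimulus on the right with probability 0.8
(right blocks) or 0.2 (left blocks); the first biased side is uniform.
Block lengths are exponential with scale 60 trials, truncated to
[20, 100] by rejection sampling and rounded to whole trials; the
truncated-exponential mean is 51.4 trials, matching the task's
empirical mean of 51. (The generator follows the continuous-exponential
description of the protocol; a geometric variant would change nothing
material at these scales.)

Default sessions are 600 trials long, near the median length of
released recordings.

## The behavioural agent

Choices come from an action-kernel agent: its subjective prior of a
rightward stimulus is an exponential running average of its own past
actions, `pi_{t+1} = (1 - alpha) pi_t + alpha * 1[a_t > 0]`, and its
policy is

    p(right) = lapse/2 + (1 - lapse) * sigmoid(slope * e + w * logit(pi)),

with `e = sign(side) * tanh(5c)/tanh(5)` the saturating signed contrast
evidence. The policy is a deliberately minimal stand-in (the update
rule is the modelled quantity; published work defers the policy to a
separate behavioural study). Defaults — alpha 0.15, slope 4.5, prior
weight 0.7, lapse 0.01 — were chosen once to reproduce the task's
hallmark behaviour: ~86% overall accuracy, ~59% accuracy on 0% contrast
trials (above chance only because the prior is exploited), >90% correct
on full-contrast trials in both block types (the session inclusion
gate), and reversal adaptation over ~5-10 trials. First-movement
latencies are log-normal with a contrast-dependent median (slower at
low contrast), clipped to the analysis range [0.08, 2.0] s.

Note one structural property of the model: with a contrast-blind
policy (slope = 0) the prior feeds back only on the agent's own
stimulus-independent actions and cannot track the block, so
above-chance zero-contrast accuracy requires both a stimulus-sensitive
policy and a non-zero prior weight. The tests assert this sign of
effect (prior weight 0.7 vs 0).

## Wheel and spikes

The wheel turns with a smooth half-sine velocity bump at each first
movement (positive velocity = rightward choice), plus a smaller
corrective movement on ~35% of trials — so movement-initiation events
detected from the trace are not one-to-one with first movements, as in
real data. This matters for the encoding model: it is what makes the
movement-initiation regressor linearly independent of the left/right
first-movement kernels.

Spike trains are inhomogeneous Poisson. Within each trial's analysis
window the log-rate is `log(baseline) + X beta + drift`, where `X` is
*exactly* the encoding model's design matrix (generator and fitter
share one definition of every event effect; a test asserts the
matrices are bit-identical) and `beta` spreads each per-event scalar
gain over that event's bases with a fixed decreasing profile. Drift is
AR(1) on a per-trial log-gain (defaults: coefficient 0.97, innovation
sd 0.15, stationary sd ~0.6), i.e. slow multiplicative drift strong
enough to induce nonsense correlations, which is the stressor the null
distributions exist for. An optional ~10 Hz multiplicative oscillation
after correct feedback emulates licking. Rates are simulated on a 5-ms
subgrid (20-ms design values held constant across sub-bins); between
trial windows the rate is baseline x drift gain. Seeding is
hierarchical (session seed spawns per-neuron seeds), so adding a neuron
never changes existing spike trains.

The tuned-scenario region gains (e.g. visual region: stim-right 2.0,
stim-left 0.3, per-neuron log-normal jitter sd 0.3) define the
fixture's effect size; they were set once so that the tuned sensory
region decodes stimulus side at balanced accuracy ~0.75 from ~7
neurons, comparable to strongly tuned regions in real recordings, and
are the operating point at which the power checks are run.

What the generator does **not** emulate: correlated noise across
neurons, multi-probe geometry, non-Poisson spiking statistics
(refractoriness, bursting), video streams, and any structural
relationship between regions other than independent drift. Passing
tests therefore demonstrate correctness and calibration of the
statistics under drift plus Poisson noise, not robustness to every
failure mode of real electrophysiology.

## Inclusion filters

Trials are dropped when a required event is missing or the
stimulus-to-first-movement latency falls outside the closed interval
[0.08, 2.00] s. Sessions must have >= 250 valid trials (release gate),
>= 400 for analysis, >= 3 incorrect trials, and >= 90% accuracy on
100%-contrast trials in both biased block types. Regions enter an
analysis with >= 2 sessions contributing >= 5 well-isolated neurons
each and >= 20 pooled. All analysis windows and bins are half-open
[start, end) — chosen so that refining a window into bins conserves
spike counts; the latency filter is closed. The two interval
conventions are deliberate and tested.

## Null distributions

* **Pseudo-sessions** (stimulus side): fresh draws from the task
  generative process above.
* **Synthetic sessions** (choice, feedback): the action-kernel model is
  fitted to the session's choices by maximum likelihood — the learning
  rate jointly with the policy nuisance parameters, by multi-start
  L-BFGS-B polished from a 21-point grid over alpha — and replayed on
  pseudo-stimuli. Recovery is ±0.05 of the generating alpha at 10^4
  trials.
* **Imposter sessions** (wheel speed/velocity): contiguous chunks of L
  trials from the concatenated pool of *other* sessions (in this
  artifact, other synthetic sessions; the contract is unchanged).
* **Linear-shift test** (point-by-point spike/behaviour correlation):
  trim n = 20 samples from both ends, rank the unshifted r^2 among the
  2n+1 integer shifts, reject at alpha = 0.05 when it lands in the top
  floor(alpha(2n+1)) = 2 of 41 (ties against rejection), giving an
  exact type-I error of 2/41 ≈ 0.049 under exchangeability.

Observed-vs-null scores become p-values with the add-one permutation
form `(1 + #{null >= obs})/(M + 1)` — strictly positive, valid, and
safe inside Fisher's method; the raw percentile form is available via a
flag. The Granger permutation keeps the raw counting form
`#{pseudo >= obs}/(M + 1)` of the original procedure (it can be exactly
zero; Fisher combination clips at 1e-300).

## Decoding

Binary targets use class-weighted (1/(2 P_class)) L1-regularized
logistic regression on single-window counts; continuous wheel targets
use Lasso on a causal lagged window of W+1 = 11 bins of 20 ms.
Cross-validation is nested: 5 interleaved outer folds, 5 inner folds
selecting the penalty from a fixed grid (10^-5..10^1 for logistic,
10^-5..10^-1 for Lasso), refit on the outer training set, concatenated
test predictions scored once (balanced accuracy / R^2), averaged over
10 runs (binary) or 2 runs (wheel) with different fold seeds. Folds
are resampled (cap 100) when a training set lacks a class. Sessions
combine per region by Fisher's method on session p-values; the effect
size is the median null-median-corrected score; significance is decided
only after Benjamini-Hochberg FDR at q = 0.01 across regions.

The logistic solver is an in-package FISTA proximal-gradient routine
with an unpenalized intercept, adaptive momentum restart, a
power-iteration Lipschitz estimate, and warm starts along the penalty
path; columns are centred first (an exact reparametrization when the
intercept is unpenalized, which conditions the problem dramatically).
Rationale: every decode is repeated for M null targets times the
multirun CV, and a general-purpose solver call is two orders of
magnitude slower at these problem sizes. The solver is validated
against scikit-learn's liblinear on the same objective in the test
suite; liblinear's intercept is penalized, so intercepts agree only
approximately while coefficients agree closely.

## Single-cell statistics

Selectivity uses the Mann-Whitney statistic in ROC-area form
P = U/(n1 n2) with midranks, min-folded so P ∈ [0, 0.5]; and the
condition-combined form `P = min(sum_j U1_j, sum_j U2_j) / sum_j n1_j
n2_j` over conditions j that hold the other task variables fixed.
Orientation is kept consistent for one side across conditions *before*
summation, and the min-fold applied after: the literal per-condition
fold would make exactly opposing effects in two conditions look
maximally selective (a worked example in the tests shows 0.5 vs 0.0);
the literal form remains available behind a flag. Significance comes
from permutations of the tested label within strata of the other task
variables inside each individual block (3000 by default); extremeness
is two-sided, |P - 0.5|. A neuron is *sensitive* when the simple-MW
permutation p < 0.001 and the condition-combined p < 0.05. Per-session
fractions of sensitive neurons are referred to Binomial(N_i, 5e-5)
survival probabilities, Fisher-combined, and BH-corrected across
regions.

Responsiveness uses Wilcoxon rank-sum between baseline (-200-0 ms
pre-stimulus) rates and five canonical task windows, rates normalized
per second. The time-shift test for continuous behaviour traces
computes 40 shifted correlations at offsets 50-1000 ms (both signs) and
p = m/41. RF mapping averages spike rates 0-100 ms after on/off
luminance transitions per pixel of the 15x15 sparse-noise grid, fits a
2-D Gaussian (Levenberg-Marquardt from a moment-based start; diverged
fits count as no RF), and compares variance explained against 200
spatial shuffles of pixel positions; a neuron has an RF when either
polarity's shuffle p < 0.01.

## Population trajectories

Per region and variable, cells pooled across sessions contribute
trial-averaged rates per condition in overlapping 12.5-ms bins at 2-ms
stride over 0-150 ms (final partial bin dropped; >= 20 cells required).
The distance is `d(t) = ||m1(t) - m2(t)|| / sqrt(N)` in spikes/s, the
modulation amplitude `A = max_t d - min_t d`, and the latency the first
bin start where d reaches its minimum + 0.7 A (undefined when A = 0 —
note a constant condition offset yields d > 0 but A = 0 by design).
Pseudo-trials permute the condition label within strata of the other
variables per session; for feedback, choices are permuted and compared
with the true stimulus sides to derive pseudo-feedback;
p = (n+1)/(M+1) with M = 1000 by default. Because per-trial drift
contributes a time-constant offset to m1 - m2 rather than temporal
modulation, this null is mildly conservative for A under strong drift —
verified empirically, and the safe direction for a false-positive
criterion.

## Encoding model

Counts in 20-ms bins over a per-trial window of -0.4 to +1.1 s around
stimulus onset are regressed on raised-cosine bases laid out in
log-warped time, `0.5 (1 + cos(pi (phi(t) - c_j)/d))` with
`phi(t) = log(t + 0.05)` and centres equally spaced in phi so the first
basis peaks at lag 0 and the supports tile the kernel span (the printed
form of the basis in the source literature is dimensionally ambiguous;
this is the standard raised-cosine/log-stretch construction and a unit
test asserts peak, support and coverage properties). Regressors:
left/right stimulus onset (5 bases / 400 ms, height scaled by
tanh(5c)/tanh 5), correct/incorrect feedback (5/400 ms), anticausal
left/right first-movement kernels (3/200 ms), an anticausal
movement-initiation kernel at every detected wheel-movement onset
(3/300 ms), the wheel-speed trace convolved with anticausal bases
(3/300 ms), and the block probability as a per-trial step. Fitting is
ridge with the intercept unpenalized, the penalty selected by 5-fold CV
over uniform-random (non-contiguous) trial folds from
{1e-2, 1e-1, 1, 10, 100}; each regressor group's contribution is
Delta R^2 = R^2_full - R^2_without_group, refit on the same folds with
the same selected penalty. Pair sensitivities are log10 |Delta R^2_A -
Delta R^2_B| for the left/right stimulus, left/right movement and
correct/incorrect feedback pairs. No significance is attached to
encoding scores (no convenient null exists); effect sizes only.

## Granger interactions

Whole-recording spikes binned at 12.5 ms are averaged across each
region's neurons (>= 10 required), cut into non-overlapping 10-s
segments, and the pair's cross-spectral density is estimated by
multitaper averaging (DPSS, NW = 3, K = 5 — the method's standard
defaults; configurable). Wilson's spectral matrix factorization
(S = psi psi^H, causal psi; iterative plus-operator algorithm, 30
iterations suffice at these spectra) yields the transfer function and
innovation covariance without an autoregressive fit, and the Geweke
measure per direction is averaged over the full positive-frequency
band into one score per directed pair. Significance: random segmentwise
swaps of the two region labels (M = 1000); across-pair correction is
Benjamini-Yekutieli (dependence among pairs sharing regions); sessions
combine by mean score plus Fisher. On a VAR toy with known coupling the
scores match the closed-form Geweke value and the direction is
recovered in >= 95/100 simulations.

## Aggregation

Fisher's method refers -2 sum log p to chi-square with 2k dof
(p clipped at 1e-300); FDR uses the statsmodels step-up
implementations. The comparison table min-max-normalizes effect sizes
to [0, 1] within each analysis (degenerate ranges map to all zeros) and
orders regions canonically, not by effect, for diffability.

## Problem sizes used by the test suite

The suite runs everything at desk scale, chosen as its own study
conditions: calibration uses 20 drift-only ensembles of 30 regions with
reduced null counts (M = 50), 140-trial sessions, 4 neurons/region for
the decoding and single-cell arms and 20 cells/region for the
trajectory arm; recovery uses 10^4 trials (action kernel), one
150 spikes/s neuron over 800 trials (encoding), 6000 stimulus frames
(RF), and 100 VAR simulations of 100 s at 80 Hz (Granger). Note that
at M = 50 the smallest achievable permutation p is 1/51 > 0.001, so no
neuron can pass the single-cell dual criterion in the reduced-M
calibration: its false-positive control holds trivially there; the
non-trivial behaviour of that pipeline is covered separately at
n_perm = 1500-3000 in the unit tests.

## Known limitations

* The decision policy is a stand-in; only the prior update rule is the
  modelled component. Fitted nuisance parameters are not interpretable.
* The generator's exponential rate link means the linear encoding model
  is misspecified in an amplitude-dependent way; weight recovery is
  meaningful at moderate log-gains (the noiseless distortion ceiling is
  corr ~0.996 at the amplitudes used).
* Imposter pools built from synthetic sessions share the generative
  process across "mice", which real imposters do not.
* The Granger score is bivariate; common input from a third region is
  not conditioned away.
* Latencies measured on the synthetic data are near zero by
  construction (event kernels start at lag 0); latency code is
  validated against closed-form curves instead.
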