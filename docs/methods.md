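# Methods

`bartstop` implements the analysis chain for a continuous-time balloon risk
task recorded with intracranial microelectrodes: task/behavior modelling, a
regularized Poisson GLM of single-unit spiking, LFP band-power and
time-frequency analysis with cluster-based permutation statistics, and a
Bayesian sparse proportional-hazards model predicting voluntary stop
decisions from neural band power. Because intraoperative recordings of this
kind are not publicly depositable, the package ships a synthetic-data
generator that emulates the statistical structure each analysis assumes;
all statistical guarantees quoted below are demonstrated on that generator.

## Task and behavior model

Balloons inflate at a constant value rate alpha = 30 points/s and pop at a
Gaussian time tau ~ N(mu, sigma^2) cued by color: red (3, 0.9^2) s, orange
(6.5, 1.95^2) s, yellow (10, 3^2) s. Stopping at time t banks alpha*t points
with probability equal to the survival function, so

    E[R | t] = alpha * t * (1 - Phi((t - mu) / sigma)).

`behavior.optimal_stop_time` maximizes this on (0, mu + 6 sigma] by a 1 ms
grid search with bounded golden-section refinement; the objective is cheap,
one-dimensional, and unimodal for mu > 0, so this sidesteps optimizer
tolerance disputes. The optimum is invariant to alpha (a positive scale on
the objective). For the three printed colors the optima are 2.322, 5.030,
and 7.738 s.

Gaussian pop times are truncated at zero by redrawing. For the task's
parameterizations (mu >= 3.3 sigma) redraws are vanishingly rare, so the
realized moments match the nominal ones. Control trials are assigned by
exact quota (25% forced; gray no-reward trials are a separate configurable
quota, default 10%) with a seeded shuffle, which makes control proportions
deterministic test targets rather than binomial draws. The inter-trial
interval (default 3 s) and trials per session (default 200) are not
properties of the task rules; they are configuration with documented
defaults.

## Spiking model

Spike counts in Delta-t = 50 ms bins are Poisson with log-rate

    log f = beta0 + beta . X + gamma * log(t - t0 + 1),

where X contains: a whole-trial indicator, disjoint inflation and outcome
indicators, an outcome-type indicator (no-points vs the banked reference),
and trial-type indicators (one per risk color, plus control) against the
inter-trial baseline reference. The last term is a power-law gain in
elapsed trial time, f proportional to (t - t0 + 1)^gamma; the natural log
is used (the exponent algebra is base-free). The trial indicator equals
inflation + outcome exactly, so the design is deliberately multicollinear —
handled by regularization, not orthogonalization.

Fitting minimizes the Poisson negative log-likelihood plus an elastic-net
penalty. No installed Python package provides a Poisson elastic-net *path*
with cross-validation, so the path solver is implemented here: IRLS with
covariance-method coordinate descent, warm starts along 100 log-spaced
lambdas from lambda_max (the smallest value zeroing all coefficients) down
to 1e-4 lambda_max, intercept unpenalized, columns standardized internally.
The unpenalized limit is verified against statsmodels GLM in the test
suite. Lambda and the mixing parameter are chosen by 10-fold
cross-validated Poisson deviance on seeded random partitions of bins
(temporal autocorrelation makes such folds optimistic; this mirrors the
standard practice for this analysis and is noted as a caveat). The 1-SE
rule returns the largest lambda within one standard error of the best mean
deviance; "min" and unpenalized fits are available for comparison. Unit
inclusion requires a session-average rate in [5, 100] spikes/s, bounds
inclusive. Effect sizes are (exp(beta)-1)*100 percent change from baseline;
the elapsed-time effect is ((t+1)^gamma - 1)*100 at a representative t = 5 s.
A shuffle control permutes bin order and refits; on simulated sessions it
yields zero surviving effects.

## LFP processing

Channels are common-average referenced (exact zero cross-channel mean),
band-passed with zero-phase 4th-order Butterworth filters into delta
(0.1-4), theta (4-8), alpha (8-13), beta (13-30), gamma (30-80) Hz (the
0.1 Hz delta edge is a high-pass/low-pass pair), downsampled to 200 Hz with
polyphase anti-aliasing, and converted to instantaneous power as the
squared magnitude of the analytic signal. Artifacts are detected as railing
(|x| >= 99.9% of the channel max sustained >= 50 ms) or aberrant power
(> 10 robust SDs above the channel median of 100 ms smoothed squared
signal), padded by a 100 ms guard; all thresholds configurable.

Peri-event traces take the median across events of log power, z-scored per
channel against the whole session (chosen over epoch-local statistics and
documented as such), so channels with different dynamic ranges average with
equal weight; an un-z-scored average is available for the contrast where
normalization qualitatively changes the sign of the beta-band effect.

Time-frequency maps use a complex Morlet wavelet with w = 9 cycles on 40
log-spaced frequencies from 2.5 to 50 Hz, computed by FFT convolution with
reflection padding; unit-energy normalization is used (the choice cancels
in all decibel-normalized outputs). Baseline normalization is
I = 10 log10(P(f,t)/P0(f)) with P0 the across-trials mean power per
frequency in B = (-1.5, -0.5) s before the event; condition contrasts are
10 log10(P1/P2) with no baseline.

## Cluster-based permutation statistics

Per pixel, a two-group F statistic (the squared pooled-variance t, df =
(1, n_a + n_b - 2)) compares decibel maps, with the pooled variance
replaced by its mean over a 5x5 pixel neighborhood (truncated at edges;
mean smoothing of the variance was chosen among the under-determined
variants). Pixels beyond the 0.9 / below the 0.1 quantile of the central F
law are grouped into 4-connected clusters per tail; cluster mass is
|sum log F| (positive in both tails for these deciles). The null is the
permutation distribution of the maximum cluster mass over *both* tails —
using one combined maximum rather than one per tail keeps the family-wise
error at the nominal level for the whole map (two per-tail nulls would sum
to ~2x nominal). Observed clusters are scored
p = (1 + #{null >= mass}) / (1 + n_perm) and retained at p < 0.05. On 500
null datasets (20 vs 20 maps of 40x80 pixels, 200 permutations) the
family-wise rejection rate is statistically indistinguishable from 0.05,
and an injected +3 dB block of 10x10 pixels is detected and localized in
over 95% of runs.

## Hazard model of stop decisions

Voluntary stopping is modelled in discrete trial time (40 Hz bins, matching
the decimated power grid) as a proportional-hazards process

    lambda_i(t) = h_i(t; m_i, s_i) * exp(mu + X(t) . beta),

with h_i the hazard of a normal event-time law per risk level i, computed
through the log survival function so the Mills ratio stays stable and
monotone to z >= 8. X(t) holds one regressor per (channel, band): the mean
over the trailing 0.5 s of standardized log power (mean of logs, not log of
means; the alternative is a flag), re-standardized over retained bins. Bins
run from trial start to the stop (event = 1 in the bin containing the stop
of a banked free trial) or to the pop (censored, all zeros); control trials
are excluded since voluntary stopping is undefined there, and only
within-trial bins enter the likelihood (h_i is defined in trial time). The
binary indicators are treated as Poisson counts with mean lambda*dt.

Priors: m_i ~ N(7.5, 5^2) s, s_i ~ half-N(5), mu ~ N(0, 2^2), and a
horseshoe on beta — non-centered, beta_j = z_j * lam_j * tau with z_j ~
N(0,1) and half-Cauchy(0,1) local and global scales — so irrelevant
channel/band regressors shrink toward zero while true effects escape.

Sampling uses an affine-invariant ensemble sampler (emcee) with
differential-evolution moves, 36 walkers per chain, initialized in a tight
ball at the posterior mode (L-BFGS on the log posterior), run as
independent ensembles ("chains") with the first half discarded and a
thinning fraction of 5. R-hat and bulk ESS are computed by treating each
walker as a chain (arviz); failures are listed in the fit's notes and
`converged` flag, never hidden. The intercept mu and the hazard-shape
parameters (m_i, s_i) trade off along a weakly identified ridge, which
dominates the autocorrelation time; coefficient marginals mix much faster
than the shape block, and short chains should be read accordingly. Rate
guards: |log s| <= 10, z <= 35, and eta clipped at exp(50) flag divergent
excursions as -inf rather than overflowing.

On simulated data the model recovers the ordering of risk-level locations
m = (3, 6.5, 10) s, shrinks all coefficients onto zero when the generative
beta is zero, and excludes zero for an injected coefficient of 1 (hazard x e
per regressor SD) at 300 trials. Effects are reported as
(exp(beta)-1)*100 percent hazard change per SD of the regressor.

The generative inverse (`synthetic_data.simulate_hazard_stops`) thins a
Bernoulli process at the same 40 Hz discretization, so fitted and generated
models share their time-discretization bias; the test oracle for the
stop-time law is the exact discrete implied event-time distribution.

## Synthetic data: what it does and does not emulate

The generator reproduces: Gaussian pop times per color, linear reward,
quota-based control trials, spike trains from the exact fitted GLM family
(including the power-law time gain), LFP as 1/f-spectrum background noise
(spectrally shaped white noise, exponent 1) plus band-limited sinusoids
whose amplitude ramps linearly ahead of voluntary stops, and stop times
from the hazard model with known coefficients. It does not emulate
pathophysiological beta bursting, cross-channel covariance structure,
non-stationary artifacts of the operating theater, or spike-sorting noise.
Passing tests therefore demonstrate correctness of the estimators under
the models' own assumptions — not robustness to the full messiness of
intraoperative recordings.

## Problem sizes and numerical choices

Simulated study sizes used in the test suite and acceptance script —
sessions of 200-300 trials, 20 replicates for GLM recovery, 500 null
datasets (200 permutations each) for cluster calibration, and hazard fits
of 4 chains x 500 iterations on ~50-80k bins — were chosen as the smallest
sizes at which the statistical claims are cleanly testable. Degenerate
inputs are handled explicitly: all-zero spike counts floor the baseline
rate at 1e-3 spikes/s; constant TFR maps receive a variance floor in the F
statistic; single-channel common-average referencing warns that it zeroes
the signal; hazard discretizations where lambda*dt > 1 in more than 1% of
bins abort with guidance to refine the grid.
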