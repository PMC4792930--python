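# Methods

`specdcm` implements a complete resting-state effective-connectivity
analysis: a spectral generative model of multichannel BOLD, its
inversion from empirical cross-spectra, Bayesian selection and averaging
over a constrained model space, and group-level statistics relating
connectivity to age and cognition. A seeded synthetic cohort generator
provides data with the statistical structure the analysis assumes, so
every stage can be validated end to end.

## Generative model

Neural activity in a network of `n` nodes follows linear stochastic
dynamics

    dx/dt = A x + v(t)

where `A` (Hz) is the effective-connectivity matrix. Self-connections
are parameterized as `A_ii = -0.5 * exp(a_ii)`: a log-scaling of a
-0.5 Hz reference rate, so that "stronger self-inhibition" is a positive
scalar and `A` cannot lose its negative diagonal during unconstrained
optimization. Off-diagonal entries are free coupling rates; a model is
admissible only while every eigenvalue of `A` has a negative real part.

The endogenous fluctuations `v` have node-wise power-law spectra
`g_v(w) = exp(alpha_v) * w^(-beta_v)` (`w` in rad/s), the standard
two-parameter description of scale-free neural noise. The exponent is
stored directly (not log-transformed); its reference value is 0.5, a
mildly 1/f-like spectrum, and both the priors and the synthetic
generator are centred there. Observation noise is a single global
power law `g_e(w) = exp(alpha_e) * w^(-beta_e)` added to every channel,
scaled by a fixed reference (1/128) that puts the in-band SNR well
above one at the reference parameters.

Each node's BOLD response comes from the balloon/windkessel model
linearized about its resting fixed point: vasodilatory signal with
decay rate `kappa = 0.64 * exp(decay)` 1/s and autoregulation
`gamma = 0.32` 1/s; blood flow; venous volume with transit time
`tau = 2 * exp(transit)` s and Grubb exponent 0.32; deoxyhemoglobin
with resting extraction fraction 0.4; and a BOLD readout with
`V0 = 0.04`, `k1 = 2.77`, `k2_eff = 0.4 * eps`, `k3_eff = 1 - eps`,
`eps = exp(epsilon)` the intravascular/extravascular mixing ratio
(3T coefficient values; all constants overridable through
`BalloonConstants`). The linearized transfer function is evaluated in
closed form as a cascade (flow, volume, dHb), which a unit test checks
against RK4 integration of the state equations to better than 2% L2
error (measured: ~1e-6 relative).

The predicted cross-spectral density is

    G_y(w) = K(w) (iwI - A)^-1 G_v(w) (iwI - A)^-H K(w)^H + G_e(w) I

with `K` the diagonal matrix of hemodynamic kernels. Convention: all
interfaces take frequencies in Hz; stored CSD values are two-sided
densities with respect to angular frequency (the per-Hz density is
`2*pi` larger). The analysis band is 32 linearly spaced frequencies
from the fundamental `1/(n_volumes * TR)` to 0.1 Hz, the conventional
upper edge of resting-state bandpass filtering.

Epsilon is treated as a global scalar (one per subject, not per node);
the observation-noise amplitude is likewise global. Both choices keep
the full 3-node model at 24 free parameters: 9 coupling, 6 fluctuation,
2 noise, 6 hemodynamic, 1 epsilon.

## Synthetic cohort

The generator emulates a population-based lifespan cohort: by default
200 subjects (602 by configuration) with ages uniform on [18, 88],
255-volume runs at TR = 1.97 s, and a 3-node between-network system.
Each subject's parameter vector is `baseline + slope * (age - 53) +
Gaussian jitter`, redrawn (up to 100 times) until stable. Default age
slopes per year follow the empirical aging picture: +0.003 on every
self-inhibition log-scaling, -0.002 on every decay-rate log-scaling
(slower vasodilatory decay, i.e. longer hemodynamic decay times),
+0.004 on one node's fluctuation exponent, -0.004 on one node's
amplitude, and ±0.002 on two couplings. Magnitudes were chosen once so
that the spread over 70 years stays within roughly two prior standard
deviations — detectable by regression at n = 200 yet not in conflict
with the shrinkage priors. Between-subject jitter: 0.03 (couplings,
self, hemodynamics), 0.05 (fluctuations), 0.02 (noise, epsilon).

BOLD is synthesized in the frequency domain: circularly-symmetric
complex Gaussian DFT coefficients coloured by an eigenvalue square root
of the predicted CSD at each positive frequency, Hermitian-symmetrized
and inverse-transformed. The population spectrum of the simulated
series therefore equals the model prediction exactly (no integrator
bias), and a fixed seed gives bit-identical series. An explicit
Euler–Maruyama integrator is not provided; the frequency-domain route is
cross-checked against Welch estimates (band means within ~2%) and
against the closed-form single-node spectrum.

Cognition: six scores (fluid intelligence, crystallized intelligence,
visual short-term memory, response consistency, multitasking, face
recognition) are generated as

    score_k = w_k * z(profile) * (1 + lambda * z(age)) + beta_k * z(age) + noise

where the connectivity profile is a configured linear map of the true
parameters (default: one coupling minus one self-connection),
`lambda = 0.3` is the age-moderation strength, `beta_k` are negative
age slopes, and the noise SD is 0.8 per score. The cognitive-score
covariance beyond this one-factor structure is not modelled (nothing
constrains it), which is the main respect in which the cognition data
are simpler than real batteries. Covariates: gender, handedness and
education are age-independent; head motion gets a small positive age
slope (+0.002 mm/year), mirroring why motion is controlled for.

What passing tests on this cohort do *not* show: robustness to
non-stationarity, motion artifacts, non-power-law neural spectra,
vascular heterogeneity beyond the balloon parameters, or sampling
biases of a real cohort — none of these are generated.

## Spectral estimation

Observed series are linearly detrended, standardized per channel, fit
with a least-squares multivariate autoregressive model (default order
8; statsmodels VAR, AutoReg for one channel), and the implied spectral
matrix `dt/(2 pi) H Sigma H^H` is evaluated on the analysis band and
rescaled to original units (so absolute scale is preserved despite the
standardization). The lagged design's condition number is checked
(error above 1e10). Against the generating model the estimate agrees to
~13-17% band-average relative error at 16,384 volumes — residual bias
reflecting the long-memory power-law dynamics, which matters for the
error model below. Functional connectivity is the Fisher-z transformed
Pearson correlation matrix, with hard errors on constant or duplicated
channels rather than infinities.

## Inversion

The observed CSD is stacked per frequency into real parts of the upper
triangle plus imaginary parts of the strict upper triangle. Priors are
Gaussian and diagonal: couplings N(0, 1/64), self log-scalings
N(0, 1/256), fluctuation/noise amplitudes N(0, 1/64), exponents
N(0.5, 1/64), hemodynamic log-scalings N(0, 1/256). A zero-variance,
zero-mean prior switches a connection off; switched-off entries are
excluded from optimization and restored as exact zeros with zero
posterior variance.

The error model is Gaussian with a single log-precision hyperparameter,
with two deliberate refinements, both adopted after measured failures
of the plain scheme on this estimator's output:

1. **Entry scaling** (`data_scaling="entry"`): each stacked value is
   divided by its natural scale — cross-spectral entries by
   `sqrt(S_ii(f) S_jj(f))` (a coherence scale), auto-spectral entries
   by their band-mean power (preserving shape information along
   frequency). Without it the largest low-frequency auto-spectral
   values dominate the single-precision likelihood and the estimator's
   sampling error masquerades as strong coupling evidence.
2. **Precision hyperprior**: the log precision gets a Gaussian prior
   with variance 1/128, centred where the residual variance would be
   `hyper_fraction = 1.0` times the band variance of the (scaled)
   observed spectrum. The centre depends only on the data, never on
   the model, so model comparison is unaffected by the choice. A pure
   maximum-likelihood precision lets richly parameterized models
   inflate the precision by absorbing spectral-estimation error, which
   defeats the Occam penalty entirely.

Optimization is Gauss–Newton ascent on the free energy with
Levenberg–Marquardt damping and strict step rejection: a candidate step
is kept only if F increases, otherwise the damping is quadrupled (up to
12 retries per iteration); accepted steps halve it. Jacobians are
central differences (step 1e-4) over a batched forward model.
Convergence: |dF| < 0.01 nats on 4 consecutive accepted steps, cap 128
iterations; a stall immediately after a sub-tolerance step also counts
as converged. The posterior is the Laplace approximation at the final
iterate, symmetrized with a PSD eigenvalue floor. The accepted-step F
sequence is non-decreasing by construction and asserted in tests.

The standalone `free_energy` operation reports the simpler
point-estimate quantity (prior covariance, ML precision, no scaling or
trace terms); `invert`'s internal objective adds the Gauss–Newton
expectation terms, the scaling and the hyperprior penalty.

Variance explained is `1 - sum|obs - pred|^2 / sum|obs - band-mean|^2`
over the stacked parts on the *raw* (unscaled) spectrum, band-mean
taken per matrix entry, clipped to [0, 1]. Subjects are retained
regardless of convergence; only fits with variance explained below 0.1
are flagged for exclusion from group statistics.

**Bayesian model reduction.** `reduce_model` scores any reduced model
(connections switched off) analytically from the full-model posterior
via the Gaussian evidence-ratio identity, returning the evidence change
and the reduced posterior. Scoring the space this way — rather than
refitting each model — removes the advantage dense models gain from
fitting the estimator's systematic misfit, and is how the model-space
stages of the pipeline and the model-recovery validation operate
(measured on synthetic groups: per-model refitting recovered the
generating model in 0/10 replicates; full fit + reduction in 7/10).
Per-model refitting remains available (any switched-off prior).

## Model space

All `2^(n*n)` binary adjacency patterns (guarded to n ≤ 5), filtered
by: mandatory self-connections; connectedness, read as "no node lacks
both incoming and outgoing between-node links" (the weakest reading —
and for n = 3 the only one that leaves 54 of the 512 models; stronger
weak/strong digraph readings are available as options); optional
sagittal symmetry under a left/right relabelling; homotopic pairs
constrained to bidirectional-or-absent; and required links. Filtering
is idempotent and the output order is lexicographic. Working subsets
(e.g. 8 of 54 for fast studies) are taken evenly spaced through the
filtered list, always including the full model.

## Model comparison and averaging

Fixed-effects selection: softmax of free energies summed over subjects.
Random-effects selection (pipeline default, matching the use of
exceedance probabilities): variational Dirichlet updates over subject-
wise model posteriors with `alpha0 = 1`, exceedance probabilities by
seeded Monte-Carlo (default 1e6 draws, chunked). BMA is deterministic
moment matching — mixture mean and mixture variance per parameter, with
an optional Occam window in nats — weighted per subject by posterior
model probabilities; parameters absent from a model contribute zeros.

## Group statistics

All regressions are on standardized variables. Age prediction is OLS of
z(age) on z(parameters) plus covariates, reporting the multiple
correlation R and per-coefficient 95% CIs. CCA is computed by SVD of
the ridge-guarded whitened cross-covariance; variates are unit
variance, each weight vector's largest-magnitude element is positive,
and structure correlations (variable-variate correlations) flag
|r| < 0.3 as low contribution. Inference on the first canonical pair is
by row permutation of Y (default 1000 permutations, seeded), with
Bartlett's chi-square as the analytic secondary. The moderation model
regresses the cognitive variate W1 on age, the connectivity variate V1,
their product (formed from standardized terms), and covariates; because
canonical signs are arbitrary, V1 is flipped if corr(V1, W1) < 0 so the
interaction sign is interpretable. Age groups for simple slopes are
tertiles. Multiple-testing control is Benjamini–Hochberg across the
multivariate analyses. Complete cases only, with logged exclusion
counts. The functional-connectivity reanalysis runs the identical code
path on Fisher-z values.

## Validation problem sizes

The test suite and `scripts/acceptance.py` validate at sizes chosen for
a single CPU: 20 replicates for parameter recovery at 255 volumes
(mean coupling correlation ~0.93, threshold 0.6), 10 replicates of
20-subject groups over an 8-model subset for model recovery, a
602-subject cohort for the full pipeline statistics and the variance-
explained diagnostic (median ~84%, threshold 75%), 16,384 volumes for
spectral consistency, and 100 repeats at 199 permutations for null
calibration of the CCA p-value.

## Known limitations

Single-state linear nodes (no bilinear or two-state variants);
stationary connectivity (no time-varying coupling); global epsilon and
observation-noise amplitude; MAR spectral estimation inherits a
long-memory bias of order 15% band error that the error model absorbs
rather than removes; the plausibility rules for 4-node lateralized
spaces produce whatever count the stated rules imply — the package logs
its counts and does not hard-code expectations for them.
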