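# Methods

`gripdcm` re-implements, end to end, a spectral dynamic-causal-modelling
analysis of effective connectivity in a five-source cortical "grasping
network" (IPL, M1, PMv, SMA, DLPFC) during a visually guided precision-grip
task, and validates every stage on synthetic cohorts whose generative
structure matches the assumptions of the analysis. This note documents the
models, the numerical choices, and what the synthetic validation does and
does not establish.

## Behavioural scoring

Precision-grip performance is the root-mean-square error (RMSE) between the
force trace and the horizontal target line at 10 % of maximal voluntary
contraction, computed over the full 120-s trial with no trimming. Scores are
`−ln(RMSE)` (natural log; reverse-coded so higher = more precise). Group
differences use a classic pooled one-way ANOVA — matching a between/within
degrees-of-freedom split of (k−1, n−k) — and pairwise pooled-variance
two-sample t-tests with df = n₁+n₂−2, Holm step-down adjusted. The df
convention is stated in the output because alternative conventions
(Welch-corrected df) exist in the literature.

## Spectral data features

Multichannel recordings are mean-removed and projected onto their leading
left singular vectors (orthonormal, variance-ordered spatial modes; default
4 modes). Cross-spectral densities are estimated on a 1-Hz grid over
4–48 Hz (45 bins) either from a least-squares multivariate autoregression
(default order 8; analytic spectrum of the fitted model, flagged as an
error when the companion matrix has a root on or outside the unit circle)
or by Welch's averaged periodogram (Hann window, 1-Hz resolution, 50 %
overlap). All spectra follow the one-sided convention of
`scipy.signal.welch` with `G[i, j] = E[X_i · conj(X_j)]`; matrices are
projected onto the Hermitian subspace so `G(f) = G(f)ᴴ` holds exactly.
A least-squares rather than Bayesian autoregression is used because the
estimator only provides data features, not inference, at this stage; the
two estimators agree within sampling error on long stationary series and
this is asserted by a test.

## Generative model

Each source is a convolution-based neural mass with three populations
(spiny stellate, inhibitory interneuron, pyramidal). Membrane potentials
obey second-order synaptic dynamics `v̈ = (H/τ)·m − (2/τ)·v̇ − v/τ²` with
excitatory kernel (τ_e = 4 ms, H_e = 8 mV) and inhibitory kernel
(τ_i = 16 ms, H_i = 32 mV); pyramidal cells carry separate excitatory and
inhibitory compartments, giving 8 states per source (40 in total). Firing
rates are a centred sigmoid of potential, taken as `s·tanh(v)`; the slope
at the operating point defaults to s = 0.175, chosen once so that the
default network is comfortably stable (largest Jacobian eigenvalue real
part ≈ −11) while extrinsic couplings remain clearly identifiable in the
predicted spectra (a 0.3 log-scaling perturbation of any single edge moves
the spectra by 0.7–5 % in Frobenius norm). Intrinsic gains are
γ = 128·[1, 0.8, 0.25, 0.25].

The network has 14 extrinsic connections: backward DLPFC→PMv, DLPFC→SMA,
PMv→M1, SMA→M1, PMv→IPL, SMA→IPL; forward connections in the reverse
directions; and reciprocal lateral PMv↔SMA. Forward connections drive
spiny-stellate populations, backward connections drive pyramidal and
inhibitory populations, lateral connections drive all three. Each edge's
strength is baseline × exp(θ) with baselines 32 (forward), 16 (backward),
4 (lateral), so the free coupling parameters θ are unit-less log-scalings
with zero-mean Gaussian priors (variance 1/8).

The operating point is fixed at the origin with the centred sigmoid — no
root-finding — matching the linear-systems treatment of stationary
spectra. Predicted cross-spectra follow from the transfer function
`T(f) = C(2πif·I − J)⁻¹B` evaluated by a direct (batched) resolvent solve
per frequency bin: `G_y = L·T·G_u·Tᴴ·Lᴴ + G_n`, with innovations
`g_u(f) = exp(a1)·f^(−exp(a2))` per source entering at the stellate
populations. The innovations exponent prior is centred at a2 = −32, i.e.
exp(a2) ≈ 10⁻¹⁴ — a flat innovations spectrum rather than the 1/f shape
used for resting-state data, appropriate for task data whose spectra do
not follow 1/f. Observation noise is a channel-specific plus a common
power-law term. The lead field is a synthetic fixed-gain matrix (smooth
random mixing, unit-norm columns, fixed seed) standing in for a
volume-conduction head model, which is out of scope; it is configuration
shared between data generation and fitting. Source coordinates are stored
as configuration only.

Time-series simulation samples the stationary solution of the linearized
stochastic system directly in the frequency domain (circulant embedding):
complex-Gaussian innovations with density g_u are pushed through T(f) and
the lead field and observation noise is added, so the Welch spectrum of
the output converges to the analytic prediction by construction. This is
an exact sampler for the stationary Gaussian process, not a time-stepping
integrator; a test verifies the empirical-to-analytic agreement.

## Variational Laplace inversion

Observed spectra are vectorized (real upper triangle including the
diagonal, then strict-upper imaginary parts, per bin; imaginary diagonals
are identically zero and dropped) and modelled as prediction plus i.i.d.
Gaussian error with precision exp(λ). The data vector is rescaled to unit
root-mean-square, with the same factor applied to predictions, so the
noise hyperprior refers to a common scale across subjects and models; the
default hyperprior on λ is N(hE = 18, hC = 1/128) — a deliberately high
prior log precision with a single precision component across modes and
bins. Free parameters by default are the couplings and the spectral
nuisance parameters; intrinsic mass constants are fixed (configurable).

Optimization alternates (i) closed-form Newton updates of λ (with its
Laplace variance) and (ii) Levenberg-Marquardt steps on the parameter
mean, with the posterior covariance `Σ = (exp(λ)JᵀJ + Π₀)⁻¹` at each
iterate. Jacobians are central finite differences (step 10⁻³ in
log-scaling units; robustness preferred over speed at desk scale), with
all perturbed models evaluated in one batched resolvent solve. A step is
accepted only if the full free energy — including the `tr(JΣJᵀ)` expected
log-likelihood correction, which makes F exact for linear models —
increases; damping doubles on rejection and halves on acceptance, and
proposals that destabilize the network count as rejections. Convergence:
|ΔF| < 0.01 over 4 consecutive iterations, 64-iteration default cap.
Initialization is at the prior mean; an optional multistart flag exists.
Variance explained is `100·(1 − SS_res/SS_tot)` over the concatenated
real and imaginary parts with an uncentred total sum of squares.

## Model comparison

The hidden-IPL control model removes every extrinsic edge touching the
IPL while keeping the source in the dynamics and lead field, so both
models explain the same data dimensionality. Random-effects BMS uses the
variational Dirichlet scheme (uniform prior counts α₀ = 1, log-sum-exp
normalized responsibilities). Exceedance probabilities use the exact Beta
tail for two models and seeded Monte-Carlo Dirichlet sampling (default
10⁶ draws) otherwise. The Bayes omnibus risk is
`1/(1 + exp(F_RFX − F_null))` with both free energies from the
variational scheme, and the protected exceedance probability is
`(1−bor)·xp + bor/K`. Probabilities are reported unrounded. Note the
free-energy BOR approaches 1 only asymptotically in the number of
subjects when evidences are identical (≈ 0.85 at n = 12); the symmetric
pxp = 1/K holds exactly regardless.

## Parametric empirical Bayes

Only the 14 extrinsic couplings go to the second level. Because
first-level posteriors are Gaussian, each subject's evidence as a
function of its coupling prior is available in closed form (Bayesian
model reduction, BMR), so each fit is summarized by the implied data
precision `Λᵢ = Σᵢ⁻¹ − C₀⁻¹` on the coupling sub-block (eigenvalue-floored
for data-uninformed directions) and the de-shrunk estimate
`tᵢ = Λᵢ⁻¹(Σᵢ⁻¹μᵢ − C₀⁻¹μ₀)`. The hierarchy
`θᵢ = Xᵢβ + εᵢ, εᵢ ~ N(0, exp(−γ)I), β ~ N(0, B)` is then a conjugate
Gaussian GLM given γ: the β posterior is closed-form and the second-level
free energy is exact, so empirical Bayes reduces to a one-dimensional
optimization of γ (coarse grid plus bounded Brent; the accepted-F trace
is monotone by construction). The β prior variance defaults to the
first-level coupling prior variance (1/8); γ has a Gaussian prior
N(4, 1/64) in log space. γ is treated as a point estimate with its prior
density included in F.

The design matrix is [intercept, mean-centred performance, mean-centred
ordinal age-group code (1–4), re-centred product of the two centred
columns]; a dummy-coding alternative is available by flag. Ordinal coding
is the default because the group analysis reports one group effect per
connection.

BMR scores any combination of second-level effects switched off (prior
variance pinned to 10⁻⁸, mean 0). With ≤ 8 free effects the 2^k model
space is searched exhaustively; otherwise effects are ranked by the
evidence change of removing each alone, the 8 least-contributing are
searched exhaustively, effects switched off in the winning model are
pruned, and the loop repeats until nothing is pruned (ties broken by the
fixed regressor-major, canonical-edge ordering). The final ≤ 256 models
are averaged with softmax evidence weights (models more than 20 nats
below the best are dropped; their weight is ≤ e⁻²⁰); the posterior
probability of an effect is the summed weight of models containing it,
thresholded at pp > 0.95 (strict). Subject-level estimates are then
re-referenced by BMR to empirical priors centred on the group prediction
Xᵢβ with covariance `exp(−γ̂)·I + Xᵢ Σ_β Xᵢᵀ`. In the infinite
between-subject-variance limit this returns the de-shrunk (likelihood)
estimates, which coincide with the first-level means exactly when the
first-level prior is weak.

## Prediction

Leave-one-out cross-validation throughout. Regression: per-fold OLS of
the target (performance, or age in months) on the 14 extracted couplings
plus intercept, with a ridge fallback (and a warning) on rank-deficient
folds. Both r² conventions are reported: the squared Pearson correlation
between predicted and observed (headline, matching the
"association between actual and predicted" convention) and 1 − SSE/SST.
Classification: QDA with class-specific covariances shrunk by
`Σ_k + 10⁻⁶·tr(Σ_k)/p·I` (class sizes of ~19–28 with 14 features are
near-singular), priors equal to training class frequencies; accuracy with
an exact (Clopper-Pearson) 95 % CI and a one-sided exact binomial test
against the no-information rate, i.e. the largest class share (28/88 at
the study composition). A normal-approximation baseline test would give a
different p-value; the exact tail is reported.

## Synthetic cohorts

The generator inverts the second level's own generative assumption:
couplings are `θᵢ = Xᵢβ + εᵢ` with the design built by the same
conventions as the analysis, between-subject sd 0.05, and planted effects
of magnitude 0.3 that qualitatively mirror the study findings
(performance → ±0.3 on the PMv↔IPL loop; age → +0.3 on backward SMA→IPL;
interactions → +0.3 on forward PMv→DLPFC and backward SMA→M1;
commonalities zero). Default group sizes are 22/19/19/28 (total 88);
group performance means (0.30/0.50/0.60/0.80, sd 0.25) improve into
adulthood and yield behavioural ANOVA F statistics of the same order as
the study's; ages in months are drawn per group as 108±7, 156±7, 206±7,
301±34. Spectra are the model prediction at the true couplings plus
Hermitian complex-Gaussian noise of relative scale 0.005 (rms-referenced);
unstable coupling draws are resampled up to 10 times. Force traces are
the target line plus 1/f-plus-white noise (100 samples/s, 120 s, default
half the noise power in the 1/f component) scaled so behavioural scoring
recovers the planted score exactly. All randomness descends from a single
seed via spawned generators, so identical configs reproduce identical
cohorts.

What the synthetic validation shows: that the full chain — inversion,
model selection, PEB/BMR, prediction — recovers the structure it assumes,
with correct sign and calibrated-enough uncertainty, at study-like sample
sizes. What it does not show: robustness to model misspecification (real
EEG has artifacts, non-Gaussian noise, volume conduction through a real
head model, and sources outside the network), since the generator and the
fitted model share the same family by design.

## Problem sizes and iteration caps

Simulation-heavy checks run at desk scale, as the package's own choice of
problem size: recovery simulations use 10 cohorts of 40 subjects with the
inverter capped at 10 iterations (patience 2) and couplings-only free
parameters; the model-comparison analog uses 16 subjects at a 16-iteration
cap. At these caps subject fits converge to the same optima as the default
settings on these data (the free-energy trace is flat well before the
cap); the caps are exposed as options, not hard-coded. The analysis
drivers under `analysis/` run the full 88-subject cohort at a 16-iteration
cap.

## Known limitations

- The inverter's single precision component treats all vectorized
  spectral elements as equally noisy; Hermitian noise makes diagonal
  elements twice as variable as off-diagonals, so posterior uncertainty
  is approximate (the credible-interval coverage test uses an adaptive
  noise hyperprior).
- γ (between-subject precision) is a point estimate; its posterior
  uncertainty is not propagated into β.
- The greedy search reproduces the exhaustive result exactly only for
  ≤ 8 effects; beyond that it is the standard iterated block
  approximation.
- The synthetic lead field is not a physical head model; coupling
  estimates are identifiable relative to it, not to scalp anatomy.
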