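# Methods

This note documents the models, numerical choices and limitations of
`spectraldcm`.  Everything quantitative stated here is computed by the test
suite or by `scripts/acceptance.py`; nothing is quoted from external
analyses.

## Generative model

Neuronal dynamics are linear and stochastic: `dx/dt = J x + v`, with the
effective Jacobian `J` built from directed coupling rates (Hz, column →
row) and self-connections `-0.5 exp(s_i)`.  The log-scaling `s_i` keeps
self-connections strictly inhibitory for any real value, and at `s = 0`
with zero couplings the system is stable with a 0.5 Hz decay per region.
Linearization makes the stationary cross-spectral density available in
closed form, which is what permits fitting in the spectral domain; the
price is that state-dependent (bilinear) effects and task inputs are out
of scope.

Neural fluctuations and observation noise have power-law spectra
`g(f) = alpha f^-beta`.  Amplitudes are region-specific and exponents
shared across regions (one `beta_v`, one `beta_e`); this resolves an
ambiguity in the model class with the most common convention and keeps the
parameter count linear in `n`.  All rate and amplitude parameters are
optimized as log-deviations from canonical values so positivity is
structural.

The hemodynamic stage is a linearized two-parameter kernel per region: a
difference of exponentials with decay rate 0.64 s⁻¹ and transit rate
0.5 s⁻¹, normalized to unit gain at zero frequency,

    h(t) = κγ/(κ−γ) (e^{−γt} − e^{−κt}),    H(f) = κγ / ((κ+2πif)(γ+2πif)).

It is smooth, low-pass, exactly canonical at zero log-deviations, and its
analytic transform agrees with the discrete transform of the sampled
kernel to <1% on the default grid (tested).  A full nonlinear balloon
model would change the phase detail of the gain but not the structure of
the analysis; the two free parameters per region (decay and transit
log-deviations) capture the dominant subject-to-subject kernel variation.

**Canonical noise scales.** `alpha_v = 0.06`, `alpha_e = 0.03` (both with
canonical exponent 1) were chosen once so that, at the prior mean, the
modeled region variance over the default band is ≈1 — matching time
series standardized to unit grand variance — with a 4:1
neural-to-observation variance ratio, a realistic signal-to-noise regime
for ROI-averaged BOLD.

**Frequency grid.** 32 log-spaced points from 1/128 Hz (the conventional
high-pass cutoff) to 0.2 Hz (Nyquist for TR 2.5 s).

## Data features

Cross-spectra are estimated by a multivariate autoregressive (MAR) model
of fixed order 8, fitted by least squares with a ridge of 1e−6 times the
mean predictor variance, and evaluated as `S(f) = TR · A(f)^{-1} Σ A(f)^{-H}`.
A parametric estimator is essential at ~90-scan run lengths where raw
periodograms are unusable; the order is fixed rather than data-driven for
reproducibility and is exposed in the configuration.  Estimated spectra
are Hermitian and positive semidefinite by construction and verified
against closed-form AR spectra and white-noise coherence in the tests.

Time series are standardized before estimation: columns centered, then
divided by one grand standard deviation so relative amplitudes between
regions are preserved (they inform region-specific fluctuation
amplitudes).

**Effective degrees of freedom.** The MAR spectrum is a smooth function of
`order·n² + n(n+1)/2` fitted statistics, while the feature vector (real
and imaginary parts over 32 frequencies) is several times longer.  An
estimated `CrossSpectra` therefore carries its effective dof, and the
inversion tempers the likelihood by `min(1, dof/N_features)`.  Without
this, first-level posteriors are overconfident and the group level sees
subject noise as signal; with it, null cohorts are calibrated (tested:
false severity retentions in ≤2 of 20 null replicates).

## Variational-Laplace inversion

The posterior is Gaussian; the free energy `F = accuracy − KL(q‖prior)` is
maximized by damped Gauss–Newton on the mean with Levenberg–Marquardt
damping and step-halving: a proposal is accepted only if its fully
refreshed free energy does not decrease, so the trace over accepted steps
is nondecreasing by construction.  Residual precisions (one for the real
part, one for the imaginary part of the features) are updated in closed
form between steps, with an upper bound of 1e10 so that noise-free
self-consistency problems stay finite.  Convergence: |ΔF| < 0.01 on three
consecutive accepted steps, or 128 iterations (flagged, not fatal).
Gradients and curvatures use central finite differences (step 1e−4 in the
packed space); with ≤ ~35 parameters this is cheap and avoids hand-derived
gradients of the rational spectral model.  The posterior covariance is the
inverse curvature at the optimum, eigenvalue-clipped at 1e−8.  Inversion
is fully deterministic: identical inputs give bit-identical results.

Priors (diagonal): couplings N(0, 1/64); self log-scalings and
hemodynamic log-deviations N(0, 1/256); log-amplitudes and exponent
deviations N(0, 1/64).  Initialization at the prior mean; no random
restarts.

Known biases: at short run lengths (~91 scans) the MAR spectrum is biased
at the lowest frequencies and the inversion partially compensates by
inflating self-decay and attenuating couplings; coupling *correlations*
with truth remain high (the recovery benchmark at 2¹² scans achieves
median r ≈ 0.91 across 20 replicates), but absolute coupling magnitudes
can be over- or under-estimated by a factor of ~2.  Group-level covariate
slopes inherit this scale bias; their signs and detection are what the
package's tests guarantee.

## Parametric empirical Bayes

Subject parameters (all couplings, including self-connections; noise and
hemodynamic parameters stay first-level) enter a linear-Gaussian second
level `theta_i = (x_i ⊗ I) β + ε_i`, `ε ~ N(0, e^{-γ} I)`.  Each subject
contributes the *likelihood* implied by their posterior/prior pair
(precision difference); directions where the posterior is no tighter than
the prior are projected out so the likelihood stays normalizable.  Given
γ everything is conjugate, so the evidence is closed-form; γ (single
shared random-effects component, hyperprior N(0, 2²) on the log-precision)
is optimized by bounded scalar search on [−8, 8].  Group-effect priors are
N(0, 1/16) per effect.  Design columns: group mean, then mean-centered
severity and age, then sex and (follow-up only) treatment coded ±0.5 so
the mean column stays interpretable.

Model reduction uses the analytic Gaussian identity, exact at this level;
pruning shrinks an effect's prior variance to 1e−8 (a soft zero that keeps
all matrices full-rank).  The greedy search prunes the best single effect
while evidence improves, then enumerates all 2^k prior combinations over
the k ≤ 8 effects whose final decisions were least decisive (smallest
|evidence change when flipped|), with ties broken in packing order.
Bayesian model averaging weights this model set by softmax of free
energies; an effect's posterior probability Pp is the total weight of
models in which it is free, and the retention threshold is Pp > 0.95.
Effects pruned before the neighborhood stage have Pp = 0 exactly; this
model-weight definition of Pp is a declared choice.

## Leave-one-out prediction

For each held-out subject, the group model is refitted on the rest, and
the held-out centered severity score is a latent variable with the
training scores' empirical mean and variance as its prior.  Conditioning
on the subject's connectivity likelihood is closed-form; group effects
enter by their posterior means by default (a flag enables moment-matched
marginalization over the group-effect posterior).  Predictive validity is
the Pearson correlation between predictions and actual scores with a
one-tailed p-value via the t-transform — one-tailed because only a
positive out-of-sample correlation evidences predictive validity.
Connections are selected once from the full-sample analysis (the
thresholded severity effects), not re-selected inside each fold; this
mirrors the standard procedure but carries an optimism risk for the
selected-connection correlation, which is why the null calibration is
tested with permuted severity scores.

## Synthetic cohorts

The generator emulates the study conditions: 2–4-region sensorimotor
networks, 4-minute runs at TR 2.5 s (91 scans after discarding the first
five), severity scores spanning the mild-to-moderate range (patients
10–30, controls 0–9, ~70% patients), age ~N(33, 9²) truncated to 18–55,
~73% female, optional 50/50 treatment.  Subject couplings are the group
mean plus centered-covariate effects plus N(0, 0.1²) between-subject
variation, resampled (≤100 tries) until stable.  Default group-mean
patterns encode excitatory-forward/inhibitory-backward coupling in
sensory networks and the reverse in motor networks, as sign-convention
fixtures.  BOLD is generated by Euler–Maruyama at dt = 0.1 s (integrated
exactly per eigenmode by linear filtering), with power-law fluctuations
synthesized by frequency-domain shaping (exact target spectrum in
expectation; DC excluded), hemodynamic convolution, downsampling to TR, a
60 s burn-in, and power-law observation noise added on the TR grid.  The
average periodogram of simulated runs matches the closed-form spectra
within 10% band-averaged (tested with 50 seeded runs).

Because detection of per-BDI-point slopes of ~0.01 from 91-scan runs with
20 subjects is genuinely underpowered, recovery-oriented tests use the
generator's long-run setting (2¹² scans) and/or 40 subjects, and
group-level calibration tests use `emulate_first_level`, which constructs
coherent synthetic first-level posteriors (a Bayesian update of the prior
with a noisy measurement of each coupling) instead of paying for hundreds
of inversions.  What passing tests show: the chain recovers directed
couplings, covariate effects and their signs, and is calibrated under the
null, under the statistical structure the model assumes.  What they do
not show: robustness to nonlinear hemodynamics, non-power-law
physiological noise, motion artifacts, or regional timing confounds —
none of which the generator emulates.

## Pipeline

Runs are reproducible from config + data alone; reports are byte-identical
across repeated runs (timings go to `run.log`, never into reports).
Subjects failing inversion (exception or non-convergence) are excluded per
network with a logged reason.  Multiple-comparison handling beyond the Pp
threshold is deliberately absent (Bayesian reporting); LOO p-values are
reported raw.  The problem sizes used by the acceptance script — 50
Monte-Carlo runs, 20 inversion replicates, 20+20 group-level replicates,
10+20 LOO cohorts, one 20-subject end-to-end run — were chosen as the
smallest sizes at which the binomial/median summaries are stable.
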