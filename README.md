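# spectraldcm

Effective-connectivity analysis of resting-state BOLD time series by
spectral dynamic causal modeling (DCM), with group-level parametric
empirical Bayes (PEB), Bayesian model reduction (BMR) and leave-one-out
(LOO) covariate prediction.

The package is aimed at researchers who want to ask directional questions
about small brain networks — e.g. whether top-down (backward) and bottom-up
(forward) influences between hierarchically organized sensorimotor regions
differ in strength and sign, and whether those influences covary with a
clinical score such as depression severity — without access to heavyweight
neuroimaging toolchains.  It operates on plain text region time series
(TSV) and covariate tables (CSV), and ships a seeded synthetic-cohort
generator so every stage can be validated against known ground truth.

## The model

Neuronal dynamics in an *n*-region network are linear and stochastic,

```
dx/dt = J x(t) + v(t)
```

where the off-diagonal entries of `J` (Hz) are directed coupling rates
(column → row) and the diagonal is the self-inhibition `-0.5 exp(s_i)`.
Neural fluctuations `v` and observation noise `e` have scale-free spectra

```
g_v(f) = alpha_v f^-beta_v        g_e(f) = alpha_e f^-beta_e
```

and the observed BOLD signal `y = h(x) + e` follows a linearized
hemodynamic kernel.  The model is fitted not to the time series but to
their second-order statistics: the complex cross-spectral density

```
G_y(f) = D(f) H(f) G_v(f) H(f)* D(f)* + G_e(f),    H(f) = (2πi f I − J)^-1
```

with `D(f)` the diagonal hemodynamic gain.  A Gaussian posterior over all
parameters is optimized by variational Laplace (free-energy maximization);
subjects are combined in a hierarchical linear model over their coupling
posteriors (PEB) with covariates [mean, severity, age, sex, optionally
treatment]; group effects are pruned by BMR, averaged by model evidence
(BMA) and thresholded at 95% posterior probability; and predictive validity
is assessed by leave-one-out prediction of the severity score, scored by
the Pearson correlation between predicted and actual scores.

## Worked example

Simulate a 20-subject motor-network cohort in which severity increases the
backward SMA→MC coupling and decreases the forward MC→SMA coupling, then
run the full chain:

```
spectraldcm simulate --config cfg.yaml --subjects 20 --scans 4096 \
    --effect "bdi:SMA<-MC:0.012" --effect "bdi:MC<-SMA:-0.012"
spectraldcm all --config cfg.yaml
```

with `cfg.yaml`:

```yaml
networks: [left_motor]
data_dir: data
out_dir: results
seed: 0
```

The run prints the LOO table and writes `results/summary.txt`, which for
this configuration reads (output of the code, abbreviated):

```
network: left_motor
  subjects included: 20
  minimum variance explained by the model fit: 93.13%
  mean: connections at Pp > 0.95:
    MC -> SMA: -0.3319 (inhibitory, Pp=1.000)
    SMA -> MC: +0.2598 (excitatory, Pp=1.000)
    ...
  bdi: connections at Pp > 0.95:
    MC -> SMA: +0.0275 (excitatory, Pp=1.000)
    SMA -> MC: -0.0193 (inhibitory, Pp=1.000)
  age: no connections at Pp > 0.95
  sex: no connections at Pp > 0.95
```

and `results/loo.csv`:

```
network,correlation,p_value,note
left_motor,0.7184,0.00018,
```

Reading: the group-mean forward coupling (MC → SMA) is inhibitory and the
backward coupling excitatory — the motor-network pattern encoded by the
generator; the severity covariate pushes both in the opposite direction,
with the generated signs recovered; age and sex (generated without
effects) retain nothing; and holding each subject out in turn, their
severity score is predicted from the two retained couplings with
out-of-sample correlation r = 0.72 (one-tailed p = 0.0002).

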