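# Methods

This note documents the models, algorithms and numerical choices behind
`treolss`, in the spirit of a pharmacometric analysis report: what is
assumed, what is estimated, and what the synthetic experiments do and do
not demonstrate.

## Structural and statistical model

Treosulfan disposition after intravenous infusion is described by a linear
two-compartment model with zero-order input at rate `D / t_inf` into the
central compartment and first-order elimination from it. The closed-form
solution is the standard bi-exponential infusion expression built from the
micro rate constants `k10 = Cl/V1`, `k12 = Q/V1`, `k21 = Q/V2` and the
disposition exponents `alpha > beta` (roots of
`s^2 - (k10+k12+k21) s + k10 k21`). The implementation handles the
one-compartment limit `Q = 0` exactly and guards the (measure-zero)
repeated-root case; it is verified against an adaptive ODE integration to
a relative tolerance of 1e-6 over random parameter sweeps.

Individual parameters are log-normal around allometrically scaled typical
values referenced to 70 kg:

    theta_i = theta * (BW_i / 70)^beta * exp(eta_i)

with fixed exponents `beta = 0.75` for clearance and `1` for the two
volumes; the intercompartmental clearance Q carries interindividual
variability (IIV) but no bodyweight effect (adding one worsened the
original model fit). The initially estimated exponents (0.804 / 0.959 /
0.925) can be restored through the model configuration, but are not the
default. Random effects are trivariate normal on the log scale for
(Cl, V1, Q), with a single free correlation between `eta_Cl` and `eta_V1`;
`eta_V2` is fixed at zero. Residual variability is proportional,
`C_obs = C_pred (1 + eps1)`, `eps1 ~ N(0, b^2)`; additive and combined
error models are implemented for the model-building harness.

The packaged default configuration (`treolss/data/final_model.yaml`) holds
the final pediatric estimates: Cl 14.7 L/h/70 kg, V1 26.0 L/70 kg,
Q 2.25 L/h, V2 9.93 L/70 kg, IIV 25.5 / 51.4 / 38.6 %, corr(eta_Cl,
eta_V1) = 0.714, b = 0.188. The IIV correlation entry reported as
"71.4 %" is interpreted as the correlation coefficient (the reporting
convention of the estimation software), not a covariance.

For a linear system the exposure is `AUC(0-inf) = D / Cl`, which is also
the quantity every limited sampling strategy ultimately predicts.

## Virtual pediatric cohort

The simulator emulates the covariate and design structure of the study
population:

* **Bodyweight**: Normal(26.9, 15.7^2) kg truncated to [5, 55] kg. The
  stated moments are the real cohort's; the bounds bracket the realized
  range of the published virtual cohort. Truncating this very wide normal
  necessarily shifts the mean of generated cohorts up to ~28.2 kg and
  shrinks the SD to ~13.4 kg; no truncation of the stated normal can
  reproduce the published realization (26.26 +/- 16.54) in expectation, so
  this residual mismatch is a property of the design, not a bug.
* **Body surface area** from the weight-only power formula
  `BSA[cm2] = 4.688 W[g]^(0.8168 - 0.0154 log10 W[g])` (~1.85 m2 at 70 kg,
  ~0.97 m2 at 26.9 kg).
* **Dosing**: total dose = dose level (10, 12 or 14 g/m2) x BSA, infused
  over 1 h or 2 h. The three strategy-development groups are 12 g/m2-1 h,
  12 g/m2-2 h and 14 g/m2-2 h, 100 subjects each.
* **Sampling**: the candidate grid 0.5, 1, 1.5, 2, 2.5, 3, 4, 6, 8 and
  12 h after infusion start; every subject receives the full grid and
  strategies subset it downstream.
* **Censoring**: records below the limit of quantification are flagged BLQ
  and excluded from analysis. The default LOQ is 0.0556 mg/L (0.2 umol/L
  at 278.3 g/mol). At study dose levels no on-grid sample at or before 8 h
  approaches it, so results are insensitive to this value.

**Residual noise in the virtual cohorts.** `simulate_group` applies the
proportional error model by default (this is what a fitting experiment
needs). The limited-sampling workflow, however, simulates
*prediction-level* profiles (IIV only, `residual_error=False`). This is a
deliberate reading of the source procedure: the LSS cohort there was
simulated as model predictions and filtered on "predicted" concentrations,
and the published regression quality (adjusted R2 up to 0.9998, MAPE below
1 %) is only attainable on prediction-level profiles - a simple variance
budget shows that 18.8 % multiplicative noise on each sample caps any
2-point regression near R2 ~ 0.76. Consequently the reported strategy
performance quantifies *model-intrinsic* prediction quality (how well 2-3
predicted concentrations determine exposure given IIV); it does not
include assay error, which in practice adds to the errors reported here.

A 15-subject generator reproduces the original study's mixed design
(1 x 10 g/m2-1 h, 4 x 12-1 h, 4 x 12-2 h, 6 x 14-2 h; 7 subjects on a
sparse 6-sample schedule, 8 on a rich 10-sample schedule - 122 records)
for exercising the fitting engine on study-like sparsity.

All generators draw from `numpy` Generators; a run-level master seed
spawns per-stage child seeds deterministically (`config.stage_seed`), and
identical seeds reproduce datasets byte-identically through the CSV
round-trip.

## Non-compartmental AUC

`AUC(0-last)` uses linear-up/log-down interpolation: linear trapezoids on
rising or flat segments and whenever an endpoint is zero, log trapezoids
on strictly falling segments. Profiles are anchored at (0, 0) because
dosing is an infusion starting at t = 0. The terminal slope `lambda_z`
comes from a log-linear regression over trailing windows of at least three
points strictly after the peak, selecting the window with the best
adjusted R2 (ties within 1e-4 go to the longer window); a non-negative
slope in every window raises an estimation error rather than returning a
value. `AUC(0-inf) = AUC(0-last) + C_last / lambda_z`. On noise-free
model profiles over the candidate grid the total discretization error is
below 2 % of `D/Cl`; because the same NCA value is the reference
("observed" AUC) for both regression and Bayesian strategies, this bias
largely cancels in the prediction-error metrics.

## Limited sampling strategies

Candidate time sets are all 2- and 3-subsets of the grid that exclude
samples *during* the infusion and the 12 h sample; the end-of-infusion
time itself is admissible (the published 2-h-infusion equations sample at
exactly 2 h). Per group, subjects are split 50:50 at the subject level
into learning and validation halves; every candidate subset is fitted by
ordinary least squares of the NCA reference AUC on the concentrations at
those times (`LimitedSamplingRegressor`, an sklearn-compatible estimator),
and subsets are ranked by adjusted R2 with a deterministic
earliest-then-fewest tie-break. The winners are validated on the held-out
half via relative prediction errors (PE, MPE, MAPE, RMSE, counts outside
+/-20 %).

The top 3-point subsets are statistical near-ties (adjusted-R2 gaps below
0.005 among the leaders), so the exact winning triple is not stable
information - neither across our seeds nor, presumably, in the original
single realization. The 2-point winners ({1.5, 6} h for 1-h infusions,
{2, 6} h for 2-h infusions) are stable and match the published choices.

## Bayesian individual estimation

With the population model fixed, the individual random effects minimize

    sum_j [ (c_j - f_j(eta))^2 / (b f_j(eta))^2 + 2 ln(b f_j(eta)) ]
      + eta' Omega^-1 eta

over the eta-carrying parameters (Cl, V1, Q). The default estimator is
the posterior mode (MAP) by multi-start bounded quasi-Newton (L-BFGS-B,
starts at the prior mode plus four prior draws, simplex polish), chosen
for speed and determinism; a Metropolis-within-Gibbs sampler provides the
posterior-*mean* alternative, with Robbins-Monro proposal adaptation over
the burn-in half of the chain. Individual exposure is `D / Cl_i`. Scored
against the same NCA reference as the regression strategies, Bayesian
estimation from 2-3 points shows the expected behaviour: roughly 4-7 %
MAPE, visibly wider PE dispersion than the regression equations, and
occasional predictions outside +/-20 % - the price of estimating three
random effects from two or three concentrations.

## Population fitting (SAEM) and likelihood

`fit_population` implements stochastic-approximation EM:

* **E-step**: four parallel MCMC chains per subject on the log-scale
  individual parameters; per iteration one independent proposal from the
  current population prior plus two componentwise random-walk sweeps with
  constant-gain scale adaptation toward ~35 % acceptance during burn-in.
* **M-step**: closed-form updates of the typical values (and allometric
  exponents, when estimated - a per-parameter linear regression on
  log(BW/70), exact because all coordinates share the same regressor), of
  the structured IIV covariance (diagonal / Cl-V1 block / full), and of
  the proportional or additive residual variance, all from stochastically
  approximated sufficient statistics; structural parameters without random
  effects (V2 in the final model) and the combined error model are updated
  by a short warm-started Nelder-Mead on the complete-data objective with
  Robbins-Monro damping.
* **Schedule**: step size 1 for `k1` burn-in iterations (default 300),
  then `1/k` for `k2` smoothing iterations (default 100). During burn-in
  the IIV variances and the residual SD may shrink by at most 5 % per
  iteration (simulated annealing). Without this the degenerate
  zero-noise/zero-IIV case collapses the prior early, freezes the chains
  and stalls at a displaced stationary point; with it, that case recovers
  all four typical values to ~0.1 %.
* **Convergence flag**: drift of the typical values between the two
  halves of the smoothing phase below 5 % on the log scale.

The marginal -2 log-likelihood (MOFV) is computed by importance sampling:
per subject a MAP eta and a Laplace (Gaussian) proposal from the numerical
Hessian, then vectorised weights over fixed standard-normal draws; the
Monte-Carlo SE is reported with the value. This reduces to the exact
Gaussian expression when all IIV is zero and matches 1-D adaptive
quadrature within Monte-Carlo error on toy problems. `AIC = -2LL + 2p`
and `BIC = -2LL + p ln(n_subjects)` by construction.

Standard errors come from a central-difference Hessian of the fixed-draw
importance-sampled -2LL on the natural parameter scale (relative step
5e-3); fixing the draws makes the objective deterministic and smooth, so
the Hessian is well behaved at moderate sample counts. The two SE methods
of the original software (linearization vs stochastic approximation) are
not separately replicated.

Model comparison applies the likelihood-ratio conventions of the original
model building - a MOFV drop of 10.8 (p < 0.001, 1 df) for
forward/structural inclusion and 6.67 (p < 0.01) for backward elimination
(the chi-square quantiles 10.83 / 6.63 to rounding) - and refuses the LRT
for non-nested structures, reporting AIC/BIC deltas only. A Wald z-test
helper screens estimated covariate exponents. One- and three-compartment
structures are available for the selection harness; the three-compartment
solution uses an eigendecomposition of the rate matrix.

Eta-shrinkage is `100 (1 - Var(eta_hat) / omega^2)` with the empirical-
Bayes (MAP) etas and ddof = 1. The subject-level nonparametric bootstrap
refits resampled datasets (reduced SAEM schedule by default) and reports
medians with 5th-95th percentile intervals, counting failed replicates and
aborting beyond 50 % failures.

The prediction-corrected VPC multiplies each observation (and each of the
`n_sim` simulated replicates of the same design) by (median population
prediction in the time bin) / (subject's population prediction at t), then
overlays the 5/50/95 percentiles of corrected observations on the 50 % and
95 % intervals of the same percentiles across replicates. Bins default to
the unique sampling times (quantile bins beyond 12 distinct times); empty
bins merge leftward.

## Estimator bias at study scale

Re-fitting 100-subject rich-grid cohorts simulated from the packaged
truth recovers Cl typically within ~2 % (sampling SD ~1.5 %) and b within
~2 %. The peripheral parameters are softer: across seeds the V2 estimate
scatters with an SD of ~4 % around a ~-6 % mean offset and single
realizations can sit >10 % from truth - confirmed to be properties of the
maximum-likelihood surface itself (the importance-sampled -2LL at such
estimates beats the truth), not optimizer artifacts. Q and omega_Q are
the least identified quantities, consistent with their large reported
uncertainties in the original analysis.

## Problem sizes used in the test suite

The automated tests run the pipeline at the study's own scale where that
is what is being checked (100 subjects per group for strategy development,
Bayesian evaluation and parameter recovery; three seeds for the strategy
table) and at reduced scale where only an algorithmic property is at
stake (e.g. 20-replicate bootstrap of a 30-subject cohort for CI coverage,
400 VPC replicates, shortened SAEM schedules for toy fits). These sizes
are the package's own defaults for its test battery; the library defaults
match the study (1000 VPC replicates, 300/100 SAEM iterations).

## Known limitations

* Strategy performance is measured on prediction-level profiles (see
  above); real-world application adds assay error to the reported errors.
* The epoxide metabolites are not modelled; linearity in dose is assumed
  throughout, following the source analysis.
* The SAEM M-step for non-random structural parameters is a damped
  numerical step, adequate here (at most three such parameters) but not a
  general-purpose implementation.
* BLQ records are excluded, never imputed or integrated (no M3-style
  likelihood contribution); at study dose levels this is immaterial.
* The bootstrap does not stratify by dosing group when resampling mixed
  designs.
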