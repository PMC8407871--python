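# Methods

## The model

`spmlong` implements the conventional shared-parameter model (SPM) for
longitudinal studies whose outcome collection is truncated by an informative
censoring event, together with the comparators an analyst fits alongside it.

**Longitudinal sub-model.** For subject *i* at visit *j* (time *t<sub>ij</sub>*
in years since the index visit),

    y_ij = x_ij' β + z_ij' b_i + ε_ij,   ε_ij ~ N(0, σ²),

with fixed-effect design *x<sub>ij</sub>* = (1, *t*, exposure, exposure×*t*,
adjustors, optionally adjustor×*t*) and random-effect design
*z<sub>ij</sub>* = (1) or (1, *t*). The random effects
*b<sub>i</sub>* ~ MVN(0, τ) carry each subject's latent deviation in baseline
level and slope.

**Event sub-model.** For each censoring cause *k* (one cause, or dementia and
death as competing causes) a parametric proportional-hazards model

    h_ik(t) = h_0k(t) exp( x*_i' α_k + ρ_k' b_i ),

where *x*<sub>i</sub>\** holds baseline (time-fixed) covariates and the
loading vector ρ<sub>k</sub> multiplies the shared random effects. ρ = 0
decouples the two processes; negative loadings mean subjects with worse latent
trajectories are censored faster. Because the loadings act on *b<sub>i</sub>*
directly (not on the current outcome value), the hazard's linear predictor is
constant in *t* given *b<sub>i</sub>*, so the cumulative hazard is closed-form
for every baseline family and no inner time integration is needed.

**Missingness reading.** Outcomes are conditionally independent of the event
process given *b<sub>i</sub>*. Dropout driven by the event is therefore
ignorable *given the random effects* — the "extended MAR" (XMAR) assumption —
which is weaker than the MAR assumption of a plain mixed model and far weaker
than the MCAR assumption under which GEE is valid. The package's workflow is
exactly the sensitivity triad: fit GEE (MCAR), ML mixed model (MAR) and SPM
(XMAR) with one shared design and compare the exposure effect, its
attenuation, and BIC.

## Estimation

Each subject's marginal likelihood integrates the conditional likelihood over
*b<sub>i</sub>* with **adaptive Gauss–Hermite quadrature**: a damped Newton
search (the conditional log-posterior is strictly concave) finds the
per-subject mode, the local curvature rescales the tensor-product rule, and
the weighted sum is accumulated by log-sum-exp. Default order Q = 9 per
dimension (81 nodes for intercept+slope); at the adaptive centering the
log-likelihood changes by < 1e-4 per subject between Q and Q+4 for Q ≥ 9 on
the synthetic cohorts, and a non-adaptive prior-centered rule is the fallback
if mode finding ever fails.

Maximization is quasi-Newton (L-BFGS-B with finite-difference gradients, then
a polish pass with central differences) in an unconstrained parameterization:
log σ, Cholesky factor of τ with log diagonal, log baseline rates, free α and
ρ. Two-stage initialization fits the LMM and the PH model separately and
starts every free loading at 0; up to three seeded restarts jitter the loading
starts if convergence is not reached. Any subset of loadings can be held fixed
(all-zero gives the MAR-constrained joint model whose BIC is compared with the
SPM's). Standard errors come from the numerically differentiated observed
information (central differences, relative step 1e-4); derived quantities
(declines, loading HRs) use the delta method against that covariance. AIC/BIC
count all free parameters, including baseline rates, and BIC uses the number
of *subjects* as N (the mixed-model convention; a choice the reported criteria
depend on and therefore documented here).

The LMM comparator is fitted by ML (not REML) so its likelihood, AIC and BIC
are commensurable with the joint model's; β is profiled out by GLS and the
Woodbury identity reduces everything to per-subject sufficient statistics.
statsmodels' MixedLM (ML) is used in the test suite as an independent
cross-check of the optimum, and statsmodels' GEE provides the MCAR comparator
(Gaussian family, independent/exchangeable/AR1/unstructured working
correlation, robust sandwich covariance; AR1/unstructured index occasions by
scheduled wave number). The PH fitter, joint likelihood, quadrature,
empirical-Bayes machinery and generator are authored in this package.

**Baseline hazard families.** Piecewise-constant (default: 5 intervals with
cuts at observed event-time quintiles, last interval open-ended), Weibull, and
exponential. The replicate-based benchmark uses the exponential family in both
generator and fits — correctly specified and low-dimensional, keeping a
20-replicate joint-fit study at desk scale; the piecewise default is the
recommended choice for real analyses where the baseline shape is unknown.

**Empirical-Bayes prediction** uses the posterior *mode* of *b<sub>i</sub>*
(the same object the adaptive quadrature centers on); for near-Gaussian
posteriors the mode–mean difference is negligible. For the SPM the posterior
includes the event contribution, which is what lets it track subjects whose
follow-up was truncated; the LMM posterior uses outcomes only.

**Loading hazard ratios** are reported per SD of the *random effect* from the
same fit: HR = exp(ρ̂·sd), with the sign convention made explicit ("per SD
lower/higher") so an adverse loading reads as an HR above 1. (Whether "per
SD" should instead use the outcome SD is genuinely ambiguous; the
random-effect SD reproduces the natural interpretation of a latent-level
shift.)

**Marginalized declines** over a horizon H are H·(β_time + a·β_interaction)
at exposure level a, with any adjustor×time terms averaged over the empirical
adjustor distribution; the contrast is linear in β so the delta-method SE is
exact. Attenuation of a comparator against the SPM reference is
100·(ref − comp)/ref, reported rounded to integer percent with the unrounded
value retained.

## The synthetic cohort generator

The generator emulates the structure of a community cohort of older adults
(the motivating brain-atrophy/cognition example): N subjects, a binary
exposure with prevalence 0.34, age ~ N(62.84, 4.48²) (centered age is the
modeling covariate), cognitive z-scores at scheduled waves 0/6/15/18/20 years
with ±0.5-year uniform jitter, administrative censoring at 21 years, and a
dementia hazard loading on the random effects. Default true parameters:

| quantity | value | why |
|---|---|---|
| β (intercept, time, exp, exp×t, age_c) | −0.129, −0.0476, −0.30, −0.0067, −0.02 | baseline z mean ≈ −0.23; 20-y decline ≈ −0.95 without exposure, additional −0.134 with |
| σ (residual SD) | 0.35 z | typical test–retest noise for composite z-scores |
| τ intercept SD | 0.90 z | marginal baseline SD ≈ 0.98 after adding σ and covariate variance |
| τ slope SD | 0.154 z/yr | with ρ₁ = −0.5 the slope-loading HR per SD is exp(0.077) ≈ 1.08 |
| corr(b₀, b₁) | 0.3 | lower baseline cognition accompanies steeper decline |
| α (exposure, age_c) | log 1.8, 0.05/yr | exposure and age raise the dementia hazard |
| baseline hazard | exponential, rate 0.012/yr | ≈ one third of subjects develop dementia within 20 y |
| loadings ρ | (−0.9, −0.5) | worse latent cognition → faster censoring; HR/SD ≈ 2.25 and 1.08 |
| MCAR overlay under XMAR | 0.10/wave | total attrition ≈ 55–60%, echoing the motivating cohort's 61% |

Mechanisms: `none` keeps every scheduled visit; `mcar` deletes post-baseline
visits independently; `mar` is monotone dropout with a per-wave logistic
hazard on observed covariates and the previous observed outcome; `xmar`
deletes all visits after the (latent-effect-driven) event plus the MCAR
overlay; `xmar_competing` adds death as a second cause. The baseline visit is
never deleted. Under the non-XMAR mechanisms the emitted event table is
censored at the administrative horizon — there the event process is only a
missingness driver, and keeping real event times without truncating visits
would violate the "no visit after the event" data invariant. One master seed
drives two derived, independent streams (cohort and missingness), so
re-applying the mechanism to the retained full cohort reproduces the emitted
dataset bit for bit.

**What the generator does not emulate:** practice effects and curvilinear
decline, visit-time dependence on health, covariate measurement error,
exposure-dependent adjustor distributions, interval-censored dementia onset,
and MNAR mechanisms beyond the shared-random-effects structure. Passing
recovery tests therefore show the estimator is correct *under its own
assumptions*, not that those assumptions hold in any real cohort.

## The replicate benchmark

`spmlong.study.recovery_study` runs 20 replicates of n = 500 under `xmar`
(exponential baseline in truth and fits) and summarizes: bias of the
exposure×time estimate for GEE/LMM/SPM, recovery of the loadings, 95% Wald
coverage, the per-replicate estimate ordering GEE ≥ LMM ≥ SPM, BIC of the SPM
vs the zero-loading joint model, and pooled observed-vs-predicted Pearson
correlations among event-dropout subjects for SPM vs LMM. Problem sizes were
chosen so the whole study runs in a few minutes on one core while leaving the
bias ordering |bias GEE| > |bias LMM| > |bias SPM| clearly resolved in the
summary.

Two of the benchmark's count statistics are intrinsically knife-edge under
these conditions: in replicates whose realized dropout happens to carry little
information about the slopes, the LMM and SPM estimates (and the two models'
prediction correlations) agree to within ~1e-4, and the sign of the difference
is statistical noise. The mean ordering |bias GEE| > |bias LMM| > |bias SPM| is the
reproducible finding; the per-replicate ordering and correlation-win counts
fluctuate widely across seeds (roughly 9–16 and 15–18 of 20) because the
violating replicates are ties decided by noise.

## Numerical choices and degenerate inputs

- SD-scale free parameters are bounded in (7.5e-5, e⁸); a variance component
  driven to the lower bound is reported as near-zero with a boundary warning
  rather than an error (noise-free data are legal input).
- Exponents inside hazard terms are clipped at ±700 before `exp` to keep
  intermediate overflow from poisoning a whole likelihood evaluation.
- Exact event-time ties are legal: the parametric likelihood needs no tie
  handling.
- A Hessian that is not positive definite at the optimum flags the fit's SEs
  as unreliable but still returns the fit; non-convergence is likewise a
  flagged state so the comparison report can render every row.
- Subjects with zero visits contribute an empty longitudinal product (their
  event record still informs the fit); subjects with no event record
  contribute longitudinal terms only.
- Monte-Carlo cross-checks of the marginal likelihood use importance sampling
  from a mode-centered, slightly inflated Gaussian proposal: plain prior
  sampling at 1e6 draws leaves ~3e-3 relative noise for visit-rich subjects,
  larger than the 1e-3 agreement being verified, while the importance sampler
  reaches ~2e-4 with the same draw count. The proposal choice cannot bias the
  estimate; the random-sampling integration is independent of the
  deterministic quadrature it validates.

## Known limitations

- No time-varying hazard covariates, left truncation or interval censoring.
- The loading acts on the random effects only; "current-value" association
  structures common in biomarker joint models are out of scope.
- The generalized SPM (additional non-identified random-effect sets for MNAR
  sensitivity), selection and pattern-mixture models, multiple longitudinal
  outcomes, multiple imputation and IPW are deliberately not implemented.
- Wald inference throughout; profile-likelihood or bootstrap CIs for the
  loadings would be preferable near boundaries.
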