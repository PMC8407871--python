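# spmlong

Shared-parameter joint models for longitudinal studies whose outcome
collection is cut short by an informative censoring event — the situation of
a cognitive-aging cohort in which participants stop being assessed once
dementia is diagnosed, so the steepest decliners contribute the least data.

Standard longitudinal analyses make untestable missing-data assumptions:
generalized estimating equations (GEE) are valid under MCAR, mixed models
under MAR. When dropout is driven by an event that is itself tied to the
latent outcome trajectory, both can understate an exposure effect. The
shared-parameter model (SPM) implemented here couples

- a linear mixed longitudinal sub-model
  *y<sub>ij</sub>* = *x<sub>ij</sub>*′β + *z<sub>ij</sub>*′*b<sub>i</sub>* + ε<sub>ij</sub>,
  ε<sub>ij</sub> ~ N(0, σ²), *b<sub>i</sub>* ~ MVN(0, τ), with
- one or two cause-specific parametric proportional-hazards sub-models
  *h<sub>ik</sub>*(t) = *h*<sub>0k</sub>(t) exp(*x*<sub>i</sub>\*′α<sub>k</sub> + ρ<sub>k</sub>′*b<sub>i</sub>*),

through loading factors ρ<sub>k</sub> on the shared random effects. Outcomes
and censoring are conditionally independent given *b<sub>i</sub>* ("extended
MAR"); nonzero loadings are direct evidence that the dropout is informative.
The marginal likelihood integrates the random effects out by adaptive
Gauss–Hermite quadrature and is maximized by quasi-Newton with two-stage
initialization. The package also provides the GEE and ML-mixed-model
comparators, empirical-Bayes prediction, marginalized decline contrasts with
delta-method CIs, loading hazard ratios per SD, percent attenuation, a
competing-risks (dementia + death) extension, a Table-style comparison
report, and a calibrated synthetic cohort generator with MCAR/MAR/XMAR
missingness mechanisms so the full sensitivity workflow runs without any
restricted data.

It is primarily a library (see `examples/`), with a thin `spmlong` CLI for
shell use (`simulate`, `fit-lmm`, `fit-gee`, `fit-ph`, `fit-spm`, `contrast`,
`compare`).

## Worked example

```python
import spmlong as sl

data, _ = sl.simulate_cohort(sl.SimConfig(n=400, mechanism="xmar", seed=3))
table = sl.compare_models(data, sl.default_spec(),
                          options=sl.SPMOptions(baseline="exponential"))
print(sl.render_report(table, "text"))
```

prints (run it yourself — `python examples/03_compare_missingness_assumptions.py`):

```
Model       Decline w/o exposure  Decline w/ exposure  Additional decline (95% CI)  p      Attenuation  AIC     BIC
----------  --------------------  -------------------  ---------------------------  -----  -----------  ------  ------
SPM (XMAR)  -0.853                -1.173               -0.320 (-1.058, 0.418)       0.396  -ref-        4810.1  4866.0
GLMM (MAR)  -0.845                -1.147               -0.302 (-1.034, 0.430)       0.419  6%           4857.1  4905.0
GEE (MCAR)  -0.750                -0.974               -0.224 (-1.057, 0.608)       0.597  30%          –       –

Loading factors (hazard ratio per SD of random effect):
  SPM (XMAR) cause 0 effect 0: HR 2.04 (1.63, 2.56) per SD lower
  SPM (XMAR) cause 0 effect 1: HR 1.00 (0.76, 1.32) per SD lower
```

Reading it: each row is the same design under a different missing-data
assumption. "Decline" is the marginalized 20-year change in the standardized
cognitive outcome; "Additional decline" is the exposure×time contrast with
Wald CI and p-value. On this cohort — simulated with truly informative
dropout — the GEE estimate sits 30% closer to zero than the joint-model
reference and the mixed model 6% closer: the attenuation pattern expected
when fast decliners leave the study early. The MAR row's AIC/BIC are the
mixed model plus an independent event fit (the zero-loading joint model), so
lower SPM values favor the informative-coupling reading. The loading row
HR 2.04 per SD *lower* baseline cognition says latently worse subjects were
censored about twice as fast per SD — the mechanism behind the attenuation.
(Single-cohort estimates are noisy at n=400; the replicate benchmark below
shows the systematic pattern.)

Other entry points, one script each in `examples/`:
`01_simulate_cohort.py` (generator and its calibration anchors),
`02_fit_joint_model.py` (declines and loading HRs from one joint fit),
`04_competing_risks.py` (dementia + death sharing one set of random effects).

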