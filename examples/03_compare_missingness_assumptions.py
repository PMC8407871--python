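"""The headline sensitivity workflow: GEE (MCAR) vs LMM (MAR) vs SPM (XMAR).

Fits the three models with a shared design on one cohort with event-driven
dropout and renders the comparison table: marginalized 20-year declines, the
additional decline under exposure, percent attenuation of each comparator
against the joint-model reference, and AIC/BIC (not defined for GEE).
"""

import spmlong as sl

data, _ = sl.simulate_cohort(sl.SimConfig(n=400, mechanism="xmar", seed=3))
table = sl.compare_models(data, sl.default_spec(),
                          options=sl.SPMOptions(baseline="exponential"))
print(sl.render_report(table, "text"))
# Reading the table: under informative dropout the GEE and mixed-model rows
# sit closer to zero than the joint-model reference (positive attenuation),
# because both treat the truncated trajectories of fast decliners as ignorable.
# A lower SPM BIC than the constrained (zero-loading) alternative supports the
# extended-MAR reading of the data.
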