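"""Five-year outcome probabilities for eight patient profiles.

A covariate-adjusted Weibull fit (age on death transitions, FEV1 %
predicted and prior-year exacerbations on exacerbation transitions)
predicts state occupancy for the 2x2x2 grid of profiles: age 55/70,
FEV1 40/55 % predicted, 1/2 prior-year exacerbations.
"""

from exacmsm import events as ev
from exacmsm import parametric as pm
from exacmsm import predict as pr
from exacmsm import synth

effects = synth.DEFAULT_EFFECTS + (
    synth.TruthEffect(
        pm.CovariateTerm("prior_exac", "prior_exacs",
                         ev.EXACERBATION_TRANSITIONS, center=1.0), 0.25),
)
cfg = synth.GeneratorConfig(n=4000, seed=1, covariate_effects=effects)
df = synth.simulate_dataset(cfg)
fit = pm.fit(df, "weibull", tuple(e.term for e in effects))

prof = pr.eight_profiles(fit, grid_days=[1826.0])
sel = prof[prof.grouping == "severe_or_death"]
print("P(>=1 severe exacerbation or death) at 5 years, by profile:")
for row in sel.itertuples():
    print(f"  age {row.age:.0f}, FEV1 {row.fev1pp:.0f}%, "
          f"{row.prior_exacs:.0f} prior exac: {row.probability:.1%}")
# within each age/FEV1 cell, a second prior-year exacerbation raises the
# 5-year risk of a severe event or death
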