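"""Fit all seven parametric families and rank them by AIC.

The Weibull fit (shared shape, distinct per-transition rates,
proportional hazards) then yields the constant hazard ratios between
transitions — the headline comparisons of risk after different
exacerbation histories.
"""

from exacmsm import parametric as pm
from exacmsm import synth
from exacmsm.families import FAMILY_NAMES

df = synth.simulate_dataset(synth.GeneratorConfig(n=2000, seed=7))

fits = {name: pm.fit(df, name) for name in FAMILY_NAMES}
print(pm.aic_table(fits.values()).to_string(index=False))
# the generating process is Weibull (shape 1.3); families that can bend
# the hazard in time rank ahead of the exponential

wb = fits["weibull"]
pairs = [((4, 5), (1, 5)), ((4, 5), (2, 5)), ((4, 5), (3, 5)),
         ((2, 5), (1, 5)), ((3, 4), (1, 4))]
labels = {
    ((4, 5), (1, 5)): "death: severe vs none",
    ((4, 5), (2, 5)): "death: severe vs 1 moderate",
    ((4, 5), (3, 5)): "death: severe vs >=2 moderate",
    ((2, 5), (1, 5)): "death: 1 moderate vs none",
    ((3, 4), (1, 4)): "severe exac: >=2 moderate vs none",
}
print("\nhazard ratios from the Weibull fit (95% CI):")
for hr in pm.transition_hazard_ratios(wb, pairs):
    key = (hr.numerator, hr.denominator)
    print(f"  {labels[key]:35s} {hr.hr:5.1f} ({hr.ci_low:.1f}-{hr.ci_high:.1f})")
# risk of death rises steeply once a severe exacerbation has occurred
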