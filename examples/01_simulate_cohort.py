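"""Simulate a 52-week synthetic COPD trial cohort.

Draws baseline covariates matching the published trial margins and
trajectories through the five-state exacerbation/death process, then
prints the realised event counts.  The three emitted tables
(events/outcomes/baseline) are the raw-input format of the whole
package.
"""

from exacmsm import synth

cfg = synth.GeneratorConfig(n=2000, seed=7)
cohort = synth.simulate_trajectories(cfg)

print("baseline margins (n=2000):")
b = cohort.baseline
print(f"  age mean {b.age.mean():.1f} | FEV1%pred mean {b.fev1pp.mean():.1f}"
      f" | eosinophils mean {b.eos.mean():.0f}")
print(f"  male {b.male.mean():.1%} | ICS use {b.ics.mean():.1%}"
      f" | >=2 prior exacerbations {(b.prior_exacs >= 2).mean():.1%}")

print(f"\n{len(cohort.events)} exacerbation episodes, "
      f"{int(cohort.outcomes.death_day.notna().sum())} deaths")
print("realised transitions (from -> to: count):")
for (r, s), n in sorted(cohort.transition_tally.items()):
    if n:
        print(f"  {r} -> {s}: {n}")
# counts concentrate on 1->2 (first moderate) and thin out towards the
# rare late transitions (>=2 moderates to death), as in the real trial
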