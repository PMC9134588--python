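# Methods

## The process being modelled

A patient in a 52-week COPD trial occupies, at every moment on
treatment, one of five states defined by the events experienced since
randomisation: no exacerbation (1), one moderate exacerbation (2), two
or more moderate exacerbations (3), one or more severe exacerbations
(4), death (5). The process is progressive: only moves to a strictly
worse state are possible, skips are allowed, and the direct 1 → 3 move
is structurally impossible. All hazards are functions of time since
randomisation ("clock-forward"), which together with the state
definition makes the process Markov: the future depends on the past
only through the current state and the calendar time.

## Event processing

Raw exacerbation records are merged into distinct episodes when the gap
from the end of one record to the start of the next is 7 days or less
(a new episode requires a gap strictly greater than 7 days). A merged
episode takes the maximum severity of its constituents, because
severity is what routes the patient into the absorbing-into-state-4
logic and a severe event inside a moderate episode is clinically one
severe episode.

Times are integer day numbers used directly as the time coordinate
(day 1 = first treatment day, study start = 0). Three conventions keep
every sojourn strictly positive:

* an episode starting on day 1 assigns the patient to state 2/4
  immediately, at t = 0.5, after a zero-length state-1 sojourn;
* a death on the same day as a state entry is ordered after the
  exacerbation and offset to entry + 0.5;
* deaths more than 30 days after the last treatment day are treated as
  censorings at `last_treatment_day + 30`. Exacerbation transitions
  are censored at the last treatment day itself; the death transition
  is followed through the extra 30-day window.

The long-format transition dataset has one row per occupied state and
permitted exit, with delayed entry (entry at the time the state was
entered), exit time, and event/censoring status — the common input of
every fitter. Patients with any missing baseline covariate are dropped
from covariate-adjusted datasets only, with a logged count.

## Estimators

**Non-parametric.** Kaplan–Meier mortality curves reset the clock at
state entry (competing exacerbation transitions censor); all other
estimators stay on the study clock with left truncation: a subject is
in the risk set of state r from its entry to its exit. Nelson–Aalen
increments aggregate ties (d/n, Breslow-style — integer-day data
guarantee ties). The Aalen–Johansen estimator is the product-integral
of the Nelson–Aalen increments; its factor rows sum to one by
construction, so occupancy vectors do too. KM and the time-dependent
Cox model (indicator switching at the first severe exacerbation) are
computed via lifelines; with Newton step-halving fallbacks because the
severe indicator is rare and the default step can diverge.

**Semi-parametric.** One stratified Cox partial likelihood with each
transition as a stratum, Breslow ties, delayed entry and Breslow
baselines, maximised by Newton–Raphson with step-halving (relative
likelihood-change tolerance 1e-9). Coefficients may be
transition-specific or tied across transitions; with no shared
coefficients the fit decomposes into per-stratum fits, which the tests
exploit. Coefficients larger than 10 in absolute value abort with a
monotone-likelihood error.

**Parametric.** The exact multi-state log-likelihood is the row-wise
sum of cumulative-hazard increments minus log hazards at observed
transitions. Seven families: exponential, Weibull
(h = λ·a·t^(a−1), proportional hazards), Gompertz (h = λ·e^(γt)),
log-logistic, log-normal, gamma and generalised gamma in the (μ, σ, Q)
parameterisation (log-normal at Q = 0, Weibull at Q = 1, gamma at
Q = σ). Each transition has its own rate-like parameter; ancillary
shapes are shared across transitions by default (per-transition sharing
is available). Covariates enter on the log rate for the PH families
and as log time-acceleration for the AFT families; consequently
transition hazard ratios are constants only for shared-shape PH fits,
and for AFT fits the package refuses them unless a reference time is
given.

Times are converted to years internally (365.25 days) so rates are
interpretable per-year quantities; continuous covariates are centred
(age at 65 years / 10, FEV₁ %-predicted at 45 / 10, eosinophils as
log count centred at log 200) so that rate parameters describe a
reference patient. Optimisation is BFGS from three deterministic
starts (occurrence/exposure exponential rates, the same ±0.5 on the log
scale), with analytic gradients for the PH families and finite
differences otherwise; the variance-covariance matrix is the inverse
observed information (finite-difference Hessian), with a pseudo-inverse
fallback and warning if singular. Transitions with exposure but no
events are non-identifiable; their hazard is fixed at zero and flagged.
AIC = 2k − 2·loglik ranks families on the same dataset.

The Markov diagnostic refits with the patient's state-1 sojourn time
(centred, in years) as a covariate on each transition out of states
2–4; hazard ratios near 1 support the clock-forward Markov assumption.

**Prediction.** The intensity matrix Q(t) assembles the fitted hazards
for a covariate profile (covariates absent from the profile sit at
their centring values). P(t₀, t) solves the Kolmogorov forward
equations with DOP853 at atol 1e-10 / rtol 1e-8; the first step over
[t₀, t₀+ε] uses the matrix exponential of the exact interval cumulative
hazards, which also handles hazards singular at t = 0 (Weibull shape
< 1). Because Q is upper triangular, the structural zeros of P are
preserved exactly. Rows are renormalised only when the drift from 1 is
below 1e-8; larger drift raises. Reporting per 10,000 patients rounds
at the formatting layer only; with five entries per row the rounded
sums stay within ±1 of 10,000. Confidence intervals for any functional
are percentile intervals over draws from MVN(MLE, vcov) on the
unconstrained scale — positivity constraints are automatic there, and a
non-PSD vcov is repaired by eigenvalue clipping with a warning. The
profile grid (age 55/70, FEV₁ 40/55 %, 1/2 prior-year exacerbations)
reports cumulative groupings (death; ≥1 severe or death; ≥2 moderate,
severe or death; any state ≥ 2), which are nested by construction.
The default prediction grid is weekly to week 52 and 4-weekly to five
years; "4 weeks" means 28 days and a year 365.25 days.

## The synthetic cohort

The generator stands in for restricted patient-level trial data.
Baseline covariates match the published summary margins: age from a
normal with SD 7.6 truncated to [40, 80] whose *truncated* mean is
64.7 (the location is solved numerically — plain truncation would shift
the mean by ≈ 0.4 years); FEV₁ %-predicted likewise (mean 43.4, SD
10.3, bounds [25, 65]); 59.7 % male; four equal treatment arms; 80.5 %
ICS use; prior-year exacerbation counts 1/2/3/4 with probabilities
0.435/0.34/0.16/0.065 (so P(≥2) = 0.565); eosinophils lognormal
moment-matched to mean 196.4 and SD 132.8.

Trajectories are drawn by competing-risks inversion on the study clock:
given entry time t_e, the next event time solves
Λ(t) = Λ(t_e) + E with E ~ Exp(1) and Λ the total covariate-adjusted
cumulative hazard out of the current state (closed forms for the
exponential/Weibull/Gompertz truths), and the destination is drawn
proportionally to the hazards. Default per-year rates
(λ₁₂, λ₁₄, λ₁₅, λ₂₃, λ₂₄, λ₂₅, λ₃₄, λ₃₅, λ₄₅) =
(0.4, 0.1, 0.02, 0.5, 0.15, 0.04, 0.2, 0.06, 0.3) with Weibull shape
1.3 give 52-week event profiles of the right order: common moderate
exacerbations, uncommon severe ones, rare deaths concentrated after
severe events. Default covariate effects: +0.35 per decade of age on
all death transitions, −0.2 per 10 points of FEV₁ and +0.15 per log
unit of eosinophils on exacerbation transitions. Administrative
censoring at day 364, with independent exponential dropout at 0.15/year
(non-informative, matching the models' censoring assumption).

Event times are rounded up to whole days, episode durations are 7–10
days, and consecutive distinct episodes are kept more than 7 days apart
so that episode merging is the identity on generator output and
re-processing the raw tables recovers the generated paths exactly (a
tested round trip). An optional history-dependence switch multiplies
the 2 → 3 hazard by exp(b · centred state-1 sojourn in years),
providing the semi-Markov alternative for diagnostic power studies.

What the generator does *not* emulate: treatment effects on any
transition (the fitted models exclude treatment effects on death, and
per-arm efficacy is out of scope), mild exacerbations, seasonality,
informative dropout, or recurrent severe episodes within state 4.
Passing tests therefore demonstrate correctness of the estimators under
the stated process, not fidelity of any particular clinical estimate.

## Validation experiments and problem sizes

The dedicated acceptance suite and `scripts/acceptance.py` run, on one
CPU in a few minutes: the Kolmogorov solver against the matrix
exponential on 20 random progressive generators (< 1e-8 entrywise);
a coverage study of the Weibull truth (13 parameters, n = 4000, 200
replicate cohorts); the Aalen–Johansen vs generating-model occupancy
sup distance at n = 5000 over the 52-week window; Markov-diagnostic
type-I coverage (50 replicates) and power against the semi-Markov
alternative with b = 1 (25 replicates, n = 4000); and the empirical
size of the 3-df eosinophil × treatment interaction LRT at n = 800 over
1000 replicates.

A note on the coverage study: with 200 replicates the binomial SE of an
empirical coverage at 0.95 is 1.5 percentage points, so individual
parameters scatter a few points around the nominal level; the sparsest
transition (state 1 to death, ≈ 64 events per cohort) additionally
shows the usual mild small-sample anti-conservatism of Wald intervals
(empirical SE a few percent above the model SE). Median coverage
across parameters sits at the nominal level.

## Known limitations

* Hazard ratios for AFT families require a reference time; no
  time-averaged summaries are offered.
* The stratified Cox fit recomputes risk sets per event time with dense
  masks — fine for trial-sized data, not tuned for millions of rows.
* Confidence intervals are pointwise Wald/percentile; no multiplicity
  adjustment (none is part of the analysis being implemented) and no
  simultaneous bands for occupancy curves.
* The generator's day rounding and the > 7-day episode-separation rule
  introduce a small discretisation distortion relative to the
  continuous-time truth; at the default rates the induced bias is well
  inside one Monte-Carlo SE at n = 4000.
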