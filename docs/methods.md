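# Methods

## Question and structure

The package compares two nodal-staging strategies in presumed early-stage,
high-risk endometrial cancer (grade 3 endometrioid, serous or clear-cell):
routine pelvic lymphadenectomy, treated as a gold standard with no false
results, and indocyanine-green sentinel lymph node (SLN) mapping with 97%
sensitivity and perfect specificity. Both arms undergo the same
hysterectomy/BSO and one-day stay, so only nodal surgery, histopathology,
adjuvant therapy and complications are costed; any cost common to both arms
cancels out of the incremental results (a property the tests assert).

A decision tree assigns the cohort to three post-treatment substates:

* node-positive, detected and treated with the scenario's adjuvant therapy
  (EBRT, chemotherapy, or both; combined cost additive since no combined
  tariff is published);
* node-negative, vaginal brachytherapy (VBT);
* node-positive but missed, also VBT — only possible in the SLN arm.

SLN mapping succeeds bilaterally (79%), unilaterally (16%, the silent side
gets a side-specific lymphadenectomy) or fails (5%, full bilateral
lymphadenectomy). By default the 3% false-negative rate applies only to the
mapped fraction (`sensitivity_scope=mapped_only`), because failed mapping
converts to a gold-standard lymphadenectomy; `all` applies it to every
node-positive patient. Expected nodal-surgery time is 20/40/60 min for the
three mapping outcomes (10 min per SLN side, 30 min per lymphadenectomy
side) at EUR 11.08/min, plus EUR 35.18 of tracer (charged once) and the
strategy's histopathology tariff. Lymphedema and lymphocele prevalences are
applied at arm level as published (19%/6% vs 5%/2%); an `extent_weighted`
flag can instead mix the SLN arm by its lymphadenectomy fraction.

The Markov model (annual cycles, 20 cycles from age 65) adds a combined
regional/distant recurrence state and death. Transitions:

* post-treatment → recurrence at the group's annualized 5-year failure
  rate, `1 − (1 − p₅)^(1/5)`;
* everyone → dead at the age-specific background probability q(age);
* recurrence → dead combining a cancer-specific annual death probability
  with q(age) as independent competing risks,
  `1 − (1 − d)(1 − q)`.

## Calibrated conventions

The published model leaves several conversions unstated; each is a config
flag, and the defaults were calibrated jointly so that the model reproduces
the published incremental analysis and threshold sensitivities. They are
model choices, not data:

* **failure_window = first5.** The 5-year failure rates act during cycles
  1–5 only; patients disease-free at five years are treated as cured and
  face background mortality alone. Applying the annualized rates for all 20
  years (`lifetime`) roughly doubles lifetime recurrence, which is
  inconsistent with the published QALY levels and with 5-year trial data as
  the rate source. The same window governs the vaginal-recurrence terms.
* **recurrence_mortality = calibrated.** For each group the constant annual
  death probability in recurrence is solved (bisection) so the group's
  cumulative 5-year all-cause mortality in the model equals the published
  rate — the published mortality is all-cause, and all cancer deaths are
  assumed to pass through recurrence. For the missed-metastases group the
  70% target nearly equals the 67% recurrence rate, so recurrers die within
  about a cycle (probability clipped at 1 with a warning). The alternative
  `case_fatality` mode uses the annualized mortality/recurrence ratio,
  subtracting the life-table background share first
  (`mortality_input=all_cause`) or not (`cancer_specific`).
* **recurrence_mixing = static.** The single recurrence state carries a
  death probability mixed over contributing groups, weighted by expected
  incident flow at baseline (tree occupancy × annual recurrence rate). A
  `tracked` variant re-weights by the state's actual composition each
  cycle; it is cleaner dynamically but moves the threshold sensitivities
  far from the published values, so it is not the default.
* **half_cycle = on.** State rewards use the mean of start- and
  end-of-cycle occupancy, the usual within-cycle correction in cohort
  models. With full survival this reduces to the plain discounted annuity
  Σₜ 1.015⁻ᵗ = 17.169 over 20 years, which the tests pin exactly.

## Rewards

Costs per cycle: two follow-up visits (EUR 138 each) in every alive state;
chronic lymphedema treatment (prevalence × EUR 2,579.78) in post-treatment
states; expected vaginal-recurrence salvage radiotherapy (annualized rate ×
EUR 8,237.72) in post-treatment states while the failure window is active;
salvage chemotherapy (EUR 8,682.17) charged once on the incident flow into
recurrence. Upfront tree costs fall at cycle 0 undiscounted; cycle costs
discount at 4%/yr, effects at 1.5%/yr.

Utilities: post-treatment patients start from 1 and lose
`prevalence × (1 − u)` for lymphedema (u = 0.925), treatment toxicity
(radiotherapy 0.866, chemotherapy or combined 0.50; short-term probability
in cycle 1, long-term probability thereafter — short-term toxicity is
transient, long-term toxicity persists) and vaginal recurrence (0.69).
Recurrence scores 0.38, death 0. VBT toxicity carries the radiotherapy
utility.

## Background mortality

No life table is printed; the only constraint given is a remaining life
expectancy of ~20 years at age 65. The synthetic table is Gompertz,
`q(age) = min(1, a·e^{b(age−65)})`, closed out at 110. The expectancy pins
only one of the two constants; the default slope b = 0.185 (with
a = 0.002874 solved so e(65) = 20.0 exactly) was calibrated together with
the structural flags against the published base case, which a flatter table
cannot reach because it kills too many patients in the first decade, when
discounting weighs least. Users can pass any `(a, b)` or a CSV table
(columns `age,qx`); `life_expectancy` implements the half-year convention
Σ S(t) + 0.5 and is cross-checked against an individual-level simulation in
the tests.

## Probabilistic sensitivity analysis

Each iteration redraws every non-fixed parameter independently: beta for
probabilities and utilities, gamma for costs and operating times, fitted by
method of moments so the mean equals the base value. Spread comes from, in
order of preference, a printed standard deviation (chemotherapy-toxicity
utility, SD 0.21), a printed self-consistent 95% interval
(SE = width/3.92), printed binomial counts (SE = √(p(1−p)/n), e.g.
sensitivity 35/36), else a 10% relative SE. The three mapping outcomes are
drawn marginally and renormalized to the simplex. Infeasible beta moments
fall back to a [0,1]-truncated normal with a warning. No correlation
structure is imposed — none is published.

Decisions use net monetary benefit, `NMB = WTP·QALY − cost` at
WTP = EUR 20,000/QALY, which covers all four quadrants of the
cost-effectiveness plane consistently. The threshold search on SLN
sensitivity instead uses, by default, the effectiveness crossing (the
sensitivity at which SLN mapping stops being at least as effective, i.e.
stops dominating — SLN is cheaper throughout, so that is where the
published analysis declares the preference to flip); `threshold_rule=nmb`
switches to the net-benefit flip, which lies far lower because the cost
saving buys a substantial QALY allowance.

## What the synthetic data do and do not show

The life table and the PSA distributions are synthetic stand-ins
constrained by single published facts (e(65) ≈ 20; Table-level means,
intervals and counts). Passing tests therefore show internal consistency
and faithful reproduction of the published analysis under these stand-ins,
not validity against Dutch registry mortality or the true joint parameter
uncertainty. In particular, with the printed uncertainty the PSA leaves SLN
mapping cost-effective in ~99.4–99.8% of draws rather than a clean 100%:
the residual draws combine high SLN-arm lymphedema (its interval reaches
9%) with low mapping sensitivity (n = 36 binomial), and no defensible
re-reading of the printed intervals removes them.

## Numerical notes and limitations

* Threshold bisection runs to 10⁻⁴ on a fixed [0, 1] bracket; the
  recurrence-death calibration to 10⁻¹⁰.
* Printed-table inconsistencies (a base value outside its own interval, a
  suspect VBT lower bound, two shifted recurrence intervals) warn — never
  fail — and the affected intervals are excluded from distribution fitting.
* One parameter at a time is varied in the DSA (±20% endpoints); perturbing
  one mapping-outcome probability rescales the other two proportionally to
  keep the simplex.
* Not modelled: para-aortic-only metastases (~1% of patients), empty-packet
  dissection, molecular profiling/FIGO 2023 adjuvant tailoring,
  immunotherapy, second-line treatment beyond salvage chemotherapy,
  distinction between regional and distant failure, age-varying utilities,
  and any cost common to both arms (hysterectomy, hospital stay).
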