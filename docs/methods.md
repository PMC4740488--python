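# Methods

## Model structure and assumptions

`wakeupcea` is an individual-level (micro-) simulation with three stages —
stroke-onset timing, acute outcome, lifetime projection — followed by a
standard incremental cost-effectiveness layer. The simulated population is
wake-up stroke patients with no tPA contraindication other than unknown
onset time; 60% male, model entry at age 65.

### Onset timing

The quantity of interest is the *onset age*: minutes elapsed since the
stroke at a given point in the care pathway. We draw the fraction of sleep
remaining at onset, `B ∈ [0, 1]`, from either a uniform distribution (base
case) or a Beta(α, β); the onset age at wake is `sleep_minutes × B`. The
beta axis convention is deliberate: small `B` means onset close to wake, so
Beta(3,5) (mean 3/8) is "skewed toward wake time" and produces *fewer*
treatable patients than the uniform — consistent with the scenario ordering
the model is designed to explore. Delays are added as
wake-to-hospital (51 min) + door-to-needle (77 min) + MRI add-on (30 min) =
158 min. Some registry summaries fold the MRI time into a single 103-min
door-to-needle figure; we treat the component reading (77 + 30) as the
default because it is the one consistent with the model's own reported
onset-window fractions, and expose the alternative as the `timing_dtn103`
preset.

Everything downstream classifies patients by onset age **at treatment
start** (not hospital arrival): a patient is "truly eligible" if
`onset_age_at_wake + 158 < 270`. Under the uniform 8-h base case the
closed form gives 112/480 = 23.3% eligible; 6-h sleep gives 112/360 =
31.1%; Beta(4,4) gives the regularized incomplete beta
I₀.₂₃₃(4,4) = 5.6%. These closed forms (`prob_onset_age_below`,
`band_probabilities`) are used throughout the tests as deterministic
oracles for the sampler.

Base-case runs use fixed (expected-value) delays. A configuration switch
draws them from gamma distributions instead; the fit pins the mean exactly
and matches the published spread through the scale-free quantile ratio
(q75/q25 for the interquartile-range variables, q97.5/q2.5 otherwise),
because no two-parameter gamma can match a mean of 51 min and quartiles of
36/72 min simultaneously (the interval midpoint exceeds the mean while the
gamma is right-skewed). The ratio is matched by Brent root-finding on the
log-shape to 1e-6.

### Triage and acute outcome

The DWI-FLAIR mismatch test is a Bernoulli filter: positive with
probability Se = 0.62 for truly eligible patients, 1 − Sp = 0.22 otherwise.
Under the MRI-based strategy every test-positive patient is treated.

Acute outcomes are drawn from a 7-category mRS distribution. For treated
patients the favorable mass (mRS 0–1) is the odds-scale shift of the
*untreated* favorable probability — the time-banded odds ratios are
treatment-versus-control contrasts, so they act on the control odds — and
the band is chosen by onset age at treatment (1.75 up to 180 min, 1.26 to
270, 1.00 beyond; the final value is carried indefinitely past 360 min,
where onset ages up to 638 min occur in the 8-h scenario). Within {0,1}
and {2..6} the treated arm's internal proportions apportion the mass.
Symptomatic intracranial hemorrhage is not an explicit patient-level event
(its harms are embedded in the treated-arm outcome distribution); a
population-level side-calculation multiplies the wake-up share of ischemic
strokes (20%), the simulated treated share, and the sICH rate among
treated (5.5%).

Acute costs: $11,462 per stroke hospitalization without tPA, $18,182 with,
plus $488 for the MRI under the MRI-based strategy; all costs 2013 USD, no
inflation adjustment.

### Lifetime Markov model

Yearly cycles from age 65 to a cap of 110. Event order within a cycle —
recurrent stroke first (probability 0.051; fatal with probability 0.190;
survivors move to a uniformly chosen strictly-worse non-death state, from
mRS 5 staying at 5), then, only if no recurrence, background non-stroke
death — is a modelling choice; the published description does not fix it,
and swapping the order changes results by less than Monte-Carlo noise at
the default parameters. Fatal recurrence replaces (does not stack with)
background mortality in that cycle. Background mortality comes from a life
table blended by sex (`p = 0.6·p_m + 0.4·p_f`) with the state's hazard
ratio applied on the hazard scale, `1 − (1 − p)^HR`, which cannot push a
probability past 1 (plain multiplication can, at high ages with HR 2.37).

Cycle accrual uses the state occupied at the start of the cycle; patients
dying in a cycle accrue that full cycle's utility and cost (no half-cycle
correction, matching common micro-simulation defaults). Recurrence adds a
$20,079 hospitalization to the cycle. Cycle *t* (t = 1, 2, …) is
discounted by (1.03)⁻ᵗ; the acute-phase cost enters undiscounted at t = 0.

Two engines implement the same process: a vectorised Monte-Carlo engine
(one cycle per loop iteration across the whole cohort) and a deterministic
cohort-expectation engine (age-dependent transition-matrix products). The
latter is the oracle: the engines agree on expected QALYs within 0.5% at
10⁵ patients.

The Monte-Carlo engine draws full-cohort uniform arrays every cycle even
for dead patients. This wastes a few random numbers but keeps each
patient's randomness positionally aligned across runs, so paired strategy
runs under a shared seed (common random numbers) give identical
trajectories to patients whose acute outcome the treatment did not change.
CRN is on by default for comparisons and reduces the sampling variance of
incremental QALYs by roughly an order of magnitude at n = 10⁴.

## Synthetic inputs and what the tests do (and do not) show

Two inputs of the original analysis are not publicly available:

- the arm-specific 7-category mRS outcome vectors. We ship a placeholder
  with untreated favorable mass exactly 0.451 (split evenly over mRS 0/1)
  and the remainder spread over mRS 2–6 in fixed declining proportions
  5:4:3:2:1; the treated arm equals the untreated arm, which is harmless
  because the model uses the treated arm only for conditional splits.
- the life table. We synthesize a Gompertz-Makeham table,
  `q(x) = 1 − exp(−(a + b·cˣ))` with a = 2·10⁻⁴, b = 3·10⁻⁵, c = 1.1
  (annual death probability ≈1.5% at 65, ≈19% at 90 — a plausible
  65-year-old cohort), identical sex columns unless multipliers are given.

Both are labelled `synthetic` in their filenames and provenance flags and
can be replaced by user-supplied tables (`LifeTable.from_file`,
`MRSDistribution.from_table`). Consequently every acute-phase percentage
the package reports is a faithful re-computation, while lifetime QALYs,
costs, ICERs, the two-way frontier location and PSA percentages are
*internally consistent* but not comparable to the published dollar
figures; tests cover those layers with closed forms (discounted annuity),
the cohort-expectation oracle, and structural identities (CEAC curves
summing to 1, NMB/ICER decision agreement, bisection bracketing) rather
than external values.

## Sensitivity-analysis machinery

- **PSA fitting.** Probabilities → beta, positive quantities → gamma,
  ratios → lognormal, the mRS vector → Dirichlet (concentration = base
  probabilities × effective sample size 100, configurable). Fits pin the
  mean at the base value and match the published range as a central 95%
  interval (interquartile for the two "(IQR)" time variables). Lognormal
  uses the exact closed form (σ from the interval ratio, μ from the mean);
  beta matches the central-interval *width* by root-finding on the
  concentration. Ranges incompatible with the base value as a mean (three
  utility rows where the base sits on or outside the published range) are
  fitted at the range midpoint; `fit_psa_distribution` itself refuses such
  entries so the substitution is always explicit.
- **One-way.** Both strategies re-run at each range endpoint under one
  shared seed, so inert parameters give exactly zero ICER spread; entries
  sort by descending spread (dominance flips carry an infinite sentinel).
- **Two-way.** NMB-optimal strategy per (Se, Sp) grid cell at
  $100,000/QALY; the reported frontier is the smallest grid specificity at
  which the MRI strategy is optimal at the base sensitivity.
- **Threshold.** Bisection on the sign of the incremental NMB, evaluated
  with a fixed seed per point (a deterministic objective); returns the
  midpoint plus the final bracket, whose endpoints provably straddle the
  sign change.
- **PSA.** Each of the (default 10,000) draws samples all parameters
  independently, re-runs the paired comparison with CRN, and records
  (ΔQALY, ΔC); the CEAC reports the fraction of draws with positive
  incremental NMB per willingness-to-pay value.

## Numerical choices and problem sizes

Strategy runs default to 10⁵ patients (acute percentages then carry
Monte-Carlo standard errors ≈0.15 pp, comfortably inside every published
rounding). The packaged analyses and test suite use smaller inner samples
(3·10³–2·10⁴) for the analysis layers, whose assertions are structural
rather than numeric. All randomness descends from a single integer seed
through named `SeedSequence` sub-streams (onset, delays, triage, outcome,
lifetime); there is no hidden global state, and identical seeds reproduce
outputs byte-for-byte.

Validation of loaded configurations is strict: out-of-range values raise,
nothing is clamped; serialization round-trips at full float precision.
ICERs are only formed when |ΔQALY| exceeds 10⁻⁹; otherwise a labelled
marker (`unstable`, `dominant`, `dominated`) is reported.

## Known limitations

- Absolute lifetime results depend on the synthetic mRS and mortality
  fixtures (above) and should not be quoted as reproductions of the
  published QALY/cost/ICER values.
- tPA harms are not modelled as explicit events; scenarios that change
  treatment rates inherit the harm profile embedded in the outcome
  distribution.
- The recurrence process is age- and state-homogeneous (constant 5.1%/yr)
  and the uniform worse-state destination is a stylised disability
  progression.
- Sleep duration, delays and diagnostic performance are independent in the
  model; real-world correlation (e.g. faster arrival among short sleepers)
  is not represented.
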