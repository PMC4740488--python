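# wakeupcea

A cost-effectiveness micro-simulation of MRI-guided thrombolysis for acute
**wake-up stroke** — ischemic stroke first noticed on awakening, so the true
onset time during sleep is unknown and patients are conventionally excluded
from tissue-type plasminogen activator (tPA), which is only recommended
within 4.5 hours of onset.

The model compares two strategies for a cohort of wake-up stroke patients
arriving at hospital (60% male, mean age 65):

1. **MRI-based** — acute DWI-FLAIR MRI; patients with a mismatch pattern
   (lesion on diffusion-weighted imaging but not yet on FLAIR, a proxy for
   stroke age < 4.5 h) receive tPA, the rest supportive care;
2. **no treatment** — supportive care for everyone (status quo).

It is written for health-economics and stroke-services researchers who want
to study how patient- and provider-specific factors (sleep duration, onset
timing distribution, travel and door-to-needle times, diagnostic accuracy)
move the value of image-guided treatment of wake-up stroke.

## Model

Per simulated patient:

- **Onset timing.** The fraction of sleep *remaining* at stroke onset is
  drawn from a configurable distribution (uniform over the sleep period in
  the base case; Beta(α, β) variants in scenarios), so the onset age at
  wake is `sleep × fraction`. Fixed delays — 51 min wake-to-hospital,
  77 min door-to-needle, 30 min added for MRI — give the onset age at
  treatment start; closed-form band probabilities
  `F((t − delay)/sleep)` serve as a deterministic oracle for the sampler.
- **Triage.** The mismatch test is positive with probability Se = 0.62 if
  the onset age at treatment is < 270 min, and 1 − Sp = 0.22 otherwise.
- **Acute outcome.** Each patient draws a modified Rankin Scale score
  (mRS 0–6). For treated patients the probability of a favorable outcome
  (mRS 0–1, baseline p₀ = 0.451) is shifted on the odds scale,
  `p' = OR·o/(1 + OR·o)` with `o = p₀/(1 − p₀)`, using time-banded odds
  ratios OR = 1.75 (≤180 min), 1.26 (181–270), 1.00 (beyond).
- **Lifetime.** A yearly-cycle Markov model over mRS states: recurrent
  stroke (5.1%/yr, 19% fatal, survivors move to a uniformly chosen worse
  state), otherwise background mortality from a life table with
  mRS-specific hazard ratios applied as `1 − (1 − p)^HR`; state utilities
  (0.8 … 0.2) and annual costs accrue, discounted at 3%/yr.
- **CEA.** Strategy means of discounted QALYs and costs (2013 USD) give the
  incremental cost-effectiveness ratio ICER = ΔC/ΔQ, judged against a
  willingness to pay of $100,000/QALY via net monetary benefit
  NMB = λ·Q − C. One-way (tornado), two-way (Se × Sp), threshold
  (bisection on incremental NMB) and probabilistic (joint parameter draws,
  CEAC) sensitivity analyses are built in.

Two inputs of the original analysis were never published: the arm-specific
mRS outcome vectors and the life table. The package ships clearly labelled
**synthetic** stand-ins (a placeholder mRS distribution constrained only by
p₀ = 0.451, and a Gompertz-Makeham life table), so absolute lifetime QALYs,
costs and ICERs are illustrative; the acute-phase percentages are faithful.
See `docs/methods.md`.

## Worked example

```bash
wakeupcea run --n 100000 --seed 1 --out results/
```

prints `dQALY=0.043 dCost=2470 ICER=58,026 optimal=mri_based` to stderr and
writes `results/strategies.csv`:

```text
strategy,n_patients,pct_mrs01,pct_onset_lt_270,pct_onset_ge_270,pct_treated,pct_inappropriately_treated,life_years,qalys,cost,icer
no_treatment,100000,45.0,23.5,76.5,0.0,0.0,10.835,6.185,106343.0,
mri_based,100000,46.1,23.5,76.5,31.5,16.9,10.853,6.227,108813.0,"58,026"
```

Reading the MRI-based row: 23.5% of patients reach treatment within the
4.5-hour window (closed form: 112/480 = 23.3%); 31.5% test positive and
receive tPA, of whom more than half — 16.9% of all patients — are treated
beyond the window because of imperfect specificity; the favorable-outcome
share rises from 45.0% to 46.1%. The lifetime columns use the synthetic
mRS/life-table fixtures, so the ICER of $58,026/QALY illustrates the
machinery rather than reproducing a published dollar figure. A run manifest
(`manifest.json`) records the resolved parameters, seed and fixture
provenance for bit-for-bit reproduction.

Other entry points: `wakeupcea scenarios` (named presets: `base8h`,
`sleep6h`, `sleep4h`, `beta44`, `beta35`, …), `wakeupcea psa`,
`wakeupcea tornado`, `wakeupcea twoway`, `wakeupcea threshold`, and
`wakeupcea export-fixtures` to dump the editable synthetic inputs.

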