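"""Strategy-level simulation and cost-effectiveness statistics.

``run_strategy`` pushes a cohort of simulated wake-up stroke patients
through onset timing -> (MRI triage) -> acute mRS -> lifetime Markov model
and aggregates the results; ``compare`` turns two strategy aggregates into
incremental cost-effectiveness statistics (ICER, or a dominance marker);
``net_monetary_benefit`` is the linearised decision criterion used by the
sensitivity machinery.

Randomness is organised in named sub-streams of a single seed so that the
two strategies can share their onset, delay, triage and outcome draws
(common random numbers), which sharply reduces the variance of the
incremental estimates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .acute import acute_phase_cost, sample_acute_mrs
from .fixtures import default_life_table, default_mrs_distribution
from .lifetime import simulate_lifetimes
from .onset import onset_age_at_treatment, sample_delays, sample_onset_age
from .parameters import ModelParameters, ValidationError

__all__ = [
    "STRATEGIES",
    "StrategyResult",
    "CEAResult",
    "run_strategy",
    "run_comparison",
    "compare",
    "net_monetary_benefit",
]

STRATEGIES = ("no_treatment", "mri_based")

#: below this |delta QALY| an ICER is numerically meaningless
_QALY_FLOOR = 1e-9

DOMINANT = "dominant"
DOMINATED = "dominated"
UNSTABLE = "unstable"
LESS_COSTLY_LESS_EFFECTIVE = "icer_sw_quadrant"


@dataclass(frozen=True)
class StrategyResult:
    """Per-strategy aggregates over a simulated cohort."""

    strategy: str
    n_patients: int
    pct_mrs01: float
    pct_onset_lt_270: float
    pct_onset_ge_270: float
    pct_treated: float
    pct_inappropriately_treated: float
    life_years: float
    qalys: float
    cost: float

    def __post_init__(self):
        if self.pct_inappropriately_treated > self.pct_treated + 1e-9:
            raise ValidationError(
                "inappropriately treated share cannot exceed treated share"
            )


@dataclass(frozen=True)
class CEAResult:
    """Incremental statistics of an alternative versus a reference strategy."""

    delta_qalys: float
    delta_cost: float
    icer: float | None
    icer_label: str | None
    optimal_at_wtp: str

    @property
    def icer_display(self) -> str:
        if self.icer is not None:
            return f"{self.icer:,.0f}"
        return self.icer_label or ""


def _spawn_rngs(seed: int, n_streams: int = 5) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n_streams)]


def run_strategy(
    strategy: str,
    params: ModelParameters,
    n: int | None = None,
    seed: int | None = None,
    mrs_dist=None,
    life_table=None,
) -> StrategyResult:
    """Simulate ``n`` patients under one strategy; deterministic given seed.

    The same seed yields identical onset/delay/triage/outcome draws across
    strategies (common random numbers), so paired runs differ only through
    the treatment decision.  ``pct_onset_lt_270`` classifies patients by
    onset age at the (hypothetical) treatment start, i.e. including the
    full delay chain, under both strategies.
    """
    if strategy not in STRATEGIES:
        raise ValidationError(f"unknown strategy: {strategy!r}")
    params.validate()
    n = n if n is not None else params.n_patients
    seed = seed if seed is not None else params.seed
    if mrs_dist is None:
        mrs_dist = default_mrs_distribution()
    if life_table is None:
        life_table = default_life_table()

    rng_onset, rng_delay, rng_test, rng_mrs, rng_life = _spawn_rngs(seed)

    onset_wake = sample_onset_age(params.onset, params.timing.sleep_minutes, rng_onset, size=n)
    delays = sample_delays(params.timing, rng_delay, size=n)
    t_treat = onset_age_at_treatment(onset_wake, delays, "mri_based")
    threshold = params.diagnostic.eligibility_threshold_minutes
    truly_eligible = t_treat < threshold

    # triage draw consumed under both strategies to keep the streams aligned
    p_pos = np.where(
        truly_eligible, params.diagnostic.sensitivity, 1.0 - params.diagnostic.specificity
    )
    test_positive = rng_test.uniform(size=n) < p_pos
    treated = test_positive if strategy == "mri_based" else np.zeros(n, dtype=bool)

    acute_mrs = sample_acute_mrs(treated, t_treat, mrs_dist, params.treatment_effect, rng_mrs)
    acute_cost = acute_phase_cost(strategy, treated, params.costs)
    ly, qalys, life_cost = simulate_lifetimes(acute_mrs, params, life_table, rng_life)
    total_cost = acute_cost + life_cost

    return StrategyResult(
        strategy=strategy,
        n_patients=n,
        pct_mrs01=100.0 * float(np.mean(acute_mrs <= 1)),
        pct_onset_lt_270=100.0 * float(np.mean(truly_eligible)),
        pct_onset_ge_270=100.0 * float(np.mean(~truly_eligible)),
        pct_treated=100.0 * float(np.mean(treated)),
        pct_inappropriately_treated=100.0 * float(np.mean(treated & ~truly_eligible)),
        life_years=float(np.mean(ly)),
        qalys=float(np.mean(qalys)),
        cost=float(np.mean(total_cost)),
    )


def run_comparison(
    params: ModelParameters,
    n: int | None = None,
    seed: int | None = None,
    common_random_numbers: bool = True,
    mrs_dist=None,
    life_table=None,
) -> tuple[StrategyResult, StrategyResult, "CEAResult"]:
    """Run both strategies and compare them (CRN on by default)."""
    seed = seed if seed is not None else params.seed
    if common_random_numbers:
        seeds = (seed, seed)
    else:
        children = np.random.SeedSequence(seed).spawn(2)
        seeds = tuple(int(c.generate_state(1)[0] % 2**31) for c in children)
    ref = run_strategy("no_treatment", params, n, seeds[0], mrs_dist, life_table)
    alt = run_strategy("mri_based", params, n, seeds[1], mrs_dist, life_table)
    return ref, alt, compare(ref, alt, params.demographics.willingness_to_pay)


def compare(
    reference: StrategyResult,
    alternative: StrategyResult,
    wtp: float = 100_000.0,
) -> CEAResult:
    """Incremental cost-effectiveness of ``alternative`` vs ``reference``.

    The ICER is reported only in the standard trade-off quadrants; strict
    dominance in either direction and near-zero QALY differences are
    returned as labels rather than ratios.
    """
    dq = alternative.qalys - reference.qalys
    dc = alternative.cost - reference.cost
    icer: float | None = None
    label: str | None = None
    if abs(dq) < _QALY_FLOOR:
        label = UNSTABLE
    elif dq > 0 and dc < 0:
        label = DOMINANT
    elif dq < 0 and dc > 0:
        label = DOMINATED
    else:
        icer = dc / dq
        if dq < 0:
            label = LESS_COSTLY_LESS_EFFECTIVE
    nmb_ref = net_monetary_benefit(reference, wtp)
    nmb_alt = net_monetary_benefit(alternative, wtp)
    optimal = alternative.strategy if nmb_alt > nmb_ref else reference.strategy
    return CEAResult(dq, dc, icer, label, optimal)


def net_monetary_benefit(result: StrategyResult, wtp: float) -> float:
    """NMB = wtp x QALYs - cost (currency units)."""
    if wtp < 0:
        raise ValidationError("willingness to pay must be >= 0")
    return wtp * result.qalys - result.cost
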