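"""Lifetime Markov model over mRS health states.

Survivors of the acute phase enter a yearly-cycle state-transition model in
their acute mRS state.  Each cycle they face (in this order) a recurrent
stroke — fatal with the case-fatality probability, otherwise a move to a
uniformly chosen worse non-death state — and, failing recurrence,
background non-stroke mortality from a life table with an mRS-specific
hazard ratio applied on the hazard scale.  Cycles accrue state utility and
annual care costs (full-cycle accrual also in the cycle of death; no
half-cycle correction), discounted annually.

Both an individual-level Monte-Carlo engine (vectorised over patients) and
a deterministic cohort-expectation engine (transition-matrix products,
used as the oracle for the former) are provided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .parameters import (
    DemographicAndEconomicSettings,
    ModelParameters,
    ValidationError,
)

__all__ = [
    "LifeTable",
    "MarkovState",
    "LifetimeResult",
    "synthesize_life_table",
    "annual_nonstroke_death_prob",
    "recurrent_stroke_destination",
    "step_one_cycle",
    "simulate_lifetime",
    "simulate_lifetimes",
    "cohort_expectation",
]

DEAD = 6


@dataclass(frozen=True)
class LifeTable:
    """Annual all-cause death probabilities by single year of age and sex."""

    ages: np.ndarray
    qx_male: np.ndarray
    qx_female: np.ndarray
    provenance: str = "synthetic"

    def __post_init__(self):
        ages = np.asarray(self.ages)
        if len(ages) == 0 or not np.all(np.diff(ages) == 1):
            raise ValidationError("life-table ages must be contiguous 1-year steps")
        for name in ("qx_male", "qx_female"):
            q = np.asarray(getattr(self, name))
            if q.shape != ages.shape:
                raise ValidationError(f"{name} must match ages in length")
            if np.any((q < 0) | (q > 1)):
                raise ValidationError(f"{name} must be in [0, 1]")

    @property
    def max_age(self) -> float:
        return float(self.ages[-1])

    def blended_qx(self, age: float, male_fraction: float) -> float:
        """Sex-blended annual death probability; 1.0 beyond the table end."""
        if age > self.ages[-1]:
            return 1.0
        i = int(np.searchsorted(self.ages, age, side="right")) - 1
        if i < 0:
            raise ValidationError(f"age {age} below life-table start {self.ages[0]}")
        return float(
            male_fraction * self.qx_male[i] + (1.0 - male_fraction) * self.qx_female[i]
        )

    @classmethod
    def from_file(cls, path, provenance: str = "file") -> "LifeTable":
        df = pd.read_csv(path, sep=None, engine="python")
        required = {"age", "qx_male", "qx_female"}
        if not required.issubset(df.columns):
            raise ValidationError(
                f"life table must have columns {sorted(required)}, got {list(df.columns)}"
            )
        df = df.sort_values("age")
        return cls(
            df["age"].to_numpy(dtype=float),
            df["qx_male"].to_numpy(dtype=float),
            df["qx_female"].to_numpy(dtype=float),
            provenance=provenance,
        )

    def to_file(self, path) -> None:
        pd.DataFrame(
            {"age": self.ages, "qx_male": self.qx_male, "qx_female": self.qx_female}
        ).to_csv(path, sep="\t", index=False)


@dataclass
class MarkovState:
    mrs: int
    age: float


@dataclass(frozen=True)
class LifetimeResult:
    """Discounted lifetime aggregates for one patient (or a mean)."""

    life_years: float
    qalys: float
    cost: float


def synthesize_life_table(
    makeham_a: float = 0.0002,
    makeham_b: float = 0.00003,
    makeham_c: float = 1.1,
    max_age: float = 110.0,
    male_multiplier: float = 1.0,
    female_multiplier: float = 1.0,
) -> LifeTable:
    """Gompertz-Makeham synthetic life table (hazard a + b*c^age).

    Annual death probability at age x is ``1 - exp(-(a + b*c**x))``, capped
    at 1; the male/female columns are identical unless sex multipliers are
    supplied (applied on the hazard).
    """
    if makeham_a < 0 or makeham_b < 0 or makeham_c <= 0:
        raise ValidationError("Gompertz-Makeham parameters must be positive")
    ages = np.arange(0.0, max_age + 1.0)
    hazard = makeham_a + makeham_b * makeham_c**ages
    qx_m = np.minimum(1.0 - np.exp(-hazard * male_multiplier), 1.0)
    qx_f = np.minimum(1.0 - np.exp(-hazard * female_multiplier), 1.0)
    qx_m[-1] = qx_f[-1] = 1.0  # closed final interval
    return LifeTable(ages, qx_m, qx_f, provenance="synthetic")


def annual_nonstroke_death_prob(
    age: float,
    demographics: DemographicAndEconomicSettings,
    table: LifeTable,
    hr: float,
) -> float:
    """Background death probability with an mRS hazard ratio.

    The sex-blended table probability p is adjusted on the hazard scale,
    ``1 - (1 - p) ** hr``, which keeps the result a probability for any
    hr > 0 (plain multiplication can exceed 1 at high ages).
    """
    if hr <= 0:
        raise ValidationError("hazard ratio must be > 0")
    p = table.blended_qx(age, demographics.male_fraction)
    return 1.0 - (1.0 - p) ** hr


def recurrent_stroke_destination(current_mrs: int, rng: np.random.Generator) -> int:
    """Destination state after a survived recurrent stroke.

    Uniform over the strictly worse non-death states; from mRS 5 the
    patient remains in mRS 5 (death is handled by the case-fatality draw).
    """
    if not 0 <= current_mrs <= 5:
        raise ValidationError("current_mrs must be in 0..5")
    if current_mrs == 5:
        return 5
    return int(rng.integers(current_mrs + 1, 6))


def _annual_costs(params: ModelParameters) -> np.ndarray:
    c = params.costs
    return np.array([c.annual_cost_mrs0_3] * 4 + [c.annual_cost_mrs4_5] * 2)


def step_one_cycle(
    state: MarkovState,
    params: ModelParameters,
    table: LifeTable,
    rng: np.random.Generator,
    force_recurrence: bool | None = None,
    force_fatal: bool | None = None,
):
    """Advance one yearly cycle; returns (next_state, cycle_qalys, cycle_cost).

    Event order: recurrent stroke first (fatal recurrence transitions to
    death at cycle end, non-fatal moves to a worse state); otherwise
    background non-stroke death.  The cycle's utility and annual cost are
    those of the state occupied at the start of the cycle and accrue in
    full even in the cycle of death.  ``force_*`` flags override the random
    event draws (testing hook).
    """
    if state.mrs == DEAD:
        raise ValidationError("step_one_cycle called on a dead state")
    prog = params.progression
    utility = params.utilities.utility_by_mrs[state.mrs]
    cost = float(_annual_costs(params)[state.mrs])

    recurs = (
        force_recurrence
        if force_recurrence is not None
        else bool(rng.uniform() < prog.annual_recurrent_stroke_probability)
    )
    if recurs:
        cost += params.costs.recurrent_stroke_hosp_cost
        fatal = (
            force_fatal
            if force_fatal is not None
            else bool(rng.uniform() < prog.recurrent_stroke_case_fatality)
        )
        next_mrs = DEAD if fatal else recurrent_stroke_destination(state.mrs, rng)
    else:
        hr = prog.nonstroke_death_hazard_ratio_by_mrs[state.mrs]
        p_die = annual_nonstroke_death_prob(state.age, params.demographics, table, hr)
        next_mrs = DEAD if rng.uniform() < p_die else state.mrs
    return MarkovState(next_mrs, state.age + 1.0), utility, cost


def simulate_lifetime(
    initial_mrs: int,
    params: ModelParameters,
    table: LifeTable,
    rng: np.random.Generator,
) -> LifetimeResult:
    """Monte-Carlo lifetime for a single patient from ``start_age``.

    Cycle t (t = 1, 2, ...) is discounted by ``(1 + r) ** -t``.  Acute-phase
    cost is NOT included here; the caller adds it undiscounted at t = 0.
    """
    if initial_mrs == DEAD:
        return LifetimeResult(0.0, 0.0, 0.0)
    demo = params.demographics
    r = demo.annual_discount_rate
    state = MarkovState(initial_mrs, demo.start_age)
    ly = qalys = cost = 0.0
    t = 0
    while state.mrs != DEAD and state.age < demo.max_age:
        t += 1
        disc = (1.0 + r) ** -t
        state, u, c = step_one_cycle(state, params, table, rng)
        ly += disc
        qalys += disc * u
        cost += disc * c
    return LifetimeResult(ly, qalys, cost)


def simulate_lifetimes(
    initial_mrs: np.ndarray,
    params: ModelParameters,
    table: LifeTable,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised Monte-Carlo lifetimes for an array of patients.

    Same process as :func:`simulate_lifetime`, advanced one cycle per loop
    iteration for all still-alive patients simultaneously.  Returns
    per-patient (life_years, qalys, cost) arrays, discounted.
    """
    params.validate()
    demo = params.demographics
    prog = params.progression
    r = demo.annual_discount_rate
    utilities = np.asarray(params.utilities.utility_by_mrs)
    annual_cost = _annual_costs(params)
    hrs = np.asarray(prog.nonstroke_death_hazard_ratio_by_mrs)

    mrs = np.asarray(initial_mrs, dtype=np.int64).copy()
    n = mrs.shape[0]
    ly = np.zeros(n)
    qalys = np.zeros(n)
    cost = np.zeros(n)

    n_cycles = int(np.floor(demo.max_age - demo.start_age))
    for t in range(1, n_cycles + 1):
        # full-length draws every cycle keep patient i's random numbers
        # positionally aligned across runs (common random numbers): patients
        # entering in the same state follow identical trajectories
        u_rec = rng.uniform(size=n)
        u_fat = rng.uniform(size=n)
        u_dest = rng.uniform(size=n)
        u_bg = rng.uniform(size=n)

        alive = mrs != DEAD
        if not alive.any():
            continue
        age = demo.start_age + (t - 1)
        disc = (1.0 + r) ** -t
        m = mrs[alive]

        ly[alive] += disc
        qalys[alive] += disc * utilities[m]
        ccost = annual_cost[m].astype(float)

        recurs = u_rec[alive] < prog.annual_recurrent_stroke_probability
        ccost[recurs] += params.costs.recurrent_stroke_hosp_cost
        fatal = recurs & (u_fat[alive] < prog.recurrent_stroke_case_fatality)
        moved = recurs & ~fatal
        # uniform over {m+1..5}; mRS5 survivors stay put
        n_worse = np.maximum(5 - m, 1)
        dest = np.minimum(m + 1 + (u_dest[alive] * n_worse).astype(np.int64), 5)

        p_base = table.blended_qx(age, demo.male_fraction)
        p_die = 1.0 - (1.0 - p_base) ** hrs[m]
        bg_death = ~recurs & (u_bg[alive] < p_die)

        new_m = m.copy()
        new_m[moved] = dest[moved]
        new_m[fatal | bg_death] = DEAD

        cost[alive] += disc * ccost
        mrs[alive] = new_m
    return ly, qalys, cost


def cohort_expectation(
    initial_probs: np.ndarray,
    params: ModelParameters,
    table: LifeTable,
) -> LifetimeResult:
    """Deterministic expected lifetime outcomes via transition matrices.

    ``initial_probs`` is a 7-vector of state probabilities at model entry.
    Serves as the exact-expectation oracle for the Monte-Carlo engines.
    """
    params.validate()
    probs = np.asarray(initial_probs, dtype=float)
    if probs.shape != (7,) or abs(probs.sum() - 1.0) > 1e-9 or np.any(probs < 0):
        raise ValidationError("initial_probs must be a 7-state probability vector")
    demo = params.demographics
    prog = params.progression
    r = demo.annual_discount_rate
    utilities = np.append(np.asarray(params.utilities.utility_by_mrs), 0.0)
    annual_cost = np.append(_annual_costs(params), 0.0)
    hrs = np.asarray(prog.nonstroke_death_hazard_ratio_by_mrs)
    q_rec = prog.annual_recurrent_stroke_probability
    cf = prog.recurrent_stroke_case_fatality

    pi = probs.copy()
    ly = qalys = cost = 0.0
    n_cycles = int(np.floor(demo.max_age - demo.start_age))
    for t in range(1, n_cycles + 1):
        age = demo.start_age + (t - 1)
        disc = (1.0 + r) ** -t
        alive_mass = pi[:DEAD]
        ly += disc * alive_mass.sum()
        qalys += disc * float(alive_mass @ utilities[:DEAD])
        cost += disc * float(
            alive_mass @ annual_cost[:DEAD]
            + alive_mass.sum() * q_rec * params.costs.recurrent_stroke_hosp_cost
        )

        T = np.zeros((7, 7))
        T[DEAD, DEAD] = 1.0
        p_base = table.blended_qx(age, demo.male_fraction)
        for m in range(6):
            p_die = 1.0 - (1.0 - p_base) ** hrs[m]
            T[m, DEAD] += q_rec * cf  # fatal recurrence
            if m < 5:
                for d in range(m + 1, 6):
                    T[m, d] += q_rec * (1.0 - cf) / (5 - m)
            else:
                T[m, m] += q_rec * (1.0 - cf)
            T[m, DEAD] += (1.0 - q_rec) * p_die
            T[m, m] += (1.0 - q_rec) * (1.0 - p_die)
        pi = pi @ T
    return LifetimeResult(ly, qalys, cost)
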