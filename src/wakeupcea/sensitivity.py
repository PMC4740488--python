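"""Sensitivity-analysis apparatus: one-way, two-way, threshold, and PSA.

One-way analyses re-run the paired strategy comparison with a single
parameter at each end of its plausible range (tornado ordering by ICER
spread); the two-way analysis maps the NMB-optimal strategy over a
sensitivity x specificity grid; threshold search bisects on the sign of
the incremental NMB; and the probabilistic sensitivity analysis draws all
parameters jointly from fitted distributions (beta for probabilities,
gamma for positive quantities, lognormal for ratios, Dirichlet for the
mRS outcome vector) and summarises decision uncertainty as a
cost-effectiveness acceptability curve.

Distribution fitting pins the mean at the base-case value and matches the
published range as a central interval (95% by default; interquartile for
the two time variables published as IQRs) through scale-free quantile
ratios where available, 1-D root finds otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .acute import MRSDistribution
from .cea import compare, net_monetary_benefit, run_comparison, run_strategy
from .fixtures import default_mrs_distribution, placeholder_mrs_distribution
from .onset import fit_gamma_mean_interval
from .parameters import ModelParameters, set_by_path

__all__ = [
    "FitError",
    "PSAEntry",
    "PSASpec",
    "ThresholdResult",
    "TornadoEntry",
    "fit_psa_distribution",
    "default_psa_spec",
    "default_one_way_spec",
    "one_way_analysis",
    "two_way_sensitivity_specificity",
    "threshold_search",
    "run_psa",
]


class FitError(ValueError):
    """A distribution cannot be fitted to the requested mean/range."""


@dataclass(frozen=True)
class PSAEntry:
    """One parameter's uncertainty specification.

    ``interpretation`` says how (low, high) is read: a central 95% interval
    or an interquartile range.  ``mean`` defaults to the base value; it may
    be overridden when a published range is incompatible with the base
    value as a mean.
    """

    path: str
    family: str  # beta | gamma | lognormal | dirichlet | fixed
    base: float | Sequence[float]
    low: float | None = None
    high: float | None = None
    interpretation: str = "ci95"
    mean: float | None = None
    dirichlet_ess: float = 100.0

    @property
    def fitted_mean(self) -> float:
        return self.base if self.mean is None else self.mean  # type: ignore[return-value]


PSASpec = list  # list[PSAEntry]


@dataclass(frozen=True)
class ThresholdResult:
    """Outcome of a threshold search: the crossing point and its bracket.

    ``bracket`` is the final bisection interval — two evaluated parameter
    values at which the incremental NMB (same seed, common random numbers)
    has opposite signs; its width is at most the search tolerance.
    """

    value: float
    bracket: tuple[float, float]


@dataclass(frozen=True)
class TornadoEntry:
    path: str
    low: float
    high: float
    icer_low: float | None
    icer_high: float | None
    label_low: str | None
    label_high: str | None
    spread: float


class _Sampler:
    """Frozen sampler for one parameter; exposes quantiles for checking."""

    def __init__(self, draw: Callable, dist=None):
        self._draw = draw
        self.dist = dist

    def sample(self, rng: np.random.Generator, size=None):
        return self._draw(rng, size)

    def ppf(self, q):
        if self.dist is None:
            raise FitError("sampler has no quantile function")
        return self.dist.ppf(q)


def _interval_probs(interpretation: str) -> tuple[float, float]:
    if interpretation == "ci95":
        return 0.025, 0.975
    if interpretation == "iqr":
        return 0.25, 0.75
    raise FitError(f"unknown range interpretation: {interpretation!r}")


def _fit_beta(mean: float, low: float, high: float, interpretation: str):
    if not (0.0 <= low < high <= 1.0) or not (low < mean < high):
        raise FitError(
            f"beta fit infeasible: mean {mean} must lie inside ({low}, {high}) in [0,1]"
        )
    p_lo, p_hi = _interval_probs(interpretation)
    width = high - low

    def gap(log_kappa: float) -> float:
        k = np.exp(log_kappa)
        d = stats.beta(mean * k, (1.0 - mean) * k)
        return (d.ppf(p_hi) - d.ppf(p_lo)) - width

    lo_b, hi_b = -4.0, 18.0
    if gap(lo_b) < 0 or gap(hi_b) > 0:
        raise FitError(f"beta fit infeasible for mean={mean}, range=({low}, {high})")
    log_kappa = optimize.brentq(gap, lo_b, hi_b, xtol=1e-10)
    k = float(np.exp(log_kappa))
    return stats.beta(mean * k, (1.0 - mean) * k)


def _fit_gamma(mean: float, low: float, high: float, interpretation: str):
    level = 0.95 if interpretation == "ci95" else 0.50
    shape, scale = fit_gamma_mean_interval(mean, low, high, level=level)
    return stats.gamma(shape, scale=scale)


def _fit_lognormal(mean: float, low: float, high: float, interpretation: str):
    if not (0.0 < low < high) or mean <= 0:
        raise FitError(f"lognormal fit infeasible for mean={mean}, range=({low}, {high})")
    p_lo, p_hi = _interval_probs(interpretation)
    z = stats.norm.ppf(p_hi) - stats.norm.ppf(p_lo)
    sigma = float(np.log(high / low) / z)
    mu = float(np.log(mean) - 0.5 * sigma**2)  # exact arithmetic mean
    return stats.lognorm(sigma, scale=np.exp(mu))


def fit_psa_distribution(entry: PSAEntry) -> _Sampler:
    """Fit a sampler for one PSA entry; raises :class:`FitError` if infeasible."""
    if entry.family == "fixed":
        base = entry.base
        return _Sampler(lambda rng, size=None: base if size is None else np.full(size, base))
    if entry.family == "dirichlet":
        conc = np.asarray(entry.base, dtype=float) * entry.dirichlet_ess
        if np.any(conc <= 0):
            raise FitError(f"{entry.path}: Dirichlet concentration must be positive")
        return _Sampler(lambda rng, size=None: rng.dirichlet(conc, size=size))
    if entry.low is None or entry.high is None:
        raise FitError(f"{entry.path}: range required for family {entry.family!r}")
    try:
        if entry.family == "beta":
            dist = _fit_beta(entry.fitted_mean, entry.low, entry.high, entry.interpretation)
        elif entry.family == "gamma":
            dist = _fit_gamma(entry.fitted_mean, entry.low, entry.high, entry.interpretation)
        elif entry.family == "lognormal":
            dist = _fit_lognormal(entry.fitted_mean, entry.low, entry.high, entry.interpretation)
        else:
            raise FitError(f"{entry.path}: unknown family {entry.family!r}")
    except FitError:
        raise
    except ValueError as exc:
        raise FitError(f"{entry.path}: {exc}") from exc
    return _Sampler(lambda rng, size=None: dist.rvs(size=size, random_state=rng), dist)


def _auto_mean(base: float, low: float, high: float) -> float | None:
    """Base value if usable as the fitted mean, else the range midpoint."""
    return None if low < base < high else (low + high) / 2.0


def default_psa_spec(
    mrs_dist: MRSDistribution | None = None, dirichlet_ess: float = 100.0
) -> list[PSAEntry]:
    """The full published uncertainty specification.

    Utility rows whose published range is incompatible with the base value
    as a mean are fitted at the range midpoint instead (flagged via the
    ``mean`` field).
    """
    if mrs_dist is None:
        mrs_dist = default_mrs_distribution()

    def entry(path, family, base, low, high, interpretation="ci95"):
        return PSAEntry(
            path, family, base, low, high, interpretation,
            mean=_auto_mean(base, low, high),
        )

    spec = [
        entry("diagnostic.sensitivity", "beta", 0.62, 0.57, 0.67),
        entry("diagnostic.specificity", "beta", 0.78, 0.72, 0.84),
        entry("timing.wake_to_hospital_minutes", "gamma", 51.0, 36.0, 72.0, "iqr"),
        entry("timing.door_to_needle_minutes", "gamma", 77.0, 60.0, 98.0, "iqr"),
        entry("timing.mri_additional_minutes", "gamma", 30.0, 20.0, 40.0),
        entry("treatment_effect.odds_ratios[0]", "lognormal", 1.75, 1.35, 2.27),
        entry("treatment_effect.odds_ratios[1]", "lognormal", 1.26, 1.05, 1.51),
        entry("treatment_effect.odds_ratios[2]", "lognormal", 1.00, 0.95, 1.40),
        entry("progression.nonstroke_death_hazard_ratio_by_mrs[2]", "lognormal", 1.11, 1.0, 1.3),
        entry("progression.nonstroke_death_hazard_ratio_by_mrs[3]", "lognormal", 1.27, 1.2, 1.4),
        entry("progression.nonstroke_death_hazard_ratio_by_mrs[4]", "lognormal", 1.71, 1.3, 2.0),
        entry("progression.nonstroke_death_hazard_ratio_by_mrs[5]", "lognormal", 2.37, 1.5, 4.0),
        entry("progression.annual_recurrent_stroke_probability", "beta", 0.051, 0.02, 0.065),
        entry("progression.recurrent_stroke_case_fatality", "beta", 0.190, 0.10, 0.30),
        entry("costs.mri_cost", "gamma", 488.0, 390.0, 586.0),
        entry("costs.acute_hosp_no_treatment", "gamma", 11_462.0, 10_421.0, 12_503.0),
        entry("costs.acute_hosp_with_treatment", "gamma", 18_182.0, 16_798.0, 19_565.0),
        entry("costs.annual_cost_mrs0_3", "gamma", 5_293.0, 4_234.0, 6_351.0),
        entry("costs.annual_cost_mrs4_5", "gamma", 13_557.0, 10_846.0, 16_268.0),
        entry("costs.recurrent_stroke_hosp_cost", "gamma", 20_079.0, 16_063.0, 24_095.0),
        entry("utilities.utility_by_mrs[0]", "beta", 0.8, 0.8, 1.0),
        entry("utilities.utility_by_mrs[1]", "beta", 0.8, 0.8, 0.95),
        entry("utilities.utility_by_mrs[2]", "beta", 0.65, 0.68, 0.9),
        entry("utilities.utility_by_mrs[3]", "beta", 0.5, 0.45, 0.65),
        entry("utilities.utility_by_mrs[4]", "beta", 0.35, 0.1, 0.4),
        entry("utilities.utility_by_mrs[5]", "beta", 0.2, 0.001, 0.32),
        PSAEntry(
            "mrs_distribution", "dirichlet", tuple(mrs_dist.untreated),
            dirichlet_ess=dirichlet_ess,
        ),
    ]
    return spec


def default_one_way_spec() -> list[tuple[str, float, float]]:
    """(path, low, high) triples for every published one-way range."""
    skip = {"mrs_distribution"}
    return [
        (e.path, e.low, e.high)
        for e in default_psa_spec(placeholder_mrs_distribution())
        if e.path not in skip and e.low is not None
    ] + [
        ("demographics.start_age", 55.0, 75.0),
        ("demographics.male_fraction", 0.40, 0.80),
        ("timing.sleep_minutes", 240.0, 480.0),
    ]


def _icer_at(params: ModelParameters, n, seed, wtp, mrs_dist=None, life_table=None):
    _, _, cea = run_comparison(params, n, seed, True, mrs_dist, life_table)
    return cea


def one_way_analysis(
    params: ModelParameters,
    spec: Sequence[tuple[str, float, float]],
    n: int | None = None,
    seed: int | None = None,
    mrs_dist=None,
    life_table=None,
) -> list[TornadoEntry]:
    """Tornado analysis: ICER at each range endpoint, sorted by spread.

    Common random numbers (one shared seed) across every evaluation, so a
    parameter with no causal effect produces zero spread exactly.
    Dominance cases carry ``None`` ICERs and an infinite spread sentinel.
    """
    entries = []
    for path, low, high in spec:
        results = {}
        for name, value in (("low", low), ("high", high)):
            p = params.copy()
            set_by_path(p, path, value)
            results[name] = _icer_at(
                p, n, seed, params.demographics.willingness_to_pay, mrs_dist, life_table
            )
        cl, ch = results["low"], results["high"]
        if cl.icer is not None and ch.icer is not None:
            spread = abs(ch.icer - cl.icer)
        elif (cl.delta_qalys, cl.delta_cost) == (ch.delta_qalys, ch.delta_cost):
            spread = 0.0  # endpoints indistinguishable (inert parameter)
        else:
            spread = float("inf")  # dominance flip sentinel
        entries.append(
            TornadoEntry(
                path, low, high, cl.icer, ch.icer, cl.icer_label, ch.icer_label, spread
            )
        )
    return sorted(entries, key=lambda e: e.spread, reverse=True)


def two_way_sensitivity_specificity(
    params: ModelParameters,
    se_grid: Sequence[float],
    sp_grid: Sequence[float],
    wtp: float | None = None,
    n: int | None = None,
    seed: int | None = None,
    mrs_dist=None,
    life_table=None,
) -> tuple[pd.DataFrame, float | None]:
    """Optimal-strategy map over a sensitivity x specificity grid.

    Returns a tidy DataFrame (sensitivity, specificity, optimal) and the
    smallest grid specificity at which the MRI strategy is optimal for the
    grid sensitivity closest to the base value (the decision frontier).
    """
    wtp = wtp if wtp is not None else params.demographics.willingness_to_pay
    rows = []
    for se in se_grid:
        for sp in sp_grid:
            p = params.copy()
            p.diagnostic.sensitivity = float(se)
            p.diagnostic.specificity = float(sp)
            ref, alt, _ = run_comparison(p, n, seed, True, mrs_dist, life_table)
            optimal = (
                "mri_based"
                if net_monetary_benefit(alt, wtp) > net_monetary_benefit(ref, wtp)
                else "no_treatment"
            )
            rows.append({"sensitivity": se, "specificity": sp, "optimal": optimal})
    df = pd.DataFrame(rows)
    base_se = min(se_grid, key=lambda s: abs(s - params.diagnostic.sensitivity))
    at_base = df[(df.sensitivity == base_se) & (df.optimal == "mri_based")]
    frontier = float(at_base.specificity.min()) if len(at_base) else None
    return df, frontier


def threshold_search(
    params: ModelParameters,
    path: str,
    bounds: tuple[float, float],
    wtp: float | None = None,
    n: int | None = None,
    seed: int | None = None,
    tol: float = 0.5,
    mrs_dist=None,
    life_table=None,
) -> ThresholdResult | None:
    """Bisection for the parameter value where the optimal strategy flips.

    Evaluates the incremental NMB sign with common random numbers (the
    same seed at every trial point, so the objective is a deterministic
    function of the parameter value).  Returns ``None`` when the sign does
    not change over ``bounds`` (no threshold in range).
    """
    wtp = wtp if wtp is not None else params.demographics.willingness_to_pay

    def inmb(value: float) -> float:
        p = params.copy()
        set_by_path(p, path, value)
        ref, alt, _ = run_comparison(p, n, seed, True, mrs_dist, life_table)
        return net_monetary_benefit(alt, wtp) - net_monetary_benefit(ref, wtp)

    lo, hi = bounds
    f_lo, f_hi = inmb(lo), inmb(hi)
    if f_lo == 0:
        return ThresholdResult(lo, (lo, hi))
    if f_hi == 0:
        return ThresholdResult(hi, (lo, hi))
    if np.sign(f_lo) == np.sign(f_hi):
        return None
    while hi - lo > tol:
        mid = (lo + hi) / 2.0
        f_mid = inmb(mid)
        if f_mid == 0:
            return ThresholdResult(mid, (lo, hi))
        if np.sign(f_mid) == np.sign(f_lo):
            lo, f_lo = mid, f_mid
        else:
            hi = mid
    return ThresholdResult((lo + hi) / 2.0, (lo, hi))


def run_psa(
    params: ModelParameters,
    spec: Sequence[PSAEntry] | None = None,
    draws: int = 10_000,
    n_per_draw: int = 10_000,
    seed: int = 0,
    wtp_grid: Sequence[float] = (0, 25_000, 50_000, 75_000, 100_000, 150_000, 200_000),
    mrs_dist=None,
    life_table=None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Probabilistic sensitivity analysis with CEAC summarisation.

    Each draw samples every specified parameter jointly (independently
    across parameters), re-runs the paired comparison with common random
    numbers, and records the incremental (QALY, cost) pair.  The CEAC
    gives, per willingness-to-pay value, the fraction of draws in which
    each strategy has the higher NMB; the two curves sum to 1 everywhere.
    """
    if spec is None:
        spec = default_psa_spec(mrs_dist)
    if mrs_dist is None:
        mrs_dist = default_mrs_distribution()
    samplers = {e.path: fit_psa_distribution(e) for e in spec}
    root = np.random.SeedSequence(seed)
    draw_seqs = root.spawn(draws)
    inner_seed = int(root.generate_state(1)[0] % 2**31)

    records = []
    for d, seq in enumerate(draw_seqs):
        rng = np.random.default_rng(seq)
        p = params.copy()
        draw_mrs = mrs_dist
        values: dict[str, float] = {}
        for path, sampler in samplers.items():
            value = sampler.sample(rng)
            if path == "mrs_distribution":
                vec = tuple(float(x) for x in np.asarray(value) / np.sum(value))
                draw_mrs = MRSDistribution(vec, vec, provenance=mrs_dist.provenance)
            else:
                set_by_path(p, path, float(value))
                values[path] = float(value)
        ref, alt, cea = run_comparison(p, n_per_draw, inner_seed, True, draw_mrs, life_table)
        records.append(
            {"draw": d, **values, "delta_qalys": cea.delta_qalys, "delta_cost": cea.delta_cost}
        )
    df = pd.DataFrame(records)

    dq = df["delta_qalys"].to_numpy()
    dc = df["delta_cost"].to_numpy()
    ceac_rows = []
    for wtp in wtp_grid:
        p_mri = float(np.mean(wtp * dq - dc > 0))
        ceac_rows.append(
            {"wtp": wtp, "p_mri_based": p_mri, "p_no_treatment": 1.0 - p_mri}
        )
    return df, pd.DataFrame(ceac_rows)
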