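"""Stroke-onset timing during sleep and the delay chain to treatment.

A wake-up stroke happens at an unknown time during sleep.  The model draws
the fraction of sleep *remaining* at onset from a configurable distribution
(uniform in the base case; beta families in scenario analyses), so the
"onset age" — time elapsed since the stroke — at wake-up is
``sleep_minutes * fraction``.  The onset age at treatment start adds the
wake-to-hospital, door-to-needle and MRI delays.

Alongside the Monte-Carlo samplers this module exposes the closed-form
probabilities of the onset age falling below a threshold or inside
time bands; these serve as deterministic oracles for the simulation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .parameters import OnsetDistribution, TimingParameters, ValidationError

__all__ = [
    "DelaySample",
    "sample_onset_age",
    "sample_delays",
    "onset_age_at_treatment",
    "prob_onset_age_below",
    "band_probabilities",
    "fit_gamma_mean_interval",
]


@dataclass(frozen=True)
class DelaySample:
    """One draw of the three delay components (minutes)."""

    wake_to_hospital: float
    door_to_needle: float
    mri_time: float

    @property
    def total(self) -> float:
        return self.wake_to_hospital + self.door_to_needle + self.mri_time


def _fraction_dist(dist: OnsetDistribution):
    if dist.family == "uniform":
        return stats.uniform(0.0, 1.0)
    if dist.family == "beta":
        return stats.beta(dist.alpha, dist.beta)
    raise ValidationError(f"unknown onset distribution family: {dist.family!r}")


def sample_onset_age(
    dist: OnsetDistribution,
    sleep_minutes: float,
    rng: np.random.Generator,
    size: int | None = None,
):
    """Draw onset age(s) at wake: ``sleep_minutes`` x fraction-of-sleep-remaining.

    With ``size=None`` returns a scalar, else an ndarray of that length.
    """
    if sleep_minutes <= 0:
        raise ValidationError("sleep_minutes must be > 0")
    if dist.family == "uniform":
        frac = rng.uniform(0.0, 1.0, size=size)
    elif dist.family == "beta":
        frac = rng.beta(dist.alpha, dist.beta, size=size)
    else:
        raise ValidationError(f"unknown onset distribution family: {dist.family!r}")
    return sleep_minutes * frac


def fit_gamma_mean_interval(
    mean: float, low: float, high: float, level: float = 0.50
) -> tuple[float, float]:
    """Fit a gamma (shape, scale) with exact mean and a quantile *ratio* match.

    The central interval ``(low, high)`` at probability ``level`` (0.50 for an
    IQR, 0.95 for a 95% interval) is matched through the scale-free quantile
    ratio ``q_hi/q_lo``, which depends on the shape alone; the scale then
    follows from the mean.  Root-finding on the log-shape to 1e-6 relative
    tolerance on the ratio.
    """
    if not (0 < low < high) or mean <= 0:
        raise ValidationError("gamma fit requires 0 < low < high and mean > 0")
    p_lo = (1.0 - level) / 2.0
    p_hi = 1.0 - p_lo
    target = high / low

    def ratio_gap(log_shape: float) -> float:
        k = np.exp(log_shape)
        with np.errstate(divide="ignore", over="ignore"):
            return stats.gamma.ppf(p_hi, k) / stats.gamma.ppf(p_lo, k) - target

    # wider interval relative to the mean => smaller shape
    lo_b, hi_b = -6.0, 12.0
    if ratio_gap(lo_b) < 0 or ratio_gap(hi_b) > 0:
        raise ValidationError(
            f"gamma fit infeasible for mean={mean}, interval=({low}, {high})"
        )
    log_shape = optimize.brentq(ratio_gap, lo_b, hi_b, xtol=1e-10, rtol=1e-12)
    shape = float(np.exp(log_shape))
    if shape <= 0:
        raise ValidationError("non-positive fitted gamma shape")
    return shape, mean / shape


def sample_delays(
    timing: TimingParameters,
    rng: np.random.Generator,
    size: int | None = None,
) -> DelaySample:
    """Draw the delay chain; fixed mode returns the base values verbatim.

    Stochastic mode draws wake-to-hospital and door-to-needle from gamma
    distributions fitted to (mean, IQR), and the MRI add-on from a gamma
    fitted to (mean, 95% interval).
    """
    timing.validate()
    if not timing.stochastic_delays or timing.delay_distribution_family == "fixed":
        if size is None:
            return DelaySample(
                timing.wake_to_hospital_minutes,
                timing.door_to_needle_minutes,
                timing.mri_additional_minutes,
            )
        ones = np.ones(size)
        return DelaySample(
            timing.wake_to_hospital_minutes * ones,
            timing.door_to_needle_minutes * ones,
            timing.mri_additional_minutes * ones,
        )

    def draw(mean: float, interval: tuple[float, float], level: float):
        if mean == 0:
            return 0.0 if size is None else np.zeros(size)
        shape, scale = fit_gamma_mean_interval(mean, *interval, level=level)
        return rng.gamma(shape, scale, size=size)

    return DelaySample(
        draw(timing.wake_to_hospital_minutes, timing.wake_to_hospital_iqr, 0.50),
        draw(timing.door_to_needle_minutes, timing.door_to_needle_iqr, 0.50),
        draw(timing.mri_additional_minutes, timing.mri_ci95, 0.95),
    )


def onset_age_at_treatment(
    onset_age_at_wake, delays: DelaySample, strategy: str = "mri_based"
):
    """Onset age (min since stroke) at the moment treatment would start.

    Under ``no_treatment`` no needle time exists; the hospital-arrival onset
    age is returned for bookkeeping.
    """
    if strategy == "mri_based":
        return (
            onset_age_at_wake
            + delays.wake_to_hospital
            + delays.door_to_needle
            + delays.mri_time
        )
    if strategy == "no_treatment":
        return onset_age_at_wake + delays.wake_to_hospital
    raise ValidationError(f"unknown strategy: {strategy!r}")


def prob_onset_age_below(
    dist: OnsetDistribution,
    sleep_minutes: float,
    total_delay: float,
    threshold: float,
) -> float:
    """Closed-form P(onset age at treatment < threshold).

    Equals F((threshold - total_delay) / sleep_minutes) with F the CDF of
    the fraction-of-sleep-remaining distribution, clamped to [0, 1].
    """
    if threshold < 0:
        raise ValidationError("threshold must be >= 0")
    x = (threshold - total_delay) / sleep_minutes
    x = min(max(x, 0.0), 1.0)
    return float(_fraction_dist(dist).cdf(x))


def band_probabilities(
    dist: OnsetDistribution,
    sleep_minutes: float,
    total_delay: float,
    edges: Sequence[float],
) -> np.ndarray:
    """Closed-form probabilities of the onset age at treatment per band.

    ``edges`` are increasing band upper edges; the returned vector has
    ``len(edges) + 1`` entries (one open tail band) and sums to 1.
    """
    edges = list(edges)
    if any(e2 <= e1 for e1, e2 in zip(edges, edges[1:])):
        raise ValidationError("band edges must be strictly increasing")
    cdf_at = [
        prob_onset_age_below(dist, sleep_minutes, total_delay, max(e, 0.0))
        for e in edges
    ]
    probs = np.diff([0.0] + cdf_at + [1.0])
    return np.asarray(probs)
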