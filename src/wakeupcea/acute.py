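"""Acute-phase model: mismatch triage, tPA effect on mRS, acute costs.

The DWI-FLAIR mismatch test flags patients as likely within the 4.5-hour
thrombolysis window with imperfect sensitivity/specificity.  Treated
patients' probability of a favorable outcome (mRS 0-1) is shifted on the
odds scale by the time-banded odds ratio for their true onset age at
treatment; the remaining probability mass over mRS 2-6 keeps the treated
arm's internal proportions.  Acute hospitalization and MRI costs attach
here; symptomatic intracranial hemorrhage is not an explicit patient-level
event (its consequences are already embedded in the treated-arm mRS
distribution) — only a population-level side-calculation is provided.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .parameters import (
    CostParameters,
    DiagnosticPerformance,
    PopulationImpactParameters,
    TreatmentEffectSchedule,
    ValidationError,
)

__all__ = [
    "MRSDistribution",
    "PatientTrajectory",
    "classify_mismatch",
    "or_for_onset_time",
    "adjusted_favorable_probability",
    "assign_acute_mrs",
    "sample_acute_mrs",
    "treated_mrs_probabilities",
    "acute_phase_cost",
    "population_sich_increase",
]

_SUM_TOL = 1e-9


@dataclass(frozen=True)
class MRSDistribution:
    """mRS 0..6 probability vectors for the untreated and treated arms."""

    untreated: tuple[float, ...]
    treated: tuple[float, ...]
    provenance: str = "synthetic"

    def __post_init__(self):
        for name, vec in (("untreated", self.untreated), ("treated", self.treated)):
            if len(vec) != 7:
                raise ValidationError(f"{name} mRS vector must have 7 entries")
            if any(p < 0 or p > 1 for p in vec):
                raise ValidationError(f"{name} probabilities must be in [0, 1]")
            if abs(sum(vec) - 1.0) > _SUM_TOL:
                raise ValidationError(f"{name} probabilities must sum to 1")

    @property
    def p_favorable_untreated(self) -> float:
        return self.untreated[0] + self.untreated[1]

    @classmethod
    def from_table(cls, path, provenance: str = "file") -> "MRSDistribution":
        """Read an (mrs, untreated_prob, treated_prob) whitespace/comma table."""
        df = pd.read_csv(path, sep=None, engine="python")
        required = {"mrs", "untreated_prob", "treated_prob"}
        if not required.issubset(df.columns):
            raise ValidationError(
                f"mRS table must have columns {sorted(required)}, got {list(df.columns)}"
            )
        df = df.sort_values("mrs")
        if list(df["mrs"]) != list(range(7)):
            raise ValidationError("mRS table must cover scores 0..6 exactly once")
        return cls(
            tuple(float(x) for x in df["untreated_prob"]),
            tuple(float(x) for x in df["treated_prob"]),
            provenance=provenance,
        )

    def to_table(self, path) -> None:
        pd.DataFrame(
            {
                "mrs": range(7),
                "untreated_prob": self.untreated,
                "treated_prob": self.treated,
            }
        ).to_csv(path, sep="\t", index=False)


@dataclass
class PatientTrajectory:
    """Bookkeeping record of one simulated patient's acute phase."""

    onset_age_at_wake: float
    onset_age_at_treatment: float
    truly_eligible: bool
    test_positive: bool
    treated: bool
    acute_mrs: int


def classify_mismatch(
    truly_eligible,
    perf: DiagnosticPerformance,
    rng: np.random.Generator,
):
    """Apply the mismatch test: positive w.p. Se if truly eligible, 1-Sp if not.

    Accepts a scalar flag or a boolean array (vectorised over patients).
    """
    eligible = np.asarray(truly_eligible, dtype=bool)
    p_positive = np.where(eligible, perf.sensitivity, 1.0 - perf.specificity)
    u = rng.uniform(size=eligible.shape if eligible.shape else None)
    result = u < p_positive
    return bool(result) if np.isscalar(truly_eligible) or eligible.shape == () else result


def or_for_onset_time(onset_age_at_treatment, schedule: TreatmentEffectSchedule):
    """Odds ratio of the band containing the onset age at treatment.

    Band edges are inclusive upper bounds; times past the last edge get
    ``beyond_last_band_or``.  Vectorised over arrays.
    """
    edges = np.asarray(schedule.band_edges_minutes)
    ors = np.asarray(tuple(schedule.odds_ratios) + (schedule.beyond_last_band_or,))
    idx = np.searchsorted(edges, onset_age_at_treatment, side="left")
    result = ors[idx]
    return float(result) if np.isscalar(onset_age_at_treatment) else result


def adjusted_favorable_probability(p_untreated_favorable, or_value):
    """Shift a favorable-outcome probability by an odds ratio.

    Returns OR*o / (1 + OR*o) with o = p/(1-p).
    """
    p = np.asarray(p_untreated_favorable, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValidationError("favorable probability must be strictly inside (0, 1)")
    if np.any(np.asarray(or_value) <= 0):
        raise ValidationError("odds ratio must be > 0")
    odds = or_value * p / (1.0 - p)
    out = odds / (1.0 + odds)
    return float(out) if out.shape == () else out


def treated_mrs_probabilities(
    onset_age_at_treatment,
    dist: MRSDistribution,
    schedule: TreatmentEffectSchedule,
) -> np.ndarray:
    """Full 7-category outcome probabilities for a treated patient.

    The favorable mass is ``adjusted_favorable_probability`` applied to the
    *untreated* favorable mass (the odds ratios are treatment-vs-control
    contrasts); inside {0,1} and {2..6} the treated arm's internal
    proportions apportion the mass.  Vectorised: returns shape (..., 7).
    """
    or_val = or_for_onset_time(onset_age_at_treatment, schedule)
    p_fav = adjusted_favorable_probability(dist.p_favorable_untreated, or_val)
    p_fav = np.asarray(p_fav, dtype=float)

    treated = np.asarray(dist.treated)
    fav = treated[:2]
    unfav = treated[2:]
    fav_w = fav / fav.sum() if fav.sum() > 0 else np.array([0.5, 0.5])
    unfav_w = unfav / unfav.sum() if unfav.sum() > 0 else np.full(5, 0.2)

    probs = np.empty(p_fav.shape + (7,))
    probs[..., :2] = p_fav[..., None] * fav_w
    probs[..., 2:] = (1.0 - p_fav)[..., None] * unfav_w
    return probs


def sample_acute_mrs(
    treated,
    onset_age_at_treatment,
    dist: MRSDistribution,
    schedule: TreatmentEffectSchedule,
    rng: np.random.Generator,
) -> np.ndarray:
    """Vectorised acute mRS draw for arrays of patients.

    Untreated patients draw from the untreated arm; treated patients from
    the OR-adjusted category probabilities for their onset age.
    """
    treated = np.asarray(treated, dtype=bool)
    onset = np.broadcast_to(
        np.asarray(onset_age_at_treatment, dtype=float), treated.shape
    )
    probs = np.broadcast_to(np.asarray(dist.untreated), treated.shape + (7,)).copy()
    if treated.any():
        probs[treated] = treated_mrs_probabilities(onset[treated], dist, schedule)
    cum = np.cumsum(probs, axis=-1)
    u = rng.uniform(size=treated.shape)
    return (u[..., None] > cum).sum(axis=-1).astype(np.int64)


def assign_acute_mrs(
    treated: bool,
    onset_age_at_treatment: float,
    dist: MRSDistribution,
    schedule: TreatmentEffectSchedule,
    rng: np.random.Generator,
) -> int:
    """Scalar convenience wrapper around :func:`sample_acute_mrs`."""
    return int(
        sample_acute_mrs(
            np.asarray([treated]),
            np.asarray([onset_age_at_treatment]),
            dist,
            schedule,
            rng,
        )[0]
    )


def acute_phase_cost(strategy: str, treated, costs: CostParameters):
    """Acute hospitalization cost plus MRI cost under the MRI-based strategy.

    Vectorised over a boolean ``treated`` array.
    """
    treated_arr = np.asarray(treated, dtype=bool)
    if strategy == "no_treatment":
        out = np.where(
            treated_arr, np.nan, costs.acute_hosp_no_treatment
        )  # nobody is treated under no_treatment
        if treated_arr.any():
            raise ValidationError("no_treatment strategy cannot treat patients")
    elif strategy == "mri_based":
        out = costs.mri_cost + np.where(
            treated_arr, costs.acute_hosp_with_treatment, costs.acute_hosp_no_treatment
        )
    else:
        raise ValidationError(f"unknown strategy: {strategy!r}")
    return float(out) if out.shape == () else out


def population_sich_increase(
    impact: PopulationImpactParameters, treated_fraction_of_wakeup: float
) -> float:
    """Population-level sICH increase (percentage points of ischemic strokes).

    100 x (wake-up share) x (treated share of wake-up strokes) x (sICH rate
    among treated).
    """
    if not 0.0 <= treated_fraction_of_wakeup <= 1.0:
        raise ValidationError("treated fraction must be in [0, 1]")
    return (
        100.0
        * impact.wakeup_share_of_ischemic_strokes
        * treated_fraction_of_wakeup
        * impact.sich_rate_among_treated
    )
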