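"""Model parameters for the wake-up stroke cost-effectiveness model.

Every tunable quantity in the model lives in one of the dataclasses below,
grouped the way the model consumes them: timing of the sleep/delay chain,
the stroke-onset distribution, diagnostic performance of the DWI-FLAIR
mismatch test, the time-banded tPA effect schedule, long-term disease
progression, costs (2013 USD), health-state utilities, and demographic /
economic settings.  ``default_parameters()`` returns the published base
case; ``load_parameters``/``save_parameters`` round-trip a flat YAML
configuration file.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any, Sequence

import yaml

__all__ = [
    "TimingParameters",
    "OnsetDistribution",
    "DiagnosticPerformance",
    "TreatmentEffectSchedule",
    "ProgressionParameters",
    "CostParameters",
    "UtilityParameters",
    "DemographicAndEconomicSettings",
    "PopulationImpactParameters",
    "ModelParameters",
    "ParameterError",
    "ValidationError",
    "default_parameters",
    "load_parameters",
    "loads_parameters",
    "save_parameters",
    "dumps_parameters",
]


class ParameterError(ValueError):
    """Malformed configuration document (unknown key, unparseable value)."""


class ValidationError(ValueError):
    """A parameter value violates its typed bounds."""


def _check(cond: bool, field_name: str, msg: str) -> None:
    if not cond:
        raise ValidationError(f"{field_name}: {msg}")


@dataclass
class TimingParameters:
    """Delay chain from waking with stroke symptoms to needle time.

    All durations in minutes.  ``stochastic_delays`` switches the
    wake-to-hospital / door-to-needle / MRI times from their fixed base
    values to gamma draws matched to the published central intervals.
    """

    sleep_minutes: float = 480.0
    wake_to_hospital_minutes: float = 51.0
    door_to_needle_minutes: float = 77.0
    mri_additional_minutes: float = 30.0
    stochastic_delays: bool = False
    delay_distribution_family: str = "fixed"

    # central-interval bounds used only when stochastic_delays is on
    wake_to_hospital_iqr: tuple[float, float] = (36.0, 72.0)
    door_to_needle_iqr: tuple[float, float] = (60.0, 98.0)
    mri_ci95: tuple[float, float] = (20.0, 40.0)

    @property
    def total_fixed_delay(self) -> float:
        """Wake-to-hospital + door-to-needle + MRI (158 min at base case)."""
        return (
            self.wake_to_hospital_minutes
            + self.door_to_needle_minutes
            + self.mri_additional_minutes
        )

    def validate(self) -> None:
        _check(self.sleep_minutes > 0, "sleep_minutes", "must be > 0")
        for name in (
            "wake_to_hospital_minutes",
            "door_to_needle_minutes",
            "mri_additional_minutes",
        ):
            _check(getattr(self, name) >= 0, name, "must be >= 0")
        _check(
            self.delay_distribution_family in ("fixed", "gamma"),
            "delay_distribution_family",
            "must be 'fixed' or 'gamma'",
        )


@dataclass
class OnsetDistribution:
    """Distribution of the fraction of sleep REMAINING at stroke onset.

    Small sampled fractions mean onset close to wake-up.  The uniform
    family ignores alpha/beta; the beta family is parameterised so that
    e.g. Beta(3,5) places its mean at 3/8 of the sleep period before wake
    (mass skewed toward wake time).
    """

    family: str = "uniform"
    alpha: float = 1.0
    beta: float = 1.0

    def validate(self) -> None:
        _check(self.family in ("uniform", "beta"), "family", "must be 'uniform' or 'beta'")
        if self.family == "beta":
            _check(self.alpha > 0, "alpha", "must be > 0")
            _check(self.beta > 0, "beta", "must be > 0")


@dataclass
class DiagnosticPerformance:
    """Sensitivity/specificity of DWI-FLAIR mismatch for onset < 4.5 h."""

    sensitivity: float = 0.62
    specificity: float = 0.78
    eligibility_threshold_minutes: float = 270.0

    def validate(self) -> None:
        _check(0.0 <= self.sensitivity <= 1.0, "sensitivity", "must be in [0, 1]")
        _check(0.0 <= self.specificity <= 1.0, "specificity", "must be in [0, 1]")
        _check(
            self.eligibility_threshold_minutes > 0,
            "eligibility_threshold_minutes",
            "must be > 0",
        )


@dataclass
class TreatmentEffectSchedule:
    """Time-banded odds ratios for favorable outcome (mRS 0-1) with tPA.

    ``band_edges_minutes[i]`` is the inclusive upper edge of band *i*
    (minutes since true stroke onset); ``odds_ratios[i]`` applies inside
    it.  Times past the last edge receive ``beyond_last_band_or`` (the
    published schedule ends at 360 min with OR 1.00, which is carried
    forward indefinitely).
    """

    band_edges_minutes: tuple[float, ...] = (180.0, 270.0, 360.0)
    odds_ratios: tuple[float, ...] = (1.75, 1.26, 1.00)
    beyond_last_band_or: float = 1.00

    def validate(self) -> None:
        _check(
            len(self.band_edges_minutes) == len(self.odds_ratios),
            "band_edges_minutes",
            "edges and odds_ratios must have equal length",
        )
        edges = self.band_edges_minutes
        _check(
            all(e2 > e1 for e1, e2 in zip(edges, edges[1:])),
            "band_edges_minutes",
            "must be strictly increasing",
        )
        _check(
            all(o > 0 for o in self.odds_ratios) and self.beyond_last_band_or > 0,
            "odds_ratios",
            "all odds ratios must be > 0",
        )


@dataclass
class ProgressionParameters:
    """Long-term disease progression inside the Markov model."""

    nonstroke_death_hazard_ratio_by_mrs: tuple[float, ...] = (
        1.0,
        1.0,
        1.11,
        1.27,
        1.71,
        2.37,
    )
    annual_recurrent_stroke_probability: float = 0.051
    recurrent_stroke_case_fatality: float = 0.190

    def validate(self) -> None:
        _check(
            len(self.nonstroke_death_hazard_ratio_by_mrs) == 6,
            "nonstroke_death_hazard_ratio_by_mrs",
            "must cover mRS 0..5",
        )
        _check(
            all(h > 0 for h in self.nonstroke_death_hazard_ratio_by_mrs),
            "nonstroke_death_hazard_ratio_by_mrs",
            "must be > 0",
        )
        _check(
            0.0 <= self.annual_recurrent_stroke_probability <= 1.0,
            "annual_recurrent_stroke_probability",
            "must be in [0, 1]",
        )
        _check(
            0.0 <= self.recurrent_stroke_case_fatality <= 1.0,
            "recurrent_stroke_case_fatality",
            "must be in [0, 1]",
        )


@dataclass
class CostParameters:
    """Healthcare costs in 2013 USD."""

    mri_cost: float = 488.0
    acute_hosp_no_treatment: float = 11_462.0
    acute_hosp_with_treatment: float = 18_182.0
    annual_cost_mrs0_3: float = 5_293.0
    annual_cost_mrs4_5: float = 13_557.0
    recurrent_stroke_hosp_cost: float = 20_079.0

    def validate(self) -> None:
        for f in dataclasses.fields(self):
            _check(getattr(self, f.name) >= 0, f.name, "must be >= 0")


@dataclass
class UtilityParameters:
    """Health-state utilities by mRS (mRS 6 = death fixed at 0)."""

    utility_by_mrs: tuple[float, ...] = (0.8, 0.8, 0.65, 0.5, 0.35, 0.2)

    def validate(self) -> None:
        _check(len(self.utility_by_mrs) == 6, "utility_by_mrs", "must cover mRS 0..5")
        _check(
            all(0.0 <= u <= 1.0 for u in self.utility_by_mrs),
            "utility_by_mrs",
            "must be in [0, 1]",
        )


@dataclass
class DemographicAndEconomicSettings:
    start_age: float = 65.0
    male_fraction: float = 0.60
    annual_discount_rate: float = 0.03
    willingness_to_pay: float = 100_000.0
    max_age: float = 110.0

    def validate(self) -> None:
        _check(0.0 <= self.male_fraction <= 1.0, "male_fraction", "must be in [0, 1]")
        _check(self.annual_discount_rate >= 0, "annual_discount_rate", "must be >= 0")
        _check(self.willingness_to_pay >= 0, "willingness_to_pay", "must be >= 0")
        _check(self.max_age > self.start_age, "max_age", "must exceed start_age")


@dataclass
class PopulationImpactParameters:
    """Inputs to the population-level sICH side-calculation."""

    wakeup_share_of_ischemic_strokes: float = 0.20
    sich_rate_among_treated: float = 0.055

    def validate(self) -> None:
        _check(
            0.0 <= self.wakeup_share_of_ischemic_strokes <= 1.0,
            "wakeup_share_of_ischemic_strokes",
            "must be in [0, 1]",
        )
        _check(
            0.0 <= self.sich_rate_among_treated <= 1.0,
            "sich_rate_among_treated",
            "must be in [0, 1]",
        )


@dataclass
class ModelParameters:
    """Complete parameter vector for one model configuration."""

    timing: TimingParameters = field(default_factory=TimingParameters)
    onset: OnsetDistribution = field(default_factory=OnsetDistribution)
    diagnostic: DiagnosticPerformance = field(default_factory=DiagnosticPerformance)
    treatment_effect: TreatmentEffectSchedule = field(
        default_factory=TreatmentEffectSchedule
    )
    progression: ProgressionParameters = field(default_factory=ProgressionParameters)
    costs: CostParameters = field(default_factory=CostParameters)
    utilities: UtilityParameters = field(default_factory=UtilityParameters)
    demographics: DemographicAndEconomicSettings = field(
        default_factory=DemographicAndEconomicSettings
    )
    population_impact: PopulationImpactParameters = field(
        default_factory=PopulationImpactParameters
    )
    n_patients: int = 100_000
    seed: int = 2016

    def validate(self) -> None:
        for f in dataclasses.fields(self):
            value = getattr(self, f.name)
            if hasattr(value, "validate"):
                value.validate()
        _check(self.n_patients >= 1, "n_patients", "must be >= 1")

    def copy(self) -> "ModelParameters":
        return _from_dict(_to_dict(self))


_SECTION_TYPES: dict[str, type] = {
    "timing": TimingParameters,
    "onset": OnsetDistribution,
    "diagnostic": DiagnosticPerformance,
    "treatment_effect": TreatmentEffectSchedule,
    "progression": ProgressionParameters,
    "costs": CostParameters,
    "utilities": UtilityParameters,
    "demographics": DemographicAndEconomicSettings,
    "population_impact": PopulationImpactParameters,
}


def default_parameters() -> ModelParameters:
    """The published base case: 8 h sleep, uniform onset, fixed delays."""
    params = ModelParameters()
    params.validate()
    return params


def _to_dict(params: ModelParameters) -> dict[str, Any]:
    out: dict[str, Any] = {}
    for f in dataclasses.fields(params):
        value = getattr(params, f.name)
        if dataclasses.is_dataclass(value):
            sect = {}
            for sf in dataclasses.fields(value):
                v = getattr(value, sf.name)
                sect[sf.name] = list(v) if isinstance(v, tuple) else v
            out[f.name] = sect
        else:
            out[f.name] = value
    return out


def _coerce(value: Any, template: Any, key: str) -> Any:
    if isinstance(template, tuple):
        if not isinstance(value, (list, tuple)):
            raise ParameterError(f"{key}: expected a list")
        return tuple(value)
    if isinstance(template, bool):
        if not isinstance(value, bool):
            raise ParameterError(f"{key}: expected a boolean")
        return value
    if isinstance(template, float):
        if isinstance(value, bool) or not isinstance(value, (int, float)):
            raise ParameterError(f"{key}: expected a number")
        return float(value)
    if isinstance(template, int):
        if isinstance(value, bool) or not isinstance(value, int):
            raise ParameterError(f"{key}: expected an integer")
        return value
    if isinstance(template, str):
        if not isinstance(value, str):
            raise ParameterError(f"{key}: expected a string")
        return value
    return value


def _from_dict(doc: dict[str, Any]) -> ModelParameters:
    params = ModelParameters()
    for key, value in doc.items():
        if key in _SECTION_TYPES:
            if not isinstance(value, dict):
                raise ParameterError(f"{key}: expected a mapping")
            section = getattr(params, key)
            known = {f.name for f in dataclasses.fields(section)}
            for k, v in value.items():
                if k not in known:
                    raise ParameterError(f"unknown key: {key}.{k}")
                setattr(section, k, _coerce(v, getattr(section, k), f"{key}.{k}"))
        elif key in ("n_patients", "seed"):
            setattr(params, key, _coerce(value, getattr(params, key), key))
        else:
            raise ParameterError(f"unknown key: {key}")
    params.validate()
    return params


def loads_parameters(text: str) -> ModelParameters:
    """Parse a YAML configuration string into a validated ModelParameters."""
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:  # pragma: no cover - message passthrough
        raise ParameterError(f"malformed configuration: {exc}") from exc
    if doc is None:
        doc = {}
    if not isinstance(doc, dict):
        raise ParameterError("configuration root must be a mapping")
    return _from_dict(doc)


def load_parameters(path: Any) -> ModelParameters:
    """Load parameters from a YAML file; missing keys take base-case defaults."""
    with open(path, "r", encoding="utf-8") as fh:
        return loads_parameters(fh.read())


def dumps_parameters(params: ModelParameters) -> str:
    """Serialize to YAML at full floating precision (lossless round-trip)."""
    return yaml.safe_dump(_to_dict(params), sort_keys=False, default_flow_style=None)


def save_parameters(params: ModelParameters, path: Any) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(dumps_parameters(params))


def get_by_path(params: ModelParameters, path: str) -> float:
    """Resolve a dotted parameter path like ``diagnostic.sensitivity`` or
    ``utilities.utility_by_mrs[4]``."""
    obj: Any = params
    for part in path.split("."):
        idx = None
        if "[" in part:
            part, bracket = part.split("[", 1)
            idx = int(bracket.rstrip("]"))
        if not hasattr(obj, part):
            raise ParameterError(f"unknown parameter path: {path}")
        obj = getattr(obj, part)
        if idx is not None:
            obj = obj[idx]
    return obj


def set_by_path(params: ModelParameters, path: str, value: float) -> None:
    """Set a parameter by dotted path (in place); re-validates the vector."""
    parts = path.split(".")
    obj: Any = params
    for part in parts[:-1]:
        if not hasattr(obj, part):
            raise ParameterError(f"unknown parameter path: {path}")
        obj = getattr(obj, part)
    last = parts[-1]
    idx = None
    if "[" in last:
        last, bracket = last.split("[", 1)
        idx = int(bracket.rstrip("]"))
    if not hasattr(obj, last):
        raise ParameterError(f"unknown parameter path: {path}")
    if idx is None:
        setattr(obj, last, value)
    else:
        current = list(getattr(obj, last))
        current[idx] = value
        setattr(obj, last, tuple(current))
    params.validate()
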