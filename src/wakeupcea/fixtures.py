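"""Packaged synthetic inputs and the named scenario library.

The published model relies on two inputs that are not reproducible from
the open literature: the ECASS III arm-specific mRS outcome distributions
and the background-mortality life table.  This module ships documented
synthetic stand-ins — a placeholder mRS distribution constrained only by
the published untreated favorable-outcome probability (0.451), and a
Gompertz-Makeham life table — plus the scenario presets used throughout
(sleep-duration and onset-distribution variants).  Every fixture carries a
provenance flag so downstream outputs can distinguish published inputs
from synthetic ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .acute import MRSDistribution
from .lifetime import LifeTable, synthesize_life_table
from .parameters import ModelParameters, ValidationError, default_parameters

__all__ = [
    "ScenarioPreset",
    "scenario_library",
    "get_scenario",
    "placeholder_mrs_distribution",
    "default_mrs_distribution",
    "default_life_table",
    "export_fixtures",
]

# mRS 2..6 share of the non-favorable mass in the placeholder distribution:
# a fixed declining scheme (no published vector backs these splits; only the
# favorable aggregate is constrained).
_PLACEHOLDER_UNFAVORABLE_WEIGHTS = np.array([5.0, 4.0, 3.0, 2.0, 1.0]) / 15.0


@dataclass(frozen=True)
class ScenarioPreset:
    """A named parameter configuration (sleep duration / onset shape)."""

    name: str
    description: str
    overrides: dict = field(default_factory=dict)
    provenance: str = "published"

    def parameters(self) -> ModelParameters:
        params = default_parameters()
        for path, value in self.overrides.items():
            section, key = path.split(".", 1)
            setattr(getattr(params, section), key, value)
        params.validate()
        return params


def scenario_library() -> list[ScenarioPreset]:
    """Named scenarios: published sleep/onset variants plus labelled extras."""
    return [
        ScenarioPreset(
            "base8h", "8 h sleep, uniform onset, fixed delays 51+77+30 min", {}
        ),
        ScenarioPreset("sleep6h", "6 h sleep, all else base", {"timing.sleep_minutes": 360.0}),
        ScenarioPreset("sleep4h", "4 h sleep, all else base", {"timing.sleep_minutes": 240.0}),
        ScenarioPreset(
            "beta44",
            "Beta(4,4) symmetric onset over 8 h sleep",
            {"onset.family": "beta", "onset.alpha": 4.0, "onset.beta": 4.0},
        ),
        ScenarioPreset(
            "beta35",
            "Beta(3,5) onset slightly skewed toward wake time, 8 h sleep",
            {"onset.family": "beta", "onset.alpha": 3.0, "onset.beta": 5.0},
        ),
        ScenarioPreset(
            "beta26",
            "Beta(2,6) onset strongly skewed toward wake time (illustrative, "
            "not a published parameterisation)",
            {"onset.family": "beta", "onset.alpha": 2.0, "onset.beta": 6.0},
            provenance="synthetic",
        ),
        ScenarioPreset(
            "beta17",
            "Beta(1,7) onset very strongly skewed toward wake time "
            "(illustrative, not a published parameterisation)",
            {"onset.family": "beta", "onset.alpha": 1.0, "onset.beta": 7.0},
            provenance="synthetic",
        ),
        ScenarioPreset(
            "timing_dtn103",
            "Alternative reading of the timing inputs: 103-min door-to-needle "
            "inclusive of the 30-min MRI (total delay 154 min)",
            {"timing.door_to_needle_minutes": 73.0},
            provenance="synthetic",
        ),
    ]


def get_scenario(name: str) -> ScenarioPreset:
    for preset in scenario_library():
        if preset.name == name:
            return preset
    known = ", ".join(p.name for p in scenario_library())
    raise ValidationError(f"unknown scenario {name!r}; known scenarios: {known}")


def placeholder_mrs_distribution(
    p_favorable_untreated: float = 0.451,
) -> MRSDistribution:
    """Synthetic 7-category mRS distribution with the stated favorable mass.

    The untreated arm puts exactly ``p_favorable_untreated`` on mRS 0-1
    (split evenly) and spreads the rest over mRS 2-6 by a fixed declining
    scheme; the treated arm equals the untreated arm (the model uses it
    only for conditional splits inside {0,1} and {2..6}).  This is a
    labelled synthetic stand-in, not a published outcome vector.
    """
    if not 0.0 < p_favorable_untreated < 1.0:
        raise ValidationError("p_favorable_untreated must be in (0, 1)")
    p = p_favorable_untreated
    vec = np.concatenate(
        [[p / 2.0, p / 2.0], (1.0 - p) * _PLACEHOLDER_UNFAVORABLE_WEIGHTS]
    )
    vec = tuple(float(x) for x in vec)
    return MRSDistribution(vec, vec, provenance="synthetic")


def _packaged(name: str) -> Path | None:
    try:
        path = resources.files("wakeupcea").joinpath("data", name)
        if path.is_file():
            return path  # type: ignore[return-value]
    except (FileNotFoundError, ModuleNotFoundError):
        pass
    return None


def default_mrs_distribution() -> MRSDistribution:
    """The packaged synthetic mRS distribution (falls back to the generator)."""
    path = _packaged("mrs_distribution_synthetic.tsv")
    if path is not None:
        return MRSDistribution.from_table(path, provenance="synthetic")
    return placeholder_mrs_distribution()


def default_life_table() -> LifeTable:
    """The packaged synthetic Gompertz-Makeham life table."""
    path = _packaged("life_table_synthetic.tsv")
    if path is not None:
        return LifeTable.from_file(path, provenance="synthetic")
    return synthesize_life_table()


def export_fixtures(directory) -> list[Path]:
    """Write the synthetic fixtures as editable text files; returns the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    mrs_path = directory / "mrs_distribution_synthetic.tsv"
    lt_path = directory / "life_table_synthetic.tsv"
    placeholder_mrs_distribution().to_table(mrs_path)
    synthesize_life_table().to_file(lt_path)
    return [mrs_path, lt_path]
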