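"""Named simulation experiments: parameter and lookup overrides vs the base run.

Three scenario families probe the levers a product strategist could pull:
stronger internal/external influence (s1.x), improved sensory quality of the
burger (s2.x), and a higher likelihood to adopt (s3.x). Each scenario is a
small set of overrides applied on top of the base model; overrides may be
replacement constants, step inputs, ramp inputs, or whole lookup tables.

The canonical s1 definitions follow the published step formulas verbatim
(``0.151 + STEP(0.151*1.1, 2015)`` adds 110% of the base value). The source's
accompanying prose instead describes 10%/100% increases; those readings are
exposed as the non-canonical ``s1.1-prose``/``s1.2-prose`` variants.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .engine import (
    ConfigurationError,
    LookupTable,
    ModelSpec,
    RampInput,
    SimConfig,
    StepInput,
    TimeInput,
    integrate,
    Trajectory,
)
from .model import ADOPTION_LIKELIHOOD_LOOKUP, DEFAULT_CONSTANTS, ModelConstants, build_base_model

__all__ = [
    "Scenario",
    "SCENARIOS",
    "get_scenario",
    "apply_scenario",
    "run_scenario",
    "ScenarioComparison",
    "run_comparison",
]


@dataclass(frozen=True)
class Scenario:
    """A named set of overrides on model constants or lookup tables."""

    name: str
    overrides: Mapping[str, TimeInput | LookupTable] = field(default_factory=dict)
    description: str = ""


# s3.1 raises the likelihood-to-adopt lookup's middle breakpoint 0.12 -> 0.19
# (1.6x the base output at a barrier of 0.55).
_S31_LIKELIHOOD = ADOPTION_LIKELIHOOD_LOOKUP.replace_point(1, 0.55, 0.19)

_WOM_STEP = StepInput(0.151, 0.151 * 1.1, 2015)
_PROMO_STEP = StepInput(0.0036, 0.0036 * 2, 2015)

SCENARIOS: dict[str, Scenario] = {
    s.name: s
    for s in (
        Scenario("base", {}, "Base run: published constants, no overrides."),
        Scenario("s1.1", {"wom_strength": _WOM_STEP},
                 "Word-of-mouth strength stepped up from 2015 (printed formula: +110%)."),
        Scenario("s1.2", {"wom_strength": _WOM_STEP, "promo_tasters_fraction": _PROMO_STEP},
                 "s1.1 plus promotional fraction stepped up from 2015 (printed formula: +200%)."),
        Scenario("s2.1",
                 {"average_sensory_quality": RampInput(0.54, 0.8, 2017, 2048)},
                 "Sensory quality grows linearly from 0.54 in 2017 to 0.8 in 2048."),
        Scenario("s2.2",
                 {"average_sensory_quality": StepInput(0.54, 0.8 - 0.54, 2017)},
                 "Sensory quality jumps to 0.8 from 2017."),
        Scenario("s3.1", {"likelihood_to_adopt": _S31_LIKELIHOOD},
                 "Likelihood-to-adopt lookup raised: middle breakpoint (0.55, 0.12) -> (0.55, 0.19)."),
        Scenario("s3.2",
                 {"likelihood_to_adopt": _S31_LIKELIHOOD,
                  "average_sensory_quality": StepInput(0.54, 0.8 - 0.54, 2017)},
                 "s3.1 combined with the immediate quality increase of s2.2."),
        # Non-canonical variants implementing the prose percentages instead of
        # the printed step formulas; kept for exploration only.
        Scenario("s1.1-prose", {"wom_strength": StepInput(0.151, 0.151 * 0.1, 2015)},
                 "Prose reading of s1.1: +10% word-of-mouth strength from 2015."),
        Scenario("s1.2-prose",
                 {"wom_strength": StepInput(0.151, 0.151 * 0.1, 2015),
                  "promo_tasters_fraction": StepInput(0.0036, 0.0036, 2015)},
                 "Prose reading of s1.2: +10% WoM and +100% promotion from 2015."),
    )
}


def get_scenario(name: str) -> Scenario:
    try:
        return SCENARIOS[name]
    except KeyError:
        valid = ", ".join(sorted(SCENARIOS))
        raise ConfigurationError(f"unknown scenario {name!r}; valid names: {valid}") from None


def apply_scenario(model: ModelSpec, scenario: Scenario | str) -> ModelSpec:
    """Return a modified copy of the model with the scenario's overrides set."""
    if isinstance(scenario, str):
        scenario = get_scenario(scenario)
    out = model.copy()
    for element, value in scenario.overrides.items():
        if isinstance(value, LookupTable):
            if element not in out.lookups:
                raise ConfigurationError(
                    f"scenario {scenario.name!r} overrides unknown lookup {element!r}")
            out.lookups[element] = value
        else:
            if element not in out.constants:
                raise ConfigurationError(
                    f"scenario {scenario.name!r} overrides unknown constant {element!r}")
            out.constants[element] = value
    return out


def run_scenario(scenario: Scenario | str,
                 config: SimConfig | None = None,
                 constants: ModelConstants = DEFAULT_CONSTANTS) -> Trajectory:
    model = apply_scenario(build_base_model(constants), scenario)
    return integrate(model, config)


@dataclass
class ScenarioComparison:
    """Trajectories for several scenarios on a shared grid, plus base deltas."""

    trajectories: dict[str, Trajectory]
    config: SimConfig

    def long_table(self, yearly: bool = True) -> pd.DataFrame:
        """Tidy (scenario, year, variable, value) table for plotting."""
        parts = []
        for name, traj in self.trajectories.items():
            frame = traj.yearly() if yearly else traj.data.rename_axis("year")
            melted = frame.reset_index().melt(id_vars="year", var_name="variable",
                                              value_name="value")
            melted.insert(0, "scenario", name)
            parts.append(melted)
        return pd.concat(parts, ignore_index=True)

    def diff_vs_base(self, variable: str) -> pd.DataFrame:
        """Per-year scenario-minus-base differences for one variable."""
        if "base" not in self.trajectories:
            raise ConfigurationError("comparison has no 'base' scenario to diff against")
        base = self.trajectories["base"].yearly()[variable]
        out = {}
        for name, traj in self.trajectories.items():
            if name != "base":
                out[name] = traj.yearly()[variable] - base
        return pd.DataFrame(out)


def run_comparison(scenarios: list[Scenario | str],
                   config: SimConfig | None = None,
                   constants: ModelConstants = DEFAULT_CONSTANTS) -> ScenarioComparison:
    """Run every scenario on a shared grid; stock differences vs base follow
    from :meth:`ScenarioComparison.diff_vs_base`."""
    if not scenarios:
        raise ConfigurationError("at least one scenario is required")
    config = config or SimConfig()
    trajectories: dict[str, Trajectory] = {}
    for sc in scenarios:
        sc = get_scenario(sc) if isinstance(sc, str) else sc
        trajectories[sc.name] = run_scenario(sc, config, constants)
    return ScenarioComparison(trajectories=trajectories, config=config)
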