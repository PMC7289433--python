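"""The four-stock Bass diffusion model of insect-based food adoption.

The model tracks the meat-eating Dutch population through four adoption
stages: *Potential adopters* (never tasted insect-based food), *Potential
tasters* (decided to taste), *Adopters* and *Rejecters* (decided after
tasting an insect-based burger). Tasting is driven by external influence
(promotional activities, the classical Bass coefficient of innovation) and
internal influence (word-of-mouth, the coefficient of imitation), both
attenuated by a disgust-driven barrier. Adoption versus rejection depends on
the likelihood to adopt (a function of taste expectation and food
appropriateness, both rising with population familiarity), on the sensory
quality of the burger, and on market availability, which switches on in 2015.

All defaults are the published base-run values; the population is held
constant over the whole 1998-2048 horizon (a closed Bass system).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .engine import (
    Auxiliary,
    ConfigurationError,
    Flow,
    LookupTable,
    ModelSpec,
    StepInput,
    Stock,
)

__all__ = [
    "ModelConstants",
    "StockState",
    "DEFAULT_CONSTANTS",
    "APPROPRIATENESS_LOOKUP",
    "TASTE_EXPECTATION_LOOKUP",
    "TASTING_BARRIER_LOOKUP",
    "ADOPTION_LIKELIHOOD_LOOKUP",
    "SENSORY_QUALITY_LOOKUP",
    "BASE_LOOKUPS",
    "build_base_model",
    "average_familiarity",
    "barrier_towards_adopting",
    "promo_tasters_flow",
    "wom_tasters_flow",
    "adoption_rejection_rates",
]


# Empirical piecewise-linear relationships, all on the unit square.
# Appropriateness and taste expectation rise with population familiarity.
APPROPRIATENESS_LOOKUP = LookupTable(((0.0, 0.01), (0.5, 0.67), (1.0, 0.72)))
TASTE_EXPECTATION_LOOKUP = LookupTable(((0.0, 0.28), (0.5, 0.44), (1.0, 0.56)))
# Barrier towards tasting falls from 1 (no barrier) to 0 as disgust rises.
TASTING_BARRIER_LOOKUP = LookupTable(((0.0, 1.0), (0.32, 0.93), (1.0, 0.0)))
# Likelihood to adopt falls as the barrier towards adopting rises.
ADOPTION_LIKELIHOOD_LOOKUP = LookupTable(((0.0, 1.0), (0.55, 0.12), (1.0, 0.0)))
# Fraction adopting on sensory grounds as a function of average sensory quality.
SENSORY_QUALITY_LOOKUP = LookupTable(
    ((0.0, 0.0), (0.125, 0.0), (0.6, 0.5), (0.875, 1.0), (1.0, 1.0))
)

BASE_LOOKUPS: dict[str, LookupTable] = {
    "average_appropriateness": APPROPRIATENESS_LOOKUP,
    "average_taste_expectation": TASTE_EXPECTATION_LOOKUP,
    "barrier_towards_tasting": TASTING_BARRIER_LOOKUP,
    "likelihood_to_adopt": ADOPTION_LIKELIHOOD_LOOKUP,
    "sensory_quality_adoption_fraction": SENSORY_QUALITY_LOOKUP,
}


@dataclass(frozen=True)
class ModelConstants:
    """Base-run constants of the adoption model.

    total_population_census
        Population of the Netherlands in 2015 (people).
    special_diet_fraction
        Fraction with special eating habits (vegetarian, vegan, ...) excluded
        from the modelled meat-eating population.
    average_disgust_level
        Population-average disgust when facing insect-based food, in [0, 1].
    average_sensory_quality
        Normalised average sensory liking of an insect-based burger, in [0, 1].
    promo_tasters_fraction
        Fraction of potential adopters reached by promotional activities per
        year (external influence, 1/Year).
    wom_strength
        Probability that a contact with a potential adopter yields fruitful
        word-of-mouth (internal influence, acts as a per-year rate).
    availability_start_year
        Calendar year insect-based burgers became available on the market;
        adoption and rejection are impossible before it (math.inf = never).
    """

    total_population_census: float = 16_900_720.0
    special_diet_fraction: float = 0.04
    average_disgust_level: float = 0.32
    average_sensory_quality: float = 0.54
    promo_tasters_fraction: float = 0.0036
    wom_strength: float = 0.151
    availability_start_year: float = 2015.0

    def __post_init__(self) -> None:
        if self.total_population_census <= 0:
            raise ConfigurationError("total_population_census must be positive")
        for name in ("special_diet_fraction", "average_disgust_level",
                     "average_sensory_quality"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {v}")
        for name in ("promo_tasters_fraction", "wom_strength"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")

    @property
    def m(self) -> float:
        """Model population: census total minus the special-diet fraction."""
        return self.total_population_census * (1.0 - self.special_diet_fraction)


DEFAULT_CONSTANTS = ModelConstants()


@dataclass(frozen=True)
class StockState:
    """The four population stocks (people), summing to the model population."""

    potential_adopters: float
    potential_tasters: float = 0.0
    adopters: float = 0.0
    rejecters: float = 0.0

    @property
    def total(self) -> float:
        return (self.potential_adopters + self.potential_tasters
                + self.adopters + self.rejecters)


# ---------------------------------------------------------------------------
# Auxiliary formulas, exposed as separately testable functions
# ---------------------------------------------------------------------------


def average_familiarity(potential_adopters: float, m: float) -> float:
    """Fraction of the population that has tasted: (m - PA) / m."""
    if m <= 0:
        raise ConfigurationError("average familiarity is undefined for m <= 0")
    return (m - potential_adopters) / m


def barrier_towards_adopting(taste_expectation: float, appropriateness: float) -> float:
    """1 - (taste/2 + appropriateness/2); falls as either perception improves."""
    return 1.0 - (taste_expectation / 2.0 + appropriateness / 2.0)


def promo_tasters_flow(potential_adopters: float, barrier_tasting: float,
                       promo_fraction: float) -> float:
    """External influence: people per year deciding to taste via promotion."""
    return potential_adopters * barrier_tasting * promo_fraction


def wom_tasters_flow(potential_adopters: float, strength: float,
                     familiarity: float, barrier_tasting: float) -> float:
    """Internal influence: word-of-mouth needs familiar people to seed it."""
    return potential_adopters * strength * familiarity * barrier_tasting


def adoption_rejection_rates(potential_tasters: float, likelihood: float,
                             sensory_fraction: float, availability: float
                             ) -> tuple[float, float]:
    """Adoption PT*L*S*avail and rejection PT*(1-L)*(1-S)*avail.

    The two rates do not in general exhaust the tasters' stock: people can
    remain undecided (the symmetric product form is deliberate).
    """
    adoption = potential_tasters * likelihood * sensory_fraction * availability
    rejection = (1.0 - sensory_fraction) * potential_tasters * (1.0 - likelihood) * availability
    return adoption, rejection


# ---------------------------------------------------------------------------
# Model assembly
# ---------------------------------------------------------------------------


def _familiarity_aux(ctx) -> float:
    m = ctx.const("total_population")
    if m <= 0:
        # Degenerate empty-population model: nobody exists, so nobody is
        # familiar; every flow is zero regardless (PA = 0).
        return 0.0
    return average_familiarity(ctx.stock("potential_adopters"), m)


def build_base_model(constants: ModelConstants = DEFAULT_CONSTANTS) -> ModelSpec:
    """Wire the four-stock adoption model from its published formulas.

    Initial condition: the whole model population sits in *potential
    adopters*; every other stock starts empty. Availability is a unit step at
    the availability start year. The returned spec carries the declared units
    from the source tables, including the two documented inconsistencies the
    dimensional audit reports as warnings (word-of-mouth strength declared
    dimensionless but used as a per-year rate; the sensory adoption fraction
    declared per-year but used inside ``1 - fraction``).
    """
    if not isinstance(constants, ModelConstants):
        raise ConfigurationError("constants must be a ModelConstants instance")
    m = constants.m

    stocks = [
        Stock("potential_adopters", m),
        Stock("potential_tasters", 0.0),
        Stock("adopters", 0.0),
        Stock("rejecters", 0.0),
    ]

    start = constants.availability_start_year
    availability = StepInput(0.0, 1.0, start) if math.isfinite(start) else 0.0
    model_constants: dict = {
        "total_population": m,
        "average_disgust_level": constants.average_disgust_level,
        "average_sensory_quality": constants.average_sensory_quality,
        "promo_tasters_fraction": constants.promo_tasters_fraction,
        "wom_strength": constants.wom_strength,
        "availability": availability,
    }
    constant_units = {
        "total_population": "people",
        "average_disgust_level": "Dmnl",
        "average_sensory_quality": "Dmnl",
        "promo_tasters_fraction": "1/Year",
        "wom_strength": "Dmnl",
        "availability": "Dmnl",
    }
    # WoM strength multiplies a stock to form a people/Year flow: its usage
    # implies 1/Year even though it is declared dimensionless.
    constant_expected_units = dict(constant_units)
    constant_expected_units["wom_strength"] = "1/Year"

    auxiliaries = [
        Auxiliary("average_familiarity", _familiarity_aux),
        Auxiliary("average_appropriateness",
                  lambda c: c.lookup("average_appropriateness", c.aux["average_familiarity"])),
        Auxiliary("average_taste_expectation",
                  lambda c: c.lookup("average_taste_expectation", c.aux["average_familiarity"])),
        Auxiliary("barrier_towards_adopting",
                  lambda c: barrier_towards_adopting(c.aux["average_taste_expectation"],
                                                     c.aux["average_appropriateness"])),
        Auxiliary("likelihood_to_adopt",
                  lambda c: c.lookup("likelihood_to_adopt", c.aux["barrier_towards_adopting"])),
        Auxiliary("barrier_towards_tasting",
                  lambda c: c.lookup("barrier_towards_tasting", c.const("average_disgust_level"))),
        # Declared 1/Year in the source tables, but used inside (1 - fraction):
        # dimensionally it must be read as a dimensionless per-year multiplier.
        Auxiliary("sensory_quality_adoption_fraction",
                  lambda c: c.lookup("sensory_quality_adoption_fraction",
                                     c.const("average_sensory_quality")),
                  unit="1/Year", expected_unit="Dmnl"),
        Auxiliary("availability", lambda c: c.const("availability")),
        Auxiliary("promo_tasters",
                  lambda c: promo_tasters_flow(c.stock("potential_adopters"),
                                               c.aux["barrier_towards_tasting"],
                                               c.const("promo_tasters_fraction")),
                  unit="people/Year"),
        Auxiliary("wom_tasters",
                  lambda c: wom_tasters_flow(c.stock("potential_adopters"),
                                             c.const("wom_strength"),
                                             c.aux["average_familiarity"],
                                             c.aux["barrier_towards_tasting"]),
                  unit="people/Year"),
    ]

    flows = [
        Flow("potential_tasting_rate",
             lambda c: c.aux["promo_tasters"] + c.aux["wom_tasters"],
             source="potential_adopters", target="potential_tasters"),
        Flow("adoption_rate",
             lambda c: adoption_rejection_rates(c.stock("potential_tasters"),
                                                c.aux["likelihood_to_adopt"],
                                                c.aux["sensory_quality_adoption_fraction"],
                                                c.aux["availability"])[0],
             source="potential_tasters", target="adopters"),
        Flow("rejection_rate",
             lambda c: adoption_rejection_rates(c.stock("potential_tasters"),
                                                c.aux["likelihood_to_adopt"],
                                                c.aux["sensory_quality_adoption_fraction"],
                                                c.aux["availability"])[1],
             source="potential_tasters", target="rejecters"),
    ]

    return ModelSpec(
        stocks=stocks,
        flows=flows,
        auxiliaries=auxiliaries,
        constants=model_constants,
        lookups=dict(BASE_LOOKUPS),
        constant_units=constant_units,
        constant_expected_units=constant_expected_units,
    )
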