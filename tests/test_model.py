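"""Tests of the adoption model's formulas and base-run behaviour."""

import numpy as np
import pytest

from sdbass import (
    ConfigurationError,
    ModelConstants,
    SimConfig,
    build_base_model,
    integrate,
)
from sdbass.model import (
    SENSORY_QUALITY_LOOKUP,
    adoption_rejection_rates,
    average_familiarity,
    barrier_towards_adopting,
    promo_tasters_flow,
    wom_tasters_flow,
)


class TestConstants:
    def test_model_population_excludes_special_diets(self):
        c = ModelConstants()
        assert c.m == pytest.approx(16_224_691.2, abs=1e-6)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"total_population_census": 0},
            {"special_diet_fraction": 1.2},
            {"average_disgust_level": -0.1},
            {"wom_strength": -1.0},
        ],
    )
    def test_invalid_constants_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            ModelConstants(**kwargs)


class TestFormulas:
    @pytest.mark.parametrize(
        "pa_fraction, expected",
        [(1.0, 0.0), (0.0, 1.0), (0.8, 0.2)],
    )
    def test_average_familiarity(self, pa_fraction, expected):
        m = 16_224_691.2
        assert average_familiarity(pa_fraction * m, m) == pytest.approx(expected)

    def test_average_familiarity_undefined_for_empty_population(self):
        with pytest.raises(ConfigurationError):
            average_familiarity(0.0, 0.0)

    @pytest.mark.parametrize(
        "taste, approp, expected",
        [
            (0.28, 0.01, 0.855),  # lookup outputs at zero familiarity
            (1.0, 1.0, 0.0),  # no barrier
            (0.0, 0.0, 1.0),  # full barrier
        ],
    )
    def test_barrier_towards_adopting(self, taste, approp, expected):
        assert barrier_towards_adopting(taste, approp) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "pa, barrier, fraction, expected",
        [(1e6, 0.93, 0.0036, 3348.0), (1e6, 0.0, 0.0036, 0.0), (1e6, 0.93, 0.0, 0.0)],
    )
    def test_promo_tasters_flow(self, pa, barrier, fraction, expected):
        assert promo_tasters_flow(pa, barrier, fraction) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "pa, strength, familiarity, barrier, expected",
        [
            (1e6, 0.151, 0.0, 0.93, 0.0),  # word-of-mouth needs seeds
            (0.0, 0.151, 0.5, 0.93, 0.0),  # market saturated
            (1e6, 0.151, 0.2, 0.93, 28_086.0),
        ],
    )
    def test_wom_tasters_flow(self, pa, strength, familiarity, barrier, expected):
        assert wom_tasters_flow(pa, strength, familiarity, barrier) == pytest.approx(expected)

    def test_adoption_rejection_zero_before_availability(self):
        assert adoption_rejection_rates(1000.0, 0.12, 0.44, availability=0.0) == (0.0, 0.0)

    def test_adoption_rejection_perfect_product(self):
        adoption, rejection = adoption_rejection_rates(1000.0, 1.0, 1.0, 1.0)
        assert (adoption, rejection) == (1000.0, 0.0)

    def test_adoption_rejection_base_sensory_quality(self):
        sensory = SENSORY_QUALITY_LOOKUP(0.54)
        adoption, rejection = adoption_rejection_rates(1000.0, 0.12, sensory, 1.0)
        assert adoption == pytest.approx(52.4, abs=0.05)
        assert rejection == pytest.approx(495.6, abs=0.05)
        # undecided tasters remain: the two rates do not exhaust the stock
        assert adoption + rejection < 1000.0


class TestBaseModelStructure:
    def test_initial_stocks(self, base_model):
        initials = {s.name: s.initial for s in base_model.stocks}
        assert initials == {
            "potential_adopters": pytest.approx(16_224_691.2),
            "potential_tasters": 0.0,
            "adopters": 0.0,
            "rejecters": 0.0,
        }

    def test_invalid_constants_type_rejected(self):
        with pytest.raises(ConfigurationError):
            build_base_model({"wom_strength": 0.151})

    def test_empty_population_stays_empty(self):
        model = build_base_model(ModelConstants(special_diet_fraction=1.0))
        traj = integrate(model, SimConfig(t0=1998, tf=2008, dt=0.125))
        assert np.all(traj.data[traj.stock_names].to_numpy() == 0.0)


class TestBaseRunBehaviour:
    def test_tasting_barrier_is_constant_093(self, base_trajectory):
        """Disgust is fixed at 0.32, hitting the lookup breakpoint exactly."""
        assert np.all(base_trajectory["barrier_towards_tasting"] == 0.93)

    def test_monotone_stocks(self, base_trajectory):
        assert np.all(np.diff(base_trajectory["potential_adopters"]) <= 1e-9)
        assert np.all(np.diff(base_trajectory["adopters"]) >= -1e-9)
        assert np.all(np.diff(base_trajectory["rejecters"]) >= -1e-9)
        assert np.all(np.diff(base_trajectory["average_familiarity"]) >= -1e-12)

    def test_no_adoption_before_availability(self, base_trajectory):
        before = base_trajectory.data[base_trajectory.data.index < 2015.0]
        assert np.all(before["adopters"] == 0.0)
        assert np.all(before["rejecters"] == 0.0)

    def test_familiarity_hits_20_percent_anchor_in_2015(self, base_trajectory):
        assert base_trajectory.value_at("average_familiarity", 2015) == pytest.approx(
            0.20, abs=0.03
        )

    def test_dimensionless_auxiliaries_stay_in_unit_interval(self, base_trajectory):
        for name in (
            "average_familiarity",
            "average_taste_expectation",
            "average_appropriateness",
            "barrier_towards_adopting",
            "barrier_towards_tasting",
            "likelihood_to_adopt",
            "sensory_quality_adoption_fraction",
        ):
            values = base_trajectory[name]
            assert values.min() >= 0.0 and values.max() <= 1.0

    def test_flows_non_negative(self, base_trajectory):
        for name in ("potential_tasting_rate", "adoption_rate", "rejection_rate",
                     "promo_tasters", "wom_tasters"):
            assert base_trajectory[name].min() >= 0.0
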