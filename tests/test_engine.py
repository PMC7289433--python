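"""Engine-level tests: lookups, time inputs, integration, unit audit."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sdbass import (
    ConfigurationError,
    IntegrationError,
    LookupTable,
    RampInput,
    SimConfig,
    StepInput,
    audit_units,
    integrate,
    time_input_eval,
)
from sdbass.engine import Auxiliary, Flow, ModelSpec, Stock
from sdbass.model import APPROPRIATENESS_LOOKUP, TASTING_BARRIER_LOOKUP


class TestLookupTable:
    @pytest.mark.parametrize(
        "table, x, expected",
        [
            (TASTING_BARRIER_LOOKUP, 0.32, 0.93),  # exact breakpoint
            (TASTING_BARRIER_LOOKUP, 0.0, 1.0),  # first breakpoint identity
            (APPROPRIATENESS_LOOKUP, 0.25, 0.34),  # midway on the first segment
            (TASTING_BARRIER_LOOKUP, 1.5, 0.0),  # clamped above the range
            (TASTING_BARRIER_LOOKUP, -0.5, 1.0),  # clamped below the range
        ],
    )
    def test_evaluation(self, table, x, expected):
        assert table(x) == pytest.approx(expected, abs=1e-12)

    def test_non_increasing_x_rejected(self):
        with pytest.raises(ConfigurationError):
            LookupTable(((0.0, 0.0), (0.5, 0.5), (0.5, 1.0)))

    def test_single_breakpoint_rejected(self):
        with pytest.raises(ConfigurationError):
            LookupTable(((0.5, 0.5),))

    def test_breakpoint_outside_range_box_rejected(self):
        with pytest.raises(ConfigurationError):
            LookupTable(((0.0, 0.0), (1.0, 1.5)))

    @given(
        ys=st.lists(st.floats(0, 1), min_size=2, max_size=6),
        x1=st.floats(-0.5, 1.5),
        x2=st.floats(-0.5, 1.5),
    )
    @settings(max_examples=200, deadline=None)
    def test_monotone_table_gives_monotone_output(self, ys, x1, x2):
        """A lookup with non-decreasing y is a non-decreasing function of x."""
        ys = sorted(ys)
        xs = np.linspace(0, 1, len(ys))
        table = LookupTable(tuple(zip(xs, ys)))
        lo, hi = sorted((x1, x2))
        assert table(lo) <= table(hi) + 1e-12

    def test_replace_point(self):
        table = LookupTable(((0.0, 1.0), (0.55, 0.12), (1.0, 0.0)))
        raised = table.replace_point(1, 0.55, 0.19)
        assert raised(0.55) == 0.19
        assert table(0.55) == 0.12  # original untouched


class TestTimeInputs:
    @pytest.mark.parametrize(
        "value, t, expected",
        [
            (StepInput(0, 1, 2015), 2010, 0.0),  # before the step
            (StepInput(0, 1, 2015), 2015, 1.0),  # boundary inclusive at start
            (StepInput(0, 1, 2015), 2040, 1.0),
            (StepInput(0.3, 0.0, 2015), 1850, 0.3),  # zero height: constant
            (RampInput(0.54, 0.8, 2017, 2048), 2017, 0.54),
            (RampInput(0.54, 0.8, 2017, 2048), 2048, 0.8),
            (RampInput(0.54, 0.8, 2017, 2048), 2000, 0.54),  # flat before
            (RampInput(0.54, 0.8, 2017, 2048), 2060, 0.8),  # flat after
            (0.151, 2015, 0.151),  # plain constants pass through
        ],
    )
    def test_evaluation(self, value, t, expected):
        assert time_input_eval(value, t) == pytest.approx(expected, abs=1e-12)

    def test_ramp_midpoint_is_linear(self):
        ramp = RampInput(0.54, 0.8, 2017, 2048)
        mid = (2017 + 2048) / 2
        assert ramp(mid) == pytest.approx((0.54 + 0.8) / 2, abs=1e-12)

    def test_backwards_ramp_rejected(self):
        with pytest.raises(ConfigurationError):
            RampInput(0.0, 1.0, 2048, 2017)


class TestSimConfig:
    def test_grid_covers_horizon(self):
        grid = SimConfig().grid()
        assert grid[0] == 1998.0 and grid[-1] == 2048.0
        assert len(grid) == 401  # 50 years / 0.125 + 1

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"t0": 2048, "tf": 1998},
            {"dt": -0.125},
            {"dt": 0.3},  # does not divide the horizon
            {"method": "rk45"},
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            SimConfig(**kwargs)


def _two_stock_model(rate=100.0, a0=1000.0):
    return ModelSpec(
        stocks=[Stock("a", a0), Stock("b", 0.0)],
        flows=[Flow("transfer", lambda c: rate, source="a", target="b")],
    )


class TestIntegrate:
    def test_no_flows_keeps_stocks_constant(self):
        model = ModelSpec(stocks=[Stock("a", 5.0), Stock("b", 2.0)])
        traj = integrate(model, SimConfig(t0=0, tf=10, dt=0.5))
        assert np.all(traj["a"] == 5.0)
        assert np.all(traj["b"] == 2.0)

    @pytest.mark.parametrize("method", ["euler", "rk4"])
    def test_constant_flow_transfers_linearly(self, method):
        traj = integrate(_two_stock_model(), SimConfig(t0=0, tf=5, dt=0.25, method=method))
        assert traj["b"][-1] == pytest.approx(500.0, rel=1e-12)
        assert traj["a"][-1] == pytest.approx(500.0, rel=1e-12)

    def test_negative_stock_raises_naming_stock_and_time(self):
        with pytest.raises(IntegrationError, match="'a'.*t="):
            integrate(_two_stock_model(a0=10.0), SimConfig(t0=0, tf=5, dt=0.25))

    def test_negative_initial_stock_rejected(self):
        model = ModelSpec(stocks=[Stock("a", -1.0)])
        with pytest.raises(IntegrationError):
            integrate(model, SimConfig(t0=0, tf=1, dt=0.5))

    def test_flow_referencing_unknown_stock_rejected(self):
        with pytest.raises(ConfigurationError):
            ModelSpec(
                stocks=[Stock("a", 1.0)],
                flows=[Flow("f", lambda c: 0.0, source="a", target="zz")],
            )


class TestBaseModelNumerics:
    def test_conservation(self, base_trajectory):
        total = base_trajectory.total_population()
        assert np.max(np.abs(total - total[0])) <= 1e-9 * total[0]

    def test_step_size_convergence(self, base_model):
        """Halving dt changes every stock by < 0.1% of the population."""
        coarse = integrate(base_model, SimConfig(dt=0.125))
        fine = integrate(base_model, SimConfig(dt=0.0625))
        scale = coarse.total_population()[0]
        for stock in coarse.stock_names:
            dev = np.abs(fine.yearly()[stock] - coarse.yearly()[stock]).max()
            assert dev / scale < 1e-3

    def test_euler_rk4_agreement(self, base_model, base_trajectory):
        """First-order Euler stays within a sub-percent band of RK4 at
        dt=0.125 (the worst deviation, ~0.55% of the population on the
        potential-adopters stock near the adoption peak, is Euler's genuine
        truncation error for this curvature)."""
        euler = integrate(base_model, SimConfig(method="euler"))
        scale = base_trajectory.total_population()[0]
        for stock in base_trajectory.stock_names:
            dev = np.abs(euler[stock] - base_trajectory[stock]).max()
            assert dev / scale < 1e-2


class TestAuditUnits:
    def test_base_model_reports_the_two_documented_warnings(self, base_model):
        issues = audit_units(base_model)
        assert {(i.element, i.severity) for i in issues} == {
            ("wom_strength", "warning"),
            ("sensory_quality_adoption_fraction", "warning"),
        }

    def test_flow_declared_in_stock_units_is_an_error(self):
        model = ModelSpec(
            stocks=[Stock("a", 1.0), Stock("b", 0.0)],
            flows=[Flow("f", lambda c: 0.0, source="a", target="b", unit="people")],
        )
        issues = audit_units(model)
        assert [(i.element, i.severity) for i in issues] == [("f", "error")]

    def test_empty_model_passes(self):
        assert audit_units(ModelSpec()) == []
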