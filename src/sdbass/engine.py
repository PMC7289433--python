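"""Minimal deterministic stock-and-flow simulation core.

This module is a small, self-contained system-dynamics engine: piecewise-linear
lookup functions, step/ramp time inputs, a declarative model specification
(stocks, flows, auxiliaries, constants, lookups), fixed-step Euler/RK4
integration on a calendar-year grid, and a lightweight dimensional audit.

It deliberately supports only what an aggregate diffusion model needs: no
delays, arrays, conveyors or adaptive step-size control.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "ConfigurationError",
    "IntegrationError",
    "LookupTable",
    "StepInput",
    "RampInput",
    "TimeInput",
    "time_input_eval",
    "SimConfig",
    "Stock",
    "Auxiliary",
    "Flow",
    "ModelSpec",
    "Trajectory",
    "integrate",
    "UnitIssue",
    "audit_units",
]


class ConfigurationError(ValueError):
    """A model element, table or override is malformed."""


class IntegrationError(RuntimeError):
    """The integrator produced an invalid state (e.g. a negative stock)."""


# ---------------------------------------------------------------------------
# Lookup tables and time inputs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LookupTable:
    """Piecewise-linear y(x) defined by breakpoints, clamped outside the range.

    The system-dynamics ``WITH LOOKUP`` idiom: empirical nonlinear
    relationships are given as an ordered list of (x, y) breakpoints with a
    declared range box (here always the unit square). Evaluation is exact at
    breakpoints, linear between adjacent breakpoints, and clamps to the
    terminal y outside the x range.
    """

    points: tuple[tuple[float, float], ...]
    range_box: tuple[tuple[float, float], tuple[float, float]] = ((0.0, 0.0), (1.0, 1.0))

    def __post_init__(self) -> None:
        pts = tuple((float(x), float(y)) for x, y in self.points)
        object.__setattr__(self, "points", pts)
        if len(pts) < 2:
            raise ConfigurationError("lookup table needs at least 2 breakpoints")
        xs = [p[0] for p in pts]
        if any(b <= a for a, b in zip(xs, xs[1:])):
            raise ConfigurationError(f"lookup x values must be strictly increasing: {xs}")
        (xlo, ylo), (xhi, yhi) = self.range_box
        for x, y in pts:
            if not (xlo <= x <= xhi and ylo <= y <= yhi):
                raise ConfigurationError(
                    f"breakpoint ({x}, {y}) outside declared range box {self.range_box}"
                )

    @property
    def xs(self) -> np.ndarray:
        return np.array([p[0] for p in self.points])

    @property
    def ys(self) -> np.ndarray:
        return np.array([p[1] for p in self.points])

    def __call__(self, x: float) -> float:
        # np.interp clamps to the terminal y values outside the x range
        return float(np.interp(x, self.xs, self.ys))

    def replace_point(self, index: int, x: float, y: float) -> "LookupTable":
        """Return a copy with breakpoint `index` replaced by (x, y)."""
        pts = list(self.points)
        pts[index] = (x, y)
        return LookupTable(tuple(pts), self.range_box)


@dataclass(frozen=True)
class StepInput:
    """A constant that jumps by `height` at the `start` year (inclusive)."""

    base: float
    height: float
    start: float

    def __call__(self, t: float) -> float:
        return self.base + self.height if t >= self.start else self.base


@dataclass(frozen=True)
class RampInput:
    """Linear transition from start_value to end_value between two years."""

    start_value: float
    end_value: float
    start_year: float
    end_year: float

    def __post_init__(self) -> None:
        if not self.start_year < self.end_year:
            raise ConfigurationError("ramp requires start_year < end_year")

    def __call__(self, t: float) -> float:
        return float(
            np.interp(t, [self.start_year, self.end_year], [self.start_value, self.end_value])
        )


TimeInput = Union[float, int, StepInput, RampInput]


def time_input_eval(value: TimeInput, t: float) -> float:
    """Evaluate a constant or time-dependent input at calendar year t."""
    if callable(value):
        return float(value(t))
    return float(value)


# ---------------------------------------------------------------------------
# Simulation configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimConfig:
    """Fixed-step integration settings on a calendar-year grid."""

    t0: float = 1998.0
    tf: float = 2048.0
    dt: float = 0.125
    method: str = "rk4"

    def __post_init__(self) -> None:
        if not self.t0 < self.tf:
            raise ConfigurationError("t0 must precede tf")
        if self.dt <= 0:
            raise ConfigurationError("dt must be positive")
        if self.method not in ("euler", "rk4"):
            raise ConfigurationError(f"unknown method {self.method!r}; use 'euler' or 'rk4'")
        n = (self.tf - self.t0) / self.dt
        if abs(n - round(n)) > 1e-9:
            raise ConfigurationError("(tf - t0) must be a whole number of dt steps")

    @property
    def n_steps(self) -> int:
        return round((self.tf - self.t0) / self.dt)

    def grid(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.n_steps + 1)


# ---------------------------------------------------------------------------
# Model specification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Stock:
    name: str
    initial: float
    unit: str = "people"


@dataclass(frozen=True)
class Auxiliary:
    """An algebraic quantity computed each step from stocks/constants/lookups.

    `expected_unit` is the unit implied by how the element is *used* in the
    model; it defaults to the declared unit and is only set where a formula
    forces a different reading (the dimensional audit reports the mismatch).
    """

    name: str
    func: Callable[["EvalContext"], float]
    unit: str = "Dmnl"
    expected_unit: str | None = None


@dataclass(frozen=True)
class Flow:
    """A rate transferring population between stocks (source -> target)."""

    name: str
    func: Callable[["EvalContext"], float]
    source: str | None
    target: str | None
    unit: str = "people/Year"


class EvalContext:
    """Name-based access to model quantities while evaluating one time point."""

    __slots__ = ("t", "_stocks", "_constants", "_lookups", "aux")

    def __init__(self, t, stocks, constants, lookups):
        self.t = t
        self._stocks = stocks
        self._constants = constants
        self._lookups = lookups
        self.aux: dict[str, float] = {}

    def stock(self, name: str) -> float:
        return self._stocks[name]

    def const(self, name: str) -> float:
        return time_input_eval(self._constants[name], self.t)

    def lookup(self, name: str, x: float) -> float:
        return self._lookups[name](x)


@dataclass
class ModelSpec:
    """Declarative stock-and-flow model.

    Auxiliaries are evaluated in list order (earlier ones may be referenced by
    later ones through the context), then flows; every flow drains at most one
    stock and fills at most one stock, so total population is conserved
    whenever every flow has both a source and a target.
    """

    stocks: list[Stock] = field(default_factory=list)
    flows: list[Flow] = field(default_factory=list)
    auxiliaries: list[Auxiliary] = field(default_factory=list)
    constants: dict[str, TimeInput] = field(default_factory=dict)
    lookups: dict[str, LookupTable] = field(default_factory=dict)
    constant_units: dict[str, str] = field(default_factory=dict)
    constant_expected_units: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        stock_names = {s.name for s in self.stocks}
        for f in self.flows:
            for end in (f.source, f.target):
                if end is not None and end not in stock_names:
                    raise ConfigurationError(f"flow {f.name!r} references unknown stock {end!r}")

    @property
    def element_names(self) -> set[str]:
        return (
            {s.name for s in self.stocks}
            | {f.name for f in self.flows}
            | {a.name for a in self.auxiliaries}
            | set(self.constants)
            | set(self.lookups)
        )

    def copy(self) -> "ModelSpec":
        return dataclasses.replace(
            self,
            stocks=list(self.stocks),
            flows=list(self.flows),
            auxiliaries=list(self.auxiliaries),
            constants=dict(self.constants),
            lookups=dict(self.lookups),
            constant_units=dict(self.constant_units),
            constant_expected_units=dict(self.constant_expected_units),
        )

    # -- evaluation ---------------------------------------------------------

    def evaluate(self, state: np.ndarray, t: float) -> tuple[np.ndarray, dict[str, float]]:
        """Return (d state / dt, all auxiliary and flow values) at (state, t)."""
        stock_map = {s.name: float(v) for s, v in zip(self.stocks, state)}
        ctx = EvalContext(t, stock_map, self.constants, self.lookups)
        for aux in self.auxiliaries:
            ctx.aux[aux.name] = float(aux.func(ctx))
        index = {s.name: i for i, s in enumerate(self.stocks)}
        deriv = np.zeros(len(self.stocks))
        for flow in self.flows:
            rate = float(flow.func(ctx))
            ctx.aux[flow.name] = rate
            if flow.source is not None:
                deriv[index[flow.source]] -= rate
            if flow.target is not None:
                deriv[index[flow.target]] += rate
        return deriv, ctx.aux


# ---------------------------------------------------------------------------
# Trajectory container and integration
# ---------------------------------------------------------------------------


@dataclass
class Trajectory:
    """Stocks, auxiliaries and flows sampled on the simulation grid."""

    data: pd.DataFrame  # index: calendar year (float grid), one column per element
    config: SimConfig
    stock_names: list[str]

    @property
    def times(self) -> np.ndarray:
        return self.data.index.to_numpy()

    def __getitem__(self, column: str) -> np.ndarray:
        return self.data[column].to_numpy()

    def at_year(self, year: float) -> pd.Series:
        """Row at an exact grid point (raises KeyError off-grid)."""
        idx = self.data.index.get_indexer([year], method="nearest")[0]
        t = self.data.index[idx]
        if abs(t - year) > 1e-9:
            raise KeyError(f"year {year} is not on the simulation grid")
        return self.data.iloc[idx]

    def value_at(self, column: str, year: float) -> float:
        return float(self.at_year(year)[column])

    def yearly(self) -> pd.DataFrame:
        """Rows at integer calendar years (all on-grid for dt dividing 1.0)."""
        on_year = np.isclose(self.times % 1.0, 0.0, atol=1e-9)
        out = self.data.loc[on_year].copy()
        out.index = out.index.round().astype(int)
        out.index.name = "year"
        return out

    def total_population(self) -> np.ndarray:
        return self.data[self.stock_names].sum(axis=1).to_numpy()


def _check_nonnegative(state: np.ndarray, model: ModelSpec, t: float, scale: float) -> None:
    tol = -1e-9 * max(scale, 1.0)
    if state.min() < tol:
        i = int(np.argmin(state))
        raise IntegrationError(
            f"stock {model.stocks[i].name!r} became negative ({state[i]:.6g}) at t={t:g}"
        )


def integrate(model: ModelSpec, config: SimConfig | None = None) -> Trajectory:
    """Simulate the model on the fixed grid with Euler or classical RK4.

    Every stock, auxiliary and flow is recorded at every grid point; stocks are
    checked against negativity after every step (an aggregate compartment model
    must keep its populations non-negative).
    """
    config = config or SimConfig()
    state = np.array([s.initial for s in model.stocks], dtype=float)
    if state.size and state.min() < 0:
        raise IntegrationError("initial stocks must be non-negative")
    scale = float(state.sum()) if state.size else 1.0

    grid = config.grid()
    aux_rows: list[dict[str, float]] = []
    states = np.empty((grid.size, state.size))
    dt = config.dt

    for k, t in enumerate(grid):
        states[k] = state
        deriv, aux = model.evaluate(state, t)
        aux_rows.append(aux)
        if k == grid.size - 1:
            break
        # Step inputs may switch exactly at grid points. Stage times are
        # nudged inside the open interval so each step uses one-sided limits
        # of the right-hand side; this keeps the integrator at full order
        # across grid-aligned discontinuities (the recorded values above use
        # the exact, inclusive-at-start convention).
        eta = 1e-9 * dt
        if config.method == "euler":
            k1, _ = model.evaluate(state, t + eta)
            state = state + dt * k1
        else:  # classical RK4
            k1, _ = model.evaluate(state, t + eta)
            k2, _ = model.evaluate(state + 0.5 * dt * k1, t + 0.5 * dt)
            k3, _ = model.evaluate(state + 0.5 * dt * k2, t + 0.5 * dt)
            k4, _ = model.evaluate(state + dt * k3, t + dt - eta)
            state = state + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        _check_nonnegative(state, model, grid[k + 1], scale)

    frame = pd.DataFrame(states, index=pd.Index(grid, name="time"),
                         columns=[s.name for s in model.stocks])
    if aux_rows:
        aux_frame = pd.DataFrame(aux_rows, index=frame.index)
        frame = pd.concat([frame, aux_frame], axis=1)
    return Trajectory(data=frame, config=config, stock_names=[s.name for s in model.stocks])


# ---------------------------------------------------------------------------
# Dimensional audit
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class UnitIssue:
    element: str
    declared: str
    expected: str
    severity: str  # "error" | "warning"
    message: str


def audit_units(model: ModelSpec) -> list[UnitIssue]:
    """Check declared units against the units each element's role implies.

    Structural rules: all stocks share one unit U and every flow must be
    U/Year — violations are errors. For auxiliaries and constants the model
    builder may declare an `expected_unit` where the element's formula forces
    a different dimensional reading than its declared unit; those mismatches
    are reported as warnings (documented inconsistencies, not failures).
    """
    issues: list[UnitIssue] = []
    if model.stocks:
        stock_unit = model.stocks[0].unit
        for s in model.stocks:
            if s.unit != stock_unit:
                issues.append(UnitIssue(s.name, s.unit, stock_unit, "error",
                                        "all stocks must share one unit"))
        flow_unit = f"{stock_unit}/Year"
        for f in model.flows:
            if f.unit != flow_unit:
                issues.append(UnitIssue(f.name, f.unit, flow_unit, "error",
                                        "a flow must carry stock-units per year"))
    for a in model.auxiliaries:
        expected = a.expected_unit or a.unit
        if expected != a.unit:
            issues.append(UnitIssue(a.name, a.unit, expected, "warning",
                                    "declared unit conflicts with the unit its usage implies"))
    for name, declared in model.constant_units.items():
        expected = model.constant_expected_units.get(name, declared)
        if expected != declared:
            issues.append(UnitIssue(name, declared, expected, "warning",
                                    "declared unit conflicts with the unit its usage implies"))
    return issues
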