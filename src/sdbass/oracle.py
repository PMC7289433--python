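"""Closed-form and reduced-form Bass mathematics used as correctness oracles.

The potential-adopters stock of the full four-stock model obeys exactly the
classic mixed-influence Bass equation

    dN/dt = p (m - N) + (q/m) N (m - N),

with N the cumulative departures m - PA(t), p the coefficient of innovation
(promotional fraction times the tasting barrier) and q the coefficient of
imitation (word-of-mouth strength times the tasting barrier). Its closed-form
solution provides an independent check on the numerical integrator.

The downstream tasters/adopters/rejecters dynamics reduce to a
three-compartment system with time-varying adoption and rejection
coefficients c(t) and d(t); simulating that reduced system independently and
matching the full model is a second, structural oracle. The published form of
the reduced system ends its tasters equation with a ``- d(t) R(t)`` term; the
stock-flow structure drains rejection from the tasters stock (``d(t) T(t)``),
so d*T is the canonical reading here and the printed d*R is kept available as
a documented, suspected-typographical variant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .engine import ConfigurationError, SimConfig, Trajectory, time_input_eval
from .model import (
    ADOPTION_LIKELIHOOD_LOOKUP,
    APPROPRIATENESS_LOOKUP,
    BASE_LOOKUPS,
    DEFAULT_CONSTANTS,
    ModelConstants,
    SENSORY_QUALITY_LOOKUP,
    TASTE_EXPECTATION_LOOKUP,
    TASTING_BARRIER_LOOKUP,
    barrier_towards_adopting,
)

__all__ = [
    "AnalyticBassParams",
    "bass_closed_form",
    "bass_params_from_constants",
    "ExtendedBassCoefficients",
    "extract_extended_coefficients",
    "OracleResult",
    "oracle_equivalence",
    "reduced_bass_trajectory",
]


@dataclass(frozen=True)
class AnalyticBassParams:
    """Classic Bass parameters: innovation p, imitation q (per year), market m."""

    p: float
    q: float
    m: float

    def __post_init__(self) -> None:
        if self.p <= 0:
            raise ConfigurationError(
                "the closed form is undefined for p <= 0 in this parameterization")
        if self.q < 0:
            raise ConfigurationError("q must be non-negative")
        if self.m <= 0:
            raise ConfigurationError("m must be positive")


def bass_closed_form(params: AnalyticBassParams, t) -> np.ndarray | float:
    """Cumulative adopters N(t) of the mixed-influence Bass model.

    N(t) = m (1 - e^{-(p+q)t}) / (1 + (q/p) e^{-(p+q)t}), with t in years
    since the diffusion start; N(0) = 0 and N -> m as t -> infinity.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ConfigurationError("t must be non-negative")
    e = np.exp(-(params.p + params.q) * t)
    n = params.m * (1.0 - e) / (1.0 + (params.q / params.p) * e)
    return float(n) if n.ndim == 0 else n


def bass_params_from_constants(constants: ModelConstants = DEFAULT_CONSTANTS
                               ) -> AnalyticBassParams:
    """Effective (p, q, m) of the potential-adopters sub-dynamics.

    Both influence channels are attenuated by the disgust barrier, so
    p = barrier * promotional fraction and q = barrier * word-of-mouth
    strength.
    """
    barrier = TASTING_BARRIER_LOOKUP(constants.average_disgust_level)
    return AnalyticBassParams(
        p=barrier * constants.promo_tasters_fraction,
        q=barrier * constants.wom_strength,
        m=constants.m,
    )


@dataclass(frozen=True)
class ExtendedBassCoefficients:
    """Per-year coefficients of the reduced three-compartment extension.

    p2/q2 drive tasting (innovation/imitation through the disgust barrier);
    c and d are the adoption and rejection coefficients, zero while the
    product is unavailable.
    """

    p2: float
    q2: float
    c: float
    d: float


def extract_extended_coefficients(constants: ModelConstants = DEFAULT_CONSTANTS,
                                  lookups: dict | None = None,
                                  t: float = 2015.0,
                                  familiarity: float = 0.0,
                                  ) -> ExtendedBassCoefficients:
    """Evaluate (p2, q2, c, d) from the model constants and current lookups.

    c = availability * sensory fraction * likelihood-to-adopt and
    d = availability * (1 - sensory fraction) * (1 - likelihood); likelihood
    depends on the current population familiarity through the taste-
    expectation and appropriateness lookups, so c and d are time-varying.
    """
    lookups = dict(BASE_LOOKUPS) if lookups is None else lookups
    barrier_tasting = lookups["barrier_towards_tasting"](constants.average_disgust_level)
    p2 = constants.promo_tasters_fraction * barrier_tasting
    q2 = constants.wom_strength * barrier_tasting

    avail = 1.0 if t >= constants.availability_start_year else 0.0
    taste = lookups["average_taste_expectation"](familiarity)
    approp = lookups["average_appropriateness"](familiarity)
    likelihood = lookups["likelihood_to_adopt"](barrier_towards_adopting(taste, approp))
    sensory = lookups["sensory_quality_adoption_fraction"](constants.average_sensory_quality)
    return ExtendedBassCoefficients(
        p2=p2,
        q2=q2,
        c=avail * sensory * likelihood,
        d=avail * (1.0 - sensory) * (1.0 - likelihood),
    )


@dataclass(frozen=True)
class OracleResult:
    passed: bool
    max_relative_deviation: float
    at_time: float
    tolerance: float


def oracle_equivalence(trajectory: Trajectory, params: AnalyticBassParams,
                       tolerance: float = 1e-4) -> OracleResult:
    """Compare simulated cumulative departures m - PA(t) with the closed form.

    The deviation at each grid point is relative to the closed-form value
    (the initial point, where both are exactly zero, is excluded).
    """
    times = trajectory.times
    if times.size < 2:
        raise ConfigurationError("trajectory is too short for an oracle comparison")
    pa0 = trajectory["potential_adopters"][0]
    if abs(pa0 - params.m) > 1e-6 * params.m:
        raise ConfigurationError(
            f"params.m ({params.m:g}) does not match the trajectory's initial "
            f"potential adopters ({pa0:g})")
    simulated = params.m - trajectory["potential_adopters"]
    exact = bass_closed_form(params, times - times[0])
    rel = np.abs(simulated[1:] - exact[1:]) / exact[1:]
    worst = int(np.argmax(rel))
    return OracleResult(
        passed=bool(rel[worst] < tolerance),
        max_relative_deviation=float(rel[worst]),
        at_time=float(times[1 + worst]),
        tolerance=tolerance,
    )


# ---------------------------------------------------------------------------
# Reduced three-compartment system (independent of the engine module)
# ---------------------------------------------------------------------------


def _reduced_rhs(state: np.ndarray, t: float, constants: ModelConstants,
                 lookups: dict, rejection_outflow: str) -> np.ndarray:
    tasters, adopters, rejecters = state
    m = constants.m
    familiar = (tasters + adopters + rejecters) / m
    coef = extract_extended_coefficients(constants, lookups, t, familiar)
    inflow = (coef.p2 + coef.q2 * familiar) * (m - tasters - adopters - rejecters)
    rejection = coef.d * (tasters if rejection_outflow == "tasters" else rejecters)
    d_tasters = inflow - coef.c * tasters - rejection
    return np.array([d_tasters, coef.c * tasters, rejection])


def reduced_bass_trajectory(constants: ModelConstants = DEFAULT_CONSTANTS,
                            config: SimConfig | None = None,
                            lookups: dict | None = None,
                            rejection_outflow: str = "tasters") -> pd.DataFrame:
    """Integrate the reduced (T, N, R) extension with its own RK4 stepper.

    `rejection_outflow` selects the canonical ``d*T`` drain from tasters, or
    the literally printed ``d*R`` variant (``"rejecters"``; with R(0) = 0 that
    variant never produces any rejecters, which is why it is read as a typo).
    """
    if rejection_outflow not in ("tasters", "rejecters"):
        raise ConfigurationError("rejection_outflow must be 'tasters' or 'rejecters'")
    config = config or SimConfig()
    lookups = dict(BASE_LOOKUPS) if lookups is None else lookups
    grid = config.grid()
    dt = config.dt
    state = np.zeros(3)
    rows = np.empty((grid.size, 3))
    for k, t in enumerate(grid):
        rows[k] = state
        if k == grid.size - 1:
            break
        # Same one-sided treatment of grid-aligned step discontinuities as
        # the main engine, so the two integrations agree to round-off.
        eta = 1e-9 * dt
        k1 = _reduced_rhs(state, t + eta, constants, lookups, rejection_outflow)
        if config.method == "euler":
            state = state + dt * k1
        else:
            k2 = _reduced_rhs(state + 0.5 * dt * k1, t + 0.5 * dt, constants, lookups,
                              rejection_outflow)
            k3 = _reduced_rhs(state + 0.5 * dt * k2, t + 0.5 * dt, constants, lookups,
                              rejection_outflow)
            k4 = _reduced_rhs(state + dt * k3, t + dt - eta, constants, lookups,
                              rejection_outflow)
            state = state + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
    return pd.DataFrame(rows, index=pd.Index(grid, name="time"),
                        columns=["potential_tasters", "adopters", "rejecters"])
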