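"""Model verification battery: pattern, calibration, extreme-condition and
sensitivity checks.

System-dynamics practice validates a model by its behaviour, not by point
prediction: the cumulative-familiarity curve must be S-shaped, hit the
empirical ~20% familiarity anchor in 2015, and approach saturation by 2048;
the cumulative internal (word-of-mouth) influence must be roughly ten times
the cumulative external (promotional) influence; and the model must behave
sensibly at boundary parameter values while conserving its closed population.
Thresholds here are the package's own: "approximately 20%" is read as +/-3
percentage points and "approximately ten times" as a ratio in [8, 12].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .engine import ConfigurationError, SimConfig, Trajectory, audit_units, integrate
from .model import DEFAULT_CONSTANTS, ModelConstants, build_base_model
from .oracle import bass_params_from_constants, oracle_equivalence

__all__ = [
    "CheckResult",
    "ValidationReport",
    "pattern_behaviour_test",
    "influence_ratio",
    "extreme_conditions_suite",
    "SensitivityResult",
    "sensitivity_sweep",
    "full_validation_report",
]

FAMILIARITY_TARGET = 0.20
FAMILIARITY_TOLERANCE = 0.03
FAMILIARITY_CHECK_YEAR = 2015
SATURATION_YEAR = 2048
SATURATION_THRESHOLD = 0.95
INFLUENCE_RATIO_BOUNDS = (8.0, 12.0)


@dataclass(frozen=True)
class CheckResult:
    name: str
    status: str  # "pass" | "warn" | "fail"
    measured: float | None
    target: str
    detail: str = ""

    @property
    def passed(self) -> bool:
        return self.status != "fail"


@dataclass
class ValidationReport:
    checks: list[CheckResult] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return all(c.passed for c in self.checks)

    def add(self, check: CheckResult) -> None:
        self.checks.append(check)

    def to_dict(self) -> dict:
        return {
            "passed": self.passed,
            "checks": [
                {"name": c.name, "status": c.status, "measured": c.measured,
                 "target": c.target, "detail": c.detail}
                for c in self.checks
            ],
        }

    def to_text(self) -> str:
        width = max((len(c.name) for c in self.checks), default=0)
        lines = []
        for c in self.checks:
            measured = "" if c.measured is None else f"  measured={c.measured:.6g}"
            lines.append(f"[{c.status.upper():<4}] {c.name:<{width}}  "
                         f"target: {c.target}{measured}  {c.detail}".rstrip())
        lines.append("OVERALL: " + ("PASS" if self.passed else "FAIL"))
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Pattern behaviour
# ---------------------------------------------------------------------------


def _yearly_familiarity(trajectory: Trajectory) -> pd.Series:
    series = trajectory.yearly()["average_familiarity"]
    if FAMILIARITY_CHECK_YEAR not in series.index or SATURATION_YEAR not in series.index:
        raise ConfigurationError(
            f"trajectory must cover {FAMILIARITY_CHECK_YEAR} and {SATURATION_YEAR}")
    return series


def pattern_behaviour_test(trajectory: Trajectory) -> ValidationReport:
    """S-shape test on average familiarity with the 2015 calibration anchor.

    Passes iff familiarity (a) never decreases, (b) grows with a single
    interior inflection (rate rises then falls), (c) is within the tolerance
    band around 20% in 2015, and (d) exceeds 95% by 2048.
    """
    f = _yearly_familiarity(trajectory)
    report = ValidationReport()

    diffs = np.diff(f.to_numpy())
    report.add(CheckResult(
        "familiarity_non_decreasing",
        "pass" if np.all(diffs >= -1e-12) else "fail",
        float(diffs.min()) if diffs.size else None,
        "min yearly change >= 0"))

    # Single interior inflection: after light smoothing (3-point moving
    # average, to suppress grid-scale noise) the second difference must change
    # sign exactly once, from + to -.
    smooth = f.rolling(3, center=True).mean().dropna().to_numpy()
    d2 = np.diff(smooth, 2)
    eps = 1e-9 * np.max(np.abs(d2)) if d2.size else 0.0
    signs = np.sign(d2[np.abs(d2) > eps])
    transitions = np.diff(signs)
    n_down = int(np.sum(transitions < 0))
    n_up = int(np.sum(transitions > 0))
    s_shaped = n_down == 1 and n_up == 0
    report.add(CheckResult(
        "familiarity_single_inflection", "pass" if s_shaped else "fail",
        float(n_down), "exactly one +to- sign change of the second difference",
        f"up-transitions={n_up}"))

    f2015 = float(f.loc[FAMILIARITY_CHECK_YEAR])
    ok = abs(f2015 - FAMILIARITY_TARGET) <= FAMILIARITY_TOLERANCE
    report.add(CheckResult(
        "familiarity_2015_calibration", "pass" if ok else "fail", f2015,
        f"within +/-{FAMILIARITY_TOLERANCE} of {FAMILIARITY_TARGET}"))

    f2048 = float(f.loc[SATURATION_YEAR])
    report.add(CheckResult(
        "familiarity_2048_saturation",
        "pass" if f2048 > SATURATION_THRESHOLD else "fail", f2048,
        f"> {SATURATION_THRESHOLD}"))
    return report


def influence_ratio(trajectory: Trajectory) -> float:
    """Cumulative word-of-mouth tasters over cumulative promotional tasters.

    Both flows are integrated over the full horizon with the trapezoidal rule
    on the simulation grid; the model was tuned so the internal influence is
    roughly ten times the external one.
    """
    times = trajectory.times
    wom = np.trapezoid(trajectory["wom_tasters"], times)
    promo = np.trapezoid(trajectory["promo_tasters"], times)
    if promo <= 0:
        raise ConfigurationError("promotional influence integrates to zero")
    return float(wom / promo)


# ---------------------------------------------------------------------------
# Extreme conditions
# ---------------------------------------------------------------------------


def _conservation_ok(trajectory: Trajectory) -> bool:
    total = trajectory.total_population()
    scale = max(abs(total[0]), 1.0)
    return bool(np.max(np.abs(total - total[0])) <= 1e-9 * scale)


def extreme_conditions_suite(constants: ModelConstants = DEFAULT_CONSTANTS,
                             config: SimConfig | None = None) -> ValidationReport:
    """Boundary-value runs: empty population, total disgust, zero sensory
    quality, and a product that never reaches the market.

    Each run must meet its structural expectation, conserve the closed
    population, and keep every stock non-negative.
    """
    config = config or SimConfig()
    report = ValidationReport()

    def run_case(name: str, case_constants: ModelConstants, checks) -> None:
        traj = integrate(build_base_model(case_constants), config)
        end = traj.at_year(config.tf)
        for check_name, value, target, ok in checks(traj, end):
            report.add(CheckResult(f"{name}:{check_name}", "pass" if ok else "fail",
                                   value, target))
        report.add(CheckResult(f"{name}:conservation",
                               "pass" if _conservation_ok(traj) else "fail",
                               None, "total population constant"))
        min_stock = float(traj.data[traj.stock_names].to_numpy().min())
        report.add(CheckResult(f"{name}:non_negative",
                               "pass" if min_stock >= -1e-9 else "fail",
                               min_stock, "all stocks >= 0"))

    run_case(
        "empty_population", replace(constants, special_diet_fraction=1.0),
        lambda traj, end: [
            ("all_stocks_zero", float(np.abs(traj.data[traj.stock_names].to_numpy()).max()),
             "== 0", bool(np.all(traj.data[traj.stock_names].to_numpy() == 0.0))),
        ])
    run_case(
        "full_disgust", replace(constants, average_disgust_level=1.0),
        lambda traj, end: [
            ("no_tasters", float(end["potential_tasters"]), "== 0",
             end["potential_tasters"] == 0.0),
            ("no_adopters", float(end["adopters"]), "== 0", end["adopters"] == 0.0),
            ("nobody_leaves", float(end["potential_adopters"]), "== m",
             end["potential_adopters"] == constants.m),
        ])
    run_case(
        "zero_sensory_quality", replace(constants, average_sensory_quality=0.0),
        lambda traj, end: [
            ("no_adopters_ever", float(np.abs(traj["adopters"]).max()), "== 0",
             bool(np.all(traj["adopters"] == 0.0))),
        ])
    run_case(
        "never_available", replace(constants, availability_start_year=math.inf),
        lambda traj, end: [
            ("no_adopters_ever", float(np.abs(traj["adopters"]).max()), "== 0",
             bool(np.all(traj["adopters"] == 0.0))),
            ("no_rejecters_ever", float(np.abs(traj["rejecters"]).max()), "== 0",
             bool(np.all(traj["rejecters"] == 0.0))),
        ])
    return report


# ---------------------------------------------------------------------------
# Sensitivity
# ---------------------------------------------------------------------------

_SWEEPABLE = ("total_population_census", "special_diet_fraction", "average_disgust_level",
              "average_sensory_quality", "promo_tasters_fraction", "wom_strength")


@dataclass
class SensitivityResult:
    element: str
    output: str
    at_year: float
    table: pd.DataFrame  # columns: multiplier, input_value, output_value
    normalized_sensitivity: float  # (relative output change)/(relative input change) at base


def sensitivity_sweep(element: str, relative_range: float, n_points: int,
                      output: str, at_year: float,
                      constants: ModelConstants = DEFAULT_CONSTANTS,
                      config: SimConfig | None = None) -> SensitivityResult:
    """One-at-a-time sweep of a scalar constant, all else held at base.

    The element is scaled by multipliers spanning 1 +/- relative_range; the
    stated output is read off at the stated year for each run. The normalized
    sensitivity (elasticity) at the base point is estimated by a central
    difference at +/-1% of the element's base value.
    """
    if element not in _SWEEPABLE:
        raise ConfigurationError(f"unknown sweep element {element!r}; one of {_SWEEPABLE}")
    if n_points < 3:
        raise ConfigurationError("n_points must be at least 3")
    config = config or SimConfig()
    base_value = getattr(constants, element)

    def run(multiplier: float) -> float:
        c = replace(constants, **{element: base_value * multiplier})
        traj = integrate(build_base_model(c), config)
        if output not in traj.data.columns:
            raise ConfigurationError(f"unknown output {output!r}")
        return traj.value_at(output, at_year)

    multipliers = np.linspace(1.0 - relative_range, 1.0 + relative_range, n_points)
    rows = [{"multiplier": float(mult), "input_value": float(base_value * mult),
             "output_value": run(float(mult))} for mult in multipliers]

    out_base = run(1.0)
    out_up, out_dn = run(1.01), run(0.99)
    if out_up == out_dn:
        elasticity = 0.0  # structurally insensitive output
    elif out_base == 0.0:
        elasticity = math.inf
    else:
        elasticity = ((out_up - out_dn) / out_base) / 0.02

    return SensitivityResult(element=element, output=output, at_year=at_year,
                             table=pd.DataFrame(rows),
                             normalized_sensitivity=float(elasticity))


# ---------------------------------------------------------------------------
# Full report
# ---------------------------------------------------------------------------


def full_validation_report(constants: ModelConstants = DEFAULT_CONSTANTS,
                           config: SimConfig | None = None) -> ValidationReport:
    """Pattern, calibration, influence-ratio, oracle and extreme-condition
    checks on one model configuration, plus the dimensional audit."""
    config = config or SimConfig()
    model = build_base_model(constants)
    trajectory = integrate(model, config)
    report = ValidationReport()

    for check in pattern_behaviour_test(trajectory).checks:
        report.add(check)

    try:
        ratio = influence_ratio(trajectory)
        lo, hi = INFLUENCE_RATIO_BOUNDS
        report.add(CheckResult("influence_ratio", "pass" if lo <= ratio <= hi else "fail",
                               ratio, f"in [{lo}, {hi}]"))
    except ConfigurationError as exc:
        report.add(CheckResult("influence_ratio", "fail", None, "in [8, 12]", str(exc)))

    try:
        result = oracle_equivalence(trajectory, bass_params_from_constants(constants))
        report.add(CheckResult("bass_oracle_equivalence",
                               "pass" if result.passed else "fail",
                               result.max_relative_deviation,
                               f"max relative deviation < {result.tolerance}"))
    except ConfigurationError as exc:
        report.add(CheckResult("bass_oracle_equivalence", "fail", None, "< 1e-4", str(exc)))

    report.add(CheckResult("conservation",
                           "pass" if _conservation_ok(trajectory) else "fail",
                           None, "total population constant"))

    for check in extreme_conditions_suite(constants, config).checks:
        report.add(check)

    for issue in audit_units(model):
        report.add(CheckResult(f"units:{issue.element}",
                               "warn" if issue.severity == "warning" else "fail",
                               None, f"declared {issue.declared}, implied {issue.expected}",
                               issue.message))
    return report
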