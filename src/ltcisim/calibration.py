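"""Escalation-rate calibration and historical-validation arithmetic.

The expenditure side of the model grows much faster than the insured pools
alone; the extra geometric growth is collected in a single escalation rate
``esc`` acting on the net per-beneficiary cost.  Because no direct
observation of ``esc`` exists, it is pinned down in closed form from a
published scenario anchor whose revenue side is independent of ``esc``: the
scenario with individual payment rate 0.1% and its published 2030 annual
balance of ¥381.7 million.

The historical-validation helpers implement the percent-error arithmetic
used to check the model against yearbook series (insured-employee counts and
per-capita disposable income, 2012–2018).
"""

from __future__ import annotations

from dataclasses import dataclass

from .model import project_state, revenue_flows, simulate
from .params import ModelParameters
from .scenarios import Scenario, apply_scenario

__all__ = [
    "CalibrationSpec",
    "HistoricalPair",
    "calibrate_escalation",
    "calibrated",
    "simulate_calibrated",
    "percent_error",
    "mean_error",
    "mean_absolute_error",
]


@dataclass(frozen=True)
class CalibrationSpec:
    """Anchor defining the escalation calibration.

    Defaults: the individual-payment-rate-0.1% scenario, year 2030, published
    annual balance +¥381.7 million.  The anchor scenario must not touch
    expenditure-side levers, so its revenue is independent of ``esc``.
    """

    anchor_scenario: Scenario = Scenario("Test1-3", {"r_ind": 0.001})
    anchor_year: int = 2030
    anchor_balance: float = 381.7e6


def calibrate_escalation(
    params: ModelParameters, spec: CalibrationSpec | None = None
) -> float:
    """Solve for the escalation rate that reproduces the anchor balance.

    With revenue fixed by the anchor scenario, the required anchor-year
    expenditure is ``E* = revenue(anchor_year) − anchor_balance``; since
    expenditure scales as ``(1+esc)**t`` the solution is the pure power law

        ``esc = (E* / expenditure(anchor_year; esc=0)) ** (1/t) − 1``

    with ``t = anchor_year − year_start``.  Re-simulating with the returned
    rate reproduces the anchor balance to floating-point precision.
    """
    spec = spec or CalibrationSpec()
    if not params.year_start <= spec.anchor_year <= params.year_end:
        raise ValueError("anchor year outside simulation horizon")
    anchored = apply_scenario(params, spec.anchor_scenario)
    state = project_state(anchored, spec.anchor_year)
    *_, rev_total = revenue_flows(state, anchored)
    e_star = rev_total - spec.anchor_balance
    if e_star <= 0:
        raise ValueError(
            "anchor infeasible: required expenditure "
            f"{e_star:.0f} yuan is non-positive (anchor balance "
            f"{spec.anchor_balance:.0f} exceeds anchor-year revenue "
            f"{rev_total:.0f})"
        )
    t = spec.anchor_year - params.year_start
    if t == 0:
        raise ValueError("anchor year must lie after the base year")
    e_flat = state.n_insured * params.d_sev * params.net_cost_per_disabled
    return (e_star / e_flat) ** (1.0 / t) - 1.0


def calibrated(params: ModelParameters, spec: CalibrationSpec | None = None) -> ModelParameters:
    """``params`` with ``esc`` replaced by the freshly calibrated value."""
    return params.replace(esc=calibrate_escalation(params, spec))


@dataclass(frozen=True)
class HistoricalPair:
    """One actual/simulated observation of a validated yearbook series.

    ``reported_error`` holds the error rate as published, when available.
    The published income-series rates use the opposite sign convention to
    :func:`percent_error` (they equal ``100*(actual − simulated)/actual``),
    so a pair's :attr:`error` prefers the reported rate; the published mean
    error is defined over those rates as printed.
    """

    year: int
    actual: float
    simulated: float
    series: str = ""
    reported_error: float | None = None

    def __post_init__(self) -> None:
        if not self.actual > 0:
            raise ValueError("actual observation must be strictly positive")

    @property
    def error(self) -> float:
        """Reported error rate if available, else the uniform convention."""
        if self.reported_error is not None:
            return self.reported_error
        return percent_error(self.actual, self.simulated)


def percent_error(actual: float, simulated: float) -> float:
    """Signed percent deviation ``100 * (simulated − actual) / actual``."""
    if actual == 0:
        raise ValueError("percent error undefined for zero actual value")
    return 100.0 * (simulated - actual) / actual


def mean_error(pairs: list[HistoricalPair]) -> float:
    """Arithmetic mean of the signed per-pair percent errors.

    Over the full packaged validation table this reproduces the published
    0.67% average model error.
    """
    if not pairs:
        raise ValueError("mean error requires at least one pair")
    return sum(p.error for p in pairs) / len(pairs)


def mean_absolute_error(pairs: list[HistoricalPair]) -> float:
    """Arithmetic mean of the absolute per-pair percent errors."""
    if not pairs:
        raise ValueError("mean error requires at least one pair")
    return sum(abs(p.error) for p in pairs) / len(pairs)


def simulate_calibrated(
    params: ModelParameters, spec: CalibrationSpec | None = None
):
    """Convenience: calibrate ``esc`` then simulate; returns the trajectory."""
    return simulate(calibrated(params, spec))
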