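"""Policy-lever scenarios for the LTCI fund model.

Four levers are adjustable: the individual payment rate (``r_ind``), the
reimbursement ratio (``reimb``), the severe disability rate (``d_sev``), and
the enterprise contribution rate and government subsidy rate moved jointly
(``r_gov_ent`` — pilot practice keeps the two equal).  The built-in batteries
reproduce the published scenario grids:

* ``test1`` — r_ind ∈ {0.06%, 0.08%, 0.1%}
* ``test2`` — reimb ∈ {50%, 60%, 70%, 80%, 90%}
* ``test3`` — joint enterprise/government rate ∈ {0.04% … 0.07%}
* ``test4`` — d_sev ∈ {0.3%, 0.4%, 0.5%}
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .model import Trajectory, simulate
from .params import ModelParameters

__all__ = [
    "Scenario",
    "ScenarioResult",
    "BumpResult",
    "LEVERS",
    "LEVER_RANGES",
    "apply_scenario",
    "run_battery",
    "battery",
    "BATTERY_NAMES",
    "compare",
    "deficit_year",
    "bump_analysis",
    "rank_levers",
]

#: Recognised lever names, in the documented stable reporting order
#: (descending 2030 balance impact under the default parameters; the
#: d_sev/reimb tie is broken by this order).
LEVERS = ("d_sev", "reimb", "r_gov_ent", "r_ind")

#: Published scenario ranges per lever; values outside are extrapolation.
LEVER_RANGES = {
    "r_ind": (0.0006, 0.001),
    "reimb": (0.5, 0.9),
    "r_gov_ent": (0.0004, 0.0007),
    "d_sev": (0.003, 0.005),
}


@dataclass(frozen=True)
class Scenario:
    """A named set of lever overrides applied on top of base parameters."""

    name: str
    overrides: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for lever in self.overrides:
            if lever not in LEVERS:
                raise ValueError(
                    f"unknown lever {lever!r}; recognised levers: {LEVERS}"
                )

    def is_extrapolation(self) -> bool:
        """True if any override leaves its published scenario range."""
        return any(
            not LEVER_RANGES[k][0] <= v <= LEVER_RANGES[k][1]
            for k, v in self.overrides.items()
        )


@dataclass(frozen=True)
class ScenarioResult:
    """Simulation output of one scenario."""

    scenario: Scenario
    trajectory: Trajectory
    deficit_year_annual: int | None

    @property
    def name(self) -> str:
        return self.scenario.name


def apply_scenario(base: ModelParameters, s: Scenario) -> ModelParameters:
    """Return a copy of ``base`` with the scenario's levers applied.

    The joint lever sets the enterprise and government rates to the same
    value; ``base`` is never modified.
    """
    changes: dict[str, float] = {}
    for lever, value in s.overrides.items():
        if lever == "r_gov_ent":
            changes["r_gov"] = value
            changes["r_ent"] = value
        else:
            changes[lever] = value
    return base.replace(**changes)


def deficit_year(t: Trajectory, mode: str = "annual") -> int | None:
    """First year whose balance is negative, or None if never within horizon.

    ``mode`` selects the annual net flow or the cumulative fund stock.
    """
    if mode not in ("annual", "cumulative"):
        raise ValueError("mode must be 'annual' or 'cumulative'")
    attr = "balance_annual" if mode == "annual" else "balance_cumulative"
    for rec in t:
        if getattr(rec, attr) < 0:
            return rec.year
    return None


def run_battery(
    base: ModelParameters, scenarios: list[Scenario]
) -> list[ScenarioResult]:
    """Simulate every scenario against ``base``; order preserved."""
    if not scenarios:
        raise ValueError("scenario battery must be non-empty")
    results = []
    for s in scenarios:
        traj = simulate(apply_scenario(base, s))
        results.append(
            ScenarioResult(
                scenario=s,
                trajectory=traj,
                deficit_year_annual=deficit_year(traj, "annual"),
            )
        )
    return results


def _grid(name: str, lever: str, values: list[float]) -> list[Scenario]:
    return [
        Scenario(name=f"{name}-{i}", overrides={lever: v})
        for i, v in enumerate(values, start=1)
    ]


_BATTERIES = {
    "test1": ("r_ind", [0.0006, 0.0008, 0.001]),
    "test2": ("reimb", [0.5, 0.6, 0.7, 0.8, 0.9]),
    "test3": ("r_gov_ent", [0.0004, 0.0005, 0.0006, 0.0007]),
    "test4": ("d_sev", [0.003, 0.004, 0.005]),
}

BATTERY_NAMES = tuple(_BATTERIES)


def battery(name: str) -> list[Scenario]:
    """The built-in scenario battery ``name`` (test1 … test4)."""
    try:
        lever, values = _BATTERIES[name]
    except KeyError:
        raise ValueError(
            f"unknown battery {name!r}; available: {BATTERY_NAMES}"
        ) from None
    return _grid(name.capitalize(), lever, values)


def compare(
    a: ScenarioResult, b: ScenarioResult, year: int, field_name: str
) -> float:
    """``field(b, year) − field(a, year)`` in yuan/year.

    ``field_name`` is one of ``rev_total``, ``expenditure``,
    ``balance_annual``.
    """
    if field_name not in ("rev_total", "expenditure", "balance_annual"):
        raise ValueError(f"unsupported comparison field {field_name!r}")
    return getattr(b.trajectory.record(year), field_name) - getattr(
        a.trajectory.record(year), field_name
    )


@dataclass(frozen=True)
class BumpResult:
    """Effect of a relative lever bump on the annual balance.

    ``pct_change[year]`` is ``100*(balance_bumped − balance_base)/|balance_base|``
    so the sign of the effect, not of the baseline, sets the sign.  Years
    where the baseline balance is exactly zero get NaN and are listed in
    ``undefined_years``.  ``delta_final`` is the absolute balance change in
    the final simulated year, yuan/year.
    """

    lever: str
    bump: float
    pct_change: dict[int, float]
    undefined_years: tuple[int, ...]
    delta_final: float


def bump_analysis(
    base: ModelParameters, lever: str, bump: float = 0.10
) -> BumpResult:
    """Raise ``lever`` by the relative fraction ``bump`` and trace the balance.

    Reproduces the intervention-effect comparison: each lever is increased by
    10% with everything else unchanged and the per-year percent change of the
    annual balance recorded.
    """
    if lever not in LEVERS:
        raise ValueError(f"unknown lever {lever!r}; recognised levers: {LEVERS}")
    if bump <= -1:
        raise ValueError("bump must be > -1 (lever values stay positive)")
    current = base.r_gov if lever == "r_gov_ent" else getattr(base, lever)
    bumped_params = apply_scenario(
        base, Scenario("bump", {lever: current * (1.0 + bump)})
    )
    t_base = simulate(base)
    t_bump = simulate(bumped_params)
    pct: dict[int, float] = {}
    undefined: list[int] = []
    for rb, rx in zip(t_base, t_bump):
        if rb.balance_annual == 0.0:
            pct[rb.year] = math.nan
            undefined.append(rb.year)
        else:
            pct[rb.year] = (
                100.0
                * (rx.balance_annual - rb.balance_annual)
                / abs(rb.balance_annual)
            )
    last = t_base.records[-1].year
    delta_final = (
        t_bump.record(last).balance_annual - t_base.record(last).balance_annual
    )
    return BumpResult(
        lever=lever,
        bump=bump,
        pct_change=pct,
        undefined_years=tuple(undefined),
        delta_final=delta_final,
    )


def rank_levers(
    base: ModelParameters, bump: float = 0.10
) -> list[tuple[str, float]]:
    """Levers ranked by final-year absolute balance impact of a 10% bump.

    Returns ``(lever, |delta_final| in yuan)`` pairs, largest effect first;
    exact ties keep the documented stable order of :data:`LEVERS`.
    """
    effects = {lv: abs(bump_analysis(base, lv, bump).delta_final) for lv in LEVERS}
    return sorted(effects.items(), key=lambda kv: (-kv[1], LEVERS.index(kv[0])))
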