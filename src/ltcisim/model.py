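"""Deterministic annual stock-flow model of the LTCI fund.

Revenue side
    Individuals in both insured pools pay ``r_ind`` of per-capita disposable
    income; enterprises pay ``r_ent`` of per-capita GDP for the employee
    pool; the government subsidises ``r_gov`` of per-capita GDP for the
    resident pool.

Expenditure side
    The severely disabled share ``d_sev`` of all insured draws the care-mix-
    weighted cost, reimbursed at ``reimb`` and escalated geometrically at
    ``esc`` per year.

:func:`simulate` advances the system year by year with end-of-year
compounding (a discrete stock-flow recurrence); :func:`project_state` gives
the equivalent closed-form drivers for any single year, which the test suite
uses as an independent route to the same numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .params import ModelParameters, YearState

__all__ = [
    "FlowRecord",
    "Trajectory",
    "compound_growth",
    "project_state",
    "revenue_flows",
    "expenditure_flow",
    "simulate",
]


def compound_growth(x0: float, rate: float, n: int) -> float:
    """Compound ``x0`` at ``rate`` per step over ``n`` annual steps.

    Returns ``x0 * (1 + rate)**n``.  ``n`` must be a non-negative integer.
    """
    if n < 0:
        raise ValueError(f"number of compounding steps must be >= 0, got {n}")
    return x0 * (1.0 + rate) ** n


def project_state(params: ModelParameters, year: int) -> YearState:
    """Closed-form exogenous drivers at ``year``.

    Each driver is compounded independently from its base value over
    ``year - year_start`` steps.  Years outside the horizon are rejected.
    """
    if not params.year_start <= year <= params.year_end:
        raise ValueError(
            f"year {year} outside simulation horizon "
            f"[{params.year_start}, {params.year_end}]"
        )
    n = year - params.year_start
    return YearState(
        year=year,
        n_emp=compound_growth(params.n_emp0, params.g_emp, n),
        n_res=compound_growth(params.n_res0, params.g_res, n),
        di=compound_growth(params.di0, params.g_di, n),
        gdp=compound_growth(params.gdp0, params.g_gdp, n),
    )


def revenue_flows(
    state: YearState, params: ModelParameters
) -> tuple[float, float, float, float]:
    """Annual revenue components at ``state``, in yuan/year.

    Returns ``(rev_individual, rev_enterprise, rev_government, rev_total)``.
    The payer split — enterprise on the employee pool, government on the
    resident pool, individuals on both pools — is the structure that jointly
    reproduces the published cross-scenario revenue deltas for the individual
    and the joint enterprise/government levers.
    """
    rev_ind = state.n_insured * params.r_ind * state.di
    rev_ent = state.n_emp * params.r_ent * state.gdp
    rev_gov = state.n_res * params.r_gov * state.gdp
    return rev_ind, rev_ent, rev_gov, rev_ind + rev_ent + rev_gov


def expenditure_flow(state: YearState, params: ModelParameters) -> float:
    """Annual fund expenditure at ``state``, in yuan/year.

    ``n_insured * d_sev * net_cost_per_disabled * (1+esc)**t`` with
    ``t = year - year_start``: beneficiaries are the severely disabled
    insured; the net per-beneficiary cost escalates geometrically.
    """
    t = state.year - params.year_start
    return (
        state.n_insured
        * params.d_sev
        * params.net_cost_per_disabled
        * (1.0 + params.esc) ** t
    )


@dataclass(frozen=True)
class FlowRecord:
    """Fund flows of a single simulated year, in yuan/year."""

    year: int
    rev_individual: float
    rev_enterprise: float
    rev_government: float
    rev_total: float
    expenditure: float
    balance_annual: float
    balance_cumulative: float


@dataclass(frozen=True)
class Trajectory:
    """Ordered per-year fund flows over the full simulation horizon."""

    records: tuple[FlowRecord, ...] = field(repr=False)

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("trajectory must cover at least one year")
        years = [r.year for r in self.records]
        if years != list(range(years[0], years[0] + len(years))):
            raise ValueError("trajectory years must be strictly consecutive")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def years(self) -> list[int]:
        return [r.year for r in self.records]

    def record(self, year: int) -> FlowRecord:
        """The :class:`FlowRecord` for ``year`` (KeyError if outside)."""
        first = self.records[0].year
        if not first <= year <= self.records[-1].year:
            raise KeyError(f"year {year} not covered by trajectory")
        return self.records[year - first]

    def field_series(self, name: str) -> dict[int, float]:
        """Mapping year -> value of ``name`` across the horizon."""
        return {r.year: getattr(r, name) for r in self.records}

    def to_frame(self) -> pd.DataFrame:
        """Tidy one-row-per-year DataFrame of all flow fields (yuan)."""
        return pd.DataFrame([vars(r) for r in self.records])


def simulate(params: ModelParameters) -> Trajectory:
    """Run the annual stock-flow recurrence over the full horizon.

    The drivers are advanced multiplicatively at the end of each year;
    every year's revenue components, expenditure, annual balance
    (revenue − expenditure) and cumulative balance (running sum) are
    recorded.  Deterministic: no randomness anywhere.
    """
    state = YearState(
        year=params.year_start,
        n_emp=params.n_emp0,
        n_res=params.n_res0,
        di=params.di0,
        gdp=params.gdp0,
    )
    records: list[FlowRecord] = []
    cumulative = 0.0
    for year in params.years:
        rev_ind, rev_ent, rev_gov, rev_total = revenue_flows(state, params)
        exp = expenditure_flow(state, params)
        balance = rev_total - exp
        cumulative += balance
        records.append(
            FlowRecord(
                year=year,
                rev_individual=rev_ind,
                rev_enterprise=rev_ent,
                rev_government=rev_gov,
                rev_total=rev_total,
                expenditure=exp,
                balance_annual=balance,
                balance_cumulative=cumulative,
            )
        )
        # end-of-year compounding step
        state = YearState(
            year=year + 1,
            n_emp=state.n_emp * (1.0 + params.g_emp),
            n_res=state.n_res * (1.0 + params.g_res),
            di=state.di * (1.0 + params.g_di),
            gdp=state.gdp * (1.0 + params.g_gdp),
        )
    return Trajectory(records=tuple(records))
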