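"""Parameter and state containers for the LTCI fund model.

The model describes a municipal long-term-care-insurance (LTCI) fund financed
by three payers — insured individuals, enterprises, and the government — and
drained by care reimbursements for the severely disabled share of the insured
population.  :class:`ModelParameters` is the single source of truth for a run:
it holds the base-year (2019) pools and economic bases, the annual growth
rates that drive them, the payment and benefit rates, and the simulation
horizon.

Default values are the published base-year figures for Xiamen (yearbook and
field-survey data); the expenditure escalation rate ``esc`` is the one
quantity not observable directly and defaults to the value obtained by
closed-form calibration against a published scenario anchor (see
:mod:`ltcisim.calibration`).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

__all__ = [
    "ModelParameters",
    "YearState",
    "DEFAULT_ESC",
    "WAN",
    "to_millions",
    "to_billions",
]

#: Chinese counting unit 万 (10,000), used for population counts in yearbooks.
WAN = 10_000

#: Expenditure escalation rate obtained by calibrating the model so that the
#: scenario with individual payment rate 0.1% reproduces its published 2030
#: balance of ¥381.7 million.  Re-derivable at run time via
#: :func:`ltcisim.calibration.calibrate_escalation`.
DEFAULT_ESC = 0.15041247366147315

_POSITIVE = ("n_emp0", "n_res0", "di0", "gdp0", "c_inst", "c_home")
_UNIT_FRACTIONS = ("r_ind", "r_ent", "r_gov", "d_sev", "p_inst", "p_home", "reimb")
_RATES = ("g_emp", "g_res", "g_di", "g_gdp", "esc")


@dataclass(frozen=True)
class ModelParameters:
    """Complete parameter set for one simulation run.

    Monetary quantities are in yuan, populations in persons, rates are
    dimensionless fractions per year.  Instances are immutable; derive
    variants with :meth:`replace`.

    Attributes
    ----------
    n_emp0, n_res0
        Insured urban employees / urban-and-rural residents at the base year.
    di0, gdp0
        Base-year per-capita disposable income of urban residents and
        per-capita GDP — the contribution bases for individual premiums and
        for enterprise/government contributions respectively.
    g_emp, g_res, g_di, g_gdp
        Annual compound growth rates of the two insured pools and the two
        economic bases.
    r_ind
        Individual payment rate, applied to ``di`` for every insured person
        in both pools.
    r_ent, r_gov
        Enterprise contribution rate (employee pool) and government subsidy
        rate (resident pool), both applied to per-capita GDP.
    d_sev
        Severe disability rate over all insured persons; beneficiaries are
        the severely disabled insured.
    p_inst, p_home, c_inst, c_home
        Care-mix shares (institutional vs home care, summing to 1) and the
        corresponding per-capita annual care costs.
    reimb
        Reimbursement ratio: share of eligible care cost paid by the fund.
    esc
        Annual escalation of the net per-beneficiary cost beyond insured-
        population growth (cost and prevalence drift combined).
    year_start, year_end
        Inclusive simulation horizon in calendar years.
    """

    n_emp0: float = 2_738_800.0
    n_res0: float = 1_480_000.0
    di0: float = 55_870.0
    gdp0: float = 142_739.0
    g_emp: float = 0.06
    g_res: float = 0.059
    g_di: float = 0.08
    g_gdp: float = 0.05
    r_ind: float = 0.0006
    r_ent: float = 0.0004
    r_gov: float = 0.0004
    d_sev: float = 0.003
    p_inst: float = 0.03
    p_home: float = 0.97
    c_inst: float = 30_000.0
    c_home: float = 18_000.0
    reimb: float = 0.70
    esc: float = DEFAULT_ESC
    year_start: int = 2019
    year_end: int = 2030

    def __post_init__(self) -> None:
        for name in _POSITIVE:
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in _UNIT_FRACTIONS:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} must lie in [0, 1]")
        for name in _RATES:
            v = getattr(self, name)
            if not -1.0 < v < 1.0:
                raise ValueError(f"{name}={v} must lie in (-1, 1)")
        if not math.isclose(self.p_inst + self.p_home, 1.0, abs_tol=1e-12):
            raise ValueError("care-mix shares p_inst + p_home must sum to 1")
        if self.year_end < self.year_start:
            raise ValueError("year_end must not precede year_start")

    def replace(self, **changes: float) -> "ModelParameters":
        """Return a copy with ``changes`` applied (re-validated)."""
        return dataclasses.replace(self, **changes)

    @property
    def n_years(self) -> int:
        return self.year_end - self.year_start + 1

    @property
    def years(self) -> range:
        return range(self.year_start, self.year_end + 1)

    @property
    def net_cost_per_disabled(self) -> float:
        """Base-year fund cost per severely disabled person, yuan/year.

        Care-mix-weighted gross cost times the reimbursement ratio:
        ``(p_inst*c_inst + p_home*c_home) * reimb``.
        """
        return (self.p_inst * self.c_inst + self.p_home * self.c_home) * self.reimb


@dataclass(frozen=True)
class YearState:
    """Exogenous drivers at a single calendar year.

    Values equal the base-year values compounded over ``year - year_start``
    annual steps.
    """

    year: int
    n_emp: float
    n_res: float
    di: float
    gdp: float

    @property
    def n_insured(self) -> float:
        return self.n_emp + self.n_res


def to_millions(yuan: float) -> float:
    """Convert yuan to millions of yuan (reporting unit)."""
    return yuan / 1e6


def to_billions(yuan: float) -> float:
    """Convert yuan to billions of yuan (reporting unit)."""
    return yuan / 1e9
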