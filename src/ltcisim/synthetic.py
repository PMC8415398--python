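"""Synthetic yearbook series and packaged reference fixtures.

Municipal yearbook series (insured-population counts, per-capita income and
GDP) are positive and grow roughly geometrically with small year-to-year
deviations.  :func:`generate_yearbook_series` emulates that structure —
compound growth with multiplicative lognormal noise — so validation and
calibration-recovery workflows are testable without any external data.

:func:`table_fixtures` loads the packaged reference values (base-year
parameters and the 2012–2018 historical-validation series) from checksummed
CSVs shipped with the package.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .calibration import HistoricalPair
from .params import WAN, ModelParameters

__all__ = ["SyntheticSeries", "generate_yearbook_series", "table_fixtures"]

_CHECKSUMS = {
    "table1_parameters.csv": (
        "12de7a63931da4c3a04bbba6120d75b5ac4750e851c2f97b6a514fe0c1e86009"
    ),
    "table2_historical.csv": (
        "6147f263308f0d4590548cae41ef8fd770096f58d87471a084649525837d0774"
    ),
}


@dataclass(frozen=True)
class SyntheticSeries:
    """A generated annual series together with its generating parameters."""

    years: tuple[int, ...]
    values: tuple[float, ...]
    x0: float
    g: float
    sigma: float
    seed: int

    def __post_init__(self) -> None:
        if len(self.years) != len(self.values):
            raise ValueError("years and values must have equal length")
        if any(v <= 0 for v in self.values):
            raise ValueError("yearbook-style series values must be positive")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"year": self.years, "value": self.values})


def generate_yearbook_series(
    x0: float,
    g: float,
    sigma: float,
    years: range | list[int],
    seed: int,
) -> SyntheticSeries:
    """Compound-growth series with multiplicative lognormal noise.

    ``value(t) = x0 * (1+g)**t * exp(eps_t)`` with ``eps_t ~ N(0, sigma^2)``
    drawn from a generator seeded with ``seed``; ``t`` counts years from the
    first element of ``years``.  ``sigma = 0`` gives the exact deterministic
    compound-growth series.  Noise is multiplicative because yearbook-scale
    quantities are positive and grow geometrically; the default scale used
    in tests (sigma ≈ 0.02) matches the 1–2% deviations seen in historical
    validation tables.
    """
    if x0 <= 0:
        raise ValueError("x0 must be strictly positive")
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    years = tuple(years)
    rng = np.random.default_rng(seed)
    t = np.arange(len(years), dtype=float)
    eps = rng.normal(0.0, sigma, size=len(years)) if sigma > 0 else np.zeros(len(years))
    values = x0 * (1.0 + g) ** t * np.exp(eps)
    return SyntheticSeries(
        years=years,
        values=tuple(float(v) for v in values),
        x0=x0,
        g=g,
        sigma=sigma,
        seed=seed,
    )


def _load_csv(name: str) -> pd.DataFrame:
    ref = resources.files("ltcisim.data").joinpath(name)
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _CHECKSUMS[name]:
        raise RuntimeError(
            f"packaged fixture {name} is corrupt: sha256 {digest} does not "
            f"match the recorded checksum"
        )
    with ref.open("r") as fh:
        return pd.read_csv(fh)


def table_fixtures() -> tuple[ModelParameters, list[HistoricalPair]]:
    """Packaged reference values: base parameters and validation pairs.

    Returns the :class:`ModelParameters` built from the published base-year
    table (population counts converted from 万 to persons) and the fourteen
    actual/simulated historical-validation pairs with their published error
    rates.  Both come from checksummed CSVs; corruption raises.
    """
    t1 = _load_csv("table1_parameters.csv").set_index("parameter")["value"]
    params = ModelParameters(
        n_emp0=t1["insured_urban_employees"] * WAN,
        n_res0=t1["insured_urban_rural_residents"] * WAN,
        di0=t1["per_capita_disposable_income"],
        gdp0=t1["per_capita_gdp"],
        g_emp=t1["growth_insured_employees"],
        g_res=t1["growth_insured_residents"],
        g_di=t1["growth_disposable_income"],
        g_gdp=t1["growth_per_capita_gdp"],
        r_ind=t1["individual_payment_rate"],
        r_ent=t1["enterprise_contribution_rate"],
        r_gov=t1["government_subsidy_rate"],
        d_sev=t1["severe_disability_rate"],
        p_inst=t1["share_institutional_care"],
        p_home=t1["share_home_care"],
        c_inst=t1["cost_institutional_care"],
        c_home=t1["cost_home_care"],
        reimb=t1["reimbursement_ratio"],
    )
    t2 = _load_csv("table2_historical.csv")
    pairs = [
        HistoricalPair(
            year=int(r.year),
            actual=float(r.actual),
            simulated=float(r.simulated),
            series=str(r.series),
            reported_error=float(r.reported_error),
        )
        for r in t2.itertuples()
    ]
    return params, pairs
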