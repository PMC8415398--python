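"""Monte-Carlo sensitivity analysis of the fund balance.

The four policy levers (individual payment rate, reimbursement ratio, joint
enterprise/government rate, severe disability rate) are drawn independently
from uniform distributions over their published scenario ranges; each draw
is simulated and the annual fund balance summarised per year into an
envelope (min, 5th/95th percentile, median, max).  The default draw count is
200, matching the published verification count; no correlation structure
between levers is imposed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import simulate
from .params import ModelParameters
from .scenarios import LEVER_RANGES, LEVERS, Scenario, apply_scenario

__all__ = [
    "SensitivityRange",
    "Envelope",
    "DEFAULT_RANGES",
    "DEFAULT_SEED",
    "sample_parameters",
    "run_ensemble",
    "plot_envelope",
]

#: Fixed default seed, recorded in every Envelope for reproducibility.
DEFAULT_SEED = 2019


@dataclass(frozen=True)
class SensitivityRange:
    """Uniform sampling interval for one lever."""

    lever: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if self.lever not in LEVERS:
            raise ValueError(f"unknown lever {self.lever!r}")
        if self.low > self.high:
            raise ValueError("low must not exceed high")


#: The published scenario ranges, one per lever.
DEFAULT_RANGES = tuple(
    SensitivityRange(lever, *LEVER_RANGES[lever]) for lever in LEVERS
)


@dataclass(frozen=True)
class Envelope:
    """Per-year distribution summary of the annual balance across draws."""

    years: tuple[int, ...]
    minimum: tuple[float, ...]
    p5: tuple[float, ...]
    median: tuple[float, ...]
    p95: tuple[float, ...]
    maximum: tuple[float, ...]
    n_draws: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        """Tidy year × statistic table (yuan)."""
        return pd.DataFrame(
            {
                "year": self.years,
                "min": self.minimum,
                "p5": self.p5,
                "median": self.median,
                "p95": self.p95,
                "max": self.maximum,
            }
        )


def sample_parameters(
    ranges: tuple[SensitivityRange, ...] = DEFAULT_RANGES,
    n: int = 200,
    seed: int = DEFAULT_SEED,
    base: ModelParameters | None = None,
) -> list[ModelParameters]:
    """Draw ``n`` parameter sets, each lever independently uniform.

    Reproducible for a fixed seed; ``n = 0`` yields an empty list.
    """
    if n < 0:
        raise ValueError("draw count must be non-negative")
    base = base or ModelParameters()
    rng = np.random.default_rng(seed)
    draws = {r.lever: rng.uniform(r.low, r.high, size=n) for r in ranges}
    out = []
    for i in range(n):
        overrides = {lever: float(vals[i]) for lever, vals in draws.items()}
        out.append(apply_scenario(base, Scenario(f"draw-{i}", overrides)))
    return out


def run_ensemble(
    samples: list[ModelParameters],
    seed: int = DEFAULT_SEED,
) -> Envelope:
    """Simulate every sampled parameter set and summarise the balance.

    The seed is the one used to draw ``samples``; it is carried through so
    an Envelope is self-describing.
    """
    if not samples:
        raise ValueError("ensemble requires at least one sampled parameter set")
    trajectories = [simulate(p) for p in samples]
    years = tuple(trajectories[0].years)
    balances = np.array(
        [[r.balance_annual for r in t] for t in trajectories]
    )  # draws × years
    return Envelope(
        years=years,
        minimum=tuple(balances.min(axis=0)),
        p5=tuple(np.percentile(balances, 5, axis=0)),
        median=tuple(np.median(balances, axis=0)),
        p95=tuple(np.percentile(balances, 95, axis=0)),
        maximum=tuple(balances.max(axis=0)),
        n_draws=len(samples),
        seed=seed,
    )


def plot_envelope(env: Envelope, ax=None):
    """Fan chart of the balance envelope (millions of yuan).

    Matplotlib is imported lazily; returns the axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    years = env.years
    m = 1e6
    ax.fill_between(
        years,
        [v / m for v in env.minimum],
        [v / m for v in env.maximum],
        alpha=0.2,
        label="min–max",
    )
    ax.fill_between(
        years,
        [v / m for v in env.p5],
        [v / m for v in env.p95],
        alpha=0.4,
        label="5–95%",
    )
    ax.plot(years, [v / m for v in env.median], label="median")
    ax.axhline(0.0, color="k", lw=0.8)
    ax.set_xlabel("year")
    ax.set_ylabel("annual balance (million yuan)")
    ax.legend()
    return ax
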