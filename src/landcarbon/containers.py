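"""Shared in-memory containers for ensemble carbon-cycle output.

Everything downstream (diagnostics, driver decomposition, uncertainty)
operates on annual series of stocks (PgC) and fluxes (PgC yr-1), grouped
per model, per scenario and per region. Stocks are end-of-year values and
fluxes are within-year totals, so the backward difference
``C(t) - C(t-1)`` of a stock equals the year-``t`` net flux exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np

#: canonical variable names (TRENDY-style, lower case)
STOCK_VARS = ("cveg", "csoil", "clitter", "ccwd")
FLUX_VARS = ("npp", "rh", "nbp")
ALL_VARS = FLUX_VARS + STOCK_VARS

UNITS = {
    "cveg": "PgC",
    "csoil": "PgC",
    "clitter": "PgC",
    "ccwd": "PgC",
    "npp": "PgC yr-1",
    "rh": "PgC yr-1",
    "nbp": "PgC yr-1",
}

SCENARIOS = ("S0", "S1", "S2", "S3")


@dataclass(frozen=True)
class AnnualSeries:
    """A quantity sampled once per calendar year on a gap-free axis."""

    years: np.ndarray
    values: np.ndarray
    units: str = "1"

    def __post_init__(self) -> None:
        years = np.asarray(self.years, dtype=int)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "years", years)
        object.__setattr__(self, "values", values)
        if years.ndim != 1 or values.shape != years.shape:
            raise ValueError("years and values must be aligned 1-D arrays")
        if years.size < 2:
            raise ValueError("an annual series needs at least two years")
        if not np.all(np.diff(years) == 1):
            raise ValueError("years must be consecutive calendar years")

    def __len__(self) -> int:
        return self.years.size

    def at(self, year: int) -> float:
        idx = np.flatnonzero(self.years == year)
        if idx.size == 0:
            raise KeyError(f"year {year} not in series")
        return float(self.values[idx[0]])

    def window(self, start: int, end: int) -> "AnnualSeries":
        """Restrict to [start, end] inclusive."""
        if start < self.years[0] or end > self.years[-1]:
            raise ValueError(
                f"window {start}-{end} outside series span "
                f"{self.years[0]}-{self.years[-1]}"
            )
        m = (self.years >= start) & (self.years <= end)
        return AnnualSeries(self.years[m], self.values[m], self.units)

    # -- aligned arithmetic (used by the factorial driver combinations) --
    def _check_aligned(self, other: "AnnualSeries") -> None:
        if not np.array_equal(self.years, other.years):
            raise ValueError("series year axes are misaligned")
        if self.units != other.units:
            raise ValueError(f"unit mismatch: {self.units} vs {other.units}")

    def __add__(self, other: "AnnualSeries") -> "AnnualSeries":
        self._check_aligned(other)
        return AnnualSeries(self.years, self.values + other.values, self.units)

    def __sub__(self, other: "AnnualSeries") -> "AnnualSeries":
        self._check_aligned(other)
        return AnnualSeries(self.years, self.values - other.values, self.units)

    def scaled(self, factor: float) -> "AnnualSeries":
        return AnnualSeries(self.years, self.values * factor, self.units)


@dataclass(frozen=True)
class PoolFlags:
    """Which soil-system pools a model reports, and how.

    ``litter_in_soil`` marks models whose reported soil stock already
    contains the litter pool, so the separate litter output must not be
    added again when aggregating.
    """

    has_litter: bool = True
    has_cwd: bool = False
    litter_in_soil: bool = False

    def __post_init__(self) -> None:
        if self.litter_in_soil and not self.has_litter:
            raise ValueError("litter_in_soil requires has_litter")
        if self.has_cwd and not self.has_litter:
            raise ValueError("toy configurations route CWD through litter")


@dataclass
class ModelRun:
    """One model under one scenario: region -> variable -> AnnualSeries."""

    model_id: str
    scenario: str
    data: dict[str, dict[str, AnnualSeries]]
    flags: PoolFlags = field(default_factory=PoolFlags)

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        ref = None
        for region, variables in self.data.items():
            for name, series in variables.items():
                if ref is None:
                    ref = series.years
                elif not np.array_equal(series.years, ref):
                    raise ValueError(
                        f"series {region}/{name} is misaligned with the run's"
                        " year axis"
                    )
        # flags must not claim pools that are absent
        for region, variables in self.data.items():
            if self.flags.has_litter and not self.flags.litter_in_soil:
                if "clitter" not in variables:
                    raise ValueError(f"has_litter set but clitter missing ({region})")
            if self.flags.has_cwd and "ccwd" not in variables:
                raise ValueError(f"has_cwd set but ccwd missing ({region})")

    @property
    def years(self) -> np.ndarray:
        region = next(iter(self.data))
        var = next(iter(self.data[region]))
        return self.data[region][var].years

    @property
    def regions(self) -> tuple[str, ...]:
        return tuple(self.data)

    def series(self, variable: str, region: str = "global") -> AnnualSeries:
        return self.data[region][variable]


@dataclass
class ScenarioQuartet:
    """The four factorial runs (S0..S3) of one model, aligned on years."""

    model_id: str
    runs: dict[str, ModelRun]

    def __post_init__(self) -> None:
        missing = [s for s in SCENARIOS if s not in self.runs]
        if missing:
            raise ValueError(f"quartet missing scenarios: {missing}")
        ref = self.runs["S0"]
        for label in SCENARIOS[1:]:
            run = self.runs[label]
            if not np.array_equal(run.years, ref.years):
                raise ValueError(f"{label} year axis differs from S0")
            if run.flags != ref.flags:
                raise ValueError(f"{label} pool flags differ from S0")
            if run.regions != ref.regions:
                raise ValueError(f"{label} regions differ from S0")

    def __getitem__(self, label: str) -> ModelRun:
        return self.runs[label]

    @property
    def years(self) -> np.ndarray:
        return self.runs["S0"].years

    @property
    def regions(self) -> tuple[str, ...]:
        return self.runs["S0"].regions

    @property
    def flags(self) -> PoolFlags:
        return self.runs["S0"].flags
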