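"""A minimal land carbon model run under the S0-S3 factorial design.

The model is a zero-dimensional, annual-step surrogate for a dynamic
global vegetation model (DGVM): one vegetation pool, an optional litter
pool and one soil pool, driven by atmospheric CO2 (fertilization),
temperature anomaly (productivity and decomposition sensitivity) and an
agricultural land fraction (productivity/turnover blending plus an
episodic clearing flux). Because each model in the synthetic ensemble has
known parameters, every diagnostic computed downstream can be checked
against ground truth.

Pool dynamics follow dC/dt = input - C/tau. The annual update integrates
the decay implicitly (backward Euler): the outflux of year ``t`` is
evaluated on the end-of-year stock that is reported for year ``t``. This
makes the reported stocks, fluxes and the backward annual difference
mutually consistent, so the bulk turnover diagnostic tau = C/outflux
recovers the prescribed turnover time exactly on single-pool
configurations, and the steady state is preserved exactly under constant
forcing. The land-clearing flux E_lu is evaluated on the start-of-year
stock (clearing happens to the standing biomass).

Scenarios:

==  ===========  ==============  ===========
    CO2          climate         land use
==  ===========  ==============  ===========
S0  fixed        recycled        fixed
S1  transient    recycled        fixed
S2  transient    transient       fixed
S3  transient    transient       transient
==  ===========  ==============  ===========

"recycled" climate repeats the first 20 years of the temperature-anomaly
series cyclically over the whole axis, mimicking a recycled early-period
climatology in a transient-forcing intercomparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .containers import (
    SCENARIOS,
    UNITS,
    AnnualSeries,
    ModelRun,
    PoolFlags,
    ScenarioQuartet,
)

RECYCLE_PERIOD = 20  # years of early climate repeated in S0/S1
CWD_SHARE = 0.30  # reporting share of the litter pool labelled as CWD


# ---------------------------------------------------------------------------
# forcing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ForcingSet:
    """Shared forcing trajectories for one ensemble."""

    years: np.ndarray
    co2: np.ndarray      # ppm
    t_anom: np.ndarray   # K vs pre-industrial
    f_ag: np.ndarray     # agricultural land fraction, [0, 1]
    seed: int

    def __post_init__(self) -> None:
        years = np.asarray(self.years, dtype=int)
        object.__setattr__(self, "years", years)
        for name in ("co2", "t_anom", "f_ag"):
            arr = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, arr)
            if arr.shape != years.shape:
                raise ValueError(f"{name} not aligned with years")
        if not np.all(np.diff(years) == 1):
            raise ValueError("forcing years must be consecutive")
        if np.any(self.co2 <= 0):
            raise ValueError("co2 must be positive")
        if np.any((self.f_ag < 0) | (self.f_ag > 1)):
            raise ValueError("f_ag must lie in [0, 1]")

    def recycled_t_anom(self, period: int = RECYCLE_PERIOD) -> np.ndarray:
        """First ``period`` years of t_anom tiled over the full axis."""
        block = self.t_anom[:period]
        reps = int(np.ceil(self.years.size / period))
        return np.tile(block, reps)[: self.years.size]


def generate_forcing(
    years: Sequence[int],
    co2_spec: Mapping | None = None,
    climate_spec: Mapping | None = None,
    lulcc_spec: Mapping | None = None,
    seed: int = 0,
) -> ForcingSet:
    """Build deterministic (seeded) CO2 / temperature / land-use trajectories.

    co2_spec keys: ``co2_ref`` (ppm at the first year, default 280),
    ``co2_end`` (ppm at the last year, default 415). The trajectory is a
    monotone quadratic ramp between the two.

    climate_spec keys: ``onset_year`` (trend starts there; default first
    year + 20 so the recycled block is trend-free), ``slope`` (K/yr,
    default 0.01), ``sigma`` (K, Gaussian interannual noise, default 0.1).

    lulcc_spec keys: ``anchors`` mapping year -> fraction (piecewise
    linear between them, default a slow expansion 0.15 -> 0.30), and an
    optional ``spike`` = (year, extra_fraction) single-year excursion used
    to exercise the land-use spike correction downstream.
    """
    years = np.asarray(list(years), dtype=int)
    if years.size < 40 or not np.all(np.diff(years) == 1):
        raise ValueError("years must span at least 40 consecutive years")
    co2_spec = dict(co2_spec or {})
    climate_spec = dict(climate_spec or {})
    lulcc_spec = dict(lulcc_spec or {})

    co2_ref = float(co2_spec.get("co2_ref", 280.0))
    co2_end = float(co2_spec.get("co2_end", 415.0))
    x = (years - years[0]) / (years[-1] - years[0])
    co2 = co2_ref + (co2_end - co2_ref) * x**2

    onset = int(climate_spec.get("onset_year", years[0] + RECYCLE_PERIOD))
    slope = float(climate_spec.get("slope", 0.01))
    sigma = float(climate_spec.get("sigma", 0.1))
    if sigma < 0:
        raise ValueError("climate noise sigma must be non-negative")
    rng = np.random.default_rng(seed)
    trend = slope * np.clip(years - onset, 0, None)
    t_anom = trend + rng.normal(0.0, sigma, size=years.size) if sigma > 0 else trend

    anchors = dict(lulcc_spec.get("anchors", {years[0]: 0.15, 2020: 0.30}))
    ay = np.array(sorted(anchors), dtype=float)
    av = np.array([anchors[int(y)] for y in sorted(anchors)], dtype=float)
    f_ag = np.interp(years, ay, av)
    spike = lulcc_spec.get("spike")
    if spike is not None:
        spike_year, spike_amount = spike
        idx = np.flatnonzero(years == int(spike_year))
        if idx.size == 0:
            raise ValueError(f"spike year {spike_year} outside forcing span")
        f_ag = f_ag.copy()
        f_ag[idx[0]] += float(spike_amount)

    return ForcingSet(years=years, co2=co2, t_anom=t_anom, f_ag=f_ag, seed=seed)


# ---------------------------------------------------------------------------
# model parameters and scenarios
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ToyModelParams:
    """Structural parameters of one synthetic model.

    Heterogeneity across these parameters stands in for the structural
    diversity of a real multi-model ensemble (baseline productivity,
    allocation, turnover, temperature sensitivity, land-use response).
    """

    npp0: float = 55.0          # PgC/yr baseline natural NPP
    rho_ag: float = 0.7         # relative productivity of agricultural land
    beta: float = 0.5           # CO2 fertilization: NPP *= 1 + beta ln(C/C_ref)
    gamma: float = 0.0          # 1/K climate sensitivity of NPP
    tau_v_nat: float = 15.0     # yr vegetation turnover, natural land
    tau_v_ag: float = 2.0       # yr vegetation turnover, agricultural land
    tau_lit: float = 4.0        # yr litter turnover
    tau_s0: float = 25.0        # yr soil turnover at zero warming
    q10: float = 2.0            # soil decomposition temperature sensitivity
    eps_lit: float = 0.5        # litter outflux fraction transferred to soil
    lambda_lu: float = 1.0      # clearing intensity per unit f_ag increase
    p_atm: float = 0.5          # cleared biomass fraction emitted directly
    co2_ref: float = 280.0      # ppm
    flags: PoolFlags = field(default_factory=PoolFlags)

    def __post_init__(self) -> None:
        for name in ("tau_v_nat", "tau_v_ag", "tau_lit", "tau_s0"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("eps_lit", "p_atm"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not 0.0 < self.rho_ag <= 1.0:
            raise ValueError("rho_ag must lie in (0, 1]")
        if self.q10 < 1.0:
            raise ValueError("q10 must be >= 1")

    def tau_v_eff(self, f_ag: float) -> float:
        return (1.0 - f_ag) * self.tau_v_nat + f_ag * self.tau_v_ag

    def tau_s(self, t_anom: float) -> float:
        return self.tau_s0 * self.q10 ** (-t_anom / 10.0)

    def npp(self, co2: float, t_anom: float, f_ag: float) -> float:
        mix = (1.0 - f_ag) + f_ag * self.rho_ag
        fert = 1.0 + self.beta * np.log(co2 / self.co2_ref)
        clim = 1.0 + self.gamma * t_anom
        return self.npp0 * mix * fert * clim


@dataclass(frozen=True)
class ScenarioSpec:
    label: str
    co2_transient: bool
    climate_transient: bool
    lulcc_transient: bool


SCENARIO_SPECS = {
    "S0": ScenarioSpec("S0", False, False, False),
    "S1": ScenarioSpec("S1", True, False, False),
    "S2": ScenarioSpec("S2", True, True, False),
    "S3": ScenarioSpec("S3", True, True, True),
}


@dataclass(frozen=True)
class PoolState:
    cv: float
    clit: float
    cs: float


# ---------------------------------------------------------------------------
# dynamics
# ---------------------------------------------------------------------------

def analytic_steady_state(
    params: ToyModelParams,
    co2: float | None = None,
    t_anom: float = 0.0,
    f_ag: float = 0.0,
) -> PoolState:
    """Closed-form equilibrium under constant forcing and no clearing.

    With constant input the balance of each pool is C* = input * tau.
    Litter receives the whole vegetation outflux; the soil receives the
    transferred share eps_lit of the litter outflux (or, without a litter
    pool, the vegetation outflux directly).
    """
    co2 = params.co2_ref if co2 is None else co2
    npp = params.npp(co2, t_anom, f_ag)
    tau_v = params.tau_v_eff(f_ag)
    tau_s = params.tau_s(t_anom)
    cv = npp * tau_v
    if params.flags.has_litter:
        clit = npp * params.tau_lit
        cs = params.eps_lit * npp * tau_s
    else:
        clit = 0.0
        cs = npp * tau_s
    return PoolState(cv=cv, clit=clit, cs=cs)


def step_toy_model(
    state: PoolState,
    params: ToyModelParams,
    co2: float,
    t_anom: float,
    f_ag: float,
    d_f_ag: float = 0.0,
) -> tuple[PoolState, dict[str, float]]:
    """Advance one year; return the new state and the year's fluxes.

    Clearing removes ``lambda_lu * max(d_f_ag, 0)`` of the standing
    (start-of-year) biomass; a fraction ``p_atm`` of it goes straight to
    the atmosphere and the rest enters the soil system with litterfall.
    Pool decay is integrated implicitly, so mass balance
    dCv + dClit + dCs = NPP - Rh - p_atm*E_lu = NBP holds exactly.
    """
    npp = params.npp(co2, t_anom, f_ag)
    tau_v = params.tau_v_eff(f_ag)
    tau_s = params.tau_s(t_anom)

    e_lu = params.lambda_lu * max(d_f_ag, 0.0) * state.cv
    cv_new = (state.cv + npp - e_lu) * tau_v / (tau_v + 1.0)
    if cv_new < 0:
        raise RuntimeError(
            f"vegetation pool driven negative (cv={cv_new:.3g}); "
            "clearing or forcing is too aggressive for this state"
        )
    veg_out = cv_new / tau_v
    f_vs = veg_out + (1.0 - params.p_atm) * e_lu

    if params.flags.has_litter:
        clit_new = (state.clit + f_vs) * params.tau_lit / (params.tau_lit + 1.0)
        lit_out = clit_new / params.tau_lit
        soil_in = params.eps_lit * lit_out
        rh_lit = (1.0 - params.eps_lit) * lit_out
    else:
        clit_new = 0.0
        soil_in = f_vs
        rh_lit = 0.0

    cs_new = (state.cs + soil_in) * tau_s / (tau_s + 1.0)
    rh_soil = cs_new / tau_s
    if clit_new < 0 or cs_new < 0:
        raise RuntimeError("soil-system pool driven negative")

    rh = rh_lit + rh_soil
    nbp = npp - rh - params.p_atm * e_lu
    fluxes = {"npp": npp, "rh": rh, "nbp": nbp, "f_vs": f_vs, "e_lu": e_lu}
    return PoolState(cv=cv_new, clit=clit_new, cs=cs_new), fluxes


def run_scenario(
    params: ToyModelParams,
    forcing: ForcingSet,
    scenario: str | ScenarioSpec,
    model_id: str = "toy",
    window: tuple[int, int] = (1958, 2020),
    region_weights: Mapping[str, float] | None = None,
) -> ModelRun:
    """Run one model under one scenario and package TRENDY-style output.

    The run starts from the analytic pre-industrial steady state at the
    first forcing year and is stepped through the whole forcing span;
    output is restricted to ``window``. ``region_weights`` optionally
    splits every global series into fixed regional shares (the toy has no
    spatial structure); a "global" entry is always included.
    """
    spec = SCENARIO_SPECS[scenario] if isinstance(scenario, str) else scenario
    years = forcing.years
    w0, w1 = window
    if w0 < years[0] + 1 or w1 > years[-1]:
        raise ValueError(f"window {window} outside forcing span")

    co2 = forcing.co2 if spec.co2_transient else np.full(years.size, forcing.co2[0])
    t_anom = (
        forcing.t_anom if spec.climate_transient else forcing.recycled_t_anom()
    )
    f_ag = forcing.f_ag if spec.lulcc_transient else np.full(years.size, forcing.f_ag[0])

    state = analytic_steady_state(
        params, co2=co2[0], t_anom=0.0, f_ag=f_ag[0]
    )

    n = years.size
    out = {k: np.empty(n) for k in ("npp", "rh", "nbp", "cveg", "csoil", "clitter", "ccwd")}
    for i in range(n):
        dfag = f_ag[i] - f_ag[i - 1] if i > 0 else 0.0
        state, fx = step_toy_model(state, params, co2[i], t_anom[i], f_ag[i], dfag)
        out["npp"][i] = fx["npp"]
        out["rh"][i] = fx["rh"]
        out["nbp"][i] = fx["nbp"]
        out["cveg"][i] = state.cv
        lit_total = state.clit
        flags = params.flags
        if flags.has_cwd:
            out["ccwd"][i] = CWD_SHARE * lit_total
            lit_total = (1.0 - CWD_SHARE) * lit_total
        else:
            out["ccwd"][i] = 0.0
        if flags.litter_in_soil:
            out["csoil"][i] = state.cs + lit_total
            out["clitter"][i] = lit_total  # reported but already inside csoil
        else:
            out["csoil"][i] = state.cs
            out["clitter"][i] = lit_total

    m = (years >= w0) & (years <= w1)
    wyears = years[m]
    flags = params.flags

    def pack(scale: float) -> dict[str, AnnualSeries]:
        variables = {}
        for name in ("npp", "rh", "nbp", "cveg", "csoil"):
            variables[name] = AnnualSeries(wyears, out[name][m] * scale, UNITS[name])
        if flags.has_litter:
            # reported even when it is also folded into csoil (mirrors models
            # whose soil output already contains litter)
            variables["clitter"] = AnnualSeries(wyears, out["clitter"][m] * scale, UNITS["clitter"])
        if flags.has_cwd:
            variables["ccwd"] = AnnualSeries(wyears, out["ccwd"][m] * scale, UNITS["ccwd"])
        return variables

    data = {"global": pack(1.0)}
    if region_weights:
        total = sum(region_weights.values())
        if not np.isclose(total, 1.0):
            raise ValueError("region weights must sum to 1")
        for region, weight in region_weights.items():
            data[region] = pack(float(weight))

    return ModelRun(model_id=model_id, scenario=spec.label, data=data, flags=flags)


def run_quartet(
    params: ToyModelParams,
    forcing: ForcingSet,
    model_id: str = "toy",
    window: tuple[int, int] = (1958, 2020),
    region_weights: Mapping[str, float] | None = None,
) -> ScenarioQuartet:
    """All four factorial scenarios of one model on shared forcing."""
    runs = {
        label: run_scenario(params, forcing, label, model_id, window, region_weights)
        for label in SCENARIOS
    }
    return ScenarioQuartet(model_id=model_id, runs=runs)


# ---------------------------------------------------------------------------
# ensemble generation
# ---------------------------------------------------------------------------

#: default sampling ranges for the synthetic ensemble; chosen to give
#: inter-model spread of realistic qualitative character (documented in
#: docs/methods.md)
DEFAULT_PARAM_RANGES: dict[str, tuple[float, float]] = {
    "npp0": (45.0, 65.0),
    "rho_ag": (0.5, 0.9),
    "beta": (0.3, 0.7),
    "gamma": (-0.02, 0.02),
    "tau_v_nat": (8.0, 25.0),
    "tau_v_ag": (1.0, 4.0),
    "tau_lit": (2.0, 6.0),
    "tau_s0": (15.0, 40.0),
    "q10": (1.5, 2.5),
    "eps_lit": (0.3, 0.7),
    "lambda_lu": (0.5, 1.5),
    "p_atm": (0.4, 0.8),
}

#: P(has_litter), P(has_cwd | has_litter), P(litter_in_soil | has_litter)
DEFAULT_FLAG_PROBS = {"has_litter": 0.85, "has_cwd": 0.3, "litter_in_soil": 0.2}


def sample_params(
    rng: np.random.Generator,
    parameter_ranges: Mapping[str, tuple[float, float]] | None = None,
    flag_probabilities: Mapping[str, float] | None = None,
) -> ToyModelParams:
    ranges = {**DEFAULT_PARAM_RANGES, **(parameter_ranges or {})}
    probs = {**DEFAULT_FLAG_PROBS, **(flag_probabilities or {})}
    draws = {}
    for name, (lo, hi) in ranges.items():
        if hi < lo:
            raise ValueError(f"empty range for {name}: ({lo}, {hi})")
        draws[name] = float(rng.uniform(lo, hi))
    has_litter = bool(rng.random() < probs["has_litter"])
    has_cwd = bool(has_litter and rng.random() < probs["has_cwd"])
    litter_in_soil = bool(has_litter and rng.random() < probs["litter_in_soil"])
    flags = PoolFlags(has_litter, has_cwd, litter_in_soil)
    return ToyModelParams(flags=flags, **draws)


def generate_ensemble(
    n_models: int = 18,
    forcing: ForcingSet | None = None,
    parameter_ranges: Mapping[str, tuple[float, float]] | None = None,
    flag_probabilities: Mapping[str, float] | None = None,
    seed: int = 0,
    window: tuple[int, int] = (1958, 2020),
    region_weights: Mapping[str, float] | None = None,
) -> list[ScenarioQuartet]:
    """Sample ``n_models`` parameter sets and run all four scenarios each.

    All models share one forcing realisation (common forcing, different
    structure); parameters are drawn independently and uniformly from the
    stated ranges. Deterministic for a fixed seed.
    """
    if n_models < 2:
        raise ValueError("an ensemble needs at least two models")
    rng = np.random.default_rng(seed)
    if forcing is None:
        forcing = generate_forcing(range(1901, 2021), seed=seed)
    quartets = []
    for i in range(n_models):
        params = sample_params(rng, parameter_ranges, flag_probabilities)
        model_id = f"TOY{i:02d}"
        quartets.append(
            run_quartet(params, forcing, model_id, window, region_weights)
        )
    return quartets
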