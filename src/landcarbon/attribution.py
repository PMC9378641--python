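"""Process attribution of changes in vegetation and soil carbon stocks.

The core idea: express each bulk pool with dC/dt = input - C/tau, diagnose
an annual turnover time tau and input flux from model output, approximate
the pool by its steady state C_hat = input * tau, and split the change in
C_hat between a reference year and an end year into

    input term        = d(input) * tau_ref
    output term       = input_ref * d(tau)      (bulk turnover change)
    interaction term  = d(input) * d(tau)

whose sum equals d(C_hat) exactly. Because the steady-state approximation
(and the collapse of many internal pools into one) does not capture the
actual simulated stock change dC, the residual delta = dC - d(C_hat) is
then redistributed over the three terms in proportion to their absolute
magnitudes, so the adjusted terms sum to dC exactly.

Diagnostics:
    tau_v = Cv / (NPP - dCv)      vegetation turnover time (yr)
    tau_s = Cs / Rh               bulk soil-system turnover time (yr)
    f_vs  = dCs + Rh              vegetation-to-soil flux (PgC yr-1)

where dC is the backward annual difference. Non-positive denominators are
flagged missing (NaN), never clamped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import AnnualSeries, ModelRun
from .io import aggregate_soil_pools

POOLS = ("vegetation", "soil")

TERM_COLUMNS = [
    "input",
    "output",
    "interaction",
    "delta_hat",
    "delta_actual",
    "correction",
    "input_adj",
    "output_adj",
    "interaction_adj",
]


def annual_change(values: np.ndarray | AnnualSeries) -> np.ndarray:
    """Backward annual difference; the first year uses the forward one."""
    if isinstance(values, AnnualSeries):
        values = values.values
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least two years to difference")
    out = np.empty_like(values)
    out[1:] = values[1:] - values[:-1]
    out[0] = values[1] - values[0]
    return out


def diagnose_tau_v(cv: np.ndarray, npp: np.ndarray, dcv: np.ndarray) -> np.ndarray:
    """tau_v = Cv / (NPP - dCv), NaN where the outflux is non-positive."""
    cv, npp, dcv = (np.asarray(a, float) for a in (cv, npp, dcv))
    outflux = npp - dcv
    with np.errstate(divide="ignore", invalid="ignore"):
        tau = np.where(outflux > 0, cv / outflux, np.nan)
    return tau


def diagnose_tau_s(cs: np.ndarray, rh: np.ndarray) -> np.ndarray:
    """tau_s = Cs / Rh, NaN where Rh is non-positive."""
    cs, rh = np.asarray(cs, float), np.asarray(rh, float)
    with np.errstate(divide="ignore", invalid="ignore"):
        tau = np.where(rh > 0, cs / rh, np.nan)
    return tau


def diagnose_f_vs(dcs: np.ndarray, rh: np.ndarray) -> np.ndarray:
    """Vegetation-to-soil flux implied by the soil balance: dCs + Rh."""
    return np.asarray(dcs, float) + np.asarray(rh, float)


def steady_state_pool(inputs: np.ndarray, tau: np.ndarray) -> np.ndarray:
    """Steady-state stock C_hat = input * tau (NaN tau propagates)."""
    return np.asarray(inputs, float) * np.asarray(tau, float)


def decompose_change(
    input_ref: float, input_end: float, tau_ref: float, tau_end: float
) -> tuple[float, float, float]:
    """Split d(C_hat) into input, turnover and interaction terms.

    Exact identity: the three terms sum to
    input_end*tau_end - input_ref*tau_ref.
    """
    d_input = input_end - input_ref
    d_tau = tau_end - tau_ref
    return (d_input * tau_ref, input_ref * d_tau, d_input * d_tau)


def scale_to_actual(
    terms: Sequence[float], delta_actual: float
) -> tuple[float, float, float]:
    """Redistribute delta = dC - sum(terms) by relative term magnitude.

    Adjusted terms sum to ``delta_actual`` exactly. If all three terms are
    zero the whole correction is assigned to the input term (degenerate
    rule, keeps the sum identity).
    """
    terms = np.asarray(terms, dtype=float)
    delta = delta_actual - terms.sum()
    denom = np.abs(terms).sum()
    if denom == 0.0:
        adjusted = terms.copy()
        adjusted[0] += delta
    else:
        adjusted = terms + np.abs(terms) / denom * delta
    return tuple(float(v) for v in adjusted)


@dataclass(frozen=True)
class PoolSeries:
    """Aligned stock / input / turnover series for one bulk pool."""

    years: np.ndarray
    stock: np.ndarray
    inputs: np.ndarray
    tau: np.ndarray


def pool_diagnostics(run: ModelRun, pool: str, region: str = "global") -> PoolSeries:
    """Stock, input flux and diagnosed turnover time for one pool."""
    if pool == "vegetation":
        cv = run.series("cveg", region)
        npp = run.series("npp", region).values
        dcv = annual_change(cv.values)
        tau = diagnose_tau_v(cv.values, npp, dcv)
        return PoolSeries(cv.years, cv.values, npp, tau)
    if pool == "soil":
        cs = aggregate_soil_pools(run, region)
        rh = run.series("rh", region).values
        dcs = annual_change(cs.values)
        f_vs = diagnose_f_vs(dcs, rh)
        tau = diagnose_tau_s(cs.values, rh)
        return PoolSeries(cs.years, cs.values, f_vs, tau)
    raise ValueError(f"unknown pool {pool!r} (expected one of {POOLS})")


def _endpoint(values: np.ndarray, years: np.ndarray, year: int, window: int) -> float:
    """Mean over a centred window of ``window`` years, clipped to range."""
    idx = int(np.flatnonzero(years == year)[0])
    half = (window - 1) // 2
    lo = max(0, idx - half)
    hi = min(values.size, idx + half + 1)
    return float(np.mean(values[lo:hi]))


def attribute_pool_change(
    run: ModelRun,
    pool: str,
    ref_year: int = 1959,
    end_years: Sequence[int] | int = 2020,
    region: str = "global",
    endpoint_window: int = 1,
) -> pd.DataFrame:
    """Time-resolved decomposition of a pool's stock change since ref_year.

    For each end year the input flux and turnover time at the two
    endpoints feed :func:`decompose_change`; the terms are then adjusted
    to the actual stock change with :func:`scale_to_actual`. Years whose
    turnover diagnostic is flagged missing yield NaN rows. Endpoint values
    are single-year by default; ``endpoint_window`` > 1 averages a centred
    window to damp interannual noise.
    """
    if isinstance(end_years, (int, np.integer)):
        end_years = [int(end_years)]
    ps = pool_diagnostics(run, pool, region)
    if ref_year not in ps.years or any(y not in ps.years for y in end_years):
        raise ValueError("requested years outside the run's span")

    input_ref = _endpoint(ps.inputs, ps.years, ref_year, endpoint_window)
    tau_ref = _endpoint(ps.tau, ps.years, ref_year, endpoint_window)
    stock_ref = ps.stock[np.flatnonzero(ps.years == ref_year)[0]]

    rows = []
    for year in end_years:
        input_end = _endpoint(ps.inputs, ps.years, year, endpoint_window)
        tau_end = _endpoint(ps.tau, ps.years, year, endpoint_window)
        stock_end = ps.stock[np.flatnonzero(ps.years == year)[0]]
        delta_actual = float(stock_end - stock_ref)
        if np.isnan(tau_ref) or np.isnan(tau_end):
            rows.append({c: np.nan for c in TERM_COLUMNS} | {"year": year})
            continue
        terms = decompose_change(input_ref, input_end, tau_ref, tau_end)
        adjusted = scale_to_actual(terms, delta_actual)
        delta_hat = float(sum(terms))
        rows.append(
            {
                "year": year,
                "input": terms[0],
                "output": terms[1],
                "interaction": terms[2],
                "delta_hat": delta_hat,
                "delta_actual": delta_actual,
                "correction": delta_actual - delta_hat,
                "input_adj": adjusted[0],
                "output_adj": adjusted[1],
                "interaction_adj": adjusted[2],
            }
        )
    df = pd.DataFrame(rows).set_index("year")
    df.attrs.update({"pool": pool, "region": region, "model": run.model_id,
                     "scenario": run.scenario, "ref_year": ref_year})
    return df[TERM_COLUMNS]


def attribution_factors(
    run: ModelRun,
    pool: str,
    ref_year: int = 1959,
    end_year: int = 2020,
    region: str = "global",
    endpoint_window: int = 1,
) -> dict[str, float]:
    """The four spread-decomposition factors for one model and pool.

    Returns baseline input, input change, baseline turnover and turnover
    change between the reference and end years.
    """
    ps = pool_diagnostics(run, pool, region)
    input_ref = _endpoint(ps.inputs, ps.years, ref_year, endpoint_window)
    input_end = _endpoint(ps.inputs, ps.years, end_year, endpoint_window)
    tau_ref = _endpoint(ps.tau, ps.years, ref_year, endpoint_window)
    tau_end = _endpoint(ps.tau, ps.years, end_year, endpoint_window)
    return {
        "input_ref": input_ref,
        "d_input": input_end - input_ref,
        "tau_ref": tau_ref,
        "d_tau": tau_end - tau_ref,
    }


def terms_to_tidy(
    df: pd.DataFrame, model: str, scenario: str, region: str, pool: str,
    driver: str | None = None,
) -> pd.DataFrame:
    """Long-format rows (one per term per year) for CSV export."""
    out = df.reset_index().melt(id_vars="year", var_name="term", value_name="value")
    out.insert(0, "model", model)
    out.insert(1, "scenario", scenario)
    out.insert(2, "region", region)
    out.insert(3, "pool", pool)
    if driver is not None:
        out.insert(4, "driver", driver)
    out["units"] = "PgC"
    return out
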