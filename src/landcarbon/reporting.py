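"""Presentation-layer computations: smoothing, local regression, period
statistics, driver-dominance RGB composites and ensemble summary tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import UnivariateSpline, make_smoothing_spline

from .containers import AnnualSeries


def smooth_spline_series(
    series: AnnualSeries | tuple[np.ndarray, np.ndarray],
    order: int = 4,
    smoothing: float | None = None,
) -> np.ndarray:
    """Penalized-spline smoothing evaluated at the input years.

    ``order`` is the B-spline order (order 4 = piecewise cubic, the
    default). For order 4 this is a second-derivative-penalty smoothing
    spline: smoothing -> 0 interpolates the data and smoothing -> inf
    tends to the ordinary least-squares line; ``smoothing=None`` picks the
    penalty by generalized cross-validation. Order 5 (quartic pieces) is
    available via a knot-reduction spline whose ``smoothing`` is a
    residual budget.
    """
    if isinstance(series, AnnualSeries):
        x, y = series.years.astype(float), series.values
    else:
        x, y = np.asarray(series[0], float), np.asarray(series[1], float)
    if x.size < order + 1:
        raise ValueError(f"need at least {order + 1} points for order {order}")
    if order == 4:
        spline = make_smoothing_spline(x, y, lam=smoothing)
        return np.asarray(spline(x))
    if order == 5:
        spline = UnivariateSpline(x, y, k=4, s=smoothing)
        return np.asarray(spline(x))
    raise ValueError("order must be 4 (cubic pieces) or 5 (quartic pieces)")


def local_regression(
    series: AnnualSeries | tuple[np.ndarray, np.ndarray],
    span: float = 0.5,
) -> np.ndarray:
    """Tricube-weighted local linear fit at each year (LOESS, degree 1).

    At each point the ``ceil(span * n)`` nearest neighbours are weighted
    by (1 - (d/d_max)^3)^3 and a straight line is fitted by weighted
    least squares. ``span`` = 1 uses every point.
    """
    if isinstance(series, AnnualSeries):
        x, y = series.years.astype(float), series.values
    else:
        x, y = np.asarray(series[0], float), np.asarray(series[1], float)
    n = x.size
    if not 0.0 < span <= 1.0:
        raise ValueError("span must lie in (0, 1]")
    if n < 4:
        raise ValueError("need at least 4 points")
    k = max(2, int(np.ceil(span * n)))

    fitted = np.empty(n)
    for i in range(n):
        d = np.abs(x - x[i])
        idx = np.argsort(d, kind="stable")[:k]
        dmax = d[idx].max()
        if dmax == 0:
            fitted[i] = y[idx].mean()
            continue
        w = (1 - (d[idx] / dmax) ** 3) ** 3
        w = np.clip(w, 0.0, None)
        if w.sum() == 0 or np.count_nonzero(w) < 2:
            raise ValueError("degenerate neighbourhood: all weights vanish")
        # weighted least squares for y = a + b (x - x0)
        xw = x[idx] - x[i]
        sw, sx, sxx = w.sum(), (w * xw).sum(), (w * xw * xw).sum()
        sy, sxy = (w * y[idx]).sum(), (w * xw * y[idx]).sum()
        det = sw * sxx - sx * sx
        if det == 0:
            fitted[i] = sy / sw
        else:
            fitted[i] = (sxx * sy - sx * sxy) / det
    return fitted


@dataclass(frozen=True)
class PeriodStat:
    period: tuple[int, int]
    mean: float
    trend: float  # per year, in the series' units


def period_mean_and_trend(
    series: AnnualSeries,
    periods: Sequence[tuple[int, int]],
) -> list[PeriodStat]:
    """Simple mean and OLS slope (vs year) over each [start, end] period."""
    stats = []
    for start, end in periods:
        sub = series.window(start, end)
        if len(sub) == 0:
            raise ValueError(f"empty period {start}-{end}")
        slope = float(np.polyfit(sub.years.astype(float), sub.values, 1)[0])
        stats.append(PeriodStat((start, end), float(sub.values.mean()), slope))
    return stats


def acceleration(
    series: AnnualSeries,
    early: tuple[int, int],
    late: tuple[int, int],
) -> float:
    """Post-breakpoint acceleration: the OLS slope over the later period.

    For a flux series in PgC yr-1 the result is in PgC yr-2 (multiply by
    1000 for TgC yr-2).
    """
    return period_mean_and_trend(series, [late])[0].trend


def rgb_driver_composite(
    clim: np.ndarray,
    co2: np.ndarray,
    lulcc: np.ndarray,
    net: np.ndarray,
    scale: float = 1.0,
) -> np.ndarray:
    """Driver-dominance RGBA composite (CLIM=red, CO2=green, LULCC=blue).

    Each channel is the driver's share of the total absolute change, so
    the channels sum to one wherever any driver is nonzero and are
    invariant to rescaling all drivers together. Alpha saturates with the
    magnitude of the net change: min(1, |net| / scale).
    """
    clim, co2, lulcc, net = (np.asarray(a, float) for a in (clim, co2, lulcc, net))
    total = np.abs(clim) + np.abs(co2) + np.abs(lulcc)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(total > 0, np.abs(clim) / total, 0.0)
        g = np.where(total > 0, np.abs(co2) / total, 0.0)
        b = np.where(total > 0, np.abs(lulcc) / total, 0.0)
    alpha = np.where(total > 0, np.minimum(1.0, np.abs(net) / scale), 0.0)
    return np.stack([r, g, b, alpha], axis=-1)


def save_rgba_png(rgba: np.ndarray, path) -> None:
    """Write an (ny, nx, 4) RGBA array as a PNG image."""
    import matplotlib.image as mpimg

    arr = np.asarray(rgba, dtype=float)
    if arr.ndim != 3 or arr.shape[-1] != 4:
        raise ValueError("expected an (ny, nx, 4) RGBA array")
    mpimg.imsave(path, np.clip(arr, 0.0, 1.0))


def summary_tables(terms: pd.DataFrame) -> pd.DataFrame:
    """Ensemble mean +/- std per region, pool, driver and term.

    ``terms`` is the tidy per-model table from
    :func:`landcarbon.drivers.ensemble_driver_terms`. Rows are ordered
    deterministically; values are in PgC.
    """
    if terms.empty:
        raise ValueError("no attribution results to summarise")
    keys = [c for c in ("region", "pool", "driver", "year", "term") if c in terms.columns]
    grouped = terms.groupby(keys, sort=True)["value"]
    table = grouped.agg(mean="mean", std=lambda v: v.std(ddof=1), n_models="count")
    table["units"] = "PgC"
    return table.reset_index()


def format_summary(table: pd.DataFrame, decimals: int = 1) -> pd.DataFrame:
    """Human-readable 'mean ± std (n)' rendering of a summary table."""
    out = table.copy()
    out["mean ± std"] = [
        f"{m:.{decimals}f} ± {s:.{decimals}f} (n={int(n)})"
        for m, s, n in zip(out["mean"], out["std"], out["n_models"])
    ]
    return out.drop(columns=["mean", "std", "n_models"])
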