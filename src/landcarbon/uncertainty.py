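"""Ensemble summaries and spread decomposition.

The spread (sample standard deviation across models) of the steady-state
stock change d(C_hat) = d(input)*tau_ref + input_ref*d(tau) +
d(input)*d(tau) is decomposed one factor at a time: for each of the four
factors (baseline input, input change, baseline turnover, turnover
change), d(C_hat) is recomputed per model using that model's own value of
the factor and the multi-model mean of the other three, and the standard
deviation of the resulting values is reported as that factor's
contribution to spread.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

SPREAD_COMPONENTS = (
    "baseline_input",
    "delta_input",
    "baseline_turnover",
    "delta_turnover",
)

#: which factor column each spread component substitutes with model values
_COMPONENT_FACTOR = {
    "baseline_input": "input_ref",
    "delta_input": "d_input",
    "baseline_turnover": "tau_ref",
    "delta_turnover": "d_tau",
}

FACTOR_COLUMNS = ("input_ref", "d_input", "tau_ref", "d_tau")


def ensemble_stats(values: Iterable[float]) -> tuple[float, float]:
    """Multi-model mean and sample (n-1) standard deviation."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size < 2:
        raise ValueError("need at least two models for a spread")
    return float(arr.mean()), float(arr.std(ddof=1))


def delta_c_hat(input_ref, d_input, tau_ref, d_tau):
    """Steady-state stock change from the four factors (bilinear)."""
    return d_input * tau_ref + input_ref * d_tau + d_input * d_tau


def spread_decomposition(factors: pd.DataFrame) -> dict[str, float]:
    """One-factor-at-a-time decomposition of the d(C_hat) ensemble spread.

    ``factors`` has one row per model and columns input_ref, d_input,
    tau_ref, d_tau. Returns the spread attributable to each component
    plus ``all_own``, the spread of d(C_hat) with every model using its
    own four values.
    """
    missing = [c for c in FACTOR_COLUMNS if c not in factors.columns]
    if missing:
        raise ValueError(f"factor table missing columns: {missing}")
    if len(factors) < 2:
        raise ValueError("need at least two models")
    if factors[list(FACTOR_COLUMNS)].isna().any().any():
        raise ValueError("factor table contains missing values")

    means = {c: float(factors[c].mean()) for c in FACTOR_COLUMNS}
    out: dict[str, float] = {}
    for component, own_col in _COMPONENT_FACTOR.items():
        args = {
            c: (factors[c].to_numpy() if c == own_col else means[c])
            for c in FACTOR_COLUMNS
        }
        values = delta_c_hat(**args)
        out[component] = _sample_std(values)
    own = delta_c_hat(*(factors[c].to_numpy() for c in FACTOR_COLUMNS))
    out["all_own"] = _sample_std(own)
    return out


def _sample_std(values: np.ndarray) -> float:
    # identical values have exactly zero spread; np.std would leave a
    # round-off residual from the mean subtraction
    if np.ptp(values) == 0.0:
        return 0.0
    return float(np.std(values, ddof=1))


def agreement_fraction(changes: Iterable[float], threshold: float = 0.8) -> tuple[float, bool]:
    """Fraction of models agreeing with the majority sign, and stippling.

    Zeros count towards n but towards neither sign. The stipple flag marks
    cells where fewer than ``threshold`` of the models agree on the
    direction of change.
    """
    arr = np.asarray(list(changes), dtype=float)
    if arr.size == 0:
        raise ValueError("need at least one model")
    n_pos = int(np.sum(arr > 0))
    n_neg = int(np.sum(arr < 0))
    fraction = max(n_pos, n_neg) / arr.size
    return float(fraction), bool(fraction < threshold)


def agreement_mask(changes: np.ndarray, threshold: float = 0.8) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised :func:`agreement_fraction` over a (model, ...) stack."""
    arr = np.asarray(changes, dtype=float)
    n_pos = np.sum(arr > 0, axis=0)
    n_neg = np.sum(arr < 0, axis=0)
    fraction = np.maximum(n_pos, n_neg) / arr.shape[0]
    return fraction, fraction < threshold
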