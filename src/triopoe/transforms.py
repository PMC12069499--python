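"""Trait preprocessing: rank inverse-normal, log, z-score, and derived indices.

The inverse-normal transform is the rank-based Blom variant
Phi^-1((r - 3/8) / (n + 1/4)) with average ranks for ties; missing values
propagate and are excluded from the ranking.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Any

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TransformedTrait",
    "inverse_normal_transform",
    "zscore",
    "log_transform",
    "apply_transform",
    "derive_bmi",
    "derive_whr",
    "derive_ldl_friedewald",
]


@dataclass
class TransformedTrait:
    """A transformed trait column with provenance."""

    name: str
    transform: str
    values: pd.Series
    provenance: dict[str, Any]


def _as_float_array(values) -> tuple[np.ndarray, Any]:
    """Coerce to float ndarray, remembering a pandas index if one was given."""
    if isinstance(values, pd.Series):
        return values.to_numpy(dtype=float), values.index
    return np.asarray(values, dtype=float), None


def _wrap(out: np.ndarray, index) -> np.ndarray | pd.Series:
    if index is not None:
        return pd.Series(out, index=index)
    return out


def inverse_normal_transform(values, offset: float = 0.375):
    """Rank-based inverse-normal transform (Blom offset by default).

    Non-missing values get Phi^-1((r - offset) / (n + 1 - 2*offset)) where r is
    the 1-based average rank among non-missing values; NaNs stay NaN.  Requires
    at least two non-missing values.
    """
    arr, index = _as_float_array(values)
    mask = np.isfinite(arr)
    n = int(mask.sum())
    if n == 0:
        raise ValueError("inverse_normal_transform: all values are missing")
    if n < 2:
        raise ValueError("inverse_normal_transform: need at least 2 non-missing values")
    ranks = stats.rankdata(arr[mask], method="average")
    quantiles = (ranks - offset) / (n + 1.0 - 2.0 * offset)
    out = np.full_like(arr, np.nan)
    out[mask] = stats.norm.ppf(quantiles)
    return _wrap(out, index)


def zscore(values):
    """Center and scale to unit sample SD (ddof=1); NaNs propagate."""
    arr, index = _as_float_array(values)
    mask = np.isfinite(arr)
    if mask.sum() < 2:
        raise ValueError("zscore: need at least 2 non-missing values")
    sd = np.std(arr[mask], ddof=1)
    if sd == 0:
        raise ValueError("zscore: zero variance")
    out = np.full_like(arr, np.nan)
    out[mask] = (arr[mask] - np.mean(arr[mask])) / sd
    return _wrap(out, index)


def log_transform(values, base: float | None = None):
    """Natural log by default (``base=2`` for log2); inputs must be positive."""
    arr, index = _as_float_array(values)
    mask = np.isfinite(arr)
    if (arr[mask] <= 0).any():
        raise ValueError("log_transform: inputs must be strictly positive")
    out = np.full_like(arr, np.nan)
    out[mask] = np.log(arr[mask])
    if base is not None:
        out[mask] /= np.log(base)
    return _wrap(out, index)


def apply_transform(values, kind: str):
    """Dispatch a named transform: none | log | log2 | log_z | inverse_normal | zscore."""
    if kind in (None, "none"):
        return values
    if kind == "log":
        return log_transform(values)
    if kind == "log_z":
        return zscore(log_transform(values))
    if kind == "log2":
        return log_transform(values, base=2)
    if kind == "inverse_normal":
        return inverse_normal_transform(values)
    if kind == "zscore":
        return zscore(values)
    raise ValueError(f"unknown transform {kind!r}")


def derive_bmi(weight_kg, height_m):
    """Body mass index: weight (kg) / height (m) squared."""
    w = np.asarray(weight_kg, dtype=float)
    h = np.asarray(height_m, dtype=float)
    if (h <= 0).any() or (w <= 0).any():
        raise ValueError("derive_bmi: weight and height must be positive")
    out = w / h**2
    return float(out) if out.ndim == 0 else out


def derive_whr(waist_cm, hip_cm):
    """Waist-to-hip circumference ratio."""
    waist = np.asarray(waist_cm, dtype=float)
    hip = np.asarray(hip_cm, dtype=float)
    if (waist <= 0).any() or (hip <= 0).any():
        raise ValueError("derive_whr: circumferences must be positive")
    out = waist / hip
    return float(out) if out.ndim == 0 else out


def derive_ldl_friedewald(total_chol, hdl, triglycerides, tg_divisor: float = 2.2,
                          tg_limit: float = 4.5):
    """LDL-cholesterol by the Friedewald formula, LDL = TC - HDL - TG/divisor.

    Defaults use mmol/l conventions (divisor 2.2, validity bound 4.5 mmol/l);
    pass ``tg_divisor=5, tg_limit=400`` for mg/dl.  Values with triglycerides
    above the validity bound come back as NaN with a warning.
    """
    tc = np.asarray(total_chol, dtype=float)
    hd = np.asarray(hdl, dtype=float)
    tg = np.asarray(triglycerides, dtype=float)
    out = tc - hd - tg / tg_divisor
    over = tg >= tg_limit
    if over.any():
        n = int(np.atleast_1d(over).sum())
        warnings.warn(
            f"derive_ldl_friedewald: {n} value(s) with triglycerides >= {tg_limit} "
            "set to missing (formula not valid)",
            stacklevel=2,
        )
        out = np.where(over, np.nan, out)
    return float(out) if np.ndim(out) == 0 else out
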