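"""Model-performance metrics: MAE, RMSE and R^2 per analyte and data subset.

MAE = mean |C_E - C_M| and RMSE = sqrt(mean (C_E - C_M)^2), where C_E is the
experimental and C_M the model concentration, both in mass %.  The report is
computed on the linear concentration scale (the scale on which the errors
have physical units); because the network is trained on log2 targets the
log2-scale counterparts are carried as secondary columns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ann_quant import DatasetSplit, MLPModel

__all__ = ["EvalReport", "mae", "rmse", "r_squared", "evaluate"]

ANALYTES = ("ethanol", "acetone")
SUBSETS = ("learning", "test", "validation")


def _check_pair(c_exp, c_mod) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(c_exp, dtype=float)
    b = np.asarray(c_mod, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    if a.size == 0:
        raise ValueError("empty input")
    return a, b


def mae(c_exp, c_mod) -> float:
    """Mean absolute error between experimental and modelled concentrations."""
    a, b = _check_pair(c_exp, c_mod)
    return float(np.mean(np.abs(a - b)))


def rmse(c_exp, c_mod) -> float:
    """Root mean square error; always >= MAE (power-mean inequality)."""
    a, b = _check_pair(c_exp, c_mod)
    return float(np.sqrt(np.mean((a - b) ** 2)))


def r_squared(c_exp, c_mod) -> float:
    """Coefficient of determination 1 - SS_res/SS_tot.

    Undefined (raises) when the experimental values are constant, since the
    null model's variance is zero.
    """
    a, b = _check_pair(c_exp, c_mod)
    ss_tot = float(np.sum((a - a.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("R^2 undefined for constant experimental values")
    ss_res = float(np.sum((a - b) ** 2))
    return 1.0 - ss_res / ss_tot


@dataclass
class EvalReport:
    """One row per (analyte, subset): n, R^2, MAE, RMSE plus log2-scale variants."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        filled = self.table[self.table["n"] > 0]
        if not np.all(filled["rmse"].to_numpy() >= filled["mae"].to_numpy() - 1e-15):
            raise ValueError("invariant violated: rmse < mae in some cell")

    def cell(self, analyte: str, subset: str) -> pd.Series:
        t = self.table
        row = t[(t["analyte"] == analyte) & (t["subset"] == subset)]
        if row.empty:
            raise KeyError(f"no cell ({analyte}, {subset})")
        return row.iloc[0]


def evaluate(
    model: MLPModel,
    features: np.ndarray,
    concentrations_pct: np.ndarray,
    split: DatasetSplit,
) -> EvalReport:
    """Score a trained quantifier per analyte and per data subset.

    ``concentrations_pct`` holds the true (ethanol, acetone) mass fractions
    in % per sample.  Predictions come from the network's log2 output,
    exponentiated back to the linear scale for the primary metrics.  Empty
    subsets yield a row with n = 0 and NaN metrics.
    """
    x = np.asarray(features, float)
    c_true = np.asarray(concentrations_pct, float)
    if c_true.shape != (x.shape[0], 2):
        raise ValueError(f"concentrations must be (n, 2), got {c_true.shape}")
    log2_pred = model.predict_log2(x)
    c_pred = 2.0**log2_pred
    log2_true = np.log2(c_true)

    rows = []
    for subset, idx in split.subsets().items():
        for k, analyte in enumerate(ANALYTES):
            if idx.size == 0:
                rows.append(
                    {
                        "analyte": analyte,
                        "subset": subset,
                        "n": 0,
                        "r_squared": np.nan,
                        "mae": np.nan,
                        "rmse": np.nan,
                        "r_squared_log2": np.nan,
                        "mae_log2": np.nan,
                        "rmse_log2": np.nan,
                    }
                )
                continue
            t_lin, p_lin = c_true[idx, k], c_pred[idx, k]
            t_log, p_log = log2_true[idx, k], log2_pred[idx, k]

            def _r2_or_nan(t, p):
                # constant truth (tiny subsets): R^2 undefined, flagged as NaN
                try:
                    return r_squared(t, p)
                except ValueError:
                    return np.nan

            rows.append(
                {
                    "analyte": analyte,
                    "subset": subset,
                    "n": int(idx.size),
                    "r_squared": _r2_or_nan(t_lin, p_lin),
                    "mae": mae(t_lin, p_lin),
                    "rmse": rmse(t_lin, p_lin),
                    "r_squared_log2": _r2_or_nan(t_log, p_log),
                    "mae_log2": mae(t_log, p_log),
                    "rmse_log2": rmse(t_log, p_log),
                }
            )
    return EvalReport(table=pd.DataFrame(rows))
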