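"""Residual and influence diagnostics for fitted response-surface models.

Per run: raw residual e_i, leverage h_i (hat-matrix diagonal), internally
and externally studentized residuals, deletion residual e_i/(1−h_i), Cook's
distance, and DFFITS, with flags at the usual thresholds. Outlying or
influential runs are flagged, never deleted: a high-leverage point can be
perfectly well described by the model, and removing it discards the most
informative corner of the design.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .model import FittedModel

__all__ = ["residual_diagnostics", "plot_series"]


def residual_diagnostics(
    fit: FittedModel,
    leverage_threshold: float | None = None,
    cooks_threshold: float = 1.0,
) -> pd.DataFrame:
    """Per-run diagnostics table.

    Internally studentized: r_i = e_i / (s·sqrt(1 − h_i)). Externally
    studentized: same but with the delete-one residual variance s_(−i)².
    Cook's distance D_i = r_i²·h_i / (p·(1 − h_i)) with p the parameter
    count including the intercept. DFFITS_i = r_ext,i·sqrt(h_i/(1−h_i)).
    Default leverage threshold 2p/n.

    Runs with h_i = 1 have no studentized residual; they are flagged
    (``undefined`` column) rather than raising.
    """
    if fit.df_resid < 2:
        raise ValueError("external studentization needs at least 2 residual df")
    e = fit.residuals
    h = fit.leverage
    n, p = fit.n, fit.p
    s = fit.s
    if leverage_threshold is None:
        leverage_threshold = 2.0 * p / n

    one_minus_h = 1.0 - h
    undefined = one_minus_h < 1e-12
    safe = np.where(undefined, np.nan, one_minus_h)

    r_int = e / (s * np.sqrt(safe))
    # delete-one variance: s_(-i)^2 = ((n-p) s^2 - e_i^2/(1-h_i)) / (n-p-1)
    s2_del = ((n - p) * s**2 - e**2 / safe) / (n - p - 1)
    s2_del = np.clip(s2_del, 0.0, None)
    with np.errstate(divide="ignore", invalid="ignore"):
        r_ext = e / np.sqrt(s2_del * safe)
    cooks = r_int**2 * h / (p * safe)
    dffits = r_ext * np.sqrt(h / safe)
    deletion = e / safe

    return pd.DataFrame(
        {
            "residual": e,
            "leverage": h,
            "r_internal": r_int,
            "r_external": r_ext,
            "deletion_residual": deletion,
            "cooks_d": cooks,
            "dffits": dffits,
            "undefined": undefined,
            "outlier_95": np.abs(r_ext) > 2,
            "outlier_997": np.abs(r_ext) > 3,
            "high_leverage": h > leverage_threshold,
            "influential": cooks > cooks_threshold,
        }
    )


def _plotting_positions(n: int) -> np.ndarray:
    # Blom-type positions (i − 0.375)/(n + 0.25)
    i = np.arange(1, n + 1)
    return (i - 0.375) / (n + 0.25)


def plot_series(fit: FittedModel, kind: str, run_order=None) -> dict:
    """Data series for a diagnostic plot, as ``{"x", "y", "thresholds", ...}``.

    Kinds: ``normal_probability`` (ordered externally studentized residuals
    vs. normal quantiles), ``residual_vs_predicted``, ``residual_vs_run``,
    ``predicted_vs_actual``, ``cooks``, ``leverage``.
    """
    diag = residual_diagnostics(fit)
    n, p = fit.n, fit.p
    # an (essentially) interpolating fit has no residual scale to studentize
    # against; its residual series are reported as zeros
    if fit.s <= 1e-10 * max(1.0, float(np.linalg.norm(fit.y))):
        diag = diag.copy()
        for col in ("r_internal", "r_external", "residual"):
            diag[col] = 0.0
    if kind == "normal_probability":
        r = np.sort(diag["r_external"].to_numpy())
        q = stats.norm.ppf(_plotting_positions(n))
        return {"x": q, "y": r, "thresholds": [], "xlabel": "normal quantile",
                "ylabel": "externally studentized residual"}
    if kind == "residual_vs_predicted":
        return {"x": fit.fitted, "y": diag["r_external"].to_numpy(),
                "thresholds": [-3, -2, 0, 2, 3], "xlabel": "predicted",
                "ylabel": "externally studentized residual"}
    if kind == "residual_vs_run":
        order = np.asarray(run_order) if run_order is not None else np.arange(1, n + 1)
        idx = np.argsort(order)
        return {"x": order[idx], "y": diag["r_external"].to_numpy()[idx],
                "thresholds": [-3, -2, 0, 2, 3], "xlabel": "run order",
                "ylabel": "externally studentized residual"}
    if kind == "predicted_vs_actual":
        return {"x": fit.y, "y": fit.fitted, "thresholds": [],
                "xlabel": "actual", "ylabel": "predicted"}
    if kind == "cooks":
        return {"x": np.arange(1, n + 1), "y": diag["cooks_d"].to_numpy(),
                "thresholds": [1.0], "xlabel": "run", "ylabel": "Cook's distance"}
    if kind == "leverage":
        return {"x": np.arange(1, n + 1), "y": diag["leverage"].to_numpy(),
                "thresholds": [2.0 * p / n], "xlabel": "run", "ylabel": "leverage"}
    raise ValueError(f"unknown plot kind {kind!r}")
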