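"""Point prediction, interval estimation, error propagation, and surface grids.

For a point x0 (expanded term vector) and a fit with residual sd s on
n − p df:

* mean prediction  ŷ = x0·b with standard error SE = s·sqrt(x0ᵀ(XᵀX)⁻¹x0)
  and confidence interval ŷ ± t(1−α/2, n−p)·SE;
* a single future observation has SE_pred = s·sqrt(1 + x0ᵀ(XᵀX)⁻¹x0) and
  prediction interval ŷ ± t·SE_pred;
* a two-sided tolerance interval covering a proportion P of all future
  observations with confidence 1 − α uses the multiplier
  t(1−α/2, n−p)·sqrt(x0ᵀ(XᵀX)⁻¹x0) + z((1+P)/2)·sqrt((n−p)/χ²(α, n−p)),
  combining the design-dependent mean-uncertainty term with a
  χ²-inflated normal population term.

Published coefficient-only models (no n, p, s, XᵀX) support mean prediction
and propagation of error but raise :class:`MissingVarianceError` on interval
requests — variance is never invented.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .model import FittedModel, PolynomialModel

__all__ = [
    "PredictionResult",
    "SurfaceGrid",
    "MissingVarianceError",
    "predict",
    "interval",
    "poe",
    "surface_grid",
]


class MissingVarianceError(ValueError):
    """Interval requested on a model without variance information."""


@dataclass
class PredictionResult:
    point_actual: dict
    point_coded: dict
    y_hat: float
    x0: np.ndarray
    se: float | None = None
    se_pred: float | None = None
    interval: tuple | None = None
    interval_kind: str | None = None
    extrapolated: bool = False


def _coded_point(model: PolynomialModel, point, units: str = "actual") -> np.ndarray:
    names = model.spec.factor_names
    if isinstance(point, dict):
        vals = np.array([point[n] for n in names], dtype=float)
    else:
        vals = np.asarray(point, dtype=float)
    if units == "coded":
        return vals
    if model.factors is None:
        raise ValueError("model carries no factor definitions; pass units='coded'")
    fmap = {f.name: f for f in model.factors}
    return np.array([fmap[n].code(v) for n, v in zip(names, vals)])


def _actual_point(model: PolynomialModel, coded: np.ndarray) -> dict:
    if model.factors is None:
        return {}
    fmap = {f.name: f for f in model.factors}
    return {n: float(fmap[n].decode(c)) for n, c in zip(model.spec.factor_names, coded)}


def predict(model: PolynomialModel, point, units: str = "actual") -> PredictionResult:
    """Mean prediction at one point (actual units by default).

    Points outside the coded [−1, 1] knowledge space are allowed but
    flagged ``extrapolated``.
    """
    coded = _coded_point(model, point, units)
    x0 = model.spec.row(coded)
    y_hat = float(x0 @ model.b)
    return PredictionResult(
        point_actual=_actual_point(model, coded),
        point_coded=dict(zip(model.spec.factor_names, coded.tolist())),
        y_hat=y_hat,
        x0=x0,
        extrapolated=bool(np.any(np.abs(coded) > 1 + 1e-9)),
    )


def _require_variance(model) -> FittedModel:
    missing = [a for a in ("s", "xtx_inv", "X") if getattr(model, a, None) is None
               or (a == "s" and not np.isfinite(getattr(model, "s", np.nan)))]
    if not isinstance(model, FittedModel) or missing:
        raise MissingVarianceError(
            "interval estimation needs a fitted model with n, p, s and (X'X)^-1; "
            f"missing: {missing or 'fit state'}"
        )
    return model


def ti_multiplier(n: int, p: int, h0: float, alpha: float, proportion: float) -> float:
    """Two-sided regression tolerance-interval multiplier (in units of s)."""
    t = stats.t.ppf(1 - alpha / 2, n - p)
    z = stats.norm.ppf(0.5 + proportion / 2)
    chi2 = stats.chi2.ppf(alpha, n - p)
    return float(t * np.sqrt(h0) + z * np.sqrt((n - p) / chi2))


def interval(
    model,
    point,
    kind: str = "CI",
    alpha: float = 0.05,
    proportion: float = 0.99,
    units: str = "actual",
) -> PredictionResult:
    """Confidence (CI), prediction (PI), or tolerance (TI) interval at a point.

    ``proportion`` is the population coverage P of the tolerance interval
    (ignored for CI/PI). Intervals are symmetric about the mean prediction.
    """
    fit = _require_variance(model)
    res = predict(model, point, units)
    x0 = res.x0
    h0 = float(x0 @ fit.xtx_inv @ x0)
    s = fit.s
    df = fit.df_resid
    res.se = s * np.sqrt(h0)
    res.se_pred = s * np.sqrt(1.0 + h0)
    t = stats.t.ppf(1 - alpha / 2, df)
    if kind == "CI":
        half = t * res.se
    elif kind == "PI":
        half = t * res.se_pred
    elif kind == "TI":
        half = s * ti_multiplier(fit.n, fit.p, h0, alpha, proportion)
    else:
        raise ValueError(f"unknown interval kind {kind!r}")
    res.interval = (res.y_hat - half, res.y_hat + half)
    res.interval_kind = kind
    return res


def poe(
    model: PolynomialModel,
    point,
    factor_sds: dict,
    include_residual: bool = True,
    units: str = "actual",
) -> float:
    """First-order propagation of error: predicted response sd at a point.

    ``factor_sds`` maps factor names to standard deviations in actual units.
    sd² = Σ (∂ŷ/∂actual_i)²·σ_i² (+ s² if ``include_residual`` and the model
    has a residual sd). Gradients are analytic, taken in coded units and
    chained through the coding map (∂coded/∂actual = 1/half_range).
    """
    coded = _coded_point(model, point, units)
    g_coded = model.gradient_coded(coded)
    if model.factors is None:
        raise ValueError("propagation of error needs factor definitions for unit conversion")
    fmap = {f.name: f for f in model.factors}
    var = 0.0
    for name, g in zip(model.spec.factor_names, g_coded):
        sd = float(factor_sds.get(name, 0.0))
        if sd < 0:
            raise ValueError(f"negative sd for factor {name!r}")
        var += (g / fmap[name].half_range) ** 2 * sd**2
    if include_residual:
        s = getattr(model, "s", None)
        if s is not None and np.isfinite(s):
            var += float(s) ** 2
    return float(np.sqrt(var))


@dataclass
class SurfaceGrid:
    """Rectangular grid of predictions over two varying factors."""

    axis_names: tuple
    axis_coded: tuple  # two 1-D coded-level arrays
    axis_actual: tuple
    slice_coded: dict  # fixed coded values of the remaining factors
    y_hat: np.ndarray  # shape (len(axis1), len(axis2))
    lo: np.ndarray | None = None
    hi: np.ndarray | None = None
    interval_kind: str | None = None

    def to_long_frame(self):
        import pandas as pd

        a1, a2 = np.meshgrid(self.axis_actual[0], self.axis_actual[1], indexing="ij")
        data = {
            self.axis_names[0]: a1.ravel(),
            self.axis_names[1]: a2.ravel(),
            "y_hat": self.y_hat.ravel(),
        }
        if self.lo is not None:
            data["lo"] = self.lo.ravel()
            data["hi"] = self.hi.ravel()
        return pd.DataFrame(data)


def surface_grid(
    model: PolynomialModel,
    axes: tuple,
    resolution: int = 51,
    slice_coded: dict | None = None,
    interval_kind: str | None = None,
    alpha: float = 0.05,
    proportion: float = 0.99,
    coded_range: tuple = (-1.0, 1.0),
) -> SurfaceGrid:
    """Grid of mean predictions over two factors, others held at a slice.

    ``axes`` names exactly two factors; the rest default to coded 0.
    ``interval_kind`` adds companion lower/upper bound grids (CI/PI/TI).
    """
    if len(axes) != 2:
        raise ValueError("surface_grid needs exactly two varying axes")
    if resolution < 2:
        raise ValueError("resolution must be >= 2 per axis")
    names = model.spec.factor_names
    for a in axes:
        if a not in names:
            raise ValueError(f"unknown axis factor {a!r}")
    slice_coded = dict(slice_coded or {})
    grid1 = np.linspace(coded_range[0], coded_range[1], resolution)
    grid2 = np.linspace(coded_range[0], coded_range[1], resolution)
    G1, G2 = np.meshgrid(grid1, grid2, indexing="ij")
    pts = np.zeros((G1.size, len(names)))
    for j, n in enumerate(names):
        if n == axes[0]:
            pts[:, j] = G1.ravel()
        elif n == axes[1]:
            pts[:, j] = G2.ravel()
        else:
            pts[:, j] = slice_coded.get(n, 0.0)
    y = model.predict_coded(pts).reshape(G1.shape)

    lo = hi = None
    if interval_kind is not None and interval_kind != "none":
        fit = _require_variance(model)
        from .model import expand_points

        X0 = expand_points(pts, model.spec)
        h0 = np.einsum("ij,jk,ik->i", X0, fit.xtx_inv, X0)
        s, df = fit.s, fit.df_resid
        t = stats.t.ppf(1 - alpha / 2, df)
        if interval_kind == "CI":
            half = t * s * np.sqrt(h0)
        elif interval_kind == "PI":
            half = t * s * np.sqrt(1.0 + h0)
        elif interval_kind == "TI":
            z = stats.norm.ppf(0.5 + proportion / 2)
            chi2 = stats.chi2.ppf(alpha, df)
            half = s * (t * np.sqrt(h0) + z * np.sqrt(df / chi2))
        else:
            raise ValueError(f"unknown interval kind {interval_kind!r}")
        half = half.reshape(G1.shape)
        lo, hi = y - half, y + half

    if model.factors is not None:
        fmap = {f.name: f for f in model.factors}
        actual1 = fmap[axes[0]].decode(grid1)
        actual2 = fmap[axes[1]].decode(grid2)
    else:
        actual1, actual2 = grid1, grid2

    return SurfaceGrid(
        axis_names=tuple(axes),
        axis_coded=(grid1, grid2),
        axis_actual=(actual1, actual2),
        slice_coded=slice_coded,
        y_hat=y,
        lo=lo,
        hi=hi,
        interval_kind=interval_kind,
    )
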