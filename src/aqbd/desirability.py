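"""Derringer–Suich desirability and graphical (overlay) optimization.

Each response prediction ŷ is transformed to a desirability d(ŷ) ∈ [0, 1]
by a linear ramp toward its goal (maximize / minimize / target / in_range),
optionally raised to a weight exponent; the overall desirability D is the
geometric mean of the individual d's, so any fully undesirable response
(d = 0) zeroes D. Overlay optimization instead thresholds each response
surface at its limits and intersects the pass regions, optionally requiring
the relevant confidence / prediction / tolerance bound — not just the mean
prediction — to satisfy each limit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .prediction import surface_grid

__all__ = [
    "GoalSpec",
    "OverlayMap",
    "desirability",
    "overall_desirability",
    "optimize_desirability",
    "overlay",
]


@dataclass(frozen=True)
class GoalSpec:
    """Optimization goal for one response.

    maximize: d ramps 0→1 over [lower, upper] (both required);
    minimize: 1→0 over [lower, upper]; target: two one-sided ramps peaking
    at ``target``; in_range: indicator of [lower, upper].
    """

    response_name: str
    goal: str
    lower: float | None = None
    upper: float | None = None
    target: float | None = None
    weight: float = 1.0

    def __post_init__(self):
        if self.goal not in ("maximize", "minimize", "target", "in_range"):
            raise ValueError(f"unknown goal {self.goal!r}")
        if self.weight <= 0:
            raise ValueError("weight must be positive")
        if self.goal in ("maximize", "minimize", "in_range"):
            if self.lower is None or self.upper is None:
                raise ValueError(f"goal {self.goal!r} needs both lower and upper anchors")
        if self.goal == "target":
            if None in (self.lower, self.upper, self.target):
                raise ValueError("target goal needs lower, upper and target")
            if not self.lower < self.target < self.upper:
                raise ValueError("need lower < target < upper")
        if self.lower is not None and self.upper is not None and not self.lower < self.upper:
            raise ValueError("need lower < upper")


def desirability(value, goal: GoalSpec):
    """Individual desirability d(value) ∈ [0, 1]; vectorized over value."""
    v = np.asarray(value, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("desirability requires finite response values")
    lo, up, w = goal.lower, goal.upper, goal.weight
    if goal.goal == "maximize":
        d = np.clip((v - lo) / (up - lo), 0.0, 1.0) ** w
    elif goal.goal == "minimize":
        d = np.clip((up - v) / (up - lo), 0.0, 1.0) ** w
    elif goal.goal == "target":
        t = goal.target
        left = np.clip((v - lo) / (t - lo), 0.0, 1.0)
        right = np.clip((up - v) / (up - t), 0.0, 1.0)
        d = np.where(v <= t, left, right) ** w
    else:  # in_range
        d = ((v >= lo) & (v <= up)).astype(float)
    return d if d.shape else float(d)


def overall_desirability(ds):
    """Geometric mean of individual desirabilities (zero if any is zero)."""
    arr = np.asarray(ds, dtype=float)
    if arr.size == 0:
        raise ValueError("overall desirability of an empty list is undefined")
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("individual desirabilities must lie in [0, 1]")
    if np.any(arr == 0):
        return 0.0
    return float(np.exp(np.mean(np.log(arr))))


def _eval_models(models: dict, pts: np.ndarray) -> dict:
    return {name: m.predict_coded(pts) for name, m in models.items()}


@dataclass
class OptimizationResult:
    point_coded: dict
    point_actual: dict
    D: float
    predictions: dict
    feasible: bool


def optimize_desirability(
    models: dict,
    goals: list,
    resolution: int = 51,
    polish_iters: int = 60,
) -> OptimizationResult:
    """Maximize overall desirability over the coded knowledge space.

    Deterministic: exhaustive search on a ``resolution``-per-axis coded grid
    followed by a shrinking coordinate polish. ``models`` maps response name
    to a polynomial model (all models must share the factor set). Returns a
    ``feasible=False`` result (D = 0 everywhere) rather than raising when
    the goals cannot be met anywhere.
    """
    for g in goals:
        if g.response_name not in models:
            raise ValueError(f"no model for response {g.response_name!r}")
    names = next(iter(models.values())).spec.factor_names
    k = len(names)
    axes = [np.linspace(-1, 1, resolution)] * k
    mesh = np.meshgrid(*axes, indexing="ij")
    pts = np.column_stack([m.ravel() for m in mesh])

    def D_at(p):
        preds = {g.response_name: models[g.response_name].predict_coded(np.atleast_2d(p))
                 for g in goals}
        ds = [desirability(preds[g.response_name], g) for g in goals]
        arr = np.vstack(ds)
        with np.errstate(divide="ignore"):
            out = np.where(np.any(arr == 0, axis=0), 0.0,
                           np.exp(np.mean(np.log(np.clip(arr, 1e-300, None)), axis=0)))
        return out

    Dgrid = D_at(pts)
    best = int(np.argmax(Dgrid))
    x = pts[best].copy()
    step = 2.0 / (resolution - 1)
    # shrinking coordinate search within the coded cube
    for _ in range(polish_iters):
        improved = False
        for j in range(k):
            for delta in (-step, step):
                cand = x.copy()
                cand[j] = np.clip(cand[j] + delta, -1, 1)
                if D_at(cand[None, :])[0] > D_at(x[None, :])[0] + 1e-15:
                    x = cand
                    improved = True
        if not improved:
            step /= 2
            if step < 1e-6:
                break

    Dbest = float(D_at(x[None, :])[0])
    preds = {name: float(m.predict_coded(x[None, :])[0]) for name, m in models.items()}
    some_model = next(iter(models.values()))
    actual = {}
    if some_model.factors is not None:
        fmap = {f.name: f for f in some_model.factors}
        actual = {n: float(fmap[n].decode(c)) for n, c in zip(names, x)}
    return OptimizationResult(
        point_coded=dict(zip(names, x.tolist())),
        point_actual=actual,
        D=Dbest,
        predictions=preds,
        feasible=Dbest > 0,
    )


@dataclass
class OverlayMap:
    """Pass/fail classification of a 2-factor grid against response limits.

    ``classification`` codes: 2 = point estimate and interval both pass,
    1 = point estimate passes but some interval bound fails (only when an
    interval kind is requested; without intervals passes are coded 2),
    0 = point estimate fails.
    """

    axis_names: tuple
    axis_coded: tuple
    axis_actual: tuple
    slice_coded: dict
    per_response_pass: dict
    classification: np.ndarray
    interval_kind: str | None

    @property
    def pass_all(self) -> np.ndarray:
        return self.classification == 2

    def to_long_frame(self):
        import pandas as pd

        a1, a2 = np.meshgrid(self.axis_actual[0], self.axis_actual[1], indexing="ij")
        return pd.DataFrame(
            {
                self.axis_names[0]: a1.ravel(),
                self.axis_names[1]: a2.ravel(),
                "classification": self.classification.ravel(),
            }
        )


def overlay(
    models: dict,
    limits: dict,
    axes: tuple,
    resolution: int = 51,
    slice_coded: dict | None = None,
    interval_kind: str | None = None,
    alpha: float = 0.05,
    proportion: float = 0.99,
) -> OverlayMap:
    """Superimpose response surfaces and classify the grid against limits.

    ``limits`` maps response name to a dict with optional ``"lower"`` and/or
    ``"upper"`` keys. With ``interval_kind`` in {"CI","PI","TI"}, a point is
    fully acceptable only when the relevant interval bound (lower bound for
    a lower limit, upper bound for an upper limit) also meets each limit.
    """
    if not limits:
        raise ValueError("overlay needs at least one response limit")
    for name, lim in limits.items():
        if name not in models:
            raise ValueError(f"no model for response {name!r}")
        if "lower" not in lim and "upper" not in lim:
            raise ValueError(f"response {name!r}: need a lower and/or upper limit")

    per_pass = {}
    per_pass_interval = {}
    grids = {}
    for name, lim in limits.items():
        g = surface_grid(models[name], axes, resolution, slice_coded,
                         interval_kind=interval_kind, alpha=alpha, proportion=proportion)
        grids[name] = g
        ok = np.ones_like(g.y_hat, dtype=bool)
        ok_int = np.ones_like(g.y_hat, dtype=bool)
        if "lower" in lim:
            ok &= g.y_hat >= lim["lower"]
            if g.lo is not None:
                ok_int &= g.lo >= lim["lower"]
        if "upper" in lim:
            ok &= g.y_hat <= lim["upper"]
            if g.hi is not None:
                ok_int &= g.hi <= lim["upper"]
        per_pass[name] = ok
        per_pass_interval[name] = ok & ok_int

    all_point = np.logical_and.reduce(list(per_pass.values()))
    all_int = np.logical_and.reduce(list(per_pass_interval.values()))
    if interval_kind in (None, "none"):
        classification = np.where(all_point, 2, 0)
    else:
        classification = np.where(all_int, 2, np.where(all_point, 1, 0))

    g0 = next(iter(grids.values()))
    return OverlayMap(
        axis_names=tuple(axes),
        axis_coded=g0.axis_coded,
        axis_actual=g0.axis_actual,
        slice_coded=dict(slice_coded or {}),
        per_response_pass=per_pass,
        classification=classification,
        interval_kind=interval_kind,
    )
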