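"""Capability indices and Monte-Carlo MODR construction.

The method-operable design region (MODR) is the part of the knowledge space
where every response meets its specification limits *with assurance*: at
each candidate operating point, small random perturbations of the method
parameters (flow rate, % organic, temperature, ...) are simulated, each
model is evaluated through the perturbed settings (optionally adding
response noise at the fit's residual sd), and a process-capability index is
computed per response from the simulated output distribution. The point
belongs to the MODR when all indices meet the threshold (default
Cpk >= 1.33, i.e. specification limits at least 4 simulated standard
deviations from the simulated mean).

A common draw matrix is reused (shifted) at every grid point, so MODR
boundaries are smooth and enlarging the input sigmas can only shrink the
pass set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .desirability import OverlayMap

__all__ = [
    "SpecLimits",
    "RobustnessConfig",
    "MODRMap",
    "capability",
    "monte_carlo_modr",
    "verify_par",
    "check_verification_runs",
]


@dataclass(frozen=True)
class SpecLimits:
    """Edges of failure for one response (at least one of LSL/USL)."""

    response_name: str
    lsl: float | None = None
    usl: float | None = None
    target: float | None = None

    def __post_init__(self):
        if self.lsl is None and self.usl is None:
            raise ValueError(f"{self.response_name}: need at least one specification limit")
        if self.lsl is not None and self.usl is not None and not self.lsl < self.usl:
            raise ValueError(f"{self.response_name}: LSL must be below USL")


def capability(mean: float, sd: float, limits: SpecLimits, index: str = "Cpk") -> float:
    """Process-capability index from a mean, sd, and specification limits.

    Cp = (USL−LSL)/(6σ); Cp,lower = (x̄−LSL)/(3σ); Cp,upper = (USL−x̄)/(3σ);
    Cpk = min of the applicable one-sided indices; Cpm = (USL−LSL) /
    (6·sqrt(σ² + (x̄−T)²)); Cpkm = Cpk / sqrt(1 + ((x̄−T)/σ)²).

    sd = 0 with a compliant mean returns +inf (infinite capability);
    a non-compliant mean returns −inf.
    """
    if sd < 0:
        raise ValueError("sd must be nonnegative")
    lsl, usl, target = limits.lsl, limits.usl, limits.target

    if index in ("Cp", "Cpm") and (lsl is None or usl is None):
        raise ValueError(f"{index} needs both LSL and USL")
    if index in ("Cpm", "Cpkm") and target is None:
        raise ValueError(f"{index} needs a target")

    if sd == 0:
        ok = (lsl is None or mean >= lsl) and (usl is None or mean <= usl)
        return np.inf if ok else -np.inf

    if index == "Cp":
        return (usl - lsl) / (6 * sd)
    one_sided = []
    if lsl is not None:
        one_sided.append((mean - lsl) / (3 * sd))
    if usl is not None:
        one_sided.append((usl - mean) / (3 * sd))
    cpk = min(one_sided)
    if index == "Cpk":
        return cpk
    if index == "Cpm":
        return (usl - lsl) / (6 * np.sqrt(sd**2 + (mean - target) ** 2))
    if index == "Cpkm":
        return cpk / np.sqrt(1 + ((mean - target) / sd) ** 2)
    raise ValueError(f"unknown capability index {index!r}")


@dataclass
class RobustnessConfig:
    """Monte-Carlo settings.

    ``factor_variations`` maps factor names to the maximum expected
    variation in actual units, interpreted as ±3σ (so σ = variation / 3).
    ``response_noise`` adds N(0, s) measurement noise using each fitted
    model's residual sd when available.
    """

    factor_variations: dict
    index: str = "Cpk"
    threshold: float = 1.33
    n_sims: int = 10000
    seed: int | None = None
    response_noise: bool = True

    def __post_init__(self):
        if any(v < 0 for v in self.factor_variations.values()):
            raise ValueError("factor variations must be >= 0")
        if self.n_sims < 100:
            raise ValueError("n_sims must be >= 100")

    def sigma_coded(self, factors) -> np.ndarray:
        """Per-factor simulation sd in coded units."""
        fmap = {f.name: f for f in factors}
        out = []
        for name in (f.name for f in factors):
            var = float(self.factor_variations.get(name, 0.0))
            out.append(var / 3.0 / fmap[name].half_range)
        return np.array(out)


@dataclass
class MODRMap:
    axis_names: tuple
    axis_coded: tuple
    axis_actual: tuple
    slice_coded: dict
    index: str
    threshold: float
    capability_values: dict  # response -> grid of index values
    sim_mean: dict
    sim_sd: dict
    pass_grid: np.ndarray
    extrapolation_fraction: np.ndarray
    warnings: list = field(default_factory=list)

    def to_long_frame(self) -> pd.DataFrame:
        a1, a2 = np.meshgrid(self.axis_actual[0], self.axis_actual[1], indexing="ij")
        data = {
            self.axis_names[0]: a1.ravel(),
            self.axis_names[1]: a2.ravel(),
            "pass": self.pass_grid.ravel(),
        }
        for name, grid in self.capability_values.items():
            data[f"{name}_{self.index}"] = grid.ravel()
        return pd.DataFrame(data)


def monte_carlo_modr(
    models: dict,
    limits: list,
    config: RobustnessConfig,
    axes: tuple,
    resolution: int = 21,
    slice_coded: dict | None = None,
) -> MODRMap:
    """Monte-Carlo MODR over a 2-factor grid (other factors at a fixed slice).

    At each grid point, ``config.n_sims`` perturbed coded settings are drawn
    from N(point, diag(σ²)) with σ from ``factor_variations`` (±3σ in actual
    units), every limited response model is evaluated, optional response
    noise is added, and the configured capability index is computed from the
    simulated mean and sd. The same standard-normal draw matrix is shifted
    to every grid point (common random numbers).
    """
    lim_map = {l.response_name: l for l in limits}
    for name in lim_map:
        if name not in models:
            raise ValueError(f"no model for limited response {name!r}")
    some = next(iter(models.values()))
    if some.factors is None:
        raise ValueError("models must carry factor definitions")
    names = some.spec.factor_names
    factors = some.factors
    sigma = config.sigma_coded(factors)

    rng = np.random.default_rng(config.seed)
    Z = rng.standard_normal((config.n_sims, len(names)))
    noise = {
        name: rng.standard_normal(config.n_sims) for name in lim_map
    }

    grid1 = np.linspace(-1, 1, resolution)
    grid2 = np.linspace(-1, 1, resolution)
    ax_idx = [names.index(a) for a in axes]
    base = np.zeros(len(names))
    for j, n in enumerate(names):
        base[j] = (slice_coded or {}).get(n, 0.0)

    shape = (resolution, resolution)
    cap_grids = {name: np.zeros(shape) for name in lim_map}
    mean_grids = {name: np.zeros(shape) for name in lim_map}
    sd_grids = {name: np.zeros(shape) for name in lim_map}
    pass_grid = np.zeros(shape, dtype=bool)
    extrap = np.zeros(shape)
    warnings: list = []

    for i1, g1 in enumerate(grid1):
        for i2, g2 in enumerate(grid2):
            center = base.copy()
            center[ax_idx[0]] = g1
            center[ax_idx[1]] = g2
            draws = center + Z * sigma
            frac_out = float(np.mean(np.any(np.abs(draws) > 1 + 1e-12, axis=1)))
            extrap[i1, i2] = frac_out
            ok = True
            for name, lim in lim_map.items():
                model = models[name]
                y = model.predict_coded(draws)
                if config.response_noise:
                    s = getattr(model, "s", None)
                    if s is not None and np.isfinite(s):
                        y = y + noise[name] * float(s)
                m = float(np.mean(y))
                sd = float(np.std(y, ddof=1))
                mean_grids[name][i1, i2] = m
                sd_grids[name][i1, i2] = sd
                c = capability(m, sd, lim, config.index)
                cap_grids[name][i1, i2] = c
                if not c >= config.threshold:
                    ok = False
            pass_grid[i1, i2] = ok

    n_warn = int(np.sum(extrap > 0.01))
    if n_warn:
        warnings.append(
            f"{n_warn} grid point(s) have >1% of Monte-Carlo draws outside the coded "
            "knowledge space; capability there relies on model extrapolation"
        )

    fmap = {f.name: f for f in factors}
    return MODRMap(
        axis_names=tuple(axes),
        axis_coded=(grid1, grid2),
        axis_actual=(fmap[axes[0]].decode(grid1), fmap[axes[1]].decode(grid2)),
        slice_coded=dict(slice_coded or {}),
        index=config.index,
        threshold=config.threshold,
        capability_values=cap_grids,
        sim_mean=mean_grids,
        sim_sd=sd_grids,
        pass_grid=pass_grid,
        extrapolation_fraction=extrap,
        warnings=warnings,
    )


@dataclass
class PARVerdict:
    passed: bool
    failing_points: list  # list of (axis1_actual, axis2_actual)
    n_inside: int


def verify_par(modr: MODRMap, par: dict) -> PARVerdict:
    """Check a proven-acceptable-range rectangle against the MODR grid.

    ``par`` maps each MODR axis name to an (low, high) tuple in actual
    units. Passes iff every grid point inside the rectangle passes.
    """
    for name in modr.axis_names:
        if name not in par:
            raise ValueError(f"PAR must bound axis {name!r}")
    (lo1, hi1), (lo2, hi2) = par[modr.axis_names[0]], par[modr.axis_names[1]]
    a1, a2 = modr.axis_actual
    in1 = (a1 >= lo1) & (a1 <= hi1)
    in2 = (a2 >= lo2) & (a2 <= hi2)
    if not (in1.any() and in2.any()):
        raise ValueError("PAR rectangle does not intersect the MODR grid")
    failing = []
    for i1 in np.flatnonzero(in1):
        for i2 in np.flatnonzero(in2):
            if not modr.pass_grid[i1, i2]:
                failing.append((float(a1[i1]), float(a2[i2])))
    n_inside = int(in1.sum() * in2.sum())
    return PARVerdict(passed=not failing, failing_points=failing, n_inside=n_inside)


def check_verification_runs(predicted: dict, experimental: dict) -> pd.DataFrame:
    """Compare verification-run measurements with predicted interval bounds.

    ``predicted`` maps response name to (y_hat, low, high); ``experimental``
    maps response name to the measured value. Bounds are closed: a value
    exactly on a bound is within.
    """
    if set(predicted) != set(experimental):
        missing = set(predicted) ^ set(experimental)
        raise ValueError(f"mismatched response names: {sorted(missing)}")
    rows = []
    for name in predicted:
        y_hat, lo, hi = predicted[name]
        val = experimental[name]
        rows.append((name, val, y_hat, lo, hi, lo <= val <= hi))
    return pd.DataFrame(
        rows, columns=["response", "experimental", "predicted", "low", "high", "within"]
    )


def modr_consistent_with_overlay(modr: MODRMap, overlay_map: OverlayMap) -> bool:
    """True iff the MODR pass set is a subset of the mean-performance pass set."""
    return bool(np.all(~modr.pass_grid | overlay_map.pass_all))
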