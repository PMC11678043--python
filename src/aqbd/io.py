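"""Reading/writing design and response tables, project configuration, and
the end-to-end pipeline runner.

Exchange format: comma-separated, period decimal, UTF-8, mandatory header.
A design+response CSV has a run-id column, one column per factor (actual
units), and one column per response. Configuration (YAML or JSON, same
schema) gathers factor definitions, responses, selection settings, goals,
specification limits, and robustness settings under a single top-level
seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .anova import anova_table, fit_statistics
from .design import DesignMatrix, FactorDefinition
from .desirability import GoalSpec, optimize_desirability, overlay
from .diagnostics import residual_diagnostics
from .model import ModelSpec
from .robustness import RobustnessConfig, SpecLimits, monte_carlo_modr
from .selection import SelectionConfig, select_model

__all__ = [
    "ValidationError",
    "ProjectConfig",
    "read_design_responses",
    "load_config",
    "run_pipeline",
]


class ValidationError(ValueError):
    """Input file or configuration failed validation; message has coordinates."""


def _parse_factors(obj) -> list:
    factors = []
    for f in obj:
        try:
            factors.append(
                FactorDefinition(str(f["name"]), str(f.get("units", "")),
                                 float(f["low"]), float(f["high"]))
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ValidationError(f"bad factor definition {f!r}: {exc}") from exc
    return factors


@dataclass
class ProjectConfig:
    """Validated project configuration driving :func:`run_pipeline`."""

    factors: list
    responses: list
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    goals: list = field(default_factory=list)
    limits: list = field(default_factory=list)
    robustness: RobustnessConfig | None = None
    overlay_axes: tuple | None = None
    grid_resolution: int = 21
    seed: int = 0

    def __post_init__(self):
        names = {f.name for f in self.factors}
        for g in self.goals:
            if g.response_name not in self.responses:
                raise ValidationError(f"goal references unknown response {g.response_name!r}")
        for l in self.limits:
            if l.response_name not in self.responses:
                raise ValidationError(f"limit references unknown response {l.response_name!r}")
        if self.overlay_axes is not None:
            for a in self.overlay_axes:
                if a not in names:
                    raise ValidationError(f"overlay axis {a!r} is not a factor")

    def digest(self) -> str:
        blob = json.dumps(
            {
                "factors": [(f.name, f.units, f.low, f.high) for f in self.factors],
                "responses": self.responses,
                "selection": vars(self.selection),
                "goals": [vars(g) for g in self.goals],
                "limits": [
                    {"response": l.response_name, "lsl": l.lsl, "usl": l.usl, "target": l.target}
                    for l in self.limits
                ],
                "robustness": (
                    {
                        "variations": self.robustness.factor_variations,
                        "index": self.robustness.index,
                        "threshold": self.robustness.threshold,
                        "n_sims": self.robustness.n_sims,
                        "response_noise": self.robustness.response_noise,
                    }
                    if self.robustness
                    else None
                ),
                "axes": self.overlay_axes,
                "resolution": self.grid_resolution,
                "seed": self.seed,
            },
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_config(path) -> ProjectConfig:
    """Load and validate a YAML/JSON project configuration."""
    text = Path(path).read_text(encoding="utf-8")
    obj = yaml.safe_load(text)  # YAML is a superset of JSON
    if not isinstance(obj, dict):
        raise ValidationError(f"{path}: config must be a mapping")
    try:
        factors = _parse_factors(obj["factors"])
        responses = [str(r) for r in obj["responses"]]
    except KeyError as exc:
        raise ValidationError(f"{path}: missing required key {exc}") from exc

    sel = obj.get("selection", {})
    selection = SelectionConfig(
        direction=sel.get("direction", "backward"),
        criterion=sel.get("criterion", "partial_F"),
        f_in=float(sel.get("f_in", 4.0)),
        f_out=float(sel.get("f_out", 4.0)),
        alpha=float(sel.get("alpha", 0.05)),
        enforce_hierarchy=bool(sel.get("enforce_hierarchy", False)),
    )
    goals = [
        GoalSpec(
            response_name=g["response"],
            goal=g["goal"],
            lower=g.get("lower"),
            upper=g.get("upper"),
            target=g.get("target"),
            weight=float(g.get("weight", 1.0)),
        )
        for g in obj.get("goals", [])
    ]
    limits = [
        SpecLimits(
            response_name=l["response"],
            lsl=l.get("lsl"),
            usl=l.get("usl"),
            target=l.get("target"),
        )
        for l in obj.get("limits", [])
    ]
    seed = int(obj.get("seed", 0))
    robustness = None
    if "robustness" in obj:
        r = obj["robustness"]
        robustness = RobustnessConfig(
            factor_variations={str(k): float(v) for k, v in r["factor_variations"].items()},
            index=r.get("index", "Cpk"),
            threshold=float(r.get("threshold", 1.33)),
            n_sims=int(r.get("n_sims", 10000)),
            seed=seed,
            response_noise=bool(r.get("response_noise", True)),
        )
    axes = tuple(obj["overlay_axes"]) if "overlay_axes" in obj else None
    return ProjectConfig(
        factors=factors,
        responses=responses,
        selection=selection,
        goals=goals,
        limits=limits,
        robustness=robustness,
        overlay_axes=axes,
        grid_resolution=int(obj.get("grid_resolution", 21)),
        seed=seed,
    )


def read_design_responses(path, factors: list, responses: list | None = None):
    """Read a design+response CSV into (DesignMatrix, response DataFrame).

    Factor columns hold actual units and are matched by name; coded levels
    and point roles are inferred. Validation errors name the offending
    column/row.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise ValidationError(f"{path}: cannot parse CSV: {exc}") from exc
    for f in factors:
        if f.name not in df.columns:
            raise ValidationError(f"{path}: missing factor column {f.name!r}")
    run_col = next((c for c in ("run_id", "run", "Run") if c in df.columns), None)
    if run_col is not None and df[run_col].duplicated().any():
        dup = df[run_col][df[run_col].duplicated()].tolist()
        raise ValidationError(f"{path}: duplicate run id(s) {dup}")

    if responses is None:
        skip = {f.name for f in factors} | {run_col, "role", "run_order"} | {
            f"{f.name}_coded" for f in factors
        }
        responses = [c for c in df.columns if c not in skip and c is not None]
    for col in [f.name for f in factors] + list(responses):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            row = int(vals.index[vals.isna()][0]) + 2  # 1-based + header
            cell = df[col][vals.isna()].iloc[0]
            hint = ""
            if isinstance(cell, str) and "," in cell:
                hint = " (decimal commas are not supported; use period decimals)"
            raise ValidationError(
                f"{path}: non-numeric value {cell!r} in column {col!r}, line {row}{hint}"
            )
        df[col] = vals

    table = {"run_id": df[run_col].to_numpy() if run_col else np.arange(1, len(df) + 1)}
    coded_cols = {}
    for f in factors:
        coded = f.code(df[f.name].to_numpy())
        coded_cols[f.name] = coded
        table[f"{f.name}_coded"] = coded
        table[f"{f.name}_actual"] = df[f.name].to_numpy()
    coded_arr = np.column_stack(list(coded_cols.values()))
    roles = np.where(
        np.all(np.abs(coded_arr) < 1e-9, axis=1),
        "center",
        np.where(np.sum(np.abs(coded_arr) > 1e-9, axis=1) == 1, "axial", "cube"),
    )
    table["role"] = roles
    table["run_order"] = np.arange(1, len(df) + 1)
    design = DesignMatrix(factors=list(factors), runs=pd.DataFrame(table))
    return design, df[list(responses)].copy()


def run_pipeline(config: ProjectConfig, data_path, out_dir) -> dict:
    """Run fit → select → diagnose → optimize → overlay → MODR end to end.

    Writes per-response coefficient/ANOVA/diagnostics CSVs, selection
    traces, overlay and MODR maps, and a single ``summary.json`` stamped
    with the config digest and seed. Returns the summary dict.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    design, resp = read_design_responses(data_path, config.factors, config.responses)
    factor_names = tuple(f.name for f in config.factors)
    full = ModelSpec.full_quadratic(factor_names)

    summary = {
        "config_digest": config.digest(),
        "seed": config.seed,
        "n_runs": design.n_runs,
        "responses": {},
    }
    fits = {}
    for rname in config.responses:
        y = resp[rname].to_numpy(dtype=float)
        fit, trace = select_model(design, y, full, config.selection)
        fit.response_name = rname
        fits[rname] = fit
        fit.coefficients_table().to_csv(out / f"coefficients_{_slug(rname)}.csv", index=False)
        tab = anova_table(fit, design)
        tab.to_frame().to_csv(out / f"anova_{_slug(rname)}.csv", index=False)
        stats_ = fit_statistics(fit)
        residual_diagnostics(fit).to_csv(out / f"diagnostics_{_slug(rname)}.csv", index=False)
        (out / f"selection_{_slug(rname)}.json").write_text(
            json.dumps(trace.to_json_obj(), indent=1)
        )
        summary["responses"][rname] = {
            "terms": fit.spec.term_names,
            "coefficients": [float(v) for v in fit.b],
            "s": fit.s,
            "r2": stats_.r2,
            "r2_adj": stats_.r2_adj,
            "r2_pred": stats_.r2_pred,
            "f_model": tab.f_model,
            "p_model": tab.p_model,
            "lack_of_fit_f": tab.f_lof,
            "lack_of_fit_testable": tab.lof_testable,
        }

    if config.goals:
        opt = optimize_desirability(fits, config.goals)
        summary["optimum"] = {
            "point_actual": opt.point_actual,
            "point_coded": opt.point_coded,
            "overall_desirability": opt.D,
            "feasible": opt.feasible,
        }

    axes = config.overlay_axes or factor_names[:2]
    if config.limits:
        lim_map = {}
        for l in config.limits:
            d = {}
            if l.lsl is not None:
                d["lower"] = l.lsl
            if l.usl is not None:
                d["upper"] = l.usl
            lim_map[l.response_name] = d
        ov = overlay(fits, lim_map, tuple(axes), resolution=config.grid_resolution)
        ov.to_long_frame().to_csv(out / "overlay.csv", index=False)
        summary["overlay"] = {
            "axes": list(axes),
            "pass_fraction": float(np.mean(ov.pass_all)),
        }

    if config.robustness is not None and config.limits:
        modr = monte_carlo_modr(
            fits, config.limits, config.robustness, tuple(axes),
            resolution=config.grid_resolution,
        )
        modr.to_long_frame().to_csv(out / "modr.csv", index=False)
        summary["modr"] = {
            "axes": list(axes),
            "index": config.robustness.index,
            "threshold": config.robustness.threshold,
            "n_sims": config.robustness.n_sims,
            "pass_fraction": float(np.mean(modr.pass_grid)),
            "warnings": modr.warnings,
        }

    (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    return summary


def _slug(name: str) -> str:
    return "".join(c if c.isalnum() else "_" for c in name)
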