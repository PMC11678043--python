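# aqbd

Analytical quality-by-design (AQbD) data treatment for chromatographic
method development, as an open library and command-line tool.

When an HPLC/UHPLC method is developed under AQbD, the critical method
parameters (CMPs — e.g. flow rate, % organic modifier, column temperature)
are varied in a designed experiment, the critical method attributes (CMAs —
retention factor *k*, tailing factor, resolution *Rs*) are modeled as
response surfaces, and a *method operable design region* (MODR) is derived:
the multivariate region of settings where every CMA meets its specification
*with assurance*, not just on average. Commercial packages (Fusion QbD,
Design-Expert) automate this chain; `aqbd` implements the same data
treatment openly so every number in it can be audited and reproduced.

## What it computes

* **Designs** — face-centered (or user-α) central composite designs with
  coded↔actual transforms and seeded run-order randomization
  (`aqbd.design`).
* **Models** — quadratic response-surface fits by QR-based ordinary least
  squares in coded units,
  `y = β₀ + Σᵢβᵢxᵢ + Σᵢ<ⱼβᵢⱼxᵢxⱼ + Σᵢβᵢᵢxᵢ² + ε`, with standard errors,
  t-based CIs and p-values (`aqbd.model`).
* **ANOVA** — regression-significance F-test, lack-of-fit vs. pure-error
  F-test from replicate groups, R², adjusted R², and PRESS-based predicted
  R² (`aqbd.anova`).
* **Selection** — forward/backward/stepwise term selection under partial-F
  (F-to-remove, default 4), p-value, AICc or BIC criteria, with optional
  model hierarchy, reproducing both major software behaviors
  (`aqbd.selection`).
* **Diagnostics** — studentized residuals, leverage, Cook's distance,
  DFFITS, and the data series behind the standard residual plots
  (`aqbd.diagnostics`).
* **Prediction** — point predictions, confidence/prediction/tolerance
  intervals, first-order propagation of error, and response-surface grids
  (`aqbd.prediction`).
* **Multi-response optimization** — Derringer–Suich desirabilities, overall
  desirability `D = (d₁d₂…dₙ)^{1/n}`, and interval-aware overlay
  (graphical) optimization (`aqbd.desirability`).
* **MODR** — Monte-Carlo simulation of CMP variation through the fitted
  models with process-capability indices (Cp, Cpk, Cpm, Cpkm); the MODR is
  the region with all indices ≥ 1.33, with PAR-rectangle verification and
  verification-run checking (`aqbd.robustness`).

A complete worked example — a published three-curcuminoid UHPLC separation
optimized over flow rate (0.6–1.0 mL/min), % acetonitrile (50–70%) and
temperature (25–50 °C), with eight response models — ships as the
`curcuminoid` fixture (`aqbd.fixtures`), together with a synthetic-response
generator for simulation studies.

## Worked example

Predict the BMC retention factor at the study's verification point
(0.825 mL/min, 55% acetonitrile, 35 °C):

```sh
$ aqbd predict --response "k BMC" --at "0.825,55,35"
{
 "response": "k BMC",
 "point_actual": {"A": 0.825, "B": 55.0, "C": 35.0},
 "point_coded": {"A": 0.125, "B": -0.5, "C": -0.2},
 "y_hat": 3.6471,
 "extrapolated": false
}
```

The point is coded with centers (0.8, 60, 37.5) and half-ranges
(0.2, 10, 12.5); the reduced quadratic `k = 2.13 − 2.22·B − 0.518·C +
0.435·BC + 1.04·B²` then gives k ≈ 3.65, in line with the study's reported
prediction of 3.64 and its measured verification value of 3.49.

The same models drive the robustness maps. At the verification flow slice
(A = 0.125 coded), thresholding the eight mean response surfaces at their
limits (k ≥ 2, tailing ≤ 1.2, Rs ≥ 2) against a Monte-Carlo Cpk ≥ 1.33
requirement (input variation ±0.024 mL/min, ±1.5%, ±1.5 °C as ±3σ):

```text
mean-performance pass fraction: 0.526
MODR (Cpk>=1.33) pass fraction: 0.420
```

The capability-based MODR is strictly smaller than the mean-performance
region: settings that are acceptable *on average* near an edge of failure
are excluded once realistic input variation is simulated through the
models.

In Python the same example is three lines:

```python
from aqbd import load_fixture, predict
fx = load_fixture("curcuminoid")
print(predict(fx.models["k BMC"], fx.verification_point_actual).y_hat)  # 3.6471
```

## CLI

`aqbd design | fit | select | predict | optimize | overlay | modr |
fixtures | pipeline` — see `aqbd --help`. `pipeline` runs the whole chain
from a YAML/JSON config plus a design+response CSV and writes coefficient,
ANOVA, diagnostics, overlay and MODR tables with a seed-stamped
`summary.json`.

See `docs/methods.md` for the statistical methods, defaults, and known
limitations.
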