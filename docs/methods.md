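# Methods

## Model and assumptions

All modeling is second-order polynomial regression in coded factor units,

y = β₀ + Σᵢ βᵢxᵢ + Σᵢ<ⱼ βᵢⱼxᵢxⱼ + Σᵢ βᵢᵢxᵢ² + ε,  ε ~ i.i.d. N(0, σ²),

over the knowledge space, the coded cube [−1, 1]ᵏ spanned by a central
composite design. Coding is the affine map coded = (actual − center)/half-range;
`decode` is computed as low + (coded + 1)·half-range so the −1/0/+1 design
levels are reproduced exactly in floating point. All inference (standard
errors, CIs, F-tests, intervals) assumes this model form with homoscedastic
Gaussian error; no response transformation is applied.

Fitting uses an economy QR factorization rather than the normal equations;
(XᵀX)⁻¹ is formed from R⁻¹ only for standard errors and interval
quadratic forms. Rank is checked by SVD: singular values below 1e−10 of
the largest raise a singular-design error naming the aliased terms.
Default confidence level is 95% (α = 0.05) throughout.

## ANOVA and lack of fit

The corrected total SS splits into regression and residual; the residual
further into lack of fit and pure error using replicate groups, detected
by coded-level equality within 1e−9 (value-based, so imported tables
without role labels still work; in a CCD the groups are the replicated
center points, giving df_PE = n_c − 1). When replicates are absent or
numerically identical the lack-of-fit test is flagged "not testable"
rather than failing. When MS_PE is more than 100× smaller than MS_r the
report carries an advisory: a pure error estimated from repeated
injections of one solution (instead of independently prepared replicates)
understates experimental error and inflates the lack-of-fit F, a common
reading error in DOE practice.

PRESS uses the leave-one-out identity e₍₋ᵢ₎ = eᵢ/(1 − hᵢ); runs with
leverage 1 are excluded from PRESS with a per-run flag. Predicted
R² = 1 − PRESS/SS_T.

## Stepwise selection

Partial F for a candidate removal/addition is the extra-SS ratio with the
*full* (larger) model's residual mean square as denominator, so a
single-term partial F equals the squared t statistic of that coefficient.
Defaults mirror the two commercial behaviors:

* `SelectionConfig.fusion_preset()` — backward, partial-F, F-to-remove 4,
  no hierarchy;
* `SelectionConfig.design_expert_preset()` — backward, p-value at
  α = 0.05, hierarchy on (main effects are retained whenever a surviving
  interaction or quadratic contains them).

F_in ≥ F_out is enforced to prevent add/remove cycling. An F threshold and
a p-value threshold are deliberately independent knobs: F = 4 corresponds
to α = P(F(1, df) > 4), which is near but not equal to 0.05 at small df.
Ties in the step criterion are broken deterministically by dropping the
highest-order term first (quadratics, then interactions, then mains).
AICc/BIC use the Gaussian likelihood at the ML variance SSr/n with all
constants kept, so values are comparable only across models on the same
data; the AICc correction 2p(p+1)/(n−p−1) requires n − p − 1 ≥ 1.

A caution on what selection can deliver: with any fixed stay-threshold,
each spurious candidate term survives backward elimination with the null
probability P(F(1, df) > F_out) (~5–7% at F_out = 4), *independent of the
noise scale*, so the probability of recovering a generating term set
exactly is bounded by (1 − p_null)^(#spurious) (~70–77% here), however
strong the signal. The test suite therefore asserts what the method
guarantees — generating terms are retained, and exact recovery occurs in
the majority of replicates — rather than near-certain exact recovery.

## Diagnostics

Internally studentized residuals use s·√(1 − hᵢ); externally studentized
use the delete-one variance. Cook's distance is rᵢ²hᵢ/(p(1 − hᵢ)) with p
the parameter count *including* the intercept, the textbook convention
(the equivalent DFFITS conversion Dᵢ = DFFITSᵢ²·(s₍₋ᵢ₎²/s²)/p is asserted
numerically in the tests). Flags: |r| > 2 (95%) and |r| > 3 (99.7%)
for outliers, hᵢ > 2p/n for leverage (the alternative (p+1)/n threshold is
available via argument), Dᵢ > 1 for influence. Outliers are only flagged,
never removed: a high-leverage, high-D run can be perfectly well described
by the model and deleting it discards the most informative corner of the
design. Normal-probability plotting positions are Blom's
(i − 0.375)/(n + 0.25). An interpolating fit (s ≈ 0) has no residual scale
to studentize against; its residual plot series are reported as zeros.

## Intervals

At an expanded point vector x₀ with h₀ = x₀ᵀ(XᵀX)⁻¹x₀:

* CI: ŷ ± t(1−α/2, n−p)·s·√h₀ (mean response);
* PI: ŷ ± t(1−α/2, n−p)·s·√(1 + h₀) (one future observation);
* TI: ŷ ± s·[t(1−α/2, n−p)·√h₀ + z((1+P)/2)·√((n−p)/χ²(α, n−p))] — an
  approximate two-sided regression tolerance interval covering a
  proportion P of future observations with confidence 1 − α, composed of
  the design-dependent mean-uncertainty term and a χ²-inflated normal
  population term. It is intentionally conservative (TI ⊇ PI at P ≥ 0.90);
  the empirical-coverage test on the prediction interval is the
  quantitative arbiter of the interval machinery.

Published coefficient-only models carry no variance information and raise
on interval requests rather than inventing one; they support mean
prediction and propagation of error only.

Propagation of error is first-order: sd² = Σᵢ (∂ŷ/∂actualᵢ)²σᵢ² (+ s²
optionally), with analytic polynomial gradients chained through the coding
map. For quadratic models this is accurate for small input sigmas (the
tests verify 5% agreement with Monte-Carlo at coded σ = 0.05) and degrades
as curvature × σ² grows.

## Desirability and overlay

Derringer–Suich ramps (linear, optional weight exponent; `in_range` is an
indicator) and the geometric-mean overall desirability. Maximize/minimize
goals require an explicit second anchor (the ramp needs two ends); when a
published study states only one bound, the model's own extremum over the
knowledge space is a reasonable anchor and is what the CLI uses.
Optimization is a deterministic full-grid search (default 51 per axis)
with a shrinking coordinate polish — three-factor quadratics are cheap to
enumerate, and a seedless deterministic optimum is worth more here than a
faster stochastic one.

Overlay classification is per grid point: 2 (point estimate and, if
requested, the relevant interval bound meet every limit), 1 (point passes,
some interval bound fails), 0 (point fails). Lower limits are checked
against interval lower bounds and upper limits against upper bounds.

## Monte-Carlo MODR

At each grid point, n_sims CMP vectors are drawn from N(point, diag σ²)
in coded units, with σ = (max expected variation)/3 per the ±3σ input
convention; every limited response model is evaluated and the chosen
capability index (default Cpk, threshold 1.33) is computed from the
simulated sample mean and sd. Which uncertainty sources the commercial
implementations simulate is not publicly specified, so they are explicit
toggles here: CMP perturbation always; additive response noise at the
fit's residual sd on by default (skipped automatically for coefficient-only
models, which carry no s); coefficient-vector sampling is not simulated.
Cpm and Cpkm use the standard Taguchi forms Cpm = (USL−LSL)/(6√(s²+(x̄−T)²))
and Cpkm = Cpk/√(1+((x̄−T)/s)²). sd = 0 (a degenerate simulation) yields
±∞ capability depending on mean compliance, which makes the
zero-variation MODR coincide exactly with the mean-performance overlay.

One standard-normal draw matrix is generated per map and shifted to every
grid point (common random numbers), so MODR boundaries are smooth and
raising the input sigmas or the threshold provably never grows the pass
set at fixed seed. Grid points where >1% of draws leave the coded cube are
flagged: capability there relies on extrapolating the fitted polynomial.

## Synthetic data

`generate_responses` emulates the assumed data-generating process —
deterministic quadratic truth plus i.i.d. Gaussian error per run — on any
design, seeded. Default noise sd 0.104 matches the residual scale of the
fixture's replicated-design retention-factor ANOVA (√0.0108); for
simulation of the other response families the tests use 0.01 for tailing
factors (≈1% of a typical tailing value, consistent with the width of the
study's reported two-sigma verification bounds) and 0.05 for resolutions.
What this generator does *not* emulate: run-order drift, heteroscedastic
or correlated errors, column aging, or any chromatographic peak-shape
physics. Passing tests therefore demonstrate correctness of the statistics
under the stated model, not robustness of conclusions to violations of it.

## Fixture fidelity

The built-in curcuminoid fixture stores the *published rounded*
coefficients. Evaluating them at the verification point reproduces the
study's reported predictions to within one unit of the last printed
decimal; five of the eight responses round-trip exactly at 2 dp, the BMC
retention factor evaluates to 3.65 against a reported 3.64 (the original
software evidently used unrounded coefficients), and two responses
(tailing CUR, Rs DMC-CUR) evaluate to 1.10/3.25 against reported
1.09/3.26 and are excluded from exact round-trip guarantees. The raw
19-run single-solution response table is shipped verbatim for
transparency but quarantined behind an acknowledge-inconsistency flag: its
center-point spread is orders of magnitude larger than the pure error of
the published replicated-design ANOVA, so no ANOVA value derived from it
is asserted anywhere.

## Problem sizes

Default grids are 51 per axis for surfaces/overlays and 21 for Monte-Carlo
MODR maps with n_sims = 10 000 — enough for visually smooth boundaries on
three-factor problems. The statistical verification suite uses 500
replicates for coverage/recovery simulations, 10⁵ draws for the
capability convergence check, and 11–21-point grids with 1000–5000 draws
for the monotonicity properties; these sizes give Monte-Carlo errors well
inside the asserted tolerances.
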