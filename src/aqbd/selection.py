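"""Stepwise term selection for response-surface models.

Implements the two behaviors common in DOE software: partial-F stepwise
selection with an F-to-add / F-to-remove threshold (default 4), and
p-value selection at a significance level (default 0.05), plus AICc / BIC
criteria. The partial F for removing one term from the current model equals
the squared t statistic of that term's coefficient, so partial-F selection
at threshold F and p-value selection at alpha = P(F(1, df) > F) take
identical single-term steps. An optional hierarchy constraint keeps a main
effect whenever a surviving interaction or quadratic term contains it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .model import FittedModel, ModelSpec, fit_model, term_name

__all__ = [
    "SelectionConfig",
    "SelectionTrace",
    "partial_f",
    "information_criteria",
    "select_model",
]


class NestingError(ValueError):
    """Models passed to partial_f are not nested."""


@dataclass
class SelectionConfig:
    """Knobs for stepwise selection.

    ``direction``: forward, backward, or stepwise (forward with re-testing).
    ``criterion``: partial_F, p_value, aicc, or bic.
    ``f_in`` / ``f_out``: partial-F thresholds to add / remove (require
    f_in >= f_out to prevent add/remove cycling).
    ``enforce_hierarchy``: retain main effects contained in surviving
    higher-order terms.
    """

    direction: str = "backward"
    criterion: str = "partial_F"
    f_in: float = 4.0
    f_out: float = 4.0
    alpha: float = 0.05
    enforce_hierarchy: bool = False

    def __post_init__(self):
        if self.direction not in ("forward", "backward", "stepwise"):
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.criterion not in ("partial_F", "p_value", "aicc", "bic"):
            raise ValueError(f"unknown criterion {self.criterion!r}")
        if self.f_in < self.f_out:
            raise ValueError("f_in must be >= f_out (prevents add/remove cycling)")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")

    @classmethod
    def fusion_preset(cls) -> "SelectionConfig":
        """Backward partial-F elimination at F = 4, no hierarchy."""
        return cls(direction="backward", criterion="partial_F", f_out=4.0,
                   enforce_hierarchy=False)

    @classmethod
    def design_expert_preset(cls) -> "SelectionConfig":
        """Backward p-value elimination at alpha = 0.05 with hierarchy."""
        return cls(direction="backward", criterion="p_value", alpha=0.05,
                   enforce_hierarchy=True)


@dataclass
class SelectionTrace:
    """Audit trail: one (action, term, criterion value) entry per step."""

    steps: list = field(default_factory=list)

    def record(self, action: str, term, value: float, terms_after) -> None:
        self.steps.append(
            {
                "action": action,
                "term": term_name(term),
                "value": float(value),
                "model_terms": [term_name(t) for t in terms_after],
            }
        )

    def to_json_obj(self) -> list:
        return list(self.steps)


def partial_f(fit_full: FittedModel, fit_reduced: FittedModel) -> float:
    """Partial F-ratio for the terms dropped from full to reduced.

    F = (SS_R,full − SS_R,reduced) / Δdf divided by the full model's MS_r.
    For a single dropped term this equals the square of that term's t
    statistic in the full model.
    """
    full_terms = set(fit_full.spec.terms)
    red_terms = set(fit_reduced.spec.terms)
    if not red_terms < full_terms:
        raise NestingError("reduced model's terms must be a strict subset of the full model's")
    if not np.allclose(fit_full.y, fit_reduced.y):
        raise NestingError("models were fitted to different response vectors")
    delta_df = len(full_terms) - len(red_terms)
    # SS_R difference equals the SSr difference with opposite sign (same SS_T)
    num = (fit_reduced.ss_resid - fit_full.ss_resid) / delta_df
    ms_resid = fit_full.ss_resid / fit_full.df_resid
    return float(max(num, 0.0) / ms_resid) if ms_resid > 0 else np.inf


def information_criteria(fit: FittedModel) -> tuple[float, float]:
    """(AICc, BIC) under a Gaussian likelihood at the ML variance SSr/n.

    −2 ln L = n·ln(2π·SSr/n) + n; AICc adds 2p + 2p(p+1)/(n−p−1) counting
    p regression coefficients (the small-sample correction requires
    n − p − 1 >= 1); BIC adds p·ln(n). Values are comparable only across
    models fitted to the same data.
    """
    n, p = fit.n, fit.p
    if n - p - 1 < 1:
        raise ValueError(f"AICc undefined: n − p − 1 = {n - p - 1} < 1")
    ssr = fit.ss_resid
    if ssr <= 0:
        return (-np.inf, -np.inf)
    m2ll = n * np.log(2 * np.pi * ssr / n) + n
    aicc = m2ll + 2 * p + 2 * p * (p + 1) / (n - p - 1)
    bic = m2ll + p * np.log(n)
    return (float(aicc), float(bic))


# Canonical removal preference for ties: quadratics, then interactions, then
# mains (higher-order structure is dropped first); deterministic.
def _tie_rank(term) -> tuple:
    if len(term) == 2 and term[0] == term[1]:
        order = 0
    elif len(term) == 2:
        order = 1
    else:
        order = 2
    return (order, term)


def _protected_terms(spec: ModelSpec) -> set:
    """Main effects required by surviving higher-order terms (hierarchy)."""
    protected = set()
    for t in spec.terms:
        if len(t) >= 2:
            for name in set(t):
                protected.add((name,))
    return protected


def _criterion_value(fit_with, fit_without, config: SelectionConfig, direction: str):
    """Score one candidate move. Returns (score, better_if_lower)."""
    if config.criterion in ("partial_F", "p_value"):
        F = partial_f(fit_with, fit_without)
        if config.criterion == "partial_F":
            return F
        return float(stats.f.sf(F, 1, fit_with.df_resid))
    aicc, bic = information_criteria(fit_with if direction == "forward" else fit_without)
    return aicc if config.criterion == "aicc" else bic


def select_model(design, y, candidate_terms: ModelSpec, config: SelectionConfig | None = None):
    """Stepwise selection over the candidate term set.

    Returns ``(FittedModel, SelectionTrace)``. Backward elimination starts
    from the full candidate model and repeatedly drops the weakest term
    while it fails the stay criterion; forward starts from the intercept
    and adds the strongest term while it passes the entry criterion;
    stepwise is forward with re-testing of included terms after each
    addition. The intercept is never removed.
    """
    if config is None:
        config = SelectionConfig()
    trace = SelectionTrace()

    def fit(spec):
        return fit_ols_cached(design, y, spec)

    cache: dict = {}

    def fit_ols_cached(design_, y_, spec):
        key = spec.terms
        if key not in cache:
            cache[key] = fit_model(design_, y_, spec)
        return cache[key]

    if config.direction == "backward":
        spec = candidate_terms
        spec = _backward(fit, spec, config, trace)
    else:
        spec = ModelSpec(candidate_terms.factor_names, (tuple(),))
        spec = _forward(fit, spec, candidate_terms, config, trace,
                        retest=(config.direction == "stepwise"))

    if config.enforce_hierarchy:
        spec = _restore_hierarchy(fit, spec, candidate_terms, trace)

    return fit(spec), trace


def _removal_candidates(spec: ModelSpec, config: SelectionConfig):
    terms = [t for t in spec.terms if t != ()]
    if config.enforce_hierarchy:
        protected = _protected_terms(spec)
        terms = [t for t in terms if t not in protected]
    return terms


def _should_remove(value, config: SelectionConfig) -> bool:
    if config.criterion == "partial_F":
        return value < config.f_out
    if config.criterion == "p_value":
        return value > config.alpha
    return True  # information criteria: any improving move was already vetted


def _backward(fit, spec, config, trace):
    while True:
        candidates = _removal_candidates(spec, config)
        if not candidates:
            return spec
        full_fit = fit(spec)
        if config.criterion in ("partial_F", "p_value"):
            scored = []
            for t in candidates:
                val = _criterion_value(full_fit, fit(spec.drop(t)), config, "backward")
                scored.append((val, t))
            # weakest term: smallest partial F / largest p; ties drop the
            # higher-order term first (deterministic)
            if config.criterion == "partial_F":
                weakest_val = min(v for v, _ in scored)
                top = [vt for vt in scored if vt[0] == weakest_val]
            else:
                weakest_val = max(v for v, _ in scored)
                top = [vt for vt in scored if vt[0] == weakest_val]
            worst = min(top, key=lambda vt: _tie_rank(vt[1]))
            if not _should_remove(worst[0], config):
                return spec
            spec = spec.drop(worst[1])
            trace.record("remove", worst[1], worst[0], spec.terms)
        else:  # information criterion: drop the term whose removal improves most
            cur = information_criteria(full_fit)[0 if config.criterion == "aicc" else 1]
            scored = [
                (information_criteria(fit(spec.drop(t)))[0 if config.criterion == "aicc" else 1], t)
                for t in candidates
            ]
            best = min(scored, key=lambda vt: (vt[0], _tie_rank(vt[1])))
            if best[0] >= cur:
                return spec
            spec = spec.drop(best[1])
            trace.record("remove", best[1], best[0], spec.terms)


def _forward(fit, spec, candidates_spec, config, trace, retest=False):
    while True:
        remaining = [t for t in candidates_spec.terms if t not in spec.terms]
        if not remaining:
            break
        moved = False
        if config.criterion in ("partial_F", "p_value"):
            scored = []
            for t in remaining:
                bigger = spec.add(t)
                val = _criterion_value(fit(bigger), fit(spec), config, "forward")
                scored.append((val, t))
            if config.criterion == "partial_F":
                best = max(scored, key=lambda vt: (vt[0],))
                top = [vt for vt in scored if vt[0] == best[0]]
                best = max(top, key=lambda vt: _tie_rank(vt[1]))
                enters = best[0] > config.f_in
            else:
                best = min(scored, key=lambda vt: (vt[0], _tie_rank(vt[1])))
                enters = best[0] < config.alpha
            if enters:
                spec = spec.add(best[1])
                trace.record("add", best[1], best[0], spec.terms)
                moved = True
        else:
            cur = information_criteria(fit(spec))[0 if config.criterion == "aicc" else 1]
            scored = [
                (information_criteria(fit(spec.add(t)))[0 if config.criterion == "aicc" else 1], t)
                for t in remaining
            ]
            best = min(scored, key=lambda vt: (vt[0], _tie_rank(vt[1])))
            if best[0] < cur:
                spec = spec.add(best[1])
                trace.record("add", best[1], best[0], spec.terms)
                moved = True
        if moved and retest and config.criterion in ("partial_F", "p_value"):
            spec = _backward(fit, spec, config, trace)
        if not moved:
            break
    return spec


def _restore_hierarchy(fit, spec, candidates_spec, trace):
    changed = True
    while changed:
        changed = False
        for req in sorted(_protected_terms(spec)):
            if req not in spec.terms and req in candidates_spec.terms:
                spec = spec.add(req)
                trace.record("add", req, np.nan, spec.terms)
                changed = True
    return spec
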