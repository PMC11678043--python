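"""Polynomial response-surface models and ordinary least squares fitting.

Models are second-order polynomials in the coded factor levels,

    y = b0 + sum_i b_i x_i + sum_{i<j} b_ij x_i x_j + sum_i b_ii x_i^2 + e,

with i.i.d. Gaussian error. All fitting happens in coded (−1..+1) units;
actual-unit coefficients are a reporting convenience only. The solver uses
a QR factorization rather than the normal equations, with a singular-value
rank check so aliased terms are reported by name instead of producing a
silently unstable fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .design import DesignMatrix, FactorDefinition

__all__ = [
    "Term",
    "ModelSpec",
    "PolynomialModel",
    "FittedModel",
    "SingularDesignError",
    "SaturatedModelError",
    "build_model_matrix",
    "fit_ols",
    "coefficient_significance",
]

# A term is a sorted tuple of factor names: () intercept, ("B",) main effect,
# ("B","C") two-factor interaction, ("B","B") pure quadratic.
Term = tuple


class SingularDesignError(np.linalg.LinAlgError):
    """Model matrix is rank-deficient: some terms are aliased on this design."""


class SaturatedModelError(ValueError):
    """No residual degrees of freedom (n <= p)."""


def term_name(term: Term) -> str:
    if len(term) == 0:
        return "1"
    if len(term) == 2 and term[0] == term[1]:
        return f"{term[0]}^2"
    return "*".join(term)


def parse_term(text: str) -> Term:
    """Parse ``"1"``, ``"B"``, ``"B*C"`` / ``"BC"``-style, or ``"B^2"``."""
    t = text.strip()
    if t in ("1", "intercept", "Intercept"):
        return ()
    if "^2" in t or "**2" in t:
        base = t.replace("**2", "").replace("^2", "").strip()
        return (base, base)
    if "*" in t or ":" in t:
        parts = sorted(p.strip() for p in t.replace(":", "*").split("*"))
        return tuple(parts)
    return (t,)


@dataclass(frozen=True)
class ModelSpec:
    """An ordered polynomial term set over named factors.

    The intercept is always present and always first. Interaction terms are
    stored with their factor names sorted, so ``B*C`` and ``C*B`` are the
    same term.
    """

    factor_names: tuple
    terms: tuple

    def __post_init__(self):
        terms = list(self.terms)
        if () not in terms:
            terms = [()] + terms
        seen = set()
        canon = []
        for t in terms:
            t = tuple(sorted(t))
            for name in t:
                if name not in self.factor_names:
                    raise ValueError(f"term {term_name(t)!r} references unknown factor {name!r}")
            if t in seen:
                raise ValueError(f"duplicate term {term_name(t)!r}")
            seen.add(t)
            canon.append(t)
        object.__setattr__(self, "terms", tuple(canon))
        object.__setattr__(self, "factor_names", tuple(self.factor_names))

    @classmethod
    def from_strings(cls, factor_names, term_texts) -> "ModelSpec":
        return cls(tuple(factor_names), tuple(parse_term(t) for t in term_texts))

    @classmethod
    def full_quadratic(cls, factor_names) -> "ModelSpec":
        names = list(factor_names)
        terms = [()]
        terms += [(n,) for n in names]
        terms += [
            tuple(sorted((names[i], names[j])))
            for i in range(len(names))
            for j in range(i + 1, len(names))
        ]
        terms += [(n, n) for n in names]
        return cls(tuple(names), tuple(terms))

    @property
    def term_names(self) -> list[str]:
        return [term_name(t) for t in self.terms]

    @property
    def p(self) -> int:
        return len(self.terms)

    def drop(self, term: Term) -> "ModelSpec":
        t = tuple(sorted(term))
        if t == ():
            raise ValueError("cannot drop the intercept")
        return ModelSpec(self.factor_names, tuple(x for x in self.terms if x != t))

    def add(self, term: Term) -> "ModelSpec":
        return ModelSpec(self.factor_names, self.terms + (tuple(sorted(term)),))

    def row(self, coded_point) -> np.ndarray:
        """Expanded point vector x0 for one coded point (dict or sequence)."""
        return expand_points(np.atleast_2d(_point_array(coded_point, self.factor_names)), self)[0]


def _point_array(point, factor_names) -> np.ndarray:
    if isinstance(point, dict):
        return np.array([point[n] for n in factor_names], dtype=float)
    return np.asarray(point, dtype=float)


def expand_points(coded: np.ndarray, spec: ModelSpec) -> np.ndarray:
    """Expand an (n, k) coded-level array to the (n, p) model matrix."""
    coded = np.asarray(coded, dtype=float)
    idx = {n: j for j, n in enumerate(spec.factor_names)}
    cols = []
    for t in spec.terms:
        col = np.ones(coded.shape[0])
        for name in t:
            col = col * coded[:, idx[name]]
        cols.append(col)
    return np.column_stack(cols)


def build_model_matrix(design, spec: ModelSpec) -> np.ndarray:
    """Expanded model matrix for a design or a table/array of coded points."""
    if isinstance(design, DesignMatrix):
        coded = design.coded()[list(spec.factor_names)].to_numpy()
    elif isinstance(design, pd.DataFrame):
        missing = [n for n in spec.factor_names if n not in design.columns]
        if missing:
            raise ValueError(f"design table is missing factor column(s) {missing}")
        coded = design[list(spec.factor_names)].to_numpy(dtype=float)
    else:
        coded = np.atleast_2d(np.asarray(design, dtype=float))
    return expand_points(coded, spec)


@dataclass
class PolynomialModel:
    """Coefficients-only model: supports mean prediction and gradients.

    Used for published coefficient sets where the underlying raw data (and
    hence any variance information) is unavailable; interval estimates
    require a :class:`FittedModel`.
    """

    spec: ModelSpec
    b: np.ndarray
    factors: list[FactorDefinition] | None = None
    response_name: str = "y"

    def predict_coded(self, coded) -> np.ndarray:
        X = expand_points(np.atleast_2d(np.asarray(coded, dtype=float)), self.spec)
        return X @ self.b

    def gradient_coded(self, coded_point) -> np.ndarray:
        """Analytic gradient of the polynomial w.r.t. each coded factor."""
        x = _point_array(coded_point, self.spec.factor_names)
        idx = {n: j for j, n in enumerate(self.spec.factor_names)}
        g = np.zeros(len(x))
        for coef, t in zip(self.b, self.spec.terms):
            for pos, name in enumerate(t):
                rest = t[:pos] + t[pos + 1 :]
                val = coef
                for other in rest:
                    val *= x[idx[other]]
                g[idx[name]] += val
        return g


@dataclass
class FittedModel(PolynomialModel):
    """An OLS fit with full inference state.

    Attributes beyond the coefficient vector: standard errors ``se_b``,
    two-sided ``p_b`` and t-based confidence limits ``ci_b`` at level
    1 − alpha, residual standard deviation ``s``, the model matrix ``X``,
    response vector ``y``, leverages (diagonal of the hat matrix) and
    the unscaled coefficient covariance ``xtx_inv`` = (X'X)^-1.
    """

    se_b: np.ndarray = None
    ci_b: np.ndarray = None
    p_b: np.ndarray = None
    s: float = np.nan
    X: np.ndarray = None
    y: np.ndarray = None
    xtx_inv: np.ndarray = None
    leverage: np.ndarray = None
    alpha: float = 0.05
    warnings: list = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def df_resid(self) -> int:
        return self.n - self.p

    @property
    def fitted(self) -> np.ndarray:
        return self.X @ self.b

    @property
    def residuals(self) -> np.ndarray:
        return self.y - self.fitted

    @property
    def ss_resid(self) -> float:
        return float(self.residuals @ self.residuals)

    def hat_matrix(self) -> np.ndarray:
        return self.X @ self.xtx_inv @ self.X.T

    def coefficients_table(self) -> pd.DataFrame:
        """Per-term estimate / SE / CI / p table (coded units)."""
        return pd.DataFrame(
            {
                "term": self.spec.term_names,
                "estimate": self.b,
                "se": self.se_b,
                "ci_low": self.ci_b[:, 0],
                "ci_high": self.ci_b[:, 1],
                "p_value": self.p_b,
            }
        )


_RANK_RTOL = 1e-10


def fit_ols(
    X: np.ndarray,
    y: np.ndarray,
    spec: ModelSpec | None = None,
    alpha: float = 0.05,
    factors: list[FactorDefinition] | None = None,
    response_name: str = "y",
) -> FittedModel:
    """Fit y = X b + e by least squares via QR, with t-based inference.

    Raises
    ------
    SingularDesignError
        If X is rank-deficient (singular values below ``1e-10`` times the
        largest); the message names the aliased columns.
    SaturatedModelError
        If n <= p, leaving no residual degrees of freedom.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.shape[0] != n:
        raise ValueError(f"X has {n} rows but y has {y.shape[0]}")
    if n <= p:
        raise SaturatedModelError(
            f"n = {n} runs cannot support p = {p} parameters with residual df"
        )

    sv = linalg.svdvals(X)
    if sv[-1] < _RANK_RTOL * sv[0]:
        aliased = _aliased_columns(X, spec)
        raise SingularDesignError(f"model matrix is rank deficient; aliased terms: {aliased}")

    Q, R = linalg.qr(X, mode="economic")
    b = linalg.solve_triangular(R, Q.T @ y)
    resid = y - X @ b
    ssr = float(resid @ resid)
    df = n - p
    s2 = ssr / df
    Rinv = linalg.solve_triangular(R, np.eye(p))
    xtx_inv = Rinv @ Rinv.T
    se = np.sqrt(s2 * np.diag(xtx_inv))
    tcrit = stats.t.ppf(1 - alpha / 2, df)
    ci = np.column_stack([b - tcrit * se, b + tcrit * se])
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, b / se, np.inf * np.sign(b))
    pvals = 2 * stats.t.sf(np.abs(tstat), df)
    leverage = np.einsum("ij,ij->i", Q, Q)

    return FittedModel(
        spec=spec if spec is not None else ModelSpec(tuple(), tuple()),
        b=b,
        factors=factors,
        response_name=response_name,
        se_b=se,
        ci_b=ci,
        p_b=pvals,
        s=float(np.sqrt(s2)),
        X=X,
        y=y,
        xtx_inv=xtx_inv,
        leverage=leverage,
        alpha=alpha,
    )


def _aliased_columns(X: np.ndarray, spec: ModelSpec | None) -> list[str]:
    """Name the columns involved in rank deficiency (smallest singular directions)."""
    _, sv, vt = linalg.svd(X, full_matrices=False)
    null = vt[sv < _RANK_RTOL * sv[0]]
    names = spec.term_names if spec is not None else [f"col{j}" for j in range(X.shape[1])]
    involved = sorted({names[j] for row in null for j in np.flatnonzero(np.abs(row) > 1e-6)})
    return involved


def fit_model(design, y, spec: ModelSpec, alpha: float = 0.05, response_name: str = "y"):
    """Convenience: expand the design under ``spec`` and fit."""
    X = build_model_matrix(design, spec)
    factors = design.factors if isinstance(design, DesignMatrix) else None
    return fit_ols(X, y, spec=spec, alpha=alpha, factors=factors, response_name=response_name)


def coefficient_significance(fit: FittedModel, alpha: float | None = None) -> pd.DataFrame:
    """Per-term significance verdicts: a term is non-significant iff its
    t-based confidence interval at level 1 − alpha contains zero (equivalent
    to p > alpha)."""
    if fit.df_resid < 1:
        raise SaturatedModelError("no residual degrees of freedom for inference")
    if alpha is None or alpha == fit.alpha:
        ci = fit.ci_b
    else:
        tcrit = stats.t.ppf(1 - alpha / 2, fit.df_resid)
        ci = np.column_stack([fit.b - tcrit * fit.se_b, fit.b + tcrit * fit.se_b])
    contains_zero = (ci[:, 0] <= 0) & (ci[:, 1] >= 0)
    return pd.DataFrame(
        {
            "term": fit.spec.term_names,
            "estimate": fit.b,
            "ci_low": ci[:, 0],
            "ci_high": ci[:, 1],
            "p_value": fit.p_b,
            "significant": ~contains_zero,
        }
    )
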