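"""ANOVA decomposition, lack-of-fit testing, and the R-squared family.

The corrected total sum of squares is split as SS_T = SS_R + SS_r, and the
residual further into lack-of-fit and pure error, SS_r = SS_LoF + SS_PE,
using replicate groups (runs with identical coded levels — in a CCD,
the replicated center points). Two F-tests follow: regression significance
F = MS_R / MS_r on (p−1, n−p) df, and lack of fit F = MS_LoF / MS_PE on
(m−p, n−m) df where m is the number of distinct design points.

Pure error measures only replicate-to-replicate scatter; when it is very
small relative to the residual mean square (e.g. repeated injections of a
single solution rather than independently prepared replicates), the
lack-of-fit F is inflated and the verdict should be read with caution —
the report carries an advisory flag for that situation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .model import FittedModel

__all__ = ["AnovaTable", "FitStatistics", "anova_table", "fit_statistics"]

_REPLICATE_TOL = 1e-9


@dataclass
class AnovaTable:
    ss_total: float
    ss_model: float
    ss_resid: float
    ss_lof: float
    ss_pe: float
    df_model: int
    df_resid: int
    df_lof: int
    df_pe: int
    f_model: float
    p_model: float
    f_lof: float | None
    p_lof: float | None
    n_distinct_points: int
    lof_testable: bool
    pure_error_advisory: bool = False
    notes: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        """Tabular report: Source / SS / df / MS / F / p."""

        def ms(ss, df):
            return ss / df if df > 0 else np.nan

        rows = [
            ("Model", self.ss_model, self.df_model, ms(self.ss_model, self.df_model),
             self.f_model, self.p_model),
            ("Residual", self.ss_resid, self.df_resid, ms(self.ss_resid, self.df_resid),
             np.nan, np.nan),
            ("Lack of Fit", self.ss_lof, self.df_lof, ms(self.ss_lof, self.df_lof),
             self.f_lof if self.f_lof is not None else np.nan,
             self.p_lof if self.p_lof is not None else np.nan),
            ("Pure Error", self.ss_pe, self.df_pe, ms(self.ss_pe, self.df_pe), np.nan, np.nan),
            ("Cor Total", self.ss_total, self.df_model + self.df_resid, np.nan, np.nan, np.nan),
        ]
        return pd.DataFrame(rows, columns=["source", "SS", "df", "MS", "F", "p"])


@dataclass
class FitStatistics:
    r2: float
    r2_adj: float
    r2_pred: float
    press: float
    excluded_runs: list = field(default_factory=list)


def replicate_groups(coded: np.ndarray, tol: float = _REPLICATE_TOL) -> list[np.ndarray]:
    """Group run indices whose coded levels agree within ``tol``."""
    coded = np.asarray(coded, dtype=float)
    keys = np.round(coded / tol).astype(np.int64) if tol > 0 else coded
    groups: dict = {}
    for i, row in enumerate(map(tuple, keys)):
        groups.setdefault(row, []).append(i)
    return [np.array(v) for v in groups.values()]


def anova_table(fit: FittedModel, design=None) -> AnovaTable:
    """ANOVA with regression and lack-of-fit F-tests.

    ``design`` supplies the coded run levels used to find replicate groups;
    it may be a DesignMatrix, a coded-level DataFrame/array, or None (in
    which case replicate detection falls back to identical model-matrix
    rows, which is equivalent for any model containing all design factors).
    """
    y = fit.y
    n = fit.n
    p = fit.p
    ybar = y.mean()
    ss_total = float(((y - ybar) ** 2).sum())
    ss_resid = fit.ss_resid
    ss_model = ss_total - ss_resid

    if design is None:
        coded = fit.X
    elif hasattr(design, "coded"):
        coded = design.coded().to_numpy()
    elif isinstance(design, pd.DataFrame):
        coded = design.to_numpy(dtype=float)
    else:
        coded = np.asarray(design, dtype=float)

    groups = replicate_groups(coded)
    m = len(groups)
    ss_pe = 0.0
    for g in groups:
        if len(g) > 1:
            ss_pe += float(((y[g] - y[g].mean()) ** 2).sum())
    df_pe = n - m
    df_lof = m - p
    ss_lof = max(ss_resid - ss_pe, 0.0)

    df_model = p - 1
    df_resid = n - p
    ms_model = ss_model / df_model if df_model > 0 else np.nan
    ms_resid = ss_resid / df_resid
    f_model = ms_model / ms_resid if ms_resid > 0 else np.inf
    p_model = float(stats.f.sf(f_model, df_model, df_resid)) if np.isfinite(f_model) else 0.0

    notes = []
    lof_testable = df_pe > 0 and df_lof > 0 and ss_pe > 0
    if df_pe == 0:
        notes.append("no replicate group of size >= 2: pure error has 0 df, lack of fit not testable")
    elif ss_pe == 0:
        notes.append(
            "replicates are numerically identical (pure error = 0): lack of fit not testable"
        )
    if lof_testable:
        ms_lof = ss_lof / df_lof
        ms_pe = ss_pe / df_pe
        f_lof = ms_lof / ms_pe
        p_lof = float(stats.f.sf(f_lof, df_lof, df_pe))
    else:
        f_lof = p_lof = None

    advisory = False
    if df_pe > 0 and ss_pe > 0:
        ms_pe = ss_pe / df_pe
        if ms_pe * 100 < ms_resid:
            advisory = True
            notes.append(
                "pure error mean square is >100x smaller than the residual mean square; "
                "a very small pure error inflates the lack-of-fit F — verify that the "
                "replicates are authentic (independently prepared), not repeated injections"
            )

    return AnovaTable(
        ss_total=ss_total,
        ss_model=ss_model,
        ss_resid=ss_resid,
        ss_lof=ss_lof,
        ss_pe=ss_pe,
        df_model=df_model,
        df_resid=df_resid,
        df_lof=df_lof,
        df_pe=df_pe,
        f_model=float(f_model),
        p_model=p_model,
        f_lof=f_lof,
        p_lof=p_lof,
        n_distinct_points=m,
        lof_testable=lof_testable,
        pure_error_advisory=advisory,
        notes=notes,
    )


def fit_statistics(fit: FittedModel) -> FitStatistics:
    """R², adjusted R², and PRESS-based predicted R².

    PRESS uses the leave-one-out shortcut e_(−i) = e_i / (1 − h_i); runs
    with leverage 1 have no deletion residual and are excluded with a
    warning (listed in ``excluded_runs``).
    """
    y = fit.y
    n, p = fit.n, fit.p
    ss_total = float(((y - y.mean()) ** 2).sum())
    ss_resid = fit.ss_resid
    r2 = 1.0 - ss_resid / ss_total if ss_total > 0 else 1.0
    r2_adj = 1.0 - (ss_resid / (n - p)) / (ss_total / (n - 1)) if ss_total > 0 else 1.0

    h = fit.leverage
    e = fit.residuals
    excluded = [int(i) for i in np.flatnonzero(1 - h < 1e-12)]
    keep = np.setdiff1d(np.arange(n), excluded)
    press = float(np.sum((e[keep] / (1 - h[keep])) ** 2))
    r2_pred = 1.0 - press / ss_total if ss_total > 0 else 1.0
    return FitStatistics(r2=r2, r2_adj=r2_adj, r2_pred=r2_pred, press=press,
                         excluded_runs=excluded)
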