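"""Central composite designs and coded/actual factor transforms.

A face-centered central composite design (FCC-CCD) for k factors consists of
2**k factorial ("cube") points at coded levels ±1, 2k axial points at ±alpha
on one axis (alpha = 1 for face-centered, so axial runs sit on the faces of
the cube at the factors' low/high levels), and replicated center points.
Coding is the affine map coded = (actual − center) / half_range, so the
knowledge space is the coded cube [−1, 1]**k.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FactorDefinition",
    "DesignMatrix",
    "InvalidDesignError",
    "make_ccd",
    "code_levels",
    "decode_levels",
]


class InvalidDesignError(ValueError):
    """Raised when a requested design cannot be constructed."""


@dataclass(frozen=True)
class FactorDefinition:
    """One critical method parameter (CMP) and its experimental range.

    Parameters
    ----------
    name : str
        Factor identifier, e.g. ``"A"`` or ``"flow_rate"``.
    units : str
        Physical units of the actual levels, e.g. ``"mL/min"``.
    low, high : float
        Actual-unit levels mapped to coded −1 and +1.
    """

    name: str
    units: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.low) and np.isfinite(self.high)):
            raise ValueError(f"factor {self.name!r}: bounds must be finite")
        if not self.high > self.low:
            raise ValueError(
                f"factor {self.name!r}: high ({self.high}) must exceed low ({self.low})"
            )

    @property
    def center(self) -> float:
        return 0.5 * (self.low + self.high)

    @property
    def half_range(self) -> float:
        return 0.5 * (self.high - self.low)

    def code(self, actual):
        """Map actual units to coded units (−1 at low, 0 at center, +1 at high)."""
        return (np.asarray(actual, dtype=float) - self.center) / self.half_range

    def decode(self, coded):
        """Inverse of :meth:`code` (exact at the −1/0/+1 design levels)."""
        return self.low + (np.asarray(coded, dtype=float) + 1.0) * self.half_range


def code_levels(actual, factor: FactorDefinition):
    """Functional alias for :meth:`FactorDefinition.code`."""
    return factor.code(actual)


def decode_levels(coded, factor: FactorDefinition):
    """Functional alias for :meth:`FactorDefinition.decode`."""
    return factor.decode(coded)


@dataclass
class DesignMatrix:
    """A run table plus the factor definitions that code it.

    ``runs`` has one row per experiment with columns ``run_id``, ``role``
    (cube / axial / center), ``<name>_coded`` and ``<name>_actual`` per
    factor, and ``run_order`` (the randomized execution position). Rows are
    kept in canonical construction order; sort by ``run_order`` to obtain
    the execution sequence.
    """

    factors: list[FactorDefinition]
    runs: pd.DataFrame
    alpha: float = 1.0
    seed: int | None = None
    warnings: list[str] = field(default_factory=list)

    @property
    def factor_names(self) -> list[str]:
        return [f.name for f in self.factors]

    def coded(self) -> pd.DataFrame:
        """Coded-level columns only, named by factor."""
        cols = {f.name: self.runs[f"{f.name}_coded"].to_numpy() for f in self.factors}
        return pd.DataFrame(cols, index=self.runs.index)

    def actual(self) -> pd.DataFrame:
        cols = {f.name: self.runs[f"{f.name}_actual"].to_numpy() for f in self.factors}
        return pd.DataFrame(cols, index=self.runs.index)

    @property
    def n_runs(self) -> int:
        return len(self.runs)

    def to_csv(self, path) -> None:
        self.runs.to_csv(path, index=False)


def make_ccd(
    factors: list[FactorDefinition],
    alpha: float | str = "face_centered",
    n_center: int = 5,
    seed: int | None = None,
) -> DesignMatrix:
    """Build a central composite design.

    Parameters
    ----------
    factors : list of FactorDefinition
        The k >= 2 factors under study.
    alpha : float or "face_centered"
        Axial distance in coded units. ``"face_centered"`` sets alpha = 1 so
        axial runs coincide with the factors' low/high actual levels.
    n_center : int
        Number of replicated center points. At least 2 are needed for a pure
        error estimate (a warning is recorded otherwise).
    seed : int, optional
        Seed for the run-order randomization. The randomization is a pure
        permutation stored in ``run_order``; the canonical row order
        (cube, axial, center) is preserved.

    Returns
    -------
    DesignMatrix
        2**k + 2k + n_center runs with point roles labeled.
    """
    k = len(factors)
    if k < 2:
        raise InvalidDesignError(f"a CCD needs at least 2 factors, got {k}")
    if n_center < 1:
        raise InvalidDesignError("n_center must be >= 1")
    if alpha == "face_centered":
        a = 1.0
    else:
        a = float(alpha)
        if not (np.isfinite(a) and a > 0):
            raise InvalidDesignError(f"alpha must be positive and finite, got {alpha!r}")

    warnings: list[str] = []
    if n_center < 2:
        warnings.append(
            "n_center < 2: no replicated center points, lack-of-fit will not be testable"
        )

    rows = []
    for levels in itertools.product((-1.0, 1.0), repeat=k):
        rows.append(("cube", levels))
    for i in range(k):
        for sgn in (-1.0, 1.0):
            levels = [0.0] * k
            levels[i] = sgn * a
            rows.append(("axial", tuple(levels)))
    for _ in range(n_center):
        rows.append(("center", (0.0,) * k))

    n = len(rows)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)

    table = {"run_id": np.arange(1, n + 1), "role": [r[0] for r in rows]}
    for j, f in enumerate(factors):
        coded = np.array([r[1][j] for r in rows])
        table[f"{f.name}_coded"] = coded
        table[f"{f.name}_actual"] = f.decode(coded)
    table["run_order"] = order + 1

    return DesignMatrix(
        factors=list(factors),
        runs=pd.DataFrame(table),
        alpha=a,
        seed=seed,
        warnings=warnings,
    )
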