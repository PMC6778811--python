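"""Time-covariable bases for random regression: normalized Legendre
polynomials and B-splines on the day grid.

Days are mapped onto the standardized interval [-1, 1] (Legendre) or used
directly on [t_min, t_max] (B-splines).  The Legendre design is built as
``Phi = M @ Lambda`` where M is the Vandermonde matrix of the standardized
time covariate and Lambda holds the polynomial coefficients, scaled so the
columns are orthonormal under the continuous inner product on [-1, 1]
(P̄_j = sqrt((2j+1)/2) P_j).  B-splines use equidistant knots and the
Cox-de Boor recursion with the right endpoint closed, giving a partition of
unity on the whole day range and K = s + d - 1 basis functions for s knots
of degree d.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial import legendre as npleg

__all__ = [
    "BasisSpec",
    "BasisMatrix",
    "standardize_time",
    "legendre_basis",
    "bspline_basis",
    "n_coefficients",
    "build_basis",
]


@dataclass(frozen=True)
class BasisSpec:
    family: str  # "legendre" | "bspline"
    degree: int = 1
    n_knots: int | None = None  # bspline only (s)
    t_min: float = 1.0
    t_max: float = 20.0

    def __post_init__(self):
        if self.family not in ("legendre", "bspline"):
            raise ValueError(f"unknown basis family {self.family!r}")
        if self.degree < 0:
            raise ValueError("degree must be >= 0")
        if self.t_min >= self.t_max:
            raise ValueError("t_min must be < t_max")
        if self.family == "bspline":
            if self.n_knots is None or self.n_knots < 2:
                raise ValueError("bspline basis needs n_knots >= 2")
            if self.n_knots + self.degree - 1 < 1:
                raise ValueError("K = s + d - 1 must be >= 1")

    @property
    def K(self) -> int:
        return n_coefficients(self)

    @property
    def knots(self) -> np.ndarray | None:
        """Equidistant interior+boundary knot sites (bspline only)."""
        if self.family != "bspline":
            return None
        return np.linspace(self.t_min, self.t_max, self.n_knots)


@dataclass(frozen=True)
class BasisMatrix:
    """Covariable matrix Phi with one row per evaluation day."""

    Phi: np.ndarray
    days: np.ndarray
    spec: BasisSpec
    M: np.ndarray | None = None  # Legendre: powers of standardized time
    Lambda: np.ndarray | None = None  # Legendre: polynomial coefficients

    def __post_init__(self):
        Phi = np.asarray(self.Phi, dtype=float)
        if not np.isfinite(Phi).all():
            raise ValueError("non-finite basis values")
        if Phi.shape[1] != self.spec.K:
            raise ValueError(f"Phi has {Phi.shape[1]} columns, spec K = {self.spec.K}")
        object.__setattr__(self, "Phi", Phi)
        object.__setattr__(self, "days", np.asarray(self.days, dtype=float))

    @property
    def K(self) -> int:
        return self.Phi.shape[1]

    def row(self, day: float) -> np.ndarray:
        """Covariable row for a given day (must lie on the stored grid)."""
        idx = np.where(np.isclose(self.days, day))[0]
        if idx.size == 0:
            raise KeyError(f"day {day} not on the basis grid")
        return self.Phi[idx[0]]


def standardize_time(t, t_min: float = 1.0, t_max: float = 20.0):
    """Map day t in [t_min, t_max] linearly onto [-1, 1]."""
    t = np.asarray(t, dtype=float)
    if t_min >= t_max:
        raise ValueError("t_min must be < t_max")
    if np.any(t < t_min) or np.any(t > t_max):
        raise ValueError(f"day outside [{t_min}, {t_max}]: no extrapolation")
    x = -1.0 + 2.0 * (t - t_min) / (t_max - t_min)
    return x if x.ndim else float(x)


def legendre_basis(
    days, d: int = 1, t_min: float = 1.0, t_max: float = 20.0
) -> BasisMatrix:
    """Normalized Legendre design Phi = M @ Lambda at the standardized days.

    Column j holds P̄_j(x) = sqrt((2j+1)/2) P_j(x), j = 0..d, so K = d + 1.
    """
    spec = BasisSpec("legendre", degree=d, t_min=t_min, t_max=t_max)
    days = np.atleast_1d(np.asarray(days, dtype=float))
    x = np.atleast_1d(standardize_time(days, t_min, t_max))
    M = np.vander(x, d + 1, increasing=True)
    Lam = np.zeros((d + 1, d + 1))
    for j in range(d + 1):
        e = np.zeros(j + 1)
        e[j] = 1.0
        coef = npleg.leg2poly(e)  # monomial coefficients of P_j
        Lam[: j + 1, j] = coef * np.sqrt((2 * j + 1) / 2.0)
    Phi = M @ Lam
    return BasisMatrix(Phi, days, spec, M=M, Lambda=Lam)


def _cox_de_boor(t: np.ndarray, knots: np.ndarray, d: int) -> np.ndarray:
    """Evaluate all degree-d B-splines on an extended knot vector.

    Zero-degree splines are half-open interval indicators; the last interval
    is closed so the basis sums to one at the right endpoint.  0/0 terms in
    the recursion are taken as 0 (repeated boundary knots).
    """
    n_basis = knots.size - d - 1
    t = np.asarray(t, dtype=float)
    last = knots[-1]
    B = np.zeros((t.size, knots.size - 1))
    for i in range(knots.size - 1):
        lo, hi = knots[i], knots[i + 1]
        if hi == last:
            B[:, i] = (t >= lo) & (t <= hi)
        else:
            B[:, i] = (t >= lo) & (t < hi)
    # a closed right end would double-count where repeated end knots give
    # zero-width intervals; keep only the last nonzero-width indicator
    for i in range(knots.size - 2, 0, -1):
        if knots[i] == last:
            B[:, i] = 0.0
    for deg in range(1, d + 1):
        Bn = np.zeros((t.size, knots.size - 1 - deg))
        for i in range(knots.size - 1 - deg):
            left_den = knots[i + deg] - knots[i]
            right_den = knots[i + deg + 1] - knots[i + 1]
            term = np.zeros(t.size)
            if left_den > 0:
                term += (t - knots[i]) / left_den * B[:, i]
            if right_den > 0:
                term += (knots[i + deg + 1] - t) / right_den * B[:, i + 1]
            Bn[:, i] = term
        B = Bn
    assert B.shape[1] == n_basis
    return B


def bspline_basis(
    days, s: int, d: int = 1, t_min: float = 1.0, t_max: float = 20.0
) -> BasisMatrix:
    """B-spline design on s equidistant knots spanning [t_min, t_max].

    Boundary knots are repeated d extra times for the recursion, giving
    K = s + d - 1 basis functions.
    """
    spec = BasisSpec("bspline", degree=d, n_knots=s, t_min=t_min, t_max=t_max)
    days = np.atleast_1d(np.asarray(days, dtype=float))
    if np.any(days < t_min) or np.any(days > t_max):
        raise ValueError(f"day outside [{t_min}, {t_max}]: no extrapolation")
    base = spec.knots
    if np.unique(base).size != base.size:
        raise ValueError("coincident knots")
    ext = np.concatenate([np.full(d, base[0]), base, np.full(d, base[-1])])
    Phi = _cox_de_boor(days, ext, d)
    return BasisMatrix(Phi, days, spec)


def n_coefficients(spec: BasisSpec) -> int:
    """Number of regression coefficients K: d+1 (Legendre), s+d-1 (B-spline)."""
    if spec.family == "legendre":
        return spec.degree + 1
    return spec.n_knots + spec.degree - 1


def build_basis(spec: BasisSpec, days) -> BasisMatrix:
    """Evaluate the basis described by ``spec`` on a day grid."""
    if spec.family == "legendre":
        return legendre_basis(days, spec.degree, spec.t_min, spec.t_max)
    return bspline_basis(days, spec.n_knots, spec.degree, spec.t_min, spec.t_max)
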