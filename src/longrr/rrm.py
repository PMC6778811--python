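"""Genomic random regression model (RRM) fitted by EM-REML.

The model for the adjusted phenotype of accession i on day t is

    y_it = phi_t' beta + phi_t' u_i + phi_t' pe_i + e_it

with phi_t a row of the basis matrix Phi, u the additive-genetic and pe the
permanent-environment regression coefficients, and heterogeneous residual
variances per day.  Jointly,

    y = X beta + Z u + Q pe + e,
    Var(u) = G (x) Cu,   Var(pe) = I (x) Cpe,   Var(e) = R = diag(sigma2_t),

where G is the genomic relationship matrix and Cu, Cpe are K x K covariance
functions among basis coefficients.  Estimation runs expectation-maximization
REML on the mixed-model equations: each iteration solves the MME at the
current variance components and replaces (Cu, Cpe, sigma2) by their
conditional expectations, which keeps every update positive (semi-)definite
and the restricted log-likelihood non-decreasing.

The implied genetic covariance between days is Phi Cu Phi'; genetic values at
any day inside the modelled window are Phi_t u_i, which is what makes the
model usable for forecasting days without phenotypes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg as sla

from .basis import BasisMatrix, BasisSpec, build_basis
from .genotypes import GenomicRelationship
from .phenotypes import BlueTable

__all__ = [
    "RRMData",
    "VarianceComponents",
    "RRMFit",
    "assemble",
    "reml_fit",
    "reml_loglik",
    "count_parameters",
    "information_criteria",
    "genetic_trajectory",
    "genetic_covariance_over_time",
]

_LOG2PI = np.log(2.0 * np.pi)


@dataclass(frozen=True)
class VarianceComponents:
    Cu: np.ndarray  # K x K additive-genetic covariance function
    Cpe: np.ndarray  # K x K permanent-environment covariance function
    sigma2_eps: np.ndarray  # residual variance per day on the basis grid

    def __post_init__(self):
        Cu = np.atleast_2d(np.asarray(self.Cu, dtype=float))
        Cpe = np.atleast_2d(np.asarray(self.Cpe, dtype=float))
        s2 = np.atleast_1d(np.asarray(self.sigma2_eps, dtype=float))
        for name, C in (("Cu", Cu), ("Cpe", Cpe)):
            if not np.allclose(C, C.T, atol=1e-8):
                raise ValueError(f"{name} must be symmetric")
        if (s2 <= 0).any():
            raise ValueError("residual variances must be strictly positive")
        object.__setattr__(self, "Cu", Cu)
        object.__setattr__(self, "Cpe", Cpe)
        object.__setattr__(self, "sigma2_eps", s2)


@dataclass(frozen=True)
class RRMData:
    """Observations plus the implicit design of the random regression model.

    X, Z and Q are never materialised: every observation r carries its
    accession index and its row of Phi, which is all the mixed-model
    equations need.
    """

    y: np.ndarray  # stacked observations, accession-major day-minor
    acc_idx: np.ndarray  # observation -> accession index
    day_idx: np.ndarray  # observation -> row of phi.Phi
    phi: BasisMatrix
    G: GenomicRelationship
    accession_ids: np.ndarray

    @property
    def n_accessions(self) -> int:
        return self.accession_ids.size

    @property
    def n_obs(self) -> int:
        return self.y.size

    @property
    def K(self) -> int:
        return self.phi.K


@dataclass(frozen=True)
class RRMFit:
    beta: np.ndarray  # fixed regression (population mean trajectory)
    u: np.ndarray  # K x n genetic coefficients (BLUP)
    pe: np.ndarray | None  # K x n permanent-environment coefficients
    vc: VarianceComponents
    logL: float
    p: int
    n_obs: int
    rank_X: int
    half_aic: float
    half_bic: float
    converged: bool
    n_iter: int
    logL_path: np.ndarray
    data: RRMData

    @property
    def accession_ids(self) -> np.ndarray:
        return self.data.accession_ids


def assemble(blues: BlueTable, phi: BasisMatrix, G: GenomicRelationship) -> RRMData:
    """Stack a BLUE table into observation vectors aligned with Phi and G.

    The accession sets of the BLUE table and of G must coincide; G is
    reordered to the BLUE table's accession order.  Days of the table must
    lie on the basis grid, but each accession may contribute any subset of
    days (missing accession-days are simply absent rows).
    """
    blue_acc = list(blues.accession_ids)
    g_acc = list(G.accession_ids)
    if set(blue_acc) != set(g_acc):
        diff = set(blue_acc) ^ set(g_acc)
        raise ValueError(f"accession mismatch between BLUEs and G: {sorted(diff)[:10]}")
    order = [g_acc.index(a) for a in blue_acc]
    G = G.subset(np.asarray(order))

    day_map = {}
    for j, d in enumerate(phi.days):
        day_map[float(d)] = j
    ys, accs, dids = [], [], []
    vals = blues.values
    for i, acc in enumerate(blue_acc):
        for d in vals.columns:
            v = vals.at[acc, d]
            if np.isnan(v):
                continue
            key = float(d)
            if key not in day_map:
                raise ValueError(f"day {d} not on the basis grid")
            ys.append(v)
            accs.append(i)
            dids.append(day_map[key])
    return RRMData(
        np.asarray(ys, float),
        np.asarray(accs, int),
        np.asarray(dids, int),
        phi,
        G,
        np.asarray(blue_acc),
    )


def count_parameters(spec: BasisSpec, t_max: int = 20) -> int:
    """Variance parameters: two unstructured K x K covariance functions plus
    one residual variance per day, p = 2 * K(K+1)/2 + t_max."""
    K = spec.K
    return K * (K + 1) + int(t_max)


def information_criteria(
    logL: float, p: int, n_obs: int, rank_X: int
) -> tuple[float, float]:
    """(-1/2 AIC, -1/2 BIC): logL - p and logL - p/2 * ln(n_obs - rank_X)."""
    if n_obs <= rank_X:
        raise ValueError("n_obs must exceed rank_X")
    half_aic = logL - p
    half_bic = logL - 0.5 * p * np.log(n_obs - rank_X)
    return half_aic, half_bic


def _default_init(data: RRMData) -> VarianceComponents:
    """Overdispersed, scale-aware starting values.

    Half the phenotypic variance is assigned to each of the genetic and
    permanent-environment terms (isotropic in coefficient space, scaled by
    the mean squared basis-row norm so the implied day-wise variance is on
    the right scale) and half of the day-wise variance to the residual.
    """
    y, K = data.y, data.K
    used = np.unique(data.day_idx)
    # within-day variance is the relevant phenotypic scale; the pooled
    # variance of y would also count the mean-curve spread across days
    day_vars = []
    s2 = np.full(data.phi.days.size, np.nan)
    for t in used:
        yt = y[data.day_idx == t]
        v = float(np.var(yt)) if yt.size > 1 else 0.0
        day_vars.append(v)
        s2[t] = 0.5 * v if v > 0 else 1.0
    vy = float(np.mean([v for v in day_vars if v > 0]) or 1.0)
    s2[np.isnan(s2)] = 0.5 * vy
    rownorm = float(np.mean(np.sum(data.phi.Phi[used] ** 2, axis=1))) or 1.0
    alpha = 0.5 * vy / rownorm
    return VarianceComponents(alpha * np.eye(K), alpha * np.eye(K), s2)


class _MMEWork:
    """One evaluation of the mixed-model equations at fixed components."""

    def __init__(self, data: RRMData, vc: VarianceComponents, include_pe: bool,
                 Ginv: np.ndarray, logdetG: float):
        n, K = data.n_accessions, data.K
        phi_obs = data.phi.Phi[data.day_idx]  # n_obs x K
        w = 1.0 / vc.sigma2_eps[data.day_idx]
        wphi = phi_obs * w[:, None]

        # per-accession weighted cross-products D_i = sum_t w_t phi_t phi_t'
        D = np.zeros((n, K, K))
        np.add.at(D, data.acc_idx, wphi[:, :, None] * phi_obs[:, None, :])
        b = np.zeros((n, K))
        np.add.at(b, data.acc_idx, wphi * data.y[:, None])
        S = D.sum(axis=0)  # X'R^-1 X
        bX = b.sum(axis=0)

        Cuinv, logdetCu = _pd_inv(vc.Cu, "Cu")
        GC = np.kron(Ginv, Cuinv)

        nblk = 2 if include_pe else 1
        dim = K + nblk * n * K
        C = np.zeros((dim, dim))
        rhs = np.zeros(dim)
        C[:K, :K] = S
        rhs[:K] = bX
        Drow = D.transpose(1, 0, 2).reshape(K, n * K)
        u0 = K
        C[:K, u0:u0 + n * K] = Drow
        C[u0:u0 + n * K, :K] = Drow.T
        Dblock = np.zeros((n * K, n * K))
        for i in range(n):
            Dblock[i * K:(i + 1) * K, i * K:(i + 1) * K] = D[i]
        C[u0:u0 + n * K, u0:u0 + n * K] = Dblock + GC
        rhs[u0:u0 + n * K] = b.reshape(-1)
        logdet_prior = K * logdetG + n * logdetCu
        if include_pe:
            Cpeinv, logdetCpe = _pd_inv(vc.Cpe, "Cpe")
            p0 = K + n * K
            C[:K, p0:] = Drow
            C[p0:, :K] = Drow.T
            C[u0:u0 + n * K, p0:] = Dblock
            C[p0:, u0:u0 + n * K] = Dblock
            C[p0:, p0:] = Dblock + np.kron(np.eye(n), Cpeinv)
            rhs[p0:] = b.reshape(-1)
            logdet_prior += n * logdetCpe

        self.logdetC, self.theta, self.Cinv = _chol_solve_inv(C, rhs)
        ypy = float(np.dot(w * data.y, data.y) - self.theta @ rhs)

        rank_X = int(np.linalg.matrix_rank(data.phi.Phi[np.unique(data.day_idx)]))
        nu = data.n_obs - rank_X
        logdetR = float(np.sum(np.log(vc.sigma2_eps[data.day_idx])))
        # error-contrast likelihood with the |X'X| normalization, so logL is
        # invariant to how the fixed-effect basis is scaled
        XtX = phi_obs.T @ phi_obs
        logdetXtX = float(np.linalg.slogdet(XtX)[1])
        self.logL = -0.5 * (
            nu * _LOG2PI + logdetR + logdet_prior + self.logdetC + ypy - logdetXtX
        )
        self.rank_X = rank_X
        self.include_pe = include_pe
        self.n, self.K = n, K
        self.beta = self.theta[:K]
        self.U = self.theta[K:K + n * K].reshape(n, K).T
        self.P = (
            self.theta[K + n * K:].reshape(n, K).T if include_pe else None
        )
        self._data = data
        self._phi_obs = phi_obs
        self._vc = vc

    def em_update(self, Ginv: np.ndarray) -> VarianceComponents:
        data, n, K = self._data, self.n, self.K
        Cinv, U = self.Cinv, self.U
        u0 = K
        Cuu = Cinv[u0:u0 + n * K, u0:u0 + n * K].reshape(n, K, n, K)
        T_u = np.einsum("ij,ikjl->kl", Ginv, Cuu)
        Cu_new = (U @ Ginv @ U.T + T_u) / n
        Cu_new = (Cu_new + Cu_new.T) / 2

        if self.include_pe:
            p0 = K + n * K
            Cpp = Cinv[p0:, p0:].reshape(n, K, n, K)
            T_pe = np.einsum("ikil->kl", Cpp)
            Cpe_new = (self.P @ self.P.T + T_pe) / n
            Cpe_new = (Cpe_new + Cpe_new.T) / 2
        else:
            Cpe_new = self._vc.Cpe

        # residuals and prediction-error variance per observation; the row of
        # [X Z Q] for observation r repeats phi_r in each participating
        # block, so w_r' Cinv w_r collapses to phi_r' M_i phi_r with M_i the
        # sum of the relevant K x K blocks of Cinv.
        fitted = self._phi_obs @ self.beta + np.einsum(
            "rk,kr->r", self._phi_obs, U[:, data.acc_idx]
        )
        if self.include_pe:
            fitted += np.einsum("rk,kr->r", self._phi_obs, self.P[:, data.acc_idx])
        resid = data.y - fitted

        M = np.empty((n, K, K))
        for i in range(n):
            ui = slice(u0 + i * K, u0 + (i + 1) * K)
            Mi = (
                Cinv[:K, :K]
                + Cinv[:K, ui] + Cinv[ui, :K]
                + Cinv[ui, ui]
            )
            if self.include_pe:
                p0 = K + n * K
                pi = slice(p0 + i * K, p0 + (i + 1) * K)
                Mi = (
                    Mi
                    + Cinv[:K, pi] + Cinv[pi, :K]
                    + Cinv[ui, pi] + Cinv[pi, ui]
                    + Cinv[pi, pi]
                )
            M[i] = Mi
        pev = np.einsum("rk,rkl,rl->r", self._phi_obs, M[data.acc_idx], self._phi_obs)

        s2_new = self._vc.sigma2_eps.copy()
        contrib = resid ** 2 + pev
        for t in np.unique(data.day_idx):
            sel = data.day_idx == t
            s2_new[t] = float(contrib[sel].sum() / sel.sum())
        return VarianceComponents(Cu_new, Cpe_new, np.maximum(s2_new, 1e-12))


def _chol_solve_inv(C: np.ndarray, rhs: np.ndarray):
    """Cholesky-based log-determinant, solve and full symmetric inverse.

    Uses LAPACK potrf/potrs/potri so the inverse costs one dim^3/3 pass
    instead of a triangular solve against the identity.
    """
    L, info = sla.lapack.dpotrf(C, lower=1)
    if info != 0:
        raise np.linalg.LinAlgError(
            "mixed-model equations numerically singular; increase the G ridge"
        )
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    theta, info = sla.lapack.dpotrs(L, rhs, lower=1)
    inv, info = sla.lapack.dpotri(L, lower=1)
    inv = np.tril(inv) + np.tril(inv, -1).T
    return logdet, theta, inv


def _pd_inv(C: np.ndarray, name: str) -> tuple[np.ndarray, float]:
    """Inverse and log-determinant of a (near-)PD covariance matrix.

    EM iterates can reach the PD boundary; a tiny relative jitter keeps the
    inverse defined without materially changing the objective.
    """
    C = np.atleast_2d(C)
    jitter = 0.0
    scale = max(np.trace(C) / C.shape[0], 1e-12)
    for _ in range(6):
        try:
            cf = sla.cho_factor(C + jitter * np.eye(C.shape[0]), lower=True)
            logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
            return sla.cho_solve(cf, np.eye(C.shape[0])), logdet
        except sla.LinAlgError:
            jitter = scale * 1e-10 if jitter == 0 else jitter * 100
    raise np.linalg.LinAlgError(f"{name} is numerically singular")


def reml_loglik(
    data: RRMData, vc: VarianceComponents, include_pe: bool = True
) -> float:
    """Restricted log-likelihood at fixed variance components (MME path)."""
    Ginv, logdetG = _pd_inv(data.G.G, "G")
    return _MMEWork(data, vc, include_pe, Ginv, logdetG).logL


def reml_fit(
    data: RRMData,
    init: VarianceComponents | None = None,
    max_iter: int = 500,
    tol: float = 1e-6,
    param_tol: float = 1e-4,
    include_pe: bool = True,
    t_max: int | None = None,
) -> RRMFit:
    """EM-REML fit of the random regression model.

    Iterates mixed-model-equation solves and conditional-expectation updates
    of (Cu, Cpe, sigma2) until the log-likelihood change drops below ``tol``
    and the largest relative parameter change below ``param_tol``, or
    ``max_iter`` is reached (then a warning is raised and the fit returned
    with ``converged=False``).
    """
    vc = init if init is not None else _default_init(data)
    Ginv, logdetG = _pd_inv(data.G.G, "G")
    logs = []
    converged = False
    work = None
    used_days = np.unique(data.day_idx)
    for it in range(max_iter):
        work = _MMEWork(data, vc, include_pe, Ginv, logdetG)
        logs.append(work.logL)
        vc_new = work.em_update(Ginv)
        dlog = np.inf if it == 0 else logs[-1] - logs[-2]
        dpar = _max_rel_change(vc, vc_new, used_days)
        vc = vc_new
        if it > 0 and abs(dlog) < tol and dpar < param_tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"EM-REML did not meet the convergence criteria in {max_iter} "
            "iterations; returning the last iterate",
            stacklevel=2,
        )
    # final solve at the converged components
    work = _MMEWork(data, vc, include_pe, Ginv, logdetG)
    logs.append(work.logL)
    tm = t_max if t_max is not None else data.phi.days.size
    p = count_parameters(data.phi.spec, tm)
    half_aic, half_bic = information_criteria(work.logL, p, data.n_obs, work.rank_X)
    return RRMFit(
        beta=work.beta,
        u=work.U,
        pe=work.P,
        vc=vc,
        logL=work.logL,
        p=p,
        n_obs=data.n_obs,
        rank_X=work.rank_X,
        half_aic=half_aic,
        half_bic=half_bic,
        converged=converged,
        n_iter=len(logs),
        logL_path=np.asarray(logs),
        data=data,
    )


def _max_rel_change(
    old: VarianceComponents, new: VarianceComponents, used_days: np.ndarray
) -> float:
    def rel(a, b):
        denom = max(np.max(np.abs(a)), 1e-12)
        return float(np.max(np.abs(b - a)) / denom)

    return max(
        rel(old.Cu, new.Cu),
        rel(old.Cpe, new.Cpe),
        rel(old.sigma2_eps[used_days], new.sigma2_eps[used_days]),
    )


def genetic_trajectory(fit: RRMFit, accession, days=None) -> np.ndarray:
    """Genetic values g_it = Phi_t u_i at the requested days.

    Days may include time points without phenotypes; they must lie inside
    the basis window (no extrapolation beyond [t_min, t_max]).
    """
    ids = list(fit.accession_ids)
    if accession not in ids:
        raise KeyError(f"unknown accession {accession!r}")
    i = ids.index(accession)
    phi = fit.data.phi
    if days is None:
        Phi = phi.Phi
    else:
        Phi = build_basis(phi.spec, np.atleast_1d(days)).Phi
    return Phi @ fit.u[:, i]


def genetic_covariance_over_time(
    vc: VarianceComponents, phi: BasisMatrix, which: str = "genetic"
) -> np.ndarray:
    """Day x day covariance implied by the coefficient covariance: Phi C Phi'."""
    C = vc.Cu if which == "genetic" else vc.Cpe
    out = phi.Phi @ C @ phi.Phi.T
    return (out + out.T) / 2
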