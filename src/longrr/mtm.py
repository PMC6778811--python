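"""Multi-trait GBLUP baseline: each day is a separate trait.

    y = X beta + Z u + e,   Var(u) = G (x) Sigma_u,   Var(e) = I (x) Sigma_e,

with unstructured t x t genetic (Sigma_u) and residual (Sigma_e) covariance
matrices and a per-day intercept as the only fixed effect (phenotypes enter
pre-adjusted).  Fitted by the same EM-REML scheme as the random regression
module.  With an unstructured 20 x 20 Sigma the model is close to
unidentifiable at a few hundred lines, so it is intended - and certified by
the test suite - for modest numbers of days.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg as sla

from .genotypes import GenomicRelationship
from .phenotypes import BlueTable
from .rrm import _pd_inv, _LOG2PI

__all__ = ["MTMFit", "mtm_fit", "mtm_predict_newlines"]


@dataclass(frozen=True)
class MTMFit:
    Sigma_u: np.ndarray  # t x t genetic covariance across days
    Sigma_eps: np.ndarray  # t x t residual covariance
    mu: np.ndarray  # per-day intercept
    u_hat: np.ndarray  # accession x t BLUP genetic values
    logL: float
    converged: bool
    n_iter: int
    logL_path: np.ndarray
    accession_ids: np.ndarray
    days: np.ndarray


def mtm_fit(
    blues: BlueTable,
    G: GenomicRelationship,
    max_iter: int = 500,
    tol: float = 1e-6,
    init: tuple[np.ndarray, np.ndarray] | None = None,
) -> MTMFit:
    """EM-REML fit of the multi-trait model on a complete accession x day table."""
    blue_acc = list(blues.accession_ids)
    g_acc = list(G.accession_ids)
    if set(blue_acc) != set(g_acc):
        diff = set(blue_acc) ^ set(g_acc)
        raise ValueError(f"accession mismatch between BLUEs and G: {sorted(diff)[:10]}")
    G = G.subset(np.asarray([g_acc.index(a) for a in blue_acc]))

    Y = blues.to_array()  # n x t
    n, t = Y.shape
    Ginv, logdetG = _pd_inv(G.G, "G")

    if init is None:
        S = np.cov(Y.T) if t > 1 else np.atleast_2d(np.var(Y))
        S = np.atleast_2d(S)
        Su = 0.5 * S + 0.1 * np.mean(np.diag(S)) * np.eye(t)
        Se = 0.5 * np.diag(np.diag(S)) + 0.1 * np.mean(np.diag(S)) * np.eye(t)
    else:
        Su, Se = (np.atleast_2d(np.asarray(m, float)) for m in init)

    logs = []
    converged = False
    stop_next = False
    for it in range(max_iter + 1):
        Seinv, logdetSe = _pd_inv(Se, "Sigma_eps")
        Suinv, logdetSu = _pd_inv(Su, "Sigma_u")

        dim = t + n * t
        C = np.zeros((dim, dim))
        C[:t, :t] = n * Seinv
        for i in range(n):
            blk = slice(t + i * t, t + (i + 1) * t)
            C[:t, blk] = Seinv
            C[blk, :t] = Seinv
        C[t:, t:] = np.kron(np.eye(n), Seinv) + np.kron(Ginv, Suinv)
        rhs = np.zeros(dim)
        rhs[:t] = Seinv @ Y.sum(axis=0)
        rhs[t:] = (Y @ Seinv).reshape(-1)

        try:
            cf = sla.cho_factor(C, lower=True, check_finite=False)
        except sla.LinAlgError:
            if it == 0:
                raise np.linalg.LinAlgError(
                    "mixed-model equations singular at the starting values"
                )
            # degenerate traits can push Sigma_eps onto the PD boundary;
            # stop at the last well-conditioned iterate
            warnings.warn(
                "covariance estimate reached the PD boundary; stopping early",
                stacklevel=2,
            )
            Su, Se = Su_prev, Se_prev
            break
        logdetC = 2.0 * np.sum(np.log(np.diag(cf[0])))
        theta = sla.cho_solve(cf, rhs, check_finite=False)
        Cinv = sla.cho_solve(cf, np.eye(dim), check_finite=False)

        mu = theta[:t]
        U = theta[t:].reshape(n, t)  # accession x t
        ypy = float(np.einsum("it,ts,is->", Y, Seinv, Y) - theta @ rhs)
        # error-contrast likelihood with the |X'X| = |n I_t| normalization,
        # matching the rrm module's convention
        logL = -0.5 * (
            (n * t - t) * _LOG2PI
            + n * logdetSe
            + t * logdetG
            + n * logdetSu
            + logdetC
            + ypy
            - t * np.log(n)
        )
        logs.append(logL)
        if stop_next or it == max_iter:
            break

        Cuu = Cinv[t:, t:].reshape(n, t, n, t)
        T_u = np.einsum("ij,ikjl->kl", Ginv, Cuu)
        Su_new = (U.T @ Ginv @ U + T_u) / n
        Su_new = (Su_new + Su_new.T) / 2

        resid = Y - mu[None, :] - U
        Se_new = resid.T @ resid
        Cbb = Cinv[:t, :t]
        for i in range(n):
            blk = slice(t + i * t, t + (i + 1) * t)
            Se_new += (
                Cbb + Cinv[:t, blk] + Cinv[blk, :t] + Cinv[blk, blk]
            )
        Se_new = (Se_new + Se_new.T) / (2 * n)

        dpar = max(
            np.max(np.abs(Su_new - Su)) / max(np.max(np.abs(Su)), 1e-12),
            np.max(np.abs(Se_new - Se)) / max(np.max(np.abs(Se)), 1e-12),
        )
        dlog = np.inf if it == 0 else logs[-1] - logs[-2]
        Su_prev, Se_prev = Su, Se
        Su, Se = Su_new, Se_new
        if it > 0 and abs(dlog) < tol and dpar < 1e-4:
            # one more pass so the reported logL and BLUPs match the final Sigmas
            converged = True
            stop_next = True
    if not converged:
        warnings.warn(
            f"MTM EM-REML did not converge in {max_iter} iterations; an "
            "unstructured covariance over many days may need far more "
            "iterations or a rank-reduced model",
            stacklevel=2,
        )
    return MTMFit(
        Sigma_u=Su,
        Sigma_eps=Se,
        mu=mu,
        u_hat=U,
        logL=logs[-1],
        converged=converged,
        n_iter=len(logs),
        logL_path=np.asarray(logs),
        accession_ids=np.asarray(blue_acc),
        days=blues.days,
    )


def mtm_predict_newlines(
    fit: MTMFit, G_tst_trn: np.ndarray, G_trn_trn: np.ndarray
) -> np.ndarray:
    """Project training BLUPs onto unphenotyped lines, day by day:
    g_tst,t = G_tst,trn G_trn,trn^-1 g_trn,t."""
    G_tst_trn = np.atleast_2d(np.asarray(G_tst_trn, float))
    G_trn_trn = np.asarray(G_trn_trn, float)
    try:
        cf = sla.cho_factor(G_trn_trn, lower=True)
    except sla.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "singular training-set relationship matrix; add a diagonal ridge"
        ) from exc
    return G_tst_trn @ sla.cho_solve(cf, fit.u_hat)
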