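"""Brute-force oracles kept independent of the library's solver paths."""

import numpy as np


def direct_reml_loglik(data, vc, include_pe=True):
    """REML log-likelihood from the explicit dense covariance matrix.

    Builds V = Z (G x Cu) Z' [+ Q (I x Cpe) Q'] + R observation by
    observation and evaluates the error-contrast restricted likelihood
    -2logL = nu*log(2pi) + log|V| + log|X'V^-1 X| - log|X'X| + y'Py.
    Never touches the mixed-model-equation path.
    """
    Phi = data.phi.Phi
    n = data.n_accessions
    K = Phi.shape[1]
    n_obs = data.n_obs
    X = Phi[data.day_idx]
    Z = np.zeros((n_obs, n * K))
    for r in range(n_obs):
        i = data.acc_idx[r]
        Z[r, i * K:(i + 1) * K] = Phi[data.day_idx[r]]
    V = Z @ np.kron(data.G.G, vc.Cu) @ Z.T + np.diag(vc.sigma2_eps[data.day_idx])
    if include_pe:
        V += Z @ np.kron(np.eye(n), vc.Cpe) @ Z.T
    Vi = np.linalg.inv(V)
    XVX = X.T @ Vi @ X
    P = Vi - Vi @ X @ np.linalg.inv(XVX) @ X.T @ Vi
    _, ldV = np.linalg.slogdet(V)
    _, ldX = np.linalg.slogdet(XVX)
    _, ldXtX = np.linalg.slogdet(X.T @ X)
    nu = n_obs - np.linalg.matrix_rank(X)
    return float(
        -0.5 * (nu * np.log(2 * np.pi) + ldV + ldX - ldXtX + data.y @ P @ data.y)
    )


def random_pd_components(rng, K, t, scale=1.0):
    from longrr.rrm import VarianceComponents

    L1 = rng.standard_normal((K, K)) * scale
    L2 = rng.standard_normal((K, K)) * scale
    return VarianceComponents(
        L1 @ L1.T + 0.1 * scale ** 2 * np.eye(K),
        L2 @ L2.T + 0.1 * scale ** 2 * np.eye(K),
        rng.uniform(0.5, 3.0, t) * scale ** 2,
    )
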