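"""Independent dense-matrix REML oracle for cross-checking the engine.

Everything here is built directly from the record table with dense numpy
linear algebra (explicit Kronecker products, generic optimiser with
numerical gradients) and deliberately shares no code with the package's
block-likelihood implementation.
"""

from __future__ import annotations

import numpy as np
import scipy.optimize as sopt

LOG2PI = np.log(2 * np.pi)


def dense_matrices(data):
    """X, Z, Sigma and y assembled naively from the records."""
    env_ids = data.env_ids
    varieties = data.varieties
    t, m = len(env_ids), len(varieties)
    rec = data.records
    n = len(rec)
    X = np.zeros((n, t))
    Z = np.zeros((n, m * t))
    y = np.zeros(n)
    sig = np.zeros(n)
    for a, row in enumerate(rec.itertuples(index=False)):
        j = env_ids.index(row.env_id)
        i = varieties.index(row.variety)
        X[a, j] = 1.0
        Z[a, j * m + i] = 1.0  # u ordered varieties within environments
        y[a] = row.mean
        sig[a] = 1.0 / row.weight
    return X, Z, np.diag(sig), y


def dense_loglik(data, G):
    """Residual log-likelihood from fully dense matrices."""
    X, Z, Sigma, y = dense_matrices(data)
    m = len(data.varieties)
    H = Z @ np.kron(G, np.eye(m)) @ Z.T + Sigma
    n, t = X.shape
    sign, logdetH = np.linalg.slogdet(H)
    if sign <= 0:
        return -np.inf
    Hi = np.linalg.inv(H)
    A = X.T @ Hi @ X
    signA, logdetA = np.linalg.slogdet(A)
    if signA <= 0:
        return -np.inf
    tau = np.linalg.solve(A, X.T @ Hi @ y)
    e = y - X @ tau
    return -0.5 * ((n - t) * LOG2PI + logdetH + logdetA + e @ Hi @ e)


def _make_G(kind, theta, t, k=1):
    if kind == "DIAG":
        return np.diag(np.exp(theta))
    if kind == "CS":
        return np.exp(theta[0]) * np.ones((t, t)) + np.exp(theta[1]) * np.eye(t)
    if kind == "FA":
        L = theta[: t * k].reshape(t, k)
        return L @ L.T + np.diag(np.exp(theta[t * k:]))
    if kind == "US":
        C = np.zeros((t, t))
        C[np.tril_indices(t)] = theta
        return C @ C.T + 1e-10 * np.eye(t)
    raise ValueError(kind)


def _n_free(kind, t, k=1):
    return {"DIAG": t, "CS": 2, "FA": t * k + t, "US": t * (t + 1) // 2}[kind]


def brute_force_fit(data, kind, k=1, n_restarts=12, seed=0):
    """Generic dense-likelihood optimiser: many random restarts of L-BFGS
    with numerical gradients on an unconstrained parametrisation.

    The FA parametrisation here is fully free (no triangular constraint):
    the maximum of the likelihood is unaffected by the rotation
    indeterminacy, so the maximised value is comparable.
    """
    t = len(data.env_ids)
    rng = np.random.default_rng(seed)
    p = _n_free(kind, t, k)

    def negll(theta):
        ll = dense_loglik(data, _make_G(kind, theta, t, k))
        return 1e12 if not np.isfinite(ll) else -ll

    # scale guess from the data
    s = max(float(np.var(data.records["mean"].to_numpy())), 1e-3)
    best = None
    for r in range(n_restarts):
        if kind == "FA":
            theta0 = np.r_[
                rng.normal(0, np.sqrt(s / 2), t * k), np.log(np.full(t, s / 2)) + rng.normal(0, 0.3, t)
            ]
        elif kind == "US":
            theta0 = np.linalg.cholesky(
                s * ((0.2 + 0.6 * rng.random()) * np.ones((t, t)) + 0.5 * np.eye(t))
            )[np.tril_indices(t)]
        else:
            theta0 = np.log(np.full(p, s / 2)) + rng.normal(0, 0.5, p)
        res = sopt.minimize(negll, theta0, method="L-BFGS-B",
                            options={"maxiter": 2000, "ftol": 1e-13, "gtol": 1e-8})
        if best is None or res.fun < best.fun:
            best = res
    return {"loglik": -best.fun, "G": _make_G(kind, best.x, t, k), "theta": best.x}
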