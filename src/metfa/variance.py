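"""Between-environment genetic variance structures.

The second-stage model places var(u) = G_e (x) I_m on the variety-by-
environment effects, where G_e is a t x t symmetric positive (semi)definite
matrix.  Supported forms:

DIAG   G_e = diag(sigma^2_g1..t)           independent environments
CS     G_e = s2g J_t + s2ge I_t            compound symmetry (variety main
                                           effects + iid V x E interaction)
VC     G_e = s2g J_t + sum_f s2f B_f + s2r I_t
                                           partitioned variance components
                                           (B_f indicator of shared level of
                                           factor f, e.g. region, year)
FA(k)  G_e = Lambda Lambda' + diag(psi)    factor analytic of order k
US     G_e = L L'                          unstructured (Cholesky-param.)

Each structure exposes an unconstrained optimisation parametrisation theta
(variances on the log scale with a small positive floor standing in for
boundary-fixed zeros; loadings free with the upper triangle pinned at zero
for identifiability) and the chain rule from d loglik / d G_e to
d loglik / d theta.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import SpecError

__all__ = ["VarianceModelSpec", "FAParameters", "PeripheralTerm", "VARIANCE_FLOOR"]

#: variances pinned at this floor are treated as "fixed at zero"
VARIANCE_FLOOR = 1e-8
_LOG_FLOOR = np.log(VARIANCE_FLOOR)
_LOG_CEIL = np.log(1e6)


@dataclass(frozen=True)
class PeripheralTerm:
    """An optional iid random non-genetic factor (e.g. a year effect)."""

    factor: str  # environment attribute name: "year", "region", "location"


@dataclass(frozen=True)
class VarianceModelSpec:
    """Specification of the form of G_e (plus optional peripheral terms)."""

    kind: str
    order: int = 0  # FA order k
    partition_factors: tuple[str, ...] = ("region", "year", "region_year")
    peripheral_terms: tuple[PeripheralTerm, ...] = ()

    def __post_init__(self):
        if self.kind not in ("DIAG", "CS", "VC", "FA", "US"):
            raise SpecError(f"unknown variance structure {self.kind!r}")
        if self.kind == "FA" and self.order < 1:
            raise SpecError("FA order must be >= 1")

    # convenience constructors ------------------------------------------------
    @classmethod
    def diag(cls, **kw):
        return cls("DIAG", **kw)

    @classmethod
    def cs(cls, **kw):
        return cls("CS", **kw)

    @classmethod
    def vc(cls, factors=("region", "year", "region_year"), **kw):
        return cls("VC", partition_factors=tuple(factors), **kw)

    @classmethod
    def fa(cls, order: int, **kw):
        return cls("FA", order=order, **kw)

    @classmethod
    def us(cls, **kw):
        return cls("US", **kw)

    def label(self) -> str:
        return f"FA{self.order}" if self.kind == "FA" else self.kind

    def n_params(self, t: int) -> int:
        k = self.order
        base = {
            "DIAG": t,
            "CS": 2,
            "VC": 2 + len(self.partition_factors),
            "FA": t * (k + 1) - k * (k - 1) // 2,
            "US": t * (t + 1) // 2,
        }[self.kind]
        return base + len(self.peripheral_terms)

    def validate_for(self, t: int) -> None:
        if self.kind == "FA" and not (1 <= self.order < t):
            raise SpecError(f"FA order {self.order} must satisfy 1 <= k < t={t}")

    def structure(self, t: int, env_labels: dict[str, np.ndarray] | None = None):
        self.validate_for(t)
        if self.kind == "DIAG":
            return _Diag(t)
        if self.kind == "CS":
            return _CS(t)
        if self.kind == "VC":
            if env_labels is None:
                raise SpecError("VC structure needs environment factor labels")
            blocks = []
            for f in self.partition_factors:
                if f not in env_labels:
                    raise SpecError(f"unknown partition factor {f!r}")
                lab = np.asarray(env_labels[f])
                blocks.append((f, (lab[:, None] == lab[None, :]).astype(float)))
            return _VC(t, blocks)
        if self.kind == "FA":
            return _FA(t, self.order)
        return _US(t)


@dataclass
class FAParameters:
    """Loadings and specific variances of a factor analytic structure.

    During estimation the k(k-1)/2 upper-triangle loadings are fixed at zero;
    ``constraint_mask`` marks those entries.
    """

    loadings: np.ndarray  # (t, k)
    specific_variances: np.ndarray  # (t,)

    @property
    def order(self) -> int:
        return self.loadings.shape[1]

    @property
    def constraint_mask(self) -> np.ndarray:
        t, k = self.loadings.shape
        return np.triu(np.ones((t, k), dtype=bool), 1)

    def G(self) -> np.ndarray:
        L = self.loadings
        return L @ L.T + np.diag(self.specific_variances)


# ---------------------------------------------------------------------------
# structure implementations
#
# Contract: theta is the unconstrained optimisation vector;
#   unpack(theta) -> G_e (t x t)
#   grad(theta, M) -> d loglik / d theta, where d loglik = -1/2 <M, dG>_F
#   params(theta)  -> user-facing parameter object
#   inits(...)     -> list of deterministic starting values


class _Diag:
    name = "DIAG"

    def __init__(self, t):
        self.t = t

    def nfree(self):
        return self.t

    def bounds(self):
        return [(_LOG_FLOOR, _LOG_CEIL)] * self.t

    def unpack(self, theta):
        return np.diag(np.exp(theta))

    def grad(self, theta, M):
        return -0.5 * np.diag(M) * np.exp(theta)

    def dG_stack(self, theta):
        out = np.zeros((self.t, self.t, self.t))
        idx = np.arange(self.t)
        out[idx, idx, idx] = np.exp(theta)
        return out

    def params(self, theta):
        return {"gvar": np.exp(theta)}

    def pack(self, params):
        return np.log(np.maximum(np.asarray(params["gvar"], float), VARIANCE_FLOOR))

    def inits(self, sigma2_diag, rng):
        return [np.log(np.maximum(sigma2_diag, 10 * VARIANCE_FLOOR))]


class _CS:
    name = "CS"

    def __init__(self, t):
        self.t = t

    def nfree(self):
        return 2

    def bounds(self):
        return [(_LOG_FLOOR, _LOG_CEIL)] * 2

    def unpack(self, theta):
        s2g, s2ge = np.exp(theta)
        return s2g * np.ones((self.t, self.t)) + s2ge * np.eye(self.t)

    def grad(self, theta, M):
        s2g, s2ge = np.exp(theta)
        return np.array([-0.5 * M.sum() * s2g, -0.5 * np.trace(M) * s2ge])

    def dG_stack(self, theta):
        s2g, s2ge = np.exp(theta)
        return np.stack([s2g * np.ones((self.t, self.t)), s2ge * np.eye(self.t)])

    def params(self, theta):
        s2g, s2ge = np.exp(theta)
        return {"sigma2_g": s2g, "sigma2_ge": s2ge}

    def pack(self, params):
        return np.log(
            np.maximum([params["sigma2_g"], params["sigma2_ge"]], VARIANCE_FLOOR)
        )

    def inits(self, sigma2_diag, rng):
        s = max(float(np.mean(sigma2_diag)), 10 * VARIANCE_FLOOR)
        return [np.log([s / 2, s / 2]), np.log([0.8 * s, 0.2 * s])]


class _VC:
    name = "VC"

    def __init__(self, t, blocks):
        self.t = t
        self.blocks = blocks  # list of (factor name, t x t indicator)

    def nfree(self):
        return 2 + len(self.blocks)

    def bounds(self):
        return [(_LOG_FLOOR, _LOG_CEIL)] * self.nfree()

    def _patterns(self):
        pats = [np.ones((self.t, self.t))]
        pats += [B for _, B in self.blocks]
        pats.append(np.eye(self.t))
        return pats

    def unpack(self, theta):
        v = np.exp(theta)
        return sum(s * B for s, B in zip(v, self._patterns()))

    def grad(self, theta, M):
        v = np.exp(theta)
        return np.array([-0.5 * np.sum(M * B) * s for s, B in zip(v, self._patterns())])

    def dG_stack(self, theta):
        v = np.exp(theta)
        return np.stack([s * B for s, B in zip(v, self._patterns())])

    def params(self, theta):
        v = np.exp(theta)
        out = {"sigma2_main": v[0]}
        for (f, _), s in zip(self.blocks, v[1:]):
            out[f"sigma2_{f}"] = s
        out["sigma2_resid"] = v[-1]
        return out

    def pack(self, params):
        vals = [params["sigma2_main"]]
        vals += [params[f"sigma2_{f}"] for f, _ in self.blocks]
        vals.append(params["sigma2_resid"])
        return np.log(np.maximum(vals, VARIANCE_FLOOR))

    def inits(self, sigma2_diag, rng):
        s = max(float(np.mean(sigma2_diag)), 10 * VARIANCE_FLOOR)
        p = self.nfree()
        return [np.full(p, np.log(s / p)), np.log(np.r_[0.5 * s, np.full(p - 1, 0.5 * s / (p - 1))])]


class _FA:
    name = "FA"

    def __init__(self, t, k):
        self.t, self.k = t, k
        # free loadings: lambda_{jr} with j >= r (upper triangle of the first
        # k rows fixed at zero for identifiability)
        self.free = np.array([(j, r) for r in range(k) for j in range(t) if j >= r])

    def nfree(self):
        return len(self.free) + self.t

    def nload(self):
        return len(self.free)

    def bounds(self):
        return [(None, None)] * self.nload() + [(_LOG_FLOOR, _LOG_CEIL)] * self.t

    def _lambda(self, theta):
        L = np.zeros((self.t, self.k))
        L[self.free[:, 0], self.free[:, 1]] = theta[: self.nload()]
        return L

    def unpack(self, theta):
        L = self._lambda(theta)
        psi = np.exp(theta[self.nload():])
        return L @ L.T + np.diag(psi)

    def grad(self, theta, M):
        L = self._lambda(theta)
        psi = np.exp(theta[self.nload():])
        gL = -(M @ L)  # d loglik / d Lambda (free entries)
        gpsi = -0.5 * np.diag(M) * psi
        return np.r_[gL[self.free[:, 0], self.free[:, 1]], gpsi]

    def dG_stack(self, theta):
        t = self.t
        L = self._lambda(theta)
        psi = np.exp(theta[self.nload():])
        out = np.zeros((self.nfree(), t, t))
        for a, (j, r) in enumerate(self.free):
            out[a, j, :] += L[:, r]
            out[a, :, j] += L[:, r]
        idx = np.arange(t)
        out[self.nload() + idx, idx, idx] = psi
        return out

    def params(self, theta) -> FAParameters:
        return FAParameters(self._lambda(theta), np.exp(theta[self.nload():]))

    def pack(self, fa: FAParameters):
        L = np.asarray(fa.loadings, float)
        psi = np.maximum(np.asarray(fa.specific_variances, float), VARIANCE_FLOOR)
        return np.r_[L[self.free[:, 0], self.free[:, 1]], np.log(psi)]

    def constrain(self, L: np.ndarray) -> np.ndarray:
        """Rotate an arbitrary loading matrix to the lower-triangular
        identification (zero upper triangle) without changing Lambda Lambda'."""
        # LQ via QR of the transpose of the leading k x k rows' span
        q, _ = np.linalg.qr(L[: self.k].T, mode="complete")
        out = L @ q
        # fix signs so leading diagonal entries are non-negative
        for r in range(self.k):
            if out[r, r] < 0:
                out[:, r] *= -1
        out[np.triu_indices_from(out[: self.k], 1)] = 0.0
        return out

    def inits(self, sigma2_diag, rng):
        """Deterministic restarts from diagonal-fit variances with an
        assumed common inter-environment correlation."""
        s = np.maximum(sigma2_diag, 10 * VARIANCE_FLOOR)
        d = np.sqrt(s)
        starts = []
        for rho in (0.5, 0.8, 0.2):
            G0 = np.outer(d, d) * (rho + (1 - rho) * np.eye(self.t))
            w, V = np.linalg.eigh(G0)
            idx = np.argsort(w)[::-1][: self.k]
            L0 = V[:, idx] * np.sqrt(np.maximum(w[idx], 1e-6))
            L0 = self.constrain(L0)
            psi0 = np.maximum(np.diag(G0) - np.sum(L0**2, axis=1), 0.05 * s)
            starts.append(np.r_[L0[self.free[:, 0], self.free[:, 1]], np.log(psi0)])
        jit = starts[0].copy()
        jit[: self.nload()] *= 1 + 0.1 * rng.standard_normal(self.nload())
        starts.append(jit)
        return starts

    def warm_from(self, fa: FAParameters, sigma2_diag):
        """Start for FA(k) from a fitted FA(k-1): append a small new column."""
        t, k = self.t, self.k
        L = np.zeros((t, k))
        L[:, : fa.order] = fa.loadings
        scale = 0.1 * np.sqrt(np.maximum(np.mean(sigma2_diag), 10 * VARIANCE_FLOOR))
        L[k - 1:, k - 1] = scale
        L = self.constrain(L)
        psi = np.maximum(fa.specific_variances, 10 * VARIANCE_FLOOR)
        return np.r_[L[self.free[:, 0], self.free[:, 1]], np.log(psi)]


class _US:
    name = "US"

    def __init__(self, t):
        self.t = t
        self.rows, self.cols = np.tril_indices(t)
        self.isdiag = self.rows == self.cols

    def nfree(self):
        return len(self.rows)

    def bounds(self):
        return [
            (0.5 * _LOG_FLOOR, 0.5 * _LOG_CEIL) if d else (None, None)
            for d in self.isdiag
        ]

    def _chol(self, theta):
        L = np.zeros((self.t, self.t))
        vals = theta.copy()
        vals[self.isdiag] = np.exp(theta[self.isdiag])
        L[self.rows, self.cols] = vals
        return L

    def unpack(self, theta):
        L = self._chol(theta)
        return L @ L.T

    def grad(self, theta, M):
        L = self._chol(theta)
        W = -(M @ L)  # d loglik / d L
        g = W[self.rows, self.cols].copy()
        g[self.isdiag] *= L[self.rows[self.isdiag], self.cols[self.isdiag]]
        return g

    def dG_stack(self, theta):
        L = self._chol(theta)
        out = np.zeros((self.nfree(), self.t, self.t))
        for a, (j, c, d) in enumerate(zip(self.rows, self.cols, self.isdiag)):
            dl = L[j, c] if d else 1.0  # chain through the log-diagonal
            out[a, j, :] += dl * L[:, c]
            out[a, :, j] += dl * L[:, c]
        return out

    def params(self, theta):
        return {"G": self.unpack(theta)}

    def pack(self, params):
        L = np.linalg.cholesky(
            np.asarray(params["G"], float) + VARIANCE_FLOOR * np.eye(self.t)
        )
        vals = L[self.rows, self.cols].copy()
        vals[self.isdiag] = np.log(np.maximum(vals[self.isdiag], np.sqrt(VARIANCE_FLOOR)))
        return vals

    def inits(self, sigma2_diag, rng):
        s = np.maximum(sigma2_diag, 10 * VARIANCE_FLOOR)
        d = np.sqrt(s)
        starts = []
        for rho in (0.3, 0.7):
            G0 = np.outer(d, d) * (rho + (1 - rho) * np.eye(self.t))
            starts.append(self.pack({"G": G0}))
        return starts
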