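"""REML estimation and EBLUP prediction for the weighted second-stage model.

Model: y = X tau + Z u + (Z_p u_p) + eta, with
  var(u)   = G_e (x) I_m      (between-environment genetic variance, any of
                               the structures in :mod:`metfa.variance`)
  var(eta) = Sigma            (diagonal, reciprocals of the supplied weights;
                               known from the first stage)
  X maps records to trial means; Z maps records to variety-by-environment
  cells ordered as varieties within environments.

Because distinct varieties' effects are independent under G_e (x) I_m and
Sigma is diagonal, the marginal variance H = Z (G_e (x) I_m) Z' + Sigma is
block diagonal by variety.  The residual log-likelihood

  l_R = -1/2 [ (n - t) log 2*pi + log|H| + log|X'H^-1 X| + y'Py ]

is therefore accumulated from per-variety blocks of dimension t_i (the
number of trials the variety was grown in), and its gradient with respect
to G_e has the closed form -1/2 (A - S2 - S3) (see ``_loglik``), which each
structure chains to its own parameters.  Varieties sharing an incidence
pattern are batched through stacked linear algebra.  The additive constant
-(n-t)/2 log 2*pi is included, so values are comparable with any dense
multivariate-normal implementation.

With peripheral (non-genetic) random terms the block structure is lost and
a dense implementation is used instead; this path targets small datasets.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
import scipy.linalg as sla
import scipy.optimize as sopt
import scipy.sparse as sp
from scipy import stats

from .data import METData
from .errors import SpecError, ValidationError
from .variance import FAParameters, VarianceModelSpec

__all__ = [
    "FitControl",
    "FittedModel",
    "build_design",
    "residual_loglik",
    "reml_fit",
    "fa_eblups",
    "component_blups",
    "info_criteria",
    "remlrt",
]

_LOG2PI = np.log(2 * np.pi)


# ---------------------------------------------------------------------------
# design matrices (for interoperability and the dense peripheral path)

def build_design(data: METData):
    """Design matrices (X, Z, Sigma) of the second-stage model.

    X is the n x t trial-mean indicator, Z the sparse n x (m t) incidence of
    variety-by-environment cells (u ordered as varieties within
    environments), Sigma the n x n diagonal of reciprocal weights.
    """
    env_ids = data.env_ids
    varieties = data.varieties
    eidx = {e: i for i, e in enumerate(env_ids)}
    vidx = {v: i for i, v in enumerate(varieties)}
    n, t, m = data.n, data.t, data.m
    rows = np.arange(n)
    ej = np.array([eidx[e] for e in data.records["env_id"]])
    vi = np.array([vidx[v] for v in data.records["variety"]])
    X = np.zeros((n, t))
    X[rows, ej] = 1.0
    Z = sp.csr_matrix((np.ones(n), (rows, ej * m + vi)), shape=(n, m * t))
    Sigma = np.diag(1.0 / data.records["weight"].to_numpy(float))
    return X, Z, Sigma


# ---------------------------------------------------------------------------
# per-variety block core

class _Core:
    """Precomputed incidence grouping for the block-diagonal likelihood."""

    def __init__(self, data: METData):
        self.env_ids = data.env_ids
        self.varieties = data.varieties
        self.t = data.t
        self.m = data.m
        self.n = data.n
        eidx = {e: i for i, e in enumerate(self.env_ids)}
        vidx = {v: i for i, v in enumerate(self.varieties)}
        rec = data.records
        ej = np.array([eidx[e] for e in rec["env_id"]])
        vi = np.array([vidx[v] for v in rec["variety"]])
        y = rec["mean"].to_numpy(float)
        sig = 1.0 / rec["weight"].to_numpy(float)

        per_var: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = []
        for i in range(self.m):
            sel = np.where(vi == i)[0]
            order = np.argsort(ej[sel])
            sel = sel[order]
            per_var.append((ej[sel], y[sel], sig[sel]))

        patterns: dict[tuple, list[int]] = {}
        for i, (J, _, _) in enumerate(per_var):
            patterns.setdefault(tuple(J), []).append(i)
        self.groups = []
        for J, members in patterns.items():
            Ja = np.array(J, dtype=int)
            Y = np.stack([per_var[i][1] for i in members])
            S = np.stack([per_var[i][2] for i in members])
            self.groups.append({"J": Ja, "vids": np.array(members), "Y": Y, "S": S})

        # moment starting values for the per-environment genetic variances
        s2 = np.zeros(self.t)
        for j in range(self.t):
            sel = ej == j
            yy, ss = y[sel], sig[sel]
            v = np.var(yy, ddof=1) if sel.sum() > 1 else 0.0
            s2[j] = max(v - ss.mean(), 0.05 * max(v, 1e-4))
        self.sigma2_moment = s2

    # -- likelihood --------------------------------------------------------
    def loglik(self, G: np.ndarray, want_grad: bool = False, want_cache: bool = False):
        t, n = self.t, self.n
        A = np.zeros((t, t))
        b = np.zeros(t)
        q = 0.0
        logdetH = 0.0
        cache = []
        for grp in self.groups:
            J, Y, S = grp["J"], grp["Y"], grp["S"]
            g, ti = Y.shape
            H = np.broadcast_to(G[np.ix_(J, J)], (g, ti, ti)).copy()
            H[:, np.arange(ti), np.arange(ti)] += S
            sign, ld = np.linalg.slogdet(H)
            if np.any(sign <= 0) or not np.all(np.isfinite(ld)):
                return None
            Hinv = np.linalg.inv(H)
            logdetH += float(ld.sum())
            A[np.ix_(J, J)] += Hinv.sum(axis=0)
            r0 = np.einsum("gij,gj->gi", Hinv, Y)
            b[J] += r0.sum(axis=0)
            q += float(np.einsum("gi,gi->", r0, Y))
            cache.append((grp, Hinv, r0))
        try:
            cA, low = sla.cho_factor(A)
        except np.linalg.LinAlgError:
            return None
        logdetA = 2.0 * float(np.sum(np.log(np.diag(cA))))
        tau = sla.cho_solve((cA, low), b)
        yPy = q - float(b @ tau)
        ll = -0.5 * ((n - t) * _LOG2PI + logdetH + logdetA + yPy)

        out: dict[str, Any] = {"ll": ll, "tau": tau, "A": A}
        if want_grad or want_cache:
            Ainv = sla.cho_solve((cA, low), np.eye(t))
            out["Ainv"] = Ainv
            if want_grad:
                S2 = np.zeros((t, t))
                S3 = np.zeros((t, t))
                for grp, Hinv, r0 in cache:
                    J = grp["J"]
                    R = r0 - np.einsum("gij,j->gi", Hinv, tau[J])
                    S3[np.ix_(J, J)] += np.einsum("gi,gj->ij", R, R)
                    S2[np.ix_(J, J)] += np.einsum(
                        "gab,bc,gcd->ad", Hinv, Ainv[np.ix_(J, J)], Hinv
                    )
                out["M"] = A - S2 - S3
            if want_cache:
                out["cache"] = cache
        return out

    def average_information(self, dG: np.ndarray, res: dict) -> np.ndarray:
        """Average-information matrix 0.5 w_a' P w_b with w_a = dH_a P y,
        accumulated from the per-variety blocks."""
        p = dG.shape[0]
        t = self.t
        tau, Ainv = res["tau"], res["Ainv"]
        AI = np.zeros((p, p))
        U = np.zeros((p, t))
        for grp, Hinv, r0 in res["cache"]:
            J = grp["J"]
            R = r0 - np.einsum("gij,j->gi", Hinv, tau[J])
            dJJ = dG[np.ix_(np.arange(p), J, J)]
            W = np.einsum("pab,gb->gpa", dJJ, R)
            HW = np.einsum("gab,gpb->gpa", Hinv, W)
            AI += np.einsum("gpa,gqa->pq", W, HW)
            U[:, J] += HW.sum(axis=0)
        AI -= U @ Ainv @ U.T
        return 0.5 * AI

    # -- EBLUPs and PEV ------------------------------------------------------
    def eblups(self, G: np.ndarray, fa: FAParameters | None = None):
        """EBLUPs and PEV blocks at the given G_e (and FA parameters).

        Returns per-variety quantities: total effects u~ for every cell
        (observed or not), factor scores f~ and regression residuals d~ for
        FA structures, with prediction error variance blocks from the
        coefficient-matrix inverse (the A^-1 term carries the uncertainty of
        the estimated trial means).
        """
        res = self.loglik(G, want_cache=True)
        if res is None:
            raise ValidationError("G_e proposal is not positive definite")
        t, m = self.t, self.m
        tau, Ainv = res["tau"], res["Ainv"]
        k = fa.order if fa is not None else 0
        Rfull = np.zeros((m, t))
        u = np.zeros((m, t))
        u_blocks = np.zeros((m, t, t))
        f = np.zeros((m, k)) if k else None
        f_blocks = np.zeros((m, k, k)) if k else None
        delta = np.zeros((m, t))
        delta_pev = np.zeros((m, t))
        observed = np.zeros((m, t), dtype=bool)

        for grp, Hinv, r0 in res["cache"]:
            J, vids = grp["J"], grp["vids"]
            R = r0 - np.einsum("gij,j->gi", Hinv, tau[J])
            W = Hinv - np.einsum("gab,bc,gcd->gad", Hinv, Ainv[np.ix_(J, J)], Hinv)
            GJ = G[:, J]  # (t, ti)
            Rfull[np.ix_(vids, J)] = R
            observed[np.ix_(vids, J)] = True
            u[vids] = np.einsum("tj,gj->gt", GJ, R)
            u_blocks[vids] = G - np.einsum("aj,gjl,bl->gab", GJ, W, GJ)
            if fa is not None:
                LJ = fa.loadings[J]  # (ti, k)
                psi = fa.specific_variances
                f[vids] = np.einsum("jr,gj->gr", LJ, R)
                f_blocks[vids] = np.eye(k) - np.einsum("jr,gjl,ls->grs", LJ, W, LJ)
                delta[np.ix_(vids, J)] = psi[J] * R
                dblk = psi[None, J] - (psi[J] ** 2) * np.einsum("gjj->gj", W)
                dpev = np.tile(psi, (len(vids), 1))
                dpev[:, J] = dblk
                delta_pev[vids] = dpev

        out = {
            "tau": tau,
            "tau_cov": Ainv,
            "u": u,
            "u_blocks": u_blocks,
            "u_diag": np.einsum("gtt->gt", u_blocks).copy(),
            "observed": observed,
            "rfull": Rfull,
            "loglik": res["ll"],
        }
        if fa is not None:
            out.update(scores=f, f_blocks=f_blocks, delta=delta, delta_pev=delta_pev)
        return out


# ---------------------------------------------------------------------------
# dense path (peripheral random terms)

class _DenseCore:
    """Dense-matrix likelihood used when peripheral random terms are present."""

    def __init__(self, data: METData, spec: VarianceModelSpec):
        self.data = data
        self.n, self.t, self.m = data.n, data.t, data.m
        self.X, self.Z, _ = build_design(data)
        self.y = data.records["mean"].to_numpy(float)
        self.sig = 1.0 / data.records["weight"].to_numpy(float)
        eidx = {e: i for i, e in enumerate(data.env_ids)}
        vidx = {v: i for i, v in enumerate(data.varieties)}
        self.ej = np.array([eidx[e] for e in data.records["env_id"]])
        self.vi = np.array([vidx[v] for v in data.records["variety"]])
        self.Zp = []
        for term in spec.peripheral_terms:
            attr = data.env_attr(term.factor)
            levels = sorted(attr.unique())
            lidx = {l: i for i, l in enumerate(levels)}
            Zt = np.zeros((self.n, len(levels)))
            lab = np.array([lidx[attr[e]] for e in data.records["env_id"]])
            Zt[np.arange(self.n), lab] = 1.0
            self.Zp.append(Zt)

    def H(self, G, pvars):
        same = self.vi[:, None] == self.vi[None, :]
        H = np.where(same, G[np.ix_(self.ej, self.ej)], 0.0)
        H[np.arange(self.n), np.arange(self.n)] += self.sig
        for s2, Zt in zip(pvars, self.Zp):
            H += s2 * (Zt @ Zt.T)
        return H

    def loglik(self, G, pvars):
        H = self.H(G, pvars)
        try:
            cH = sla.cho_factor(H)
        except np.linalg.LinAlgError:
            return None
        logdetH = 2.0 * float(np.sum(np.log(np.diag(cH[0]))))
        Hiy = sla.cho_solve(cH, self.y)
        HiX = sla.cho_solve(cH, self.X)
        A = self.X.T @ HiX
        cA, low = sla.cho_factor(A)
        logdetA = 2.0 * float(np.sum(np.log(np.diag(cA))))
        tau = sla.cho_solve((cA, low), self.X.T @ Hiy)
        e = self.y - self.X @ tau
        Pe = sla.cho_solve(cH, e)
        yPy = float(e @ Pe)
        ll = -0.5 * ((self.n - self.t) * _LOG2PI + logdetH + logdetA + yPy)
        return {"ll": ll, "tau": tau, "A": A, "cH": cH, "Pe": Pe}


# ---------------------------------------------------------------------------
# fitted model container

@dataclass
class FitControl:
    """Optimiser settings (quasi-Newton on the unconstrained parametrisation)."""

    max_iter: int = 500
    gtol: float = 1e-5
    ftol: float = 1e-10
    extra_restarts: int = 0
    max_starts: int | None = None  # cap on the number of starting points
    seed: int = 0


@dataclass
class FittedModel:
    """A converged (or diagnosed) REML fit with EBLUPs and PEV blocks."""

    spec: VarianceModelSpec
    env_ids: list[str]
    varieties: list[str]
    params: Any  # FAParameters or dict of variance components
    G: pd.DataFrame  # estimated G_e, env x env
    tau: pd.Series
    tau_se: pd.Series
    residual_loglik: float
    n_params: int
    converged: bool
    n_iter: int
    n: int
    m: int
    t: int
    u_blup: pd.DataFrame  # m x t totals u~ (all cells)
    observed: pd.DataFrame  # m x t booleans
    pev: dict = field(default_factory=dict)  # u_blocks, u_diag, f_blocks, ...
    scores: pd.DataFrame | None = None  # m x k (FA only)
    delta: pd.DataFrame | None = None  # m x t (FA only)
    peripheral: dict = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)
    _core: Any = field(default=None, repr=False)

    @property
    def order(self) -> int:
        return self.spec.order if self.spec.kind == "FA" else 0

    def fa_parameters(self) -> FAParameters:
        if not isinstance(self.params, FAParameters):
            raise SpecError("not a factor analytic fit")
        return self.params

    def summary(self) -> dict:
        out = {
            "model": self.spec.label(),
            "n": self.n,
            "m": self.m,
            "t": self.t,
            "n_params": self.n_params,
            "residual_loglik": self.residual_loglik,
            "converged": self.converged,
            "n_iter": self.n_iter,
        }
        aic, bic = info_criteria(self)
        out.update(aic=aic, bic=bic)
        return out


def _env_labels(data: METData) -> dict[str, np.ndarray]:
    regions = np.array([e.region for e in data.environments])
    years = np.array([str(e.year) for e in data.environments])
    return {
        "region": regions,
        "year": years,
        "region_year": np.char.add(np.char.add(regions, "_"), years),
        "location": np.array([e.location for e in data.environments]),
    }


# ---------------------------------------------------------------------------
# public operations

def residual_loglik(params, data: METData, spec: VarianceModelSpec) -> float:
    """Residual log-likelihood of the model at the given structure parameters.

    ``params`` is structure specific: an :class:`FAParameters` for FA, a dict
    for the other structures (see each structure's ``params`` output), or a
    ready-made G_e matrix under key ``"G"`` for US.
    """
    if spec.peripheral_terms:
        raise SpecError("residual_loglik with peripheral terms: use reml_fit")
    core = _Core(data)
    if isinstance(params, FAParameters):
        # evaluate the implied G_e directly: the estimation constraint is not
        # required for evaluation (e.g. rotated loadings are admissible)
        G = params.G()
    else:
        struct = spec.structure(data.t, _env_labels(data))
        G = struct.unpack(struct.pack(params))
    res = core.loglik(G)
    if res is None:
        raise ValidationError("variance parameters give a non-positive-definite model")
    return res["ll"]


def reml_fit(
    data: METData,
    spec: VarianceModelSpec,
    init=None,
    control: FitControl | None = None,
) -> FittedModel:
    """Maximise the residual log-likelihood and return the fitted model.

    Quasi-Newton (L-BFGS-B) with analytic gradients on an unconstrained
    parametrisation; several deterministic restarts seeded from a
    diagonal-moment start, keeping the best.  Specific variances that end on
    the 1e-8 floor correspond to boundary estimates "fixed at zero".
    """
    control = control or FitControl()
    spec.validate_for(data.t)
    struct = spec.structure(data.t, _env_labels(data))
    rng = np.random.default_rng(control.seed)

    if spec.peripheral_terms:
        return _reml_fit_dense(data, spec, struct, init, control, rng)

    core = _Core(data)
    t0 = time.perf_counter()

    def objective(theta):
        res = core.loglik(struct.unpack(theta), want_grad=True)
        if res is None:
            return np.inf, np.zeros_like(theta)
        return -res["ll"], -struct.grad(theta, res["M"])

    starts = []
    if init is not None:
        starts.append(np.asarray(struct.pack(init), float))
    starts.extend(struct.inits(core.sigma2_moment, rng))
    for _ in range(control.extra_restarts):
        base = starts[-1]
        starts.append(base + 0.2 * rng.standard_normal(base.size))
    if control.max_starts is not None:
        starts = starts[: control.max_starts]

    best = None
    total_iter = 0
    for theta0 in starts:
        res = sopt.minimize(
            objective,
            theta0,
            jac=True,
            method="L-BFGS-B",
            bounds=struct.bounds(),
            options={
                "maxiter": min(control.max_iter, 80),
                "ftol": max(control.ftol, 1e-9),
                "gtol": control.gtol,
            },
        )
        total_iter += res.nit
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun - 1e-10):
            best = res
    if best is None:
        raise ValidationError("REML optimisation failed from every start")

    # Newton (average information) polish of the quasi-Newton solution
    theta, ai_iter, ai_conv = _ai_polish(core, struct, best.x, control)
    total_iter += ai_iter
    theta = _snap_boundaries(core, struct, theta)
    final = core.loglik(struct.unpack(theta), want_grad=True)
    grad_max = float(np.max(np.abs(struct.grad(theta, final["M"]))))
    best_ll = final["ll"]

    G = struct.unpack(theta)
    params = struct.params(theta)
    fa = params if isinstance(params, FAParameters) else None
    ebl = core.eblups(G, fa)
    converged = bool(ai_conv or best.success or grad_max < 100 * control.gtol)
    if not converged:
        warnings.warn(
            f"REML did not converge for {spec.label()} "
            f"(status {best.status}: {best.message}; grad_max={grad_max:.2e})",
            stacklevel=2,
        )

    env_ids, varieties = core.env_ids, core.varieties
    pev = {
        "u_blocks": ebl["u_blocks"],
        "u_diag": pd.DataFrame(ebl["u_diag"], index=varieties, columns=env_ids),
        "tau_cov": ebl["tau_cov"],
    }
    scores = delta = None
    if fa is not None:
        pev["f_blocks"] = ebl["f_blocks"]
        pev["delta_diag"] = pd.DataFrame(ebl["delta_pev"], index=varieties, columns=env_ids)
        scores = pd.DataFrame(
            ebl["scores"], index=varieties, columns=[f"fac{r+1}" for r in range(fa.order)]
        )
        delta = pd.DataFrame(ebl["delta"], index=varieties, columns=env_ids)

    return FittedModel(
        spec=spec,
        env_ids=env_ids,
        varieties=varieties,
        params=params,
        G=pd.DataFrame(G, index=env_ids, columns=env_ids),
        tau=pd.Series(ebl["tau"], index=env_ids),
        tau_se=pd.Series(np.sqrt(np.diag(ebl["tau_cov"])), index=env_ids),
        residual_loglik=float(best_ll),
        n_params=spec.n_params(data.t),
        converged=converged,
        n_iter=int(total_iter),
        n=core.n,
        m=core.m,
        t=core.t,
        u_blup=pd.DataFrame(ebl["u"], index=varieties, columns=env_ids),
        observed=pd.DataFrame(ebl["observed"], index=varieties, columns=env_ids),
        pev=pev,
        scores=scores,
        delta=delta,
        diagnostics={
            "grad_max": grad_max,
            "n_starts": len(starts),
            "ai_iterations": ai_iter,
            "wall_s": time.perf_counter() - t0,
            "rfull": ebl["rfull"],
        },
        _core=core,
    )


def _ai_polish(core: _Core, struct, theta: np.ndarray, control: FitControl):
    """Average-information Newton refinement of a quasi-Newton solution.

    AI-REML converges quadratically near the optimum where L-BFGS can crawl;
    bound-pinned parameters (variances on the floor) are held on an active
    set.  Returns (theta, n_iter, converged).
    """
    bounds = struct.bounds()
    lb = np.array([b[0] if b[0] is not None else -np.inf for b in bounds])
    ub = np.array([b[1] if b[1] is not None else np.inf for b in bounds])
    p = len(theta)
    if p * core.t * core.t > 5e7:  # AI stack too large; keep the L-BFGS answer
        return theta, 0, False

    res = core.loglik(struct.unpack(theta), want_grad=True, want_cache=True)
    if res is None:
        return theta, 0, False
    ll = res["ll"]
    converged = False
    nit = 0
    for _ in range(60):
        nit += 1
        g = struct.grad(theta, res["M"])
        at_lb = (theta <= lb + 1e-10) & (g < 0)
        at_ub = (theta >= ub - 1e-10) & (g > 0)
        free = ~(at_lb | at_ub)
        gmax = np.max(np.abs(g[free])) if free.any() else 0.0
        if gmax < control.gtol:
            converged = True
            break
        AI = core.average_information(struct.dG_stack(theta), res)
        Af = AI[np.ix_(free, free)]
        ridge = 1e-8 * max(np.trace(Af) / max(free.sum(), 1), 1e-8)
        step = np.zeros(p)
        try:
            step[free] = np.linalg.solve(Af + ridge * np.eye(free.sum()), g[free])
        except np.linalg.LinAlgError:
            break
        improved = False
        alpha = 1.0
        for _ in range(25):
            cand = np.clip(theta + alpha * step, lb, ub)
            r2 = core.loglik(struct.unpack(cand), want_grad=True, want_cache=True)
            if r2 is not None and r2["ll"] > ll:
                rel = (r2["ll"] - ll) / max(abs(ll), 1.0)
                theta, res, ll = cand, r2, r2["ll"]
                improved = True
                if rel < control.ftol:
                    g2 = struct.grad(theta, res["M"])
                    converged = bool(np.max(np.abs(g2[free])) < 100 * control.gtol)
                break
            alpha *= 0.5
        if not improved:
            # no ascent available: accept as (locally) converged on ll scale
            converged = gmax < 100 * control.gtol
            break
        if converged:
            break
    return theta, nit, converged


def _snap_boundaries(core: _Core, struct, theta: np.ndarray) -> np.ndarray:
    """Pin near-zero bounded variance parameters exactly on their floor.

    The log parametrisation is flat as a variance approaches zero, so the
    optimiser can stall a little above the boundary; a parameter is snapped
    to the floor ("fixed at zero") whenever doing so does not lower the
    log-likelihood beyond numerical noise.
    """
    bounds = struct.bounds()
    cand = [
        i
        for i, b in enumerate(bounds)
        if b[0] is not None and np.isfinite(b[0]) and theta[i] < b[0] + 12.0
        and theta[i] > b[0] + 1e-12
    ]
    if not cand:
        return theta
    res = core.loglik(struct.unpack(theta))
    ll = res["ll"]
    trial = theta.copy()
    for i in cand:
        trial[i] = bounds[i][0]
    r2 = core.loglik(struct.unpack(trial))
    if r2 is not None and r2["ll"] >= ll - 1e-9:
        return trial
    # joint snap lost likelihood: try each parameter on its own
    out = theta.copy()
    for i in cand:
        trial = out.copy()
        trial[i] = bounds[i][0]
        r2 = core.loglik(struct.unpack(trial))
        if r2 is not None and r2["ll"] >= ll - 1e-9:
            out, ll = trial, max(ll, r2["ll"])
    return out


def _reml_fit_dense(data, spec, struct, init, control, rng):
    """Fit with peripheral random terms via the dense likelihood."""
    dense = _DenseCore(data, spec)
    npph = len(spec.peripheral_terms)

    def split(theta):
        return theta[:-npph], np.exp(theta[-npph:])

    def objective(theta):
        th, pvars = split(theta)
        res = dense.loglik(struct.unpack(th), pvars)
        return np.inf if res is None else -res["ll"]

    starts = []
    core = _Core(data)
    base_inits = (
        [np.asarray(struct.pack(init), float)] if init is not None else []
    ) + struct.inits(core.sigma2_moment, rng)
    p0 = np.log(np.full(npph, max(np.mean(core.sigma2_moment) / 2, 1e-4)))
    for b in base_inits:
        starts.append(np.r_[b, p0])

    bounds = struct.bounds() + [(np.log(1e-8), np.log(1e6))] * npph
    best = None
    total_iter = 0
    for theta0 in starts:
        res = sopt.minimize(
            objective, theta0, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": control.max_iter, "ftol": control.ftol},
        )
        total_iter += res.nit
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun - 1e-10):
            best = res
    if best is None:
        raise ValidationError("REML optimisation failed from every start")

    th, pvars = split(best.x)
    G = struct.unpack(th)
    params = struct.params(th)
    fa = params if isinstance(params, FAParameters) else None
    res = dense.loglik(G, pvars)

    # EBLUPs via the full projection matrix (small-n path)
    n, t, m = dense.n, dense.t, dense.m
    Hinv = sla.cho_solve(res["cH"], np.eye(n))
    Ainv = np.linalg.inv(res["A"])
    P = Hinv - Hinv @ dense.X @ Ainv @ dense.X.T @ Hinv
    Pe = res["Pe"]
    u = np.zeros((m, t))
    u_blocks = np.zeros((m, t, t))
    observed = np.zeros((m, t), dtype=bool)
    for i in range(m):
        sel = np.where(dense.vi == i)[0]
        J = dense.ej[sel]
        CJ = G[:, J]
        u[i] = CJ @ Pe[sel]
        u_blocks[i] = G - CJ @ P[np.ix_(sel, sel)] @ CJ.T
        observed[i, J] = True

    env_ids, varieties = data.env_ids, data.varieties
    return FittedModel(
        spec=spec,
        env_ids=env_ids,
        varieties=varieties,
        params=params,
        G=pd.DataFrame(G, index=env_ids, columns=env_ids),
        tau=pd.Series(res["tau"], index=env_ids),
        tau_se=pd.Series(np.sqrt(np.diag(Ainv)), index=env_ids),
        residual_loglik=float(res["ll"]),
        n_params=spec.n_params(data.t),
        converged=bool(best.success),
        n_iter=int(total_iter),
        n=n,
        m=m,
        t=t,
        u_blup=pd.DataFrame(u, index=varieties, columns=env_ids),
        observed=pd.DataFrame(observed, index=varieties, columns=env_ids),
        pev={
            "u_blocks": u_blocks,
            "u_diag": pd.DataFrame(
                np.einsum("gtt->gt", u_blocks), index=varieties, columns=env_ids
            ),
            "tau_cov": Ainv,
        },
        peripheral={
            term.factor: float(s2) for term, s2 in zip(spec.peripheral_terms, pvars)
        },
        diagnostics={"dense_path": True},
    )


def fa_eblups(data: METData, loadings: np.ndarray, psi: np.ndarray) -> dict:
    """EBLUPs and PEV blocks with the FA variance parameters held fixed.

    This is the "additional iteration of model fitting" used to put scores on
    a rotated scale: the (rotated) loadings are incorporated as known and the
    mixed-model solutions recomputed.
    """
    fa = FAParameters(np.asarray(loadings, float), np.asarray(psi, float))
    core = _Core(data)
    ebl = core.eblups(fa.G(), fa)
    varieties, env_ids = core.varieties, core.env_ids
    k = fa.order
    return {
        "scores": pd.DataFrame(
            ebl["scores"], index=varieties, columns=[f"fac{r+1}" for r in range(k)]
        ),
        "delta": pd.DataFrame(ebl["delta"], index=varieties, columns=env_ids),
        "u": pd.DataFrame(ebl["u"], index=varieties, columns=env_ids),
        "f_blocks": ebl["f_blocks"],
        "u_blocks": ebl["u_blocks"],
        "observed": pd.DataFrame(ebl["observed"], index=varieties, columns=env_ids),
        "loglik": ebl["loglik"],
    }


def component_blups(fit: FittedModel, data: METData) -> dict[str, pd.DataFrame]:
    """EBLUPs of the individual variance components of a CS or VC fit.

    Returns the variety main effects and, for each partition factor, the
    per-level interaction EBLUPs (e.g. variety-by-region effects used for
    long-term regional predictions).
    """
    if fit.spec.kind not in ("CS", "VC"):
        raise SpecError("component BLUPs are defined for CS and VC fits")
    R = fit.diagnostics.get("rfull")
    if R is None:
        raise SpecError("fit was produced without cached solutions")
    labels = _env_labels(data)
    out = {}
    p = fit.params
    out["main"] = pd.DataFrame(
        {"effect": p["sigma2_main" if "sigma2_main" in p else "sigma2_g"] * R.sum(axis=1)},
        index=fit.varieties,
    )
    if fit.spec.kind == "CS":
        out["interaction"] = pd.DataFrame(
            p["sigma2_ge"] * R, index=fit.varieties, columns=fit.env_ids
        )
        return out
    for f in fit.spec.partition_factors:
        lab = labels[f]
        levels = sorted(set(lab))
        eff = np.stack([R[:, lab == l].sum(axis=1) for l in levels], axis=1)
        out[f] = pd.DataFrame(
            p[f"sigma2_{f}"] * eff, index=fit.varieties, columns=levels
        )
    out["resid"] = pd.DataFrame(
        p["sigma2_resid"] * R, index=fit.varieties, columns=fit.env_ids
    )
    return out


def info_criteria(fit: FittedModel, residual_df: int | None = None) -> tuple[float, float]:
    """AIC and BIC on the residual log-likelihood scale.

    AIC = -2 l_R + 2 p;  BIC = -2 l_R + p log(nu) with nu = n - rank(X)
    residual degrees of freedom.
    """
    if residual_df is None:
        residual_df = fit.n - fit.t
    if residual_df <= 0:
        raise ValidationError("residual degrees of freedom must be positive")
    p = fit.n_params
    ll = fit.residual_loglik
    return -2.0 * ll + 2.0 * p, -2.0 * ll + p * float(np.log(residual_df))


_NESTINGS = {
    ("DIAG", "FA"),
    ("DIAG", "US"),
    ("CS", "FA"),
    ("CS", "US"),
    ("CS", "VC"),
    ("FA", "FA"),
    ("FA", "US"),
    ("VC", "US"),
}


def remlrt(fit_null: FittedModel, fit_alt: FittedModel):
    """Residual maximum likelihood ratio test between nested variance models.

    The statistic 2 (l_alt - l_null) is floored at zero and referred to a
    chi-square with df equal to the difference in parameter counts.  When the
    null pins parameters on a boundary (an extra factor) the true null law is
    a chi-square mixture, so the plain chi-square p-value is conservative.
    """
    kn, ka = fit_null.spec.kind, fit_alt.spec.kind
    if kn == ka:
        nested = kn != "FA" or fit_null.spec.order <= fit_alt.spec.order
    else:
        nested = (kn, ka) in _NESTINGS
    if not nested:
        raise SpecError(f"{fit_null.spec.label()} is not nested in {fit_alt.spec.label()}")
    if fit_null.env_ids != fit_alt.env_ids or fit_null.n != fit_alt.n:
        raise SpecError("REMLRT requires the same data and fixed effects")
    df = fit_alt.n_params - fit_null.n_params
    stat = max(0.0, 2.0 * (fit_alt.residual_loglik - fit_null.residual_loglik))
    p = float(stats.chi2.sf(stat, df)) if df > 0 else float(stat == 0.0)
    return stat, df, p
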