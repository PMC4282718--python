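"""Post-fit factor analytic tools.

Goodness of fit (percentage of genetic variance accounted for), sequential
model-order selection, principal-component rotation of the loadings,
regression-component predictions with their prediction error variances,
genetic correlations and Mrode-style prediction accuracies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import METData
from .errors import SpecError, ValidationError
from .reml import FitControl, FittedModel, info_criteria, reml_fit, remlrt
from .variance import FAParameters, VarianceModelSpec

__all__ = [
    "variance_explained",
    "select_order",
    "OrderSelection",
    "rotate_pc",
    "RotatedSolution",
    "predictions",
    "PredictionSet",
    "genetic_correlation",
    "accuracy",
]


def variance_explained(fa: FAParameters) -> tuple[np.ndarray, float]:
    """Percentage of genetic variance accounted for by the k factors.

    Per environment: v_j = 100 sum_r lambda_rj^2 / (sum_r lambda_rj^2 + psi_j);
    overall: vbar = 100 tr(Lambda Lambda') / tr(Lambda Lambda' + psi).
    vbar is the genetic-variance-weighted mean of the v_j.
    """
    common = np.sum(fa.loadings**2, axis=1)
    total = common + fa.specific_variances
    v = np.full(len(total), np.nan)
    ok = total > 0
    if not ok.all():
        warnings.warn(
            "environment(s) with zero genetic variance: v_j undefined", stacklevel=2
        )
    v[ok] = 100.0 * common[ok] / total[ok]
    vbar = 100.0 * common.sum() / total.sum()
    return v, float(vbar)


@dataclass
class OrderSelection:
    """Result of the sequential FA order-selection loop."""

    fits: dict[int, FittedModel]
    chosen: int
    table: pd.DataFrame  # per order: n_params, loglik, AIC, BIC, vbar, REMLRT
    threshold_reached: bool
    vbar: dict[int, float]
    v_env: dict[int, np.ndarray]


def select_order(
    data: METData,
    max_order: int,
    vbar_threshold: float = 80.0,
    control: FitControl | None = None,
) -> OrderSelection:
    """Fit FA1, FA2, ... until the overall percentage of genetic variance
    accounted for reaches ``vbar_threshold`` (or ``max_order``).

    Each fit is warm-started from the previous order.  AIC, BIC and the
    REMLRT against the preceding order are reported for every order but do
    not drive the choice: likelihood-based criteria tend to select
    unnecessarily high orders (AIC, REMLRT) or underfit (BIC), so the
    variance-accounted-for threshold decides.
    """
    if not (1 <= max_order < data.t):
        raise SpecError(f"max_order must be in [1, t-1]; got {max_order} with t={data.t}")
    fits: dict[int, FittedModel] = {}
    vbar: dict[int, float] = {}
    v_env: dict[int, np.ndarray] = {}
    rows = []
    chosen = None
    prev = None
    for k in range(1, max_order + 1):
        spec = VarianceModelSpec.fa(k)
        init = None
        if prev is not None:
            struct = spec.structure(data.t)
            init_theta = struct.warm_from(prev.fa_parameters(), np.diag(prev.G.to_numpy()))
            init = struct.params(init_theta)
        try:
            fit = reml_fit(data, spec, init=init, control=control)
        except Exception as exc:  # pragma: no cover - defensive
            warnings.warn(f"FA{k} fit failed ({exc}); stopping at FA{k-1}", stacklevel=2)
            break
        if not fit.converged:
            warnings.warn(f"FA{k} did not converge; stopping", stacklevel=2)
        fits[k] = fit
        v, vb = variance_explained(fit.fa_parameters())
        vbar[k], v_env[k] = vb, v
        aic, bic = info_criteria(fit)
        row = {
            "order": k,
            "n_params": fit.n_params,
            "loglik": fit.residual_loglik,
            "aic": aic,
            "bic": bic,
            "vbar": vb,
        }
        if prev is not None:
            stat, df, p = remlrt(prev, fit)
            row.update(remlrt_stat=stat, remlrt_df=df, remlrt_p=p)
        rows.append(row)
        prev = fit
        if vb >= vbar_threshold:
            chosen = k
            break
        if not fit.converged:
            break
    if not fits:
        raise ValidationError("no FA model could be fitted")
    threshold_reached = chosen is not None
    if chosen is None:
        chosen = max(fits)
        warnings.warn(
            f"variance-accounted-for threshold {vbar_threshold}% not reached by "
            f"FA{chosen} (vbar={vbar[chosen]:.1f}%)",
            stacklevel=2,
        )
    return OrderSelection(
        fits=fits,
        chosen=chosen,
        table=pd.DataFrame(rows).set_index("order"),
        threshold_reached=threshold_reached,
        vbar=vbar,
        v_env=v_env,
    )


@dataclass
class RotatedSolution:
    """Principal-component rotation of a fitted FA solution.

    The rotation V diagonalises Lambda' Lambda so the first rotated factor
    carries the maximum genetic covariance; Lambda* Lambda*' is unchanged.
    Column signs are fixed so each rotated loading column sums non-negative.
    """

    rotated_loadings: pd.DataFrame  # t x k
    rotated_scores: pd.DataFrame  # m x k
    rotation: np.ndarray  # k x k orthogonal
    score_pev: np.ndarray  # (m, k, k) per-variety PEV blocks of f*
    factor_variance_pct: np.ndarray  # share of total genetic variance per factor
    degenerate: bool = False  # repeated eigenvalues: basis not unique

    @property
    def order(self) -> int:
        return self.rotation.shape[0]

    def score_se(self) -> pd.DataFrame:
        se = np.sqrt(np.einsum("mkk->mk", self.score_pev))
        return pd.DataFrame(
            se, index=self.rotated_scores.index, columns=self.rotated_scores.columns
        )


def rotate_pc(fit: FittedModel) -> RotatedSolution:
    """Rotate estimated loadings and scores to the principal component solution.

    Eigen-decomposes Lambda' Lambda = V Theta V' (Theta non-increasing) and
    sets Lambda* = Lambda V, f* = V' f.  The PEV of the rotated scores is the
    orthogonal transform (V' . V) of the per-variety PEV blocks, identical to
    what a refit with Lambda* held fixed produces (the likelihood is
    invariant under the rotation).
    """
    if fit.spec.kind != "FA":
        raise SpecError("rotation applies to factor analytic fits")
    if not fit.converged:
        warnings.warn("rotating a non-converged fit", stacklevel=2)
    fa = fit.fa_parameters()
    L = fa.loadings
    k = fa.order
    LtL = L.T @ L
    theta, V = np.linalg.eigh(LtL)
    order = np.argsort(theta)[::-1]
    theta, V = theta[order], V[:, order]
    degenerate = bool(np.any(np.abs(np.diff(theta)) < 1e-10 * max(theta.max(), 1.0)))
    if degenerate:
        warnings.warn("repeated eigenvalues: rotated basis is not unique", stacklevel=2)
    Lstar = L @ V
    # sign convention: non-negative column sums of rotated loadings
    signs = np.where(Lstar.sum(axis=0) < 0, -1.0, 1.0)
    Lstar = Lstar * signs
    V = V * signs

    fstar = fit.scores.to_numpy() @ V
    pev_rot = np.einsum("rk,mrs,sl->mkl", V, fit.pev["f_blocks"], V)
    total = float(np.sum(L**2) + np.sum(fa.specific_variances))
    pct = 100.0 * theta / total
    cols = [f"fac{r+1}" for r in range(k)]
    return RotatedSolution(
        rotated_loadings=pd.DataFrame(Lstar, index=fit.env_ids, columns=cols),
        rotated_scores=pd.DataFrame(fstar, index=fit.varieties, columns=cols),
        rotation=V,
        score_pev=pev_rot,
        factor_variance_pct=pct,
        degenerate=degenerate,
    )


@dataclass
class PredictionSet:
    """Variety-by-environment predictions decomposed as u~ = beta~ + delta~.

    beta~ (the regression component, defined for every cell whether or not
    the variety was grown) is the grower-facing prediction; delta~ is the
    environment-specific residual, zero for unobserved cells.  ``beta_pev``
    holds per-variety t x t PEV blocks of beta~; standard errors ignore
    uncertainty in the estimated variance parameters.
    """

    beta: pd.DataFrame  # m x t
    delta: pd.DataFrame  # m x t
    total: pd.DataFrame  # m x t
    beta_pev: np.ndarray  # (m, t, t)
    observed_mask: pd.DataFrame  # m x t

    def beta_se(self) -> pd.DataFrame:
        se = np.sqrt(np.maximum(np.einsum("mtt->mt", self.beta_pev), 0.0))
        return pd.DataFrame(se, index=self.beta.index, columns=self.beta.columns)


def predictions(fit: FittedModel, rot: RotatedSolution) -> PredictionSet:
    """Regression-component predictions from a rotated FA fit.

    beta~_ij = sum_r lambda*_rj f*_ri for all m x t cells; the PEV of beta~
    is (Lambda* (x) I_m) V_f* (Lambda*' (x) I_m), realised per variety as
    Lambda* V_f*_i Lambda*'.
    """
    Lstar = rot.rotated_loadings.to_numpy()
    fstar = rot.rotated_scores.to_numpy()
    if Lstar.shape[1] != fstar.shape[1]:
        raise ValidationError("loading / score dimension mismatch")
    if list(rot.rotated_loadings.index) != fit.env_ids:
        raise ValidationError("rotation does not belong to this fit")
    beta = pd.DataFrame(fstar @ Lstar.T, index=fit.varieties, columns=fit.env_ids)
    delta = fit.delta.copy()
    total = beta + delta
    beta_pev = np.einsum("tr,mrs,us->mtu", Lstar, rot.score_pev, Lstar)
    return PredictionSet(
        beta=beta,
        delta=delta,
        total=total,
        beta_pev=beta_pev,
        observed_mask=fit.observed.copy(),
    )


def genetic_correlation(G_e: np.ndarray | pd.DataFrame) -> pd.DataFrame | np.ndarray:
    """Between-environment genetic correlation matrix C_e = D_e G_e D_e,
    with D_e the inverse square roots of the genetic variances."""
    G = np.asarray(G_e, float)
    d = np.diag(G)
    bad = np.where(d <= 0)[0]
    if bad.size:
        names = (
            [G_e.index[i] for i in bad] if isinstance(G_e, pd.DataFrame) else list(bad)
        )
        raise ValidationError(f"zero genetic variance for environment(s) {names}")
    D = 1.0 / np.sqrt(d)
    C = np.clip(G * np.outer(D, D), -1.0, 1.0)
    np.fill_diagonal(C, 1.0)
    if isinstance(G_e, pd.DataFrame):
        return pd.DataFrame(C, index=G_e.index, columns=G_e.columns)
    return C


def accuracy(fit: FittedModel) -> tuple[pd.DataFrame, pd.Series]:
    """Accuracy of the total variety-by-environment predictions.

    Per cell: r_ij = sqrt(max(0, 1 - PEV(u~_ij) / Ghat_e[j, j])), the standard
    correlation between true and predicted effect for an individual.  The
    per-environment value averages cells over the varieties grown there.
    """
    gvar = np.diag(fit.G.to_numpy())
    if np.any(gvar <= 0):
        raise ValidationError("accuracy undefined for zero genetic variance")
    pev = fit.pev["u_diag"].to_numpy()
    ratio = pev / gvar[None, :]
    if np.any(ratio > 1 + 1e-8):
        warnings.warn("PEV exceeds genetic variance; accuracy clipped at 0", stacklevel=2)
    per_cell = np.sqrt(np.clip(1.0 - ratio, 0.0, None))
    per_cell = pd.DataFrame(per_cell, index=fit.varieties, columns=fit.env_ids)
    obs = fit.observed.to_numpy()
    with np.errstate(invalid="ignore"):
        env_mean = np.where(
            obs.any(axis=0),
            (per_cell.to_numpy() * obs).sum(axis=0) / np.maximum(obs.sum(axis=0), 1),
            np.nan,
        )
    return per_cell, pd.Series(env_mean, index=fit.env_ids)
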