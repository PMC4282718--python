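"""Simplified first-stage (individual trial) analysis.

Each trial is analysed as a randomised complete block design (RCBD) with
additive fixed replicate and variety effects, fitted by ordinary least
squares.  The outputs feeding the second stage are the adjusted variety
means, their statistical weights (reciprocal variances of the adjusted
means), the variety F-ratio used by the no-genetic-variance filter, and the
residual (error) mean square.  This deliberately replaces the spatial
mixed-model analyses used operationally; the second stage only consumes
means and diagonal weights.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .data import Environment, METData
from .errors import NoDataError, ValidationError

__all__ = ["PlotData", "TrialSummary", "analyze_trial", "summaries_to_met"]

# residual mean squares below this are treated as numerically zero when
# forming weights (perfect fits would otherwise give infinite weight)
_MS_FLOOR = 1e-12


@dataclass
class PlotData:
    """Plot-level yields for one trial: columns replicate, variety, yield."""

    trial: str
    plots: pd.DataFrame

    def __post_init__(self):
        need = {"replicate", "variety", "yield"}
        if not need.issubset(self.plots.columns):
            raise ValidationError(f"plot table needs columns {sorted(need)}")
        dup = self.plots.duplicated(subset=["replicate", "variety"])
        if dup.any():
            raise ValidationError(f"duplicate (replicate, variety) plot in trial {self.trial}")


@dataclass
class TrialSummary:
    """First-stage results for one trial."""

    trial: str
    variety_means: pd.Series
    weights: pd.Series
    f_ratio: float
    error_ms: float
    trial_mean: float
    extras: dict = field(default_factory=dict)


def analyze_trial(plots: PlotData) -> TrialSummary:
    """Two-way additive RCBD analysis of one trial.

    Fits yield = mean + replicate + variety + error by least squares.  The
    adjusted mean of a variety is its prediction averaged over all replicate
    levels; its weight is 1 / Var(adjusted mean).  For a balanced trial with
    r replicates and residual mean square s^2 every weight is r / s^2.
    """
    df = plots.plots.reset_index(drop=True)
    varieties = sorted(df["variety"].astype(str).unique())
    reps = sorted(df["replicate"].astype(str).unique())
    if len(varieties) < 2:
        raise ValidationError("need at least 2 varieties for a trial analysis")
    nv, nr, nobs = len(varieties), len(reps), len(df)

    vmap = {v: i for i, v in enumerate(varieties)}
    rmap = {r: i for i, r in enumerate(reps)}
    y = df["yield"].to_numpy(float)

    if nr < 2:
        warnings.warn(
            f"trial {plots.trial}: fewer than 2 replicates; no F-ratio, naive weights",
            stacklevel=2,
        )
        means = df.groupby(df["variety"].astype(str))["yield"].mean().reindex(varieties)
        resid_var = float(np.var(y, ddof=1)) if nobs > 1 else 1.0
        w = pd.Series(1.0 / max(resid_var, _MS_FLOOR), index=varieties)
        return TrialSummary(plots.trial, means, w, np.nan, resid_var, float(np.mean(y)))

    # full design: intercept + (nr-1) replicate dummies + (nv-1) variety dummies
    X = np.zeros((nobs, 1 + (nr - 1) + (nv - 1)))
    X[:, 0] = 1.0
    for i, (r, v) in enumerate(zip(df["replicate"].astype(str), df["variety"].astype(str))):
        if rmap[r] > 0:
            X[i, rmap[r]] = 1.0
        if vmap[v] > 0:
            X[i, nr - 1 + vmap[v]] = 1.0
    fit = sm.OLS(y, X).fit()
    if fit.df_resid <= 0:
        raise ValidationError(f"trial {plots.trial}: zero residual degrees of freedom")
    error_ms = float(fit.ssr / fit.df_resid)

    # partial F for variety effects
    contrast = np.zeros((nv - 1, X.shape[1]))
    for j in range(nv - 1):
        contrast[j, nr - 1 + 1 + j] = 1.0
    if error_ms <= _MS_FLOOR:
        f_ratio = np.inf
    else:
        f_ratio = float(fit.f_test(contrast).fvalue)

    # adjusted means: prediction averaged over replicate levels
    L = np.zeros((nv, X.shape[1]))
    L[:, 0] = 1.0
    L[:, 1:nr] = 1.0 / nr
    for v, j in vmap.items():
        if j > 0:
            L[j, nr - 1 + j] = 1.0
    means = pd.Series(L @ fit.params, index=varieties)
    cov = fit.cov_params()
    var_adj = np.einsum("ij,jk,ik->i", L, np.asarray(cov), L)
    weights = pd.Series(1.0 / np.maximum(var_adj, _MS_FLOOR), index=varieties)

    return TrialSummary(
        trial=plots.trial,
        variety_means=means,
        weights=weights,
        f_ratio=f_ratio,
        error_ms=error_ms,
        trial_mean=float(np.mean(y)),
    )


def summaries_to_met(summaries: list[TrialSummary], metadata: dict[str, Environment]) -> METData:
    """Stack first-stage summaries into a second-stage METData.

    ``metadata`` maps each trial id to its Environment attributes; the trial
    mean yield and error mean square observed in stage 1 are attached.
    """
    if not summaries:
        raise NoDataError("no trial summaries supplied")
    environments, rows = [], []
    for s in sorted(summaries, key=lambda s: s.trial):
        if s.trial not in metadata:
            raise ValidationError(f"no environment metadata for trial {s.trial}")
        env = metadata[s.trial]
        env.trial_mean_yield = s.trial_mean
        env.error_ms = s.error_ms
        environments.append(env)
        for v in s.variety_means.index:
            rows.append((v, env.env_id, float(s.variety_means[v]), float(s.weights[v])))
    records = pd.DataFrame(rows, columns=["variety", "env_id", "mean", "weight"])
    return METData(environments=environments, records=records)
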