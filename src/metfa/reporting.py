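"""Grower-facing report computations.

All outputs are plot-ready tables; figure rendering is a thin optional layer
on top so everything can be exercised (and tested) headless.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .data import METData
from .errors import ValidationError
from .postfit import PredictionSet, RotatedSolution

__all__ = [
    "OrderedCorrelation",
    "order_correlation",
    "LatentRegressionData",
    "latent_regression",
    "regional_predictions",
    "environment_panel",
]


@dataclass
class OrderedCorrelation:
    """Correlation matrix reordered by a dendrogram so highly correlated
    environments sit together on a heatmap."""

    order: list[str]
    merge_tree: np.ndarray  # scipy linkage matrix
    correlation: pd.DataFrame  # reordered C_e


def order_correlation(C_e: pd.DataFrame, linkage: str = "average") -> OrderedCorrelation:
    """Agglomerative clustering of environments with I - C_e as dissimilarity.

    The leaf order of the dendrogram gives the display permutation.  The
    linkage is configurable; average linkage is the default.
    """
    C = np.asarray(C_e, float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValidationError("correlation matrix must be square")
    labels = (
        list(C_e.index) if isinstance(C_e, pd.DataFrame) else [str(i) for i in range(len(C))]
    )
    # dissimilarity 1 - c_ij between distinct environments, 0 on the diagonal
    D = 1.0 - C
    np.fill_diagonal(D, 0.0)
    D = np.maximum((D + D.T) / 2.0, 0.0)
    if len(C) == 1:
        return OrderedCorrelation(labels, np.empty((0, 4)), pd.DataFrame(C, index=labels, columns=labels))
    Z = hierarchy.linkage(squareform(D, checks=False), method=linkage)
    leaves = hierarchy.leaves_list(Z)
    ordered = [labels[i] for i in leaves]
    Cdf = pd.DataFrame(C, index=labels, columns=labels).loc[ordered, ordered]
    return OrderedCorrelation(order=ordered, merge_tree=Z, correlation=Cdf)


@dataclass
class LatentRegressionData:
    """Data behind one latent regression plot (one variety, one factor).

    For factor s the y-axis is the regression component adjusted for the
    preceding factors, beta~_ij - sum_{r<s} lambda*_rj f*_ri, the x-axis the
    rotated loading lambda*_sj, and the fitted line has slope f*_si.
    """

    variety: str
    factor_index: int
    points: pd.DataFrame  # env_id, x, y, observed
    slope: float


def latent_regression(
    preds: PredictionSet, rot: RotatedSolution, variety: str, factor_index: int
) -> LatentRegressionData:
    """Partial-residual data for the latent regression plot of one factor."""
    k = rot.order
    if not 1 <= factor_index <= k:
        raise ValidationError(f"factor index must be in [1, {k}]")
    if variety not in preds.beta.index:
        raise ValidationError(f"unknown variety {variety!r}")
    Lstar = rot.rotated_loadings
    f = rot.rotated_scores.loc[variety]
    y = preds.beta.loc[variety].copy()
    for r in range(factor_index - 1):
        y = y - Lstar.iloc[:, r] * f.iloc[r]
    pts = pd.DataFrame(
        {
            "env_id": Lstar.index,
            "x": Lstar.iloc[:, factor_index - 1].to_numpy(),
            "y": y.to_numpy(),
            "observed": preds.observed_mask.loc[variety].to_numpy(),
        }
    )
    return LatentRegressionData(
        variety=variety,
        factor_index=factor_index,
        points=pts,
        slope=float(f.iloc[factor_index - 1]),
    )


def regional_predictions(
    preds: PredictionSet,
    env_groups: dict[str, list[str]],
    weights: dict[str, pd.Series] | None = None,
) -> pd.DataFrame:
    """Per-variety group means of the regression components beta~.

    Long-term regional predictions are simple (or weighted) averages of
    beta~ across the environments of each group; the standard error uses the
    full per-variety PEV block of beta~ for the group, not independent
    diagonals.  Weights are normalised to sum to one within a group.
    """
    env_ids = list(preds.beta.columns)
    eidx = {e: i for i, e in enumerate(env_ids)}
    rows = []
    for group, envs in env_groups.items():
        if not envs:
            raise ValidationError(f"empty environment group {group!r}")
        missing = [e for e in envs if e not in eidx]
        if missing:
            raise ValidationError(f"group {group!r} references unknown environments {missing}")
        w = np.ones(len(envs))
        if weights is not None and group in weights:
            w = np.asarray([weights[group][e] for e in envs], float)
        if w.sum() <= 0:
            raise ValidationError(f"group {group!r} weights sum to zero")
        w = w / w.sum()
        cols = [eidx[e] for e in envs]
        mean = preds.beta.iloc[:, cols].to_numpy() @ w
        block = preds.beta_pev[:, cols][:, :, cols]
        var = np.einsum("a,mab,b->m", w, block, w)
        for v, mu, s2 in zip(preds.beta.index, mean, var):
            rows.append((v, group, float(mu), float(np.sqrt(max(s2, 0.0)))))
    return pd.DataFrame(rows, columns=["variety", "group", "prediction", "se"])


def environment_panel(
    preds: PredictionSet, data: METData, region: str, varieties: list[str] | None = None
) -> pd.DataFrame:
    """Long-format prediction table for one region's location-by-year panels.

    One row per (location, year, variety): the regression-component
    prediction, its standard error, whether the variety was grown in the
    trial, and the trial mean yield (the quantitative grading of the
    environment shown on the panel axis).
    """
    envs = [e for e in data.environments if e.region == region]
    if not envs:
        raise ValidationError(f"unknown or empty region {region!r}")
    varieties = list(varieties) if varieties is not None else list(preds.beta.index)
    se = preds.beta_se()
    rows = []
    for e in envs:
        for v in varieties:
            rows.append(
                (
                    region,
                    e.location,
                    e.year,
                    e.env_id,
                    v,
                    float(preds.beta.loc[v, e.env_id]),
                    float(se.loc[v, e.env_id]),
                    bool(preds.observed_mask.loc[v, e.env_id]),
                    e.trial_mean_yield,
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "region",
            "location",
            "year",
            "env_id",
            "variety",
            "prediction",
            "se",
            "observed",
            "trial_mean_yield",
        ],
    ).sort_values(["location", "year", "variety"], ignore_index=True)
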