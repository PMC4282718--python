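"""Synthetic national-variety-trial-like MET data with known truth.

The generator emulates the structural features of national testing data
that drive the second-stage analysis: environments formed as locations x
years with regional groupings, yearly entry and retirement of varieties (a
moving window of connectivity: varieties never return once retired),
factor-analytic genetic effects u = (Lambda (x) I) f + delta, and strongly
heterogeneous trial error variances (log-uniform over a configurable range,
two hundred-fold by default).  Plot-level RCBD data can be generated on top
so the first-stage analysis is exercisable end to end.

It does not emulate spatial field trend, frost/disease events, or
non-random placement of varieties within regions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import orthogonal_procrustes

from .data import ConnectivityTable, Environment, METData, connectivity, connectivity_components, env_key
from .errors import ValidationError
from .stage1 import PlotData

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_met",
    "resimulate_met",
    "simulate_plots",
    "recovery_report",
]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of a simulated MET.

    Defaults mirror a five-year national mega-region dataset: 40 locations
    by 5 years (~200 trials) in 8 regions, ~200 varieties turning over from
    year to year, a factor analytic genetic model of order 5, three
    replicates, and trial error variances spanning a 200-fold range.
    """

    n_locations: int = 40
    n_years: int = 5
    n_regions: int = 8
    m: int = 200
    k_true: int = 5
    loading_law: tuple = ("normal", 0.3, 0.12)  # factor 1 (absolute value)
    psi_law: tuple = ("uniform", 0.005, 0.05)
    error_var_range: tuple[float, float] = (0.01, 2.0)  # (t/ha)^2, log-uniform
    trial_mean_range: tuple[float, float] = (0.8, 5.0)  # t/ha
    replicates: int = 3
    retention: float = 0.75  # per-year probability a variety is kept on
    entry_rate: int | None = None  # new varieties per year (derived if None)
    loading_mean_corr: float = 0.0  # optional link factor-1 loading ~ trial mean
    rep_effect_sd: float = 0.1  # t/ha, replicate (block) effects at plot level
    first_year: int = 2009
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.retention <= 1):
            raise ValidationError("retention must be in (0, 1]")
        for lo, hi in (self.error_var_range, self.trial_mean_range):
            if not (0 < lo <= hi):
                raise ValidationError("ranges must be positive and ordered")
        if self.k_true < 1 or self.m < 2:
            raise ValidationError("need k_true >= 1 and m >= 2")


@dataclass
class SimTruth:
    """Generative truth underlying a simulated MET dataset."""

    env_ids: list[str]
    varieties: list[str]
    Lambda_true: np.ndarray  # (t, k)
    psi_true: np.ndarray  # (t,)
    Ge_true: np.ndarray  # (t, t)
    scores_true: np.ndarray  # (m, k)
    u_true: np.ndarray  # (m, t)
    trial_means: np.ndarray  # (t,)
    error_vars: np.ndarray  # (t,)
    incidence: np.ndarray  # (m, t) booleans
    config: SimConfig = field(repr=False, default=None)


def _draw(law: tuple, size, rng) -> np.ndarray:
    kind = law[0]
    if kind == "uniform":
        return rng.uniform(law[1], law[2], size)
    if kind == "normal":
        return rng.normal(law[1], law[2], size)
    if kind == "lognormal":
        return rng.lognormal(law[1], law[2], size)
    raise ValidationError(f"unknown distribution law {kind!r}")


def _incidence(cfg: SimConfig, rng) -> tuple[list[str], np.ndarray]:
    """Variety-by-year activity via the entry/retirement process.

    Retired varieties never return.  The year-one cohort and the yearly
    intake are sized so the total number of distinct varieties is close to
    the configured m.
    """
    Y, p = cfg.n_years, cfg.retention
    if cfg.entry_rate is not None:
        entry = cfg.entry_rate
        first = max(2, cfg.m - (Y - 1) * entry)
    else:
        first = max(2, int(round(cfg.m / (1 + (Y - 1) * (1 - p)))))
        entry = None
    active = list(range(first))
    next_id = first
    activity = {y: None for y in range(Y)}
    activity[0] = list(active)
    for y in range(1, Y):
        survivors = [v for v in active if rng.random() < p]
        n_new = entry if entry is not None else max(first - len(survivors), 0)
        newcomers = list(range(next_id, next_id + n_new))
        next_id += n_new
        active = survivors + newcomers
        if len(active) == 0:  # keep every year populated
            active = [next_id]
            next_id += 1
        activity[y] = list(active)
    mreal = next_id
    width = len(str(mreal - 1))
    varieties = [f"V{str(i).zfill(width)}" for i in range(mreal)]
    act = np.zeros((mreal, Y), dtype=bool)
    for y, ids in activity.items():
        act[np.array(ids, dtype=int), y] = True
    return varieties, act


def simulate_met(config: SimConfig) -> tuple[METData, SimTruth]:
    """Generate a second-stage MET dataset and its truth, deterministically
    under the configured seed."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    years = [cfg.first_year + y for y in range(cfg.n_years)]
    locations = [f"Loc{str(i).zfill(2)}" for i in range(cfg.n_locations)]
    region_of = {
        loc: f"R{(i * cfg.n_regions) // cfg.n_locations + 1}" for i, loc in enumerate(locations)
    }
    environments = []
    env_year = []
    for loc in locations:
        for yr in years:
            environments.append(Environment(env_key(loc, yr), loc, yr, region_of[loc]))
            env_year.append(yr - cfg.first_year)
    order = np.argsort([e.env_id for e in environments])
    environments = [environments[i] for i in order]
    env_year = np.array(env_year)[order]
    t = len(environments)

    trial_means = rng.uniform(*cfg.trial_mean_range, t)
    lo, hi = cfg.error_var_range
    error_vars = np.exp(rng.uniform(np.log(lo), np.log(hi), t))

    # loadings: factor 1 positive, optionally tied to trial mean yield
    Lam = np.zeros((t, cfg.k_true))
    lam1 = np.abs(_draw(cfg.loading_law, t, rng))
    if cfg.loading_mean_corr > 0:
        z = (trial_means - trial_means.mean()) / max(trial_means.std(), 1e-12)
        rho = cfg.loading_mean_corr
        base = np.sort(lam1)[np.argsort(np.argsort(rho * z + np.sqrt(1 - rho**2) * rng.standard_normal(t)))]
        lam1 = base
    Lam[:, 0] = lam1
    scale = cfg.loading_law[2] if len(cfg.loading_law) > 2 else 0.1
    decay = 0.8 ** np.arange(1, cfg.k_true)
    for r in range(1, cfg.k_true):
        Lam[:, r] = rng.normal(0.0, scale * decay[r - 1], t)
    psi = np.abs(_draw(cfg.psi_law, t, rng))
    Ge = Lam @ Lam.T + np.diag(psi)

    varieties, activity = _incidence(cfg, rng)
    mreal = len(varieties)
    incidence = activity[:, env_year]  # (m, t): grown in all trials of active years

    f = rng.standard_normal((mreal, cfg.k_true))
    delta = rng.standard_normal((mreal, t)) * np.sqrt(psi)[None, :]
    u = f @ Lam.T + delta

    e = rng.standard_normal((mreal, t)) * np.sqrt(error_vars / cfg.replicates)[None, :]
    y = trial_means[None, :] + u + e
    weights = cfg.replicates / error_vars

    env_ids = [e_.env_id for e_ in environments]
    vi, ej = np.where(incidence)
    records = pd.DataFrame(
        {
            "variety": [varieties[i] for i in vi],
            "env_id": [env_ids[j] for j in ej],
            "mean": y[vi, ej],
            "weight": weights[ej],
        }
    )
    for e_, mu, ems in zip(environments, trial_means, error_vars):
        e_.trial_mean_yield = float(mu)
        e_.error_ms = float(ems)
    data = METData(environments=environments, records=records)

    truth = SimTruth(
        env_ids=env_ids,
        varieties=varieties,
        Lambda_true=Lam,
        psi_true=psi,
        Ge_true=Ge,
        scores_true=f,
        u_true=u,
        trial_means=trial_means,
        error_vars=error_vars,
        incidence=incidence,
        config=cfg,
    )

    comps = connectivity_components(connectivity(data, "trial"), min_common=1)
    if len(comps) > 1:
        warnings.warn(
            f"simulated dataset is disconnected ({len(comps)} components); "
            "sizes " + ", ".join(str(len(c)) for c in comps),
            stacklevel=2,
        )
    return data, truth


def resimulate_met(truth: SimTruth, seed: int) -> tuple[METData, SimTruth]:
    """New data replicate from an existing truth (Lambda, psi, trial means,
    error variances and incidence held fixed; scores, residuals and noise
    redrawn).  Used for repeated-sampling studies of estimator behaviour."""
    cfg = truth.config
    rng = np.random.default_rng(seed)
    t = len(truth.env_ids)
    mreal = len(truth.varieties)
    k = truth.Lambda_true.shape[1]
    f = rng.standard_normal((mreal, k))
    delta = rng.standard_normal((mreal, t)) * np.sqrt(truth.psi_true)[None, :]
    u = f @ truth.Lambda_true.T + delta
    e = rng.standard_normal((mreal, t)) * np.sqrt(truth.error_vars / cfg.replicates)[None, :]
    y = truth.trial_means[None, :] + u + e
    weights = cfg.replicates / truth.error_vars
    vi, ej = np.where(truth.incidence)
    records = pd.DataFrame(
        {
            "variety": [truth.varieties[i] for i in vi],
            "env_id": [truth.env_ids[j] for j in ej],
            "mean": y[vi, ej],
            "weight": weights[ej],
        }
    )
    environments = [
        Environment(env_id, env_id.rsplit("_", 1)[0], int(env_id.rsplit("_", 1)[1]),
                    f"R{j % max(cfg.n_regions, 1) + 1}",
                    trial_mean_yield=float(mu), error_ms=float(ev))
        for j, (env_id, mu, ev) in enumerate(
            zip(truth.env_ids, truth.trial_means, truth.error_vars)
        )
    ]
    data = METData(environments=environments, records=records)
    new_truth = SimTruth(
        env_ids=truth.env_ids,
        varieties=truth.varieties,
        Lambda_true=truth.Lambda_true,
        psi_true=truth.psi_true,
        Ge_true=truth.Ge_true,
        scores_true=f,
        u_true=u,
        trial_means=truth.trial_means,
        error_vars=truth.error_vars,
        incidence=truth.incidence,
        config=cfg,
    )
    return data, new_truth


def simulate_plots(config: SimConfig, truth: SimTruth) -> list[PlotData]:
    """Plot-level RCBD data consistent with a simulated MET truth.

    Each trial gets ``replicates`` complete blocks of its active varieties;
    plot errors have the trial's error variance, so the first-stage analysis
    recovers means and weights consistent with the second-stage records.
    """
    cfg = config
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 815]))
    out = []
    for j, env_id in enumerate(truth.env_ids):
        vids = np.where(truth.incidence[:, j])[0]
        reps = [f"rep{r+1}" for r in range(cfg.replicates)]
        rep_eff = rng.normal(0.0, cfg.rep_effect_sd, cfg.replicates)
        rows = []
        for r, (rep, re) in enumerate(zip(reps, rep_eff)):
            noise = rng.normal(0.0, np.sqrt(truth.error_vars[j]), len(vids))
            for v, eps in zip(vids, noise):
                rows.append(
                    (
                        rep,
                        truth.varieties[v],
                        truth.trial_means[j] + re + truth.u_true[v, j] + eps,
                    )
                )
        out.append(
            PlotData(trial=env_id, plots=pd.DataFrame(rows, columns=["replicate", "variety", "yield"]))
        )
    return out


def recovery_report(fit, truth: SimTruth) -> dict:
    """Compare a fitted model against the generative truth.

    Loadings are identified only up to rotation, so estimated loadings and
    scores are aligned to the truth by orthogonal Procrustes before
    factor-wise comparisons.  Always reports the relative Frobenius error of
    G_e; FA fits of matching order add the variance-accounted-for error and
    per-factor score correlations.
    """
    Ge_hat = fit.G.to_numpy()
    Ge = truth.Ge_true
    out = {
        "ge_rel_frobenius": float(np.linalg.norm(Ge_hat - Ge) / np.linalg.norm(Ge)),
        "model": fit.spec.label(),
    }
    common = np.sum(truth.Lambda_true**2)
    out["vbar_true"] = float(100.0 * common / (common + truth.psi_true.sum()))

    if fit.spec.kind == "FA":
        fa = fit.fa_parameters()
        chat = np.sum(fa.loadings**2)
        out["vbar_hat"] = float(100.0 * chat / (chat + fa.specific_variances.sum()))
        out["vbar_abs_error"] = abs(out["vbar_hat"] - out["vbar_true"])
        if fa.order == truth.Lambda_true.shape[1]:
            R, _ = orthogonal_procrustes(fa.loadings, truth.Lambda_true)
            La = fa.loadings @ R
            out["loading_rel_error"] = float(
                np.linalg.norm(La - truth.Lambda_true) / np.linalg.norm(truth.Lambda_true)
            )
            fa_scores = fit.scores.to_numpy() @ R
            corrs = []
            for r in range(fa.order):
                c = np.corrcoef(fa_scores[:, r], truth.scores_true[:, r])[0, 1]
                corrs.append(float(abs(c)))
            out["score_correlations"] = corrs

    # accuracy calibration: empirical corr(u~, u) per environment vs model-based
    from .postfit import accuracy

    try:
        _, env_acc = accuracy(fit)
        uhat = fit.u_blup.to_numpy()
        obs = truth.incidence
        emp = np.full(len(truth.env_ids), np.nan)
        for j in range(len(truth.env_ids)):
            sel = obs[:, j]
            if sel.sum() > 2:
                emp[j] = np.corrcoef(uhat[sel, j], truth.u_true[sel, j])[0, 1]
        ok = np.isfinite(emp)
        out["accuracy_model_mean"] = float(np.nanmean(env_acc.to_numpy()[ok]))
        out["accuracy_empirical_mean"] = float(np.nanmean(emp[ok]))
    except ValidationError:
        pass
    return out
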