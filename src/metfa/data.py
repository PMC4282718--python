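"""Data model, I/O, filtering and connectivity diagnostics for second-stage MET data.

A multi-environment trial (MET) dataset holds variety means from a series of
field trials.  An *environment* is a location-year combination; each record is
the estimated mean yield of one variety in one environment together with a
statistical weight (the reciprocal variance of the mean, carried forward from
the individual-trial analyses).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import NoDataError, SchemaError, ValidationError

__all__ = [
    "Environment",
    "METData",
    "ConnectivityTable",
    "env_key",
    "read_met_csv",
    "write_met_csv",
    "filter_dataset",
    "connectivity",
    "connectivity_components",
]

#: canonical record columns, in storage order
RECORD_COLUMNS = ["variety", "env_id", "mean", "weight"]


def env_key(location, year) -> str:
    """Environment identifier: trial location name joined with year."""
    return f"{location}_{int(year)}"


@dataclass
class Environment:
    """A trial environment (location-year) with its reporting attributes."""

    env_id: str
    location: str
    year: int
    region: str
    mega_region: str | None = None
    trial_mean_yield: float | None = None
    error_ms: float | None = None


@dataclass
class METData:
    """Second-stage MET dataset: environments, varieties and weighted means.

    ``records`` has columns ``variety, env_id, mean, weight`` with at most one
    row per (variety, env_id).  Weights are carried exactly as supplied.
    """

    environments: list[Environment]
    records: pd.DataFrame
    variety_flags: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self):
        env_ids = [e.env_id for e in self.environments]
        if len(set(env_ids)) != len(env_ids):
            raise ValidationError("duplicate env_id in environment register")
        self.records = self.records.reset_index(drop=True)[RECORD_COLUMNS]
        unknown = set(self.records["env_id"]) - set(env_ids)
        if unknown:
            raise ValidationError(f"records reference unregistered environments: {sorted(unknown)}")
        bad = self.records.index[~(self.records["weight"] > 0)]
        if len(bad):
            raise ValidationError(f"non-positive weight at record row(s) {list(bad[:5])}")
        dup = self.records.duplicated(subset=["variety", "env_id"])
        if dup.any():
            rows = self.records.loc[dup, ["variety", "env_id"]].iloc[0]
            raise ValidationError(
                f"duplicate record for variety {rows['variety']!r} in environment {rows['env_id']!r}"
            )

    # -- registers ---------------------------------------------------------
    @property
    def env_ids(self) -> list[str]:
        return [e.env_id for e in self.environments]

    @property
    def varieties(self) -> list[str]:
        return sorted(self.records["variety"].unique())

    @property
    def n(self) -> int:
        """Number of records (length of the data vector y)."""
        return len(self.records)

    @property
    def m(self) -> int:
        """Number of varieties."""
        return self.records["variety"].nunique()

    @property
    def t(self) -> int:
        """Number of environments (trials)."""
        return len(self.environments)

    def environment(self, env_id: str) -> Environment:
        for e in self.environments:
            if e.env_id == env_id:
                return e
        raise KeyError(env_id)

    def env_attr(self, name: str) -> pd.Series:
        """Per-environment attribute as a Series indexed by env_id."""
        return pd.Series({e.env_id: getattr(e, name) for e in self.environments})

    def varieties_in(self, env_id: str) -> set[str]:
        return set(self.records.loc[self.records["env_id"] == env_id, "variety"])

    def is_filler(self, variety: str) -> bool:
        return bool(self.variety_flags.get(variety, False))


@dataclass
class ConnectivityTable:
    """Pairwise variety-in-common counts between trials, plus group averages.

    ``pairwise_common[j, j]`` is the number of varieties grown in trial j.
    The group table averages off-diagonal counts over all cross-group trial
    pairs; its diagonal is the mean per-trial variety count within the group.
    """

    pairwise_common: pd.DataFrame
    group_average: pd.DataFrame
    diagonal_average: pd.Series


# ---------------------------------------------------------------------------
# I/O

_MANDATORY = ["location", "year", "region", "variety", "mean", "weight"]


def read_met_csv(path, schema: dict[str, str] | None = None) -> METData:
    """Read a second-stage MET dataset from CSV.

    ``schema`` maps the canonical column names (location, year, region,
    variety, mean, weight, and optionally filler / mega_region /
    trial_mean_yield / error_ms) to the actual column names in the file.
    """
    schema = dict(schema or {})
    df = pd.read_csv(path)
    colmap = {name: schema.get(name, name) for name in _MANDATORY}
    missing = [c for c in colmap.values() if c not in df.columns]
    if missing:
        raise SchemaError(f"missing column(s) {missing} in {path}")
    out = pd.DataFrame({k: df[v] for k, v in colmap.items()})
    for name in _MANDATORY:
        na = out.index[out[name].isna()]
        if len(na):
            raise ValidationError(f"missing value in column {name!r} at row(s) {list(na[:5])}")
    out["year"] = out["year"].astype(int)
    out["env_id"] = [env_key(l, y) for l, y in zip(out["location"], out["year"])]

    def _optional(name):
        col = schema.get(name, name)
        return df[col] if col in df.columns else None

    env_extra = {}
    for name in ("mega_region", "trial_mean_yield", "error_ms"):
        col = _optional(name)
        if col is not None:
            env_extra[name] = col

    environments = []
    for env_id, grp in out.groupby("env_id", sort=True):
        i = grp.index[0]
        kw = {k: v.iloc[i] for k, v in env_extra.items()}
        environments.append(
            Environment(
                env_id=env_id,
                location=str(grp["location"].iloc[0]),
                year=int(grp["year"].iloc[0]),
                region=str(grp["region"].iloc[0]),
                **kw,
            )
        )

    filler_col = _optional("filler")
    flags = {}
    if filler_col is not None:
        filler = filler_col.fillna(False).astype(bool)
        for v, fl in zip(out["variety"], filler):
            flags[str(v)] = flags.get(str(v), False) or bool(fl)

    records = out[["variety", "env_id", "mean", "weight"]].astype(
        {"variety": str, "mean": float, "weight": float}
    )
    return METData(environments=environments, records=records, variety_flags=flags)


def write_met_csv(data: METData, path) -> None:
    """Write a METData back to the canonical CSV layout."""
    env = {e.env_id: e for e in data.environments}
    rec = data.records.copy()
    rec["location"] = [env[i].location for i in rec["env_id"]]
    rec["year"] = [env[i].year for i in rec["env_id"]]
    rec["region"] = [env[i].region for i in rec["env_id"]]
    rec["filler"] = [data.is_filler(v) for v in rec["variety"]]
    cols = ["location", "year", "region", "variety", "mean", "weight", "filler"]
    rec[cols].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Filtering

@dataclass
class TrialFlags:
    """Per-trial diagnostics feeding the inclusion rules."""

    f_ratio: float | None = None
    diag_gvar_zero: bool | None = None


def filter_dataset(
    data: METData,
    trial_flags: dict[str, TrialFlags] | None = None,
    min_trials: int = 4,
) -> tuple[METData, pd.DataFrame]:
    """Apply the MET inclusion rules; return the kept data and a removal log.

    Trials are dropped when they show no genetic variance: a first-stage
    variety F-ratio below 1, or a genetic variance pinned at zero in a
    diagonal-model fit.  Varieties are then dropped when grown in fewer than
    ``min_trials`` of the remaining trials, or when flagged as fillers.  The
    variety rule runs in a single pass after trial removal.
    """
    trial_flags = trial_flags or {}
    known = set(data.env_ids)
    unknown = set(trial_flags) - known
    if unknown:
        raise ValidationError(f"trial_flags reference unknown environments: {sorted(unknown)}")

    log = []
    drop_envs = set()
    for env_id in data.env_ids:
        fl = trial_flags.get(env_id)
        if fl is None:
            continue
        if fl.f_ratio is not None and fl.f_ratio < 1:
            drop_envs.add(env_id)
            log.append(("environment", env_id, "no genetic variance (F<1)", f"F={fl.f_ratio:g}"))
        elif fl.diag_gvar_zero:
            drop_envs.add(env_id)
            log.append(("environment", env_id, "no genetic variance (diag zero)", ""))

    rec = data.records[~data.records["env_id"].isin(drop_envs)]
    counts = rec.groupby("variety")["env_id"].nunique()
    drop_vars = set()
    for v in sorted(data.records["variety"].unique()):
        c = int(counts.get(v, 0))
        if data.is_filler(v):
            drop_vars.add(v)
            log.append(("variety", v, "filler", ""))
        elif c < min_trials:
            drop_vars.add(v)
            log.append(("variety", v, f"grown in fewer than {min_trials} trials", f"count={c}"))
    rec = rec[~rec["variety"].isin(drop_vars)]

    if rec.empty:
        raise NoDataError("no data remain after filtering")
    keep_envs = set(rec["env_id"])
    environments = [e for e in data.environments if e.env_id in keep_envs]
    for e in data.environments:
        if e.env_id not in keep_envs and e.env_id not in drop_envs:
            log.append(("environment", e.env_id, "emptied by variety removal", ""))
    flags = {v: f for v, f in data.variety_flags.items() if v in set(rec["variety"])}
    out = METData(environments=environments, records=rec.reset_index(drop=True), variety_flags=flags)
    log_df = pd.DataFrame(log, columns=["entity_type", "entity", "rule", "detail"])
    return out, log_df


# ---------------------------------------------------------------------------
# Connectivity

_GROUPINGS = ("trial", "region", "region_year")


def connectivity(data: METData, group_by: str = "region") -> ConnectivityTable:
    """Varieties-in-common table between trials, averaged by a grouping factor.

    Connectivity governs the estimability of between-environment genetic
    covariances: the information for a covariance comes from the varieties
    the two trials share.
    """
    if group_by not in _GROUPINGS:
        raise ValidationError(f"unknown grouping factor {group_by!r}; expected one of {_GROUPINGS}")

    env_ids = data.env_ids
    idx = {e: i for i, e in enumerate(env_ids)}
    t = len(env_ids)
    # incidence matrix varieties x trials
    varieties = data.varieties
    vidx = {v: i for i, v in enumerate(varieties)}
    inc = np.zeros((len(varieties), t), dtype=int)
    for v, e in zip(data.records["variety"], data.records["env_id"]):
        inc[vidx[v], idx[e]] = 1
    common = inc.T @ inc  # diagonal = varieties per trial
    pairwise = pd.DataFrame(common, index=env_ids, columns=env_ids)

    if group_by == "trial":
        labels = {e: e for e in env_ids}
    elif group_by == "region":
        labels = {e.env_id: e.region for e in data.environments}
    else:
        labels = {e.env_id: f"{e.region}_{e.year}" for e in data.environments}
    groups = sorted(set(labels.values()))
    gidx = {g: [idx[e] for e in env_ids if labels[e] == g] for g in groups}

    gavg = pd.DataFrame(np.zeros((len(groups), len(groups))), index=groups, columns=groups)
    diag_avg = pd.Series({g: float(np.mean(common[np.array(ii), np.array(ii)])) for g, ii in gidx.items()})
    for a in groups:
        for b in groups:
            if a == b:
                # diagonal mirrors the per-trial variety count convention
                gavg.loc[a, b] = diag_avg[a]
            else:
                block = common[np.ix_(gidx[a], gidx[b])]
                gavg.loc[a, b] = float(block.mean())
    return ConnectivityTable(pairwise_common=pairwise, group_average=gavg, diagonal_average=diag_avg)


def connectivity_components(table: ConnectivityTable, min_common: int = 1) -> list[list[str]]:
    """Connected components of the trial graph with edges where the pairwise
    common-variety count reaches ``min_common``.

    A single component certifies that the dataset can be analysed as one
    mega-region (possibly through a moving window of connectivity); fully
    disconnected subsets make factor analytic models unfittable.
    """
    if min_common < 1:
        raise ValidationError("min_common must be >= 1")
    from scipy.sparse import csgraph, csr_matrix

    env_ids = list(table.pairwise_common.index)
    adj = (table.pairwise_common.to_numpy() >= min_common).astype(int)
    np.fill_diagonal(adj, 0)
    ncomp, labels = csgraph.connected_components(csr_matrix(adj), directed=False)
    comps = [[] for _ in range(ncomp)]
    for e, lab in zip(env_ids, labels):
        comps[lab].append(e)
    comps.sort(key=lambda c: (-len(c), c))
    return comps
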