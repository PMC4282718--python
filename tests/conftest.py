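import numpy as np
import pandas as pd
import pytest

from metfa.data import Environment, METData


def make_met(
    t=3,
    m=8,
    seed=0,
    frac_missing=0.0,
    G=None,
    weights=(2.0, 10.0),
    trial_means=None,
    regions=None,
    years=None,
):
    """Small deterministic MET dataset drawn from a known G_e."""
    rng = np.random.default_rng(seed)
    if G is None:
        d = rng.uniform(0.2, 0.6, t)
        G = np.outer(np.sqrt(d), np.sqrt(d)) * (0.6 + 0.4 * np.eye(t))
    if trial_means is None:
        trial_means = rng.uniform(1.5, 4.0, t)
    years = years or [2020 + (j % 2) for j in range(t)]
    regions = regions or [f"R{1 + (2 * j) // t}" for j in range(t)]
    envs = [
        Environment(f"L{j:02d}_{years[j]}", f"L{j:02d}", years[j], regions[j])
        for j in range(t)
    ]
    u = rng.multivariate_normal(np.zeros(t), G, size=m)
    rows = []
    for i in range(m):
        for j in range(t):
            if frac_missing and rng.random() < frac_missing:
                continue
            w = rng.uniform(*weights)
            y = trial_means[j] + u[i, j] + rng.normal(0, np.sqrt(1 / w))
            rows.append((f"v{i:02d}", envs[j].env_id, y, w))
    # guarantee every environment and variety is represented
    present_envs = {r[1] for r in rows}
    for j in range(t):
        if envs[j].env_id not in present_envs:
            rows.append(("v00", envs[j].env_id, trial_means[j], 5.0))
    rec = pd.DataFrame(rows, columns=["variety", "env_id", "mean", "weight"])
    rec = rec.drop_duplicates(subset=["variety", "env_id"])
    return METData(environments=envs, records=rec), G


@pytest.fixture
def met_small():
    data, G = make_met(t=3, m=8, seed=1)
    return data


@pytest.fixture
def met_missing():
    data, G = make_met(t=3, m=10, seed=2, frac_missing=0.25)
    return data
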