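import numpy as np
import pandas as pd
import pytest

from beetox import (compute_toxic_load, consensus_table, default_scenario,
                    fill_missing_series, generate_scenario,
                    standardize_and_filter)
from beetox.loads import annual_totals


@pytest.fixture(scope="session")
def default_data():
    """The default scenario (with missingness), seed 0."""
    return generate_scenario(default_scenario(seed=0))


@pytest.fixture(scope="session")
def clean_data():
    """The default scenario with all missingness disabled, seed 0."""
    return generate_scenario(default_scenario(seed=0, p_missing_use=0.0,
                                              p_withheld=0.0))


def run_to_loads(config, data):
    """Consensus + toxic load + gap filling for a generated scenario."""
    clean = standardize_and_filter(data.toxicity)
    catalog = [c.compound_id for c in config.compounds]
    moa = {c.compound_id: c.moa_group for c in config.compounds}
    consensus = consensus_table(clean, catalog, moa)
    raw = compute_toxic_load(data.use, consensus)
    return consensus, fill_missing_series(raw, config.year_list,
                                          fips_universe=data.counties["fips"])


def national_folds(config, data):
    """Recovered national contact/oral fold-changes for a scenario."""
    _, loads = run_to_loads(config, data)
    nat = annual_totals(loads).set_index("year")
    y0, y1 = config.years
    return {route: float(nat.loc[y1, f"{route}_load"] / nat.loc[y0, f"{route}_load"])
            for route in ("contact", "oral")}


def toxicity_frame(rows):
    """Build a toxicity-record table from (compound, route, value, units,
    bound, source_tier, duration_days, life_stage) tuples."""
    return pd.DataFrame(rows, columns=["compound", "route", "value", "units",
                                       "bound", "source_tier", "duration_days",
                                       "life_stage"])


def exact_mk_p(series) -> float:
    """Exact two-sided Mann-Kendall p by enumerating all orderings."""
    from itertools import permutations

    x = np.asarray(series, dtype=float)
    n = x.size
    iu = np.triu_indices(n, k=1)

    def s_stat(v):
        return np.sign(v[iu[1]] - v[iu[0]]).sum()

    s_obs = abs(s_stat(x))
    perms = np.array(list(permutations(x)))
    diffs = np.sign(perms[:, iu[1]] - perms[:, iu[0]])
    s_all = diffs.sum(axis=1)
    return float(np.mean(np.abs(s_all) >= s_obs))


def brute_jenks_ssd(values, k):
    """Minimal within-class SSD over all contiguous partitions of the sorted
    values that never split tied values; returns (ssd, interior breaks)."""
    from itertools import combinations

    xs = np.sort(np.asarray(values, dtype=float))
    cut_positions = [i for i in range(1, xs.size) if xs[i - 1] != xs[i]]
    best = (np.inf, None)
    for cuts in combinations(cut_positions, k - 1):
        bounds = (0, *cuts, xs.size)
        ssd = 0.0
        for a, b in zip(bounds[:-1], bounds[1:]):
            seg = xs[a:b]
            ssd += float(((seg - seg.mean()) ** 2).sum())
        if ssd < best[0]:
            best = (ssd, tuple(float(xs[c - 1]) for c in cuts))
    return best


def brute_ward(vectors):
    """Greedy minimum-variance agglomeration computed directly from member
    vectors (no Lance-Williams): returns merges [(i, j, height, count)] with
    the same node-id and height conventions as beetox.cluster.ward_cluster.
    """
    x = np.asarray(vectors, dtype=float)
    n = x.shape[0]
    members = {i: [i] for i in range(n)}

    def sse(idx):
        pts = x[idx]
        return float(((pts - pts.mean(axis=0)) ** 2).sum())

    merges = []
    next_id = n
    while len(members) > 1:
        best = None
        for i in sorted(members):
            for j in sorted(members):
                if j <= i:
                    continue
                cost = sse(members[i] + members[j]) - sse(members[i]) - sse(members[j])
                if best is None or cost < best[0]:
                    best = (cost, i, j)
        cost, i, j = best
        merged = members.pop(i) + members.pop(j)
        merges.append((i, j, float(np.sqrt(2.0 * cost)), len(merged)))
        members[next_id] = merged
        next_id += 1
    return merges
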