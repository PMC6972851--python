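"""Hierarchical time-series clustering of regional toxic-load series.

Regional annual series differ by orders of magnitude in absolute load, so
they are first normalized to fold-change relative to the first year; the
normalized vectors are then agglomerated with Ward's minimum-variance
criterion on a Euclidean distance matrix.  The merge heights follow the
convention in which leaves start at the Euclidean distance and cluster
distances are updated with the Lance-Williams recurrence on squared
distances (the "ward.D2" convention shared by the common reference
implementations), so trees are directly comparable with those packages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = ["RegionSeries", "MergeTree", "normalize_series", "ward_cluster"]


@dataclass(frozen=True)
class RegionSeries:
    """One region's annual series (e.g., oral toxic load by year)."""

    region: str
    years: tuple
    values: tuple
    normalized: bool = False


@dataclass(frozen=True)
class MergeTree:
    """Agglomeration result: n-1 merges over n labelled leaves.

    Nodes 0..n-1 are the leaves (in ``labels`` order); merge i creates node
    n+i.  Each merge records (left, right, height, member count), heights
    non-decreasing under Ward's criterion.
    """

    labels: tuple
    merges: tuple  # of (left, right, height, count)
    _members: dict = field(default_factory=dict, repr=False, compare=False)

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def members(self, node: int) -> frozenset:
        """Leaf labels under a node id."""
        n = self.n_leaves
        if node < n:
            return frozenset([self.labels[node]])
        left, right, _, _ = self.merges[node - n]
        return self.members(left) | self.members(right)

    def top_split(self):
        """The two label sets separated by the final (root) merge."""
        left, right, _, _ = self.merges[-1]
        return self.members(left), self.members(right)

    def to_newick(self) -> str:
        """Newick string with branch lengths = parent height - child height."""
        n = self.n_leaves
        heights = {i: 0.0 for i in range(n)}
        for i, (_, _, h, _) in enumerate(self.merges):
            heights[n + i] = h

        def render(node: int, parent_h: float) -> str:
            bl = parent_h - heights[node]
            if node < n:
                return f"{self.labels[node]}:{bl:.6g}"
            left, right, h, _ = self.merges[node - n]
            return f"({render(left, h)},{render(right, h)}):{bl:.6g}"

        root = n + len(self.merges) - 1
        left, right, h, _ = self.merges[-1]
        return f"({render(left, h)},{render(right, h)});"

    def to_table(self):
        """Merge list as a DataFrame (one row per merge)."""
        import pandas as pd

        return pd.DataFrame(self.merges, columns=["left", "right", "height", "count"])


def normalize_series(series: RegionSeries) -> RegionSeries:
    """Convert an absolute series to fold-change relative to its first year."""
    v0 = series.values[0]
    if not v0 > 0:
        raise ValueError(f"cannot normalize series {series.region!r}: "
                         f"first-year value {v0!r} is not positive")
    vals = tuple(v / v0 for v in series.values)
    return RegionSeries(region=series.region, years=series.years,
                        values=vals, normalized=True)


def ward_cluster(series) -> MergeTree:
    """Agglomerate equal-length series with Ward's linkage.

    Parameters
    ----------
    series : sequence of RegionSeries
        At least two series of equal length (normalize first for the
        fold-change analysis; this function clusters whatever it is given).

    Notes
    -----
    Distances start as Euclidean between the series vectors; after merging
    clusters i and j the distance to any cluster m follows
    ``d(ij,m)^2 = [(n_i+n_m) d_im^2 + (n_j+n_m) d_jm^2 - n_m d_ij^2] / (n_i+n_j+n_m)``.
    Ties in the minimum merge distance are broken by the lexicographically
    smallest (left, right) node-id pair, making the tree deterministic for a
    given input order.
    """
    series = list(series)
    if len(series) < 2:
        raise ValueError("ward_cluster needs at least two series")
    lengths = {len(s.values) for s in series}
    if len(lengths) != 1:
        raise ValueError(f"series have unequal lengths: {sorted(lengths)}")
    labels = tuple(s.region for s in series)
    if len(set(labels)) != len(labels):
        raise ValueError("series labels must be unique")
    x = np.array([s.values for s in series], dtype=float)
    n = len(series)

    # squared distances between active nodes
    d2: dict = {}
    for i in range(n):
        for j in range(i + 1, n):
            d2[(i, j)] = float(np.sum((x[i] - x[j]) ** 2))
    size = {i: 1 for i in range(n)}
    active = set(range(n))
    merges = []
    next_id = n
    for _ in range(n - 1):
        best = None
        for i in sorted(active):
            for j in sorted(active):
                if j <= i:
                    continue
                key = (i, j)
                if best is None or d2[key] < best[0]:
                    best = (d2[key], i, j)
        _, i, j = best
        h = math.sqrt(d2[(i, j)])
        merges.append((i, j, h, size[i] + size[j]))
        new = next_id
        next_id += 1
        for m in sorted(active - {i, j}):
            si, sj, sm = size[i], size[j], size[m]
            dim = d2[(min(i, m), max(i, m))]
            djm = d2[(min(j, m), max(j, m))]
            dij = d2[(i, j)]
            d2[(m, new)] = ((si + sm) * dim + (sj + sm) * djm - sm * dij) / (si + sj + sm)
        size[new] = size[i] + size[j]
        active -= {i, j}
        active.add(new)
    return MergeTree(labels=labels, merges=tuple(merges))
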