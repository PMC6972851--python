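"""Fisher-Jenks natural-breaks classification.

Natural breaks partition a set of numeric county values into k classes that
minimize the total within-class sum of squared deviations from class means,
under the constraint that classes are contiguous intervals of the sorted
values.  The exact optimum is found by dynamic programming over the distinct
values (so tied values can never be split across classes).  A zero-centered
variant, used for change maps where sign matters, classifies negative and
non-negative values separately with a forced class boundary at zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["BreaksResult", "jenks_breaks", "zero_centered_breaks"]


@dataclass(frozen=True)
class BreaksResult:
    """A k-class natural-breaks classification of a value list."""

    k: int
    #: k+1 boundaries: data minimum, k-1 interior cuts, data maximum.
    #: Class c (0-based) is (breaks[c], breaks[c+1]], except class 0 which
    #: also contains the minimum.
    breaks: tuple
    #: Class index (0..k-1) for each input value, in input order.
    assignment: np.ndarray = field(repr=False)
    #: Goodness of variance fit, 1 - SSD_within / SSD_total, in [0, 1].
    gvf: float
    #: Total within-class sum of squared deviations at the optimum.
    ssd_within: float


def _weighted_prefix(values: np.ndarray, weights: np.ndarray):
    w = np.concatenate([[0.0], np.cumsum(weights)])
    wx = np.concatenate([[0.0], np.cumsum(weights * values)])
    wx2 = np.concatenate([[0.0], np.cumsum(weights * values * values)])
    return w, wx, wx2


def _interval_ssd(w, wx, wx2, i: int, j: int) -> float:
    """SSD of distinct values i..j inclusive (0-based) about their mean."""
    sw = w[j + 1] - w[i]
    sx = wx[j + 1] - wx[i]
    sx2 = wx2[j + 1] - wx2[i]
    return max(sx2 - sx * sx / sw, 0.0)


def jenks_breaks(values, k: int) -> BreaksResult:
    """Exact Fisher-Jenks optimal classification into k classes.

    Parameters
    ----------
    values : sequence of float
        Finite values to classify; at least k distinct values required.
    k : int
        Number of classes, k >= 1.

    Notes
    -----
    The dynamic program runs over the distinct sorted values weighted by
    multiplicity, which is both O(k m^2) in the number m of distinct values
    and guarantees equal values always share a class.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("values must be a non-empty 1-d sequence")
    if not np.all(np.isfinite(x)):
        raise ValueError("values must be finite")
    if k < 1:
        raise ValueError("k must be >= 1")
    uniq, counts = np.unique(x, return_counts=True)
    m = uniq.size
    if k > m:
        raise ValueError(f"k={k} exceeds the number of distinct values ({m})")

    w, wx, wx2 = _weighted_prefix(uniq, counts.astype(float))
    total_ssd = _interval_ssd(w, wx, wx2, 0, m - 1)

    # cost[c][j]: minimal SSD of splitting uniq[0..j] into c+1 classes
    inf = float("inf")
    cost = np.full((k, m), inf)
    split = np.zeros((k, m), dtype=int)  # first index of the last class
    for j in range(m):
        cost[0, j] = _interval_ssd(w, wx, wx2, 0, j)
    for c in range(1, k):
        for j in range(c, m):
            best, best_i = inf, c
            for i in range(c, j + 1):
                cand = cost[c - 1, i - 1] + _interval_ssd(w, wx, wx2, i, j)
                if cand < best:
                    best, best_i = cand, i
            cost[c, j] = best
            split[c, j] = best_i

    # backtrack class start indices
    starts = [0] * k
    j = m - 1
    for c in range(k - 1, 0, -1):
        starts[c] = split[c, j]
        j = starts[c] - 1
    uppers = [uniq[starts[c + 1] - 1] for c in range(k - 1)]
    brks = (float(uniq[0]), *map(float, uppers), float(uniq[-1]))

    interior = np.array(uppers, dtype=float)
    assignment = np.searchsorted(interior, x, side="left")
    ssd_within = float(cost[k - 1, m - 1])
    gvf = 0.0 if total_ssd == 0 else 1.0 - ssd_within / total_ssd
    return BreaksResult(k=k, breaks=brks, assignment=assignment,
                        gvf=float(gvf), ssd_within=ssd_within)


def zero_centered_breaks(values, k: int) -> BreaksResult:
    """Natural breaks with a forced class boundary at zero.

    Negative and non-negative values are classified separately; the class
    budget k is split between the two sides in proportion to their share of
    the values (at least one class per side).  Intended for diverging change
    maps where the sign of the value is meaningful.  One-signed input falls
    back to plain :func:`jenks_breaks` with a warning.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("values must be a non-empty 1-d sequence")
    neg_mask = x < 0
    pos_mask = ~neg_mask
    if k < 2 or not neg_mask.any() or not pos_mask.any():
        if neg_mask.any() and pos_mask.any():
            raise ValueError("zero-centered classification requires k >= 2")
        warnings.warn("one-signed input: falling back to plain natural breaks",
                      RuntimeWarning, stacklevel=2)
        return jenks_breaks(x, k)

    neg, pos = x[neg_mask], x[pos_mask]
    k_neg = int(round(k * neg.size / x.size))
    k_neg = min(max(k_neg, 1), k - 1)
    # never ask a side for more classes than it has distinct values
    k_neg = min(k_neg, np.unique(neg).size)
    k_pos = min(k - k_neg, np.unique(pos).size)
    k_neg = min(k - k_pos, np.unique(neg).size)

    res_neg = jenks_breaks(neg, k_neg)
    res_pos = jenks_breaks(pos, k_pos)

    brks = (*res_neg.breaks[:-1], 0.0,
            *res_pos.breaks[1:-1], float(res_pos.breaks[-1]))
    assignment = np.empty(x.size, dtype=int)
    assignment[neg_mask] = res_neg.assignment
    assignment[pos_mask] = res_pos.assignment + k_neg

    # gvf over the combined partition
    total = float(np.sum((x - x.mean()) ** 2))
    within = res_neg.ssd_within + res_pos.ssd_within
    # zero boundary splits the sides, so add nothing else: side SSDs are exact
    gvf = 0.0 if total == 0 else 1.0 - within / total
    return BreaksResult(k=k_neg + k_pos, breaks=brks, assignment=assignment,
                        gvf=float(gvf), ssd_within=float(within))
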