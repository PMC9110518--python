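"""Independent brute-force oracles used by the tests.

These deliberately avoid the package's own code paths: explicit loops,
explicit histogram arrays, explicit permutation enumeration.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def brute_force_threshold(
    values,
    n_bins: int = 128,
    sd_multiplier: float = 0.5,
    base_rule: str = "freq95",
    bin_edges=None,
):
    """Loop-based reimplementation of the histogram threshold rule.

    Returns (counts, mode_value, base_value, sd, threshold).
    """
    values = [float(v) for v in np.ravel(values)]
    vmin, vmax = min(values), max(values)
    if vmax == vmin:
        return np.array([len(values)]), vmin, vmin, 0.0, vmin
    if bin_edges is None:
        edges = [vmin + (vmax - vmin) * i / n_bins for i in range(n_bins + 1)]
    else:
        edges = list(bin_edges)
        n_bins = len(edges) - 1
    counts = [0] * n_bins
    for v in values:
        # last bin is closed on the right, as in numpy.histogram
        placed = False
        for b in range(n_bins - 1):
            if edges[b] <= v < edges[b + 1]:
                counts[b] += 1
                placed = True
                break
        if not placed and v >= edges[n_bins - 1]:
            # right-closed last bin; guard against the top edge rounding
            # below the true maximum in floating point
            counts[n_bins - 1] += 1
    mode_idx = 0
    for b in range(n_bins):
        if counts[b] > counts[mode_idx]:
            mode_idx = b
    centers = [(edges[b] + edges[b + 1]) / 2.0 for b in range(n_bins)]
    mode_value = centers[mode_idx]
    if base_rule == "freq95":
        base_idx = mode_idx
        for b in range(mode_idx, n_bins):
            if counts[b] <= 0.95 * counts[mode_idx]:
                base_idx = b
                break
        base_value = centers[base_idx]
    else:
        base_value = 0.95 * mode_value
    n = len(values)
    mean = sum(values) / n
    sd = (sum((v - mean) ** 2 for v in values) / (n - 1)) ** 0.5 if n > 1 else 0.0
    return np.array(counts), mode_value, base_value, sd, base_value + sd_multiplier * sd


def kw_statistic(groups) -> float:
    """Tie-corrected Kruskal-Wallis statistic computed from first principles."""
    from scipy.stats import rankdata

    pooled = np.concatenate([np.asarray(g, float) for g in groups])
    n = pooled.size
    ranks = rankdata(pooled)
    h = 0.0
    start = 0
    for g in groups:
        m = len(g)
        h += m * (ranks[start : start + m].mean() - (n + 1) / 2.0) ** 2
        start += m
    h *= 12.0 / (n * (n + 1))
    _, t = np.unique(pooled, return_counts=True)
    c = 1.0 - np.sum(t**3 - t) / (n**3 - n)
    return h / c if c > 0 else 0.0


def kw_permutation_p(groups, n_draws: int = 100_000, seed: int = 0) -> float:
    """Monte-Carlo permutation p-value of the tie-corrected KW statistic."""
    rng = np.random.default_rng(seed)
    sizes = [len(g) for g in groups]
    pooled = np.concatenate([np.asarray(g, float) for g in groups])
    observed = kw_statistic(groups)
    count = 0
    for _ in range(n_draws):
        perm = rng.permutation(pooled)
        split = np.split(perm, np.cumsum(sizes)[:-1])
        if kw_statistic(split) >= observed - 1e-12:
            count += 1
    return (count + 1) / (n_draws + 1)


def exact_ranksum_two_sided_pvalues(x, y):
    """Exact two-sided rank-sum p-values attainable for |x| vs |y| splits.

    Enumerates every split of the pooled sample into groups of the given
    sizes and returns the exact two-sided p of the observed rank sum plus
    the minimum attainable p.
    """
    from scipy.stats import rankdata

    pooled = np.asarray(list(x) + list(y), float)
    n_x = len(x)
    ranks = rankdata(pooled)
    observed = ranks[:n_x].sum()
    expect = n_x * (len(pooled) + 1) / 2.0
    sums = np.array(
        [ranks[list(c)].sum() for c in combinations(range(len(pooled)), n_x)]
    )
    dev = np.abs(sums - expect)
    p_obs = np.mean(dev >= abs(observed - expect) - 1e-12)
    p_min = np.min(
        [np.mean(dev >= d - 1e-12) for d in np.unique(dev)]
    )
    return float(p_obs), float(p_min)
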