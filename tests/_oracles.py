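"""Independent brute-force oracles used to check the fast implementations.

Everything here is deliberately naive (enumeration, O(n^2) scans) and
shares no code with the package.
"""

from itertools import combinations
from math import comb

import numpy as np


def brute_force_regions(manifest, min_sites=6, max_span=1000):
    """All containment-maximal qualifying windows by O(n^2) enumeration.

    A qualifying window [i, j] is contained in another qualifying window
    iff one of its single-step extensions [i-1, j] or [i, j+1] also
    qualifies: any strictly larger container [i', j'] admits such an
    extension as a subwindow, with at least as many sites and a span no
    larger than the container's (< max_span).  So maximality reduces to
    checking the two one-step extensions.

    Returns a set of (chrom, start, end, member site_id tuple).
    """
    maximal = set()
    for chrom, block in manifest.groupby("chrom", sort=False):
        pos = block["pos"].to_numpy()
        ids = block["site_id"].to_numpy()
        n = len(pos)

        def qualifies(i, j):
            return (0 <= i <= j < n and j - i + 1 >= min_sites
                    and pos[j] - pos[i] < max_span)

        for i in range(n):
            for j in range(i, n):
                if pos[j] - pos[i] >= max_span:
                    break
                if (qualifies(i, j) and not qualifies(i - 1, j)
                        and not qualifies(i, j + 1)):
                    maximal.add((chrom, int(pos[i]), int(pos[j]),
                                 tuple(ids[i:j + 1])))
    return maximal


def wilcoxon_exact_two_sided(x, y):
    """Two-sided rank-sum p by full enumeration of rank assignments.

    Valid only without ties.  Enumerates all C(n_x + n_y, n_x) ways the
    x-sample could occupy ranks and counts rank sums at least as
    extreme (two-sided, doubling convention capped at 1).
    """
    x, y = list(x), list(y)
    n_x, n = len(x), len(x) + len(y)
    ranks = np.argsort(np.argsort(np.concatenate([x, y]))) + 1
    w_obs = ranks[:n_x].sum()
    sums = [sum(c) for c in combinations(range(1, n + 1), n_x)]
    mean_w = n_x * (n + 1) / 2
    dev = abs(w_obs - mean_w)
    extreme = sum(1 for s in sums if abs(s - mean_w) >= dev - 1e-12)
    return min(extreme / len(sums), 1.0)


def bh_step_up(p_values):
    """Hand-rolled Benjamini–Hochberg step-up adjustment."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    prev = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        k = m - rank_from_top
        prev = min(prev, p[idx] * m / k)
        adjusted[idx] = prev
    return np.minimum(adjusted, 1.0)


def hypergeom_pmf(a, row1, row2, col1):
    """P(top-left cell = a) for fixed margins (row1, row2, col1)."""
    n = row1 + row2
    return comb(row1, a) * comb(row2, col1 - a) / comb(n, col1)


def fisher_two_sided(table):
    """Two-sided Fisher p by enumeration over all tables with the
    observed margins, summing probabilities <= the observed table's."""
    (a, b), (c, d) = table
    row1, row2, col1 = a + b, c + d, a + c
    lo = max(0, col1 - row2)
    hi = min(col1, row1)
    p_obs = hypergeom_pmf(a, row1, row2, col1)
    total = 0.0
    for k in range(lo, hi + 1):
        p_k = hypergeom_pmf(k, row1, row2, col1)
        if p_k <= p_obs * (1 + 1e-9):
            total += p_k
    return min(total, 1.0)


def auc_pairwise(scores, labels):
    """AUC as the fraction of case-control pairs ordered correctly,
    ties counting one half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def random_manifest(rng, n_sites, n_chroms=3, max_gap=400):
    """A random sorted CpG manifest for window-oracle comparisons."""
    import pandas as pd

    chroms = np.sort(rng.integers(1, n_chroms + 1, size=n_sites))
    rows = []
    i = 0
    for chrom in np.unique(chroms):
        n = int((chroms == chrom).sum())
        gaps = rng.integers(1, max_gap, size=n)
        pos = np.cumsum(gaps) + 100
        for p in pos:
            rows.append((f"cg{i:06d}", str(chrom), int(p), "+", ""))
            i += 1
    return pd.DataFrame(rows,
                        columns=["site_id", "chrom", "pos", "strand", "gene"])
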