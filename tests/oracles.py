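"""Independent brute-force oracles used to validate the implementation.

Everything here is deliberately naive — exhaustive loops and closed
forms — and shares no code with the package's own computations.
"""

from __future__ import annotations

import math
from itertools import product

import numpy as np


def check_tree_bruteforce(prevalence, parents, eps=0.05) -> bool:
    """Exhaustive cross-rule + pigeonhole check over all node pairs.

    ``prevalence``: clones x regions; ``parents``: list, -1 for root.
    The cross rule is checked over every ancestor-descendant pair, not
    just direct edges.
    """
    k, n_regions = np.asarray(prevalence).shape
    prevalence = np.asarray(prevalence, float)

    def ancestors(i):
        out = []
        while parents[i] != -1:
            i = parents[i]
            out.append(i)
        return out

    for child in range(k):
        for anc in ancestors(child):
            for r in range(n_regions):
                if prevalence[child, r] > prevalence[anc, r] + eps:
                    return False
    for parent in range(k):
        kids = [c for c in range(k) if parents[c] == parent]
        if not kids:
            continue
        for r in range(n_regions):
            if sum(prevalence[c, r] for c in kids) > prevalence[parent, r] + eps:
                return False
    return True


def enumerate_trees_bruteforce(prevalence, eps=0.05):
    """All feasible parent vectors (root = clone with max total prevalence)."""
    prevalence = np.asarray(prevalence, float)
    k = prevalence.shape[0]
    root = int(np.argmax(prevalence.sum(axis=1)))
    others = [i for i in range(k) if i != root]
    feasible = []
    for combo in product(range(k), repeat=len(others)):
        parents = [0] * k
        parents[root] = -1
        for c, p in zip(others, combo):
            parents[c] = p
        if any(parents[c] == c for c in others):
            continue
        ok = True
        for c in others:
            seen = set()
            cur = c
            while parents[cur] != -1:
                cur = parents[cur]
                if cur in seen:
                    ok = False
                    break
                seen.add(cur)
            if not ok:
                break
        if ok and check_tree_bruteforce(prevalence, parents, eps):
            feasible.append(tuple(parents))
    return feasible


def epiallele_metrics_bruteforce(counts):
    """Entropy/epipolymorphism/PDR by enumerating every read."""
    reads = []
    for i, c in enumerate(counts):
        pattern = format(i, "04b")
        reads.extend([pattern] * int(c))
    n = len(reads)
    freqs = {}
    for r in reads:
        freqs[r] = freqs.get(r, 0) + 1
    entropy = 0.0
    epipoly = 1.0
    for c in freqs.values():
        p = c / n
        entropy -= p * math.log2(p)
        epipoly -= p * p
    pdr = sum(1 for r in reads if r not in ("0000", "1111")) / n
    return entropy, epipoly, pdr


def fisher_exact_bruteforce(a, b, c, d):
    """Two-sided Fisher exact p-value by hypergeometric enumeration."""
    def comb(n, k):
        return math.comb(n, k)

    row1, row2 = a + b, c + d
    col1 = a + c
    n = row1 + row2
    denom = comb(n, col1)

    def prob(x):
        if x < 0 or x > row1 or col1 - x < 0 or col1 - x > row2:
            return 0.0
        return comb(row1, x) * comb(row2, col1 - x) / denom

    p_obs = prob(a)
    return sum(prob(x) for x in range(0, min(row1, col1) + 1)
               if prob(x) <= p_obs * (1 + 1e-9))


def partial_pearson_bruteforce(a, b, z):
    """Partial correlation via explicit OLS residuals (statsmodels)."""
    import statsmodels.api as sm

    z = np.asarray(z, float)
    if z.ndim == 1:
        z = z[:, None]
    X = sm.add_constant(z)
    ra = sm.OLS(np.asarray(a, float), X).fit().resid
    rb = sm.OLS(np.asarray(b, float), X).fit().resid
    return float(np.corrcoef(ra, rb)[0, 1])
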