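"""Independent brute-force oracles used to check the implementation.

These deliberately avoid the package's vectorised code paths: weights come
from direct string comparison of rank columns, Delta+ from explicit pair
enumeration, U statistics from pair counting, and permutation p-values
from exhaustive split enumeration.
"""

from __future__ import annotations

import itertools
from fractions import Fraction

import numpy as np

STEP1_BY_LEVEL = {"genus": 1, "family": 2, "order": 3, "class": 4, "none": 5}


def lineage_map(tax) -> dict[str, tuple[str, str, str, str]]:
    return {
        row["species"]: (row["genus"], row["family"], row["order"], row["class"])
        for _, row in tax.frame.iterrows()
    }


def brute_pair_weight(lineages: dict, a: str, b: str, offset: int = 0) -> float:
    ga, fa, oa, ca = lineages[a]
    gb, fb, ob, cb = lineages[b]
    if ga == gb:
        level = "genus"
    elif fa == fb:
        level = "family"
    elif oa == ob:
        level = "order"
    elif ca == cb:
        level = "class"
    else:
        level = "none"
    return STEP1_BY_LEVEL[level] + offset


def brute_delta_plus(tax, assemblage, offset: int = 0) -> float:
    """Mean pairwise weight via explicit enumeration of all i < j pairs."""
    lineages = lineage_map(tax)
    species = sorted(set(assemblage))
    pairs = list(itertools.combinations(species, 2))
    return sum(brute_pair_weight(lineages, a, b, offset) for a, b in pairs) / len(pairs)


def brute_u_statistic(x, y) -> tuple[float, float]:
    """(U1, U2) by direct pair counting with half-credit for ties."""
    u1 = 0.0
    for xi in x:
        for yj in y:
            if xi > yj:
                u1 += 1.0
            elif xi == yj:
                u1 += 0.5
    return u1, len(x) * len(y) - u1


def exact_permutation_p(x, y, stat=np.median) -> Fraction:
    """Two-sided permutation p over all C(n1+n2, n1) splits (exact)."""
    pooled = list(x) + list(y)
    n1 = len(x)
    observed = abs(stat(np.asarray(x, float)) - stat(np.asarray(y, float)))
    hits, total = 0, 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        a = np.array([pooled[i] for i in idx], dtype=float)
        b = np.array([pooled[i] for i in range(len(pooled)) if i not in idx], dtype=float)
        total += 1
        if abs(stat(a) - stat(b)) >= observed - 1e-12:
            hits += 1
    return Fraction(hits, total)


def enumerate_subset_deltas(tax, pool, s):
    """Delta+ of every size-s subset of the pool (exhaustive funnel support)."""
    return sorted(brute_delta_plus(tax, subset) for subset in itertools.combinations(pool, s))
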