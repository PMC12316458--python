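"""Brute-force reference implementations, independent of the package.

These deliberately avoid the production code paths (and their integer
shortcuts): the permutation oracle enumerates actual re-splits of labelled
observations with ``itertools.combinations`` and exact ``Fraction``
arithmetic, and the Fisher oracle enumerates the full hypergeometric
support with ``math.comb``.
"""

from fractions import Fraction
from itertools import combinations
from math import comb


def delta_fraction(counts_a, counts_b) -> Fraction:
    na, nb = sum(counts_a), sum(counts_b)
    return sum(
        abs(Fraction(ka, na) - Fraction(kb, nb))
        for ka, kb in zip(counts_a, counts_b)
    )


def exact_permutation_p(counts_a, counts_b) -> Fraction:
    """Exact p over every way to re-split the pooled labelled observations."""
    m = len(counts_a)
    labels = []
    for cat in range(m):
        labels += [cat] * (counts_a[cat] + counts_b[cat])
    n_a = sum(counts_a)
    n_total = len(labels)
    delta_obs = delta_fraction(counts_a, counts_b)
    hits = 0
    total = 0
    for idx in combinations(range(n_total), n_a):
        chosen = set(idx)
        ka = [0] * m
        kb = [0] * m
        for i, lab in enumerate(labels):
            if i in chosen:
                ka[lab] += 1
            else:
                kb[lab] += 1
        total += 1
        if delta_fraction(ka, kb) >= delta_obs:
            hits += 1
    return Fraction(hits, total)


def exact_fisher_two_sided_p(table) -> Fraction:
    """Point-probability two-sided Fisher p by full enumeration."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = comb(n, c1)
    p_obs = Fraction(comb(r1, a) * comb(r2, c1 - a), denom)
    total = Fraction(0)
    for aa in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = Fraction(comb(r1, aa) * comb(r2, c1 - aa), denom)
        if p <= p_obs:
            total += p
    return total
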