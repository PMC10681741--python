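"""Independent brute-force oracles used by the test suite.

Everything here is written from first principles (exact rational
arithmetic, exhaustive enumeration) and never calls the implementation it
checks.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction


# --- exact conditional heterozygote-count distribution --------------------

def het_pmf(n: int, n_alt: int) -> dict[int, Fraction]:
    """P(h heterozygotes | n genotypes, n_alt alternate alleles) under HWE.

    Counting arguments only: choose which genotypes are hom-alt/het, times
    2^h phase orderings, over all C(2n, n_alt) allele arrangements.
    """
    denom = math.comb(2 * n, n_alt)
    pmf: dict[int, Fraction] = {}
    h = n_alt % 2
    while h <= min(n_alt, 2 * n - n_alt):
        n_aa = (n_alt - h) // 2
        n_rr = n - h - n_aa
        if n_rr >= 0:
            ways = math.comb(n, n_aa) * math.comb(n - n_aa, h) * 2 ** h
            pmf[h] = Fraction(ways, denom)
        h += 2
    assert sum(pmf.values()) == 1
    return pmf


def excess_het_score(n_rr: int, n_het: int, n_aa: int) -> float:
    """Phred of the one-sided upper tail P(H >= observed)."""
    n = n_rr + n_het + n_aa
    n_alt = n_het + 2 * n_aa
    pmf = het_pmf(n, n_alt)
    tail = sum(p for h, p in pmf.items() if h >= n_het)
    return max(0.0, -10.0 * math.log10(float(tail)))


def hwe_two_sided_p(n_rr: int, n_het: int, n_aa: int) -> float:
    """Min-likelihood two-sided exact HWE p-value."""
    n = n_rr + n_het + n_aa
    n_alt = n_het + 2 * min(n_rr, n_aa)
    pmf = het_pmf(n, n_alt)
    p_obs = pmf[n_het]
    return float(min(Fraction(1), sum(p for p in pmf.values() if p <= p_obs)))


# --- confusion-table truth table ------------------------------------------

#: allele-dose policy: FP asserts extra alt alleles, FN misses them.
ALLELE_DOSE_TABLE = {
    (0, 0): "TN", (0, 1): "FP", (0, 2): "FP",
    (1, 0): "FN", (1, 1): "TP", (1, 2): "FP",
    (2, 0): "FN", (2, 1): "FN", (2, 2): "TP",
}


def tally(truth_codes, imputed_codes, drop_concordant_homref=True):
    """Brute-force TP/FP/FN/TN tally over paired code sequences."""
    counts = {"TP": 0, "FP": 0, "FN": 0, "TN": 0}
    for t, c in zip(truth_codes, imputed_codes):
        if t < 0 or c < 0:
            continue
        if drop_concordant_homref and t == 0 and c == 0:
            continue
        counts[ALLELE_DOSE_TABLE[(t, c)]] += 1
    return counts


# --- graph oracles ---------------------------------------------------------

def min_vertex_cover(nodes, edges) -> int:
    """Size of a minimum vertex cover by subset enumeration (|V| <= ~15)."""
    nodes = list(nodes)
    best = len(nodes)
    for r in range(len(nodes) + 1):
        for subset in itertools.combinations(nodes, r):
            s = set(subset)
            if all(a in s or b in s for a, b in edges):
                return r
    return best


def max_matching_count(centers_a, centers_b, max_dist) -> int:
    """Maximum one-to-one matching size within a center-distance bound."""
    edges = [
        (i, j)
        for i, a in enumerate(centers_a)
        for j, b in enumerate(centers_b)
        if abs(a - b) <= max_dist
    ]

    def rec(idx: int, used_b: frozenset) -> int:
        if idx == len(centers_a):
            return 0
        best = rec(idx + 1, used_b)
        for i, j in edges:
            if i == idx and j not in used_b:
                best = max(best, 1 + rec(idx + 1, used_b | {j}))
        return best

    return rec(0, frozenset())
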