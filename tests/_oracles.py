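"""Independent brute-force oracles used by the test suite.

These deliberately avoid scipy/statsmodels so they can cross-check the
library's probability computations: the Poisson tail is summed term by
term in floating point, the hypergeometric tail is summed in exact
integer arithmetic, interval merging is re-done with union-find, and
variant overlap with an all-pairs scan.
"""

from __future__ import annotations

import math
from fractions import Fraction


def poisson_upper_tail(k: int, lam: float) -> float:
    """P(X >= k) for X ~ Poisson(lam), by direct term summation."""
    if k <= 0:
        return 1.0
    if lam == 0:
        return 0.0
    # start at the term for i = k, computed in log space for stability
    log_term = -lam + k * math.log(lam) - math.lgamma(k + 1)
    term = math.exp(log_term)
    total = 0.0
    i = k
    while term > 0 and (term > total * 1e-18 or i < lam + 10):
        total += term
        i += 1
        term *= lam / i
        if i > k + 100000:  # pragma: no cover - safety net
            break
    return min(total, 1.0)


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N, K, n), exact integer enumeration."""
    if k <= max(0, n + K - N):
        return 1.0
    hi = min(n, K)
    if k > hi:
        return 0.0
    num = 0
    for i in range(k, hi + 1):
        num += math.comb(K, i) * math.comb(N - K, n - i)
    return float(Fraction(num, math.comb(N, n)))


def union_find_merge(intervals):
    """Merge (chrom, start, end) triples by >= 1 bp overlap, via union-find.

    Quadratic and order-free: the reference for the sweep-line merge.
    Returns sorted merged spans.
    """
    items = list(intervals)
    parent = list(range(len(items)))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb

    for i in range(len(items)):
        for j in range(i + 1, len(items)):
            ci, si, ei = items[i][:3]
            cj, sj, ej = items[j][:3]
            if ci == cj and si < ej and sj < ei:
                union(i, j)
    groups = {}
    for i, it in enumerate(items):
        groups.setdefault(find(i), []).append(it)
    merged = []
    for members in groups.values():
        chrom = members[0][0]
        merged.append(
            (chrom, min(m[1] for m in members), max(m[2] for m in members))
        )
    return sorted(merged)


def all_pairs_overlap(variants, domains):
    """Brute-force (snp_id, trait, chrom, start, end) hit triples.

    variants: iterables of (snp_id, chrom, position, trait, p_value);
    domains: (chrom, start, end, status). No sorting or indexing.
    """
    hits = set()
    for snp_id, vchrom, pos, trait, p in variants:
        for chrom, start, end, status in domains:
            if vchrom == chrom and start <= pos < end:
                hits.add((snp_id, trait, chrom, start, end, status))
    return hits
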