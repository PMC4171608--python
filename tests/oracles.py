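"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written from first principles (naive enumeration,
exact rational arithmetic) and must stay independent of the code paths
it checks.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb


def brute_force_repeats(seq: str, min_unit: int = 1, max_unit: int = 6) -> set[tuple[int, int, int]]:
    """Every maximal perfect tandem run, by testing all (start, period) pairs.

    Returns {(start, end, period)} for runs of >= 2 full units whose
    substring has minimal period == period, excluding runs containing N.
    """

    def min_period(sub: str) -> int:
        for q in range(1, len(sub)):
            if all(sub[i] == sub[i - q] for i in range(q, len(sub))):
                return q
        return len(sub)

    n = len(seq)
    found: set[tuple[int, int, int]] = set()
    for p in range(min_unit, max_unit + 1):
        for start in range(n):
            end = start + p
            while end < n and seq[end] == seq[end - p]:
                end += 1
            if end - start < 2 * p:
                continue
            if start > 0 and seq[start - 1] == seq[start - 1 + p]:
                continue  # not left-maximal
            sub = seq[start:end]
            if "N" in sub:
                continue
            if min_period(sub) != p:
                continue
            found.add((start, end, p))
    return found


def fisher_exact_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p by exact rational hypergeometric enumeration."""
    n = a + b + c + d
    if n == 0:
        return 1.0
    r1, c1 = a + b, a + c
    denom = comb(n, c1)
    lo = max(0, c1 - (c + d))
    hi = min(r1, c1)
    p_obs = Fraction(comb(r1, a) * comb(n - r1, c1 - a), denom)
    total = Fraction(0)
    for k in range(lo, hi + 1):
        pk = Fraction(comb(r1, k) * comb(n - r1, c1 - k), denom)
        if pk <= p_obs:
            total += pk
    return float(min(total, Fraction(1)))


def bh_oracle(p_values: list[float], q_star: float) -> list[bool]:
    """Textbook BH step-up: largest k with p_(k) <= (k/m) q_star passes."""
    m = len(p_values)
    if m == 0 or q_star <= 0:
        return [False] * m
    indexed = sorted(range(m), key=lambda i: p_values[i])
    k_max = 0
    for rank, i in enumerate(indexed, start=1):
        if p_values[i] <= rank / m * q_star:
            k_max = rank
    passed = [False] * m
    for rank, i in enumerate(indexed, start=1):
        if rank <= k_max:
            passed[i] = True
    return passed


def roc_oracle(
    pos: list[float], neg: list[float]
) -> tuple[float, float, float]:
    """Exhaustive-threshold confusion-matrix search for the Youden optimum.

    Returns (cutoff, sensitivity, specificity); ties on J break toward
    higher specificity then higher threshold, matching the documented
    rule.
    """
    best = None
    for t in sorted(set(pos) | set(neg)):
        tp = sum(1 for x in pos if x >= t)
        fp = sum(1 for x in neg if x >= t)
        sens = tp / len(pos)
        spec = (len(neg) - fp) / len(neg)
        j = sens + spec - 1.0
        key = (j, spec, t)
        if best is None or key > best[0]:
            best = (key, t, sens, spec)
    return best[1], best[2], best[3]


def nearest_distance_oracle(
    intervals: list[tuple[str, int, int]], chrom: str, start: int, end: int
) -> float:
    """All-pairs minimum gap distance (0 on overlap) to features on chrom."""
    best = float("inf")
    for c, s, e in intervals:
        if c != chrom:
            continue
        if s < end and e > start:
            return 0.0
        gap = s - end if s >= end else start - e
        best = min(best, gap)
    return max(best, 0.0)
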