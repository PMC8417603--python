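"""Independent brute-force oracles used by the test suite.

Deliberately naive re-derivations of the quantities the library computes:
an O(k^2) double loop for the pairwise Gini, exhaustive unordered-pair
enumeration for the Simpson index, an explicit trapezoid sum for curve
areas, and direct-formula evaluations for Hoover, Rosenbluth, entropy and
Atkinson.  They share no code with the library (plain Python loops and
``math`` only) so that agreement is evidence, not tautology.
"""

import itertools
import math


def oracle_gini_pairwise(units):
    """G = (1/2k) * sum_ij |p_i - p_j| by explicit double loop (k <= 100)."""
    units = list(units)
    k = len(units)
    if k > 100:
        raise ValueError("pairwise oracle limited to k <= 100")
    total = sum(units)
    p = [u / total for u in units]
    s = 0.0
    for i in range(k):
        for j in range(k):
            s += abs(p[i] - p[j])
    return s / (2.0 * k)


def oracle_hoover(units):
    """H = (1/2) * sum |p_i - 1/k| by direct loop."""
    units = list(units)
    k = len(units)
    total = sum(units)
    return 0.5 * sum(abs(u / total - 1.0 / k) for u in units)


def oracle_rosenbluth(units):
    """R = 1/(2 * sum i*p_(i) - 1) with explicit descending sort."""
    units = sorted(units, reverse=True)
    total = sum(units)
    acc = sum((i + 1) * (u / total) for i, u in enumerate(units))
    return 1.0 / (2.0 * acc - 1.0)


def oracle_hhi(units):
    """Sum of squared shares over positive components."""
    total = sum(units)
    return sum((u / total) ** 2 for u in units if u > 0)


def oracle_simpson_enumerate(counts):
    """Same-component probability by enumerating all unordered unit pairs.

    Each unit is tagged with its component; all C(N, 2) pairs are listed
    and the same-component fraction counted.  Limited to N <= 30.
    """
    tags = []
    for comp, c in enumerate(counts):
        if c != int(c):
            raise ValueError("integer counts required")
        tags.extend([comp] * int(c))
    n = len(tags)
    if n > 30:
        raise ValueError("enumeration oracle limited to N <= 30")
    if n < 2:
        raise ValueError("need at least two units")
    pairs = list(itertools.combinations(range(n), 2))
    same = sum(1 for a, b in pairs if tags[a] == tags[b])
    return same / len(pairs)


def oracle_area_trapezoid(x, y):
    """Area under a polyline by an explicit trapezoid sum."""
    area = 0.0
    for i in range(len(x) - 1):
        area += (x[i + 1] - x[i]) * (y[i] + y[i + 1]) / 2.0
    return area


def oracle_shannon(counts, base=2):
    """-sum p log_a p over positive counts, plain math."""
    total = sum(counts)
    acc = 0.0
    for c in counts:
        if c > 0:
            p = c / total
            acc -= p * math.log(p, base)
    return acc


def oracle_generalized_entropy(units, alpha):
    """Three-branch GE by direct formula evaluation."""
    units = list(units)
    k = len(units)
    total = sum(units)
    nbar = total / k
    r = [u / nbar for u in units]
    if alpha == 1:
        return sum(x * math.log(x) for x in r if x > 0) / k
    if alpha == 0:
        return -sum(math.log(x) for x in r) / k
    return sum(x**alpha - 1.0 for x in r) / (k * alpha * (alpha - 1.0))


def oracle_atkinson(units, epsilon):
    """1 - (power mean of order 1-eps)/mean, plain math."""
    units = list(units)
    k = len(units)
    nbar = sum(units) / k
    if epsilon == 0:
        return 0.0
    if epsilon == 1:
        if any(u == 0 for u in units):
            return 1.0
        gm = math.exp(sum(math.log(u) for u in units) / k)
        return 1.0 - gm / nbar
    q = 1.0 - epsilon
    if q < 0 and any(u == 0 for u in units):
        return 1.0
    pm = (sum(u**q for u in units) / k) ** (1.0 / q)
    return 1.0 - pm / nbar
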