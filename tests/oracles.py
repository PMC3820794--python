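"""Independent brute-force oracles for the summary statistics.

Everything here is written as explicit loops over pairs and sites, straight
from the textbook definitions, deliberately sharing no code with the
package implementations.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

MISSING = -1


def pi_bruteforce(alleles: np.ndarray, site_ok: np.ndarray, n_assayable: int) -> float:
    """Mean pairwise difference per assayable site, by pair enumeration."""
    total = 0.0
    for col in np.nonzero(site_ok)[0]:
        called = [a for a in alleles[:, col] if a != MISSING]
        n = len(called)
        if n < 2:
            continue
        diff = sum(
            1 for a, b in itertools.combinations(called, 2) if a != b
        )
        total += diff / (n * (n - 1) / 2)
    return total / n_assayable


def tajimas_d_bruteforce(alleles: np.ndarray, site_ok: np.ndarray) -> float:
    """Tajima's D by direct formula evaluation at the modal sample size."""
    pi_total = 0.0
    ns = []
    S = 0
    for col in np.nonzero(site_ok)[0]:
        called = [a for a in alleles[:, col] if a != MISSING]
        n = len(called)
        k = sum(called)
        if 0 < k < n:
            S += 1
            ns.append(n)
            diff = sum(
                1 for a, b in itertools.combinations(called, 2) if a != b
            )
            pi_total += diff / (n * (n - 1) / 2)
    if S == 0:
        return float("nan")
    counts = {}
    for n in ns:
        counts[n] = counts.get(n, 0) + 1
    n = max(sorted(counts), key=lambda x: counts[x])
    if n < 4:
        return float("nan")
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return (pi_total - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))


def fst_bruteforce(
    alleles_a: np.ndarray, alleles_b: np.ndarray, site_ok: np.ndarray
) -> float:
    """Hudson F_ST = 1 - Hw/Hb with explicit within/between pair loops."""
    hw_sum = 0.0
    hb_sum = 0.0
    for col in np.nonzero(site_ok)[0]:
        ca = [a for a in alleles_a[:, col] if a != MISSING]
        cb = [a for a in alleles_b[:, col] if a != MISSING]
        if len(ca) < 2 or len(cb) < 2:
            continue
        hw_a = sum(
            1 for x, y in itertools.combinations(ca, 2) if x != y
        ) / (len(ca) * (len(ca) - 1) / 2)
        hw_b = sum(
            1 for x, y in itertools.combinations(cb, 2) if x != y
        ) / (len(cb) * (len(cb) - 1) / 2)
        hb = sum(1 for x in ca for y in cb if x != y) / (len(ca) * len(cb))
        hw_sum += 0.5 * (hw_a + hw_b)
        hb_sum += hb
    if hb_sum == 0:
        return float("nan")
    return 1.0 - hw_sum / hb_sum


def partition_bruteforce(
    alleles_a: np.ndarray, alleles_b: np.ndarray, site_ok: np.ndarray
):
    """(shared, fixed, private_a, private_b) SNP counts by enumeration."""
    shared = fixed = private_a = private_b = 0
    for col in np.nonzero(site_ok)[0]:
        ca = {int(a) for a in alleles_a[:, col] if a != MISSING}
        cb = {int(a) for a in alleles_b[:, col] if a != MISSING}
        seg_a = len(ca) > 1
        seg_b = len(cb) > 1
        if seg_a and seg_b:
            shared += 1
        elif seg_a:
            private_a += 1
        elif seg_b:
            private_b += 1
        elif ca and cb and ca != cb:
            fixed += 1
    return np.array([shared, fixed, private_a, private_b])


def ks_statistic_bruteforce(values: np.ndarray) -> float:
    """Max empirical-CDF gap against U(0,1)."""
    x = np.sort(np.asarray(values, dtype=float))
    n = len(x)
    d = 0.0
    for i, v in enumerate(x, start=1):
        d = max(d, i / n - v, v - (i - 1) / n)
    return d
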