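"""Independent brute-force oracles used across the test suite.

These deliberately re-derive results by exhaustive enumeration or direct
formula, sharing no code with the implementation paths they check.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np

from declust.model import DEStatus

NS = DEStatus.NOT_SIGNIFICANT


def brute_force_runs(
    statuses: list[DEStatus], circular: bool
) -> set[tuple[int, int, DEStatus]]:
    """Every maximal monochromatic DE run as (start, length, direction).

    Enumerates all windows exhaustively and keeps those that are
    single-direction DE and not extendable on either side. A run covering
    the whole circle is reported once with start 0.
    """
    n = len(statuses)
    runs: set[tuple[int, int, DEStatus]] = set()
    if n == 0:
        return runs
    for start in range(n):
        d = statuses[start]
        if d is NS:
            continue
        for length in range(1, n + 1):
            if not circular and start + length > n:
                break
            # incremental monochromatic check: window grows one gene at a time
            if statuses[(start + length - 1) % n] is not d:
                break
            if circular and length == n:
                runs.add((0, n, d))
                continue
            if circular:
                extendable = (
                    statuses[(start - 1) % n] is d
                    or statuses[(start + length) % n] is d
                )
            else:
                extendable = (start > 0 and statuses[start - 1] is d) or (
                    start + length < n and statuses[start + length] is d
                )
            if not extendable:
                runs.add((start, length, d))
    return runs


def clusters_as_tuples(clusters) -> set[tuple[int, int, DEStatus]]:
    return {(c.start_ordinal, c.length, c.direction) for c in clusters}


def fisher_enumeration(a: int, b: int, c: int, d: int, alternative: str) -> float:
    """Exact Fisher P by full enumeration over tables with fixed margins.

    Point probabilities are exact rationals, so the two-sided tie rule
    (include tables whose probability does not exceed the observed one)
    involves no floating-point comparison.
    """
    r1, r2, c1, n = a + b, c + d, a + c, a + b + c + d
    if n == 0:
        return 1.0
    denom = comb(n, c1)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    probs = {
        x: Fraction(comb(r1, x) * comb(r2, c1 - x), denom)
        for x in range(lo, hi + 1)
    }
    if alternative == "greater":
        total = sum(p for x, p in probs.items() if x >= a)
    elif alternative == "two-sided":
        total = sum(p for p in probs.values() if p <= probs[a])
    else:
        raise ValueError(alternative)
    return float(total)


def bh_formula(p_values) -> np.ndarray:
    """Direct BH step-up: sort, q_i = p_i * m / i, enforce monotonicity."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out


def revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]
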