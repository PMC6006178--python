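"""Exact Wigner 3j symbols for integer angular momenta.

The triple-correlation kernel contracts shell coefficients with pairs of 3j
symbols; the engine caches every distinct symbol it touches, so a fast exact
evaluation matters.  The Racah single-sum formula is evaluated in exact
integer/rational arithmetic and converted to float at the end, which is
numerically exact to double precision for the orders used here (l <= ~40).
"""

from __future__ import annotations

from fractions import Fraction
from functools import lru_cache
from math import factorial, isqrt

__all__ = ["wigner_3j", "triangle_ok"]


def triangle_ok(l1: int, l2: int, l3: int) -> bool:
    """Triangle inequality |l1-l2| <= l3 <= l1+l2."""
    return abs(l1 - l2) <= l3 <= l1 + l2


@lru_cache(maxsize=None)
def _wigner_3j_exact(l1, l2, l3, m1, m2, m3):
    # selection rules
    if m1 + m2 + m3 != 0 or not triangle_ok(l1, l2, l3):
        return 0, Fraction(0)
    if abs(m1) > l1 or abs(m2) > l2 or abs(m3) > l3:
        return 0, Fraction(0)

    # squared prefactor (rational): Delta(l1 l2 l3) * prod (li +- mi)!
    pref = Fraction(
        factorial(l1 + l2 - l3) * factorial(l1 - l2 + l3) * factorial(-l1 + l2 + l3),
        factorial(l1 + l2 + l3 + 1),
    )
    pref *= (
        factorial(l1 + m1) * factorial(l1 - m1)
        * factorial(l2 + m2) * factorial(l2 - m2)
        * factorial(l3 + m3) * factorial(l3 - m3)
    )

    kmin = max(0, l2 - l3 - m1, l1 - l3 + m2)
    kmax = min(l1 + l2 - l3, l1 - m1, l2 + m2)
    s = Fraction(0)
    for k in range(kmin, kmax + 1):
        den = (
            factorial(k)
            * factorial(l1 + l2 - l3 - k)
            * factorial(l1 - m1 - k)
            * factorial(l2 + m2 - k)
            * factorial(l3 - l2 + m1 + k)
            * factorial(l3 - l1 - m2 + k)
        )
        s += Fraction((-1) ** k, den)
    sign = (-1) ** (l1 - l2 - m3)
    return sign, (s, pref)


def _sqrt_fraction(fr: Fraction) -> float:
    # exact square root when available, float fallback otherwise
    n, d = fr.numerator, fr.denominator
    rn, rd = isqrt(n), isqrt(d)
    if rn * rn == n and rd * rd == d:
        return rn / rd
    return float(fr) ** 0.5


@lru_cache(maxsize=None)
def wigner_3j(l1: int, l2: int, l3: int, m1: int, m2: int, m3: int) -> float:
    """Wigner 3j symbol (l1 l2 l3; m1 m2 m3), standard normalization.

    Returns 0.0 when the selection rules (m1+m2+m3 = 0, triangle rule,
    |mi| <= li) fail.
    """
    for v in (l1, l2, l3, m1, m2, m3):
        if int(v) != v:
            raise ValueError("integer angular momenta only")
    sign, payload = _wigner_3j_exact(int(l1), int(l2), int(l3), int(m1), int(m2), int(m3))
    if sign == 0:
        return 0.0
    s, pref = payload
    return sign * float(s) * _sqrt_fraction(pref)
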