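"""Independent oracles for the exact-test machinery.

The rational-arithmetic oracle enumerates the hypergeometric distribution
with exact integer binomials (fractions.Fraction), applying the same
declared tie rule as the implementation but with exact comparisons; the
log-space oracle recomputes point probabilities from lgamma for tables too
large for exact arithmetic to be cheap.  Neither shares any code with the
package implementation.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

TIE_NUM, TIE_DEN = 10**7 + 1, 10**7  # the 1 + 1e-7 relative tie gauge


def two_sided_exact(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exact rational enumeration of one table.

    Hypergeometric numerators are built by the exact term ratio
    M(k+1)/M(k) = (r1-k)(c1-k) / ((k+1)(r2-c1+k+1)), so only one large
    binomial is evaluated per table; works for control margins in the tens
    of thousands as long as the case margin keeps the support small.
    """
    n = a + b + c + d
    r1, r2, c1 = a + b, c + d, a + c
    lo, hi = max(0, c1 - r2), min(r1, c1)
    terms: list[Fraction] = []
    term = Fraction(comb(r1, lo) * comb(r2, c1 - lo))
    for k in range(lo, hi + 1):
        terms.append(term)
        if k < hi:
            term = term * Fraction((r1 - k) * (c1 - k), (k + 1) * (r2 - c1 + k + 1))
    p_obs = terms[a - lo]
    threshold = p_obs * Fraction(TIE_NUM, TIE_DEN)
    total = sum(t for t in terms if t <= threshold)
    return float(Fraction(total, comb(n, c1)))


def two_sided_exact_all(n: int, r1: int, c1: int) -> dict[int, float]:
    """Two-sided p for every feasible a given margins (row1=r1, col1=c1, total=n)."""
    r2 = n - r1
    denom = comb(n, c1)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    pmfs = {k: Fraction(comb(r1, k) * comb(r2, c1 - k), denom) for k in range(lo, hi + 1)}
    gauge = Fraction(TIE_NUM, TIE_DEN)
    out = {}
    for a, p_obs in pmfs.items():
        threshold = p_obs * gauge
        out[a] = float(sum(p for p in pmfs.values() if p <= threshold))
    return out


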