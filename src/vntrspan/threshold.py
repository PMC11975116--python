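"""Binomial model for the minimum spanning-read threshold.

With ``n`` spanning reads over a heterozygous locus and no allele dropout,
the number of reads ``x`` drawn from one allele is Binomial(n, 1/2).  The
genotyper miscalls the site as homozygous when one allele contributes 2 or
fewer reads, i.e. when ``x ≤ 2`` or ``x ≥ n − 2``:

    Perr(n) = P(x ≥ n − 2  or  x ≤ 2)

For ``n ≤ 5`` the two tails overlap and the event is certain; for ``n ≥ 6``
Perr(n) = 2·(1 + n + C(n, 2)) / 2**n, which is strictly decreasing.  All
arithmetic is exact (``fractions.Fraction``); floats appear only at the
reporting boundary.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb
from typing import Optional

import pandas as pd

__all__ = ["perr", "perr_fraction", "min_spanning_threshold", "perr_table"]


def perr_fraction(n: int, allele_balance: Fraction = Fraction(1, 2)) -> Fraction:
    """Exact miscall probability P(x ≤ 2 or x ≥ n − 2) for x ~ Binomial(n, p).

    The union is evaluated over the set of outcomes, so overlapping tails
    (``n ≤ 5``) are counted once and the result never exceeds 1.
    """
    if n < 1:
        raise ValueError(f"n must be ≥ 1, got {n}")
    p = Fraction(allele_balance)
    if not 0 <= p <= 1:
        raise ValueError(f"allele balance must be in [0, 1], got {p}")
    q = 1 - p
    outcomes = set(range(0, 3)) | set(range(max(n - 2, 0), n + 1))
    return sum(Fraction(comb(n, i)) * p**i * q ** (n - i) for i in sorted(outcomes))


def perr(n: int, allele_balance: float = 0.5) -> float:
    """Miscall probability as a float; see :func:`perr_fraction`."""
    return float(perr_fraction(n, Fraction(allele_balance).limit_denominator(10**9)))


def min_spanning_threshold(alpha: float, allele_balance: float = 0.5) -> int:
    """Smallest n with Perr(n) < ``alpha``.

    At alpha = 0.01 this is 15 reads, the spanning-read threshold used to
    call a locus well-covered.
    """
    if not 0 < alpha <= 1:
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    a = Fraction(alpha).limit_denominator(10**9)
    p = Fraction(allele_balance).limit_denominator(10**9)
    n = 1
    while perr_fraction(n, p) >= a:
        n += 1
    return n


def perr_table(n_min: int = 1, n_max: int = 30, alpha: Optional[float] = None) -> pd.DataFrame:
    """Tabulate Perr(n) over a range; optionally mark the threshold for alpha."""
    rows = []
    for n in range(n_min, n_max + 1):
        f = perr_fraction(n)
        rows.append({"n": n, "perr": float(f), "perr_exact": f"{f.numerator}/{f.denominator}"})
    df = pd.DataFrame(rows)
    if alpha is not None:
        df["below_alpha"] = df["perr"] < alpha
    return df
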