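"""Independent brute-force oracles used to cross-check the implementation.

Each oracle is written as the most naive possible enumeration, sharing no
code with the package internals, so agreement is evidence of correctness
rather than tautology.
"""

from fractions import Fraction
from itertools import combinations


def strlike_oracle(M: str, k: int) -> Fraction:
    """Naive STR-likeness score: full string enumeration of masks and offsets.

    Builds every masked string explicitly (mask character '-' matches
    anything on either side), doubles it, and slides the full-size window
    over offsets 1..n-1.  Score is 1 when some masked alignment is perfect,
    otherwise the best unmasked similarity (n - Hamming)/n.
    """
    M = M.upper()
    n = len(M)
    if n == 1:
        return Fraction(0)

    def hamming(a: str, b: str) -> int:
        return sum(1 for x, y in zip(a, b) if x != "-" and y != "-" and x != y)

    doubled = M + M
    best = max(n - hamming(M, doubled[o:o + n]) for o in range(1, n))
    if best == n:
        return Fraction(1)
    for size in range(1, k + 1):
        for mask in combinations(range(n), size):
            masked = "".join("-" if i in mask else c for i, c in enumerate(M))
            md = masked + masked
            for o in range(1, n):
                if hamming(masked, md[o:o + n]) == 0:
                    return Fraction(1)
    return Fraction(best, n)


def consistency_oracle(pair1, pair2) -> str:
    """Rule-checker for the three-way consistency taxonomy, from first principles."""
    s1, s2 = tuple(sorted(pair1)), tuple(sorted(pair2))
    if s1 == s2:
        return "consistent"
    observed = sorted(set(s1) | set(s2))
    any_het = (s1[0] != s1[1]) or (s2[0] != s2[1])
    if len(observed) == 2 and any_het:
        return "partially_consistent"
    return "inconsistent"


def mendelian_oracle(child, mother, father) -> bool:
    """Exhaustive enumeration of the four transmission assignments."""
    for cm, cf in ((child[0], child[1]), (child[1], child[0])):
        for ma in mother:
            for fa in father:
                if cm == ma and cf == fa:
                    return True
    return False


def spanning_counts_oracle(reads, loci) -> dict:
    """All-pairs spanning tally: (locus_id, sample_id) -> count."""
    out = {}
    for locus in loci:
        for read in reads:
            if (
                read.interval.chrom == locus.interval.chrom
                and read.interval.start < locus.interval.start
                and read.interval.end > locus.interval.end
            ):
                key = (locus.locus_id, read.sample_id)
                out[key] = out.get(key, 0) + 1
    return out
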