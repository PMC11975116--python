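"""STR-likeness score for VNTR consensus motifs.

A motif with an imperfect internal repeat (``AAAAGA``, ``TATATCTA``) behaves
like a short tandem repeat: the genotyper can slide repeat units against each
other and mis-estimate the count, so such loci are excluded from consistency
analyses.  The score measures how close a motif is to a circular internal
repeat.

Given a motif ``M`` of length ``n``, every non-trivial circular alignment is
examined by comparing ``M`` against a window of size ``n`` in the doubled
string ``M·M`` at offsets 1 … n−1 (the identity offset is skipped).  The
base score is the best similarity ``(n − Hamming distance)/n`` over those
offsets.  Masking then detects *imperfect* internal repeats: up to ``k``
characters may be masked (a masked character matches anything, in both
copies of the doubled string), and if some mask set makes an alignment
perfect, the motif scores 1.0 — e.g. masking the G of ``AAAAGA`` exposes a
perfect single-base repeat.  The mask budget is ``k = ⌈n/10⌉`` for
``n ≤ 40`` and 1 for longer motifs (to bound the search).  Motifs scoring
> 0.8 are flagged STR-like.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from itertools import combinations
from math import ceil
from typing import Optional, Sequence, Tuple

__all__ = ["MotifScore", "mask_budget", "strlike_score", "filter_str_like"]

DEFAULT_CUTOFF = 0.8


@dataclass(frozen=True)
class MotifScore:
    motif: str
    n: int
    k: int
    score: float
    score_exact: Fraction
    is_str_like: bool


def mask_budget(n: int, budget_rule: str = "standard") -> int:
    """Maximum number of masked characters for a motif of length ``n``.

    ``budget_rule="standard"``: ⌈n/10⌉ for n ≤ 40, else 1 (compute-limiting
    for long motifs).  ``"inverted"`` selects the opposite reading of the
    ambiguous rule: 1 for n ≤ 40, ⌈n/10⌉ otherwise.
    """
    if n < 1:
        raise ValueError(f"motif length must be ≥ 1, got {n}")
    ceil_rule = ceil(n / 10)
    if budget_rule == "standard":
        return ceil_rule if n <= 40 else 1
    if budget_rule == "inverted":
        return 1 if n <= 40 else ceil_rule
    raise ValueError(f"unknown budget rule {budget_rule!r}")


def _can_mask_perfect(mismatches: Sequence[int], offset: int, n: int, k: int) -> bool:
    """Whether ≤ k masks remove every mismatch of one circular alignment.

    Comparison index ``j`` pairs motif position ``j`` with position
    ``(offset + j) mod n``; masking position ``p`` hides every comparison
    that touches ``p`` on either side (both copies in the doubled string
    inherit the mask).  Only positions appearing in some mismatching pair
    can help, so the exact search enumerates subsets of that candidate set.
    """
    if not mismatches:
        return True
    if len(mismatches) > 2 * k:  # each mask repairs at most 2 comparisons
        return False
    covers: dict = {}
    for j in mismatches:
        for p in (j, (offset + j) % n):
            covers.setdefault(p, set()).add(j)
    cands = sorted(covers)
    need = set(mismatches)
    for size in range(1, min(k, len(cands)) + 1):
        for combo in combinations(cands, size):
            repaired = set()
            for p in combo:
                repaired |= covers[p]
            if repaired >= need:
                return True
    return False


def strlike_score(
    motif: str,
    max_masks: Optional[int] = None,
    cutoff: float = DEFAULT_CUTOFF,
    budget_rule: str = "standard",
) -> MotifScore:
    """Score a consensus motif for (imperfect) circular internal repeats.

    The score is the best unmasked circular-alignment similarity, raised to
    1.0 when masking ≤ k characters exposes a perfect internal repeat.  A
    length-1 motif has no non-trivial offset and scores 0.
    """
    M = motif.upper()
    n = len(M)
    if n == 0:
        raise ValueError("empty motif")
    k = mask_budget(n, budget_rule) if max_masks is None else max_masks
    best_mism = n
    perfect = False
    mism_by_offset = []
    for offset in range(1, n):
        mism = [j for j in range(n) if M[j] != M[(offset + j) % n]]
        mism_by_offset.append((offset, mism))
        best_mism = min(best_mism, len(mism))
    if best_mism == 0:
        perfect = True
    elif k > 0:
        perfect = any(
            _can_mask_perfect(mism, offset, n, k)
            for offset, mism in sorted(mism_by_offset, key=lambda om: len(om[1]))
            if len(mism) <= 2 * k
        )
    if perfect:
        score = Fraction(1)
    elif n > 1:
        score = Fraction(n - best_mism, n)
    else:
        score = Fraction(0)
    return MotifScore(
        motif=M,
        n=n,
        k=k,
        score=float(score),
        score_exact=score,
        is_str_like=score > Fraction(cutoff).limit_denominator(10**6),
    )


def filter_str_like(
    loci: Sequence,
    cutoff: float = DEFAULT_CUTOFF,
    budget_rule: str = "standard",
) -> Tuple[list, list]:
    """Partition loci into (kept, discarded) by motif score > ``cutoff``.

    Input order is preserved in both outputs.
    """
    cut = Fraction(cutoff).limit_denominator(10**6)
    kept, discarded = [], []
    for locus in loci:
        ms = strlike_score(locus.motif, cutoff=cutoff, budget_rule=budget_rule)
        (discarded if ms.score_exact > cut else kept).append(locus)
    return kept, discarded
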