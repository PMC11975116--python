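"""Diploid repeat-count genotype calling and quality control.

The caller here is a deliberately simple spanning-read estimator: each
reliable read's repeat count is the length of its sequence between the two
flank anchors divided by the motif length, rounded to the nearest integer.
It is a stand-in for a full HMM-based tandem-repeat genotyper, adequate for
synthetic data where reads carry clean repeat arrays; its purpose is to
exercise the support filters and the downstream consistency metrics, not to
genotype real reads.

Quality control follows two axes: (1) cross-read-set consistency — two calls
at the same locus/sample are *consistent* when the sorted allele pairs are
identical, *partially consistent* when one call is homozygous for an allele
of the other (heterozygous) call, and *inconsistent* otherwise; (2) trio
Mendelian consistency — the child's pair must be explainable by one allele
from each parent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from math import floor
from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple

import pandas as pd

from .catalog import VntrLocus
from .coverage import AlignedRead

__all__ = [
    "GenotypeCall",
    "ConsistencyVerdict",
    "Trio",
    "estimate_repeat_count",
    "call_genotype",
    "classify_consistency",
    "mendelian_consistent",
    "consistency_summary",
    "mendelian_summary",
    "genotype_table",
    "write_genotype_table",
    "read_genotype_table",
]

MIN_ALLELE_SUPPORT = 3


@dataclass(frozen=True)
class GenotypeCall:
    """Unordered diploid repeat-count call; ``alleles is None`` means no-call."""

    alleles: Optional[Tuple[int, int]]
    locus_id: str = ""
    sample_id: str = ""
    support: Mapping[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.alleles is not None:
            object.__setattr__(self, "alleles", tuple(sorted(self.alleles)))

    @property
    def is_nocall(self) -> bool:
        return self.alleles is None

    @property
    def is_homozygous(self) -> bool:
        return self.alleles is not None and self.alleles[0] == self.alleles[1]

    @property
    def is_heterozygous(self) -> bool:
        return self.alleles is not None and self.alleles[0] != self.alleles[1]

    def allele_set(self) -> frozenset:
        return frozenset(self.alleles) if self.alleles is not None else frozenset()


@dataclass(frozen=True)
class ConsistencyVerdict:
    value: str  # consistent | partially_consistent | inconsistent | not_comparable
    homozygous_side: str = "none"  # first | second | both | none


@dataclass(frozen=True)
class Trio:
    child: str
    mother: str
    father: str

    def __post_init__(self) -> None:
        if len({self.child, self.mother, self.father}) != 3:
            raise ValueError("trio members must be three distinct samples")


def _round_half_away(x: float) -> int:
    return int(floor(x + 0.5)) if x >= 0 else -int(floor(-x + 0.5))


def estimate_repeat_count(read: AlignedRead, locus: VntrLocus) -> Optional[int]:
    """Repeat count carried by one spanning read.

    Anchors are the last read base aligned before the array start and the
    first read base aligned at/after the array end; the read segment between
    them, divided by the motif length and rounded half-away-from-zero, is
    the count.  Returns None when an anchor is missing (read excluded
    upstream by the reliability filter in normal operation).
    """
    liv = locus.interval
    left_q = read.query_anchor_before(liv.start)
    right_q = read.query_anchor_at_or_after(liv.end)
    if left_q is None or right_q is None:
        return None
    segment = right_q - left_q - 1
    rc = _round_half_away(segment / locus.motif_length)
    return rc if rc >= 1 else None


def call_genotype(
    support: Mapping[int, int],
    min_support: int = MIN_ALLELE_SUPPORT,
    locus_id: str = "",
    sample_id: str = "",
) -> GenotypeCall:
    """Call a diploid genotype from per-repeat-count reliable-read tallies.

    Counts with fewer than ``min_support`` reliable reads are discarded (the
    accuracy filter, guarding against spurious heterozygous calls).  One
    surviving count → homozygous; two or more → the two best-supported counts,
    ties broken toward the smaller repeat count; none → no-call.
    """
    surviving = {rc: s for rc, s in support.items() if s >= min_support}
    if not surviving:
        alleles = None
    elif len(surviving) == 1:
        (rc,) = surviving
        alleles = (rc, rc)
    else:
        ranked = sorted(surviving.items(), key=lambda kv: (-kv[1], kv[0]))
        alleles = (ranked[0][0], ranked[1][0])
    return GenotypeCall(
        alleles=alleles, locus_id=locus_id, sample_id=sample_id, support=dict(support)
    )


def classify_consistency(g1: GenotypeCall, g2: GenotypeCall) -> ConsistencyVerdict:
    """Compare two calls for the same locus/sample from different read sets."""
    if g1.locus_id and g2.locus_id and g1.locus_id != g2.locus_id:
        raise ValueError(f"locus mismatch: {g1.locus_id} vs {g2.locus_id}")
    if g1.sample_id and g2.sample_id and g1.sample_id != g2.sample_id:
        raise ValueError(f"sample mismatch: {g1.sample_id} vs {g2.sample_id}")
    if g1.is_nocall or g2.is_nocall:
        return ConsistencyVerdict("not_comparable")
    if g1.alleles == g2.alleles:
        side = "both" if g1.is_homozygous else "none"
        return ConsistencyVerdict("consistent", side)
    union = g1.allele_set() | g2.allele_set()
    if len(union) == 2 and (g1.is_heterozygous or g2.is_heterozygous):
        side = "first" if g1.is_homozygous else "second"
        return ConsistencyVerdict("partially_consistent", side)
    return ConsistencyVerdict("inconsistent")


def mendelian_consistent(child: GenotypeCall, mother: GenotypeCall, father: GenotypeCall) -> bool:
    """True iff the child's alleles admit one-from-each-parent transmission."""
    if child.is_nocall or mother.is_nocall or father.is_nocall:
        raise ValueError("mendelian_consistent requires three complete calls")
    a, b = child.alleles
    m, f = mother.allele_set(), father.allele_set()
    return (a in m and b in f) or (a in f and b in m)


# ---------------------------------------------------------------------------
# tabular layer


def genotype_table(calls: Iterable[GenotypeCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        rows.append(
            {
                "locus_id": c.locus_id,
                "sample_id": c.sample_id,
                "allele1": c.alleles[0] if c.alleles else pd.NA,
                "allele2": c.alleles[1] if c.alleles else pd.NA,
                "support": json.dumps({str(k): v for k, v in sorted(c.support.items())}),
            }
        )
    return pd.DataFrame(rows, columns=["locus_id", "sample_id", "allele1", "allele2", "support"])


def write_genotype_table(calls: Iterable[GenotypeCall], path) -> None:
    genotype_table(calls).to_csv(path, sep="\t", index=False)


def read_genotype_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"locus_id": str, "sample_id": str})
    return df


def _calls_from_table(df: pd.DataFrame) -> Dict[Tuple[str, str], GenotypeCall]:
    calls = {}
    for r in df.itertuples():
        if pd.isna(r.allele1) or pd.isna(r.allele2):
            alleles = None
        else:
            alleles = (int(r.allele1), int(r.allele2))
        support = {}
        if "support" in df.columns and isinstance(r.support, str) and r.support:
            support = {int(k): v for k, v in json.loads(r.support).items()}
        calls[(str(r.locus_id), str(r.sample_id))] = GenotypeCall(
            alleles=alleles, locus_id=str(r.locus_id), sample_id=str(r.sample_id), support=support
        )
    return calls


def _as_call_map(table) -> Dict[Tuple[str, str], GenotypeCall]:
    if isinstance(table, pd.DataFrame):
        return _calls_from_table(table)
    return dict(table)


def consistency_summary(
    calls_a,
    calls_b,
    catalog: Optional[Sequence[VntrLocus]] = None,
    strlike_scores: Optional[Mapping[str, float]] = None,
    strlike_cutoff: float = 0.8,
    max_ref_array_length: Optional[int] = None,
) -> dict:
    """Cross-read-set consistency fractions per sample and pooled.

    ``calls_a``/``calls_b`` are genotype DataFrames or (locus, sample)→call
    mappings from two read sets.  Loci may be restricted to a catalog, to
    reference arrays shorter than ``max_ref_array_length`` (short-read mode),
    and to motifs with STR-likeness score ≤ ``strlike_cutoff``.  Also reports
    which side of each partially consistent pair was homozygous.
    """
    a = _as_call_map(calls_a)
    b = _as_call_map(calls_b)
    shared = sorted(set(a) & set(b))
    if not shared:
        raise ValueError("no shared (locus, sample) pairs between the two call sets")
    keep_locus = _locus_filter(catalog, strlike_scores, strlike_cutoff, max_ref_array_length)

    per_sample: Dict[str, Dict[str, int]] = {}
    side_tally = {"first": 0, "second": 0}
    verdicts = []
    for key in shared:
        lid, sid = key
        if not keep_locus(lid):
            continue
        v = classify_consistency(a[key], b[key])
        verdicts.append({"locus_id": lid, "sample_id": sid, "verdict": v.value,
                         "homozygous_side": v.homozygous_side})
        tally = per_sample.setdefault(sid, {"consistent": 0, "partially_consistent": 0,
                                            "inconsistent": 0, "not_comparable": 0})
        tally[v.value] += 1
        if v.value == "partially_consistent":
            side_tally[v.homozygous_side] += 1

    def _fracs(t: Dict[str, int]) -> dict:
        comparable = t["consistent"] + t["partially_consistent"] + t["inconsistent"]
        if comparable == 0:
            return {"comparable": 0}
        return {
            "comparable": comparable,
            "consistent": t["consistent"] / comparable,
            "partially_consistent": t["partially_consistent"] / comparable,
            "inconsistent": t["inconsistent"] / comparable,
            "not_comparable": t["not_comparable"],
        }

    pooled = {"consistent": 0, "partially_consistent": 0, "inconsistent": 0, "not_comparable": 0}
    for t in per_sample.values():
        for k in pooled:
            pooled[k] += t[k]
    n_partial = side_tally["first"] + side_tally["second"]
    return {
        "per_sample": {sid: _fracs(t) for sid, t in sorted(per_sample.items())},
        "pooled": _fracs(pooled),
        "partial_homozygous_side": {
            "first": side_tally["first"] / n_partial if n_partial else None,
            "second": side_tally["second"] / n_partial if n_partial else None,
            "n_partial": n_partial,
        },
        "verdicts": pd.DataFrame(
            verdicts, columns=["locus_id", "sample_id", "verdict", "homozygous_side"]
        ),
    }


def _locus_filter(catalog, strlike_scores, strlike_cutoff, max_ref_array_length):
    allowed = None
    if catalog is not None:
        allowed = set()
        for loc in catalog:
            if max_ref_array_length is not None and loc.ref_array_length >= max_ref_array_length:
                continue
            allowed.add(loc.locus_id)

    def keep(locus_id: str) -> bool:
        if allowed is not None and locus_id not in allowed:
            return False
        if strlike_scores is not None:
            score = strlike_scores.get(locus_id)
            if score is not None and score > strlike_cutoff:
                return False
        return True

    return keep


def mendelian_summary(
    calls,
    trios: Sequence[Trio],
    catalog: Optional[Sequence[VntrLocus]] = None,
    strlike_scores: Optional[Mapping[str, float]] = None,
    strlike_cutoff: float = 0.8,
    max_ref_array_length: Optional[int] = None,
) -> dict:
    """Per-trio and pooled Mendelian consistency over loci with complete calls.

    The denominator is the set of loci where child, mother and father all
    have calls, after catalog/length/STR-like restriction; loci with any
    no-call are excluded.
    """
    call_map = _as_call_map(calls)
    keep_locus = _locus_filter(catalog, strlike_scores, strlike_cutoff, max_ref_array_length)
    loci = sorted({lid for lid, _ in call_map})
    per_trio = {}
    pooled_n = pooled_ok = 0
    for trio in trios:
        n = ok = 0
        for lid in loci:
            if not keep_locus(lid):
                continue
            c = call_map.get((lid, trio.child))
            m = call_map.get((lid, trio.mother))
            f = call_map.get((lid, trio.father))
            if c is None or m is None or f is None or c.is_nocall or m.is_nocall or f.is_nocall:
                continue
            n += 1
            if mendelian_consistent(c, m, f):
                ok += 1
        per_trio[trio.child] = {"n_loci": n, "consistent_fraction": ok / n if n else None}
        pooled_n += n
        pooled_ok += ok
    return {
        "per_trio": per_trio,
        "pooled": {
            "n_loci": pooled_n,
            "consistent_fraction": pooled_ok / pooled_n if pooled_n else None,
        },
    }
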