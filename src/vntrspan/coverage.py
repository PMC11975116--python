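"""Spanning/reliable read counting and coverage classification.

A *spanning* read is one whose aligned reference span strictly contains the
VNTR interval with at least 1 bp of flank on each side — only such reads see
both boundaries of the tandem array and can support a repeat-count call.  A
*reliable* read additionally aligns ≥ 10 bp of flank on each side with ≥ 95%
base identity per flank, which screens out mismapped or clipped reads.

Coverage tiers follow the spanning-read threshold model: a locus is
well-covered when the cross-sample median spanning count is ≥ 15 (the point
where the binomial miscall probability drops below 1%), high when ≥ 63, and
uncovered when the median is 0.  Cross-sample homogeneity is summarised by
the population variance of counts projected to a cap of 30.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .catalog import GenomicInterval, VntrLocus

__all__ = [
    "AlignedRead",
    "LocusCoverage",
    "CoverageClassification",
    "is_spanning",
    "is_reliable",
    "count_spanning",
    "probe_distance",
    "classify_coverage",
    "normalize_per_million",
    "efficiency",
    "load_alignments",
    "coverage_table",
]

WELL_COVERED_THRESHOLD = 15
HIGH_COVERED_THRESHOLD = 63
PROJECTION_CAP = 30
MIN_FLANK = 10
MIN_FLANK_MATCH = 0.95
MAX_FLANK_WINDOW = 100

# SAM CIGAR op codes (pysam convention)
_CONSUMES_QUERY = {0, 1, 4, 7, 8}
_CONSUMES_REF = {0, 2, 3, 7, 8}


@dataclass
class AlignedRead:
    """One mapped read: reference span, sequence, and CIGAR.

    The per-base alignment is kept as pysam-style ``cigartuples`` (a list of
    (op, length) pairs) rather than an expanded pair list, so thousands of
    multi-kilobase reads stay cheap; positional queries walk the CIGAR.
    """

    read_id: str
    sample_id: str
    interval: GenomicInterval
    sequence: str
    cigartuples: Sequence[Tuple[int, int]]

    @classmethod
    def from_pysam(cls, seg, sample_id: str) -> "AlignedRead":
        return cls(
            read_id=seg.query_name,
            sample_id=sample_id,
            interval=GenomicInterval(seg.reference_name, seg.reference_start, seg.reference_end),
            sequence=(seg.query_sequence or "").upper(),
            cigartuples=list(seg.cigartuples or ()),
        )

    def _blocks(self):
        """Yield (op, q_start, r_start, length) for each CIGAR op."""
        q, r = 0, self.interval.start
        for op, length in self.cigartuples:
            yield op, q, r, length
            if op in _CONSUMES_QUERY:
                q += length
            if op in _CONSUMES_REF:
                r += length

    def ref_to_query_range(self, lo: int, hi: int) -> Dict[int, Optional[int]]:
        """Map reference positions in [lo, hi) to read positions (None = deleted)."""
        out: Dict[int, Optional[int]] = {}
        for op, q0, r0, length in self._blocks():
            if op not in _CONSUMES_REF:
                continue
            if r0 >= hi:
                break
            s, e = max(r0, lo), min(r0 + length, hi)
            if s >= e:
                continue
            if op in (0, 7, 8):
                for r in range(s, e):
                    out[r] = q0 + (r - r0)
            else:  # D/N: reference consumed with no read base
                for r in range(s, e):
                    out[r] = None
        return out

    def query_anchor_before(self, pos: int) -> Optional[int]:
        """Read position of the last aligned base at reference position < ``pos``."""
        best = None
        for op, q0, r0, length in self._blocks():
            if r0 >= pos:
                break
            if op in (0, 7, 8):
                e = min(r0 + length, pos)
                if e > r0:
                    best = q0 + (e - r0) - 1
        return best

    def query_anchor_at_or_after(self, pos: int) -> Optional[int]:
        """Read position of the first aligned base at reference position ≥ ``pos``."""
        for op, q0, r0, length in self._blocks():
            if op in (0, 7, 8) and r0 + length > pos:
                return q0 + max(0, pos - r0)
        return None


@dataclass
class LocusCoverage:
    locus_id: str
    sample_id: str
    n_spanning: int = 0
    n_reliable: int = 0
    reliable_by_repeat_count: Dict[int, int] = field(default_factory=dict)
    probe_distance: Optional[int] = None
    spanning_per_million: Optional[float] = None

    def __post_init__(self) -> None:
        if self.n_reliable > self.n_spanning:
            raise ValueError("n_reliable cannot exceed n_spanning")


@dataclass
class CoverageClassification:
    locus_id: str
    median_spanning: float
    tier: str
    cross_sample_variance: float


def is_spanning(read: AlignedRead, locus: VntrLocus) -> bool:
    """True iff the read's aligned span strictly contains the VNTR interval."""
    iv, liv = read.interval, locus.interval
    return iv.chrom == liv.chrom and iv.start < liv.start and iv.end > liv.end


def is_reliable(
    read: AlignedRead,
    locus: VntrLocus,
    reference,
    min_flank: int = MIN_FLANK,
    min_match: float = MIN_FLANK_MATCH,
    max_flank: int = MAX_FLANK_WINDOW,
    short_read_mode: bool = False,
) -> bool:
    """Flank-anchoring filter for genotype-supporting reads.

    Requires ≥ ``min_flank`` aligned reference bp on each side of the VNTR
    and a per-flank identity of ≥ ``min_match`` over the flank window (up to
    ``max_flank`` bp per side of what the read actually covers).  A deleted
    reference base counts as a mismatch.  ``short_read_mode`` limits the
    identity window to exactly ``min_flank`` bp, the relaxed criterion used
    when one side of a comparison is short reads.
    """
    liv = locus.interval
    left_avail = liv.start - read.interval.start
    right_avail = read.interval.end - liv.end
    if left_avail < min_flank or right_avail < min_flank:
        return False
    window_cap = min_flank if short_read_mode else max_flank
    seq = read.sequence

    for lo, hi in (
        (liv.start - min(left_avail, window_cap), liv.start),
        (liv.end, liv.end + min(right_avail, window_cap)),
    ):
        try:
            ref_seq = reference.fetch(liv.chrom, lo, hi).upper()
        except (KeyError, ValueError) as exc:
            raise KeyError(f"reference unavailable for flank [{lo},{hi}): {exc}") from None
        if len(ref_seq) < hi - lo:
            raise KeyError(f"reference unavailable for flank [{lo},{hi})")
        r2q = read.ref_to_query_range(lo, hi)
        matches = 0
        for off, rpos in enumerate(range(lo, hi)):
            qpos = r2q.get(rpos)
            if qpos is not None and seq[qpos] == ref_seq[off]:
                matches += 1
        if matches / (hi - lo) < min_match:
            return False
    return True


def count_spanning(
    locus: VntrLocus,
    reads: Iterable[AlignedRead],
    reference,
    min_flank: int = MIN_FLANK,
    min_match: float = MIN_FLANK_MATCH,
    short_read_mode: bool = False,
    with_repeat_counts: bool = True,
) -> Dict[str, LocusCoverage]:
    """Tally spanning and reliable reads at one locus, per sample.

    ``reliable_by_repeat_count`` maps each estimated repeat count to the
    number of reliable reads supporting it (the input to genotype calling).
    """
    from .genotyping import estimate_repeat_count  # local: avoids module cycle

    per_sample: Dict[str, LocusCoverage] = {}
    for read in reads:
        if not is_spanning(read, locus):
            continue
        cov = per_sample.setdefault(
            read.sample_id, LocusCoverage(locus_id=locus.locus_id, sample_id=read.sample_id)
        )
        cov.n_spanning += 1
        if is_reliable(
            read, locus, reference,
            min_flank=min_flank, min_match=min_match, short_read_mode=short_read_mode,
        ):
            cov.n_reliable += 1
            if with_repeat_counts:
                rc = estimate_repeat_count(read, locus)
                if rc is not None:
                    cov.reliable_by_repeat_count[rc] = cov.reliable_by_repeat_count.get(rc, 0) + 1
    return per_sample


def probe_distance(locus: VntrLocus, probes: Sequence[GenomicInterval]) -> Optional[int]:
    """Distance in bp from the locus to the nearest probe-covered interval.

    0 if any probe overlaps the locus; missing (None) when no probe lies on
    the locus chromosome.
    """
    same_chrom = [p for p in probes if p.chrom == locus.interval.chrom]
    if not same_chrom:
        return None
    return min(locus.interval.gap_to(p) for p in same_chrom)


def classify_coverage(
    per_sample: Sequence[LocusCoverage],
    well_threshold: int = WELL_COVERED_THRESHOLD,
    high_threshold: int = HIGH_COVERED_THRESHOLD,
    projection_cap: int = PROJECTION_CAP,
) -> CoverageClassification:
    """Classify one locus across samples by median spanning count.

    The homogeneity statistic is the population variance of per-sample
    counts after projecting values ≥ ``projection_cap`` down to the cap.
    """
    if not per_sample:
        raise ValueError("classify_coverage requires at least one sample")
    locus_ids = {c.locus_id for c in per_sample}
    if len(locus_ids) != 1:
        raise ValueError(f"mixed loci in classification input: {sorted(locus_ids)}")
    counts = np.array([c.n_spanning for c in per_sample], dtype=float)
    median = float(np.median(counts))
    if median == 0:
        tier = "uncovered"
    elif median >= high_threshold:
        tier = "high"
    elif median >= well_threshold:
        tier = "well_covered"
    else:
        tier = "low"
    projected = np.minimum(counts, projection_cap)
    return CoverageClassification(
        locus_id=per_sample[0].locus_id,
        median_spanning=median,
        tier=tier,
        cross_sample_variance=float(np.var(projected)),
    )


def normalize_per_million(cov: LocusCoverage, total_mapped_reads: int) -> float:
    """Spanning reads per million mapped reads in the sample."""
    if total_mapped_reads <= 0:
        raise ValueError("total_mapped_reads must be positive")
    return cov.n_spanning * 1_000_000 / total_mapped_reads


def efficiency(reads: Iterable[AlignedRead], catalog: Sequence[VntrLocus]) -> float:
    """Fraction of mapped reads overlapping at least one catalog locus."""
    if not catalog:
        raise ValueError("efficiency requires a non-empty catalog")
    trees: Dict[str, IntervalTree] = {}
    for loc in catalog:
        trees.setdefault(loc.interval.chrom, IntervalTree()).addi(
            loc.interval.start, loc.interval.end
        )
    total = hits = 0
    for read in reads:
        total += 1
        tree = trees.get(read.interval.chrom)
        if tree is not None and tree.overlap(read.interval.start, read.interval.end):
            hits += 1
    return hits / total if total else 0.0


def load_alignments(
    path,
    default_sample: Optional[str] = None,
    include_secondary: bool = False,
) -> List[AlignedRead]:
    """Read a SAM/BAM file into AlignedRead objects.

    Sample identity comes from the read's RG tag mapped to the header SM
    field, falling back to ``default_sample``.  Secondary and supplementary
    alignments are skipped by default; duplicates are kept (long-read
    protocols lack duplicate marking).
    """
    import pysam

    reads: List[AlignedRead] = []
    with pysam.AlignmentFile(str(path), check_sq=False) as af:
        rg_to_sm = {
            rg.get("ID"): rg.get("SM", rg.get("ID"))
            for rg in af.header.to_dict().get("RG", [])
        }
        for seg in af.fetch(until_eof=True):
            if seg.is_unmapped:
                continue
            if not include_secondary and (seg.is_secondary or seg.is_supplementary):
                continue
            sample = default_sample
            if seg.has_tag("RG"):
                sample = rg_to_sm.get(seg.get_tag("RG"), seg.get_tag("RG"))
            if sample is None:
                raise ValueError(f"read {seg.query_name} has no RG tag and no default sample")
            reads.append(AlignedRead.from_pysam(seg, sample))
    return reads


def coverage_table(
    reads: Sequence[AlignedRead],
    catalog: Sequence[VntrLocus],
    reference,
    samples: Optional[Sequence[str]] = None,
    min_flank: int = MIN_FLANK,
    min_match: float = MIN_FLANK_MATCH,
    short_read_mode: bool = False,
    probes: Optional[Sequence[GenomicInterval]] = None,
) -> Tuple[pd.DataFrame, Dict[Tuple[str, str], LocusCoverage]]:
    """Single-pass per-locus-per-sample coverage over a whole catalog.

    Returns a tidy DataFrame plus the underlying LocusCoverage objects keyed
    by (locus_id, sample_id).  Samples seen in the read set (or listed
    explicitly) get zero rows at loci they do not cover.
    """
    trees: Dict[str, IntervalTree] = {}
    for loc in catalog:
        trees.setdefault(loc.interval.chrom, IntervalTree()).addi(
            loc.interval.start, loc.interval.end, loc
        )
    loci_by_id = {loc.locus_id: loc for loc in catalog}
    sample_ids = set(samples or [])
    covs: Dict[Tuple[str, str], LocusCoverage] = {}
    per_locus_reads: Dict[str, List[AlignedRead]] = {lid: [] for lid in loci_by_id}
    for read in reads:
        sample_ids.add(read.sample_id)
        tree = trees.get(read.interval.chrom)
        if tree is None:
            continue
        for hit in tree.overlap(read.interval.start, read.interval.end):
            per_locus_reads[hit.data.locus_id].append(read)
    for lid, locus in loci_by_id.items():
        pd_dist = probe_distance(locus, probes) if probes is not None else None
        per_sample = count_spanning(
            locus, per_locus_reads[lid], reference,
            min_flank=min_flank, min_match=min_match, short_read_mode=short_read_mode,
        )
        for sid in sorted(sample_ids):
            cov = per_sample.get(sid) or LocusCoverage(locus_id=lid, sample_id=sid)
            cov.probe_distance = pd_dist
            covs[(lid, sid)] = cov
    rows = [
        {
            "locus_id": lid,
            "sample_id": sid,
            "n_spanning": c.n_spanning,
            "n_reliable": c.n_reliable,
            "probe_distance": c.probe_distance,
        }
        for (lid, sid), c in sorted(covs.items())
    ]
    return (
        pd.DataFrame(rows, columns=["locus_id", "sample_id", "n_spanning", "n_reliable", "probe_distance"]),
        covs,
    )
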