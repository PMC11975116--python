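"""VNTR catalog ingestion, curation and annotation.

A VNTR (Variable Number Tandem Repeat) here is any tandem-repeat locus whose
consensus motif is at least 6 bp.  Candidate loci come from Tandem Repeats
Finder ``.dat`` output or a simple BED dialect; curation keeps gene-proximal
loci (gene body, UTR, or up to 500 bp upstream of a transcription start site)
that do not fall in LINE/SINE elements or segmental duplications, where
short-read mapping and probe design are unreliable.

Coordinates are BED-style 0-based half-open throughout; 1-based formats
(TRF ``.dat``, SAM) are converted at the I/O boundary.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd
from intervaltree import IntervalTree

__all__ = [
    "GenomicInterval",
    "VntrLocus",
    "Gene",
    "AnnotationSet",
    "CurationResult",
    "read_trf_records",
    "curate",
    "gc_content",
    "annotate_gc",
    "is_autosome",
    "write_catalog",
    "read_catalog",
]

_AUTOSOME_RE = re.compile(r"^(chr)?([1-9]|1[0-9]|2[0-2])$")

#: fixed order in which exclusion filters are applied; the first failing
#: filter is the one recorded in the exclusion log.
FILTER_ORDER = ("motif", "repeat_element", "segdup", "proximity", "chromosome")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on ``chrom``."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.end <= self.start:
            raise ValueError(f"empty/inverted interval: [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def gap_to(self, other: "GenomicInterval") -> Optional[int]:
        """Gap in bp between two intervals on the same chromosome (0 if they overlap)."""
        if self.chrom != other.chrom:
            return None
        if self.overlaps(other):
            return 0
        if other.end <= self.start:
            return self.start - other.end
        return other.start - self.end


@dataclass
class VntrLocus:
    """One cataloged tandem-repeat locus with its consensus motif."""

    locus_id: str
    interval: GenomicInterval
    motif: str
    annotation: str = "none"
    gc: Optional[float] = None

    def __post_init__(self) -> None:
        self.motif = self.motif.upper()

    @property
    def motif_length(self) -> int:
        return len(self.motif)

    @property
    def ref_array_length(self) -> int:
        return len(self.interval)

    @property
    def ref_repeat_count(self) -> float:
        return self.ref_array_length / self.motif_length


@dataclass(frozen=True)
class Gene:
    """Gene body with strand and derived TSS; optional exon/UTR sub-intervals."""

    interval: GenomicInterval
    strand: str = "+"
    name: str = ""
    exons: tuple = ()
    utrs: tuple = ()

    @property
    def tss(self) -> int:
        # 0-based position of the transcription start (first transcribed base)
        return self.interval.start if self.strand == "+" else self.interval.end - 1


@dataclass
class AnnotationSet:
    genes: Sequence[Gene] = ()
    excluded_repeats: Sequence[GenomicInterval] = ()
    segdups: Sequence[GenomicInterval] = ()


@dataclass
class CurationResult:
    kept: list
    excluded: list  # list of (VntrLocus, reason) tuples

    def exclusion_log(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "locus_id": loc.locus_id,
                    "chrom": loc.interval.chrom,
                    "start": loc.interval.start,
                    "end": loc.interval.end,
                    "reason": reason,
                }
                for loc, reason in self.excluded
            ],
            columns=["locus_id", "chrom", "start", "end", "reason"],
        )


def _locus_id(chrom: str, start: int, end: int) -> str:
    return f"{chrom}:{start}-{end}"


def read_trf_records(path: Union[str, Path], format: str = "bed") -> list:
    """Parse candidate tandem-repeat records into :class:`VntrLocus` objects.

    No filtering is applied here; short motifs and repeat-element loci are
    removed later by :func:`curate`.

    Parameters
    ----------
    path
        Input file.
    format
        ``"bed"`` — ≥4 columns: chrom, start, end, motif[, name]; or
        ``"trf_dat"`` — Tandem Repeats Finder ``.dat`` output (1-based
        inclusive coordinates, consensus motif in column 14).
    """
    path = Path(path)
    if format == "bed":
        return _read_bed(path)
    if format == "trf_dat":
        return _read_trf_dat(path)
    raise ValueError(f"unknown catalog format: {format!r}")


def _read_bed(path: Path) -> list:
    loci = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: expected ≥4 BED columns, got {len(fields)}")
            chrom, start_s, end_s, motif = fields[:4]
            try:
                start, end = int(start_s), int(end_s)
                iv = GenomicInterval(chrom, start, end)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            name = fields[4] if len(fields) > 4 else _locus_id(chrom, start, end)
            loci.append(VntrLocus(locus_id=name, interval=iv, motif=motif))
    return loci


# TRF .dat data lines: start end period copies consensus_size %match %indel
# score %A %C %G %T entropy consensus_motif repeat_sequence
_TRF_FIELDS = 15


def _read_trf_dat(path: Path) -> list:
    loci = []
    chrom = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("Sequence:"):
                chrom = line.split(None, 1)[1].split()[0]
                continue
            if line.startswith(("Parameters:", "Version", "Program", "@")):
                if line.startswith("@"):
                    chrom = line[1:].split()[0]
                continue
            fields = line.split()
            if not fields[0].isdigit():
                continue  # header boilerplate
            if chrom is None:
                raise ValueError(f"{path}:{lineno}: data record before any 'Sequence:' header")
            if len(fields) < _TRF_FIELDS - 1:  # repeat seq may be absent in trimmed files
                raise ValueError(
                    f"{path}:{lineno}: expected ≥{_TRF_FIELDS - 1} TRF fields, got {len(fields)}"
                )
            try:
                start1, end1 = int(fields[0]), int(fields[1])
                motif = fields[13]
                iv = GenomicInterval(chrom, start1 - 1, end1)  # 1-based incl -> 0-based half-open
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed TRF record ({exc})") from None
            loci.append(VntrLocus(locus_id=_locus_id(chrom, start1 - 1, end1), interval=iv, motif=motif))
    return loci


def is_autosome(chrom: str) -> bool:
    return bool(_AUTOSOME_RE.match(chrom))


def _tree(intervals: Iterable[GenomicInterval]) -> dict:
    trees: dict = {}
    for iv in intervals:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv)
    return trees


def _hits(trees: dict, iv: GenomicInterval, containment: bool) -> bool:
    tree = trees.get(iv.chrom)
    if tree is None:
        return False
    if not containment:
        return bool(tree.overlap(iv.start, iv.end))
    return any(h.begin <= iv.start and h.end >= iv.end for h in tree.overlap(iv.start, iv.end))


def _in_promoter(locus: VntrLocus, gene: Gene, tss_flank: int, strand_aware: bool) -> bool:
    iv = locus.interval
    if iv.chrom != gene.interval.chrom:
        return False
    if gene.strand == "+" or not strand_aware:
        # upstream window [TSS - flank, TSS) on the forward strand
        if gene.interval.start - tss_flank <= iv.start < gene.interval.start:
            return True
    if gene.strand == "-" or not strand_aware:
        tss_end = gene.interval.end  # first upstream base is at tss_end
        if tss_end < iv.end <= tss_end + tss_flank:
            return True
    return False


def _annotate(locus: VntrLocus, overlapping: Sequence[Gene]) -> str:
    """Label a gene-overlapping locus: exonic > utr > intronic; exon+intron -> multiple."""
    iv = locus.interval
    hits_exon = hits_utr = hits_intron = False
    for g in overlapping:
        exon_cov = [e for e in (*g.exons, ) if iv.overlaps(e)]
        utr_cov = [u for u in (*g.utrs, ) if iv.overlaps(u)]
        if exon_cov:
            hits_exon = True
        if utr_cov:
            hits_utr = True
        # intronic = part of the gene body not covered by any exon/UTR
        covered = sorted((f.start, f.end) for f in (*g.exons, *g.utrs))
        pos = max(iv.start, g.interval.start)
        endpos = min(iv.end, g.interval.end)
        for s, e in covered:
            if s > pos:
                break
            pos = max(pos, e)
        if pos < endpos:
            hits_intron = True
    if hits_exon and hits_intron:
        return "multiple"
    if hits_exon:
        return "exonic"
    if hits_utr:
        return "utr"
    return "intronic"


def curate(
    candidates: Sequence[VntrLocus],
    ann: AnnotationSet,
    tss_flank: int = 500,
    min_motif: int = 6,
    autosomes_only: bool = False,
    containment: bool = False,
    strand_aware_promoter: bool = True,
) -> CurationResult:
    """Apply the catalog curation filters and annotate retained loci.

    A locus is kept iff all of the following hold, tested in a fixed order so
    every exclusion has exactly one attributed reason: motif length ≥
    ``min_motif``; no overlap with a LINE/SINE interval; no overlap with a
    segmental-duplication interval; overlap with a gene body or position
    within ``tss_flank`` bp upstream of a TSS; and, if ``autosomes_only``,
    an autosomal chromosome.  ``containment=True`` switches the two
    repeat-exclusion filters from any-overlap to full containment.
    """
    rep_trees = _tree(ann.excluded_repeats)
    segdup_trees = _tree(ann.segdups)
    gene_trees: dict = {}
    for g in ann.genes:
        gene_trees.setdefault(g.interval.chrom, IntervalTree()).addi(
            g.interval.start, g.interval.end, g
        )

    kept, excluded = [], []
    for loc in candidates:
        iv = loc.interval
        if loc.motif_length < min_motif:
            excluded.append((loc, "motif"))
            continue
        if _hits(rep_trees, iv, containment):
            excluded.append((loc, "repeat_element"))
            continue
        if _hits(segdup_trees, iv, containment):
            excluded.append((loc, "segdup"))
            continue
        tree = gene_trees.get(iv.chrom)
        body_hits = [h.data for h in tree.overlap(iv.start, iv.end)] if tree is not None else []
        if body_hits:
            label = _annotate(loc, body_hits)
        elif any(
            _in_promoter(loc, g, tss_flank, strand_aware_promoter)
            for g in ann.genes
            if g.interval.chrom == iv.chrom
        ):
            label = "promoter"
        else:
            excluded.append((loc, "proximity"))
            continue
        if autosomes_only and not is_autosome(iv.chrom):
            excluded.append((loc, "chromosome"))
            continue
        kept.append(replace_annotation(loc, label))
    return CurationResult(kept=kept, excluded=excluded)


def replace_annotation(locus: VntrLocus, label: str) -> VntrLocus:
    return VntrLocus(
        locus_id=locus.locus_id,
        interval=locus.interval,
        motif=locus.motif,
        annotation=label,
        gc=locus.gc,
    )


def gc_content(
    locus: VntrLocus,
    reference,
    flank: int = 100,
) -> Optional[float]:
    """GC fraction of the locus window extended by ``flank`` bp on each side.

    ``reference`` is any object with ``fetch(chrom, start, end)`` (e.g.
    :class:`pysam.FastaFile`) or a mapping of chromosome name to sequence.
    N bases are excluded from the denominator; an all-N window returns
    ``None`` (missing) rather than 0.  The window is truncated at contig
    edges.
    """
    iv = locus.interval
    start = max(0, iv.start - flank)
    end = iv.end + flank
    if hasattr(reference, "fetch"):
        try:
            seq = reference.fetch(iv.chrom, start, end)
        except (KeyError, ValueError) as exc:
            raise KeyError(f"interval {iv} absent from reference: {exc}") from None
    else:
        try:
            contig = reference[iv.chrom]
        except KeyError:
            raise KeyError(f"chromosome {iv.chrom!r} absent from reference") from None
        seq = str(contig[start : min(end, len(contig))])
    if not seq:
        raise KeyError(f"interval {iv} absent from reference")
    seq = seq.upper()
    denom = sum(1 for b in seq if b != "N")
    if denom == 0:
        return None
    gc = seq.count("G") + seq.count("C")
    return gc / denom


def annotate_gc(loci: Sequence[VntrLocus], reference, flank: int = 100) -> list:
    """Return loci with their ``gc`` field filled in."""
    out = []
    for loc in loci:
        out.append(
            VntrLocus(
                locus_id=loc.locus_id,
                interval=loc.interval,
                motif=loc.motif,
                annotation=loc.annotation,
                gc=gc_content(loc, reference, flank=flank),
            )
        )
    return out


def write_catalog(loci: Sequence[VntrLocus], path: Union[str, Path]) -> None:
    df = pd.DataFrame(
        [
            {
                "locus_id": l.locus_id,
                "chrom": l.interval.chrom,
                "start": l.interval.start,
                "end": l.interval.end,
                "motif": l.motif,
                "annotation": l.annotation,
            }
            for l in loci
        ],
        columns=["locus_id", "chrom", "start", "end", "motif", "annotation"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_catalog(path: Union[str, Path]) -> list:
    df = pd.read_csv(path, sep="\t")
    return [
        VntrLocus(
            locus_id=str(r.locus_id),
            interval=GenomicInterval(str(r.chrom), int(r.start), int(r.end)),
            motif=str(r.motif),
            annotation=str(r.annotation),
        )
        for r in df.itertuples()
    ]
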