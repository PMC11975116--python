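"""Synthetic reference, cohort and read-set generator with known truth.

Everything the pipeline consumes can be generated here: a reference contig
with planted tandem-repeat arrays, diploid samples and trios with Mendelian
allele transmission, and HiFi-like pre-aligned read sets under either of two
sampling models:

* ``targeted`` — hybridization-capture behaviour: the expected spanning
  depth at a locus decays logistically once the locus GC content passes a
  knee (default 0.60, where PCR amplification of capture libraries starts to
  fail) and once the distance to the nearest probe passes 1 kb, down to a
  configurable dropout floor.
* ``wgs`` — unbiased whole-genome sampling at a uniform expected depth.

Reads are emitted pre-aligned at their true coordinates (flank bases match
the reference; the repeat array carries the haplotype's repeat count as an
insertion/deletion against the reference array), so no external aligner is
involved and every output is bit-reproducible from the seed.  Substitution
errors are planted at a configurable rate; indel errors are off.

The defaults describe the study conditions the generator emulates: motif
length ≥ 6 bp, 4 samples, per-locus targeted depth 30, HiFi-like 0.2%
substitution rate, read-length medians of ~4.2 kb (targeted, sheared
capture libraries) and ~18 kb (WGS), and 76% of loci non-polymorphic.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .catalog import AnnotationSet, Gene, GenomicInterval, VntrLocus, gc_content
from .coverage import AlignedRead
from .genotyping import GenotypeCall, Trio

__all__ = [
    "SimulationConfig",
    "SimulatedReference",
    "TruthSet",
    "SimReads",
    "SimBundle",
    "simulate_reference",
    "simulate_individuals",
    "simulate_reads",
    "simulate_all",
    "dropout_factor",
    "sample_locus_depths",
]

_BASES = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    """Knobs for the synthetic cohort; defaults are the emulated study conditions."""

    seed: int = 0
    n_loci: int = 50
    motif_length_range: Tuple[int, int] = (6, 30)
    repeat_count_range: Tuple[int, int] = (3, 15)
    n_samples: int = 4
    n_trios: int = 0
    mode: str = "targeted"  # targeted | wgs
    read_length_median: Optional[float] = None  # default 4200 targeted / 18000 wgs
    read_length_sigma: float = 0.35
    substitution_rate: float = 0.002
    depth: float = 30.0  # expected spanning reads per locus per sample before dropout
    gc_knee: float = 0.60
    gc_slope: float = 30.0  # logistic steepness per unit GC fraction
    probe_knee: float = 1000.0  # bp
    probe_slope: float = 0.005  # logistic steepness per bp
    dropout_floor: float = 0.05
    nonpolymorphic_fraction: float = 0.76
    de_novo_rate: float = 0.0  # per child per locus
    truncated_flank_rate: float = 0.0  # spanning reads with < 10 bp on one flank
    nonspanning_rate: float = 0.3  # expected non-spanning reads, as a fraction of depth
    n_off_target: int = 0  # off-target reads per sample
    margin: int = 5000  # reference bp flanking each locus slot
    gc_low_range: Tuple[float, float] = (0.30, 0.55)
    gc_high_range: Tuple[float, float] = (0.65, 0.85)
    high_gc_fraction: float = 0.5
    probe_length: int = 120
    probe_overlap_fraction: float = 0.6
    probe_max_distance: int = 3000
    promoter_fraction: float = 0.1
    n_segdup_decoys: int = 2
    n_line_decoys: int = 2
    n_intergenic_decoys: int = 2
    n_short_motif_decoys: int = 2
    contig: str = "chrS"

    def __post_init__(self) -> None:
        if self.mode not in ("targeted", "wgs"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.motif_length_range[0] < 6:
            raise ValueError("motif length range must start at ≥ 6 for VNTR loci")
        for r in (self.substitution_rate, self.dropout_floor, self.nonpolymorphic_fraction,
                  self.de_novo_rate, self.truncated_flank_rate):
            if not 0 <= r <= 1:
                raise ValueError(f"rate {r} outside [0, 1]")

    @property
    def effective_read_length_median(self) -> float:
        if self.read_length_median is not None:
            return self.read_length_median
        return 4200.0 if self.mode == "targeted" else 18000.0

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


class RefSeq:
    """Minimal fetchable reference over in-memory contigs."""

    def __init__(self, contigs: Dict[str, str]):
        self._contigs = contigs

    def fetch(self, chrom: str, start: int, end: int) -> str:
        if chrom not in self._contigs:
            raise KeyError(f"unknown contig {chrom!r}")
        return self._contigs[chrom][max(0, start):end]

    def lengths(self) -> Dict[str, int]:
        return {c: len(s) for c, s in self._contigs.items()}


@dataclass
class SimulatedReference:
    config: SimulationConfig
    contig: str
    sequence: str
    loci: List[VntrLocus]  # curatable target loci, gc annotated
    candidates: List[VntrLocus]  # targets + planted decoys, unannotated
    annotation: AnnotationSet
    probes: List[GenomicInterval]
    locus_meta: pd.DataFrame  # locus_id, gc, probe_distance, ref_repeat_count

    def reference(self) -> RefSeq:
        return RefSeq({self.contig: self.sequence})

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "reference.fa", "w") as fh:
            fh.write(f">{self.contig}\n")
            for i in range(0, len(self.sequence), 80):
                fh.write(self.sequence[i:i + 80] + "\n")
        _write_bed(outdir / "candidates.bed",
                   [(l.interval, l.motif, l.locus_id) for l in self.candidates])
        _write_bed(outdir / "probes.bed", [(p, ".", ".") for p in self.probes])
        _write_bed(outdir / "segdups.bed", [(p, ".", ".") for p in self.annotation.segdups])
        _write_bed(outdir / "line_sine.bed", [(p, ".", ".") for p in self.annotation.excluded_repeats])
        with open(outdir / "genes.tsv", "w") as fh:
            fh.write("chrom\tstart\tend\tstrand\tname\texons\tutrs\n")
            for g in self.annotation.genes:
                ex = ";".join(f"{e.start}-{e.end}" for e in g.exons)
                ut = ";".join(f"{u.start}-{u.end}" for u in g.utrs)
                fh.write(f"{g.interval.chrom}\t{g.interval.start}\t{g.interval.end}"
                         f"\t{g.strand}\t{g.name}\t{ex}\t{ut}\n")
        self.locus_meta.to_csv(outdir / "locus_meta.tsv", sep="\t", index=False)
        with open(outdir / "sim_config.json", "w") as fh:
            fh.write(self.config.to_json())


def _write_bed(path, rows) -> None:
    with open(path, "w") as fh:
        for iv, motif, name in rows:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{motif}\t{name}\n")


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(_BASES[rng.choice(4, size=length, p=probs)])


def simulate_reference(cfg: SimulationConfig, rng: Optional[np.random.Generator] = None) -> SimulatedReference:
    """Build a synthetic contig with planted VNTR arrays and annotations.

    Each target locus occupies its own slot: ``margin`` bp of flank on each
    side, with the 100 bp adjacent to the array drawn at the locus's target
    GC so that the measured window GC lands on the intended side of the GC
    knee.  Decoy loci (inside segdup/LINE intervals, far from genes, or with
    short motifs) exercise the curation filters.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    margin = cfg.margin
    if margin < 300:
        raise ValueError("margin must be ≥ 300 bp to fit GC windows and probes")
    parts: List[str] = []
    pos = 0
    loci: List[VntrLocus] = []
    candidates: List[VntrLocus] = []
    genes: List[Gene] = []
    probes: List[GenomicInterval] = []
    segdups: List[GenomicInterval] = []
    lines: List[GenomicInterval] = []
    planted_probe_dist: Dict[str, Optional[int]] = {}

    n_high = int(round(cfg.n_loci * cfg.high_gc_fraction))
    gc_targets = np.concatenate([
        rng.uniform(*cfg.gc_high_range, size=n_high),
        rng.uniform(*cfg.gc_low_range, size=cfg.n_loci - n_high),
    ])
    rng.shuffle(gc_targets)

    def plant(motif_len_range, gc_target, decoy=None):
        nonlocal pos
        mlen = int(rng.integers(motif_len_range[0], motif_len_range[1] + 1))
        motif = _random_seq(rng, mlen, gc_target)
        ref_rc = int(rng.integers(max(3, cfg.repeat_count_range[0]), cfg.repeat_count_range[1] + 1))
        array = motif * ref_rc
        left = _random_seq(rng, margin - 100, 0.45) + _random_seq(rng, 100, gc_target)
        right = _random_seq(rng, 100, gc_target) + _random_seq(rng, margin - 100, 0.45)
        start = pos + margin
        end = start + len(array)
        parts.extend([left, array, right])
        pos = end + margin
        iv = GenomicInterval(cfg.contig, start, end)
        locus = VntrLocus(locus_id=f"{cfg.contig}:{start}-{end}", interval=iv, motif=motif)
        candidates.append(locus)
        if decoy is None:
            loci.append(locus)
        return locus

    for gc_t in gc_targets:
        locus = plant(cfg.motif_length_range, float(gc_t))
        iv = locus.interval
        # gene context: mostly gene-body overlap, some promoter placement
        if rng.random() < cfg.promoter_fraction and len(iv) <= 450:
            d = int(rng.integers(len(iv) + 1, 501))
            gstart = iv.start + d
            genes.append(Gene(GenomicInterval(cfg.contig, gstart, gstart + 1000), "+",
                              name=f"G_{locus.locus_id}"))
        else:
            giv = GenomicInterval(cfg.contig, iv.start - 200, iv.end + 200)
            kind = rng.choice(["intronic", "exonic", "multiple", "utr"])
            exons, utrs = (), ()
            if kind == "exonic":
                exons = (giv,)
            elif kind == "multiple":
                exons = (GenomicInterval(cfg.contig, giv.start, iv.start + len(iv) // 2),)
            elif kind == "utr":
                utrs = (giv,)
            genes.append(Gene(giv, "+", name=f"G_{locus.locus_id}", exons=exons, utrs=utrs))
        # probe placement
        if rng.random() < cfg.probe_overlap_fraction:
            probes.append(GenomicInterval(cfg.contig, iv.start, iv.start + cfg.probe_length))
            planted_probe_dist[locus.locus_id] = 0
        else:
            d = int(rng.integers(50, cfg.probe_max_distance + 1))
            probes.append(GenomicInterval(cfg.contig, iv.start - d - cfg.probe_length, iv.start - d))
            planted_probe_dist[locus.locus_id] = d

    # decoys: each gets a gene (so only the intended filter fires), except intergenic ones
    for _ in range(cfg.n_segdup_decoys):
        loc = plant(cfg.motif_length_range, 0.45, decoy="segdup")
        segdups.append(GenomicInterval(cfg.contig, loc.interval.start - 500, loc.interval.end + 500))
        genes.append(Gene(GenomicInterval(cfg.contig, loc.interval.start - 200, loc.interval.end + 200), "+"))
    for _ in range(cfg.n_line_decoys):
        loc = plant(cfg.motif_length_range, 0.45, decoy="line")
        lines.append(GenomicInterval(cfg.contig, loc.interval.start - 500, loc.interval.end + 500))
        genes.append(Gene(GenomicInterval(cfg.contig, loc.interval.start - 200, loc.interval.end + 200), "+"))
    for _ in range(cfg.n_intergenic_decoys):
        plant(cfg.motif_length_range, 0.45, decoy="intergenic")
    for _ in range(cfg.n_short_motif_decoys):
        loc = plant((4, 5), 0.45, decoy="short_motif")
        genes.append(Gene(GenomicInterval(cfg.contig, loc.interval.start - 200, loc.interval.end + 200), "+"))

    sequence = "".join(parts)
    ref = RefSeq({cfg.contig: sequence})
    gc_measured = {l.locus_id: gc_content(l, ref, flank=100) for l in loci}
    loci = [
        VntrLocus(locus_id=l.locus_id, interval=l.interval, motif=l.motif,
                  annotation=l.annotation, gc=gc_measured[l.locus_id])
        for l in loci
    ]
    meta = pd.DataFrame(
        [
            {
                "locus_id": l.locus_id,
                "gc": l.gc,
                "probe_distance": planted_probe_dist[l.locus_id],
                "motif_length": l.motif_length,
                "ref_repeat_count": int(round(l.ref_repeat_count)),
                "ref_array_length": l.ref_array_length,
            }
            for l in loci
        ]
    )
    return SimulatedReference(
        config=cfg,
        contig=cfg.contig,
        sequence=sequence,
        loci=loci,
        candidates=candidates,
        annotation=AnnotationSet(genes=genes, excluded_repeats=lines, segdups=segdups),
        probes=probes,
        locus_meta=meta,
    )


@dataclass
class TruthSet:
    """Planted diploid genotypes for every sample and locus."""

    genotypes: Dict[Tuple[str, str], Tuple[int, int]]  # (locus_id, sample) -> (a1, a2)
    samples: List[str]
    trios: List[Trio]
    polymorphic: set = field(default_factory=set)

    def genotype_calls(self) -> List[GenotypeCall]:
        return [
            GenotypeCall(alleles=alleles, locus_id=lid, sample_id=sid)
            for (lid, sid), alleles in sorted(self.genotypes.items())
        ]

    def to_table(self) -> pd.DataFrame:
        rows = [
            {"locus_id": lid, "sample_id": sid, "allele1": min(a), "allele2": max(a)}
            for (lid, sid), a in sorted(self.genotypes.items())
        ]
        return pd.DataFrame(rows, columns=["locus_id", "sample_id", "allele1", "allele2"])


def simulate_individuals(
    cfg: SimulationConfig,
    catalog: Sequence[VntrLocus],
    rng: Optional[np.random.Generator] = None,
) -> TruthSet:
    """Draw diploid repeat counts for founders and transmit alleles to trio children.

    A ``nonpolymorphic_fraction`` of loci is fixed at the reference repeat
    count in everyone; at polymorphic loci founder haplotypes are uniform
    over ``repeat_count_range``.  Trio children receive one allele from each
    parent uniformly; with probability ``de_novo_rate`` per locus one child
    haplotype is replaced by an allele absent from both parents (a planted
    Mendelian violation).
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 1)
    founders = [f"S{i + 1:02d}" for i in range(cfg.n_samples)]
    trios = []
    trio_parents = []
    for t in range(cfg.n_trios):
        f, m, c = f"T{t + 1}F", f"T{t + 1}M", f"T{t + 1}C"
        trios.append(Trio(child=c, mother=m, father=f))
        trio_parents.extend([f, m])
    samples = founders + [s for t in trios for s in (t.father, t.mother, t.child)]

    lo, hi = cfg.repeat_count_range
    genotypes: Dict[Tuple[str, str], Tuple[int, int]] = {}
    polymorphic = set()
    for locus in catalog:
        ref_rc = int(round(locus.ref_repeat_count))
        poly = rng.random() >= cfg.nonpolymorphic_fraction
        if poly:
            polymorphic.add(locus.locus_id)
        for sid in founders + trio_parents:
            if poly:
                alleles = (int(rng.integers(lo, hi + 1)), int(rng.integers(lo, hi + 1)))
            else:
                alleles = (ref_rc, ref_rc)
            genotypes[(locus.locus_id, sid)] = alleles
        for trio in trios:
            ma = genotypes[(locus.locus_id, trio.mother)]
            fa = genotypes[(locus.locus_id, trio.father)]
            child = [ma[int(rng.integers(2))], fa[int(rng.integers(2))]]
            if cfg.de_novo_rate and rng.random() < cfg.de_novo_rate:
                parental = set(ma) | set(fa)
                options = [a for a in range(lo, hi + 1) if a not in parental]
                novel = int(rng.choice(options)) if options else max(hi, ref_rc) + 1
                child[int(rng.integers(2))] = novel
            genotypes[(locus.locus_id, trio.child)] = tuple(child)
    return TruthSet(genotypes=genotypes, samples=samples, trios=trios, polymorphic=polymorphic)


def dropout_factor(cfg: SimulationConfig, gc: float, probe_dist: Optional[int]) -> float:
    """Multiplicative depth retention in [floor², 1] for a targeted locus.

    Two independent logistic decays: one past the GC knee, one past the
    probe-distance knee; each bottoms out at ``dropout_floor``.  WGS mode is
    bias-free (returns 1).
    """
    if cfg.mode == "wgs":
        return 1.0
    fl = cfg.dropout_floor
    f_gc = fl + (1 - fl) / (1 + math.exp(cfg.gc_slope * (gc - cfg.gc_knee)))
    d = float(probe_dist) if probe_dist is not None else 10 * cfg.probe_knee
    f_pd = fl + (1 - fl) / (1 + math.exp(cfg.probe_slope * (d - cfg.probe_knee)))
    return f_gc * f_pd


def sample_locus_depths(
    cfg: SimulationConfig,
    gc: Sequence[float],
    probe_dist: Sequence[Optional[int]],
    rng: np.random.Generator,
) -> np.ndarray:
    """Poisson spanning-read counts for one sample over a set of loci."""
    lam = np.array([cfg.depth * dropout_factor(cfg, g, d) for g, d in zip(gc, probe_dist)])
    return rng.poisson(lam)


@dataclass
class SimReads:
    reads: List[AlignedRead]
    sidecar: pd.DataFrame  # read_id, sample_id, locus_id, allele, category
    total_mapped: Dict[str, int]

    def spanning_truth_counts(self) -> pd.DataFrame:
        """Planted spanning-read tallies per locus per sample."""
        df = self.sidecar[self.sidecar["category"] == "spanning"]
        return (
            df.groupby(["locus_id", "sample_id"]).size().rename("n_spanning").reset_index()
        )

    def write_sam(self, path, simref: SimulatedReference) -> None:
        import pysam

        header = {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": simref.contig, "LN": len(simref.sequence)}],
            "RG": [{"ID": s, "SM": s} for s in sorted(self.total_mapped)],
        }
        ordered = sorted(self.reads, key=lambda r: (r.interval.start, r.read_id))
        with pysam.AlignmentFile(str(path), "wh", header=header) as out:
            for read in ordered:
                seg = pysam.AlignedSegment(out.header)
                seg.query_name = read.read_id
                seg.query_sequence = read.sequence
                seg.flag = 0
                seg.reference_id = 0
                seg.reference_start = read.interval.start
                seg.mapping_quality = 60
                seg.cigartuples = list(read.cigartuples)
                seg.set_tag("RG", read.sample_id)
                out.write(seg)


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        base = arr[i].decode()
        choices = [b for b in "ACGT" if b != base]
        arr[i] = choices[int(rng.integers(3))].encode()
    return arr.tobytes().decode()


def simulate_reads(
    cfg: SimulationConfig,
    truth: TruthSet,
    simref: SimulatedReference,
    rng: Optional[np.random.Generator] = None,
) -> SimReads:
    """Generate pre-aligned spanning, non-spanning and off-target reads.

    For each sample × locus the number of spanning reads is Poisson with
    mean ``depth × dropout_factor(gc, probe_distance)`` (uniform ``depth`` in
    WGS mode).  Each spanning read carries one haplotype's repeat array with
    flank lengths drawn from the read-length model, truncated at the locus
    slot margin; repeat-count differences from the reference appear as a
    single insertion or deletion at the array's 3' end.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 2)
    seq = simref.sequence
    contig = simref.contig
    margin = cfg.margin
    meta = simref.locus_meta.set_index("locus_id")
    mu = math.log(cfg.effective_read_length_median)
    reads: List[AlignedRead] = []
    sidecar_rows = []
    total = {s: 0 for s in truth.samples}

    def emit(read: AlignedRead, locus_id: str, allele, category: str) -> None:
        reads.append(read)
        total[read.sample_id] += 1
        sidecar_rows.append(
            {"read_id": read.read_id, "sample_id": read.sample_id,
             "locus_id": locus_id, "allele": allele, "category": category}
        )

    for locus in simref.loci:
        lid = locus.locus_id
        iv = locus.interval
        mlen = locus.motif_length
        ref_array_len = iv.end - iv.start
        gc = meta.loc[lid, "gc"]
        pdist = meta.loc[lid, "probe_distance"]
        lam = cfg.depth * dropout_factor(cfg, float(gc), int(pdist) if pd.notna(pdist) else None)
        for sid in truth.samples:
            alleles = truth.genotypes[(lid, sid)]
            n_span = int(rng.poisson(lam))
            for i in range(n_span):
                hap = int(rng.integers(2))
                rc = alleles[hap]
                array = locus.motif * rc
                L = int(rng.lognormal(mu, cfg.read_length_sigma))
                f_total = max(L - len(array), 2)
                f_l = 1 + int(rng.integers(0, f_total - 1)) if f_total > 2 else 1
                f_r = f_total - f_l
                f_l = min(max(f_l, 1), margin - 10)
                f_r = min(max(f_r, 1), margin - 10)
                if cfg.truncated_flank_rate and rng.random() < cfg.truncated_flank_rate:
                    if rng.integers(2):
                        f_l = int(rng.integers(1, 10))
                    else:
                        f_r = int(rng.integers(1, 10))
                left = seq[iv.start - f_l: iv.start]
                right = seq[iv.end: iv.end + f_r]
                read_seq = _mutate(rng, left + array + right, cfg.substitution_rate)
                cigar: List[Tuple[int, int]] = []
                if rc * mlen == ref_array_len:
                    cigar = [(0, f_l + rc * mlen + f_r)]
                elif rc * mlen > ref_array_len:
                    cigar = [(0, f_l + ref_array_len), (1, rc * mlen - ref_array_len), (0, f_r)]
                else:
                    cigar = [(0, f_l + rc * mlen), (2, ref_array_len - rc * mlen), (0, f_r)]
                read = AlignedRead(
                    read_id=f"{sid}:{lid}:sp{i}",
                    sample_id=sid,
                    interval=GenomicInterval(contig, iv.start - f_l, iv.end + f_r),
                    sequence=read_seq,
                    cigartuples=cigar,
                )
                emit(read, lid, rc, "spanning")
            n_non = int(rng.poisson(cfg.nonspanning_rate * lam))
            for i in range(n_non):
                # partial read: enters the array but stops inside it
                f = int(rng.integers(200, margin - 10))
                rstart = iv.start - f
                rend = int(rng.integers(iv.start + 1, iv.end))
                read_seq = _mutate(rng, seq[rstart:rend], cfg.substitution_rate)
                read = AlignedRead(
                    read_id=f"{sid}:{lid}:ns{i}",
                    sample_id=sid,
                    interval=GenomicInterval(contig, rstart, rend),
                    sequence=read_seq,
                    cigartuples=[(0, rend - rstart)],
                )
                emit(read, lid, pd.NA, "nonspanning")

    if cfg.n_off_target:
        # placed deep in a locus's left spacer: ≥ margin−500 bp from any array
        for sid in truth.samples:
            for i in range(cfg.n_off_target):
                locus = simref.loci[int(rng.integers(len(simref.loci)))]
                rstart = locus.interval.start - margin + 100
                rend = rstart + 400
                read = AlignedRead(
                    read_id=f"{sid}:offt{i}",
                    sample_id=sid,
                    interval=GenomicInterval(contig, rstart, rend),
                    sequence=_mutate(rng, seq[rstart:rend], cfg.substitution_rate),
                    cigartuples=[(0, rend - rstart)],
                )
                emit(read, "", pd.NA, "offtarget")

    sidecar = pd.DataFrame(
        sidecar_rows, columns=["read_id", "sample_id", "locus_id", "allele", "category"]
    )
    return SimReads(reads=reads, sidecar=sidecar, total_mapped=total)


@dataclass
class SimBundle:
    config: SimulationConfig
    reference: SimulatedReference
    truth: TruthSet
    reads: SimReads


def simulate_all(cfg: SimulationConfig) -> SimBundle:
    """Reference, individuals and reads in one deterministic pass."""
    simref = simulate_reference(cfg)
    truth = simulate_individuals(cfg, simref.loci)
    reads = simulate_reads(cfg, truth, simref)
    return SimBundle(config=cfg, reference=simref, truth=truth, reads=reads)
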