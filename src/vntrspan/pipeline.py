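"""End-to-end orchestration of the VNTR coverage and genotyping QC stages.

A run executes, in dependency order: simulate → curate → score-motifs →
count-spanning → genotype → concordance → mendelian → perr → report.  All
tabular stage outputs are TSV with headers, summaries are JSON, and the
resolved configuration is written beside the outputs, so every number in the
report is recomputable from the stage files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd
import yaml

from . import catalog as cat
from . import coverage as covmod
from . import genotyping as gt
from . import strlike as sl
from . import threshold as thr
from .simulate import SimulationConfig, simulate_all, simulate_reads

log = logging.getLogger("vntrspan")

__all__ = ["RunConfig", "run"]


@dataclass
class RunConfig:
    """Thresholds and simulation settings for a pipeline run."""

    seed: int = 7
    well_threshold: int = 15
    high_threshold: int = 63
    projection_cap: int = 30
    gc_cut: float = 0.60
    strlike_cutoff: float = 0.8
    min_support: int = 3
    min_flank: int = 10
    min_match: float = 0.95
    tss_flank: int = 500
    short_read_length_cut: int = 150
    perr_alpha: float = 0.01
    variance_cut: float = 0.2
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    compare_mode: str = "wgs"  # read-set B for the concordance stage

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimulationConfig(**{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in (raw.pop("simulation", {}) or {}).items()
        })
        cfg = cls(simulation=sim, **raw)
        return cfg

    def resolved(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _write_json(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_jsonable)
        fh.write("\n")


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, pd.DataFrame):
        return x.to_dict(orient="records")
    raise TypeError(f"not JSON serializable: {type(x)}")


def run(config: RunConfig, outdir, overwrite: bool = False) -> dict:
    """Execute all stages on a simulated cohort and write the report bundle.

    Raises ``FileExistsError`` if ``outdir`` already holds a report and
    ``overwrite`` is not set (partial outputs are never silently replaced).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if (outdir / "report.json").exists() and not overwrite:
        raise FileExistsError(f"{outdir}/report.json exists; pass overwrite to replace")
    config.simulation.seed = config.simulation.seed or config.seed
    with open(outdir / "config_resolved.yaml", "w") as fh:
        yaml.safe_dump(config.resolved(), fh, sort_keys=True)

    # ---- simulate -----------------------------------------------------
    log.info("simulate: %d loci, %d samples, %d trios, mode=%s",
             config.simulation.n_loci, config.simulation.n_samples,
             config.simulation.n_trios, config.simulation.mode)
    bundle = simulate_all(config.simulation)
    simref, truth, simreads = bundle.reference, bundle.truth, bundle.reads
    simref.write(outdir / "sim")
    truth.to_table().to_csv(outdir / "sim" / "truth_genotypes.tsv", sep="\t", index=False)
    simreads.sidecar.to_csv(outdir / "sim" / "truth_reads.tsv", sep="\t", index=False)
    simreads.write_sam(outdir / "sim" / "reads_a.sam", simref)

    # ---- curate -------------------------------------------------------
    log.info("curate: tss_flank=%d, min_motif=6", config.tss_flank)
    cur = cat.curate(simref.candidates, simref.annotation, tss_flank=config.tss_flank)
    reference = simref.reference()
    curated = cat.annotate_gc(cur.kept, reference)
    cat.write_catalog(curated, outdir / "catalog.tsv")
    cur.exclusion_log().to_csv(outdir / "exclusions.tsv", sep="\t", index=False)

    # ---- score motifs -------------------------------------------------
    scores = {l.locus_id: sl.strlike_score(l.motif, cutoff=config.strlike_cutoff)
              for l in curated}
    pd.DataFrame(
        [{"locus_id": lid, "motif": m.motif, "n": m.n, "k": m.k,
          "score": m.score, "is_str_like": m.is_str_like}
         for lid, m in sorted(scores.items())]
    ).to_csv(outdir / "motif_scores.tsv", sep="\t", index=False)

    # ---- count spanning ----------------------------------------------
    log.info("count-spanning: min_flank=%d, min_match=%.2f",
             config.min_flank, config.min_match)
    cov_df, covs = covmod.coverage_table(
        simreads.reads, curated, reference,
        samples=truth.samples, min_flank=config.min_flank,
        min_match=config.min_match, probes=simref.probes,
    )
    for (lid, sid), c in covs.items():
        c.spanning_per_million = covmod.normalize_per_million(
            c, max(simreads.total_mapped.get(sid, 0), 1)
        )
    cov_df["spanning_per_million"] = [
        covs[(r.locus_id, r.sample_id)].spanning_per_million for r in cov_df.itertuples()
    ]
    cov_df.to_csv(outdir / "coverage.tsv", sep="\t", index=False)

    classifications = {}
    for lid in sorted({k[0] for k in covs}):
        per_sample = [covs[(lid, sid)] for sid in sorted(truth.samples)]
        classifications[lid] = covmod.classify_coverage(
            per_sample, config.well_threshold, config.high_threshold, config.projection_cap
        )
    cls_df = pd.DataFrame(
        [{"locus_id": lid, "median_spanning": c.median_spanning, "tier": c.tier,
          "cross_sample_variance": c.cross_sample_variance}
         for lid, c in sorted(classifications.items())]
    )
    cls_df.to_csv(outdir / "classification.tsv", sep="\t", index=False)

    # ---- genotype (read set A) ---------------------------------------
    log.info("genotype: min_support=%d", config.min_support)
    calls_a = {
        (lid, sid): gt.call_genotype(c.reliable_by_repeat_count, config.min_support,
                                     locus_id=lid, sample_id=sid)
        for (lid, sid), c in covs.items()
    }
    gt.write_genotype_table(calls_a.values(), outdir / "genotypes_a.tsv")

    # ---- concordance against a second read set ------------------------
    cfg_b = dataclasses.replace(
        config.simulation, mode=config.compare_mode, seed=config.simulation.seed + 101,
        read_length_median=None,
    )
    reads_b = simulate_reads(cfg_b, truth, simref)
    _, covs_b = covmod.coverage_table(
        reads_b.reads, curated, reference,
        samples=truth.samples, min_flank=config.min_flank, min_match=config.min_match,
    )
    calls_b = {
        key: gt.call_genotype(c.reliable_by_repeat_count, config.min_support,
                              locus_id=key[0], sample_id=key[1])
        for key, c in covs_b.items()
    }
    gt.write_genotype_table(calls_b.values(), outdir / "genotypes_b.tsv")
    score_map = {lid: m.score for lid, m in scores.items()}
    consistency = gt.consistency_summary(
        calls_a, calls_b, catalog=curated,
        strlike_scores=score_map, strlike_cutoff=config.strlike_cutoff,
    )
    consistency["verdicts"].to_csv(outdir / "consistency_verdicts.tsv", sep="\t", index=False)

    # ---- mendelian -----------------------------------------------------
    mendelian = None
    if truth.trios:
        mendelian = gt.mendelian_summary(
            calls_a, truth.trios, catalog=curated,
            strlike_scores=score_map, strlike_cutoff=config.strlike_cutoff,
        )

    # ---- perr ----------------------------------------------------------
    perr_df = thr.perr_table(1, 30, alpha=config.perr_alpha)
    perr_df.to_csv(outdir / "perr.tsv", sep="\t", index=False)

    # ---- report --------------------------------------------------------
    report = _build_report(config, curated, scores, cov_df, cls_df, covs,
                           simreads, consistency, mendelian)
    _write_json(report, outdir / "report.json")
    return report


def _build_report(config, curated, scores, cov_df, cls_df, covs, simreads,
                  consistency, mendelian) -> dict:
    n_catalog = len(curated)
    tiers = cls_df["tier"].value_counts().to_dict()
    tier_counts = {t: int(tiers.get(t, 0)) for t in ("uncovered", "low", "well_covered", "high")}
    tier_pct = {t: 100.0 * c / n_catalog if n_catalog else None for t, c in tier_counts.items()}

    gc_map = {l.locus_id: l.gc for l in curated}
    median_map = dict(zip(cls_df["locus_id"], cls_df["median_spanning"]))
    quadrants = {"low_gc_covered": 0, "low_gc_uncovered": 0,
                 "high_gc_covered": 0, "high_gc_uncovered": 0}
    for lid in gc_map:
        gc_hi = gc_map[lid] is not None and gc_map[lid] >= config.gc_cut
        covered = median_map.get(lid, 0) >= config.well_threshold
        key = f"{'high' if gc_hi else 'low'}_gc_{'covered' if covered else 'uncovered'}"
        quadrants[key] += 1

    eff = covmod.efficiency(simreads.reads, curated)

    # repeat-count histogram and motif-length trend over mean supported counts
    rc_rows = []
    for (lid, _sid), c in covs.items():
        for rc, n in c.reliable_by_repeat_count.items():
            rc_rows.extend([rc] * n)
    rc_hist = pd.Series(rc_rows).value_counts().sort_index() if rc_rows else pd.Series(dtype=int)
    mlen_trend: Dict[int, float] = {}
    by_mlen: Dict[int, list] = {}
    for l in curated:
        med = median_of_supported_counts(covs, l.locus_id)
        if med is not None:
            by_mlen.setdefault(l.motif_length, []).append(med)
    mlen_trend = {m: float(np.mean(v)) for m, v in sorted(by_mlen.items())}
    trend_corr = None
    if len(mlen_trend) >= 3:
        from scipy.stats import spearmanr

        rho, _p = spearmanr(list(mlen_trend.keys()), list(mlen_trend.values()))
        trend_corr = float(rho)

    var_frac = float((cls_df["cross_sample_variance"] < config.variance_cut).mean()) if n_catalog else None

    report = {
        "catalog": {
            "denominator": n_catalog,
            "note": f"percentages use the curated catalog of {n_catalog} loci",
            "str_like_discarded": int(sum(1 for m in scores.values() if m.is_str_like)),
        },
        "thresholds": {
            "well_threshold": config.well_threshold,
            "high_threshold": config.high_threshold,
            "projection_cap": config.projection_cap,
            "gc_cut": config.gc_cut,
            "strlike_cutoff": config.strlike_cutoff,
            "min_support": config.min_support,
            "min_flank": config.min_flank,
            "min_match": config.min_match,
            "tss_flank": config.tss_flank,
            "variance_cut": config.variance_cut,
        },
        "coverage": {
            "tier_counts": tier_counts,
            "tier_percent": tier_pct,
            "quadrants": quadrants,
            "efficiency": eff,
            "fraction_low_projected_variance": var_frac,
        },
        "alleles": {
            "repeat_count_histogram": {int(k): int(v) for k, v in rc_hist.items()},
            "motif_length_mean_repeat_count": mlen_trend,
            "motif_length_repeat_count_spearman": trend_corr,
        },
        "consistency": {
            "pooled": consistency["pooled"],
            "per_sample": consistency["per_sample"],
            "partial_homozygous_side": consistency["partial_homozygous_side"],
        },
        "mendelian": mendelian,
        "perr_threshold": {
            "alpha": config.perr_alpha,
            "min_spanning_reads": thr.min_spanning_threshold(config.perr_alpha),
        },
    }
    return report


def median_of_supported_counts(covs, locus_id) -> Optional[float]:
    """Median repeat count among reliable reads at one locus, pooled over samples."""
    vals = []
    for (lid, _sid), c in covs.items():
        if lid != locus_id:
            continue
        for rc, n in c.reliable_by_repeat_count.items():
            vals.extend([rc] * n)
    return float(np.median(vals)) if vals else None
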