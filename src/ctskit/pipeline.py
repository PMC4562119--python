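"""End-to-end orchestration: occupancy partition -> invariance filter ->
top-N selection -> motif scan and arity classification -> signal profiles,
clustering and track aggregation -> annotation enrichment, with a
machine-readable run report.

All constants default to the analysis constants: motif p < 1e-4, +/-100 bp
summit windows, 10-kb heatmap windows, 300-bp footprint windows, 2-kb
promoter flanks, 4-kb TSS association, 5-kb promoter-binding flanks,
top 1000 regions per class, densities in tags per 10 million.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import classify as cls
from . import enrichment as enr
from . import profiles as prof
from .genomic_io import Genome, Peak, ScoreTrack, TagLibrary, write_peaks
from .motif import (
    DEFAULT_GRANULARITY,
    DEFAULT_P_THRESHOLD,
    PWM,
    scan,
    score_distribution,
)

log = logging.getLogger("ctskit.pipeline")


@dataclass
class PipelineParams:
    motif_p_threshold: float = DEFAULT_P_THRESHOLD
    summit_flank: int = 100
    heatmap_window: int = 5000  # half-width of the 10-kb window
    heatmap_bin: int = 100
    footprint_window: int = 150  # half-width of the 300-bp window
    footprint_bin: int = 5
    footprint_min_prominence: float = 0.3
    promoter_flank: int = 2000
    tss_association_flank: int = 4000
    de_promoter_flank: int = 5000
    top_n: int = 1000
    k: int = 2
    kmeans_seed: int = 0
    kmeans_normalization: str = "linear"
    fisher_sidedness: str = "greater"
    granularity: float = DEFAULT_GRANULARITY

    def __post_init__(self):
        positives = [
            self.motif_p_threshold,
            self.summit_flank,
            self.heatmap_window,
            self.heatmap_bin,
            self.footprint_window,
            self.footprint_bin,
            self.promoter_flank,
            self.tss_association_flank,
            self.de_promoter_flank,
            self.k,
            self.granularity,
        ]
        if any(x <= 0 for x in positives):
            raise ValueError("all pipeline constants must be positive")


@dataclass
class PipelineInputs:
    genome: Genome
    peaks_ctcf: list[Peak]
    peaks_boris: list[Peak]
    motif: PWM
    tags: dict[str, TagLibrary] = field(default_factory=dict)
    tracks: dict[str, ScoreTrack] = field(default_factory=dict)
    tss: enr.AnnotationSet | None = None
    changed_genes: set[str] | None = None
    extra_ctcf_peak_sets: list[list[Peak]] = field(default_factory=list)
    truth: object | None = None  # SimTruth, for recovery on synthetic runs


@dataclass
class RunReport:
    occupancy_counts: dict[str, int]
    class_sizes: dict[str, int]  # after invariance + top-N selection
    arity_percent: dict[str, float]  # % of class regions that are 2xCTS
    gap_histogram: dict[str, dict[str, int]]
    orientation_counts: dict[str, dict[str, int]]
    average_profiles: dict[str, list[float]] = field(default_factory=dict)
    cluster_sizes: dict[str, int] = field(default_factory=dict)
    footprint_dips: dict[str, int] = field(default_factory=dict)
    enrichment: dict[str, dict] = field(default_factory=dict)
    association: dict[str, dict[str, float]] = field(default_factory=dict)
    recovery: dict[str, float] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)
    fingerprint: dict[str, str] = field(default_factory=dict)

    def to_json(self) -> str:
        def default(o):
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            raise TypeError(type(o))

        return json.dumps(self.__dict__, indent=2, sort_keys=True, default=default)


class ConfigurationError(ValueError):
    pass


def _stage(name: str, t0: float, **sizes) -> float:
    dt = time.perf_counter() - t0
    info = " ".join(f"{k}={v}" for k, v in sizes.items())
    log.info("stage=%s wall=%.2fs %s", name, dt, info)
    return time.perf_counter()


def classify_regions(
    inputs: PipelineInputs, params: PipelineParams
) -> list[cls.ClassifiedRegion]:
    """Occupancy partition, invariance filter, top-N and arity per region."""
    part = cls.classify_occupancy(inputs.peaks_ctcf, inputs.peaks_boris)
    dist = score_distribution(inputs.motif, params.granularity)
    regions: list[cls.ClassifiedRegion] = []
    w = inputs.motif.width
    for occ in cls.OccupancyClass:
        peaks = part.peaks_in_class(occ)
        if inputs.extra_ctcf_peak_sets and occ is not cls.OccupancyClass.BORIS_ONLY:
            peaks = cls.invariant_regions(
                [peaks, *inputs.extra_ctcf_peak_sets]
            )
        known = [p for p in peaks if p.chrom in inputs.genome]
        if len(known) < len(peaks):
            log.warning(
                "dropped %d %s peaks on chromosomes absent from the genome",
                len(peaks) - len(known),
                occ.value,
            )
        peaks = known
        peaks = cls.rank_top(peaks, params.top_n)
        for p in peaks:
            lo = p.summit - params.summit_flank
            hi = p.summit + params.summit_flank + w
            seq = inputs.genome.fetch(p.chrom, lo, hi)
            hits = scan(
                seq,
                inputs.motif,
                params.motif_p_threshold,
                chrom=p.chrom,
                offset=lo,
                dist=dist,
            )
            regions.append(
                cls.classify_region(p, occ, hits, params.summit_flank)
            )
    return regions


def _class_regions(regions, occ):
    return [r for r in regions if r.occupancy is occ]


def run_pipeline(
    inputs: PipelineInputs,
    params: PipelineParams | None = None,
    out_dir: str | Path | None = None,
) -> RunReport:
    """Execute the full analysis; write tables when ``out_dir`` is given.

    Idempotent given identical inputs and seeds: the report carries no
    timestamps, and all randomness (k-means seeding) flows from params.
    """
    if params is None:
        params = PipelineParams()
    if inputs.genome is None or inputs.motif is None:
        raise ConfigurationError("genome and motif are mandatory inputs")
    if inputs.peaks_ctcf is None:
        raise ConfigurationError("CTCF peak set is mandatory")
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    t0 = time.perf_counter()
    part = cls.classify_occupancy(inputs.peaks_ctcf, inputs.peaks_boris)
    occupancy_counts = {c.value: n for c, n in part.counts().items()}
    t0 = _stage("occupancy", t0, **occupancy_counts)

    regions = classify_regions(inputs, params)
    t0 = _stage("arity", t0, regions=len(regions))

    class_sizes, arity_percent, gap_hist, orient_counts = {}, {}, {}, {}
    for occ in cls.OccupancyClass:
        rs = _class_regions(regions, occ)
        class_sizes[occ.value] = len(rs)
        two = sum(r.arity is cls.SiteArity.TWO_X for r in rs)
        arity_percent[occ.value] = 100.0 * two / len(rs) if rs else 0.0
        gaps = [r.geometry.gap for r in rs if r.geometry]
        hist: dict[str, int] = {}
        for g in gaps:
            key = f"{(g // 10) * 10}-{(g // 10) * 10 + 9}"
            hist[key] = hist.get(key, 0) + 1
        gap_hist[occ.value] = dict(sorted(hist.items(), key=lambda kv: int(kv[0].split("-")[0])))
        oc: dict[str, int] = {}
        for r in rs:
            if r.geometry:
                key = r.geometry.orientation.value
                oc[key] = oc.get(key, 0) + 1
        orient_counts[occ.value] = oc

    report = RunReport(
        occupancy_counts,
        class_sizes,
        arity_percent,
        gap_hist,
        orient_counts,
        fingerprint={
            "package": "ctskit",
            "params": json.dumps(vars(params), sort_keys=True),
        },
    )

    # signal profiles and heatmap clustering
    summits_by_class = {
        occ: [(r.peak.chrom, r.peak.summit) for r in _class_regions(regions, occ)]
        for occ in cls.OccupancyClass
    }
    for factor, lib in inputs.tags.items():
        for occ, anchors in summits_by_class.items():
            if not anchors:
                continue
            pm = prof.profile_matrix(
                lib, anchors, params.heatmap_window, params.heatmap_bin
            )
            report.average_profiles[f"{factor}:{occ.value}"] = list(
                np.round(prof.average_profile(pm), 6)
            )
        ctcf_side = (
            summits_by_class[cls.OccupancyClass.CTCF_ONLY]
            + summits_by_class[cls.OccupancyClass.CTCF_AND_BORIS]
        )
        if len(ctcf_side) >= params.k:
            pm = prof.profile_matrix(
                lib, ctcf_side, params.heatmap_window, params.heatmap_bin
            )
            res = prof.kmeans_rows(
                pm,
                params.k,
                seed=params.kmeans_seed,
                normalization=params.kmeans_normalization,
            )
            for j in range(params.k):
                report.cluster_sizes[f"{factor}:cluster{j}"] = int(
                    (res.labels == j).sum()
                )
            if out is not None:
                np.savetxt(
                    out / f"kmeans_labels_{factor}.tsv",
                    res.labels,
                    fmt="%d",
                )
    t0 = _stage("profiles", t0, factors=len(inputs.tags))

    # per-base track aggregation anchored at the leftmost accepted motif
    for track_name, track in inputs.tracks.items():
        for arity in cls.SiteArity:
            anchors = []
            for r in regions:
                if r.arity is arity and r.hits:
                    h = r.hits[0]
                    anchors.append((h.chrom, h.start + h.width // 2))
            if not anchors:
                continue
            vec = prof.aggregate_track(
                track, anchors, params.footprint_window, params.footprint_bin
            )
            key = f"{track_name}:{arity.value}"
            report.average_profiles[key] = list(np.round(vec, 6))
            report.footprint_dips[key] = prof.count_protection_dips(
                vec, params.footprint_min_prominence
            )
    t0 = _stage("tracks", t0, tracks=len(inputs.tracks))

    # annotation association and expression enrichment
    if inputs.tss is not None:
        report.association = {
            kind: {c.value: round(frac, 6) for c, frac in fracs.items()}
            for kind, fracs in enr.class_association(
                inputs.tss, regions, params.tss_association_flank
            ).items()
        }
        if inputs.changed_genes is not None and inputs.tss.gene_ids:
            universe = set(inputs.tss.gene_ids)
            changed = set(inputs.changed_genes) & universe
            for label, classes in {
                "CTCF_AND_BORIS": [cls.OccupancyClass.CTCF_AND_BORIS],
                "CTCF_ONLY": [cls.OccupancyClass.CTCF_ONLY],
                "BORIS_ONLY": [cls.OccupancyClass.BORIS_ONLY],
                "ANY": list(cls.OccupancyClass),
            }.items():
                bound = enr.bound_gene_set(
                    regions,
                    inputs.tss,
                    params.de_promoter_flank,
                    classes,
                )
                table = enr.ContingencyTable.from_sets(
                    bound, changed, universe
                )
                res = enr.fisher_enrichment(table, params.fisher_sidedness)
                report.enrichment[label] = {
                    "a": table.a,
                    "b": table.b,
                    "c": table.c,
                    "d": table.d,
                    "odds_ratio": round(res.odds_ratio, 4)
                    if np.isfinite(res.odds_ratio)
                    else str(res.odds_ratio),
                    "pvalue": float(f"{res.pvalue:.4g}"),
                    "sidedness": res.sidedness,
                }
    t0 = _stage("enrichment", t0)

    # recovery against planted truth (synthetic runs)
    if inputs.truth is not None:
        report.recovery = recovery_metrics(inputs.truth, regions)

    if out is not None:
        table = cls.classification_table(regions)
        table.to_csv(out / "classification.tsv", sep="\t", index=False)
        report.outputs["classification"] = "classification.tsv"
        for occ in cls.OccupancyClass:
            path = out / f"peaks_{occ.value}.bed"
            write_peaks(path, [r.peak for r in _class_regions(regions, occ)])
            report.outputs[occ.value] = path.name
        (out / "report.json").write_text(report.to_json())
        report.outputs["report"] = "report.json"
    return report


def recovery_metrics(truth, regions: Sequence[cls.ClassifiedRegion]) -> dict:
    """Fraction of planted paired sites classified 2xCTS and planted single
    sites classified 1xCTS, matching sites to regions by summit position."""
    by_summit: dict[tuple[str, int], cls.ClassifiedRegion] = {}
    for r in regions:
        if r.occupancy is cls.OccupancyClass.BORIS_ONLY:
            continue
        by_summit[(r.peak.chrom, r.peak.summit)] = r
    n_paired = n_paired_2x = n_single = n_single_1x = 0
    for row in truth.table.itertuples():
        r = by_summit.get((row.chrom, row.center))
        if r is None:
            continue
        if row.arity == "paired":
            n_paired += 1
            n_paired_2x += r.arity is cls.SiteArity.TWO_X
        else:
            n_single += 1
            n_single_1x += r.arity is cls.SiteArity.ONE_X
    return {
        "paired_sites_matched": n_paired,
        "single_sites_matched": n_single,
        "paired_classified_2x_fraction": (
            n_paired_2x / n_paired if n_paired else float("nan")
        ),
        "single_classified_1x_fraction": (
            n_single_1x / n_single if n_single else float("nan")
        ),
    }
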