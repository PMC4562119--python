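"""Active-region construction, binding/annotation association and
Fisher's-exact enrichment statistics, plus a priority-based genomic
distribution of peak summits (promoter > exon > intron > intergenic).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .classify import ClassifiedRegion, OccupancyClass
from .genomic_io import GenomicInterval, Peak


@dataclass
class AnnotationSet:
    """Named intervals, optionally carrying gene identifiers.

    ``anchor`` says whether consumers should treat each record as a point
    (its TSS; the interval start for +/unstranded, end-1 for -) or as the
    full interval.
    """

    name: str
    intervals: list[GenomicInterval]
    gene_ids: list[str] | None = None
    anchor: str = "point"  # "point" (TSS) or "interval"

    def __post_init__(self):
        if self.gene_ids is not None:
            if len(self.gene_ids) != len(self.intervals):
                raise ValueError("one gene id per interval required")
            if len(set(self.gene_ids)) != len(self.gene_ids):
                raise ValueError("gene identifiers must be unique in a set")

    def __len__(self) -> int:
        return len(self.intervals)

    def anchor_points(self) -> list[tuple[str, int]]:
        pts = []
        for iv in self.intervals:
            pos = iv.end - 1 if iv.strand == "-" else iv.start
            pts.append((iv.chrom, pos))
        return pts


def read_tss_bed(source) -> AnnotationSet:
    """BED6 TSS records; column 4 carries the gene identifier."""
    from .genomic_io import parse_intervals

    peaks = parse_intervals(source, "bed6")
    ids = [p.name for p in peaks]
    if len(set(ids)) != len(ids) or "." in ids:
        ids = [f"{p.name}_{i}" if p.name == "." else p.name for i, p in enumerate(peaks)]
    return AnnotationSet(
        "tss", [p.interval for p in peaks], gene_ids=ids, anchor="point"
    )


# ---------------------------------------------------------------------------
# interval helpers


def _merged_arrays(intervals: Iterable[tuple[str, int, int]]):
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in intervals:
        by_chrom.setdefault(chrom, []).append((s, e))
    merged = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        ms, me = [], []
        for s, e in ivs:
            if ms and s <= me[-1]:
                me[-1] = max(me[-1], e)
            else:
                ms.append(s)
                me.append(e)
        merged[chrom] = (np.array(ms), np.array(me))
    return merged


def _overlaps(merged, chrom: str, start: int, end: int) -> bool:
    if chrom not in merged:
        return False
    ms, me = merged[chrom]
    j = int(np.searchsorted(ms, end, side="left")) - 1
    return j >= 0 and me[j] > start


def _peak_triples(peaks: Sequence[Peak]):
    return [(p.chrom, p.start, p.end) for p in peaks]


# ---------------------------------------------------------------------------
# operations


def active_regions(
    tss: AnnotationSet,
    mark1_peaks: Sequence[Peak],
    mark2_peaks: Sequence[Peak],
    flank: int = 2000,
) -> AnnotationSet:
    """TSSs whose +/- flank window overlaps a peak from *both* mark sets.

    Mirrors the construction of active promoters from TSSs extended 2 kb
    up/downstream intersected with two activity marks (e.g. H3K4me3 and
    RNAPII); regions positive for both marks are kept.
    """
    m1 = _merged_arrays(_peak_triples(mark1_peaks))
    m2 = _merged_arrays(_peak_triples(mark2_peaks))
    keep_iv, keep_id = [], []
    for i, (chrom, pos) in enumerate(tss.anchor_points()):
        lo, hi = max(0, pos - flank), pos + flank + 1
        if _overlaps(m1, chrom, lo, hi) and _overlaps(m2, chrom, lo, hi):
            keep_iv.append(tss.intervals[i])
            if tss.gene_ids is not None:
                keep_id.append(tss.gene_ids[i])
    return AnnotationSet(
        f"active_{tss.name}",
        keep_iv,
        gene_ids=keep_id if tss.gene_ids is not None else None,
        anchor="point",
    )


def active_enhancers(
    mark1_peaks: Sequence[Peak], mark2_peaks: Sequence[Peak]
) -> AnnotationSet:
    """Direct intersection of two mark peak sets (no TSS anchoring)."""
    m2 = _merged_arrays(_peak_triples(mark2_peaks))
    ivs = [
        p.interval
        for p in mark1_peaks
        if _overlaps(m2, p.chrom, p.start, p.end)
    ]
    return AnnotationSet("active_enhancers", ivs, anchor="interval")


def _distance_to_peak(pos: int, start: int, end: int) -> int:
    """0 inside the (half-open) peak, else bp to the nearest edge."""
    if start <= pos < end:
        return 0
    return start - pos if pos < start else pos - (end - 1)


def _min_distance(merged, chrom: str, pos: int) -> float:
    if chrom not in merged:
        return math.inf
    ms, me = merged[chrom]
    j = int(np.searchsorted(ms, pos, side="right"))
    best = math.inf
    if j > 0:
        best = min(best, _distance_to_peak(pos, int(ms[j - 1]), int(me[j - 1])))
    if j < len(ms):
        best = min(best, _distance_to_peak(pos, int(ms[j]), int(me[j])))
    return best


def class_association(
    annotations: AnnotationSet,
    classified: Sequence[ClassifiedRegion],
    flank: int = 4000,
) -> dict[str, dict[OccupancyClass, float]]:
    """Fraction of annotation anchors with a peak of each class within
    <= flank bp (inclusive; distance 0 inside a peak).

    Returns {"raw": per-class fraction counting anchors toward every
    qualifying class, "exclusive": per-class fraction counting each anchor
    only for its single nearest class}.
    """
    anchors = annotations.anchor_points()
    n = len(anchors)
    raw = {c: 0 for c in OccupancyClass}
    exclusive = {c: 0 for c in OccupancyClass}
    merged_by_class = {
        c: _merged_arrays(
            _peak_triples(
                [r.peak for r in classified if r.occupancy is c]
            )
        )
        for c in OccupancyClass
    }
    for chrom, pos in anchors:
        dists = {
            c: _min_distance(merged_by_class[c], chrom, pos)
            for c in OccupancyClass
        }
        qualifying = [c for c, d in dists.items() if d <= flank]
        for c in qualifying:
            raw[c] += 1
        if qualifying:
            nearest = min(qualifying, key=lambda c: dists[c])
            exclusive[nearest] += 1
    denom = max(n, 1)
    return {
        "raw": {c: raw[c] / denom for c in OccupancyClass},
        "exclusive": {c: exclusive[c] / denom for c in OccupancyClass},
    }


def bound_gene_set(
    classified: Sequence[ClassifiedRegion],
    tss: AnnotationSet,
    flank: int = 5000,
    classes: Iterable[OccupancyClass] = tuple(OccupancyClass),
) -> set[str]:
    """Genes whose TSS lies within <= flank bp of a peak of any requested
    class (promoter-binding definition, +/- 5 kb from the TSS)."""
    if tss.gene_ids is None:
        raise ValueError("TSS annotation set must carry gene identifiers")
    classes = set(classes)
    merged = _merged_arrays(
        _peak_triples([r.peak for r in classified if r.occupancy in classes])
    )
    bound = set()
    for gene, (chrom, pos) in zip(tss.gene_ids, tss.anchor_points()):
        if _min_distance(merged, chrom, pos) <= flank:
            bound.add(gene)
    return bound


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 table: a=bound&changed, b=bound&unchanged, c=unbound&changed,
    d=unbound&unchanged."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be nonnegative")
        if self.total == 0:
            raise ValueError("empty table")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    @classmethod
    def from_sets(
        cls, bound: set[str], changed: set[str], universe: set[str]
    ) -> "ContingencyTable":
        bound &= universe
        changed &= universe
        a = len(bound & changed)
        b = len(bound - changed)
        c = len(changed - bound)
        d = len(universe - bound - changed)
        return cls(a, b, c, d)


@dataclass
class EnrichmentResult:
    odds_ratio: float  # inf when b*c == 0 and a*d > 0; nan for 0/0
    pvalue: float
    sidedness: str
    table: ContingencyTable
    fractions: dict[str, float] = field(default_factory=dict)


def fisher_enrichment(
    table: ContingencyTable, sidedness: str = "greater"
) -> EnrichmentResult:
    """Sample odds ratio (ad/bc) and exact hypergeometric p-value.

    ``sidedness`` is "greater" (enrichment) or "two_sided". A 0/0 odds
    ratio is reported as nan with the p-value still computed.
    """
    if sidedness not in ("greater", "two_sided"):
        raise ValueError("sidedness must be 'greater' or 'two_sided'")
    a, b, c, d = table.a, table.b, table.c, table.d
    ad, bc = a * d, b * c
    if bc == 0:
        odds = math.nan if ad == 0 else math.inf
    else:
        odds = ad / bc
    alternative = "greater" if sidedness == "greater" else "two-sided"
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative=alternative)
    frac = {
        "changed_given_bound": a / (a + b) if a + b else math.nan,
        "changed_given_unbound": c / (c + d) if c + d else math.nan,
    }
    return EnrichmentResult(float(odds), float(p), sidedness, table, frac)


def odds_ratio_confint(
    table: ContingencyTable, alpha: float = 0.05
) -> tuple[float, float]:
    """Exact (conditional, Fisher) confidence interval for the odds ratio.

    Inverts the tails of Fisher's noncentral hypergeometric distribution of
    cell a given the margins.
    """
    from scipy.optimize import brentq

    a, b, c, d = table.a, table.b, table.c, table.d
    n = table.total
    r1, c1 = a + b, a + c
    a_min = max(0, r1 + c1 - n)
    a_max = min(r1, c1)

    def sf_geq(psi: float) -> float:  # P(X >= a | psi)
        dist = stats.nchypergeom_fisher(n, c1, r1, psi)
        return float(dist.sf(a - 1))

    def cdf_leq(psi: float) -> float:  # P(X <= a | psi)
        dist = stats.nchypergeom_fisher(n, c1, r1, psi)
        return float(dist.cdf(a))

    half = alpha / 2.0
    if a == a_min:
        lo = 0.0
    else:
        lo = brentq(lambda x: sf_geq(math.exp(x)) - half, -50, 50)
        lo = math.exp(lo)
    if a == a_max:
        hi = math.inf
    else:
        hi = brentq(lambda x: cdf_leq(math.exp(x)) - half, -50, 50)
        hi = math.exp(hi)
    return lo, hi


# ---------------------------------------------------------------------------
# genomic distribution


@dataclass(frozen=True)
class Transcript:
    name: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: tuple[tuple[int, int], ...]

    @property
    def tss(self) -> int:
        return self.end - 1 if self.strand == "-" else self.start


@dataclass
class GeneModel:
    transcripts: list[Transcript]


CATEGORIES = ("promoter", "exon", "intron", "intergenic")


def genomic_distribution(
    peaks: Sequence[Peak],
    gene_model: GeneModel,
    promoter_flank: int = 2000,
) -> dict[str, float]:
    """Fraction of peak summits per genomic category.

    Each summit gets exactly one category by the fixed priority
    promoter (TSS +/- promoter_flank) > exon > intron > intergenic, so the
    fractions sum to 1 over any non-empty peak set.
    """
    promoters = _merged_arrays(
        (
            t.chrom,
            max(0, t.tss - promoter_flank),
            t.tss + promoter_flank + 1,
        )
        for t in gene_model.transcripts
    )
    exons = _merged_arrays(
        (t.chrom, s, e) for t in gene_model.transcripts for s, e in t.exons
    )
    spans = _merged_arrays(
        (t.chrom, t.start, t.end) for t in gene_model.transcripts
    )
    counts = dict.fromkeys(CATEGORIES, 0)
    for p in peaks:
        s = p.summit
        if _overlaps(promoters, p.chrom, s, s + 1):
            counts["promoter"] += 1
        elif _overlaps(exons, p.chrom, s, s + 1):
            counts["exon"] += 1
        elif _overlaps(spans, p.chrom, s, s + 1):
            counts["intron"] += 1
        else:
            counts["intergenic"] += 1
    n = max(len(peaks), 1)
    return {k: v / n for k, v in counts.items()}
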