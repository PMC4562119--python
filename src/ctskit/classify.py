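"""Occupancy-class partition and motif-arity (1xCTS vs 2xCTS) classification.

Two peak sets (factor A = CTCF, factor B = BORIS) are partitioned by the
reciprocal >= 1 bp overlap rule into CTCF-only, CTCF&BORIS and BORIS-only
classes. Each selected region is then classified by the number of accepted,
non-overlapping CTCF-motif hits within +/- flank of its summit: regions
with two or more are clustered sites (2xCTS), the rest single sites (1xCTS).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np

from .genomic_io import Peak
from .motif import MotifHit


class OccupancyClass(Enum):
    CTCF_ONLY = "CTCF_ONLY"
    CTCF_AND_BORIS = "CTCF_AND_BORIS"
    BORIS_ONLY = "BORIS_ONLY"


class SiteArity(Enum):
    ONE_X = "1xCTS"
    TWO_X = "2xCTS"


class Orientation(Enum):
    TANDEM_PLUS = "tandem_plus"
    TANDEM_MINUS = "tandem_minus"
    CONVERGENT = "convergent"
    DIVERGENT = "divergent"


@dataclass(frozen=True)
class PairGeometry:
    """Spacing and strand configuration of the closest accepted motif pair."""

    gap: int  # bp between end of left motif and start of right motif
    orientation: Orientation

    def __post_init__(self):
        if self.gap < 0:
            raise ValueError("gap must be >= 0 for non-overlapping pairs")


@dataclass
class ClassifiedRegion:
    peak: Peak
    occupancy: OccupancyClass
    arity: SiteArity
    hits: list[MotifHit]
    geometry: PairGeometry | None = None

    def __post_init__(self):
        if (self.arity is SiteArity.TWO_X) != (self.geometry is not None):
            raise ValueError("geometry present iff arity is 2xCTS")

    @property
    def n_motifs(self) -> int:
        return len(self.hits)


# ---------------------------------------------------------------------------
# occupancy


def _overlap_any(peaks: Sequence[Peak], others: Sequence[Peak]) -> np.ndarray:
    """Boolean vector: does peak i overlap (>=1 bp) any peak in ``others``."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for p in others:
        by_chrom.setdefault(p.chrom, []).append((p.start, p.end))
    merged: dict[str, tuple[np.ndarray, np.ndarray]] = {}
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
    out = np.zeros(len(peaks), dtype=bool)
    for i, p in enumerate(peaks):
        if p.chrom not in merged:
            continue
        ms, me = merged[p.chrom]
        j = int(np.searchsorted(ms, p.end, side="left")) - 1
        out[i] = j >= 0 and me[j] > p.start
    return out


@dataclass
class OccupancyPartition:
    """Per-peak classes for both input sets plus class membership lists."""

    a_classes: list[OccupancyClass]
    b_classes: list[OccupancyClass]
    peaks_a: list[Peak]
    peaks_b: list[Peak]

    def peaks_in_class(self, cls: OccupancyClass) -> list[Peak]:
        if cls is OccupancyClass.BORIS_ONLY:
            return [
                p for p, c in zip(self.peaks_b, self.b_classes) if c is cls
            ]
        return [p for p, c in zip(self.peaks_a, self.a_classes) if c is cls]

    def counts(self) -> dict[OccupancyClass, int]:
        return {
            OccupancyClass.CTCF_ONLY: self.a_classes.count(
                OccupancyClass.CTCF_ONLY
            ),
            OccupancyClass.CTCF_AND_BORIS: self.a_classes.count(
                OccupancyClass.CTCF_AND_BORIS
            ),
            OccupancyClass.BORIS_ONLY: self.b_classes.count(
                OccupancyClass.BORIS_ONLY
            ),
        }


def classify_occupancy(
    peaks_a: Sequence[Peak], peaks_b: Sequence[Peak]
) -> OccupancyPartition:
    """Partition peaks by the reciprocal >= 1 bp overlap rule.

    A-peaks overlapping any B-peak are CTCF&BORIS; the remaining A-peaks
    are CTCF-only and the non-overlapping B-peaks BORIS-only.
    """
    peaks_a = list(peaks_a)
    peaks_b = list(peaks_b)
    a_hit = _overlap_any(peaks_a, peaks_b)
    b_hit = _overlap_any(peaks_b, peaks_a)
    a_classes = [
        OccupancyClass.CTCF_AND_BORIS if h else OccupancyClass.CTCF_ONLY
        for h in a_hit
    ]
    b_classes = [
        OccupancyClass.CTCF_AND_BORIS if h else OccupancyClass.BORIS_ONLY
        for h in b_hit
    ]
    return OccupancyPartition(a_classes, b_classes, peaks_a, peaks_b)


def invariant_regions(peak_sets: Sequence[Sequence[Peak]]) -> list[Peak]:
    """Peaks of the first set that overlap a peak in every other set.

    First-set coordinates, summits and scores are retained (cross-sample
    invariance acts as a filter, mirroring per-cell-line region lists kept
    only when occupied in all lines).
    """
    if len(peak_sets) == 0:
        raise ValueError("need at least one peak set")
    anchor = list(peak_sets[0])
    keep = np.ones(len(anchor), dtype=bool)
    for other in peak_sets[1:]:
        keep &= _overlap_any(anchor, list(other))
    return [p for p, k in zip(anchor, keep) if k]


def rank_top(regions: Sequence, n: int):
    """Top-n by peak score, ties broken by (chrom, start) ascending.

    Works on Peaks or ClassifiedRegions (anything with .peak or acting as a
    peak itself).
    """
    if n < 0:
        raise ValueError("n must be >= 0")

    def peak_of(r):
        return r.peak if hasattr(r, "peak") else r

    ordered = sorted(
        regions,
        key=lambda r: (-peak_of(r).score, peak_of(r).chrom, peak_of(r).start),
    )
    return ordered[:n]


# ---------------------------------------------------------------------------
# arity


def collapse_hits(hits: Iterable[MotifHit]) -> list[MotifHit]:
    """Greedily keep lowest-p hits whose spans do not overlap (>= 1 bp).

    A palindromic site matched on both strands at the same start therefore
    contributes a single accepted occurrence.
    """
    ordered = sorted(hits, key=lambda h: (h.pvalue, -h.score, h.start, h.strand))
    accepted: list[MotifHit] = []
    for h in ordered:
        if all(h.end <= a.start or a.end <= h.start for a in accepted):
            accepted.append(h)
    accepted.sort(key=lambda h: h.start)
    return accepted


def site_arity(
    peak: Peak, hits: Sequence[MotifHit], flank: int = 100
) -> tuple[SiteArity, list[MotifHit]]:
    """Classify a region as 1xCTS or 2xCTS from its summit-window motifs.

    Hits whose start lies in [summit - flank, summit + flank] are collapsed
    to non-overlapping occurrences; >= 2 survivors make the region 2xCTS.
    Returns the arity and the accepted hits sorted by start.
    """
    windowed = [
        h
        for h in hits
        if h.chrom == peak.chrom
        and peak.summit - flank <= h.start <= peak.summit + flank
    ]
    accepted = collapse_hits(windowed)
    arity = SiteArity.TWO_X if len(accepted) >= 2 else SiteArity.ONE_X
    return arity, accepted


_ORIENT = {
    ("+", "+"): Orientation.TANDEM_PLUS,
    ("-", "-"): Orientation.TANDEM_MINUS,
    ("+", "-"): Orientation.CONVERGENT,
    ("-", "+"): Orientation.DIVERGENT,
}


def pair_geometry(left: MotifHit, right: MotifHit) -> PairGeometry:
    """Gap and orientation of an ordered, non-overlapping motif pair."""
    if left.start > right.start:
        raise ValueError("left hit must start at or before right hit")
    if right.start < left.end:
        raise ValueError("overlapping spans: geometry undefined")
    gap = right.start - left.end
    return PairGeometry(gap, _ORIENT[(left.strand, right.strand)])


def classify_region(
    peak: Peak,
    occupancy: OccupancyClass,
    hits: Sequence[MotifHit],
    flank: int = 100,
) -> ClassifiedRegion:
    """Full per-region classification: arity plus closest-pair geometry."""
    arity, accepted = site_arity(peak, hits, flank)
    geometry = None
    if arity is SiteArity.TWO_X:
        gaps = [
            (accepted[i + 1].start - accepted[i].end, i)
            for i in range(len(accepted) - 1)
        ]
        _, i = min(gaps)
        geometry = pair_geometry(accepted[i], accepted[i + 1])
    return ClassifiedRegion(peak, occupancy, arity, accepted, geometry)


def classification_table(regions: Sequence[ClassifiedRegion]):
    """Tabular (pandas) view of classified regions for TSV export."""
    import pandas as pd

    rows = []
    for r in regions:
        rows.append(
            {
                "name": r.peak.name,
                "chrom": r.peak.chrom,
                "start": r.peak.start,
                "end": r.peak.end,
                "summit": r.peak.summit,
                "score": r.peak.score,
                "occupancy": r.occupancy.value,
                "arity": r.arity.value,
                "n_motifs": r.n_motifs,
                "gap": r.geometry.gap if r.geometry else -1,
                "orientation": (
                    r.geometry.orientation.value if r.geometry else "."
                ),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "name",
            "chrom",
            "start",
            "end",
            "summit",
            "score",
            "occupancy",
            "arity",
            "n_motifs",
            "gap",
            "orientation",
        ],
    )
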