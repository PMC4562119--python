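"""Synthetic genomes, ChIP tag libraries, cleavage tracks and annotations
with a machine-readable planted-truth ledger.

The generator instantiates the two-class site architecture the analysis is
built to recover: single 20-bp motif instances (1xCTS, bound by CTCF
alone) and clustered pairs of instances separated by a 30-60 bp linker in
mixed orientations (2xCTS, co-bound by CTCF and BORIS with boosted
amplitude). Every source of randomness flows from the config seed.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
import numpy as np
import pandas as pd

from .classify import Orientation
from .enrichment import AnnotationSet
from .genomic_io import (
    Genome,
    GenomicInterval,
    Peak,
    ScoreTrack,
    TagLibrary,
    reverse_complement,
)
from .motif import PWM, build_pwm

BASES = "ACGT"

# Synthetic 20-bp CTCF-like count matrix (counts per 100 sites): a
# high-information consensus with a few softer flanking columns. This is a
# constructed stand-in with the information content (~1.1 bits/column)
# typical of the CTCF core motif, not a matrix derived from real ChIP data.
_SYNTHETIC_CTCF_CONSENSUS = "TGGCCACCAGGGGGCGCTAC"
_SOFT_COLUMNS = (0, 1, 9, 18, 19)  # lower-information positions


def default_ctcf_pwm(pseudocount: float = 0.1) -> PWM:
    counts = np.full((4, 20), 4.0)
    for j, base in enumerate(_SYNTHETIC_CTCF_CONSENSUS):
        b = BASES.index(base)
        if j in _SOFT_COLUMNS:
            counts[:, j] = 10.0
            counts[b, j] = 70.0
        else:
            counts[b, j] = 88.0
    return build_pwm(counts, pseudocount=pseudocount)


_ORIENT_STRANDS = {
    Orientation.TANDEM_PLUS: ("+", "+"),
    Orientation.TANDEM_MINUS: ("-", "-"),
    Orientation.CONVERGENT: ("+", "-"),
    Orientation.DIVERGENT: ("-", "+"),
}
_ORIENT_ORDER = (
    Orientation.TANDEM_PLUS,
    Orientation.TANDEM_MINUS,
    Orientation.CONVERGENT,
    Orientation.DIVERGENT,
)


@dataclass
class SimConfig:
    """Study conditions for the synthetic benchmark.

    Defaults follow the simulated experiment the acceptance checks run:
    a 10-Mb chromosome carrying 500 single and 500 paired sites with
    30-60 bp linkers in mixed orientations, one million tags per factor
    with 10-fold site enrichment and a 2x amplitude boost at co-bound
    sites.
    """

    genome_length: int = 10_000_000
    n_single_sites: int = 500
    n_paired_sites: int = 500
    gap_range: tuple[int, int] = (30, 60)
    orientation_mix: tuple[float, float, float, float] = (
        0.25,
        0.25,
        0.25,
        0.25,
    )
    motif: PWM = field(default_factory=default_ctcf_pwm)
    boris_bound_fraction_of_paired: float = 1.0
    tag_depth: int = 1_000_000
    enrichment_fold: float = 10.0
    cobound_amplitude_boost: float = 2.0
    fragment_sd: float = 50.0
    seed: int = 0
    chrom: str = "chrS"
    gc_content: float = 0.5
    consensus_only: bool = False
    peak_half_width: int = 200
    # cleavage track
    cleavage_baseline: float = 1.0
    cleavage_dip_depth: float = 0.6
    cleavage_noise_sd: float = 0.05
    cleavage_noise_halfwidth: int = 500
    # annotations
    n_genes: int = 2000
    p_tss_paired: float = 0.9
    p_tss_single: float = 0.1
    tss_offset_max: int = 800
    planted_odds_ratio: float = 4.0
    baseline_change_rate: float = 0.2
    promoter_bind_flank: int = 5000

    def __post_init__(self):
        if self.gap_range[0] < 0 or self.gap_range[0] > self.gap_range[1]:
            raise ValueError("invalid gap_range")
        if not np.isclose(sum(self.orientation_mix), 1.0):
            raise ValueError("orientation_mix must sum to 1")
        if min(self.n_single_sites, self.n_paired_sites) < 0:
            raise ValueError("site counts must be >= 0")

    @property
    def n_sites(self) -> int:
        return self.n_single_sites + self.n_paired_sites


class PlacementError(ValueError):
    pass


class SimTruth:
    """Planted-site ledger backed by a DataFrame.

    Columns: site_id, chrom, center, arity (single|paired), left_start,
    right_start, gap, orientation, bound_by, boost. For single sites
    right_start and gap are -1 and orientation is '.'.
    """

    COLUMNS = [
        "site_id",
        "chrom",
        "center",
        "arity",
        "left_start",
        "right_start",
        "gap",
        "orientation",
        "bound_by",
        "boost",
    ]

    def __init__(self, table: pd.DataFrame, seed: int, motif_width: int):
        self.table = table.reset_index(drop=True)
        self.seed = seed
        self.motif_width = motif_width

    def __len__(self) -> int:
        return len(self.table)

    def sites(self, arity: str | None = None) -> pd.DataFrame:
        if arity is None:
            return self.table
        return self.table[self.table.arity == arity]

    def to_tsv(self, dest) -> None:
        close = False
        if not hasattr(dest, "write"):
            dest = open(dest, "w")
            close = True
        try:
            dest.write(f"# seed={self.seed} motif_width={self.motif_width}\n")
            self.table.to_csv(dest, sep="\t", index=False)
        finally:
            if close:
                dest.close()

    @classmethod
    def from_tsv(cls, source) -> "SimTruth":
        if hasattr(source, "read"):
            text = source.read()
        else:
            with open(source) as fh:
                text = fh.read()
        header, _, rest = text.partition("\n")
        meta = dict(
            kv.split("=") for kv in header.lstrip("# ").split() if "=" in kv
        )
        table = pd.read_csv(io.StringIO(rest), sep="\t")
        return cls(table, int(meta["seed"]), int(meta["motif_width"]))


def _site_layout(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Assign non-overlapping site positions on a regular slot grid.

    One site per slot with a jittered in-slot position guarantees
    non-overlap and a minimum spacing of half a slot between site centers.
    """
    n = config.n_sites
    if n == 0:
        return pd.DataFrame(columns=SimTruth.COLUMNS)
    slot = config.genome_length // n
    w = config.motif.width
    max_span = 2 * w + config.gap_range[1]
    if slot < max(4 * config.peak_half_width, 2 * max_span + 200):
        raise PlacementError(
            "genome too short to place sites without overlap; "
            "increase genome_length or reduce site counts"
        )
    jitter_max = slot // 4
    arity = np.array(
        ["single"] * config.n_single_sites + ["paired"] * config.n_paired_sites
    )
    rng.shuffle(arity)
    rows = []
    for i in range(n):
        center = i * slot + slot // 2 + int(
            rng.integers(-jitter_max, jitter_max + 1)
        )
        if arity[i] == "single":
            left = center - w // 2
            rows.append(
                dict(
                    site_id=f"site{i:05d}",
                    chrom=config.chrom,
                    center=center,
                    arity="single",
                    left_start=left,
                    right_start=-1,
                    gap=-1,
                    orientation=".",
                    bound_by="CTCF",
                    boost=1.0,
                )
            )
        else:
            gap = int(
                rng.integers(config.gap_range[0], config.gap_range[1] + 1)
            )
            orient = _ORIENT_ORDER[
                rng.choice(4, p=np.asarray(config.orientation_mix))
            ]
            span = 2 * w + gap
            left = center - span // 2
            right = left + w + gap
            cobound = (
                rng.random() < config.boris_bound_fraction_of_paired
            )
            rows.append(
                dict(
                    site_id=f"site{i:05d}",
                    chrom=config.chrom,
                    center=center,
                    arity="paired",
                    left_start=left,
                    right_start=right,
                    gap=gap,
                    orientation=orient.value,
                    bound_by="CTCF+BORIS" if cobound else "CTCF",
                    boost=config.cobound_amplitude_boost if cobound else 1.0,
                )
            )
    return pd.DataFrame(rows, columns=SimTruth.COLUMNS)


def _sample_instance(pwm: PWM, rng, consensus_only: bool) -> str:
    if consensus_only:
        return pwm.consensus
    cols = [rng.choice(4, p=pwm.probs[:, j]) for j in range(pwm.width)]
    return "".join(BASES[b] for b in cols)


def simulate_genome(config: SimConfig) -> tuple[Genome, SimTruth]:
    """I.i.d. background sequence with motif instances planted per layout."""
    rng = np.random.default_rng([config.seed, 0])
    gc = config.gc_content
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    codes = rng.choice(4, size=config.genome_length, p=probs).astype(np.int8)
    layout = _site_layout(config, rng)
    w = config.motif.width

    def plant(start: int, strand: str) -> None:
        word = _sample_instance(config.motif, rng, config.consensus_only)
        if strand == "-":
            word = reverse_complement(word)
        codes[start : start + w] = [BASES.index(b) for b in word]

    for row in layout.itertuples():
        if row.arity == "single":
            plant(row.left_start, "+" if rng.random() < 0.5 else "-")
        else:
            s_left, s_right = _ORIENT_STRANDS[Orientation(row.orientation)]
            plant(row.left_start, s_left)
            plant(row.right_start, s_right)
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    seq = lut[codes].tobytes().decode("ascii")
    genome = Genome({config.chrom: seq})
    return genome, SimTruth(layout, config.seed, w)


def _amplitudes(truth: SimTruth, factor: str, config: SimConfig):
    """Per-bound-site expected tag counts and the background total.

    Site amplitude = enrichment_fold x background density x peak footprint
    x boost; the background total is solved so the overall expectation
    equals tag_depth.
    """
    tab = truth.table
    if factor == "CTCF":
        bound = np.ones(len(tab), dtype=bool)
    elif factor == "BORIS":
        bound = tab.bound_by.str.contains("BORIS").to_numpy()
    else:
        raise ValueError("factor must be 'CTCF' or 'BORIS'")
    boosts = tab.boost.to_numpy(dtype=float) * bound
    footprint = 2 * config.peak_half_width
    coef = config.enrichment_fold * footprint / config.genome_length
    background_total = config.tag_depth / (1.0 + coef * boosts.sum())
    amps = config.enrichment_fold * (
        background_total / config.genome_length
    ) * footprint * boosts
    return amps, background_total, bound


def simulate_chip(
    truth: SimTruth, factor: str, config: SimConfig
) -> TagLibrary:
    """Background-uniform plus site-centred Gaussian tag pileups.

    CTCF occupies every planted site; BORIS only the co-bound paired
    sites, which also carry the amplitude boost.
    """
    offset = {"CTCF": 1, "BORIS": 2}[factor]
    rng = np.random.default_rng([config.seed, offset])
    amps, background_total, bound = _amplitudes(truth, factor, config)
    n_bg = rng.poisson(background_total)
    positions = [rng.integers(0, config.genome_length, size=n_bg)]
    centers = truth.table.center.to_numpy()
    n_site = rng.poisson(amps)
    for c, n in zip(centers, n_site):
        if n == 0:
            continue
        pos = np.rint(c + rng.normal(0, config.fragment_sd, size=n))
        positions.append(
            np.clip(pos, 0, config.genome_length - 1).astype(np.int64)
        )
    return TagLibrary({config.chrom: np.concatenate(positions)})


def truth_peaks(
    truth: SimTruth, factor: str, config: SimConfig
) -> list[Peak]:
    """Peak records derived directly from the truth ledger.

    Peak calling is outside this package's scope, so the simulator emits
    the peaks a caller would recover: one peak of +/- peak_half_width
    around each bound site center, scored by expected enrichment.
    """
    _, _, bound = _amplitudes(truth, factor, config)
    peaks = []
    for row, is_bound in zip(truth.table.itertuples(), bound):
        if not is_bound:
            continue
        start = max(0, row.center - config.peak_half_width)
        end = min(config.genome_length, row.center + config.peak_half_width)
        peaks.append(
            Peak(
                GenomicInterval(row.chrom, start, end),
                summit=row.center,
                score=config.enrichment_fold * row.boost,
                name=f"{factor}_{row.site_id}",
            )
        )
    return peaks


def simulate_cleavage(truth: SimTruth, config: SimConfig) -> ScoreTrack:
    """Accessibility baseline with 20-bp protection dips at planted motifs.

    Per-base Gaussian noise is added within +/- cleavage_noise_halfwidth of
    each site; the track is constant baseline elsewhere (footprint
    aggregation only reads site-proximal windows).
    """
    rng = np.random.default_rng([config.seed, 3])
    w = truth.motif_width
    starts: list[np.ndarray] = []
    ends: list[np.ndarray] = []
    values: list[np.ndarray] = []
    prev_end = 0
    hw = config.cleavage_noise_halfwidth
    for row in truth.table.sort_values("center").itertuples():
        z0 = max(prev_end, row.center - hw)
        z1 = min(config.genome_length, row.center + hw)
        if z0 > prev_end:
            starts.append(np.array([prev_end]))
            ends.append(np.array([z0]))
            values.append(np.array([config.cleavage_baseline]))
        base = np.arange(z0, z1)
        v = np.full(len(base), config.cleavage_baseline)
        if config.cleavage_noise_sd > 0:
            v += rng.normal(0, config.cleavage_noise_sd, size=len(base))
        spans = [(row.left_start, row.left_start + w)]
        if row.right_start >= 0:
            spans.append((row.right_start, row.right_start + w))
        for s, e in spans:
            v[(base >= s) & (base < e)] -= config.cleavage_dip_depth
        starts.append(base)
        ends.append(base + 1)
        values.append(v)
        prev_end = z1
    if prev_end < config.genome_length:
        starts.append(np.array([prev_end]))
        ends.append(np.array([config.genome_length]))
        values.append(np.array([config.cleavage_baseline]))
    return ScoreTrack.from_arrays(
        config.chrom,
        np.concatenate(starts),
        np.concatenate(ends),
        np.concatenate(values),
    )


@dataclass
class AnnotationSim:
    """Planted TSS annotations and expression-change gene lists."""

    tss: AnnotationSet
    changed: list[str]
    unchanged: list[str]
    genes: pd.DataFrame  # gene_id, chrom, tss, site_id ('' if background), bound, changed


def simulate_annotations(truth: SimTruth, config: SimConfig) -> AnnotationSim:
    """TSSs enriched near paired sites plus expression-change labels drawn
    at a planted odds ratio relative to promoter binding.

    Each paired site receives a nearby gene TSS with probability
    p_tss_paired, each single site with p_tss_single; remaining genes (up
    to n_genes) land uniformly on the genome, and their planted
    promoter-bound status is read off their distance to the nearest site
    (within promoter_bind_flank of a peak edge counts as bound). Change
    labels are Bernoulli with odds(bound) = planted_odds_ratio x
    odds(baseline_change_rate).
    """
    rng = np.random.default_rng([config.seed, 4])
    rows = []
    for row in truth.table.itertuples():
        p = (
            config.p_tss_paired
            if row.arity == "paired"
            else config.p_tss_single
        )
        if rng.random() < p:
            offset = int(
                rng.integers(-config.tss_offset_max, config.tss_offset_max + 1)
            )
            rows.append(
                dict(
                    chrom=row.chrom,
                    tss=max(0, row.center + offset),
                    site_id=row.site_id,
                    bound=True,
                )
            )
    n_background = max(0, config.n_genes - len(rows))
    if n_background:
        centers = np.sort(truth.table.center.to_numpy())
        positions = np.sort(
            rng.integers(0, config.genome_length, size=n_background)
        )
        if len(centers):
            idx = np.searchsorted(centers, positions)
            left = np.abs(
                positions - centers[np.clip(idx - 1, 0, len(centers) - 1)]
            )
            right = np.abs(
                positions - centers[np.clip(idx, 0, len(centers) - 1)]
            )
            dist = np.minimum(left, right)
        else:
            dist = np.full(len(positions), np.inf)
        # bound iff within promoter_bind_flank of a peak edge
        near = dist <= config.promoter_bind_flank + config.peak_half_width
        for pos, is_near in zip(positions, near):
            rows.append(
                dict(
                    chrom=config.chrom,
                    tss=int(pos),
                    site_id="",
                    bound=bool(is_near),
                )
            )
    genes = pd.DataFrame(rows)
    genes.insert(0, "gene_id", [f"gene{i:05d}" for i in range(len(genes))])
    p0 = config.baseline_change_rate
    odds1 = config.planted_odds_ratio * p0 / (1 - p0)
    p1 = odds1 / (1 + odds1)
    prob = np.where(genes.bound.to_numpy(), p1, p0)
    genes["changed"] = rng.random(len(genes)) < prob
    intervals = [
        GenomicInterval(r.chrom, r.tss, r.tss + 1, "+")
        for r in genes.itertuples()
    ]
    tss = AnnotationSet(
        "synthetic_tss",
        intervals,
        gene_ids=list(genes.gene_id),
        anchor="point",
    )
    changed = list(genes.gene_id[genes.changed])
    unchanged = list(genes.gene_id[~genes.changed])
    return AnnotationSim(tss, changed, unchanged, genes)
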