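"""Recovery and calibration benchmarks.

Each function regenerates its inputs from a seed, runs the package's own
machinery against an independent oracle (exhaustive enumeration, brute
force, closed form or planted truth) and returns summary metrics. They
double as the package's acceptance surface: the test suite asserts their
thresholds and the acceptance script reports their values.
"""

from __future__ import annotations

import math

import numpy as np

from . import classify as cls
from .enrichment import (
    ContingencyTable,
    fisher_enrichment,
    odds_ratio_confint,
)
from .genomic_io import GenomicInterval, Peak, TagLibrary
from .motif import (
    PWM,
    _column_bins,
    build_pwm,
    discover_motif_oops,
    scan,
    score_distribution,
)
from .pipeline import PipelineInputs, run_pipeline
from .profiles import aggregate_track, count_protection_dips, profile_matrix
from .simulate import (
    SimConfig,
    SimTruth,
    _site_layout,
    simulate_annotations,
    simulate_cleavage,
    simulate_genome,
    truth_peaks,
)


def _random_seq(rng, n: int) -> str:
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    return lut[rng.integers(0, 4, size=n)].tobytes().decode("ascii")


def _all_words(w: int) -> np.ndarray:
    """(4^w, w) array of all base-code words."""
    idx = np.arange(4**w)
    return (idx[:, None] // 4 ** np.arange(w - 1, -1, -1)[None, :]) % 4


# ---------------------------------------------------------------------------
# 1. exact p-values vs exhaustive enumeration


def pvalue_enumeration_check(
    seed: int, n_pwms: int = 50, max_w: int = 8, thresholds_per_pwm: int = 20
) -> dict:
    """Compare DP survival probabilities with full enumeration over 4^w
    words for random PWMs of width <= max_w.

    The enumeration computes each word's background probability and its
    discretized score (the same per-column bins the DP convolves), so DP
    and enumeration must agree to floating-point accuracy — well within
    the one-bin tolerance the scanner guarantees.
    """
    rng = np.random.default_rng([seed, 101])
    max_err = 0.0
    for _ in range(n_pwms):
        w = int(rng.integers(4, max_w + 1))
        pwm = build_pwm(
            rng.integers(0, 60, size=(4, w)), pseudocount=0.5
        )
        dist = score_distribution(pwm)
        bins = _column_bins(pwm, dist.granularity)
        words = _all_words(w)
        word_bins = bins[words, np.arange(w)].sum(axis=1)
        word_probs = pwm.background[words].prod(axis=1)
        order = np.argsort(word_bins)
        sorted_bins = word_bins[order]
        tail = np.cumsum(word_probs[order][::-1])[::-1]
        pick = rng.choice(len(words), size=thresholds_per_pwm, replace=False)
        for i in pick:
            k = int(word_bins[i])
            j = int(np.searchsorted(sorted_bins, k, side="left"))
            enum_p = float(tail[j]) if j < len(tail) else 0.0
            dp_p = dist.sf_at_bin(k)
            max_err = max(max_err, abs(dp_p - enum_p))
    return {"max_abs_error": max_err, "n_pwms": n_pwms}


# ---------------------------------------------------------------------------
# 2. expected hit rate of the threshold scanner


def scan_hit_rate_check(
    seed: int, n_seeds: int = 20, length: int = 100_000, w: int = 20
) -> dict:
    """Mean both-strand hit count on i.i.d. uniform sequence vs the
    closed-form expectation 2*(L-w+1)*1e-4.

    Uses a generic random-count PWM: its score distribution is effectively
    continuous near the threshold, so the attained p matches 1e-4.
    """
    rng = np.random.default_rng([seed, 102])
    pwm = build_pwm(rng.integers(1, 60, size=(4, w)), pseudocount=0.5)
    dist = score_distribution(pwm)
    counts = []
    for _ in range(n_seeds):
        seq = _random_seq(rng, length)
        counts.append(len(scan(seq, pwm, 1e-4, dist=dist)))
    counts = np.asarray(counts, dtype=float)
    expected = 2 * (length - w + 1) * 1e-4
    se = float(counts.std(ddof=1) / math.sqrt(n_seeds))
    return {
        "mean_hits": float(counts.mean()),
        "expected_hits": expected,
        "standard_error": se,
        "n_seeds": n_seeds,
    }


# ---------------------------------------------------------------------------
# 3. occupancy partition vs brute force


def occupancy_bruteforce_check(
    seed: int, n_instances: int = 50, max_peaks: int = 2000
) -> dict:
    """classify_occupancy vs O(n^2) all-pairs intersection."""
    rng = np.random.default_rng([seed, 103])
    mismatches = 0
    total_peaks = 0
    for _ in range(n_instances):
        n = int(rng.integers(50, max_peaks + 1))
        m = int(rng.integers(50, max_peaks + 1))

        def make(k):
            starts = rng.integers(0, 1_000_000, size=k)
            lengths = rng.integers(50, 500, size=k)
            chroms = rng.integers(0, 2, size=k)
            return [
                Peak(
                    GenomicInterval(f"chr{c}", int(s), int(s + L)),
                    int(s + L // 2),
                )
                for s, L, c in zip(starts, lengths, chroms)
            ]

        a, b = make(n), make(m)
        part = cls.classify_occupancy(a, b)

        def brute(xs, ys):
            ys_arr = {}
            for q in ys:
                ys_arr.setdefault(q.chrom, []).append((q.start, q.end))
            out = []
            for p in xs:
                hits = ys_arr.get(p.chrom, [])
                if hits:
                    s, e = np.array(hits).T
                    out.append(bool(np.any((s < p.end) & (p.start < e))))
                else:
                    out.append(False)
            return out

        got_a = [
            c is cls.OccupancyClass.CTCF_AND_BORIS for c in part.a_classes
        ]
        got_b = [
            c is cls.OccupancyClass.CTCF_AND_BORIS for c in part.b_classes
        ]
        mismatches += sum(x != y for x, y in zip(got_a, brute(a, b)))
        mismatches += sum(x != y for x, y in zip(got_b, brute(b, a)))
        total_peaks += n + m
    return {
        "mismatches": mismatches,
        "n_instances": n_instances,
        "total_peaks": total_peaks,
    }


# ---------------------------------------------------------------------------
# 4. end-to-end planted-arity recovery


def arity_recovery_check(seed: int, config: SimConfig | None = None) -> dict:
    """Full synthetic run at the default study conditions (10-Mb genome,
    500 single + 500 paired sites, 30-60 bp gaps)."""
    if config is None:
        config = SimConfig(seed=seed)
    genome, truth = simulate_genome(config)
    inputs = PipelineInputs(
        genome=genome,
        peaks_ctcf=truth_peaks(truth, "CTCF", config),
        peaks_boris=truth_peaks(truth, "BORIS", config),
        motif=config.motif,
        truth=truth,
    )
    report = run_pipeline(inputs)
    return {
        "paired_classified_2x_fraction": report.recovery[
            "paired_classified_2x_fraction"
        ],
        "single_classified_1x_fraction": report.recovery[
            "single_classified_1x_fraction"
        ],
        "n_paired": report.recovery["paired_sites_matched"],
        "n_single": report.recovery["single_sites_matched"],
    }


# ---------------------------------------------------------------------------
# 5. footprint dichotomy


def footprint_dichotomy_check(
    seed: int, config: SimConfig | None = None, min_prominence: float = 0.3
) -> dict:
    """Per-site protection-dip counts on the synthetic cleavage track:
    single sites should show one dip, paired sites two."""
    if config is None:
        config = SimConfig(seed=seed)
    # the genome sequence itself is not needed for the cleavage benchmark;
    # rebuild only the site layout from the same seeded stream
    layout_rng = np.random.default_rng([config.seed, 0])
    layout = _site_layout(config, layout_rng)
    truth = SimTruth(layout, config.seed, config.motif.width)
    track = simulate_cleavage(truth, config)
    w = truth.motif_width
    results = {"single": [0, 0], "paired": [0, 0]}
    for row in truth.table.itertuples():
        anchor = (row.chrom, row.left_start + w // 2)
        vec = aggregate_track(track, [anchor], window=150, bin=5)
        dips = count_protection_dips(vec, min_prominence)
        expected = 1 if row.arity == "single" else 2
        results[row.arity][0] += dips == expected
        results[row.arity][1] += 1
    return {
        "single_one_dip_fraction": results["single"][0] / results["single"][1],
        "paired_two_dip_fraction": results["paired"][0] / results["paired"][1],
        "n_single": results["single"][1],
        "n_paired": results["paired"][1],
    }


# ---------------------------------------------------------------------------
# 6. Fisher exactness and operating characteristics


def fisher_enumeration_check(max_total: int = 40) -> dict:
    """fisher_enrichment('greater') vs explicit hypergeometric tail sums
    for every 2x2 table with grand total <= max_total."""
    max_err = 0.0
    n_tables = 0
    for n in range(1, max_total + 1):
        for r1 in range(n + 1):
            for c1 in range(n + 1):
                lo = max(0, r1 + c1 - n)
                hi = min(r1, c1)
                if lo > hi:
                    continue
                denom = math.comb(n, r1)
                pmf = np.array(
                    [
                        math.comb(c1, x) * math.comb(n - c1, r1 - x) / denom
                        for x in range(lo, hi + 1)
                    ]
                )
                tails = np.cumsum(pmf[::-1])[::-1]
                for x in range(lo, hi + 1):
                    a = x
                    b = r1 - x
                    c = c1 - x
                    d = n - r1 - c
                    res = fisher_enrichment(
                        ContingencyTable(a, b, c, d), "greater"
                    )
                    max_err = max(max_err, abs(res.pvalue - tails[x - lo]))
                    n_tables += 1
    return {"max_abs_error": max_err, "n_tables": n_tables}


def _fisher_sim_table(seed: int, planted_or: float) -> ContingencyTable:
    """Planted-truth contingency table from the annotation simulator at the
    sparse-site regime (minority of genes promoter-bound)."""
    cfg = SimConfig(
        seed=seed,
        n_single_sites=50,
        n_paired_sites=50,
        planted_odds_ratio=planted_or,
    )
    rng = np.random.default_rng([cfg.seed, 0])
    layout = _site_layout(cfg, rng)
    truth = SimTruth(layout, cfg.seed, cfg.motif.width)
    ann = simulate_annotations(truth, cfg)
    g = ann.genes
    return ContingencyTable(
        int((g.bound & g.changed).sum()),
        int((g.bound & ~g.changed).sum()),
        int((~g.bound & g.changed).sum()),
        int((~g.bound & ~g.changed).sum()),
    )


def fisher_operating_characteristics(
    seed: int, n_null: int = 100, n_alt: int = 20
) -> dict:
    """Type-I error at planted OR = 1 and exact-CI coverage at OR = 4."""
    base = int(np.random.default_rng([seed, 106]).integers(0, 2**20))
    rejections = 0
    for i in range(n_null):
        t = _fisher_sim_table(base + i, 1.0)
        if fisher_enrichment(t, "greater").pvalue < 0.05:
            rejections += 1
    covered = 0
    for i in range(n_alt):
        t = _fisher_sim_table(base + 10_000 + i, 4.0)
        lo, hi = odds_ratio_confint(t)
        covered += lo <= 4.0 <= hi
    return {
        "null_rejection_rate": rejections / n_null,
        "or4_ci_coverage": covered / n_alt,
        "n_null": n_null,
        "n_alt": n_alt,
    }


# ---------------------------------------------------------------------------
# 7. normalization invariance


def normalization_invariance_check(seed: int) -> dict:
    """Duplicating every tag (doubling the library) must leave the
    normalized profile matrix bitwise unchanged."""
    rng = np.random.default_rng([seed, 107])
    lib = TagLibrary({"c": rng.integers(0, 200_000, size=20_000)})
    doubled = lib.concat(lib)
    anchors = [("c", int(p)) for p in rng.integers(5000, 195_000, 50)]
    a = profile_matrix(lib, anchors, window=5000, bin=100)
    b = profile_matrix(doubled, anchors, window=5000, bin=100)
    return {
        "max_abs_deviation": float(np.abs(a.values - b.values).max()),
        "n_anchors": len(anchors),
    }


# ---------------------------------------------------------------------------
# 8. EM motif recovery


def em_recovery_check(
    seed: int,
    n_runs: int = 20,
    n_sequences: int = 50,
    seq_length: int = 200,
    w: int = 20,
) -> dict:
    """Planted fixed 20-mer recovered as the discovered PWM consensus."""
    from .genomic_io import reverse_complement

    master = np.random.default_rng([seed, 108])
    recovered = 0
    for run in range(n_runs):
        rng = np.random.default_rng([seed, 108, run])
        planted = _random_seq(rng, w)
        seqs = []
        for _ in range(n_sequences):
            s = list(_random_seq(rng, seq_length))
            pos = int(rng.integers(0, seq_length - w + 1))
            word = (
                planted if rng.random() < 0.5 else reverse_complement(planted)
            )
            s[pos : pos + w] = word
            seqs.append("".join(s))
        res = discover_motif_oops(
            seqs, w=w, seed=int(master.integers(0, 2**20))
        )
        if res.pwm.consensus in (planted, reverse_complement(planted)):
            recovered += 1
    return {"recovery_rate": recovered / n_runs, "n_runs": n_runs}
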