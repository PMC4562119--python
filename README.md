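# ctskit

Classification of single versus clustered CTCF target sites (1xCTS /
2xCTS) from dual-factor ChIP-seq occupancy.

CTCF is a ubiquitous 11-zinc-finger chromatin organizer; BORIS (CTCFL) is
its germline-restricted paralog with an identical DNA-binding domain,
aberrantly expressed in many cancers. When both proteins are mapped by
ChIP-seq in the same cells, their peak sets partition the CTCF binding
landscape into CTCF-only, CTCF&BORIS and BORIS-only occupancy classes —
and the classes turn out to be structurally different: regions bound by
both factors typically contain **two or more closely spaced CTCF motifs**
(clustered sites, 2xCTS, with ~30–60 bp linkers in varying orientations),
while CTCF-only regions carry a **single motif** (1xCTS). The clustered
class concentrates at active promoters and enhancers and behaves as the
transcription-factor face of CTCF. `ctskit` implements this analysis as a
tested, reusable pipeline for epigenomics researchers, exercisable
entirely on synthetic data with planted ground truth.

## What it computes

- **Occupancy classes** — peaks from two factors are partitioned by the
  reciprocal overlap rule: peaks sharing ≥ 1 bp are co-bound
  (CTCF&BORIS); the remainders are CTCF-only / BORIS-only. Regions
  invariant across additional samples can be required, and the top-*n*
  regions per class selected by peak score.
- **Motif arity** — each region's ±100 bp summit window is scanned with a
  position weight matrix. A window word *w* is scored in bits,
  S(w) = Σⱼ log₂ ( p(wⱼ, j) / q(wⱼ) ), and assigned the exact p-value
  P(S ≥ s) under the 0-order background *q*, computed by
  dynamic-programming convolution of the discretized per-column score
  distribution (default grid 10⁻³ bit). Hits with p < 10⁻⁴ on either
  strand are collapsed to non-overlapping occurrences; ≥ 2 survivors make
  the region 2xCTS, and the closest pair's gap and strand orientation
  (tandem/convergent/divergent) are reported.
- **Motif discovery** — a one-occurrence-per-sequence (OOPS) EM
  discoverer estimates a 20-bp PWM from summit-window sequences,
  considering both strands, with seeded multi-start and a retrievable
  likelihood trace.
- **Signal profiles** — summit-anchored tag-density matrices normalized
  to tags per 10 million mapped tags (10-kb windows), per-class average
  profiles, deterministic k-means heatmap clustering (linear min-max or
  rank row normalization), and per-base track aggregation (300-bp
  windows) for DNaseI-style cleavage, conservation or histone-retention
  tracks, including prominence-based counting of protection dips (one dip
  at 1xCTS, two at 2xCTS).
- **Enrichment statistics** — active promoter/enhancer construction from
  mark overlaps, class/annotation association fractions, promoter-bound
  gene sets (±5 kb of the TSS) and Fisher's exact test with the sample
  odds ratio OR = ad/bc and an exact conditional confidence interval.
- **Synthetic benchmark** — a seeded generator plants single and paired
  motif instances (gaps 30–60 bp, mixed orientations), factor-specific
  tag pileups (BORIS only at paired sites, boosted amplitude when
  co-bound), protection-dip cleavage tracks and TSS/expression-change
  annotations with a configurable planted odds ratio, all recorded in a
  machine-readable truth ledger for recovery testing.

## Worked example

```python
import ctskit as ck

config = ck.SimConfig(genome_length=1_000_000,
                      n_single_sites=50, n_paired_sites=50, seed=7)
genome, truth = ck.simulate_genome(config)
report = ck.run_pipeline(ck.PipelineInputs(
    genome=genome,
    peaks_ctcf=ck.truth_peaks(truth, "CTCF", config),
    peaks_boris=ck.truth_peaks(truth, "BORIS", config),
    motif=config.motif,
    truth=truth,
))
print(report.occupancy_counts)
print(report.arity_percent)
print(report.recovery)
```

prints

```
{'CTCF_ONLY': 50, 'CTCF_AND_BORIS': 50, 'BORIS_ONLY': 0}
{'CTCF_ONLY': 0.0, 'CTCF_AND_BORIS': 100.0, 'BORIS_ONLY': 0.0}
{'paired_sites_matched': 50, 'single_sites_matched': 50,
 'paired_classified_2x_fraction': 1.0, 'single_classified_1x_fraction': 1.0}
```

meaning: the 50 co-bound regions (planted paired sites) all contain two
accepted motif occurrences in their summit windows (100 % 2xCTS), the 50
CTCF-only regions contain one (0 % 2xCTS), and every planted site is
recovered in its true class. The `examples/` directory has one short
script per capability (scanning, classification, profiles, footprints,
enrichment, motif discovery); each prints the numbers it computes and a
line on what they mean. A thin CLI mirrors the stages:
`ctskit simulate|scan|classify|profile|enrich|run`.

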