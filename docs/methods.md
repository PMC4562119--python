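# Methods

## The analysis model

`ctskit` operationalizes a structural dichotomy among CTCF binding
regions. A ChIP-seq peak for CTCF either contains a single 20-bp CTCF
target site (1xCTS) or a cluster of two or more sites separated by a
short linker (2xCTS). The package's working model, which the synthetic
generator instantiates and the pipeline recovers, is:

- 1xCTS regions are bound by a CTCF monomer only;
- 2xCTS regions are co-bound — by CTCF and its paralog BORIS where BORIS
  is expressed — with higher total ChIP amplitude, two protection
  footprints, and preferential placement at active promoters/enhancers.

The pipeline therefore composes five measurements: occupancy partition of
two peak sets, motif-arity classification of each region, tag-density
profiling, per-base track aggregation, and binding/expression enrichment.

## Occupancy partition

Two peaks co-occupy a region if their intervals share at least 1 bp
(reciprocal overlap). Factor-A peaks overlapping any factor-B peak are
CTCF&BORIS; the remainders are CTCF-only and BORIS-only. The partition is
computed with a merged-interval binary search and is checked against
brute-force all-pairs intersection in the benchmark suite. Regions
"invariant" across further samples are first-set peaks overlapping a peak
in every other set; the first set's coordinates and summits are retained,
so invariance acts purely as a filter. Top-*n* selection ranks by the
peak score column (the ranking statistic of the upstream peak caller;
any statistic can be loaded into that column), with ties broken by
(chromosome, start) for determinism.

## Motif model and exact p-values

A motif is a 4×w probability matrix with a 0-order background. Counts are
converted with a background-proportional pseudocount (default 0.1):
p(b,j) = (n(b,j) + 0.1·q(b)) / (N(j) + 0.1). Scores are log-odds in bits.
The null distribution of the score is computed exactly: each column's
four log-odds values are snapped to a grid of 1/1000 bit and the pmf of
their background-weighted sum is built by iterated convolution. A
window's p-value is the survival probability of its *discretized* score —
the scanner sums the same per-column integer bins the convolution uses,
so scanner p-values agree with exhaustive enumeration over all 4^w words
to floating-point accuracy (verified for w ≤ 8), and are within one grid
bin of the continuous-score tail. The default grid keeps the
discretization error far below the 10⁻⁴ decision threshold.

Scanning reports every position and strand with p < 10⁻⁴ (both-strand
duplicates at palindromic sites included; collapsing is the consumer's
policy). The default background is uniform for reproducibility, with an
option to estimate composition from the scanned sequences.

A note on threshold calibration: for a near-consensus matrix whose
columns share identical log-odds values, the score distribution is
concentrated on a coarse lattice, and the largest attainable p below
10⁻⁴ can be substantially smaller (for the packaged synthetic motif,
~6.4×10⁻⁵). The scanner is exact about this — it simply means such
matrices yield conservatively fewer background hits than the nominal
rate. The hit-rate calibration benchmark therefore uses a generic
random-count PWM, whose score distribution is effectively continuous near
the threshold.

## Arity classification and pair geometry

Hits whose start lies within ±100 bp of the peak summit (the summit of
the BORIS peak for BORIS-only regions, CTCF otherwise) are collapsed
greedily by ascending p-value to a non-overlapping set, so a palindromic
double report or two overlapping matches of one strong site cannot fake a
cluster — a deliberately conservative policy against false 2xCTS calls.
Two or more survivors make the region 2xCTS. For 2xCTS regions the
closest adjacent pair defines the geometry: gap = right.start − left.end,
orientation from the strand pair (tandem +/+, tandem −/−, convergent
+/−, divergent −/+). Extra hits beyond the closest pair are recorded in
the count only.

## Signal profiles and clustering

Tag densities are single-base tag counts per bin, normalized to tags per
10 million mapped tags. Heatmap windows default to ±5 kb around summits
with 100-bp bins; footprint windows to ±150 bp around the (left) motif
center with 5-bp bins. Bin sizes are package choices made to resolve the
structure at each scale; both are parameters. Row normalization for
clustering is "linear" (per-row min-max to [0,1]) or "rank" (per-row rank
transform). k-means uses deterministic farthest-point seeding from a
seeded RNG and plain Lloyd iteration with a recorded, provably
non-increasing within-cluster-sum-of-squares trace; the unit tests
cross-check its objective against scikit-learn's KMeans.

Per-base tracks (cleavage, conservation, histone retention) follow
bedGraph coverage semantics — absent bases are 0, not missing. Protection
dips are local minima of the aggregated profile with prominence at least
0.3 of the baseline units (half the simulated dip depth), counted with a
standard peak-prominence routine on the negated profile.

## Enrichment statistics

Active promoters are TSSs whose ±2 kb window overlaps peaks of both
activity marks; active enhancers are direct intersections of two mark
peak sets. The original construction additionally required the highest
enrichment over input; input tracks are not modeled here, so mark-peak
presence stands in for that criterion (a documented simplification).
Association fractions count an annotation anchor for a class when a class
peak lies within an inclusive distance threshold (0 inside a peak, else
bp to the nearest edge; "within 4 kb" is measured to the peak edge, a
parameterized choice since edge-vs-summit is not dictated by the
phrasing). Promoter-bound gene sets use ±5 kb of the TSS. Fisher's exact
test reports the sample odds ratio ad/bc (infinite when bc = 0 with
ad > 0, undefined 0/0 flagged) and the exact hypergeometric p-value;
sidedness defaults to one-sided "greater" for enrichment claims since the
original reports raw p and OR without stating sidedness, and two-sided is
available. The exact confidence interval inverts the tails of Fisher's
noncentral hypergeometric distribution. Genomic distribution assigns
each summit one category by fixed priority promoter (TSS ±2 kb) > exon >
intron > intergenic, so fractions sum to 1; the cited annotation tools'
precedence is version-dependent, so the order is pinned and documented.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes,
with full determinism under a single seed (all streams are derived from
it):

- **Genome** — i.i.d. background (GC configurable, default 0.5) of
  10 Mb, with 500 single and 500 paired 20-bp motif instances planted on
  a jittered slot grid that guarantees non-overlap and wide spacing.
  Instances are sampled from the PWM (so scanner p-value behavior is
  exercised); a consensus-only mode exists for deterministic tests.
  Paired instances are separated by a uniform 30–60 bp gap — spanning
  the observed spacings at characterized clustered promoters and the
  30–40 bp linker regime — with orientations drawn uniformly from the
  four strand configurations.
- **Motif** — the packaged default is a synthetic 20-bp CTCF-like count
  matrix (a constructed stand-in, not derived from real ChIP data) with
  ~1.1 bits/column information content, typical of the CTCF core motif;
  at that strength a PWM-sampled instance passes the 10⁻⁴ scan with
  probability ≈ 0.99.
- **ChIP tags** — uniform background plus Gaussian pileups
  (σ = 50 bp) at bound sites. CTCF binds every site; BORIS only paired
  sites (fraction configurable, default 1.0). Site amplitude is
  enrichment_fold (default 10) × background density × peak footprint,
  with a 2× boost at co-bound sites; the background total is solved so
  the expected library size equals tag_depth (default 10⁶).
- **Cleavage track** — constant accessibility baseline 1.0 with
  rectangular 20-bp protection dips of depth 0.6 at motif spans and
  per-base Gaussian noise (σ = 0.05) within ±500 bp of sites; constant
  elsewhere, which keeps the text serialization tractable and is
  invisible to the site-anchored consumers.
- **Annotations** — each paired site receives a nearby gene TSS with
  probability 0.9, each single site 0.1 (TSS offset ≤ 800 bp); the
  remaining genes (total 2000) land uniformly, with planted bound status
  read off their distance to the nearest site so truth and detection
  stay consistent. Expression-change labels are Bernoulli with
  odds(bound) = planted OR (default 4) × odds(baseline rate 0.2).

What the generator does **not** emulate: read-length/quality effects,
mappability and repeats, fragment-size distributions, input/control
tracks, peak-caller artifacts, inter-site spacing heterogeneity of real
genomes, or diploidy. Passing recovery benchmarks therefore demonstrates
the correctness and calibration of the analysis machinery under the
stated model, not performance on real libraries.

## Benchmark study conditions and problem sizes

- Arity recovery runs the full default conditions: 10-Mb genome, 500
  single + 500 paired sites. Measured recovery is ≈ 97 % of paired sites
  called 2xCTS and ≈ 98 % of single sites called 1xCTS; the residuals are
  PWM-sampled instances below the scan threshold (pairs need both) and
  occasional spurious background hits adjacent to a single site.
- Footprint dichotomy is evaluated per site at default noise (1000
  sites).
- The Fisher operating-characteristics benchmark uses a sparser layout
  (50 + 50 sites on 10 Mb, 2000 genes) so that a minority of genes are
  promoter-bound, as in real gene/peak geometries; at the default
  density nearly every gene lies within ±5 kb of a peak and the
  contingency table degenerates. Exactness is checked by full
  enumeration of all 2×2 tables with grand total ≤ 40.
- Hit-rate calibration scans 20 seeded 100-kb uniform sequences;
  EM recovery uses 20 runs of 50 × 200 bp sequences.

## Numerical choices and degenerate inputs

- Coordinates are 0-based half-open throughout; narrowPeak summit
  offsets become absolute positions at parse time; missing summits fall
  back to the interval midpoint.
- Tags are single-base 5′ positions with a configurable shift (default
  0), since upstream shifting/extension conventions vary.
- Score-grid granularity 10⁻³ bit; EM convergence at relative
  log-likelihood change < 10⁻⁶ or 200 iterations; EM restarts are seeded
  from the most frequent w-mers (deterministic given the seed).
- Normalized profile values are exactly invariant to integer scaling of
  the library (binary-float scaling identity), and de-normalized row
  sums reproduce raw window counts exactly.
- Empty peak sets, empty BORIS inputs, windows containing N, zero-count
  columns with zero pseudocount, and 0/0 odds ratios all take defined
  error or degenerate-output paths exercised in the tests.
- Unknown chromosomes in secondary inputs are skipped with a warning
  rather than raised, for robustness to annotation/genome mismatches.

## Known limitations

- Arity counts beyond 2 do not refine geometry (closest pair only).
- The promoter definition reduces "highest enrichment vs input" to mark
  presence.
- No BAM/bigWig input; text formats only.
- The scanner's exactness is relative to the discretized score; matrices
  with extremely coarse score lattices attain conservative thresholds
  (see the calibration note above).
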