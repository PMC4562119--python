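"""Summit-anchored tag-density profiles and k-means heatmap clustering.

Simulates factor-specific ChIP tags, builds normalized (tags per 10
million) density matrices around peak summits and shows that 2-means
clustering of the BORIS signal separates co-bound from CTCF-only regions.
"""

import numpy as np
from sklearn.metrics import adjusted_rand_score

import ctskit as ck

config = ck.SimConfig(
    genome_length=1_000_000,
    n_single_sites=50,
    n_paired_sites=50,
    tag_depth=400_000,
    seed=3,
)
genome, truth = ck.simulate_genome(config)
boris = ck.simulate_chip(truth, "BORIS", config)

peaks = ck.truth_peaks(truth, "CTCF", config)
part = ck.classify_occupancy(peaks, ck.truth_peaks(truth, "BORIS", config))
anchors = [(p.chrom, p.summit) for p in part.peaks_a]
cobound = [
    c is ck.OccupancyClass.CTCF_AND_BORIS for c in part.a_classes
]

pm = ck.profile_matrix(boris, anchors, window=5000, bin=100)
print(
    f"profile matrix: {pm.values.shape[0]} regions x {pm.n_bins} bins, "
    f"library {pm.library_size} tags"
)
avg = ck.average_profile(pm)
center = pm.n_bins // 2
print(
    f"mean BORIS density: center bin {avg[center]:.0f} vs edge bin "
    f"{avg[0]:.0f} tags/10M"
)

res = ck.kmeans_rows(pm, k=2, seed=0, normalization="linear")
ari = adjusted_rand_score(cobound, res.labels)
print(f"2-means on min-max-normalized rows: ARI vs occupancy = {ari:.2f}")
print(
    "BORIS tag pileups exist only at co-bound paired sites, so the heatmap "
    "clustering recovers the occupancy partition from signal shape alone."
)
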