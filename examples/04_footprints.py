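"""Protection footprints: one dip at single sites, two at clustered sites.

Aggregates a simulated DNaseI-style cleavage track in 300-bp windows
anchored at the (left) motif center and counts protection dips by
prominence.
"""

import ctskit as ck

config = ck.SimConfig(
    genome_length=1_000_000, n_single_sites=50, n_paired_sites=50, seed=9
)
genome, truth = ck.simulate_genome(config)
track = ck.simulate_cleavage(truth, config)

for arity in ("single", "paired"):
    sites = truth.sites(arity)
    anchors = [
        (row.chrom, row.left_start + truth.motif_width // 2)
        for row in sites.itertuples()
    ]
    vec = ck.aggregate_track(track, anchors, window=150, bin=5)
    dips = ck.count_protection_dips(vec, min_prominence=0.3)
    print(
        f"{arity:>6} sites (n={len(sites)}): aggregate cleavage minimum "
        f"{vec.min():.2f}, protection dips = {dips}"
    )
print(
    "Single sites show one 20-bp protection dip; paired sites show two "
    "dips separated by the 30-60 bp linker, the footprint signature of a "
    "clustered 2xCTS."
)
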