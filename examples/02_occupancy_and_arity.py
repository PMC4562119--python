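"""Occupancy classes and motif arity (1xCTS vs 2xCTS).

Simulates a small genome with planted single and paired CTCF motifs,
derives CTCF and BORIS peak sets, partitions them by the reciprocal
1-bp-overlap rule and classifies each region's motif arity within
+/- 100 bp of the summit.
"""

import ctskit as ck

config = ck.SimConfig(
    genome_length=1_000_000, n_single_sites=50, n_paired_sites=50, seed=7
)
genome, truth = ck.simulate_genome(config)
inputs = ck.PipelineInputs(
    genome=genome,
    peaks_ctcf=ck.truth_peaks(truth, "CTCF", config),
    peaks_boris=ck.truth_peaks(truth, "BORIS", config),
    motif=config.motif,
    truth=truth,
)
report = ck.run_pipeline(inputs)

print("occupancy counts:", report.occupancy_counts)
print("percent 2xCTS per class:", report.arity_percent)
print("gap histogram (CTCF&BORIS):", report.gap_histogram["CTCF_AND_BORIS"])
print("orientations:", report.orientation_counts["CTCF_AND_BORIS"])
print("recovery vs planted truth:", report.recovery)
print(
    "Co-bound (CTCF&BORIS) regions are almost all 2xCTS — they carry two "
    "scanned motif occurrences 30-60 bp apart — while CTCF-only regions "
    "are single-motif sites."
)
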