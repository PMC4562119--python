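import io

import numpy as np
import pytest

import ctskit as ck
from ctskit.simulate import PlacementError, _site_layout


class TestSimulateGenome:
    def test_seed_determinism(self, tiny_sim):
        cfg, genome, truth = tiny_sim
        genome2, truth2 = ck.simulate_genome(cfg)
        assert genome2.sequence(cfg.chrom) == genome.sequence(cfg.chrom)
        assert truth2.table.equals(truth.table)

    def test_truth_counts_match_config(self, tiny_sim):
        cfg, _, truth = tiny_sim
        assert len(truth.sites("single")) == cfg.n_single_sites
        assert len(truth.sites("paired")) == cfg.n_paired_sites

    def test_gaps_within_configured_range(self, tiny_sim):
        cfg, _, truth = tiny_sim
        gaps = truth.sites("paired").gap
        assert gaps.between(*cfg.gap_range).all()

    def test_planted_instances_present_in_sequence(self):
        cfg = ck.SimConfig(
            genome_length=100_000,
            n_single_sites=5,
            n_paired_sites=5,
            consensus_only=True,
            seed=3,
        )
        genome, truth = ck.simulate_genome(cfg)
        seq = genome.sequence(cfg.chrom)
        consensus = cfg.motif.consensus
        rc = ck.reverse_complement(consensus)
        for row in truth.table.itertuples():
            word = seq[row.left_start : row.left_start + 20]
            assert word in (consensus, rc)
            if row.right_start >= 0:
                word2 = seq[row.right_start : row.right_start + 20]
                assert word2 in (consensus, rc)

    def test_placement_error_on_tiny_genome(self):
        with pytest.raises(PlacementError):
            ck.simulate_genome(
                ck.SimConfig(genome_length=5000, n_single_sites=50,
                             n_paired_sites=0)
            )

    def test_truth_roundtrip_tsv(self, tiny_sim):
        _, _, truth = tiny_sim
        buf = io.StringIO()
        truth.to_tsv(buf)
        buf.seek(0)
        back = ck.SimTruth.from_tsv(buf)
        assert back.seed == truth.seed
        assert back.motif_width == truth.motif_width
        assert back.table.equals(truth.table)


class TestSimulateChip:
    def test_boris_absent_at_single_sites(self, tiny_sim):
        """BORIS tag counts at single sites should look like background."""
        cfg, _, truth = tiny_sim
        boris = ck.simulate_chip(truth, "BORIS", cfg)
        singles = truth.sites("single")
        site_counts = np.array(
            [
                boris.count_in(cfg.chrom, c - 200, c + 200)
                for c in singles.center
            ]
        )
        # background control windows far from any site
        rng = np.random.default_rng(0)
        centers = np.sort(truth.table.center.to_numpy())
        ctrl = []
        while len(ctrl) < len(site_counts):
            p = int(rng.integers(1000, cfg.genome_length - 1000))
            if np.abs(centers - p).min() > 2000:
                ctrl.append(boris.count_in(cfg.chrom, p - 200, p + 200))
        from scipy.stats import mannwhitneyu

        _, p = mannwhitneyu(site_counts, np.array(ctrl))
        assert p > 0.01

    def test_cobound_sites_exceed_single_sites_for_ctcf(self, tiny_sim):
        cfg, _, truth = tiny_sim
        ctcf = ck.simulate_chip(truth, "CTCF", cfg)
        def mean_count(df):
            return np.mean(
                [ctcf.count_in(cfg.chrom, c - 200, c + 200) for c in df.center]
            )
        cobound = truth.table[truth.table.bound_by == "CTCF+BORIS"]
        singles = truth.sites("single")
        assert mean_count(cobound) > 1.5 * mean_count(singles)

    def test_depth_linearity(self, tiny_sim):
        cfg, _, truth = tiny_sim
        deep = ck.SimConfig(**{**vars(cfg), "tag_depth": cfg.tag_depth * 2})
        t1 = ck.simulate_chip(truth, "CTCF", cfg)
        t2 = ck.simulate_chip(truth, "CTCF", deep)
        assert t2.total / t1.total == pytest.approx(2.0, rel=0.05)

    def test_total_near_tag_depth(self, tiny_sim):
        cfg, _, truth = tiny_sim
        lib = ck.simulate_chip(truth, "CTCF", cfg)
        assert lib.total == pytest.approx(cfg.tag_depth, rel=0.05)


class TestSimulateCleavage:
    def test_noise_free_minima_at_motifs(self, tiny_sim):
        cfg, _, truth = tiny_sim
        quiet = ck.SimConfig(**{**vars(cfg), "cleavage_noise_sd": 0.0})
        track = ck.simulate_cleavage(truth, quiet)
        row = truth.sites("paired").iloc[0]
        v = track.values_over(
            cfg.chrom, row.center - 150, row.center + 150
        )
        dip_level = cfg.cleavage_baseline - cfg.cleavage_dip_depth
        offsets = np.nonzero(np.isclose(v, dip_level))[0] + row.center - 150
        expected = set(range(row.left_start, row.left_start + 20)) | set(
            range(row.right_start, row.right_start + 20)
        )
        assert set(offsets.tolist()) == expected

    def test_paired_dip_centers_separated_by_gap_plus_width(self, tiny_sim):
        cfg, _, truth = tiny_sim
        row = truth.sites("paired").iloc[0]
        left_center = row.left_start + 10
        right_center = row.right_start + 10
        assert right_center - left_center == row.gap + 20

    def test_seed_determinism(self, tiny_sim):
        cfg, _, truth = tiny_sim
        t1 = ck.simulate_cleavage(truth, cfg)
        t2 = ck.simulate_cleavage(truth, cfg)
        s1, e1, v1 = t1.records(cfg.chrom)
        s2, e2, v2 = t2.records(cfg.chrom)
        assert np.array_equal(s1, s2) and np.array_equal(v1, v2)


class TestSimulateAnnotations:
    def test_extreme_probabilities(self, tiny_sim):
        cfg, _, truth = tiny_sim
        extreme = ck.SimConfig(
            **{**vars(cfg), "p_tss_paired": 1.0, "p_tss_single": 0.0,
               "n_genes": 0}
        )
        ann = ck.simulate_annotations(truth, extreme)
        site_genes = ann.genes[ann.genes.site_id != ""]
        linked = set(site_genes.site_id)
        paired_ids = set(truth.sites("paired").site_id)
        assert linked == paired_ids
        offsets = []
        centers = truth.table.set_index("site_id").center
        for g in site_genes.itertuples():
            offsets.append(abs(g.tss - centers[g.site_id]))
        assert max(offsets) <= extreme.tss_offset_max

    def test_determinism_and_gene_count(self, tiny_sim):
        cfg, _, truth = tiny_sim
        a1 = ck.simulate_annotations(truth, cfg)
        a2 = ck.simulate_annotations(truth, cfg)
        assert a1.genes.equals(a2.genes)
        assert len(a1.genes) >= cfg.n_genes

    def test_changed_rate_reflects_planted_odds(self, tiny_sim):
        cfg, _, truth = tiny_sim
        big = ck.SimConfig(**{**vars(cfg), "n_genes": 5000,
                              "planted_odds_ratio": 4.0})
        ann = ck.simulate_annotations(truth, big)
        g = ann.genes
        p0 = g[~g.bound].changed.mean()
        p1 = g[g.bound].changed.mean()
        odds = (p1 / (1 - p1)) / (p0 / (1 - p0))
        assert odds == pytest.approx(4.0, rel=0.35)

    def test_gene_lists_partition_genes(self, tiny_sim):
        cfg, _, truth = tiny_sim
        ann = ck.simulate_annotations(truth, cfg)
        assert len(ann.changed) + len(ann.unchanged) == len(ann.genes)
        assert set(ann.changed).isdisjoint(ann.unchanged)


class TestTruthPeaks:
    def test_factor_specific_peak_sets(self, tiny_sim):
        cfg, _, truth = tiny_sim
        ctcf = ck.truth_peaks(truth, "CTCF", cfg)
        boris = ck.truth_peaks(truth, "BORIS", cfg)
        assert len(ctcf) == len(truth)
        n_cobound = (truth.table.bound_by == "CTCF+BORIS").sum()
        assert len(boris) == n_cobound

    def test_summits_at_site_centers(self, tiny_sim):
        cfg, _, truth = tiny_sim
        for p, c in zip(
            ck.truth_peaks(truth, "CTCF", cfg), truth.table.center
        ):
            assert p.summit == c


class TestSiteLayout:
    def test_sites_do_not_overlap(self, tiny_sim):
        cfg, _, truth = tiny_sim
        spans = []
        for row in truth.table.itertuples():
            end = (
                row.left_start + 20
                if row.right_start < 0
                else row.right_start + 20
            )
            spans.append((row.left_start, end))
        spans.sort()
        assert all(b[0] >= a[1] for a, b in zip(spans, spans[1:]))
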