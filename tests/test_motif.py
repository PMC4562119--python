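import io
import itertools

import numpy as np
import pytest

import ctskit as ck
from ctskit.motif import DegenerateInputError, _column_bins

from conftest import random_sequence


def enumerate_words(w):
    return ["".join(t) for t in itertools.product("ACGT", repeat=w)]


def enumeration_pvalue(pwm, score, granularity=1e-3):
    """Brute-force P(Score >= score) over all 4^w words, computed on the
    same per-column score bins the DP convolves."""
    bins = _column_bins(pwm, granularity)
    w = pwm.width
    total = 0.0
    k = int(round(score / granularity))
    for word in itertools.product(range(4), repeat=w):
        b = sum(bins[base, j] for j, base in enumerate(word))
        if b >= k:
            total += np.prod([pwm.background[base] for base in word])
    return total


class TestBuildPwm:
    def test_pseudocount_arithmetic(self):
        pwm = ck.build_pwm(
            [[10], [0], [0], [0]], pseudocount=1.0, background=[0.25] * 4
        )
        expected = np.array([10.25, 0.25, 0.25, 0.25]) / 11
        assert np.allclose(pwm.probs[:, 0], expected)

    def test_zero_counts_zero_pseudocount_rejected(self):
        with pytest.raises(DegenerateInputError):
            ck.build_pwm(np.zeros((4, 3)), pseudocount=0.0)

    def test_columns_sum_to_one(self, rng):
        for _ in range(10):
            pwm = ck.build_pwm(rng.integers(0, 99, (4, 8)), pseudocount=0.3)
            assert np.allclose(pwm.probs.sum(axis=0), 1.0)


class TestLogOddsScore:
    def test_consensus_closed_form(self):
        # prob -> 1 per consensus base, uniform bg: w * log2(4) bits
        counts = np.zeros((4, 20))
        counts[0] = 1e9  # all-A consensus, vanishing pseudocount effect
        pwm = ck.build_pwm(counts, pseudocount=1e-6)
        assert ck.logodds_score(pwm, "A" * 20) == pytest.approx(40.0, abs=1e-4)

    def test_hand_arithmetic_w2(self):
        pwm = ck.PWM(
            np.array([[0.5, 0.25], [0.5, 0.25], [0.0, 0.25], [0.0, 0.25]]),
            np.full(4, 0.25),
        )
        assert ck.logodds_score(pwm, "AC") == pytest.approx(1.0)

    def test_minus_strand_scores_revcomp(self, small_pwm, rng):
        for _ in range(20):
            word = random_sequence(rng, small_pwm.width)
            assert ck.logodds_score(small_pwm, word, "-") == pytest.approx(
                ck.logodds_score(small_pwm, ck.reverse_complement(word), "+")
            )

    def test_word_with_n_has_no_score(self, small_pwm):
        assert np.isnan(ck.logodds_score(small_pwm, "ACGNTA"))


class TestScoreDistribution:
    def test_w1_uniform_mass(self):
        pwm = ck.build_pwm([[5], [9], [2], [7]], pseudocount=0.5)
        dist = ck.score_distribution(pwm)
        assert np.isclose(dist.pmf.sum(), 1.0)
        assert np.allclose(np.sort(dist.pmf[dist.pmf > 0]), [0.25] * 4)

    def test_support_endpoints_are_column_extreme_sums(self, small_pwm):
        dist = ck.score_distribution(small_pwm)
        bins = _column_bins(small_pwm, dist.granularity)
        assert dist.offset == bins.min(axis=0).sum()
        lo = small_pwm.log_odds
        assert dist.max_score == pytest.approx(
            np.round(lo / dist.granularity).max(axis=0).sum()
            * dist.granularity
        )

    def test_matches_enumeration_w6(self, rng):
        for _ in range(3):
            pwm = ck.build_pwm(rng.integers(0, 30, (4, 6)), pseudocount=0.4)
            dist = ck.score_distribution(pwm)
            words = enumerate_words(6)
            scores = np.array([ck.logodds_score(pwm, w) for w in words])
            for s in rng.choice(scores, size=4, replace=False):
                assert dist.pvalue(s) == pytest.approx(
                    enumeration_pvalue(pwm, s), abs=1e-12
                )


class TestScoreToPvalue:
    def test_unique_maximizer(self):
        # every column strongly favors one base -> unique best word
        counts = np.full((4, 6), 1.0)
        for j in range(6):
            counts[j % 4, j] = 500.0
        pwm = ck.build_pwm(counts, pseudocount=0.1)
        dist = ck.score_distribution(pwm)
        assert ck.score_to_pvalue(dist, dist.max_score) == pytest.approx(
            0.25**6
        )

    def test_p_is_one_at_support_minimum(self, small_pwm):
        dist = ck.score_distribution(small_pwm)
        assert ck.score_to_pvalue(dist, dist.min_score) == 1.0
        assert ck.score_to_pvalue(dist, dist.min_score - 5) == 1.0

    def test_monotone_nonincreasing(self, small_pwm):
        dist = ck.score_distribution(small_pwm)
        grid = np.linspace(dist.min_score - 1, dist.max_score + 1, 200)
        ps = [ck.score_to_pvalue(dist, s) for s in grid]
        assert all(b <= a + 1e-15 for a, b in zip(ps, ps[1:]))


class TestScan:
    def test_planted_consensus_single_hit(self, rng):
        pwm = ck.default_ctcf_pwm()
        bg = random_sequence(rng, 500)
        seq = bg[:50] + pwm.consensus + bg[50 + 20 :]
        hits = ck.scan(seq, pwm, 1e-4)
        assert len(hits) == 1
        assert hits[0].start == 50 and hits[0].strand == "+"

    def test_revcomp_sequence_mirrors_hits(self, rng):
        pwm = ck.default_ctcf_pwm()
        bg = random_sequence(rng, 300)
        seq = bg[:100] + pwm.consensus + bg[120:]
        fwd = ck.scan(seq, pwm, 1e-4)
        rev = ck.scan(ck.reverse_complement(seq), pwm, 1e-4)
        L = len(seq)
        mirrored = sorted(
            (L - h.end, {"+": "-", "-": "+"}[h.strand], round(h.score, 6))
            for h in fwd
        )
        assert mirrored == sorted(
            (h.start, h.strand, round(h.score, 6)) for h in rev
        )

    def test_translation_invariance(self, rng, small_pwm):
        seq = random_sequence(rng, 400)
        hits = ck.scan(seq, small_pwm, 5e-3)
        shifted = ck.scan(seq, small_pwm, 5e-3, offset=1000)
        assert [(h.start + 1000, h.strand) for h in hits] == [
            (h.start, h.strand) for h in shifted
        ]

    def test_n_windows_skipped(self, small_pwm):
        hits = ck.scan("N" * 50, small_pwm, 0.99)
        assert hits == []

    def test_short_sequence_empty(self, small_pwm):
        assert ck.scan("ACG", small_pwm, 0.5) == []


class TestMemeFormat:
    def test_roundtrip(self, small_pwm):
        buf = io.StringIO()
        ck.write_meme(buf, small_pwm, "test")
        buf.seek(0)
        back = ck.read_meme(buf)
        assert back.width == small_pwm.width
        assert np.allclose(back.probs, small_pwm.probs, atol=1e-5)
        assert np.allclose(back.background, small_pwm.background, atol=1e-4)


class TestDiscoverOops:
    planted = "GATTACAGATTACAGATTAC"

    def _sequences(self, seed, n=30, length=120):
        rng = np.random.default_rng(seed)
        seqs = []
        for _ in range(n):
            s = list(random_sequence(rng, length))
            pos = int(rng.integers(0, length - 20 + 1))
            word = (
                self.planted
                if rng.random() < 0.5
                else ck.reverse_complement(self.planted)
            )
            s[pos : pos + 20] = word
            seqs.append("".join(s))
        return seqs

    def test_recovers_planted_consensus(self):
        res = ck.discover_motif_oops(self._sequences(3), w=20, seed=3)
        assert res.pwm.consensus in (
            self.planted,
            ck.reverse_complement(self.planted),
        )

    def test_loglik_trace_nondecreasing(self):
        res = ck.discover_motif_oops(self._sequences(5), w=20, seed=5)
        assert all(
            b >= a - 1e-8 * max(1, abs(a))
            for a, b in zip(res.trace, res.trace[1:])
        )

    def test_degenerate_identical_sequences(self):
        seqs = ["ACGTACGT"] * 3
        res = ck.discover_motif_oops(
            seqs, w=8, use_revcomp=False, seed=0, n_restarts=1, max_iter=2
        )
        # single placement per sequence: PWM is the pseudocounted one-word matrix
        assert res.pwm.consensus == "ACGTACGT"

    def test_too_short_sequence_rejected(self):
        with pytest.raises(ValueError):
            ck.discover_motif_oops(["ACGT", "ACGTACGTACGT"], w=8)
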